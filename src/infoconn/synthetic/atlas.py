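"""Synthetic ROI atlas generation.

The default atlas emulates a meta-analytic parcellation with 242 nodes,
each of at least 30 voxels. Voxel counts are drawn uniformly; no spatial
structure is modeled because all downstream pattern analyses are
voxel-order invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import InvalidArgumentError

DEFAULT_N_ROIS = 242
DEFAULT_MIN_VOXELS = 30
DEFAULT_MAX_VOXELS = 120


@dataclass(frozen=True)
class SyntheticAtlas:
    """Ordered ROI labels with per-ROI voxel counts."""

    roi_ids: tuple[int, ...]
    voxel_counts: tuple[int, ...]
    min_voxels: int = DEFAULT_MIN_VOXELS

    def __post_init__(self) -> None:
        if len(self.roi_ids) != len(self.voxel_counts):
            raise InvalidArgumentError("roi_ids and voxel_counts length mismatch")
        if len(set(self.roi_ids)) != len(self.roi_ids):
            raise InvalidArgumentError("roi_ids must be unique")
        if any(v < self.min_voxels for v in self.voxel_counts):
            raise InvalidArgumentError(
                f"all voxel counts must be >= {self.min_voxels}"
            )

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    @property
    def n_voxels_total(self) -> int:
        return int(sum(self.voxel_counts))

    def voxel_count(self, roi_id: int) -> int:
        return self.voxel_counts[self.roi_ids.index(roi_id)]

    def voxel_slices(self) -> dict[int, slice]:
        """Contiguous voxel index ranges per ROI in a flattened voxel axis."""
        out: dict[int, slice] = {}
        start = 0
        for rid, n in zip(self.roi_ids, self.voxel_counts):
            out[rid] = slice(start, start + n)
            start += n
        return out

    def label_volume(self) -> np.ndarray:
        """Small 3D integer label volume; 0 = background, else roi id.

        Voxels are packed in scan order into the smallest near-cubic grid
        that fits them plus a one-voxel background margin.
        """
        n = self.n_voxels_total
        side = int(np.ceil(n ** (1 / 3))) + 1
        vol = np.zeros(side**3, dtype=np.int32)
        flat = np.concatenate(
            [np.full(c, rid, dtype=np.int32) for rid, c in zip(self.roi_ids, self.voxel_counts)]
        )
        vol[: flat.size] = flat
        return vol.reshape(side, side, side)


def generate_atlas(
    n_rois: int = DEFAULT_N_ROIS,
    min_voxels: int = DEFAULT_MIN_VOXELS,
    max_voxels: int = DEFAULT_MAX_VOXELS,
    seed: int = 0,
) -> SyntheticAtlas:
    """Draw an atlas with ``n_rois`` ROIs and uniform voxel counts.

    Deterministic given ``seed``. ROI ids are 1..n_rois (0 is background).
    """
    if n_rois < 1:
        raise InvalidArgumentError("n_rois must be positive")
    if min_voxels < 1:
        raise InvalidArgumentError("min_voxels must be >= 1")
    if max_voxels < min_voxels:
        raise InvalidArgumentError("max_voxels must be >= min_voxels")
    rng = np.random.default_rng(seed)
    counts = rng.integers(min_voxels, max_voxels + 1, size=n_rois)
    return SyntheticAtlas(
        roi_ids=tuple(range(1, n_rois + 1)),
        voxel_counts=tuple(int(c) for c in counts),
        min_voxels=min_voxels,
    )
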