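"""Generative model for trial-level multivoxel patterns.

Each (ROI, context) owns a fixed unit-norm voxel template. Trial-to-trial
variation is a multiplicative gain shared across coupled ROIs: per trial,
latent standard-normal factors with correlation matrix ``C`` (the
coupling matrix) are mapped through an exponential to positive
amplitudes. Informational connectivity detects exactly this shared
trial-level representational fidelity, so the coupling entry C[i, j] is
the planted ground truth for edge (i, j).

Planted experimental effects are additive coupling deltas scoped to a
(group, session) cell and optionally to a single context, which is how
context-specific network reconfiguration is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import InvalidArgumentError
from .atlas import SyntheticAtlas


@dataclass(frozen=True)
class CouplingEffect:
    """Additive change to one coupling entry in one design cell.

    ``context=None`` applies the delta in both contexts.
    """

    group: str
    session: str
    edge: tuple[int, int]  # roi ids, order-free
    delta: float
    context: str | None = None


@dataclass
class GenerativeModel:
    """Parameters controlling synthetic pattern generation.

    Attributes
    ----------
    coupling : base symmetric coupling matrix with unit diagonal and
        off-diagonal entries in [0, 1]; ``None`` means identity
        (independent ROIs).
    reliability : fraction of each trial's signal carried by the fixed
        context template (1 = perfectly reliable patterns).
    gain_sd : log-scale spread of the per-trial multiplicative gain.
    noise_sd : additive voxelwise noise standard deviation.
    signal_scale : overall amplitude of the signal component.
    p_correct : probability a retrieval trial is answered correctly.
    effects : planted coupling deltas per (group, session[, context]).
    seed : root seed; all template and trial randomness derives from it.
    """

    n_rois: int
    coupling: np.ndarray | None = None
    reliability: float = 1.0
    gain_sd: float = 0.7
    noise_sd: float = 0.12
    signal_scale: float = 1.0
    p_correct: float = 0.85
    effects: list[CouplingEffect] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 1:
            raise InvalidArgumentError("n_rois must be positive")
        if not 0.0 <= self.reliability <= 1.0:
            raise InvalidArgumentError("reliability must be in [0, 1]")
        if self.noise_sd < 0 or self.gain_sd < 0:
            raise InvalidArgumentError("noise_sd and gain_sd must be >= 0")
        if not 0.0 <= self.p_correct <= 1.0:
            raise InvalidArgumentError("p_correct must be in [0, 1]")
        if self.coupling is not None:
            C = np.asarray(self.coupling, dtype=float)
            if C.shape != (self.n_rois, self.n_rois):
                raise InvalidArgumentError("coupling shape must be (n_rois, n_rois)")
            if not np.allclose(C, C.T):
                raise InvalidArgumentError("coupling must be symmetric")
            if not np.allclose(np.diag(C), 1.0):
                raise InvalidArgumentError("coupling diagonal must be 1")
            off = C[~np.eye(self.n_rois, dtype=bool)]
            if off.size and (off.min() < 0 or off.max() > 1):
                raise InvalidArgumentError("coupling entries must be in [0, 1]")
            self.coupling = C

    # -- coupling ---------------------------------------------------------

    def _edge_index(self, edge: tuple[int, int], roi_ids: tuple[int, ...]) -> tuple[int, int]:
        i, j = edge
        if i not in roi_ids or j not in roi_ids or i == j:
            raise InvalidArgumentError(f"effect references unknown edge {edge}")
        return roi_ids.index(i), roi_ids.index(j)

    def effective_coupling(
        self,
        group: str,
        session: str,
        context: str,
        roi_ids: tuple[int, ...],
    ) -> np.ndarray:
        """Base coupling plus all planted deltas matching this cell."""
        C = np.eye(self.n_rois) if self.coupling is None else self.coupling.copy()
        for eff in self.effects:
            if eff.group != group or eff.session != session:
                continue
            if eff.context is not None and eff.context != context:
                continue
            a, b = self._edge_index(eff.edge, roi_ids)
            C[a, b] += eff.delta
            C[b, a] += eff.delta
        off = C[~np.eye(self.n_rois, dtype=bool)]
        if off.size and (off.min() < -1e-12 or off.max() > 1 + 1e-12):
            raise InvalidArgumentError(
                "planted deltas push a coupling outside [0, 1]"
            )
        return C

    def gain_transform(self, C: np.ndarray) -> np.ndarray:
        """Cholesky-like factor mapping iid normals to coupled factors.

        Entrywise-edited coupling matrices need not be positive
        definite; such matrices are projected to the nearest PSD
        correlation matrix (eigenvalue clipping + diagonal rescale).
        """
        try:
            return np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            w, V = np.linalg.eigh(C)
            w = np.maximum(w, 1e-8)
            P = (V * w) @ V.T
            d = np.sqrt(np.diag(P))
            P = P / np.outer(d, d)
            return np.linalg.cholesky(P + 1e-10 * np.eye(C.shape[0]))

    # -- templates --------------------------------------------------------

    def template(self, atlas: SyntheticAtlas, roi_id: int, context: str) -> np.ndarray:
        """Fixed unit-norm voxel template for (ROI, context); seed-stable."""
        ci = {"spatial": 0, "temporal": 1}.get(context)
        if ci is None:
            raise InvalidArgumentError(f"unknown context {context!r}")
        idx = atlas.roi_ids.index(roi_id)
        rng = np.random.default_rng([self.seed, 7001, idx, ci])
        v = rng.standard_normal(atlas.voxel_counts[idx])
        return v / np.linalg.norm(v)

    def validate_against(self, atlas: SyntheticAtlas) -> None:
        if atlas.n_rois != self.n_rois:
            raise InvalidArgumentError(
                f"model built for {self.n_rois} ROIs, atlas has {atlas.n_rois}"
            )
        for eff in self.effects:
            self._edge_index(eff.edge, atlas.roi_ids)


def coupling_matrix(n_rois: int, edges: dict[tuple[int, int], float],
                    roi_ids: tuple[int, ...] | None = None) -> np.ndarray:
    """Convenience builder: identity plus named off-diagonal couplings.

    ``edges`` maps (roi_id_i, roi_id_j) to a coupling in [0, 1];
    ``roi_ids`` defaults to 1..n_rois.
    """
    ids = roi_ids or tuple(range(1, n_rois + 1))
    C = np.eye(n_rois)
    for (i, j), c in edges.items():
        a, b = ids.index(i), ids.index(j)
        C[a, b] = C[b, a] = c
    return C
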