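"""Within-context representational similarity matrices (RSMs).

For one ROI, the RSM holds Fisher-z Pearson correlations between
trial-wise voxel patterns, restricted to trial pairs from different
runs within the same context (cross-run pairing avoids temporal
autocorrelation within a run). Retrieval RSMs can be restricted to
correct trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidArgumentError, NoValidPairsError

FISHER_CLIP = 1e-7


def fisher_z(r, clip: float = FISHER_CLIP):
    """atanh with clipping of |r| to 1 − ``clip`` to avoid infinities."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1 + 1e-12):
        raise InvalidArgumentError("|r| must be <= 1")
    bound = 1.0 - clip
    if np.any(np.abs(arr) > bound):
        warnings.warn("correlation at |r|=1 clipped before Fisher z", stacklevel=2)
    out = np.arctanh(np.clip(arr, -bound, bound))
    return float(out) if np.isscalar(r) else out


@dataclass
class RSM:
    """Fisher-z trial-pair similarity matrix with a validity mask.

    ``z`` and ``valid`` are (n, n) over the selected trials; ``trials``
    carries the metadata rows (including original trial ids) for those
    trials. Diagonal and same-run entries are invalid.
    """

    z: np.ndarray
    valid: np.ndarray
    trials: pd.DataFrame
    roi_id: int | None = None
    context: str = "all"
    phase: str = "encoding"

    @property
    def n_valid_pairs(self) -> int:
        return int(np.triu(self.valid, 1).sum())


def select_trials(
    trials: pd.DataFrame,
    context: str,
    phase: str,
    correct_only: bool = False,
) -> np.ndarray:
    """Row mask of trials entering an RSM; selection uses metadata only,
    so it is identical across ROIs sharing a design."""
    if context not in ("spatial", "temporal", "all"):
        raise InvalidArgumentError(f"unknown context {context!r}")
    # copy: to_numpy() may alias the column and &= would mutate the table
    sel = trials["included"].to_numpy(dtype=bool).copy()
    if context != "all":
        sel &= (trials["context"] == context).to_numpy()
    if correct_only:
        sel &= trials["correct"].to_numpy(dtype=bool)
    return sel


def within_context_rsm(
    patterns: np.ndarray,
    trials: pd.DataFrame,
    context: str = "all",
    phase: str = "encoding",
    correct_only: bool = False,
    roi_id: int | None = None,
) -> RSM:
    """RSM over cross-run same-context trial pairs for one ROI.

    ``patterns`` is (n_trials, n_voxels) aligned with ``trials`` (needs
    columns run, context, included and, when ``correct_only``, correct).
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.shape[0] != len(trials):
        raise InvalidArgumentError("patterns and trials length mismatch")
    sel = select_trials(trials, context, phase, correct_only)
    sub = trials[sel].reset_index(drop=True)
    if len(sub) < 2 or sub["run"].nunique() < 2:
        raise NoValidPairsError(
            "need >= 2 included trials spanning >= 2 runs for this context"
        )
    X = patterns[sel]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.corrcoef(X)
    runs = sub["run"].to_numpy()
    valid = runs[:, None] != runs[None, :]
    if context == "all":
        # pooled type still pairs within context only; cross-context
        # pairs are masked (all three RSM types are within-context)
        ctxs = sub["context"].to_numpy()
        valid &= ctxs[:, None] == ctxs[None, :]
    np.fill_diagonal(valid, False)
    valid &= np.isfinite(r)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        z = np.where(valid, fisher_z(np.where(np.isfinite(r), r, 0.0)), np.nan)
    return RSM(z=z, valid=valid, trials=sub, roi_id=roi_id, context=context, phase=phase)


def vectorize_rsm(rsm: RSM) -> tuple[np.ndarray, np.ndarray]:
    """Valid entries in deterministic row-major upper-triangle order.

    Returns (values, pairs) where pairs[k] = (trial_i, trial_j) in the
    original trial ids, so vectors from ROIs sharing a design align
    entry-for-entry.
    """
    iu, ju = np.triu_indices(rsm.z.shape[0], k=1)
    keep = rsm.valid[iu, ju]
    if keep.sum() < 3:
        raise InsufficientDataError("fewer than 3 valid RSM entries")
    ids = rsm.trials["trial"].to_numpy()
    pairs = np.column_stack([ids[iu[keep]], ids[ju[keep]]])
    return rsm.z[iu[keep], ju[keep]], pairs


def rsm_stack(
    pattern_set,
    context: str = "all",
    phase: str = "encoding",
    correct_only: bool = False,
) -> dict[int, RSM]:
    """RSMs for every ROI of one participant-session pattern set."""
    trials = pattern_set.trials[phase]
    return {
        rid: within_context_rsm(
            pats, trials, context=context, phase=phase,
            correct_only=correct_only, roi_id=rid,
        )
        for rid, pats in pattern_set.patterns[phase].items()
    }
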