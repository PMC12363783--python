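"""Informational connectivity: ROI-pair RSM correlations and edge tests.

An informational connectivity matrix (ICM) correlates the vectorized
RSMs of every ROI pair over their common valid trial pairs (Fisher-z).
Group-specific pre-to-post edge changes are tested with a Welch t
contrast of the target group against the pooled remaining groups, a
group-label permutation null, and Benjamini–Hochberg FDR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidArgumentError
from .similarity import RSM, fisher_z, vectorize_rsm

logger = logging.getLogger(__name__)


@dataclass
class ICM:
    """Symmetric ROI-by-ROI Fisher-z informational connectivity matrix."""

    z: np.ndarray
    roi_ids: tuple[int, ...]
    context: str = "all"
    session: str | None = None
    participant: str | None = None

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    def edge(self, i: int, j: int) -> float:
        a, b = self.roi_ids.index(i), self.roi_ids.index(j)
        return float(self.z[a, b])


def _pair_key(pairs: np.ndarray) -> np.ndarray:
    """Stable 1-D key per (i, j) trial pair for alignment between ROIs."""
    return pairs[:, 0].astype(np.int64) * 1_000_003 + pairs[:, 1].astype(np.int64)


def compute_icm(
    rsms: dict[int, RSM],
    context: str = "all",
    session: str | None = None,
    participant: str | None = None,
) -> ICM:
    """Correlate RSM vectors across all ROI pairs.

    When all ROIs share identical valid-pair sets (the common case: one
    design, metadata-driven selection), the full matrix is computed in
    one vectorized correlation; otherwise each pair is correlated over
    the intersection of its valid pairs.
    """
    roi_ids = tuple(rsms.keys())
    if len(roi_ids) < 2:
        raise InvalidArgumentError("need >= 2 ROIs")
    vecs, keys = {}, {}
    for rid in roi_ids:
        v, pairs = vectorize_rsm(rsms[rid])
        vecs[rid], keys[rid] = v, _pair_key(pairs)
    first = keys[roi_ids[0]]
    aligned = all(
        k.size == first.size and np.array_equal(k, first) for k in keys.values()
    )
    n = len(roi_ids)
    z = np.full((n, n), np.nan)
    if aligned:
        M = np.vstack([vecs[rid] for rid in roi_ids])
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(M)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z = fisher_z(np.clip(r, -1.0, 1.0))
        z = (z + z.T) / 2.0  # exact symmetry despite float round-off
    else:
        for a in range(n):
            for b in range(a + 1, n):
                ka, kb = keys[roi_ids[a]], keys[roi_ids[b]]
                common, ia, ib = np.intersect1d(ka, kb, return_indices=True)
                if common.size < 3:
                    logger.warning(
                        "edge (%s, %s) has %d common pairs; masked",
                        roi_ids[a], roi_ids[b], common.size,
                    )
                    continue
                va, vb = vecs[roi_ids[a]][ia], vecs[roi_ids[b]][ib]
                if va.std() == 0 or vb.std() == 0:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    z[a, b] = z[b, a] = fisher_z(
                        float(np.clip(np.corrcoef(va, vb)[0, 1], -1, 1))
                    )
        np.fill_diagonal(z, fisher_z(1.0 - 1e-9))
    np.fill_diagonal(z, np.nan)  # diagonal undefined by contract
    return ICM(z=z, roi_ids=roi_ids, context=context, session=session,
               participant=participant)


def edge_change(icm_pre: ICM, icm_post: ICM) -> np.ndarray:
    """Per-edge z_post − z_pre; NaN wherever either side is masked."""
    if icm_pre.roi_ids != icm_post.roi_ids:
        raise InvalidArgumentError("ICMs must share the same ROI set")
    if icm_pre.context != icm_post.context:
        raise InvalidArgumentError("ICMs must share the same context")
    return icm_post.z - icm_pre.z


def edge_vector(matrix: np.ndarray) -> np.ndarray:
    """Upper-triangle (i < j) entries in row-major order."""
    iu, ju = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu, ju]


def edge_index(n_rois: int, roi_ids: tuple[int, ...]) -> pd.DataFrame:
    iu, ju = np.triu_indices(n_rois, k=1)
    return pd.DataFrame(
        {"roi_i": [roi_ids[i] for i in iu], "roi_j": [roi_ids[j] for j in ju]}
    )


def _welch_t(deltas: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Vectorized Welch t per column: target rows vs remaining rows."""
    a, b = deltas[target], deltas[~target]
    n1, n2 = a.shape[0], b.shape[0]
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    v1 = a.var(axis=0, ddof=1)
    v2 = b.var(axis=0, ddof=1)
    denom = np.sqrt(v1 / n1 + v2 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (m1 - m2) / np.where(denom > 0, denom, 1.0), 0.0)
    return t


def group_edge_contrast(
    deltas: np.ndarray,
    groups: np.ndarray,
    target_group: str,
) -> np.ndarray:
    """Observed Welch t per edge: target group vs pooled others.

    ``deltas`` is (n_participants, n_edges) of per-participant edge
    changes; rows with NaN in an edge drop that edge to NaN (handled by
    callers via listwise masks).
    """
    groups = np.asarray(groups)
    target = groups == target_group
    if target.sum() < 2 or (~target).sum() < 2:
        raise InvalidArgumentError("need >= 2 participants per side")
    if np.isnan(deltas[target]).all(axis=0).any():
        warnings.warn("some edges are fully masked in the target group", stacklevel=2)
    t = _welch_t(deltas, target)
    if np.any((deltas.std(axis=0) == 0)):
        warnings.warn("zero-variance edges; t set to 0", stacklevel=2)
    return t


def permutation_null(
    deltas: np.ndarray,
    groups: np.ndarray,
    target_group: str,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided permutation p per edge by shuffling group labels.

    Group sizes are preserved in each draw. p uses the add-one
    estimator: (1 + #{|t_perm| >= |t_obs|}) / (1 + n_perm).
    Returns (t_observed, p).
    """
    if n_perm < 1:
        raise InvalidArgumentError("n_perm must be >= 1")
    groups = np.asarray(groups)
    t_obs = group_edge_contrast(deltas, groups, target_group)
    target = groups == target_group
    n_subj = deltas.shape[0]
    rng = np.random.default_rng(seed)
    count = np.zeros(deltas.shape[1])
    abs_obs = np.abs(t_obs)
    # batched: each batch draws permuted target-membership masks
    batch = max(1, min(n_perm, 2_000_000 // max(deltas.size, 1)))
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        masks = np.empty((b, n_subj), dtype=bool)
        for i in range(b):
            masks[i] = target[rng.permutation(n_subj)]
        t_perm = _welch_t_batched(deltas, masks)
        count += (np.abs(t_perm) >= abs_obs[None, :] - 1e-12).sum(axis=0)
        done += b
    p = (1.0 + count) / (1.0 + n_perm)
    return t_obs, p


def _welch_t_batched(deltas: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Welch t for many permuted target masks at once.

    ``masks`` is (n_perm, n_subj) boolean; returns (n_perm, n_edges).
    """
    D, D2 = deltas, deltas**2
    n1 = masks.sum(axis=1, keepdims=True).astype(float)
    n2 = masks.shape[1] - n1
    M = masks.astype(float)
    s1, s1sq = M @ D, M @ D2
    tot, totsq = D.sum(axis=0)[None, :], D2.sum(axis=0)[None, :]
    s2, s2sq = tot - s1, totsq - s1sq
    m1, m2 = s1 / n1, s2 / n2
    v1 = (s1sq - n1 * m1**2) / (n1 - 1)
    v2 = (s2sq - n2 * m2**2) / (n2 - 1)
    v1 = np.maximum(v1, 0.0)
    v2 = np.maximum(v2, 0.0)
    denom = np.sqrt(v1 / n1 + v2 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, (m1 - m2) / np.where(denom > 0, denom, 1.0), 0.0)


def fdr_bh(p: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (rejection mask, adjusted q-values)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidArgumentError("p values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    qvals = ranked * m / np.arange(1, m + 1)
    qvals = np.minimum.accumulate(qvals[::-1])[::-1]
    qvals = np.minimum(qvals, 1.0)
    out_q = np.empty(m)
    out_q[order] = qvals
    reject = out_q <= q
    return reject, out_q


def edge_contrast_table(
    deltas: np.ndarray,
    groups: np.ndarray,
    roi_ids: tuple[int, ...],
    target_group: str,
    context: str = "all",
    n_perm: int = 10_000,
    seed: int = 0,
    q: float = 0.05,
) -> pd.DataFrame:
    """Full edgewise inference: t, permutation p, FDR q, direction.

    ``deltas`` is (n_participants, n_rois, n_rois) of per-participant
    edge-change matrices. Edges masked (NaN) for any participant are
    dropped listwise and logged.
    """
    n_rois = len(roi_ids)
    flat = np.stack([edge_vector(d) for d in deltas])
    idx = edge_index(n_rois, roi_ids)
    ok = ~np.isnan(flat).any(axis=0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("dropping %d edges with masked participants", n_dropped)
    t_obs, p = permutation_null(flat[:, ok], groups, target_group, n_perm, seed)
    reject, qvals = fdr_bh(p, q)
    table = idx[ok].reset_index(drop=True)
    table["t"] = t_obs
    table["p"] = p
    table["q"] = qvals
    table["significant"] = reject
    table["direction"] = np.where(t_obs >= 0, "post>pre", "post<pre")
    table["context"] = context
    table["contrast"] = f"{target_group} vs others"
    return table.sort_values("q", kind="stable").reset_index(drop=True)
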