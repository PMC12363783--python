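"""Multivariate distance between spatial and temporal connectivity profiles.

For each ROI, its connectivity profile (row of the ICM, excluding the
self edge and masked entries) is extracted from the spatial and the
temporal ICM; the distance is 1 minus the Pearson or Spearman
correlation between the two profiles. Pre-to-post changes are tested
per ROI with paired t tests and FDR across ROIs. The paired test is
reported as post − pre, so a positive t means greater post distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import ICM, fdr_bh
from .errors import InsufficientDataError, InvalidArgumentError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceResult:
    roi_id: int
    distance: float
    metric: str
    session: str | None = None
    participant: str | None = None


def roi_profile_distance(
    icm_spatial: ICM,
    icm_temporal: ICM,
    roi_id: int,
    metric: str = "pearson",
) -> DistanceResult:
    """1 − correlation between one ROI's spatial and temporal profiles."""
    if icm_spatial.roi_ids != icm_temporal.roi_ids:
        raise InvalidArgumentError("ICMs must share the same ROI set")
    if metric not in ("pearson", "spearman"):
        raise InvalidArgumentError(f"unknown metric {metric!r}")
    k = icm_spatial.roi_ids.index(roi_id)
    row_s = np.delete(icm_spatial.z[k], k)
    row_t = np.delete(icm_temporal.z[k], k)
    ok = np.isfinite(row_s) & np.isfinite(row_t)
    if ok.sum() < 3:
        raise InsufficientDataError(
            f"roi {roi_id}: only {int(ok.sum())} common profile entries"
        )
    if metric == "pearson":
        r = stats.pearsonr(row_s[ok], row_t[ok]).statistic
    else:
        r = stats.spearmanr(row_s[ok], row_t[ok]).statistic
    return DistanceResult(
        roi_id=roi_id,
        distance=float(1.0 - r),
        metric=metric,
        session=icm_spatial.session,
        participant=icm_spatial.participant,
    )


def all_roi_distances(
    icm_spatial: ICM, icm_temporal: ICM, metric: str = "pearson"
) -> pd.DataFrame:
    """Profile distances for every ROI; ROIs lacking data are skipped."""
    rows = []
    for rid in icm_spatial.roi_ids:
        try:
            res = roi_profile_distance(icm_spatial, icm_temporal, rid, metric)
        except InsufficientDataError as e:
            logger.info("skipping roi %s: %s", rid, e)
            continue
        rows.append((res.participant, res.session, rid, metric, res.distance))
    return pd.DataFrame(
        rows, columns=["participant", "session", "roi", "metric", "distance"]
    )


def distance_session_test(
    distances: pd.DataFrame,
    group_members: list[str] | None = None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Paired t (post − pre) of profile distance per ROI, BH-FDR across ROIs.

    ``distances`` is tidy (participant, session, roi, metric, distance)
    with sessions 'pre' and 'post'. Participants missing a session are
    dropped with a log message. Returns a table with one row per
    (roi, metric): t, p, q, n, significant.
    """
    df = distances
    if group_members is not None:
        df = df[df["participant"].isin(group_members)]
    rows = []
    for (roi, metric), sub in df.groupby(["roi", "metric"], sort=True):
        wide = sub.pivot_table(
            index="participant", columns="session", values="distance"
        )
        if not {"pre", "post"}.issubset(wide.columns):
            continue
        both = wide.dropna(subset=["pre", "post"])
        dropped = len(wide) - len(both)
        if dropped:
            logger.info("roi %s: dropped %d participants missing a session", roi, dropped)
        if len(both) < 2:
            raise InsufficientDataError(
                f"roi {roi}: fewer than 2 participants with both sessions"
            )
        diff = both["post"] - both["pre"]
        if np.allclose(diff.std(ddof=1), 0):
            t, p = (0.0, 1.0)
        else:
            res = stats.ttest_rel(both["post"], both["pre"])
            t, p = float(res.statistic), float(res.pvalue)
        rows.append((roi, metric, t, max(p, np.finfo(float).tiny), len(both)))
    table = pd.DataFrame(rows, columns=["roi", "metric", "t", "p", "n"])
    out = []
    for metric, sub in table.groupby("metric", sort=True):
        reject, qv = fdr_bh(sub["p"].to_numpy(), q)
        sub = sub.copy()
        sub["q"] = qv
        sub["significant"] = reject
        out.append(sub)
    return (
        pd.concat(out).sort_values(["metric", "q"], kind="stable").reset_index(drop=True)
    )
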