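"""Single-trial response estimation via least-squares-separate GLMs.

One GLM per trial: the trial of interest gets its own regressor while
all remaining trials of the same kind share one; task regressors are
convolved with a canonical double-gamma HRF; six motion parameters, one
spike regressor per high-motion frame, and discrete-cosine drift terms
(100 s cutoff, approximating a nonlinear high-pass) are appended as
nuisance columns. Motion censoring follows the framewise-displacement
convention: FD > 0.9 mm flags a frame, a run is dropped when more than
20% of its frames are flagged or absolute displacement exceeds half a
voxel (1.25 mm), and a trial is dropped when any flagged frame falls
inside its modeled response window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .errors import IllPosedError, InvalidArgumentError

FD_THRESHOLD_MM = 0.9
RUN_CENSOR_FRACTION = 0.2
MAX_ABS_DISPLACEMENT_MM = 1.25
FD_ROTATION_RADIUS_MM = 50.0

# canonical double-gamma parameters (SPM-style defaults)
HRF_PEAK_DELAY_S = 6.0
HRF_UNDERSHOOT_DELAY_S = 16.0
HRF_DISPERSION_S = 1.0
HRF_UNDERSHOOT_RATIO = 6.0
HRF_DURATION_S = 32.0

_OVERSAMPLE_DT = 0.05  # seconds; fine grid for event convolution


def double_gamma_hrf(tr: float, duration: float = HRF_DURATION_S) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``tr`` seconds.

    Difference of two gamma densities (peak 6 s, undershoot 16 s, unit
    dispersions, 6:1 ratio), peak-normalized to 1; value at t=0 is 0.
    """
    if tr <= 0:
        raise InvalidArgumentError("tr must be positive")
    t = np.arange(0.0, duration + tr / 2, tr)
    return _hrf_values(t)


def _hrf_values(t: np.ndarray) -> np.ndarray:
    h = gamma_dist.pdf(t, HRF_PEAK_DELAY_S / HRF_DISPERSION_S, scale=HRF_DISPERSION_S)
    u = gamma_dist.pdf(
        t, HRF_UNDERSHOOT_DELAY_S / HRF_DISPERSION_S, scale=HRF_DISPERSION_S
    )
    h = h - u / HRF_UNDERSHOOT_RATIO
    peak = np.max(np.abs(h))
    return h / peak if peak > 0 else h


def convolve_events(
    intervals: list[tuple[float, float]],
    n_frames: int,
    tr: float,
) -> np.ndarray:
    """HRF-convolved boxcar regressor for a list of (onset, duration).

    Events are laid out on a fine grid, convolved with the double-gamma
    kernel, and sampled at frame acquisition times (frame i at i*tr).
    """
    if tr <= 0 or n_frames < 1:
        raise InvalidArgumentError("need positive tr and at least one frame")
    dt = _OVERSAMPLE_DT
    total = n_frames * tr + HRF_DURATION_S
    grid = np.zeros(int(np.ceil(total / dt)) + 1)
    for onset, dur in intervals:
        if dur <= 0:
            continue
        a = int(round(onset / dt))
        b = int(round((onset + dur) / dt))
        grid[a:b] = 1.0
    kern = _hrf_values(np.arange(0.0, HRF_DURATION_S + dt, dt))
    conv = np.convolve(grid, kern)[: grid.size] * dt
    frame_idx = np.round(np.arange(n_frames) * tr / dt).astype(int)
    return conv[frame_idx]


# ---------------------------------------------------------------------------
# motion


def framewise_displacement(
    motion: np.ndarray, radius_mm: float = FD_ROTATION_RADIUS_MM
) -> np.ndarray:
    """Per-frame FD: sum |Δtranslation| + radius × sum |Δrotation|.

    ``motion`` is (n_frames, 6): 3 translations in mm then 3 rotations
    in radians. The first frame's FD is defined as 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise InvalidArgumentError("motion trace must be (n_frames, 6)")
    if motion.shape[0] < 1:
        raise InvalidArgumentError("motion trace must have >= 1 frame")
    if not np.all(np.isfinite(motion)):
        raise InvalidArgumentError("motion trace contains non-finite values")
    d = np.abs(np.diff(motion, axis=0))
    fd = np.concatenate(
        [[0.0], d[:, :3].sum(axis=1) + radius_mm * d[:, 3:].sum(axis=1)]
    )
    return fd


@dataclass
class CensorMask:
    """Frame-level censoring plus run-level exclusion decision."""

    fd: np.ndarray
    censored: np.ndarray  # bool per frame
    run_excluded: bool = False
    reason: str = ""

    @property
    def n_frames(self) -> int:
        return self.fd.size

    @property
    def censored_fraction(self) -> float:
        return float(self.censored.mean())


def censor_mask_from_motion(
    motion: np.ndarray,
    fd_threshold: float = FD_THRESHOLD_MM,
    run_censor_fraction: float = RUN_CENSOR_FRACTION,
    max_abs_mm: float = MAX_ABS_DISPLACEMENT_MM,
    radius_mm: float = FD_ROTATION_RADIUS_MM,
) -> CensorMask:
    """Build a censor mask from a motion trace.

    Absolute displacement is measured as the largest translation
    excursion from the first frame's position.
    """
    fd = framewise_displacement(motion, radius_mm)
    censored = fd > fd_threshold
    motion = np.asarray(motion, dtype=float)
    abs_disp = float(np.abs(motion[:, :3] - motion[0, :3]).max()) if motion.size else 0.0
    excluded, reason = False, ""
    frac = float(censored.mean())
    if frac > run_censor_fraction:
        excluded, reason = True, (
            f"{100 * frac:.1f}% of frames exceed FD {fd_threshold} mm"
        )
    elif abs_disp > max_abs_mm:
        excluded, reason = True, (
            f"absolute displacement {abs_disp:.2f} mm exceeds {max_abs_mm} mm"
        )
    return CensorMask(fd=fd, censored=censored, run_excluded=excluded, reason=reason)


# ---------------------------------------------------------------------------
# design matrices

TRIAL_EVENT = {"encoding": "encode", "retrieval": "source"}


@dataclass
class DesignMatrix:
    """Frame-by-regressor matrix with labeled columns."""

    matrix: np.ndarray
    labels: list[str]
    tr: float

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.labels):
            raise InvalidArgumentError("column count must equal label count")

    def column(self, label: str) -> np.ndarray:
        return self.matrix[:, self.labels.index(label)]


def _dct_drift(n_frames: int, tr: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine high-pass drift columns below 1/cutoff Hz."""
    order = int(np.floor(2 * n_frames * tr / cutoff_s))
    t = np.arange(n_frames)
    cols = [
        np.cos(np.pi * (t + 0.5) * k / n_frames) for k in range(1, max(order, 0) + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_frames, 0))


def _rt_intervals(
    rows: pd.DataFrame, require_rt: bool = True
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """(onset, RT) response intervals and (onset+RT, window−RT) remainders."""
    resp, rem = [], []
    for _, r in rows.iterrows():
        rt = r["response_time"]
        if pd.isna(rt):
            if require_rt:
                raise InvalidArgumentError(
                    f"response_time missing for event at onset {r['onset']}"
                )
            continue
        window = float(r["duration"])
        if rt > window:
            warnings.warn(
                f"response time {rt} exceeds window {window}; clipping", stacklevel=3
            )
            rt = window
        resp.append((float(r["onset"]), float(rt)))
        if window - rt > 0:
            rem.append((float(r["onset"]) + float(rt), window - float(rt)))
    return resp, rem


def build_lss_design(
    events: pd.DataFrame,
    trial_index: int,
    phase: str,
    n_frames: int,
    tr: float,
    motion: np.ndarray | None = None,
    censor: CensorMask | None = None,
    drift_cutoff_s: float | None = 100.0,
) -> DesignMatrix:
    """Least-squares-separate design for one trial of interest.

    Encoding task columns: trial of interest (stimulus window), all
    other trials, rating response periods, rating remainders, ITI
    fixations, instructions; the odd/even baseline stays unmodeled.
    Retrieval task columns: trial of interest (source-judgment RT),
    other source trials (their RTs), source remainders, item-probe
    response periods, item remainders, instructions; ITI unmodeled.
    Nuisance: 6 motion columns, one spike column per censored frame,
    DCT drift, intercept.
    """
    if phase not in TRIAL_EVENT:
        raise InvalidArgumentError(f"unknown phase {phase!r}")
    ev = events.sort_values("onset")
    kind = TRIAL_EVENT[phase]
    trial_rows = ev[ev["trial_type"] == kind]
    if trial_index not in set(trial_rows["trial"].dropna().astype(int)):
        raise InvalidArgumentError(f"trial {trial_index} not found in events")

    cols: list[np.ndarray] = []
    labels: list[str] = []

    def add(label: str, intervals: list[tuple[float, float]]) -> None:
        cols.append(convolve_events(intervals, n_frames, tr))
        labels.append(label)

    this = trial_rows[trial_rows["trial"].astype(int) == trial_index]
    others = trial_rows[trial_rows["trial"].astype(int) != trial_index]
    if phase == "encoding":
        add("trial_of_interest",
            [(float(r["onset"]), float(r["duration"])) for _, r in this.iterrows()])
        add("other_trials",
            [(float(r["onset"]), float(r["duration"])) for _, r in others.iterrows()])
        ratings = ev[ev["trial_type"] == "rating"]
        resp, rem = _rt_intervals(ratings)
        add("rating_period", resp)
        add("post_response_period", rem)
        itis = ev[ev["trial_type"] == "iti"]
        add("iti", [(float(r["onset"]), float(r["duration"])) for _, r in itis.iterrows()])
    else:
        resp_t, rem_t = _rt_intervals(this)
        resp_o, rem_o = _rt_intervals(others)
        add("trial_of_interest", resp_t)
        add("other_trials", resp_o)
        add("post_response_period", rem_t + rem_o)
        items = ev[ev["trial_type"] == "item"]
        iresp, irem = _rt_intervals(items)
        add("item_period", iresp)
        add("item_remainder", irem)
    instr = ev[ev["trial_type"] == "instruction"]
    add("instructions",
        [(float(r["onset"]), float(r["duration"])) for _, r in instr.iterrows()])

    X = np.column_stack(cols)
    if not np.any(np.abs(X[:, 0]) > 0):
        raise InvalidArgumentError("trial-of-interest column is all zero")

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (n_frames, 6):
            raise InvalidArgumentError("motion must be (n_frames, 6)")
        mc = motion - motion.mean(axis=0)
        keep = np.ptp(mc, axis=0) > 0  # constant parameters carry no information
        X = np.hstack([X, mc[:, keep]])
        labels += [f"motion_{i}" for i in np.flatnonzero(keep)]
    if censor is not None:
        if censor.n_frames != n_frames:
            raise InvalidArgumentError("censor mask length must match frames")
        for f in np.flatnonzero(censor.censored):
            spike = np.zeros(n_frames)
            spike[f] = 1.0
            X = np.hstack([X, spike[:, None]])
            labels.append(f"spike_{f}")
    if drift_cutoff_s:
        drift = _dct_drift(n_frames, tr, drift_cutoff_s)
        if drift.shape[1]:
            X = np.hstack([X, drift])
            labels += [f"drift_{i}" for i in range(drift.shape[1])]
    X = np.hstack([X, np.ones((n_frames, 1))])
    labels.append("intercept")
    return DesignMatrix(matrix=X, labels=labels, tr=tr)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class TrialEstimate:
    """Voxelwise beta and t for one trial's regressor of interest."""

    trial: int
    beta: np.ndarray
    t: np.ndarray
    included: bool = True
    reason: str = ""
    run: int | None = None
    context: str | None = None
    correct: bool | None = None


def lss_fit(
    series: np.ndarray, design: DesignMatrix, trial: int = 0, rcond: float = 1e-10
) -> TrialEstimate:
    """OLS fit of one LS-S design; returns beta and t for the trial column.

    ``series`` is (n_frames, n_voxels).
    """
    Y = np.asarray(series, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise InvalidArgumentError("series frame count must match design")
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify near-collinear columns via tiny R diagonal entries
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [design.labels[i] for i in np.flatnonzero(diag < rcond * diag.max())]
        raise IllPosedError(f"design is rank deficient; collinear columns: {bad}")
    if n - rank <= 0:
        raise IllPosedError("no residual degrees of freedom")
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = n - rank
    sigma2 = (resid**2).sum(axis=0) / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    j = design.labels.index("trial_of_interest")
    se = np.sqrt(sigma2 * XtX_inv[j, j])
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta[j] / se, 0.0)
    return TrialEstimate(trial=trial, beta=beta[j], t=tval)


# ---------------------------------------------------------------------------
# censoring decisions


def censor(
    events: pd.DataFrame,
    mask: CensorMask,
    run_frames: int,
    tr: float,
    phase: str = "encoding",
) -> tuple[pd.DataFrame, bool]:
    """Per-trial inclusion flags plus the run-level exclusion decision.

    A trial is excluded when any censored frame falls inside
    [onset, onset + duration] of its modeled response window. Returns a
    copy of the trial rows with ``included`` and ``reason`` columns, and
    the run-exclusion flag.
    """
    if mask.n_frames != run_frames:
        raise InvalidArgumentError("mask length must equal run_frames")
    kind = TRIAL_EVENT.get(phase)
    if kind is None:
        raise InvalidArgumentError(f"unknown phase {phase!r}")
    trials = events[events["trial_type"] == kind].copy()
    frame_times = np.arange(run_frames) * tr
    included, reasons = [], []
    bad_frames = np.flatnonzero(mask.censored)
    for _, r in trials.iterrows():
        if mask.run_excluded:
            included.append(False)
            reasons.append(f"run excluded: {mask.reason}")
            continue
        lo, hi = float(r["onset"]), float(r["onset"]) + float(r["duration"])
        hit = [
            f for f in bad_frames if lo - 1e-9 <= frame_times[f] <= hi + 1e-9
        ]
        if hit:
            included.append(False)
            reasons.append(f"censored frames in trial window: {hit}")
        else:
            included.append(True)
            reasons.append("")
    trials["included"] = included
    trials["reason"] = reasons
    return trials, mask.run_excluded


def estimate_run(
    series: np.ndarray,
    events: pd.DataFrame,
    phase: str,
    tr: float,
    motion: np.ndarray | None = None,
    drift_cutoff_s: float | None = 100.0,
    fd_threshold: float = FD_THRESHOLD_MM,
) -> list[TrialEstimate]:
    """LS-S estimates for every trial in one run, with censoring applied.

    Excluded trials are still returned, flagged ``included=False`` with
    a reason code, and carry NaN estimates when the run is excluded.
    """
    n_frames = series.shape[0]
    mask = (
        censor_mask_from_motion(motion, fd_threshold=fd_threshold)
        if motion is not None
        else CensorMask(
            fd=np.zeros(n_frames), censored=np.zeros(n_frames, dtype=bool)
        )
    )
    flags, run_excluded = censor(events, mask, n_frames, tr, phase)
    out: list[TrialEstimate] = []
    for _, row in flags.iterrows():
        tri = int(row["trial"])
        if run_excluded:
            est = TrialEstimate(
                trial=tri,
                beta=np.full(series.shape[1], np.nan),
                t=np.full(series.shape[1], np.nan),
            )
        else:
            design = build_lss_design(
                events, tri, phase, n_frames, tr,
                motion=motion, censor=mask if mask.censored.any() else None,
                drift_cutoff_s=drift_cutoff_s,
            )
            est = lss_fit(series, design, trial=tri)
        est.included = bool(row["included"])
        est.reason = row["reason"]
        est.run = int(row["run"]) if "run" in row and pd.notna(row["run"]) else None
        est.context = row.get("context")
        acc = row.get("accuracy")
        est.correct = bool(acc) if pd.notna(acc) else None
        out.append(est)
    return out
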