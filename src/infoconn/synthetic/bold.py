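"""Synthetic BOLD runs with matching event tables and motion traces.

Each run's signal is a sum over events of amplitude × HRF-convolved
boxcar, with per-trial spatial maps equal to gain × context template,
plus optional drift and Gaussian noise. Event timing follows the
source-memory layout: an instruction period, then per trial a 6 s
stimulus (encoding) or 6 s item probe + 6 s source judgment (retrieval),
a response window, and an ITI. Motion traces are smooth random walks
into which high-FD spikes can be injected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..design import StudyDesign
from ..errors import InvalidArgumentError
from ..estimation import HRF_DURATION_S, convolve_events
from .atlas import SyntheticAtlas
from .model import GenerativeModel
from .patterns import _stable_key

INSTRUCTION_S = 4.0
RATING_WINDOW_S = 6.0
DEFAULT_ITI_S = 2.0
TAIL_S = 20.0


@dataclass
class BoldRun:
    """One synthetic run: signal, events, motion, and ground truth."""

    phase: str
    run: int
    signal: np.ndarray  # (n_frames, n_voxels_total)
    events: pd.DataFrame
    motion: np.ndarray  # (n_frames, 6)
    tr: float
    true_amplitudes: dict[int, np.ndarray]  # roi_id -> per-trial gain


def _run_events(
    design: StudyDesign,
    phase: str,
    run: int,
    contexts: list[str],
    rts: np.ndarray,
    item_rts: np.ndarray | None,
    iti_s: float,
    first_trial: int,
) -> pd.DataFrame:
    rows = []
    t = 0.0
    rows.append((t, INSTRUCTION_S, "instruction", None, np.nan, np.nan, np.nan, run))
    t += INSTRUCTION_S
    dur = design.trial_duration_seconds
    for k, ctx in enumerate(contexts):
        tri = first_trial + k
        if phase == "encoding":
            rows.append((t, dur, "encode", ctx, np.nan, np.nan, tri, run))
            t += dur
            rows.append((t, RATING_WINDOW_S, "rating", ctx, rts[k], np.nan, tri, run))
            t += RATING_WINDOW_S
        else:
            rows.append((t, dur, "item", ctx, item_rts[k], np.nan, tri, run))
            t += dur
            rows.append((t, RATING_WINDOW_S, "source", ctx, rts[k], np.nan, tri, run))
            t += RATING_WINDOW_S
        rows.append((t, iti_s, "iti", None, np.nan, np.nan, tri, run))
        t += iti_s
    return pd.DataFrame(
        rows,
        columns=[
            "onset", "duration", "trial_type", "context",
            "response_time", "accuracy", "trial", "run",
        ],
    )


def _motion_trace(
    rng: np.random.Generator,
    n_frames: int,
    walk_sd_mm: float,
    spike_frames: list[int],
    spike_mm: float,
) -> np.ndarray:
    steps = rng.standard_normal((n_frames, 6))
    steps[:, :3] *= walk_sd_mm
    steps[:, 3:] *= walk_sd_mm / 50.0
    motion = np.cumsum(steps, axis=0)
    for f in spike_frames:
        if not 0 < f < n_frames:
            raise InvalidArgumentError(f"spike frame {f} outside run")
        # one-frame x-translation excursion: FD = spike_mm at f (and at
        # f+1 on the way back, if that frame exists)
        motion[f, 0] += spike_mm
    return motion


def generate_bold_session(
    design: StudyDesign,
    atlas: SyntheticAtlas,
    model: GenerativeModel,
    seed: int = 0,
    phase: str = "encoding",
    participant: str = "sub-000",
    group: str = "navigation",
    session: str = "pre",
    noise_sd: float = 0.0,
    drift_amplitude: float = 0.0,
    nuisance_amplitude: float = 0.0,
    iti_seconds: float = DEFAULT_ITI_S,
    motion_walk_sd_mm: float = 0.0,
    motion_spikes: dict[int, list[int]] | None = None,
    spike_mm: float = 0.5,
) -> list[BoldRun]:
    """Generate all runs of one phase for one participant-session.

    ``motion_spikes`` maps run index to frame indices that receive a
    translation jump of ``spike_mm`` in x (FD contribution 2×spike_mm
    at the jump and return). Ground-truth per-trial ROI amplitudes are
    recorded on each run for recovery checks.
    """
    if phase not in ("encoding", "retrieval"):
        raise InvalidArgumentError(f"unknown phase {phase!r}")
    model.validate_against(atlas)
    rng = np.random.default_rng([model.seed, 31, _stable_key(participant), seed])
    n_runs = design.encoding_runs if phase == "encoding" else design.retrieval_runs
    per_run = (
        design.trials_per_encoding_run
        if phase == "encoding"
        else design.trials_per_retrieval_run
    )
    table = design.trial_table(phase)
    slices = atlas.voxel_slices()
    templates = {
        (rid, ctx): model.template(atlas, rid, ctx)
        for rid in atlas.roi_ids
        for ctx in design.contexts
    }
    trial_block = design.trial_duration_seconds + RATING_WINDOW_S + iti_seconds
    run_len_s = INSTRUCTION_S + per_run * trial_block + TAIL_S
    n_frames = int(np.ceil(run_len_s / design.tr_seconds))
    if (n_frames - 1) * design.tr_seconds < INSTRUCTION_S + per_run * trial_block:
        raise InvalidArgumentError("run too short for trial layout plus HRF tail")

    runs: list[BoldRun] = []
    for run in range(n_runs):
        sub = table[table["run"] == run]
        contexts = list(sub["context"])
        rts = rng.uniform(0.8, 4.0, size=per_run)
        item_rts = rng.uniform(0.8, 4.0, size=per_run) if phase == "retrieval" else None
        events = _run_events(
            design, phase, run, contexts, rts, item_rts, iti_seconds,
            first_trial=int(sub["trial"].iloc[0]),
        )
        # trial amplitudes from the coupled-gain model, context by context
        amps = {rid: np.empty(per_run) for rid in atlas.roi_ids}
        for ctx in design.contexts:
            sel = np.array([c == ctx for c in contexts])
            if not sel.any():
                continue
            C = model.effective_coupling(group, session, ctx, atlas.roi_ids)
            L = model.gain_transform(C)
            g = np.exp(
                model.gain_sd * (L @ rng.standard_normal((model.n_rois, int(sel.sum()))))
            )
            for k, rid in enumerate(atlas.roi_ids):
                amps[rid][sel] = g[k]
        signal = np.zeros((n_frames, atlas.n_voxels_total))
        enc_rows = events[events["trial_type"] == ("encode" if phase == "encoding" else "source")]
        for k, (_, row) in enumerate(enc_rows.iterrows()):
            dur = (
                float(row["duration"])
                if phase == "encoding"
                else float(row["response_time"])
            )
            reg = convolve_events([(float(row["onset"]), dur)], n_frames, design.tr_seconds)
            ctx = row["context"]
            for rid in atlas.roi_ids:
                sl = slices[rid]
                signal[:, sl] += np.outer(
                    reg, amps[rid][k] * model.signal_scale * templates[(rid, ctx)]
                )
        if nuisance_amplitude > 0:
            for kind in ("rating", "item", "instruction", "iti"):
                rows = events[events["trial_type"] == kind]
                if rows.empty:
                    continue
                ivals = [
                    (float(r["onset"]), float(r["duration"])) for _, r in rows.iterrows()
                ]
                reg = convolve_events(ivals, n_frames, design.tr_seconds)
                signal += nuisance_amplitude * reg[:, None]
        if drift_amplitude > 0:
            t = np.arange(n_frames) / n_frames
            signal += drift_amplitude * (
                t[:, None] + np.cos(2 * np.pi * t * 0.7)[:, None]
            )
        if noise_sd > 0:
            signal += noise_sd * rng.standard_normal(signal.shape)
        spikes = (motion_spikes or {}).get(run, [])
        motion = _motion_trace(rng, n_frames, motion_walk_sd_mm, spikes, spike_mm)
        runs.append(
            BoldRun(
                phase=phase, run=run, signal=signal, events=events,
                motion=motion, tr=design.tr_seconds, true_amplitudes=amps,
            )
        )
    return runs
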