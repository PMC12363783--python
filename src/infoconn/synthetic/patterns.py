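"""Trial-by-voxel pattern generation for whole study designs.

Patterns stand in for single-trial t-maps: per trial and ROI, a positive
gain times the (ROI, context) template plus voxel noise. Gains for
coupled ROIs share latent factors, which is the planted informational
connectivity.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..design import PHASES, StudyDesign
from ..errors import InvalidArgumentError
from .atlas import SyntheticAtlas
from .model import GenerativeModel


@dataclass
class TrialPatternSet:
    """All trial patterns for one participant-session.

    ``patterns[phase][roi_id]`` is an (n_trials, n_voxels) array aligned
    with ``trials[phase]`` (columns: trial, run, context, correct,
    included).
    """

    participant: str
    group: str
    session: str
    patterns: dict[str, dict[int, np.ndarray]]
    trials: dict[str, pd.DataFrame]

    def roi_ids(self) -> tuple[int, ...]:
        return tuple(next(iter(self.patterns.values())).keys())

    def n_trials(self, phase: str) -> int:
        return len(self.trials[phase])


def _stable_key(label: str) -> int:
    """Process-independent integer key for a participant label."""
    return zlib.crc32(label.encode("utf-8"))


def _phase_patterns(
    design: StudyDesign,
    atlas: SyntheticAtlas,
    model: GenerativeModel,
    templates: dict[tuple[int, str], np.ndarray],
    group: str,
    session: str,
    phase: str,
    rng: np.random.Generator,
) -> tuple[dict[int, np.ndarray], pd.DataFrame]:
    table = design.trial_table(phase)
    roi_patterns = {
        rid: np.empty((len(table), atlas.voxel_count(rid))) for rid in atlas.roi_ids
    }
    for ctx in design.contexts:
        sel = (table["context"] == ctx).to_numpy()
        n_t = int(sel.sum())
        C = model.effective_coupling(group, session, ctx, atlas.roi_ids)
        L = model.gain_transform(C)
        gains = np.exp(model.gain_sd * (L @ rng.standard_normal((model.n_rois, n_t))))
        for k, rid in enumerate(atlas.roi_ids):
            u = templates[(rid, ctx)]
            if model.reliability < 1.0:
                jit = rng.standard_normal((n_t, u.size))
                jit /= np.linalg.norm(jit, axis=1, keepdims=True)
                base = (
                    np.sqrt(model.reliability) * u[None, :]
                    + np.sqrt(1.0 - model.reliability) * jit
                )
            else:
                base = u[None, :]
            x = model.signal_scale * gains[k][:, None] * base
            if model.noise_sd > 0:
                x = x + model.noise_sd * rng.standard_normal(x.shape)
            roi_patterns[rid][sel] = x
    table = table.copy()
    table["correct"] = (
        rng.random(len(table)) < model.p_correct if phase == "retrieval" else True
    )
    table["included"] = True
    return roi_patterns, table


def generate_pattern_dataset(
    design: StudyDesign,
    atlas: SyntheticAtlas,
    model: GenerativeModel,
    participant: str = "sub-000",
    group: str = "navigation",
    session: str = "pre",
    phases: tuple[str, ...] = PHASES,
    participant_key: int | None = None,
) -> TrialPatternSet:
    """Generate one participant-session of trial patterns.

    Deterministic given the model seed, the participant key (derived
    from the label by a stable CRC when not given), and the session.
    """
    model.validate_against(atlas)
    if group not in design.groups:
        raise InvalidArgumentError(f"unknown group {group!r}")
    if session not in design.sessions:
        raise InvalidArgumentError(f"unknown session {session!r}")
    for phase in phases:
        if phase not in PHASES:
            raise InvalidArgumentError(f"unknown phase {phase!r}")
    key = _stable_key(participant) if participant_key is None else participant_key
    si = design.sessions.index(session)
    templates = {
        (rid, ctx): model.template(atlas, rid, ctx)
        for rid in atlas.roi_ids
        for ctx in design.contexts
    }
    patterns: dict[str, dict[int, np.ndarray]] = {}
    trials: dict[str, pd.DataFrame] = {}
    for phase in phases:
        rng = np.random.default_rng([model.seed, 11, key, si, PHASES.index(phase)])
        roi_patterns, table = _phase_patterns(
            design, atlas, model, templates, group, session, phase, rng
        )
        patterns[phase] = roi_patterns
        trials[phase] = table
    return TrialPatternSet(
        participant=participant, group=group, session=session,
        patterns=patterns, trials=trials,
    )


def generate_study_patterns(
    design: StudyDesign,
    atlas: SyntheticAtlas,
    model: GenerativeModel,
    phases: tuple[str, ...] = ("encoding",),
) -> list[TrialPatternSet]:
    """Pattern sets for every participant and session in the design.

    Participant substreams are keyed by roster position, so output is
    deterministic given the model seed regardless of labels.
    """
    out = []
    for idx, row in design.participants().iterrows():
        for session in design.sessions:
            out.append(
                generate_pattern_dataset(
                    design, atlas, model,
                    participant=row["participant"],
                    group=row["group"],
                    session=session,
                    phases=phases,
                    participant_key=int(idx),
                )
            )
    return out
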