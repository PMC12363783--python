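"""Study design description: groups, sessions, runs and trial layout.

The default design mirrors a pre/post cognitive-training source-memory
experiment: three training arms, two scan sessions, four encoding runs
(context-pure, alternating spatial/temporal) and four retrieval runs
(both contexts mixed within run).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

GROUPS = ("navigation", "verbal_memory", "video_control")
SESSIONS = ("pre", "post")
CONTEXTS = ("spatial", "temporal")
PHASES = ("encoding", "retrieval")


@dataclass(frozen=True)
class StudyDesign:
    """Layout of one participant-session of the source-memory task.

    Encoding runs are context-pure and alternate spatial/temporal;
    retrieval runs mix both contexts, balanced within run.
    """

    groups: tuple[str, ...] = GROUPS
    n_per_group: int = 24
    sessions: tuple[str, ...] = SESSIONS
    encoding_runs: int = 4
    retrieval_runs: int = 4
    trials_per_encoding_run: int = 20
    trials_per_retrieval_run: int = 25
    contexts: tuple[str, ...] = CONTEXTS
    tr_seconds: float = 1.56
    trial_duration_seconds: float = 6.0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise InvalidArgumentError("n_per_group must be >= 1")
        if self.encoding_runs < 2 or self.retrieval_runs < 2:
            raise InvalidArgumentError(
                "need >= 2 runs per phase for cross-run similarity"
            )
        if self.trials_per_encoding_run < 2 or self.trials_per_retrieval_run < 2:
            raise InvalidArgumentError("need > 1 trial per run per context")
        if (self.retrieval_runs * self.trials_per_retrieval_run) % len(self.contexts):
            raise InvalidArgumentError(
                "retrieval trials must balance across contexts within the phase"
            )
        if self.tr_seconds <= 0 or self.trial_duration_seconds <= 0:
            raise InvalidArgumentError("durations must be positive")

    @property
    def n_encoding_trials(self) -> int:
        return self.encoding_runs * self.trials_per_encoding_run

    @property
    def n_retrieval_trials(self) -> int:
        return self.retrieval_runs * self.trials_per_retrieval_run

    def encoding_run_context(self, run: int) -> str:
        """Context of a (zero-based) encoding run; runs alternate contexts."""
        return self.contexts[run % len(self.contexts)]

    def trial_table(self, phase: str) -> pd.DataFrame:
        """Per-trial metadata for one participant-session and phase.

        Columns: trial (global index), run (zero-based), context.
        Retrieval runs interleave contexts so both appear in every run.
        """
        if phase not in PHASES:
            raise InvalidArgumentError(f"unknown phase {phase!r}")
        rows = []
        if phase == "encoding":
            per_run = self.trials_per_encoding_run
            for run in range(self.encoding_runs):
                ctx = self.encoding_run_context(run)
                rows.extend((run, ctx) for _ in range(per_run))
        else:
            per_run = self.trials_per_retrieval_run
            k = 0  # contexts alternate across run boundaries so the
            for run in range(self.retrieval_runs):  # phase stays balanced
                for _ in range(per_run):
                    rows.append((run, self.contexts[k % len(self.contexts)]))
                    k += 1
        df = pd.DataFrame(rows, columns=["run", "context"])
        df.insert(0, "trial", np.arange(len(df)))
        return df

    def participants(self) -> pd.DataFrame:
        """Participant roster: participant id and group label."""
        rows = [
            (f"sub-{g[:3]}{i:02d}", g)
            for g in self.groups
            for i in range(self.n_per_group)
        ]
        return pd.DataFrame(rows, columns=["participant", "group"])

    def to_dict(self) -> dict:
        return asdict(self)
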