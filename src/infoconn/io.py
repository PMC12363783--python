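"""File formats: HDF5 pattern/ICM containers, events.tsv, motion .par.

HDF5 layout for pattern sets follows
``/sub-XX/ses-{pre,post}/{enc,ret}/roi-<id>`` with trial metadata stored
alongside each phase group.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import InvalidArgumentError
from .synthetic.patterns import TrialPatternSet

_PHASE_KEY = {"encoding": "enc", "retrieval": "ret"}
_PHASE_FROM_KEY = {v: k for k, v in _PHASE_KEY.items()}


def save_pattern_set(path: str | Path, ps: TrialPatternSet) -> None:
    with h5py.File(path, "a") as f:
        g = f.require_group(f"{ps.participant}/ses-{ps.session}")
        g.attrs["group"] = ps.group
        for phase, rois in ps.patterns.items():
            pg = g.require_group(_PHASE_KEY[phase])
            for rid, arr in rois.items():
                if f"roi-{rid}" in pg:
                    del pg[f"roi-{rid}"]
                pg.create_dataset(f"roi-{rid}", data=arr)
            tbl = ps.trials[phase]
            for col in ("trial", "run"):
                _replace(pg, f"meta_{col}", tbl[col].to_numpy(dtype=np.int64))
            _replace(
                pg, "meta_context",
                np.array([c.encode() for c in tbl["context"]]),
            )
            for col in ("correct", "included"):
                _replace(pg, f"meta_{col}", tbl[col].to_numpy(dtype=bool))


def _replace(group: h5py.Group, name: str, data: np.ndarray) -> None:
    if name in group:
        del group[name]
    group.create_dataset(name, data=data)


def load_pattern_sets(path: str | Path) -> list[TrialPatternSet]:
    out: list[TrialPatternSet] = []
    with h5py.File(path, "r") as f:
        for sub in sorted(f.keys()):
            for ses_key in sorted(f[sub].keys()):
                g = f[f"{sub}/{ses_key}"]
                session = ses_key.removeprefix("ses-")
                patterns: dict[str, dict[int, np.ndarray]] = {}
                trials: dict[str, pd.DataFrame] = {}
                for pk, phase in _PHASE_FROM_KEY.items():
                    if pk not in g:
                        continue
                    pg = g[pk]
                    rois = {
                        int(k.removeprefix("roi-")): pg[k][()]
                        for k in pg.keys()
                        if k.startswith("roi-")
                    }
                    tbl = pd.DataFrame(
                        {
                            "trial": pg["meta_trial"][()],
                            "run": pg["meta_run"][()],
                            "context": [c.decode() for c in pg["meta_context"][()]],
                            "correct": pg["meta_correct"][()].astype(bool),
                            "included": pg["meta_included"][()].astype(bool),
                        }
                    )
                    patterns[phase] = dict(sorted(rois.items()))
                    trials[phase] = tbl
                out.append(
                    TrialPatternSet(
                        participant=sub,
                        group=g.attrs.get("group", ""),
                        session=session,
                        patterns=patterns,
                        trials=trials,
                    )
                )
    return out


def write_events_tsv(path: str | Path, events: pd.DataFrame) -> None:
    events.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["n/a"])


def write_motion_par(path: str | Path, motion: np.ndarray) -> None:
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise InvalidArgumentError("motion must be (n_frames, 6)")
    np.savetxt(path, motion, fmt="%.8f")


def read_motion_par(path: str | Path) -> np.ndarray:
    motion = np.loadtxt(path)
    if motion.ndim == 1:
        motion = motion[None, :]
    if motion.shape[1] != 6:
        raise InvalidArgumentError("motion file must have 6 columns")
    return motion


def save_icms(path: str | Path, icms: list) -> None:
    """Store a list of ICM objects under /<participant>/<session>/<context>."""
    with h5py.File(path, "a") as f:
        for icm in icms:
            g = f.require_group(f"{icm.participant}/{icm.session}")
            name = f"icm-{icm.context}"
            if name in g:
                del g[name]
            d = g.create_dataset(name, data=icm.z)
            d.attrs["roi_ids"] = np.asarray(icm.roi_ids, dtype=np.int64)


def load_icms(path: str | Path) -> list:
    from .connectivity import ICM

    out = []
    with h5py.File(path, "r") as f:
        for sub in sorted(f.keys()):
            for ses in sorted(f[sub].keys()):
                g = f[f"{sub}/{ses}"]
                for name in sorted(g.keys()):
                    if not name.startswith("icm-"):
                        continue
                    d = g[name]
                    out.append(
                        ICM(
                            z=d[()],
                            roi_ids=tuple(int(r) for r in d.attrs["roi_ids"]),
                            context=name.removeprefix("icm-"),
                            session=ses,
                            participant=sub,
                        )
                    )
    return out


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise InvalidArgumentError("config file must contain a mapping")
    return cfg
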