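"""CSV schemas shared across the pipeline.

All tabular interchange is plain CSV (UTF-8, "." decimal).  Times are in
minutes end-to-end; concentration units (ug/mL plasma, ug/g brain) are
carried in column metadata conventions, never converted silently.

Schemas
-------
design:         std_order, point_type, <factor>.coded, <factor>.natural ...
response:       std_order, <response name>
concentrations: subject_id, arm, matrix, time_min, conc, blq (0/1)
formulations:   name, brain_auc, plasma_auc [, dte_percent]
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .nca import ConcProfile

__all__ = ["read_concentrations", "write_concentrations",
           "read_formulations", "profiles_from_frame"]

_CONC_COLUMNS = ["subject_id", "arm", "matrix", "time_min", "conc", "blq"]


def read_concentrations(path) -> pd.DataFrame:
    """Read a long-format concentration table, validating the schema."""
    frame = pd.read_csv(path)
    missing = [c for c in _CONC_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"concentration CSV lacks columns: {missing}")
    return frame


def write_concentrations(frame_or_profiles, path, arm: str = "arm1") -> None:
    if isinstance(frame_or_profiles, pd.DataFrame):
        frame = frame_or_profiles
    else:
        rows = []
        for p in frame_or_profiles:
            for t, c, b in zip(p.times, p.concentrations, p.blq):
                rows.append({"subject_id": p.subject_id, "arm": arm,
                             "matrix": p.matrix, "time_min": t, "conc": c,
                             "blq": int(b)})
        frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False, columns=_CONC_COLUMNS)


def profiles_from_frame(frame: pd.DataFrame):
    """Group a long concentration table into per-subject ConcProfiles.

    Returns ``{(arm, matrix): [ConcProfile, ...]}``; rows are sorted by
    time within each subject.
    """
    out: dict[tuple[str, str], list[ConcProfile]] = {}
    for (arm, matrix, subj), sub in frame.groupby(
            ["arm", "matrix", "subject_id"], sort=True):
        sub = sub.sort_values("time_min")
        prof = ConcProfile(
            subject_id=str(subj), matrix=str(matrix),
            times=sub["time_min"].to_numpy(dtype=float),
            concentrations=sub["conc"].to_numpy(dtype=float),
            blq=sub["blq"].to_numpy(dtype=bool))
        out.setdefault((str(arm), str(matrix)), []).append(prof)
    return out


def read_formulations(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    for col in ("name", "brain_auc", "plasma_auc"):
        if col not in frame.columns:
            raise ValueError(f"formulation CSV lacks column {col!r}")
    return frame
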