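"""Long-format CSV interchange for visit histories.

One row per patient-visit with columns ``patient_id``, ``onset_time``,
``visit_time``, ``damaged_<area>`` per joint area, optional
``active_<area>`` columns and any further covariate columns.  Counts vary
per patient, so the long format is the natural shape; capacities are
configurable to support toy designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model_core import (
    DEFAULT_AREAS,
    DataError,
    JointArea,
    PatientHistory,
    validate_patient,
)

__all__ = ["read_visits", "write_visits", "ValidationReport"]


@dataclass
class ValidationReport:
    """What the loader changed: merged duplicate-date rows, per patient."""

    n_patients: int = 0
    n_rows: int = 0
    merged_rows: list[int] = field(default_factory=list)

    def __str__(self) -> str:
        msg = f"{self.n_patients} patients from {self.n_rows} rows"
        if self.merged_rows:
            msg += f"; merged duplicate-date rows {self.merged_rows}"
        return msg


def read_visits(
    path: str | Path,
    areas: Sequence[JointArea] = DEFAULT_AREAS,
    merge_duplicates: bool = False,
    extra_covariates: Sequence[str] = (),
    stayer_covariates: Sequence[str] = (),
) -> tuple[list[PatientHistory], ValidationReport]:
    """Load and validate visit histories from a long-format CSV.

    Duplicate visit dates are an error unless ``merge_duplicates`` is set,
    in which case rows sharing a date are merged keeping the maximum
    counts.  Capacity violations, decreasing counts and onset-after-entry
    raise :class:`DataError` naming the offending rows.
    """
    df = pd.read_csv(path)
    required = ["patient_id", "onset_time", "visit_time"] + [
        f"damaged_{a.label}" for a in areas
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"missing required columns: {missing}")
    report = ValidationReport(n_rows=len(df))
    for a in areas:
        col = f"damaged_{a.label}"
        bad = df.index[(df[col] < 0) | (df[col] > a.capacity)].tolist()
        if bad:
            raise DataError(
                f"column {col!r} outside [0, {a.capacity}] at rows {bad}"
            )
    patients: list[PatientHistory] = []
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("visit_time")
        dup = grp["visit_time"].duplicated(keep=False)
        if dup.any():
            if not merge_duplicates:
                raise DataError(
                    f"patient {pid}: duplicate visit dates at rows "
                    f"{grp.index[dup].tolist()} (pass merge_duplicates=True to merge)"
                )
            report.merged_rows.extend(grp.index[grp["visit_time"].duplicated()].tolist())
            grp = grp.groupby("visit_time", as_index=False).max()
        active = {}
        for a in areas:
            col = f"active_{a.label}"
            if col in grp.columns:
                active[a.label] = grp[col].to_numpy()
        pt = PatientHistory(
            patient_id=str(pid),
            onset_time=float(grp["onset_time"].iloc[0]),
            visit_times=grp["visit_time"].to_numpy(dtype=float),
            cum_damage={
                a.label: grp[f"damaged_{a.label}"].to_numpy() for a in areas
            },
            active=active,
            extra_covariates={
                c: grp[c].to_numpy(dtype=float) for c in extra_covariates
            },
            stayer_covariates={
                c: float(grp[c].iloc[0]) for c in stayer_covariates
            },
        )
        validate_patient(pt, areas)
        patients.append(pt)
    report.n_patients = len(patients)
    return patients, report


def write_visits(
    patients: Sequence[PatientHistory],
    path: str | Path,
    areas: Sequence[JointArea] = DEFAULT_AREAS,
) -> None:
    """Write visit histories to the long-format CSV schema."""
    rows = []
    for pt in patients:
        for j, t in enumerate(pt.visit_times):
            row = {
                "patient_id": pt.patient_id,
                "onset_time": pt.onset_time,
                "visit_time": float(t),
            }
            for a in areas:
                row[f"damaged_{a.label}"] = int(pt.cum_damage[a.label][j])
            for k, v in pt.active.items():
                row[f"active_{k}"] = int(v[j])
            for k, v in pt.extra_covariates.items():
                row[k] = float(v[j])
            for k, v in pt.stayer_covariates.items():
                row[k] = v
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
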