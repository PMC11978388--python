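"""Landmark time-slice transformation of irregular longitudinal records.

A cohort's observations are consolidated onto a fixed grid of time slices
(default: nine slices covering [-1, 24] months at a nominal 3-month
interval). Within a slice each variable takes its newest measurement
(largest time). A cell that misses any dictionary variable while the
patient is under follow-up makes that cell *incomplete* and every later
cell *unavailable* — loss to surveillance is absorbing. The single
exception is a patient holding cancer-free status across the gap with real
data re-appearing later: the interior missing slice is filled by carrying
the previous slice forward (LOCF).

Each available cell carries a landmark time (the newest observation time in
the cell, standing in for the slice's imaging examination) from which
overall survival is re-based for that slice's landmark analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .exceptions import ConfigurationError

STATUS_COMPLETE = "complete"
STATUS_INCOMPLETE = "incomplete"
STATUS_UNAVAILABLE = "unavailable"
STATUS_IMPUTED = "imputed_locf"

AVAILABLE_STATUSES = (STATUS_COMPLETE, STATUS_IMPUTED)


@dataclass(frozen=True)
class SliceScheme:
    """Contiguous, non-overlapping periods defining the slice grid.

    The first period is closed on both ends; subsequent periods are
    half-open ``(lo, hi]`` so that every in-range time belongs to exactly
    one slice.
    """

    boundaries: tuple[tuple[float, float], ...] = (
        (-1, 1), (1, 3), (3, 6), (6, 9), (9, 12),
        (12, 15), (15, 18), (18, 21), (21, 24),
    )
    nominal_interval_months: float = 3.0

    def __post_init__(self) -> None:
        for (a, b), (c, d) in zip(self.boundaries, self.boundaries[1:]):
            if b != c or a >= b or c >= d:
                raise ConfigurationError("slice periods must be contiguous and increasing")

    @property
    def n_slices(self) -> int:
        return len(self.boundaries)

    def period(self, slice_index: int) -> tuple[float, float]:
        """Period for 1-based ``slice_index``."""
        return self.boundaries[slice_index - 1]

    @property
    def slice_indices(self) -> range:
        return range(1, self.n_slices + 1)


DEFAULT_SCHEME = SliceScheme()


def assign_slice(time_months: float, scheme: SliceScheme = DEFAULT_SCHEME) -> int | None:
    """Map a time to its 1-based slice index, or None when out of range."""
    lo0, _ = scheme.boundaries[0]
    if time_months < lo0 or time_months > scheme.boundaries[-1][1]:
        return None
    for i, (lo, hi) in enumerate(scheme.boundaries, start=1):
        if (time_months >= lo if i == 1 else time_months > lo) and time_months <= hi:
            return i
    return None


@dataclass(frozen=True)
class Cutoff:
    """Binarization rule: value on the adverse side of ``threshold`` maps to 1.

    ``adverse_direction`` "ge" flags values >= threshold (e.g. large tumor),
    "le" flags values <= threshold (e.g. low albumin).
    """

    threshold: float
    adverse_direction: str = "ge"

    def apply(self, values: pd.Series) -> pd.Series:
        if self.adverse_direction == "ge":
            flags = values >= self.threshold
        elif self.adverse_direction == "le":
            flags = values <= self.threshold
        else:
            raise ConfigurationError(
                f"adverse_direction must be 'ge' or 'le', got {self.adverse_direction!r}")
        out = flags.astype(float)
        out[values.isna()] = np.nan
        return out


#: Stock cutoffs for the HCC covariate dictionary. Tumor diameter uses the
#: 70 mm rule; labs use common clinical decision limits.
DEFAULT_CUTOFFS: dict[str, Cutoff] = {
    "age": Cutoff(50, "ge"),
    "diameter_mm": Cutoff(70, "ge"),
    "n_lesions": Cutoff(4, "ge"),
    "afp": Cutoff(25, "ge"),
    "alb": Cutoff(35, "le"),
    "tbil": Cutoff(34, "ge"),
    "pt": Cutoff(13, "ge"),
    "child_pugh_score": Cutoff(7, "ge"),
}


def save_cutoffs(cutoffs: Mapping[str, Cutoff], path: str | Path) -> None:
    payload = {k: {"threshold": c.threshold, "adverse_direction": c.adverse_direction}
               for k, c in cutoffs.items()}
    Path(path).write_text(json.dumps(payload, indent=2))


def load_cutoffs(path: str | Path) -> dict[str, Cutoff]:
    payload = json.loads(Path(path).read_text())
    return {k: Cutoff(v["threshold"], v.get("adverse_direction", "ge"))
            for k, v in payload.items()}


@dataclass
class LandmarkSurvival:
    """Survival re-based to a slice's landmark.

    Contains exactly the patients with an available cell at the slice and
    follow-up extending beyond their landmark; ``time_from_landmark`` is
    overall survival minus the landmark time.
    """

    slice_index: int
    patient_ids: np.ndarray
    time_from_landmark: np.ndarray
    event: np.ndarray

    def __len__(self) -> int:
        return len(self.patient_ids)

    def subset(self, ids: Iterable[str]) -> "LandmarkSurvival":
        mask = np.isin(self.patient_ids, np.asarray(list(ids)))
        return LandmarkSurvival(self.slice_index, self.patient_ids[mask],
                                self.time_from_landmark[mask], self.event[mask])


@dataclass
class SliceTable:
    """Patients x slices grid of consolidated covariates.

    ``values`` is indexed by (patient_id, slice_index) with one column per
    dictionary variable; ``status`` and ``landmark`` are patient x slice
    frames. Outcomes pass through from the cohort.
    """

    scheme: SliceScheme
    values: pd.DataFrame
    status: pd.DataFrame
    landmark: pd.DataFrame
    outcomes: pd.DataFrame
    variables: list[str]
    kinds: dict[str, str] = field(default_factory=dict)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.status.index)

    def cell_status(self, patient_id: str, slice_index: int) -> str:
        return self.status.at[patient_id, slice_index]

    def available_ids(self, slice_index: int) -> np.ndarray:
        col = self.status[slice_index]
        return col.index[col.isin(AVAILABLE_STATUSES)].to_numpy()

    def cell_values(self, patient_id: str, slice_index: int) -> pd.Series:
        return self.values.loc[(patient_id, slice_index)]

    def slice_values(self, slice_index: int, ids: Sequence[str] | None = None) -> pd.DataFrame:
        """Variable frame (rows = patients) for one slice."""
        frame = self.values.xs(slice_index, level="slice_index")
        if ids is not None:
            frame = frame.loc[list(ids)]
        return frame

    def to_csv(self, path: str | Path) -> None:
        flat = self.values.reset_index()
        key = pd.MultiIndex.from_frame(flat[["patient_id", "slice_index"]])
        status_flat = self.status.stack(future_stack=True)
        status_flat.index.names = ["patient_id", "slice_index"]
        landmark_flat = self.landmark.stack(future_stack=True)
        landmark_flat.index.names = ["patient_id", "slice_index"]
        flat.insert(2, "status", status_flat.reindex(key).to_numpy())
        flat.insert(3, "landmark_months", landmark_flat.reindex(key).to_numpy())
        flat.to_csv(path, index=False)


def build_slice_table(cohort: Cohort, scheme: SliceScheme = DEFAULT_SCHEME) -> SliceTable:
    """Consolidate a cohort onto the slice grid.

    Deterministic and idempotent: depends only on the cohort contents.
    """
    variables = cohort.dictionary.names
    obs = cohort.observations.copy()
    obs["value"] = pd.to_numeric(obs["value"])
    obs["slice_index"] = [assign_slice(t, scheme) for t in obs["time_months"]]
    obs = obs[obs["slice_index"].notna()]
    obs["slice_index"] = obs["slice_index"].astype(int)

    # newest value per (patient, slice, variable); stable for tied times
    obs = obs.sort_values("time_months", kind="stable")
    newest = obs.groupby(["patient_id", "slice_index", "variable"], sort=False).tail(1)

    patients = cohort.patient_ids
    slice_cols = list(scheme.slice_indices)
    raw_values = newest.pivot_table(index=["patient_id", "slice_index"],
                                    columns="variable", values="value",
                                    aggfunc="last")
    raw_times = newest.pivot_table(index=["patient_id", "slice_index"],
                                   columns="variable", values="time_months",
                                   aggfunc="last")

    full_index = pd.MultiIndex.from_product(
        [patients, slice_cols], names=["patient_id", "slice_index"])
    raw_values = raw_values.reindex(index=full_index, columns=variables)
    raw_times = raw_times.reindex(index=full_index, columns=variables)

    complete_raw = raw_values.notna().all(axis=1).unstack("slice_index")
    any_raw = raw_values.notna().any(axis=1).unstack("slice_index")
    newest_time = raw_times.max(axis=1).unstack("slice_index")

    cfs_by_pid: dict[str, list[tuple[float, float]]] = {}
    for _, row in cohort.cfs.iterrows():
        cfs_by_pid.setdefault(row["patient_id"], []).append(
            (row["start_months"], row["end_months"]))

    status = pd.DataFrame(STATUS_UNAVAILABLE, index=patients, columns=slice_cols)
    landmark = pd.DataFrame(np.nan, index=patients, columns=slice_cols)
    values = raw_values.copy()

    os_by_pid = cohort.outcomes.set_index("patient_id")["os_months"]
    for pid in patients:
        episodes = cfs_by_pid.get(pid, [])
        complete_row = complete_raw.loc[pid]
        lost = False
        prev_available: int | None = None
        for s in slice_cols:
            lo, hi = scheme.period(s)
            if lost:
                break  # absorbing: stays unavailable
            if complete_row[s]:
                status.at[pid, s] = STATUS_COMPLETE
                landmark.at[pid, s] = newest_time.at[pid, s]
                prev_available = s
                continue
            # missing data in this slice; dead-before-period patients simply
            # stop contributing (no later data exists by invariant)
            if os_by_pid[pid] <= lo:
                lost = True
                continue
            in_cfs = any(a <= lo and hi <= b for a, b in episodes)
            later_real = any(complete_row[t] for t in slice_cols if t > s)
            if in_cfs and later_real and prev_available is not None:
                values.loc[(pid, s)] = values.loc[(pid, prev_available)].values
                status.at[pid, s] = STATUS_IMPUTED
                landmark.at[pid, s] = hi  # nominal: period upper bound
                prev_available = s
            else:
                if any_raw.at[pid, s]:
                    status.at[pid, s] = STATUS_INCOMPLETE
                lost = True

    # unavailable cells carry no values
    status_flat = status.stack(future_stack=True)
    status_flat.index.names = ["patient_id", "slice_index"]
    dead_cells = status_flat.reindex(values.index) == STATUS_UNAVAILABLE
    values.loc[dead_cells.to_numpy()] = np.nan

    outcomes = cohort.outcomes[["patient_id", "os_months", "event"]].copy()
    kinds = {v.name: v.kind for v in cohort.dictionary}
    return SliceTable(scheme=scheme, values=values, status=status,
                      landmark=landmark, outcomes=outcomes,
                      variables=variables, kinds=kinds)


def landmark_survival(table: SliceTable, slice_index: int) -> LandmarkSurvival:
    """Landmark risk set at a slice: available cell, follow-up past landmark."""
    if not 1 <= slice_index <= table.scheme.n_slices:
        raise ConfigurationError(f"slice_index {slice_index} out of range")
    avail = table.available_ids(slice_index)
    os_by_pid = table.outcomes.set_index("patient_id")
    lm = table.landmark.loc[avail, slice_index]
    os_months = os_by_pid.loc[avail, "os_months"]
    keep = os_months.to_numpy() > lm.to_numpy()
    ids = np.asarray(avail)[keep]
    return LandmarkSurvival(
        slice_index=slice_index,
        patient_ids=ids,
        time_from_landmark=(os_months.to_numpy() - lm.to_numpy())[keep],
        event=os_by_pid.loc[ids, "event"].to_numpy().astype(int),
    )


def binarize(table: SliceTable, cutoffs: Mapping[str, Cutoff],
             variables: Sequence[str] | None = None) -> pd.DataFrame:
    """Binary feature grid: 1 = adverse level, indexed like ``table.values``.

    Binary dictionary variables pass through; every other variable used must
    have a cutoff or a :class:`ConfigurationError` names it.
    """
    variables = list(variables) if variables is not None else table.variables
    out = {}
    for name in variables:
        col = table.values[name]
        if name in cutoffs:
            out[name] = cutoffs[name].apply(col)
        elif table.kinds.get(name) == "binary" or set(
                col.dropna().unique()).issubset({0.0, 1.0}):
            out[name] = col.astype(float)
        else:
            raise ConfigurationError(
                f"no binarization cutoff declared for variable {name!r}")
    return pd.DataFrame(out, index=table.values.index)
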