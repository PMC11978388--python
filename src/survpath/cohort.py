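"""Domain types and file IO for longitudinal cohorts.

The interchange format is long (tidy): one row per observation
``(patient_id, variable, value, time_months)``, a per-patient outcome table
``(patient_id, os_months, event)``, optional cancer-free-status episodes
``(patient_id, start_months, end_months)`` and a JSON covariate dictionary.

Time is measured in months since initial diagnosis; observations from the
pre-treatment workup may carry times down to -1 month. Missing values are
absent rows, never sentinels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .exceptions import (
    CohortFormatError,
    CohortIntegrityError,
    CohortValidationError,
)

#: Earliest admissible observation time (months relative to diagnosis).
TIME_FLOOR = -1.0

OBS_COLUMNS = ["patient_id", "variable", "value", "time_months"]
OUTCOME_COLUMNS = ["patient_id", "os_months", "event"]
CFS_COLUMNS = ["patient_id", "start_months", "end_months"]

VARIABLE_KINDS = ("continuous", "binary", "ordinal")


@dataclass(frozen=True)
class Variable:
    """One entry of the covariate dictionary."""

    name: str
    kind: str  # continuous | binary | ordinal
    units: str = ""
    lo: float = -math.inf
    hi: float = math.inf

    def __post_init__(self) -> None:
        if self.kind not in VARIABLE_KINDS:
            raise CohortValidationError(
                f"variable {self.name!r}: unknown kind {self.kind!r}"
            )

    def in_range(self, value: float) -> bool:
        if self.kind == "binary":
            return value in (0, 1, 0.0, 1.0)
        return self.lo <= value <= self.hi


class CovariateDictionary:
    """Ordered mapping of variable name -> :class:`Variable`."""

    def __init__(self, variables: Iterable[Variable]):
        self._vars: dict[str, Variable] = {}
        for v in variables:
            if v.name in self._vars:
                raise CohortValidationError(f"duplicate variable name {v.name!r}")
            self._vars[v.name] = v

    def __contains__(self, name: str) -> bool:
        return name in self._vars

    def __getitem__(self, name: str) -> Variable:
        return self._vars[name]

    def __iter__(self):
        return iter(self._vars.values())

    def __len__(self) -> int:
        return len(self._vars)

    @property
    def names(self) -> list[str]:
        return list(self._vars)

    def to_json(self, path: str | Path) -> None:
        payload = {
            v.name: {
                "kind": v.kind,
                "units": v.units,
                "range": [None if math.isinf(v.lo) else v.lo,
                          None if math.isinf(v.hi) else v.hi],
            }
            for v in self
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CovariateDictionary":
        payload = json.loads(Path(path).read_text())
        variables = []
        for name, entry in payload.items():
            lo, hi = entry.get("range", [None, None])
            variables.append(
                Variable(
                    name=name,
                    kind=entry["kind"],
                    units=entry.get("units", ""),
                    lo=-math.inf if lo is None else float(lo),
                    hi=math.inf if hi is None else float(hi),
                )
            )
        return cls(variables)


def default_dictionary(extra: Iterable[Variable] = ()) -> CovariateDictionary:
    """The stock HCC covariate dictionary.

    Eleven baseline prognostic features (demographics, tumor burden,
    liver-function labs) plus the follow-up variable ``new_lesion``.
    Further variables are user-supplied via ``extra``.
    """
    base = [
        Variable("age", "continuous", "years", 0, 120),
        Variable("diameter_mm", "continuous", "mm", 0, 400),
        Variable("n_lesions", "ordinal", "count", 0, 50),
        Variable("vascular_invasion", "binary"),
        Variable("massive_ascites", "binary"),
        Variable("mild_moderate_ascites", "binary"),
        Variable("afp", "continuous", "IU/ml", 0, 1e7),
        Variable("alb", "continuous", "g/L", 5, 70),
        Variable("tbil", "continuous", "umol/L", 0, 1000),
        Variable("pt", "continuous", "s", 5, 60),
        Variable("child_pugh_score", "ordinal", "points", 5, 15),
        Variable("new_lesion", "binary"),
    ]
    return CovariateDictionary(base + list(extra))


@dataclass
class Violation:
    """One validation finding; ``patient_id`` is None for file-level issues."""

    code: str
    message: str
    patient_id: str | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        pid = f" [{self.patient_id}]" if self.patient_id else ""
        return f"{self.code}{pid}: {self.message}"


@dataclass
class Cohort:
    """A longitudinal cohort: observations, outcomes, CFS episodes, dictionary.

    ``observations``: DataFrame with columns patient_id, variable, value,
    time_months. ``outcomes``: one row per patient with os_months and the
    death indicator ``event``. ``cfs``: cancer-free-status episodes.
    """

    observations: pd.DataFrame
    outcomes: pd.DataFrame
    cfs: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=CFS_COLUMNS))
    dictionary: CovariateDictionary = field(default_factory=default_dictionary)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.outcomes["patient_id"])

    @property
    def n_patients(self) -> int:
        return len(self.outcomes)

    def __post_init__(self) -> None:
        self.observations = self.observations.reset_index(drop=True)
        self.outcomes = self.outcomes.reset_index(drop=True)
        self.cfs = self.cfs.reset_index(drop=True)


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{what}: missing required column(s) {missing}")


def read_cohort(
    obs_path: str | Path,
    outcome_path: str | Path,
    cfs_path: str | Path | None = None,
    dict_path: str | Path | None = None,
) -> Cohort:
    """Read and validate a cohort from the CSV/JSON interchange files.

    Raises :class:`CohortFormatError` for structural problems,
    :class:`CohortIntegrityError` for referential ones and
    :class:`CohortValidationError` when values violate invariants.
    """
    obs = pd.read_csv(obs_path, dtype={"patient_id": str, "variable": str})
    outcomes = pd.read_csv(outcome_path, dtype={"patient_id": str})
    _require_columns(obs, OBS_COLUMNS, "observations")
    _require_columns(outcomes, OUTCOME_COLUMNS, "outcomes")
    if cfs_path is not None and Path(cfs_path).exists():
        cfs = pd.read_csv(cfs_path, dtype={"patient_id": str})
        _require_columns(cfs, CFS_COLUMNS, "cfs")
    else:
        cfs = pd.DataFrame(columns=CFS_COLUMNS)
    dictionary = (
        CovariateDictionary.from_json(dict_path)
        if dict_path is not None
        else default_dictionary()
    )
    cohort = Cohort(obs, outcomes, cfs, dictionary)

    dup = outcomes["patient_id"][outcomes["patient_id"].duplicated()]
    if len(dup):
        raise CohortIntegrityError(
            f"outcomes: duplicated patient_id(s): {sorted(set(dup))}"
        )
    orphans = set(obs["patient_id"]) - set(outcomes["patient_id"])
    if orphans:
        raise CohortIntegrityError(
            f"observations without outcome row: {sorted(orphans)}"
        )
    report = validate_cohort(cohort)
    if report:
        raise CohortValidationError(
            "; ".join(str(v) for v in report[:10])
            + (f" (+{len(report) - 10} more)" if len(report) > 10 else "")
        )
    return cohort


def write_cohort(cohort: Cohort, dir_path: str | Path) -> dict[str, Path]:
    """Write the interchange file set; returns the paths written."""
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "observations": out / "observations.csv",
        "outcomes": out / "outcomes.csv",
        "cfs": out / "cfs.csv",
        "dictionary": out / "dictionary.json",
    }
    cohort.observations.to_csv(paths["observations"], index=False,
                               columns=OBS_COLUMNS)
    cohort.outcomes.to_csv(paths["outcomes"], index=False,
                           columns=OUTCOME_COLUMNS)
    cohort.cfs.to_csv(paths["cfs"], index=False, columns=CFS_COLUMNS)
    cohort.dictionary.to_json(paths["dictionary"])
    return paths


def validate_cohort(cohort: Cohort) -> list[Violation]:
    """Check every declared invariant; returns findings (empty iff valid).

    Pure: does not mutate the cohort and repeated calls agree.
    """
    report: list[Violation] = []
    obs, outcomes, cfs = cohort.observations, cohort.outcomes, cohort.cfs

    dup = outcomes["patient_id"][outcomes["patient_id"].duplicated()]
    for pid in sorted(set(dup)):
        report.append(Violation("duplicate_outcome", "patient appears twice in outcomes", pid))
    bad_event = outcomes[~outcomes["event"].isin([0, 1])]
    for _, row in bad_event.iterrows():
        report.append(Violation("bad_event", f"event={row['event']} not in {{0,1}}",
                                row["patient_id"]))
    neg_os = outcomes[outcomes["os_months"] < 0]
    for _, row in neg_os.iterrows():
        report.append(Violation("negative_os", f"os_months={row['os_months']} < 0",
                                row["patient_id"]))

    known = set(outcomes["patient_id"])
    for pid in sorted(set(obs["patient_id"]) - known):
        report.append(Violation("missing_outcome", "observations but no outcome row", pid))
    early = obs[obs["time_months"] < TIME_FLOOR]
    for _, row in early.iterrows():
        report.append(Violation(
            "time_below_floor",
            f"{row['variable']} at {row['time_months']} months precedes the "
            f"pre-diagnosis window floor ({TIME_FLOOR})",
            row["patient_id"]))
    for name in sorted(set(obs["variable"]) - set(cohort.dictionary.names)):
        report.append(Violation("unknown_variable", f"{name!r} not in dictionary"))

    os_by_pid = outcomes.set_index("patient_id")["os_months"]
    merged = obs[obs["patient_id"].isin(known)]
    after = merged[merged["time_months"] > merged["patient_id"].map(os_by_pid)]
    for pid in sorted(set(after["patient_id"])):
        report.append(Violation("observation_after_outcome",
                                "observation dated after death/last follow-up", pid))

    values = pd.to_numeric(obs["value"], errors="coerce")
    for _, row in obs[values.isna() & obs["value"].notna()].iterrows():
        report.append(Violation("non_numeric_value",
                                f"{row['variable']}={row['value']!r}",
                                row["patient_id"]))
    for name, grp_idx in obs.groupby("variable").groups.items():
        if name not in cohort.dictionary:
            continue
        var = cohort.dictionary[name]
        vals = values.loc[grp_idx]
        if var.kind == "binary":
            bad_mask = vals.notna() & ~vals.isin([0.0, 1.0])
        else:
            bad_mask = vals.notna() & ((vals < var.lo) | (vals > var.hi))
        for idx in vals.index[bad_mask]:
            report.append(Violation(
                "value_out_of_range",
                f"{name}={values.loc[idx]} outside [{var.lo}, {var.hi}]",
                obs.loc[idx, "patient_id"]))

    if len(cfs):
        bad = cfs[cfs["start_months"] >= cfs["end_months"]]
        for _, row in bad.iterrows():
            report.append(Violation("cfs_empty_episode",
                                    f"start {row['start_months']} >= end {row['end_months']}",
                                    row["patient_id"]))
        for pid, grp in cfs.sort_values("start_months").groupby("patient_id"):
            prev_end = None
            for _, row in grp.iterrows():
                if prev_end is not None and row["start_months"] < prev_end:
                    report.append(Violation("cfs_overlap",
                                            "overlapping cancer-free episodes", pid))
                prev_end = max(prev_end or row["end_months"], row["end_months"])
    return report
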