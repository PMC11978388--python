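"""Synthetic longitudinal HCC-like cohorts with known ground truth.

The generator emulates an intermediate-stage liver-cancer cohort followed on
a 3-month grid: baseline covariates drawn to match published cohort
marginals (age >= 50 in 63.5%, male 89.4%, HBV 92.8%, AFP >= 25 in 67.6%,
Child-Pugh A 91.9%, tumor >= 5 cm in 67.2%, >= 4 lesions in 57.8%), a
first-order per-slice disease process (response / stable / progression
moves tumor diameter, lesion count, AFP and liver labs; new lesions arrive
mostly under progression), and death driven by a piecewise-constant hazard
multiplied by ``exp(linear predictor of the CURRENT binarized covariates)``.
Because risk tracks the current state, later-slice covariates genuinely
out-predict baseline ones - the structural premise that lets a landmark
model beat baseline-trained static classifiers.

Follow-up realism: administrative censoring, per-slice loss to surveillance
(observations stop, survival follow-up continues), a small fraction of deep
responders holding cancer-free status with interior missing slices (to
exercise LOCF filling), and uniformly jittered visit times within each
period (to exercise newest-value selection and landmark anchoring).

The emitted cohort is a deterministic masking of the returned ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import Cohort, CovariateDictionary, Variable, default_dictionary
from .exceptions import ConfigurationError
from .timeslice import DEFAULT_CUTOFFS, DEFAULT_SCHEME, Cutoff, SliceScheme


def _default_hazard_coefs() -> dict[str, float]:
    """Log hazard ratios on the adverse level of each binarized covariate.

    Baseline tumor-burden and liver-function axes carry moderate effects;
    the dominant late effect sits on the follow-up recurrence flag
    ``new_lesion``, which is deliberately absent from the baseline feature
    set - the structural reason trajectory-aware models can out-predict
    baseline-trained ones at late landmarks.
    """
    return {
        "age": 0.10,
        "diameter_mm": 0.35,
        "n_lesions": 0.25,
        "vascular_invasion": 0.50,
        "massive_ascites": 0.45,
        "mild_moderate_ascites": 0.15,
        "afp": 0.20,
        "alb": 0.15,
        "tbil": 0.15,
        "pt": 0.10,
        "child_pugh_score": 0.20,
        "new_lesion": 1.50,
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-level simulation settings; defaults emulate the study cohort."""

    n_patients: int = 2000
    seed: int = 0
    # baseline marginals (prevalence of the tabulated level)
    p_age_ge50: float = 0.635
    p_male: float = 0.894
    p_hbv: float = 0.928
    p_afp_ge25: float = 0.676
    p_child_a: float = 0.919
    p_size_ge5cm: float = 0.672
    p_lesions_ge4: float = 0.578
    p_vascular_invasion: float = 0.05
    p_massive_ascites: float = 0.03
    p_mild_ascites: float = 0.15
    # per-slice disease dynamics
    p_response: float = 0.20
    p_stable: float = 0.55
    p_progression: float = 0.25
    # recurrence process: a latent recurrence-prone subtype keeps seeding new
    # intrahepatic lesions during follow-up; the event is recorded only as
    # the follow-up flag "new_lesion", not in the baseline feature set
    p_recurrence_type: float = 0.40
    p_new_lesion_recurrent: float = 0.60
    p_new_lesion_sporadic: float = 0.02
    # survival process
    hazard_coefs: Mapping[str, float] = field(default_factory=_default_hazard_coefs)
    baseline_hazard_per_month: float = 0.012
    # follow-up processes
    admin_censor_lo: float = 30.0
    admin_censor_hi: float = 84.0
    dropout_prob_per_slice: float = 0.03
    cfs_fraction: float = 0.05
    p_cfs_slice_missing: float = 0.5
    p_repeat_measurement: float = 0.15

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        probs = [self.p_response, self.p_stable, self.p_progression]
        if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
            raise ConfigurationError("transition probabilities must sum to 1")
        for name in ("p_age_ge50", "p_male", "p_hbv", "p_afp_ge25",
                     "p_child_a", "p_size_ge5cm", "p_lesions_ge4",
                     "p_vascular_invasion", "p_massive_ascites",
                     "p_mild_ascites", "p_recurrence_type",
                     "p_new_lesion_recurrent", "p_new_lesion_sporadic",
                     "dropout_prob_per_slice",
                     "cfs_fraction", "p_cfs_slice_missing",
                     "p_repeat_measurement"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.baseline_hazard_per_month <= 0:
            raise ConfigurationError("baseline hazard must be positive")


@dataclass
class GroundTruth:
    """Latent trajectories and event processes behind a generated cohort."""

    trajectories: pd.DataFrame  # (patient_id, slice_index) x variables + lp/state
    patients: pd.DataFrame      # death_time, censor_time, os_months, event, dropout_slice
    cfs: pd.DataFrame
    scheme: SliceScheme
    config: GeneratorConfig

    def lp_at(self, slice_index: int) -> pd.Series:
        return self.trajectories.xs(slice_index, level="slice_index")["lp"]


_SIM_VARIABLES = [
    "age", "male", "hbv", "diameter_mm", "n_lesions", "vascular_invasion",
    "massive_ascites", "mild_moderate_ascites", "afp", "alb", "tbil", "pt",
    "child_pugh_score", "new_lesion",
]


def simulation_dictionary() -> CovariateDictionary:
    """Stock dictionary plus the static demographics the generator emits."""
    return default_dictionary(extra=[
        Variable("male", "binary"),
        Variable("hbv", "binary"),
    ])


def _child_pugh(alb, tbil, pt, massive, mild):
    score = (5
             + (alb <= 35) + (alb <= 28)
             + (tbil >= 34) + (tbil >= 51)
             + (pt >= 13) + (pt >= 16)
             + 2 * massive + mild)
    return np.clip(score, 5, 15)


def _binarized(state: dict[str, np.ndarray],
               cutoffs: Mapping[str, Cutoff] = DEFAULT_CUTOFFS) -> dict[str, np.ndarray]:
    out = {}
    for name, arr in state.items():
        if name in cutoffs:
            c = cutoffs[name]
            out[name] = (arr >= c.threshold if c.adverse_direction == "ge"
                         else arr <= c.threshold).astype(float)
        else:
            out[name] = np.asarray(arr, dtype=float)
    return out


def generate(config: GeneratorConfig = GeneratorConfig(),
             scheme: SliceScheme = DEFAULT_SCHEME) -> tuple[Cohort, GroundTruth]:
    """Simulate a cohort; returns the observable Cohort and its GroundTruth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    n_slices = scheme.n_slices
    pids = np.array([f"P{i:05d}" for i in range(n)])

    # ---- baseline state ---------------------------------------------------
    over50 = rng.random(n) < config.p_age_ge50
    age = np.where(over50, rng.uniform(50, 78, n), rng.uniform(20, 50 - 1e-9, n))
    male = (rng.random(n) < config.p_male).astype(float)
    hbv = (rng.random(n) < config.p_hbv).astype(float)
    big = rng.random(n) < config.p_size_ge5cm
    diameter = np.where(big, rng.uniform(50, 160, n), rng.uniform(15, 50 - 1e-9, n))
    many = rng.random(n) < config.p_lesions_ge4
    n_lesions = np.where(many, rng.integers(4, 10, n), rng.integers(1, 4, n)).astype(float)
    afp_high = rng.random(n) < config.p_afp_ge25
    afp = np.where(afp_high, np.exp(rng.uniform(np.log(25), np.log(5e4), n)),
                   np.exp(rng.uniform(np.log(1.0), np.log(25 - 1e-9), n)))
    child_b = rng.random(n) >= config.p_child_a
    # labs drawn consistently with the intended Child-Pugh class
    alb = np.where(child_b, rng.uniform(26, 35, n), rng.uniform(36, 50, n))
    tbil = np.where(child_b, rng.uniform(25, 55, n), rng.uniform(6, 25, n))
    pt = np.where(child_b, rng.uniform(13, 17, n), rng.uniform(10.5, 13 - 1e-9, n))
    vi = (rng.random(n) < config.p_vascular_invasion).astype(float)
    massive = (rng.random(n) < config.p_massive_ascites).astype(float)
    mild = (rng.random(n) < config.p_mild_ascites).astype(float)

    state = {
        "age": age, "male": male, "hbv": hbv, "diameter_mm": diameter,
        "n_lesions": n_lesions, "vascular_invasion": vi,
        "massive_ascites": massive, "mild_moderate_ascites": mild,
        "afp": afp, "alb": alb, "tbil": tbil, "pt": pt,
        "child_pugh_score": _child_pugh(alb, tbil, pt, massive, mild),
        "new_lesion": np.zeros(n),
    }

    recurrence_type = rng.random(n) < config.p_recurrence_type

    coefs = dict(config.hazard_coefs)
    states_by_slice: list[dict[str, np.ndarray]] = []
    transitions = np.zeros((n, n_slices), dtype=int)  # 0 resp, 1 stable, 2 prog
    transitions[:, 0] = 1

    def record(st):
        states_by_slice.append({k: v.copy() for k, v in st.items()})

    record(state)
    for s in range(1, n_slices):
        u = rng.random(n)
        cat = np.where(u < config.p_response, 0,
                       np.where(u < config.p_response + config.p_stable, 1, 2))
        transitions[:, s] = cat
        resp, stab, prog = cat == 0, cat == 1, cat == 2

        growth = np.ones(n)
        growth[prog] = rng.uniform(1.10, 1.50, prog.sum())
        growth[stab] = rng.uniform(0.95, 1.10, stab.sum())
        growth[resp] = rng.uniform(0.45, 0.85, resp.sum())
        state["diameter_mm"] = np.clip(state["diameter_mm"] * growth, 5, 350)

        # the new-lesion flag records fresh intrahepatic foci seen on this
        # slice's imaging; the counted target lesions evolve separately
        p_new = np.where(recurrence_type, config.p_new_lesion_recurrent,
                         config.p_new_lesion_sporadic)
        newles = (rng.random(n) < p_new).astype(float)
        state["new_lesion"] = newles
        lesion_drift = np.where(prog, (rng.random(n) < 0.25).astype(float),
                                np.where(resp, -(rng.random(n) < 0.25).astype(float), 0.0))
        state["n_lesions"] = np.clip(state["n_lesions"] + lesion_drift, 1, 40)

        afp_mult = np.ones(n)
        afp_mult[prog] = rng.uniform(1.5, 4.0, prog.sum())
        afp_mult[stab] = rng.uniform(0.8, 1.3, stab.sum())
        afp_mult[resp] = rng.uniform(0.2, 0.7, resp.sum())
        state["afp"] = np.clip(state["afp"] * afp_mult, 0.5, 5e6)

        alb_shift = rng.uniform(-1.0, 1.0, n) - 1.5 * prog + 0.8 * resp
        state["alb"] = np.clip(state["alb"] + alb_shift, 18, 55)
        tbil_mult = np.where(prog, rng.uniform(1.0, 1.35, n), rng.uniform(0.9, 1.1, n))
        state["tbil"] = np.clip(state["tbil"] * tbil_mult, 4, 400)
        state["pt"] = np.clip(state["pt"] + rng.uniform(-0.2, 0.2, n) + 0.25 * prog, 9, 30)

        state["vascular_invasion"] = np.maximum(
            state["vascular_invasion"], (prog & (rng.random(n) < 0.10)).astype(float))
        state["massive_ascites"] = np.maximum(
            state["massive_ascites"], (prog & (rng.random(n) < 0.05)).astype(float))
        state["mild_moderate_ascites"] = np.maximum(
            state["mild_moderate_ascites"], (prog & (rng.random(n) < 0.08)).astype(float))
        state["child_pugh_score"] = _child_pugh(
            state["alb"], state["tbil"], state["pt"],
            state["massive_ascites"], state["mild_moderate_ascites"])
        record(state)

    # ---- cancer-free-status overrides ------------------------------------
    first_resp = np.full(n, -1)
    for s in range(1, min(6, n_slices)):
        hit = (transitions[:, s] == 0) & (first_resp < 0)
        first_resp[hit] = s
    candidates = np.flatnonzero(first_resp >= 1)
    n_cfs = int(round(config.cfs_fraction * n))
    cfs_idx = (rng.choice(candidates, size=min(n_cfs, len(candidates)),
                          replace=False) if n_cfs and len(candidates) else
               np.array([], dtype=int))
    cfs_start_slice = {int(i): int(first_resp[i]) for i in cfs_idx}
    for i, s0 in cfs_start_slice.items():
        for s in range(s0, n_slices):
            states_by_slice[s]["diameter_mm"][i] = np.clip(
                states_by_slice[s0 - 1]["diameter_mm"][i] * 0.2, 5, 30)
            states_by_slice[s]["afp"][i] = rng.uniform(1.5, 8.0)
            states_by_slice[s]["new_lesion"][i] = 0.0
            states_by_slice[s]["vascular_invasion"][i] = 0.0
            states_by_slice[s]["n_lesions"][i] = 1.0

    # ---- linear predictor and death --------------------------------------
    lp = np.zeros((n, n_slices))
    for s in range(n_slices):
        b = _binarized(states_by_slice[s])
        lp[:, s] = sum(coefs[k] * b[k] for k in coefs)

    uppers = np.array([hi for _, hi in scheme.boundaries])
    seg_bounds = np.concatenate([[0.0], uppers])  # hazard origin at diagnosis
    target = rng.exponential(1.0, n)
    death = np.full(n, np.inf)
    cum = np.zeros(n)
    for s in range(n_slices):
        lam = config.baseline_hazard_per_month * np.exp(lp[:, s])
        width = seg_bounds[s + 1] - seg_bounds[s]
        new_cum = cum + lam * width
        hit = (death == np.inf) & (new_cum >= target)
        death[hit] = seg_bounds[s] + (target[hit] - cum[hit]) / lam[hit]
        cum = new_cum
    # beyond the grid the hazard freezes at the final state
    lam_last = config.baseline_hazard_per_month * np.exp(lp[:, -1])
    rest = (death == np.inf)
    death[rest] = seg_bounds[-1] + (target[rest] - cum[rest]) / lam_last[rest]

    censor = rng.uniform(config.admin_censor_lo, config.admin_censor_hi, n)
    os_months = np.minimum(death, censor)
    event = (death <= censor).astype(int)

    # ---- loss to surveillance --------------------------------------------
    drop_draw = rng.random((n, n_slices))
    dropout_slice = np.full(n, n_slices + 1)
    for s in range(1, n_slices):  # baseline visit always happens
        hit = (drop_draw[:, s] < config.dropout_prob_per_slice) & (dropout_slice > n_slices)
        dropout_slice[hit] = s + 1

    # ---- CFS missing-slice pattern ---------------------------------------
    cfs_missing: dict[int, set[int]] = {}
    cfs_rows = []
    for i, s0 in cfs_start_slice.items():
        lo0, _ = scheme.period(s0 + 1)
        end = min(scheme.boundaries[-1][1], float(os_months[i]))
        if end <= lo0:
            continue
        cfs_rows.append({"patient_id": pids[i], "start_months": lo0,
                         "end_months": end})
        covered = [s for s in range(s0 + 1, n_slices + 1)
                   if scheme.period(s)[1] <= end and s < dropout_slice[i]]
        # keep the first and last covered slices observed so the gap has an
        # anchor before it and real data after it
        interior = covered[1:-1] if len(covered) > 2 else []
        missing = {s for s in interior
                   if rng.random() < config.p_cfs_slice_missing}
        cfs_missing[i] = missing

    # ---- emit observations -------------------------------------------------
    obs_rows = {"patient_id": [], "variable": [], "value": [], "time_months": []}
    visit_time = np.full((n, n_slices), np.nan)
    margin = 0.01  # keeps rounded times inside the period and before os
    for s in range(1, n_slices + 1):
        lo, hi = scheme.period(s)
        for i in range(n):
            if s >= dropout_slice[i]:
                continue
            if os_months[i] <= lo + 2 * margin:
                continue
            if s in cfs_missing.get(i, ()):  # CFS gap: no visit this slice
                continue
            v_hi = min(hi, os_months[i] - margin)
            v_lo = lo + margin
            v = rng.uniform(v_lo, v_hi) if v_hi > v_lo else (lo + v_hi) / 2
            visit_time[i, s - 1] = v
            st = states_by_slice[s - 1]
            for name in _SIM_VARIABLES:
                obs_rows["patient_id"].append(pids[i])
                obs_rows["variable"].append(name)
                obs_rows["value"].append(float(st[name][i]))
                obs_rows["time_months"].append(float(v))
            if rng.random() < config.p_repeat_measurement and v > lo + margin:
                t2 = rng.uniform(lo + margin, v)
                obs_rows["patient_id"].append(pids[i])
                obs_rows["variable"].append("afp")
                obs_rows["value"].append(float(st["afp"][i]))
                obs_rows["time_months"].append(float(t2))

    observations = pd.DataFrame(obs_rows)
    outcomes = pd.DataFrame({
        "patient_id": pids,
        "os_months": np.round(os_months, 4),
        "event": event,
    })
    observations["time_months"] = observations["time_months"].round(4)
    observations["value"] = observations["value"].round(4)
    cfs_df = pd.DataFrame(cfs_rows, columns=["patient_id", "start_months",
                                             "end_months"])
    cohort = Cohort(observations, outcomes, cfs_df, simulation_dictionary())

    traj_index = pd.MultiIndex.from_product(
        [pids, range(1, n_slices + 1)], names=["patient_id", "slice_index"])
    traj = pd.DataFrame(
        {name: np.concatenate([states_by_slice[s][name][:, None]
                               for s in range(n_slices)], axis=1).ravel()
         for name in _SIM_VARIABLES},
        index=traj_index)
    traj["lp"] = lp.ravel()
    traj["state"] = transitions.ravel()
    patients = pd.DataFrame({
        "patient_id": pids, "death_time": death, "censor_time": censor,
        "os_months": os_months, "event": event, "dropout_slice": dropout_slice,
        "recurrence_type": recurrence_type,
    }).set_index("patient_id")
    truth = GroundTruth(trajectories=traj, patients=patients, cfs=cfs_df,
                        scheme=scheme, config=config)
    return cohort, truth


def truth_cindex(truth: GroundTruth, slice_index: int,
                 horizon_months: float) -> float:
    """Oracle concordance: the generator's own current-slice linear predictor.

    Uses the nominal landmark (the slice's period upper bound) and every
    patient with follow-up beyond it, regardless of observability.
    """
    from .evaluation import td_cindex

    _, hi = truth.scheme.period(slice_index)
    pts = truth.patients
    alive = pts["os_months"] > hi
    lps = truth.lp_at(slice_index).loc[pts.index[alive]]
    return td_cindex(lps.to_numpy(),
                     (pts.loc[alive, "os_months"] - hi).to_numpy(),
                     pts.loc[alive, "event"].to_numpy(),
                     horizon_months)


def planted_split_fixture(n: int, hazard_ratio: float, seed: int,
                          n_markers: int = 6,
                          baseline_rate: float = 0.03) -> tuple[Cohort, str]:
    """Cohort where exactly one binary marker carries the stated hazard ratio.

    All markers are Bernoulli(1/2); survival is exponential with rate
    ``baseline_rate * hazard_ratio**x_planted`` and no censoring. Marker
    values are constant over the first two slices so a tree can bifurcate at
    the root. Returns the cohort and the planted marker's name.
    """
    rng = np.random.default_rng(seed)
    names = [f"marker_{chr(ord('a') + k)}" for k in range(n_markers)]
    planted = names[int(rng.integers(n_markers))]
    pids = [f"S{i:05d}" for i in range(n)]
    x = {name: rng.integers(0, 2, n).astype(float) for name in names}
    rate = baseline_rate * hazard_ratio ** x[planted]
    t_death = rng.exponential(1.0 / rate)

    rows = {"patient_id": [], "variable": [], "value": [], "time_months": []}
    for s, (lo, hi) in enumerate(((-1.0, 1.0), (1.0, 3.0)), start=1):
        for i in range(n):
            if t_death[i] <= lo and s > 1:
                continue
            v = rng.uniform(lo, min(hi, t_death[i])) if min(hi, t_death[i]) > lo else lo
            for name in names:
                rows["patient_id"].append(pids[i])
                rows["variable"].append(name)
                rows["value"].append(x[name][i])
                rows["time_months"].append(round(float(v), 4))
    observations = pd.DataFrame(rows)
    outcomes = pd.DataFrame({"patient_id": pids,
                             "os_months": np.round(t_death, 4),
                             "event": 1})
    dictionary = CovariateDictionary([Variable(nm, "binary") for nm in names])
    cohort = Cohort(observations, outcomes,
                    pd.DataFrame(columns=["patient_id", "start_months",
                                          "end_months"]),
                    dictionary)
    return cohort, planted
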