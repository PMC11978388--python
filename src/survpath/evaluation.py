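"""Time-dependent concordance C(t, dt) and model comparison.

``C(t, dt)`` measures, at a prediction time t (a slice landmark), how well
risk scores order the deaths occurring within the evaluation window dt: a
pair is comparable when the earlier subject dies within dt of the landmark
and the other subject is followed longer; it is concordant when the dying
subject carries the higher risk (risk ties count one half). The truncated
Harrell form weights every comparable pair equally; the IPCW variant
reweights pairs by the inverse squared Kaplan-Meier censoring-survival
estimate, removing the censoring-distribution dependence.

Uncertainty comes from repeated subsampling (default: 10 draws of
two-thirds of the eligible patients); subgroup-based models drop subgroups
below three members within each draw before scoring. Two models are
compared with a Z statistic on the resampling means and standard
deviations, at a Bonferroni-corrected alpha (default family of 55 tests).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .exceptions import ConfigurationError, EvaluationError
from .static_models import StaticModelBundle, features_at_slice
from .timeslice import LandmarkSurvival, SliceTable, landmark_survival

VARIANTS = ("harrell_truncated", "ipcw")


@dataclass(frozen=True)
class EvalConfig:
    """Resampling and comparison settings."""

    n_rep: int = 10
    subsample_fraction: float = 2.0 / 3.0
    min_subgroup: int = 3
    seed: int = 0
    concordance_variant: str = "harrell_truncated"
    prediction_slices: tuple[int, ...] = (1, 3, 5, 7, 9)
    horizons: tuple[float, ...] = (6, 12, 24, 36, 48)
    family_alpha: float = 0.05
    n_tests: int = 55
    shared_draws: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.subsample_fraction <= 1:
            raise ConfigurationError("subsample_fraction must be in (0, 1]")
        if self.concordance_variant not in VARIANTS:
            raise ConfigurationError(
                f"concordance_variant must be one of {VARIANTS}")


@dataclass
class CIndexResult:
    """Resampled C(t, dt) for one model at one grid cell."""

    model_name: str
    prediction_slice: int
    horizon_months: float
    mean: float
    sd: float
    n_rep: int
    n_effective: int
    n_undefined: int = 0

    @property
    def defined(self) -> bool:
        return np.isfinite(self.mean)


@dataclass
class ComparisonResult:
    model_a: str
    model_b: str
    prediction_slice: int
    horizon_months: float
    z_statistic: float
    p_value: float
    corrected_alpha: float
    significant_after_correction: bool


def _censoring_survival_before(times: np.ndarray, events: np.ndarray,
                               at: np.ndarray) -> np.ndarray:
    """Left limit G(t-) of the KM censoring-survival estimate."""
    kmf = KaplanMeierFitter()
    kmf.fit(times, 1 - events)
    eps = 1e-9
    pred = kmf.predict(np.maximum(at - eps, 0.0))
    return np.atleast_1d(np.asarray(pred, dtype=float))


def td_cindex(
    risks: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    horizon_months: float,
    variant: str = "harrell_truncated",
) -> float:
    """Time-dependent concordance of risk scores over one evaluation window.

    Comparable pairs (i, j): subject i dies at ``times[i] <= horizon`` and
    subject j survives past ``times[i]``. Concordance credit: 1 when
    ``risks[i] > risks[j]``, 0.5 on a risk tie. Returns NaN (flagged
    undefined) when no pair is comparable.
    """
    if variant not in VARIANTS:
        raise ConfigurationError(f"unknown concordance variant {variant!r}")
    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    idx_i = np.flatnonzero((events == 1) & (times <= horizon_months))
    if len(idx_i) == 0:
        return np.nan
    if variant == "ipcw":
        g = _censoring_survival_before(times, events, times[idx_i])
        w_i = 1.0 / np.maximum(g, 1e-12) ** 2
    else:
        w_i = np.ones(len(idx_i))
    t_i = times[idx_i][:, None]
    r_i = risks[idx_i][:, None]
    comparable = times[None, :] > t_i  # strict: j outlives i
    credit = np.where(r_i > risks[None, :], 1.0,
                      np.where(r_i == risks[None, :], 0.5, 0.0))
    num = float(np.sum(w_i[:, None] * comparable * credit))
    den = float(np.sum(w_i[:, None] * comparable))
    if den == 0:
        return np.nan
    return num / den


RiskFn = Callable[[Sequence[str]], pd.Series]


def resample_cindex(
    risk_fn: RiskFn,
    ls: LandmarkSurvival,
    horizon_months: float,
    config: EvalConfig,
    model_name: str = "model",
    rng: np.random.Generator | None = None,
) -> CIndexResult:
    """Mean and SD of C(t, dt) over seeded subsample draws.

    ``risk_fn`` maps a patient-id subset to a risk Series (possibly on a
    further-filtered index, so per-draw subgroup filtering applies);
    patients it drops are excluded from that draw's pair set. Draws with no
    comparable pair are skipped and counted in ``n_undefined``.
    """
    rng = rng or np.random.default_rng(config.seed)
    ids = np.asarray(ls.patient_ids)
    n_draw = int(np.floor(config.subsample_fraction * len(ids)))
    if n_draw < 2:
        raise EvaluationError("subsample size below 2")
    values, n_effs = [], []
    n_undefined = 0
    pos = {pid: k for k, pid in enumerate(ids)}
    for _ in range(config.n_rep):
        draw = rng.choice(ids, size=n_draw, replace=False)
        scored = risk_fn(list(draw))
        scored = scored.dropna()
        if len(scored) < 2:
            n_undefined += 1
            continue
        sel = np.array([pos[p] for p in scored.index])
        c = td_cindex(scored.to_numpy(), ls.time_from_landmark[sel],
                      ls.event[sel], horizon_months,
                      config.concordance_variant)
        if np.isnan(c):
            n_undefined += 1
            continue
        values.append(c)
        n_effs.append(len(scored))
    if not values:
        raise EvaluationError(
            f"{model_name}: C(t,dt) undefined in every subsample draw")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return CIndexResult(model_name=model_name,
                        prediction_slice=ls.slice_index,
                        horizon_months=horizon_months,
                        mean=mean, sd=sd, n_rep=len(values),
                        n_effective=int(np.round(np.mean(n_effs))),
                        n_undefined=n_undefined)


def apply_subgroup_filter(assignments: Mapping[str, int | None],
                          min_subgroup: int = 3) -> list[str]:
    """Patients whose subgroup reaches ``min_subgroup`` members in-sample."""
    counts: dict[int, int] = {}
    for nid in assignments.values():
        if nid is not None:
            counts[nid] = counts.get(nid, 0) + 1
    return [p for p, nid in assignments.items()
            if nid is not None and counts[nid] >= min_subgroup]


def bonferroni_threshold(family_alpha: float, n_tests: int) -> float:
    """Per-test alpha controlling the family-wise error rate."""
    if n_tests < 1:
        raise ConfigurationError("n_tests must be >= 1")
    return family_alpha / n_tests


def compare_models(a: CIndexResult, b: CIndexResult,
                   corrected_alpha: float = 0.05 / 55) -> ComparisonResult:
    """Z test on two resampled c-index summaries.

    The two resampling SDs are treated as independent standard errors.
    Both SDs zero: equal means give z = 0 (p = 1); differing means give an
    infinite z flagged significant.
    """
    diff = a.mean - b.mean
    denom = float(np.sqrt(a.sd**2 + b.sd**2))
    if denom == 0:
        z = 0.0 if diff == 0 else float(np.copysign(np.inf, diff))
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / denom
        p = float(2.0 * stats.norm.sf(abs(z)))
    return ComparisonResult(a.model_name, b.model_name, a.prediction_slice,
                            a.horizon_months, z, p, corrected_alpha,
                            bool(p < corrected_alpha))


def _derive_rng(seed: int, t: int, horizon: float) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, int(t), int(horizon * 1000)]))


def evaluation_grid(
    static_bundles: Mapping[str, StaticModelBundle],
    slice_table: SliceTable,
    sp_results,  # SurvivalPathResults; untyped to avoid an import cycle
    config: EvalConfig,
) -> tuple[list[CIndexResult], list[ComparisonResult]]:
    """The full models x prediction-slices x horizons evaluation.

    Static models score each slice's feature vectors with their
    horizon-matched classifier; the survival-path model scores via node
    membership (subgroups under ``min_subgroup`` dropped per draw). With
    ``shared_draws`` every model sees the same subsamples within a cell.
    Cells whose risk set is empty or degenerate are flagged absent
    (NaN mean).
    """
    results: list[CIndexResult] = []
    comparisons: list[ComparisonResult] = []
    corrected = bonferroni_threshold(config.family_alpha, config.n_tests)

    for t in config.prediction_slices:
        ls = landmark_survival(slice_table, t)
        if len(ls) < 3:
            for name in [*static_bundles, "SP"]:
                results.append(CIndexResult(name, t, np.nan, np.nan, 0.0, 0, 0))
            continue
        try:
            feats = features_at_slice(slice_table, t, list(ls.patient_ids))
        except Exception:
            feats = None
        for horizon in config.horizons:
            cell: dict[str, CIndexResult] = {}
            for name, bundle in static_bundles.items():
                def static_risk(ids, _b=bundle, _h=horizon):
                    return _b.predict_risk(feats.loc[list(ids)], _h)

                cell[name] = _cell_result(static_risk, ls, horizon, config,
                                          name, t)
            if sp_results is not None:
                def sp_risk(ids):
                    return sp_results.node_risk_scores(
                        t, horizon, patient_ids=ids,
                        min_subgroup=config.min_subgroup,
                        table=slice_table)

                cell["SP"] = _cell_result(sp_risk, ls, horizon, config, "SP", t)
            results.extend(cell.values())
            if "SP" in cell and cell["SP"].defined:
                for name in static_bundles:
                    if cell[name].defined:
                        comparisons.append(
                            compare_models(cell["SP"], cell[name], corrected))
    return results, comparisons


def _cell_result(risk_fn: RiskFn, ls: LandmarkSurvival, horizon: float,
                 config: EvalConfig, name: str, t: int) -> CIndexResult:
    if config.shared_draws:
        rng = _derive_rng(config.seed, t, horizon)
    else:
        name_key = zlib.crc32(name.encode()) % (2**31)
        rng = _derive_rng(config.seed + name_key, t, horizon)
    try:
        return resample_cindex(risk_fn, ls, horizon, config, name, rng)
    except EvaluationError:
        return CIndexResult(name, t, horizon, np.nan, np.nan, 0, 0,
                            config.n_rep)


def results_frame(results: Sequence[CIndexResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "model": r.model_name, "prediction_slice": r.prediction_slice,
        "horizon_months": r.horizon_months, "mean": r.mean, "sd": r.sd,
        "n_rep": r.n_rep, "n_effective": r.n_effective,
        "n_undefined": r.n_undefined,
    } for r in results])


def comparisons_frame(comparisons: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "model_a": c.model_a, "model_b": c.model_b,
        "prediction_slice": c.prediction_slice,
        "horizon_months": c.horizon_months, "z": c.z_statistic,
        "p_value": c.p_value, "corrected_alpha": c.corrected_alpha,
        "significant": c.significant_after_correction,
    } for c in comparisons])
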