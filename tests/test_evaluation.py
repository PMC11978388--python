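"""Time-dependent concordance, resampling, Z tests and the grid."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import survpath as sp
from survpath.evaluation import EvalConfig
from survpath.exceptions import EvaluationError
from survpath.timeslice import LandmarkSurvival


def brute_force_cindex(risks, times, events, horizon):
    """Exhaustive pair enumeration oracle for the truncated Harrell form."""
    num = den = 0.0
    for i, j in itertools.permutations(range(len(times)), 2):
        if events[i] == 1 and times[i] <= horizon and times[i] < times[j]:
            den += 1
            if risks[i] > risks[j]:
                num += 1
            elif risks[i] == risks[j]:
                num += 0.5
    return np.nan if den == 0 else num / den


def test_perfect_concordance():
    times = np.array([2.0, 4.0, 6.0, 8.0])
    risks = -times  # exactly reverse-ordered
    assert sp.td_cindex(risks, times, np.ones(4, int), 10) == 1.0


def test_tied_risks_give_half_credit():
    times = np.array([2.0, 4.0, 6.0, 8.0])
    assert sp.td_cindex(np.zeros(4), times, np.ones(4, int), 10) == 0.5


def test_four_patient_worked_example():
    """times {2,4,6,8} all events, risks {0.9,0.1,0.8,0.2}: 4 of 6 pairs."""
    risks = np.array([0.9, 0.1, 0.8, 0.2])
    times = np.array([2.0, 4.0, 6.0, 8.0])
    events = np.ones(4, int)
    assert sp.td_cindex(risks, times, events, 10) == pytest.approx(4 / 6)
    assert brute_force_cindex(risks, times, events, 10) == pytest.approx(4 / 6)


def test_horizon_truncates_pairs():
    risks = np.array([0.9, 0.1, 0.8, 0.2])
    times = np.array([2.0, 4.0, 6.0, 8.0])
    events = np.ones(4, int)
    c = sp.td_cindex(risks, times, events, 3)  # only the t=2 death counts
    assert c == pytest.approx(brute_force_cindex(risks, times, events, 3))
    assert c == 1.0


def test_matches_enumeration_on_random_instances():
    rng = np.random.default_rng(42)
    for _ in range(60):
        n = int(rng.integers(3, 40))
        times = rng.exponential(10, n)
        risks = rng.random(n)
        events = np.ones(n, int)
        horizon = float(rng.uniform(2, 30))
        mine = sp.td_cindex(risks, times, events, horizon)
        oracle = brute_force_cindex(risks, times, events, horizon)
        if np.isnan(oracle):
            assert np.isnan(mine)
        else:
            assert mine == pytest.approx(oracle, abs=1e-12)


def test_ipcw_equals_harrell_without_censoring():
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = int(rng.integers(5, 40))
        times = rng.exponential(10, n)
        risks = rng.random(n)
        events = np.ones(n, int)
        a = sp.td_cindex(risks, times, events, 15, "harrell_truncated")
        b = sp.td_cindex(risks, times, events, 15, "ipcw")
        assert a == pytest.approx(b, abs=1e-12)


def test_ipcw_reweights_under_censoring():
    rng = np.random.default_rng(3)
    n = 200
    times = rng.exponential(10, n)
    events = (rng.random(n) < 0.6).astype(int)
    risks = rng.random(n)
    c = sp.td_cindex(risks, times, events, 15, "ipcw")
    assert 0.0 <= c <= 1.0


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 10_000))
def test_flip_symmetry(seed):
    """Negating tie-free risks maps c to 1 - c."""
    rng = np.random.default_rng(seed)
    n = 20
    times = rng.exponential(10, n)
    risks = rng.permutation(n).astype(float)  # distinct risks
    events = np.ones(n, int)
    c = sp.td_cindex(risks, times, events, 25)
    c_neg = sp.td_cindex(-risks, times, events, 25)
    assert c + c_neg == pytest.approx(1.0)


def test_no_comparable_pair_is_flagged():
    times = np.array([5.0, 6.0])
    events = np.array([0, 0])
    assert np.isnan(sp.td_cindex(np.array([0.1, 0.2]), times, events, 10))


# --------------------------------------------------------------- resampling
def _ls(times, events):
    ids = [f"p{i}" for i in range(len(times))]
    return LandmarkSurvival(1, np.asarray(ids), np.asarray(times, float),
                            np.asarray(events, int))


def _risk_fn_from(series):
    return lambda ids: series.loc[list(ids)]


def test_full_fraction_gives_zero_sd():
    rng = np.random.default_rng(0)
    t = rng.exponential(10, 60)
    ls = _ls(t, np.ones(60, int))
    risks = pd.Series(-t, index=ls.patient_ids)
    config = EvalConfig(subsample_fraction=1.0, n_rep=10, seed=5)
    res = sp.resample_cindex(_risk_fn_from(risks), ls, 20, config)
    assert res.sd == 0.0
    assert res.mean == 1.0  # perfect risks


def test_resampling_is_seeded():
    rng = np.random.default_rng(1)
    t = rng.exponential(10, 80)
    ls = _ls(t, (rng.random(80) < 0.7).astype(int))
    risks = pd.Series(rng.random(80), index=ls.patient_ids)
    config = EvalConfig(seed=9)
    a = sp.resample_cindex(_risk_fn_from(risks), ls, 12, config)
    b = sp.resample_cindex(_risk_fn_from(risks), ls, 12, config)
    assert (a.mean, a.sd) == (b.mean, b.sd)


def test_all_draws_undefined_raises():
    ls = _ls([5.0, 6.0, 7.0], [0, 0, 0])  # no event: no comparable pair
    risks = pd.Series([0.1, 0.2, 0.3], index=ls.patient_ids)
    with pytest.raises(EvaluationError):
        sp.resample_cindex(_risk_fn_from(risks), ls, 10, EvalConfig(seed=0))


def test_null_risks_are_calibrated():
    """Random risks give mean c within 0.5 +/- 0.03 over 200 replicates."""
    rng = np.random.default_rng(2024)
    values = []
    for _ in range(200):
        n = 100
        t = rng.exponential(15, n)
        e = (rng.random(n) < 0.7).astype(int)
        values.append(sp.td_cindex(rng.random(n), t, e, 24))
    assert np.nanmean(values) == pytest.approx(0.5, abs=0.03)


# ------------------------------------------------------------ subgroup rule
def test_subgroup_filter_examples():
    assignments = {f"a{i}": 1 for i in range(20)} | {"b0": 2, "b1": 2}
    kept = sp.apply_subgroup_filter(assignments, 3)
    assert len(kept) == 20 and all(k.startswith("a") for k in kept)
    assert sorted(sp.apply_subgroup_filter(assignments, 1)) == \
        sorted(assignments)
    big = {f"x{i}": i % 3 for i in range(9)}
    assert sorted(sp.apply_subgroup_filter(big, 3)) == sorted(big)


# ----------------------------------------------------------------- Z tests
def _res(mean, sd, name="m"):
    return sp.CIndexResult(name, 1, 24, mean, sd, 10, 100)


def test_z_test_closed_form():
    cmp = sp.compare_models(_res(0.70, 0.01, "a"), _res(0.60, 0.01, "b"),
                            corrected_alpha=0.0009)
    assert cmp.z_statistic == pytest.approx(0.1 / np.sqrt(2e-4), rel=1e-9)
    assert cmp.z_statistic == pytest.approx(7.071, abs=1e-3)
    assert cmp.p_value < 1e-11
    assert cmp.significant_after_correction


def test_z_test_equal_means():
    cmp = sp.compare_models(_res(0.6, 0.02), _res(0.6, 0.02))
    assert cmp.z_statistic == 0.0 and cmp.p_value == 1.0


def test_z_test_antisymmetry():
    a, b = _res(0.7, 0.02, "a"), _res(0.64, 0.03, "b")
    assert sp.compare_models(a, b).z_statistic == \
        pytest.approx(-sp.compare_models(b, a).z_statistic)


def test_z_test_degenerate_sds():
    cmp = sp.compare_models(_res(0.7, 0.0), _res(0.6, 0.0))
    assert np.isinf(cmp.z_statistic) and cmp.significant_after_correction


def test_bonferroni_threshold():
    assert round(sp.bonferroni_threshold(0.05, 55), 4) == 0.0009
    assert sp.bonferroni_threshold(0.05, 1) == 0.05
    assert sp.bonferroni_threshold(0.05, 5) == pytest.approx(0.01)


# ----------------------------------------------------------------- the grid
def test_grid_shape_and_determinism(synthetic_table, fitted_tree):
    ls1 = sp.landmark_survival(synthetic_table, 1)
    feats = sp.features_at_slice(synthetic_table, 1, list(ls1.patient_ids))
    bundles = {"GNB": sp.fit_static("GNB", feats, ls1, horizons=(12, 24),
                                    seed=0)}
    config = EvalConfig(seed=4, prediction_slices=(1, 5), horizons=(12, 24))
    results, comps = sp.evaluation_grid(bundles, synthetic_table, fitted_tree,
                                        config)
    # 2 models x 2 slices x 2 horizons
    assert len(results) == 8
    again, _ = sp.evaluation_grid(bundles, synthetic_table, fitted_tree,
                                  config)
    for r1, r2 in zip(results, again):
        assert (r1.model_name, r1.mean, r1.sd) == (r2.model_name, r2.mean,
                                                   r2.sd)
    for c in comps:
        assert c.model_a == "SP"
        assert c.corrected_alpha == pytest.approx(0.05 / 55)
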