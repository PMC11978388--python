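"""Survival-path tree: growth laws, node statistics, routing, export."""

import json

import numpy as np
import pytest

import survpath as sp
from survpath.exceptions import ModelConstructionError, ScoringError
from survpath.timeslice import AVAILABLE_STATUSES


# ---------------------------------------------------------------- km_median
@pytest.mark.parametrize("times,events,expected", [
    ([1, 2, 3, 4, 5], [1, 1, 1, 1, 1], 3.0),   # S(3) = 0.4 <= 0.5
    ([5, 8, 11], [0, 0, 0], None),              # all censored: not reached
    ([7.0], [1], 7.0),                          # S drops to 0 at 7
    ([2, 4, 6, 8], [1, 0, 0, 0], None),         # S stays at 0.75
])
def test_km_median(times, events, expected):
    med = sp.km_median(np.asarray(times, float), np.asarray(events, int))
    if expected is None:
        assert med is None
    else:
        assert med == pytest.approx(expected)


# ------------------------------------------------------------- select_split
def _fixture_parts(n, hr, seed, **kw):
    cohort, planted = sp.planted_split_fixture(n, hr, seed, **kw)
    table = sp.build_slice_table(cohort)
    grid = sp.binarize(table, {})
    ls = sp.landmark_survival(table, 1)
    next_avail = [p for p in table.patient_ids
                  if table.cell_status(p, 2) in AVAILABLE_STATUSES]
    return table, grid, ls, next_avail, planted


def test_select_split_recovers_planted_variable():
    table, grid, ls, next_avail, planted = _fixture_parts(300, 3.0, 5)
    choice = sp.select_split(table.patient_ids, 1, grid, ls, next_avail,
                             sp.SPConfig())
    assert choice is not None
    var, screen = choice
    assert var == planted
    assert screen.p_value < 0.05 and screen.hazard_ratio > 1.5


def test_select_split_none_when_nothing_significant():
    table, grid, ls, next_avail, _ = _fixture_parts(200, 1.0, 3)
    choice = sp.select_split(table.patient_ids, 1, grid, ls, next_avail,
                             sp.SPConfig(alpha=1e-6))
    assert choice is None


def test_select_split_respects_min_split():
    """A variable splitting 290/10 is ineligible at min_split 15."""
    table, grid, ls, next_avail, planted = _fixture_parts(300, 4.0, 5)
    rare = grid.copy()
    # keep only 10 adverse patients on the planted variable everywhere
    adverse_ids = [p for p in table.patient_ids
                   if rare.at[(p, 1), planted] == 1.0][:10]
    for p in table.patient_ids:
        val = 1.0 if p in adverse_ids else 0.0
        for s in (1, 2):
            if (p, s) in rare.index:
                rare.at[(p, s), planted] = val
    choice = sp.select_split(table.patient_ids, 1, rare, ls, next_avail,
                             sp.SPConfig())
    assert choice is None or choice[0] != planted


def test_select_split_needs_twice_min_split():
    table, grid, ls, next_avail, _ = _fixture_parts(20, 2.5, 0)
    assert sp.select_split(table.patient_ids, 1, grid, ls, next_avail,
                           sp.SPConfig(min_split=15)) is None


# -------------------------------------------------------------------- grow
def test_degenerate_tree_is_single_chain(synthetic_table):
    """With an unattainable alpha no split fires: one path, a chain."""
    res = sp.grow(synthetic_table, sp.SPConfig(alpha=1e-15))
    assert res.n_paths == 1
    assert all(len(n.children) <= 1 for n in res.nodes.values())
    assert all(n.slice_index <= 9 for n in res.nodes.values())


def test_planted_split_at_root():
    cohort, planted = sp.planted_split_fixture(300, 3.0, 2)
    table = sp.build_slice_table(cohort)
    res = sp.grow(table, sp.SPConfig(), cutoffs={})
    root = res.root
    assert root.split_variable == planted
    adverse, non_adverse = (res.nodes[c] for c in root.children)
    grid = sp.binarize(table, {})
    next_avail = {p for p in root.patient_ids
                  if table.cell_status(p, 2) in AVAILABLE_STATUSES}
    assert set(adverse.patient_ids) | set(non_adverse.patient_ids) == next_avail
    assert not set(adverse.patient_ids) & set(non_adverse.patient_ids)
    assert all(grid.at[(p, 1), planted] == 1.0 for p in adverse.patient_ids)


def test_tree_laws_on_synthetic_cohort(fitted_tree, synthetic_table):
    """Partition, refit-significance, child sizes and monotone n."""
    res, table = fitted_tree, synthetic_table
    grid = sp.binarize(table, sp.DEFAULT_CUTOFFS)
    for node in res.nodes.values():
        if node.split_variable is not None:
            a, b = (res.nodes[c] for c in node.children)
            s = node.slice_index
            avail_next = {p for p in node.patient_ids
                          if table.cell_status(p, s + 1) in AVAILABLE_STATUSES}
            assert set(a.patient_ids) | set(b.patient_ids) == avail_next
            assert not set(a.patient_ids) & set(b.patient_ids)
            assert a.n >= res.config.min_split
            assert b.n >= res.config.min_split
            # refit the recorded split on the node's landmark survival
            ls = sp.landmark_survival(table, s).subset(node.patient_ids)
            x = grid.xs(s, level="slice_index").loc[
                list(ls.patient_ids), node.split_variable].to_numpy()
            refit = sp.cox_screen(x, ls.time_from_landmark, ls.event)
            assert refit.eligible and refit.p_value < res.config.alpha
        for c in node.children:
            assert res.nodes[c].n <= node.n
            assert res.nodes[c].slice_index == node.slice_index + 1
    assert res.n_paths == len(res.leaves)


def test_growth_is_deterministic(synthetic_table):
    a = sp.grow(synthetic_table)
    b = sp.grow(synthetic_table)
    assert a.skeleton() == b.skeleton()


def test_empty_first_slice_raises():
    cohort, _ = sp.planted_split_fixture(30, 1.0, 0)
    cohort.observations = cohort.observations[
        cohort.observations["time_months"] > 1.0]
    table = sp.build_slice_table(cohort)
    with pytest.raises(ModelConstructionError):
        sp.grow(table, cutoffs={})


# ---------------------------------------------------------------- routing
def test_training_patients_route_to_their_node(fitted_tree):
    res = fitted_tree
    for node in res.nodes_at_slice(4)[:3]:
        for pid in node.patient_ids[:5]:
            assert res.assign_to_node(pid, 4) == node.node_id


def test_routing_stops_at_unavailability(fitted_tree, synthetic_table):
    res, table = fitted_tree, synthetic_table
    # find a patient available at slice 1 but not at slice 5
    for pid in table.patient_ids:
        ok1 = table.cell_status(pid, 1) in AVAILABLE_STATUSES
        bad5 = table.cell_status(pid, 5) not in AVAILABLE_STATUSES
        if ok1 and bad5:
            assert res.assign_to_node(pid, 5) is None
            assert res.assign_to_node(pid, 9) is None
            break
    else:
        pytest.skip("no partially-followed patient in fixture")


def test_unknown_patient_raises(fitted_tree):
    with pytest.raises(ScoringError):
        fitted_tree.assign_to_node("nobody", 3)


# ------------------------------------------------------------- risk scores
def test_node_risk_scores_monotone_in_node_survival(fitted_tree):
    res = fitted_tree
    slice_index = 3
    risks = res.node_risk_scores(slice_index, 24)
    assert ((risks >= 0) & (risks <= 1)).all()
    # risks must equal 1 - node KM survival, so ordering follows survival
    by_node = {}
    for pid in risks.index:
        nid = res.assign_to_node(pid, slice_index)
        by_node.setdefault(nid, set()).add(risks[pid])
    for nid, values in by_node.items():
        assert len(values) == 1
        (risk,) = values
        assert risk == pytest.approx(1 - res.node_survival_at(nid, 24))


def test_small_subgroups_receive_no_score(fitted_tree):
    res = fitted_tree
    node = res.nodes_at_slice(3)[0]
    ids = list(node.patient_ids[:2])  # a subgroup of 2 within the sample
    risks = res.node_risk_scores(3, 24, patient_ids=ids, min_subgroup=3)
    assert len(risks) == 0


def test_single_node_model_gives_equal_scores(synthetic_table):
    res = sp.grow(synthetic_table, sp.SPConfig(alpha=1e-15))
    risks = res.node_risk_scores(1, 24)
    assert risks.nunique() == 1
    c = sp.td_cindex(risks.to_numpy(),
                     *_ls_arrays(synthetic_table, 1, risks.index), 24)
    assert c == pytest.approx(0.5)


def _ls_arrays(table, slice_index, ids):
    ls = sp.landmark_survival(table, slice_index).subset(ids)
    return ls.time_from_landmark, ls.event


# ------------------------------------------------------------------ export
def test_dot_export_counts_and_labels(fitted_tree):
    dot = fitted_tree.to_dot()
    n_nodes = dot.count("[label=\"")  # node statements carry labels
    assert dot.count(" -> ") == len(fitted_tree.nodes) - 1
    root = fitted_tree.root
    assert f'n{root.node_id} [label="{root.node_id}/{root.n}/' in dot


def test_dot_marks_unreached_median():
    cohort, _ = sp.planted_split_fixture(40, 1.0, 1)
    table = sp.build_slice_table(cohort)
    res = sp.grow(table, sp.SPConfig(alpha=1e-15), cutoffs={})
    res.root.median_os_months = None  # a node whose KM never reaches 0.5
    assert f'label="1/{res.root.n}/NA"' in res.to_dot()
    assert json.loads(res.to_json())["nodes"][0]["median_os_months"] is None


def test_json_round_trip_preserves_skeleton(fitted_tree):
    doc = fitted_tree.to_json()
    skeleton = sp.SurvivalPathResults.skeleton_from_json(doc)
    assert skeleton == fitted_tree.skeleton()
    payload = json.loads(doc)
    assert payload["config"]["min_split"] == fitted_tree.config.min_split


def test_unsupported_export_format(fitted_tree):
    from survpath.exceptions import ConfigurationError
    with pytest.raises(ConfigurationError):
        fitted_tree.export_tree("svg")
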