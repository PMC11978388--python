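"""Cascading survival-path model.

The model converts a slice table into a tree of patient subgroups: one node
per (slice, subgroup). At each slice boundary a node either bifurcates on
the binarized covariate with the strongest univariate Cox association with
the node's landmark survival (Wald p below ``alpha``, both resulting
subnodes at least ``min_split`` patients) or passes its still-available
patients forward as a single child. Patients whose cells become unavailable
leave the tree silently. Every node records its sample size and the
Kaplan-Meier median overall survival measured from its own slice landmark;
a root-to-leaf route is a *survival path* summarizing one evolving
prognostic subgroup.

Usage follows the Model/Results idiom::

    model = SurvivalPath(slice_table, cutoffs=DEFAULT_CUTOFFS)
    res = model.fit()
    print(res.summary())
    res.to_dot()
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .cox import CoxScreenResult, cox_screen
from .exceptions import ConfigurationError, ModelConstructionError, ScoringError
from .timeslice import (
    AVAILABLE_STATUSES,
    Cutoff,
    DEFAULT_CUTOFFS,
    LandmarkSurvival,
    SliceTable,
    binarize,
    landmark_survival,
)


@dataclass(frozen=True)
class SPConfig:
    """Growth hyperparameters.

    ``alpha`` is the split significance threshold; ``min_split`` the minimum
    size of each resulting subnode; ``candidate_variables`` restricts the
    screened covariates (default: every binarizable dictionary variable).
    """

    alpha: float = 0.05
    min_split: int = 15
    n_slices: int = 9
    candidate_variables: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0,1), got {self.alpha}")
        if self.min_split < 2:
            raise ConfigurationError(f"min_split must be >= 2, got {self.min_split}")


@dataclass
class SPNode:
    """One subgroup at one slice."""

    node_id: int
    slice_index: int
    patient_ids: tuple[str, ...]
    parent_id: int | None = None
    split_variable: str | None = None  # set on the parent when it bifurcates
    children: tuple[int, ...] = ()
    median_os_months: float | None = None  # None encodes "not reached"
    screen: CoxScreenResult | None = None

    @property
    def n(self) -> int:
        return len(self.patient_ids)

    @property
    def is_leaf(self) -> bool:
        return not self.children


def km_median(times: np.ndarray, events: np.ndarray) -> float | None:
    """Kaplan-Meier median: smallest time with S(t) <= 0.5, else None.

    None encodes the "median not reached" condition.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=int))
    med = kmf.median_survival_time_
    return None if np.isinf(med) else float(med)


def select_split(
    node_patients: Sequence[str],
    slice_index: int,
    bin_grid: pd.DataFrame,
    ls: LandmarkSurvival,
    next_available: Sequence[str] | None,
    config: SPConfig,
) -> tuple[str, CoxScreenResult] | None:
    """Choose the bifurcation variable for a node, or None.

    A candidate qualifies when its univariate Cox fit on the node's landmark
    survival is finite with Wald p < alpha and both level subsets - measured
    on the patients that remain available at the next slice - reach
    ``min_split``. The winner has minimal p; ties break by larger |log HR|,
    then lexicographic name.
    """
    ls_node = ls.subset(node_patients)
    if len(ls_node) < 2 * config.min_split:
        return None
    slice_bin = bin_grid.xs(slice_index, level="slice_index")
    feats = slice_bin.loc[list(ls_node.patient_ids)]
    next_ids = list(next_available) if next_available is not None else []
    next_feats = slice_bin.loc[next_ids] if next_ids else None

    candidates = config.candidate_variables or tuple(bin_grid.columns)
    best: tuple[float, float, str, CoxScreenResult] | None = None
    for name in sorted(candidates):
        xcol = feats[name].to_numpy()
        if np.isnan(xcol).any():
            continue
        if next_feats is None:
            continue
        x_next = next_feats[name].to_numpy()
        n_adv = int(np.nansum(x_next == 1))
        n_non = int(np.nansum(x_next == 0))
        if n_adv < config.min_split or n_non < config.min_split:
            continue
        res = cox_screen(xcol, ls_node.time_from_landmark, ls_node.event, name)
        if not res.eligible or not np.isfinite(res.p_value):
            continue
        if res.p_value >= config.alpha:
            continue
        key = (res.p_value, -abs(res.coefficient), name)
        if best is None or key < (best[0], best[1], best[2]):
            best = (res.p_value, -abs(res.coefficient), name, res)
    if best is None:
        return None
    return best[2], best[3]


class SurvivalPath:
    """Survival-path model specification bound to a slice table.

    Parameters
    ----------
    slice_table : consolidated patients x slices covariate grid.
    cutoffs : binarization rules per non-binary variable (1 = adverse).
    config : growth hyperparameters.
    """

    def __init__(
        self,
        slice_table: SliceTable,
        cutoffs: Mapping[str, Cutoff] | None = None,
        config: SPConfig | None = None,
    ):
        self.slice_table = slice_table
        self.cutoffs = dict(cutoffs if cutoffs is not None else DEFAULT_CUTOFFS)
        self.config = config or SPConfig()
        if self.config.n_slices > slice_table.scheme.n_slices:
            raise ConfigurationError(
                "config.n_slices exceeds the slice table's scheme")

    def fit(self) -> "SurvivalPathResults":
        """Grow the tree breadth-first across slices. Deterministic."""
        table, config = self.slice_table, self.config
        variables = list(config.candidate_variables) if config.candidate_variables \
            else table.variables
        bin_grid = binarize(table, self.cutoffs, variables)
        ls_by_slice = {s: landmark_survival(table, s)
                       for s in range(1, config.n_slices + 1)}
        # only patients in a slice's landmark risk set take part at that slice
        risk_ids = {s: set(ls.patient_ids) for s, ls in ls_by_slice.items()}

        root_ids = tuple(pid for pid in table.patient_ids if pid in risk_ids[1])
        if not root_ids:
            raise ModelConstructionError("no patient has an available first slice")

        nodes: dict[int, SPNode] = {}
        next_id = 1

        def new_node(slice_index: int, ids: tuple[str, ...],
                     parent: int | None) -> SPNode:
            nonlocal next_id
            ls_node = ls_by_slice[slice_index].subset(ids)
            node = SPNode(
                node_id=next_id, slice_index=slice_index, patient_ids=ids,
                parent_id=parent,
                median_os_months=km_median(ls_node.time_from_landmark,
                                           ls_node.event) if len(ls_node) else None,
            )
            nodes[next_id] = node
            next_id += 1
            return node

        current = [new_node(1, root_ids, None)]
        slice_bin_cache = {s: bin_grid.xs(s, level="slice_index")
                           for s in range(1, config.n_slices + 1)}
        for s in range(1, config.n_slices):
            nxt: list[SPNode] = []
            for node in current:
                avail_next = tuple(pid for pid in node.patient_ids
                                   if pid in risk_ids[s + 1])
                if not avail_next:
                    continue  # path ends; patients left silently
                choice = select_split(node.patient_ids, s, bin_grid,
                                      ls_by_slice[s], avail_next, config)
                if choice is not None:
                    var, screen = choice
                    xvals = slice_bin_cache[s][var]
                    adverse = tuple(p for p in avail_next if xvals[p] == 1)
                    non_adverse = tuple(p for p in avail_next if xvals[p] == 0)
                    node.split_variable = var
                    node.screen = screen
                    child_a = new_node(s + 1, adverse, node.node_id)
                    child_b = new_node(s + 1, non_adverse, node.node_id)
                    node.children = (child_a.node_id, child_b.node_id)
                    nxt.extend([child_a, child_b])
                else:
                    child = new_node(s + 1, avail_next, node.node_id)
                    node.children = (child.node_id,)
                    nxt.append(child)
            current = nxt
        return SurvivalPathResults(self, nodes, bin_grid, ls_by_slice)


class SurvivalPathResults:
    """Fitted survival-path tree with node statistics and scoring."""

    def __init__(self, model: SurvivalPath, nodes: dict[int, SPNode],
                 bin_grid: pd.DataFrame,
                 ls_by_slice: dict[int, LandmarkSurvival]):
        self.model = model
        self.nodes = nodes
        self._bin_grid = bin_grid
        self._ls_by_slice = ls_by_slice
        self._km_cache: dict[int, KaplanMeierFitter] = {}
        # routing caches keyed by the table being scored (training table and
        # any bound external table)
        self._tables: dict[int, tuple[SliceTable, pd.DataFrame]] = {
            id(model.slice_table): (model.slice_table, bin_grid)}
        self._assign_cache: dict[tuple[int, int], dict[str, int | None]] = {}

    # -- structure ---------------------------------------------------------
    @property
    def root(self) -> SPNode:
        return self.nodes[1]

    @property
    def config(self) -> SPConfig:
        return self.model.config

    def nodes_at_slice(self, slice_index: int) -> list[SPNode]:
        return [n for n in self.nodes.values() if n.slice_index == slice_index]

    @property
    def leaves(self) -> list[SPNode]:
        return [n for n in self.nodes.values() if n.is_leaf]

    @property
    def n_paths(self) -> int:
        """Number of distinct root-to-leaf survival paths."""
        return len(self.leaves)

    # -- scoring -----------------------------------------------------------
    def _resolve_table(self, table: SliceTable | None) -> tuple[SliceTable, pd.DataFrame]:
        if table is None:
            table = self.model.slice_table
        key = id(table)
        if key not in self._tables:
            grid = binarize(table, self.model.cutoffs,
                            list(self._bin_grid.columns))
            self._tables[key] = (table, grid)
        return self._tables[key]

    def assign_to_node(self, patient_id: str, slice_index: int,
                       table: SliceTable | None = None) -> int | None:
        """Route a patient down the recorded splits to its node at a slice.

        Works for training and held-out patients alike (pass the held-out
        ``table``); returns None when the patient is unavailable at any
        slice along the route or the tree has no node there.
        """
        table, bin_grid = self._resolve_table(table)
        if patient_id not in table.status.index:
            raise ScoringError(f"unknown patient {patient_id!r}")
        node = self.root
        if table.cell_status(patient_id, 1) not in AVAILABLE_STATUSES:
            return None
        for s in range(1, slice_index):
            if table.cell_status(patient_id, s + 1) not in AVAILABLE_STATUSES:
                return None
            if not node.children:
                return None
            if node.split_variable is None:
                node = self.nodes[node.children[0]]
            else:
                x = bin_grid.at[(patient_id, s), node.split_variable]
                if np.isnan(x):
                    return None
                node = self.nodes[node.children[0] if x == 1 else node.children[1]]
        return node.node_id

    def _node_km(self, node_id: int) -> KaplanMeierFitter | None:
        """Training KM curve of a node's landmark survival (cached)."""
        if node_id not in self._km_cache:
            node = self.nodes[node_id]
            ls = self._ls_by_slice[node.slice_index].subset(node.patient_ids)
            if len(ls) == 0:
                self._km_cache[node_id] = None
            else:
                kmf = KaplanMeierFitter()
                kmf.fit(ls.time_from_landmark, ls.event)
                self._km_cache[node_id] = kmf
        return self._km_cache[node_id]

    def node_survival_at(self, node_id: int, horizon_months: float) -> float:
        kmf = self._node_km(node_id)
        if kmf is None:
            return np.nan
        return float(kmf.predict(horizon_months))

    def node_risk_scores(
        self,
        slice_index: int,
        horizon_months: float,
        patient_ids: Sequence[str] | None = None,
        min_subgroup: int = 3,
        table: SliceTable | None = None,
    ) -> pd.Series:
        """Per-patient risk 1 - S_node(horizon) at a prediction slice.

        ``patient_ids`` defaults to the training patients present at the
        slice; held-out patients are scored by passing their ``table``.
        Node survival is always the training Kaplan-Meier estimate.
        Patients falling in subgroups smaller than ``min_subgroup`` (counted
        within the evaluated sample) receive no score and are dropped from
        the result.
        """
        if patient_ids is None:
            ids = [p for node in self.nodes_at_slice(slice_index)
                   for p in node.patient_ids]
        else:
            ids = list(patient_ids)
        resolved, _ = self._resolve_table(table)
        cache = self._assign_cache.setdefault((id(resolved), slice_index), {})
        assignment = {}
        for pid in ids:
            if pid not in cache:
                cache[pid] = self.assign_to_node(pid, slice_index, resolved)
            if cache[pid] is not None:
                assignment[pid] = cache[pid]
        counts: dict[int, int] = {}
        for nid in assignment.values():
            counts[nid] = counts.get(nid, 0) + 1
        keep = {p: nid for p, nid in assignment.items()
                if counts[nid] >= min_subgroup}
        risk_by_node = {nid: 1.0 - self.node_survival_at(nid, horizon_months)
                        for nid in set(keep.values())}
        out = pd.Series({p: risk_by_node[nid] for p, nid in keep.items()},
                        dtype=float)
        return out.dropna()

    # -- presentation ------------------------------------------------------
    def summary(self) -> pd.DataFrame:
        """Node table: id, slice, n, split variable, Cox stats, median OS."""
        rows = []
        for node in sorted(self.nodes.values(), key=lambda n: n.node_id):
            rows.append({
                "node_id": node.node_id,
                "slice_index": node.slice_index,
                "parent_id": node.parent_id,
                "n": node.n,
                "split_variable": node.split_variable,
                "hazard_ratio": node.screen.hazard_ratio if node.screen else np.nan,
                "p_value": node.screen.p_value if node.screen else np.nan,
                "median_os_months": (np.nan if node.median_os_months is None
                                     else node.median_os_months),
            })
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        head = (f"SurvivalPathResults: {len(self.nodes)} nodes, "
                f"{self.n_paths} paths, alpha={self.config.alpha}, "
                f"min_split={self.config.min_split}\n")
        return head + self.summary().to_string(index=False)

    @staticmethod
    def _median_label(median: float | None) -> str:
        return "NA" if median is None else f"{median:.1f}"

    def to_dot(self) -> str:
        """Graphviz DOT rendering; node labels are "id/n/medianOS"."""
        lines = ["digraph survival_path {", "  rankdir=TB;",
                 "  node [shape=box, fontsize=10];"]
        for node in sorted(self.nodes.values(), key=lambda n: n.node_id):
            label = f"{node.node_id}/{node.n}/{self._median_label(node.median_os_months)}"
            lines.append(f'  n{node.node_id} [label="{label}"];')
        for node in sorted(self.nodes.values(), key=lambda n: n.node_id):
            if node.split_variable is not None and len(node.children) == 2:
                a, b = node.children
                lines.append(f'  n{node.node_id} -> n{a} '
                             f'[label="{node.split_variable}: adverse"];')
                lines.append(f'  n{node.node_id} -> n{b} '
                             f'[label="{node.split_variable}: non-adverse"];')
            else:
                for c in node.children:
                    lines.append(f"  n{node.node_id} -> n{c};")
        lines.append("}")
        return "\n".join(lines)

    def to_json(self) -> str:
        payload = {
            "config": {
                "alpha": self.config.alpha,
                "min_split": self.config.min_split,
                "n_slices": self.config.n_slices,
            },
            "cutoffs": {k: {"threshold": c.threshold,
                            "adverse_direction": c.adverse_direction}
                        for k, c in self.model.cutoffs.items()},
            "nodes": [
                {
                    "node_id": n.node_id,
                    "slice_index": n.slice_index,
                    "parent_id": n.parent_id,
                    "n": n.n,
                    "patient_ids": list(n.patient_ids),
                    "split_variable": n.split_variable,
                    "children": list(n.children),
                    "median_os_months": n.median_os_months,
                }
                for n in sorted(self.nodes.values(), key=lambda x: x.node_id)
            ],
        }
        return json.dumps(payload, indent=2)

    def export_tree(self, fmt: str) -> str:
        """Render the tree as "dot" or "json"."""
        if fmt == "dot":
            return self.to_dot()
        if fmt == "json":
            return self.to_json()
        raise ConfigurationError(f"unsupported export format {fmt!r}")

    @staticmethod
    def skeleton_from_json(document: str) -> dict:
        """Parse an exported tree back into a comparable skeleton dict."""
        payload = json.loads(document)
        return {
            "config": payload["config"],
            "nodes": {
                n["node_id"]: (n["slice_index"], n["parent_id"], n["n"],
                               n["split_variable"], tuple(n["children"]),
                               n["median_os_months"])
                for n in payload["nodes"]
            },
        }

    def skeleton(self) -> dict:
        return self.skeleton_from_json(self.to_json())


def grow(slice_table: SliceTable, config: SPConfig | None = None,
         cutoffs: Mapping[str, Cutoff] | None = None) -> SurvivalPathResults:
    """Functional entry point: fit a survival-path tree on a slice table."""
    return SurvivalPath(slice_table, cutoffs=cutoffs, config=config).fit()
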