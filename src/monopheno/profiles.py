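"""Phenotype profiles: OP rule engine, donor clustering, component profiles.

Three layers of donor phenotyping sit on top of the marker quantitation:

* **OP profiles** — per (donor, subpopulation) labels assigned by a rule
  table of qualitative bin conjunctions (``CD49d_bri^hi AND CD162_bri^hi
  -> OP-01``); rules are data (``data/op_rules.json``), evaluated
  most-specific first.
* **Global phenotypes I-IV** — communities of donors on the bipartite
  donor/profile graph, computed by deterministic greedy modularity on the
  shared-profile donor projection; singleton communities are reported as
  non-clustered.
* **Component profiles a-e** — per-donor detection of the component
  subpopulations of sm14+16+ cells in CD43/CD49d/CD62L space (boxes over a
  neg/dim/hi level grid), mapped onto the published profile letters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Union

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ConfigurationError, InsufficientDataError, ValidationError
from .events import EventTable
from .quantitation import MarkerSummary

UNCLASSIFIED = "unclassified"
NON_CLUSTERED = "non-clustered"

#: component subpopulations of sm14+16+ cells in CD43/CD49d/CD62L space
COMPONENTS = ("P1", "Pint", "P2", "P3", "E")

#: marker-level boxes per component (levels: neg / dim / hi per marker)
COMPONENT_BOXES: Dict[str, Dict[str, Set[str]]] = {
    # CD43+ CD49d+ CD62Lhi
    "P1": {"CD43": {"hi"}, "CD49d": {"hi"}, "CD62L": {"hi"}},
    # intermediate between P1 and P2, variable CD43
    "Pint": {"CD43": {"dim"}, "CD49d": {"hi"}, "CD62L": {"hi"}},
    # CD43dim/neg CD49dhi CD62Ldim
    "P2": {"CD43": {"neg", "dim"}, "CD49d": {"hi"}, "CD62L": {"dim"}},
    # CD43neg CD49ddim CD62Lhi
    "P3": {"CD43": {"neg"}, "CD49d": {"dim"}, "CD62L": {"hi"}},
    # donor-10 major population: CD43+ CD49dhi CD62Ldim
    "E": {"CD43": {"hi"}, "CD49d": {"hi"}, "CD62L": {"dim"}},
}

#: component sets defining each profile letter (exact-match semantics; the
#: profile-e minor population falls inside the P1 box)
VISNE_PROFILE_MAP: Dict[FrozenSet[str], str] = {
    frozenset({"P1", "P2", "P3"}): "a",
    frozenset({"P2", "P3"}): "b",
    frozenset({"P1", "Pint", "P2"}): "c",
    frozenset({"P1", "P2"}): "d",
    frozenset({"E", "P1"}): "e",
}

_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")


# ---------------------------------------------------------------------------
# OP rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OPClause:
    marker: str
    mfi: Optional[FrozenSet[str]]   # admissible MFI bins; None = any
    pct: Optional[FrozenSet[str]]   # admissible percent bins; None = any

    def satisfied_by(self, mfi_bin: str, pct_bin: str) -> bool:
        if self.mfi is not None and mfi_bin not in self.mfi:
            return False
        if self.pct is not None and pct_bin not in self.pct:
            return False
        return True


@dataclass(frozen=True)
class OPRule:
    op_id: str
    subpopulation: str
    clauses: tuple
    priority: int = 0
    placeholder: bool = False

    @property
    def markers(self) -> Set[str]:
        return {c.marker for c in self.clauses}


def load_op_rules(path=None) -> List[OPRule]:
    """Load the rule table (packaged default or an external JSON file)."""
    if path is None:
        raw = json.loads(resources.files("monopheno.data")
                         .joinpath("op_rules.json").read_text())
    else:
        with open(path, "r", encoding="utf-8") as fh:
            raw = json.load(fh)
    rules = []
    seen = set()
    for entry in raw["rules"]:
        op_id = entry["op_id"]
        if op_id in seen:
            raise ConfigurationError(f"duplicate rule id {op_id!r}")
        seen.add(op_id)
        clauses = tuple(
            OPClause(marker=c["marker"],
                     mfi=frozenset(c["mfi"]) if c.get("mfi") else None,
                     pct=frozenset(c["pct"]) if c.get("pct") else None)
            for c in entry["clauses"])
        placeholder = bool(entry.get("placeholder", False))
        if not clauses and not placeholder:
            raise ConfigurationError(f"rule {op_id!r} has no clauses")
        rules.append(OPRule(op_id=op_id, subpopulation=entry["subpopulation"],
                            clauses=clauses,
                            priority=int(entry.get("priority", len(clauses))),
                            placeholder=placeholder))
    return rules


def _rule_order(rule: OPRule):
    return (-rule.priority, rule.op_id)


def assign_op_profile(summaries: Sequence[MarkerSummary],
                      rules: Sequence[OPRule]) -> str:
    """Highest-priority rule satisfied by the bins of one (donor,
    subpopulation); ``unclassified`` when none matches."""
    if not summaries:
        raise ValidationError("assign_op_profile requires at least one summary")
    subpops = {s.subpopulation for s in summaries}
    if len(subpops) != 1:
        raise ValidationError(f"summaries span several subpopulations: {sorted(subpops)}")
    subpop = subpops.pop()
    bins = {}
    for s in summaries:
        if s.mfi_bin is None or s.percent_bin is None:
            raise ValidationError(f"summary for {s.marker!r} has no bins assigned")
        bins[s.marker] = (s.mfi_bin, s.percent_bin)

    applicable = sorted((r for r in rules
                         if r.subpopulation == subpop and r.clauses),
                        key=_rule_order)
    missing = sorted(set().union(*(r.markers for r in applicable)) - set(bins)) \
        if applicable else []
    if missing:
        raise ValidationError(f"missing marker(s) for rule evaluation: {', '.join(missing)}")
    for rule in applicable:
        if all(c.satisfied_by(*bins[c.marker]) for c in rule.clauses):
            return rule.op_id
    return UNCLASSIFIED


class OPRuleClassifier(BaseEstimator):
    """Rule-table classifier with a scikit-learn estimator surface.

    ``fit`` loads/sorts the rule table; ``predict`` maps each element of a
    sequence of per-(donor, subpopulation) summary lists onto an OP id.
    """

    def __init__(self, rules: Optional[Sequence[OPRule]] = None):
        self.rules = rules

    def fit(self, X=None, y=None) -> "OPRuleClassifier":
        rules = self.rules if self.rules is not None else load_op_rules()
        self.rules_ = sorted(rules, key=_rule_order)
        return self

    def predict(self, X: Sequence[Sequence[MarkerSummary]]) -> List[str]:
        if not hasattr(self, "rules_"):
            self.fit()
        return [assign_op_profile(summaries, self.rules_) for summaries in X]


# ---------------------------------------------------------------------------
# donor-profile graph and global phenotypes
# ---------------------------------------------------------------------------

@dataclass
class ProfileGraph:
    """Bipartite donor/profile graph with donor communities."""

    graph: nx.Graph                   # bipartite: donors + profile ids
    donor_projection: nx.Graph        # donors, weighted by shared profiles
    communities: List[Set]            # multi-donor communities, ordered
    donor_cluster: Dict[object, str]  # donor -> roman label or non-clustered

    def community_of(self, donor) -> Set:
        for community in self.communities:
            if donor in community:
                return set(community)
        return {donor}


class DonorPhenotypeClusterer(BaseEstimator):
    """Greedy-modularity clustering of donors by shared OP profiles.

    ``fit`` takes a mapping donor -> iterable of profile ids, builds the
    bipartite graph, projects it onto donors (edge weight = number of
    shared profiles) and extracts communities with deterministic greedy
    modularity maximisation; ties are broken by the sorted node order used
    to build the graph. Multi-donor communities are labelled with roman
    numerals by their smallest donor id; singletons are non-clustered.
    """

    def __init__(self, resolution: float = 1.0):
        self.resolution = resolution

    def fit(self, X: Mapping[object, Iterable[str]], y=None) -> "DonorPhenotypeClusterer":
        if not X:
            raise ValidationError("empty donor->profile assignments")
        donors = sorted(X, key=str)
        if len(donors) < 2:
            raise ValidationError("clustering requires at least 2 donors")
        graph = nx.Graph()
        graph.add_nodes_from(donors, bipartite=0)
        for donor in donors:
            for op in sorted(set(X[donor])):
                graph.add_node(op, bipartite=1)
                graph.add_edge(donor, op)

        projection = nx.bipartite.weighted_projected_graph(graph, donors)
        if projection.number_of_edges() == 0:
            communities: List[Set] = []
        else:
            raw = nx.community.greedy_modularity_communities(
                projection, weight="weight", resolution=self.resolution)
            communities = [set(c) for c in raw if len(c) >= 2]
        def _min_donor(community):
            try:
                return (0, min(community), "")
            except TypeError:
                return (1, 0, str(min(community, key=str)))

        communities.sort(key=_min_donor)

        donor_cluster = {d: NON_CLUSTERED for d in donors}
        for i, community in enumerate(communities):
            label = _ROMAN[i] if i < len(_ROMAN) else f"C{i + 1}"
            for donor in community:
                donor_cluster[donor] = label
        self.graph_ = graph
        self.result_ = ProfileGraph(graph=graph, donor_projection=projection,
                                    communities=communities,
                                    donor_cluster=donor_cluster)
        self.labels_ = donor_cluster
        return self


def cluster_global_phenotypes(assignments: Mapping[object, Iterable[str]],
                              resolution: float = 1.0) -> ProfileGraph:
    """Cluster donors into global monocyte phenotypes from their OP sets."""
    return DonorPhenotypeClusterer(resolution=resolution).fit(assignments).result_


# ---------------------------------------------------------------------------
# component subpopulations and profile letters
# ---------------------------------------------------------------------------

@dataclass
class ComponentFlags:
    """Presence flags and event fractions of the component subpopulations."""

    flags: Dict[str, bool]
    fractions: Dict[str, float]
    n_events: int


def default_component_cutoffs(positivity_thresholds: Mapping[str, float],
                              dim_mode: float = 300.0,
                              hi_mode: float = 3000.0,
                              ) -> Dict[str, tuple]:
    """Per-marker (neg, dim/hi) level cutoffs: negative below the isotype
    positivity threshold; dim vs hi split at the geometric midpoint of the
    two configured intensity modes."""
    split = float(np.sqrt(dim_mode * hi_mode))
    return {m: (float(t), split) for m, t in positivity_thresholds.items()}


def _levels(values: np.ndarray, neg_cut: float, hi_cut: float) -> np.ndarray:
    out = np.full(len(values), "dim", dtype=object)
    out[values < neg_cut] = "neg"
    out[values >= hi_cut] = "hi"
    return out


def detect_component_subpopulations(events: Union[EventTable, pd.DataFrame],
                                    thresholds: Mapping[str, tuple],
                                    min_fraction: float = 0.05,
                                    min_events: int = 30) -> ComponentFlags:
    """Flag each component present iff the fraction of sm14+16+ events
    inside its CD43/CD49d/CD62L box reaches ``min_fraction``."""
    df = events.data if isinstance(events, EventTable) else events
    n = len(df)
    if n < min_events:
        raise InsufficientDataError(
            f"component detection needs >= {min_events} events, got {n}")
    markers = ("CD43", "CD49d", "CD62L")
    missing = [m for m in markers if m not in df.columns or m not in thresholds]
    if missing:
        raise ValidationError(f"missing marker column/threshold: {', '.join(missing)}")
    levels = {m: _levels(df[m].to_numpy(dtype=float), *thresholds[m]) for m in markers}
    fractions = {}
    for comp, box in COMPONENT_BOXES.items():
        inside = np.ones(n, dtype=bool)
        for marker, allowed in box.items():
            inside &= np.isin(levels[marker], list(allowed))
        fractions[comp] = float(inside.mean())
    flags = {comp: fractions[comp] >= min_fraction for comp in COMPONENT_BOXES}
    return ComponentFlags(flags=flags, fractions=fractions, n_events=n)


def assign_visne_profile(flags: Union[ComponentFlags, Mapping[str, bool]]) -> str:
    """Map component presence flags onto the profile letters a-e
    (exact-set semantics); any other combination is unclassified."""
    table = flags.flags if isinstance(flags, ComponentFlags) else dict(flags)
    present = frozenset(k for k, v in table.items() if v)
    return VISNE_PROFILE_MAP.get(present, UNCLASSIFIED)


# ---------------------------------------------------------------------------
# published reference inputs
# ---------------------------------------------------------------------------

def load_table1_assignments() -> Dict[int, List[str]]:
    """Published donor -> OP-profile assignments for the connectivity graph."""
    raw = json.loads(resources.files("monopheno.data")
                     .joinpath("table1_donor_profiles.json").read_text())
    return {int(k): list(v) for k, v in raw["assignments"].items()}


def load_table2_groups() -> Dict[str, List[int]]:
    """Published profile letter -> donor list for the component profiles."""
    raw = json.loads(resources.files("monopheno.data")
                     .joinpath("table2_donor_groups.json").read_text())
    return {k: list(v) for k, v in raw["profiles"].items()}


@dataclass
class PhenotypeAssignment:
    """Complete phenotype record of one donor."""

    donor_id: str
    op_by_subpop: Dict[str, str] = field(default_factory=dict)
    global_phenotype: str = NON_CLUSTERED
    visne_profile: str = UNCLASSIFIED
    component_flags: Dict[str, bool] = field(default_factory=dict)
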