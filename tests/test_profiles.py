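"""OP rule engine, donor-profile clustering, component profiles."""

import itertools

import numpy as np
import pytest

from monopheno import (MarkerSummary, ValidationError, assign_op_profile,
                       assign_visne_profile, cluster_global_phenotypes,
                       default_component_cutoffs,
                       detect_component_subpopulations, load_op_rules,
                       load_table1_assignments, load_table2_groups,
                       simulate_component_events)
from monopheno.defaults import VISNE_WEIGHTS
from monopheno.profiles import UNCLASSIFIED, VISNE_PROFILE_MAP, _rule_order

RULES = load_op_rules()

CUTS = default_component_cutoffs({"CD43": 76.0, "CD49d": 76.0, "CD62L": 76.0})


def _summary(subpop, marker, mfi_bin, pct_bin):
    return MarkerSummary(donor_id="1", subpopulation=subpop, marker=marker,
                         mfi_mab=0, mfi_ig=0, specific_mfi=100,
                         percent_positive=80, n_events=500, flag_low_n=False,
                         mfi_bin=mfi_bin, percent_bin=pct_bin)


def _summaries(subpop, bins):
    return [_summary(subpop, m, mfi, pct) for m, (mfi, pct) in bins.items()]


class TestOPRules:
    def test_cd62l_med_sets_donor_apart(self):
        # bright adhesion expression with intermediate-MFI CD62L defines the
        # second profile of the classical small subset
        bins = {"CD49d": ("bri", "hi"), "CD162": ("bri", "hi"),
                "CD62L": ("med", "hi"), "CD43": ("med", "hi")}
        assert assign_op_profile(_summaries("sm14+16neg", bins), RULES) == "OP-02"

    def test_all_negative_bins_unclassified(self):
        bins = {m: ("neg", "neg") for m in ("CD49d", "CD162", "CD62L", "CD43")}
        assert assign_op_profile(_summaries("sm14+16neg", bins), RULES) == \
            UNCLASSIFIED

    def test_missing_marker_listed_in_error(self):
        bins = {"CD49d": ("bri", "hi")}
        with pytest.raises(ValidationError, match="CD162"):
            assign_op_profile(_summaries("sm14+16neg", bins), RULES)

    def test_mixed_subpopulations_rejected(self):
        mixed = [_summary("sm14+16neg", "CD49d", "bri", "hi"),
                 _summary("la14+16neg", "CD43", "dim", "hi")]
        with pytest.raises(ValidationError):
            assign_op_profile(mixed, RULES)

    @pytest.mark.parametrize("subpop", ["sm14+16neg", "la14+16neg", "sm14+16+",
                                        "la14+16+", "sm14dim16+",
                                        "sm14dim16neg"])
    def test_random_bins_match_brute_force_evaluation(self, subpop):
        mfi_levels = ("neg", "dim", "med", "bri")
        pct_levels = ("neg", "lo", "int", "hi")
        markers = ("CD49d", "CD162", "CD62L", "CD43")
        applicable = sorted((r for r in RULES
                             if r.subpopulation == subpop and r.clauses),
                            key=_rule_order)

        def oracle(bins):
            for rule in applicable:  # already in priority order
                ok = True
                for clause in rule.clauses:
                    mfi, pct = bins[clause.marker]
                    if clause.mfi is not None and mfi not in clause.mfi:
                        ok = False
                    if clause.pct is not None and pct not in clause.pct:
                        ok = False
                if ok:
                    return rule.op_id
            return UNCLASSIFIED

        rng = np.random.default_rng(hash(subpop) % 2 ** 31)
        for _ in range(300):
            bins = {m: (mfi_levels[rng.integers(4)], pct_levels[rng.integers(4)])
                    for m in markers}
            assert assign_op_profile(_summaries(subpop, bins), RULES) == \
                oracle(bins)

    def test_specificity_priority(self):
        # a donor satisfying both the base profile and its CD43-low variant
        # must receive the more specific variant
        bins = {"CD49d": ("bri", "hi"), "CD162": ("bri", "hi"),
                "CD43": ("dim", "lo"), "CD62L": ("bri", "hi")}
        assert assign_op_profile(_summaries("sm14+16neg", bins), RULES) == "OP-03"


class TestDonorClustering:
    def test_identical_profiles_cluster_together(self):
        assignments = {1: {"OP-01", "OP-10"}, 2: {"OP-01", "OP-10"},
                       3: {"OP-04", "OP-11"}, 4: {"OP-04", "OP-11"}}
        pg = cluster_global_phenotypes(assignments)
        assert pg.donor_cluster[1] == pg.donor_cluster[2]
        assert pg.donor_cluster[3] == pg.donor_cluster[4]
        assert pg.donor_cluster[1] != pg.donor_cluster[3]

    def test_published_connectivity_table_recovers_cluster_one(self):
        pg = cluster_global_phenotypes(load_table1_assignments())
        assert pg.community_of(1) == {1, 2, 11, 12, 21}
        assert pg.donor_cluster[1] == "I"

    def test_disjoint_profiles_separate(self):
        assignments = {1: {"OP-01"}, 2: {"OP-01"}, 3: {"OP-33"}, 4: {"OP-33"}}
        pg = cluster_global_phenotypes(assignments)
        assert pg.donor_cluster[1] != pg.donor_cluster[3]

    def test_isolated_donor_non_clustered(self):
        assignments = {1: {"OP-01"}, 2: {"OP-01"}, 3: {"OP-50"}}
        pg = cluster_global_phenotypes(assignments)
        assert pg.donor_cluster[3] == "non-clustered"

    def test_determinism(self):
        assignments = load_table1_assignments()
        a = cluster_global_phenotypes(assignments)
        b = cluster_global_phenotypes(assignments)
        assert a.donor_cluster == b.donor_cluster

    def test_empty_assignments_rejected(self):
        with pytest.raises(ValidationError):
            cluster_global_phenotypes({})


class TestComponents:
    def test_mixture_without_p1_flags_b_pattern(self):
        events = simulate_component_events({"P2": 0.6, "P3": 0.4}, 4000, 1)
        flags = detect_component_subpopulations(events, CUTS)
        assert not flags.flags["P1"] and flags.flags["P2"] and flags.flags["P3"]
        assert assign_visne_profile(flags) == "b"

    def test_all_components_absent_unclassified(self):
        events = simulate_component_events({"P1": 1.0}, 1000, 1)
        # move every event out of all boxes by zeroing the channels
        events[["CD43", "CD49d", "CD62L"]] = 1.0
        flags = detect_component_subpopulations(events, CUTS)
        assert not any(flags.flags.values())
        assert assign_visne_profile(flags) == UNCLASSIFIED

    def test_mixture_fractions_recovered(self):
        weights = {"P1": 0.5, "P2": 0.3, "P3": 0.2}
        events = simulate_component_events(weights, 10_000, 7)
        flags = detect_component_subpopulations(events, CUTS)
        assert all(flags.flags[c] for c in weights)
        for comp, w in weights.items():
            sd = np.sqrt(w * (1 - w) / len(events))
            assert abs(flags.fractions[comp] - w) < 4 * sd + 0.01

    def test_adding_in_box_events_never_clears_flag(self):
        events = simulate_component_events({"P1": 0.9, "P2": 0.1}, 2000, 3)
        flags = detect_component_subpopulations(events, CUTS)
        more_p2 = simulate_component_events({"P2": 1.0}, 2000, 4)
        import pandas as pd
        combined = pd.concat([events, more_p2], ignore_index=True)
        flags2 = detect_component_subpopulations(combined, CUTS)
        assert flags2.flags["P2"] >= flags.flags["P2"]

    def test_visne_truth_table_exhaustive(self):
        components = ("P1", "Pint", "P2", "P3", "E")
        for present in itertools.chain.from_iterable(
                itertools.combinations(components, k) for k in range(6)):
            flags = {c: c in present for c in components}
            expected = VISNE_PROFILE_MAP.get(frozenset(present), UNCLASSIFIED)
            assert assign_visne_profile(flags) == expected

    def test_published_groups_recovered_across_seeds(self):
        groups = load_table2_groups()
        for seed in (1, 2, 3):
            for letter, donors in groups.items():
                for donor in donors:
                    events = simulate_component_events(
                        VISNE_WEIGHTS[letter], 5000, 1000 * seed + donor)
                    flags = detect_component_subpopulations(events, CUTS)
                    assert assign_visne_profile(flags) == letter, (seed, donor)
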