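"""Sequential gating: individual gates, end-to-end recovery, invariants."""

import numpy as np
import pandas as pd
import pytest

from monopheno import (EventTable, GateConfig, InsufficientDataError,
                       ValidationError, classify_cd14_cd16, exclude_doublets,
                       exclude_lineage, default_gate_config, run_gating,
                       select_cd14, split_scatter_clusters)
from monopheno.gating import UNASSIGNED, GATE_LABELS
from monopheno.panel import SCATTER_COLUMNS
from monopheno.simulate import SUBPOPULATIONS, generate_donor

from conftest import fixed_fraction_config

EXPLICIT = GateConfig(lineage_threshold=100.0, cd14_threshold=100.0,
                      cd14_dim_boundary=1000.0, cd16_threshold=100.0)


def _scatter_frame(n, rng, fsc=1e5, ssc=6e4, extra=None):
    df = pd.DataFrame({
        "FSC-A": fsc * np.exp(0.1 * rng.standard_normal(n)),
        "SSC-A": ssc * np.exp(0.1 * rng.standard_normal(n)),
        "FSC-W": 7e4 * np.exp(0.05 * rng.standard_normal(n)),
    })
    df["FSC-H"] = 0.95 * df["FSC-A"] * np.exp(0.03 * rng.standard_normal(n))
    df["SSC-H"] = 0.95 * df["SSC-A"]
    df["SSC-W"] = 7e4 * np.exp(0.05 * rng.standard_normal(n))
    for col, val in (extra or {}).items():
        df[col] = val
    return df


class TestLineageAndCD14:
    def test_zero_lineage_signal_all_retained(self):
        df = _scatter_frame(50, np.random.default_rng(0), extra={"LIN": 0.0})
        assert exclude_lineage(df, EXPLICIT).all()

    def test_all_above_threshold_all_excluded(self):
        df = _scatter_frame(50, np.random.default_rng(0), extra={"LIN": 500.0})
        assert not exclude_lineage(df, EXPLICIT).any()

    def test_lineage_truth_fraction_recovered(self):
        cfg = fixed_fraction_config(seed=3, lineage_fraction=0.6)
        sample = generate_donor(cfg, 1, sets=[3])
        mask = exclude_lineage(sample.stained[3], default_gate_config(),
                               isotype=sample.isotype[3])
        n = len(mask)
        p_keep = 1.0 - 0.6 * (1.0 - cfg.doublet_rate) \
            - cfg.doublet_rate * (1 - 0.4 ** 2)  # doublets with a lymphocyte member
        sd = np.sqrt(n * p_keep * (1 - p_keep))
        assert abs(mask.sum() - n * p_keep) < 4 * sd + 0.01 * n

    def test_cd14_threshold_closed_below(self):
        df = _scatter_frame(3, np.random.default_rng(0),
                            extra={"CD14": [100.0, 99.999, 100.001]})
        df["CD14"] = [100.0, 99.999, 100.001]
        assert select_cd14(df, EXPLICIT).tolist() == [True, False, True]

    def test_all_zero_cd14_none_retained(self):
        df = _scatter_frame(20, np.random.default_rng(0), extra={"CD14": 0.0})
        assert not select_cd14(df, EXPLICIT).any()

    def test_monocyte_truth_events_retained(self, donor_sample):
        stained = donor_sample.stained[3]
        mask = select_cd14(stained, default_gate_config(),
                           isotype=donor_sample.isotype[3])
        mono = stained.truth.str.startswith(("sm", "la")).to_numpy()
        assert mask[mono].mean() > 0.999


class TestScatterSplit:
    def _two_modes(self, n_small=3000, n_large=400, seed=0):
        rng = np.random.default_rng(seed)
        small = _scatter_frame(n_small, rng, fsc=1e5, ssc=6e4)
        large = _scatter_frame(n_large, rng, fsc=2.2e5, ssc=1.1e5)
        df = pd.concat([small, large], ignore_index=True)
        truth = np.array(["small"] * n_small + ["large"] * n_large)
        return df, truth

    def test_well_separated_modes_recovered(self):
        df, truth = self._two_modes()
        labels, _ = split_scatter_clusters(df, EXPLICIT)
        assert (labels[truth == "small"] == "small").mean() >= 0.99
        assert (labels[truth == "large"] == "large").mean() >= 0.99

    def test_degenerate_scatter_all_small_with_warning(self):
        df = _scatter_frame(200, np.random.default_rng(0))
        for col in SCATTER_COLUMNS:
            df[col] = 1000.0
        labels, warnings = split_scatter_clusters(df, EXPLICIT)
        assert (labels == "small").all()
        assert any("degenerate" in w for w in warnings)

    def test_scaling_fsc_preserves_labels(self):
        df, _ = self._two_modes(seed=4)
        labels, _ = split_scatter_clusters(df, EXPLICIT)
        scaled = df.copy()
        for col in ("FSC-A", "FSC-H"):
            scaled[col] *= 2.0
        labels2, _ = split_scatter_clusters(scaled, EXPLICIT)
        assert (labels == labels2).mean() > 0.995

    def test_too_few_events_raises(self):
        df = _scatter_frame(50, np.random.default_rng(0))
        with pytest.raises(InsufficientDataError):
            split_scatter_clusters(df, EXPLICIT)


class TestDoubletExclusion:
    def _cluster(self, n=4000, doublet_rate=0.03, seed=0):
        rng = np.random.default_rng(seed)
        singlets = _scatter_frame(n, rng)
        n_doub = int(n * doublet_rate)
        a = _scatter_frame(n_doub, rng)
        b = _scatter_frame(n_doub, rng)
        doublets = pd.DataFrame({
            "FSC-A": a["FSC-A"] + b["FSC-A"],
            "FSC-H": np.maximum(a["FSC-H"], b["FSC-H"]),
            "FSC-W": 1.8 * (a["FSC-W"] + b["FSC-W"]) / 2,
            "SSC-A": a["SSC-A"] + b["SSC-A"],
            "SSC-H": np.maximum(a["SSC-H"], b["SSC-H"]),
            "SSC-W": 1.8 * (a["SSC-W"] + b["SSC-W"]) / 2,
        })
        df = pd.concat([singlets, doublets], ignore_index=True)
        truth = np.array(["singlet"] * n + ["doublet"] * n_doub)
        return df, truth

    def test_no_doublets_high_retention(self):
        df, _ = self._cluster(doublet_rate=0.0)
        assert exclude_doublets(df, EXPLICIT).mean() >= 0.99

    def test_doublet_recovery_with_low_singlet_loss(self):
        df, truth = self._cluster()
        mask = exclude_doublets(df, EXPLICIT)
        assert (~mask[truth == "doublet"]).mean() >= 0.90
        assert (~mask[truth == "singlet"]).mean() <= 0.05

    def test_duplication_stability(self):
        df, _ = self._cluster(n=500, seed=2)
        mask = exclude_doublets(df, EXPLICIT)
        doubled = pd.concat([df, df], ignore_index=True)
        mask2 = exclude_doublets(doubled, EXPLICIT)
        assert (mask2[:len(df)] == mask).all()
        assert (mask2[len(df):] == mask).all()

    def test_small_cluster_raises(self):
        df, _ = self._cluster(n=20)
        with pytest.raises(InsufficientDataError):
            exclude_doublets(df.iloc[:30], EXPLICIT)


class TestClassification:
    THR = {"cd14_dim_boundary": 1000.0, "cd16_threshold": 100.0}

    def _events(self, cd14, cd16):
        df = _scatter_frame(len(cd14), np.random.default_rng(0))
        df["CD14"] = cd14
        df["CD16"] = cd16
        return df

    def test_bright_cd14_no_cd16_is_classical_small(self):
        df = self._events([5000.0], [0.0])
        assert classify_cd14_cd16(df, "small", self.THR, EXPLICIT)[0] == "sm14+16neg"

    def test_boundary_conventions(self):
        df = self._events([999.99, 1000.0], [150.0, 150.0])
        labels = classify_cd14_cd16(df, "small", self.THR, EXPLICIT)
        assert labels.tolist() == ["sm14dim16+", "sm14+16+"]

    def test_large_cluster_dim_events_unassigned(self):
        df = self._events([500.0, 5000.0], [0.0, 0.0])
        labels = classify_cd14_cd16(df, "large", self.THR, EXPLICIT)
        assert labels.tolist() == [UNASSIGNED, "la14+16neg"]

    def test_invalid_cluster_rejected(self):
        with pytest.raises(ValidationError):
            classify_cd14_cd16(self._events([1.0], [1.0]), "medium",
                               self.THR, EXPLICIT)

    def test_grid_matches_brute_force_rule_table(self):
        rng = np.random.default_rng(1)
        cd14 = 10 ** rng.uniform(1, 5.5, size=10_000)
        cd16 = 10 ** rng.uniform(1, 5.0, size=10_000)
        config = default_gate_config()
        labels = classify_cd14_cd16(self._events(cd14, cd16), "small",
                                    self.THR, config)

        def oracle(c14, c16):
            if c14 > config.cd14_upper or c16 > config.cd16_upper:
                return UNASSIGNED
            bright = c14 >= self.THR["cd14_dim_boundary"]
            pos = c16 >= self.THR["cd16_threshold"]
            return {(True, False): "sm14+16neg", (True, True): "sm14+16+",
                    (False, True): "sm14dim16+",
                    (False, False): "sm14dim16neg"}[(bright, pos)]

        expected = [oracle(a, b) for a, b in zip(cd14, cd16)]
        assert labels.tolist() == expected


class TestRunGating:
    def test_empty_table_gives_empty_result(self, donor_sample):
        empty = EventTable(
            data=donor_sample.stained[3].data.iloc[:0].copy(),
            donor_id="x", set_id=3)
        res = run_gating(empty, donor_sample.isotype[3],
                         default_gate_config())
        assert res.n_events == 0
        assert all(v == 0 for v in res.counts.values())

    def test_labels_partition_events(self, gate_result, donor_sample):
        n = len(donor_sample.stained[3])
        assert sum(gate_result.counts.values()) == n
        assert set(gate_result.labels.unique()) <= set(GATE_LABELS)

    def test_rerun_is_identical(self, donor_sample):
        cfg = default_gate_config()
        a = run_gating(donor_sample.stained[3], donor_sample.isotype[3], cfg)
        b = run_gating(donor_sample.stained[3], donor_sample.isotype[3], cfg)
        assert (a.labels == b.labels).all()
        assert a.thresholds == b.thresholds

    def test_permutation_equivariance(self, donor_sample):
        cfg = default_gate_config()
        base = run_gating(donor_sample.stained[3], donor_sample.isotype[3], cfg)
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(donor_sample.stained[3]))
        shuffled = EventTable(
            data=donor_sample.stained[3].data.iloc[perm].reset_index(drop=True),
            donor_id=donor_sample.stained[3].donor_id, set_id=3)
        res = run_gating(shuffled, donor_sample.isotype[3], cfg)
        assert (res.labels.to_numpy() == base.labels.to_numpy()[perm]).all()

    def test_raising_cd16_threshold_monotone(self, donor_sample):
        counts = []
        for thr in (100.0, 400.0, 1600.0):
            cfg = GateConfig(lineage_threshold=100.0, cd14_threshold=100.0,
                             cd14_dim_boundary=1000.0, cd16_threshold=thr)
            res = run_gating(donor_sample.stained[3], donor_sample.isotype[3], cfg)
            counts.append((res.counts["sm14+16+"], res.counts["la14+16+"],
                           res.counts["sm14dim16+"]))
        for a, b in zip(counts, counts[1:]):
            assert all(x >= y for x, y in zip(a, b))

    def test_subpop_recovery_within_multinomial_noise(self):
        cfg = fixed_fraction_config(seed=9, events_per_donor=40_000)
        sample = generate_donor(cfg, 1, sets=[3])
        res = run_gating(sample.stained[3], sample.isotype[3],
                         default_gate_config())
        expected = {"sm14+16neg": 77.2, "sm14+16+": 4.4, "sm14dim16+": 3.2,
                    "sm14dim16neg": 2.4, "la14+16neg": 79.2, "la14+16+": 10.0}
        parents = {pop: ("small" if pop.startswith("sm") else "large")
                   for pop in SUBPOPULATIONS}
        n_parent = {"small": sum(res.counts[p] for p in SUBPOPULATIONS
                                 if p.startswith("sm")),
                    "large": sum(res.counts[p] for p in SUBPOPULATIONS
                                 if p.startswith("la"))}
        for pop, pct in expected.items():
            n = max(n_parent[parents[pop]], 1)
            p = pct / 100
            tol = 100 * 4 * np.sqrt(p * (1 - p) / n) + 1.0  # + leakage margin
            assert abs(res.subpop_percentages[pop] - pct) < tol, pop

    def test_donor_without_dim16neg_reports_near_zero_and_flags(self):
        cfg = fixed_fraction_config(seed=9)
        sample = generate_donor(cfg, 20, sets=[3])  # not a carrier donor
        res = run_gating(sample.stained[3], sample.isotype[3],
                         default_gate_config())
        assert res.subpop_percentages["sm14dim16neg"] < 0.2
        assert res.subpop_absent["sm14dim16neg"] == \
            (res.counts["sm14dim16neg"] == 0)
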