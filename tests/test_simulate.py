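"""The synthetic-data generator: determinism, geometry, truth consistency."""

import numpy as np
import pandas as pd
import pytest

from heteroseq import (
    call_expressed,
    classify_calls,
    default_scenario,
    expected_count_table,
    recovery_report,
    run_contrasts,
    simulate,
)
from heteroseq.simulate import ConfigError, SimulationConfig, write_simulation
from heteroseq.io_tables import read_annotation, read_count_table


def small_cfg(**kw):
    defaults = dict(n_genes=400, seed=7)
    defaults.update(kw)
    return default_scenario(**defaults)


class TestSimulate:
    def test_seed_determinism_byte_identical(self, tmp_path):
        a = simulate(small_cfg())
        b = simulate(small_cfg())
        pd.testing.assert_frame_equal(a.counts.genes, b.counts.genes)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        assert a.annotation == b.annotation
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        write_simulation(a, d1)
        write_simulation(b, d2)
        for name in ("counts.tsv", "annot.tsv", "truth.tsv", "sizes.yaml"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_different_seeds_differ(self):
        a = simulate(small_cfg(seed=1))
        b = simulate(small_cfg(seed=2))
        assert not a.counts.genes.equals(b.counts.genes)

    def test_counts_are_valid_and_lengths_floored(self):
        res = simulate(small_cfg())
        g = res.counts.genes
        for col in ("count_P1", "count_P2", "count_F1"):
            assert (g[col] >= 0).all()
            assert g[col].dtype.kind == "i"
        assert (g["length_bp"] >= 200).all()

    def test_te_fraction_zero_means_no_te(self):
        res = simulate(small_cfg(te_fraction=0.0))
        assert not any(a.is_te for a in res.annotation.values())

    def test_bad_proportions_rejected(self):
        with pytest.raises(ConfigError, match="sum"):
            simulate(small_cfg(mode_proportions={"ADD": 0.5, "ODO": 0.4}))
        with pytest.raises(ConfigError, match="OTHER"):
            simulate(small_cfg(mode_proportions={"ADD": 0.5, "OTHER": 0.5}))
        with pytest.raises(ConfigError, match="partial_parent_fold"):
            simulate(small_cfg(partial_parent_fold=1.5))

    def test_truth_mode_geometry(self):
        res = simulate(small_cfg(n_genes=2000))
        t = res.truth.set_index("gene_id")
        hi = np.maximum(t["rate_P1"], t["rate_P2"])
        lo = np.minimum(t["rate_P1"], t["rate_P2"])
        mid = (hi + lo) / 2
        f1 = t["rate_F1"]
        m = t["true_mode"]
        assert np.allclose(f1[m == "ADD"], mid[m == "ADD"])
        assert np.allclose(f1[m == "HPD"], hi[m == "HPD"])
        assert np.allclose(f1[m == "LPD"], lo[m == "LPD"])
        assert (f1[m == "ODO"] > hi[m == "ODO"] * 1.5).all()
        assert (f1[m == "UDO"] < lo[m == "UDO"] / 1.5).all()
        between = (f1 > lo) & (f1 < hi)
        assert between[m == "PPD"].all() and between[m == "NPD"].all()
        assert (f1[m == "PPD"] > mid[m == "PPD"]).all()
        assert (f1[m == "NPD"] < mid[m == "NPD"]).all()

    def test_expected_rpkm_matches_configured_rate(self):
        # all-additive, equal parents via tiny effect is not allowed; use ADD mix
        cfg = small_cfg(n_genes=3000, mode_proportions={"ADD": 1.0})
        res = simulate(cfg)
        table = res.counts
        lengths = table.genes["length_bp"].to_numpy()
        lib = table.lib_sizes["F1"]
        observed_rpkm = 1e9 * table.counts("F1") / (lib * lengths)
        expected = res.truth["rate_F1"].to_numpy()
        # law of large numbers across genes: mean relative error is small
        mask = expected * lengths * lib / 1e9 > 50  # genes with enough counts
        rel = observed_rpkm[mask] / expected[mask]
        assert abs(np.mean(rel) - 1.0) < 0.02

    def test_all_add_f1_matches_midparent_scaling(self):
        cfg = small_cfg(n_genes=5000, mode_proportions={"ADD": 1.0})
        res = simulate(cfg)
        t = res.truth
        # every expected F1 count equals midparent of expected parent counts
        assert np.allclose(t["mu_F1"], (t["mu_P1"] + t["mu_P2"]) / 2)
        # and realized counts agree in aggregate within Poisson error
        total_f1 = res.counts.counts("F1").sum()
        total_mp = t["mu_F1"].sum()
        assert abs(total_f1 - total_mp) < 4 * np.sqrt(total_mp)

    def test_injected_enrichment_hits_target_rate(self):
        cfg = small_cfg(
            n_genes=5000, injected_enrichment=("A06", "LPD", 5.0), seed=11
        )
        res = simulate(cfg)
        t = res.truth
        lpd = t[t["true_mode"] == "LPD"]
        frac = (lpd["chromosome"] == "A06").mean()
        base = cfg.chromosome_weights["A06"]
        assert frac == pytest.approx(5 * base, abs=0.06)

    def test_written_tables_reload_cleanly(self, tmp_path):
        res = simulate(small_cfg())
        paths = write_simulation(res, tmp_path)
        table = read_count_table(paths["counts"], sizes_path=paths["sizes"])
        assert table == res.counts
        annot = read_annotation(paths["annot"])
        assert annot == res.annotation


class TestRecoveryReport:
    def test_perfect_calls_give_identity_confusion(self):
        truth = pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3"],
                "true_mode": ["ODO", "UDO", "HPD"],
                "rate_P1": [100.0] * 3,
                "rate_P2": [100.0] * 3,
                "rate_F1": [100.0] * 3,
            }
        )
        calls = pd.DataFrame({"gene_id": truth["gene_id"], "mode": truth["true_mode"]})
        rep = recovery_report(calls, truth)
        assert rep["accuracy"] == 1.0
        assert all(v == 1.0 for v in rep["per_mode_recovery"].values())
        conf = rep["confusion"]
        assert (np.diag(conf.loc[["HPD", "ODO", "UDO"], ["HPD", "ODO", "UDO"]]) == 1).all()

    def test_unknown_called_gene_is_an_error(self):
        truth = pd.DataFrame(
            {
                "gene_id": ["g1"],
                "true_mode": ["ODO"],
                "rate_P1": [1.0],
                "rate_P2": [1.0],
                "rate_F1": [4.0],
            }
        )
        calls = pd.DataFrame({"gene_id": ["gX"], "mode": ["ODO"]})
        with pytest.raises(ValueError, match="gX"):
            recovery_report(calls, truth)

    def test_non_deg_excluded_from_accuracy(self):
        truth = pd.DataFrame(
            {
                "gene_id": ["g1", "g2"],
                "true_mode": ["ODO", "ADD"],
                "rate_P1": [100.0, 100.0],
                "rate_P2": [100.0, 100.0],
                "rate_F1": [400.0, 100.0],
            }
        )
        calls = pd.DataFrame({"gene_id": ["g1"], "mode": ["ODO"]})
        rep = recovery_report(calls, truth)
        assert rep["n_deg"] == 1 and rep["accuracy"] == 1.0
        assert rep["confusion"].at["ADD", "not_DEG"] == 1


class TestNoiselessRoundTrip:
    def test_expected_counts_recover_modes_exactly(self):
        res = simulate(small_cfg(n_genes=1500, seed=3))
        table = expected_count_table(res)
        de = run_contrasts(table)
        calls = classify_calls(de, call_expressed(table))
        rep = recovery_report(calls, res.truth, min_rate=100.0)
        assert rep["n_deg"] > 100
        assert all(v == 1.0 for v in rep["per_mode_recovery"].values())


class TestRobustnessToOverdispersion:
    def test_nb_counts_still_recover_strong_modes(self):
        # with replicate-free NB noise the additivity test is anticonservative,
        # but strongly displaced modes (ODO) remain recoverable
        res = simulate(small_cfg(n_genes=2000, dispersion=0.1, seed=5))
        de = run_contrasts(res.counts)
        calls = classify_calls(de, call_expressed(res.counts))
        rep = recovery_report(calls, res.truth, min_rate=100.0)
        assert rep["per_mode_recovery"]["ODO"] >= 0.8
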