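"""Hypergeometric enrichment scans and TE regulation calls."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heteroseq.enrichment import top_hit
from heteroseq import (
    chromosome_scan,
    classify_te,
    enrichment_matrix,
    go_enrich,
    hypergeom_enrich,
)
from heteroseq.io_tables import GeneAnnotation


def exact_upper_tail(k, N, K, n):
    """P(X >= k) by combinatorial enumeration; the small-N oracle."""
    total = 0
    for j in range(k, min(K, n) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / math.comb(N, n)


def _genes(n, prefix="g"):
    return [f"{prefix}{i}" for i in range(n)]


class TestHypergeomEnrich:
    def test_two_of_two_from_five_in_ten(self):
        bg = _genes(10)
        res = hypergeom_enrich(bg[:2], bg[:5], bg)
        assert res["p_value"] == pytest.approx(10 / 45)
        assert (res["k"], res["K"], res["n"], res["N"]) == (2, 5, 2, 10)

    def test_zero_overlap_upper_tail_is_one(self):
        bg = _genes(10)
        assert hypergeom_enrich(bg[:3], bg[5:], bg)["p_value"] == pytest.approx(1.0)

    def test_unit_equals_background_forces_one(self):
        bg = _genes(20)
        assert hypergeom_enrich(bg[:7], bg, bg)["p_value"] == pytest.approx(1.0)

    def test_constructed_tail_sum(self):
        # 20-gene background, 5-gene term, 4-gene set, overlap 3:
        # p = [C(5,3)C(15,1) + C(5,4)C(15,0)] / C(20,4)
        bg = _genes(20)
        term = bg[:5]
        deg = bg[2:5] + [bg[10]]
        expected = (math.comb(5, 3) * 15 + math.comb(5, 4)) / math.comb(20, 4)
        assert hypergeom_enrich(deg, term, bg)["p_value"] == pytest.approx(expected)

    def test_empty_background_is_domain_error(self):
        with pytest.raises(ValueError):
            hypergeom_enrich(["g"], ["g"], [])

    @given(
        N=st.integers(1, 25),
        K=st.integers(0, 25),
        n=st.integers(0, 25),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=120, deadline=None)
    def test_matches_full_enumeration(self, N, K, n, seed):
        K, n = min(K, N), min(n, N)
        rng = np.random.default_rng(seed)
        bg = _genes(N)
        unit = list(rng.choice(bg, size=K, replace=False))
        gene_set = list(rng.choice(bg, size=n, replace=False))
        res = hypergeom_enrich(gene_set, unit, bg)
        k = len(set(unit) & set(gene_set))
        assert res["p_value"] == pytest.approx(exact_upper_tail(k, N, K, n), abs=1e-12)

    def test_lower_tail_complements_upper(self):
        bg = _genes(12)
        lo = hypergeom_enrich(bg[:4], bg[:6], bg, tail="lower")
        # here k = 4 (the set lies inside the unit): P(X<=4) = 1 - P(X>=5)
        assert lo["p_value"] == pytest.approx(1 - exact_upper_tail(5, 12, 6, 4))


def _annot_for(calls_chrom):
    return {
        g: GeneAnnotation(g, chrom) for g, chrom in calls_chrom.items()
    }


class TestChromosomeScan:
    def test_single_chromosome_background_all_p_one(self):
        calls = pd.DataFrame(
            {"gene_id": _genes(30), "mode": ["LPD"] * 15 + ["HPD"] * 15}
        )
        annot = _annot_for({g: "A01" for g in _genes(30)})
        scan, totals = chromosome_scan(calls, annot)
        a01 = scan[scan["unit"] == "A01"]
        assert np.allclose(a01["p_value"], 1.0)
        assert set(totals["subgenome"]) == {"A"}

    def test_unplaced_genes_excluded_from_background(self):
        calls = pd.DataFrame({"gene_id": _genes(10), "mode": ["LPD"] * 10})
        chroms = {g: ("A01" if i < 6 else "unplaced") for i, g in enumerate(_genes(10))}
        scan, totals = chromosome_scan(calls, _annot_for(chroms))
        assert (scan["N"] == 6).all()
        assert set(totals["subgenome"]) == {"A", "unassigned"}

    def test_injected_excess_is_detected(self, rng):
        # 40 of 60 LPD genes on A06 vs a uniform 200-gene ADD background
        chroms = {}
        modes = {}
        genes = _genes(260)
        all_chroms = [f"A{i:02d}" for i in range(1, 11)]
        for i, g in enumerate(genes):
            if i < 60:
                modes[g] = "LPD"
                chroms[g] = "A06" if i < 40 else all_chroms[i % 10]
            else:
                modes[g] = "ADD"
                chroms[g] = all_chroms[i % 10]
        calls = pd.DataFrame({"gene_id": genes, "mode": [modes[g] for g in genes]})
        scan, _ = chromosome_scan(calls, _annot_for(chroms))
        best = top_hit(scan)
        assert (best["unit"], best["gene_set_label"]) == ("A06", "LPD")
        assert best["fdr"] < 0.001

    def test_label_shuffle_destroys_enrichment(self, rng):
        genes = _genes(260)
        all_chroms = [f"A{i:02d}" for i in range(1, 11)]
        chroms = {g: ("A06" if i < 40 else all_chroms[i % 10]) for i, g in enumerate(genes)}
        modes = ["LPD" if i < 60 else "ADD" for i in range(260)]
        annot = _annot_for(chroms)
        hits = 0
        for _ in range(20):
            shuffled = rng.permutation(modes)
            calls = pd.DataFrame({"gene_id": genes, "mode": shuffled})
            scan, _ = chromosome_scan(calls, annot)
            hits += int((scan["fdr"] < 0.05).any())
        assert hits <= 1  # >= 95% of shuffles show nothing


class TestGoEnrich:
    def test_term_covering_exactly_the_deg_set(self):
        bg = _genes(30)
        deg = bg[:5]
        annot = {g: GeneAnnotation(g, "A01", frozenset({"GO:X"})) for g in deg}
        res = go_enrich(deg, annot, bg).set_index("unit")
        # the smallest achievable p for n=5, K=5, N=30
        assert res.at["GO:X", "p_value"] == pytest.approx(
            1 / math.comb(30, 5) * 1, abs=1e-12
        )

    def test_small_terms_excluded(self):
        bg = _genes(30)
        annot = {
            bg[0]: GeneAnnotation(bg[0], "A01", frozenset({"GO:RARE"})),
            bg[1]: GeneAnnotation(bg[1], "A01", frozenset({"GO:RARE"})),
        }
        res = go_enrich(bg[:5], annot, bg, min_genes=3)
        assert len(res) == 0

    def test_no_annotation_warns_and_returns_empty(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="heteroseq.enrichment"):
            res = go_enrich(_genes(3), {}, _genes(10))
        assert res.empty
        assert "no GO-annotated" in caplog.text

    def test_matrix_pivot(self):
        bg = _genes(30)
        annot = {g: GeneAnnotation(g, "A01", frozenset({"GO:X"})) for g in bg[:6]}
        scans = {
            "P1_vs_F1": go_enrich(bg[:5], annot, bg),
            "P2_vs_F1": go_enrich(bg[5:10], annot, bg),
        }
        mat = enrichment_matrix(scans)
        assert mat.shape == (1, 2)
        assert set(mat.columns) == {"P1_vs_F1", "P2_vs_F1"}


def _expr(rows):
    return pd.DataFrame(
        {
            "gene_id": list(rows),
            "expressed_P1": [r[0] for r in rows.values()],
            "expressed_P2": [r[1] for r in rows.values()],
            "expressed_F1": [r[2] for r in rows.values()],
        }
    )


def _mp_de(signs):
    return pd.DataFrame(
        {
            "gene_id": list(signs),
            "contrast": "MP_vs_F1",
            "sign": list(signs.values()),
        }
    )


class TestClassifyTe:
    def test_rule_table(self):
        annot = {
            g: GeneAnnotation(g, "A01", frozenset(), True, "hAT")
            for g in ("tA", "tI", "tU", "tD")
        }
        expr = _expr(
            {
                "tA": (False, False, True),
                "tI": (True, True, False),
                "tU": (True, True, True),
                "tD": (True, False, True),
            }
        )
        de = _mp_de({"tA": 1, "tI": 0, "tU": 1, "tD": -1})
        calls = classify_te(annot, expr, de).set_index("gene_id")
        assert calls.at["tA", "regulation"] == "Active"
        assert calls.at["tI", "regulation"] == "Inactive"
        assert calls.at["tU", "regulation"] == "Up"
        assert calls.at["tD", "regulation"] == "Down"

    def test_unclassifiable_gene_excluded(self):
        annot = {"t1": GeneAnnotation("t1", "A01", frozenset(), True, "hAT")}
        # expressed everywhere but no significant midparent shift: no rule fits
        calls = classify_te(annot, _expr({"t1": (True, True, True)}), _mp_de({"t1": 0}))
        assert calls.empty

    def test_one_regulation_per_gene(self):
        flags = list(itertools.product([False, True], repeat=3))
        annot = {
            f"t{i}": GeneAnnotation(f"t{i}", "C03", frozenset(), True, "En/Spm")
            for i in range(len(flags))
        }
        for sign in (-1, 0, 1):
            expr = _expr({f"t{i}": f for i, f in enumerate(flags)})
            de = _mp_de({f"t{i}": sign for i in range(len(flags))})
            calls = classify_te(annot, expr, de)
            assert calls["gene_id"].is_unique

    def test_non_te_genes_ignored(self):
        annot = {"g1": GeneAnnotation("g1", "A01", frozenset(), False, "")}
        calls = classify_te(annot, _expr({"g1": (False, False, True)}), _mp_de({"g1": 1}))
        assert calls.empty
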