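"""Hypergeometric enrichment scans and transposable-element regulation calls.

Two scans share one primitive, the upper-tail hypergeometric test
``P(X >= k)`` for drawing ``k`` members of a unit (a chromosome or a GO term,
``K`` background members) in a gene set of size ``n`` from a background of
``N`` genes:

* chromosome scan -- does a dominance class accumulate on particular
  chromosomes?  Background is the set of DEGs with a chromosome assignment
  (placement of DEGs, not expression propensity, is what is being compared).
* GO scan -- are functional terms over-represented in a DEG set against an
  annotated background?

Both apply Benjamini-Hochberg correction across their tests.  The upper tail
matches the accumulation question; a depletion (lower-tail) scan is available
behind a flag.

TE-like genes are classified by presence/absence and quantitative shift in
the hybrid: Active (expressed in F1 only), Inactive (parentally expressed,
silent in F1), Up/Down (expressed in F1 and at least one parent, with a
significant shift from the midparent).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .detest import bh_fdr
from .dominance import MODES
from .io_tables import CHROMOSOMES, GeneAnnotation

logger = logging.getLogger(__name__)

TE_REGULATIONS = ("Active", "Inactive", "Up", "Down")


def hypergeom_enrich(
    set_genes: Iterable[str],
    unit_genes: Iterable[str],
    background: Iterable[str],
    tail: str = "upper",
) -> dict:
    """One hypergeometric enrichment test; returns k, K, n, N and the p-value.

    ``set_genes`` and ``unit_genes`` must be subsets of ``background``.
    Upper tail gives ``P(X >= k)`` (accumulation); ``tail='lower'`` gives
    ``P(X <= k)`` (depletion).
    """
    background = frozenset(background)
    if not background:
        raise ValueError("background gene set is empty")
    set_genes = frozenset(set_genes) & background
    unit_genes = frozenset(unit_genes) & background
    k = len(set_genes & unit_genes)
    big_k, n, big_n = len(unit_genes), len(set_genes), len(background)
    if tail == "upper":
        p = float(hypergeom.sf(k - 1, big_n, big_k, n))
    elif tail == "lower":
        p = float(hypergeom.cdf(k, big_n, big_k, n))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return {"k": k, "K": big_k, "n": n, "N": big_n, "p_value": min(p, 1.0)}


def chromosome_scan(
    calls: pd.DataFrame,
    annot: Mapping[str, GeneAnnotation],
    tail: str = "upper",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test every (chromosome, dominance class) pair for accumulation.

    Background is the set of classified DEGs that carry a chromosome
    assignment.  Returns ``(results, subgenome_totals)``: the scan frame with
    BH correction across all tests, and per-subgenome (A / C / unassigned)
    gene-action totals.
    """
    chrom_of = {
        g: annot[g].chromosome if g in annot else "unplaced"
        for g in calls["gene_id"]
    }
    sub_of = {
        g: annot[g].subgenome if g in annot else "unassigned"
        for g in calls["gene_id"]
    }
    placed = calls[[chrom_of[g] in CHROMOSOMES for g in calls["gene_id"]]]
    background = frozenset(placed["gene_id"])

    rows = []
    if background:
        by_chrom = {
            c: frozenset(g for g in background if chrom_of[g] == c)
            for c in CHROMOSOMES
        }
        present_modes = [m for m in MODES if (placed["mode"] == m).any()]
        for mode in present_modes:
            mode_genes = frozenset(placed.loc[placed["mode"] == mode, "gene_id"])
            for chrom in CHROMOSOMES:
                res = hypergeom_enrich(mode_genes, by_chrom[chrom], background, tail)
                rows.append({"unit": chrom, "gene_set_label": mode, **res})
    results = pd.DataFrame(
        rows, columns=["unit", "gene_set_label", "k", "K", "n", "N", "p_value"]
    )
    results["fdr"] = bh_fdr(results["p_value"].to_numpy()) if len(results) else []

    totals = (
        calls.assign(subgenome=[sub_of[g] for g in calls["gene_id"]])
        .groupby(["subgenome", "mode"], sort=True)
        .size()
        .rename("n_genes")
        .reset_index()
    )
    return results, totals


def go_enrich(
    deg_set: Iterable[str],
    annot: Mapping[str, GeneAnnotation],
    background: Iterable[str],
    min_genes: int = 3,
    tail: str = "upper",
) -> pd.DataFrame:
    """Hypergeometric GO-term over-representation for one gene set.

    Terms annotating fewer than ``min_genes`` background genes are excluded
    (singleton terms would otherwise dominate the BH correction).  Returns an
    empty frame with a warning when no background gene carries a GO term.
    """
    background = frozenset(background)
    deg_set = frozenset(deg_set) & background
    term_genes: dict[str, set[str]] = {}
    for g in background:
        if g in annot:
            for t in annot[g].go_terms:
                term_genes.setdefault(t, set()).add(g)
    columns = ["unit", "gene_set_label", "k", "K", "n", "N", "p_value", "fdr"]
    if not term_genes:
        logger.warning("no GO-annotated genes in background; empty enrichment")
        return pd.DataFrame(columns=columns)
    rows = []
    for term in sorted(term_genes):
        genes = term_genes[term]
        if len(genes) < min_genes:
            continue
        res = hypergeom_enrich(deg_set, genes, background, tail)
        rows.append({"unit": term, "gene_set_label": "DEG", **res})
    out = pd.DataFrame(rows, columns=columns[:-1])
    out["fdr"] = bh_fdr(out["p_value"].to_numpy()) if len(out) else []
    return out


def top_hit(scan: pd.DataFrame) -> pd.Series:
    """The scan row with the smallest FDR, ties broken by raw p-value.

    BH-adjusted values tie frequently (they are running minima, and cap at
    1), so the raw p-value decides between equally-adjusted rows.
    """
    if scan.empty:
        raise ValueError("empty enrichment scan has no top hit")
    return scan.sort_values(["fdr", "p_value"], kind="mergesort").iloc[0]


def enrichment_matrix(scans: Mapping[str, pd.DataFrame], value: str = "p_value") -> pd.DataFrame:
    """Pivot several labelled GO scans into a term x gene-set value matrix.

    ``scans`` maps a gene-set label (e.g. a contrast name) to its
    :func:`go_enrich` output; the result is the matrix behind a typical
    enrichment heat map (rendering itself is out of scope).
    """
    frames = []
    for label, df in scans.items():
        if len(df):
            frames.append(df.assign(gene_set_label=label))
    if not frames:
        return pd.DataFrame()
    long = pd.concat(frames, ignore_index=True)
    return long.pivot(index="unit", columns="gene_set_label", values=value)


def classify_te(
    annot: Mapping[str, GeneAnnotation],
    expr: pd.DataFrame,
    de: pd.DataFrame,
) -> pd.DataFrame:
    """Classify TE-flagged genes as Active / Inactive / Up / Down in the hybrid.

    Active: expressed in F1 but in neither parent.  Inactive: expressed in at
    least one parent but not in F1.  Up/Down: expressed in F1 and >=1 parent
    with a significant F1-vs-midparent shift (+1 / -1).  Genes fitting no rule
    are excluded with a log notice.  Each classified gene receives exactly one
    regulation label.
    """
    te_ids = [g for g, a in annot.items() if a.is_te]
    flags = expr.set_index("gene_id")
    mp_sign = (
        de[de["contrast"] == "MP_vs_F1"].set_index("gene_id")["sign"]
        if len(de)
        else pd.Series(dtype=int)
    )
    rows, skipped = [], []
    for g in te_ids:
        if g not in flags.index:
            skipped.append(g)
            continue
        in_p1 = bool(flags.at[g, "expressed_P1"])
        in_p2 = bool(flags.at[g, "expressed_P2"])
        in_f1 = bool(flags.at[g, "expressed_F1"])
        sign = int(mp_sign.get(g, 0))
        if in_f1 and not in_p1 and not in_p2:
            regulation = "Active"
        elif (in_p1 or in_p2) and not in_f1:
            regulation = "Inactive"
        elif in_f1 and (in_p1 or in_p2) and sign == 1:
            regulation = "Up"
        elif in_f1 and (in_p1 or in_p2) and sign == -1:
            regulation = "Down"
        else:
            skipped.append(g)
            continue
        rows.append(
            {
                "gene_id": g,
                "regulation": regulation,
                "chromosome": annot[g].chromosome,
            }
        )
    if skipped:
        logger.info("%d TE gene(s) fit no regulation rule; excluded", len(skipped))
    return pd.DataFrame(rows, columns=["gene_id", "regulation", "chromosome"])
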