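"""Synthetic three-library count tables with known gene-action truth.

The generator emulates the study design the pipeline targets: two parental
lines and their hybrid, one pooled RNA library each, uniquely-mapped per-gene
counts.  Every gene draws a base expression rate (RPKM scale, log-normal), a
dominance mode from a configurable mixture, and per-library rates from the
mode's geometry; counts are then Poisson (or gamma-Poisson for over-dispersed
robustness scenarios) at ``rate * length * lib_size / 1e9``, so a gene's
expected RPKM equals its configured rate.

Mode geometry (``f`` = ``effect_fold``, parents split ``sqrt(rho)`` above and
below the base rate with ``rho`` the parental separation):

=====  =========================================
ADD    lambda_F1 = (lambda_P1 + lambda_P2) / 2
HPD    lambda_F1 = max(parents)
LPD    lambda_F1 = min(parents)
ODO    lambda_F1 = max(parents) * f
UDO    lambda_F1 = min(parents) / f
PPD    lambda_F1 = midparent * sqrt(f)
NPD    lambda_F1 = midparent / sqrt(f)
=====  =========================================

For PPD/NPD the parents are separated by ``partial_parent_fold`` (default 10,
i.e. strongly divergent parental alleles) rather than ``effect_fold``: the
hybrid must sit *strictly between* the parents after its ``sqrt(f)``
displacement from the midparent, which is geometrically impossible when the
parents are only ``f``-fold apart.

Chromosome weights default to the A/C/unplaced proportions of a typical
allopolyploid mapping (A ~52%, C ~38%, unplaced ~10%); an optional injected
enrichment re-draws the chromosomes of one mode's genes with a boosted weight
for one chromosome, giving the enrichment scan a known positive control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dominance import MODES
from .io_tables import (
    A_CHROMOSOMES,
    C_CHROMOSOMES,
    CHROMOSOMES,
    UNPLACED,
    CountTable,
    GeneAnnotation,
    write_annotation,
    write_count_table,
)

#: Default mode mixture: the dominance-pattern counts of a published
#: interspecific Brassica hybrid table (1840 additive and 353/191/593/193/
#: 1635/1981 across the six nonadditive modes), normalized.
TABLE_MODE_COUNTS = {
    "ADD": 1840,
    "HPD": 353,
    "LPD": 191,
    "ODO": 593,
    "UDO": 193,
    "PPD": 1635,
    "NPD": 1981,
}

TE_FAMILIES = ("En/Spm", "Retrotransposon", "hAT", "Tam1", "Mutator")


def _default_mode_proportions() -> dict[str, float]:
    total = sum(TABLE_MODE_COUNTS.values())
    return {m: c / total for m, c in TABLE_MODE_COUNTS.items()}


def _default_chromosome_weights() -> dict[str, float]:
    w = {c: 0.517 / len(A_CHROMOSOMES) for c in A_CHROMOSOMES}
    w.update({c: 0.377 / len(C_CHROMOSOMES) for c in C_CHROMOSOMES})
    w[UNPLACED] = 0.106
    return w


class ConfigError(ValueError):
    """A simulation configuration violates one of its invariants."""


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the desk-scale scenario.

    ``base_log_mean``/``base_log_sd`` parameterize the log-normal base rate in
    RPKM (median ~25, sigma 1.5: a moderately expressed leaf-transcriptome
    subset).  ``dispersion`` d gives counts a negative-binomial variance
    ``mu * (1 + d*mu)``; 0 means Poisson, the sampling model of single pooled
    libraries.  Lengths are log-normal with mean ~1300 bp, floored at 200 bp.
    ``injected_enrichment`` is ``(chromosome, mode, fold)``.
    """

    n_genes: int = 5000
    lib_sizes: tuple[int, int, int] = (2_000_000, 2_000_000, 2_000_000)
    mode_proportions: dict[str, float] = field(
        default_factory=_default_mode_proportions
    )
    effect_fold: float = 2.0
    partial_parent_fold: float = 10.0
    base_log_mean: float = math.log(25.0)
    base_log_sd: float = 1.5
    dispersion: float = 0.0
    length_log_mean: float = math.log(1300.0) - 0.25**2 / 2
    length_log_sd: float = 0.25
    min_length: int = 200
    chromosome_weights: dict[str, float] = field(
        default_factory=_default_chromosome_weights
    )
    injected_enrichment: tuple[str, str, float] | None = None
    go_n_terms: int = 50
    go_terms_per_gene: float = 1.0
    te_fraction: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        if any(n < 1 for n in self.lib_sizes):
            raise ConfigError("library sizes must be positive")
        unknown = set(self.mode_proportions) - set(MODES)
        if unknown:
            raise ConfigError(f"unknown mode(s) in proportions: {sorted(unknown)}")
        if "OTHER" in self.mode_proportions:
            raise ConfigError("OTHER is a residual class and cannot be simulated")
        total = sum(self.mode_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"mode proportions sum to {total!r}, not 1")
        if any(p < 0 for p in self.mode_proportions.values()):
            raise ConfigError("mode proportions must be non-negative")
        if self.effect_fold < 1:
            raise ConfigError("effect_fold must be >= 1")
        if self.partial_parent_fold <= self.effect_fold:
            raise ConfigError(
                "partial_parent_fold must exceed effect_fold so PPD/NPD hybrids "
                "lie between the parents"
            )
        if self.dispersion < 0:
            raise ConfigError("dispersion must be non-negative")
        if not 0 <= self.te_fraction <= 1:
            raise ConfigError("te_fraction must lie in [0, 1]")
        if self.injected_enrichment is not None:
            chrom, mode, fold = self.injected_enrichment
            if chrom not in CHROMOSOMES:
                raise ConfigError(f"injected chromosome {chrom!r} unknown")
            if mode not in MODES or mode == "OTHER":
                raise ConfigError(f"injected mode {mode!r} not simulable")
            if fold < 1:
                raise ConfigError("injected enrichment fold must be >= 1")


@dataclass
class SimulationResult:
    counts: CountTable
    annotation: dict[str, GeneAnnotation]
    truth: pd.DataFrame


def _mode_rates(cfg: SimulationConfig, rng: np.random.Generator):
    """Per-gene true modes and (lambda_P1, lambda_P2, lambda_F1) RPKM rates."""
    n = cfg.n_genes
    mode_names = list(cfg.mode_proportions)
    probs = np.array([cfg.mode_proportions[m] for m in mode_names])
    modes = rng.choice(mode_names, size=n, p=probs)
    base = rng.lognormal(cfg.base_log_mean, cfg.base_log_sd, size=n)
    f = cfg.effect_fold
    partial = np.isin(modes, ("PPD", "NPD"))
    rho = np.where(partial, cfg.partial_parent_fold, f)
    hi = base * np.sqrt(rho)
    lo = base / np.sqrt(rho)
    hi_is_p1 = rng.random(n) < 0.5
    lam_p1 = np.where(hi_is_p1, hi, lo)
    lam_p2 = np.where(hi_is_p1, lo, hi)
    mid = (hi + lo) / 2.0
    lam_f1 = np.select(
        [
            modes == "ADD",
            modes == "HPD",
            modes == "LPD",
            modes == "ODO",
            modes == "UDO",
            modes == "PPD",
            modes == "NPD",
        ],
        [mid, hi, lo, hi * f, lo / f, mid * math.sqrt(f), mid / math.sqrt(f)],
    )
    return modes, lam_p1, lam_p2, lam_f1


def _draw_counts(mu: np.ndarray, dispersion: float, rng: np.random.Generator):
    if dispersion == 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mu)  # gamma-Poisson = negative binomial
    return rng.poisson(lam)


def _assign_chromosomes(
    cfg: SimulationConfig, modes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    labels = list(cfg.chromosome_weights)
    weights = np.array([cfg.chromosome_weights[c] for c in labels], dtype=float)
    weights = weights / weights.sum()
    chroms = rng.choice(labels, size=len(modes), p=weights)
    if cfg.injected_enrichment is not None:
        chrom, mode, fold = cfg.injected_enrichment
        # the target mode's genes land on the target chromosome at exactly
        # fold x the background rate; other chromosomes absorb the difference
        idx = labels.index(chrom)
        p_target = min(fold * weights[idx], 1.0)
        boosted = weights * (1.0 - p_target) / (1.0 - weights[idx])
        boosted[idx] = p_target
        target = modes == mode
        chroms[target] = rng.choice(labels, size=int(target.sum()), p=boosted)
    return chroms


def simulate(config: SimulationConfig) -> SimulationResult:
    """Generate a count table, annotation map and truth table.

    Deterministic under ``config.seed``: the same configuration yields
    byte-identical tables.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    gene_ids = np.array([f"g{i:05d}" for i in range(1, n + 1)])

    lengths = rng.lognormal(cfg.length_log_mean, cfg.length_log_sd, size=n)
    lengths = np.maximum(np.rint(lengths).astype(np.int64), cfg.min_length)

    modes, lam_p1, lam_p2, lam_f1 = _mode_rates(cfg, rng)
    lib = dict(zip(("P1", "P2", "F1"), cfg.lib_sizes))
    mu = {
        "P1": lam_p1 * lengths * lib["P1"] / 1e9,
        "P2": lam_p2 * lengths * lib["P2"] / 1e9,
        "F1": lam_f1 * lengths * lib["F1"] / 1e9,
    }
    counts = {k: _draw_counts(mu[k], cfg.dispersion, rng) for k in ("P1", "P2", "F1")}

    chroms = _assign_chromosomes(cfg, modes, rng)

    terms = np.array([f"GO:{i:07d}" for i in range(1, cfg.go_n_terms + 1)])
    term_weights = 1.0 / np.arange(1, cfg.go_n_terms + 1)
    term_weights = term_weights / term_weights.sum()
    n_terms = np.minimum(rng.poisson(cfg.go_terms_per_gene, size=n), cfg.go_n_terms)
    go_lists = [
        frozenset(rng.choice(terms, size=k, replace=False, p=term_weights))
        if k
        else frozenset()
        for k in n_terms
    ]

    is_te = rng.random(n) < cfg.te_fraction
    families = rng.choice(TE_FAMILIES, size=n)

    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "length_bp": lengths,
            "count_P1": counts["P1"],
            "count_P2": counts["P2"],
            "count_F1": counts["F1"],
        }
    )
    table = CountTable(genes, lib)
    annotation = {
        g: GeneAnnotation(
            g,
            chroms[i],
            go_lists[i],
            bool(is_te[i]),
            families[i] if is_te[i] else "",
        )
        for i, g in enumerate(gene_ids)
    }
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_mode": modes,
            "rate_P1": lam_p1,
            "rate_P2": lam_p2,
            "rate_F1": lam_f1,
            "mu_P1": mu["P1"],
            "mu_P2": mu["P2"],
            "mu_F1": mu["F1"],
            "chromosome": chroms,
            "go_terms": [";".join(sorted(s)) for s in go_lists],
            "is_te": is_te,
        }
    )
    return SimulationResult(table, annotation, truth)


def expected_count_table(result: SimulationResult) -> CountTable:
    """Noiseless companion table: counts are the rounded expected values.

    Classifying these recovers every true mode exactly for effect folds >= 2
    and rates >= 100 RPKM -- the geometry round-trip check.
    """
    genes = result.counts.genes.copy()
    truth = result.truth
    for lib in ("P1", "P2", "F1"):
        genes[f"count_{lib}"] = np.rint(truth[f"mu_{lib}"].to_numpy()).astype(np.int64)
    return CountTable(genes, dict(result.counts.lib_sizes))


def write_simulation(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write counts.tsv, sizes.yaml, annot.tsv and truth.tsv into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "sizes": outdir / "sizes.yaml",
        "annot": outdir / "annot.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_count_table(result.counts, paths["counts"], paths["sizes"])
    write_annotation(result.annotation, paths["annot"])
    result.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def recovery_report(
    calls: pd.DataFrame,
    truth: pd.DataFrame,
    min_rate: float | None = None,
) -> dict:
    """Confusion matrix and per-mode recovery of the classifier against truth.

    Genes outside the DEG filter appear in the ``not_DEG`` column of the
    confusion matrix but are excluded from recovery and accuracy (headline
    numbers are conditional on a gene being classifiable at all).
    ``min_rate`` restricts the evaluation to genes whose true midparent rate
    is at least that many RPKM.
    """
    unknown = set(calls["gene_id"]) - set(truth["gene_id"])
    if unknown:
        raise ValueError(f"called gene(s) missing from truth: {sorted(unknown)[:3]}")
    t = truth.set_index("gene_id")
    called = calls.set_index("gene_id")["mode"]
    frame = pd.DataFrame(
        {
            "true_mode": t["true_mode"],
            "called": called.reindex(t.index).fillna("not_DEG"),
            "mid_rate": (t["rate_P1"] + t["rate_P2"]) / 2.0,
        }
    )
    if min_rate is not None:
        frame = frame[frame["mid_rate"] >= min_rate]
    confusion = pd.crosstab(frame["true_mode"], frame["called"])
    deg = frame[frame["called"] != "not_DEG"]
    per_mode = {}
    for mode in sorted(frame["true_mode"].unique()):
        sub = deg[deg["true_mode"] == mode]
        per_mode[mode] = float((sub["called"] == mode).mean()) if len(sub) else float("nan")
    accuracy = float((deg["called"] == deg["true_mode"]).mean()) if len(deg) else float("nan")
    return {
        "confusion": confusion,
        "per_mode_recovery": per_mode,
        "accuracy": accuracy,
        "n_evaluated": int(len(frame)),
        "n_deg": int(len(deg)),
    }


def default_scenario(seed: int = 0, **overrides) -> SimulationConfig:
    """The desk-scale default scenario with a given seed."""
    return replace(SimulationConfig(), seed=seed, **overrides)
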