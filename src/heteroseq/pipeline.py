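"""One-call orchestration: simulate/load -> quantify -> test -> classify -> enrich.

:func:`run` executes the enabled stages in dependency order, writes every
intermediate table under the output directory, and returns (and writes) a
machine-readable summary JSON with expressed-gene counts, Venn regions, DEG
tallies per contrast, the dominance-mode summary, enrichment hits, the TE
regulation tally and (when Ct data is supplied) qPCR concordance.  Each stage
logs its parameters and row counts; a failure halts with an error naming the
stage, leaving earlier outputs in place.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import detest, dominance, enrichment, qpcr, quantify
from . import simulate as sim  # bound before the package re-exports shadow it
from .io_tables import (
    read_annotation,
    read_count_table,
    read_ct_table,
    write_results,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "quantify", "detest", "classify", "enrich", "qpcr")

#: Stage -> stages it needs.
_DEPENDENCIES = {
    "quantify": (),
    "detest": (),
    "classify": ("detest", "quantify"),
    "enrich": ("classify", "quantify"),
    "qpcr": ("detest",),
}


class StageError(RuntimeError):
    """A pipeline stage failed or a dependency was disabled."""


@dataclass
class RunConfig:
    """Inputs, thresholds and step toggles for one pipeline run.

    Either ``sim`` (a :class:`~heteroseq.simulate.SimulationConfig`) or the
    ``counts_path``/``sizes_path`` pair must be provided; ``annot_path`` is
    required for enrichment unless the data was simulated.
    """

    outdir: str | Path = "heteroseq_run"
    sim: sim.SimulationConfig | None = None
    counts_path: str | Path | None = None
    sizes_path: str | Path | None = None
    annot_path: str | Path | None = None
    ct_path: str | Path | None = None
    qpcr_calibrator: str = "P1"
    min_count: int = quantify.DEFAULT_MIN_COUNT
    min_rpkm: float = quantify.DEFAULT_MIN_RPKM
    alpha: float = 0.05
    min_log2fc: float = 0.0
    min_genes: int = 3
    steps: tuple[str, ...] = field(
        default_factory=lambda: ("quantify", "detest", "classify", "enrich")
    )

    def validate(self) -> None:
        unknown = set(self.steps) - set(STAGES)
        if unknown:
            raise StageError(f"unknown stage(s): {sorted(unknown)}")
        for stage in self.steps:
            for dep in _DEPENDENCIES.get(stage, ()):
                if dep not in self.steps:
                    raise StageError(
                        f"stage {stage!r} requires stage {dep!r}, which is disabled"
                    )
        if self.sim is None and self.counts_path is None:
            raise StageError("either a simulation config or a counts path is required")
        if not 0 < self.alpha < 1:
            raise StageError("alpha must lie in (0, 1)")
        if self.min_count < 0 or self.min_rpkm < 0 or self.min_log2fc < 0:
            raise StageError("thresholds must be non-negative")


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns the summary dict written to summary.json."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"parameters": {
        "min_count": config.min_count,
        "min_rpkm": config.min_rpkm,
        "alpha": config.alpha,
        "min_log2fc": config.min_log2fc,
        "min_genes": config.min_genes,
        "steps": list(config.steps),
    }}

    # ---- inputs ----------------------------------------------------------
    annot = None
    truth = None
    try:
        if config.sim is not None:
            logger.info("simulate: n_genes=%d seed=%d",
                        config.sim.n_genes, config.sim.seed)
            result = sim.simulate(config.sim)
            sim.write_simulation(result, outdir)
            table, annot, truth = result.counts, result.annotation, result.truth
            summary["simulate"] = {"n_genes": table.n_genes, "seed": config.sim.seed}
        else:
            table = read_count_table(
                config.counts_path, sizes_path=config.sizes_path
            )
            if config.annot_path is not None:
                annot = read_annotation(config.annot_path)
    except StageError:
        raise
    except Exception as exc:  # pragma: no cover - error path
        raise StageError(f"stage 'input' failed: {exc}") from exc

    expr = de = calls = None

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    # ---- quantify --------------------------------------------------------
    if "quantify" in config.steps:
        def _quantify():
            logger.info("quantify: min_count=%d min_rpkm=%g",
                        config.min_count, config.min_rpkm)
            expr = quantify.call_expressed(table, config.min_count, config.min_rpkm)
            write_results(expr, outdir / "expr.tsv")
            venn = quantify.venn_partition(expr)
            return expr, venn
        expr, venn = _stage("quantify", _quantify)
        summary["expressed"] = {
            lib: int(expr[f"expressed_{lib}"].sum()) for lib in ("P1", "P2", "F1")
        }
        summary["venn"] = venn.counts
        summary["venn"]["silenced_in_hybrid"] = len(venn.silenced_in_hybrid)
        summary["venn"]["activated_in_hybrid"] = len(venn.activated_in_hybrid)
        logger.info("quantify: %s genes expressed per library", summary["expressed"])

    # ---- exact tests -----------------------------------------------------
    if "detest" in config.steps:
        def _detest():
            logger.info("detest: alpha=%g min_log2fc=%g", config.alpha,
                        config.min_log2fc)
            de = detest.run_contrasts(
                table, alpha=config.alpha, min_log2fc=config.min_log2fc
            )
            write_results(de, outdir / "de.tsv")
            return de
        de = _stage("detest", _detest)
        deg_counts = {}
        for contrast in detest.CONTRASTS:
            sub = de[de["contrast"] == contrast]
            up = int((sub["sign"] > 0).sum())
            down = int((sub["sign"] < 0).sum())
            deg_counts[contrast] = {"total": up + down, "up": up, "down": down}
        summary["deg"] = deg_counts
        summary["deg"]["n_deg_genes"] = len(detest.deg_gene_ids(de))
        logger.info("detest: %d DEG genes", summary["deg"]["n_deg_genes"])

    # ---- dominance classification ---------------------------------------
    if "classify" in config.steps:
        def _classify():
            calls = dominance.classify_calls(de, expr)
            write_results(calls, outdir / "dominance.tsv")
            return calls
        calls = _stage("classify", _classify)
        mode_summary = dominance.summarize_modes(calls)
        write_results(mode_summary, outdir / "mode_summary.tsv")
        summary["modes"] = {
            row.category: {"number": int(row.number), "percentage": row.percentage}
            for row in mode_summary.itertuples()
        }
        if truth is not None:
            report = sim.recovery_report(calls, truth)
            summary["recovery"] = {
                "accuracy": report["accuracy"],
                "per_mode": report["per_mode_recovery"],
            }
        logger.info("classify: %d DEGs classified", len(calls))

    # ---- enrichment ------------------------------------------------------
    if "enrich" in config.steps:
        if annot is None:
            raise StageError("stage 'enrich' requires an annotation table")
        def _enrich():
            chrom_scan, sub_totals = enrichment.chromosome_scan(calls, annot)
            write_results(chrom_scan, outdir / "enrich_chromosome.tsv")
            write_results(sub_totals, outdir / "subgenome_totals.tsv")
            go = enrichment.go_enrich(
                set(calls["gene_id"]), annot, set(table.gene_ids),
                min_genes=config.min_genes,
            )
            write_results(go, outdir / "enrich_go.tsv")
            te = enrichment.classify_te(annot, expr, de)
            write_results(te, outdir / "te_calls.tsv")
            return chrom_scan, go, te
        chrom_scan, go, te = _stage("enrich", _enrich)
        hits = chrom_scan[chrom_scan["fdr"] < config.alpha]
        summary["enrichment"] = {
            "chromosome_hits": [
                {"unit": r.unit, "mode": r.gene_set_label, "fdr": r.fdr}
                for r in hits.itertuples()
            ],
            "go_hits": int((go["fdr"] < config.alpha).sum()) if len(go) else 0,
        }
        summary["te"] = {
            reg: int((te["regulation"] == reg).sum())
            for reg in enrichment.TE_REGULATIONS
        }
        logger.info("enrich: %d chromosome hits", len(hits))

    # ---- qPCR concordance ------------------------------------------------
    if "qpcr" in config.steps and config.ct_path is not None:
        def _qpcr():
            ct = read_ct_table(config.ct_path)
            folds = qpcr.fold_table(ct, sample="F1", calibrator=config.qpcr_calibrator)
            contrast = f"{config.qpcr_calibrator}_vs_F1"
            conc, table_q = qpcr.concordance(folds, de, contrast=contrast)
            write_results(table_q, outdir / "qpcr_concordance.tsv")
            return conc
        summary["qpcr"] = _stage("qpcr", _qpcr)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    logger.info("run complete; summary at %s", outdir / "summary.json")
    return summary
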