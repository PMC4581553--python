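"""Relative qPCR quantification (2^-ddCt) and concordance with RNA-seq calls.

For each (gene, sample) the target Ct is normalized to an internal-control
reference Ct (replicates averaged on the Ct scale first), then referenced to
a calibrator sample::

    dCt   = mean(ct_target) - mean(ct_reference)          per sample
    ddCt  = dCt_sample - dCt_calibrator
    fold  = 2 ** -ddCt

Concordance between qPCR folds and transcriptome calls is directional: a gene
agrees when the sign of its log2 qPCR fold matches the significant direction
of the same RNA-seq contrast.  Folds of exactly 1 are ties: counted as
non-agreements but reported in a separate "neutral" column.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def delta_ct(ct: pd.DataFrame, gene_id: str, sample: str) -> float:
    """Replicate-averaged dCt (target minus reference) for one gene/sample."""
    sub = ct[(ct["gene_id"] == gene_id) & (ct["sample"] == sample)]
    if sub.empty:
        raise ValueError(f"no Ct records for gene {gene_id!r} in sample {sample!r}")
    if sub["ct_reference"].isna().any():
        raise ValueError(f"missing reference Ct for sample {sample!r}")
    return float(sub["ct_target"].mean() - sub["ct_reference"].mean())


def ddct_fold(ct: pd.DataFrame, gene_id: str, sample: str, calibrator: str) -> float:
    """2^-ddCt fold change of ``sample`` relative to ``calibrator``."""
    ddct = delta_ct(ct, gene_id, sample) - delta_ct(ct, gene_id, calibrator)
    return float(2.0 ** -ddct)


def fold_table(
    ct: pd.DataFrame, sample: str = "F1", calibrator: str = "P1"
) -> pd.DataFrame:
    """Per-gene 2^-ddCt folds of ``sample`` against ``calibrator``."""
    genes = ct["gene_id"].unique()
    rows = [
        {"gene_id": g, "fold": ddct_fold(ct, g, sample, calibrator)} for g in genes
    ]
    return pd.DataFrame(rows, columns=["gene_id", "fold"])


def concordance(
    qpcr_folds: pd.DataFrame, de: pd.DataFrame, contrast: str = "P1_vs_F1"
) -> tuple[dict, pd.DataFrame]:
    """Direction agreement between qPCR folds and one RNA-seq contrast.

    Returns ``(summary, table)``: the summary counts agreements,
    disagreements and neutral ties (fold exactly 1) over the shared genes;
    the table lists the per-gene verdicts.  Agreement requires the RNA-seq
    direction to be significant and match ``sign(log2 fold)``.
    """
    seq = de[de["contrast"] == contrast].set_index("gene_id")["sign"]
    shared = [g for g in qpcr_folds["gene_id"] if g in seq.index]
    if not shared:
        logger.warning("no shared genes between qPCR folds and RNA-seq results")
    rows = []
    for g in shared:
        fold = float(qpcr_folds.set_index("gene_id").at[g, "fold"])
        q_sign = 0 if fold == 1.0 else int(np.sign(np.log2(fold)))
        s_sign = int(seq[g])
        if q_sign == 0:
            verdict = "neutral"
        elif q_sign == s_sign:
            verdict = "agree"
        else:
            verdict = "disagree"
        rows.append(
            {"gene_id": g, "qpcr_fold": fold, "qpcr_sign": q_sign,
             "rnaseq_sign": s_sign, "verdict": verdict}
        )
    table = pd.DataFrame(
        rows,
        columns=["gene_id", "qpcr_fold", "qpcr_sign", "rnaseq_sign", "verdict"],
    )
    summary = {
        "n": len(table),
        "agree": int((table["verdict"] == "agree").sum()) if len(table) else 0,
        "disagree": int((table["verdict"] == "disagree").sum()) if len(table) else 0,
        "neutral": int((table["verdict"] == "neutral").sum()) if len(table) else 0,
    }
    return summary, table
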