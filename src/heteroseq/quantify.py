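"""Within-sample expression quantification and expressed-set algebra.

RPKM (reads per kilobase of transcript per million mapped reads) normalizes a
raw uniquely-mapped count ``C`` for gene length ``L`` (bp) and library size
``N``::

    RPKM = 1e9 * C / (N * L)

A gene is called *expressed* in a library when its count and RPKM both clear
configurable floors (count >= 5 and RPKM >= 0.5 by default) -- a guard against
single stray reads that still keeps genuinely low-expression genes.  The
three boolean expression vectors induce the seven-region partition of the
three-set Venn diagram, from which hybrid-specific activation (expressed only
in F1) and silencing (expressed in both parents but not in F1) fall out as set
algebra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tables import LIBRARIES, CountTable

DEFAULT_MIN_COUNT = 5
DEFAULT_MIN_RPKM = 0.5

#: The seven disjoint regions of a three-set Venn diagram, keyed by which
#: libraries express the gene.
VENN_REGIONS = (
    "P1_only",
    "P2_only",
    "F1_only",
    "P1_P2_only",
    "P1_F1_only",
    "P2_F1_only",
    "all_three",
)


def rpkm(count, length_bp, lib_size):
    """Reads per kilobase per million mapped reads; vectorized.

    Linear in ``count`` and inversely proportional to both ``length_bp`` and
    ``lib_size``.  Zero or negative lengths/library sizes are domain errors.
    """
    count = np.asarray(count, dtype=float)
    length_bp = np.asarray(length_bp, dtype=float)
    lib_size = np.asarray(lib_size, dtype=float)
    if np.any(length_bp < 1):
        raise ValueError("gene length must be >= 1 bp")
    if np.any(lib_size < 1):
        raise ValueError("library size must be >= 1")
    if np.any(count < 0):
        raise ValueError("counts must be non-negative")
    out = 1e9 * count / (lib_size * length_bp)
    return out.item() if out.ndim == 0 else out


def call_expressed(
    table: CountTable,
    min_count: int = DEFAULT_MIN_COUNT,
    min_rpkm: float = DEFAULT_MIN_RPKM,
) -> pd.DataFrame:
    """Compute per-library RPKM and boolean expressed flags.

    Returns a frame with columns ``gene_id``, ``rpkm_P1/P2/F1`` and
    ``expressed_P1/P2/F1``.  The expressed flag is the deterministic rule
    ``count >= min_count AND rpkm >= min_rpkm``.
    """
    out = pd.DataFrame({"gene_id": table.gene_ids})
    lengths = table.genes["length_bp"].to_numpy()
    for lib in LIBRARIES:
        counts = table.counts(lib)
        vals = rpkm(counts, lengths, table.lib_sizes[lib])
        out[f"rpkm_{lib}"] = vals
        out[f"expressed_{lib}"] = (counts >= min_count) & (vals >= min_rpkm)
    return out


@dataclass(frozen=True)
class VennPartition:
    """Seven-region partition of genes expressed in at least one library.

    ``regions`` maps each region name to the frozenset of gene ids it holds.
    The derived sets fall out of the partition: genes silenced in the hybrid
    are exactly the P1-and-P2-only region; genes activated in the hybrid are
    exactly the F1-only region.
    """

    regions: dict[str, frozenset[str]]

    @property
    def counts(self) -> dict[str, int]:
        return {name: len(self.regions[name]) for name in VENN_REGIONS}

    @property
    def silenced_in_hybrid(self) -> frozenset[str]:
        """Expressed in both parents but not in F1."""
        return self.regions["P1_P2_only"]

    @property
    def activated_in_hybrid(self) -> frozenset[str]:
        """Expressed in F1 but in neither parent."""
        return self.regions["F1_only"]

    @property
    def n_expressed_any(self) -> int:
        return sum(len(s) for s in self.regions.values())


def venn_partition(expr: pd.DataFrame) -> VennPartition:
    """Partition expressed genes into the seven Venn regions.

    The regions are disjoint by construction and their union is the set of
    genes expressed in at least one of P1, P2, F1.
    """
    p1 = expr["expressed_P1"].to_numpy(dtype=bool)
    p2 = expr["expressed_P2"].to_numpy(dtype=bool)
    f1 = expr["expressed_F1"].to_numpy(dtype=bool)
    ids = expr["gene_id"].to_numpy()
    masks = {
        "P1_only": p1 & ~p2 & ~f1,
        "P2_only": ~p1 & p2 & ~f1,
        "F1_only": ~p1 & ~p2 & f1,
        "P1_P2_only": p1 & p2 & ~f1,
        "P1_F1_only": p1 & ~p2 & f1,
        "P2_F1_only": ~p1 & p2 & f1,
        "all_three": p1 & p2 & f1,
    }
    regions = {name: frozenset(ids[m]) for name, m in masks.items()}
    return VennPartition(regions)
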