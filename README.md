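# heteroseq

Transcriptome heterosis analysis for a parent/parent/hybrid trio of bulk
RNA-seq libraries — the classical design for asking *how* a hybrid's gene
expression departs from its parents: additively, dominantly, or beyond either
parent.

The package targets the interspecific *Brassica* setting (an allotetraploid
oilseed parent P1 with A and C subgenomes, a diploid A-genome parent P2, and
their F1 hybrid), but nothing in it is species-specific: the inputs are a
per-gene count table for three libraries, gene lengths, library sizes, and an
annotation table (chromosome A01–A10/C01–C09/unplaced, GO terms, transposable
element flags).

## What it computes

**Expression.** Within-sample abundance as RPKM, `1e9·C/(N·L)` for count *C*,
library size *N*, gene length *L*; expressed/silent calls per library
(default: count ≥ 5 and RPKM ≥ 0.5); the seven-region Venn partition of the
three expressed sets, including hybrid-specific activation (expressed only in
F1) and silencing (expressed in both parents, silent in F1).

**Differential expression.** The Audic–Claverie exact test on raw counts:
the predictive probability of count *y* given count *x* and library-size
ratio *r = N2/N1* is

    p(y|x) = r^y (x+y)! / ( x! y! (1+r)^(x+y+1) )

computed in log-gamma space; two-sided p-values by minimum-likelihood
ordering; Benjamini–Hochberg FDR within each of four contrasts: P1 vs F1,
P2 vs F1, F1 vs its expected midparent count, and P1 vs P2.

**Gene action.** Every differentially expressed gene (DEG) is classified into
one mode by a fixed decision tree over the three signed outcomes:
additivity (ADD, F1 ≈ midparent), high-/low-parent dominance (HPD/LPD,
F1 ≈ one parent while the parents differ), over-/underdominance (ODO/UDO,
F1 beyond both parents), positive/negative partial dominance (PPD/NPD,
F1 strictly between the parents but off the midparent), and a residual OTHER.
Midparent heterosis is reported as `MPH = 100·h/((P1+P2)/2)` (midparent = 100).

**Enrichment.** Upper-tail hypergeometric tests with BH correction:
per-(chromosome × mode) accumulation scans with A/C-subgenome totals, and
GO-term over-representation (term × gene-set p-value matrix exportable).
TE-flagged genes are classified Active / Inactive / Up / Down in the hybrid.

**Validation.** 2^−ΔΔCt relative qPCR quantification and direction
concordance against the transcriptome calls, and a synthetic-data generator
that produces count tables with known gene-action truth so that the whole
pipeline is testable without any download.

## Worked example

```python
from heteroseq import (simulate, default_scenario, call_expressed,
                       run_contrasts, classify_calls, recovery_report)

res = simulate(default_scenario(seed=1234))   # 5,000 genes, known modes
expr = call_expressed(res.counts)             # RPKM + expressed flags
de = run_contrasts(res.counts)                # 4 exact-test contrasts
calls = classify_calls(de, expr)              # one mode per DEG
rep = recovery_report(calls, res.truth, min_rate=100.0)
print(rep["per_mode_recovery"])
```

prints (from `python examples/simulate_and_classify.py`):

```
recovery on the >=100-RPKM stratum (1178 classifiable genes):
  ADD: 100.0%
  HPD: 92.7%
  LPD: 100.0%
  NPD: 99.0%
  ODO: 100.0%
  PPD: 98.8%
  UDO: 100.0%
overall accuracy: 99.1%
```

i.e. on well-expressed genes every true gene-action mode is recovered from
counts alone; the hardest case is high-parent dominance, whose binding
contrast (F1 vs midparent) is only a 4/3-fold change when the parents differ
two-fold. The `examples/` directory holds one short script per capability
(exact test, simulation + classification, enrichment scan, qPCR concordance,
full pipeline); each prints what it computes and what the numbers mean.

A thin CLI mirrors the library:

```
heteroseq simulate --seed 17 -o simdir/
heteroseq quantify --counts simdir/counts.tsv --lib-sizes simdir/sizes.yaml -o expr.tsv
heteroseq detest   --counts simdir/counts.tsv --lib-sizes simdir/sizes.yaml -o de.tsv
heteroseq classify --de de.tsv --expr expr.tsv -o dominance.tsv
heteroseq enrich   --dominance dominance.tsv --annot simdir/annot.tsv --mode chromosome -o enrich.tsv
heteroseq run      --seed 17 --outdir run/     # everything, summary.json at the end
```

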