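# Methods

## The design being modelled

One pooled RNA library per line — parent P1, parent P2, their F1 hybrid —
with per-gene counts of uniquely mapped reads. There are no biological
replicates anywhere in the model: the only stochasticity the inference
machinery accounts for is the technical (Poisson) sampling of reads from a
fixed transcript pool. Library sizes are supplied as metadata and never
inferred from column sums, because uniquely-mapped counts undercount
multi-mapping genes by construction.

## Expression and expressed sets

RPKM = 1e9·C/(N·L). A gene is *expressed* in a library when its count ≥
`min_count` (default 5) and RPKM ≥ `min_rpkm` (default 0.5). The count floor
guards against stray reads in shallow genes; the RPKM floor removes
length/depth artifacts in long genes. Both are configurable; neither is a
statistical test, and downstream DEG status does not depend on them.

The three boolean vectors induce the seven disjoint Venn regions. Two derived
sets matter biologically: *silenced in hybrid* (= the P1∩P2-only region) and
*activated in hybrid* (= the F1-only region).

## The exact test

For counts x (library N1) and y (library N2), the posterior-predictive
distribution of y given x is negative binomial with x+1 successes and success
probability 1/(1+r), r = N2/N1 — equivalently p(y|x) = r^y (x+y)! / (x! y!
(1+r)^(x+y+1)). The implementation evaluates the log-pmf via log-gamma
(overflow-safe for any counts) and takes cdf/sf values from
`scipy.stats.nbinom`; the direct log-space formula doubles as an independent
cross-check in the tests.

Two-sided p-values use minimum-likelihood ordering: the total mass of all
outcomes y′ with p(y′|x) ≤ p(y|x). The pmf is unimodal, so the sum is one
cdf plus one sf after a vectorized binary search for the cut point on the
side opposite the observation. Outcomes within 1e-9 of the observed log-pmf
count as ties and are included — without a slack, floating-point noise would
drop exactly-tied terms. One-sided tails are available (`sided='greater'`/
`'less'`).

This ordering reproduces the closed forms (p = 2^-y for x=0 at r=1; p = 1
for the modal outcome) but is *not* exactly symmetric under
(x,N1)↔(y,N2) — the predictive distribution conditions on x, and for
moderate counts the two orientations can differ noticeably (e.g. 0.64 vs
0.43 at x=5,y=3,r=1). A symmetric alternative (the conditional binomial
test) would lose the closed-form tails; we keep the predictive form and note
the asymmetry here.

Four contrasts per gene: P1 vs F1, P2 vs F1, MP vs F1, and P1 vs P2 (needed
to order the parents). The midparent reference count is
round(((x_P1/N_P1 + x_P2/N_P2)/2)·N_F1), i.e. the additivity expectation
placed on the F1's scale and tested with r = 1; rounding is configurable
(round/floor/ceil). Treating the midparent as a fixed count is conservative:
its true sampling variance is about half that of a real count of the same
size. Benjamini–Hochberg correction (statsmodels) runs within each contrast.

A contrast is *significant* when FDR < `alpha` (default 0.05) and
|log2 RPKM ratio| (pseudocount 1) ≥ `min_log2fc`. The fold gate defaults to
**0** (off): at two-fold effect sizes the binding classification contrast
(F1 vs midparent under parental dominance) is only a 4/3-fold change, so any
fold gate ≥ log2(4/3) ≈ 0.415 would force dominant genes into the additive
class by construction. The gate exists for users who want the classical
"significant and ≥2-fold" DEG definition for reporting.

## Gene-action classification

"≈" means non-significance of the corresponding contrast at the configured
FDR. The decision tree runs in fixed order: (1) F1 ≈ midparent → ADD;
(2) F1 above both parents → ODO; (3) below both → UDO; then, only if the
parents differ significantly, (4) F1 ≈ high parent and above the low → HPD;
(5) F1 ≈ low parent and below the high → LPD; (6) F1 strictly between
significantly different parents and off the midparent → PPD (above it) or
NPD (below); (7) everything else → OTHER. The order makes the eight modes a
partition: every DEG (significant against at least one parent) receives
exactly one label. When the parents do not differ significantly, HPD/LPD/
PPD/NPD are unreachable by construction and the residual branch absorbs the
gene.

MPH = 100·h/midparent on the RPKM scale; genes whose parents are both at
zero RPKM (hybrid-activated) get MPH = NaN rather than a division error in
bulk classification (the scalar `mph()` raises, as a zero midparent is a
domain error for the statistic itself).

Mode summaries report the three top-level rows (Additivity, Nonadditivity,
Others) as percentages of all DEGs and the six nonadditive modes as
percentages of the nonadditive total, the convention of published dominance
tables; percentages are rounded to two decimals.

## Enrichment

One upper-tail hypergeometric test per unit: P(X ≥ k) for k set-genes in a
K-gene unit, set size n, background N (`scipy.stats.hypergeom.sf`). The
upper tail matches the accumulation question; a depletion scan sits behind
`tail='lower'`. BH correction runs across each scan.

*Chromosome scan*: one test per (chromosome × dominance class); the
background is the set of classified DEGs **with** a chromosome — the scan
asks where DEGs sit, not whether chromosomes differ in expression
propensity. Unplaced genes are excluded from tests but appear in the
per-subgenome totals. *GO scan*: one test per term with ≥ `min_genes`
(default 3) background members — singleton terms would otherwise dominate
the BH ordering. No GO-DAG propagation: terms are treated as flat labels.
When scans are compared, the top hit is the smallest FDR with ties broken by
raw p-value (BH-adjusted values are running minima and tie frequently).

*TE regulation*: Active = expressed in F1, in neither parent; Inactive =
expressed in ≥1 parent, silent in F1; Up/Down = expressed in F1 and ≥1
parent with a significant midparent contrast (+1/−1). The rules are mutually
exclusive; TE genes fitting none (e.g. expressed everywhere with no
significant shift) are excluded with a log notice.

## qPCR

ΔCt = mean(target Ct) − mean(reference Ct) per sample, replicates averaged
on the Ct scale (standard practice; Ct is already logarithmic). ΔΔCt against
a calibrator sample, fold = 2^−ΔΔCt. Concordance with RNA-seq is purely
directional — sign(log2 fold) against the significant direction of the same
contrast — making it invariant to monotone rescaling of either input. Folds
of exactly 1 are counted as a separate *neutral* column, not as agreement.
No amplification-efficiency (Pfaffl) correction.

## The synthetic-data generator

The generator emulates the three-library design at desk scale. Defaults:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 5,000 | desk-scale subset of a ~40k-gene transcriptome |
| `lib_sizes` | 2×10⁶ each | mapped reads per library |
| `mode_proportions` | published table counts, normalized | 27.1% ADD; HPD/LPD/ODO/UDO/PPD/NPD ∝ 353/191/593/193/1635/1981 |
| `effect_fold` f | 2.0 | parental separation and hybrid displacement |
| `partial_parent_fold` | 10.0 | parental separation for PPD/NPD genes |
| `base_log_mean`, `base_log_sd` | ln 25, 1.5 | log-normal base rate, RPKM |
| `dispersion` | 0.0 | NB var = μ(1+dμ); 0 = Poisson |
| lengths | log-normal, mean ≈ 1300 bp, floor 200 | assembly-like unigene lengths |
| chromosome weights | A 51.7%, C 37.7%, unplaced 10.6% | allopolyploid mapping proportions |
| `te_fraction` | 0.01 | TE-flagged gene fraction |

Per gene: a base rate λ, a mode, a random parent orientation; parents at
λ·√ρ and λ/√ρ (ρ = `effect_fold`, or `partial_parent_fold` for PPD/NPD);
the hybrid rate from the mode geometry (ADD: midparent; HPD/LPD: the
high/low parent; ODO/UDO: beyond the high/low parent by f; PPD/NPD:
midparent ·/÷ √f). Counts are Poisson at rate·L·N/1e9, so expected RPKM
equals the configured rate. An optional injected enrichment places one
mode's genes on one chromosome at exactly fold× the background probability —
the scan's positive control.

Design notes, made once and kept:

* **Poisson default.** The exact test models technical sampling of single
  pooled libraries — the design being emulated. Under replicate-free
  negative-binomial noise (dispersion 0.1, CV ≈ 30% at high counts) the
  Poisson-based test necessarily flags well-expressed additive genes as
  non-additive, which is a statement about the test's assumptions, not a
  bug; a robustness test exercises dispersion 0.1 and shows strongly
  displaced modes (ODO) still recover. The `dispersion` knob exists for
  exactly such experiments.
* **PPD/NPD parental separation.** With parents only f-fold apart at f = 2,
  a hybrid at midparent·√f would sit *above the high parent* — partial
  dominance would be geometrically impossible. Partial-dominance genes
  therefore get strongly divergent parental alleles (10-fold by default;
  any value comfortably above f², i.e. where midparent·√f < high parent,
  works), keeping the hybrid strictly between the parents.
* **Base-rate scale.** Median 25 RPKM with log-sd 1.5 describes a
  moderately expressed leaf-transcriptome subset; at the default depth and
  lengths, 100 RPKM ≈ 260 expected counts, which is where the weakest
  contrast (a 4/3-fold change) first has essentially full power.

What the generator deliberately does **not** emulate: homoeolog
cross-mapping between the A and C subgenomes (counts are unambiguous by
assumption), read-level artifacts (no FASTQ), biological replicate variance
(see Poisson note), correlated GO structure (terms are sparse, Zipf-weighted,
independent of mode), and gene-family structure. Passing recovery tests
therefore show the inference machinery is correct *under its own sampling
model* — not that real cross-species mapping noise is harmless.

## Recovery benchmarks and what they show

On the default scenario, evaluation is restricted to the ≥100-RPKM stratum
and to genes passing the DEG filter; per-mode recovery is then ≥ 90% for
every mode (typically 93–100%; the binding cases are HPD/LPD, whose
midparent contrast is a 4/3-fold change). Classifying the *noiseless*
rounded expected counts recovers every mode exactly on that stratum — the
pure geometry round-trip. On an equal-rate null, the fraction of genes at
BH FDR < 0.05 stays within Monte-Carlo error of zero. The injected 5×
chromosome excess is the scan's top hit in ≈ 90–100% of seeded replicates
(the loss mode is sampling: a replicate where few of the ~140 LPD genes land
on the target chromosome *and* survive classification leaves k ≈ 10, whose
p-value a best-of-150 null cell occasionally beats).

## Numerical choices

* Log-space pmf with log-gamma everywhere; no factorials at runtime.
* Tie tolerance 1e-9 in log-pmf for minimum-likelihood inclusion.
* Midparent rounding: nearest integer (configurable).
* BH via statsmodels `multipletests(method='fdr_bh')`.
* Top-hit selection: (fdr, p_value) lexicographic, stable sort.
* Percentages rounded half-even to two decimals in mode summaries.
* Seeded `numpy.random.default_rng` throughout; a fixed config is
  byte-identical across runs.

## Limitations

Single-library design: no replicate-aware inference (negative-binomial GLMs
are out of scope by design). RPKM only — no TPM or between-sample
normalization beyond the library-size ratio inside the test. GO enrichment
is flat (no ancestor propagation). The qPCR module computes the concordance
*report*; with no published raw Ct values there is nothing to reproduce
beyond the format and forced values. Gene identifiers are opaque strings;
no attempt is made to reconcile A- and C-genome identifier schemes.
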