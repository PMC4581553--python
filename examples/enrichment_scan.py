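"""Chromosome accumulation scan with an injected positive control.

Low-parent-dominance (LPD) genes are placed on chromosome A06 at 5x their
background rate; the hypergeometric scan over every (chromosome, mode) pair
should report exactly that pair as its strongest hit.
"""

from heteroseq import (
    call_expressed,
    chromosome_scan,
    classify_calls,
    default_scenario,
    run_contrasts,
    simulate,
)
from heteroseq.enrichment import top_hit

cfg = default_scenario(seed=2024, injected_enrichment=("A06", "LPD", 5.0))
res = simulate(cfg)
de = run_contrasts(res.counts)
calls = classify_calls(de, call_expressed(res.counts))

scan, subgenomes = chromosome_scan(calls, res.annotation)
best = top_hit(scan)
print(f"top hit: {best['unit']} x {best['gene_set_label']} "
      f"(k={best['k']} of n={best['n']} set genes on a {best['K']}-gene "
      f"chromosome, background {best['N']}; p={best['p_value']:.2e}, "
      f"FDR={best['fdr']:.2e})")

sig = scan[scan["fdr"] < 0.05]
print(f"{len(sig)} of {len(scan)} (chromosome, mode) tests below FDR 0.05")

print("\nper-subgenome gene-action totals (A vs C complement):")
print(subgenomes.pivot(index="mode", columns="subgenome", values="n_genes")
      .fillna(0).astype(int).to_string())
print("-> the injected excess is the only signal; everything else is the "
      "uniform placement null")
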