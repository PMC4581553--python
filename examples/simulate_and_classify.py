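"""Simulate the desk-scale scenario, classify gene action, check recovery.

The generator draws 5,000 genes with a known dominance-mode mixture (the
proportions of a published interspecific Brassica hybrid table), produces
Poisson counts for the two parents and the hybrid, and the pipeline then
recovers each gene's mode from the three exact-test contrasts.
"""

from heteroseq import (
    call_expressed,
    classify_calls,
    default_scenario,
    recovery_report,
    run_contrasts,
    simulate,
    summarize_modes,
)

res = simulate(default_scenario(seed=1234))
expr = call_expressed(res.counts)           # RPKM + expressed flags
de = run_contrasts(res.counts)              # 4 exact-test contrasts, BH FDR
calls = classify_calls(de, expr)            # one mode per DEG

print("mode summary over", len(calls), "DEGs (number / percentage):")
print(summarize_modes(calls).to_string(index=False))

# against the generator's truth, restricted to well-expressed genes
rep = recovery_report(calls, res.truth, min_rate=100.0)
print("\nrecovery on the >=100-RPKM stratum"
      f" ({rep['n_deg']} classifiable genes):")
for mode, rec in sorted(rep["per_mode_recovery"].items()):
    print(f"  {mode}: {rec:.1%}")
print(f"overall accuracy: {rep['accuracy']:.1%}")
print("-> each true gene-action mode is recovered from counts alone;"
      " additive genes are the ones the midparent contrast leaves alone")
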