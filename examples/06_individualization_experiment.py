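"""The headline experiment: replicates vs highly inbred relatives.

Builds the calibrated panel with 23 replicate pairs plus a trio of nearly
clonal full sibs (seven generations of sib mating, F ~ 0.785) and asks each
estimator to classify every pair at the 0.8 relatedness threshold.
"""

from radkin import make_individualization_panel, run_individualization

gm, cat, st, inbred_pairs = make_individualization_panel(seed=1)
report = run_individualization(gm, st, inbred_pairs, maf_grid=(0.025,))[0.025]

print(f"panel: {gm.n_samples} samples x {report.n_loci} loci, threshold 0.8")
print(f"{'estimator':<10} {'replicates detected':>20} {'inbred separated':>18}")
for est in ("king", "dyadml"):
    print(
        f"{est:<10} {report.replicates_detected[est]:>10}/"
        f"{report.replicates_total:<9} {report.inbred_separated[est]:>9}/"
        f"{report.inbred_total}"
    )
pv = report.pair_values
inb = pv[pv.category == "inbred-relative"]
print("\ninbred-relative dyad relatedness:")
print(inb.pivot_table(index=["sample_i", "sample_j"], columns="estimator",
                      values="r").round(3))
print(
    "\nBoth estimators flag every replicate (r > 0.8), but only the "
    "allele-frequency-free counting estimator keeps the inbred relatives "
    "below the threshold; the likelihood estimator, fed panel-wide "
    "frequencies, reports them as near-clones (r > 1.5) and would merge "
    "distinct animals."
)
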