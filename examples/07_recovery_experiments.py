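"""Estimator recovery on simulated pedigrees, homogeneous vs structured.

With homogeneous Hardy-Weinberg founders both estimators are unbiased; with
founders from one drifted, inbred deme (while the likelihood estimator sees
panel-wide mixture frequencies) the likelihood estimator inflates distant
kin and the counting estimator deflates parent-offspring — the two failure
modes that matter for kin networks in fragmented populations.
"""

from radkin import (
    hwe_founder_draw,
    run_relatedness_recovery,
    structured_founder_draw,
)

n_sims = 25  # keep the demo quick; the experiments default to 100

hom = run_relatedness_recovery(
    founder_draw=hwe_founder_draw(), n_sims=n_sims, seed=1
)
struct = run_relatedness_recovery(
    founder_draw=structured_founder_draw(), n_sims=n_sims, seed=1
)

print(f"{n_sims} simulations per category; mean estimated r\n")
print(f"{'category':<24} {'theory':>6} {'hom king':>9} {'hom dyad':>9} "
      f"{'str king':>9} {'str dyad':>9}")
for cat in hom.table.category.unique():
    print(
        f"{cat:<24} {hom.theoretical(cat):>6.4f} "
        f"{hom.mean_of(cat, 'king'):>9.3f} {hom.mean_of(cat, 'dyadml'):>9.3f} "
        f"{struct.mean_of(cat, 'king'):>9.3f} "
        f"{struct.mean_of(cat, 'dyadml'):>9.3f}"
    )
print(
    "\nHomogeneous founders: both columns track theory. Structured inbred "
    "founders: the likelihood column is inflated upward (most strongly for "
    "distant kin), while the counting column underestimates "
    "parent-offspring — the direction pattern that makes frequency-free "
    "estimation the safer default here."
)
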