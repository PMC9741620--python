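"""Nine-state maximum-likelihood relatedness with bootstrap CIs.

Simulates a full-sib dyad at Hardy-Weinberg equilibrium, estimates its
Jacquard coefficients by EM, and attaches a 100-replicate locus-bootstrap
confidence interval.
"""

import numpy as np

from radkin import (
    GenotypeMatrix,
    Pedigree,
    bootstrap_ci,
    cross_genotypes,
    estimate_jacquard,
)

rng = np.random.default_rng(5)
n_loci = 1400
p = rng.uniform(0.05, 0.5, n_loci)
u = rng.random((2, n_loci))
founders = np.zeros((2, n_loci), dtype=np.int8)
founders[u < p**2] = 2
founders[(u >= p**2) & (u < p**2 + 2 * p * (1 - p))] = 1

ped = Pedigree({"A": (None, None), "B": (None, None),
                "S1": ("A", "B"), "S2": ("A", "B")})
fgm = GenotypeMatrix(("A", "B"), tuple(f"L{j}" for j in range(n_loci)), founders)
gm = cross_genotypes(ped, fgm, seed=11)

g1, g2 = gm.sample_calls("S1"), gm.sample_calls("S2")
est = estimate_jacquard(g1, g2, p, "S1", "S2")
lo, hi, ok = bootstrap_ci(g1, g2, p, n_boot=100, seed=11)

print(f"full-sib dyad over {est.n_loci} loci (theoretical r = 0.5)")
print(f"  r-hat = {est.relatedness:.3f}   95% CI [{lo:.3f}, {hi:.3f}]")
print(f"  implied inbreeding: F_i = {est.f_i:.3f}, F_j = {est.f_j:.3f}")
print("  Delta-hat =", np.round(est.coefficients.delta, 3))
print(
    "Most mass sits on states S7/S8/S9 (the non-inbred sharing states) in "
    "the classic 1/4 : 1/2 : 1/4 full-sib pattern, and the CI excludes 0."
)
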