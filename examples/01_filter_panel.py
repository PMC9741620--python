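"""Standard SNP-panel filtering: call rate, MAF, LD pruning.

Builds a small synthetic panel, degrades it, and runs the filter pipeline
in the canonical order (call-rate 0.9 -> one SNP per locus -> MAF 0.025 ->
LD pruning at r^2 > 0.8).
"""

import numpy as np

from radkin import (
    GenotypeMatrix,
    LocusCatalog,
    calibrated_config,
    simulate_panel,
    standard_filter_pipeline,
)
from radkin.genodata import MISSING

gm, cat, st, truth = simulate_panel(calibrated_config(seed=1, replicate_pairs=0))

# degrade: sprinkle missingness and duplicate a column to create perfect LD
rng = np.random.default_rng(0)
calls = gm.calls.copy()
calls[rng.random(calls.shape) < 0.08] = MISSING
calls[:, 1] = calls[:, 0]
gm = GenotypeMatrix(gm.samples, gm.loci, calls)

filtered = standard_filter_pipeline(gm, cat)
print(f"input panel:    {gm.n_samples} samples x {gm.n_loci} loci")
print(f"filtered panel: {filtered.n_samples} samples x {filtered.n_loci} loci")
print(
    "Loci failing the 90% call-rate bar, rare variants (MAF < 0.025) and "
    "one of each perfectly correlated pair are gone; the survivors are the "
    "panel every downstream estimator works from."
)
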