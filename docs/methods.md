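# Methods

`radkin` implements the statistical machinery needed to study a small,
fragmented, highly inbred population genotyped at a reduced-representation
(ddRAD-style) SNP panel: panel filtering, per-individual diversity and
inbreeding, two contrasting pairwise relatedness estimators, pedigree
theory and simulation, a calibrated synthetic-population generator, and the
individualization/recovery experiments that compare the estimators.  This
note records the models, the defaults and why, the numerical choices, and
what the synthetic data does and does not show.

## Genotype model and panel filters

Genotypes are stored as minor-allele dosage in {0, 1, 2} with a missing
sentinel; both relatedness estimators depend on dosage only, so allele
identities live exclusively in catalog metadata.  VCF input is re-polarized
on read so every locus's counted allele has frequency ≤ 0.5; write∘read is
consequently a fixpoint from the first read onwards rather than an
unconditional identity.

Filters follow the conventional pipeline order — call-rate ≥ 0.9 → one SNP
per RAD locus (lowest position, input order on ties) → MAF ≥ 0.025 → LD
pruning at r² > 0.8 — and the composition is idempotent.  LD pruning is a
greedy, order-preserving scan dropping the *later* of any violating pair,
with an optional window (default all pairs; panels here are ~10³ loci).
Genotype correlations use pairwise-complete observations; monomorphic
columns are treated as uncorrelated.  MAF is recomputed at each stage on
the current sample set.

## Heterozygosity and inbreeding

Per-individual heterozygosity is reported as heterozygous sites per
megabase: numerator the count of heterozygous calls, denominator the summed
sequenced length of loci *called in that sample* (a full-catalog
denominator is available by flag; the per-sample default avoids downward
bias from missingness).  When a catalog carries `total_callable_bp` — a SNP
panel embedded in a larger callable fraction whose monomorphic mass is not
materialized — the denominator is scaled to that total by the sample's
called fraction.

Two single-individual inbreeding estimators:

* **Moment** (observed vs expected homozygosity):
  F̂ = (O_hom − E_hom)/(L − E_hom) with E_hom = Σ(1 − 2p(1−p)) over called
  loci; clamped to [−1, 1]; undefined (NaN) when all called loci are
  monomorphic.  The 2n/(2n−1) small-sample correction is off by default
  and available for parity with tools that apply it.
* **Maximum likelihood**: maximizes Σ log P(g | F, p) with
  P(hom minor) = Fp + (1−F)p², P(het) = (1−F)2p(1−p),
  P(hom major) = F(1−p) + (1−F)(1−p)², for F ∈ [0, 1] by bounded scalar
  optimization (tolerance 1e−6, endpoints checked explicitly).  The
  boundary constraint makes F̂ for a truly non-inbred individual sit in the
  positive half of its sampling distribution (~0.01–0.04 at 1400 loci);
  tests budget for this.

Both estimators condition on supplied allele frequencies and measure
recent, frequency-detectable inbreeding; runs-of-homozygosity approaches to
deep-past inbreeding are out of scope.

## Counting (allele-frequency-free) kinship

For a dyad, over loci called in both samples, with m = min(N_het_i,
N_het_j):

    φ̂ = (N_het_both − 2·N_opp_hom) / (2m) + 1/2 − (N_het_i + N_het_j) / (4m)

and relatedness r = 2φ̂.  Identical vectors give r = 1 exactly — the
replicate criterion — and the estimate depends only on the pair's own
genotypes, so it is invariant to panel composition and hence robust to
population structure.  m = 0 (no heterozygotes in one sample) is
inestimable and reported as NaN.  The estimator carries a small negative
O(1/L) finite-panel bias from the min() in the denominator, visible as a
mean of roughly −0.01 to −0.05 across unrelated HWE panels at 1400 loci.

Duplicate detection thresholds relatedness strictly above 0.8 (the
threshold most favorable to both estimator families) and returns connected
components of the threshold graph: replicate groups are equivalence
classes, so transitive closure is the right semantics.  Negative estimates
are retained in matrices but never become network edges.

## Nine-state likelihood relatedness

The dyadic estimator parameterizes relatedness *with inbreeding* by the
nine condensed identity-state probabilities Δ1..Δ9, with

    r = 2(Δ1 + (Δ3 + Δ5 + Δ7)/2 + Δ8/4),
    F_i = Δ1+Δ2+Δ3+Δ4,  F_j = Δ1+Δ2+Δ5+Δ6.

Per-state genotype-pair probabilities are *derived at run time* from the
allele-slot partitions (each IBD class draws the minor allele independently
with the locus frequency) rather than transcribed from a table —
transcription is the main error risk — and are unit-tested against the
closed-form literature expressions.  Loci missing in either sample, with
missing frequency, or monomorphic are skipped and counted.

Δ̂ maximizes the mixture log-likelihood by EM on the 8-simplex: per-locus
state responsibilities, Δ update = mean responsibility, uniform start,
stop when the log-likelihood gain drops below 1e−6 or after 2000
iterations (non-convergence returns the best iterate, flagged).  EM is
monotone and respects the simplex by construction; an optional seeded
5-start Dirichlet restart handles flat likelihoods.  After convergence,
components below 1e−8 are snapped to zero and Δ renormalized so that e.g. a
truly unrelated dyad can report exactly r = 0.

r is deliberately **not truncated at 1**: under inbreeding r = 2φ can
legitimately exceed 1, and near-clonal inbred relatives really do produce
r > 1.5 (this is precisely the failure mode the individualization
experiment demonstrates).

Confidence intervals are 95% percentile intervals over 100 locus
bootstraps (seeded, deterministic).  Because the estimator is constrained
to r ≥ 0, its MLE for unrelated dyads is strictly positive most of the
time, and percentile CIs for unrelated pairs frequently exclude 0 by a
hair; the significance filter (CI lower bound > 0, boundary counts as
overlap) is therefore liberal for the likelihood estimator — matching the
estimator family's known tendency to report many weak "significant"
relationships where the counting estimator reports few.

## Pedigrees

Exact kinship uses the classical recursion φ(x,x) = (1+F_x)/2,
φ(x,y) = (φ(sire_x, y) + φ(dam_x, y))/2, expanding the member of greater
generation depth (which can never be an ancestor of the shallower one).
Founders are mutually unrelated by convention and carry assigned F
(default 0); a non-founder's F is its parents' kinship.

Two simulators complement the theory.  `gene_drop_ibd` drops unique
founder-allele labels (merged within a founder with probability equal to
its F) and scores IBD exactly over the four allele pairings per replicate —
the independent Monte Carlo oracle for the recursion.  `cross_genotypes`
drops real founder *genotypes*: one allele drawn uniformly from each
parent per locus, loci unlinked, missing parental calls propagating to the
offspring.  Founder inbreeding enters theory via φ(x,x) but the crossing
simulator takes founder genotypes as given — their realized homozygosity
already embodies it.  Linkage and mutation are not modeled (panels are
post-pruning, approximately independent loci).

The canonical relationship pedigrees cover seven categories
(parent–offspring and full sibs r = 0.5; half sibs, grandparent, avuncular
r = 0.25; half-avuncular r = 0.125; half-first cousins r = 0.0625) and four
parental-mating categories for offspring F (0, 0.25, 0.125, 0.03125).
Published pedigree-figure topologies are not recoverable from text, so
these canonical stand-ins plus a pedigree-file reader are shipped instead.

## Synthetic panels

`simulate_panel` draws ancestral minor-allele frequencies from a spectrum
(default Uniform(0.1, 0.5)), subpopulation frequencies from the
Balding–Nichols beta model with per-subpopulation divergence, and
individual genotypes with within-individual allelic correlation F.
Monomorphic sequence is carried as a `total_callable_bp` constant rather
than materialized.  Replicate samples copy a distinct source, mask calls
at the missingness rate, and flip genotypes one dosage step (symmetric,
direction random for hets) at the error rate — the simplest error model
that can defeat exact-match duplicate detection.  A truth record stores
every latent value so expected summaries are available in closed form;
seeded runs are byte-reproducible.

**Calibrated preset** (the study conditions): 45 individuals in 4
subpopulations (15/14/12/4), divergence 0.05 each, founder F
0.1/0.15/0.25/0.78, 1400 loci × 143 bp inside 5 Mb callable, 23 replicate
pairs at 10% missingness with no genotyping error.  Expected heterozygosity
is 104.6·(1−Fst)(1−F) SNPs/Mb ≈ 23–94 across subpopulations, spanning the
observed tens-of-SNPs/Mb regime with the small isolated subpopulation at
the bottom.  The preset was calibrated on these closed-form expectations;
the divergence value keeps a two-group structure detectable while leaving
the isolated subpopulation's distinctiveness to its extreme inbreeding, as
in the real population.

What the generator does *not* emulate: residual linkage between loci,
locus-specific coverage/error structure, admixture or migration between
subpopulations, and background kinship among founders.  Passing tests
therefore demonstrate estimator behavior under the stated statistical
structure, not under every pathology of real ddRAD data.

## Experiments

*Individualization.*  The panel is the calibrated preset plus a trio of
nearly clonal animals produced by seven successive generations of full-sib
mating seeded from the isolated subpopulation's frequencies (terminal
F = 0.785, matching the ~0.78 of the most inbred real animals; true trio
relatedness ≈ 1.65), with a replicate of one trio member — 23 replicate
pairs and 5 distinct-individual comparisons in total, mirroring the real
design.  Each estimator classifies every pair at the 0.8 threshold, at
each MAF setting in {0.025, 0.1, 0.2, 0.3}, with likelihood-estimator
frequencies recomputed panel-wide after each filter (the field situation).
The counting estimator detects all replicates *and* separates all inbred
relatives; the likelihood estimator detects all replicates but reports the
inbred relatives as near-clones.  No multiple-testing correction is
applied anywhere beyond the CI filter, by design.

*Relatedness/inbreeding recovery.*  100 gene-drop simulations per
category (1400 loci).  The homogeneous baseline draws HWE founders and
feeds the likelihood estimator the generating frequencies, isolating
estimator behavior: both estimators recover all category means within
±0.05.  The structured design draws all founders from one
Balding–Nichols deme (Fst 0.2) with founder F ~ Uniform(0.0175, 0.4783),
while the likelihood estimator sees the balanced two-deme mixture
frequencies — what a panel-wide estimate over a structured study sample
delivers.  This inflates the likelihood estimator upward (most strongly
for distant kin) and deflates the counting estimator's parent–offspring
and grandparent means, the qualitative pattern of interest.  Frequencies
*can* instead be recomputed from the simulated pedigree panel itself
(`freq_mode="panel"`), but for the small canonical pedigrees the dyad then
dominates its own frequency estimate and the likelihood collapses toward
unrelatedness — a known degeneracy, documented rather than defaulted.
Inbreeding recovery under the same structured design is markedly more
accurate than relatedness recovery, since a single individual's F absorbs
frequency misspecification more gracefully than a dyad's nine-state
mixture.

*Networks.*  Estimates pass to edges when significant (CI lower bound > 0
for the likelihood estimator; positive value for the counting estimator),
with edges classed close (r ≥ 0.2) or distant, weight = relatedness.

## Problem sizes and determinism

Defaults were chosen so every experiment runs comfortably on one core:
1400-locus panels, 100 simulations per recovery category, 100 bootstrap
replicates, 20,000 gene-drop replicates in oracle comparisons.  Every
stochastic routine takes a seed and is reproducible bit-for-bit given it;
seeds derived internally are drawn below 2³¹.

## Known limitations

* The likelihood estimator's EM can need thousands of iterations near the
  simplex boundary; the 2000-iteration cap trades a ~1e−3 relatedness
  resolution for speed (unconverged runs are flagged).
* The counting estimator is inestimable for dyads without heterozygotes in
  both members — a real concern at extreme inbreeding with tiny panels.
* Founders are assumed mutually unrelated in pedigree theory; real
  founders with unknown background kinship bias "theoretical" values low.
* The significance filter inherits the percentile bootstrap's liberality
  for boundary-constrained estimates (see above); treat likelihood-side
  distant edges as hypotheses, not findings.
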