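"""Allele-frequency-free pairwise kinship (KING-robust) and duplicate detection.

The estimator uses only the genotypes of the pair being compared — no panel
allele frequencies — which makes it robust to population structure: adding
or removing other samples can never change a pair's estimate.  With

    m  = min(N_het_i, N_het_j)

over the loci called in both samples, the robust kinship is

    phi_hat = (N_het_both - 2 N_opp_hom) / (2 m) + 1/2 - (N_het_i + N_het_j) / (4 m)

where N_het_i / N_het_j count heterozygous loci in each sample, N_het_both
loci heterozygous in both, and N_opp_hom loci with opposite homozygotes
(0 vs 2).  Identical genotype vectors give phi = 1/2 exactly, i.e.
relatedness r = 2 phi = 1 — the criterion used to recognize sequencing
replicates of the same physical individual.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeMatrix

__all__ = [
    "PairCounts",
    "RelatednessEstimate",
    "pair_counts",
    "king_robust_kinship",
    "kinship_matrix",
    "kinship_table",
    "detect_duplicates",
]


@dataclass(frozen=True)
class PairCounts:
    """Shared-loci genotype counts for one dyad."""

    n_het_i: int
    n_het_j: int
    n_het_both: int
    n_opp_hom: int
    l_shared: int

    def __post_init__(self) -> None:
        if self.n_het_both > min(self.n_het_i, self.n_het_j):
            raise ValueError("n_het_both exceeds a marginal het count")
        if self.n_opp_hom + self.n_het_both > self.l_shared:
            raise ValueError("counts exceed shared loci")


@dataclass(frozen=True)
class RelatednessEstimate:
    sample_i: str
    sample_j: str
    estimator: str
    kinship: float  # phi; relatedness r = 2 phi by construction
    n_loci: int
    ci_low: float | None = None
    ci_high: float | None = None

    @property
    def relatedness(self) -> float:
        return 2.0 * self.kinship


def pair_counts(gi: np.ndarray, gj: np.ndarray) -> PairCounts:
    """Tally het/opposite-homozygote counts over loci called in both samples."""
    gi = np.asarray(gi)
    gj = np.asarray(gj)
    if gi.shape != gj.shape:
        raise ValueError("genotype vectors must share locus ordering and length")
    shared = (gi != MISSING) & (gj != MISSING)
    a, b = gi[shared], gj[shared]
    return PairCounts(
        n_het_i=int((a == 1).sum()),
        n_het_j=int((b == 1).sum()),
        n_het_both=int(((a == 1) & (b == 1)).sum()),
        n_opp_hom=int((np.abs(a - b) == 2).sum()),
        l_shared=int(shared.sum()),
    )


def king_robust_kinship(pc: PairCounts) -> float:
    """Robust kinship phi from pair counts; NaN when neither sample is het.

    m = min of the two heterozygote counts; with m = 0 the estimator is
    undefined (no within-pair heterozygosity to scale by).
    """
    m = min(pc.n_het_i, pc.n_het_j)
    if m == 0:
        return float("nan")
    return (
        (pc.n_het_both - 2.0 * pc.n_opp_hom) / (2.0 * m)
        + 0.5
        - (pc.n_het_i + pc.n_het_j) / (4.0 * m)
    )


def kinship_matrix(gm: GenotypeMatrix) -> pd.DataFrame:
    """Symmetric sample x sample relatedness matrix (r = 2 phi), NaN diagonal."""
    if gm.n_samples < 2:
        raise ValueError("need at least two samples")
    n = gm.n_samples
    mat = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            phi = king_robust_kinship(pair_counts(gm.calls[i], gm.calls[j]))
            mat[i, j] = mat[j, i] = 2.0 * phi
    return pd.DataFrame(mat, index=list(gm.samples), columns=list(gm.samples))


def kinship_table(gm: GenotypeMatrix) -> list[RelatednessEstimate]:
    """All unordered pairs as RelatednessEstimate records."""
    out = []
    for i in range(gm.n_samples):
        for j in range(i + 1, gm.n_samples):
            pc = pair_counts(gm.calls[i], gm.calls[j])
            out.append(
                RelatednessEstimate(
                    gm.samples[i],
                    gm.samples[j],
                    "king-robust",
                    king_robust_kinship(pc),
                    pc.l_shared,
                )
            )
    return out


def detect_duplicates(
    matrix: pd.DataFrame, threshold: float = 0.8
) -> list[set[str]]:
    """Cluster samples whose pairwise relatedness exceeds ``threshold``.

    Pairs with r strictly above the threshold are joined and connected
    components returned as putative physical individuals (replicate groups
    are equivalence classes, so closure is transitive).  Missing estimates
    count as below threshold.  Singletons are included.
    """
    g = nx.Graph()
    g.add_nodes_from(matrix.index)
    vals = matrix.to_numpy()
    ids = list(matrix.index)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r = vals[i, j]
            if np.isfinite(r) and r > threshold:
                g.add_edge(ids[i], ids[j])
    return sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
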