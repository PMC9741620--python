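"""Per-individual diversity statistics: heterozygosity rate and inbreeding.

Two inbreeding estimators are provided.  The moment estimator compares
observed to expected homozygote counts (the PLINK ``--het`` statistic),

    F_hat = (O_hom - E_hom) / (L_called - E_hom),   E_hom = sum(1 - 2 p (1-p))

over loci called in the individual.  The likelihood estimator maximizes the
single-individual genotype likelihood under the inbreeding model

    P(hom minor) = F p + (1-F) p**2
    P(het)       = (1-F) 2 p (1-p)
    P(hom major) = F (1-p) + (1-F) (1-p)**2

for F in [0, 1] by bounded scalar optimization.  Both condition on the panel
allele frequencies and measure recent, frequency-detectable inbreeding —
not the deep-past signal that runs of homozygosity capture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .genodata import MISSING, GenotypeMatrix, LocusCatalog, allele_freqs

__all__ = [
    "DiversityRecord",
    "heterozygosity_rate",
    "inbreeding_moment",
    "inbreeding_ml",
    "diversity_table",
]


@dataclass(frozen=True)
class DiversityRecord:
    sample_id: str
    n_het: int
    callable_bp: float
    het_snps_per_mb: float
    f_moment: float
    f_ml: float


def heterozygosity_rate(
    calls: np.ndarray,
    cat: LocusCatalog,
    loci: tuple[str, ...],
    per_sample_denominator: bool = True,
) -> tuple[int, float, float]:
    """Heterozygous-site count, callable length and rate in SNPs/Mb.

    The numerator counts heterozygous calls; the denominator sums the
    sequenced lengths of loci with a non-missing call in this sample
    (``per_sample_denominator=False`` uses the full catalog length instead).
    When the catalog carries ``total_callable_bp`` — a panel of polymorphic
    loci embedded in a larger callable genome fraction — the denominator is
    scaled up to that total by the sample's called fraction.
    """
    lengths = cat.lengths_for(loci)
    called = calls != MISSING
    if per_sample_denominator:
        callable_bp = float(lengths[called].sum())
    else:
        callable_bp = float(lengths.sum())
    if cat.total_callable_bp is not None:
        frac = callable_bp / float(lengths.sum())
        callable_bp = cat.total_callable_bp * frac
    if callable_bp <= 0:
        raise ValueError("zero callable length: heterozygosity rate undefined")
    n_het = int((calls == 1).sum())
    return n_het, callable_bp, 1e6 * n_het / callable_bp


def inbreeding_moment(
    gm: GenotypeMatrix,
    freqs: np.ndarray | None = None,
    small_sample_correction: bool = False,
) -> np.ndarray:
    """Moment (observed vs expected homozygosity) inbreeding per sample.

    Returns NaN where the estimator is undefined (all called loci
    monomorphic).  ``small_sample_correction`` applies the 2n/(2n-1) factor
    to the expected heterozygosity, for parity with tools that use it;
    default off.  Estimates are clamped to [-1, 1].
    """
    p = allele_freqs(gm) if freqs is None else np.asarray(freqs, dtype=float)
    het_exp = 2.0 * p * (1.0 - p)
    if small_sample_correction:
        n = (gm.calls != MISSING).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            het_exp = het_exp * (2.0 * n) / (2.0 * n - 1.0)
    called = gm.calls != MISSING
    informative = called & ~np.isnan(p)
    o_hom = (informative & (gm.calls != 1)).sum(axis=1).astype(float)
    e_hom = np.where(informative, 1.0 - het_exp[None, :], 0.0).sum(axis=1)
    l_called = informative.sum(axis=1).astype(float)
    denom = l_called - e_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (o_hom - e_hom) / denom
    f = np.where(np.isclose(denom, 0.0), np.nan, f)
    return np.clip(f, -1.0, 1.0)


def _genotype_loglik(f: float, dose: np.ndarray, p: np.ndarray) -> float:
    q = 1.0 - p
    probs = np.empty_like(p)
    probs[dose == 0] = f * q[dose == 0] + (1 - f) * q[dose == 0] ** 2
    probs[dose == 1] = (1 - f) * 2 * p[dose == 1] * q[dose == 1]
    probs[dose == 2] = f * p[dose == 2] + (1 - f) * p[dose == 2] ** 2
    return float(np.log(np.maximum(probs, 1e-300)).sum())


def inbreeding_ml(
    calls: np.ndarray, freqs: np.ndarray, tol: float = 1e-6
) -> float:
    """Maximum-likelihood inbreeding coefficient for one individual, in [0, 1].

    Loci that are missing in the sample, frequency-missing, or monomorphic
    (p in {0, 1}) carry no information and are skipped.  Returns NaN when no
    informative locus remains.
    """
    p = np.asarray(freqs, dtype=float)
    ok = (calls != MISSING) & ~np.isnan(p) & (p > 0) & (p < 1)
    if not ok.any():
        return float("nan")
    dose, p = calls[ok].astype(int), p[ok]
    res = minimize_scalar(
        lambda f: -_genotype_loglik(f, dose, p),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": tol},
    )
    # bounded Brent can stall a hair inside the boundary; compare endpoints
    best_f, best_ll = float(res.x), -float(res.fun)
    for f0 in (0.0, 1.0):
        ll = _genotype_loglik(f0, dose, p)
        if ll > best_ll:
            best_f, best_ll = f0, ll
    return min(max(best_f, 0.0), 1.0)


def diversity_table(
    gm: GenotypeMatrix,
    cat: LocusCatalog,
    per_sample_denominator: bool = True,
) -> pd.DataFrame:
    """Heterozygosity rate plus both inbreeding estimators for every sample.

    Columns: sample_id, n_het, callable_bp, het_snps_per_mb, f_moment, f_ml.
    """
    freqs = allele_freqs(gm)
    f_mom = inbreeding_moment(gm, freqs)
    rows = []
    for i, sid in enumerate(gm.samples):
        calls = gm.calls[i]
        n_het, cbp, rate = heterozygosity_rate(
            calls, cat, gm.loci, per_sample_denominator
        )
        rows.append(
            DiversityRecord(
                sid, n_het, cbp, rate, float(f_mom[i]), inbreeding_ml(calls, freqs)
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
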