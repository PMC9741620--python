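"""Nine-state identity model: genotype-pair table, EM estimator, bootstrap."""

import numpy as np
import pytest

from radkin import (
    JacquardCoefficients,
    bootstrap_ci,
    dyad_loglik,
    estimate_jacquard,
    filter_significant,
    state_genotype_probs,
)
from radkin.jacquard import DyadEstimate

from .conftest import hwe_genotypes


def closed_form_table(p: float) -> np.ndarray:
    """Literature closed-form genotype-pair probabilities per condensed state.

    Independent oracle for the partition-enumeration implementation.
    Index convention: dosage of the minor allele (0 = hom major, 2 = hom
    minor); ``t[k, gi, gj]``.
    """
    q = 1.0 - p
    hwe = np.array([q * q, 2 * p * q, p * p])
    t = np.zeros((9, 3, 3))
    # S1: all four alleles IBD
    t[0, 2, 2], t[0, 0, 0] = p, q
    # S2: within-individual IBD only, the two groups independent
    t[1, 2, 2], t[1, 2, 0], t[1, 0, 2], t[1, 0, 0] = p * p, p * q, q * p, q * q
    # S3: i inbred, its allele also in j
    t[2, 2, 2], t[2, 2, 1], t[2, 0, 1], t[2, 0, 0] = p * p, p * q, q * p, q * q
    # S4: i inbred, j independent HWE
    t[3, 2, :], t[3, 0, :] = p * hwe, q * hwe
    # S5 / S6: mirror images of S3 / S4
    t[4] = t[2].T
    t[5] = t[3].T
    # S7: both of i's alleles matched across, none within
    t[6, 0, 0], t[6, 1, 1], t[6, 2, 2] = q * q, 2 * p * q, p * p
    # S8: exactly one allele shared across
    t[7, 2, 2], t[7, 2, 1], t[7, 1, 2] = p**3, p * p * q, p * p * q
    t[7, 1, 1] = p * q  # p*q*q + q*p*p
    t[7, 0, 0], t[7, 0, 1], t[7, 1, 0] = q**3, q * q * p, q * q * p
    # S9: fully independent HWE
    t[8] = np.outer(hwe, hwe)
    return t


class TestStateTable:
    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5])
    def test_matches_closed_form_oracle(self, p):
        np.testing.assert_allclose(
            state_genotype_probs(p), closed_form_table(p), atol=1e-12
        )

    def test_spot_values(self):
        t = state_genotype_probs(0.5)
        assert t[8, 1, 1] == pytest.approx(0.25)  # S9, independent hets
        assert t[6, 1, 1] == pytest.approx(0.5)  # S7, identical het pair
        assert state_genotype_probs(0.3)[0, 2, 2] == pytest.approx(0.3)  # S1

    def test_each_state_distribution_sums_to_one(self):
        t = state_genotype_probs(np.array([0.05, 0.2, 0.45]))
        np.testing.assert_allclose(t.sum(axis=(1, 2)), 1.0)

    def test_degenerate_frequency_rejected(self):
        with pytest.raises(ValueError):
            state_genotype_probs(0.0)


class TestCoefficients:
    def test_relatedness_and_inbreeding_identities(self):
        d = np.array([0.1, 0.05, 0.1, 0.05, 0.1, 0.05, 0.2, 0.15, 0.2])
        jc = JacquardCoefficients(d)
        assert jc.relatedness == pytest.approx(
            2 * (d[0] + (d[2] + d[4] + d[6]) / 2 + d[7] / 4)
        )
        assert jc.f_i == pytest.approx(d[:4].sum())
        assert jc.f_j == pytest.approx(d[0] + d[1] + d[4] + d[5])

    def test_off_simplex_rejected(self):
        with pytest.raises(ValueError):
            JacquardCoefficients(np.full(9, 0.2))


class TestDyadLoglik:
    def test_pure_state_nine_single_het_locus(self):
        e9 = np.eye(9)[8]
        ll = dyad_loglik(np.array([1]), np.array([1]), np.array([0.5]), e9)
        assert ll == pytest.approx(np.log(0.25))

    def test_pure_state_seven_equals_hwe_product(self, rng):
        p = rng.uniform(0.1, 0.5, 50)
        g = hwe_genotypes(p, 1, rng)[0]
        e7 = np.eye(9)[6]
        hwe = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        expected = float(np.log(hwe[g, np.arange(50)]).sum())
        assert dyad_loglik(g, g, p, e7) == pytest.approx(expected)

    def test_mixture_bounded_by_best_pure_state(self, rng):
        p = np.array([0.3])
        gi, gj = np.array([1]), np.array([2])
        d = rng.dirichlet(np.ones(9))
        pure = [dyad_loglik(gi, gj, p, np.eye(9)[k]) for k in range(9)]
        assert dyad_loglik(gi, gj, p, d) <= max(pure) + 1e-12


class TestEstimateJacquard:
    def test_identical_copies_give_relatedness_one(self, rng):
        p = rng.uniform(0.05, 0.5, 1400)
        g = hwe_genotypes(p, 1, rng)[0]
        est = estimate_jacquard(g, g, p)
        # sampling noise can make the copied individual look slightly
        # inbred, and r = 2*phi is deliberately not truncated at 1
        assert est.relatedness == pytest.approx(1.0, abs=0.05)

    def test_unrelated_pair_collapses_to_state_nine(self, rng):
        p = rng.uniform(0.05, 0.5, 1400)
        g = hwe_genotypes(p, 2, rng)
        est = estimate_jacquard(g[0], g[1], p)
        assert est.relatedness < 0.05
        assert est.coefficients.delta[8] > 0.9

    def test_full_sibling_recovery(self, rng):
        # non-inbred full sibs at HWE: mean r-hat near 0.5
        from radkin import Pedigree, cross_genotypes

        ped = Pedigree(
            {"A": (None, None), "B": (None, None), "S1": ("A", "B"), "S2": ("A", "B")}
        )
        vals = []
        for _ in range(25):
            p = rng.uniform(0.05, 0.5, 1400)
            founders = hwe_genotypes(p, 2, rng)
            from radkin import GenotypeMatrix

            fgm = GenotypeMatrix(
                ("A", "B"), tuple(f"L{j}" for j in range(1400)), founders
            )
            gm = cross_genotypes(ped, fgm, seed=int(rng.integers(2**31)))
            est = estimate_jacquard(
                gm.sample_calls("S1"), gm.sample_calls("S2"), p
            )
            vals.append(est.relatedness)
        assert abs(np.mean(vals) - 0.5) < 0.05

    def test_no_shared_loci_raises(self):
        with pytest.raises(ValueError):
            estimate_jacquard(np.array([-1]), np.array([1]), np.array([0.5]))


class TestBootstrap:
    def test_identically_informative_identical_samples_zero_width(self):
        # one locus pattern repeated: every resample carries the same
        # information, so the CI collapses
        g = np.tile(np.array([1], dtype=np.int8), 100)
        p = np.full(100, 0.5)
        lo, hi, ok = bootstrap_ci(g, g, p, n_boot=20, seed=0)
        assert ok
        assert hi - lo == pytest.approx(0.0, abs=1e-9)

    def test_seed_determinism(self, rng):
        p = rng.uniform(0.1, 0.5, 200)
        g = hwe_genotypes(p, 2, rng)
        a = bootstrap_ci(g[0], g[1], p, n_boot=30, seed=42)
        b = bootstrap_ci(g[0], g[1], p, n_boot=30, seed=42)
        assert a == b

    def test_unrelated_pair_lower_bound_below_kin_range(self, rng):
        # the boundary-constrained estimator keeps r >= 0, so unrelated
        # CIs need not touch 0 — but their lower bound stays far below any
        # kinship class
        p = rng.uniform(0.05, 0.5, 1400)
        lows = []
        for _ in range(5):
            g = hwe_genotypes(p, 2, rng)
            lo, _, _ = bootstrap_ci(g[0], g[1], p, n_boot=30, seed=1)
            lows.append(lo)
        assert max(lows) < 0.05


class TestSignificanceFilter:
    def _est(self, ci_low, ci_high):
        d = np.zeros(9)
        d[8] = 1.0
        return DyadEstimate(
            "a", "b", JacquardCoefficients(d), 0.0, 10, True, ci_low, ci_high
        )

    def test_boundary_rules(self):
        kept = filter_significant(
            [self._est(0.1, 0.4), self._est(-0.02, 0.3), self._est(0.0, 0.3)]
        )
        assert [(e.ci_low, e.ci_high) for e in kept] == [(0.1, 0.4)]

    def test_missing_ci_raises(self):
        d = np.zeros(9)
        d[8] = 1.0
        est = DyadEstimate("a", "b", JacquardCoefficients(d), 0.0, 10, True)
        with pytest.raises(ValueError):
            filter_significant([est])
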