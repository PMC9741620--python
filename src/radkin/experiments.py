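"""The three computational experiments, plus kin-network construction.

1. *Individualization*: can pairwise relatedness distinguish sequencing
   replicates of one individual (true r = 1) from distinct but highly
   inbred, mutually related individuals?  The counting estimator, which
   uses only the two genotype vectors, separates them; the nine-state
   likelihood estimator, fed panel-wide allele frequencies from a
   structured panel, inflates related inbred dyads past the replicate
   threshold.

2. *Relatedness recovery*: gene-drop pedigree simulations per relationship
   category, comparing each estimator's mean against the exact pedigree
   value — unbiasedness baseline with homogeneous HWE founders, systematic
   distortions with structured inbred founders.

3. *Inbreeding recovery*: the same design for the offspring of related
   parents, comparing single-individual likelihood and moment estimators
   of F against pedigree theory.

Networks: significant relatedness estimates become edges, split into close
(r >= 0.2) and distant classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .diversity import inbreeding_ml, inbreeding_moment
from .genodata import (
    GenotypeMatrix,
    LocusCatalog,
    SampleTable,
    allele_freqs,
    filter_maf,
)
from .jacquard import DyadEstimate, estimate_jacquard
from .king import RelatednessEstimate, king_robust_kinship, pair_counts
from .pedigree import (
    Pedigree,
    cross_genotypes,
    inbred_offspring_pedigrees,
    relationship_pedigrees,
    theoretical_inbreeding,
    theoretical_kinship,
)
from .synthpop import (
    ReplicateSpec,
    SyntheticPopulationConfig,
    add_replicates,
    calibrated_config,
    simulate_panel,
)

__all__ = [
    "IndividualizationReport",
    "RecoveryReport",
    "make_inbred_lineage",
    "make_individualization_panel",
    "run_individualization",
    "run_relatedness_recovery",
    "run_inbreeding_recovery",
    "hwe_founder_draw",
    "structured_founder_draw",
    "build_network",
]


# ---------------------------------------------------------------------------
# pairwise estimation helpers


def _pair_r_king(gm: GenotypeMatrix, a: str, b: str) -> float:
    pc = pair_counts(gm.sample_calls(a), gm.sample_calls(b))
    return 2.0 * king_robust_kinship(pc)


def _pair_r_dyadml(
    gm: GenotypeMatrix, a: str, b: str, freqs: np.ndarray
) -> float:
    est = estimate_jacquard(
        gm.sample_calls(a), gm.sample_calls(b), freqs, a, b
    )
    return est.relatedness


# ---------------------------------------------------------------------------
# individualization experiment


@dataclass
class IndividualizationReport:
    """Replicate-vs-inbred-relative classification outcome per estimator."""

    threshold: float
    replicates_total: int
    inbred_total: int
    replicates_detected: dict[str, int]
    inbred_separated: dict[str, int]
    pair_values: pd.DataFrame  # estimator, category, sample_i, sample_j, r
    n_loci: int

    def accuracy(self, estimator: str) -> float:
        """Fraction of all classification decisions made correctly."""
        total = self.replicates_total + self.inbred_total
        good = self.replicates_detected[estimator] + self.inbred_separated[estimator]
        return good / total


def make_inbred_lineage(
    founder_freqs: np.ndarray,
    n_generations: int = 8,
    n_offspring: int = 3,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, Pedigree, list[str]]:
    """Simulate a lineage of repeated full-sib mating within a small deme.

    Two founders are drawn at the supplied (typically drifted
    subpopulation) frequencies; each subsequent generation mates two full
    sibs.  Seven generations of sib mating bring the terminal inbreeding
    coefficient to ~0.785, the regime of the most isolated animals, and
    leave the terminal sibs nearly clonal.  Returns the genotypes of all
    lineage members, the pedigree, and the ids of the ``n_offspring``
    terminal sibs.
    """
    rng = np.random.default_rng(seed)
    parents: dict[str, tuple[str | None, str | None]] = {
        "F0a": (None, None),
        "F0b": (None, None),
    }
    prev = ("F0a", "F0b")
    for g in range(1, n_generations):
        s1, s2 = f"G{g}a", f"G{g}b"
        parents[s1] = prev
        parents[s2] = prev
        prev = (s1, s2)
    terminal = [f"T{k + 1}" for k in range(n_offspring)]
    for t in terminal:
        parents[t] = prev
    ped = Pedigree(parents)

    p = np.asarray(founder_freqs, dtype=float)
    u = rng.random((2, p.shape[0]))
    hom_minor = p**2
    het = 2 * p * (1 - p)
    calls = np.zeros((2, p.shape[0]), dtype=np.int8)
    calls[u < hom_minor] = 2
    calls[(u >= hom_minor) & (u < hom_minor + het)] = 1
    founder_gm = GenotypeMatrix(("F0a", "F0b"), tuple(f"L{j + 1:05d}" for j in range(p.shape[0])), calls)
    gm = cross_genotypes(ped, founder_gm, seed=int(rng.integers(0, 2**31 - 1)))
    return gm, ped, terminal


def make_individualization_panel(
    seed: int = 0,
    n_replicate_pairs: int = 23,
    n_inbred: int = 3,
) -> tuple[GenotypeMatrix, LocusCatalog, SampleTable, list[tuple[str, str]]]:
    """Calibrated panel plus a highly inbred related trio, replicate of one.

    The background panel carries ``n_replicate_pairs - 1`` ordinary
    replicate pairs; the inbred lineage contributes ``n_inbred`` terminal
    full sibs drawn from the isolated subpopulation's frequencies, and a
    replicate sample of the first of them (same missingness spec), for a
    total of ``n_replicate_pairs`` replicate pairs and
    ``2 * (n_inbred - 1)`` + ... distinct-individual comparisons among the
    inbred animals: all trio pairs plus the replicate against the other
    members (five comparisons for a trio).
    """
    rng = np.random.default_rng(seed)
    cfg = calibrated_config(
        seed=int(rng.integers(0, 2**31 - 1)),
        replicate_pairs=n_replicate_pairs - 1,
    )
    gm, cat, st, truth = simulate_panel(cfg)

    # inbred lineage seeded from the isolated subpopulation's frequencies
    inbred_subpop = int(np.argmax(cfg.founder_f))
    lineage_gm, _, terminal = make_inbred_lineage(
        truth.subpop_freqs[inbred_subpop],
        n_offspring=n_inbred,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    term_calls = np.vstack([lineage_gm.sample_calls(t) for t in terminal])
    names = [f"INB{k + 1}" for k in range(n_inbred)]
    gm = gm.with_samples(names, term_calls)
    table = st.table
    table = pd.concat(
        [
            table,
            pd.DataFrame(
                {
                    "sample_id": names,
                    "locality": ["isolated"] * n_inbred,
                    "sex": ["unknown"] * n_inbred,
                    "replicate_group": pd.Series([pd.NA] * n_inbred, dtype="object"),
                }
            ),
        ],
        ignore_index=True,
    )
    gm, table, _ = add_replicates(
        gm,
        table,
        ReplicateSpec(n_pairs=1, missingness=cfg.replicates.missingness),
        seed=int(rng.integers(0, 2**31 - 1)),
        sources=[names[0]],
    )
    rep_name = f"{names[0]}_rep"

    # distinct-individual comparisons among the inbred animals
    inbred_pairs = [
        (names[i], names[j])
        for i in range(n_inbred)
        for j in range(i + 1, n_inbred)
    ]
    inbred_pairs += [(rep_name, n) for n in names[1:]]
    return gm, cat, SampleTable(table), inbred_pairs


def run_individualization(
    gm: GenotypeMatrix,
    sample_table: SampleTable,
    inbred_pairs: list[tuple[str, str]],
    estimators: tuple[str, ...] = ("king", "dyadml"),
    threshold: float = 0.8,
    maf_grid: tuple[float, ...] = (0.025, 0.1, 0.2, 0.3),
) -> dict[float, IndividualizationReport]:
    """Classify replicate and inbred-relative pairs at each MAF setting.

    A replicate pair is *detected* when its relatedness exceeds the
    threshold; an inbred-relative pair is *correctly separated* when its
    relatedness does not.  The likelihood estimator receives panel-wide
    allele frequencies recomputed after each MAF filter, exactly the
    condition under which population structure inflates it.
    """
    rep_pairs = sample_table.replicate_pairs()
    rep_pairs = [p for p in rep_pairs if p not in inbred_pairs]
    if not rep_pairs:
        raise ValueError("no replicate pairs defined in the sample table")

    reports: dict[float, IndividualizationReport] = {}
    for maf in maf_grid:
        sub = filter_maf(gm, maf)
        freqs = allele_freqs(sub)
        rows = []
        detected = {e: 0 for e in estimators}
        separated = {e: 0 for e in estimators}
        for est in estimators:
            for cat_name, pairs in (
                ("replicate", rep_pairs),
                ("inbred-relative", inbred_pairs),
            ):
                for a, b in pairs:
                    if est == "king":
                        r = _pair_r_king(sub, a, b)
                    elif est == "dyadml":
                        r = _pair_r_dyadml(sub, a, b, freqs)
                    else:
                        raise ValueError(f"unknown estimator {est!r}")
                    rows.append(
                        {
                            "estimator": est,
                            "category": cat_name,
                            "sample_i": a,
                            "sample_j": b,
                            "r": r,
                        }
                    )
                    if cat_name == "replicate" and r > threshold:
                        detected[est] += 1
                    if cat_name == "inbred-relative" and not r > threshold:
                        separated[est] += 1
        reports[maf] = IndividualizationReport(
            threshold=threshold,
            replicates_total=len(rep_pairs),
            inbred_total=len(inbred_pairs),
            replicates_detected=detected,
            inbred_separated=separated,
            pair_values=pd.DataFrame(rows),
            n_loci=sub.n_loci,
        )
    return reports


# ---------------------------------------------------------------------------
# recovery experiments


@dataclass
class RecoveryReport:
    """Per-category estimator means/SDs against pedigree theory."""

    table: pd.DataFrame  # category, theoretical, estimator, mean, sd, n_sims

    def mean_of(self, category: str, estimator: str) -> float:
        t = self.table
        row = t[(t["category"] == category) & (t["estimator"] == estimator)]
        return float(row["mean"].iloc[0])

    def theoretical(self, category: str) -> float:
        t = self.table
        return float(t[t["category"] == category]["theoretical"].iloc[0])


def hwe_founder_draw(
    n_loci: int = 1400, maf_low: float = 0.05, maf_high: float = 0.5
):
    """Homogeneous-population founder sampler: HWE, non-inbred.

    Per simulation, locus frequencies are drawn Uniform(maf_low, maf_high)
    and every founder genotyped independently at HWE.  Returns
    ``(draw(founders, rng) -> (GenotypeMatrix, true_freqs))``.
    """

    def draw(founders: list[str], rng: np.random.Generator):
        p = rng.uniform(maf_low, maf_high, size=n_loci)
        u = rng.random((len(founders), n_loci))
        calls = np.zeros((len(founders), n_loci), dtype=np.int8)
        calls[u < p[None, :] ** 2] = 2
        het_hi = (p**2 + 2 * p * (1 - p))[None, :]
        calls[(u >= p[None, :] ** 2) & (u < het_hi)] = 1
        gm = GenotypeMatrix(
            tuple(founders), tuple(f"L{j + 1:05d}" for j in range(n_loci)), calls
        )
        return gm, p

    return draw


def structured_founder_draw(
    n_loci: int = 1400,
    fst: float = 0.2,
    founder_f_range: tuple[float, float] = (0.0175, 0.4783),
    maf_low: float = 0.05,
    maf_high: float = 0.5,
):
    """Structured, inbred founder sampler: pedigree founders share one deme.

    Ancestral frequencies are drawn per simulation; two demes' frequencies
    follow the Balding–Nichols beta model at divergence ``fst``.  All
    pedigree founders come from the *first* deme, each with an inbreeding
    coefficient drawn uniformly from ``founder_f_range`` (the regime of
    real founders with moderate but nonzero inbreeding).  The frequencies
    reported for the estimators are the balanced two-deme mixture — what a
    panel-wide frequency estimate over the whole structured study sample
    would deliver — so same-deme dyads systematically share drifted
    alleles the frequency model does not expect.
    """

    def draw(founders: list[str], rng: np.random.Generator):
        p_anc = rng.uniform(maf_low, maf_high, size=n_loci)
        a = p_anc * (1 - fst) / fst
        b = (1 - p_anc) * (1 - fst) / fst
        demes = np.clip(
            rng.beta(a[None, :].repeat(2, 0), b[None, :].repeat(2, 0)),
            1e-4,
            1 - 1e-4,
        )
        q = demes[0]
        calls = np.zeros((len(founders), n_loci), dtype=np.int8)
        for i in range(len(founders)):
            f = rng.uniform(*founder_f_range)
            u = rng.random(n_loci)
            hom_minor = f * q + (1 - f) * q**2
            het = (1 - f) * 2 * q * (1 - q)
            calls[i][u < hom_minor] = 2
            calls[i][(u >= hom_minor) & (u < hom_minor + het)] = 1
        gm = GenotypeMatrix(
            tuple(founders), tuple(f"L{j + 1:05d}" for j in range(n_loci)), calls
        )
        return gm, demes.mean(axis=0)

    return draw


def run_relatedness_recovery(
    pedigrees: dict[str, tuple[Pedigree, tuple[str, str]]] | None = None,
    founder_draw=None,
    n_sims: int = 100,
    seed: int = 0,
    freq_mode: str = "truth",
) -> RecoveryReport:
    """Estimate each category's dyad with both estimators over gene drops.

    ``freq_mode`` selects the frequencies fed to the likelihood estimator:
    ``"truth"`` uses the frequency vector reported by the founder draw (the
    generating frequencies for the homogeneous sampler; the panel-wide
    deme mixture for the structured one — the inflation mechanism),
    ``"panel"`` recomputes frequencies from the simulated pedigree panel
    itself.  The latter is degenerate for very small pedigrees, where the
    dyad dominates its own frequency estimate.
    """
    if pedigrees is None:
        pedigrees = relationship_pedigrees()
    if founder_draw is None:
        founder_draw = hwe_founder_draw()
    if freq_mode not in ("truth", "panel"):
        raise ValueError("freq_mode must be 'truth' or 'panel'")
    rng = np.random.default_rng(seed)
    rows = []
    for cat, (ped, (a, b)) in pedigrees.items():
        theo = 2.0 * theoretical_kinship(ped, a, b)
        vals: dict[str, list[float]] = {"king": [], "dyadml": []}
        for _ in range(n_sims):
            founder_gm, p_true = founder_draw(ped.founders(), rng)
            gm = cross_genotypes(ped, founder_gm, seed=int(rng.integers(0, 2**31 - 1)))
            freqs = p_true if freq_mode == "truth" else allele_freqs(gm)
            vals["king"].append(_pair_r_king(gm, a, b))
            vals["dyadml"].append(_pair_r_dyadml(gm, a, b, freqs))
        for est, v in vals.items():
            arr = np.asarray(v)
            rows.append(
                {
                    "category": cat,
                    "theoretical": theo,
                    "estimator": est,
                    "mean": float(np.nanmean(arr)),
                    "sd": float(np.nanstd(arr, ddof=1)),
                    "n_sims": n_sims,
                }
            )
    return RecoveryReport(pd.DataFrame(rows))


def run_inbreeding_recovery(
    pedigrees: dict[str, tuple[Pedigree, str]] | None = None,
    founder_draw=None,
    n_sims: int = 100,
    seed: int = 0,
    freq_mode: str = "truth",
) -> RecoveryReport:
    """Estimate target offspring's F (likelihood and moment) over gene drops."""
    if pedigrees is None:
        pedigrees = inbred_offspring_pedigrees()
    if founder_draw is None:
        founder_draw = hwe_founder_draw()
    rng = np.random.default_rng(seed)
    rows = []
    for cat, (ped, target) in pedigrees.items():
        theo = theoretical_inbreeding(ped, target)
        vals: dict[str, list[float]] = {"ml": [], "moment": []}
        for _ in range(n_sims):
            founder_gm, p_true = founder_draw(ped.founders(), rng)
            gm = cross_genotypes(ped, founder_gm, seed=int(rng.integers(0, 2**31 - 1)))
            freqs = p_true if freq_mode == "truth" else allele_freqs(gm)
            calls = gm.sample_calls(target)
            vals["ml"].append(inbreeding_ml(calls, freqs))
            one = GenotypeMatrix((target,), gm.loci, calls[None, :])
            vals["moment"].append(float(inbreeding_moment(one, freqs)[0]))
        for est, v in vals.items():
            arr = np.asarray(v)
            rows.append(
                {
                    "category": cat,
                    "theoretical": theo,
                    "estimator": est,
                    "mean": float(np.nanmean(arr)),
                    "sd": float(np.nanstd(arr, ddof=1)),
                    "n_sims": n_sims,
                }
            )
    return RecoveryReport(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# kin networks


def build_network(
    estimates: list[RelatednessEstimate | DyadEstimate],
    close_threshold: float = 0.2,
    localities: dict[str, str] | None = None,
) -> nx.Graph:
    """Significant relatedness estimates as an undirected weighted network.

    Estimates carrying a bootstrap CI pass the filter when the CI lower
    bound exceeds 0; estimates without a CI (the counting estimator) pass
    when positive.  Edges are classed ``close`` when r >= close_threshold,
    ``distant`` otherwise; weight = relatedness.
    """
    g = nx.Graph()
    for est in estimates:
        r = est.relatedness
        ci_low = getattr(est, "ci_low", None)
        if ci_low is not None:
            keep = ci_low > 0
        else:
            keep = np.isfinite(r) and r > 0
        if not keep:
            continue
        a, b = est.sample_i, est.sample_j
        for node in (a, b):
            g.add_node(
                node, locality=(localities or {}).get(node, "unknown")
            )
        g.add_edge(
            a,
            b,
            relatedness=float(r),
            weight=float(r),
            kin_class="close" if r >= close_threshold else "distant",
        )
    return g
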