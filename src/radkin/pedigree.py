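"""Pedigrees: exact kinship/inbreeding recursion and genotype crossing.

Theoretical kinship uses the classical recursion

    phi(x, x) = (1 + F_x) / 2
    phi(x, y) = (phi(sire_x, y) + phi(dam_x, y)) / 2     (x a descendant of
                                                          neither parent of y)

with founders mutually unrelated and founder inbreeding F supplied (default
0); a non-founder's F equals the kinship of its parents.

Two simulators complement the theory: ``cross_genotypes`` drops real founder
*genotypes* through the pedigree (one allele drawn uniformly from each
parent per locus, loci unlinked), the procedure used to test estimators on
realistic founder data whose realized homozygosity already embodies founder
inbreeding; and ``gene_drop_ibd`` drops unique founder-allele *labels* to
give a Monte Carlo estimate of kinship, serving as the independent oracle
for the recursion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeMatrix

__all__ = [
    "Pedigree",
    "theoretical_kinship",
    "theoretical_inbreeding",
    "cross_genotypes",
    "gene_drop_ibd",
    "read_pedigree_tsv",
    "relationship_pedigrees",
    "inbred_offspring_pedigrees",
]


@dataclass
class Pedigree:
    """Directed acyclic parentage structure.

    ``parents`` maps member id -> (sire, dam); founders map to (None, None).
    ``founder_f`` assigns founder inbreeding coefficients (default 0).
    """

    parents: dict[str, tuple[str | None, str | None]]
    founder_f: dict[str, float] = field(default_factory=dict)
    cohort: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ind, (sire, dam) in self.parents.items():
            if (sire is None) != (dam is None):
                raise ValueError(f"{ind}: non-founders need both parents recorded")
            for par in (sire, dam):
                if par is not None and par not in self.parents:
                    raise ValueError(f"{ind}: unknown parent {par}")
        for f in self.founder_f:
            if f not in self.parents:
                raise ValueError(f"founder_f references unknown member {f}")
        self.topological_order()  # raises on cycles

    @property
    def members(self) -> list[str]:
        return list(self.parents)

    def founders(self) -> list[str]:
        return [m for m, (s, _) in self.parents.items() if s is None]

    def is_founder(self, ind: str) -> bool:
        return self.parents[ind][0] is None

    def topological_order(self) -> list[str]:
        """Members ordered parents-before-offspring (cycle check included)."""
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(ind: str) -> None:
            st = state.get(ind, 0)
            if st == 1:
                raise ValueError(f"parentage cycle involving {ind}")
            if st == 2:
                return
            state[ind] = 1
            for par in self.parents[ind]:
                if par is not None:
                    visit(par)
            state[ind] = 2
            order.append(ind)

        for ind in self.parents:
            visit(ind)
        return order

    def depth(self, ind: str) -> int:
        sire, dam = self.parents[ind]
        if sire is None:
            return 0
        return 1 + max(self.depth(sire), self.depth(dam))


def theoretical_inbreeding(ped: Pedigree, a: str) -> float:
    """F of ``a``: assigned value for founders, parental kinship otherwise."""
    if a not in ped.parents:
        raise KeyError(f"unknown member {a}")
    sire, dam = ped.parents[a]
    if sire is None:
        return float(ped.founder_f.get(a, 0.0))
    return theoretical_kinship(ped, sire, dam)


def theoretical_kinship(ped: Pedigree, a: str, b: str) -> float:
    """Exact kinship phi(a, b) by recursion on the pedigree."""
    for ind in (a, b):
        if ind not in ped.parents:
            raise KeyError(f"unknown member {ind}")

    cache: dict[tuple[str, str], float] = {}

    def phi(x: str, y: str) -> float:
        key = (x, y) if x <= y else (y, x)
        if key in cache:
            return cache[key]
        if x == y:
            val = (1.0 + theoretical_inbreeding(ped, x)) / 2.0
        else:
            # recurse through the deeper member: it cannot be an ancestor
            # of the shallower one, so the transmission argument applies
            if ped.depth(x) < ped.depth(y):
                x, y = y, x
            sire, dam = ped.parents[x]
            if sire is None:
                val = 0.0  # two founders: unrelated by convention
            else:
                val = (phi(sire, y) + phi(dam, y)) / 2.0
        cache[key] = val
        return val

    return phi(a, b)


def cross_genotypes(
    ped: Pedigree, founder_gm: GenotypeMatrix, seed: int | None = None
) -> GenotypeMatrix:
    """Drop founder genotypes through the pedigree (unlinked Mendelian loci).

    Every founder must have a genotype row in ``founder_gm``.  Each
    non-founder receives, per locus, one allele drawn uniformly from each
    parent's two alleles, independently across loci.  A missing parental
    call makes the offspring call missing at that locus.  Deterministic
    given ``seed``.
    """
    founders = ped.founders()
    missing_f = [f for f in founders if f not in founder_gm.samples]
    if missing_f:
        raise ValueError(f"founders without genotypes: {missing_f}")
    rng = np.random.default_rng(seed)
    n_loci = founder_gm.n_loci
    geno: dict[str, np.ndarray] = {
        f: founder_gm.sample_calls(f).copy() for f in founders
    }

    def gamete(g: np.ndarray) -> np.ndarray:
        """One transmitted allele per locus: dosage contribution in {0, 1}."""
        allele = np.where(g == 2, 1, 0).astype(np.int8)
        hets = g == 1
        allele[hets] = rng.integers(0, 2, size=int(hets.sum()), dtype=np.int8)
        allele[g == MISSING] = MISSING
        return allele

    for ind in ped.topological_order():
        if ped.is_founder(ind):
            continue
        sire, dam = ped.parents[ind]
        a1, a2 = gamete(geno[sire]), gamete(geno[dam])
        child = (a1 + a2).astype(np.int8)
        child[(a1 == MISSING) | (a2 == MISSING)] = MISSING
        geno[ind] = child

    order = ped.topological_order()
    return GenotypeMatrix(
        tuple(order), founder_gm.loci, np.vstack([geno[m] for m in order])
    )


def gene_drop_ibd(
    ped: Pedigree, a: str, b: str, n_reps: int = 10_000, seed: int | None = None
) -> float:
    """Monte Carlo kinship: drop unique founder-allele labels, score IBD.

    Each founder gets two unique labels (merged with probability equal to
    its founder F, so assigned founder inbreeding is honored); labels are
    transmitted Mendelianly.  The estimate is the mean over replicates of
    the probability that one allele drawn from ``a`` matches one drawn from
    ``b`` — averaged exactly over the four allele pairings per replicate.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    order = ped.topological_order()
    founders = ped.founders()
    total = 0.0
    for _ in range(n_reps):
        labels: dict[str, tuple[int, int]] = {}
        nxt = 0
        for f in founders:
            f_coef = float(ped.founder_f.get(f, 0.0))
            if f_coef > 0 and rng.random() < f_coef:
                labels[f] = (nxt, nxt)
            else:
                labels[f] = (nxt, nxt + 1)
            nxt += 2
        for ind in order:
            if ped.is_founder(ind):
                continue
            sire, dam = ped.parents[ind]
            labels[ind] = (
                labels[sire][rng.integers(0, 2)],
                labels[dam][rng.integers(0, 2)],
            )
        la, lb = labels[a], labels[b]
        total += sum(x == y for x in la for y in lb) / 4.0
    return total / n_reps


# ---------------------------------------------------------------------------
# pedigree file I/O


def read_pedigree_tsv(path) -> Pedigree:
    """Read a pedigree TSV: id, sire, dam, founder_F, cohort.

    ``0`` or empty marks an unknown parent (founder).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    parents = {}
    founder_f = {}
    cohort = {}
    for _, row in df.iterrows():
        ind = row["id"]
        sire = row.get("sire")
        dam = row.get("dam")
        sire = None if pd.isna(sire) or sire in ("0", "") else sire
        dam = None if pd.isna(dam) or dam in ("0", "") else dam
        parents[ind] = (sire, dam)
        if "founder_F" in df.columns and pd.notna(row["founder_F"]) and sire is None:
            founder_f[ind] = float(row["founder_F"])
        if "cohort" in df.columns and pd.notna(row.get("cohort")):
            cohort[ind] = str(row["cohort"])
    return Pedigree(parents, founder_f, cohort)


# ---------------------------------------------------------------------------
# canonical pedigrees for the relationship-recovery experiments


def relationship_pedigrees(
    founder_f: float = 0.0,
) -> dict[str, tuple[Pedigree, tuple[str, str]]]:
    """Canonical pedigree per relationship category, with the scored dyad.

    Categories (theoretical r with non-inbred, unrelated founders):
    parent-offspring 0.5, full-siblings 0.5, half-siblings 0.25,
    grandparent-grandchild 0.25, uncle-nephew 0.25, half-uncle 0.125,
    half-first-cousins 0.0625.  ``founder_f`` assigns a common inbreeding
    coefficient to every founder.
    """
    def ped(parents: dict, pair: tuple[str, str]):
        founders = [m for m, (s, _) in parents.items() if s is None]
        return (
            Pedigree(parents, {f: founder_f for f in founders}),
            pair,
        )

    return {
        "parent-offspring": ped(
            {"A": (None, None), "B": (None, None), "O": ("A", "B")}, ("A", "O")
        ),
        "full-siblings": ped(
            {
                "A": (None, None),
                "B": (None, None),
                "S1": ("A", "B"),
                "S2": ("A", "B"),
            },
            ("S1", "S2"),
        ),
        "half-siblings": ped(
            {
                "A": (None, None),
                "B": (None, None),
                "C": (None, None),
                "H1": ("A", "B"),
                "H2": ("A", "C"),
            },
            ("H1", "H2"),
        ),
        "grandparent-grandchild": ped(
            {
                "A": (None, None),
                "B": (None, None),
                "C": (None, None),
                "P": ("A", "B"),
                "G": ("P", "C"),
            },
            ("A", "G"),
        ),
        "uncle-nephew": ped(
            {
                "A": (None, None),
                "B": (None, None),
                "C": (None, None),
                "U": ("A", "B"),
                "P": ("A", "B"),
                "N": ("P", "C"),
            },
            ("U", "N"),
        ),
        "half-uncle-half-nephew": ped(
            {
                "A": (None, None),
                "B": (None, None),
                "C": (None, None),
                "D": (None, None),
                "U": ("A", "B"),
                "P": ("A", "C"),
                "N": ("P", "D"),
            },
            ("U", "N"),
        ),
        "half-first-cousins": ped(
            {
                "A": (None, None),
                "B": (None, None),
                "C": (None, None),
                "D": (None, None),
                "E": (None, None),
                "P1": ("A", "B"),
                "P2": ("A", "C"),
                "X1": ("P1", "D"),
                "X2": ("P2", "E"),
            },
            ("X1", "X2"),
        ),
    }


def inbred_offspring_pedigrees(
    founder_f: float = 0.0,
) -> dict[str, tuple[Pedigree, str]]:
    """Canonical pedigrees producing offspring of related parents.

    Categories and theoretical offspring F (non-inbred founders):
    none 0, full-siblings 0.25, half-siblings 0.125,
    half-first-cousins 0.03125.  Returns (pedigree, target offspring id).
    """
    rel = relationship_pedigrees(founder_f)
    out: dict[str, tuple[Pedigree, str]] = {}

    base, _ = rel["parent-offspring"]
    none_ped = Pedigree(
        dict(base.parents), dict(base.founder_f), dict(base.cohort)
    )
    out["none"] = (none_ped, "O")

    for cat, target in (
        ("full-siblings", 0.25),
        ("half-siblings", 0.125),
        ("half-first-cousins", 0.03125),
    ):
        ped, (x, y) = rel[cat]
        parents = dict(ped.parents)
        parents["F_off"] = (x, y)
        out[cat] = (
            Pedigree(parents, dict(ped.founder_f), dict(ped.cohort)),
            "F_off",
        )
    return out
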