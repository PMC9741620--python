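"""Genotype data model, VCF/TSV readers and writers, and SNP-panel filters.

The central container is :class:`GenotypeMatrix`: individuals x biallelic
loci, each call coded as the count of the panel-minor allele (0, 1, 2) or
missing (-1).  Dosage is all either relatedness estimator in this package
needs, so no allele identities are stored beyond the catalog metadata.

The panel filters mirror the standard reduced-representation pipeline:
call-rate, one SNP per RAD locus, minor-allele frequency, and greedy LD
pruning on genotype correlation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "LocusCatalog",
    "SampleTable",
    "read_vcf",
    "write_vcf",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_sample_table",
    "read_locus_catalog",
    "allele_freqs",
    "filter_call_rate",
    "filter_maf",
    "ld_prune",
    "first_snp_per_locus",
    "standard_filter_pipeline",
]


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed into a biallelic SNP panel."""


class EmptyPanelError(ValueError):
    """Raised when an input yields zero usable biallelic SNPs."""


@dataclass(frozen=True)
class GenotypeMatrix:
    """Samples x loci minor-allele dosage matrix.

    Parameters
    ----------
    samples
        Ordered, unique sample identifiers.
    loci
        Ordered, unique locus identifiers.
    calls
        ``(n_samples, n_loci)`` int8 array with entries in {0, 1, 2} or
        :data:`MISSING`.
    """

    samples: tuple[str, ...]
    loci: tuple[str, ...]
    calls: np.ndarray

    def __post_init__(self) -> None:
        calls = np.asarray(self.calls, dtype=np.int8)
        object.__setattr__(self, "samples", tuple(self.samples))
        object.__setattr__(self, "loci", tuple(self.loci))
        object.__setattr__(self, "calls", calls)
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample identifiers must be unique")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("locus identifiers must be unique")
        if calls.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"calls shape {calls.shape} != "
                f"({len(self.samples)}, {len(self.loci)})"
            )
        ok = (calls == MISSING) | ((calls >= 0) & (calls <= 2))
        if not ok.all():
            raise ValueError("calls must be 0, 1, 2 or missing (-1)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def sample_calls(self, sample: str) -> np.ndarray:
        """Dosage vector for one sample."""
        return self.calls[self.sample_index(sample)]

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to loci selected by a boolean or index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            self.samples,
            tuple(self.loci[i] for i in keep),
            self.calls[:, keep],
        )

    def subset_samples(self, names: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in names]
        return GenotypeMatrix(tuple(names), self.loci, self.calls[idx])

    def with_samples(
        self, names: list[str], calls: np.ndarray
    ) -> "GenotypeMatrix":
        """Append extra samples (rows) sharing this panel's loci."""
        calls = np.asarray(calls, dtype=np.int8).reshape(len(names), self.n_loci)
        return GenotypeMatrix(
            self.samples + tuple(names),
            self.loci,
            np.vstack([self.calls, calls]),
        )


@dataclass
class LocusCatalog:
    """Per-locus metadata: sequenced length, panel MAF, optional position.

    ``table`` is indexed by locus id with columns ``length_bp``, ``maf``,
    ``chrom``, ``pos`` (1-based, as in VCF) and optionally ``radtag`` — the
    parent RAD-locus id used by the one-SNP-per-locus filter.

    ``total_callable_bp``: when set, the catalog represents a SNP panel
    embedded in a larger callable genome fraction (polymorphic loci plus the
    implicit monomorphic mass); per-sample heterozygosity denominators are
    scaled to it.
    """

    table: pd.DataFrame
    total_callable_bp: float | None = None

    def __post_init__(self) -> None:
        t = self.table
        if "length_bp" not in t.columns:
            raise ValueError("catalog requires a length_bp column")
        if (t["length_bp"] <= 0).any():
            raise ValueError("locus lengths must be > 0")
        if "maf" in t.columns:
            m = t["maf"].dropna()
            if ((m < 0) | (m > 0.5)).any():
                raise ValueError("MAF must lie in [0, 0.5]")

    def lengths_for(self, loci: tuple[str, ...]) -> np.ndarray:
        return self.table.loc[list(loci), "length_bp"].to_numpy(dtype=float)

    def subset(self, loci: tuple[str, ...]) -> "LocusCatalog":
        return LocusCatalog(self.table.loc[list(loci)].copy(), self.total_callable_bp)


@dataclass
class SampleTable:
    """Sample metadata: locality, sex and replicate grouping.

    Samples sharing a ``replicate_group`` are sequencing replicates of the
    same physical individual.  A sample may appear in at most one group.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "locality", "sex", "replicate_group")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"sample table requires column {col!r}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("sample ids must be unique")
        bad = ~self.table["sex"].isin(["F", "M", "unknown"])
        if bad.any():
            raise ValueError("sex must be F, M or unknown")

    def replicate_pairs(self) -> list[tuple[str, str]]:
        """All unordered sample pairs belonging to the same replicate group."""
        pairs: list[tuple[str, str]] = []
        grouped = self.table.dropna(subset=["replicate_group"])
        for _, grp in grouped.groupby("replicate_group"):
            ids = sorted(grp["sample_id"])
            pairs.extend(
                (ids[i], ids[j])
                for i in range(len(ids))
                for j in range(i + 1, len(ids))
            )
        return pairs

    def locality_of(self, sample: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample]
        return str(row["locality"].iloc[0]) if len(row) else "unknown"


# ---------------------------------------------------------------------------
# allele frequencies and polarization


def allele_freqs(gm: GenotypeMatrix) -> np.ndarray:
    """Per-locus minor-allele frequency from non-missing calls.

    Returns NaN for loci with zero called genotypes.
    """
    calls = gm.calls
    called = calls != MISSING
    n_called = called.sum(axis=0)
    minor = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = minor / (2.0 * n_called)
    freq = np.where(n_called == 0, np.nan, freq)
    return freq


def _polarize(calls: np.ndarray) -> np.ndarray:
    """Flip loci so the counted allele is the panel-minor one (freq <= 0.5)."""
    calls = calls.copy()
    called = calls != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = alt / (2.0 * n_called)
    flip = freq > 0.5
    cols = calls[:, flip]
    calls[:, flip] = np.where(cols == MISSING, MISSING, 2 - cols)
    return calls


# ---------------------------------------------------------------------------
# VCF I/O


def read_vcf(path, default_length_bp: float = 1.0):
    """Read a VCF into a (GenotypeMatrix, LocusCatalog) pair.

    Only biallelic SNP records with GT fields are kept; other records are
    skipped.  Genotype codes count the panel-minor allele: sites whose ALT
    frequency exceeds 0.5 are re-polarized after reading.  ``./.`` maps to
    missing.

    ``default_length_bp`` fills catalog lengths when the VCF carries no
    locus-length annotation (the usual case); callers that need real
    sequenced lengths should merge a locus catalog afterwards.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare Exception on bad files
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    samples = tuple(vcf.samples)
    loci: list[str] = []
    rows: list[np.ndarray] = []
    chroms: list[str] = []
    poss: list[int] = []
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            continue
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = var.gt_types
        col = np.full(len(samples), MISSING, dtype=np.int8)
        col[gt == 0] = 0
        col[gt == 1] = 1
        col[gt == 3] = 2
        lid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        loci.append(lid)
        rows.append(col)
        chroms.append(var.CHROM)
        poss.append(var.POS)
    vcf.close()
    if not loci:
        raise EmptyPanelError(f"no biallelic SNPs in {path}")

    calls = _polarize(np.column_stack(rows))
    gm = GenotypeMatrix(samples, tuple(loci), calls)
    cat = LocusCatalog(
        pd.DataFrame(
            {
                "length_bp": default_length_bp,
                "maf": allele_freqs(gm),
                "chrom": chroms,
                "pos": poss,
            },
            index=pd.Index(loci, name="locus_id"),
        )
    )
    return gm, cat


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, cat: LocusCatalog | None, path) -> None:
    """Write a GenotypeMatrix as a minimal VCF 4.2 file (GT only).

    Loci without catalog coordinates are placed on a synthetic contig
    ``panel`` at consecutive 1-based positions.  REF/ALT are written as A/C
    placeholders: the panel stores dosage, not allele identities.
    """
    if cat is not None:
        missing_loci = set(gm.loci) - set(cat.table.index)
        if missing_loci:
            raise ValueError(f"catalog lacks loci: {sorted(missing_loci)[:5]}")
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write("##contig=<ID=panel>\n")
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
        + ("\t" + "\t".join(gm.samples) if gm.samples else "")
        + "\n"
    )
    for j, locus in enumerate(gm.loci):
        chrom, pos = "panel", j + 1
        if cat is not None and {"chrom", "pos"} <= set(cat.table.columns):
            row = cat.table.loc[locus]
            if pd.notna(row.get("chrom")) and pd.notna(row.get("pos")):
                chrom, pos = str(row["chrom"]), int(row["pos"])
        gts = "\t".join(_GT_CODE[int(c)] for c in gm.calls[:, j])
        line = f"{chrom}\t{pos}\t{locus}\tA\tC\t.\tPASS\t.\tGT"
        buf.write(line + ("\t" + gts if gm.samples else "") + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# TSV I/O


def write_genotype_tsv(gm: GenotypeMatrix, path) -> None:
    """Rows = samples, columns = loci, cells 0/1/2/NA."""
    df = pd.DataFrame(
        np.where(gm.calls == MISSING, np.nan, gm.calls),
        index=list(gm.samples),
        columns=list(gm.loci),
    )
    df.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")


def read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    calls = df.to_numpy(dtype=float)
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    return GenotypeMatrix(
        tuple(str(s) for s in df.index),
        tuple(str(c) for c in df.columns),
        calls,
    )


def read_sample_table(path) -> SampleTable:
    return SampleTable(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


def read_locus_catalog(path, total_callable_bp: float | None = None) -> LocusCatalog:
    df = pd.read_csv(path, sep="\t", index_col="locus_id")
    return LocusCatalog(df, total_callable_bp)


# ---------------------------------------------------------------------------
# panel filters


def filter_call_rate(gm: GenotypeMatrix, min_called_fraction: float) -> GenotypeMatrix:
    """Keep loci genotyped in at least ``min_called_fraction`` of samples."""
    if not 0 < min_called_fraction <= 1:
        raise ValueError("min_called_fraction must be in (0, 1]")
    frac = (gm.calls != MISSING).mean(axis=0)
    return gm.subset_loci(frac >= min_called_fraction)


def filter_maf(gm: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    """Keep loci whose panel MAF (recomputed now) is >= ``min_maf``."""
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    freq = allele_freqs(gm)
    maf = np.minimum(freq, 1 - freq)
    with np.errstate(invalid="ignore"):
        keep = np.where(np.isnan(maf), min_maf <= 0, maf >= min_maf)
    return gm.subset_loci(keep)


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns, pairwise-complete."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv, yv = x[ok].astype(float), y[ok].astype(float)
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = ((xv - xv.mean()) * (yv - yv.mean())).mean() / (sx * sy)
    return float(r * r)


def ld_prune(
    gm: GenotypeMatrix, r2_max: float = 0.8, window: int | None = None
) -> GenotypeMatrix:
    """Greedy order-preserving LD pruning on genotype correlation.

    Scanning loci in panel order, a locus is dropped when its squared
    correlation with any previously *retained* locus within ``window``
    retained predecessors exceeds ``r2_max`` (default: all pairs — panels
    here are ~1e3 loci).  Deterministic; the earlier locus always wins.
    """
    if not 0 < r2_max <= 1:
        raise ValueError("r2_max must be in (0, 1]")
    kept: list[int] = []
    for j in range(gm.n_loci):
        cands = kept if window is None else kept[-window:]
        if all(
            _pairwise_r2(gm.calls[:, j], gm.calls[:, k]) <= r2_max for k in cands
        ):
            kept.append(j)
    return gm.subset_loci(np.asarray(kept, dtype=int))


def first_snp_per_locus(gm: GenotypeMatrix, cat: LocusCatalog) -> GenotypeMatrix:
    """Keep one SNP per parent RAD locus: the lowest-position SNP.

    Requires a ``radtag`` column in the catalog grouping SNPs by RAD locus;
    without one the matrix already holds one SNP per locus and is returned
    unchanged.  Position ties (or absent positions) are broken by input order.
    """
    if "radtag" not in cat.table.columns:
        return gm
    t = cat.table.loc[list(gm.loci)]
    pos = t["pos"] if "pos" in t.columns else pd.Series(range(len(t)), index=t.index)
    order = pd.DataFrame(
        {"radtag": t["radtag"].to_numpy(), "pos": pos.to_numpy(), "j": range(len(t))}
    )
    keep = (
        order.sort_values(["pos", "j"], kind="stable")
        .groupby("radtag", sort=False)
        .head(1)["j"]
        .sort_values()
        .to_numpy()
    )
    return gm.subset_loci(keep)


def standard_filter_pipeline(
    gm: GenotypeMatrix,
    cat: LocusCatalog,
    min_called_fraction: float = 0.9,
    min_maf: float = 0.025,
    r2_max: float = 0.8,
) -> GenotypeMatrix:
    """Call-rate 0.9 → one SNP per locus → MAF 0.025 → LD pruning at r²>0.8.

    The composition is idempotent: applying it to its own output returns the
    same panel.
    """
    gm = filter_call_rate(gm, min_called_fraction)
    gm = first_snp_per_locus(gm, cat)
    gm = filter_maf(gm, min_maf)
    return ld_prune(gm, r2_max)
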