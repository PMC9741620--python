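"""Genotype container, VCF/TSV round trips, and the SNP-panel filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radkin import (
    GenotypeMatrix,
    LocusCatalog,
    allele_freqs,
    filter_call_rate,
    filter_maf,
    first_snp_per_locus,
    ld_prune,
    read_genotype_tsv,
    read_vcf,
    standard_filter_pipeline,
    write_genotype_tsv,
    write_vcf,
)
from radkin.genodata import MISSING, EmptyPanelError, _pairwise_r2

from .conftest import hwe_matrix


VCF_TWO_SAMPLES = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsampA\tsampB
chr1\t100\tsnp1\tA\tC\t.\tPASS\t.\tGT\t0/1\t1/1
chr1\t200\tsnp2\tG\tT\t.\tPASS\t.\tGT\t./.\t0/0
"""


class TestGenotypeMatrix:
    def test_rejects_bad_codes(self):
        with pytest.raises(ValueError):
            GenotypeMatrix(("a",), ("L1",), np.array([[3]]))

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValueError):
            GenotypeMatrix(("a", "a"), ("L1",), np.zeros((2, 1)))

    def test_shape_checked(self):
        with pytest.raises(ValueError):
            GenotypeMatrix(("a",), ("L1", "L2"), np.zeros((1, 1)))


class TestVcf:
    def test_read_polarizes_to_minor_allele(self, tmp_path):
        # ALT frequency 3/4 at snp1 -> re-polarized so counted allele is minor
        vcf = tmp_path / "in.vcf"
        vcf.write_text(VCF_TWO_SAMPLES)
        gm, cat = read_vcf(vcf)
        j = gm.loci.index("snp1")
        assert list(gm.calls[:, j]) == [1, 0]
        assert cat.table.loc["snp1", "maf"] == pytest.approx(0.25)

    def test_missing_gt_maps_to_missing(self, tmp_path):
        vcf = tmp_path / "in.vcf"
        vcf.write_text(VCF_TWO_SAMPLES)
        gm, _ = read_vcf(vcf)
        j = gm.loci.index("snp2")
        assert gm.calls[gm.sample_index("sampA"), j] == MISSING

    def test_empty_panel_raises(self, tmp_path):
        vcf = tmp_path / "empty.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
        )
        with pytest.raises(EmptyPanelError):
            read_vcf(vcf)

    def test_single_sample_gt_codes(self, tmp_path):
        gm = GenotypeMatrix(
            ("s1",), ("a", "b", "c", "d"), np.array([[0, 1, 2, MISSING]])
        )
        out = tmp_path / "o.vcf"
        write_vcf(gm, None, out)
        body = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        assert [l.split("\t")[-1] for l in body] == ["0/0", "0/1", "1/1", "./."]

    def test_round_trip_is_a_fixpoint_on_polarized_panels(self, tmp_path, rng):
        # reading polarizes to the panel-minor allele, so write∘read is the
        # identity from the first read onwards
        p = rng.uniform(0.1, 0.5, 30)
        gm = hwe_matrix(p, 5, rng)
        calls = gm.calls.copy()
        calls[rng.random(calls.shape) < 0.1] = MISSING
        gm0 = GenotypeMatrix(gm.samples, gm.loci, calls)
        out1, out2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        write_vcf(gm0, None, out1)
        gm1, _ = read_vcf(out1)
        write_vcf(gm1, None, out2)
        gm2, _ = read_vcf(out2)
        assert gm2.samples == gm1.samples == gm0.samples
        assert gm2.loci == gm1.loci == gm0.loci
        np.testing.assert_array_equal(gm2.calls, gm1.calls)
        # and the only admissible change on first read is a polarization flip
        flipped = (gm1.calls != gm0.calls) & (gm0.calls != MISSING)
        assert np.all(gm1.calls[flipped] == 2 - gm0.calls[flipped])

    def test_tsv_round_trip(self, tmp_path, small_gm):
        out = tmp_path / "g.tsv"
        write_genotype_tsv(small_gm, out)
        gm2 = read_genotype_tsv(out)
        assert gm2.samples == small_gm.samples
        np.testing.assert_array_equal(gm2.calls, small_gm.calls)


class TestAlleleFreqs:
    @pytest.mark.parametrize(
        "column, expected",
        [([0, 1, 2], 0.5), ([0, 0, 1], 1 / 6), ([MISSING] * 3, np.nan)],
    )
    def test_hand_counts(self, column, expected):
        gm = GenotypeMatrix(
            ("a", "b", "c"), ("L1",), np.array(column).reshape(3, 1)
        )
        f = allele_freqs(gm)[0]
        if np.isnan(expected):
            assert np.isnan(f)
        else:
            assert f == pytest.approx(expected)


class TestCallRateFilter:
    def test_boundary_is_inclusive(self):
        # 9/10 called at threshold 0.9 kept; 8/10 dropped
        calls = np.ones((10, 2), dtype=np.int8)
        calls[0, 0] = MISSING
        calls[:2, 1] = MISSING
        gm = GenotypeMatrix(
            tuple(f"s{i}" for i in range(10)), ("keep", "drop"), calls
        )
        assert filter_call_rate(gm, 0.9).loci == ("keep",)

    def test_matches_enumeration_oracle(self):
        # all call counts 0..10 against a grid of thresholds
        n = 10
        cols = []
        for k in range(n + 1):
            col = np.full(n, MISSING, dtype=np.int8)
            col[:k] = 1
            cols.append(col)
        gm = GenotypeMatrix(
            tuple(f"s{i}" for i in range(n)),
            tuple(f"c{k}" for k in range(n + 1)),
            np.column_stack(cols),
        )
        for thr in [0.05, 0.1, 0.3, 0.5, 0.9, 1.0]:
            expected = tuple(f"c{k}" for k in range(n + 1) if k / n >= thr)
            assert filter_call_rate(gm, thr).loci == expected


class TestMafFilter:
    def test_singleton_frequency(self):
        # 10 samples, one het carrier: MAF = 1/20 = 0.05
        col = np.zeros((10, 1), dtype=np.int8)
        col[0] = 1
        gm = GenotypeMatrix(tuple(f"s{i}" for i in range(10)), ("L1",), col)
        assert filter_maf(gm, 0.025).n_loci == 1
        assert filter_maf(gm, 0.1).n_loci == 0

    def test_zero_threshold_is_identity(self, small_gm):
        assert filter_maf(small_gm, 0.0).loci == small_gm.loci

    def test_all_het_locus_always_kept(self):
        gm = GenotypeMatrix(
            tuple(f"s{i}" for i in range(6)),
            ("L1",),
            np.ones((6, 1), dtype=np.int8),
        )
        assert filter_maf(gm, 0.5).n_loci == 1


class TestLdPrune:
    def test_identical_columns_drop_second(self, rng):
        col = rng.integers(0, 3, 20).astype(np.int8)
        gm = GenotypeMatrix(
            tuple(f"s{i}" for i in range(20)),
            ("L1", "L2"),
            np.column_stack([col, col]),
        )
        assert ld_prune(gm, 0.8).loci == ("L1",)

    def test_uncorrelated_columns_kept(self):
        a = np.array([0, 0, 2, 2], dtype=np.int8)
        b = np.array([0, 2, 0, 2], dtype=np.int8)
        gm = GenotypeMatrix(("w", "x", "y", "z"), ("L1", "L2"), np.column_stack([a, b]))
        assert ld_prune(gm, 0.8).loci == ("L1", "L2")

    def test_result_matches_brute_force_oracle(self, rng):
        for trial in range(10):
            calls = rng.integers(0, 3, (12, 5)).astype(np.int8)
            gm = GenotypeMatrix(
                tuple(f"s{i}" for i in range(12)),
                tuple(f"L{j}" for j in range(5)),
                calls,
            )
            pruned = ld_prune(gm, 0.5)
            kept = [gm.loci.index(l) for l in pruned.loci]
            # no retained pair violates the bound
            for ai in range(len(kept)):
                for bi in range(ai + 1, len(kept)):
                    r2 = _pairwise_r2(calls[:, kept[ai]], calls[:, kept[bi]])
                    assert r2 <= 0.5 + 1e-12
            # greedy oracle: independent forward scan
            expect: list[int] = []
            for j in range(5):
                if all(
                    _pairwise_r2(calls[:, j], calls[:, k]) <= 0.5 for k in expect
                ):
                    expect.append(j)
            assert kept == expect


class TestFirstSnpPerLocus:
    def test_lowest_position_wins(self):
        import pandas as pd

        gm = GenotypeMatrix(
            ("a", "b"),
            ("s1", "s2", "s3"),
            np.array([[0, 1, 2], [1, 1, 0]], dtype=np.int8),
        )
        cat = LocusCatalog(
            pd.DataFrame(
                {
                    "length_bp": [100, 100, 100],
                    "radtag": ["t1", "t1", "t2"],
                    "pos": [50, 10, 7],
                },
                index=pd.Index(["s1", "s2", "s3"], name="locus_id"),
            )
        )
        assert first_snp_per_locus(gm, cat).loci == ("s2", "s3")


class TestPipelineProperties:
    def test_pipeline_idempotent(self, rng):
        import pandas as pd

        p = rng.uniform(0.01, 0.5, 60)
        gm = hwe_matrix(p, 20, rng)
        calls = gm.calls.copy()
        calls[rng.random(calls.shape) < 0.05] = MISSING
        # duplicate a column to give the LD filter something to remove
        calls[:, 1] = calls[:, 0]
        gm = GenotypeMatrix(gm.samples, gm.loci, calls)
        cat = LocusCatalog(
            pd.DataFrame(
                {"length_bp": 143.0},
                index=pd.Index(list(gm.loci), name="locus_id"),
            )
        )
        once = standard_filter_pipeline(gm, cat)
        twice = standard_filter_pipeline(once, cat.subset(once.loci))
        assert twice.loci == once.loci
        np.testing.assert_array_equal(twice.calls, once.calls)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_polarization_bounds_maf(self, seed):
        rng = np.random.default_rng(seed)
        calls = rng.integers(-1, 3, (8, 12)).astype(np.int8)
        from radkin.genodata import _polarize

        gm = GenotypeMatrix(
            tuple(f"s{i}" for i in range(8)),
            tuple(f"L{j}" for j in range(12)),
            _polarize(calls),
        )
        f = allele_freqs(gm)
        assert np.all((f[~np.isnan(f)] <= 0.5 + 1e-12))
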