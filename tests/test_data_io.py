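import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridgp.data_io import (
    CrossTable,
    GenotypeMatrix,
    MetabolomeMatrix,
    PhenotypeTable,
    filter_snps,
    impute_missing,
    read_crosses,
    read_genotypes,
    read_metabolome,
    read_phenotypes,
    subset_metabolome,
    write_crosses,
    write_genotypes,
    write_metabolome,
    write_phenotypes,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadGenotypes:
    def test_letter_codes_map_to_plus_minus_one(self, tmp_path):
        p = _write(
            tmp_path,
            "g.tsv",
            "line\tm1\tm2\nL1\tAA\taa\nL2\taa\tAA\nL3\tAA\tAA\n",
        )
        G = read_genotypes(p)
        assert G.codes.shape == (3, 2)
        assert set(np.unique(G.codes)) <= {-1.0, 1.0}
        # 'A' sorts before 'a': AA -> +1, aa -> -1
        assert G.codes[0, 0] == 1.0 and G.codes[0, 1] == -1.0

    def test_heterozygote_maps_to_zero(self, tmp_path):
        p = _write(tmp_path, "g.tsv", "line\tm1\nL1\tAC\nL2\tAA\nL3\tCC\n")
        G = read_genotypes(p)
        assert G.codes[0, 0] == 0.0

    def test_all_missing_column_retained(self, tmp_path):
        p = _write(tmp_path, "g.tsv", "line\tm1\tm2\nL1\t1\tNA\nL2\t-1\tNA\n")
        G = read_genotypes(p)
        assert G.n_markers == 2
        assert G.missing_fraction()[1] == 1.0

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_genotypes(tmp_path / "absent.tsv")

    def test_unknown_format(self, tmp_path):
        p = _write(tmp_path, "g.tsv", "line\tm1\nL1\t1\n")
        with pytest.raises(ValueError, match="format"):
            read_genotypes(p, format="plink")

    def test_vcf_multiallelic_skipped(self, tmp_path):
        # 5 sites, one multi-allelic: 4 markers loaded
        vcf = "\n".join(
            [
                "##fileformat=VCFv4.2",
                '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
                "##contig=<ID=1,length=1000>",
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3",
                "1\t100\ts1\tA\tG\t.\tPASS\t.\tGT\t0/0\t1/1\t0/0",
                "1\t200\ts2\tC\tT\t.\tPASS\t.\tGT\t1/1\t1/1\t0/0",
                "1\t300\ts3\tG\tA,C\t.\tPASS\t.\tGT\t0/0\t1/1\t2/2",
                "1\t400\ts4\tT\tC\t.\tPASS\t.\tGT\t0/1\t0/0\t1/1",
                "1\t500\ts5\tA\tT\t.\tPASS\t.\tGT\t0/0\t./.\t1/1",
                "",
            ]
        )
        p = _write(tmp_path, "toy.vcf", vcf)
        G = read_genotypes(p, format="vcf")
        assert G.n_markers == 4
        assert G.marker_ids == ["s1", "s2", "s4", "s5"]
        assert G.line_ids == ["S1", "S2", "S3"]
        np.testing.assert_allclose(G.codes[:, 0], [1.0, -1.0, 1.0])
        assert G.codes[0, 2] == 0.0  # het
        assert np.isnan(G.codes[1, 3])  # ./.

    def test_hapmap_reader(self, tmp_path):
        header = (
            "rs#\talleles\tchrom\tpos\tstrand\tassembly#\tcenter\tprotLSID\t"
            "assayLSID\tpanelLSID\tQCcode\tL1\tL2\tL3"
        )
        rows = ["h1\tA/G\t1\t100\t+\t.\t.\t.\t.\t.\t.\tAA\tGG\tAG",
                "h2\tC/T\t1\t200\t+\t.\t.\t.\t.\t.\t.\tCC\tNN\tTT"]
        p = _write(tmp_path, "g.hmp.txt", header + "\n" + "\n".join(rows) + "\n")
        G = read_genotypes(p, format="hapmap")
        assert G.marker_ids == ["h1", "h2"]
        np.testing.assert_allclose(G.codes[:, 0], [1.0, -1.0, 0.0])
        assert np.isnan(G.codes[1, 1])


class TestFilterSnps:
    def _geno(self, cols):
        codes = np.column_stack(cols)
        return GenotypeMatrix(
            [f"L{i}" for i in range(codes.shape[0])],
            [f"m{j}" for j in range(codes.shape[1])],
            codes,
        )

    def test_maf_010_kept(self):
        G = self._geno([np.array([1.0] * 9 + [-1.0])])
        assert filter_snps(G).n_markers == 1

    def test_maf_004_removed(self):
        # 2 of 50 minor alleles -> MAF 0.04 < 0.05
        ok = np.array([1.0] * 40 + [-1.0] * 10)  # MAF 0.2
        bad = np.array([1.0] * 48 + [-1.0] * 2)
        out = filter_snps(self._geno([ok, bad]))
        assert out.marker_ids == ["m0"]

    def test_missing_rate_02_removed(self):
        ok = np.array([1.0] * 5 + [-1.0] * 5)
        bad = np.array([1.0] * 4 + [-1.0] * 4 + [np.nan, np.nan])
        out = filter_snps(self._geno([ok, bad]))
        assert out.marker_ids == ["m0"]

    def test_boundaries_kept(self):
        # MAF exactly 0.05 (1/20 minor) and missing exactly 0.10 kept
        maf_edge = np.array([1.0] * 19 + [-1.0])
        miss_edge = np.array([1.0] * 9 + [-1.0] * 9 + [np.nan, np.nan])
        out = filter_snps(self._geno([maf_edge, miss_edge]), missing_max=0.1)
        assert out.n_markers == 2

    def test_all_removed_errors(self):
        G = self._geno([np.array([1.0] * 10)])  # MAF 0
        with pytest.raises(ValueError, match="all markers"):
            filter_snps(G)

    def test_idempotent(self, rng):
        codes = rng.choice([-1.0, 1.0, np.nan], size=(40, 30), p=[0.45, 0.45, 0.1])
        G = GenotypeMatrix(
            [f"L{i}" for i in range(40)], [f"m{j}" for j in range(30)], codes
        )
        once = filter_snps(G)
        twice = filter_snps(once)
        assert once.marker_ids == twice.marker_ids
        np.testing.assert_array_equal(once.codes, twice.codes)


class TestImputeMissing:
    def test_mean_zero(self):
        G = GenotypeMatrix(["a", "b", "c"], ["m"], np.array([[-1.0], [1.0], [np.nan]]))
        assert impute_missing(G).codes[2, 0] == 0.0

    def test_no_missing_identity(self, rng):
        codes = rng.choice([-1.0, 1.0], size=(5, 4))
        G = GenotypeMatrix([f"L{i}" for i in range(5)], [f"m{j}" for j in range(4)], codes)
        np.testing.assert_array_equal(impute_missing(G).codes, codes)

    def test_hand_mean_one_third(self):
        G = GenotypeMatrix(
            list("abcd"), ["m"], np.array([[1.0], [1.0], [np.nan], [-1.0]])
        )
        np.testing.assert_allclose(impute_missing(G).codes[2, 0], 1.0 / 3.0)

    def test_all_missing_marker_errors(self):
        G = GenotypeMatrix(list("ab"), ["m"], np.array([[np.nan], [np.nan]]))
        with pytest.raises(ValueError, match="filter"):
            impute_missing(G)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_preserves_observed_means(self, seed):
        r = np.random.default_rng(seed)
        codes = r.choice([-1.0, 1.0, np.nan], size=(12, 6), p=[0.4, 0.4, 0.2])
        codes[0] = 1.0  # ensure every marker observed at least once
        G = GenotypeMatrix([f"L{i}" for i in range(12)], [f"m{j}" for j in range(6)], codes)
        out = impute_missing(G)
        np.testing.assert_allclose(out.codes.mean(axis=0), np.nanmean(codes, axis=0))
        assert not np.isnan(out.codes).any()


class TestRoundTrips:
    def test_genotype_round_trip(self, tmp_path, rng):
        codes = rng.choice([-1.0, 0.0, 1.0, np.nan], size=(8, 5))
        G = GenotypeMatrix([f"L{i}" for i in range(8)], [f"mk{j}" for j in range(5)], codes)
        write_genotypes(G, tmp_path / "g.tsv")
        back = read_genotypes(tmp_path / "g.tsv")
        assert back.line_ids == G.line_ids and back.marker_ids == G.marker_ids
        np.testing.assert_array_equal(back.codes, G.codes)

    def test_metabolome_round_trip(self, tmp_path, rng):
        vals = rng.uniform(0, 10, size=(6, 4))
        Mx = MetabolomeMatrix(
            ["a", "a", "b", "b", "c", "c"],
            [f"m{j}" for j in range(4)],
            vals,
            replicate_index=["r1", "r2"] * 3,
        )
        write_metabolome(Mx, tmp_path / "mx.tsv")
        back = read_metabolome(tmp_path / "mx.tsv")
        assert back.replicate_index == Mx.replicate_index
        np.testing.assert_allclose(back.values, vals)

    def test_phenotype_round_trip(self, tmp_path):
        P = PhenotypeTable(["e1", "e2"], ["t1"], np.array([[1.5], [np.nan]]))
        write_phenotypes(P, tmp_path / "p.tsv")
        back = read_phenotypes(tmp_path / "p.tsv")
        np.testing.assert_array_equal(back.values, P.values)

    def test_cross_round_trip(self, tmp_path):
        C = CrossTable.from_records([("h1", "a", "b"), ("h2", "a", "c")])
        write_crosses(C, tmp_path / "c.tsv")
        back = read_crosses(tmp_path / "c.tsv")
        pd.testing.assert_frame_equal(back.table, C.table)


class TestSubsetMetabolome:
    def _mx(self, n_leaf, n_seed):
        m = n_leaf + n_seed
        ids = [f"m{j}" for j in range(m)]
        meta = pd.DataFrame(
            {"tissue": ["leaf"] * n_leaf + ["seed"] * n_seed}, index=ids
        )
        return MetabolomeMatrix(
            ["l1", "l2"], ids, np.ones((2, m)), meta=meta
        )

    def test_rice_683_of_1000(self):
        out = subset_metabolome(self._mx(683, 317), "leaf")
        assert out.n_metabolites == 683

    def test_identity_when_all_match(self):
        Mx = self._mx(5, 0)
        out = subset_metabolome(Mx, "leaf")
        assert out.metabolite_ids == Mx.metabolite_ids

    def test_unknown_tissue_errors(self):
        with pytest.raises(ValueError, match="tissue"):
            subset_metabolome(self._mx(3, 3), "root")


class TestInvariants:
    def test_duplicate_unordered_pair_rejected(self):
        with pytest.raises(ValueError, match="parent pairs"):
            CrossTable.from_records([("h1", "a", "b"), ("h2", "b", "a")])

    def test_unknown_parent_rejected(self):
        G = GenotypeMatrix(["a", "b"], ["m"], np.array([[1.0], [-1.0]]))
        C = CrossTable.from_records([("h1", "a", "z")])
        with pytest.raises(ValueError, match="absent"):
            C.validate_parents(G)

    def test_codes_outside_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[-1, 1\]"):
            GenotypeMatrix(["a"], ["m"], np.array([[2.0]]))

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            MetabolomeMatrix(["a"], ["m"], np.array([[-1.0]]))

    def test_duplicate_line_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            GenotypeMatrix(["a", "a"], ["m"], np.array([[1.0], [1.0]]))
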