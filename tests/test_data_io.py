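"""Readers/writers are mutual inverses; dosage conventions; alignment."""

import numpy as np
import pandas as pd
import pytest

from gpcattle.data import (GenotypeMatrix, PhenotypeTable, align_samples,
                           read_genotypes, read_phenotypes, write_phenotypes,
                           write_plink_raw, write_vcf)
from gpcattle.simulate import SimulationConfig, simulate_dataset, simulate_genotypes


def _toy_geno(dosages, missing=None):
    dosages = np.asarray(dosages, dtype=float)
    mask = np.zeros_like(dosages, dtype=bool) if missing is None else missing
    n, m = dosages.shape
    return GenotypeMatrix(
        dosages=np.ma.masked_array(dosages, mask=mask),
        sample_ids=[f"s{i}" for i in range(n)],
        marker_ids=[f"m{j}" for j in range(m)],
        chromosome=["1"] * m,
        position=np.arange(1, m + 1),
        counted_allele=["A"] * m,
        other_allele=["G"] * m,
    )


class TestPlinkRaw:
    def test_round_trip_identical_dosages(self, tmp_path):
        cfg = SimulationConfig(n_individuals=10, n_markers=20,
                               missing_rate=0.15, seed=3)
        geno = simulate_genotypes(cfg)
        path = tmp_path / "g.raw"
        write_plink_raw(geno, path)
        back = read_genotypes(path, format="plink_raw")
        np.testing.assert_array_equal(geno.dosages.filled(-9),
                                      back.dosages.filled(-9))
        assert list(back.marker_ids) == list(geno.marker_ids)
        assert list(back.counted_allele) == list(geno.counted_allele)

    def test_direct_dosage_mapping(self, tmp_path):
        path = tmp_path / "g.raw"
        path.write_text(
            "FID IID PAT MAT SEX PHENOTYPE m1_A m2_A m3_A\n"
            "a a 0 0 0 -9 0 1 2\n")
        geno = read_genotypes(path)
        np.testing.assert_array_equal(geno.values()[0], [0.0, 1.0, 2.0])

    def test_bad_dosage_rejected_with_line(self, tmp_path):
        path = tmp_path / "g.raw"
        path.write_text(
            "FID IID PAT MAT SEX PHENOTYPE m1_A\n"
            "a a 0 0 0 -9 1\n"
            "b b 0 0 0 -9 3\n")
        with pytest.raises(ValueError, match="line 3"):
            read_genotypes(path)

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "g.raw"
        path.write_text("FOO BAR\n1 2\n")
        with pytest.raises(ValueError, match="header"):
            read_genotypes(path)


class TestVcf:
    def test_gt_conventions(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "1\t100\tv1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\n"
            "1\t200\tv2\tA\tG\t.\t.\t.\tGT\t1|1\t./.\n")
        geno = read_genotypes(path, format="vcf")
        assert geno.dosages[0, 0] == 0 and geno.dosages[1, 0] == 1
        assert geno.dosages[0, 1] == 2            # phased hom-alt
        assert np.ma.is_masked(geno.dosages[1, 1])
        assert list(geno.counted_allele) == ["G", "G"]

    def test_non_biallelic_rejected_with_record(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "1\t100\tv1\tA\tG,T\t.\t.\t.\tGT\t0/1\n")
        with pytest.raises(ValueError, match="record 1"):
            read_genotypes(path, format="vcf")

    def test_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_individuals=8, n_markers=12,
                               missing_rate=0.1, seed=5)
        geno = simulate_genotypes(cfg)
        path = tmp_path / "rt.vcf"
        write_vcf(geno, path)
        back = read_genotypes(path, format="vcf")
        np.testing.assert_array_equal(geno.dosages.filled(-9),
                                      back.dosages.filled(-9))


class TestPhenotypeIO:
    def test_na_cell_becomes_missing(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("id\tgender\tfarm\tyear\tage\tlw\n"
                        "a\tg1\tf1\t2008\t600\t500\n"
                        "b\tg2\tf1\t2009\t610\tNA\n"
                        "c\tg1\tf2\t2008\t620\t480\n")
        tab = read_phenotypes(path)
        assert tab.trait_names == ("lw",)
        assert np.isnan(tab.trait("lw")).sum() == 1

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("id\tgender\tfarm\tyear\tage\tlw\n"
                        "a\tg1\tf1\t2008\t600\t500\n"
                        "a\tg2\tf1\t2009\t610\t460\n")
        with pytest.raises(ValueError, match="'a'"):
            read_phenotypes(path)

    def test_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_individuals=15, n_markers=10, seed=6)
        _, pheno, _ = simulate_dataset(cfg)
        path = tmp_path / "p.tsv"
        write_phenotypes(pheno, path)
        back = read_phenotypes(path)
        pd.testing.assert_frame_equal(pheno.df, back.df, check_dtype=False,
                                      atol=1e-12)


class TestAlignment:
    def _pheno(self, ids):
        return PhenotypeTable(pd.DataFrame({
            "id": ids, "gender": "g1", "farm": "f1", "year": "2008",
            "age": 600.0, "trait": 1.0}))

    def test_same_ids_different_order(self):
        geno = _toy_geno(np.zeros((3, 2)))
        pheno = self._pheno(["s2", "s0", "s1"])
        g2, p2 = align_samples(geno, pheno)
        assert list(g2.sample_ids) == list(p2.sample_ids)
        assert set(g2.sample_ids) == {"s0", "s1", "s2"}

    def test_intersection(self):
        geno = _toy_geno(np.zeros((5, 2)))
        pheno = self._pheno(["s1", "s3", "s4"])
        g2, p2 = align_samples(geno, pheno)
        assert list(g2.sample_ids) == ["s1", "s3", "s4"]
        assert p2.n_samples == 3

    def test_disjoint_rejected(self):
        geno = _toy_geno(np.zeros((2, 2)))
        pheno = self._pheno(["x1", "x2"])
        with pytest.raises(ValueError, match="shared"):
            align_samples(geno, pheno)


class TestGenotypeMatrixInvariants:
    def test_duplicate_sample_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            GenotypeMatrix(np.ma.zeros((2, 1)), ["a", "a"], ["m"], ["1"],
                           [1], ["A"], ["G"])

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            GenotypeMatrix(np.ma.zeros((1, 2)), ["a"], ["m1", "m2"],
                           ["1", "1"], [5, 1], ["A", "A"], ["G", "G"])

    def test_out_of_range_dosage_rejected(self):
        with pytest.raises(ValueError, match="dosage"):
            _toy_geno([[0.0, 3.0]])
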