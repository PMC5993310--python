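"""Format readers/writers and the genotype container invariants."""

import numpy as np
import pytest

from genoclust import (
    GenotypeFormatError,
    GenotypeMatrix,
    from_dosage,
    read_counts_csv,
    read_genepop,
    read_structure,
    read_vcf_biallelic,
    write_counts_csv,
    write_genepop,
    write_structure,
)


class TestGenotypeMatrix:
    def test_row_sums_must_equal_ploidy(self):
        counts = np.array([[2, 1], [1, 1]])  # first row sums to 3
        with pytest.raises(ValueError, match="individual 1 at locus 1"):
            GenotypeMatrix(
                counts=counts, ploidy=2, locus_names=["L1"],
                allele_labels=[["1", "2"]], individual_ids=["a", "b"],
                missing_mask=np.zeros((2, 1), dtype=bool),
            )

    def test_missing_block_must_be_zero(self):
        counts = np.array([[2, 0]])
        with pytest.raises(ValueError):
            GenotypeMatrix(
                counts=counts, ploidy=2, locus_names=["L1"],
                allele_labels=[["1", "2"]], individual_ids=["a"],
                missing_mask=np.array([[True]]),
            )

    def test_monomorphic_locus_requires_flag(self):
        counts = np.array([[2], [2]])
        kwargs = dict(
            counts=counts, ploidy=2, locus_names=["L1"], allele_labels=[["1"]],
            individual_ids=["a", "b"], missing_mask=np.zeros((2, 1), dtype=bool),
        )
        with pytest.raises(ValueError, match="monomorphic"):
            GenotypeMatrix(**kwargs)
        g = GenotypeMatrix(**kwargs, allow_monomorphic=True)
        assert g.total_alleles == 1

    def test_from_dosage_layout(self):
        g = from_dosage(np.array([[2, 0], [1, -1]]))
        assert g.counts.tolist() == [[2, 0, 0, 2], [1, 1, 0, 0]]
        assert g.missing_mask.tolist() == [[False, False], [False, True]]
        assert g.total_alleles == 4 and g.n_loci == 2


class TestGenepop:
    def test_two_individual_transcription(self, tmp_path):
        p = tmp_path / "toy.gen"
        p.write_text("title\nL1\npop\na , 0101\nb , 0102\n")
        g, pops = read_genepop(p)
        assert g.counts.tolist() == [[2, 0], [1, 1]]
        assert g.n_alleles_per_locus.tolist() == [2]
        assert pops == [0, 0]

    def test_all_zero_code_is_missing(self, tmp_path):
        p = tmp_path / "toy.gen"
        p.write_text("t\nL1,L2\npop\na , 0000 0102\nb , 0102 0202\n")
        g, _ = read_genepop(p)
        assert g.missing_mask[0, 0] and not g.missing_mask[0, 1]
        assert g.counts[0, :2].tolist() == [0, 0]

    def test_three_pop_blocks(self, tmp_path):
        lines = ["t", "L1"]
        for b in range(3):
            lines.append("pop")
            lines += [f"b{b}i{i} , 010{1 + (b + i) % 2}" for i in range(4)]
        p = tmp_path / "toy.gen"
        p.write_text("\n".join(lines) + "\n")
        g, pops = read_genepop(p)
        assert g.n_individuals == 12
        assert pops == [0] * 4 + [1] * 4 + [2] * 4

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.gen"
        p.write_text("t\nL1\npop\na 0101\n")  # no comma
        with pytest.raises(GenotypeFormatError, match=":4"):
            read_genepop(p)

    def test_inconsistent_code_width_rejected(self, tmp_path):
        p = tmp_path / "bad.gen"
        p.write_text("t\nL1,L2\npop\na , 0101 001001\n")
        with pytest.raises(GenotypeFormatError, match="width"):
            read_genepop(p)

    def test_round_trip(self, tmp_path, random_matrix):
        p = tmp_path / "rt.gen"
        write_genepop(random_matrix, p)
        g2, _ = read_genepop(p)
        assert np.array_equal(g2.counts, random_matrix.counts)
        assert np.array_equal(g2.missing_mask, random_matrix.missing_mask)
        assert g2.individual_ids == random_matrix.individual_ids


class TestStructure:
    def test_two_row_dialect(self, tmp_path):
        p = tmp_path / "toy.str"
        p.write_text("L1\nind1 1\nind1 2\n")
        g = read_structure(p, ploidy=2)
        assert g.counts.tolist() == [[1, 1]]

    def test_missing_code(self, tmp_path):
        p = tmp_path / "toy.str"
        p.write_text("L1 L2\nind1 -9 1\nind1 2 2\nind2 1 1\nind2 2 2\n")
        g = read_structure(p, ploidy=2)
        assert g.missing_mask[0, 0] and not g.missing_mask[0, 1]
        assert not g.missing_mask[1].any()

    def test_row_count_not_divisible_by_ploidy(self, tmp_path):
        p = tmp_path / "bad.str"
        p.write_text("L1\nind1 1\nind1 2\nind2 1\n")
        with pytest.raises(GenotypeFormatError, match="divisible"):
            read_structure(p, ploidy=2)

    def test_one_row_dialect(self, tmp_path):
        p = tmp_path / "toy.str"
        p.write_text("L1 L2\nind1 1 2 1 1\nind2 1 1 1 2\n")
        g = read_structure(p, ploidy=2, one_row_per_individual=True)
        # L1: ind1 heterozygous, ind2 homozygous '1'; L2 mirrored
        assert g.counts.tolist() == [[1, 1, 2, 0], [2, 0, 1, 1]]

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        dosage = rng.integers(0, 3, size=(5, 3))
        g = from_dosage(dosage)
        p = tmp_path / "rt.str"
        write_structure(g, p)
        g2 = read_structure(p, ploidy=2)
        assert g2 == g


class TestCountsCsv:
    def test_documented_dialect(self, tmp_path):
        p = tmp_path / "toy.csv"
        p.write_text("id,l1.1,l1.2,l2.1,l2.2\nind1,1,1,2,0\n")
        g = read_counts_csv(p, ploidy=2)
        assert g.counts.tolist() == [[1, 1, 2, 0]]
        assert g.locus_names == ["l1", "l2"]

    def test_bad_row_sum_names_cell(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("id,l1.1,l1.2\nind1,2,1\n")
        with pytest.raises(GenotypeFormatError, match="locus 1"):
            read_counts_csv(p, ploidy=2)

    def test_round_trip_with_missing(self, tmp_path, random_matrix):
        p = tmp_path / "rt.csv"
        write_counts_csv(random_matrix, p)
        assert read_counts_csv(p, ploidy=2) == random_matrix


class TestVcf:
    VCF = (
        "##fileformat=VCFv4.2\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
        "1\t100\t.\tA\tT\t.\t.\t.\tGT\t0/1\t1/1\n"
        "1\t200\trs2\tG\tC\t.\t.\t.\tGT\t0/0\t./.\n"
        "1\t300\t.\tA\tT,C\t.\t.\t.\tGT\t0/1\t0/2\n"
    )

    def test_biallelic_ingestion(self, tmp_path):
        p = tmp_path / "toy.vcf"
        p.write_text(self.VCF)
        g = read_vcf_biallelic(p)
        assert g.n_loci == 2 and g.n_sites_skipped == 1
        # site 1: s1 0/1 -> (1,1); s2 1/1 -> (0,2)
        assert g.counts[:, :2].tolist() == [[1, 1], [0, 2]]
        assert g.missing_mask[1, 1]  # s2 at rs2 is ./.

    def test_no_biallelic_sites_errors(self, tmp_path):
        p = tmp_path / "empty.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "1\t1\t.\tA\tT,C\t.\t.\t.\tGT\t0/1\n"
        )
        with pytest.raises(GenotypeFormatError, match="no biallelic"):
            read_vcf_biallelic(p)
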