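"""Supermatrix concatenation, Degen recoding, saturation index and exports."""

from itertools import product

import numpy as np
import pytest

from mitocomp.divergence import Alignment
from mitocomp.errors import MitocompError
from mitocomp.genetic_code import BASES, INVERTEBRATE_MITO, SET_FOR_IUPAC
from mitocomp.matrix_builder import (
    SuperMatrix,
    concatenate,
    degen_recode,
    degen_table,
    export,
    read_phylip,
    saturation_index,
    write_phylip,
)


def _aln(ids, rows, coding=False):
    return Alignment(ids=list(ids), rows=list(rows), coding=coding)


class TestConcatenate:
    def test_lengths_and_partitions_tile(self):
        a = _aln("xyz", ["A" * 300] * 3)
        b = _aln("xyz", ["C" * 450] * 3)
        sm = concatenate([("g1", a), ("g2", b)])
        assert sm.length == 750
        parts = sm.gene_partitions()
        assert [(p.start, p.end) for p in parts] == [(1, 300), (301, 750)]
        covered = sorted(
            k for p in parts for k in range(p.start, p.end + 1))
        assert covered == list(range(1, 751))

    def test_thirteen_coding_genes_give_39_codon_partitions(self):
        alns = [(f"g{i}", _aln("ab", ["ATGAAA", "ATGAAA"], coding=True))
                for i in range(13)]
        sm = concatenate(alns)
        assert len(sm.codon_partitions()) == 39

    def test_missing_taxon_filled_with_gaps(self):
        a = _aln(["x", "y"], ["ACG", "ACG"])
        b = _aln(["x"], ["TTTT"])
        sm = concatenate([("g1", a), ("g2", b)])
        assert sm.rows["y"] == "ACG" + "----"

    def test_duplicate_taxon_rejected(self):
        bad = _aln(["x", "x"], ["ACG", "ACG"])
        with pytest.raises(MitocompError, match="duplicate"):
            concatenate([("g", bad)])


class TestDegenRecode:
    def test_known_codons(self):
        table = degen_table(INVERTEBRATE_MITO)
        assert table["CTA"] == "YTN"   # Leu: CTN family + TTA via pos1
        assert table["ATG"] == "ATR"   # Met = ATA/ATG under mito code
        assert table["TGG"] == "TGR"   # Trp = TGA/TGG under mito code

    def test_table_matches_exhaustive_enumeration_oracle(self):
        """Every position symbol covers exactly the amino-acid-preserving
        substitutions, checked by independent brute-force enumeration."""
        code = INVERTEBRATE_MITO
        table = degen_table(code)
        for codon in map("".join, product(BASES, repeat=3)):
            if code.is_stop(codon):
                assert table[codon] == codon
                continue
            aa = code.amino_acid(codon)
            for p in range(3):
                expected = {
                    b for b in BASES
                    if code.amino_acid(codon[:p] + b + codon[p + 1:]) == aa}
                assert SET_FOR_IUPAC[table[codon][p]] == expected, codon

    def test_serine_families_never_blend(self):
        table = degen_table(INVERTEBRATE_MITO)
        for codon in ("TCT", "TCC", "TCA", "TCG"):
            assert SET_FOR_IUPAC[table[codon][0]] == {"T"}
        for codon in ("AGT", "AGC", "AGA", "AGG"):
            assert SET_FOR_IUPAC[table[codon][0]] == {"A"}

    def _matrix(self, rows, coding=True):
        alns = [("g", _aln([f"t{i}" for i in range(len(rows))], rows,
                           coding=coding))]
        return concatenate(alns)

    def test_idempotent_on_all_sense_codons(self):
        rows = ["".join(map("".join, product(BASES, repeat=3)))] * 2
        sm = self._matrix(rows)
        once = degen_recode(sm)
        twice = degen_recode(once)
        assert once.rows == twice.rows

    def test_amino_acid_preserved_for_single_position_expansions(self):
        """Each recoded position, expanded with the other two positions held
        at the observed codon, only ever yields the original amino acid."""
        code = INVERTEBRATE_MITO
        rows = ["".join(map("".join, product(BASES, repeat=3)))] * 2
        sm = degen_recode(self._matrix(rows))
        row = sm.rows["t0"]
        for k in range(0, len(row), 3):
            original = rows[0][k: k + 3]
            if code.is_stop(original):
                continue
            recoded = row[k: k + 3]
            for p in range(3):
                aas = {
                    code.amino_acid(original[:p] + b + original[p + 1:])
                    for b in SET_FOR_IUPAC[recoded[p]]}
                assert aas == {code.amino_acid(original)}, original

    def test_gap_codons_become_nnn_and_noncoding_untouched(self):
        a = _aln(["x", "y"], ["ATG---", "ATGCTA"], coding=True)
        b = _aln(["x", "y"], ["GGGG", "CCCC"], coding=False)
        sm = degen_recode(concatenate([("cds", a), ("rrn", b)]))
        assert sm.rows["x"] == "ATRNNNGGGG"
        assert sm.rows["y"].endswith("CCCC")


class TestSaturationIndex:
    def test_invariant_alignment_zero(self):
        sm = SuperMatrix(taxa=["a", "b", "c", "d"],
                         rows={t: "AAAA" for t in "abcd"}, partitions=[])
        assert saturation_index(sm).iss_observed == 0.0

    def test_fully_random_equal_frequency_alignment_near_one(self):
        rng = np.random.default_rng(13)
        taxa = [f"t{i}" for i in range(8)]
        rows = {t: "".join(rng.choice(list("ACGT"), size=10000))
                for t in taxa}
        sm = SuperMatrix(taxa=taxa, rows=rows, partitions=[])
        res = saturation_index(sm)
        assert res.iss_observed == pytest.approx(1.0, abs=0.02)
        # finite-sample reference for 8 sequences sits well below 2 bits
        assert 1.6 < res.full_saturation_entropy < 2.0

    def test_maximally_variable_site_entropy(self):
        # a 4-taxon site carrying all four bases has the full 2 bits;
        # the full-saturation reference for 4 sequences is below 2 bits,
        # so a single such site scores above 1
        sm = SuperMatrix(
            taxa=list("abcd"),
            rows={"a": "A", "b": "C", "c": "G", "d": "T"}, partitions=[])
        res = saturation_index(sm)
        assert res.mean_site_entropy == pytest.approx(2.0)
        assert res.full_saturation_entropy < 2.0
        assert res.iss_observed == pytest.approx(
            2.0 / res.full_saturation_entropy)

    def test_invariant_under_taxon_and_site_permutation(self):
        rng = np.random.default_rng(23)
        taxa = [f"t{i}" for i in range(5)]
        mat = rng.choice(list("ACGT"), size=(5, 400))
        rows = {t: "".join(mat[i]) for i, t in enumerate(taxa)}
        sm = SuperMatrix(taxa=taxa, rows=rows, partitions=[])
        ref = saturation_index(sm).iss_observed
        perm = rng.permutation(400)
        rows2 = {t: "".join(mat[i][perm]) for i, t in enumerate(taxa)}
        sm2 = SuperMatrix(taxa=taxa[::-1], rows=rows2, partitions=[])
        assert saturation_index(sm2).iss_observed == pytest.approx(ref)

    def test_all_gap_columns_skipped(self):
        sm = SuperMatrix(taxa=list("ab"),
                         rows={"a": "A-A", "b": "A-A"}, partitions=[])
        assert saturation_index(sm).skipped_columns == 1


class TestExports:
    def _toy_matrix(self):
        a = _aln(["sp one", "sp_two", "sp3"],
                 ["ATGCTAAAA", "ATGCTGAAA", "ATACTAAAG"], coding=True)
        b = _aln(["sp one", "sp_two", "sp3"], ["GGTT", "GCTT", "GGTA"])
        return concatenate([("cds", a), ("rrn", b)])

    def test_phylip_round_trip_byte_identical(self, tmp_path):
        sm = self._toy_matrix()
        p1, p2 = tmp_path / "m1.phy", tmp_path / "m2.phy"
        write_phylip(sm, p1)
        back = read_phylip(p1)
        write_phylip(back, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_raxml_partition_lines(self, tmp_path):
        alns = [(f"g{i}", _aln("ab", ["ATGAAA", "ATGAAA"], coding=True))
                for i in range(13)]
        sm = concatenate(alns)
        export(sm, tmp_path / "mat", formats=("raxml",))
        lines = (tmp_path / "mat.partitions.txt").read_text().splitlines()
        codon_lines = [l for l in lines if "\\3" in l]
        assert len(codon_lines) == 39

    def test_nexus_parses_in_independent_reader(self, tmp_path):
        import dendropy
        sm = self._toy_matrix()
        export(sm, tmp_path / "toy", formats=("nexus",))
        mat = dendropy.DnaCharacterMatrix.get(
            path=str(tmp_path / "toy.nex"), schema="nexus")
        assert len(mat) == 3
        assert mat.max_sequence_size == sm.length

    def test_sanitized_name_mapping_written(self, tmp_path):
        sm = self._toy_matrix()
        written = export(sm, tmp_path / "toy", formats=("phylip",))
        assert str(tmp_path / "toy.names.tsv") in written
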