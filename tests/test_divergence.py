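"""Pairwise divergence, syn/rep classification, Pi and sliding windows."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitocomp.divergence import (
    Alignment,
    nucleotide_diversity,
    pairwise_identity,
    pairwise_stats,
    sliding_window,
)
from mitocomp.errors import ArityError, WindowError


def _aln(*rows, coding=False):
    return Alignment(ids=[f"t{i}" for i in range(len(rows))],
                     rows=list(rows), coding=coding)


class TestPairwiseStats:
    def test_identical_rows(self):
        d = pairwise_stats(_aln("ATGAAA", "ATGAAA", coding=True), 0, 1)
        assert (d.variable_sites, d.synonymous, d.replacement) == (0, 0, 0)

    def test_synonymous_change(self):
        d = pairwise_stats(_aln("ATA", "ATG", coding=True), 0, 1)
        assert (d.variable_sites, d.synonymous, d.replacement) == (1, 1, 0)

    def test_replacement_change(self):
        d = pairwise_stats(_aln("ATT", "ATG", coding=True), 0, 1)
        assert (d.variable_sites, d.synonymous, d.replacement) == (1, 0, 1)

    def test_syn_plus_rep_equals_variable(self, clade):
        from mitocomp.synthetic import gene_alignments
        genomes, _ = clade
        for gene, aln in gene_alignments(genomes).items():
            if not aln.coding:
                continue
            for i, j in combinations(range(aln.n), 2):
                d = pairwise_stats(aln, i, j, gene=gene)
                assert d.synonymous + d.replacement == d.variable_sites
                assert d.variable_sites <= d.compared_sites

    def test_gap_columns_dropped_pairwise(self):
        d = pairwise_stats(_aln("ATGAAA", "ATG-AA", coding=False), 0, 1)
        assert d.compared_sites == 5 and d.variable_sites == 0

    def test_pathway_method_averages_orderings(self):
        # TTT (Phe) vs TTA (Leu): single replacement step either way
        d = pairwise_stats(_aln("TTT", "TTA", coding=True), 0, 1,
                           method="pathway")
        assert (d.synonymous, d.replacement) == (0, 1)
        # CTT (Leu) vs CTA (Leu): synonymous
        d2 = pairwise_stats(_aln("CTT", "CTA", coding=True), 0, 1,
                            method="pathway")
        assert (d2.synonymous, d2.replacement) == (1, 0)


class TestNucleotideDiversity:
    def test_identical_rows_zero(self):
        assert nucleotide_diversity(_aln("ACGTACGTAC", "ACGTACGTAC")) == 0.0

    def test_hand_counted_three_rows(self):
        # pairwise differences 1, 2, 1 over length 10 -> (0.1+0.2+0.1)/3
        a = "AAAAAAAAAA"
        b = "CAAAAAAAAA"
        c = "CCAAAAAAAA"
        assert nucleotide_diversity(_aln(a, b, c)) == pytest.approx(4 / 30)

    def test_requires_two_rows(self):
        with pytest.raises(ArityError):
            nucleotide_diversity(Alignment(ids=["x"], rows=["ACGT"]))

    def test_matches_brute_force_on_small_alignments(self):
        """Pi equals hand-summed pairwise p-distances on <=10-column
        alignments, across many random cases."""
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(2, 5))
            L = int(rng.integers(1, 11))
            rows = ["".join(rng.choice(list("ACGT-"), size=L))
                    for _ in range(n)]
            if all("-" in r for r in rows) and L == 1:
                continue
            expected_terms = []
            for a, b in combinations(rows, 2):
                cols = [(x, y) for x, y in zip(a, b)
                        if x in "ACGT" and y in "ACGT"]
                if cols:
                    expected_terms.append(
                        sum(x != y for x, y in cols) / len(cols))
                else:
                    expected_terms.append(0.0)
            expected = sum(expected_terms) / (n * (n - 1) / 2)
            assert nucleotide_diversity(_aln(*rows)) == pytest.approx(expected)

    def test_binomial_consistency_with_simulated_divergence(self, shallow_clade):
        from mitocomp.synthetic import gene_alignments
        genomes, truth = shallow_clade
        aln = gene_alignments(genomes)["cox1"]
        pi = nucleotide_diversity(aln)
        # expected pairwise divergence ~ rate 0.75 * mean path length
        assert 0 < pi < 0.05


class TestSlidingWindow:
    def test_point_count_and_constant_zero(self):
        aln = _aln("A" * 500, "A" * 500, "A" * 500)
        track = sliding_window(aln, window=250, step=25)
        assert len(track.points) == 11
        assert all(pi == 0.0 for _, pi in track.points)

    def test_window_longer_than_alignment(self):
        with pytest.raises(WindowError):
            sliding_window(_aln("ACGT", "ACGT"), window=250)

    @given(st.integers(min_value=250, max_value=4000),
           st.integers(min_value=1, max_value=250),
           st.integers(min_value=10, max_value=250))
    def test_point_count_formula(self, L, step, window):
        if window > L:
            return
        aln = _aln("A" * L, "A" * L)
        track = sliding_window(aln, window=window, step=step)
        assert len(track.points) == (L - window) // step + 1

    def test_nonoverlapping_windows_partition_mismatches(self, clade):
        from mitocomp.synthetic import gene_alignments
        genomes, _ = clade
        aln = gene_alignments(genomes)["cox1"]
        L = aln.length - aln.length % 100
        trimmed = _aln(*[r[:L] for r in aln.rows])
        track = sliding_window(trimmed, window=100, step=100)
        total = 0
        for w, (mid, _) in enumerate(track.points):
            win = trimmed.window(w * 100, 100)
            for a, b in combinations(win.rows, 2):
                total += sum(x != y for x, y in zip(a, b))
        whole = sum(sum(x != y for x, y in zip(a, b))
                    for a, b in combinations(trimmed.rows, 2))
        assert total == whole

    def test_hypervariable_block_found(self, default_genome):
        """A single 250 bp hypervariable block dominates the Pi profile."""
        genome, _ = default_genome
        rng = np.random.default_rng(4)
        base = genome.sequence[:2000]
        rows = [list(base) for _ in range(3)]
        lo = 875  # block [875, 1125)
        for r in rows[1:]:
            for k in range(lo, lo + 250):
                if rng.random() < 0.5:
                    r[k] = rng.choice([b for b in "ACGT" if b != r[k]])
        track = sliding_window(_aln(*["".join(r) for r in rows]))
        mid, _ = track.max_point
        assert lo <= mid <= lo + 250

    def test_window_pi_bounded_by_max_pairwise_distance(self, clade):
        from mitocomp.synthetic import gene_alignments
        genomes, _ = clade
        aln = gene_alignments(genomes)["nad2"]
        track = sliding_window(aln, window=250, step=50)
        for w, (mid, pi) in enumerate(track.points):
            win = aln.window(w * 50, 250)
            dmax = max(
                sum(x != y for x, y in zip(a, b)) / 250
                for a, b in combinations(win.rows, 2))
            assert pi <= dmax + 1e-12


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity(_aln("ACGT", "ACGT")) == 100.0

    def test_gap_counts_as_character(self):
        assert pairwise_identity(_aln("AAAA", "AAA-")) == pytest.approx(75.0)

    def test_monotone_degradation_under_mutation(self):
        rng = np.random.default_rng(9)
        base = "".join(rng.choice(list("ACGT"), size=300))
        rows = [base, base, base]
        prev = 100.0
        for nmut in (5, 25, 80):
            mutated = list(base)
            for k in rng.choice(300, size=nmut, replace=False):
                mutated[k] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[k]]
            val = pairwise_identity(_aln(rows[0], rows[1], "".join(mutated)))
            assert val < prev
            prev = val
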