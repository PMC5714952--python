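"""The synthetic-genome generator: architecture truth, composition targets,
evolution with controllable synonymous:replacement ratio."""

import pytest

from mitocomp.architecture import ANCESTRAL_GENE_ORDER, gene_order, junctions
from mitocomp.composition import base_composition
from mitocomp.divergence import nucleotide_diversity, pairwise_stats
from mitocomp.errors import SpecError
from mitocomp.genome_io import PCG, extract_gene, translate
from mitocomp.synthetic import (
    EvolutionSpec,
    GenomeSpec,
    evolve,
    gene_alignments,
    simulate_genome,
)


class TestSimulateGenome:
    def test_default_genome_architecture(self, default_genome):
        genome, truth = default_genome
        assert gene_order(genome) == ANCESTRAL_GENE_ORDER
        rep = junctions(genome)
        assert rep.gap("atp8", "atp6") == -7
        assert genome.length == truth["genome_length"] == 15188

    def test_truth_table_matches_annotation(self, default_genome):
        genome, truth = default_genome
        feats = truth["features"]
        assert len(feats) == len(genome.features) == 38
        for f in genome.features:
            row = feats[feats.name == f.name].iloc[0]
            assert (row.start, row.end, row.strand) == \
                (f.start, f.end, f.strand)

    def test_truncated_stop_genes(self, default_genome):
        genome, _ = default_genome
        for name, expect in (("cox2", "T-"), ("nad4", "T-"), ("nad5", "T-"),
                             ("cox1", None), ("atp8", None)):
            cds = extract_gene(genome, genome.feature(name))
            t = translate(cds, complete_trailing=True)
            assert t.truncated_stop == expect, name

    def test_at_richness_within_band(self):
        genome, _ = simulate_genome(GenomeSpec(seed=42))
        at = base_composition(genome.sequence).at_percent
        assert 76.0 <= at <= 78.5

    def test_zero_overlap_spec_conserves_length_exactly(self):
        spec = GenomeSpec(seed=3, gaps={k: max(v, 0)
                                        for k, v in GenomeSpec().gaps.items()})
        genome, truth = simulate_genome(spec)
        assert sum(f.length for f in genome.features) + \
            sum(truth["gaps"].values()) == genome.length

    def test_circular_conservation_across_seeds(self):
        """Sum of junction gaps plus feature lengths equals genome length
        for every seeded genome (the circular bookkeeping identity)."""
        for seed in range(20):
            genome, _ = simulate_genome(GenomeSpec(seed=seed))
            rep = junctions(genome)
            assert sum(g for _, _, g in rep.junctions) + \
                sum(f.length for f in genome.features) == genome.length

    def test_overlap_longer_than_gene_rejected(self):
        spec = GenomeSpec()
        spec.gaps[("trnI", "trnQ")] = -70
        with pytest.raises(SpecError):
            simulate_genome(spec)

    def test_every_pcg_translates(self):
        genome, _ = simulate_genome(GenomeSpec(seed=77))
        for f in genome.features_of_kind(PCG):
            translate(extract_gene(genome, f), complete_trailing=True)


class TestEvolve:
    def test_zero_branch_lengths_identity(self, default_genome):
        genome, _ = default_genome
        espec = EvolutionSpec(
            branch_lengths={"AB": 0.0, "A": 0.0, "B": 0.0, "C": 0.0}, seed=5)
        genomes, truth = evolve(genome, espec)
        assert all(g.sequence == genome.sequence for g in genomes)
        assert len(truth["events"]) == 0

    def test_annotations_carried_over(self, clade, default_genome):
        genome, _ = default_genome
        genomes, _ = clade
        for g in genomes:
            assert len(g.features) == len(genome.features)
            assert g.length == genome.length

    def test_realized_event_ratio_near_target(self, clade):
        """With syn_rep_ratio 4 over ~1e4 mutable PCG sites, the realized
        event classes land in the binomial band [3.2, 4.8]."""
        _, truth = clade
        per = truth["per_gene_classes"]
        syn, rep = per["syn"].sum(), per["rep"].sum()
        assert syn + rep > 2000
        assert 3.2 <= syn / rep <= 4.8

    def test_estimator_recovers_ratio_at_low_saturation(self, shallow_clade):
        """Site-classification on gap-free alignments recovers the 4:1
        synonymous:replacement ratio within 20% when multiple hits are rare."""
        genomes, truth = shallow_clade
        syn = rep = 0.0
        for gene, aln in gene_alignments(genomes).items():
            if not aln.coding:
                continue
            for i in range(aln.n):
                for j in range(i + 1, aln.n):
                    d = pairwise_stats(aln, i, j, gene=gene)
                    syn += d.synonymous
                    rep += d.replacement
        assert 4 * 0.7 <= syn / rep <= 4 * 1.3

    def test_estimates_match_realized_events_when_no_multiple_hits(
            self, default_genome):
        """With very short branches and no site hit twice, observed per-gene
        variable sites equal the generator's realized event counts."""
        genome, _ = default_genome
        espec = EvolutionSpec(
            branch_lengths={"AB": 0.0005, "A": 0.001, "B": 0.001, "C": 0.001},
            seed=0)
        genomes, truth = evolve(genome, espec)
        assert truth["max_hits_per_site"] == 1
        ev = truth["events"]
        alns = gene_alignments(genomes, kinds=(PCG,))
        for gene, aln in alns.items():
            for i, taxon_i in enumerate("ABC"):
                for j, taxon_j in enumerate("ABC"):
                    if j <= i:
                        continue
                    path = {"AB": {"A", "B"}, "AC": {"A", "AB", "C"},
                            "BC": {"B", "AB", "C"}}[taxon_i + taxon_j]
                    n_events = len(ev[(ev.gene == gene)
                                      & ev.branch.isin(path)])
                    d = pairwise_stats(aln, i, j, gene=gene)
                    assert d.variable_sites == n_events, (gene, taxon_i,
                                                          taxon_j)

    def test_rate_multipliers_rank_per_gene_diversity(self, default_genome):
        """cox1 at multiplier 0.3 vs nad2 at 2.0: nad2 must come out more
        diverse in nearly every replicate."""
        genome, _ = default_genome
        wins = 0
        n = 8
        for seed in range(n):
            espec = EvolutionSpec(
                per_gene_rate={"cox1": 0.3, "nad2": 2.0}, seed=100 + seed)
            genomes, _ = evolve(genome, espec)
            alns = gene_alignments(genomes)
            if nucleotide_diversity(alns["nad2"]) > \
                    nucleotide_diversity(alns["cox1"]):
                wins += 1
        assert wins >= n - 1

    def test_determinism(self, default_genome):
        genome, _ = default_genome
        a, _ = evolve(genome, EvolutionSpec(seed=9))
        b, _ = evolve(genome, EvolutionSpec(seed=9))
        assert [g.sequence for g in a] == [g.sequence for g in b]
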