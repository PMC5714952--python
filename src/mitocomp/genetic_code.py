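"""Genetic-code tables for mitochondrial translation.

The toolkit works under the invertebrate mitochondrial code (NCBI translation
table 5) by default: ATA encodes Met, AGA/AGG encode Ser, TGA encodes Trp, and
the only stop codons are TAA and TAG.  The table is taken from Biopython's
``Bio.Data.CodonTable`` registry so that any other numbered code can be used
for outgroup taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from Bio.Data import CodonTable

BASES = "ACGT"

#: IUPAC degenerate nucleotide symbols keyed by the sorted base set they cover.
IUPAC_FOR_SET = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("AC"): "M",
    frozenset("GT"): "K",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("ACT"): "H",
    frozenset("CGT"): "B",
    frozenset("ACG"): "V",
    frozenset("AGT"): "D",
    frozenset("ACGT"): "N",
}

SET_FOR_IUPAC = {sym: s for s, sym in IUPAC_FOR_SET.items()}


@dataclass(frozen=True)
class GeneticCode:
    """A codon translation table with start-codon information.

    Attributes
    ----------
    table_id:
        NCBI translation table number (5 = invertebrate mitochondrial).
    codon_map:
        Mapping of all 64 codons to one-letter amino acids, with ``*`` for
        stop codons.
    start_codons:
        Codons usable as initiators under this table.
    """

    table_id: int
    codon_map: dict = field(repr=False)
    start_codons: frozenset = field(repr=False)

    @classmethod
    def from_table_id(cls, table_id: int = 5) -> "GeneticCode":
        tbl = CodonTable.unambiguous_dna_by_id[table_id]
        codon_map = dict(tbl.forward_table)
        for stop in tbl.stop_codons:
            codon_map[stop] = "*"
        # forward_table omits stops; after adding them all 64 must be present
        assert len(codon_map) == 64
        return cls(
            table_id=table_id,
            codon_map=codon_map,
            start_codons=frozenset(tbl.start_codons),
        )

    def amino_acid(self, codon: str) -> str:
        return self.codon_map[codon.upper()]

    def is_stop(self, codon: str) -> bool:
        return self.codon_map.get(codon.upper()) == "*"

    @property
    def stop_codons(self) -> frozenset:
        return frozenset(c for c, aa in self.codon_map.items() if aa == "*")

    @property
    def sense_codons(self) -> tuple:
        """The non-stop codons, in lexicographic order."""
        return tuple(
            c for c in ("".join(p) for p in product(BASES, repeat=3))
            if self.codon_map[c] != "*"
        )

    def synonymous_family(self, codon: str) -> tuple:
        """All codons encoding the same amino acid as ``codon`` (stops excluded)."""
        aa = self.amino_acid(codon)
        if aa == "*":
            return tuple(sorted(self.stop_codons))
        return tuple(c for c in self.sense_codons if self.codon_map[c] == aa)


#: The default code used throughout: invertebrate mitochondrial (table 5).
INVERTEBRATE_MITO = GeneticCode.from_table_id(5)

_COMPLEMENT = str.maketrans("ACGTNRYMKSWHBVD-", "TGCANYRKMSWDVBH-")


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving IUPAC degeneracy and gaps."""
    return seq.translate(_COMPLEMENT)[::-1]
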