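"""Gene order, overlap/spacer census, control-region location and tRNA pairing.

The 37-gene arrangement of the putative ancestral insect mitogenome
(typified by *Drosophila yakuba*) is built in as the reference order;
gene-order comparison is rotation-normalized to start at trnI, since the
molecule is circular and the deposited origin is arbitrary.

Junction arithmetic works purely on J-strand coordinates: for consecutive
features a, b the signed gap is ``start_b - end_a`` (negative = overlap,
positive = intergenic spacer, 0 = abutting), wrapping across the origin.
Strand is ignored, because overlaps such as trnW–trnC span opposite
strands.  The control region participates in the junction list (its flanks
are rrnS and trnI) but is excluded from the overlap and spacer totals,
which by convention cover only the gene-to-gene junctions.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .errors import ContainmentError, MissingAnchorError, StructureError
from .genome_io import CONTROL_REGION, MitoGenome

#: (gene, strand) along the J strand, starting from trnI: the ancestral
#: insect gene order.  The control region sits between rrnS and trnI.
ANCESTRAL_ORDER: Tuple[Tuple[str, str], ...] = (
    ("trnI", "J"), ("trnQ", "N"), ("trnM", "J"), ("nad2", "J"),
    ("trnW", "J"), ("trnC", "N"), ("trnY", "N"), ("cox1", "J"),
    ("trnL2", "J"), ("cox2", "J"), ("trnK", "J"), ("trnD", "J"),
    ("atp8", "J"), ("atp6", "J"), ("cox3", "J"), ("trnG", "J"),
    ("nad3", "J"), ("trnA", "J"), ("trnR", "J"), ("trnN", "J"),
    ("trnS1", "J"), ("trnE", "J"), ("trnF", "N"), ("nad5", "N"),
    ("trnH", "N"), ("nad4", "N"), ("nad4l", "N"), ("trnT", "J"),
    ("trnP", "N"), ("nad6", "J"), ("cob", "J"), ("trnS2", "J"),
    ("nad1", "N"), ("trnL1", "N"), ("rrnL", "N"), ("trnV", "N"),
    ("rrnS", "N"), ("CR", "J"),
)


@dataclass(frozen=True)
class GeneOrder:
    """Rotation-normalized circular gene order read along the J strand."""

    entries: Tuple[Tuple[str, str], ...]

    @staticmethod
    def _normalize(entries) -> Tuple[Tuple[str, str], ...]:
        entries = tuple(entries)
        names = [e[0] for e in entries]
        if "trnI" in names:
            k = names.index("trnI")
            entries = entries[k:] + entries[:k]
        return entries

    @classmethod
    def from_entries(cls, entries) -> "GeneOrder":
        return cls(cls._normalize(entries))

    def diff(self, other: "GeneOrder") -> List[Tuple[int, Optional[tuple], Optional[tuple]]]:
        """Positions at which two orders disagree, as (index, self, other)."""
        a, b = self.entries, other.entries
        out = []
        for i in range(max(len(a), len(b))):
            ea = a[i] if i < len(a) else None
            eb = b[i] if i < len(b) else None
            if ea != eb:
                out.append((i, ea, eb))
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneOrder):
            return NotImplemented
        return self.entries == other.entries

    def __hash__(self):
        return hash(self.entries)


#: The ancestral order as a GeneOrder (already starts at trnI).
ANCESTRAL_GENE_ORDER = GeneOrder.from_entries(ANCESTRAL_ORDER)


def gene_order(genome: MitoGenome) -> GeneOrder:
    """Gene order of ``genome`` along the J strand, normalized to start at trnI."""
    feats = sorted(genome.features, key=lambda f: f.start)
    return GeneOrder.from_entries((f.name, f.strand) for f in feats)


@dataclass
class JunctionReport:
    """Signed gaps between consecutive features around the circle."""

    junctions: List[Tuple[str, str, int]]
    overlap_bp: int
    overlap_junctions: int
    spacer_bp: int
    spacer_count: int
    cr_junctions: List[Tuple[str, str, int]] = field(default_factory=list)

    def gap(self, gene_a: str, gene_b: str) -> int:
        for a, b, g in self.junctions:
            if (a, b) == (gene_a, gene_b):
                return g
        raise KeyError((gene_a, gene_b))


def junctions(genome: MitoGenome) -> JunctionReport:
    """Census of all inter-feature gaps (overlaps and spacers) of a genome.

    n features yield n junctions around the circle.  Junctions flanking the
    control region are listed but kept out of the overlap/spacer totals.
    """
    feats = sorted(genome.features, key=lambda f: (f.start, f.end))
    if not feats:
        return JunctionReport([], 0, 0, 0, 0)
    L = genome.length
    juncs: List[Tuple[str, str, int]] = []
    for a, b in zip(feats, feats[1:]):
        if b.end <= a.end and not a.wrap:
            raise ContainmentError(f"{b.name} is contained within {a.name}")
        juncs.append((a.name, b.name, b.start - a.end))
    last, first = feats[-1], feats[0]
    if genome.circular:
        # wrap-flagged last features already have end > L, so the same
        # formula covers both cases
        juncs.append((last.name, first.name, first.start + L - last.end))
    overlap_bp = overlap_junctions = spacer_bp = spacer_count = 0
    cr_juncs = []
    cr_names = {f.name for f in feats if f.kind == CONTROL_REGION}
    for a, b, g in juncs:
        if a in cr_names or b in cr_names:
            cr_juncs.append((a, b, g))
            continue
        if g < 0:
            overlap_bp += -g
            overlap_junctions += 1
        elif g > 0:
            spacer_bp += g
            spacer_count += 1
    return JunctionReport(
        junctions=juncs,
        overlap_bp=overlap_bp,
        overlap_junctions=overlap_junctions,
        spacer_bp=spacer_bp,
        spacer_count=spacer_count,
        cr_junctions=cr_juncs,
    )


def locate_control_region(genome: MitoGenome) -> Tuple[int, int, int]:
    """(start, end, length) of the rrnS → trnI span along the J strand.

    ``end`` may exceed the genome length when the region wraps the origin.
    Spans shorter than 50 bp are returned with a warning.
    """
    try:
        rrns = genome.feature("rrnS")
    except KeyError:
        raise MissingAnchorError("rrnS not annotated; cannot anchor control region")
    try:
        trni = genome.feature("trnI")
    except KeyError:
        raise MissingAnchorError("trnI not annotated; cannot anchor control region")
    L = genome.length
    start = rrns.end % L
    end = trni.start
    if end <= start:
        end += L
    length = end - start
    if length < 50:
        warnings.warn(
            f"rrnS-trnI span of {length} bp is unusually short for a control "
            "region", stacklevel=2)
    return start, end, length


@dataclass
class TrnaPairCensus:
    """Base-pair classes and arm presence of one tRNA secondary structure."""

    watson_crick: int
    gu_wobble: int
    mismatches: Dict[str, int]
    arms: Dict[str, bool]
    pairs: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def total_pairs(self) -> int:
        return self.watson_crick + self.gu_wobble + sum(self.mismatches.values())


def _pair_label(b1: str, b2: str) -> str:
    # report in RNA alphabet, order-insensitive
    r1, r2 = sorted(b.replace("T", "U") for b in (b1, b2))
    return f"{r1}-{r2}"


def trna_pair_census(trna_seq: str, structure: str) -> TrnaPairCensus:
    """Classify every base pair of a dot-bracket tRNA structure.

    Pairs are Watson-Crick (A-U, G-C), G-U wobble, or a named mismatch.
    Arm flags are derived from the stem count: a canonical cloverleaf has
    four stems (acceptor + DHU + anticodon + T-psi-C, i.e. three hairpin
    loops); structures with only two hairpins — the trnS1(AGN) case, where
    the DHU arm is replaced by a loop — get ``DHU: False``.
    """
    seq = trna_seq.upper().replace("U", "T")
    if len(seq) != len(structure):
        raise StructureError("sequence and structure lengths differ")
    stack: List[int] = []
    pairs: List[Tuple[int, int]] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unmatched ')' at position {i}")
            pairs.append((stack.pop(), i))
        elif ch != ".":
            raise StructureError(f"invalid structure character {ch!r}")
    if stack:
        raise StructureError(f"unmatched '(' at position {stack[-1]}")
    pairs.sort()
    wc = gu = 0
    mismatches: Dict[str, int] = {}
    for i, j in pairs:
        duo = frozenset((seq[i], seq[j]))
        if duo in (frozenset("AT"), frozenset("GC")):
            wc += 1
        elif duo == frozenset("GT"):
            gu += 1
        else:
            label = _pair_label(seq[i], seq[j])
            mismatches[label] = mismatches.get(label, 0) + 1
    pairset = set(pairs)
    stems = sum(1 for (i, j) in pairs if (i - 1, j + 1) not in pairset)
    hairpins = len(re.findall(r"\(\.+\)", structure))
    arms = {
        "acceptor": stems > 0,
        "DHU": hairpins >= 3 and stems >= 4,
        "anticodon": hairpins >= 1,
        "TpsiC": hairpins >= 2,
    }
    return TrnaPairCensus(watson_crick=wc, gu_wobble=gu, mismatches=mismatches,
                          arms=arms, pairs=pairs)
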