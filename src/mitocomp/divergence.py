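"""Pairwise divergence, synonymous/replacement classification and Pi.

Nucleotide diversity (Pi) is the average per-site p-distance over all
unordered sequence pairs, computed on mutually ungapped, unambiguous
columns (pairwise deletion; complete deletion available by flag).  The
sliding-window profile evaluates Pi in alignment coordinates: gap columns
keep their positions on the x-axis but never contribute to a distance.

Variable sites of a coding comparison are split into synonymous and
replacement changes.  The default classifier works site by site: a
differing site in codon k is synonymous iff substituting the second row's
base at that site into the first row's codon (other positions held fixed)
preserves the amino acid.  This guarantees synonymous + replacement =
variable sites, as a per-gene bookkeeping table requires.  A
pathway-averaging classifier in the style of Nei & Gojobori (counting
fractional synonymous changes over all substitution orderings between the
two codons, stop-free pathways only) is available via ``method="pathway"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations
from typing import Dict, List, Tuple

from Bio import SeqIO

from .errors import ArityError, FrameError, WindowError
from .genetic_code import INVERTEBRATE_MITO, GeneticCode

_UNAMBIG = frozenset("ACGT")


@dataclass
class Alignment:
    """A multiple sequence alignment over {A,C,G,T,N,-}."""

    ids: List[str]
    rows: List[str]
    coding: bool = False
    frame_offset: int = 0

    def __post_init__(self):
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows have unequal lengths")
        self.rows = [r.upper() for r in self.rows]

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n(self) -> int:
        return len(self.rows)

    @classmethod
    def from_fasta(cls, path, coding: bool = False, frame_offset: int = 0) -> "Alignment":
        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(ids=ids, rows=rows, coding=coding, frame_offset=frame_offset)

    def window(self, start: int, width: int) -> "Alignment":
        return Alignment(
            ids=self.ids,
            rows=[r[start: start + width] for r in self.rows],
            coding=False,
        )


@dataclass(frozen=True)
class DivergencePair:
    gene: str
    variable_sites: int
    synonymous: float
    replacement: float
    compared_sites: int


def _pair_columns(a: str, b: str):
    """Indices of columns where both rows carry an unambiguous base."""
    return [k for k, (x, y) in enumerate(zip(a, b))
            if x in _UNAMBIG and y in _UNAMBIG]


def pairwise_stats(
    aln: Alignment,
    i: int,
    j: int,
    code: GeneticCode = INVERTEBRATE_MITO,
    gene: str = "",
    method: str = "site",
) -> DivergencePair:
    """Variable-site and synonymous/replacement tallies for rows i and j.

    For coding alignments the rows must be stop-stripped, in-frame coding
    sequences.  ``method`` selects the site-substitution classifier
    (default) or Nei-Gojobori-style pathway averaging.
    """
    a, b = aln.rows[i], aln.rows[j]
    cols = _pair_columns(a, b)
    diffs = [k for k in cols if a[k] != b[k]]
    if not aln.coding:
        return DivergencePair(gene, len(diffs), 0, 0, len(cols))
    if (aln.length - aln.frame_offset) % 3:
        raise FrameError(
            f"coding alignment length {aln.length} with frame offset "
            f"{aln.frame_offset} is not codon-complete")
    syn = rep = 0.0
    if method == "site":
        for k in diffs:
            c = (k - aln.frame_offset) // 3
            lo = aln.frame_offset + 3 * c
            codon_a = a[lo: lo + 3]
            if any(x not in _UNAMBIG for x in codon_a):
                rep += 1  # cannot resolve frame context; conservative
                continue
            mutated = codon_a[: k - lo] + b[k] + codon_a[k - lo + 1:]
            if code.is_stop(codon_a) or code.is_stop(mutated):
                rep += 1
                continue
            if code.amino_acid(mutated) == code.amino_acid(codon_a):
                syn += 1
            else:
                rep += 1
    elif method == "pathway":
        n_codons = (aln.length - aln.frame_offset) // 3
        for c in range(n_codons):
            lo = aln.frame_offset + 3 * c
            ca, cb = a[lo: lo + 3], b[lo: lo + 3]
            if ca == cb:
                continue
            if any(x not in _UNAMBIG for x in ca + cb):
                continue
            s, r = _pathway_counts(ca, cb, code)
            syn += s
            rep += r
    else:
        raise ValueError(f"unknown classification method {method!r}")
    return DivergencePair(gene, len(diffs), syn, rep, len(cols))


def _pathway_counts(ca: str, cb: str, code: GeneticCode) -> Tuple[float, float]:
    """Average synonymous/replacement steps over all stop-free pathways."""
    sites = [p for p in range(3) if ca[p] != cb[p]]
    results = []
    for order in permutations(sites):
        cur = ca
        s = r = 0
        ok = True
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1:]
            if code.is_stop(nxt):
                ok = False
                break
            if code.amino_acid(nxt) == code.amino_acid(cur):
                s += 1
            else:
                r += 1
            cur = nxt
        if ok:
            results.append((s, r))
    if not results:  # every pathway passes through a stop; count all as replacement
        return 0.0, float(len(sites))
    ms = sum(s for s, _ in results) / len(results)
    mr = sum(r for _, r in results) / len(results)
    return ms, mr


def nucleotide_diversity(aln: Alignment, complete_deletion: bool = False) -> float:
    """Pi: mean pairwise p-distance over all unordered row pairs."""
    if aln.n < 2:
        raise ArityError("nucleotide diversity requires at least 2 sequences")
    if complete_deletion:
        keep = [k for k in range(aln.length)
                if all(r[k] in _UNAMBIG for r in aln.rows)]
        rows = ["".join(r[k] for k in keep) for r in aln.rows]
        aln = Alignment(ids=aln.ids, rows=rows)
    total = 0.0
    npairs = 0
    for a, b in combinations(aln.rows, 2):
        cols = _pair_columns(a, b)
        npairs += 1
        if cols:
            d = sum(1 for k in cols if a[k] != b[k])
            total += d / len(cols)
    return total / npairs


@dataclass
class DiversityTrack:
    window: int
    step: int
    points: List[Tuple[float, float]]
    per_gene_pi: Dict[str, float] = field(default_factory=dict)

    @property
    def max_point(self) -> Tuple[float, float]:
        return max(self.points, key=lambda p: p[1])


def sliding_window(
    aln: Alignment, window: int = 250, step: int = 25
) -> DiversityTrack:
    """Sliding-window Pi profile in alignment coordinates.

    Yields ``floor((L - window)/step) + 1`` points; each point's x is the
    window midpoint (start + window/2).
    """
    if window > aln.length:
        raise WindowError(
            f"window {window} exceeds alignment length {aln.length}")
    points = []
    nwin = (aln.length - window) // step + 1
    for w in range(nwin):
        start = w * step
        pi = nucleotide_diversity(aln.window(start, window))
        points.append((start + window / 2, pi))
    return DiversityTrack(window=window, step=step, points=points)


def pairwise_identity(aln: Alignment) -> float:
    """Percentage of columns identical across all rows (gaps are characters)."""
    if aln.n < 2:
        raise ArityError("pairwise identity requires at least 2 sequences")
    if aln.length == 0:
        return 100.0
    same = sum(1 for k in range(aln.length)
               if all(r[k] == aln.rows[0][k] for r in aln.rows))
    return 100.0 * same / aln.length
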