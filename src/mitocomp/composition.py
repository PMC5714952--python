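"""Base composition, A+T content and strand-skew statistics.

Strand asymmetry follows the usual skew definitions

    AT-skew = (A - T) / (A + T)        GC-skew = (G - C) / (G + C)

computed on the majority (J) strand as deposited.  Region-level summaries
(whole genome, protein-coding genes, the two rRNAs, the pooled tRNAs and
the control region) concatenate member gene subsequences in deposited-strand
orientation, in genome order, so that the skews describe the molecule's
strand asymmetry rather than coding-strand usage; a ``coding_orientation``
flag switches to coding-strand concatenation.  Ambiguous bases (N) are
tolerated but excluded from every count.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Optional

from .errors import EmptyInputError, FrameError
from .genome_io import CONTROL_REGION, PCG, RRNA, TRNA, MitoGenome, extract_gene
from .genetic_code import reverse_complement


@dataclass(frozen=True)
class CompositionSummary:
    """Per-region base counts, A+T content and strand skews.

    ``at_skew``/``gc_skew`` are None when the corresponding denominator
    (A+T, G+C) is zero.  ``at_percent`` is carried at full precision;
    rounding to one decimal happens only when tables are serialized.
    """

    region: str
    length: int
    a: int
    c: int
    g: int
    t: int
    at_percent: float
    at_skew: Optional[float]
    gc_skew: Optional[float]


def base_composition(seq: str, region: str = "custom") -> CompositionSummary:
    """Exact base counts, A+T% and skews of a nucleotide sequence."""
    if not seq:
        raise EmptyInputError("cannot summarize an empty sequence")
    counts = Counter(seq.upper())
    a, c, g, t = counts["A"], counts["C"], counts["G"], counts["T"]
    counted = a + c + g + t
    if counted == 0:
        raise EmptyInputError("sequence contains no unambiguous A/C/G/T bases")
    at, gc = a + t, g + c
    return CompositionSummary(
        region=region,
        length=len(seq),
        a=a, c=c, g=g, t=t,
        at_percent=100.0 * at / counted,
        at_skew=(a - t) / at if at else None,
        gc_skew=(g - c) / gc if gc else None,
    )


def skew(seq: str):
    """(AT-skew, GC-skew) of a sequence; a component is None when undefined."""
    summary = base_composition(seq)
    return summary.at_skew, summary.gc_skew


_REGION_ORDER = ("whole", "PCGs", "rrnL", "rrnS", "tRNAs", "CR")


def region_composition(
    genome: MitoGenome, coding_orientation: bool = False
) -> list:
    """One :class:`CompositionSummary` per region class of ``genome``.

    Regions follow the conventional comparative-table layout: whole
    molecule, all PCGs concatenated, rrnL, rrnS, all tRNAs concatenated,
    control region.  A missing region class is omitted with a warning.
    """
    pieces = {
        "PCGs": [], "tRNAs": [], "rrnL": [], "rrnS": [], "CR": [],
    }
    for f in genome.features:
        seq = extract_gene(genome, f)
        if not coding_orientation and f.strand == "N":
            seq = reverse_complement(seq)  # back to deposited J strand
        if f.kind == PCG:
            pieces["PCGs"].append(seq)
        elif f.kind == TRNA:
            pieces["tRNAs"].append(seq)
        elif f.kind == RRNA and f.name in ("rrnL", "rrnS"):
            pieces[f.name].append(seq)
        elif f.kind == CONTROL_REGION:
            pieces["CR"].append(seq)

    out = [base_composition(genome.sequence, region="whole")]
    for region in _REGION_ORDER[1:]:
        joined = "".join(pieces[region])
        if not joined:
            warnings.warn(f"region {region!r} not annotated in {genome.id}; "
                          "summary omitted", stacklevel=2)
            continue
        out.append(base_composition(joined, region=region))
    return out


def codon_position_at(pcg_sequences) -> tuple:
    """A+T% at first, second and third codon positions pooled across genes.

    Sequences must be in coding orientation with (complete or truncated)
    stop codons already removed, so every length is divisible by 3.
    """
    pools = ["", "", ""]
    for seq in pcg_sequences:
        seq = seq.upper()
        if len(seq) % 3:
            raise FrameError(
                f"coding sequence length {len(seq)} not divisible by 3"
            )
        for p in range(3):
            pools[p] += seq[p::3]
    if not any(pools):
        raise EmptyInputError("no coding sequence provided")
    return tuple(base_composition(pool).at_percent for pool in pools)
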