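"""Start/stop codon identification, codon counting and RSCU.

Insect mitochondrial protein genes frequently end on an incomplete stop
codon — a bare T or TA at the DNA level completed to TAA by
post-transcriptional polyadenylation.  Stop classification is therefore
driven by gene length modulo 3: a length divisible by 3 must end in a
complete TAA/TAG, remainder 1 in a lone T ("T-"), remainder 2 in TA
("TA-").  Codon counting excludes the (possibly truncated) stop of every
gene and includes the start codon, matching the convention of the usual
codon-usage software, so the per-genome non-stop total equals

    sum over genes of  floor(length/3) - [stop is complete].

RSCU for codon c in synonymous family F is count(c) * |F| / sum of counts
over F; the family mean is 1 whenever the family is observed at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .errors import AnnotationInconsistencyError, FrameError
from .genetic_code import INVERTEBRATE_MITO, GeneticCode

COMPLETE_STOPS = ("TAA", "TAG")


@dataclass(frozen=True)
class StartStopReport:
    gene: str
    start_codon: str
    stop_codon: str  # TAA / TAG / "T-" / "TA-"
    length: int

    @property
    def stop_is_complete(self) -> bool:
        return not self.stop_codon.endswith("-")

    @property
    def nonstop_codons(self) -> int:
        """Codons contributed to usage totals (start included, stop excluded)."""
        return self.length // 3 - (1 if self.stop_is_complete else 0)


@dataclass
class CodonUsageTable:
    """Codon counts (and, once filled, RSCU values) over the sense codons."""

    counts: Dict[str, int]
    total_nonstop: int
    skipped_ambiguous: int = 0
    rscu: Dict[str, Optional[float]] = field(default_factory=dict)
    missing: List[str] = field(default_factory=list)


def detect_start_stop(gene: str, cds: str) -> StartStopReport:
    """Classify the start and (possibly truncated) stop codon of a CDS.

    ``cds`` must be in coding orientation.  Non-canonical starts (e.g. the
    TTG of nad5 in some leafhoppers) are reported verbatim, not rejected.
    """
    cds = cds.upper()
    if len(cds) < 4:
        raise FrameError(f"{gene}: CDS of {len(cds)} nt is too short")
    start = cds[:3]
    rem = len(cds) % 3
    if rem == 0:
        stop = cds[-3:]
        if stop not in COMPLETE_STOPS:
            raise AnnotationInconsistencyError(
                f"{gene}: length {len(cds)} requires a complete TAA/TAG stop, "
                f"found {stop!r}"
            )
    elif rem == 1:
        if cds[-1] != "T":
            raise AnnotationInconsistencyError(
                f"{gene}: length mod 3 = 1 requires a trailing T, "
                f"found {cds[-1]!r}"
            )
        stop = "T-"
    else:
        if cds[-2:] != "TA":
            raise AnnotationInconsistencyError(
                f"{gene}: length mod 3 = 2 requires trailing TA, "
                f"found {cds[-2:]!r}"
            )
        stop = "TA-"
    return StartStopReport(gene=gene, start_codon=start, stop_codon=stop,
                           length=len(cds))


def nonstop_total(reports) -> int:
    """Total non-stop codons implied by gene lengths and stop completeness."""
    return sum(r.nonstop_codons for r in reports)


def count_codons(
    pcgs: List[Tuple[str, str]],
    code: GeneticCode = INVERTEBRATE_MITO,
) -> CodonUsageTable:
    """Count every codon of every gene, excluding each gene's stop.

    ``pcgs`` is a list of (gene name, coding-orientation CDS).  Codons
    containing an ambiguous base are skipped and tallied separately.
    """
    counts = {c: 0 for c in code.sense_codons}
    skipped = 0
    total = 0
    for gene, cds in pcgs:
        report = detect_start_stop(gene, cds)
        body_len = 3 * report.nonstop_codons
        body = cds.upper()[:body_len]
        for i in range(0, body_len, 3):
            codon = body[i: i + 3]
            if any(b not in "ACGT" for b in codon):
                skipped += 1
                continue
            if codon not in counts:  # internal stop: annotation problem
                raise AnnotationInconsistencyError(
                    f"{gene}: internal stop codon {codon} at position {i}"
                )
            counts[codon] += 1
            total += 1
    return CodonUsageTable(counts=counts, total_nonstop=total,
                           skipped_ambiguous=skipped)


def synonymous_families(
    code: GeneticCode = INVERTEBRATE_MITO, split_isoacceptor: bool = False
) -> Dict[str, Tuple[str, ...]]:
    """Synonymous codon families keyed by label, stop codons excluded.

    By default families are defined by amino acid (the convention of the
    standard codon-usage software: under the invertebrate mitochondrial
    code Leu and Ser are 6- and 8-fold families, Met and Trp 2-fold).
    With ``split_isoacceptor`` the Leu and Ser families are split by codon
    class as on RSCU plots: L1 = CUN, L2 = UUR, S1 = AGN, S2 = UCN.
    """
    by_aa: Dict[str, list] = {}
    for codon in code.sense_codons:
        by_aa.setdefault(code.amino_acid(codon), []).append(codon)
    if not split_isoacceptor:
        return {aa: tuple(cods) for aa, cods in by_aa.items()}
    fams: Dict[str, Tuple[str, ...]] = {}
    for aa, cods in by_aa.items():
        if aa == "L":
            fams["L1(CUN)"] = tuple(c for c in cods if c.startswith("CT"))
            fams["L2(UUR)"] = tuple(c for c in cods if c.startswith("TT"))
        elif aa == "S":
            fams["S1(AGN)"] = tuple(c for c in cods if c.startswith("AG"))
            fams["S2(UCN)"] = tuple(c for c in cods if c.startswith("TC"))
        else:
            fams[aa] = tuple(cods)
    return fams


def rscu(
    table: CodonUsageTable,
    code: GeneticCode = INVERTEBRATE_MITO,
    split_isoacceptor: bool = False,
) -> CodonUsageTable:
    """Fill the RSCU values and missing-codon list of a codon-count table."""
    values: Dict[str, Optional[float]] = {}
    for fam in synonymous_families(code, split_isoacceptor).values():
        fam_total = sum(table.counts[c] for c in fam)
        for c in fam:
            if fam_total == 0:
                values[c] = None
            else:
                values[c] = table.counts[c] * len(fam) / fam_total
    table.rscu = values
    table.missing = sorted(c for c, n in table.counts.items() if n == 0)
    return table


def amino_acid_usage(
    table: CodonUsageTable,
    code: GeneticCode = INVERTEBRATE_MITO,
    split_isoacceptor: bool = False,
) -> Dict[str, int]:
    """Amino-acid usage counts, optionally splitting the Leu/Ser families."""
    usage: Dict[str, int] = {}
    for label, fam in synonymous_families(code, split_isoacceptor).items():
        usage[label] = sum(table.counts[c] for c in fam)
    return usage
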