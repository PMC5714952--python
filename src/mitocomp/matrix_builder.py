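"""Phylogenetic supermatrix construction, Degen recoding and saturation index.

``concatenate`` stitches per-gene alignments into one matrix with a
partition map (1-based inclusive coordinates, the convention of partition
files); coding genes additionally carry codon-position subpartitions.

``degen_recode`` makes synonymous change largely invisible: each codon
position p is replaced by the IUPAC symbol covering exactly the bases
that, holding the other two observed positions fixed, encode the same
amino acid.  The recoding table is derived algorithmically from the
genetic-code table, so any NCBI code works; serine's AGN and UCN families
never blend because no single-position change converts one into the other.

``saturation_index`` reports the observed substitution-saturation index:
the ratio of mean per-site entropy to the entropy expected at full
saturation (the matrix-wide base-frequency entropy).  The simulation-based
critical values used to judge significance are out of scope here; compare
the observed index against them externally.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple

from .divergence import Alignment
from .errors import FrameError, MitocompError
from .genetic_code import (
    BASES,
    INVERTEBRATE_MITO,
    IUPAC_FOR_SET,
    SET_FOR_IUPAC,
    GeneticCode,
)


@dataclass(frozen=True)
class Partition:
    name: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    codon_position: Optional[int] = None  # 1..3 for codon subpartitions
    coding: bool = False


@dataclass
class SuperMatrix:
    taxa: List[str]
    rows: Dict[str, str]
    partitions: List[Partition]
    recoding: str = "none"
    gblocks_filtered: Optional[bool] = None  # upstream filtering, pass-through

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def gene_partitions(self) -> List[Partition]:
        return [p for p in self.partitions if p.codon_position is None]

    def codon_partitions(self) -> List[Partition]:
        return [p for p in self.partitions if p.codon_position is not None]


def concatenate(
    gene_alignments: List[Tuple[str, Alignment]],
    taxa: Optional[List[str]] = None,
) -> SuperMatrix:
    """Concatenate per-gene alignments into a supermatrix.

    ``gene_alignments`` is an ordered list of (gene name, alignment).
    Taxa missing from a gene are filled with '-'.  Coding genes (alignments
    with ``coding=True``) get three codon-position subpartitions in
    addition to their gene partition.
    """
    if taxa is None:
        seen = []
        for _, aln in gene_alignments:
            for t in aln.ids:
                if t not in seen:
                    seen.append(t)
        taxa = seen
    rows = {t: [] for t in taxa}
    partitions: List[Partition] = []
    pos = 0
    for gene, aln in gene_alignments:
        if len(set(aln.ids)) != len(aln.ids):
            dup = [t for t in aln.ids if aln.ids.count(t) > 1][0]
            raise MitocompError(f"duplicate taxon {dup!r} in gene {gene}")
        if aln.length == 0:
            raise MitocompError(f"gene {gene}: empty alignment")
        by_taxon = dict(zip(aln.ids, aln.rows))
        for t in taxa:
            rows[t].append(by_taxon.get(t, "-" * aln.length))
        start, end = pos + 1, pos + aln.length
        partitions.append(Partition(gene, start, end, coding=aln.coding))
        if aln.coding:
            if aln.length % 3:
                raise FrameError(
                    f"gene {gene}: coding alignment length {aln.length} "
                    "not divisible by 3")
            for p in (1, 2, 3):
                partitions.append(
                    Partition(f"{gene}_pos{p}", start + p - 1, end,
                              codon_position=p, coding=True))
        pos = end
    return SuperMatrix(
        taxa=list(taxa),
        rows={t: "".join(parts) for t, parts in rows.items()},
        partitions=partitions,
    )


_DEGEN_CACHE: Dict[int, Dict[str, str]] = {}


def degen_table(code: GeneticCode = INVERTEBRATE_MITO) -> Dict[str, str]:
    """The full codon → degenerate-codon recoding table under ``code``.

    For each sense codon and position p, the recoded symbol covers the set
    of bases b such that replacing position p with b (other positions
    fixed) yields a codon with the same amino acid.  Stop codons recode to
    themselves.
    """
    table: Dict[str, str] = {}
    for c1 in BASES:
        for c2 in BASES:
            for c3 in BASES:
                codon = c1 + c2 + c3
                aa = code.amino_acid(codon)
                if aa == "*":
                    table[codon] = codon
                    continue
                out = []
                for p in range(3):
                    same = frozenset(
                        b for b in BASES
                        if code.amino_acid(codon[:p] + b + codon[p + 1:]) == aa
                    )
                    out.append(IUPAC_FOR_SET[same])
                table[codon] = "".join(out)
    return table


def degen_recode(matrix: SuperMatrix, code: GeneticCode = INVERTEBRATE_MITO) -> SuperMatrix:
    """Degen-recode the coding partitions of a supermatrix.

    Codons containing gaps or ambiguity codes become NNN; non-coding
    partitions are untouched.  The operation is idempotent: degenerate
    symbols already present re-expand to codon sets that all encode one
    amino acid and recode to themselves.
    """
    if code.table_id not in _DEGEN_CACHE:
        _DEGEN_CACHE[code.table_id] = degen_table(code)
    table = _DEGEN_CACHE[code.table_id]
    new_rows = {t: list(r) for t, r in matrix.rows.items()}
    for part in matrix.gene_partitions():
        if not part.coding:
            continue
        if (part.end - part.start + 1) % 3:
            raise FrameError(f"partition {part.name} not divisible by 3")
        for t in matrix.taxa:
            row = matrix.rows[t]
            for lo in range(part.start - 1, part.end, 3):
                codon = row[lo: lo + 3]
                new_rows[t][lo: lo + 3] = _recode_codon(codon, table, code)
    return replace(
        matrix,
        rows={t: "".join(r) for t, r in new_rows.items()},
        recoding="degen",
    )


def _recode_codon(codon: str, table: Dict[str, str], code: GeneticCode) -> str:
    if codon in table:
        return table[codon]
    if any(b not in SET_FOR_IUPAC for b in codon):
        return "NNN"  # gap or unknown symbol inside the codon
    # degenerate but resolvable: expand, recode every expansion, re-join
    expansions = [
        b1 + b2 + b3
        for b1 in SET_FOR_IUPAC[codon[0]]
        for b2 in SET_FOR_IUPAC[codon[1]]
        for b3 in SET_FOR_IUPAC[codon[2]]
    ]
    recoded = {table[c] for c in expansions}
    if len(recoded) == 1:
        return recoded.pop()
    # mixed degeneracy classes: already-recoded symbols stay as they are,
    # which makes the operation idempotent
    return codon


@dataclass(frozen=True)
class SaturationResult:
    iss_observed: float
    mean_site_entropy: float
    full_saturation_entropy: float
    n_taxa: int
    n_sites: int
    skipped_columns: int = 0


def _expected_full_saturation_entropy(n: int, freqs) -> float:
    """Expected per-site entropy of ``n`` sequences drawn i.i.d. from
    ``freqs`` — the full-saturation reference of Xia's Iss.

    The naive limit -sum q log2 q overstates what a finite sample can
    reach: with n sequences the per-base count is Binomial(n, q_b), so the
    expectation is taken over that distribution.
    """
    h = 0.0
    for q in freqs:
        if q == 0:
            continue
        for k in range(1, n + 1):
            p = math.comb(n, k) * q ** k * (1 - q) ** (n - k)
            h -= p * (k / n) * math.log2(k / n)
    return h


def saturation_index(matrix: SuperMatrix) -> SaturationResult:
    """Observed substitution-saturation index of a supermatrix.

    Mean per-site entropy (base frequencies among non-gap states at each
    column) divided by the expected entropy at full saturation for the
    same number of sequences and the matrix-wide base frequencies, so that
    a completely randomized alignment scores ~1 regardless of taxon count.
    All-gap columns are skipped and counted.
    """
    if len(matrix.taxa) < 4:
        warnings.warn("saturation index is unreliable below 4 taxa",
                      stacklevel=2)
    global_counts = {b: 0 for b in BASES}
    site_entropies = []
    skipped = 0
    L = matrix.length
    rows = [matrix.rows[t] for t in matrix.taxa]
    for k in range(L):
        counts = {b: 0 for b in BASES}
        for r in rows:
            ch = r[k]
            if ch in SET_FOR_IUPAC and len(SET_FOR_IUPAC[ch]) == 1:
                counts[ch] += 1
        n = sum(counts.values())
        if n == 0:
            skipped += 1
            continue
        for b in BASES:
            global_counts[b] += counts[b]
        h = -sum((c / n) * math.log2(c / n) for c in counts.values() if c)
        site_entropies.append(h)
    if not site_entropies:
        raise MitocompError("matrix has no scorable columns")
    total = sum(global_counts.values())
    freqs = [c / total for c in global_counts.values()]
    h_full = _expected_full_saturation_entropy(len(matrix.taxa), freqs)
    h_mean = sum(site_entropies) / len(site_entropies)
    return SaturationResult(
        iss_observed=h_mean / h_full if h_full else 0.0,
        mean_site_entropy=h_mean,
        full_saturation_entropy=h_full,
        n_taxa=len(matrix.taxa),
        n_sites=len(site_entropies),
        skipped_columns=skipped,
    )


# ---------------------------------------------------------------------------
# exports

_NAME_SANITIZE = re.compile(r"[^\w.]")


def _sanitized_taxa(taxa: List[str], max_len: int = 99) -> Tuple[Dict[str, str], bool]:
    mapping = {}
    used = set()
    changed = False
    for t in taxa:
        s = _NAME_SANITIZE.sub("_", t)[:max_len]
        base = s
        k = 1
        while s in used:
            s = f"{base}_{k}"
            k += 1
        used.add(s)
        if s != t:
            changed = True
        mapping[t] = s
    return mapping, changed


def write_phylip(matrix: SuperMatrix, path) -> None:
    """Relaxed PHYLIP (name, two spaces, full row on one line)."""
    mapping, _ = _sanitized_taxa(matrix.taxa)
    with open(path, "w") as fh:
        fh.write(f" {len(matrix.taxa)} {matrix.length}\n")
        for t in matrix.taxa:
            fh.write(f"{mapping[t]}  {matrix.rows[t]}\n")


def read_phylip(path) -> SuperMatrix:
    """Re-import a relaxed PHYLIP file written by :func:`write_phylip`."""
    with open(path) as fh:
        header = fh.readline().split()
        n, L = int(header[0]), int(header[1])
        taxa, rows = [], {}
        for line in fh:
            if not line.strip():
                continue
            name, seq = line.split(None, 1)
            taxa.append(name)
            rows[name] = seq.strip()
    if len(taxa) != n or any(len(r) != L for r in rows.values()):
        raise MitocompError(f"inconsistent PHYLIP file {path}")
    return SuperMatrix(taxa=taxa, rows=rows, partitions=[])


def write_nexus(matrix: SuperMatrix, path) -> None:
    """NEXUS with a DATA block and a SETS block carrying the partitions."""
    mapping, _ = _sanitized_taxa(matrix.taxa)
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(matrix.taxa)} NCHAR={matrix.length};\n")
        fh.write("  FORMAT DATATYPE=DNA MISSING=N GAP=-;\n  MATRIX\n")
        for t in matrix.taxa:
            fh.write(f"    {mapping[t]}  {matrix.rows[t]}\n")
        fh.write("  ;\nEND;\n\nBEGIN SETS;\n")
        for p in matrix.partitions:
            if p.codon_position is None:
                fh.write(f"  CHARSET {p.name} = {p.start}-{p.end};\n")
            else:
                fh.write(
                    f"  CHARSET {p.name} = {p.start}-{p.end}\\3;\n")
        fh.write("END;\n")


def write_raxml_partitions(matrix: SuperMatrix, path, by_codon: bool = True) -> None:
    """RAxML-style partition file; codon mode writes start-end\\3 lines."""
    with open(path, "w") as fh:
        parts = matrix.codon_partitions() if by_codon else []
        covered = {p.name.rsplit("_pos", 1)[0] for p in parts}
        for p in parts:
            fh.write(f"DNA, {p.name} = {p.start}-{p.end}\\3\n")
        for p in matrix.gene_partitions():
            if by_codon and p.coding and p.name in covered:
                continue
            fh.write(f"DNA, {p.name} = {p.start}-{p.end}\n")


def export(matrix: SuperMatrix, prefix, formats=("phylip", "nexus", "raxml")) -> List[str]:
    """Write the matrix in the requested formats; returns the paths written."""
    written = []
    prefix = str(prefix)
    if "phylip" in formats:
        write_phylip(matrix, prefix + ".phy")
        written.append(prefix + ".phy")
    if "nexus" in formats:
        write_nexus(matrix, prefix + ".nex")
        written.append(prefix + ".nex")
    if "raxml" in formats:
        write_raxml_partitions(matrix, prefix + ".partitions.txt")
        written.append(prefix + ".partitions.txt")
    mapping, changed = _sanitized_taxa(matrix.taxa)
    if changed:
        with open(prefix + ".names.tsv", "w") as fh:
            for t, s in mapping.items():
                fh.write(f"{t}\t{s}\n")
        written.append(prefix + ".names.tsv")
    return written
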