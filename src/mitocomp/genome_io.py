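"""Reading, writing and strand/coordinate-safe handling of annotated mitogenomes.

Coordinates are 0-based half-open throughout the toolkit; the GenBank
1-based inclusive convention is converted only at the I/O boundary.  A
feature spanning the origin of the circular molecule is represented with
``end > genome length`` and an explicit ``wrap`` flag rather than as split
intervals, so every gene stays a single feature.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, NamedTuple, Optional

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .errors import (
    AnnotationConflictError,
    AnnotationInconsistencyError,
    BoundsError,
    EmptyInputError,
    FrameError,
    ParseError,
    PrematureStopError,
)
from .genetic_code import INVERTEBRATE_MITO, GeneticCode, reverse_complement

PCG = "PCG"
TRNA = "tRNA"
RRNA = "rRNA"
CONTROL_REGION = "control_region"
OTHER = "other"

#: Minimum unannotated rrnS–trnI span accepted as a control region.
MIN_CONTROL_REGION = 50

#: Codon-family suffix for the Leu/Ser isoacceptor tRNAs.
_ISOACCEPTOR = {
    ("LEU", "CUN"): "trnL1",
    ("LEU", "UUR"): "trnL2",
    ("SER", "AGN"): "trnS1",
    ("SER", "UCN"): "trnS2",
}

#: Anticodons (DNA alphabet, as annotated) of the four isoacceptors.
_ISOACCEPTOR_BY_ANTICODON = {
    ("LEU", "TAG"): "trnL1",
    ("LEU", "TAA"): "trnL2",
    ("SER", "GCT"): "trnS1",
    ("SER", "TCT"): "trnS1",
    ("SER", "TGA"): "trnS2",
}


@dataclass(frozen=True)
class GeneFeature:
    """A single annotated gene on a circular mitogenome.

    ``start``/``end`` are 0-based half-open genome coordinates.  For a
    feature spanning the origin, ``wrap`` is True and ``end`` exceeds the
    genome length by the number of bases past the origin.  ``strand`` is
    ``"J"`` for the majority strand as deposited and ``"N"`` for its
    complement.
    """

    name: str
    kind: str
    start: int
    end: int
    strand: str = "J"
    wrap: bool = False
    anticodon: Optional[str] = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"{self.name}: empty or inverted interval")
        if self.strand not in ("J", "N"):
            raise ValueError(f"{self.name}: strand must be J or N")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MitoGenome:
    """A circular mitochondrial genome with its ordered feature annotations."""

    id: str
    sequence: str
    circular: bool = True
    features: list = field(default_factory=list)

    def __post_init__(self):
        if not self.sequence:
            raise EmptyInputError("genome sequence is empty")
        self.sequence = self.sequence.upper()
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        for f in self.features:
            if f.start < 0 or f.start >= len(self.sequence):
                raise BoundsError(f"{f.name}: start {f.start} outside genome")
            limit = len(self.sequence) * (2 if f.wrap else 1)
            if f.end > limit:
                raise BoundsError(f"{f.name}: end {f.end} outside genome")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def features_of_kind(self, kind: str) -> list:
        return [f for f in self.features if f.kind == kind]

    def __len__(self) -> int:
        return len(self.sequence)


class Translation(NamedTuple):
    """Protein product plus the truncated-stop flag ('T-' / 'TA-' / None)."""

    protein: str
    truncated_stop: Optional[str]


# ---------------------------------------------------------------------------
# gene-name canonicalization


def _load_name_table() -> dict:
    with resources.files("mitocomp.data").joinpath("gene_names.yaml").open() as fh:
        return yaml.safe_load(fh)


_NAME_TABLE = _load_name_table()
_NORMALIZE = re.compile(r"[\s\-_]+")

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def _norm(label: str) -> str:
    return _NORMALIZE.sub("", label).upper()


def canonical_gene_name(
    label: str, kind: str, anticodon: Optional[str] = None
) -> Optional[str]:
    """Map a GenBank gene/product label to its canonical name.

    Returns None when the label is not recognized; callers decide whether
    that is an error.  tRNA labels such as ``tRNA-Ser(AGN)`` or ``trnS1``
    resolve the Leu/Ser isoacceptors via the codon-family parenthetical or,
    failing that, the annotated anticodon.
    """
    raw = label.strip()
    key = _norm(raw)
    if kind == PCG:
        return _NAME_TABLE["protein_coding"].get(key)
    if kind == RRNA:
        return _NAME_TABLE["rRNA"].get(key)
    if kind == CONTROL_REGION:
        return _NAME_TABLE["control_region"].get(key, "CR")
    if kind == TRNA:
        m = re.match(
            r"(?:TRNA|TRN)[\-]?([A-Z]{1,3}\d?)(?:\((\w{3})\))?", key
        )
        if not m:
            return None
        body, fam = m.group(1), m.group(2)
        if body in ("L1", "L2", "S1", "S2"):
            return f"trn{body}"
        aa3 = body if body in _AA3.values() else _AA3.get(body[0])
        if body in ("LEU", "SER") or (len(body) == 1 and aa3 in ("LEU", "SER")):
            aa3 = "LEU" if aa3 == "LEU" or body == "LEU" else "SER"
            if fam:
                fam = fam.replace("T", "U") if "U" not in fam else fam
                hit = _ISOACCEPTOR.get((aa3, fam))
                if hit:
                    return hit
            if anticodon:
                hit = _ISOACCEPTOR_BY_ANTICODON.get((aa3, anticodon.upper()))
                if hit:
                    return hit
            return None
        if aa3 in _NAME_TABLE["trna_single"]:
            return _NAME_TABLE["trna_single"][aa3]
        return None
    return None


# ---------------------------------------------------------------------------
# GenBank I/O


def _feature_label(feat: SeqFeature) -> str:
    for q in ("gene", "product", "note"):
        if q in feat.qualifiers:
            return feat.qualifiers[q][0]
    return ""


def _feature_anticodon(feat: SeqFeature) -> Optional[str]:
    ac = feat.qualifiers.get("anticodon")
    if not ac:
        return None
    m = re.search(r"seq\s*:\s*([acgtu]{3})", ac[0], re.IGNORECASE)
    if m:
        return m.group(1).upper().replace("U", "T")
    if re.fullmatch(r"[ACGTUacgtu]{3}", ac[0].strip()):
        return ac[0].strip().upper().replace("U", "T")
    return None


_KIND_FOR_GB = {"CDS": PCG, "tRNA": TRNA, "rRNA": RRNA, "D-loop": CONTROL_REGION}


def _location_to_coords(feat: SeqFeature, genome_len: int):
    loc = feat.location
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        # origin-spanning join(x..L, 1..y) -> wrap feature
        if (
            len(parts) == 2
            and int(parts[0].start) == 0
            and int(parts[1].end) == genome_len
        ):
            return int(parts[1].start), genome_len + int(parts[0].end), True
        raise ParseError(f"unsupported compound location {loc}")
    return int(loc.start), int(loc.end), False


def read_genbank(path, min_control_region: int = MIN_CONTROL_REGION) -> MitoGenome:
    """Parse a GenBank flat file into a :class:`MitoGenome`.

    Gene names are canonicalized (``ND2`` → ``nad2``, ``COI`` → ``cox1``,
    ``tRNA-Ser(AGN)`` → ``trnS1``, ...).  When no control region is annotated,
    the unannotated span between ``rrnS`` and ``trnI`` is labelled ``CR``
    provided it is at least ``min_control_region`` bp long.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError on bad input
        raise ParseError(f"cannot parse GenBank file {path}: {exc}") from exc

    circular = record.annotations.get("topology", "circular") == "circular"
    features = []
    seen = set()
    for feat in record.features:
        kind = _KIND_FOR_GB.get(feat.type)
        if kind is None:
            all_quals = " ".join(
                v for q in ("gene", "product", "note")
                for v in feat.qualifiers.get(q, []))
            if feat.type == "misc_feature" and (
                re.search(r"control region|A\+?T[- ]rich", all_quals,
                          re.IGNORECASE)
                or _norm(all_quals).startswith("CR")
            ):
                kind = CONTROL_REGION
            else:
                continue
        anticodon = _feature_anticodon(feat)
        label = _feature_label(feat)
        name = canonical_gene_name(label, kind, anticodon)
        if name is None:
            name = _norm(label) or f"{kind}_{len(features)}"
        if name in seen and name != "CR":
            raise AnnotationConflictError(
                f"duplicate canonical gene name {name!r} in {record.id}"
            )
        seen.add(name)
        start, end, wrap = _location_to_coords(feat, len(record.seq))
        strand = "N" if feat.location.strand == -1 else "J"
        features.append(
            GeneFeature(
                name=name, kind=kind, start=start, end=end,
                strand=strand, wrap=wrap, anticodon=anticodon,
            )
        )

    genome = MitoGenome(
        id=record.id or record.name,
        sequence=str(record.seq),
        circular=circular,
        features=features,
    )
    if not any(f.kind == CONTROL_REGION for f in genome.features):
        cr = _infer_control_region(genome, min_control_region)
        if cr is not None:
            genome.features.append(cr)
            genome.features.sort(key=lambda f: (f.start, f.end))
    return genome


def _infer_control_region(genome: MitoGenome, min_len: int) -> Optional[GeneFeature]:
    try:
        rrns = genome.feature("rrnS")
        trni = genome.feature("trnI")
    except KeyError:
        return None
    start = rrns.end % genome.length
    end = trni.start
    wrap = False
    if end <= start:
        end += genome.length
        wrap = end > genome.length
    if end - start < min_len:
        return None
    return GeneFeature(
        name="CR", kind=CONTROL_REGION, start=start, end=end, strand="J", wrap=wrap
    )


_GB_TYPE_FOR_KIND = {PCG: "CDS", TRNA: "tRNA", RRNA: "rRNA",
                     CONTROL_REGION: "misc_feature", OTHER: "misc_feature"}

_PRODUCT_FOR_TRNA = {
    "trnL1": "tRNA-Leu(CUN)", "trnL2": "tRNA-Leu(UUR)",
    "trnS1": "tRNA-Ser(AGN)", "trnS2": "tRNA-Ser(UCN)",
}
_AA1_FOR_TRNA = {v: k for k, v in _NAME_TABLE["trna_single"].items()}


def write_genbank(genome: MitoGenome, path) -> None:
    """Write a :class:`MitoGenome` as a GenBank flat file that round-trips
    through :func:`read_genbank` feature-for-feature."""
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id[:16],
        description="mitochondrial genome, complete sequence",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
        },
    )
    L = genome.length
    for f in genome.features:
        strand = -1 if f.strand == "N" else 1
        if f.wrap and f.end > L:
            loc = CompoundLocation(
                [SimpleLocation(f.start, L, strand),
                 SimpleLocation(0, f.end - L, strand)]
            )
        else:
            loc = SimpleLocation(f.start, f.end, strand)
        quals = {"gene": [f.name]}
        if f.kind == TRNA:
            if f.name in _PRODUCT_FOR_TRNA:
                quals["product"] = [_PRODUCT_FOR_TRNA[f.name]]
            else:
                aa3 = _AA1_FOR_TRNA.get(f.name, "XAA")
                quals["product"] = [f"tRNA-{aa3.capitalize()}"]
            if f.anticodon:
                quals["anticodon"] = [f"(pos:complement(0..0),aa:Xaa,seq:{f.anticodon.lower()})"]
        elif f.kind == CONTROL_REGION:
            quals["note"] = ["control region"]
        record.features.append(
            SeqFeature(loc, type=_GB_TYPE_FOR_KIND[f.kind], qualifiers=quals)
        )
    SeqIO.write(record, str(path), "genbank")


# ---------------------------------------------------------------------------
# sequence extraction and translation


def extract_gene(genome: MitoGenome, feature: GeneFeature) -> str:
    """Return the coding-orientation sequence of ``feature``.

    J-strand features are taken verbatim from the deposited strand;
    N-strand features are reverse-complemented.  Origin-spanning features
    are stitched across position 0.
    """
    L = genome.length
    if feature.end > L:
        if not feature.wrap:
            raise BoundsError(
                f"{feature.name}: end {feature.end} beyond genome length {L} "
                "without wrap flag"
            )
        seq = genome.sequence[feature.start:] + genome.sequence[: feature.end - L]
    else:
        seq = genome.sequence[feature.start:feature.end]
    if feature.strand == "N":
        seq = reverse_complement(seq)
    return seq


def translate(
    cds: str,
    code: GeneticCode = INVERTEBRATE_MITO,
    complete_trailing: bool = False,
) -> Translation:
    """Translate a coding sequence codon-by-codon under ``code``.

    A terminal complete stop codon is not included in the protein.  With
    ``complete_trailing``, a trailing T or TA (length mod 3 of 1 or 2) is
    treated as a truncated stop completed to TAA by polyadenylation and
    reported via the ``truncated_stop`` flag.  An internal stop raises
    :class:`PrematureStopError`.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise FrameError(f"coding sequence of {len(cds)} nt is too short")
    rem = len(cds) % 3
    truncated = None
    body = cds
    if rem:
        if not complete_trailing:
            raise FrameError(
                f"length {len(cds)} not divisible by 3 (pass complete_trailing "
                "for genes with truncated stops)"
            )
        tail = cds[-rem:]
        if tail not in ("T", "TA"):
            raise AnnotationInconsistencyError(
                f"trailing bases {tail!r} cannot be completed to a TAA stop"
            )
        truncated = "T-" if rem == 1 else "TA-"
        body = cds[:-rem]
    aas = []
    n_codons = len(body) // 3
    for i in range(n_codons):
        codon = body[3 * i: 3 * i + 3]
        if "N" in codon or any(b not in "ACGT" for b in codon):
            aas.append("X")
            continue
        aa = code.amino_acid(codon)
        if aa == "*":
            if i == n_codons - 1 and truncated is None:
                return Translation("".join(aas), None)
            raise PrematureStopError(i, codon)
        aas.append(aa)
    return Translation("".join(aas), truncated)


def export_gene_fasta(genome: MitoGenome, path, kinds: Iterable = (PCG, TRNA, RRNA)) -> None:
    """Write every feature of the requested kinds as coding-orientation FASTA
    with headers ``<genome_id>|<gene>|<strand>``."""
    with open(path, "w") as fh:
        for f in genome.features:
            if f.kind not in kinds:
                continue
            fh.write(f">{genome.id}|{f.name}|{f.strand}\n")
            seq = extract_gene(genome, f)
            for i in range(0, len(seq), 70):
                fh.write(seq[i: i + 70] + "\n")


def rotate_genome(genome: MitoGenome, offset: int) -> MitoGenome:
    """Rotate the origin of a circular genome by ``offset`` bases.

    Feature coordinates are shifted accordingly; features that come to span
    the new origin get the wrap flag.  Useful for testing rotation
    invariance of downstream statistics.
    """
    L = genome.length
    offset %= L
    seq = genome.sequence[offset:] + genome.sequence[:offset]
    feats = []
    for f in genome.features:
        start = (f.start - offset) % L
        end = start + f.length
        feats.append(replace(f, start=start, end=end, wrap=end > L))
    return MitoGenome(id=genome.id, sequence=seq, circular=genome.circular,
                      features=feats)
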