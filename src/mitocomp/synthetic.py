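"""Synthetic annotated mitogenomes and evolved descendants with known truth.

The generator emulates a leafhopper-like insect mitogenome: a ~15.2 kb
circular molecule carrying the 37-gene ancestral order with canonical
strands, heavy A+T bias varying by region, positive J-strand AT-skew and
negative GC-skew, short gene overlaps (the conserved atp8–atp6 and
nad4–nad4l 7 bp overlaps among them), small intergenic spacers, truncated
T/TA stop codons, and an A+T-rich control region between rrnS and trnI.
Overlapping protein genes share bases that satisfy both reading frames:
codons that fall on already-written bases are re-sampled under both
genes' constraints (start codon present, no internal stop, proper stop or
truncated tail), so every generated genome passes annotation-level
validation by construction.

``evolve`` produces a three-taxon clade from a root genome by per-site
substitution sampling without indels, with a controllable realized
synonymous:replacement ratio inside protein genes and per-gene rate
multipliers, recording every substitution event as ground truth.

All randomness flows from the single seed in the spec.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .architecture import ANCESTRAL_ORDER
from .divergence import Alignment
from .errors import SpecError
from .genetic_code import INVERTEBRATE_MITO, GeneticCode
from .genome_io import (
    CONTROL_REGION,
    PCG,
    RRNA,
    TRNA,
    GeneFeature,
    MitoGenome,
    extract_gene,
    translate,
)

_BASES = ("A", "C", "G", "T")
_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}
_STOPS = ("TAA", "TAG")

#: Default per-gene lengths: protein genes near the published leafhopper
#: values (three genes end on truncated stops by virtue of length mod 3),
#: rRNAs ~1.2 kb / ~740 bp, tRNAs 65-66 bp.
_DEFAULT_PCG_LENGTHS = {
    "nad2": 975, "cox1": 1536, "cox2": 682, "atp8": 153, "atp6": 654,
    "cox3": 780, "nad3": 354, "nad5": 1666, "nad4": 1309, "nad4l": 273,
    "nad6": 477, "cob": 1137, "nad1": 933,
}
_DEFAULT_RRNA_LENGTHS = {"rrnL": 1199, "rrnS": 739}
_LONG_TRNAS = {"trnL1", "trnL2", "trnS1", "trnS2", "trnK"}

#: Default junction gaps (bp): negative = overlap.  Ten overlapping
#: junctions totalling 31 bp and ten spacers totalling 70 bp, the census
#: of a typical deltocephaline leafhopper mitogenome.
_DEFAULT_GAPS = {
    ("trnI", "trnQ"): -3,
    ("trnQ", "trnM"): 5,
    ("nad2", "trnW"): 6,
    ("trnW", "trnC"): -8,
    ("trnC", "trnY"): -1,
    ("trnY", "cox1"): 26,
    ("cox1", "trnL2"): 4,
    ("cox2", "trnK"): 3,
    ("trnK", "trnD"): -1,
    ("atp8", "atp6"): -7,
    ("cox3", "trnG"): -1,
    ("trnA", "trnR"): 5,
    ("trnR", "trnN"): -1,
    ("trnN", "trnS1"): -1,
    ("trnE", "trnF"): 9,
    ("nad4", "nad4l"): -7,
    ("nad4l", "trnT"): 2,
    ("trnP", "nad6"): 2,
    ("nad6", "cob"): -1,
    ("trnS2", "nad1"): 8,
}

#: Region-class (A+T fraction, AT-skew, GC-skew) targets on the J strand.
_DEFAULT_REGION_TARGETS = {
    PCG: (0.763, 0.090, -0.161),
    RRNA: (0.805, -0.120, 0.200),
    TRNA: (0.768, 0.049, -0.112),
    CONTROL_REGION: (0.819, -0.026, -0.100),
    "spacer": (0.79, 0.0, -0.1),
}

_START_WEIGHTS = {"ATA": 0.35, "ATG": 0.25, "ATT": 0.20, "ATC": 0.10, "TTG": 0.10}
_STOP_WEIGHTS = {"TAA": 0.85, "TAG": 0.15}


def default_trna_lengths() -> Dict[str, int]:
    return {
        name: (66 if name in _LONG_TRNAS else 65)
        for name, _ in ANCESTRAL_ORDER
        if name.startswith("trn")
    }


@dataclass
class GenomeSpec:
    """Parameters of a synthetic mitogenome.

    Defaults reproduce the leafhopper-scale architecture: the ancestral
    gene order, published-scale gene lengths, an 847 bp control region and
    the default junction census, which together give a 15,188 bp molecule.
    """

    gene_order: Tuple[Tuple[str, str], ...] = ANCESTRAL_ORDER
    pcg_lengths: Dict[str, int] = dc_field(default_factory=lambda: dict(_DEFAULT_PCG_LENGTHS))
    rrna_lengths: Dict[str, int] = dc_field(default_factory=lambda: dict(_DEFAULT_RRNA_LENGTHS))
    trna_lengths: Dict[str, int] = dc_field(default_factory=default_trna_lengths)
    cr_length: int = 847
    gaps: Dict[Tuple[str, str], int] = dc_field(default_factory=lambda: dict(_DEFAULT_GAPS))
    region_targets: Dict[str, Tuple[float, float, float]] = dc_field(
        default_factory=lambda: dict(_DEFAULT_REGION_TARGETS))
    genome_id: str = "synthetic_mitogenome"
    seed: int = 0

    def feature_length(self, name: str) -> int:
        if name in self.pcg_lengths:
            return self.pcg_lengths[name]
        if name in self.rrna_lengths:
            return self.rrna_lengths[name]
        if name in self.trna_lengths:
            return self.trna_lengths[name]
        if name == "CR":
            return self.cr_length
        raise SpecError(f"no length for feature {name!r}")

    def feature_kind(self, name: str) -> str:
        if name in self.pcg_lengths:
            return PCG
        if name in self.rrna_lengths:
            return RRNA
        if name.startswith("trn"):
            return TRNA
        if name == "CR":
            return CONTROL_REGION
        return "other"

    def validate(self) -> None:
        for (a, b), g in self.gaps.items():
            if g < 0 and -g >= min(self.feature_length(a), self.feature_length(b)):
                raise SpecError(f"overlap at {a}-{b} longer than a flanking gene")
        for name, n in self.pcg_lengths.items():
            if n < 6:
                raise SpecError(f"{name}: PCG length {n} too short")
        for name, (at, *_s) in self.region_targets.items():
            if not 0 < at < 1:
                raise SpecError(f"{name}: A+T fraction must be in (0,1)")


def _dist_from_targets(at: float, at_skew: float, gc_skew: float) -> np.ndarray:
    """P(A,C,G,T) on the J strand from A+T fraction and the two skews."""
    pa = at / 2 * (1 + at_skew)
    pt = at / 2 * (1 - at_skew)
    pg = (1 - at) / 2 * (1 + gc_skew)
    pc = (1 - at) / 2 * (1 - gc_skew)
    return np.array([pa, pc, pg, pt])


def _complement_dist(dist: np.ndarray) -> np.ndarray:
    pa, pc, pg, pt = dist
    return np.array([pt, pg, pc, pa])


def _stop_adjusted_dist(target: np.ndarray, iterations: int = 40) -> np.ndarray:
    """Base distribution whose stop-rejected codon marginal equals ``target``.

    Interior PCG codons are drawn i.i.d. per base but re-drawn whenever the
    codon is a stop, which skims off A/T-rich codons and pulls realized
    composition below the nominal distribution.  A fixed-point iteration
    inflates the draw distribution until the conditional (non-stop) marginal
    matches the target.
    """
    dist = target.copy()
    stop_idx = [tuple(_BASES.index(b) for b in s) for s in _STOPS]
    for _ in range(iterations):
        marginal = np.zeros(4)
        total = 0.0
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    if (i, j, k) in stop_idx:
                        continue
                    w = dist[i] * dist[j] * dist[k]
                    total += w
                    for b in (i, j, k):
                        marginal[b] += w
        marginal /= 3 * total
        dist = dist * target / marginal
        dist /= dist.sum()
    return dist


def _sample_bases(rng: np.random.Generator, n: int, dist: np.ndarray) -> List[str]:
    idx = rng.choice(4, size=n, p=dist)
    return [_BASES[i] for i in idx]


def _weighted_choice(rng: np.random.Generator, options: Dict[str, float]) -> str:
    keys = list(options)
    w = np.array([options[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=w / w.sum())]


def _codon_kind(j: int, length: int) -> str:
    """start / internal / stop for complete codon j of a CDS of ``length``."""
    n_codons, rem = divmod(length, 3)
    if j == 0:
        return "start"
    if rem == 0 and j == n_codons - 1:
        return "stop"
    return "internal"


def _enumerate_codon(
    rng: np.random.Generator,
    kind: str,
    fixed: Dict[int, str],
    dist: np.ndarray,
) -> Optional[str]:
    """Sample a codon of the given kind consistent with fixed positions.

    Enumerates the candidate set (start codons, stop codons, or all
    non-stop codons weighted by the base distribution) and returns None
    when no candidate is compatible — the overlap-conflict signal.
    """
    if kind == "start":
        cands = dict(_START_WEIGHTS)
    elif kind == "stop":
        cands = dict(_STOP_WEIGHTS)
    else:
        cands = {}
        base_p = {b: dist[i] for i, b in enumerate(_BASES)}
        for b1 in _BASES:
            for b2 in _BASES:
                for b3 in _BASES:
                    c = b1 + b2 + b3
                    if c not in _STOPS:
                        cands[c] = base_p[b1] * base_p[b2] * base_p[b3]
    ok = {c: w for c, w in cands.items()
          if all(c[p] == b for p, b in fixed.items())}
    if not ok:
        return None
    return _weighted_choice(rng, ok)


class _FeatureLayout:
    """Bookkeeping for one placed feature: genome positions in coding order."""

    def __init__(self, feature: GeneFeature, genome_len: int):
        self.feature = feature
        L = genome_len
        raw = list(range(feature.start, feature.end))
        if feature.strand == "N":
            raw = raw[::-1]
        self.positions = [p % L for p in raw]

    def read(self, seq: List[Optional[str]], i: int) -> Optional[str]:
        b = seq[self.positions[i]]
        if b is None:
            return None
        return _COMP[b] if self.feature.strand == "N" else b

    def write(self, seq: List[Optional[str]], i: int, base: str) -> None:
        seq[self.positions[i]] = (
            _COMP[base] if self.feature.strand == "N" else base)


def _generate_cds(rng, length: int, dist: np.ndarray) -> List[str]:
    """A random CDS: weighted start, stop-free interior, TAA/TAG or T/TA end."""
    n_codons, rem = divmod(length, 3)
    out: List[str] = list(_weighted_choice(rng, _START_WEIGHTS))
    n_internal = n_codons - 1 - (1 if rem == 0 else 0)
    bases = _sample_bases(rng, 3 * n_internal, dist)
    for j in range(n_internal):
        codon = "".join(bases[3 * j: 3 * j + 3])
        while codon in _STOPS:
            codon = "".join(_sample_bases(rng, 3, dist))
        out.extend(codon)
    if rem == 0:
        out.extend(_weighted_choice(rng, _STOP_WEIGHTS))
    else:
        out.extend("T" if rem == 1 else "TA")
    return out


def simulate_genome(spec: Optional[GenomeSpec] = None) -> Tuple[MitoGenome, dict]:
    """Generate an annotated synthetic mitogenome and its truth table.

    Returns the genome plus a dict recording every feature, the junction
    gaps, the composition targets and the seed.
    """
    spec = spec or GenomeSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    # --- layout ---------------------------------------------------------
    order = list(spec.gene_order)
    features: List[GeneFeature] = []
    pos = 0
    for k, (name, strand) in enumerate(order):
        if k > 0:
            prev = order[k - 1][0]
            pos += spec.gaps.get((prev, name), 0)
        length = spec.feature_length(name)
        features.append(GeneFeature(
            name=name, kind=spec.feature_kind(name),
            start=pos, end=pos + length, strand=strand))
        pos += length
    L = pos + spec.gaps.get((order[-1][0], order[0][0]), 0)
    if any(f.start < 0 for f in features):
        raise SpecError("layout produced negative coordinates")

    # --- sequence -------------------------------------------------------
    seq: List[Optional[str]] = [None] * L
    owner: List[Optional[_FeatureLayout]] = [None] * L
    dists = {
        region: _dist_from_targets(*target)
        for region, target in spec.region_targets.items()
    }
    layouts: Dict[str, _FeatureLayout] = {}
    for feat in features:
        layout = _FeatureLayout(feat, L)
        layouts[feat.name] = layout
        j_dist = dists.get(feat.kind, dists["spacer"])
        coding_dist = (_complement_dist(j_dist) if feat.strand == "N" else j_dist)
        if feat.kind == PCG:
            coding_dist = _stop_adjusted_dist(coding_dist)
            _place_pcg(rng, layout, seq, owner, coding_dist)
        else:
            for i in range(feat.length):
                if layout.read(seq, i) is None:
                    layout.write(seq, i, _BASES[rng.choice(4, p=coding_dist)])
        for p in layout.positions:
            if owner[p] is None:
                owner[p] = layout
    spacer_dist = dists["spacer"]
    for p in range(L):
        if seq[p] is None:
            seq[p] = _BASES[rng.choice(4, p=spacer_dist)]

    genome = MitoGenome(
        id=spec.genome_id, sequence="".join(seq), circular=True,
        features=features)

    # construction-time validation: every PCG must translate cleanly
    for feat in genome.features_of_kind(PCG):
        translate(extract_gene(genome, feat), complete_trailing=True)

    truth = {
        "seed": spec.seed,
        "genome_length": L,
        "features": pd.DataFrame(
            [(f.name, f.kind, f.strand, f.start, f.end, f.length)
             for f in features],
            columns=["name", "kind", "strand", "start", "end", "length"]),
        "gaps": {
            (order[k - 1][0] if k else order[-1][0], name):
                spec.gaps.get(
                    (order[k - 1][0] if k else order[-1][0], name), 0)
            for k, (name, _) in enumerate(order)
        },
        "region_targets": dict(spec.region_targets),
    }
    return genome, truth


def _place_pcg(rng, layout: _FeatureLayout, seq, owner, dist, max_tries: int = 2000):
    """Write a PCG into the genome, resolving shared-base frame constraints.

    Codons (and the truncated tail) that fall on bases already written by
    an overlapping neighbour are re-drawn under both genes' constraints;
    because resolving one conflict can rewrite bases a previously patched
    codon depended on, patching repeats until a full pass is conflict-free.
    """
    feat = layout.feature
    length = feat.length
    cds = _generate_cds(rng, length, dist)
    n_codons, rem = divmod(length, 3)
    fixed_idx = [i for i in range(length) if layout.read(seq, i) is not None]
    bad_codons = sorted({i // 3 for i in fixed_idx if i < 3 * n_codons})
    tail_idx = [i for i in fixed_idx if i >= 3 * n_codons]
    for _outer in range(50):
        conflict = False
        for j in bad_codons:
            kind = _codon_kind(j, length)
            fixed = {i - 3 * j: layout.read(seq, i)
                     for i in range(3 * j, 3 * j + 3)
                     if layout.read(seq, i) is not None}
            codon = _enumerate_codon(rng, kind, fixed, dist)
            if codon is None:
                codon = _resolve_overlap(rng, layout, j, kind, seq, owner,
                                         dist, max_tries)
                conflict = True
            cds[3 * j: 3 * j + 3] = codon
            for p in range(3):
                layout.write(seq, 3 * j + p, codon[p])
        for i in range(3 * n_codons, length):
            want = "T" if i == 3 * n_codons else "A"
            have = layout.read(seq, i)
            if have is not None and have != want and i in tail_idx:
                _resolve_tail_conflict(rng, layout, i, want, seq, owner,
                                       max_tries)
                conflict = True
            cds[i] = want
            layout.write(seq, i, want)
        if not conflict:
            break
    else:
        raise SpecError(f"{feat.name}: could not stabilize overlap constraints")
    for i, b in enumerate(cds):
        layout.write(seq, i, b)


def _owner_codon_positions(other: _FeatureLayout, genome_positions) -> List[int]:
    """Coding-codon indices of ``other`` touching the given genome positions."""
    hits = set()
    pos_index = {p: i for i, p in enumerate(other.positions)}
    for p in genome_positions:
        if p in pos_index:
            hits.add(pos_index[p] // 3)
    return sorted(hits)


def _resample_owner(rng, other: _FeatureLayout, coding_idx: List[int], seq,
                    dist_other) -> None:
    """Re-draw the owner's codons/bases covering a conflict window."""
    feat = other.feature
    if feat.kind == PCG:
        length = feat.length
        n_codons, rem = divmod(length, 3)
        for j in coding_idx:
            if j >= n_codons:  # tail base: content is forced, cannot move
                continue
            kind = _codon_kind(j, length)
            codon = _enumerate_codon(rng, kind, {}, dist_other)
            for p in range(3):
                other.write(seq, 3 * j + p, codon[p])
    else:
        for j in coding_idx:
            for i in range(3 * j, min(3 * j + 3, feat.length)):
                other.write(seq, i, _BASES[rng.choice(4, p=dist_other)])


def _conflict_owner(layout, seq_positions, owner):
    owners = {id(owner[p]): owner[p] for p in seq_positions
              if owner[p] is not None and owner[p] is not layout}
    if len(owners) != 1:
        return None
    return next(iter(owners.values()))


def _owner_dist(other: _FeatureLayout) -> np.ndarray:
    # the owner's coding distribution is re-derived loosely; overlap windows
    # are a handful of bases, so an A+T-rich uniform-ish draw suffices
    return np.array([0.40, 0.11, 0.11, 0.38])


def _resolve_overlap(rng, layout, j, kind, seq, owner, dist, max_tries) -> str:
    feat = layout.feature
    window = [layout.positions[i] for i in range(3 * j, 3 * j + 3)]
    other = _conflict_owner(layout, window, owner)
    if other is None:
        raise SpecError(
            f"overlap at {feat.name} codon {j} cannot be resolved "
            "(multiple owners or unowned fixed bases)")
    other_idx = _owner_codon_positions(other, window)
    for _ in range(max_tries):
        _resample_owner(rng, other, other_idx, seq, _owner_dist(other))
        fixed = {i - 3 * j: layout.read(seq, i)
                 for i in range(3 * j, 3 * j + 3)
                 if layout.read(seq, i) is not None}
        codon = _enumerate_codon(rng, kind, fixed, dist)
        if codon is not None:
            return codon
    raise SpecError(
        f"overlap between {other.feature.name} and {feat.name} forces a "
        f"frame conflict at codon {j}")


def _resolve_tail_conflict(rng, layout, i, want, seq, owner, max_tries) -> None:
    feat = layout.feature
    p = layout.positions[i]
    other = _conflict_owner(layout, [p], owner)
    if other is None:
        raise SpecError(f"tail conflict at {feat.name} position {i}")
    other_idx = _owner_codon_positions(other, [p])
    for _ in range(max_tries):
        _resample_owner(rng, other, other_idx, seq, _owner_dist(other))
        if layout.read(seq, i) == want:
            return
    raise SpecError(
        f"overlap between {other.feature.name} and {feat.name} forces a "
        "truncated-stop conflict")


# ---------------------------------------------------------------------------
# sequence evolution


def _default_gene_rates() -> Dict[str, float]:
    # relative variability mirroring the published per-gene Pi ranking,
    # normalized to the mean protein-gene diversity
    from .reference import GENE_PI
    rates = {g: pi / 0.20 for g, pi in GENE_PI.items()}
    rates["CR"] = 2.0
    return rates


@dataclass
class EvolutionSpec:
    """A rooted three-taxon clade ((A,B),C) with branch lengths in expected
    substitutions per site for a rate-1 gene."""

    taxa: Tuple[str, str, str] = ("A", "B", "C")
    branch_lengths: Dict[str, float] = dc_field(
        default_factory=lambda: {"AB": 0.05, "A": 0.135, "B": 0.135, "C": 0.15})
    syn_rep_ratio: float = 4.0
    per_gene_rate: Dict[str, float] = dc_field(default_factory=_default_gene_rates)
    transition_bias: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.syn_rep_ratio <= 0:
            raise SpecError("syn_rep_ratio must be positive")
        if any(t < 0 for t in self.branch_lengths.values()):
            raise SpecError("branch lengths must be non-negative")
        if any(m <= 0 for m in self.per_gene_rate.values()):
            raise SpecError("rate multipliers must be positive")


class _EvolvingGenome:
    """Mutable copy of a genome with per-PCG coding sequences kept in sync."""

    def __init__(self, genome: MitoGenome):
        self.genome = genome
        self.seq = list(genome.sequence)
        self.layouts = {
            f.name: _FeatureLayout(f, genome.length) for f in genome.features}
        self.coding = {
            f.name: list(extract_gene(genome, f))
            for f in genome.features_of_kind(PCG)}

    def clone(self) -> "_EvolvingGenome":
        c = copy.copy(self)
        c.seq = list(self.seq)
        c.coding = {g: list(s) for g, s in self.coding.items()}
        return c

    def to_genome(self, taxon: str) -> MitoGenome:
        return MitoGenome(
            id=f"{self.genome.id}_{taxon}",
            sequence="".join(self.seq),
            circular=self.genome.circular,
            features=list(self.genome.features))


def _mutable_sites(genome: MitoGenome) -> Tuple[Dict[str, List[int]], List[int]]:
    """Per-feature mutable coding indices, plus intergenic genome positions.

    Bases shared by two features, start codons and stop codons/tails are
    frozen so that annotations stay valid under evolution.
    """
    L = genome.length
    count = [0] * L
    for f in genome.features:
        for p in range(f.start, f.end):
            count[p % L] += 1
    shared = {p for p in range(L) if count[p] > 1}
    per_feature: Dict[str, List[int]] = {}
    for f in genome.features:
        layout = _FeatureLayout(f, L)
        if f.kind == PCG:
            n_codons, rem = divmod(f.length, 3)
            stop_from = 3 * (n_codons - 1) if rem == 0 else 3 * n_codons
            idx = [i for i in range(3, stop_from)
                   if layout.positions[i] not in shared]
        else:
            idx = [i for i in range(f.length)
                   if layout.positions[i] not in shared]
        per_feature[f.name] = idx
    intergenic = [p for p in range(L) if count[p] == 0]
    return per_feature, intergenic


def _propose_base(rng, current: str, kappa: float) -> str:
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    others = [b for b in _BASES if b != current]
    weights = [kappa if b == transitions[current] else 1.0 for b in others]
    w = np.array(weights) / sum(weights)
    return others[rng.choice(3, p=w)]


def _evolve_branch(
    rng, state: _EvolvingGenome, t: float, espec: EvolutionSpec,
    mutable: Dict[str, List[int]], intergenic: List[int],
    code: GeneticCode, events: List[dict], branch: str,
) -> None:
    genome = state.genome
    ratio = espec.syn_rep_ratio
    p_syn = ratio / (1 + ratio)
    for f in genome.features:
        sites = mutable[f.name]
        if not sites:
            continue
        rate = espec.per_gene_rate.get(f.name, 1.0)
        n_events = rng.poisson(t * rate * len(sites))
        layout = state.layouts[f.name]
        if f.kind == PCG:
            coding = state.coding[f.name]
            for _ in range(n_events):
                want_syn = rng.random() < p_syn
                for _try in range(3000):
                    i = sites[rng.integers(len(sites))]
                    old = coding[i]
                    new = _propose_base(rng, old, espec.transition_bias)
                    c0 = 3 * (i // 3)
                    codon_old = "".join(coding[c0: c0 + 3])
                    codon_new = (codon_old[: i - c0] + new
                                 + codon_old[i - c0 + 1:])
                    if code.is_stop(codon_new):
                        continue
                    is_syn = (code.amino_acid(codon_new)
                              == code.amino_acid(codon_old))
                    if is_syn != want_syn:
                        continue
                    coding[i] = new
                    layout.write(state.seq, i, new)
                    events.append({
                        "branch": branch, "gene": f.name,
                        "site": i, "from": old, "to": new,
                        "class": "syn" if is_syn else "rep"})
                    break
        else:
            for _ in range(n_events):
                i = sites[rng.integers(len(sites))]
                old = layout.read(state.seq, i)
                new = _propose_base(rng, old, espec.transition_bias)
                layout.write(state.seq, i, new)
                events.append({
                    "branch": branch, "gene": f.name,
                    "site": i, "from": old, "to": new, "class": "noncoding"})
    if intergenic:
        n_events = rng.poisson(t * len(intergenic))
        for _ in range(n_events):
            p = intergenic[rng.integers(len(intergenic))]
            old = state.seq[p]
            new = _propose_base(rng, old, espec.transition_bias)
            state.seq[p] = new
            events.append({
                "branch": branch, "gene": "intergenic",
                "site": p, "from": old, "to": new, "class": "noncoding"})


def evolve(
    genome: MitoGenome,
    espec: Optional[EvolutionSpec] = None,
    code: GeneticCode = INVERTEBRATE_MITO,
) -> Tuple[List[MitoGenome], dict]:
    """Evolve three descendants of ``genome`` along the clade ((A,B),C).

    Returns the descendant genomes (annotations carried over unchanged —
    no indels are simulated) and a truth dict with the realized event
    table, per-gene class totals and the maximum per-site hit count.
    """
    espec = espec or EvolutionSpec()
    espec.validate()
    rng = np.random.default_rng(espec.seed)
    mutable, intergenic = _mutable_sites(genome)
    root = _EvolvingGenome(genome)
    events: List[dict] = []
    bl = espec.branch_lengths
    internal = root.clone()
    _evolve_branch(rng, internal, bl.get("AB", 0.0), espec, mutable,
                   intergenic, code, events, "AB")
    ta, tb, tc = espec.taxa
    tip_a = internal.clone()
    _evolve_branch(rng, tip_a, bl.get("A", 0.0), espec, mutable, intergenic,
                   code, events, "A")
    tip_b = internal.clone()
    _evolve_branch(rng, tip_b, bl.get("B", 0.0), espec, mutable, intergenic,
                   code, events, "B")
    tip_c = root.clone()
    _evolve_branch(rng, tip_c, bl.get("C", 0.0), espec, mutable, intergenic,
                   code, events, "C")
    genomes = [tip_a.to_genome(ta), tip_b.to_genome(tb), tip_c.to_genome(tc)]

    ev = pd.DataFrame(events, columns=["branch", "gene", "site", "from", "to",
                                       "class"])
    if len(ev):
        per_gene = (ev[ev["class"].isin(["syn", "rep"])]
                    .groupby(["gene", "class"]).size().unstack(fill_value=0))
        hits = ev.groupby(["gene", "site"]).size()
        max_hits = int(hits.max())
    else:
        per_gene = pd.DataFrame(columns=["syn", "rep"])
        max_hits = 0
    truth = {
        "seed": espec.seed,
        "events": ev,
        "per_gene_classes": per_gene,
        "max_hits_per_site": max_hits,
        "branch_lengths": dict(bl),
        "syn_rep_ratio": espec.syn_rep_ratio,
    }
    return genomes, truth


def gene_alignments(
    genomes: List[MitoGenome],
    kinds: Tuple[str, ...] = (PCG, RRNA),
    strip_stops: bool = True,
) -> Dict[str, Alignment]:
    """Per-gene alignments of gap-free homologous genomes (e.g. from evolve).

    Protein genes are returned stop-stripped and flagged coding so that
    divergence statistics can classify sites; rRNAs are returned verbatim.
    """
    out: Dict[str, Alignment] = {}
    ref = genomes[0]
    for feat in ref.features:
        if feat.kind not in kinds:
            continue
        rows = []
        for g in genomes:
            seq = extract_gene(g, g.feature(feat.name))
            if feat.kind == PCG and strip_stops:
                n_codons, rem = divmod(len(seq), 3)
                body = 3 * (n_codons - 1) if rem == 0 else 3 * n_codons
                seq = seq[:body]
            rows.append(seq)
        out[feat.name] = Alignment(
            ids=[g.id for g in genomes], rows=rows,
            coding=(feat.kind == PCG))
    return out
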