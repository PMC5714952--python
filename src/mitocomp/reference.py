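"""Published reference values for the three *Scaphoideus* mitogenomes.

These tables transcribe the deposited/published per-gene annotations of
the leafhoppers *S. maai* (GenBank KY817243), *S. nigrivalveus* (KY817244)
and *S. varius* (KY817245): gene lengths with start and stop codons
(truncated stops written ``T-``/``TA-``), region-level composition
summaries, and per-gene nucleotide diversity among the three species.
They serve as inputs to bookkeeping computations — e.g. deriving total
non-stop codon counts from gene lengths and stop completeness — and as
cross-checks when the full sequence records are available locally.
"""

from __future__ import annotations

from typing import Dict, Tuple

from .codon_usage import StartStopReport

SPECIES = ("S_maai", "S_nigrivalveus", "S_varius")

ACCESSIONS = {
    "S_maai": "KY817243",
    "S_nigrivalveus": "KY817244",
    "S_varius": "KY817245",
}

GENOME_LENGTHS = {"S_maai": 15188, "S_nigrivalveus": 15235, "S_varius": 15207}

#: Per-gene (start codon, stop codon, length) of the 13 protein-coding genes.
PCG_TABLE: Dict[str, Dict[str, Tuple[str, str, int]]] = {
    "S_maai": {
        "nad2": ("ATA", "TAA", 975),
        "cox1": ("ATG", "TAA", 1536),
        "cox2": ("ATA", "T-", 682),
        "atp8": ("ATT", "TAA", 153),
        "atp6": ("ATG", "TAG", 654),
        "cox3": ("ATG", "TAA", 780),
        "nad3": ("ATT", "TAA", 354),
        "nad5": ("TTG", "T-", 1666),
        "nad4": ("ATG", "T-", 1309),
        "nad4l": ("ATT", "TAA", 273),
        "nad6": ("ATA", "TAA", 477),
        "cob": ("ATG", "TAA", 1137),
        "nad1": ("ATA", "TAA", 933),
    },
    "S_nigrivalveus": {
        "nad2": ("ATA", "TAA", 975),
        "cox1": ("ATG", "TAG", 1536),
        "cox2": ("ATA", "T-", 682),
        "atp8": ("ATT", "TAA", 153),
        "atp6": ("ATG", "TAA", 654),
        "cox3": ("ATG", "TAA", 780),
        "nad3": ("ATC", "TAA", 354),
        "nad5": ("TTG", "TAA", 1668),
        "nad4": ("ATG", "T-", 1309),
        "nad4l": ("ATT", "TAA", 276),
        "nad6": ("ATT", "TAA", 477),
        "cob": ("ATG", "TAG", 1137),
        "nad1": ("ATA", "TAA", 933),
    },
    "S_varius": {
        "nad2": ("ATA", "TAA", 978),
        "cox1": ("ATG", "TAA", 1536),
        "cox2": ("ATA", "T-", 682),
        "atp8": ("ATA", "TAA", 153),
        "atp6": ("ATG", "TAA", 654),
        "cox3": ("ATG", "TAA", 780),
        "nad3": ("ATT", "TAA", 354),
        "nad5": ("TTG", "TAA", 1668),
        "nad4": ("ATG", "T-", 1309),
        "nad4l": ("ATT", "TAA", 276),
        "nad6": ("ATA", "TAA", 480),
        "cob": ("ATG", "TAA", 1137),
        "nad1": ("ATT", "T-", 931),
    },
}

#: Region-level (length, A+T %, AT-skew, GC-skew) per species.
REGION_TABLE: Dict[str, Dict[str, Tuple[int, float, float, float]]] = {
    "S_maai": {
        "whole": (15188, 77.2, 0.083, -0.158),
        "PCGs": (10929, 76.3, 0.090, -0.161),
        "rrnL": (1199, 81.2, -0.121, 0.181),
        "rrnS": (739, 78.6, -0.102, 0.178),
        "tRNAs": (1435, 76.8, 0.049, -0.112),
        "CR": (847, 81.9, -0.026, -0.100),
    },
    "S_nigrivalveus": {
        "whole": (15235, 76.5, 0.093, -0.154),
        "PCGs": (10934, 75.7, 0.099, -0.160),
        "rrnL": (1204, 79.8, -0.120, 0.228),
        "rrnS": (743, 77.7, -0.130, 0.193),
        "tRNAs": (1440, 76.1, 0.067, -0.071),
        "CR": (902, 83.1, -0.023, 0.018),
    },
    "S_varius": {
        "whole": (15207, 75.9, 0.075, -0.178),
        "PCGs": (10938, 74.7, 0.079, -0.178),
        "rrnL": (1203, 79.7, -0.127, 0.300),
        "rrnS": (743, 77.4, -0.106, 0.274),
        "tRNAs": (1439, 76.1, 0.043, -0.054),
        "CR": (762, 83.4, -0.014, -0.006),
    },
}

#: Per-gene nucleotide diversity (Pi) among the three species, and the two
#: rRNAs, as published with the sliding-window analysis.
GENE_PI = {
    "nad2": 0.23, "cox1": 0.15, "cox2": 0.17, "atp8": 0.27, "atp6": 0.20,
    "cox3": 0.18, "nad3": 0.19, "nad5": 0.21, "nad4": 0.21, "nad4l": 0.16,
    "nad6": 0.24, "cob": 0.17, "nad1": 0.18, "rrnL": 0.20, "rrnS": 0.17,
}

#: Control-region lengths.
CR_LENGTHS = {"S_maai": 847, "S_nigrivalveus": 902, "S_varius": 762}

#: Overlap census: (total overlap bp, number of overlapping junctions).
OVERLAP_CENSUS = {
    "S_maai": (31, 10), "S_nigrivalveus": (34, 11), "S_varius": (30, 9),
}

#: Intergenic spacers excluding the control region: (count, total bp).
SPACER_CENSUS = {
    "S_maai": (10, 70), "S_nigrivalveus": (9, 46), "S_varius": (13, 152),
}


def start_stop_reports(species: str):
    """The published per-gene start/stop/length rows as StartStopReport objects."""
    return [
        StartStopReport(gene=g, start_codon=s, stop_codon=e, length=n)
        for g, (s, e, n) in PCG_TABLE[species].items()
    ]
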