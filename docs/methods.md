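# Methods

This note documents the statistical and algorithmic choices behind
`mitocomp`, the parameters that matter, and what the synthetic-data tests
do and do not demonstrate.

## Coordinates, strands and the circular molecule

Internally all coordinates are 0-based half-open; the GenBank 1-based
inclusive convention is converted only at the I/O boundary, so
overlap/spacer arithmetic reduces to the sign of `start_b − end_a`. A
feature spanning the origin is one feature with `end > genome length` and
an explicit wrap flag, never a split interval — every gene stays a single
row in every table. Strands are labelled J (majority, as deposited) and N
(its complement). Ambiguous bases (N) are tolerated by the parser and
excluded from all composition counts, so partial genomes degrade
gracefully rather than erroring.

Gene-name canonicalization is data (`data/gene_names.yaml`), seeded with
the spellings common in leafhopper GenBank deposits (ND2/nad2, COI/cox1,
CYTB/cob, tRNA-Ser(AGN)/trnS1, ...). Leu/Ser isoacceptors are resolved
from the codon-family parenthetical or the annotated anticodon; an
unresolvable `tRNA-Ser` is deliberately left uncanonicalized rather than
guessed.

## Composition and skew

AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C); a degenerate denominator
yields a null component, not an error or a zero. Region summaries
concatenate member genes **in deposited-strand (J) orientation, in genome
order**. The alternative — coding orientation — would mix strands in the
PCG and tRNA rows and flip the sign structure of their skews; since
published composition tables for these genomes show a positive PCG
AT-skew, a whole-molecule J-strand property, J-orientation is the default
and `--coding-orientation` the flag. Percentages are carried at full
precision and rounded (A+T% to 1 decimal, skews to 3, Pi to 2) only when
tables are serialized.

## Codon usage

Stop classification is driven by length mod 3 — 0 requires a terminal
TAA/TAG, 1 a terminal T ("T-"), 2 a terminal TA ("TA-") — with
inconsistent terminal bases an annotation error rather than a warning.
Codon totals include the start codon and exclude each gene's (possibly
truncated) stop, the convention of the standard codon-usage software;
under it the per-genome total equals Σ genes (⌊length/3⌋ − [stop
complete]), which is the identity the published totals
(3632/3633/3635 non-stop codons) satisfy.

RSCU families default to amino-acid families (under the invertebrate
mitochondrial code: Leu 6-fold, Ser 8-fold, Met and Trp 2-fold via
ATA/ATG and TGA/TGG). The `split_isoacceptor` option splits Leu and Ser
by codon class (L1 = CUN, L2 = UUR, S1 = AGN, S2 = UCN) as RSCU plots are
usually labelled; family means equal 1 in either convention whenever the
family is observed. Amino-acid usage is reported both pooled and split
for the same reason.

## Architecture

Junction gaps ignore strand (real overlaps such as trnW–trnC span
opposite strands) and tile the full circle: n features give n junctions
and Σ gaps + Σ feature lengths = genome length exactly, an identity
asserted on every synthetic genome. The control region participates in
the junction list (its flanks are rrnS and trnI) but is excluded from the
overlap and spacer totals, which conventionally cover gene-to-gene
junctions only. Overlapping junction pairs are counted once each.

tRNA pairing census: dot-bracket structures are stack-parsed; pairs are
Watson-Crick (A-U, G-C), G-U wobble, or a named mismatch. Arm presence is
inferred from stem counts (maximal helix runs): a canonical cloverleaf
has four stems enclosing three hairpin loops; a structure with two
hairpins — the trnS1(AGN) pattern where the DHU arm is replaced by a
loop — gets `DHU: False`. Structures with internal loops or bulges split
stems and may need manual reading; the census is meant for the clean
predicted structures it consumes, not for structure prediction, which is
out of scope.

## Divergence

Pi is the mean pairwise p-distance over unordered pairs, computed on
mutually ungapped unambiguous columns (pairwise deletion; complete
deletion by flag). No multiple-hit correction is applied anywhere — the
statistics are deliberately raw counts and p-distances. Sliding windows
(default 250 bp / 25 bp, ⌊(L−window)/step⌋+1 points) use alignment
coordinates: gap columns keep their place on the x-axis but never enter a
distance.

Synonymous/replacement classification defaults to the site-substitution
rule: a differing site is synonymous iff substituting the other row's
base into the first row's codon, other positions fixed, preserves the
amino acid. This guarantees syn + rep = variable sites per gene, the
bookkeeping identity a per-gene divergence table needs. The
pathway-averaging alternative (all stop-free substitution orderings
between the two codons, Nei-Gojobori style) is available via
`method="pathway"`; it yields fractional counts and is closer to what
population-genetics software reports, but the two differ only at codons
hit more than once.

## Supermatrix, Degen, saturation

Partitions are recorded 1-based inclusive (the partition-file
convention); each coding gene carries three codon-position subpartitions
(13 PCGs → 39). Degen recoding is derived algorithmically from the
genetic-code table: position p of a codon becomes the IUPAC symbol over
exactly the bases that, holding the other two observed positions fixed,
encode the same amino acid (CTA→YTN, ATG→ATR, TGG→TGR under the mito
code). Because the rule conditions on the observed codon, the AGN and UCN
serine families never blend. Codons containing gaps or unknown symbols
become NNN. Already-degenerate codons re-recode only when all their
expansions agree and are otherwise left unchanged, which makes the
operation idempotent; note that, as in published Degen tables, the full
cross-expansion of a recoded codon (e.g. YTN) can cover a second amino
acid — the per-position guarantee is what the method provides.

The substitution-saturation index is reported as observed Iss only: mean
per-site entropy divided by its full-saturation expectation. That
expectation is computed for the actual number of sequences — per-base
counts at a fully saturated site are Binomial(n, q_b) in the matrix-wide
frequencies q, and the expected entropy of such a site is well below
−Σ q log₂ q for small n (≈1.68 bits for n = 8 at uniform q). With this
finite-sample reference a fully randomized alignment scores ≈1 for any
taxon count, which is what makes the index interpretable. The critical
values against which Iss is judged significant are derived by simulation
in dedicated software and are intentionally not reproduced; the report
prints observed Iss with a pointer. Upstream alignment filtering is
likewise not re-implemented: alignments are inputs, and a pass-through
flag records whether filtering was applied.

## Synthetic data: what it emulates, and what it does not

`GenomeSpec` defaults reproduce a deltocephaline leafhopper mitogenome at
scale: the 37-gene ancestral order with canonical strands, published-scale
gene lengths (three genes — cox2, nad4, nad5 — end on truncated stops by
virtue of length mod 3), an 847 bp control region, ten overlapping
junctions totalling 31 bp (including the conserved 7 bp atp8–atp6 and
nad4–nad4l overlaps and the 8 bp trnW–trnC cross-strand overlap) and ten
spacers totalling 70 bp (26 bp at trnY–cox1), giving a 15,188 bp circle.
Region A+T targets (PCGs 76.3%, rRNA 80.5%, tRNA 76.8%, CR 81.9%) and
J-strand skew targets follow the same published scale. Because interior
PCG codons are resampled whenever they form a stop, the naive base
distribution would undershoot A+T by ~1%; a fixed-point adjustment
inflates the draw distribution until the conditional-on-non-stop marginal
matches the target. Bases shared by overlapping genes are drawn jointly
under both genes' constraints (valid start, no internal stop, correct
stop or T/TA tail), with bounded rejection; an overlap that forces an
unsatisfiable frame raises a spec error naming the junction.

`EvolutionSpec` evolves a rooted three-taxon clade ((A,B),C) by per-site
substitution sampling without indels, so alignments of the descendants
are column-correct by construction and divergence statistics are tested
in isolation from aligner behaviour. Within protein genes each event's
class is drawn first (synonymous with probability r/(1+r) at
syn:rep ratio r, default 4) and a matching site/base change is then
rejection-sampled, never creating a stop and never touching start codons,
stop codons/tails, or overlap-shared bases — so annotations stay valid.
Per-gene rate multipliers default to the published per-gene diversity
ranking normalized to the mean protein-gene value (nad2/nad6/atp8 high,
cox1/nad4l low; CR at 2.0), and branch lengths default to
{AB: 0.05, A: 0.135, B: 0.135, C: 0.15} expected substitutions/site,
chosen so that the realized mean protein-gene p-distance lands near 0.20
after multiple-hit shrinkage — the study-scale divergence. All randomness
flows from one explicit seed.

What passing synthetic tests does **not** show: the generator draws sites
independently (no codon-usage autocorrelation, no realistic
control-region repeat structure, no rate heterogeneity within genes
beyond the syn/rep split, no indels), so agreement on synthetic data
validates the statistics' arithmetic and bookkeeping, not their behaviour
under alignment error or compositional heterogeneity between taxa. The
syn:rep estimator is validated in the low-saturation regime (multiple
hits rare); at study-scale divergence the event-level ratio in the truth
table remains near 4:1 but the site-level estimate is attenuated by
multiple hits at synonymous positions, which is expected and visible in
the truth tables.

## Problem sizes and determinism

The test suite simulates full-size (~15.2 kb) genomes — about a hundred
across the whole suite — and clades at two divergence depths; the
acceptance script runs one genome, two clades and the full downstream
pipeline. Every stochastic test is seeded (hypothesis runs derandomized),
and the CLI writes byte-identical outputs for identical inputs and seed.
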