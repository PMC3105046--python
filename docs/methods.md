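# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open; interval arithmetic
(overlaps, flank extensions, window enumeration) never needs ±1
corrections. User-facing positions are either 1-based inclusive (as
printed genomic spans are) or signed TSS-relative offsets with no zero: the
transcription start site is +1 and the base immediately upstream is −1.
Promoter-element positions quoted as "N bp upstream" therefore map to −N.
The no-zero convention is an assumption — published TSS-relative
coordinates rarely state whether the base before the TSS is −1 or 0 — and
`tss_relative`/`tss_absolute` form an exact bijection under it, which the
test suite asserts.

## A+T content

The point statistic is (#A + #T)/(#A + #T + #G + #C); `N` bases are removed
from numerator and denominator, so masked bases never dilute an estimate,
and an all-N window is undefined (NaN in profiles, an error as a point
value). Sliding profiles default to step 1 (denser steps are subsamples of
it) and drop trailing partial windows rather than padding, which would bias
edge estimates. Whole-region fractions, not window averages, are the
primary summary for regions; the two agree in the interior and differ only
through edge handling.

## Pairwise alignment and element delineation

The aligner is a three-layer affine-gap Gotoh dynamic programme (layers for
match/mismatch, gap-in-A, gap-in-B; gap runs cost `open + (L−1)·extend`;
layer switches between opposite gap types re-pay the opening penalty). Rows
are computed with vectorised numpy recurrences — the within-row horizontal
gap recurrence is a running maximum, computed in closed form with a
cumulative maximum — so a 1.5-kb × 1-kb problem takes ~0.1 s. Traceback
ties are broken deterministically: diagonal over gap-in-A over gap-in-B.
Scores are validated against exhaustive path enumeration on short inputs.

Default scoring is match +2, mismatch −3, gap open −10, gap extend −2.
The stiff opening penalty is deliberate: in AT-rich, low-complexity
promoter DNA, a weak opening penalty allows the *optimal* alignment to
fragment a long insertion gap, because interleaving a few flank bases into
the insert exploits chance matches (each rescued mismatch gains
`match − mismatch` = 5, while each extra gap run costs only
`|open − extend|`). At `open = −5` roughly 2% of seeded 5%-divergence
ortholog pairs produced fragmented, boundary-shifted elements; at −10
contiguity wins unless three or more rescued mismatches cluster in one
segment, and element recovery was boundary-exact on all seeds tested.

Insertion elements are maximal gap-column runs in one alignment row,
merged when separated by fewer than `merge_gap` (default 10) non-gap
columns; a merged group is kept when its summed gap length reaches
`min_len` (default 50, chosen to separate real 98/495-bp elements from
alignment noise). The reported element is the host-coordinate span from the
first to the last gap column — a contiguous, deletable interval whose
length can exceed the summed gap length when runs were merged across
matched columns. Elements are labelled ATRS1, ATRS2, … by TSS proximity
(most proximal first), following the convention that the proximal element
carries the lowest index.

Percent identity counts identical non-gap columns over all columns in the
scored range, gaps included in the denominator. Published ortholog-identity
figures rarely state their convention; this one is reproducible and is the
one this package reports.

TSS mapping slides the first 50 bases of a full-length cDNA along the
genomic sequence ungapped and takes the best-identity position, requiring
90% anchor identity; below that there is no confident anchor and the
mapping refuses rather than guesses.

## Motif scanning

Matching uses IUPAC degeneracy sets compiled to overlapping-match regular
expressions. An `N` in the scanned text matches only a consensus `N`:
masked bases never create hits. The heat-shock element is modelled as two
adjacent copies of `NTTCNNGAAN` (head-to-tail dimer, no spacer — published
descriptions of the dimer do not state whether gaps were permitted, and
adjacency is the stricter reading). That unit is self-reverse-complementary,
so HSE scanning is strand-symmetric by construction. Overlapping dimer
windows are resolved greedily left to right, matching the discrete, named
HSEs of promoter schematics. The TATA search uses `TATAWAW` within
[−45, −20] (a position is reported in the source material, not a consensus;
this is the standard insect TATA, configurable), preferring the most
TSS-proximal match. Zeste sites use the GAG-core consensus `YGAGYG` on both
strands; mutagenesis operates on annotated coordinates rather than
rediscovered motifs, so the exact consensus only matters for screening.

The default control-screen exclusion library is {HSE dimer, Zeste, GAGA}.
A TATA consensus is deliberately excluded: in AT-rich DNA, TATA-like words
occur every few hundred bases, and including them empties the candidate set
for any realistic tolerance.

## Matched-control selection

The screen follows the published procedure literally: a uniformly random
fragment (default 5 Mb; proportional to chromosome length across
chromosomes), exhaustive step-1 enumeration of windows of the exact target
length within ±0.3 percentage points of the target A+T (the "±0.3%" is
read as percentage points, not relative), strand-aware gene flanks (300 bp
upstream of the 5′ end, 200 bp downstream of the 3′ end; unstranded
annotations get the larger flank on both sides), a motif-free filter, and a
uniform random final choice. Window enumeration is O(n) via rolling counts
and is verified against naive per-window recomputation. Surviving windows
are not deduplicated before the draw (no dedup rule is published);
per-stage attrition counts are attached to every selection and to the
empty-set error.

**Quantisation.** A length-L window's A+T percentage lies on a 100/L grid.
For L = 98 the grid spacing is 1.02 points, so no window is within 0.3
points of exactly 65.000%; the nearest attainable compositions are 63/98
and 64/98. The screen's operational target is therefore the composition of
the element being replaced (64/98 = 65.31%, 371/495 = 74.95%), which is
what "a desired A+T content" means when the desired content is an existing
element's. The acceptance script uses these element-matched targets.

## Reporter constructs

Constructs are promoter inserts only (the vector backbone adds nothing to
insert-vs-insert comparisons). Each construct stores its parent sequence
and an ordered list of non-overlapping edits in parent coordinates;
the sequence is always the replay of the edits, asserted at construction,
so manifests are complete provenance. Deletions shorten by the element
length; replacements and site mutations conserve length (a length-changing
replacement is refused — matched-replacement designs conserve spacing).
Site-directed mutations verify the expected motif (e.g. GAG) at each
annotated footprint before substituting (e.g. AGA), refusing silently-wrong
edits. The wild-type amplicon spans from 65 bp upstream of the most distal
HSE to 135 bp downstream of the TSS. Restriction validation counts KpnI
(GGTACC), BglII (AGATCT), and PacI (TTAATTAA) sites by default and warns
when a cloning enzyme would cut internally.

## Assay statistics

Ratios are firefly/Renilla per replicate; fold induction is the ratio of
group means (heat shock over control). Group comparison is one-way ANOVA
(scipy) plus Tukey HSD with the Tukey–Kramer standard error for unbalanced
groups. Significance decisions compare the pairwise studentized-range
statistic against the critical value from
`scipy.stats.studentized_range.ppf`, cached per (α, k, df); the adjusted
p-value matrix is computed lazily from the same distribution's survival
function (one ppf evaluation serves any number of comparisons, keeping a
10⁴-replicate calibration loop at well under a millisecond per call, while
decisions and p-values remain mutually consistent). The all-identical
boundary case is reported as F = 0, p = 1. Tukey runs on raw ratios to
mirror common assay practice; luminescence is multiplicative, so a log
transform of the ratios before comparison is a reasonable user choice.
The heat-shock-versus-control contrast uses Welch's t test by default
(unequal variances are the safe assumption for multiplicative signals);
a pooled-variance test is available via `equal_var=True`. One-way ANOVA is
run within treatment across constructs; a two-factor
(construct × treatment) model is intentionally out of scope.

The compact letter display uses insert-and-absorb: start with one column
holding all groups; for every significant pair, split each column
containing both members into two columns (each lacking one member) and
absorb columns that became subsets; letter the surviving columns by the
highest-mean group they contain. This represents the significance relation
exactly — groups share a letter if and only if their adjusted difference is
not significant — and that equivalence is asserted on every result.

## Synthetic data

`make_genome` draws i.i.d. bases under a position-dependent A+T
probability (default: a sinusoid between 0.55 and 0.80 with a 50-kb period,
sweeping through the compositions relevant to matched-control screens) and
places non-overlapping stranded genes uniformly. `make_promoter_pair`
builds a ~900-bp insertion-free promoter (73% A+T background, TATA at −30,
four HSE dimers at −75/−140/−310/−550) and an insertion-bearing ortholog
carrying a 495-bp, 75% A+T element between HSE2 and HSE3 and a 98-bp, 65%
A+T element (with two `TGAGTG` Zeste sites) between HSE3 and HSE4 —
mirroring the element sizes, compositions, and placements of the motivating
system. Element compositions are planted by exact base-count shuffling, so
realised A+T equals the target up to 1/length quantisation. Backgrounds and
inserts are rejection-sampled so that exactly the planted HSE dimers and
TATA box exist; insertion ends are arranged to differ from their flanking
bases and divergence substitutions avoid planted motif footprints plus a
10-bp guard zone around insertion boundaries, keeping gap placement
unambiguous so that boundary-exact recovery is a property of the method
rather than luck. Divergence is applied to the insertion-bearing sequence
as uniform random substitutions at the requested per-base rate.

`make_luminescence` draws firefly signal as baseline × construct
multiplier × (induction multiplier under heat shock) × exp(N(0, σ²)) and
Renilla as its own log-normal channel (σ = 0.1 each by default, five
replicates). Default effect multipliers plant the headline reporter
phenotypes: wild type 1.0, element-1 deletion 3.0 (elevated expression; no
published magnitude, set to a clearly separable threefold), element-2
deletion 1/7 (the sevenfold collapse), double deletion 1.1 (near wild
type), and tenfold heat-shock induction.

What the fixtures do **not** emulate: real promoters have repeats,
microsatellites, context-dependent substitution processes, and indel
evolution beyond two clean insertions; real genomes have genes with
structure (UTRs, introns) and non-stationary composition beyond a smooth
landscape; real assays have plate effects, transfection-efficiency drift,
and heavier-tailed noise. Passing tests therefore demonstrate correctness
of the algorithms under controlled truth, not that any particular
biological promoter will align unambiguously or that assay noise is
log-normal.

## Problem sizes and determinism

The test and acceptance workloads use a 1-Mb single-chromosome genome with
20 genes, 50 seeded ortholog pairs for recovery checks, 200 random
100-bp fixtures for scanner/oracle agreement, 10⁴ replicates for the null
calibration of the letter display, and 300 seeds for effect-recovery
envelopes. Every generator and every random choice flows from an explicit
seed (numpy `default_rng`); identical seeds give bitwise-identical outputs.
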