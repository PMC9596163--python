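# Methods

## Coordinate conventions and interval algebra

All intervals are 0-based half-open `[start, end)`; BED input maps
directly and any 1-based source format would be converted at the reader.
Overlap requires at least `min_overlap_bp` shared bases (default 1, the
most permissive choice and the bedtools default). `normalize` merges
touching intervals (`end_i == start_j`): the screen reasons about covered
*footprints*, for which book-ended fragments are one region.

The primitives — `normalize`, `multi_intersect` (bases covered by every
input set), `filter_overlapping` (anchor peaks kept whole),
`subtract`, point-to-interval `distance` — are sorted sweeps, O(n log n)
per chromosome. They are validated two independent ways in the test
suite: exact agreement with a per-base boolean-array oracle on 1000
random instances (≤ 10 kb chromosome, ≤ 50 intervals, ≤ 4 sets), and
agreement with `bedtools merge`/`bedtools intersect -u` on random
fixtures. Strand is ignored for peak set operations; it matters only for
promoter windows.

`multi_intersect` reports the common *footprint*, not anchor peaks.
Where a screen wants one factor's peaks as the counting unit, the
`anchor:<label>` common mode keeps that factor's peaks whole if they
overlap every other set. Footprint is the default because it makes the
"common region" unit independent of which factor is listed first; both
operationalizations are exposed because the counting unit is a genuine
modelling choice.

## Promoter windows and chromatin states

A promoter window spans 1000 bp upstream through 10 bp downstream of the
TSS (1010 bp; the TSS base is the first downstream base), strand-aware
and clamped at position 0. For a + strand gene with TSS `t` this is
`[t-1000, t+10)`; for a − strand gene `[t-9, t+1001)`.

States derive from co-occurrence of four histone marks over an element
(≥ 1 bp overlap of a mark peak with the element):

| locus kind | rule (checked in order) | state |
|---|---|---|
| promoter | H3K4me3 ∧ H3K27ac | active |
| promoter | H3K27me3 ∧ no activation mark | repressed |
| promoter | H3K4me1 ∧ no activation/repression mark | poised |
| enhancer | H3K27ac | active |
| enhancer | H3K27me3 (no H3K27ac) | repressed |
| enhancer | H3K4me1 only | poised |
| any | otherwise | unclassified |

"Activation marks" are {H3K4me3, H3K27ac} at promoters and {H3K27ac} at
enhancers. Bivalent promoters (H3K4me3 + H3K27me3 without H3K27ac or
H3K4me1) satisfy no rule and stay unclassified; the screen does not
guess between poised and repressed for them, but `bivalent_as` lets a
user impose either reading. The 32-case truth table (2⁴ mark subsets ×
2 locus kinds) is asserted exhaustively in the tests.

Enhancer elements are the maximal merged runs of mark coverage outside
all promoter windows — the minimal assumption when no enhancer unit is
given. A mark peak straddling a promoter edge counts toward the promoter
(≥ 1 bp rule) while its remainder contributes to the enhancer footprint,
so promoter-assigned plus enhancer footprint exactly tile the mark
union (asserted per-base in the tests).

Element state is chromatin evidence only; coupling to expression happens
downstream in the screen's gate. This separation keeps the landscape
annotation reusable for analyses with different gating policies.

## Replicate consensus

For a factor with two replicates of unequal quality, the consensus keeps
replicate-1 peaks (their original coordinates) that either overlap a
replicate-2 peak or fall in a marked regulatory element, deduplicated.
The result is always a subset of replicate 1. Bare promoter windows
without any mark do not count as regulatory elements for this rescue —
an annotation line is not chromatin evidence. Consensus is applied
before the multi-factor intersection (configurable in principle; the
order is not identifiable from counts alone, and applying it first means
"common regions" are always built from reproducible peaks).

## Gene assignment and the expression gate

A common region associates with a gene if it overlaps the promoter
window (`in_promoter`, distance 0) or lies within `gene_window_bp`
(default 100 kb) of the *promoter-window midpoint* (`within_window`).
Distance is measured from the midpoint to the nearest base of the
region: peaks are extended objects and the nearest-base convention is
the permissive, standard choice. A region inside two genes' windows
associates with both; deduplication happens at the gene level, so a gene
with several supporting regions is one candidate.

Expression classes are quartile bands of the gating cell type's column:
`not` below q1, `low` in [q1, mean), `medium` in [mean, q3], `high`
above q3, with linearly interpolated quantiles and the bands applied in
that order (so on skewed data where the mean exceeds q3 the medium band
is simply empty, and every value still receives exactly one class —
asserted against a direct-comparison oracle on 1000 random vectors).
Boundary values follow a strict reading of "below"/"above": v = q1 is
low, v = mean is medium, v = q3 is medium. Whether classes are computed
on raw counts, CPM or FPKM is the caller's choice of input units; the
gating column and thresholds are recorded in `summary.json`.

The gate passes an association when the gene's class is allowed for the
element's state (default: active → {medium, high}, poised → {low},
repressed → {not}). Genes missing from the expression table yield
associations with `gate_passed = false` and a warning — never a silent
drop. The default screen keeps only active-promoter regions and
medium/high protein-coding genes; `required_state: any`, a wider gate,
or a larger window only ever enlarge the candidate set (monotonicity is
tested).

## Specificity ranking

No single standard statistic exists for "most specific to cell type t",
so the package defines its default as the pseudocounted log-ratio
against the strongest competitor,
`log2((v_t + 1) / (max_{c≠t} v_c + 1))` — robust to scale, zero when the
target ties its best competitor, and strictly increasing in the target
value (tested). `log_ratio_mean` and `zscore` are available as
alternatives; ties break lexicographically by gene id so ranking is
deterministic.

## Synthetic landscapes

The generator emulates the statistical structure the screen assumes, at
toy scale: 200 genes on 4 chromosomes (50 per chromosome, 250 kb
spacing, alternating strands to exercise both promoter-window branches),
20 planted targets, 3 factors, ~400 bp peaks. Planted targets get one
peak per factor centered on the promoter midpoint, H3K4me3 + H3K27ac
promoter peaks, and target-cell expression drawn from a negative
binomial (mean 500, dispersion 0.3) against a background of mean 20 —
enforced into the medium/high class by rejection re-draws (≤ 100 passes,
else an error, so the truth manifest is guaranteed true). Background
factor and mark peaks are placed uniformly but > 100 kb from every
promoter midpoint, so they can never create gene associations: on a
noise-free landscape the candidate set equals the planted set exactly,
which is the identifiability baseline the acceptance checks assert
across 20 seeds.

Noise knobs: `replicate_dropout_prob` deletes replicate-2 copies
(replicate 2 is replicate 1 jittered by ±50 bp), `mark_noise_prob`
deletes each required mark at planted promoters and sprinkles spurious
marks on non-target promoters. Under dropout 0.1 and mark noise 0.05 the
dominant loss mechanism is a planted promoter losing one of its two
activation marks (probability ≈ 1 − 0.95² ≈ 0.10), so expected recall is
≈ 0.90 while precision stays 1.0 — spurious marks create active
promoters without factor binding, which the intersection removes.

All randomness flows from one `numpy.random.default_rng(seed)` stream
(PCG64, portable across platforms) in a fixed draw order; identical
configs produce byte-identical files. What the generator does *not*
model: realistic peak-shape/signal, overlapping genes and isoform
structure, genome-scale peak counts, correlated replicate noise, or
biological covariation between chromatin state and expression beyond
the planted coupling. Passing the recovery tests therefore demonstrates
the pipeline's logic is correct under its own assumptions, not that the
rule set is biologically optimal.

## Numerical and scale choices

Problem sizes in the tests and the acceptance script (10 kb oracle
chromosomes, 1000 random oracle instances, 200-gene landscapes, 20 + 10
seeds) are chosen so the full suite runs in well under a minute per
component while leaving the per-base oracles exact; the interval sweeps
themselves are genome-scale capable. CPM columns sum to 10⁶ to within
1e-6 relative tolerance (floating-point only). JSON summaries round
percentages to 4 decimals; candidate tables are written unrounded.

## Known limitations

Peak calling, alignment, differential expression and single-cell
integration are out of scope by design. Enhancer–gene links are
distance-only; no Hi-C/capture-C input. No overlap-enrichment p-values.
The expression gate uses one gating column; multi-condition gating would
require a small extension of `ScreenConfig`.
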