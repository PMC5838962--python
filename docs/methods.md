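# Methods

## PQS model and scoring

A potential quadruplex-forming sequence is modelled as four ordered,
non-overlapping guanine runs separated by three loops. Runs are either
*perfect* maximal G tracts of ≥ `min_run_len` (default 2) guanines, or
*bulged*: two G segments of ≥ 2 guanines each split by one 1–3 nt non-G
insert, with ≥ `min_run_len + 1` guanines in total. A lone guanine
flanked by non-G never seeds a bulge — without that restriction a single
loop guanine next to a run would masquerade as a bulged run and a
spurious four-tetrad bulged reading would outrank the natural four-run
interpretation of real motifs. N is a valid character; it breaks runs
and counts as loop (or insert) material.

The score is additive and deliberately simple:

    score = T * tetrad_reward - mean(loops) * loop_penalty_per_nt - B * bulge_penalty

with `T = min over runs of min(g_count, max_run_len_counted)` and `B`
the number of bulged runs in the candidate. The defaults (reward 25,
loop penalty 1/nt, bulge penalty 25, run cap 5) encode one calibration
fact: a single bulge, or ~25 nt of extra mean loop, cancels the
stabilising effect of one extra tetrad. The constants are not a
reimplementation of any published scanner's fitted parameters — numeric
parity with such scanners is a non-goal — but they place four-run
motifs with three tetrads and short loops (the experimentally validated
kind) above the strict tier, and two-tetrad background clusters far
below it. Mismatched (non-bulge) tetrad defects are out of scope.

Loops are admissible in [1, 50] nt: genuinely long central loops
(dozens of nt) occur in biologically interesting motifs and must not be
excluded structurally; the loop penalty already demotes them. Candidate
span is capped at 110 nt. Three tiers grade hits with strict `>`
comparisons: 24 (reported), 64 (high-scoring), 65 (strict). The last
two are kept as distinct knobs on purpose: both values are in active
use as "high confidence" cuts and the package does not adjudicate
between them. `scan` itself returns hits with score ≥ the report
threshold.

Overlap policy: among overlapping candidates on the same strand the
highest score wins; ties break toward more tetrads, then shorter span,
then leftmost start. Greedy non-overlapping reporting matches how
per-element counts are tabulated downstream. Minus-strand hits come
from scanning the reverse complement; reported coordinates are always
plus-strand, 0-based half-open (GFF3 output converts to 1-based
inclusive). Determinism: identical input and parameters give identical
output; ties are broken by the total order above, never by dict or hash
order.

## Region model

LTR coordinates are inputs (BED/GFF3/TSV), never predicted. A position
is LTR if inside either annotated LTR; NEAR_LTR if within `margin` nt
of an LTR boundary (the margin defaults to 0; 350 bp reproduces the
"immediate neighborhood" convention of count statements); INT
otherwise. The margin applies to both flanks of both LTRs, since the
convention does not specify a side. Count statistics group NEAR_LTR
with LTR; density denominators always use the annotated LTR intervals
only, so the two readings (counts with neighborhood, densities without)
are both computable from one annotation.

Densities are per family and kb — each family contributes
`count/kb` and families are averaged — rather than pooled totals;
pooled totals would let a few very long families dominate. Families
with a zero-length denominator (no annotated LTRs) are excluded from
that density's mean. A hit spanning a region boundary is assigned by
its start position (the BED convention).

## Mutant design

G4 disruption substitutes G→A in the two inner runs (runs 2 and 3 in
sequence order) — the substitution position observed to damage folding
most — and by default replaces *every* inner-run guanine, which
guarantees no surviving tract of `min_run_len`. Verification re-scans
the mutant: no hit on the target strand may overlap the original
interval at the verification threshold (default: report threshold).
Inside long background sequences, weak two-tetrad candidates near the
interval can be unavoidable after disruption; verifying at the strict
threshold then asserts the loss of the quadruplex proper. The loop
control substitutes an equal-length motif inside a loop (CG→TC where a
loop offers CG), so loop lengths, run structure and score are provably
unchanged — verified by re-scan, not assumed.

## Reporter-assay statistics

lacZ units follow the Miller-style formula
`1000 * (Abs420 - blank) / (OD600 * volume_ml * time_min)`. The printed
form of that formula omits the blank, but the no-cell well is defined
as the starting value (it captures ONPG autolysis), so blank
subtraction is on by default and switchable off. Negative units are
reported as-is. Aggregation is replicate → colony mean → group: colony
means are the experimental unit (replicates of one colony are technical).
The one-way fixed-effects ANOVA is computed from between/within sums of
squares in-package; Tukey HSD adjusted p-values come from the
studentized range (scipy). Pairs are flagged at adjusted p < 0.001; the
source protocol prints the gate once as "p > 0.001" and once as
"p < 0.001", an inconsistency recorded in `AssayResult.notes` rather
than resolved.

## Expression analysis

CPM is counts over library total × 1e6; fractional counts (from
fractional multi-mapper assignment) are admissible throughout. The
low-expression filter is implemented literally: an element is removed
when at least `min_samples` (3) samples fall below CPM 45. That
direction differs from the conventional keep-rule (retain when enough
samples are *above* threshold); the conventional form is available via
`rule="keep_high"` and the package does not adjudicate the intent.

The group test is a documented stand-in for a dispersion-estimating
negative-binomial exact test: counts are adjusted to a common effective
library size (total × normalisation factor), pooled within each group,
and the treated pool is tested against Binomial(n = pooled total,
p = n_treated/n_total) with the central two-sided p-value
(2·min(cdf, sf), capped at 1 — chosen for exactness under equal
effective sizes and vectorisability). It ignores overdispersion, so its
p-values are anti-conservative for highly dispersed elements; the
|LFC| > 1.5 gate absorbs most of that in practice (see the calibration
tests), and `external_pvalues` provides a plug-point for parity studies
with a full NB test. LFC is log2 of the ratio of group mean CPMs with a
0.5 prior count. BH adjustment via statsmodels; calls at |LFC| > 1.5
and FDR < 0.05. Groups are fixed at treated/control with ≥ 3 libraries
each by default (`min_per_group`), mirroring the retained 3+3 design
the analysis assumes.

Normalisation factors multiply counts or coverage directly:
`total` is 1/library-total; `tmm` is 1/(total × TMM) with TMM the
trimmed mean of M-values (30% M-trim, 5% A-trim, precision weights)
against the library whose upper-quartile CPM is closest to the mean.
Both are scaled to geometric mean 1. Coverage aggregation is the mean
over group libraries of factor-scaled per-base coverage, with detected
G4 positions carried as an overlay.

## Synthetic data: the stated world

`gen_te_cohort` emits TE families with terminal LTRs and planted PQS.
Defaults state the world the statistics are tested in: 37% of families
carry motifs, carriers hold 1 + Poisson(2.2) of them (mean ≈ 3.2),
minus-strand probability 0.79, LTR:INT planted density ratio 2.0, LTR
length fraction ~ N(0.10, 0.02) per LTR, element lengths
Uniform(4000, 10000) nt — shorter than the largest real elements, a
compute-budget choice made once. Planted motifs draw run lengths from
{3, 4, 5} (0.4/0.4/0.2) and loops from Uniform{2..7} nt, so every
planted motif scores ≥ 68, above the strict tier.

The background guarantee is by construction rather than rejection:
background G and C homopolymer runs are capped at two nucleotides, and
under default scoring a strict-tier hit requires four runs of at least
three guanines with at most one bulge — which capped background cannot
supply on either strand. Planted motifs are therefore exactly the
strict-tier truth, and recovery, strand fractions and density ratios
are well defined. The trade-off is explicit: background *does* contain
abundant two-tetrad report-tier candidates (as real sequence does), and
the generator does not emulate nested insertions, element age structure,
GC heterogeneity or tandem repeats; a green cohort test establishes
correct bookkeeping and estimator behaviour under the stated world, not
performance on real genomic sequence.

`gen_plate_data` models lognormal colony effects (CV 15%) times small
replicate noise (CV 5%) around construct means of ~5 lacZ units
(mutant effects are multiplicative), six colonies × three replicates,
with the blank included in every reading. `gen_count_matrix` draws
per-element means from lognormal(log 150, 1) and NB counts via
gamma-Poisson at dispersion 0.1 (0 gives Poisson); planted DE elements
shift by ±true_lfc in the treated group. `gen_coverage` is piecewise
constant with a fold-change peak over the 5′ LTR and per-base Poisson
noise. All generators take explicit seeds and regenerate
byte-identically.

## Known limitations

- Scanner scores are this package's calibration, not any published
  scanner's; comparisons across tools should be made at the tier level.
- The exact-test stand-in understates p-value spread under strong
  overdispersion (see above).
- Candidate enumeration treats maximal tracts as atoms: a long G tract
  is never split to serve as two runs, and sub-tract readings (using
  part of a tract with the rest as loop) are not enumerated.
- RNA (U-containing) scanning, thermodynamic stability prediction and
  skew-based scoring are out of scope.
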