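# Methods

This note records the models implemented in `chipgas`, the parameter
choices that matter, what the synthetic data generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Coordinate and format conventions

SGA records are 1-based single positions; BED export is 0-based
half-open. Annotation intervals are 1-based inclusive internally. At equal
(chromosome, position), strands sort + before − before 0; chromosomes sort
lexicographically unless an explicit ordering is supplied. All window
memberships in the package are inclusive on both bounds: a tag at exactly
`pos ± halfwidth` counts. These conventions are enforced on read so every
downstream sweep can assume them.

## Fragment-size estimation and centering

The displacement histogram weights each same-chromosome (+,−) tag pair at
signed distance d by the product of the two counts; the implementation is
a sorted sweep proven equal to the all-pairs double loop in tests. The
fragment length is the histogram mode after a centered moving-average
smooth (default 5 bins) over a 50–500 bp search range. Smoothing turns an
isolated spike into a plateau, so ties at the smoothed maximum are broken
by the largest raw weight, then by the smallest offset — a point mass at
140 therefore reports 140, and a symmetric bimodal histogram reports the
smaller mode. The centering shift is the nearest integer to half the
estimated length (140 → 70). Centering moves + tags forward and − tags
backward by the shift, merges counts landing on the same position, sets
strand to 0, and clamps (with a log notice) positions that would fall
below 1.

## Peak calling

Defaults follow the canonical workflow: 200 bp window, 400 bp vicinity,
threshold 50, count cut-off 999999, refinement off. The dominance rule is
interpreted on *window sums*, not raw per-position counts: a candidate
must strictly exceed the window sum of every other candidate within half
the vicinity, with ties won by the leftmost position. Raw-count dominance
would make output depend on how identical fragments happen to split
across adjacent coordinates; the window-sum reading is deterministic and
is what the exhaustive oracle in the test suite encodes. The count
cut-off caps each position's count before summation. Optional refinement
reports the count-weighted mean position within the window, rounded half
up.

## GAS motif model and training

The motif is modeled as four left positions (one flank plus the TTC
half-site), three parallel spacer branches of length 2, 3 and 4 with
priors π₂, π₃, π₄, and four right positions (GAA plus one flank).
Emission rows are categorical over ACGT; background is uniform. Each
training window is explained under a ZOOPS occurrence model — zero or one
motif pass, occurrence probability γ, placement uniform within the
window — so the likelihood is an exact sum over (branch, placement) paths,
equivalent to forward–backward on the corresponding state graph (the test
suite checks the likelihood against an independent path-enumeration
oracle). EM re-estimates emissions, branch priors and γ; the
log-likelihood trace is asserted non-decreasing. N bases emit with
probability 1 from every state and are excluded from emission counts.
Training stops when the log-likelihood gain falls below `tol` (default
1e-4) or at `max_iter` (default 200); an infinite `tol` returns the
initial model untouched.

The initial model places weight 0.7 on each consensus base of TTC/GAA,
uniform flanks and spacers, and equal branch priors. Any consensus-biased
initialization reaching the same fixed point is acceptable; this one is
what the recovery tests exercise.

**Spacer emission tying.** By default only the dominant-length (spacer-3)
branch re-estimates its spacer emissions; the length-2 and length-4
branches keep background emissions and act purely as spacer-length
detectors (`adapt_spacers=(2, 3, 4)` restores fully free training). The
reason is a genuine identifiability pathology: the GAS core TTC-CCG-GAA is
self-similar — its C/G-rich spacer resembles the half-site boundaries — so
a freely adapting length-2 branch can absorb a shifted parse of a true
spacer-3 instance and retain a few percent of posterior mass at the global
maximum-likelihood solution (verified by starting EM at the generating
truth). Tying removes the parasitic parse while leaving length preference
measurable; on planted spacer-3 data the trained π₃ exceeds 0.98, with
the alternative classes below 1%.

Collapse to an 11-position matrix requires the alternative branch priors
to be at or below a floor (default 1%; residuals up to ~2% occur at
moderate sample sizes and may be accepted explicitly). The integer PWM
uses `w = int((3/ln 2)·ln(max(p, 10⁻³)/q))` with uniform background
q = 0.25: the probability floor keeps weights finite where a base was
never observed, and the scale puts one frequency doubling at +3 units.
Scanning reports the 1-based coordinate of the window's center (6th) base,
scores both strands by default with ties to forward, and skips windows
containing non-ACGT bases. Above-cutoff k-mer enumeration runs
branch-and-bound with suffix max-score bounds and is tested equivalent to
direct scanning.

## Occupancy, induction and classification

A site is occupied when strictly more than 5 centered tags fall within
±100 bp of its center. The induction statistic adds one pseudocount to
each condition's count and normalizes by the library totals before taking
the natural log; table output rounds half away from zero to two decimals.
Occupation classes for site classification are {0}, [1,5], [6,14], ≥15
tags; a site is TSS-proximal within 1 kb. Tandem pairs are same-chromosome
site pairs with center-to-center spacing in (0, 100] bp and mean score
strictly above 30; their induction is measured over ±200 bp around the
pair midpoint (integer-floored), and the induced-spacing summary keeps
pairs with log-ratio above 2. Compartment enrichment counts instances with
at least 10 bp overlap of the (merged) compartment and normalizes the
in-compartment density by the genome-wide density; tag-in-annotation
counting, in contrast, uses point containment — these are deliberately two
different rules. Conservation profiles are the count-density-normalized
feature correlation of site positions against a per-base track, so a
constant track yields a flat profile at its value.

## Synthetic data generator

The generator emulates the data-generating structure the analyses assume,
at desk scale: a single random chromosome (default 400 kb, GC 0.41)
carrying ~150 isolated motif instances sampled from a GAS-like generator
matrix, 25 near-identical repeat copies (one family, 2% per-copy
mutations of a consensus block whose two maximal-score sites sit 21 bp
apart, emulating an LTR-family consensus), 25 site-free control repeat
copies of a second family, and 20 non-repeat tandems with spacing drawn
uniformly from 18–22 bp and both sites conditioned on score ≥ 32. The
generator matrix follows the refined GAS structure (T TTC CCG GAA A; 0.85
half-site, 0.6/0.35 spacer, 0.4 flank probabilities) and is exactly
palindromic.

Tags: each site receives 100 fragment draws per condition; a draw succeeds
with the condition's occupancy rate, emits a fragment of length
round(Normal(140, 10)) centered at the site plus Normal(0, 20) positional
noise, and deposits a + tag at `center − ⌊L/2⌋` and a − tag at
`center + ⌈L/2⌉`. Stimulated occupancy is logistic in the site's integer
PWM score with midpoint 30 (the score where occupation separates from
background in the real data) and scale 2, saturating at 0.9; unstimulated
occupancy is a flat 0.005, making the unstimulated library essentially
background, as observed. Background tags are uniform at 0.0005/bp per
condition. The conservation track is 0.07 genome-wide and 0.7 within
±10 bp of planted sites.

Because the simulated region is site-dense compared with a real genome, it
is treated as a slice of a genome-scale experiment: induction
normalization uses experiment-scale library totals (15,250,744 and
13,019,977, carried in the config) rather than region sums, which would
otherwise cancel most of the induction signal — real libraries are
background-dominated and nearly equal in size between conditions.

Training-window generation for the motif module plants exactly one
instance per window at a uniform placement over a uniform-composition
background (matching the trainer's background model, so parameter-recovery
tests are well-posed). The repeat-redundancy harness appends a configured
fraction of near-identical windows spread over (default) 16 prototype
families, reflecting that real repeat content in a peak set spans many
unrelated families with the largest only a few percent; a single dominant
family would genuinely — and correctly — drag weakly constrained matrix
positions toward its particular instance.

What the generator does *not* emulate: read sequences or mapping error,
duplicate-read artifacts, chromatin accessibility or cooperative binding,
copy-number variation, non-uniform background (GC or mappability bias),
and genome-scale site sparsity. Passing tests therefore demonstrate the
correctness of the algorithms under the stated generative assumptions, not
robustness to every artifact of real libraries.

## Problem sizes

Test and acceptance runs are sized for a single CPU: genomes of 50–400 kb,
2000 training windows of 200 bp for motif recovery, 5000 fragments for
fragment-length recovery, and peak fixtures of ≤3000 records for oracle
equivalence. These sizes give stable statistics for every asserted
property while keeping the full suite around a minute of compute.

## Known limitations

- The peak caller's dominance rule at the vicinity edge follows this
  package's contract (inclusive half-vicinity, window-sum comparison);
  other implementations of the same idea may differ at exact ties.
- The HMM trainer is EM and can in principle sit at a local optimum;
  the consensus-biased initialization and the spacer tying above make the
  planted-motif fixed point the one reached in practice.
- Occupancy saturates at the simulated per-site depth (100 draws), so the
  stimulated occupancy-vs-score curve rises to ~1 rather than to the
  ~0.18 ceiling of the genome-scale experiment; the qualitative contrast
  (rising vs flat) is the modeled feature.
- `feature_correlation` holds per-chromosome target arrays in memory;
  suitable for desk-scale tracks, not whole-genome base-wise tracks.
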