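# Methods

This note documents the models, parameters and design choices behind
`thyrofish`: what is simulated, how profiles are segmented and called, how
markers are selected and FISH cases scored, and what the synthetic tests
do and do not demonstrate about real data.

## Copy-number model and simulation

An aCGH profile is a vector of per-probe log2(Cy5/Cy3) ratios against a
sex-matched reference. A tumor region at integer copy number `cn` in a
specimen of purity `p` (tumor cell fraction) over a germline baseline `b`
has expected ratio

    log2((p * cn + (1 - p) * b) / b)

so a single-copy loss at purity 0.8 sits at log2(0.6) ≈ −0.74, a female
whole-X gain at log2(1.4) ≈ +0.49 and a male whole-X gain — one extra copy
on a one-copy baseline — at log2(1.8) ≈ +0.85. Female chrY probes have no
signal in either channel and are emitted at 0. On top of the copy state
the generator adds a linear GC trend (`gc_bias * (gc − mean gc)`, default
coefficient 0.5 log2 per GC-fraction unit), a constant dye offset (default
0.1) and i.i.d. Gaussian probe noise.

Key generator defaults and why:

* **purity 0.8** — the study design's minimum tumor cell content; the most
  attenuated (hardest) study-consistent setting.
* **noise sd 0.12** — the arrays' noise magnitude is not published; 0.12
  gives per-probe |z| ≈ 6 for a single-copy loss, a mid-range value for
  good-quality oligonucleotide aCGH. It is a free parameter.
* **probe spacing 100 kb** (configurable) — a regular grid standing in for
  a 244k-feature whole-genome array at tractable size. The smallest marker
  region (22q13.2-22q13.31, 5.6 Mb) spans ≥ 3 probes at every spacing used
  in the suite (tests use 0.5–2 Mb grids for speed; the end-to-end
  reproduction uses 100 kb).
* **cohort designs** — fixed case assignments reproducing the study sets:
  training 33 cFA / 33 cFTC with marker counts 5 (1p) / 8 (22q) / 8 (X),
  one double (1p+22q) and one triple carrier, hence 21 alterations in 18
  distinct carcinomas; validation 26/34 with 3/12/4 where every 1p loss
  co-occurs with a 22q loss and X gains are isolated; feasibility 13/14
  with 2/2/2 and no co-occurrence. The training FISH arm covers 44 touch
  preparations (20 cFA / 24 cFTC) and includes one adenoma with a
  subclonal 22q loss (aberrant-nucleus fraction 0.35) — FISH-positive but
  below aCGH detectability — which supplies the study's single false
  positive.
* **background events** — whole-chromosome gains (5, 7, 9, 12, 14, 16, 17,
  20) and losses (3, 4, 8, 11, 21) shared by both classes. A
  "complex-genome" subgroup (13 of 33 cFTC, 4 of 33 cFA) carries 3–6 such
  events. Two deliberate choices: (i) the four complex adenomas jointly
  cover every background chromosome, so only the three markers are
  carcinoma-exclusive — which is what defines them as markers; (ii)
  complex genomes draw a balanced mix of gains and losses, keeping the
  profile median at the two-copy baseline. Median centering assumes the
  median probe is unaberrated; a strongly gain-dominated genome on a
  bounded grid breaks that assumption and would shift every other
  chromosome below the calling threshold.

FISH counts are simulated per nucleus: with probability
`aberrant_fraction * (1 − contamination)` the nucleus shows the aberrant
pattern (1 target : 2 controls for a locus loss; 3 X female / 2 X + 1 Y
male for an X gain), otherwise the sex-appropriate normal pattern; every
expected signal is then dropped independently with the hybridization
failure rate. Defaults: 200 nuclei per panel (so ≥ 100 remain informative
after control failures), aberrant fraction 0.6, failure rate 0.05,
contamination 0.1.

## Normalization

Locally weighted regression (lowess, `frac = 0.3`, one robustifying
iteration, `delta` = 1% of the GC range for speed) of the log2 ratio on
probe GC fraction is subtracted, then the median is subtracted. Output
median is 0 within 1e-9. Profiles with (near-)constant GC skip the first
step with a warning.

## Segmentation (CBS)

Per chromosome, probe values are arranged on a circle and the arc (i, j]
maximizing

    T(i, j) = |mean(x[i:j]) − mean(rest)| * sqrt(k (n − k) / n)

is found (the overall variance is permutation-invariant and omitted; ties
break toward smaller arc width, then smaller start). The split is accepted
when its permutation p-value `(1 + exceedances) / (1 + n_perm)` falls
below `alpha` (defaults: alpha 0.01, 10 000 permutations, minimum width 2
probes — the documented defaults of the standard CBS implementation).
Accepted splits recurse into the up-to-three resulting sub-segments; each
(sub)segment's permutation stream is seeded as
`default_rng([seed, chromosome_rank, offset, length])`, making every
decision reproducible independently of recursion order.

Permutation testing is sequential, in the spirit of the early-stopping
boundaries standard CBS uses: testing stops early (i) with rejection when
the running estimate can no longer reach alpha, or when ≥ 5 exceedances
have occurred with the estimate still at or above alpha, or when the
estimate is still ≥ alpha/2 at the 500/1000/2000/5000-permutation
checkpoints; (ii) with acceptance when the estimate is below alpha/5 at a
checkpoint. Clearly significant and clearly null splits — the vast
majority — therefore cost hundreds rather than ten thousand permutations;
only genuinely borderline splits (running p within a factor of ~2 of
alpha) pay full price, and the checkpoint rules can misclassify a split
whose true permutation p lies in that narrow band. A permuted maximum
counts as an exceedance within a relative tolerance of 1e-9, so that
permutations re-creating the observed partition tie consistently
regardless of floating-point summation order. The inner scan is
numba-compiled; the test suite checks the engine against a pure-Python
oracle that enumerates every circular split with the same permutation
stream.

No merging/pruning pass is applied beyond the recursion stop.

## Noise-adaptive calling

The per-profile threshold is `max(tau, floor)` with
`tau = median(|x[i+1] − x[i]|) / 4` over consecutive probes within a
chromosome (differences never cross a chromosome boundary, which would
inject spurious jumps) and `floor = 0.05` log2 units: on noiseless
synthetic data tau is 0 and a zero threshold would call everything. A
segment is called gain/loss when its mean reaches ±threshold and it spans
at least 3 probes. tau is computed on the normalized, unsegmented profile.

## Marker discovery

Samples are compared on the union-breakpoint grid (every interval between
consecutive segment boundaries pooled over all samples; probes belong to a
region iff their midpoint does). Regions are ranked by a two-sided
Wilcoxon rank-sum test between classes and selected greedily: keep regions
with raw p < 0.05 (no multiple-testing correction — ranking is by raw p by
design; a Benjamini–Hochberg option exists) that are normal in every
adenoma, then repeatedly take the region covering the most not-yet-covered
carcinomas, ties broken by smaller p then genome order.

The rank test runs by default on the ordinal aberration states (−1/0/+1)
with the tie-corrected normal approximation, not on the continuous segment
means. The reason is statistical, and measurable in the generator: a
recurrent alteration present in 5 of 33 carcinomas leaves the other 28
carcinoma values interleaved with the 33 adenoma values in the noise
ranks, and the rank-sum test on continuous means then has essentially no
power at any effect size (two-sided p ≈ 0.29 for 5/33 carriers, ≈ 0.09
for 8/33 — never significant at 0.05). On the discrete states the heavy
ties collapse the null variance and the same contrasts give p ≈ 0.02 and
p ≈ 0.003. Value-based testing remains available (`on="values"`), uses
the exact enumeration null for tie-free groups of ≤ 10, and is what the
enumeration oracle tests check.

The minimal common region of a marker is the intersection of the carrier
intervals; disjoint carrier intervals are an error naming the offenders.

## FISH scoring

Locus panels (1p36.31/1q25.3 and 22q13.3/22q11.2) use a ratio rule so
polyploid nuclei read correctly: with ≥ 2 control signals, target <
control is a loss (3:6 is a loss), target > control a gain, balanced is
normal; fewer than two controls (or no signals) is uninformative. CEP X/Y:
female gain is X ≥ 3; male gain is X ≥ 2 regardless of Y, including the
trisomic X=2/Y=1 pattern. The whole-chromosome-like patterns (1:1 on a
locus panel, male X=1/Y=0) are uninformative for the focal markers and
tallied separately rather than guessed into a call.

A case's panel is insufficient below 100 informative nuclei; otherwise
positive when the aberrant fraction reaches the positivity cutoff. The
cutoff is not published for the assay; 0.20 of informative nuclei — a
common clinical FISH deletion threshold — is the default, is a mandatory
explicit parameter of `score_case`, and is reported with every call. The
case is positive iff any panel is positive; insufficient cases are
excluded from accuracy tables rather than counted negative.

DNA-index ploidy: diploid [0.9, 1.1]; aneuploid [0.6, 0.9) and (1.1, 1.8);
haploid [0.5, 0.6); tetraploid [1.8, 2.2]; outside [0.5, 2.2]
unclassifiable; two or more DIs differing by > 0.05 (the flow-cytometric
CV scale — exact float equality is meaningless) are multiploid. Shared
interval endpoints are assigned to the more benign class.

## Diagnostics

Positive = assay-positive, diseased = carcinoma by histology. All
statistics are simple proportions of the pooled 2×2 table with exact
Clopper–Pearson 95% CIs (beta quantiles); this choice reproduces the
study's printed sensitivity and specificity intervals exactly after
integer rounding. Percent renderings round half up; raw fractions are
always kept in machine output. Predictive values at an assumed prevalence
π use Bayes' rule:

    PPV = sens·π / (sens·π + (1−spec)(1−π))
    NPV = spec·(1−π) / ((1−sens)·π + spec·(1−π))

## What the synthetic tests do and do not show

The generator produces piecewise-constant profiles with Gaussian noise,
whole-arm/whole-chromosome events at fixed amplitudes, and binomial FISH
counts. Passing tests therefore demonstrate the pipeline's correctness
(segmentation matches an exhaustive oracle; calls recover implanted events
with probe-level F1 ≥ 0.95; the greedy selection equals minimum set cover;
the pooled table reproduces the study statistics) — not robustness to
wave artifacts, focal amplifications, mosaic subclones, probe-specific
variance or scorer disagreement, none of which are modeled. Real-data
caveats that the clean generator surfaces explicitly:

* Ward 2-cut clustering on the three marker regions isolates a *pure*
  marker-positive cluster but does not gather *all* positives into one
  cluster: with orthogonal marker directions at different amplitudes the
  first Ward split separates the dominant-amplitude carrier group. Full
  two-cluster separation of positives from negatives, as seen in the
  study's heatmap, relies on positives sharing additional genome-wide
  structure that the clean generator deliberately omits.
* Exact per-set reproduction of the confusion table depends only on the
  scoring thresholds, not on seeds: positives sit at aberrant fractions
  ≈ 0.5 against a 0.20 cutoff and negatives at ≈ 0.09 (from hybridization
  dropout), so misclassification probabilities are ~1e-7 per panel.

## Problem sizes

The default end-to-end reproduction simulates 66 training profiles on a
whole-genome 100-kb grid (~30 000 probes), segments all of them with
10 000-permutation CBS, and scores 131 FISH cases × 3 panels × 200 nuclei;
it completes in about 2–3 minutes on one CPU. The test suite runs the same
pipeline at 0.5–2 Mb spacing where it takes seconds, and reserves the
100-kb configuration for the single end-to-end acceptance test.
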