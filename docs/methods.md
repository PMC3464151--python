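# Methods

## Model and scope

`orderspc` treats a univariate data set x₁, …, xₙ of logically comparable
measurements (canonically percentages on the 0–100 scale) and asks how the
XmR chart's dispersion statistic — the average moving range
mR̄(y) = (1/(n−1)) Σ |y_{j+1} − y_j| of an ordering y — behaves when the
ordering is arbitrary.  Three computations carry the argument:

1. **Extrema.**  Writing the sorted gaps as δⱼ = x_{j+1} − xⱼ, any ordering's
   moving-range sum is Σ cⱼ(y) δⱼ, where cⱼ(y) counts the consecutive pairs
   of y that straddle gap j.  The minimum is the sorted order (every cⱼ = 1,
   S_min = xₙ − x₁).  The maximum's coefficient vector rises 2, 4, … from
   both ends; n even peaks at n − 1 on the middle gap, n odd gives the two
   central gaps (n−2, n−1) with the larger coefficient on the larger central
   gap (the two variants coincide when the central gaps tie).  Ties (δⱼ = 0)
   need no special casing.  n = 2 is degenerate: S_min = S_max = δ₁.
2. **Resampling.**  Uniformly random permutations (numpy PCG64, explicit
   64-bit seed; each sample is a complete permutation, so every datum occurs
   exactly once per ordering, while orderings themselves are drawn with
   replacement) give the empirical distribution of mR̄ between the extrema;
   its closed form is data-dependent and not attempted.  Default 16,383
   resamples, configurable.
3. **Consequences and alternatives.**  Individuals-chart limits
   mean ± 2.66·mR̄ evaluated at mR̄_min and mR̄_max give the attainable range
   of limit widths; the report expresses the width difference as a multiple
   of the data range and counts flagged points under five schemes (the two
   XmR extremes, inner/outer Tukey fences, 3-sigma).  For unordered data the
   recommendation is always an order-free method; for ordered data, XmR.

## Numerical and convention choices

* **E2 = 2.66** (3/d2, d2 = 1.128 for moving ranges of span 2) is a named
  constant, not hard-coded inline; the moving-range chart's upper constant is
  D4 = 3.267.  Signal detection implements only the beyond-limits rule, with
  strict inequality: a point exactly on a limit is not flagged (immaterial
  for continuous data, documented for discrete).
* **Lower limits below zero** on percentage/count scales are retained raw and
  flagged `lower_clipped_at_zero`; the interpretive lower bound is 0.
* **mR̄ is summed with `math.fsum`**, so reversal invariance
  mR̄(y) = mR̄(reverse(y)) holds exactly, not just to rounding.
  `mr_bar_range` divides S_max − S_min once by n − 1, making the
  coefficient-reduction identity S_max − S_min = Σ (cⱼ − 1) δⱼ exact on
  integer data.
* **The maximising ordering** is constructed, not proved: a zigzag that
  alternates between the lower and upper halves of the sorted values
  (both middle-split choices and a mirrored variant are tried, the best
  kept).  Every construction is verified against the closed-form S_max at
  1e-12 relative tolerance; on failure the exhaustive search is used for
  n ≤ 9 and an error is raised beyond — a silent wrong ordering is never
  returned.  The exhaustive oracle enumerates one ordering per reversal pair
  (n!/2) and is capped at n = 9 (181,440 evaluations), which keeps the
  oracle-equivalence grid (n = 3…8, 200 data sets per n, mixing ties,
  arithmetic progressions with equal central gaps, and continuous draws)
  inside a few seconds.
* **Quartiles** default to Tukey hinges (medians of the sorted halves, the
  halves including the overall median for odd n), matching the method's
  attribution; linear-interpolation percentiles are selectable, and the
  report records which convention produced its numbers, plus the limit
  constant and seed, so any analysis can be restated exactly.  Sample SD
  uses the n − 1 denominator throughout; the SD of a single-element
  resample distribution is reported as 0 with a warning rather than an
  error, keeping degenerate pipelines running but flagged.
* **Percentiles** of the resample distribution use linear interpolation
  between order statistics (conventions differ, so this is stated).
  Histogram bins are equal-width over [min, max], right-open except the
  last; an all-equal distribution collapses to one zero-width bin.
* **Display rounding** follows the source tables: three significant figures
  (one decimal place for the limit values), round half to even.  Floats are
  snapped to 12 significant digits before quantisation so that arithmetic on
  printed decimals rounds as the decimals would ((75 − 16.7)/22 displays as
  2.6); JSON output always carries full precision, rounding is display-only.
* **Attribute charts** use the standard Shewhart 3-sigma limits on the pooled
  binomial (p, np) or Poisson (c, u) rate, at the minimal depth needed to
  exercise their permutation invariance: per-subgroup stair-step limits for
  p/u with varying sizes, a single limit set for c and for np (np requires a
  constant subgroup size and errors otherwise).

## Synthetic data

The real 23-ward compliance values behind the motivating example were never
published — only their summary statistics (mean 33.7, median 27.9, SD 16.9,
range 16.7–75) — so the generator emulates their character rather than the
data.  The default family is a lognormal clipped to [0, 100] with
exp(μ) = 27.9 (the published median) and σ = 0.615 (placing the unclipped
mean at 33.7).  This was chosen over a scaled Beta because, at these
moments, a Beta's right skew is too weak to keep the sample mean above the
sample median reliably at n = 23 (measured ≈ 0.73–0.79 of seeds, versus
≈ 0.94 for the clipped lognormal), and the generator's contract is that the
default family shows the mean-above-median skew that motivates preferring
Tukey's fences over the symmetric 3-sigma rule.  Beta, uniform and constant
families remain available.  What the generator does *not* emulate: any
between-ward structure (hospital-site clustering, shared trends), reporting
artefacts, or the exact tail weight of the real wards.  Passing tests
therefore demonstrate the mathematics and the software contracts on data of
the right shape, not reproduction of the unpublished measurements; the
published resampling summary and flagged counts are consequently treated as
illustrative, not as targets.

## Problem sizes

The test suite and acceptance script run the exhaustive oracle only to
n = 9, the oracle-equivalence grid at 200 data sets per n for n = 3…8, the
sandwich check at 50 data sets × 200 orderings, determinism and
extreme-attainment at 20,000 resamples of an n = 6 set, and the generator
skew contract at 1,000 seeds — sizes at which every check is exact or has
negligible Monte-Carlo error while the whole suite stays fast.

## Known limitations

* No proof of the S_max closed forms is attempted; correctness rests on the
  exhaustive oracle (n ≤ 9) plus per-call verification of the constructed
  ordering at every n.
* Only the beyond-limits signal rule is implemented — no run rules, zone
  rules, EWMA or CUSUM.
* The distribution of mR̄ between its extrema is sampled, never derived.
* Attribute charts use the normal approximation with no small-sample
  corrections; the unimodal-inequality variant of the sigma rule is out of
  scope.
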