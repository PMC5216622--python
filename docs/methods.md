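# Methods

## The problem

Dinoflagellate cysts preserved in marine sediment cores record the size of
the motile cells that produced them (cyst diameter is a 1:1 linear proxy
for cell size). Comparing cyst size distributions between two climate
intervals of the same core — here a relatively warm medieval period versus
the colder Little Ice Age in a Disko Bay (West Greenland) record — tests
the temperature–size rule through time rather than through space. A shift
in the *community* mean size can come from two sources that this package
separates:

* **intraspecific change** — species themselves growing or shrinking
  (phenotypic plasticity), and
* **interspecific change** — the community re-weighting toward larger or
  smaller species (species turnover), with species trait values fixed.

## Model and estimators

Let Ø_obs be individual cyst diameters, N_spe the number of cysts of a
species counted in a period's assemblage and N the period total, so the
species weight is w_spe = N_spe / N. With m_spe measured cysts of that
species in the period, each observation carries weight
w_obs = w_spe / m_spe, and

* x̄_intra+inter = Σ(Ø_obs · w_obs) / Σ w_obs — the community-weighted
  mean including both sources of change;
* x̄_inter = Σ(Ø_avg · w_spe) / Σ w_spe — the community-weighted mean with
  species values frozen at their cross-period means Ø_avg, so it moves
  between periods only through the weights.

The warm→cold change partitions as Δ_total = x̄(cold) − x̄(warm) at the
intra+inter level, Δ_inter likewise at the inter level, and
Δ_intra = Δ_total − Δ_inter. The partition is exact by construction;
fractions Δ_intra/Δ_total and Δ_inter/Δ_total are signed and undefined
(reported as missing) when Δ_total = 0.

Weighted dispersion uses SD_w = sqrt([Σw(x − x̄_w)²/Σw] · n/(n−1)) and
SE = SD_w/√n, where n is the number of measured cysts at the observation
level but the number of *species* at the interspecific level — the only
convention consistent with the published community table (5.97/√219 = 0.40
and 6.60/√6 = 2.69). The n/(n−1) correction makes the uniform-weight case
collapse to the ordinary sample SD; it can be disabled
(`sd_correction=False`).

Mean differences are tested with the Welch two-sample t-test (unequal
variances, Satterthwaite df, two-sided p). The community-level weighted
variant uses t = Δx̄_w / sqrt(SE_a² + SE_b²) with weighted means and SDs;
its reference formulation gives the t form but no df rule, so the default
is Satterthwaite on the weighted variance components with n_obs − 1
component dfs, with `df_mode="pooled"` (n_a + n_b − 2) exposed as the
alternative. With uniform weights the weighted test reduces exactly to the
unweighted one. No multiple-testing correction is applied across the six
species tests, matching the original analysis battery (six unweighted
tests plus one weighted community test).

Size-change conversions treat cysts as spheres: a linear change of
100·(c/r − 1)% corresponds to a volume change of 100·((c/r)³ − 1)%; the
diameter-versus-radius factor cancels in the ratio.

## Literature comparison

Published size tables give either a diameter range or, for elongate taxa,
length and width ranges. Conversion averages endpoints:
d_min = round((l_min + w_min)/2), d_max = round((l_max + w_max)/2); the
midpoint is round((min + max)/2). All rounding is half away from zero,
the rule that reproduces the published integer table cell for cell
(50.5→51, 23.5→24, 44.5→45, 34.5→35, 41.5→42 — banker's rounding would
not). Comparison flags use strict inequalities of the measured per-period
means and the measured total range against the literature range endpoints.
The literature-based community mean evaluates the interspecific estimator
with midpoints as the fixed species values and the same per-period
assemblage weights as the measured interspecific mean.

## Design choices

* **Ø_avg pooling.** "Mean size across both periods" is read as the
  n-weighted pool of all the species' measured cysts (default
  `pooling="pooled"`); the unweighted average of the two period means is
  exposed as `pooling="period_mean"`. The published rounded values cannot
  adjudicate between the two without the raw data.
* **Direction.** Deltas are comparison minus reference — cold minus warm
  here — so positive values mean larger in the cold period.
* **Included species.** Community statistics run over the intersection of
  species present in the observation and assemblage tables, with weights
  renormalized over that set.
* **Species matching** is exact string equality after whitespace trimming;
  cyst-versus-vegetative synonymy is the input file's responsibility.

## Synthetic data generator

The raw per-cyst measurements behind the study were never deposited. The
generator emulates them from what is public: per-species per-period mean,
SD and n (448 measured cysts in total across six species), assemblage
totals of 613 (warm) and 680 (cold) counted cysts, and the dominant-taxon
relative abundances (I. minutum 0.50→0.65, P. dalei 0.20→0.08,
I.? cezare 0.04→0.06 from warm to cold).

* Diameters are drawn from normal(mean, sd) truncated below at 0.1 μm —
  the study assessed normality visually and found it adequate; truncation
  only guards the positivity invariant and is numerically irrelevant at
  the fixture's parameter values (≥ 7 SDs from the bound).
* The three non-dominant measured species' abundances are not published;
  the fixture splits each period's residual fraction across B. simplex,
  S. elongatus and S. ramosus proportionally to their measured n in that
  period and renormalizes over the six species. This is a declared fixture
  convention, not a published value.
* Rare and unidentifiable cysts ("Other", roughly a fifth of the real
  assemblage) are excluded and weights renormalized over the six measured
  species, since measurements cover only those six and the observation
  weights must sum to 1 over included cysts.
* Integer counts come from largest-remainder apportionment of
  fraction × total, which conserves period totals exactly and keeps every
  count within one cyst of its exact quota. (Rounding each count and
  letting the largest species absorb the residual can push the dominant
  species several cysts off its quota; the quota rule is the property the
  fixture needs.)
* One integer seed feeds a splittable generator (`numpy` `SeedSequence`);
  each (species, period) cell gets its own substream in sorted key order,
  so output is identical under record reordering and fully reproducible.

Because the minor-species weights are a convention, exact reproduction of
the published community means (31.80/36.24 μm) and Δ_inter = 1.22 μm is
*not* claimed. Under the fixture the expected community means are ≈34.2
(warm) and ≈37.7 μm (cold), Δ_total ≈ 3.6 μm and the expected
intraspecific fraction ≈ 0.8 — the same qualitative structure
(intraspecific change dominant, community test significant, the two
Spiniferites flat). Passing tests therefore demonstrate correctness of the
estimators and the direction/shape of the published result, not the exact
published community-level numbers. What the generator does not emulate:
any temperature-driven generative mechanism (no per-°C size scaling),
within-period depth/sample structure, measurement error and the lab
convention for compressed cysts, or taphonomic effects.

## Numerical choices and degenerate inputs

* Published summary tables are treated as exact inputs where the analysis
  is pure arithmetic on them (change percentages, SE cells, the
  partition of the published community means).
* The partition identity is exact in its defining direction
  (Δ_intra := Δ_total − Δ_inter); re-summing the parts reproduces Δ_total
  to float rounding only.
* Histogram bins are aligned to multiples of the bin width (default 2 μm,
  configurable; the published figure's granularity is not stated), value x
  falling in bin ⌊x/width⌋, so halving the width refines the partition
  exactly. Normal-curve ordinates are n·width·φ(center; x̄, s).
* A single-species "community" at the interspecific level has SD = SE = 0;
  all-zero weights, inverted ranges, n < 2 groups and zero-variance test
  pairs raise typed errors rather than returning NaN.
* Monte-Carlo suite sizes (200 seeds for parameter recovery and test
  power, 1000 for generator calibration) keep the full test run at desk
  scale while leaving the binomial noise on the checked proportions well
  inside the asserted margins.

## Known limitations

* Two periods only; the partition does not generalize to k periods in
  this version.
* No bootstrap or analytic confidence interval on the partition
  fractions.
* The package reports the measured-versus-literature discrepancy but does
  not model its causes (e.g. biogeographic size clines within species).
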