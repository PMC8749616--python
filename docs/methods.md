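# Methods

`thermotex` implements a texture-analysis pipeline for detecting
pregnancy in mares from false-color infrared thermograms of the flank.
Because raw study images of this kind are generally unavailable, the
package pairs the analysis with a seeded synthetic-cohort generator
that reproduces the statistical structure the analysis assumes, so that
every stage can be exercised and validated end to end.

## Study design emulated by the generator

The default cohort mirrors a two-group longitudinal imaging design:
14 non-pregnant mares imaged at four sessions, and 26 pregnant mares in
two subgroups of 13 imaged at gestation months {4, 6, 8, 10} and
{5, 7, 9, 11} — 160 frames in total. Each frame is an 8-bit RGB
false-color thermogram with a polygonal flank ROI (bounded on the
cranial side by the vertical through the tuber coxae) and metadata
(mare id, group, subgroup, month, session).

A temperature field (°C) is simulated as

```
T(x) = base + b_mare + drift_session + smooth(x) + hotspot(x; m) + ε(x; m)
```

* `base` = 27 °C — chosen so that, with the default palette, the
  simulated dynamic range stays inside the band where the Red channel
  responds linearly to temperature (see *Palette* below);
* `b_mare ~ N(0, 0.5²)` — a per-mare random intercept standing in for
  biological variation (coat, perfusion); the literature gives no
  inter-animal model, so a Gaussian intercept is the minimal choice;
* `drift_session` — optional per-session ambient offset, default 0
  (acquisition in a closed space minimizes ambient influence);
* `smooth` — Gaussian-filtered white noise (SD 0.2 °C, correlation
  length 6 px): slowly varying surface-temperature structure;
* `hotspot` — an elliptical Gaussian over the flank with amplitude
  0.4·(m−3) °C and scale (8 + 3·(m−3)) px at gestation month m,
  absent for non-pregnant mares: the warming caused by rising uterine
  blood flow and fetal metabolism;
* `ε` — pixel-wise Gaussian noise with SD 0.12·1.35^(m−3) °C
  (0.12 °C for non-pregnant mares): fine-scale texture heterogeneity
  that grows with gestation.

Fields are clipped to the camera range 10–40 °C and rendered through a
five-point piecewise-linear palette (blue → cyan → green → magenta →
red), so low temperatures are blue-annotated, medium-high magenta and
the hottest red, as on consumer thermal cameras. Everything is
reproducible bit-for-bit from the design seed via a spawning
`SeedSequence`.

Two generator choices deserve explanation because the obvious
alternatives fail structurally:

* **Base/amplitude vs palette.** With a hotter baseline or a steeper
  amplitude the hot-spot peak crosses into the palette's magenta→red
  segment, where the Red channel is pinned at 255; the Red plane then
  *loses* texture at late months and entropy-type features turn over
  instead of rising. The defaults keep the simulated range inside the
  red-sensitive band, matching the premise that pregnancy-grade warming
  does not saturate the rendering.
* **Geometric heterogeneity schedule.** Entropy-type features respond
  roughly logarithmically to the fine-noise SD. A linear SD schedule
  therefore yields shrinking late-month increments that drown in the
  13-mare sampling error of each month's subgroup; the geometric
  schedule (growth 1.35/month) makes the increase uniform on the
  feature scale — a steady month-over-month rise, which is precisely
  the behavior the screening cascade is designed to detect.

What the generator does **not** emulate: anatomy (the flank is a flat
field, not a horse), radiometric camera physics, lactation, coat and
weather covariates, and within-mare temporal correlation beyond the
random intercept (exposed as a parameter, not asserted). Passing tests
therefore show that the *pipeline* behaves correctly under the assumed
statistical structure, not that real mares are this easy.

## Color decomposition

Each frame is decomposed into ten grayscale planes: R, G, B (copied),
Y = (299R+587G+114B)/1000, the chrominance axes

```
U = (886B − 587G − 299R + 886Θ) / 1772
V = (−114B − 587G + 701R + 701Θ) / 1402
I = (−3213B − 2744G + 5957R + 5958Θ) / 11916
Q = (3111B − 5226G + 2115R + 5226Θ) / 10452
```

and Hue/Saturation from the centered chroma vector
u = (886B−587G−299R)/886, v = (701R−587G−114B)/701:
H = Θ/(2π)·arg(u+jv) in [0,2π), S = 0.937·√(u²+v²). Θ = 255 is the
unique offset mapping every transform's range exactly onto [0, 255]
(e.g. max U = (886+886)·255/1772 = 255). Brightness is shared across
YUV/YIQ/HSB, giving 10 rather than 12 planes.

Two widely reprinted sign typos are corrected by default: the Q
transform's B-weight must be +3111 (otherwise the chroma weights do not
cancel on the gray axis and the NTSC magenta–green axis is broken), and
the v-term's R-weight must be +701 (consistent with the V numerator;
with it, 0.937·max-chroma = 255.06, i.e. 0.937 is exactly the
magenta-corner normalizer). `ColorTransformConfig(corrected_signs=False)`
reproduces the literal printed formulas for comparison. Outputs are
rounded half away from zero (configurable to floor) and clipped.

## Texture features

All features are computed inside the ROI; the pixel count N·M in the
histogram formulas is the ROI pixel count, and co-occurrence pairs
require **both** endpoints inside the mask.

*Histogram Statistics* (13): Mean, Variance, Skewness
(m₃·Var^(−3/2)), excess Kurtosis (m₄·Var^(−2) − 3), discrete
percentiles PercQQ = min{K : Σ_{k≤K} H(k) ≥ QQ/100} for
QQ ∈ {1, 10, 50, 90, 99}, and windowed dominants: Domn_r is the start
of the r-level window with maximal probability mass and Maxm_r that
mass, for r ∈ {1, 10}. Ties break to the smallest gray level (window
masses are compared as exact integer counts). Skewness/Kurtosis are 0
for a degenerate histogram; a window wider than the histogram covers
all of it.

*Haralick features* (11) on the normalized co-occurrence matrix
p(k, l) at displacement (0, 1) (horizontal, d = 1 — the study default;
other offsets are configuration): AngScMom, Contrast, Correlat,
SumOfSqs, InvDefMom, SumAverg, SumVarnc, SumEntrp, Entropy, DifVarnc,
DifEntrp, with marginal moments μ, σ of the row/column marginals and
the sum/difference distributions p_{k+l} and p_{|k−l|}. The symmetric
variant (GLCM) counts each pair in both directions; the asymmetric
variant (GLCH) counts the forward direction only.

Numerical conventions: gray levels are 0-based (k, l ∈ 0..K−1, sums in
0..2K−2); the difference family uses |k−l| (identical to the signed
difference on symmetric matrices); logarithms are natural with
0·log 0 ≡ 0; Correlat ≡ 0 when a marginal SD vanishes; σ denotes the
standard deviation of the marginal (with the variance in its place,
Correlat leaves [−1, 1] already on a two-cell matrix). K = 256 by
default; coarser quantization is available but never silently applied.

## Screening cascade

Per combination (component × approach × feature), with α = 0.05:

1. **Homogeneity** — the non-pregnant sessions are compared by an
   omnibus test: one-way ANOVA when every series passes Shapiro–Wilk
   at α, Kruskal–Wallis otherwise. Combinations where the omnibus
   rejects are discarded; survivors get a pooled mean ± SD over all
   non-pregnant values (SD may be 0 for degenerate data — flagged, not
   an error).
2. **Separation** — pooled non-pregnant values vs the eight pregnant
   month series in one omnibus test, followed by post-hoc
   control-vs-month contrasts: Tukey HSD (all pairs, scipy) for the
   parametric branch, Dunn's rank test for the non-parametric branch
   (z statistics on joint mean ranks with tie correction, Bonferroni
   over the eight control contrasts; implemented in-package). A
   combination survives when the contrast is significant from some
   month *m* through month 11; that earliest *m* is recorded. A
   `pairwise` mode (per-month Welch t / Mann–Whitney, unadjusted) is
   available; it is the mode whose per-contrast level is nominally
   exact and is therefore used for null-calibration checks.
   After this stage the GLCH branch is dropped; whether its selections
   duplicated GLCM is recorded (they do, up to degenerate cases, since
   the two matrices share all symmetric functionals).
3. **Trend** — "gradually increasing/decreasing" is formalized as a
   perfect Spearman rank correlation (±1) between per-month means and
   month with non-zero total change, i.e. strict monotonicity across
   the eight scheduled months. The rule is deliberately strict; a
   non-strict variant would admit plateaus and is easy to substitute.

No multiplicity correction is applied across the 350 combinations (by
design — the cascade screens, it does not test a single hypothesis),
and mares contributing several sessions are treated as independent
observations per month. Because the non-pregnant sessions repeat the
same animals, between-session variance is deflated relative to a fully
independent design and criterion 1 rejects *less* often than α on
image cohorts; on independent series its size is α (verified by
simulation).

## Detection accuracy

For each stage-3 survivor, thresholds t_k = mean ∓ k·SD (k = 0, 1, 2)
are derived from the criterion-1 pooled statistics, with the sign
chosen so that increasing k always *relaxes* the positivity rule
(mean − k·SD for increasing indicators, mean + k·SD for decreasing
ones). This makes sensitivity non-decreasing and specificity
non-increasing in k — the defining trade-off of the threshold family —
whereas the naive reading (mean + k·SD for increasing features) would
invert it. A mare is annotated pregnant when her value passes the
threshold strictly; ties count as non-pregnant.

Positives for month m are the pregnant mares imaged that month;
negatives are the non-pregnant mares at the concurrent session
(months (4,5) ↔ session 1, …, (10,11) ↔ session 4). Se, Sp, PPV, NPV
are reported rounded half away from zero to two decimals, with
0/0 ≡ 1.00 (the convention forced by a perfect-sensitivity,
zero-specificity classifier, whose NPV has no discordant calls).
Predictive values across assumed prevalences 0.1..1.0 follow Bayes'
rule, with the same 0/0 convention. A helper inverts 2-decimal rates
back to integer counts (unique for the denominators 14 and 13 used
here), enabling exact consistency checks of published-style tables.

## Problem sizes and tolerances

Default frames are 120×160 px (ROI ≈ 5100 px) — large enough for
stable 256-level co-occurrence statistics, small enough that the full
160-frame pipeline (350 combinations) runs in about 1.5 minutes on one
core. Oracle tests compare against naive loop implementations at
1e−9 absolute; stochastic tests fix seeds and assert inside 99–99.9%
binomial bands around exact rates. Parameter-recovery checks run 20
seeded cohorts restricted to the Red and I components (the criteria
are per-combination, so restricting extraction changes nothing) and
require each entropy-family indicator to pass all three criteria with
an increasing trend in ≥ 80% of seeds; the observed failure mode is
the designed α-level criterion-1 rejection, not a missed effect.

## Known limitations

* The generator's effect model is radially symmetric and additive;
  real pregnancy thermograms show structured, posture-dependent
  patterns.
* Specificity at relaxed thresholds (mean − 2SD) is intrinsically low
  when negatives are drawn from the same distribution that defines the
  threshold; published tables with Sp = 1.00 at every threshold imply
  month-specific negative samples sitting well below the pooled mean,
  a situation the synthetic cohort does not reproduce.
* Criterion 3's strict monotonicity is sensitive to sampling noise
  when adjacent-month increments are small relative to the subgroup
  standard error; the default effect sizes are chosen so the headline
  indicators clear this bar, weaker effects will not.
* Only the horizontal d = 1 co-occurrence displacement is exercised by
  default; other directions/distances are supported as configuration
  but not studied.
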