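# Methods

## Scope and data model

The package analyses a storage-stability experiment for small-molecule
metabolites in CSF measured by direct-infusion high-resolution MS. The
unit of observation is an m/z peak list per infusion (sample × technical
replicate); everything upstream — raw spectra, peak picking, isotope
envelopes, chromatography — is out of scope, as is the biological
interpretation of individual metabolites. The experimental layout is P
pools, each contributing one reference aliquot (frozen at −80 °C at time
zero, having undergone one freeze/thaw cycle) and one aliquot per storage
condition, each infused R times. Four condition series are modelled:
freeze/thaw cycles, −20 °C storage (months), 5–8 °C storage (hours) and
18–22 °C storage (hours).

## Annotation

Five singly-charged adduct channels are considered per neutral mass:
shifts +1.007276 ([M+H]⁺), −1.007276 ([M−H]⁻), +22.989222 ([M+Na]⁺),
+38.963158 ([M+K]⁺) and +34.969401 ([M+Cl]⁻) Da. The shifts include the
electron mass and are stored as data (editable). Matching uses a relative
tolerance, default 2 ppm, with an **inclusive** boundary: a window needs a
fixed convention to be testable, and ≤ keeps the exact theoretical value
matched at tolerance zero. Peaks outside the 70–600 m/z scan window are
dropped at ingestion with a logged count. A peak may match several
metabolites (isomers and near-collisions are real); all matches are kept
and contribute to every matching annotation. Positive- and negative-mode
peaks live in one table and both polarities contribute to the same
metabolite sum. Technical replicates are aggregated by the arithmetic mean
(median available by config) after channel summation; a replicate in which
nothing matched contributes a measured zero, not a missing value.

## Technical variability (sILC QC)

Spike-in compounds are added at fixed concentration during sample
preparation, so their variation is analysis variability by construction.
Two summaries:

* **CV** per sILC over all included samples: sample standard deviation
  (n−1 denominator — the conventional estimator; the choice is not
  material at n = 65) divided by the mean.
* **MAV** per sILC and series: per pool FC = I(extreme)/I(reference),
  then median over pools of |FC − 1|. Pools with a non-positive or missing
  reference are excluded with a warning; with no usable pool the value is
  NaN and flagged.

Summary rows (5th percentile, median, 95th percentile) use linear
interpolation of order statistics by default. The extreme percentiles are
method-sensitive at n = 17 — different quantile conventions give visibly
different 5th/95th values — so only the median (method-independent at odd
n) is treated as a reproducible summary. The analysis-variability band for
a series is 1 ± (median MAV across sILCs), so band_low + band_high = 2
exactly.

## Stability classification

Per metabolite × condition, per-pool fold changes are formed from
triplicate-averaged intensities; pools are the replication unit. The 95 %
interval across pools defaults to the t-based interval on the **mean** FC
(half-width t₀.₉₇₅,ₙ₋₁ · sd/√n). A min–max (range) interval is available
by config: with n = 3 the printed data of such studies cannot distinguish
a parametric interval from a range, and the choice affects only how many
borderline metabolites are flagged, not the machinery. Calls use strict
inequalities at the band edges (a CI limit exactly on the band is
*unaffected*). Metabolites with a non-positive reference in a pool lose
that pool's FC; with fewer than two usable pools the record is *undefined*
and excluded from affected counts (tallied separately). No multiple-testing
correction is applied to the FC classification; the band plays that role.

Counting is done at the most extreme level of each series, for the full
metabolite set and for the neurometabolic panel subset.

## Statistics battery

* **PCA** on samples, mean-centering only — intensities are deliberately
  not normalised or scaled in this assay; unit-variance scaling is a
  config option. Implemented via full-rank SVD (scikit-learn).
* **RM-ANOVA**: one-way within-subjects with pools as subjects, the
  reference entering as baseline level; F = MS_cond/MS_cond×subj with
  df (k−1), (k−1)(n−1). No sphericity correction is applied. Implemented
  as a vectorized sums-of-squares decomposition so thousands of features
  are tested at once; correctness is pinned against a from-scratch oracle,
  the paired-t² identity at two levels, and pingouin. Degenerate features
  (zero error term) yield F = 0/p = 1 when flat, F = ∞/p = 0 otherwise,
  and are flagged.
* **Kruskal–Wallis** (scipy; mid-rank tie correction, χ²₁ reference)
  compares pool-level values of the extreme condition to the reference
  (3 vs 3 by default). With three pools per group the permutation
  distribution has 20 atoms, the smallest attainable p is ≈ 0.0495, and a
  Bonferroni correction at family sizes in the hundreds can therefore
  never reject — the test is reported for completeness and the χ² p is
  verified to lie between the strict and non-strict exhaustive permutation
  tails on tie-free instances. Fully tied data give H = 0.
* **Bonferroni**: p → min(1, m·p) with the family size m equal to the
  number of features in the analysis scope (full set or panel); m may
  exceed the number of p-values passed when adjusting a subset.

Missing cells (excluded infusions) are handled per series: pools with
incomplete grids are dropped; if that would leave fewer than two pools,
the incomplete levels are dropped instead so all pools are retained. The
Kruskal–Wallis comparison independently uses every pool with both the
extreme and the reference measured.

## Synthetic-data generator

The generator emulates the study's data-generating situation, not its
instrument physics. Per metabolite a baseline intensity is drawn
log-uniformly (10⁵–10⁷ a.u. by default), split across the five adduct
channels in fixed proportions, scaled by a per-pool factor (biological
pool-composition differences; sILCs ignore it since they are spiked at
fixed concentration), multiplied by the true storage drift (a fold change
as a function of series and level; identically 1 for references and
sILCs, enforced), and jittered by lognormal technical noise exp(ε),
ε ~ N(0, σ²), drawn once per metabolite × infusion and shared across the
five adduct peaks. The summed intensity is then exactly lognormal with
CV = √(exp σ² − 1), which the tests exploit as a closed form. Optional
per-peak dropout and m/z jitter are available and off by default. Library
masses are drawn with pairwise separation > 4 ppm (twice the matching
tolerance) so synthetic matching is unambiguous unless collisions are
requested.

The default condition grid — freeze/thaw cycles 1–7; −20 °C at 1, 2, 3, 4
months; 5–8 °C at 8, 24, 48, 72, 168 h; 18–22 °C at 2, 8, 24, 48, 72,
168 h (22 conditions) — is a reconstruction consistent with every level
the assay's design mentions; the true grid is configurable because it is
not uniquely determined. Exclusions (hampered infusions) are modelled by
flagging design rows; excluded rows are generated but never contribute
downstream, which the tests verify by poisoning them.

What the generator does **not** model: isotope envelopes, in-source
fragments and multimers, injection-order drift and batch effects,
intensity-dependent noise, detector saturation, missing-not-at-random
dropout, and correlations between metabolites. Passing recovery tests on
this generator therefore shows the statistical machinery behaves as
specified under the stated noise model — not that real CSF data are this
clean.

The bundled fixture library (`synthetic_reference_library`) carries the
real neurometabolic-panel and sILC annotation names but deterministic
**synthetic** masses; it exists so end-to-end runs have realistic shape,
not for annotating real spectra. The panel's printed group lists contain
108 entries (glutamic acid appears under two groups); the fixture dedupes
to unique names.

## Analysis-scale choices

The emulated study in `analysis/` uses 204 library entries (107 panel +
17 sILC + 80 unnamed), the full 22-condition grid, triplicates, four
excluded infusions and per-infusion noise σ = 0.285, calibrated so the
sample-level sILC CV after triplicate averaging is ≈ 0.166 — the scale of
the published run this design emulates. The property-level checks use
500 metabolites × 20 seeds for classifier recovery (true FC 2.0/0.5 on
10 % of metabolites, σ = 0.07) and 150 metabolites × 50 seeds for the
global-null battery; these sizes give stable rates while keeping a full
run in the tens of seconds on one core.

## Known limitations

* With n = 3 pools the t-interval is wide and the classifier's power for
  subtle drifts (|FC − 1| comparable to the band) is limited; when an
  extreme condition loses a pool to exclusion (n = 2, t₀.₉₇₅,₁ ≈ 12.7)
  even large drifts can escape — visible in the emulated study, where a
  five-fold drifter at an exclusion-hit condition is caught by RM-ANOVA
  but not by the FC call. This mirrors the power caveat of the underlying
  design rather than a defect of the implementation.
* A few percent of null metabolites are flagged by chance (the n = 3
  sample SD can be small); the classifier bounds, not eliminates, this.
* The 5th/95th QC percentiles depend on the quantile convention and
  should not be compared across implementations.
* Annotation is by mass alone (annotation certainty level 2): isomers are
  indistinguishable and share summed intensities.
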