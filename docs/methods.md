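# Methods

This note documents the models, defaults and numerical choices behind
`notchbench`, what the synthetic benchmark does and does not emulate, and the
limitations a user should keep in mind when extrapolating from passing tests
to real data.

## The notch model

The artifact is modelled as a piecewise-linear, discontinuous, monotone map on
log2 reporter intensity. With band boundaries `l < u` (defaults 4.25 and
5.75 log2 units, the conventional visual boundaries) and slope `s > 0`:

- `x ≥ u` → `x` (unchanged);
- `x < u` → `l − s·(u − x)`.

The open interval `(l, u)` is empty of outputs, reproducing the depleted band
in intensity histograms, and every affected value is *underestimated*, never
missing. The default slope is **1.5**. A slope of exactly 1 would shift
everything below the band by the constant `u − l`, and constant shifts cancel
in within-PSM intensity *differences*; the empirical signature of the
artifact, however, includes inflated tag-vs-comparator differences at low
intensity, which requires the underestimation to grow as intensity decreases
— hence a slope above 1. This is one admissible functional form: the true
transfer curve of the affected signal processing is not publicly
characterised, and only its two qualitative properties (empty band,
monotonically worsening underestimation) are relied on by the analyses.

## The synthetic spike-in benchmark

The generator emulates a two-species spike-in: yeast peptide mass per channel
is 5 ug in the 1x group (channels 126–128N), 10 ug in 2x (128C–129C) and
30 ug in 6x (130N–131); human peptide fills every channel to 100 ug. Ground
truth fold changes follow exactly from these masses: yeast 2 and 6; human
90/95 and 70/95 (range 1.06- to 6-fold over all pairwise contrasts).

Observed intensities per PSM are

```
obs[c] = 2^(b + m) · [ (1 − i)·f[c] + i ] · 2^eps[c]
```

- `b ~ N(10, 1.5²)` log2 protein base abundance (places the low tail of the
  intensity distribution across the notch band: ~2–4% of values fall below
  the upper boundary, matching a "typical" artifact prominence);
- `m ~ N(0, 1.5²)` per-PSM ionization scale;
- `f` the species' per-channel mass fraction, normalized to mean 1 — this is
  what carries the ground-truth fold change;
- `i ~ Beta(0.5, 12)` per-PSM co-isolation interference (median ≈ 2%, mean
  ≈ 4%), skewed toward zero as expected for SPS-MS3 acquisition. The
  interference background is **channel-flat** because every channel holds the
  same total peptide mass; mixing `(1 − i)·f + i` therefore compresses
  observed ratios toward 1, the classic isobaric ratio compression;
- `eps ~ N(0, 0.4²)` multiplicative log2 reporter noise.

PSM counts per protein are shifted negative-binomial (mean 6, dispersion 0.5,
minimum 1), spread over peptide sequences at ~2 PSMs per peptide so that the
redundant-PSM prediction analysis has groups to work with. After the optional
notch distortion, cells below a detection floor (log2 4.0) drop out with
probability 0.3. Quality metrics are emitted consistently with the generated
values: co-isolation % is `100·i`; average reporter S/N is the mean
non-missing intensity divided by a fixed noise constant (16), so an S/N ≥ 10
filter removes roughly the lowest tenth of PSMs; Delta CN is drawn from
Beta(2, 2) independently of the intensities.

Default problem size is 300 yeast + 900 human proteins (~7,000–7,500 PSMs) —
the ~1:3.4 species ratio of a realistic mixed proteome at a size chosen for
desk-scale, seconds-long runs. All randomness flows from one seed through
named per-stage streams (`numpy` `SeedSequence.spawn`), so identical
parameters give bit-identical tables and any stage is individually
reproducible.

**What is not emulated:** chromatography and fractionation, label isotopic
impurity, charge states, spectrum mis-identification (Delta CN is independent
of intensity), shared peptides between species, and — importantly —
heterogeneous within-PSM channel profiles beyond the spike-in design itself
(see Limitations).

## Processing pipeline

- **Exclusions.** Species annotation uses the full matched-accession list:
  contaminant accessions dominate, then cross-species ambiguity, then
  unmapped/missing master proteins; ambiguous, contaminant and unknown PSMs
  are excluded before quantitative analysis.
- **Normalization.** Log center-median: per-channel log2 medians are shifted
  to the grand median of the original channel medians (preserving overall
  scale), then exponentiated back. Missing cells are untouched; a channel
  with no finite value is an error.
- **Filtering.** Keep rules are `delta_cn > t₁`, `coisolation < t₂`,
  `avg_sn ≥ t₃` (so 0 is the pass-all S/N level) and, optionally, no
  non-missing intensity below the notch's upper boundary. The grid crosses
  t₁ ∈ {0, 0.2, 0.5}, t₂ ∈ {100, 50, 10}%, t₃ ∈ {0, 10} and notch
  keep/remove → 36 schemas. Removals are attributed to the first failing
  metric in that order (reporting only; the kept set is order-independent).
- **Aggregation.** PSMs with any missing channel are dropped, multi-master
  PSMs are excluded at protein level (avoids double counting), features need
  ≥ 2 member PSMs, and channels are summed. Peptide-level features use the
  plain sequence string as key (modified forms are not distinguished).
- **Differential testing.** Per feature, group means and the residual
  variance `s²` (df `d = n_channels − n_groups`) feed an empirical-Bayes
  moderation: `e = log s² − ψ(d/2) + log(d/2)` is regressed on mean log2
  intensity by lowess (span 0.4, one robustifying pass); the prior df `d₀`
  solves `ψ′(d₀/2) = var(e − trend) − ψ′(d/2)` via Newton iteration on the
  trigamma function (tolerance 1e−8, ≤ 50 iterations; non-positive moment →
  `d₀ = ∞`, i.e. complete shrinkage to the trend); the posterior variance is
  `s̃² = (d₀s₀² + d·s²)/(d₀ + d)` and moderated t uses `d₀ + d` df (normal
  tail when infinite). Features with exactly zero residual variance take
  their prior variance from the trend interpolated at their mean intensity.
  With `d₀ = 0` the procedure reduces exactly to the ordinary pooled-variance
  t-test, which the tests verify against an independent implementation.
  Benjamini–Hochberg q-values are computed within each contrast (and within
  each filtering schema in grid runs).
- **Scoring.** Significance is strict (`q < threshold`, default 1%). Expected
  directions derive from the mixing design, never hard-coded. F1 treats
  every feature as truly changed (no true negatives) — valid for this design,
  meaningless for designs containing 1:1 groups.

## Notch diagnostics

- `notch_stats`: per-channel and overall fractions of non-missing intensities
  below the upper boundary and inside the band.
- `detect_notch`: histogram at 0.1 log2 bins; a band is the widest contiguous
  run of bins, ≥ 0.5 log2 wide, whose maximal count is below θ = 0.25 of the
  mean count in the 1.0-log2 windows flanking the run; flanks must each hold
  ≥ 5% of the tallest bin's count so sparse distribution tails cannot fire a
  detection. Recovers injected boundaries to within ±0.25 log2 in ≥ 90% of
  seeded replicates.
- `predict_expected`: PSMs sharing a sequence form a group; the
  highest-total-intensity PSM (ties: first in input order) is the predictor,
  groups of one or with an incomplete top PSM are dropped; each other PSM's
  adjustment factor is the ratio of its summed observed intensities to the
  top PSM's sum over the same channels, and predictions are that factor times
  the top profile. (An alternative convention — normalizing the top profile
  to total 1 and multiplying by relative adjustment factors — yields values
  off the intensity scale; the intensity-scale form is used because it makes
  observed equal predicted exactly for proportional PSMs, i.e. points on the
  equality line of an observed-vs-predicted plot.)
  "Observed below prediction" uses strict inequality; ties count as
  not-below.
- `tag_vs_comparator`: log2 single-tag intensity minus the mean log2 of a
  disjoint comparator channel set, with binned medians by observed target
  intensity.

## Known biases and limitations

- **Median equalization is biased under asymmetric spike-ins.** Channel
  medians are dominated by the majority species but shifted by the spike, so
  forcing them equal compresses the recovered fold changes (~−0.27 log2 on
  the 6x/1x contrast at these conditions) even though per-channel *totals*
  are identical by design. This is a property of the normalization, not a
  bug: real analyses that center-median normalize such designs inherit the
  same bias. The parameter-recovery check therefore runs the pipeline without
  the normalization step (which has no loading imbalance to correct in
  simulation); with it, the recovered yeast 6x/1x median log2FC is
  ~2.51 vs truth 2.585, the residual gap being co-isolation compression.
- **Adjustment factors are themselves notch-biased for flat profiles.** When
  a PSM's channels are all similar (the human background here), crossing the
  notch deflates most of its channels at once, dragging its sum-ratio
  adjustment factor down; predictions of its clean channels then land in
  sub-notch bins and read "observed above prediction". Under this design the
  pooled fraction of sub-notch observations below prediction plateaus around
  0.6–0.65 (yeast-only, whose within-PSM spread is 2.6 log2: ~0.8) rather
  than approaching 1 as it does on data with strongly heterogeneous
  within-PSM profiles. The direction is robust — well above the 0.5
  no-artifact baseline — but the magnitude is design-dependent.
- The interference model has no dependence on precursor purity, retention
  time or m/z; Delta CN carries no information; and the notch transfer
  function is an idealisation (see above).
- The F1 definition assumes all features truly change; with a 1:1 comparison
  group it would count every detection as an error or a miss.
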