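# notchbench

Simulation and benchmarking of the Orbitrap reporter-ion **notch** artifact in
isobaric (TMT) quantitative proteomics.

## The problem

Reporter-ion intensities acquired on Orbitrap Fusion/Lumos/Eclipse instruments
with older acquisition software show a characteristic depleted band — a
"notch" — in their intensity distribution (approximate log2 boundaries 4.25
and 5.75). Intensities that should fall inside the band are not missing; they
are recorded *below* it, i.e. systematically underestimated. Many published
multiplexed datasets were acquired with affected software, so the practical
question for anyone reanalysing them is: does the notch corrupt
differential-abundance results, and does removing notch-affected spectra
(PSMs) help?

`notchbench` answers this with a controlled two-species spike-in benchmark:

- **Design.** Yeast peptides are spiked into human peptides at 1x / 2x / 6x
  amounts (5, 10, 30 ug per channel; every channel filled to 100 ug with
  human peptide) across a TMT 10-plex. Every protein therefore has a known
  fold change between channel groups: yeast 2 and 6; human 90/95 ≈ 0.947 and
  70/95 ≈ 0.737 — i.e. ground-truth fold changes between 1.06 and 6.
- **Simulation.** PSM tables are generated with log-normal protein
  abundances, per-PSM ionization scales, co-isolation interference (which
  compresses ratios toward 1 because the per-channel background is flat by
  design), multiplicative reporter noise, missing values below a detection
  floor, and an injectable notch distortion: log2 intensities below the upper
  boundary `u` are remapped to `l − s·(u − x)` (lower boundary `l`, slope
  `s > 1`), which empties the band and makes underestimation grow as
  intensity decreases.
- **Analysis.** The pipeline reproduces standard PSM-level processing:
  species annotation and contaminant/ambiguity exclusions, log center-median
  normalization, four-metric PSM filtering (Delta CN, co-isolation %, average
  reporter S/N, notch removal — 36 schema combinations), summation to
  peptide/protein features (complete PSMs only, at least two per feature),
  and empirical-Bayes moderated t-testing with an intensity-dependent
  variance trend (prior df by trigamma moment matching, posterior variance
  `s̃² = (d₀s₀² + d·s²)/(d₀ + d)`), with Benjamini–Hochberg FDR control.
- **Evaluation.** Against the known ground truth, significant changes in the
  expected direction are true positives, opposite-direction ones false
  positives, non-significant features false negatives (there are no true
  negatives: everything changes). F1 is the harmonic mean of precision and
  recall, and fold-change error is measured per species.

## Worked example

```python
import numpy as np
from notchbench import (
    FilterSchema, NotchRegion, SimParams, aggregate, apply_filters,
    build_mix_design, center_median_normalize, classify_and_score,
    fit_moderated_test, notch_stats, simulate_experiment,
)

design = build_mix_design()                       # yeast 5/10/30 ug, total 100 ug
table, truth = simulate_experiment(design, SimParams(seed=1))
table = center_median_normalize(table)

notch = NotchRegion()                             # log2 boundaries 4.25 / 5.75
stats = notch_stats(table, notch)
print(f"fraction of intensities below the notch upper boundary: "
      f"{stats.loc['overall', 'frac_below_upper']:.3%}")

filtered, report = apply_filters(table, FilterSchema(0.5, 10.0, 10.0, False), notch)
print(f"strict filtering kept {report.output_count} of {report.input_count} PSMs")

matrix = aggregate(filtered, "protein")
fit = fit_moderated_test(matrix.log2_values(), table.channels.group_of(),
                         ["2x_vs_1x", "6x_vs_1x"])
for contrast in ("2x_vs_1x", "6x_vs_1x"):
    s = classify_and_score(fit.for_contrast(contrast), truth)
    print(f"{contrast}: {s.n_features} proteins, F1={s.f1:.3f}, "
          f"median yeast log2FC={s.median_log2fc['yeast']:.3f} "
          f"(truth {truth.expected_log2fc(contrast, 'yeast'):.3f})")
```

prints

```
fraction of intensities below the notch upper boundary: 2.533%
strict filtering kept 2939 of 7405 PSMs
2x_vs_1x: 707 proteins, F1=0.298, median yeast log2FC=0.816 (truth 1.000)
6x_vs_1x: 707 proteins, F1=0.869, median yeast log2FC=2.258 (truth 2.585)
```

Read: ~2.5% of simulated reporter intensities sit below the notch's upper
boundary; the strict quality filter keeps ~40% of PSMs; the subtle 2x-vs-1x
contrast is hard to detect (low F1 driven by the human 1.06-fold change going
unseen), while the 6x contrast is easy; and the recovered yeast fold changes
are compressed below truth by co-isolation interference plus the
median-equalizing normalization, as expected for real TMT data
(see `docs/methods.md`).

The command line mirrors the library:

```bash
notchbench all --seed 1 --out-dir run/        # simulate -> normalize -> 36-schema grid
notchbench simulate --out-dir sim/
notchbench filter --in sim/psms.tsv --out filtered.tsv --min-delta-cn 0.5 \
    --max-coisolation 10 --min-avg-sn 10
notchbench notch-stats --in sim/psms.tsv --out stats.tsv --detect
```

All outputs are TSV with header rows plus a JSON run manifest.

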