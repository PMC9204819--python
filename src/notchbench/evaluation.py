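"""Ground-truth benchmarking: TP/FP/FN scoring, F1, and the notch-filtering comparison.

Every feature in the spike-in design truly changes between groups, so there
are no true negatives: a significant change in the species' expected
direction is a true positive, a significant change in the opposite direction
a false positive, and a non-significant feature a false negative. F1 is the
harmonic mean of precision TP/(TP+FP) and recall TP/(TP+FN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aggregate import aggregate
from .differential import fit_moderated_test
from .exceptions import IntegrityError, ParameterError
from .filtering import apply_filters, schema_grid
from .notch import NotchRegion
from .psm_table import PSMTable
from .synthetic import DEFAULT_CONTRASTS, GroundTruth

#: Schemas leaving fewer features than this are flagged, not errored.
MIN_FEATURES = 10


@dataclass
class EvalSummary:
    """Detection and fold-change accuracy for one (schema, contrast) pair."""

    schema: str
    contrast: str
    level: str
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    n_features: int
    median_log2fc: dict[str, float] = field(default_factory=dict)
    median_abs_error: dict[str, float] = field(default_factory=dict)
    low_features: bool = False

    def to_row(self) -> dict[str, object]:
        row: dict[str, object] = {
            "schema": self.schema,
            "contrast": self.contrast,
            "level": self.level,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "n_features": self.n_features,
            "low_features": self.low_features,
        }
        for sp in sorted(set(self.median_log2fc) | set(self.median_abs_error)):
            row[f"median_log2fc_{sp}"] = self.median_log2fc.get(sp, np.nan)
            row[f"median_abs_error_{sp}"] = self.median_abs_error.get(sp, np.nan)
        return row


def _f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if (precision and recall) else 0.0
    return precision, recall, f1


def classify_and_score(
    results: pd.DataFrame,
    truth: GroundTruth,
    fdr_threshold: float = 0.01,
    schema: str = "",
    level: str = "protein",
) -> EvalSummary:
    """Score one contrast's results against the ground truth.

    ``results`` needs columns ``feature_id``, ``contrast``, ``log2fc``,
    ``q``. Significance is strict: features with q exactly at the threshold
    are not significant. The expected direction per feature is the sign of
    the ground-truth log2 fold change of its species for this contrast.
    """
    if results.empty:
        raise ParameterError("results frame is empty")
    contrasts = results["contrast"].unique()
    if len(contrasts) != 1:
        raise ParameterError("classify_and_score expects results for exactly one contrast")
    contrast = str(contrasts[0])

    species_map = truth.species_of(level)
    ids = results["feature_id"].astype(str)
    unknown = [f for f in ids if f not in species_map]
    if unknown:
        raise IntegrityError(f"features without ground-truth species: {unknown[:5]}")
    species = ids.map(species_map).to_numpy()

    expected = np.array([truth.expected_log2fc(contrast, sp) for sp in species])
    direction = np.sign(expected)
    log2fc = results["log2fc"].to_numpy(dtype=float)
    significant = results["q"].to_numpy(dtype=float) < fdr_threshold

    correct = np.sign(log2fc) == direction
    tp = int((significant & correct).sum())
    fp = int((significant & ~correct).sum())
    fn = int((~significant).sum())
    precision, recall, f1 = _f1(tp, fp, fn)

    med_fc: dict[str, float] = {}
    med_err: dict[str, float] = {}
    for sp in np.unique(species):
        sel = species == sp
        med_fc[str(sp)] = float(np.median(log2fc[sel]))
        med_err[str(sp)] = float(np.median(np.abs(log2fc[sel] - expected[sel])))

    return EvalSummary(
        schema=schema,
        contrast=contrast,
        level=level,
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f1=f1,
        n_features=len(results),
        median_log2fc=med_fc,
        median_abs_error=med_err,
        low_features=len(results) < MIN_FEATURES,
    )


def run_grid(
    table: PSMTable,
    notch: NotchRegion,
    truth: GroundTruth,
    level: str = "protein",
    fdr_threshold: float = 0.01,
    contrasts: tuple[str, ...] = DEFAULT_CONTRASTS,
    return_results: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Filter -> aggregate -> test -> score for every schema in the grid.

    ``table`` should already be normalized and species-annotated. Returns one
    row per (schema, contrast); with ``return_results`` also a mapping from
    schema name to the full per-feature test results.
    """
    groups = table.channels.group_of()
    rows: list[dict[str, object]] = []
    details: dict[str, pd.DataFrame] = {}
    for schema in schema_grid():
        filtered, _ = apply_filters(table, schema, notch)
        matrix = aggregate(filtered, level=level)
        if matrix.n_features < 2:
            for contrast in contrasts:
                rows.append(
                    EvalSummary(
                        schema=schema.name, contrast=contrast, level=level,
                        tp=0, fp=0, fn=0, precision=0.0, recall=0.0, f1=0.0,
                        n_features=matrix.n_features, low_features=True,
                    ).to_row()
                )
            continue
        fit = fit_moderated_test(matrix.log2_values(), groups, contrasts)
        if return_results:
            details[schema.name] = fit.results
        for contrast in contrasts:
            summary = classify_and_score(
                fit.for_contrast(contrast), truth, fdr_threshold, schema=schema.name, level=level
            )
            rows.append(summary.to_row())
    out = pd.DataFrame(rows)
    return (out, details) if return_results else out


def compare_notch_filtering(
    with_filter: pd.DataFrame,
    without_filter: pd.DataFrame,
    truth: GroundTruth,
    affected: set[str] | list[str],
    level: str = "protein",
) -> tuple[pd.DataFrame, list[str]]:
    """Per-feature change in fold-change error when notch filtering is applied.

    For each affected feature (>= 1 member-PSM intensity below the notch
    upper boundary) present in both result sets,

        delta = |log2FC_without - truth| - |log2FC_with - truth|

    so positive values mean notch filtering moved the estimate closer to the
    ground truth. Affected features present only without filtering are
    returned separately as lost to filtering.
    """
    for df in (with_filter, without_filter):
        if len(df["contrast"].unique()) != 1:
            raise ParameterError("expected results for exactly one contrast")
    contrast = str(without_filter["contrast"].iloc[0])
    affected = set(map(str, affected))
    species_map = truth.species_of(level)

    w = with_filter.set_index(with_filter["feature_id"].astype(str))["log2fc"]
    wo = without_filter.set_index(without_filter["feature_id"].astype(str))["log2fc"]
    common = [f for f in wo.index if f in w.index and f in affected]
    lost = [f for f in wo.index if f in affected and f not in w.index]

    rows = []
    for f in common:
        sp = species_map[f]
        exp = truth.expected_log2fc(contrast, sp)
        delta = abs(float(wo[f]) - exp) - abs(float(w[f]) - exp)
        rows.append((f, sp, float(w[f]), float(wo[f]), exp, delta))
    deltas = pd.DataFrame(
        rows,
        columns=["feature_id", "species", "log2fc_with", "log2fc_without", "expected_log2fc", "delta"],
    )
    return deltas, lost
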