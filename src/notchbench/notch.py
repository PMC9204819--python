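"""Notch characterization and redundant-PSM expected-intensity prediction.

The "notch" is a depleted band in the distribution of Orbitrap reporter-ion
intensities produced by older acquisition software; intensities that should
fall inside the band are recorded below it, i.e. systematically
underestimated. This module quantifies the band (per-channel fractions,
automatic boundary detection) and exploits redundant PSMs — several spectra
matched to the same peptide sequence — to predict what each reporter
intensity *should* have been, exposing the underestimation directly.

All boundaries are on the log2 intensity scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import safe_log2
from .exceptions import ParameterError
from .psm_table import PSMTable

#: Approximate boundaries of the depleted band, log2 intensity units.
DEFAULT_LOWER = 4.25
DEFAULT_UPPER = 5.75


@dataclass(frozen=True)
class NotchRegion:
    """Lower/upper log2-intensity boundaries of the depleted band."""

    lower: float = DEFAULT_LOWER
    upper: float = DEFAULT_UPPER

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ParameterError(f"notch lower ({self.lower}) must be < upper ({self.upper})")

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass
class PredictionSet:
    """Observed vs predicted reporter intensities for non-top PSMs.

    ``entries`` has one row per (PSM, channel) with columns ``psm_id``,
    ``sequence``, ``channel``, ``observed``, ``predicted``; ``groups`` has one
    row per retained peptide group with its top PSM id and group size. The
    top (highest-total-intensity) PSM of each group contributes no entries —
    it is the predictor.
    """

    entries: pd.DataFrame
    groups: pd.DataFrame


def notch_stats(table: PSMTable, notch: NotchRegion) -> pd.DataFrame:
    """Per-channel and overall fractions of intensities below/inside the notch.

    Returns a frame indexed by channel label plus a final ``overall`` row,
    with columns ``n`` (non-missing intensities), ``frac_below_upper``
    (log2 value < upper boundary) and ``frac_in_band`` (lower <= log2 < upper).
    Denominators count non-missing values only.
    """
    rows = []
    total_n = total_below = total_band = 0
    for label in table.channels.labels:
        vals = table.data[label].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        log2v = safe_log2(vals)
        n = len(vals)
        below = int((log2v < notch.upper).sum())
        band = int(((log2v >= notch.lower) & (log2v < notch.upper)).sum())
        rows.append((label, n, below / n if n else 0.0, band / n if n else 0.0))
        total_n += n
        total_below += below
        total_band += band
    rows.append((
        "overall",
        total_n,
        total_below / total_n if total_n else 0.0,
        total_band / total_n if total_n else 0.0,
    ))
    return pd.DataFrame(rows, columns=["channel", "n", "frac_below_upper", "frac_in_band"]).set_index("channel")


def detect_notch(
    intensities: np.ndarray,
    bin_width: float = 0.1,
    theta: float = 0.25,
    flank_width: float = 1.0,
    min_width: float = 0.5,
    min_flank_frac: float = 0.05,
) -> NotchRegion | None:
    """Detect a depleted band in a sample of positive intensities.

    Histogram the log2 intensities at ``bin_width``; a candidate band is a
    contiguous run of bins, at least ``min_width`` wide, whose largest count
    is below ``theta`` times the mean count of the ``flank_width``-wide
    windows immediately flanking the run. Flanks must be reasonably populated
    (mean count at least ``min_flank_frac`` of the tallest bin) so that
    sparse distribution tails do not fire spurious detections. The widest
    qualifying run wins; ties go to the lowest-intensity run. Returns ``None``
    when no run qualifies.
    """
    x = np.asarray(intensities, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if x.size == 0:
        raise ParameterError("detect_notch requires at least one positive intensity")
    if x.size < 1000:
        warnings.warn(f"detect_notch on only {x.size} values; boundaries may be unstable",
                      stacklevel=2)
    log2x = np.log2(x)
    lo, hi = log2x.min(), log2x.max()
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    counts, edges = np.histogram(log2x, bins=n_bins, range=(lo, lo + n_bins * bin_width))

    flank_bins = max(1, int(round(flank_width / bin_width)))
    min_bins = max(1, int(round(min_width / bin_width)))
    min_flank = min_flank_frac * counts.max()
    csum = np.concatenate([[0], np.cumsum(counts)])

    def flank_mean(a: int, b: int) -> float | None:
        """Mean count of the windows flanking bins [a, b); None if either side is absent."""
        l0, l1 = max(0, a - flank_bins), a
        r0, r1 = b, min(len(counts), b + flank_bins)
        if l1 - l0 == 0 or r1 - r0 == 0:
            return None
        left = (csum[l1] - csum[l0]) / (l1 - l0)
        right = (csum[r1] - csum[r0]) / (r1 - r0)
        if left < min_flank or right < min_flank:
            return None
        return (left + right) / 2.0

    best: tuple[int, int] | None = None
    for a in range(len(counts)):
        for b in range(a + min_bins, len(counts) + 1):
            width = b - a
            if best is not None and width <= best[1] - best[0]:
                continue
            fm = flank_mean(a, b)
            if fm is None or fm <= 0:
                continue
            if counts[a:b].max() < theta * fm:
                best = (a, b)
    if best is None:
        return None
    return NotchRegion(lower=float(edges[best[0]]), upper=float(edges[best[1]]))


def predict_expected(table: PSMTable) -> PredictionSet:
    """Predict reporter intensities of redundant PSMs from their group's top PSM.

    PSMs sharing a peptide sequence form a group. Groups with a single PSM,
    or whose top PSM (largest total intensity over its non-missing channels)
    has any missing channel, are dropped. For every other PSM *j* with
    non-missing channel set ``C_j``, an adjustment factor
    ``r_j = sum(obs_j[C_j]) / sum(top[C_j])`` scales the top PSM's profile
    onto PSM *j*'s intensity scale: ``predicted_j[c] = r_j * top[c]`` for each
    ``c`` in ``C_j``. Ties in total intensity resolve to the first PSM in
    stable input order.
    """
    labels = list(table.channels.labels)
    inten = table.intensity_matrix()
    totals = np.nansum(inten, axis=1)
    df = table.data

    entry_rows: list[tuple[str, str, str, float, float]] = []
    group_rows: list[tuple[str, str, int]] = []
    for seq, idx in df.groupby("sequence", sort=True).indices.items():
        idx = np.asarray(idx)
        if len(idx) < 2:
            continue
        top_pos = idx[np.argmax(totals[idx])]  # argmax returns first max: stable tie-break
        top = inten[top_pos]
        if np.isnan(top).any():
            continue
        group_rows.append((str(seq), str(df.at[top_pos, "psm_id"]), len(idx)))
        for j in idx:
            if j == top_pos:
                continue
            obs = inten[j]
            mask = ~np.isnan(obs)
            if not mask.any():
                continue
            r = obs[mask].sum() / top[mask].sum()
            psm_id = str(df.at[j, "psm_id"])
            for c in np.flatnonzero(mask):
                entry_rows.append((psm_id, str(seq), labels[c], float(obs[c]), float(r * top[c])))

    entries = pd.DataFrame(entry_rows, columns=["psm_id", "sequence", "channel", "observed", "predicted"])
    groups = pd.DataFrame(group_rows, columns=["sequence", "top_psm_id", "n_psms"])
    return PredictionSet(entries=entries, groups=groups)


def underestimation_fraction(preds: PredictionSet, bin_width: float = 0.5) -> pd.DataFrame:
    """Fraction of observed intensities strictly below prediction, per predicted-intensity bin.

    Entries are binned by log2 predicted intensity on a grid anchored at 0;
    ties (observed == predicted) count as not-below. Empty bins are omitted.
    Columns: ``bin_left``, ``bin_right`` (log2 units), ``n``, ``frac_below``.
    """
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    if preds.entries.empty:
        raise ParameterError("prediction set is empty")
    e = preds.entries
    log2pred = np.log2(e["predicted"].to_numpy(dtype=float))
    below = e["observed"].to_numpy(dtype=float) < e["predicted"].to_numpy(dtype=float)
    k = np.floor(log2pred / bin_width).astype(int)
    out = (
        pd.DataFrame({"k": k, "below": below})
        .groupby("k")
        .agg(n=("below", "size"), frac_below=("below", "mean"))
        .reset_index()
    )
    out["bin_left"] = out.pop("k") * bin_width
    out["bin_right"] = out["bin_left"] + bin_width
    return out[["bin_left", "bin_right", "n", "frac_below"]]


def tag_vs_comparator(
    table: PSMTable,
    target_channels: list[str] | tuple[str, ...],
    comparator_channels: list[str] | tuple[str, ...],
    bin_width: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Difference between single tag intensities and a comparator-group mean.

    For each PSM and each non-missing target channel, computes
    ``log2(target) - mean(log2 comparator)`` over the PSM's non-missing
    comparator channels; PSMs with no non-missing comparator value are
    skipped. Returns the per-entry frame (``psm_id``, ``channel``,
    ``target_log2``, ``diff``) and binned medians of the difference by
    observed target log2 intensity.
    """
    target_channels = list(target_channels)
    comparator_channels = list(comparator_channels)
    if not comparator_channels:
        raise ParameterError("comparator channel set must be non-empty")
    if set(target_channels) & set(comparator_channels):
        raise ParameterError("target and comparator channel sets must be disjoint")

    tgt = table.data[target_channels].to_numpy(dtype=float)
    cmp_ = table.data[comparator_channels].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        log2_tgt = np.log2(tgt)
        log2_cmp = np.log2(cmp_)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN rows -> skipped below
        cmp_mean = np.nanmean(log2_cmp, axis=1)

    rows = []
    ids = table.data["psm_id"].to_numpy()
    for ti, ch in enumerate(target_channels):
        t = log2_tgt[:, ti]
        ok = np.isfinite(t) & np.isfinite(cmp_mean)
        for i in np.flatnonzero(ok):
            rows.append((str(ids[i]), ch, float(t[i]), float(t[i] - cmp_mean[i])))
    entries = pd.DataFrame(rows, columns=["psm_id", "channel", "target_log2", "diff"])

    if entries.empty:
        binned = pd.DataFrame(columns=["bin_left", "bin_right", "n", "median_diff"])
    else:
        k = np.floor(entries["target_log2"].to_numpy() / bin_width).astype(int)
        binned = (
            entries.assign(k=k)
            .groupby("k")
            .agg(n=("diff", "size"), median_diff=("diff", "median"))
            .reset_index()
        )
        binned["bin_left"] = binned.pop("k") * bin_width
        binned["bin_right"] = binned["bin_left"] + bin_width
        binned = binned[["bin_left", "bin_right", "n", "median_diff"]]
    return entries, binned
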