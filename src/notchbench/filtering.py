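"""Four-metric PSM filtering, the 36-schema grid, and center-median normalization.

Filtering thresholds follow the benchmark conventions: Delta CN strictly
greater than its threshold, co-isolation strictly less than its threshold,
average reporter S/N at least its threshold (so 0 is the pass-all level), and
optionally removal of any PSM with a non-missing intensity below the upper
notch boundary. The full grid crosses Delta CN {0, 0.2, 0.5}, co-isolation
{100, 50, 10}%, average S/N {0, 10} and notch handling {keep, remove} into 36
schemas.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from ._utils import safe_log2
from .exceptions import ConfigurationError, NormalizationError, ParameterError
from .notch import NotchRegion
from .psm_table import PSMTable

DELTA_CN_LEVELS = (0.0, 0.2, 0.5)
COISOLATION_LEVELS = (100.0, 50.0, 10.0)
AVG_SN_LEVELS = (0.0, 10.0)

#: First-failing-metric attribution order for the filter report.
METRIC_ORDER = ("delta_cn", "coisolation", "avg_sn", "notch")


@dataclass(frozen=True)
class FilterSchema:
    """One combination of the four PSM filter thresholds."""

    min_delta_cn: float = 0.0
    max_coisolation: float = 100.0
    min_avg_sn: float = 0.0
    remove_notch: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_delta_cn <= 1.0:
            raise ParameterError("min_delta_cn must be in [0, 1]")
        if not 0.0 < self.max_coisolation <= 100.0:
            raise ParameterError("max_coisolation must be in (0, 100]")
        if self.min_avg_sn < 0:
            raise ParameterError("min_avg_sn must be non-negative")

    @property
    def name(self) -> str:
        notch = "remove" if self.remove_notch else "keep"
        return (
            f"dcn{self.min_delta_cn:g}_coiso{self.max_coisolation:g}"
            f"_sn{self.min_avg_sn:g}_notch{notch}"
        )


@dataclass(frozen=True)
class FilterReport:
    """Removal accounting for one filter application (first-failing metric)."""

    input_count: int
    removed_by_metric: dict[str, int]
    output_count: int

    def __post_init__(self) -> None:
        if self.output_count != self.input_count - sum(self.removed_by_metric.values()):
            raise ParameterError("filter report counts do not reconcile")


def apply_filters(
    table: PSMTable,
    schema: FilterSchema,
    notch: NotchRegion | None = None,
) -> tuple[PSMTable, FilterReport]:
    """Apply one filter schema; removals are attributed to the first failing metric.

    Keeps PSMs with ``delta_cn > min_delta_cn``, ``coisolation_pct <
    max_coisolation`` and ``avg_sn >= min_avg_sn``; with ``remove_notch``,
    additionally drops any PSM having a non-missing intensity whose log2
    value is below the upper notch boundary.
    """
    if schema.remove_notch and notch is None:
        raise ConfigurationError("remove_notch requires notch boundaries")

    d = table.data
    fails = {
        "delta_cn": ~(d["delta_cn"].to_numpy(dtype=float) > schema.min_delta_cn),
        "coisolation": ~(d["coisolation_pct"].to_numpy(dtype=float) < schema.max_coisolation),
        "avg_sn": ~(d["avg_sn"].to_numpy(dtype=float) >= schema.min_avg_sn),
    }
    if schema.remove_notch:
        inten = table.intensity_matrix()
        log2i = np.where(np.isnan(inten), np.inf, safe_log2(np.nan_to_num(inten, nan=1.0)))
        fails["notch"] = (log2i < notch.upper).any(axis=1)
    else:
        fails["notch"] = np.zeros(len(d), dtype=bool)

    removed_by: dict[str, int] = {}
    already = np.zeros(len(d), dtype=bool)
    for metric in METRIC_ORDER:
        first_fail = fails[metric] & ~already
        removed_by[metric] = int(first_fail.sum())
        already |= fails[metric]

    kept = table.with_data(d.loc[~already])
    report = FilterReport(
        input_count=len(d), removed_by_metric=removed_by, output_count=len(kept)
    )
    return kept, report


def schema_grid() -> list[FilterSchema]:
    """The 36 filter schemas (3 Delta CN x 3 co-isolation x 2 S/N x 2 notch)."""
    return [
        FilterSchema(dcn, coiso, sn, notch)
        for dcn, coiso, sn, notch in itertools.product(
            DELTA_CN_LEVELS, COISOLATION_LEVELS, AVG_SN_LEVELS, (False, True)
        )
    ]


def center_median_normalize(table: PSMTable) -> PSMTable:
    """Equalize per-channel medians on the log2 scale, preserving overall scale.

    Each channel's log2 intensities are shifted so that every channel median
    equals the grand median of the original channel medians, then
    exponentiated back. Missing values are untouched.
    """
    data = table.data.copy()
    labels = list(table.channels.labels)
    medians = {}
    for label in labels:
        vals = data[label].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals) & (vals > 0)]
        if finite.size == 0:
            raise NormalizationError(f"channel {label} has no finite positive intensities")
        medians[label] = np.median(np.log2(finite))
    grand = float(np.median(list(medians.values())))
    for label in labels:
        data[label] = data[label] * 2.0 ** (grand - medians[label])
    return table.with_data(data)
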