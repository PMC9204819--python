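"""Summation of PSM intensities to peptide- or protein-level feature matrices.

Rules: PSMs with any missing channel are removed first; at the protein level
PSMs mapping to more than one master protein are dropped (avoids double
counting); features retaining fewer than ``min_psms`` PSMs are dropped; the
remaining per-channel intensities are summed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import safe_log2
from .exceptions import IntegrityError, ParameterError
from .notch import NotchRegion
from .psm_table import ChannelSet, PSMTable, split_accessions

logger = logging.getLogger(__name__)

LEVELS = ("protein", "peptide")


@dataclass
class FeatureMatrix:
    """Per-feature summed channel intensities with species and PSM counts.

    ``data`` is indexed by feature id (protein accession or peptide sequence)
    with columns ``species``, ``n_psms`` and one column per channel label.
    No cell is missing and every feature has at least ``min_psms`` member
    PSMs by construction.
    """

    data: pd.DataFrame
    channels: ChannelSet
    level: str

    @property
    def n_features(self) -> int:
        return len(self.data)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    def values(self) -> pd.DataFrame:
        """Intensity block (features x channels)."""
        return self.data[list(self.channels.labels)]

    def log2_values(self) -> pd.DataFrame:
        return np.log2(self.values())


def _members(table: PSMTable, level: str) -> tuple[pd.DataFrame, pd.Series]:
    """Complete member PSMs usable for aggregation and their feature key."""
    if level not in LEVELS:
        raise ParameterError(f"level must be one of {LEVELS}")
    labels = list(table.channels.labels)
    d = table.data
    complete = ~d[labels].isna().any(axis=1)
    d = d.loc[complete]
    if level == "protein":
        n_masters = d["master_proteins"].map(lambda v: len(split_accessions(v)))
        multi = n_masters > 1
        if multi.any():
            logger.info("dropping %d multi-master PSMs from protein aggregation", int(multi.sum()))
        d = d.loc[n_masters == 1]
        key = d["master_proteins"].astype(str)
    else:
        key = d["sequence"].astype(str)
    return d, key


def aggregate(table: PSMTable, level: str = "protein", min_psms: int = 2) -> FeatureMatrix:
    """Sum complete PSMs to features, requiring at least ``min_psms`` per feature."""
    d, key = _members(table, level)
    labels = list(table.channels.labels)
    if d.empty:
        empty = pd.DataFrame(columns=["species", "n_psms", *labels])
        return FeatureMatrix(data=empty, channels=table.channels, level=level)

    grouped = d.assign(_feature=key).groupby("_feature", sort=True)
    n_psms = grouped.size()
    keep = n_psms[n_psms >= min_psms].index
    sums = grouped[labels].sum().loc[keep]
    species = grouped["species"].agg(lambda s: tuple(sorted(set(s)))).loc[keep]
    mixed = species.map(len) > 1
    if mixed.any():
        raise IntegrityError(f"mixed-species features: {list(species.index[mixed])[:5]}")

    out = sums.copy()
    out.insert(0, "n_psms", n_psms.loc[keep])
    out.insert(0, "species", species.map(lambda t: t[0]))
    out.index.name = "feature_id"
    return FeatureMatrix(data=out, channels=table.channels, level=level)


def notch_exposure(table: PSMTable, matrix: FeatureMatrix, notch: NotchRegion) -> pd.DataFrame:
    """Per-feature, per-channel fraction of member-PSM intensities below the notch.

    Membership matches :func:`aggregate` (complete, single-master PSMs of the
    retained features). Returns a frame indexed by feature id with one
    fraction column per channel plus ``max_fraction`` over channels.
    """
    d, key = _members(table, matrix.level)
    labels = list(table.channels.labels)
    d = d.loc[key.isin(matrix.data.index)]
    key = key.loc[d.index]
    below = pd.DataFrame(
        safe_log2(d[labels].to_numpy(dtype=float)) < notch.upper,
        index=d.index,
        columns=labels,
    )
    frac = below.assign(_feature=key).groupby("_feature")[labels].mean()
    frac = frac.reindex(matrix.data.index).fillna(0.0)
    frac["max_fraction"] = frac[labels].max(axis=1)
    frac.index.name = "feature_id"
    return frac
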