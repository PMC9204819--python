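"""PSM-level quantification tables: domain types, I/O and identity-based exclusions.

The central container is :class:`PSMTable`, a thin wrapper around a pandas
DataFrame with one row per peptide-spectrum match (PSM). Reporter-ion
intensities live in one column per channel label (e.g. ``"126"``, ``"127N"``);
missing intensities are ``NaN``. Quality metrics carried per PSM are the
Sequest Delta CN score, the co-isolation interference percentage and the
average reporter signal-to-noise.

Tables are read from delimited text exports (the Proteome Discoverer dialect
ships as the default); column naming is configuration, not code — see
:class:`Dialect`.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, FormatError, ParseError

logger = logging.getLogger(__name__)

#: Valid species annotations.
SPECIES_VALUES = ("human", "yeast", "ambiguous", "contaminant", "unknown")

#: Species annotations that disqualify a PSM from quantitative analysis.
NON_QUANTIFIABLE = ("ambiguous", "contaminant", "unknown")

DEFAULT_LABELS = ("126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C", "131")
DEFAULT_GROUPS = ("1x", "1x", "1x", "1x", "2x", "2x", "2x", "6x", "6x", "6x")

#: Metadata columns of the canonical on-disk representation, in order.
META_COLUMNS = (
    "psm_id",
    "sequence",
    "master_proteins",
    "species",
    "delta_cn",
    "coisolation_pct",
    "avg_sn",
)

# pass-all sentinel values used when an optional metric column is absent
_PASS_ALL = {"delta_cn": 1.0, "coisolation_pct": 0.0, "avg_sn": np.inf}


@dataclass(frozen=True)
class ChannelSet:
    """Ordered isobaric-tag channel labels with their spike-in group assignment.

    The default is the 10-plex layout of the benchmark design: channels
    126-128N form the 1x group, 128C-129C the 2x group and 130N-131 the 6x
    group.
    """

    labels: tuple[str, ...] = DEFAULT_LABELS
    groups: tuple[str, ...] = DEFAULT_GROUPS

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ConfigurationError("channel labels must be unique")
        if len(self.groups) != len(self.labels):
            raise ConfigurationError("one group label per channel required")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def group_names(self) -> tuple[str, ...]:
        """Distinct group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g)
        return tuple(seen)

    def group_channels(self, group: str) -> tuple[str, ...]:
        """Channel labels belonging to ``group``."""
        chans = tuple(l for l, g in zip(self.labels, self.groups) if g == group)
        if not chans:
            raise ConfigurationError(f"unknown group {group!r}")
        return chans

    def group_of(self) -> dict[str, str]:
        """Mapping channel label -> group label."""
        return dict(zip(self.labels, self.groups))


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match (record view of a table row)."""

    psm_id: str
    sequence: str
    master_proteins: tuple[str, ...]
    species: str
    intensities: tuple[float, ...]  # NaN encodes MISSING, aligned with ChannelSet
    avg_sn: float
    coisolation_pct: float
    delta_cn: float


@dataclass
class PSMTable:
    """A collection of PSMs sharing one :class:`ChannelSet`.

    ``data`` holds the metadata columns of :data:`META_COLUMNS` plus one float
    column per channel label.
    """

    data: pd.DataFrame
    channels: ChannelSet = field(default_factory=ChannelSet)
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in (*META_COLUMNS, *self.channels.labels) if c not in self.data.columns]
        if missing:
            raise FormatError(f"PSM table is missing columns: {missing}")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def intensities(self) -> pd.DataFrame:
        """Intensity block (rows: PSMs, columns: channel labels)."""
        return self.data[list(self.channels.labels)]

    def intensity_matrix(self) -> np.ndarray:
        return self.intensities.to_numpy(dtype=float)

    def with_data(self, data: pd.DataFrame, provenance: str | None = None) -> "PSMTable":
        return PSMTable(
            data=data.reset_index(drop=True),
            channels=self.channels,
            provenance=self.provenance if provenance is None else provenance,
        )

    def iter_records(self) -> Iterator[PSMRecord]:
        labels = list(self.channels.labels)
        for d in self.data.to_dict("records"):
            yield PSMRecord(
                psm_id=str(d["psm_id"]),
                sequence=str(d["sequence"]),
                master_proteins=split_accessions(d["master_proteins"]),
                species=str(d["species"]),
                intensities=tuple(float(d[l]) for l in labels),
                avg_sn=float(d["avg_sn"]),
                coisolation_pct=float(d["coisolation_pct"]),
                delta_cn=float(d["delta_cn"]),
            )


def split_accessions(cell: object) -> tuple[str, ...]:
    """Split a ';'-separated accession cell into a tuple (empty for blank/NaN)."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return ()
    text = str(cell).strip()
    if not text or text.lower() == "nan":
        return ()
    return tuple(a.strip() for a in text.split(";") if a.strip())


@dataclass(frozen=True)
class Dialect:
    """Column-name map from semantic fields to the columns of a delimited export.

    ``abundance_pattern`` is formatted with each channel label to obtain the
    per-channel intensity columns. Optional metric fields set to ``None`` fall
    back to pass-all sentinel values on read (with a logged warning).
    """

    sequence: str
    abundance_pattern: str
    master_proteins: str | None = None
    delta_cn: str | None = None
    coisolation_pct: str | None = None
    avg_sn: str | None = None
    psm_id: str | None = None
    species: str | None = None

    def abundance_column(self, label: str) -> str:
        return self.abundance_pattern.format(label=label)

    @classmethod
    def proteome_discoverer(cls) -> "Dialect":
        """Default dialect for Proteome Discoverer PSM text exports."""
        return cls(
            sequence="Annotated Sequence",
            abundance_pattern="Abundance: {label}",
            master_proteins="Master Protein Accessions",
            delta_cn="Delta Cn",
            coisolation_pct="Isolation Interference [%]",
            avg_sn="Average Reporter S/N",
        )

    @classmethod
    def canonical(cls) -> "Dialect":
        """Dialect of tables written by :func:`write_psm_table`."""
        return cls(
            sequence="sequence",
            abundance_pattern="{label}",
            master_proteins="master_proteins",
            delta_cn="delta_cn",
            coisolation_pct="coisolation_pct",
            avg_sn="avg_sn",
            psm_id="psm_id",
            species="species",
        )


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _exact_numeric(cells: pd.Series) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Parse a string column to float64 exactly (bit round-trip safe).

    Returns (values, blank mask, unparseable mask); pandas' fast parser is
    only used to *detect* bad cells, the values themselves go through
    Python's correctly rounded float conversion.
    """
    blank = cells.isna() | (cells.astype(str).str.strip() == "")
    coerced = pd.to_numeric(cells.where(~blank), errors="coerce")
    bad = coerced.isna() & ~blank & ~cells.isin(["nan", "NaN"])
    values = cells.where(~blank & ~bad).astype(float)
    return values, blank, bad


def read_psm_table(
    path: str | Path,
    dialect: Dialect | None = None,
    channels: ChannelSet | None = None,
) -> PSMTable:
    """Read a delimited PSM export into a :class:`PSMTable`.

    Blank or non-positive abundance cells become missing values. Optional
    quality-metric columns absent from the file default to pass-all values
    (Delta CN 1, co-isolation 0, average S/N +inf) with a logged warning.

    Raises
    ------
    FormatError
        If the sequence column or any abundance column is absent.
    ParseError
        If a non-blank abundance cell is not numeric (the row index is named).
    """
    path = Path(path)
    dialect = dialect or Dialect.proteome_discoverer()
    channels = channels or ChannelSet()

    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str)

    if dialect.sequence not in raw.columns:
        raise FormatError(f"mandatory column {dialect.sequence!r} not found in {path.name}")
    abundance_cols = {l: dialect.abundance_column(l) for l in channels.labels}
    for label, col in abundance_cols.items():
        if col not in raw.columns:
            raise FormatError(f"mandatory abundance column {col!r} (channel {label}) not found")

    n = len(raw)
    out = pd.DataFrame(index=range(n))
    if dialect.psm_id and dialect.psm_id in raw.columns:
        out["psm_id"] = raw[dialect.psm_id].astype(str).to_numpy()
    else:
        out["psm_id"] = [f"psm{i:06d}" for i in range(n)]
    out["sequence"] = raw[dialect.sequence].astype(str).str.strip().to_numpy()

    if dialect.master_proteins and dialect.master_proteins in raw.columns:
        out["master_proteins"] = [
            ";".join(split_accessions(v)) for v in raw[dialect.master_proteins]
        ]
    else:
        logger.warning("no master-protein column mapped; species annotation will mark rows unknown")
        out["master_proteins"] = ""

    if dialect.species and dialect.species in raw.columns:
        out["species"] = raw[dialect.species].astype(str).to_numpy()
    else:
        out["species"] = "unknown"

    for fld in ("delta_cn", "coisolation_pct", "avg_sn"):
        col = getattr(dialect, fld)
        if col is not None and col in raw.columns:
            values, _, _ = _exact_numeric(raw[col])
            out[fld] = values.fillna(_PASS_ALL[fld]).to_numpy()
        else:
            logger.warning("column for %s not mapped/found; defaulting to pass-all value %s",
                           fld, _PASS_ALL[fld])
            out[fld] = _PASS_ALL[fld]

    for label, col in abundance_cols.items():
        cells = raw[col]
        values, _, bad = _exact_numeric(cells)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric abundance {cells.iloc[row]!r} in column {col!r}, row {row}"
            )
        # zero/negative reporter intensity is not physically meaningful -> missing
        out[label] = values.where(values > 0).to_numpy(dtype=float)

    return PSMTable(data=out, channels=channels, provenance=str(path))


def write_psm_table(table: PSMTable, path: str | Path) -> None:
    """Write a table in the canonical delimited layout (TSV, or CSV by suffix).

    Missing intensities are written as empty cells; finite values round-trip
    bit-identically through :func:`read_psm_table` with the canonical dialect.
    """
    path = Path(path)
    cols = [*META_COLUMNS, *table.channels.labels]
    # repr gives the shortest decimal that round-trips the float exactly
    table.data[cols].to_csv(
        path, sep=_sep_for(path), index=False, na_rep="",
        float_format=lambda x: repr(float(x)),
    )


def annotate_species(
    table: PSMTable,
    species_map: Mapping[str, str],
    contaminants: Sequence[str] | frozenset[str] = frozenset(),
) -> PSMTable:
    """Annotate each PSM as human / yeast / ambiguous / contaminant / unknown.

    The decision uses the full matched-accession list of the PSM, not only a
    single master protein: any contaminant accession marks the PSM
    ``contaminant``; accessions mapping to both species mark it ``ambiguous``;
    no master protein (or no mapped accession) marks it ``unknown``.
    """
    if not species_map:
        raise ConfigurationError("species_map must not be empty")
    contaminants = frozenset(contaminants)

    def classify(cell: object) -> str:
        accs = split_accessions(cell)
        if not accs:
            return "unknown"
        if any(a in contaminants for a in accs):
            return "contaminant"
        mapped = {species_map[a] for a in accs if a in species_map}
        if not mapped:
            return "unknown"
        if len(mapped) > 1:
            return "ambiguous"
        return next(iter(mapped))

    data = table.data.copy()
    data["species"] = [classify(v) for v in data["master_proteins"]]
    return table.with_data(data)


def exclude_nonquantifiable(table: PSMTable) -> tuple[PSMTable, dict[str, int]]:
    """Drop ambiguous, contaminant and unknown PSMs; report counts per reason.

    Output row order is the stable input order; the reason counts sum to the
    number of rows removed.
    """
    species = table.data["species"]
    removed = species.isin(NON_QUANTIFIABLE)
    counts = dict(Counter(species[removed]))
    kept = table.with_data(table.data.loc[~removed])
    return kept, counts
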