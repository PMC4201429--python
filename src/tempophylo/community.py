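"""Presence-absence community matrices at three temporal scales.

Capture records (year, month, sample id, species id, count) are aggregated
into sample units three ways:

* ``sample`` - each sampled (year, month) is one unit; organisms in a unit
  were physically present together.
* ``calendar_month`` - all samples of the same calendar month pooled across
  years (Jan..Dec); species sharing seasonal resource use co-occur.
* ``year`` - the twelve months of each year pooled; species sharing
  long-term trends co-occur.

Abundance is collapsed to presence-absence before any analysis: the
co-occurrence null models downstream are binary-matrix nulls and the indices
are unweighted. Counts are kept in the record format only for realism of the
sampling emulation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCALES = ("sample", "calendar_month", "year")

GUILDS = (
    "piscivorous",
    "carnivorous",
    "invertivorous",
    "herbivorous",
    "detritivorous",
    "omnivorous",
    "unclassified",
)

RECORD_COLUMNS = ["year", "month", "sample_id", "species_id", "count"]


@dataclass
class CommunityMatrix:
    """0/1 occurrence matrix; rows are chronologically ordered sample units."""

    data: pd.DataFrame  # index: unit labels, columns: species ids, values 0/1 (int8)
    scale: str
    dropped_units: list[str] = field(default_factory=list)

    @property
    def units(self) -> list[str]:
        return list(self.data.index)

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def richness(self) -> pd.Series:
        return self.data.sum(axis=1)

    def to_delimited(self, sep: str = "\t") -> str:
        buf = io.StringIO()
        self.data.to_csv(buf, sep=sep, index_label="unit")
        return buf.getvalue()


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records table missing columns: {missing}")
    if len(records) == 0:
        raise ValueError("records table is empty")
    r = records.copy()
    if (r["count"] < 1).any():
        raise ValueError("counts must be >= 1")
    if not r["month"].between(1, 12).all():
        raise ValueError("months must be in 1..12")
    if (r["species_id"].astype(str).str.len() == 0).any():
        raise ValueError("species ids must be non-empty")
    return r


def build_matrix(records: pd.DataFrame, scale: str) -> CommunityMatrix:
    """Aggregate capture records into a presence-absence matrix at one scale.

    Parameters
    ----------
    records
        Long-format table with columns ``year, month, sample_id, species_id,
        count``; one row per capture event (duplicates are harmless, presence
        is idempotent).
    scale
        One of ``sample``, ``calendar_month``, ``year``.
    """
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}; expected one of {SCALES}")
    r = _validate_records(records)
    if scale == "sample":
        unit = r["year"].astype(int).map("{:04d}".format) + "-" + r["month"].astype(int).map(
            "{:02d}".format
        )
    elif scale == "calendar_month":
        unit = "M" + r["month"].astype(int).map("{:02d}".format)
    else:
        unit = "Y" + r["year"].astype(int).map("{:04d}".format)
    table = pd.crosstab(unit, r["species_id"])
    table = (table > 0).astype(np.int8)
    table = table.sort_index(axis=0).sort_index(axis=1)  # labels encode chronology
    table.index.name = "unit"
    table.columns.name = None
    return CommunityMatrix(table, scale)


def read_records(path_or_buf) -> pd.DataFrame:
    """Read a capture-record table (comma- or tab-delimited, header required)."""
    df = pd.read_csv(path_or_buf, sep=None, engine="python")
    return _validate_records(df)


def read_guilds(path_or_buf) -> pd.Series:
    """Read a species->guild table with columns ``species_id, guild``."""
    df = pd.read_csv(path_or_buf, sep=None, engine="python")
    for col in ("species_id", "guild"):
        if col not in df.columns:
            raise ValueError(f"guild table missing column {col!r}")
    if df["species_id"].duplicated().any():
        dups = df.loc[df["species_id"].duplicated(), "species_id"].tolist()
        raise ValueError(f"species mapped to more than one guild: {dups}")
    return df.set_index("species_id")["guild"]


def subset_guild(matrix: CommunityMatrix, guilds: pd.Series, guild: str) -> CommunityMatrix:
    """Restrict columns to one trophic guild; rows are kept even if emptied.

    The species pool for a guild analysis is every guild member captured at
    least once over the whole study (the columns of the returned matrix), so
    the null model shuffles within that study-wide pool.
    """
    if guild not in GUILDS:
        raise ValueError(f"unknown guild {guild!r}; expected one of {GUILDS}")
    members = [sp for sp in matrix.species if guilds.get(sp) == guild]
    if not members:
        raise ValueError(f"guild {guild!r} has no member species in the matrix")
    return CommunityMatrix(matrix.data[members].copy(), matrix.scale)


def drop_degenerate_units(
    matrix: CommunityMatrix, min_richness: int = 2
) -> tuple[CommunityMatrix, list[str]]:
    """Remove units with fewer than ``min_richness`` species present.

    Units with zero or one species carry no pairwise phylogenetic information;
    they are dropped here and their labels returned so downstream series show
    gaps at the right chronological positions.
    """
    if min_richness < 2:
        raise ValueError("min_richness must be >= 2")
    rich = matrix.richness()
    keep = rich >= min_richness
    dropped = list(matrix.data.index[~keep])
    kept = CommunityMatrix(matrix.data.loc[keep].copy(), matrix.scale, dropped_units=dropped)
    return kept, dropped
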