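"""Reading, validation and spatial partitioning of BioTIME-shaped survey tables.

Survey data are handled as long-format :class:`pandas.DataFrame` objects with
one row per presence record, i.e. one observation of one species in one
within-year sample (haul, plot visit, transect, ...) of one community.  The
canonical columns are

``study_id, community_id, year, sample_id, species_id`` (required) and
``latitude, longitude, taxon_group`` (optional).

Column names of external CSV files are mapped onto this schema through a
*dialect* dictionary, whose defaults follow the BioTIME public export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical record columns (the PresenceRecord schema)
REQUIRED_COLUMNS = ["study_id", "community_id", "year", "sample_id", "species_id"]
OPTIONAL_COLUMNS = ["latitude", "longitude", "taxon_group"]

#: default column mapping, canonical name -> column name in the input CSV,
#: following the public BioTIME export naming
DEFAULT_DIALECT = {
    "study_id": "STUDY_ID",
    "community_id": "STUDY_ID",  # communities coincide with studies until partitioned
    "year": "YEAR",
    "sample_id": "SAMPLE_DESC",
    "species_id": "GENUS_SPECIES",
    "latitude": "LATITUDE",
    "longitude": "LONGITUDE",
    "taxon_group": "TAXA",
}

KM_PER_DEG_LAT = 110.574  # mean meridian arc length per degree
KM_PER_DEG_LON_EQ = 111.320  # equatorial parallel arc per degree


@dataclass
class CommunityTimeSeries:
    """Yearly presence/absence structure of one local community.

    ``presence`` maps ``(year, sample_id)`` to the set of species recorded in
    that sample; species are pooled across samples downstream, sampling effort
    is equalised by rarefaction.  Gap years are simply absent — no imputation.
    """

    community_id: str
    presence: dict[tuple[int, str], frozenset[str]]
    taxon_group: str = "all"

    def __post_init__(self) -> None:
        if not self.presence:
            raise ValueError(f"community {self.community_id!r} has no records")
        for key, species in self.presence.items():
            if not species:
                raise ValueError(f"empty species set for {key} in {self.community_id!r}")

    @property
    def years(self) -> list[int]:
        return sorted({year for year, _ in self.presence})

    @property
    def samples_per_year(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for year, sample in self.presence:
            out.setdefault(year, []).append(sample)
        return {year: sorted(samples) for year, samples in out.items()}

    @property
    def min_samples(self) -> int:
        """Minimum number of within-year samples over all survey years."""
        return min(len(v) for v in self.samples_per_year.values())

    @property
    def species(self) -> frozenset[str]:
        out: set[str] = set()
        for sp in self.presence.values():
            out |= sp
        return frozenset(out)

    def year_pool(self, year: int, sample_ids=None) -> frozenset[str]:
        """Species pooled over (a subset of) the year's samples."""
        samples = self.samples_per_year[year] if sample_ids is None else sample_ids
        pooled: set[str] = set()
        for sid in samples:
            pooled |= self.presence[(year, sid)]
        return frozenset(pooled)


@dataclass
class ClimateSeries:
    """Annual climate series (e.g. global mean surface air temperature anomaly)."""

    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.size != self.values.size:
            raise ValueError("years and values differ in length")
        if self.years.size == 0:
            raise ValueError("empty climate series")
        if not np.all(np.diff(self.years) == 1):
            raise ValueError("climate series years must be consecutive")


def read_survey_table(path, dialect: dict | None = None) -> pd.DataFrame:
    """Read a long-format survey CSV into the canonical record frame.

    Rows with unparseable years are rejected with a warning; exact duplicate
    records are collapsed.  The returned frame carries bookkeeping counts in
    ``df.attrs`` (``n_rejected``, ``n_duplicates``).
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    raw = pd.read_csv(path, dtype=str, comment="#")
    for canon in REQUIRED_COLUMNS:
        src = dialect[canon]
        if src not in raw.columns:
            raise ValueError(f"required column {canon!r} (mapped from {src!r}) missing from {path}")

    df = pd.DataFrame()
    for canon in REQUIRED_COLUMNS + OPTIONAL_COLUMNS:
        src = dialect.get(canon)
        if src is not None and src in raw.columns:
            df[canon] = raw[src]
    if "taxon_group" not in df.columns:
        df["taxon_group"] = "all"

    years = pd.to_numeric(df["year"], errors="coerce")
    bad = years.isna() | (years % 1 != 0)
    n_rejected = int(bad.sum())
    if n_rejected:
        warnings.warn(f"rejected {n_rejected} rows with unparseable year", stacklevel=2)
    df = df.loc[~bad].copy()
    df["year"] = years[~bad].astype(int)
    for col in ("latitude", "longitude"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")

    n_before = len(df)
    df = df.drop_duplicates(subset=REQUIRED_COLUMNS).reset_index(drop=True)
    df.attrs["n_rejected"] = n_rejected
    df.attrs["n_duplicates"] = n_before - len(df)
    return df


def filter_min_year(records: pd.DataFrame, cutoff_year: int = 1927) -> tuple[pd.DataFrame, int]:
    """Drop records from survey years earlier than ``cutoff_year``.

    The cutoff year itself is retained.  Early survey years show artefacts of
    evolving survey technique, so the analysis starts at 1927 by default.
    Returns the retained records and the number removed.
    """
    keep = records["year"] >= cutoff_year
    removed = int((~keep).sum())
    return records.loc[keep].reset_index(drop=True), removed


def _bbox_area_km2(lat: np.ndarray, lon: np.ndarray) -> float:
    """Bounding-box area on a spherical-Earth local approximation."""
    dlat = float(lat.max() - lat.min())
    dlon = float(lon.max() - lon.min())
    mean_lat = float(lat.mean())
    height = dlat * KM_PER_DEG_LAT
    width = dlon * KM_PER_DEG_LON_EQ * np.cos(np.deg2rad(mean_lat))
    return height * abs(width)


def partition_grid(
    records: pd.DataFrame,
    area_threshold_km2: float = 96.0,
    cell_km: float = 10.0,
) -> pd.DataFrame:
    """Split spatially extended studies into grid-cell local communities.

    Studies whose coordinate bounding box exceeds ``area_threshold_km2`` are
    partitioned on a locally projected fixed-size km grid; each grid cell with
    records becomes its own community (``community_id`` suffixed with the cell
    index).  Smaller studies keep a single community.  This is a simplified
    stand-in for published spatial partitioning protocols.
    """
    out = records.copy()
    for study, idx in records.groupby("study_id").groups.items():
        sub = records.loc[idx]
        lat = pd.to_numeric(sub.get("latitude"), errors="coerce")
        lon = pd.to_numeric(sub.get("longitude"), errors="coerce")
        has_coords = lat.notna() & lon.notna() if lat is not None else pd.Series(False, index=sub.index)
        if not has_coords.all():
            # cannot assess extent without full coordinates
            if has_coords.any():
                warnings.warn(f"study {study!r}: incomplete coordinates, left unpartitioned", stacklevel=2)
            continue
        area = _bbox_area_km2(lat.to_numpy(), lon.to_numpy())
        if area <= area_threshold_km2:
            continue
        lat0, lon0 = float(lat.min()), float(lon.min())
        y_km = (lat - lat0) * KM_PER_DEG_LAT
        x_km = (lon - lon0) * KM_PER_DEG_LON_EQ * np.cos(np.deg2rad(lat.mean()))
        iy = np.floor(y_km / cell_km).astype(int)
        ix = np.floor(x_km / cell_km).astype(int)
        out.loc[idx, "community_id"] = [
            f"{cid}#g{gx}_{gy}" for cid, gx, gy in zip(sub["community_id"], ix, iy)
        ]
    return out


def build_series(records: pd.DataFrame) -> list[CommunityTimeSeries]:
    """Group canonical records into one :class:`CommunityTimeSeries` per community."""
    out: list[CommunityTimeSeries] = []
    for cid, sub in records.groupby("community_id", sort=True):
        presence: dict[tuple[int, str], set[str]] = {}
        for year, sample, species in zip(sub["year"], sub["sample_id"], sub["species_id"]):
            presence.setdefault((int(year), str(sample)), set()).add(str(species))
        taxa = sub["taxon_group"].mode() if "taxon_group" in sub else None
        taxon = str(taxa.iloc[0]) if taxa is not None and len(taxa) else "all"
        out.append(
            CommunityTimeSeries(
                community_id=str(cid),
                presence={k: frozenset(v) for k, v in presence.items()},
                taxon_group=taxon,
            )
        )
    return out


def flatten_series(series: CommunityTimeSeries) -> pd.DataFrame:
    """Inverse of :func:`build_series` for one community (canonical columns)."""
    rows = [
        (series.community_id, series.community_id, year, sample, sp, series.taxon_group)
        for (year, sample), species in sorted(series.presence.items())
        for sp in sorted(species)
    ]
    return pd.DataFrame(
        rows, columns=["study_id", "community_id", "year", "sample_id", "species_id", "taxon_group"]
    )


def read_climate(path) -> ClimateSeries:
    """Read a two-column (year, value) CSV into a :class:`ClimateSeries`."""
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"climate CSV {path} needs two columns (year, value)")
    years = pd.to_numeric(df.iloc[:, 0], errors="raise").astype(int).to_numpy()
    values = pd.to_numeric(df.iloc[:, 1], errors="raise").astype(float).to_numpy()
    return ClimateSeries(years=years, values=values)


def write_table(df: pd.DataFrame, path, schema_note: str | None = None) -> None:
    """Write a results table as CSV with a leading ``#`` schema header line."""
    with open(path, "w") as fh:
        cols = ", ".join(df.columns)
        fh.write(f"# schema: {schema_note or cols}\n")
        df.to_csv(fh, index=False)
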