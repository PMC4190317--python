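"""Shared data model and I/O for community matrices, site tables and rasters.

The canonical on-disk formats are plain text: CSV for the site-by-species
occurrence matrix and the site/climate table, ESRI ASCII grid (``.asc``) for
precipitation rasters, and Newick for phylogenies (handled in
:mod:`phylobeta.phylogeny`).  All readers validate on load and either repair
with a warning (derived climate variables, all-empty species columns) or fail
loudly (non-binary cells, duplicate names, malformed headers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CLIMATE_VARS",
    "CommunityMatrix",
    "SiteRecord",
    "Grid",
    "ValidationReport",
    "read_community_matrix",
    "write_community_matrix",
    "read_site_table",
    "write_site_table",
    "read_ascii_grid",
    "write_ascii_grid",
    "validate_bundle",
    "excel_to_csv",
]

#: The twelve climate/topography descriptors attached to every site:
#: four temperature variables (annual mean, max of warmest month, min of
#: coldest month, and their difference), five precipitation variables
#: (annual total, seasonality, wettest/driest quarter, and their difference)
#: and three elevation variables (max, min, range).
CLIMATE_VARS = (
    "ANNT", "MAXT", "MINT", "DIFT",
    "PPT", "PPTS", "PPTW", "PPTD", "DIFP",
    "MAEL", "MIEL", "DIEL",
)

#: (derived, minuend, subtrahend) identities enforced on every site record.
_DERIVED = (("DIFT", "MAXT", "MINT"), ("DIFP", "PPTW", "PPTD"), ("DIEL", "MAEL", "MIEL"))


@dataclass
class CommunityMatrix:
    """Binary site-by-species occurrence table.

    ``occupancy`` has one row per site and one column per species, entries in
    {0, 1}.  Site and species orderings are significant: every pairwise vector
    downstream uses the site order given here.
    """

    sites: list[str]
    species: list[str]
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy)
        if self.occupancy.shape != (len(self.sites), len(self.species)):
            raise ValueError(
                f"occupancy shape {self.occupancy.shape} does not match "
                f"{len(self.sites)} sites x {len(self.species)} species"
            )
        bad = ~np.isin(self.occupancy, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary value {self.occupancy[i, j]!r} at site "
                f"{self.sites[i]!r}, species {self.species[j]!r}"
            )
        self.occupancy = self.occupancy.astype(np.int8)
        for name, labels in (("site", self.sites), ("species", self.species)):
            dupes = {x for x in labels if labels.count(x) > 1}
            if dupes:
                raise ValueError(f"duplicate {name} name(s): {sorted(dupes)}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def richness(self) -> np.ndarray:
        """Species count per site."""
        return self.occupancy.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.occupancy, index=self.sites, columns=self.species)


@dataclass
class SiteRecord:
    """One survey site: identifier, WGS84 decimal-degree coordinates, and the
    twelve climate/topography variables (temperatures in the units declared by
    the data source, precipitation in mm, elevations in m)."""

    site_id: str
    longitude: float
    latitude: float
    climate: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [v for v in CLIMATE_VARS if v not in self.climate]
        if missing:
            raise ValueError(f"site {self.site_id!r} missing climate variables: {missing}")
        if self.climate["MAEL"] < self.climate["MIEL"]:
            raise ValueError(f"site {self.site_id!r}: MAEL < MIEL")


@dataclass
class Grid:
    """A georeferenced raster in ESRI ASCII grid convention.

    ``values`` is (n_rows, n_cols) with the FIRST row being the northernmost
    (as in the .asc format); nodata cells are stored as NaN.  ``xll``/``yll``
    are the lower-left corner of the lower-left cell, ``cellsize`` in the same
    (degree) units as the corner.
    """

    values: np.ndarray
    xll: float
    yll: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")
        if not np.isfinite(self.values[~np.isnan(self.values)]).all():
            raise ValueError("non-finite grid value outside nodata cells")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def same_georeference(self, other: "Grid", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.xll - other.xll) <= tol
            and abs(self.yll - other.yll) <= tol
            and abs(self.cellsize - other.cellsize) <= tol
        )

    def cell_of(self, longitude: float, latitude: float) -> tuple[int, int]:
        """Array (row, col) of the cell containing a point.

        Uses the floor convention: a point exactly on a cell boundary belongs
        to the higher-index (more north/east) cell.  Raises ``ValueError``
        outside the grid extent.
        """
        col = int(np.floor((longitude - self.xll) / self.cellsize))
        row_from_bottom = int(np.floor((latitude - self.yll) / self.cellsize))
        row = self.n_rows - 1 - row_from_bottom
        if not (0 <= col < self.n_cols and 0 <= row < self.n_rows):
            raise ValueError(
                f"point ({longitude}, {latitude}) falls outside grid extent"
            )
        return row, col


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.errors

    def __str__(self) -> str:  # pragma: no cover - convenience
        lines = [f"passed: {self.passed}"]
        lines += [f"ERROR: {e}" for e in self.errors]
        lines += [f"WARNING: {w}" for w in self.warnings]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Community matrix
# ---------------------------------------------------------------------------

def read_community_matrix(path: str | Path, sites_as_rows: bool = True) -> CommunityMatrix:
    """Read a binary occurrence CSV.

    The default dialect has sites as rows and species as columns (first column
    = site ids, header row = species names); ``sites_as_rows=False`` transposes
    on read.  Non-binary cells and duplicate names are hard errors; species
    columns with no occurrences are dropped with a warning; a site with no
    species at all is a hard error.
    """
    df = pd.read_csv(path, index_col=0)
    if not sites_as_rows:
        df = df.T
    sites = [str(s) for s in df.index]
    species = [str(s) for s in df.columns]
    values = df.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-binary value {values[i, j]!r} at site {sites[i]!r}, "
            f"species {species[j]!r} in {path}"
        )
    values = values.astype(np.int8)
    empty_sp = values.sum(axis=0) == 0
    if empty_sp.any():
        dropped = [sp for sp, e in zip(species, empty_sp) if e]
        warnings.warn(
            f"dropping {len(dropped)} species with no occurrences: {dropped}",
            stacklevel=2,
        )
        values = values[:, ~empty_sp]
        species = [sp for sp, e in zip(species, empty_sp) if not e]
    empty_sites = values.sum(axis=1) == 0
    if empty_sites.any():
        bad_sites = [s for s, e in zip(sites, empty_sites) if e]
        raise ValueError(f"site(s) with no species: {bad_sites}")
    return CommunityMatrix(sites=sites, species=species, occupancy=values)


def write_community_matrix(m: CommunityMatrix, path: str | Path) -> None:
    m.to_dataframe().to_csv(path, index_label="site")


# ---------------------------------------------------------------------------
# Site table
# ---------------------------------------------------------------------------

def read_site_table(path: str | Path) -> list[SiteRecord]:
    """Read the site/climate CSV into :class:`SiteRecord` objects.

    Required columns: ``site``, ``longitude``, ``latitude`` and the twelve
    climate variables.  The three derived variables (DIFT, DIFP, DIEL) are
    recomputed from their parents; a file value disagreeing by more than 1e-6
    triggers a warning and the recomputed value is kept.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"site table {path} is empty")
    required = ["site", "longitude", "latitude", *CLIMATE_VARS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"site table {path} missing column(s): {missing}")
    records: list[SiteRecord] = []
    for _, row in df.iterrows():
        climate = {v: float(row[v]) for v in CLIMATE_VARS}
        for derived, hi, lo in _DERIVED:
            expected = climate[hi] - climate[lo]
            if abs(climate[derived] - expected) > 1e-6:
                warnings.warn(
                    f"site {row['site']!r}: {derived}={climate[derived]} does not "
                    f"equal {hi}-{lo}={expected}; recomputed value kept",
                    stacklevel=2,
                )
                climate[derived] = expected
        records.append(
            SiteRecord(
                site_id=str(row["site"]),
                longitude=float(row["longitude"]),
                latitude=float(row["latitude"]),
                climate=climate,
            )
        )
    ids = [r.site_id for r in records]
    dupes = {s for s in ids if ids.count(s) > 1}
    if dupes:
        raise ValueError(f"duplicate site id(s) in {path}: {sorted(dupes)}")
    return records


def write_site_table(records: list[SiteRecord], path: str | Path) -> None:
    rows = [
        {"site": r.site_id, "longitude": r.longitude, "latitude": r.latitude, **r.climate}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ESRI ASCII grids
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path: str | Path) -> Grid:
    """Read an ESRI ASCII grid (.asc).

    Header lines ``ncols/nrows/xllcorner/yllcorner/cellsize`` are required;
    ``NODATA_value`` is optional (default -9999).  Rows run north to south.
    """
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            tokens = line.split()
            if not tokens:
                continue
            key = tokens[0].lower()
            if not rows and key in (*_HEADER_KEYS, "nodata_value"):
                if len(tokens) != 2:
                    raise ValueError(f"malformed header line in {path}: {line!r}")
                header[key] = float(tokens[1])
            else:
                rows.append([float(t) for t in tokens])
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise ValueError(f"grid {path} missing header field(s): {missing}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if len(rows) != nrows:
        raise ValueError(f"grid {path}: expected {nrows} data rows, found {len(rows)}")
    for i, r in enumerate(rows):
        if len(r) != ncols:
            raise ValueError(f"grid {path}: row {i} has {len(r)} values, expected {ncols}")
    nodata = header.get("nodata_value", -9999.0)
    values = np.array(rows, dtype=float)
    values[values == nodata] = np.nan
    return Grid(
        values=values,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=nodata,
    )


def write_ascii_grid(g: Grid, path: str | Path) -> None:
    out = g.values.copy()
    out[np.isnan(out)] = g.nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {float(g.xll)!r}\n")
        fh.write(f"yllcorner {float(g.yll)!r}\n")
        fh.write(f"cellsize {float(g.cellsize)!r}\n")
        fh.write(f"NODATA_value {float(g.nodata)!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Cross-input validation
# ---------------------------------------------------------------------------

def validate_bundle(matrix: CommunityMatrix, sites: list[SiteRecord], tree=None) -> ValidationReport:
    """Cross-check a community matrix against the site table and (optionally)
    an assembled phylogeny.  Report-only: never raises."""
    report = ValidationReport()
    by_id = {r.site_id: r for r in sites}
    for s in matrix.sites:
        if s not in by_id:
            report.errors.append(f"matrix site {s!r} has no site record")
    extra = set(by_id) - set(matrix.sites)
    if extra:
        report.warnings.append(f"site records without matrix rows: {sorted(extra)}")
    if tree is not None:
        tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        for sp in matrix.species:
            if sp not in tips:
                report.warnings.append(f"species {sp!r} not a tip of the supplied tree")
    return report


def excel_to_csv(xlsx_path: str | Path, csv_path: str | Path, sheet: int | str = 0) -> None:
    """Convert a spreadsheet (.xlsx) occurrence table to the canonical CSV.

    The pipeline proper consumes CSV only; this helper covers sources shipped
    as spreadsheets.  Requires openpyxl; legacy binary .xls is not supported
    (re-save as .xlsx or CSV first).
    """
    df = pd.read_excel(xlsx_path, sheet_name=sheet, index_col=0)
    df.to_csv(csv_path, index_label="site")
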