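"""Delimitation of climatically stable (refugial) vs unstable regions.

Long-term climate stability is inferred from annual-precipitation rasters for
the present and for Last Glacial Maximum simulations (e.g. CCSM3 and MIROC,
~21 kyr BP): each layer is binarized at its top decile (the 10% wettest
cells), and a cell is called stable only if it sits in the top decile of
every layer — the intersection map.  Survey sites are then labeled stable or
unstable by the cell they fall in, and site pairs are categorized as
within-stable, within-unstable, or between-regions for all downstream
summaries.

Quantile convention: nearest-rank on the non-nodata cells of the supplied
extent.  With n valid cells and fraction f, the threshold is the k-th largest
value where k = max(1, floor(f*n)), and every cell >= the threshold is
selected — so ties at the threshold can push the selected count slightly
above k.  The extent over which the decile is taken is whatever grid the user
supplies; clipping it differently changes the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Grid, SiteRecord

__all__ = [
    "StabilityMask",
    "RegionLabel",
    "top_quantile_mask",
    "intersect_masks",
    "classify_sites",
    "pair_region_category",
]


@dataclass
class StabilityMask:
    """Boolean raster aligned to its source :class:`~phylobeta.io.Grid`."""

    values: np.ndarray  # bool, same shape/orientation as the source grid
    xll: float
    yll: float
    cellsize: float
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)

    def to_grid(self, nodata: float = -9999.0) -> Grid:
        return Grid(values=self.values.astype(float), xll=self.xll, yll=self.yll,
                    cellsize=self.cellsize, nodata=nodata)

    def same_georeference(self, other: "StabilityMask", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.xll - other.xll) <= tol
            and abs(self.yll - other.yll) <= tol
            and abs(self.cellsize - other.cellsize) <= tol
        )


@dataclass(frozen=True)
class RegionLabel:
    site_id: str
    label: str  # "stable" | "unstable"
    row: int
    col: int


def top_quantile_mask(g: Grid, fraction: float = 0.10,
                      name: str = "grid") -> StabilityMask:
    """Binarize a precipitation grid at its upper ``fraction`` quantile.

    Cells at or above the nearest-rank threshold are True; nodata cells are
    always False.  With all valid cells equal, the threshold equals that
    value and every valid cell is selected (documented tie behavior).
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    valid = g.values[~np.isnan(g.values)]
    if valid.size == 0:
        raise ValueError("grid has no non-nodata cells")
    k = max(1, int(np.floor(fraction * valid.size)))
    threshold = np.sort(valid)[::-1][k - 1]  # k-th largest (nearest rank)
    with np.errstate(invalid="ignore"):
        mask = g.values >= threshold
    mask &= ~np.isnan(g.values)
    return StabilityMask(values=mask, xll=g.xll, yll=g.yll,
                         cellsize=g.cellsize, provenance=[name])


def intersect_masks(masks: list[StabilityMask]) -> StabilityMask:
    """Cellwise AND of aligned binary masks: stable = wet in every layer."""
    if len(masks) < 2:
        raise ValueError("need at least two masks to intersect")
    first = masks[0]
    values = first.values.copy()
    provenance = list(first.provenance)
    for m in masks[1:]:
        if not first.same_georeference(m):
            raise ValueError("masks differ in shape or georeference")
        values &= m.values
        provenance += m.provenance
    return StabilityMask(values=values, xll=first.xll, yll=first.yll,
                         cellsize=first.cellsize, provenance=provenance)


def classify_sites(mask: StabilityMask, sites: list[SiteRecord]) -> list[RegionLabel]:
    """Label each site stable/unstable by the mask cell containing it.

    Site-to-cell mapping is floor((coord - corner)/cellsize); a site exactly
    on a cell boundary belongs to the higher-index cell.  A site outside the
    grid extent is an error naming the site.
    """
    grid = Grid(values=mask.values.astype(float), xll=mask.xll, yll=mask.yll,
                cellsize=mask.cellsize)
    labels = []
    for s in sites:
        try:
            row, col = grid.cell_of(s.longitude, s.latitude)
        except ValueError as err:
            raise ValueError(f"site {s.site_id!r}: {err}") from None
        labels.append(
            RegionLabel(
                site_id=s.site_id,
                label="stable" if mask.values[row, col] else "unstable",
                row=row,
                col=col,
            )
        )
    return labels


def pair_region_category(label_i: str, label_j: str) -> str:
    """Symmetric region-pair category of two site labels."""
    for lab in (label_i, label_j):
        if lab not in ("stable", "unstable"):
            raise ValueError(f"invalid region label {lab!r}")
    if label_i == label_j:
        return f"within-{label_i}"
    return "between"
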