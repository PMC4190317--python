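"""Environmental/geographic gradients and eight-fraction variance partitioning.

The climate table is reduced by PCA on the correlation matrix (all twelve
variables standardized), and the environmental distance between two sites is
the Euclidean distance over the leading PC axes (three by default).
Geographic distance is planar Euclidean on decimal degrees by default, with a
haversine-km option.  Long-term climate condition enters as two indicator
columns coding the three region-pair categories (reference level:
within-unstable).

Variance partitioning follows the classic three-set R-squared
inclusion-exclusion for ordinary least squares: with predictor sets E
(environment), S (space) and R (refugia), seven OLS models (E, S, R, E+S,
E+R, S+R, E+S+R) are fit to one dissimilarity vector, and the unique and
shared fractions are::

    pure_E = R2(ESR) - R2(SR)            (likewise pure_S, pure_R)
    E^S^R  = sum(singles) - sum(pairs) + R2(ESR)
    E^S    = R2(E) + R2(S) - R2(ES) - E^S^R   (likewise E^R, S^R)
    residual = 1 - R2(ESR)

The eight fractions sum to one by construction; shared fractions can be
negative (suppression), which is reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .io import CLIMATE_VARS, SiteRecord

__all__ = [
    "PCAResult",
    "DistanceVector",
    "VarpartResult",
    "pca_correlation",
    "env_distance",
    "geo_distance",
    "log_transform",
    "refugia_predictors",
    "eight_fractions",
]

FRACTION_NAMES = (
    "pure_env", "pure_space", "pure_refugia",
    "env_space", "env_refugia", "space_refugia",
    "env_space_refugia", "residual",
)


@dataclass
class PCAResult:
    """PCA of standardized site variables: loadings (variables x axes),
    per-site scores (sites x axes), and variance proportion per axis."""

    loadings: np.ndarray
    scores: np.ndarray
    proportions: np.ndarray
    variables: list[str]
    site_ids: list[str]


@dataclass
class DistanceVector:
    """A lower-triangle pairwise vector keyed by (site_i, site_j), i < j in
    site-table order; the same ordering is shared by every vector in one
    analysis."""

    pairs: list[tuple[str, str]]
    values: np.ndarray
    transform: str = "raw"  # "raw" | "log"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.pairs) != len(self.values):
            raise ValueError("pair keys and values differ in length")


@dataclass
class VarpartResult:
    fractions: dict[str, float]
    r_squared: dict[str, float]  # keyed E, S, R, ES, ER, SR, ESR

    def as_series(self) -> pd.Series:
        return pd.Series({**self.fractions,
                          **{f"r2_{k}": v for k, v in self.r_squared.items()}})


def _pair_keys(site_ids: list[str]) -> list[tuple[str, str]]:
    n = len(site_ids)
    return [(site_ids[i], site_ids[j]) for i in range(n) for j in range(i + 1, n)]


def pca_correlation(records: list[SiteRecord],
                    variables: tuple[str, ...] = CLIMATE_VARS) -> PCAResult:
    """PCA on the correlation matrix of the site climate table.

    Variables are standardized to zero mean and unit (sample) variance, the
    correlation matrix eigen-decomposed, and axes ordered by decreasing
    eigenvalue.  A constant variable has no correlation structure and is a
    hard error naming it.  Loading signs are fixed so each axis's
    largest-magnitude loading is positive (a determinism convention only).
    """
    if len(records) < 3:
        raise ValueError("PCA needs at least three sites")
    data = np.array([[r.climate[v] for v in variables] for r in records], dtype=float)
    if np.isnan(data).any():
        raise ValueError("missing values in climate table")
    sd = data.std(axis=0, ddof=1)
    constant = [v for v, s in zip(variables, sd) if s == 0]
    if constant:
        raise ValueError(f"constant variable(s), cannot standardize: {constant}")
    z = (data - data.mean(axis=0)) / sd
    corr = (z.T @ z) / (len(records) - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)
    for k in range(eigvec.shape[1]):
        if eigvec[np.argmax(np.abs(eigvec[:, k])), k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    return PCAResult(
        loadings=eigvec,
        scores=z @ eigvec,
        proportions=eigval / eigval.sum(),
        variables=list(variables),
        site_ids=[r.site_id for r in records],
    )


def env_distance(pca: PCAResult, n_axes: int = 3) -> DistanceVector:
    """Pairwise Euclidean distance in the space of the leading PC axes."""
    if n_axes > pca.scores.shape[1]:
        raise ValueError(f"requested {n_axes} axes, only {pca.scores.shape[1]} available")
    return DistanceVector(
        pairs=_pair_keys(pca.site_ids),
        values=pdist(pca.scores[:, :n_axes], metric="euclidean"),
        transform="raw",
    )


def geo_distance(records: list[SiteRecord], method: str = "planar") -> DistanceVector:
    """Pairwise geographic distance between sites.

    ``planar`` is Euclidean distance on raw decimal degrees (the distance-decay
    predictor); ``haversine`` returns great-circle km on a 6371-km sphere.
    """
    coords = np.array([[r.longitude, r.latitude] for r in records], dtype=float)
    pairs = _pair_keys([r.site_id for r in records])
    if method == "planar":
        values = pdist(coords, metric="euclidean")
    elif method == "haversine":
        rad = np.radians(coords)

        def hav(u, v):
            dlon, dlat = v - u
            h = np.sin(dlat / 2) ** 2 + np.cos(u[1]) * np.cos(v[1]) * np.sin(dlon / 2) ** 2
            return 2 * 6371.0 * np.arcsin(np.sqrt(h))

        values = pdist(rad, metric=hav)
    else:
        raise ValueError(f"unknown method {method!r}")
    return DistanceVector(pairs=pairs, values=values, transform="raw")


def log_transform(dv: DistanceVector) -> DistanceVector:
    """Natural log of a distance vector, shifting exact zeros.

    Zero distances (co-located sites, identical climate profiles) are
    replaced by epsilon = smallest positive observed distance x 1e-3 before
    taking the log, so the transform is defined everywhere while leaving
    positive distances untouched.
    """
    if dv.transform == "log":
        raise ValueError("distance vector already log-transformed")
    v = dv.values.copy()
    positive = v[v > 0]
    if positive.size == 0:
        raise ValueError("all distances zero: log transform undefined")
    v[v == 0] = positive.min() * 1e-3
    return DistanceVector(pairs=dv.pairs, values=np.log(v), transform="log")


def refugia_predictors(labels: dict[str, str], site_ids: list[str]) -> tuple[np.ndarray, list[str]]:
    """Pairwise dummy coding of long-term climate condition.

    Each pair's category (within-stable / within-unstable / between) becomes
    two indicator columns with within-unstable as the reference level:
    (1,0) = within-stable, (0,1) = between, (0,0) = within-unstable.
    """
    from .stability import pair_region_category

    pairs = _pair_keys(site_ids)
    cols = np.zeros((len(pairs), 2), dtype=float)
    for k, (i, j) in enumerate(pairs):
        cat = pair_region_category(labels[i], labels[j])
        if cat == "within-stable":
            cols[k, 0] = 1.0
        elif cat == "between":
            cols[k, 1] = 1.0
    return cols, ["within_stable", "between_regions"]


def _as_design(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[:, None] if x.ndim == 1 else x


def _r_squared(y: np.ndarray, x: np.ndarray) -> float:
    n = len(y)
    design = np.column_stack([np.ones(n), x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear predictors within a set")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("response has zero variance")
    return 1.0 - float(np.sum(resid**2) / ss_tot)


def eight_fractions(y, E, S, R) -> VarpartResult:
    """Partition a dissimilarity vector's variance over three predictor sets.

    ``y`` is the response (a DistanceVector or plain array); ``E``, ``S``,
    ``R`` are predictor matrices/vectors of matching length (environment and
    space expected already log-transformed upstream).  Seven OLS fits feed the
    inclusion-exclusion identities in the module docstring.
    """
    y = np.asarray(y.values if isinstance(y, DistanceVector) else y, dtype=float)
    mats = {k: _as_design(v.values if isinstance(v, DistanceVector) else v)
            for k, v in (("E", E), ("S", S), ("R", R))}
    for k, m in mats.items():
        if len(m) != len(y):
            raise ValueError(f"predictor set {k} length {len(m)} != response {len(y)}")
    n_pred = sum(m.shape[1] for m in mats.values())
    if len(y) <= n_pred + 1:
        raise ValueError("more predictors than informative pairs")

    def r2(*keys: str) -> float:
        return _r_squared(y, np.column_stack([mats[k] for k in keys]))

    r = {
        "E": r2("E"), "S": r2("S"), "R": r2("R"),
        "ES": r2("E", "S"), "ER": r2("E", "R"), "SR": r2("S", "R"),
        "ESR": r2("E", "S", "R"),
    }
    triple = (r["E"] + r["S"] + r["R"]) - (r["ES"] + r["ER"] + r["SR"]) + r["ESR"]
    fractions = {
        "pure_env": r["ESR"] - r["SR"],
        "pure_space": r["ESR"] - r["ER"],
        "pure_refugia": r["ESR"] - r["ES"],
        "env_space": r["E"] + r["S"] - r["ES"] - triple,
        "env_refugia": r["E"] + r["R"] - r["ER"] - triple,
        "space_refugia": r["S"] + r["R"] - r["SR"] - triple,
        "env_space_refugia": triple,
        "residual": 1.0 - r["ESR"],
    }
    return VarpartResult(fractions=fractions, r_squared=r)
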