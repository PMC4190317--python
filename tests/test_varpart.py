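import numpy as np
import pytest

from phylobeta.varpart import (
    DistanceVector,
    eight_fractions,
    env_distance,
    geo_distance,
    log_transform,
    pca_correlation,
    refugia_predictors,
    FRACTION_NAMES,
)

from conftest import make_site


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_perfectly_correlated_pair_loads_symmetrically():
    rng = np.random.default_rng(0)
    sites = []
    for i in range(8):
        x = float(rng.normal())
        sites.append(make_site(f"s{i}", float(i), 0.0,
                               ANNT=x, MAXT=x + 10.0, PPT=float(rng.normal()),
                               PPTS=float(rng.normal())))
    res = pca_correlation(sites, variables=("ANNT", "MAXT", "PPT", "PPTS"))
    l1 = res.loadings[:, 0]
    assert abs(l1[0]) == pytest.approx(abs(l1[1]), abs=1e-9)


def test_pca_uncorrelated_unit_variance_gives_equal_proportions():
    # exactly orthogonal columns after standardization -> identity correlation
    a = [1.0, 1.0, -1.0, -1.0]
    b = [1.0, -1.0, 1.0, -1.0]
    sites = [make_site(f"s{i}", float(i), 0.0, ANNT=a[i], PPT=b[i]) for i in range(4)]
    res = pca_correlation(sites, variables=("ANNT", "PPT"))
    np.testing.assert_allclose(res.proportions, [0.5, 0.5], atol=1e-12)


def test_pca_scores_reproduce_standardized_data(bundle):
    res = pca_correlation(bundle.site_records)
    data = np.array([[r.climate[v] for v in res.variables] for r in bundle.site_records])
    z = (data - data.mean(axis=0)) / data.std(axis=0, ddof=1)
    np.testing.assert_allclose(res.scores @ res.loadings.T, z, atol=1e-9)
    assert res.proportions.sum() == pytest.approx(1.0)
    assert ((res.proportions >= 0) & (res.proportions <= 1)).all()
    assert (np.diff(res.proportions) <= 1e-12).all()  # sorted descending


def test_pca_constant_variable_is_named():
    sites = [make_site(f"s{i}", float(i), 0.0) for i in range(4)]  # all defaults equal
    with pytest.raises(ValueError, match="ANNT"):
        pca_correlation(sites, variables=("ANNT", "PPT"))


# ---------------------------------------------------------------------------
# Distances and predictors
# ---------------------------------------------------------------------------

def test_env_distance_identity_and_single_axis():
    sites = [make_site("a", 0, 0, ANNT=0.0, MAXT=20.0, PPT=1.0),
             make_site("b", 1, 0, ANNT=0.0, MAXT=20.0, PPT=1.0),
             make_site("c", 2, 0, ANNT=4.0, MAXT=24.0, PPT=3.0),
             make_site("d", 3, 0, ANNT=8.0, MAXT=28.0, PPT=5.0)]
    res = pca_correlation(sites, variables=("ANNT", "MAXT", "PPT"))
    dv = env_distance(res, n_axes=2)
    # identical climate profiles -> distance 0
    pair_ab = dv.values[dv.pairs.index(("a", "b"))]
    assert pair_ab == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ValueError):
        env_distance(res, n_axes=99)


def test_geo_distance_345_and_symmetry():
    sites = [make_site("o", 0.0, 0.0), make_site("p", 3.0, 4.0)]
    dv = geo_distance(sites)
    assert dv.values[0] == pytest.approx(5.0)
    assert geo_distance(sites[::-1]).values[0] == pytest.approx(5.0)
    hv = geo_distance(sites, method="haversine")
    assert hv.values[0] > 0


def test_env_distance_triangle_inequality(bundle):
    res = pca_correlation(bundle.site_records)
    dv = env_distance(res, n_axes=3)
    d = {frozenset(p): v for p, v in zip(dv.pairs, dv.values)}
    ids = [r.site_id for r in bundle.site_records][:8]
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            for k in range(j + 1, len(ids)):
                a, b, c = ids[i], ids[j], ids[k]
                assert d[frozenset((a, c))] <= d[frozenset((a, b))] + d[frozenset((b, c))] + 1e-9


def test_log_transform_shifts_zeros_only():
    dv = DistanceVector(pairs=[("a", "b"), ("a", "c"), ("b", "c")],
                        values=np.array([0.0, 2.0, 4.0]))
    out = log_transform(dv)
    assert out.transform == "log"
    assert out.values[1] == pytest.approx(np.log(2.0))
    assert out.values[0] == pytest.approx(np.log(2.0 * 1e-3))
    with pytest.raises(ValueError):
        log_transform(out)


def test_refugia_dummy_coding():
    labels = {"a": "stable", "b": "stable", "c": "unstable"}
    cols, names = refugia_predictors(labels, ["a", "b", "c"])
    assert names == ["within_stable", "between_regions"]
    np.testing.assert_array_equal(cols, [[1, 0], [0, 1], [0, 1]])
    # all-unstable reference level
    cols2, _ = refugia_predictors({"x": "unstable", "y": "unstable"}, ["x", "y"])
    np.testing.assert_array_equal(cols2, [[0, 0]])


# ---------------------------------------------------------------------------
# Eight fractions
# ---------------------------------------------------------------------------

def _random_inputs(seed, n=80):
    rng = np.random.default_rng(seed)
    E = rng.normal(size=(n, 2))
    S = rng.normal(size=n)
    R = (rng.random(size=(n, 2)) < 0.3).astype(float)
    y = rng.normal(size=n)
    return y, E, S, R


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_fractions_sum_to_one(seed):
    y, E, S, R = _random_inputs(seed)
    vp = eight_fractions(y, E, S, R)
    assert sum(vp.fractions.values()) == pytest.approx(1.0, abs=1e-9)
    assert set(vp.fractions) == set(FRACTION_NAMES)


def test_pure_fraction_recovered_from_noiseless_construction():
    rng = np.random.default_rng(4)
    n = 120
    E = rng.normal(size=n)
    # S and R orthogonal to E in-sample, so no chance shared fraction
    base = np.column_stack([np.ones(n), E])
    proj = lambda x: x - base @ np.linalg.lstsq(base, x, rcond=None)[0]
    S = proj(rng.normal(size=n))
    R = proj(rng.normal(size=n))
    y = 2.0 + 3.0 * E  # exactly a function of E
    vp = eight_fractions(y, E, S, R)
    assert vp.fractions["pure_env"] == pytest.approx(1.0, abs=1e-6)
    assert vp.fractions["residual"] == pytest.approx(0.0, abs=1e-6)
    for name in ("pure_space", "pure_refugia"):
        assert abs(vp.fractions[name]) < 1e-6


def test_pure_noise_leaves_residual_near_one():
    rng = np.random.default_rng(5)
    n = 4000
    vp = eight_fractions(rng.normal(size=n), rng.normal(size=n),
                         rng.normal(size=n), rng.normal(size=n))
    assert vp.fractions["residual"] == pytest.approx(1.0, abs=0.02)


def test_fractions_match_statsmodels_oracle():
    """pure_X = R2(full) - R2(other two) with every R2 recomputed by
    statsmodels OLS, independently of the numpy fitting route."""
    import statsmodels.api as sm

    y, E, S, R = _random_inputs(9, n=60)
    vp = eight_fractions(y, E, S, R)
    mats = {"E": E, "S": S.reshape(-1, 1), "R": R}

    def r2(*keys):
        X = sm.add_constant(np.column_stack([mats[k] for k in keys]))
        return sm.OLS(y, X).fit().rsquared

    r = {"E": r2("E"), "S": r2("S"), "R": r2("R"), "ES": r2("E", "S"),
         "ER": r2("E", "R"), "SR": r2("S", "R"), "ESR": r2("E", "S", "R")}
    for k, v in r.items():
        assert vp.r_squared[k] == pytest.approx(v, abs=1e-9)
    assert vp.fractions["pure_env"] == pytest.approx(r["ESR"] - r["SR"], abs=1e-9)
    assert vp.fractions["pure_space"] == pytest.approx(r["ESR"] - r["ER"], abs=1e-9)
    assert vp.fractions["pure_refugia"] == pytest.approx(r["ESR"] - r["ES"], abs=1e-9)
    triple = sum(r[k] for k in ("E", "S", "R")) - sum(r[k] for k in ("ES", "ER", "SR")) + r["ESR"]
    assert vp.fractions["env_space_refugia"] == pytest.approx(triple, abs=1e-9)


def test_collinear_and_undersized_inputs_error():
    y = np.arange(10, dtype=float)
    E = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])  # collinear in-set
    with pytest.raises(ValueError, match="collinear"):
        eight_fractions(y, E, np.ones(10) + np.arange(10), np.arange(10) % 2)
    with pytest.raises(ValueError, match="predictors"):
        eight_fractions(np.arange(4.0), np.arange(4.0), np.arange(4.0) ** 2,
                        np.array([0.0, 1, 0, 1]))
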