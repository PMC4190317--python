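"""Tip-label randomization null model and standardized effect sizes.

The null keeps the community matrix fixed (so species richness and all
compositional dissimilarities are unchanged by construction) and randomizes
only the identities of the species on the phylogeny: tip labels are permuted
uniformly over all tips of the assembled tree while topology and branch
lengths stay put.  For every site pair and every UniFrac component the
standardized effect size is

    SES = (observed - mean(null)) / sd(null)

with the sample standard deviation (ddof=1) over permutations.  |SES| > 1.96
is the conventional two-sided significance band: SES above it means the pair
is more phylogenetically dissimilar than its compositional dissimilarity
alone predicts, below -1.96 less so.  Pairs whose component is invariant
under relabeling (e.g. any pair on a star tree) have sd = 0 and are flagged
degenerate rather than given an SES.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import dendropy

from .io import CommunityMatrix
from .pbd import edge_tip_incidence

__all__ = ["shuffle_tip_labels", "ses_pbd", "classify_ses", "SES_THRESHOLD"]

SES_THRESHOLD = 1.96

_COMPONENTS = ("total", "turnover", "pd_diff")


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def shuffle_tip_labels(tree: dendropy.Tree,
                       rng: np.random.Generator | int | None = None) -> dendropy.Tree:
    """Return a copy of the tree with tip labels permuted uniformly at random.

    Topology and the multiset of branch lengths are untouched; only which
    label sits on which tip changes.
    """
    rng = _as_rng(rng)
    t = tree.clone(depth=1)
    t.migrate_taxon_namespace(dendropy.TaxonNamespace())
    leaves = list(t.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in leaves]
    perm = rng.permutation(len(labels))
    ns = dendropy.TaxonNamespace()
    for leaf, k in zip(leaves, perm):
        leaf.taxon = ns.require_taxon(labels[k])
    t.taxon_namespace = ns
    return t


def _component_values(shared: np.ndarray, pd_site: np.ndarray,
                      iu: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Stack of (total, turnover, pd_diff) over all pairs, shape (3, n_pairs)."""
    s = shared[iu]
    u1 = pd_site[iu[0]] - s
    u2 = pd_site[iu[1]] - s
    denom = s + u1 + u2
    total = (u1 + u2) / denom
    m = np.minimum(u1, u2)
    with np.errstate(invalid="ignore"):
        turnover = np.where(s + 2 * m > 0, 2 * m / (s + 2 * m), 0.0)
    return np.stack([total, turnover, total - turnover])


def ses_pbd(
    matrix: CommunityMatrix,
    tree: dendropy.Tree,
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
    tip_groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Observed UniFrac components, their tip-shuffle null, and SES per pair.

    ``tip_groups`` optionally restricts the permutation to within named groups
    of tips (e.g. per-region pools); by default labels are shuffled over the
    whole tip set.  Returns a long frame with one row per pair x component:
    ``site_i, site_j, component, observed, null_mean, null_sd, ses, category,
    n_perm``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = _as_rng(rng)
    tip_labels, lengths, inc = edge_tip_incidence(tree)
    n_tips = len(tip_labels)
    idx = {lab: k for k, lab in enumerate(tip_labels)}
    missing = [sp for sp in matrix.species if sp not in idx]
    if missing:
        raise ValueError(f"matrix species absent from tree: {missing}")
    sp_to_tip = np.array([idx[sp] for sp in matrix.species])
    occ_tips = np.zeros((matrix.n_sites, n_tips), dtype=bool)
    occ_tips[:, sp_to_tip] = matrix.occupancy.astype(bool)

    if tip_groups is not None:
        groups: dict[str, list[int]] = {}
        for lab, g in tip_groups.items():
            if lab not in idx:
                raise ValueError(f"tip_groups names unknown tip {lab!r}")
            groups.setdefault(g, []).append(idx[lab])
        ungrouped = sorted(set(range(n_tips)) - {i for v in groups.values() for i in v})
        if ungrouped:
            groups["__rest__"] = ungrouped
        group_idx = [np.array(v) for v in groups.values()]
    else:
        group_idx = [np.arange(n_tips)]

    iu = np.triu_indices(matrix.n_sites, 1)
    wlen = lengths[:, None]

    def components_for(occ: np.ndarray) -> np.ndarray:
        presence = (inc @ occ.T)
        pres_f = presence.astype(float)
        shared = (pres_f * wlen).T @ pres_f
        pd_site = (pres_f * wlen).sum(axis=0)
        return _component_values(shared, pd_site, iu)

    observed = components_for(occ_tips)
    acc = np.zeros_like(observed)
    acc2 = np.zeros_like(observed)
    for _ in range(n_perm):
        perm = np.arange(n_tips)
        for g in group_idx:
            perm[g] = g[rng.permutation(len(g))]
        occ_perm = np.empty_like(occ_tips)
        occ_perm[:, perm] = occ_tips
        vals = components_for(occ_perm)
        acc += vals
        acc2 += vals * vals
    null_mean = acc / n_perm
    if n_perm > 1:
        var = (acc2 - n_perm * null_mean**2) / (n_perm - 1)
        null_sd = np.sqrt(np.clip(var, 0.0, None))
    else:
        null_sd = np.zeros_like(null_mean)

    rows = []
    for k, comp in enumerate(_COMPONENTS):
        for p in range(len(iu[0])):
            sd = null_sd[k, p]
            degenerate = sd <= 1e-12
            ses = np.nan if degenerate else (observed[k, p] - null_mean[k, p]) / sd
            rows.append(
                {
                    "site_i": matrix.sites[iu[0][p]],
                    "site_j": matrix.sites[iu[1][p]],
                    "component": comp,
                    "observed": observed[k, p],
                    "null_mean": null_mean[k, p],
                    "null_sd": sd,
                    "ses": ses,
                    "category": classify_ses(ses),
                    "n_perm": n_perm,
                }
            )
    return pd.DataFrame(rows)


def classify_ses(value: float) -> str:
    """Bucket an SES against the +-1.96 band; NaN passes through as degenerate."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "degenerate"
    if value > SES_THRESHOLD:
        return "higher"
    if value < -SES_THRESHOLD:
        return "lower"
    return "null-consistent"
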