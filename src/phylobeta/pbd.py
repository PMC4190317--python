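"""Pairwise phylogenetic beta diversity: UniFrac and its decomposition.

Unweighted UniFrac is the branch-length analogue of Jaccard dissimilarity: on
the tree containing both communities, every branch is classified as shared
(tips of both communities descend from it), unique to one community, or
irrelevant (no tips of either).  With shared length ``s`` and unique lengths
``u1, u2``::

    UniFrac       = (u1 + u2) / (s + u1 + u2)
    UniFrac_Turn  = 2*min(u1, u2) / (s + 2*min(u1, u2))
    UniFrac_PD    = UniFrac - UniFrac_Turn

i.e. the same additive turnover/nestedness decomposition applied to branch
lengths instead of species counts: the turnover term captures replacement of
unique lineages net of phylogenetic-diversity differences, and the PD term
captures dissimilarity caused purely by one community spanning more
evolutionary history than the other.  The root edge (if the Newick carries
one) is excluded from all components, since it is shared by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import dendropy
import numpy as np
import pandas as pd

from .io import CommunityMatrix

__all__ = [
    "BranchComponents",
    "PBDPartition",
    "edge_tip_incidence",
    "branch_components",
    "unifrac_partition",
    "faith_pd",
    "pairwise_pbd",
]


@dataclass(frozen=True)
class BranchComponents:
    """Branch-length overlap of two communities on a pooled tree."""

    shared_bl: float
    unique_bl_1: float
    unique_bl_2: float

    def __post_init__(self) -> None:
        if min(self.shared_bl, self.unique_bl_1, self.unique_bl_2) < 0:
            raise ValueError("branch components must be non-negative")


@dataclass(frozen=True)
class PBDPartition:
    total: float
    turnover: float
    pd_diff: float


def edge_tip_incidence(tree: dendropy.Tree) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Edge/tip incidence of a tree.

    Returns ``(tip_labels, lengths, incidence)`` where ``lengths`` is the
    branch length of every edge except the root edge, and ``incidence`` is a
    boolean (n_edges, n_tips) matrix with entry (e, t) true iff tip t descends
    from (or is) the child node of edge e.  This is the whole computational
    substrate of UniFrac: any community's branch profile is an OR over its
    tips' columns.
    """
    leaves = list(tree.leaf_node_iter())
    tip_labels = [leaf.taxon.label for leaf in leaves]
    tip_index = {id(leaf): k for k, leaf in enumerate(leaves)}
    lengths: list[float] = []
    rows: list[np.ndarray] = []
    # postorder: children processed before parents, so descendant tip sets
    # can be accumulated bottom-up
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            mask = np.zeros(len(leaves), dtype=bool)
            mask[tip_index[id(node)]] = True
        else:
            mask = np.zeros(len(leaves), dtype=bool)
            for ch in node.child_nodes():
                mask |= below[id(ch)]
        below[id(node)] = mask
        if node.parent_node is not None:  # exclude the root edge
            lengths.append(node.edge.length or 0.0)
            rows.append(mask)
    return tip_labels, np.asarray(lengths, dtype=float), np.asarray(rows, dtype=bool)


def branch_components(tree: dendropy.Tree, set1, set2) -> BranchComponents:
    """Shared/unique branch lengths for two tip sets on one tree."""
    tip_labels, lengths, inc = edge_tip_incidence(tree)
    idx = {lab: k for k, lab in enumerate(tip_labels)}
    for s in (set1, set2):
        unknown = [x for x in s if x not in idx]
        if unknown:
            raise ValueError(f"unknown tip label(s): {unknown}")
        if not s:
            raise ValueError("tip sets must be non-empty")
    m1 = np.zeros(len(tip_labels), dtype=bool)
    m2 = np.zeros(len(tip_labels), dtype=bool)
    m1[[idx[x] for x in set1]] = True
    m2[[idx[x] for x in set2]] = True
    in1 = inc[:, m1].any(axis=1)
    in2 = inc[:, m2].any(axis=1)
    return BranchComponents(
        shared_bl=float(lengths[in1 & in2].sum()),
        unique_bl_1=float(lengths[in1 & ~in2].sum()),
        unique_bl_2=float(lengths[~in1 & in2].sum()),
    )


def unifrac_partition(bc: BranchComponents) -> PBDPartition:
    """Decompose branch components into UniFrac and its turnover / PD terms."""
    s, u1, u2 = bc.shared_bl, bc.unique_bl_1, bc.unique_bl_2
    if s + u1 + u2 <= 0:
        raise ValueError("all branch components zero: UniFrac undefined")
    total = (u1 + u2) / (s + u1 + u2)
    m = min(u1, u2)
    turnover = 2 * m / (s + 2 * m) if (s + 2 * m) > 0 else 0.0
    return PBDPartition(total=total, turnover=turnover, pd_diff=total - turnover)


def faith_pd(tree: dendropy.Tree, tips) -> float:
    """Faith's phylogenetic diversity: summed branch length connecting the tip
    set to the root (root edge excluded)."""
    bc = branch_components(tree, tips, tips)
    return bc.shared_bl


def _site_edge_presence(inc: np.ndarray, occupancy: np.ndarray,
                        species_to_tip: np.ndarray) -> np.ndarray:
    """(n_edges, n_sites) boolean: edge subtends >=1 species present at site."""
    # occupancy: sites x species; columns mapped into tip order
    occ_tips = np.zeros((occupancy.shape[0], inc.shape[1]), dtype=bool)
    occ_tips[:, species_to_tip] = occupancy.astype(bool)
    return inc @ occ_tips.T  # boolean matmul -> any()


def pairwise_pbd(matrix: CommunityMatrix, tree: dendropy.Tree) -> pd.DataFrame:
    """All-pairs UniFrac partition for a community matrix on an assembled tree.

    Tree tips must cover the matrix species.  Returns one row per unordered
    site pair in lower-triangle order, with branch components and the three
    partition values.
    """
    tip_labels, lengths, inc = edge_tip_incidence(tree)
    idx = {lab: k for k, lab in enumerate(tip_labels)}
    missing = [sp for sp in matrix.species if sp not in idx]
    if missing:
        raise ValueError(f"matrix species absent from tree: {missing}")
    species_to_tip = np.array([idx[sp] for sp in matrix.species])
    presence = _site_edge_presence(inc, matrix.occupancy, species_to_tip)
    pres_f = presence.astype(float)
    weighted = pres_f * lengths[:, None]
    shared = weighted.T @ pres_f          # (sites x sites) shared branch length
    pd_site = (pres_f * lengths[:, None]).sum(axis=0)
    rows = []
    for i, j in combinations(range(matrix.n_sites), 2):
        s = shared[i, j]
        bc = BranchComponents(
            shared_bl=float(s),
            unique_bl_1=float(pd_site[i] - s),
            unique_bl_2=float(pd_site[j] - s),
        )
        part = unifrac_partition(bc)
        rows.append(
            {
                "site_i": matrix.sites[i],
                "site_j": matrix.sites[j],
                "shared_bl": bc.shared_bl,
                "unique_bl_1": bc.unique_bl_1,
                "unique_bl_2": bc.unique_bl_2,
                "unifrac": part.total,
                "unifrac_turn": part.turnover,
                "unifrac_pd": part.pd_diff,
            }
        )
    return pd.DataFrame(rows)
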