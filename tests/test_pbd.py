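import subprocess

import numpy as np
import pytest

from phylobeta.cbd import pairwise_cbd
from phylobeta.io import CommunityMatrix
from phylobeta.pbd import (
    BranchComponents,
    branch_components,
    faith_pd,
    pairwise_pbd,
    unifrac_partition,
)
from phylobeta.phylogeny import parse_newick

# fixture set for the exhaustive-enumeration oracle: all <= 6 tips
SMALL_TREES = [
    "((A:1,B:1):1,(C:1,D:1):1);",
    "((A:1,B:1):2,((C:0.5,D:0.5):1.5,(E:1.2,F:1.2):0.8):1);",
    "(A:3,(B:2,(C:1,D:1):1):1);",  # ladder
    "(A:1,B:1,C:1,D:1,E:1);",      # star
    "((A:0.3,B:0.3):0.7,C:1.0);",
]


def oracle_components(newick, set1, set2):
    """Edge enumeration built from per-tip root paths, independent of the
    postorder incidence accumulation used by the implementation."""
    tree = parse_newick(newick)
    paths = {}
    for leaf in tree.leaf_node_iter():
        edges = []
        node = leaf
        while node.parent_node is not None:
            edges.append(node)
            node = node.parent_node
        paths[leaf.taxon.label] = edges
    all_edges = {id(n): n for p in paths.values() for n in p}
    e1 = {id(n) for t in set1 for n in paths[t]}
    e2 = {id(n) for t in set2 for n in paths[t]}
    length = lambda ids: sum(all_edges[i].edge.length or 0.0 for i in ids)
    return length(e1 & e2), length(e1 - e2), length(e2 - e1)


def test_branch_components_hand_examples(four_taxon_tree):
    bc = branch_components(four_taxon_tree, ["A", "B"], ["C", "D"])
    assert (bc.shared_bl, bc.unique_bl_1, bc.unique_bl_2) == (0, 3, 3)
    bc = branch_components(four_taxon_tree, ["A", "B"], ["A", "C"])
    assert (bc.shared_bl, bc.unique_bl_1, bc.unique_bl_2) == (2, 1, 2)
    bc = branch_components(four_taxon_tree, ["A", "C"], ["A", "C"])
    assert (bc.unique_bl_1, bc.unique_bl_2) == (0, 0)


def test_branch_components_unknown_tip(four_taxon_tree):
    with pytest.raises(ValueError, match="unknown"):
        branch_components(four_taxon_tree, ["A", "Z"], ["C"])


def test_branch_components_match_enumeration_oracle():
    """Implementation agrees with root-path edge enumeration on every subset
    pair of every fixture tree (<= 6 tips)."""
    from itertools import combinations

    for nwk in SMALL_TREES:
        tree = parse_newick(nwk)
        tips = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
        subsets = [list(c) for r in (1, 2, 3) for c in combinations(tips, r)]
        for s1 in subsets[:12]:
            for s2 in subsets[:12]:
                bc = branch_components(tree, s1, s2)
                exp = oracle_components(nwk, s1, s2)
                assert (bc.shared_bl, bc.unique_bl_1, bc.unique_bl_2) == pytest.approx(exp)


@pytest.mark.parametrize(
    "suu,expected",
    [
        ((2, 1, 2), (0.6, 0.5, 0.1)),
        ((0, 3, 3), (1.0, 1.0, 0.0)),
        ((5, 0, 0), (0.0, 0.0, 0.0)),
    ],
)
def test_unifrac_partition_worked_examples(suu, expected):
    part = unifrac_partition(BranchComponents(*suu))
    assert (part.total, part.turnover, part.pd_diff) == pytest.approx(expected)
    assert part.turnover + part.pd_diff == pytest.approx(part.total, abs=1e-12)


def test_unifrac_partition_all_zero_raises():
    with pytest.raises(ValueError):
        unifrac_partition(BranchComponents(0, 0, 0))


def test_faith_pd(four_taxon_tree):
    assert faith_pd(four_taxon_tree, ["A", "B"]) == pytest.approx(3.0)
    assert faith_pd(four_taxon_tree, ["A"]) == pytest.approx(2.0)
    assert faith_pd(four_taxon_tree, list("ABCD")) == pytest.approx(6.0)


def test_pd_difference_consistency(four_taxon_tree):
    """shared + unique_i equals Faith PD of community i on the pooled tree."""
    bc = branch_components(four_taxon_tree, ["A", "B"], ["A", "C"])
    assert bc.shared_bl + bc.unique_bl_1 == pytest.approx(faith_pd(four_taxon_tree, ["A", "B"]))
    assert bc.shared_bl + bc.unique_bl_2 == pytest.approx(faith_pd(four_taxon_tree, ["A", "C"]))


def test_star_tree_reduces_to_cbd(small_matrix):
    """With unit pendant branches and no internal structure, every UniFrac
    component equals its compositional counterpart."""
    star = parse_newick("(A:1,B:1,C:1,D:1);")
    pbd = pairwise_pbd(small_matrix, star)
    cbd = pairwise_cbd(small_matrix)
    np.testing.assert_allclose(pbd["unifrac"], cbd["beta_jac"], atol=1e-12)
    np.testing.assert_allclose(pbd["unifrac_turn"], cbd["beta_jtu"], atol=1e-12)
    np.testing.assert_allclose(pbd["unifrac_pd"], cbd["beta_jne"], atol=1e-12)


def test_unique_branch_monotone_under_added_tip(four_taxon_tree):
    bc0 = branch_components(four_taxon_tree, ["A"], ["C"])
    bc1 = branch_components(four_taxon_tree, ["A", "B"], ["C"])
    assert bc1.unique_bl_1 >= bc0.unique_bl_1


def test_pairwise_pbd_row_count_and_identity(bundle, assembled_tree):
    df = pairwise_pbd(bundle.matrix, assembled_tree)
    n = bundle.matrix.n_sites
    assert len(df) == n * (n - 1) // 2
    assert ((df[["unifrac", "unifrac_turn", "unifrac_pd"]] >= -1e-12).all().all())
    np.testing.assert_allclose(df["unifrac_turn"] + df["unifrac_pd"], df["unifrac"],
                               atol=1e-12)


def test_unifrac_against_r_picante(tmp_path):
    """Independent oracle: picante's unifrac on a 6-tip tree, 3 communities."""
    nwk = "((A:1,B:1):2,((C:0.5,D:0.5):1.5,(E:1.2,F:1.2):0.8):1);"
    m = CommunityMatrix(
        sites=["s1", "s2", "s3"],
        species=list("ABCDEF"),
        occupancy=np.array([
            [1, 1, 1, 0, 0, 0],
            [0, 0, 1, 1, 1, 0],
            [1, 0, 0, 0, 1, 1],
        ]),
    )
    csv = tmp_path / "comm.csv"
    m.to_dataframe().to_csv(csv, index_label="site")
    script = tmp_path / "uf.R"
    script.write_text(
        "suppressMessages(library(picante))\n"
        f'tree <- read.tree(text="{nwk}")\n'
        f'comm <- as.matrix(read.csv("{csv}", row.names=1))\n'
        'cat(sprintf("%.12f", as.vector(unifrac(comm, tree))), sep="\\n")\n'
    )
    out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True,
                         check=True)
    expected = [float(x) for x in out.stdout.split()]
    got = pairwise_pbd(m, parse_newick(nwk))["unifrac"].tolist()
    assert got == pytest.approx(expected, abs=1e-10)
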