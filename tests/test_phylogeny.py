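import pytest

from phylobeta.phylogeny import (
    GraftError,
    GraftRule,
    assemble_community_tree,
    graft_by_rule,
    graft_within_genus,
    is_ultrametric,
    leaf_labels,
    parse_newick,
    prune_to_species,
    read_graft_rules,
    root_tip_distances,
    write_graft_rules,
    write_newick,
    read_newick,
)

MASTER = "((A_x:1,B_z:1):1,(C_p:1,D_q:1):1);"


def test_prune_keeps_path_lengths():
    t = prune_to_species(parse_newick(MASTER), ["A_x", "B_z", "C_p"])
    assert leaf_labels(t) == {"A_x", "B_z", "C_p"}
    d = root_tip_distances(t)
    # pendant of C_p absorbs the suppressed internal branch: depth conserved
    assert d == pytest.approx({"A_x": 2.0, "B_z": 2.0, "C_p": 2.0})


def test_prune_all_tips_is_identity():
    master = parse_newick(MASTER)
    t = prune_to_species(master, sorted(leaf_labels(master)))
    assert root_tip_distances(t) == pytest.approx(root_tip_distances(master))


def test_prune_needs_two_matches():
    with pytest.raises(ValueError, match="fewer than two"):
        prune_to_species(parse_newick(MASTER), ["A_x", "nope"])


def test_graft_within_genus_polytomy():
    t = parse_newick("((A_x:1,A_y:1):1,B_z:2);")
    out = graft_within_genus(t, "A_w")
    assert leaf_labels(out) == {"A_x", "A_y", "A_w", "B_z"}
    d = root_tip_distances(out)
    assert list(d.values()) == pytest.approx([2.0] * 4)  # ultrametric preserved
    # three-way polytomy at the genus crown
    crown = [n for n in out.preorder_internal_node_iter()
             if {lf.taxon.label for lf in n.leaf_iter()} == {"A_x", "A_y", "A_w"}]
    assert len(crown) == 1 and len(crown[0].child_nodes()) == 3


def test_graft_single_congener_midpoint():
    t = parse_newick("((A_x:1,A_y:1):1,B_z:2);")
    out = graft_within_genus(t, "B_w")
    # congener pendant (length 2) split at its midpoint: both B tips now have
    # pendant length 1, tree still ultrametric at depth 2
    pendants = {lf.taxon.label: lf.edge.length for lf in out.leaf_node_iter()}
    assert pendants["B_w"] == pytest.approx(1.0)
    assert pendants["B_z"] == pytest.approx(1.0)
    d = root_tip_distances(out)
    assert list(d.values()) == pytest.approx([2.0] * 4)


def test_graft_duplicate_or_orphan_errors():
    t = parse_newick("((A_x:1,A_y:1):1,B_z:2);")
    with pytest.raises(GraftError, match="already"):
        graft_within_genus(t, "A_x")
    with pytest.raises(GraftError, match="Z"):
        graft_within_genus(t, "Z_new")


def test_graft_by_rule_sister_to_clade():
    t = parse_newick(MASTER)
    rule = GraftRule(species="E_n", anchor="C", fraction=0.5)
    out = graft_by_rule(t, "E_n", rule)
    d = root_tip_distances(out)
    # anchor clade (C_p, D_q) crown at depth 1, stem length 1: attach at 1.5
    assert d["E_n"] == pytest.approx(2.0)
    assert is_ultrametric(out)
    # pre-existing tip-to-tip paths unchanged
    before = root_tip_distances(t)
    for tip in before:
        assert d[tip] == pytest.approx(before[tip])


def test_graft_rule_degenerate_fraction_rejected():
    with pytest.raises(ValueError):
        GraftRule(species="E_n", anchor="C", fraction=0.0)
    with pytest.raises(ValueError):
        GraftRule(species="E_n", anchor="C", fraction=1.0)


def test_graft_rule_unresolvable_anchor():
    t = parse_newick(MASTER)
    with pytest.raises(GraftError, match="resolves to no node"):
        graft_by_rule(t, "E_n", GraftRule(species="E_n", anchor="XXX"))


def test_assemble_identity_when_all_present():
    master = parse_newick(MASTER)
    t = assemble_community_tree(master, ["A_x", "C_p", "D_q"])
    assert leaf_labels(t) == {"A_x", "C_p", "D_q"}


def test_assemble_grafts_congeners_and_rules():
    master = parse_newick(MASTER)
    rules = {"E_n": GraftRule(species="E_n", anchor="C", fraction=0.5)}
    species = ["A_x", "A_y", "B_z", "C_p", "C_q2", "D_q", "E_n"]
    t = assemble_community_tree(master, species, rules)
    assert leaf_labels(t) == set(species)
    assert is_ultrametric(t)


def test_assemble_unplaceable_errors():
    master = parse_newick(MASTER)
    with pytest.raises(GraftError, match="Z_only"):
        assemble_community_tree(master, ["A_x", "B_z", "Z_only"], {})


def test_assemble_is_deterministic(bundle):
    t1 = assemble_community_tree(bundle.master_tree, bundle.matrix.species,
                                 bundle.graft_rules)
    t2 = assemble_community_tree(bundle.master_tree, bundle.matrix.species,
                                 bundle.graft_rules)
    assert t1.as_string(schema="newick") == t2.as_string(schema="newick")
    assert leaf_labels(t1) == set(bundle.matrix.species)
    assert is_ultrametric(t1, tol=1e-8)


def test_grafting_preserves_existing_pairwise_paths(bundle, assembled_tree):
    """Pruning-only distances between two master species survive grafting."""
    from dendropy import PhylogeneticDistanceMatrix

    keep = sorted(set(bundle.matrix.species) & leaf_labels(bundle.master_tree))[:10]
    pruned = prune_to_species(bundle.master_tree, keep)
    pdm_small = PhylogeneticDistanceMatrix.from_tree(pruned)
    pdm_full = PhylogeneticDistanceMatrix.from_tree(assembled_tree)

    def dist(pdm, tree_ns, a, b):
        ta = tree_ns.get_taxon(a)
        tb = tree_ns.get_taxon(b)
        return pdm.patristic_distance(ta, tb)

    for a, b in [(keep[0], keep[1]), (keep[2], keep[5]), (keep[3], keep[9])]:
        d1 = dist(pdm_small, pruned.taxon_namespace, a, b)
        d2 = dist(pdm_full, assembled_tree.taxon_namespace, a, b)
        assert d1 == pytest.approx(d2, abs=1e-9)


def test_rules_csv_roundtrip(tmp_path):
    rules = {
        "E_n": GraftRule(species="E_n", anchor="C", mode="sister_to_clade", fraction=0.25),
        "F_m": GraftRule(species="F_m", anchor="A", mode="within_genus_polytomy"),
    }
    p = tmp_path / "rules.csv"
    write_graft_rules(rules, p)
    assert read_graft_rules(p) == rules


def test_newick_roundtrip(tmp_path, bundle):
    p = tmp_path / "t.nwk"
    write_newick(bundle.master_tree, p)
    t = read_newick(p)
    assert leaf_labels(t) == leaf_labels(bundle.master_tree)
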