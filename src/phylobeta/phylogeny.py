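"""Assembly of the community phylogeny from a master dated tree.

A regional occurrence matrix rarely matches the tip set of any published
supertree, so the analysis tree is built in two steps: prune the master tree
to the observed species, then graft species missing from it.  A species whose
genus is already in the tree is attached at the most recent common ancestor of
its congeners, creating a within-genus polytomy; a species whose genus is
absent is placed by an explicit rule naming an anchor clade and a stem
position.  All grafts preserve ultrametricity: a grafted tip's pendant branch
equals the depth (time before present) of its attachment point, so root-to-tip
distances are unchanged.

Trees are dendropy objects throughout; depths and MRCAs are computed directly
on the node structure (no cached bipartitions, which grafting would stale).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import dendropy

__all__ = [
    "GraftRule",
    "GraftError",
    "read_newick",
    "write_newick",
    "read_graft_rules",
    "write_graft_rules",
    "leaf_labels",
    "node_depth",
    "root_tip_distances",
    "is_ultrametric",
    "prune_to_species",
    "graft_within_genus",
    "graft_by_rule",
    "assemble_community_tree",
]


class GraftError(ValueError):
    """A species could not be placed on the tree."""


@dataclass(frozen=True)
class GraftRule:
    """Placement instruction for a species absent from the master tree.

    ``anchor`` names a tip, an internal node label, or a genus; ``mode`` is
    ``sister_to_clade`` (insert on the anchor clade's stem at ``fraction`` of
    its length, measured rootward from the clade's crown) or
    ``within_genus_polytomy`` (attach at the anchor clade's crown node).
    """

    species: str
    anchor: str
    mode: str = "sister_to_clade"
    fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("sister_to_clade", "within_genus_polytomy"):
            raise ValueError(f"unknown graft mode {self.mode!r}")
        if self.mode == "sister_to_clade" and not (0.0 < self.fraction < 1.0):
            raise ValueError("stem fraction must be strictly between 0 and 1")


def genus_of(label: str) -> str:
    """Genus token of a Genus_epithet tip label."""
    return label.split("_", 1)[0]


# ---------------------------------------------------------------------------
# Newick + rules I/O
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def parse_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def read_graft_rules(path: str | Path) -> dict[str, GraftRule]:
    """Load graft rules from CSV with columns species, anchor, mode, fraction."""
    rules: dict[str, GraftRule] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rules[row["species"]] = GraftRule(
                species=row["species"],
                anchor=row["anchor"],
                mode=row.get("mode") or "sister_to_clade",
                fraction=float(row.get("fraction") or 0.5),
            )
    return rules


def write_graft_rules(rules: dict[str, GraftRule], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["species", "anchor", "mode", "fraction"])
        for r in rules.values():
            w.writerow([r.species, r.anchor, r.mode, r.fraction])


# ---------------------------------------------------------------------------
# Structure helpers
# ---------------------------------------------------------------------------

def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    t = tree.clone(depth=1)
    t.migrate_taxon_namespace(dendropy.TaxonNamespace())
    return t


def node_depth(node: dendropy.Node) -> float:
    """Maximum summed branch length from ``node`` down to a descendant leaf
    (equals time before present on an ultrametric tree)."""
    best = 0.0
    stack = [(node, 0.0)]
    while stack:
        n, d = stack.pop()
        if n.is_leaf():
            best = max(best, d)
        for ch in n.child_nodes():
            stack.append((ch, d + (ch.edge.length or 0.0)))
    return best


def root_tip_distances(tree: dendropy.Tree) -> dict[str, float]:
    out: dict[str, float] = {}
    stack = [(tree.seed_node, 0.0)]
    while stack:
        n, d = stack.pop()
        if n.is_leaf():
            out[n.taxon.label] = d
        for ch in n.child_nodes():
            stack.append((ch, d + (ch.edge.length or 0.0)))
    return out


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-9) -> bool:
    d = list(root_tip_distances(tree).values())
    return max(d) - min(d) < tol


def _mrca(tree: dendropy.Tree, leaves: list[dendropy.Node]) -> dendropy.Node:
    if len(leaves) == 1:
        return leaves[0]
    paths = []
    for leaf in leaves:
        path = []
        n = leaf
        while n is not None:
            path.append(n)
            n = n.parent_node
        paths.append(path[::-1])  # root first
    mrca = paths[0][0]
    for depth in range(min(len(p) for p in paths)):
        node = paths[0][depth]
        if all(p[depth] is node for p in paths):
            mrca = node
        else:
            break
    return mrca


def _leaves_by_genus(tree: dendropy.Tree, genus: str) -> list[dendropy.Node]:
    return [leaf for leaf in tree.leaf_node_iter()
            if genus_of(leaf.taxon.label) == genus]


def _add_tip(tree: dendropy.Tree, parent: dendropy.Node, label: str,
             edge_length: float) -> dendropy.Node:
    taxon = tree.taxon_namespace.require_taxon(label)
    return parent.new_child(taxon=taxon, edge_length=edge_length)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def prune_to_species(master: dendropy.Tree, species: list[str]) -> dendropy.Tree:
    """Prune the master tree down to the requested species.

    Degree-2 nodes left by the pruning are suppressed with branch lengths
    summed, so path lengths among retained tips are conserved.  Requires at
    least two of the requested species to be present in the master tree.
    """
    present = sorted(set(species) & leaf_labels(master))
    if len(present) < 2:
        missing = sorted(set(species) - leaf_labels(master))
        raise ValueError(
            f"fewer than two requested species found in master tree; "
            f"missing: {missing}"
        )
    t = _clone(master)
    keep = set(present)
    t.retain_taxa_with_labels(present)
    # retain_taxa suppresses unifurcations; drop any residual root edge length
    # left by collapsing the old root path.
    assert leaf_labels(t) == keep
    return t


def graft_within_genus(tree: dendropy.Tree, species: str) -> dendropy.Tree:
    """Attach a species at the crown of its congeners, as a polytomy.

    With two or more congeneric tips the new tip joins their MRCA; with a
    single congener that tip's pendant branch is split at its midpoint and the
    new tip attached there.  Pendant length equals the attachment depth, so an
    ultrametric tree stays ultrametric.
    """
    t = _clone(tree)
    if species in leaf_labels(t):
        raise GraftError(f"species {species!r} already a tip")
    congeners = _leaves_by_genus(t, genus_of(species))
    if not congeners:
        raise GraftError(f"no congeneric tip for genus {genus_of(species)!r}")
    if len(congeners) >= 2:
        attach = _mrca(t, congeners)
        depth = node_depth(attach)
        _add_tip(t, attach, species, depth)
    else:
        tip = congeners[0]
        pendant = tip.edge.length or 0.0
        if pendant <= 0:
            raise GraftError(
                f"single congener {tip.taxon.label!r} has zero pendant branch"
            )
        parent = tip.parent_node
        parent.remove_child(tip)
        mid = parent.new_child(edge_length=pendant / 2.0)
        tip.edge.length = pendant / 2.0
        mid.add_child(tip)
        _add_tip(t, mid, species, pendant / 2.0)
    return t


def _resolve_anchor(tree: dendropy.Tree, anchor: str) -> dendropy.Node:
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label == anchor:
            return leaf
    for node in tree.preorder_internal_node_iter():
        if node.label == anchor:
            return node
    congeners = _leaves_by_genus(tree, anchor)
    if congeners:
        return _mrca(tree, congeners)
    raise GraftError(f"anchor {anchor!r} resolves to no node of the tree")


def graft_by_rule(tree: dendropy.Tree, species: str, rule: GraftRule) -> dendropy.Tree:
    """Place a species by an explicit anchor rule.

    ``sister_to_clade`` inserts a new node on the anchor clade's stem branch at
    ``rule.fraction`` of its length above the clade's crown, and hangs the new
    tip there; ``within_genus_polytomy`` attaches at the anchor crown itself.
    """
    t = _clone(tree)
    if species in leaf_labels(t):
        raise GraftError(f"species {species!r} already a tip")
    anchor = _resolve_anchor(t, rule.anchor)
    if rule.mode == "within_genus_polytomy":
        if anchor.is_leaf():
            raise GraftError(
                f"anchor {rule.anchor!r} is a single tip; polytomy mode needs a clade"
            )
        _add_tip(t, anchor, species, node_depth(anchor))
        return t
    if anchor.parent_node is None:
        raise GraftError(f"anchor {rule.anchor!r} is the root; it has no stem branch")
    stem = anchor.edge.length or 0.0
    if stem <= 0:
        raise GraftError(f"anchor {rule.anchor!r} has a zero-length stem branch")
    attach_depth = node_depth(anchor) + rule.fraction * stem
    parent = anchor.parent_node
    parent.remove_child(anchor)
    mid = parent.new_child(edge_length=(1.0 - rule.fraction) * stem)
    anchor.edge.length = rule.fraction * stem
    mid.add_child(anchor)
    _add_tip(t, mid, species, attach_depth)
    return t


def assemble_community_tree(
    master: dendropy.Tree,
    species: list[str],
    rules: dict[str, GraftRule] | None = None,
) -> dendropy.Tree:
    """Build the analysis tree: prune the master to the observed species, then
    graft every species the master lacks.

    Within-genus grafts are attempted first (in sorted species order, for
    determinism); species without congeners fall back to their
    :class:`GraftRule`.  Passes repeat until no further species can be placed,
    so a rule-grafted species can itself anchor later within-genus grafts.
    Any species left unplaceable raises :class:`GraftError` with the full list.
    """
    rules = rules or {}
    wanted = sorted(set(species))
    master_tips = leaf_labels(master)
    tree = prune_to_species(master, wanted)
    remaining = [sp for sp in wanted if sp not in master_tips]
    while remaining:
        progress = False
        for sp in list(remaining):
            tips = leaf_labels(tree)
            try:
                if _leaves_by_genus(tree, genus_of(sp)):
                    tree = graft_within_genus(tree, sp)
                elif sp in rules:
                    tree = graft_by_rule(tree, sp, rules[sp])
                else:
                    continue
            except GraftError:
                continue
            assert leaf_labels(tree) == tips | {sp}
            remaining.remove(sp)
            progress = True
        if not progress:
            raise GraftError(
                f"could not place species (no congener, no usable rule): {remaining}"
            )
    assert leaf_labels(tree) == set(wanted)
    return tree
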