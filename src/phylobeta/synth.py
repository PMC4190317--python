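"""Synthetic study generator: trees, climate grids, sites and communities.

Every pipeline stage is testable without external downloads because this
module fabricates all four inputs with known structure:

* a pure-birth ultrametric tree whose tips carry synthetic genus labels
  assigned to monophyletic blocks (so within-genus grafting is exercisable);
* three annual-precipitation grids (present plus two glacial-maximum
  analogues) whose top-decile sets intersect exactly in a designed patch —
  the ground-truth stable region;
* a site table with 14 stable-region and 30 unstable-region sites and twelve
  internally consistent climate/topography variables;
* an occurrence matrix built from two partially overlapping regional pools
  (155 species each, 71 shared by default, mirroring a two-region study of
  ~239 species): stable-region sites draw clade-structured endemics whose
  genera have local range centroids (occupancy decaying with distance, hence
  high turnover among stable sites), while unstable-region sites hold nested,
  richness-ordered subsets of a broad-ranged pool (hence low turnover and
  high nestedness within the unstable region).

The generator also withholds a configurable set of species from the master
tree (congeners of retained tips, plus whole genera with graft rules) so the
grafting stage runs on every synthetic bundle.  All randomness flows from the
single mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .io import (
    CommunityMatrix,
    Grid,
    SiteRecord,
    write_ascii_grid,
    write_community_matrix,
    write_site_table,
)
from .phylogeny import (
    GraftRule,
    genus_of,
    leaf_labels,
    prune_to_species,
    write_graft_rules,
    write_newick,
)
from .stability import StabilityMask

__all__ = ["ScenarioConfig", "Bundle", "simulate_tree", "simulate_landscape",
           "simulate_communities", "simulate_bundle", "write_bundle"]


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic study.

    Defaults encode the two-region design this package targets: 14 stable and
    30 unstable sites, two regional pools of 155 species overlapping by
    71/155, a 20x20 quarter-degree landscape with a 24-cell coastal stability
    patch inside the top decile of all three precipitation layers.
    """

    seed: int
    n_stable_sites: int = 14
    n_unstable_sites: int = 30
    n_species_pool: int = 155          # species per regional pool
    overlap_fraction: float = 71 / 155  # fraction of a pool shared between regions
    birth_rate: float = 1.0            # pure-birth speciation rate (per lineage)
    distance_decay: float = 1.2        # per-degree occupancy decay, endemic genera
    shared_decay: float = 0.3          # per-degree decay for broad-ranged species
    nestedness_strength: float = 0.8   # P(inclusion follows the nested ranking)
    grid_shape: tuple[int, int] = (20, 20)
    patch_rows: tuple[int, int] = (6, 14)   # array-row slice of the stable patch
    patch_cols: tuple[int, int] = (15, 18)  # array-col slice of the stable patch
    quantile_fraction: float = 0.10
    xll: float = -50.0
    yll: float = -28.0
    cellsize: float = 0.25
    max_genus_size: int = 6
    n_extra_master_tips: int = 40      # master-only tips, removed by pruning
    n_missing_congeners: int = 6       # matrix species absent from master, genus present
    n_missing_genera: int = 1          # whole matrix genera absent from master

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("overlap_fraction", "nestedness_strength", "quantile_fraction"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_stable_sites", "n_unstable_sites", "n_species_pool"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")

    @property
    def n_shared(self) -> int:
        return int(round(self.overlap_fraction * self.n_species_pool))

    @property
    def n_matrix_species(self) -> int:
        return 2 * self.n_species_pool - self.n_shared


@dataclass
class Bundle:
    """One fully simulated study, with ground truth alongside the inputs."""

    config: ScenarioConfig
    tree: dendropy.Tree            # full truth tree (matrix species + extras)
    master_tree: dendropy.Tree     # truth tree minus withheld tips
    graft_rules: dict[str, GraftRule]
    grids: dict[str, Grid]         # current, ccsm3, miroc
    truth_mask: StabilityMask
    matrix: CommunityMatrix
    site_records: list[SiteRecord]
    truth_labels: dict[str, str]   # site_id -> stable/unstable
    pools: dict[str, list[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------

def simulate_tree(n_species: int, birth_rate: float = 1.0,
                  seed: int | np.random.Generator = 0,
                  max_genus_size: int = 6) -> dendropy.Tree:
    """Pure-birth (Yule) ultrametric tree with genus labels in clade blocks.

    Lineage splits occur at exponential waiting times with total rate
    ``birth_rate * k`` over ``k`` extant lineages; simulation stops when
    ``n_species`` lineages exist and runs one further waiting time so the
    youngest split is strictly internal.  Tips are then grouped into maximal
    clades of at most ``max_genus_size`` tips, each labeled as one genus
    (``G0001_sp001`` ...), so genera are monophyletic by construction.
    """
    if n_species < 2:
        raise ValueError("need at least two species")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tree = dendropy.Tree()
    tree.is_rooted = True
    root = tree.seed_node
    t = 0.0
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        active.append((root.new_child(edge_length=0.0), 0.0))
    while len(active) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        k = int(rng.integers(len(active)))
        node, born = active.pop(k)
        node.edge.length = t - born
        for _ in range(2):
            active.append((node.new_child(edge_length=0.0), t))
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for node, born in active:
        node.edge.length = t - born

    # genus blocks: maximal clades with <= max_genus_size tips
    n_below: dict[int, int] = {}
    for node in tree.postorder_node_iter():
        n_below[id(node)] = 1 if node.is_leaf() else sum(
            n_below[id(c)] for c in node.child_nodes())
    blocks: list[list[dendropy.Node]] = []
    stack = [root]
    while stack:
        node = stack.pop()
        if n_below[id(node)] <= max_genus_size:
            blocks.append(list(node.leaf_iter()))
        else:
            stack.extend(node.child_nodes())
    ns = dendropy.TaxonNamespace()
    for g, leaves in enumerate(sorted(blocks, key=lambda b: -len(b)), start=1):
        for s, leaf in enumerate(leaves, start=1):
            leaf.taxon = ns.require_taxon(f"G{g:04d}_sp{s:03d}")
    tree.taxon_namespace = ns
    return tree


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

def simulate_landscape(cfg: ScenarioConfig,
                       rng: np.random.Generator | None = None
                       ) -> tuple[dict[str, Grid], StabilityMask]:
    """Three precipitation grids whose top-decile sets intersect exactly in
    the configured patch; the truth mask is returned alongside.

    Each layer's top decile consists of the patch cells plus layer-specific
    filler cells chosen disjointly across layers, so the three-way
    intersection is the patch and nothing else (empty if the patch is empty).
    Wet cells draw from 2000-3000 mm, dry cells from 800-1500 mm, so the
    decile threshold always separates them.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    nr, nc = cfg.grid_shape
    n = nr * nc
    k = max(1, int(np.floor(cfg.quantile_fraction * n)))
    patch = np.zeros((nr, nc), dtype=bool)
    patch[cfg.patch_rows[0]:cfg.patch_rows[1], cfg.patch_cols[0]:cfg.patch_cols[1]] = True
    p = int(patch.sum())
    if p > k:
        raise ValueError(f"patch has {p} cells but the top decile holds only {k}")
    flat_non_patch = np.flatnonzero(~patch.ravel())
    need = 3 * (k - p)
    if need > flat_non_patch.size:
        raise ValueError("grid too small for disjoint filler cells")
    fillers = rng.choice(flat_non_patch, size=need, replace=False)
    grids: dict[str, Grid] = {}
    for layer_i, name in enumerate(("current", "ccsm3", "miroc")):
        wet = patch.ravel().copy()
        wet[fillers[layer_i * (k - p):(layer_i + 1) * (k - p)]] = True
        values = rng.uniform(800.0, 1500.0, size=n)
        values[wet] = rng.uniform(2000.0, 3000.0, size=int(wet.sum()))
        grids[name] = Grid(values=values.reshape(nr, nc), xll=cfg.xll,
                           yll=cfg.yll, cellsize=cfg.cellsize)
    truth = StabilityMask(values=patch, xll=cfg.xll, yll=cfg.yll,
                          cellsize=cfg.cellsize, provenance=["designed-truth"])
    return grids, truth


# ---------------------------------------------------------------------------
# Sites and communities
# ---------------------------------------------------------------------------

def _cell_center(mask: StabilityMask, row: int, col: int) -> tuple[float, float]:
    nr = mask.values.shape[0]
    lon = mask.xll + (col + 0.5) * mask.cellsize
    lat = mask.yll + (nr - 1 - row + 0.5) * mask.cellsize
    return lon, lat


def _make_sites(cfg: ScenarioConfig, grids: dict[str, Grid], mask: StabilityMask,
                rng: np.random.Generator) -> tuple[list[SiteRecord], dict[str, str]]:
    """Site records with internally consistent climate, stable sites inside
    the patch, unstable outside."""
    nr, nc = mask.values.shape
    stable_cells = np.argwhere(mask.values)
    unstable_cells = np.argwhere(~mask.values)
    picks = [
        ("stable", stable_cells[rng.choice(len(stable_cells), cfg.n_stable_sites,
                                           replace=len(stable_cells) < cfg.n_stable_sites)]),
        ("unstable", unstable_cells[rng.choice(len(unstable_cells), cfg.n_unstable_sites,
                                               replace=False)]),
    ]
    records: list[SiteRecord] = []
    labels: dict[str, str] = {}
    i = 0
    for label, cells in picks:
        for row, col in cells:
            i += 1
            sid = f"s{i:02d}"
            lon0, lat0 = _cell_center(mask, int(row), int(col))
            lon = lon0 + rng.uniform(-0.3, 0.3) * mask.cellsize
            lat = lat0 + rng.uniform(-0.3, 0.3) * mask.cellsize
            ppt = float(grids["current"].values[row, col]) + rng.normal(0, 30)
            pptw = 0.40 * ppt * rng.uniform(0.9, 1.1)
            pptd = 0.08 * ppt * rng.uniform(0.7, 1.3)
            annt = 26.0 - 1.1 * (lat - cfg.yll) + rng.normal(0, 0.5)
            maxt = annt + rng.uniform(6, 9)
            mint = annt - rng.uniform(6, 9)
            if label == "stable":  # coastal mountain complex
                mael = rng.uniform(700, 1400)
                miel = rng.uniform(0, 200)
            else:                  # interior lowlands
                mael = rng.uniform(300, 700)
                miel = rng.uniform(100, 300)
            climate = {
                "ANNT": annt, "MAXT": maxt, "MINT": mint, "DIFT": maxt - mint,
                "PPT": ppt, "PPTS": rng.uniform(20, 60),
                "PPTW": pptw, "PPTD": pptd, "DIFP": pptw - pptd,
                "MAEL": mael, "MIEL": miel, "DIEL": mael - miel,
            }
            records.append(SiteRecord(site_id=sid, longitude=lon, latitude=lat,
                                      climate=climate))
            labels[sid] = label
    return records, labels


def _partition_pools(tree: dendropy.Tree, cfg: ScenarioConfig,
                     rng: np.random.Generator) -> dict[str, list[str]]:
    """Split tips into stable-endemic, unstable-endemic and shared pools.

    Endemic pools are built genus by genus (whole clades), so the stable
    region's endemics are clade-structured; the shared pool takes individual
    species from the remaining genera; leftovers stay master-only.
    """
    genera: dict[str, list[str]] = {}
    for lab in sorted(leaf_labels(tree)):
        genera.setdefault(genus_of(lab), []).append(lab)
    order = list(genera)
    rng.shuffle(order)
    n_endemic = cfg.n_species_pool - cfg.n_shared
    pools = {"stable_endemic": [], "unstable_endemic": [], "shared": []}
    it = iter(order)
    for key in ("stable_endemic", "unstable_endemic"):
        while len(pools[key]) < n_endemic:
            g = next(it)
            pools[key].extend(genera[g][: n_endemic - len(pools[key])])
    rest = [sp for g in it for sp in genera[g]]
    rng.shuffle(rest)
    pools["shared"] = rest[: cfg.n_shared]
    pools["extra"] = rest[cfg.n_shared:]
    if len(pools["shared"]) < cfg.n_shared:
        raise ValueError("tree has too few tips for the configured pools")
    return pools


def simulate_communities(
    cfg: ScenarioConfig,
    tree: dendropy.Tree,
    grids: dict[str, Grid],
    mask: StabilityMask,
    rng: np.random.Generator | None = None,
) -> tuple[CommunityMatrix, list[SiteRecord], dict[str, str], dict[str, list[str]]]:
    """Occurrence matrix plus site records and ground truth.

    Stable-region sites: every stable-endemic genus gets a range centroid at
    one stable site, and its species occur with probability
    ``0.9 * exp(-distance_decay * d)`` of the site-centroid distance — so
    nearby stable sites share clades and distant ones do not (distance decay
    plus clade turnover).  Shared (broad-ranged) species decay more slowly
    from centroids placed anywhere.  Unstable-region sites: the unstable pool
    is ranked once by prevalence, sites are ordered along a spatial richness
    gradient, and with probability ``nestedness_strength`` a species occurs
    iff its rank falls inside the site's richness quantile (nested subsets);
    otherwise occurrence is an independent coin flip at the same rate.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    sites, labels = _make_sites(cfg, grids, mask, rng)
    pools = _partition_pools(tree, cfg, rng)
    stable_sites = [s for s in sites if labels[s.site_id] == "stable"]
    unstable_sites = [s for s in sites if labels[s.site_id] == "unstable"]
    coords = {s.site_id: np.array([s.longitude, s.latitude]) for s in sites}

    species = sorted(pools["stable_endemic"] + pools["unstable_endemic"] + pools["shared"])
    sp_idx = {sp: k for k, sp in enumerate(species)}
    occ = np.zeros((len(sites), len(species)), dtype=np.int8)
    row = {s.site_id: k for k, s in enumerate(sites)}

    # stable region: clade-structured endemics with genus-level centroids
    genera = sorted({genus_of(sp) for sp in pools["stable_endemic"]})
    centroid = {g: coords[rng.choice([s.site_id for s in stable_sites])] for g in genera}
    for sp in pools["stable_endemic"]:
        c = centroid[genus_of(sp)]
        for s in stable_sites:
            d = float(np.linalg.norm(coords[s.site_id] - c))
            if rng.random() < 0.9 * np.exp(-cfg.distance_decay * d):
                occ[row[s.site_id], sp_idx[sp]] = 1

    # shared, broad-ranged species: gentle decay from anywhere, both regions
    for sp in pools["shared"]:
        c = coords[rng.choice([s.site_id for s in sites])]
        for s in sites:
            d = float(np.linalg.norm(coords[s.site_id] - c))
            if rng.random() < 0.65 * np.exp(-cfg.shared_decay * d):
                occ[row[s.site_id], sp_idx[sp]] = 1

    # unstable region: nested subsets along a spatial richness gradient.
    # Only the unstable endemics are nested, so a fully shared pool with
    # nestedness off makes the two regions exchangeable by construction.
    upool = pools["unstable_endemic"]
    rank = rng.permutation(len(upool))  # prevalence order, fixed once
    quantile = rank / len(upool)
    ordered = sorted(unstable_sites,
                     key=lambda s: s.longitude + s.latitude)
    fractions = np.linspace(0.85, 0.25, num=len(ordered))
    for s, f in zip(ordered, fractions):
        if not upool:
            break
        nested = quantile < f
        coin = rng.random(len(upool)) < f
        use_nested = rng.random(len(upool)) < cfg.nestedness_strength
        present = np.where(use_nested, nested, coin)
        for sp, here in zip(upool, present):
            if here:
                occ[row[s.site_id], sp_idx[sp]] = 1

    # no empty sites: seed one broad-ranged (else top-ranked endemic) species
    filler = (pools["shared"][0] if pools["shared"]
              else upool[int(np.argmin(rank))])
    for k in range(len(sites)):
        if occ[k].sum() == 0:
            occ[k, sp_idx[filler]] = 1

    keep = occ.sum(axis=0) > 0
    matrix = CommunityMatrix(
        sites=[s.site_id for s in sites],
        species=[sp for sp, kp in zip(species, keep) if kp],
        occupancy=occ[:, keep],
    )
    return matrix, sites, labels, pools


# ---------------------------------------------------------------------------
# Whole-bundle convenience
# ---------------------------------------------------------------------------

def _withhold_from_master(tree: dendropy.Tree, matrix_species: list[str],
                          cfg: ScenarioConfig, rng: np.random.Generator
                          ) -> tuple[dendropy.Tree, dict[str, GraftRule]]:
    """Drop some matrix species from the master tree so assembly must graft.

    Withholds ``n_missing_congeners`` species whose genus keeps at least one
    other tip (within-genus grafts) and ``n_missing_genera`` whole genera,
    each with sister-clade graft rules anchored on the genus nearest to it in
    the truth tree.
    """
    by_genus: dict[str, list[str]] = {}
    for sp in matrix_species:
        by_genus.setdefault(genus_of(sp), []).append(sp)
    removed: set[str] = set()
    rules: dict[str, GraftRule] = {}

    multi = [g for g, sps in sorted(by_genus.items()) if len(sps) >= 2]
    rng.shuffle(multi)
    for g in multi[: cfg.n_missing_congeners]:
        removed.add(sorted(by_genus[g])[0])

    # whole genera: anchor each on the sister clade's first genus
    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    candidates = [g for g, sps in sorted(by_genus.items())
                  if 1 <= len(sps) <= 3 and g not in multi[: cfg.n_missing_congeners]]
    rng.shuffle(candidates)
    taken = 0
    for g in candidates:
        if taken >= cfg.n_missing_genera:
            break
        members = [leaves[sp] for sp in by_genus[g] if sp in leaves]
        node = members[0]
        while node.parent_node is not None:
            sibling_tips = [lf.taxon.label
                            for ch in node.parent_node.child_nodes() if ch is not node
                            for lf in ch.leaf_iter()]
            anchors = sorted({genus_of(lb) for lb in sibling_tips} - {g})
            # the anchor genus must survive into the pruned analysis tree:
            # it needs a matrix species that is not itself withheld
            keepable = [a for a in anchors
                        if any(genus_of(sp) == a and sp not in removed
                               for sp in matrix_species)]
            if keepable:
                for sp in by_genus[g]:
                    rules[sp] = GraftRule(species=sp, anchor=keepable[0],
                                          mode="sister_to_clade", fraction=0.5)
                removed.update(by_genus[g])
                taken += 1
                break
            node = node.parent_node
    keep = sorted(set(leaf_labels(tree)) - removed)
    master = prune_to_species(tree, keep)
    return master, rules


def simulate_bundle(cfg: ScenarioConfig) -> Bundle:
    """Generate one complete, internally consistent synthetic study."""
    streams = np.random.SeedSequence(cfg.seed).spawn(4)
    rng_tree, rng_land, rng_comm, rng_master = (np.random.default_rng(s) for s in streams)
    n_tips = cfg.n_matrix_species + cfg.n_extra_master_tips
    tree = simulate_tree(n_tips, cfg.birth_rate, rng_tree, cfg.max_genus_size)
    grids, truth_mask = simulate_landscape(cfg, rng_land)
    matrix, sites, labels, pools = simulate_communities(cfg, tree, grids,
                                                        truth_mask, rng_comm)
    master, rules = _withhold_from_master(tree, matrix.species, cfg, rng_master)
    return Bundle(config=cfg, tree=tree, master_tree=master, graft_rules=rules,
                  grids=grids, truth_mask=truth_mask, matrix=matrix,
                  site_records=sites, truth_labels=labels, pools=pools)


def write_bundle(bundle: Bundle, outdir: str | Path) -> dict[str, Path]:
    """Write a bundle in exactly the formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "community": outdir / "community.csv",
        "sites": outdir / "sites.csv",
        "master_tree": outdir / "master_tree.nwk",
        "graft_rules": outdir / "graft_rules.csv",
        "current": outdir / "precip_current.asc",
        "ccsm3": outdir / "precip_ccsm3.asc",
        "miroc": outdir / "precip_miroc.asc",
    }
    write_community_matrix(bundle.matrix, paths["community"])
    write_site_table(bundle.site_records, paths["sites"])
    write_newick(bundle.master_tree, paths["master_tree"])
    write_graft_rules(bundle.graft_rules, paths["graft_rules"])
    for name in ("current", "ccsm3", "miroc"):
        write_ascii_grid(bundle.grids[name], paths[name])
    return paths
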