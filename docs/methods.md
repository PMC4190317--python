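# Methods

This note documents the models, conventions and numerical choices behind
`phylobeta`, in the order the pipeline applies them.

## Compositional beta diversity (CBD)

For a pair of sites with `a` shared species and `b`, `c` species unique to
either site, the pairwise Jaccard dissimilarity

    beta_jac = (b + c) / (a + b + c)

is split additively in two families:

* **Baselga family** — turnover `beta_jtu = 2*min(b,c) / (a + 2*min(b,c))`
  (the dissimilarity the pair would show if both sites were equally rich) and
  nestedness-resultant `beta_jne = beta_jac - beta_jtu`.
* **Carvalho family** — replacement `beta_-3 = 2*min(b,c) / (a+b+c)` and
  richness difference `beta_rich = |b - c| / (a+b+c)`.

Both families share the same total and are always emitted side by side, so
their qualitative agreement can be verified on any dataset rather than
assumed; reporting treats the Baselga split as the headline. A pair
involving an empty community raises instead of returning a boundary value:
empty sites are forbidden upstream, so a silent 0 or 1 here would mask a data
error.

## Phylogeny assembly

The analysis tree is built from a dated master phylogeny in two steps:

1. **Prune** to the observed species. Degree-2 nodes are suppressed with
   branch lengths summed, so path lengths among retained tips are conserved.
2. **Graft** species the master lacks.
   * A species whose genus is present joins the most recent common ancestor
     of its congeners as a polytomy. Its pendant length equals the depth of
     that node, which keeps the tree ultrametric — the conventional choice
     for polytomy grafting on dated trees, and required for the branch-length
     components of different pairs to be comparable.
   * A genus with a single congener has no crown node; the congener's pendant
     branch is split at its midpoint and the new tip attached there (the
     neutral choice between "crown" at depth 0 and "stem" at the full pendant
     depth).
   * A species whose genus is absent needs an explicit rule naming an anchor
     (tip, internal node label, or genus) and a mode: sister-to-clade inserts
     on the anchor's stem at a configurable fraction of its length (default
     0.5, measured rootward from the anchor crown); the degenerate fractions
     0 and 1 are rejected.

Grafting never changes path lengths between pre-existing tips, and assembly
is deterministic given inputs (species processed in sorted order, with
repeated passes so a rule-grafted species can anchor later congeners). Genus
is parsed lexically from the `Genus_epithet` label; no taxonomy service is
consulted.

## Phylogenetic beta diversity (PBD)

Unweighted UniFrac treats branch lengths the way Jaccard treats species: on
the pooled tree, a branch belongs to a community if at least one of its tips
descends from it. With shared length `s` and unique lengths `u1, u2`:

    UniFrac      = (u1 + u2) / (s + u1 + u2)
    UniFrac_Turn = 2*min(u1,u2) / (s + 2*min(u1,u2))
    UniFrac_PD   = UniFrac - UniFrac_Turn

`UniFrac_Turn` captures replacement of unique lineages net of
phylogenetic-diversity differences; `UniFrac_PD` captures the part of the
dissimilarity driven by one community spanning more evolutionary history than
the other. The identity `s + u_i = PD_i` (Faith's phylogenetic diversity of
community *i* on the pooled tree) is used both for fast all-pairs computation
and as a test invariant. The root edge, when present in the Newick, is
excluded from every component: it subtends all tips, so it is shared by
construction and contributes no discrimination. On a star tree with unit
pendant branches the three values reduce exactly to `beta_jac`, `beta_jtu`,
`beta_jne`; this reduction is the module's cross-oracle in the tests.

## Null model and SES

The null randomizes only the identities of species on the phylogeny: tip
labels are permuted uniformly over all tips of the assembled tree, leaving
topology, branch lengths and the community matrix untouched — so richness
and all compositional dissimilarities are fixed by construction. For every
pair and every UniFrac component,

    SES = (observed - mean(null)) / sd(null)

with the **sample** standard deviation (ddof = 1) over the default 999
permutations. |SES| > 1.96 is the conventional two-sided band: above it the
pair is more phylogenetically dissimilar than its species-level dissimilarity
predicts, below −1.96 less. Components invariant under relabeling (e.g. any
pair on a star tree, where the components are functions of richness alone)
have sd = 0 and are flagged `degenerate` rather than assigned an SES. The
permutation pool defaults to the full tip set; a grouped pool (`tip_groups`)
is available but off by default. Normality of the null is not assumed beyond
the ±1.96 convention.

## Climate-stability (refugium) delimitation

Each annual-precipitation raster — present plus glacial-maximum simulations —
is binarized at its top decile, and a cell is *stable* only if it is in the
top decile of every layer (cellwise AND). Conventions:

* **Quantile**: nearest-rank over the non-nodata cells of the supplied
  extent. With `n` valid cells and fraction `f`, the threshold is the k-th
  largest value, `k = max(1, floor(f*n))`, and every cell ≥ the threshold is
  selected — ties can push the count slightly above `k`; an all-constant
  grid selects everything. The extent is whatever grid the user supplies;
  clipping it differently changes the mask, and this sensitivity is
  inherent to a quantile rule.
* **Site-to-cell mapping**: `floor((coord - corner)/cellsize)`, with a point
  exactly on a boundary belonging to the higher-index (north/east) cell. A
  site outside the extent is an error naming the site.

Site pairs are then categorized within-stable / within-unstable / between,
the unit of all regional summaries.

## Gradients and variance partitioning

The twelve site variables (four temperature, five precipitation, three
elevation; the three difference variables are recomputed on load and must
match their parents) are reduced by PCA **on the correlation matrix** —
i.e. variables standardized to zero mean and unit sample variance before
eigendecomposition. Loading signs are fixed so each axis's largest-magnitude
loading is positive (a determinism convention only). Environmental distance
is Euclidean over the leading three axes; geographic distance is planar
Euclidean on decimal degrees (a haversine-km option exists and is flagged in
metadata). Long-term climate condition enters as two indicators coding the
three pair categories, reference level within-unstable.

Each dissimilarity vector is partitioned over the three predictor sets E
(environment), S (space), R (refugia) by fitting seven OLS models (E, S, R,
E+S, E+R, S+R, E+S+R) and applying R² inclusion–exclusion: pure fractions
are `R2(full) − R2(other two)`, the triple intersection is
`ΣR2(singles) − ΣR2(pairs) + R2(full)`, and the residual is `1 − R2(full)`.
The eight fractions sum to one identically; shared fractions may be negative
(suppression) and are reported as-is, rendered "−" in displays. Choices:

* E and S distances are log-transformed before fitting; the response is not.
* Exact zero distances (co-located sites, identical climate profiles) are
  shifted by ε = smallest positive observed distance × 1e-3 before the log.
* Pair ordering is the lower triangle by site-table order, enforced across
  every vector in an analysis.
* No significance test is attached to fractions; permutation-based
  alternatives (Mantel, MRM) are deliberately out of scope.

## Synthetic-data generator

The generator emulates a two-region study design so every stage is testable
offline. Defaults are fixed at the study conditions: 14 stable + 30 unstable
sites, two regional pools of 155 species with overlap fraction 71/155
(≈239 candidate species; symmetric pools are used because the generator's
two pools are exchangeable), 999 permutations, a 10% precipitation quantile,
and a 20×20 quarter-degree landscape whose 24-cell coastal patch is the
designed intersection of the three layers' top deciles.

* **Tree**: pure-birth (Yule) with rate 1.0 per lineage, ultrametric by
  construction; tips are grouped into maximal clades of ≤6 tips, each
  labeled as one genus, so genera are monophyletic and within-genus grafting
  is realistic. A configurable set of species is withheld from the master
  copy (6 congeners + 1 whole genus with sister-clade rules by default), so
  assembly must actually graft on every synthetic bundle.
* **Landscape**: each layer's top decile = designed patch plus
  layer-specific filler cells chosen disjointly across layers, so the
  three-way intersection equals the patch exactly (empty if the patch is
  empty). Wet cells draw 2000–3000 mm, dry 800–1500 mm, so the decile
  threshold always separates them.
* **Communities**: stable-region sites draw clade-structured endemics —
  each endemic genus has a range centroid at one stable site and occupancy
  `0.9·exp(−1.2·d)` in the site–centroid distance (degrees) — plus
  broad-ranged shared species decaying at 0.3/degree from centroids placed
  anywhere. Unstable-region sites hold nested subsets of the
  unstable-endemic pool: species are ranked once, sites ordered along a
  spatial richness gradient (0.85 → 0.25 of the pool), and with probability
  0.8 (the nestedness strength) a species occurs iff its rank falls inside
  the site's quantile, otherwise by an independent coin at the same rate.
  Restricting nesting to the unstable endemics makes the degenerate
  configuration (full overlap, nestedness 0, no decay) exchangeable across
  regions by construction.
* Empty sites are seeded with one broad-ranged species; species never
  observed are dropped from the matrix (they remain master-tree tips).

What the generator does **not** emulate: sampling error and detection
failure, abundance structure, non-monophyletic genera, spatially
autocorrelated climate noise beyond the latitude gradient, and mechanistic
range dynamics through glacial cycles. Tests passing on these data show the
pipeline recovers designed structure under the stated occupancy model; they
do not validate the ecological assumptions against field data.

## Problem sizes and determinism

Test and acceptance runs use the study scale throughout: 44 sites (946
pairs), ~239 species, 999 permutations; the parameter-recovery sweep uses 20
seeds. All randomness flows from one master seed, split per stage with
`numpy` seed sequences; a re-run with the same seed writes byte-identical
numeric outputs. The fast all-pairs UniFrac and null-model routines rest on
a single edge×tip incidence matrix; permutations re-index its columns rather
than rebuilding trees.

## Known limitations

* Within-genus grafting attaches at the congeners' MRCA even if the genus is
  non-monophyletic in the master tree (the MRCA then spans intruders); the
  master's topology is taken as given.
* The refugium mask depends on the raster extent supplied (quantiles are
  extent-relative) and inputs must be pre-aligned; no reprojection or
  resampling is attempted.
* Planar degree distances ignore latitude-dependent scale; use the haversine
  option where that matters.
* OLS on pairwise distances ignores the non-independence of pairs sharing a
  site; fractions are descriptive, not inferential.
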