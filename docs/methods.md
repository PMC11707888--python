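# Methods

## The model

Ortholog groups are treated as peaks on a protein fitness landscape:
within a group, weakly constrained sites substitute freely and sequence
identity decays continuously; founding a new group requires a coordinated
rewrite of mutually constrained sites, a jump that leaves a *valley* — an
empty band of pairwise identities between the within-group mode and the
between-group mode. The pipeline never thresholds identity directly;
instead it looks for that valley independently for every seed protein, so
families under different selection pressures (different within-family
identity levels) are handled symmetrically.

## Pipeline stages and the parameters that matter

### Global similarity (module `align`)

Full-length Needleman–Wunsch alignment, BLOSUM62, affine gaps with
`gap_open = −11` (first gap residue) and `gap_extend = −1`; similarity is
percent identity over all alignment columns, gap columns included
(`similarity_mode="percent_similarity"` counts positive-scoring columns
instead). Full-length alignment deliberately penalizes chimeric/multi-domain
matches that local alignment would reward. `X` scores 0 against everything
and never counts as an identity. Because co-optimal alignments can differ
in identity, the pair is aligned in canonical (lexicographically sorted)
order, which makes the value exactly symmetric. Candidates at length ratio
≥ 1.5 are excluded *before* ranking; per-species top-K defaults are 10
(prokaryote mode) and 50 (eukaryote mode) — enough slots for orthologs plus
an excess of distant homologs, so every plot contains noise.

### Signal detection (module `signals`)

Each seed's plot is z-scored per axis (population SD; a zero-variance axis
maps to 0). The affinity is a dense Gaussian *product* kernel with one
bandwidth per dimension, σ_d = min(median, 2·lower-quartile) of the absolute
pairwise differences along that axis. Rationale: after z-scoring, the noise
cloud is strongly elongated in x while the signal–noise valley lies in y; a
single isotropic bandwidth either bridges the valley or shatters the noise
cloud. The per-axis quantile rule keeps each bandwidth on the within-cluster
scale both when the noise dominates the pair population and when two
clusters of comparable mass make the difference distribution bimodal; the
quantiles are taken over positive differences only, so exactly-coincident
points (zero-divergence limits, clipped coordinates) cannot zero out an
informative axis.

Clustering follows the random-walk normalized Laplacian route: solve
L u = λ·Deg·u with L = Deg − A (equivalently I − Deg⁻¹A), pick
k = argmax of the eigengap λ_{j+1} − λ_j over j ∈ [1, 8], and run k-means
(10 restarts, fixed seed) on the rows of the n×k eigenvector matrix. The
search includes k = 1 so that a plot with no separated structure — a seed
with no surviving orthologs — yields an empty signal set rather than an
arbitrary split. Plots with fewer than `min_points = 10` hits are all noise
by convention.

Labelling: the largest cluster is noise (ties: lower centroid y, then lower
index). A cluster joins the noise — iterating to a fixpoint — when it is
not *noticeably separated* from the current noise region: its centroid
fails to rise at least `min_gap = 0.5` normalized units above the noise
set's top point (length-ratio gaps split satellites off on either side of
the main cluster, and they share its low similarity), or its minimum
point-pair distance to the noise set is below `separation = 3` bandwidth
units (at 3σ the kernel affinity is e^{−4.5} ≈ 0.01 — essentially zero) or
below `min_gap` in plain normalized units, the floor that matters when
degenerate point clouds drive the bandwidths toward zero. Whatever
remains is signal. The absorption makes the labelling robust to eigengap
overestimates of k: splitting the noise cloud into fragments leaves all
fragments noise, and a signal must clear the valley at the scale of the
whole plot — which is the discontinuity premise itself.

PPV audit: the convex hull (qhull) of the noise in normalized coordinates;
signal points strictly outside the hull are TP, points inside or on the
boundary are FP (conservative). Degenerate hulls (collinear noise) become
segments/points with the same boundary rule.

### SJI network (module `sji`)

Signal sets are augmented with the seed's own id before the Jaccard index,
so SJI(u,u) = 1 and two recent duplicates that appear in each other's
signal sets are not penalized for the trivial absence of self. Pairs are
enumerated through an inverted index (member → seeds), which finds exactly
the nonzero-SJI pairs; weights are stored at full precision with no
thresholding — filtering weak edges is the community stage's job. Seeds
with empty signal sets remain as isolated nodes so the final OGs partition
every input protein.

### OG detection (module `ogdetect`)

Community density D = 2·ΣW(u,v)/(|N|·(|N|−1)); singletons are D = 1 by
convention (vacuously dense). The recursion: split connected components;
accept a component when D ≥ threshold (inclusive, making the 0.25/0.1
presets attainable exactly); otherwise cut with Louvain (seeded, weighted);
a community Louvain cannot split, or one at the depth cap (50), is accepted
with `indivisible_flag` so the output is always a partition. After each
cut, edge weights inside a sub-community are recomputed from signal sets
intersected with its node set — weights then measure agreement *within*
the candidate group. DC is computed from those final restricted weights:
DC(v) = Σ W(v,u)/(|OG|−1) ∈ [0,1], equal to 1 only in unit-weight cliques
and 0 for singletons.

### Evaluation (module `evaluate`)

ARI and AMI are computed on the intersection of the two partitions'
universes (methods cover different protein sets; the intersection is the
only well-defined comparison). AMI uses the permutation-model expected MI
and max-entropy normalization; identical partitions score 1 even in the
all-singleton case where the general formula is 0/0. OG-size binning picks
boundaries on OG-size values (never splitting an OG, hence only
approximately equal protein mass). The DC refinement curve starts from
proteins in OGs of size ≥ 10, sorts by DC (ties by protein id), and by
default removes an equal 10%-of-the-start slice each step — ten groups
retaining 656, 590, …, 66 of 656 items — so each group is a prefix of the
previous one; a compounding schedule (10% of the *previous* group, ending
at 0.9⁹ ≈ 39%) is available behind `schedule="compounding"`. Bootstrap
stability removes round(frac·n) proteins without replacement (default 10%),
reruns signal detection → SJI → OG detection from the cached hit table,
and reports ARI against the original OGs and the Pearson correlation of DC
on surviving proteins; failed replicates are recorded as missing rather
than aborting the run.

## The synthetic generator (module `synthetic`)

`simulate_proteomes` emulates the two-regime model directly: one master
sequence; each family is founded by a jump rewriting a per-family fraction
of sites (uniform 0.6 ± 0.15) and trimmed to its own root length (uniform
150–450 residues); each species' copy then diverges independently (star
phylogeny) at a per-family rate (uniform 0.15 ± 0.05) scaled by a
per-lineage multiplier (uniform 0.5–1.5). Defaults: 10 species, 30
families, duplication probability 0.15 per species per family (inparalogs
get 0.05 extra divergence), single-residue indel rate 0.005 per site, and
rare (p = 0.02) terminal extensions of 30–70% of the length that push pairs
across the 1.5 length-ratio filter. These settings place intra-family
identity around 60–90% and inter-family identity in a continuous 10–35%
band, with an empty valley between the modes — roughly 350 proteins per
run.

The per-family and per-lineage rate variation matters: with a single
between-family divergence value, all inter-family identities coincide and
the noise collapses onto discrete horizontal strata that no plausible
clustering treats as one cloud; real noise is a continuum because
divergence times and rates vary. What the generator does *not* emulate:
substitution-matrix structure (replacements are uniform over the 19 other
residues), rate heterogeneity across sites, domain architecture, gene loss,
horizontal transfer, and tree-structured species relationships. Passing
tests therefore show that the pipeline recovers groups whenever the
valley premise holds at realistic identity levels — not that the premise
holds for any particular real clade.

`planted_plot` and `planted_graph` generate labelled point clouds and
planted-partition weighted graphs for oracle-checked tests of the
clustering and community stages in isolation.

## Numerical choices and degenerate inputs

* Eigendecomposition uses the symmetric generalized form eigh(L, Deg), so
  eigenvalues are real, in [0, 2], with λ₁ = 0; a tiny affinity floor
  (10⁻¹²) keeps degrees positive for isolated far-away points.
* K-means ties and restarts: best inertia of 10 seeded k-means++ runs.
* Top-K ties at the boundary break by lexicographic target id; Louvain
  uses a fixed seed; OG ids are assigned in deterministic member order —
  the whole pipeline is reproducible bit-for-bit given its seeds.
* Empty hit lists, plots below `min_points`, zero-variance axes, collinear
  noise hulls, empty signal sets (PPV undefined, reported as missing) and
  isolated network nodes all have explicit, tested conventions.
* The recursion accepts indivisible low-density communities instead of
  discarding them: a partition of all inputs outranks density purity.

## Problem sizes used in the tests

Oracle-equivalence tests run exact brute-force checks (alignment
enumeration at length ≤ 6, O(n³) hulls, exhaustive set partitions of 5–6
elements, permutation-model expected MI). Simulation-based tests use the
generator defaults (~350 proteins, ~60k candidate pairs per run), 100
seeded planted plots for the spectral stage, 10 end-to-end runs for family
recovery, and 20 bootstrap replicates — sizes chosen so the scientific
claims are exercised at well-powered but desk-scale instances.

## Known limitations

* Percent identity of one optimal alignment is reported even when many
  co-optimal alignments exist (the canonical pair order makes the choice
  deterministic and symmetric, not canonical among all optima).
* The largest-cluster-is-noise assumption fails for seeds whose plot
  contains more orthologs than distant homologs (possible in tiny
  collections; such seeds usually end with an empty signal set and are
  rescued by their partners' signal sets).
* Louvain is a heuristic: lowering the threshold does not provably reduce
  OG counts, and different seeds can split borderline communities
  differently (the bootstrap quantifies this).
* All-vs-all alignment is O(n²) in total protein count; the per-species
  top-K and the ratio filter bound the plot sizes, not the alignment work.
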