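# Methods

## Distances

All distances are raw p-distances: the proportion of differing sites among
comparable sites, with **pairwise deletion** — for each sequence pair, only
columns where *both* sequences carry an unambiguous residue (A/C/G/T for
nucleotides; the 20 standard amino acids for proteins) count. Gaps, N/X and
IUPAC ambiguity codes are excluded per pair, never per column across the
whole alignment. This maximises the data each pair uses and is the common
default for p-distances; published reference values are printed to two
decimals, which absorbs small policy differences, so comparisons against
printed tables round to two decimals. No Jukes–Cantor or other model
correction is applied anywhere: the genotype threshold is defined on raw
proportions. A pair with zero comparable sites has an *undefined* distance,
stored as NaN (never silently zero), excluded from clustering and
regressions, and logged.

Amino-acid distances come from codon-wise translation of a user-specified
region and frame. Any codon containing a gap or ambiguity translates to `X`
(excluded from distances); stops translate to `*` (also excluded). The
reading-frame phase of the 453–1700 rep fragment within a given alignment is
not derivable from coordinates alone, so the frame offset is a user input
(default 0).

## Genotype clustering

Genotypes are the connected components of the graph with an edge wherever
`d < threshold` (strict inequality; default threshold 0.10). Consequences of
this definition:

- A pair at exactly the threshold is between-genotype.
- The rule is single linkage, so chaining is possible in principle. It is
  surfaced, not hidden: every same-cluster pair with `d >= threshold` is
  recorded in `violations`. On data with a genuine distance gap (the rep
  region has no pairs between 7.5% and 11%) the violation list is empty and
  the clustering is unambiguous.
- Clusters are numbered by order of first appearance in the input, making
  results deterministic and label-permutation equivariant.

Missing distances contribute no edge (conservative: they can split, never
merge, when data are absent) and are excluded from the within/between
statistics, with a warning.

Threshold clustering is exposed as a scikit-learn estimator
(`ThresholdGenotypeClusterer`, a `ClusterMixin` over a precomputed square
distance matrix) so it composes with sklearn model-selection tooling;
`cluster_by_threshold` wraps it with sequence labels. Assignment of a new
aligned query (`assign_genotype` / `GenotypeAssigner`) computes the minimum
p-distance to each cluster and calls the unique cluster below threshold;
"novel" if none qualifies, an ambiguity flag (and no call) if several do —
ambiguity is a data problem the caller must see, not something to resolve by
tie-break.

The nt/aa distance-cloud partition uses box bounds (defaults: low cloud
nt ≤ 0.075 and aa ≤ 0.08; high cloud nt > 0.11 and aa > 0.06) reflecting the
empirical within/between gap in the rep region; pairs matching neither box,
or with undefined distances, are counted as unassigned so the three bins
always sum to n(n−1)/2.

## Recombination-congruence scans

**PDCP.** For two regions, each defined sequence pair contributes a point
(d_A, d_B). An ordinary least-squares line of d_B on d_A is fitted and the
RMSE of residuals reported. Regions with a shared history put all points on
a line (RMSE ≈ sampling noise); recombination between the regions scatters
them. A zero-variance predictor (e.g. identical sequences) is flagged
degenerate — slope 0, intercept mean(d_B) — rather than silently zeroed;
fewer than three defined points is an error.

**PDDM.** The alignment is tiled with sliding windows (default 500 nt,
step 250 — the window length follows the published analysis, the step is
half-overlap, chosen to resolve block structure at this scale and
configurable). Windows start at 1, 1+step, …; when the last regular window
ends short of the alignment, one final full-length window anchored at the
alignment end is appended so every column is covered; partial windows are
never produced. Because OLS is directional (d_j on d_i differs from d_i on
d_j), each grid cell stores the mean of the two directed RMSEs — symmetric
by construction — and the raw directed matrix is kept alongside.

**Low-recombination span.** As a reproducible stand-in for reading the
quiet block off a heatmap by eye: a window qualifies when its mean RMSE
against all other windows is at or below a quantile (default 0.25) of all
window means; the longest contiguous run of qualifying windows (earliest on
ties) is merged into a single region.

**Similarity scan.** Simplot-style: per full window (default 1000 nt, step
40), similarity of the query to each panel sequence is 1 − windowed
p-distance over comparable sites; windows with none are missing. Here the
plain floor((L − w)/s) + 1 window convention applies, matching similarity-
plot tools; the scan localises mosaic structure, it does not demarcate
regions, so end-anchoring is not needed.

## Neighbor joining

Standard agglomerative NJ (Q-criterion join selection, canonical
branch-length and distance-update formulas), implemented in-package so that
tie-breaking is pinned: ties in Q resolve to the lowest (row, column) index
pair, making output deterministic given input order. Negative branch-length
estimates are clamped to zero and counted on the tree object. For n = 3 the
closed three-point formulas apply; for n = 2 the single edge is split
evenly. On additive matrices NJ is exact (leaf-to-leaf path lengths
reproduce the input); the test suite verifies this against a brute-force
least-squares fit over all quartet topologies and against an independent NJ
implementation. Trees are unrooted; rooting on an outgroup is display-level
only (`--root-on`). Missing distances are an error with instructions, not
an imputation.

## Synthetic populations

`simulate_population` generates what the analysis assumes about the real
sequence population, with ground truth:

1. A uniform random root sequence (default 4400 nt, gap-free).
2. Genotype ancestors derived by independent per-site substitution to one of
   the three alternative bases. The per-lineage rate q solves
   2q − (4/3)q² = D for the target ancestor pairwise distance D (default
   0.13, the centre of the observed 0.11–0.16 between-genotype range); the
   quadratic term is the expected-overlap correction for substitutions
   hitting the same site on both lineages.
3. Members substituted from their ancestor at rate w/2 (default w = 0.05,
   inside the observed ≤ 0.075 within-genotype range), giving member pairs
   an expected distance near w.
4. Recombination as copy-replacement of a contiguous segment between two
   uniform breakpoints: per sequence, Poisson(1.0) events in the rep-analog
   region (453–1700) with donors restricted to the same genotype, and
   Poisson(0.5) events in the cap-analog region (2250–4400) with
   unrestricted donors. Donors are the current (already-evolved, possibly
   already-recombined) sequences, applied in a fixed order.

Default sizes are 4 genotypes of 30/40/20/13 members — 103 sequences, hence
5253 pairs, the population scale of the real dataset. All draws derive from
one seeded generator; a seed reproduces the alignment and truth log byte
for byte.

What the generator does **not** emulate: indels and alignment error (the
output is gap-free; pairwise deletion makes the distance machinery
indifferent to this), rate heterogeneity across sites, selection, coalescent
genealogy within genotypes, and ambiguity codes. Tests passing on these
populations therefore demonstrate the statistical machinery — threshold
separation, congruence contrasts, recovery — under the assumed structure,
not robustness to alignment artefacts in real GenBank data.

## Verification design

- Exact published quantities (the 11-serotype matrix, its four clusters, the
  0.07/0.11 separation gap, the between-genotype ranges) are recomputed from
  the packaged printed matrix. One published range cell (genotype 2 vs 3,
  printed 0.14–0.15) is irreproducible from the printed matrix, whose every
  corresponding cell reads 0.14 — presumably rounding of unrounded internal
  values upstream; the package reports (0.14, 0.14) and documents the
  discrepancy rather than matching it.
- Dataset-scale claims are recast as simulation properties: genotype
  recovery (ARI = 1 over 20 seeded replicates), mean rep×cap PDDM RMSE
  exceeding mean rep×rep RMSE, and a split-half negative control. The
  negative control follows the clonal design: a single-genotype,
  recombination-free population, even/odd column split of the whole
  alignment (2 × 2200 sites), where residual scatter is pure binomial
  sampling noise, expected ≈ √(2·d(1−d)/2200) ≈ 0.007 at d ≈ 0.05 and
  measured below 0.01. On a structured 4-genotype population the same
  split of the 1248-nt rep fragment alone carries ≈ 0.02 of sampling noise
  (624 sites per half, distances up to ≈ 0.17), which is why the control is
  defined on the clonal whole-alignment case.
- Algorithmic cores are checked against independent oracles: connected
  components vs transitive closure on 200 random matrices; NJ vs exhaustive
  least-squares over quartet topologies and vs a second NJ implementation.

## Numerical and degenerate-input conventions

- Coordinates are 1-based inclusive in every user-facing interface.
- Distance matrices serialise as square TSV with `NA` for missing; Newick
  labels with reserved characters are single-quoted.
- Uniform PDDM grids (no variance anywhere) are returned flagged, not
  erroneous; all-zero distance matrices cluster to one genotype and yield
  zero-length trees.
- Two runs of the CLI with the same inputs and seed produce byte-identical
  outputs; logs go to stderr only.

## Known limitations

- The 10% threshold is validated for the rep fragment of AAV A at current
  diversity; more divergent future taxa may need model-corrected distances.
- Capsid-based (VP1) classification is out of scope by design: rep
  genotypes supplement, not replace, it.
- Single linkage inherits the usual chaining caveat when a dataset lacks a
  clean distance gap; the violation report is the guard rail.
- The PDDM step size and the exact regression convention of the original
  congruence-scan tooling are not published; half-overlap windows and
  direction-averaged RMSE are this package's documented choices.
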