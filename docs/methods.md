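# Methods

This note documents the statistical procedures implemented in `pathmotif`,
the defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the package's known limitations.

## Cell states and atlas integration

A *cell state* is a cluster of single cells from one dataset, represented by
the arithmetic mean of its members' log-normalized expression (per-cell
depth 10⁴, `log1p`). Clusters come either from graph-based Leiden clustering
on the first 50 principal components (the Leiden resolution has no canonical
value and is a config knob) or from user-supplied annotations.

Integration across datasets intersects the detected gene sets (sorted
order), concatenates states, back-transforms the log averages with
`expm1` — the exact inverse of the `log1p` normalization; the alternative
convention `exp(x)+1` is available behind `literal_exp_plus_one=True` but
assigns nonzero "counts" to unexpressed genes and is not recommended —
renormalizes every state to a total of 10⁴, and embeds the result: the 4,000
most variable genes by dispersion ranking, unit-variance scaling, PCA (50
components for integration, 100 for dispersion measurements). PCA signs are
fixed by forcing each component's largest-magnitude loading positive, so
coordinates are reproducible across platforms. Zero-variance genes scale to
zero rather than NaN; an all-constant matrix embeds at the origin.

## Pathway scaling and the on-gate

Pathway genes have very different dynamic ranges, so each gene is scaled by
its 95th percentile across *all* states (linear-interpolation quantile,
computed before any gating) and clipped to [0, 1]. All-zero genes scale to
all-zero columns. A state is **on** when at least two pathway genes reach
0.3 on this scale; the comparison is `≥`, which avoids float-equality
fragility at the boundary. Pathways with fewer than 7 genes are rejected.

The q95 scale makes one assumption worth stating: every pathway gene should
be meaningfully expressed in at least ~5% of states. A gene expressed
essentially nowhere has a baseline-level q95, and scaling saturates its
noise to the full [0, 1] range, which can corrupt the on-gate and inject a
spurious profile. Real pathway definitions generally satisfy the assumption
(every component appears in some profile); the synthetic generator enforces
it by construction.

## Counting profiles: the silhouette Z-scan

On-states are clustered by agglomerative clustering on pairwise cosine
distances, cut to exactly *k* clusters (`scipy` `cut_tree`, i.e. the
smallest dendrogram depth yielding exactly *k*). For each *k* in the grid
(default 3–100; 3–200 for peak-width surveys) the mean per-sample silhouette
is computed on the same cosine distance matrix, with the conventions s = 0
for singleton-cluster members and for coincident points.

Because any matrix can be clustered, the observed curve is standardized
against a null: each gene's values are permuted independently across the
on-states — preserving every gene's marginal distribution exactly while
destroying gene–gene correlations — and the entire clustering procedure,
dendrogram included, is rerun per randomization (default 100; the null mean
and spread are stable well below that).

Z(k) = (s_obs(k) − mean(s_null(k))) / sd(s_null(k)), with sd using ddof = 1;
grid points with zero null spread are masked. The optimal count k_opt is
**the largest k whose (optionally smoothed) Z is at least 90% of the
maximum**; an alternative reading — the last k before Z drops below that
level for good — is available as `rule="drop"` and coincides with the
default whenever the final 90% crossing is downward. The **peak width** is
the fraction of grid values within 90% of the maximum (computed on the raw
Z); widths above 0.35 flag pathways with no well-defined profile count. The
**recurrence score** r = k_opt/N_g is reported to one decimal in summaries.

Two defaults here deserve justification, because both were settled by
simulation against planted ground truth:

* **Linkage: complete (not average).** With average linkage, cutting one
  cluster deeper tends to peel small splinters, so the observed silhouette
  declines very slowly past the true cluster count while the null's spread
  shrinks with k; the "largest k within 90% of the max" rule then
  systematically overshoots. Complete linkage produces balanced cuts, and a
  balanced split of a true cluster costs a visible silhouette drop exactly
  at K+1. On planted atlases (K ∈ {4, 6, 10}, 600 states, default noise)
  complete linkage recovers K within ±20% in ≥80% of seeds; average linkage
  does not. Both are flag-selectable everywhere.
* **Smoothing window: 1 (no smoothing).** A centered moving average of
  width w widens the 90% band upward by roughly w/2 grid steps, which is a
  pure positive bias in k_opt under the "largest k" rule. The window is a
  parameter; 3 or 5 are reasonable when the null sample is very small and
  the raw Z is spiky.

A caveat on the Z statistic itself: its null spread sd(s_null(k)) decreases
with k, so Z declines more slowly than the silhouette past the true cluster
count; the selection rule consequently has a resolution of roughly one to
two grid steps and a slight upward bias. This is a property of the
statistic, not of the implementation. Relatedly, on data whose genes truly
are independent, the observed matrix is itself a single draw from the null
population, so its grid-averaged Z is a standardized random variable with
spread near 1 (strongly correlated across k); "no structure" manifests as
mean Z scattered within roughly ±2, not pinned near zero.

## Dispersion and the motif / private calls

The dispersion of a group of states is the mean over all unordered member
pairs of Euclidean distance in the 100-PC embedding; singletons are flagged
undefined and excluded from classification. The **lower bound** (expected
dispersion of closely related states) cuts the global transcriptome
dendrogram — cosine distances in the leading 20 PCs, the same 100-PC
coordinates for the dispersion itself — into k_opt groups and collects their
dispersions. The **upper bound** permutes profile labels over the on-states
(sizes preserved; default 100 rounds) and pools the resulting dispersions.
A profile is a **motif** when its dispersion strictly exceeds the lower
bound's 90th percentile, **private** when strictly below its median,
**intermediate** otherwise (percentiles by linear interpolation; thresholds
stored in the report). Dispersion is scale-equivariant, so classifications
are invariant to a global rescaling of the embedding.

Within-group member pairs are used rather than distances between group
centroids; the centroid variant would shrink all dispersions toward zero
for tight groups and is not implemented.

## Inter-pathway coupling and trajectories

Profile labelings are extended to all integrated states with label 0 for
"pathway off" and compared pairwise with adjusted mutual information
(sklearn, expected-MI correction, "max" entropy normalization). Two constant
labelings are the same one-block partition and score 1 by convention.

For trajectory analysis the package consumes a precomputed staging (it does
not infer pseudotime). Developmental expression is log-normalized, then each
gene is mapped affinely so its [min, q95] range lands on [0, 1] — aligning
it with the integrated atlas's scaled range — and clipped. Stage-mean
profiles are matched to the nearest reference profile centroid under cosine
distance; ties go to the smallest profile id with a warning. Matching to
centroids makes the reference free of a neighbor-count parameter.

## The synthetic atlas generator

The generator supplies ground truth for every pipeline stage. It emulates:

* a **cell-type tree**: clade centroids placed mutually orthogonal at a
  fixed separation in a latent space, states at centroid + isotropic
  Gaussian noise;
* **planted profiles**: K sparse combinatorial profiles (2–4 strong genes
  of N_g at 0.7–1.0 over a < 0.1 floor), rejection-sampled to a minimum
  pairwise cosine distance of 0.5 so the planted K is identifiable, with
  every gene strong in at least one profile. Motif-truth profiles are
  assigned across ≥ 3 clades, private-truth profiles confined to one clade
  each; usage is skewed (∝ 0.5^rank) to mimic the strongly unequal profile
  memberships of real atlases; each assigned state draws an overall
  amplitude from U(0.5, 1); a configurable fraction of states (default 15%)
  is off, with heterogeneous sub-threshold baselines;
* **counts**: negative-binomial noise (variance μ + αμ², default α = 0.1,
  Poisson as α → 0) around per-state expected expression at a mean depth of
  3,000 counts/cell; background genes are a softplus of a random linear map
  of the latent coordinates with per-state totals equalized, so clade
  identity is carried by background *composition* and transcriptome
  clustering can recover the clades, while the pathway fraction of a state
  depends only on its profile;
* **multiple datasets**: states partitioned across datasets, each dataset
  dropping a random 10% of background genes, exercising gene intersection;
* **trajectories**: staged cells whose pathway profile is constant
  (`stable`), fixed in shape with geometrically decaying amplitude
  (`fade`, 1 → 0.02), or switching between the two most distant planted
  profiles at a known stage (`switch`).

Everything is bit-reproducible from its seed. The generator deliberately
does **not** emulate batch effects beyond gene-set differences, ambient RNA,
doublets, organ-specific expression programs, or realistic gene-gene
correlation structure in the background; passing tests demonstrate that the
statistics recover planted structure under idealized noise, not that the
method is robust to artifacts absent from the simulation.

## Simulation study sizes

The validation experiments use 300–600 states, 11 pathway genes, ~200
background genes, 3 datasets, 8 cells per state, k grids to 30 for planted
K ≤ 10, and 50 null randomizations — sizes at which all planted-recovery
statistics are stable while the full suite runs in minutes. Planted-count
recovery is measured as k_opt within ±20% of K over 20 seeds per
K ∈ {4, 6, 10}; motif/private recovery as balanced accuracy over 20 seeds.

## Numerical conventions and degenerate inputs

Cosine distances treat zero-norm rows as maximally distant (such rows cannot
occur among gated on-states and arise only in shuffled nulls); silhouette
uses s = 0 for singletons and coincident points; quantiles and percentiles
use linear interpolation throughout; nearest-profile ties break to the
smallest id after rounding distances to 12 decimals; majority-vote state
annotations break ties lexicographically with a logged warning; an empty
on-set, an empty gene intersection, an all-singleton lower bound, and QC
that removes every cell all raise explicit errors rather than propagating
empty results.

## Limitations

* k_opt selection inherits the one-to-two-step upward bias discussed above;
  treat r as approximate to ~±0.2 for an 11-gene pathway.
* The lower bound depends on the transcriptome dendrogram's granularity at
  k_opt; very large k_opt relative to the state count degrades it toward
  singletons.
* AMI over all states includes the off-label 0; two pathways that are off
  in the same states gain coupling from co-absence, which is intended
  behavior but worth remembering when interpreting crosstalk matrices.
* No batch correction is performed beyond pseudo-bulk averaging and
  renormalization.
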