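# Methods

This note records the modeling and numerical choices behind `mmconn`, in
the spirit of a package methods appendix: what is computed, under which
conventions, what the synthetic cohorts do and do not emulate, and where
the design was genuinely open.

## Network construction and thresholding

Functional connectivity is the Pearson correlation of region time series,
Fisher-Z transformed entrywise.  Correlations are clamped to
±(1 − 10⁻⁷) before `atanh` so that degenerate (perfectly correlated)
synthetic inputs stay finite; zero-variance regions are a hard error, since
their correlation is undefined.  Structural inputs are FA-weighted
symmetric matrices; asymmetries up to 10⁻⁸ are repaired by averaging the
two triangles, anything larger (or entries outside [0, 1)) is rejected.

Binarization conventions:

- **Sparsity** (functional): keep the K = round(s·N(N−1)/2) largest
  *positive* Fisher-Z weights.  Negative correlations never form edges —
  the dominant convention in connectome toolboxes; thresholding on |z|
  instead would require an edge-sign semantics the downstream binary
  metrics do not have.  Ties at the cutoff are broken by lexicographic
  (i, j) order so runs are deterministic.  If fewer than K positive weights
  exist, all are kept and the network carries a `shortfall` flag.
  Sweep: 26%–50% in 1% steps (25 networks); the sweep is nested by
  construction.
- **FA** (structural): edge iff weight strictly exceeds the cutoff.
  Sweep: 0.20–0.42 in 0.02 steps (12 networks).

## Graph metrics and their conventions

All metrics are defined on undirected binary graphs.  Two conventions are
fixed package-wide (both are common in the literature, which rarely states
them):

- characteristic path length **L** averages BFS distances over *connected*
  ordered pairs only; the disconnected-pair fraction is always reported
  alongside, so disconnection is visible rather than silently absorbed;
- efficiency-type metrics average 1/d over *all* ordered pairs with
  1/∞ = 0, so they degrade smoothly as networks fragment.  A consequence
  used as a test invariant: mean(E_nod) = E_glob exactly.

Small-world normalization uses an ensemble (default M = 100; M = 10 in the
reduced profile) of degree-preserving randomizations built by attempted
double-edge swaps, 10·|E| attempts per network, rejecting self-loops and
multi-edges.  γ and λ divide by the *mean* of the null distribution
(per-null ratio averaging is the other option; mean-of-null is the common
choice and is configurable at the call site by normalizing manually).
σ = γ/λ holds to machine precision by construction.  Graphs admitting no
valid swap (stars) yield verbatim copies with a `degenerate` flag; graphs
with fewer than 2 edges, or whose nulls have zero mean clustering or path
length, produce NaN indices rather than a fabricated number.

Betweenness is unnormalized shortest-path betweenness (each unordered pair
counted once).  Only its ordering is consumed by the attack analysis, so
any affine normalization would cancel.

## Attack resilience

Targeted attack deletes nodes in descending betweenness computed **once**
on the intact network (ties: ascending node index); random attack averages
uniformly random deletion orders (default 100 replicates, 25 in the
reduced profile).  Deleted nodes are isolated rather than removed: the node
set and the N(N−1) efficiency denominator stay fixed, which makes curves
comparable across steps and targeted curves provably monotone
non-increasing (a property test).  The recomputing-betweenness and
shrinking-graph variants are deliberate non-features; the fixed scheme
matches the single-sort description of the attack analysis this package
reimplements.  Curves are summarized by trapezoidal AUC over removal
fraction, normalized by the intact efficiency (0 for empty graphs).
Attacks run at fixed thresholds (defaults: sparsity 0.26, FA 0.42).

## Statistics

The group statistic is the difference of group means, tested by label
permutation with the add-one two-sided p-value
(#{|perm| ≥ |obs|}+1)/(n_perm+1); no reported p can fall below
1/(n_perm+1) and constant data give p = 1.  Default 5,000 permutations;
the reduced profile uses 1,000.  Multi-variable families (thresholds of a
sweep, regions of a nodal comparison) share one label shuffle per
iteration, the standard choice when many metrics are tested on one subject
sample.  FDR correction is Benjamini–Hochberg step-up, applied per family:
across the thresholds of one global metric within one modality, and across
all regions for nodal tests (families are re-formable by calling `fdr_bh`
on any subset).  Clinical correlations are Pearson r with t-distributed
p-values, computed on patients only, restricted to regions flagged by the
nodal comparison.

## The synthetic cohort generator

The generator provides cohorts with *known* ground truth so that every
downstream stage can be validated by recovery rather than by reproducing
unavailable subject data.

**Backbone.** A Watts–Strogatz graph: ring lattice of even mean degree k,
each edge rewired with probability p = 0.1.  The backbone is hand-rolled
(not a library call) because the generator tracks which nodes carry
rewired shortcut edges; the planted lesion targets exactly those.  Default
density is ≈ 0.5 (k = 124 at 246 regions; k = 30 at the 60-region reduced
profile).  This density is deliberate: with the backbone denser than the
top of the sparsity sweep, every thresholded network consists of backbone
edges only, so planted differences propagate cleanly instead of being
diluted by sampling-noise edges (at sparser backbones the spurious noise
edges act as random shortcuts and invert the sign of the planted
path-length effect).

**Functional arm.** The group target correlation matrix is
edge_correlation (default 0.4) on backbone edges and 0 elsewhere,
projected to a valid correlation matrix by eigenvalue clipping at 10⁻⁸
plus unit-diagonal renormalization (nearest-correlation fallback if the
clipped matrix still fails Cholesky).  Subjects are i.i.d. draws of 230
zero-mean multivariate-normal timepoints.  Projection shrinks realized
edge correlations below target as density grows (measured: 0.38 at a
30-region k = 6 backbone; 0.33 at 60/30; 0.24 at 246/124) and leaks small
positive correlation to near-lattice non-edges; `edge_correlation` is
therefore a pre-projection target, and the generator's Monte-Carlo
recovery test runs on the mild-backbone configuration where target and
realization agree to ±0.05.

**Planted effects.** The functional effect multiplies target correlations
on edges incident to the affected regions by a factor (default 0.3);
affected regions default to the 10 highest-betweenness backbone nodes —
the shortcut carriers.  Consequences, all verified by the acceptance
tests: patients' λ shifts across the sweep (below controls at the
strictest thresholds, above from mid-sweep up, where the lesioned hubs
disconnect and paths must detour); the affected regions show strong nodal
efficiency deficits at sparsity 0.26; and patient networks lose global
efficiency faster under targeted attack.  Because the lesion reshapes the
whole network, many non-planted regions also differ — recovery is measured
as recall of planted regions, not as specificity.  The structural effect
shifts the Beta-distributed FA mean (default 0.35, concentration 50) by
+0.05 on affected edges in patients, so patients retain more hub edges at
high FA cutoffs.

**Clinical scores.** score = intercept + slope · E_nod(reference region)
+ N(0, noise_sd), truncated at 0 and rounded to one decimal like a
rating-scale total.  The reference is the first affected hub's nodal
efficiency at sparsity 0.38 — mid-sweep, where the lesioned hub is still
connected and its efficiency varies continuously across subjects (at 0.26
it is largely disconnected and zero-inflated, which would make a
correlation target meaningless).  Defaults (slope 28, intercept −4.9,
noise SD 4.5) were calibrated once on the reduced profile to give a
patient score mean ≈ 9.9, SD ≈ 4.9 and a generating score–reference
correlation ≈ 0.4, and then frozen.  Controls receive healthy-range
baseline scores (N(2.5, 1.5), truncated) independent of network state,
since applying the patient model to controls would invert the expected
group contrast.

**What the generator does not emulate.** No hemodynamics, temporal
autocorrelation or band-pass structure (timepoints are i.i.d.; only the
spatial covariance matters to the analysis), no scanner or motion
artifacts, no tractography streamlines, no spatial atlas geometry.
Passing recovery tests therefore demonstrates that the *analysis* detects
effects of the planted kind at the study's sample sizes — not that any
particular real dataset contains them.

## Determinism and problem sizes

Every source of randomness derives from a master seed plus stable stream
indices (stage, modality, subject, threshold), so identical configs give
byte-identical outputs (asserted in the suite) and stages can be rerun in
isolation.  Validation runs use the reduced profile — 60 regions,
42/38 subjects, 10-network nulls, 1,000 permutations — chosen so the whole
suite and the acceptance script each complete in a few minutes on one
core; the full 246-region, 5,000-permutation, 100-null profile is the
library default for real runs.  Heavy kernels (all-pairs BFS, local
efficiency, double-edge swaps) are numba-compiled with transparent pure
Python/SciPy fallbacks.

## Known limitations

- Binary undirected graphs only; no weighted metric variants, modularity,
  rich-club or NBS-style cluster statistics.
- FDR families are fixed to the two described above; other groupings must
  be assembled manually from the raw permutation p-values.
- The planted functional effect changes the network globally; it cannot
  emulate a *focal* difference confined to the affected regions.
- Group comparisons adjust for no covariates (age/sex regression is out of
  scope).
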