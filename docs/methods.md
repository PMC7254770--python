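# Methods

This note records the models, conventions and numerical choices behind
`funconn`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Synthetic cohort model

Each subject's regional time series are drawn from a stationary Gaussian
process: innovations e_t ~ N(0, R) with R the group's latent correlation
matrix, coloured by a shared AR(1),

    x_t = φ x_{t−1} + √(1−φ²) e_t,   x_0 = e_0,

which makes the process stationary from the first volume with marginal
covariance exactly R. Because every region shares the same temporal kernel,
the cross-spectral density is proportional to R at all frequencies, so both
the AR colouring and the subsequent zero-phase band-pass filter (0.01–0.1 Hz,
4th-order Butterworth, applied forward and backward) leave the expected
zero-lag correlation matrix equal to R. Planted effects on R are therefore
recovered by downstream sample correlations without bias, which the
convergence test (500 subjects, max |sample − latent| < 0.05) verifies.

Defaults mirror a typical resting-state acquisition: 197 volumes at
TR = 3 s, 90 regions, groups of 64 and 66 subjects, AR(1) coefficient 0.3.
The latent structure is modular: within-community correlation 0.45
(overridable per community), between-community 0.12, with a DMN-like
community defined on the standard AAL-90 label scheme. A core–periphery
variant is available through `community_pair_overrides`. Group B differs
from group A only by planted latent increments on named region pairs
(default: bilateral parahippocampal gyrus to eight DMN regions, +0.15). If
the planted matrix leaves the positive-semidefinite cone it is projected
back by eigenvalue clipping and re-normalized to unit diagonal; the maximum
absolute deviation introduced is reported so experiments can verify their
designs are PSD-exact (the bundled validation designs are).

Planted covariates use the conditional-normal construction against each
subject's *realized* metric: the target nodal metric m is computed from the
subject's generated series through the default construction (band-pass,
Pearson, Bonferroni threshold, positive weights), standardized to z, and the
covariate is ρ z + √(1−ρ²) ε with ε ~ N(0,1). The population correlation is
exactly ρ with no iterative fitting; sampling noise at n subjects is
approximately (1−ρ²)/√n.

What the generator does *not* emulate: head motion and its censoring,
physiological noise structure, spatial autocorrelation of the underlying
voxel signals, scanner drifts, non-Gaussian BOLD amplitude distributions,
and site effects. Passing tests therefore demonstrate the *statistical
machinery* — calibration, recovery, determinism — not robustness to fMRI
artefacts. One consequence of the band-limited colouring is worth noting:
the correlation-test p-values use the nominal sample size (T − 2 degrees of
freedom), while filtering reduces the effective degrees of freedom, so edge
retention near the threshold is more variable than the nominal Bonferroni
level suggests. This is faithful to common practice (toolboxes compute
nominal p-values on filtered series); the validation designs place baseline
correlations away from the retention boundary where stability matters.

## Network construction

Pearson r per region pair; two-sided p from t = r√(df/(1−r²)), df = T − 2.
An edge is retained iff p < α / n_tests with n_tests fixed at the full pair
count N(N−1)/2 (4005 for N = 90) regardless of how many pairs are testable.
The handling of significant *negative* correlations is a policy, not a
hidden constant: `positive` (default) keeps only positive retained r as the
weight, `absolute` keeps |r|, `keep-signed` keeps r and is rejected by the
metric stages, which assume nonnegative weights. Precomputed correlation
matrices can be supplied directly, with the time-point count required to
form p-values.

## Graph metrics

Conventions, fixed package-wide:

- **Edge length** 1/w: stronger correlation = shorter functional distance.
- **Weighted clustering**: geometric-mean-of-triangle-weights with weights
  rescaled by the graph maximum (bounded in [0, 1]; agrees with networkx's
  weighted clustering, which the tests verify).
- **Disconnected pairs**: d = ∞ contributes 0 to efficiencies; the
  characteristic path length averages finite distances only and the count of
  unreachable pairs is reported alongside. Isolated nodes have strength,
  clustering and efficiencies 0 and undefined (NaN) path length.
- **Small-worldness** σ = γ/λ with null means over degree- and
  weight-preserving Maslov–Sneppen rewired surrogates (default 100 nulls,
  10·|E| attempted double-edge swaps, weights carried with their edges,
  connectedness not enforced). The identity-null check (γ = λ = σ = 1) and
  a dense-random band (σ ∈ [0.8, 1.2]) guard the normalization.
- **Hierarchy** β from the least-squares slope of log c against log k over
  nodes with k ≥ 2 and c > 0 (sign convention c ∝ k^−β); undefined for
  regular graphs and the exclusion count is reported.
- **Assortativity**: Pearson correlation of endpoint degrees over the edge
  list with both orientations included (Newman's form).
- **Network strength** is the *mean* nodal strength (a sum convention would
  scale Table-style magnitudes by N; mean is the default and the choice is
  configurable at the reporting layer by multiplying back).

All five nodal metrics and the global aggregates are verified to 1e−9
against brute-force oracles (exhaustive relaxation for shortest paths,
triple enumeration for clustering) on random graphs up to n = 12.

## Rich club, hubs, connection classes, distance

φ^w(k) = W_club / Σ of the |E_club| largest weights anywhere in the graph,
over club members with binary degree > k, for k = 1 … k_max − 1. Levels
with fewer than two members or no club edges are stored as missing (never
0, which would corrupt the normalized curve φ_norm = φ/φ_rand). Hubs are
the top ⌈fraction·N⌉ regions by mean binary degree across all subjects,
both groups pooled (strength ranking is available); boundary ties are all
included and the inflation logged. Edge classes partition the edge set by
endpoint hub membership (rich-club / feeder / local) and conserve both edge
count and total strength, which is asserted as an invariant.

Distance terciles divide [d_min, d_max] of the atlas's pairwise centroid
distances into three equal-width intervals [d_min, b1], (b1, b2],
(b2, d_max]. The reference extremes 7.61 and 150.98 mm give b1 = 55.4 and
b2 = 103.19 mm, which the acceptance suite checks exactly. The bundled
90-region centroid table is a synthetic stand-in (plausible, bilaterally
mirrored MNI-like coordinates; minimum pairwise distance 8.2 mm, maximum
172.7 mm); real studies should supply the genuine atlas table.

## Group inference

Two-sample t-tests use the pooled-variance (Student) convention by default,
Welch optionally. Global properties and connection-class summaries are
uncorrected (α = 0.05); nodal properties are Benjamini–Hochberg corrected
within each metric family (90 tests per family, q = 0.05). Metric–covariate
correlations are pairwise-complete Pearson r with the n used reported — a
covariate observed in a subsample is handled simply by dropping missing
values, and pairs with fewer than 3 complete observations are flagged
missing.

The NBS runs one contrast per call: one-sided B > A (default, matching the
reporting convention that the patient-like group shows *higher* strength),
one-sided A > B, or two-sided. Edgewise pooled t-statistics on weights
(absent edges contribute 0; edges with zero pooled variance are undefined
and never suprathreshold) are thresholded at t > t_crit(primary α);
components are maximal connected sets of suprathreshold edges; per
permutation of group labels the maximal component size in links is
recorded, and corrected p = (1 + #{null ≥ observed}) / (1 + n_permutations),
so p is never 0 and the test is exact up to Monte-Carlo error. Permutations
are full label shuffles without stratification. Family-wise error is
calibrated per one-sided analysis: the validation suite checks that the
fraction of null replicates with any significant component falls inside the
exact binomial 95% band around 0.05 (running both tails would control each
at its own level, not jointly). Permutation-count stability and
label-swap symmetry (swapping groups with the opposite tail reproduces the
components and corrected p) are asserted.

## Classification

Feature families: 4005 upper-triangle connection weights (row-major pair
order) and 270 nodal properties (90 strength, 90 nodal global efficiency,
90 nodal local efficiency, in that block order). Within every leave-one-out
fold: two-sample t-test selection at p < 0.001 and z-scoring computed on
the training subjects only (an explicit mutation test asserts held-out
subjects cannot influence selection); one linear kernel per family,
trace-normalized on the training block so the larger family does not
dominate; fusion K = βK_conn + (1−β)K_nodal with β on the grid
{0, 0.1, …, 1} chosen by inner stratified 5-fold cross-validation on the
training subjects (ties broken toward β = 0.5); soft-margin SVM (C = 1)
predicts the held-out subject. A `whole_sample` selection mode (selection
once on all subjects, as some studies describe) is available for
comparison but is not the default, since it leaks label information into
the folds. Empty selections fall back to the single smallest-p feature so
every fold predicts. Group B is the positive class; ROC points sweep the
unique decision scores and the trapezoid AUC equals the rank-statistic
(tie-midpoint) AUC, verified against pair enumeration.

## Validation experiment sizes

The validation suite (`funconn.validation`) fixes these problem sizes as
its defaults: NBS null calibration with 200 replicates (150 in the
reproduction script) of 20 + 20 subjects and 500 permutations; planted
6-node-clique recovery (+0.3 latent, 30 + 30 subjects) over 20 seeds;
covariate recovery at 500 subjects; the feeder/local pattern over 20 seeds
of 40 + 40 subjects; 50 label permutations for the classifier chance band
(30 in the script); and a 8 + 8-subject demo pipeline run twice for
byte-level determinism (the run log with timings is the one file excluded
from the comparison). The feeder/local design uses a 30-region dominant-
degree community, baseline correlations placed away from the retention
boundary (0.55 within / 0.05 between), one planted increment per region
(+0.40) so the design stays PSD-exact, and deltas only on pairs with at
least one periphery endpoint.

## Known limitations

- The generator's realism gaps listed above; in particular, nominal
  correlation-test degrees of freedom on filtered series.
- Local efficiency recomputes shortest paths on each neighborhood subgraph
  (O(N · dijkstra)); at 90 regions this is ~50 ms per subject, fine for
  cohort scale but the slowest metric.
- The MKL is a two-kernel simplex grid search, not a general MKL solver;
  with more than two families the grid would need replacing.
- Rich-club normalization and σ share the rewired-null ensemble design but
  draw independent ensembles; at 100 nulls the Monte-Carlo error on φ_norm
  is a few percent, which the ER band test bounds.
- Hub selection at a fraction boundary with tied mean degrees inflates the
  hub set (deterministically, with the inflation logged) rather than
  breaking ties arbitrarily.
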