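# Methods

This note documents the models, estimators and numerical choices behind
`netkappa`, and what the synthetic test bed does and does not establish.

## Synthetic cohort model

The generator emulates a longitudinal sleep-deprivation design: `n_subjects
= 28` people scanned under three conditions (`RW` reference, `TSD`, `CSR`),
`n_regions = 89`, `n_volumes = 384` (8 minutes at `tr_seconds = 1.25`).

**Subject structure.** Each subject draws per-node connection strengths
`u_i`: hubs (`hub_fraction = 0.15`, i.e. 13 of 89 regions, always the first
regions in index order) narrowly around `sqrt(a)` and periphery broadly
around `sqrt(c)`, where `(a, b, c) = base_connectivity = (0.83, 0.34,
0.14)` are the within-hub / hub–periphery / periphery–periphery correlation
levels. The rank-one structure `r_ij ~ u_i u_j` (cross block rescaled to
`b`, symmetric jitter `subject_jitter_sd = 0.02`) gives every subject a
heterogeneous, reproducible degree profile — the only regime in which a
hub-disruption slope is informative. The levels are chosen for testability
of the pipeline, not as estimates of empirical BOLD coupling; a spec of
levels whose block matrix is not positive definite raises
`ParameterizationError`.

**Disruption implant.** A condition with target slope κ transforms the
subject's reference degree sequence affinely, `d'_i = (1+κ) d_i + c`, with
`c` chosen to preserve the total edge count, values clipped to `[1, N-1]`
and rebalanced by largest-remainder rounding. The sequence is realized as
an actual graph (Havel–Hakimi construction, seeded double-edge-swap
rewiring, degree-preserving cross-component repair so realizations are
always connected). Regressing `d' − d` on `d` recovers κ up to rounding;
the acceptance suite verifies mean recovery within ±0.1 over 20 subjects
for κ ∈ {−0.8, −0.5, −0.2, 0}.

**From graphs to covariances.** When time series are requested, each
condition's generating correlation matrix is built from its realized
adjacency: on-edge correlations get a flat boost (`r_on = 0.45`) on top of
a smooth off-edge gradient (0.03–0.20) driven by disruption-reweighted node
strengths, projected to the nearest valid correlation matrix
(eigenvalue clipping + diagonal renormalization). By construction the
noiseless fixed-budget graph of this matrix reproduces the implanted
adjacency exactly. Conditions with κ = 0 reuse the reference matrix
unchanged.

**Temporal model.** Series are AR(1)-filtered multivariate Gaussians,
`x_t = φ x_{t−1} + sqrt(1−φ²) ε_t` with `ε_t ~ N(0, Σ)` and `temporal_ar φ
= 0.3`: the stationary cross-sectional covariance equals Σ exactly, and
because all regions share the same spectrum, band-limited (wavelet)
correlations equal the generating correlations at every scale. Optional
white measurement noise (`noise_sd`, default 0) attenuates correlations by
`1/(1+σ²)`.

**All randomness flows from one seed** through `numpy.random.SeedSequence`
spawning: per-subject streams, then per-condition streams, so any subject
is independently reproducible and outputs are bitwise identical across
runs.

**What the generator does not emulate.** Finite-scan estimation noise is
the dominant realism it *does* carry: at 384 volumes the scale-3
correlation estimator has an effective sample size of ~67, so measured
degree profiles are noisy versions of the implanted ones. Consequences,
measured and accepted: (i) a test–retest κ between two scans of the same
covariance is ≈ −0.08, not 0; (ii) measured κ for disrupted conditions
overshoots its target by ~0.1–0.15 (flattened degree profiles are harder to
measure, pushing slopes toward −1). Exact ±0.1 recovery is therefore a
property of the degree-sequence route; the time-series route recovers
disruption with correct sign, monotone ordering and approximate scale.
Divergence between the two deprived conditions arises naturally because
each condition's adjacency is an independent realization of its degree
sequence. Not modeled at all: physiological noise, motion, spatial
autocorrelation of parcels, anti-correlated networks, condition-order or
circadian effects.

**Graph-cohort fast path.** `generate_graph_cohort` skips time series and
jitters degree sequences directly (`condition_noise_sd = 1.5` edges per
node, sum-preserving, applied to *every* condition including the reference
so that equal-target conditions are exchangeable — the property the
permutation-calibration studies require). The value stands in for
finite-scan degree estimation noise at a realistic magnitude.

## Wavelet connectivity

MODWT via the standard pyramid recursion with filters taken from
PyWavelets (`sym4`, the least-asymmetric length-8 filter; configurable).
Level j isolates `(1/(2^{j+1}TR), 1/(2^j TR))` Hz. Boundary handling:
reflection extension, then circular filtering, truncated back to T; the
first `L_j = (2^j − 1)(L − 1)` boundary-affected coefficients are excluded
from correlation estimation (the unbiased-estimator convention). The
Parseval identity is exact in circular mode and is tested there.

**Effective degrees of freedom.** Detail series are band-limited, hence
autocorrelated; the variance of a null correlation is `c_j / T_used` with
`c_j` the sum of squared autocorrelations of the equivalent level-j filter
(≈ 1.7, 2.5, 5.0, 10.0 for levels 1–4 with `sym4`). Significance counting
uses Fisher's z with `df = T_used / c_j`. We chose this over the cruder
`T_used / 2^j` octave heuristic because only the filter-derived value
calibrates: the predicted null sd at level 3 (0.122) matches simulation
(0.121), and the null significant-edge count lands at `alpha × N(N−1)/2`
within 20 %, which the octave heuristic misses by a factor of ~5.

## Graph construction

Distance transform `d = 1 − |r|`; MST by Kruskal with edges inserted in
lexicographic pair order so ties in `|r|` resolve reproducibly; remaining
edges added by descending `|r|` (a signed-r mode exists — "strongest"
correlations is ambiguous — but `|r|` is the default, consistent with the
absolute-value MST). MST edges count against the budget. Built graphs are
always connected with exactly the budgeted edge count; budgets below `N−1`
or above `N(N−1)/2` are errors.

## Metrics

Degree centrality divides by the *maximum* degree in the network (a flag
restores the textbook `N−1` normalization). Clustering and closeness are
the standard local definitions; all nodal and global metrics are verified
against explicit brute-force implementations (triangle counting,
Floyd–Warshall) on random graphs up to N = 20. Community structure for
modularity uses deterministic greedy modularity maximization (a seeded
Louvain option exists; the seed is logged). "Average graph distance between
communities" is interpreted as the mean geodesic distance over node pairs
in different communities; with a single community it is recorded as
missing (NaN), never zero.

## Hub Disruption Index

Ordinary least squares of the per-node change on the reference value,
aligned by node id (misaligned inputs are an error, not a silent
positional join). The regression includes an intercept by default — a
fitted line in the conventional sense — with a force-through-origin flag
matching the defining equation literally; both paths are tested. A
zero-variance reference makes the slope undefined and raises. The
group-level variant regresses on the group-mean reference profile and is
provided for the first validation test.

## Permutation validation

All tests use the add-one convention `p = (1 + #extreme) / (1 + n_perm)`
(never zero) and are bit-reproducible from (inputs, seed, n_perm).
Two-tailed p-values are centered on the *null mean* because several of
these nulls are not centered at zero by construction (an uncentered option
exists). Cohen's d is defined against the null distribution:
`(observed − mean(null)) / sd(null)`. Default `n_perm = 10 000`.

- *Node shuffle*: per permutation, deprived-condition node labels are
  shuffled per subject; statistic `mean(κ_within − κ_group)`.
- *Pair break*: deprived scans re-paired with uniformly permuted reference
  scans (self-pairing allowed, probability 1/n); statistic mean κ_within.
- *Condition shuffle*: within-subject label swaps exchange regressor and
  response; the null samples the 2^S orientation choices, vectorized from
  per-subject forward/reverse slopes.

Type-I calibration of the condition-shuffle and paired sign-flip tests is
checked on null cohorts (12 subjects, 30 regions, 90 edges — sizes chosen
to make replicate studies practical) with `n_perm = 1000`, requiring a
rejection rate in [0.03, 0.07] at α = 0.05: over 200 replicates for the
condition-shuffle test and over 1000 for the paired test, whose per-
replicate cost is higher but whose rate estimator needs the extra
precision — at 200 replicates the band would flag a perfectly calibrated
test about 20 % of the time, at 1000 it is a ~3σ check. A separate
2000-replicate study confirmed the paired test's p-values are uniform
(KS p = 0.14, rejection rate 0.045). The sign-flip test is also checked
against exhaustive 2^6 enumeration.

## Covariate-constrained embedding

Geodesic distances come from shortest paths over the Euclidean k-NN graph
(`k = 6` default, automatically escalated with a warning when
disconnected). The embedding minimizes raw stress
`Σ_{i<j} (d_geo − ‖y_i − y_j‖)²` with `y_i[0] = α κ_i` clamped and the
remaining coordinates free, by L-BFGS-B with an analytic gradient, jointly
over α and the free coordinates. Initialization: classical MDS on the
geodesic distances, α from the least-squares projection of the covariate
onto coordinate 0. Monotone non-increase of stress over accepted iterates
is asserted in tests. A normalized stress (divided by `Σ d_geo²`) is also
reported. A constant covariate makes α unidentifiable; the fit falls back
to the unconstrained embedding with a warning. Feature matrices with
constant-zero columns (nodal clustering has structural zeros) are refused
unless explicitly overridden. The centroid-distance test reports the
upper-tail permutation probability of the observed between-group centroid
distance; leave-one-out diagnostics exist in a fast fixed-embedding mode
and a refit mode.

## Multiple comparisons and reporting

Benjamini–Hochberg step-up within family: q = 0.05 for global-metric
families, q = 0.1 for nodal families (few global tests, many nodal ones).
BH is delegated to `statsmodels.multipletests` and verified against a
literal step-up oracle. Linear mixed-effects condition contrasts are
intentionally out of scope; the permutation comparisons are the supported
inferential path and the report labels them as such.

## Problem sizes and runtime

The default test suite runs the full 89-region design where cheap (κ
recovery, acceptance pipeline) and scaled cohorts (30–40 regions, 12–20
subjects) for the replication-heavy calibration studies; the acceptance
script runs the complete 28 × 3 × 89 × 384 pipeline with
`n_perm = 10 000`, totalling well under a minute on one CPU.

## Known limitations

- The bundled 89-region node table carries real names and MNI centroids
  for only 19 regions; the rest are synthetic placeholders (file name says
  so), sufficient for plumbing and plotting, not anatomy.
- The time-series route's measured κ overshoots strong disruption targets
  by ~0.1–0.15 (see above); calibrated recovery holds on the
  degree-sequence route.
- CCML's stress definition follows this package's documented choice; other
  covariate-constrained formulations may normalize differently.
- The generator's hub set is shared across subjects (hub *strengths* and
  peripheral profiles are subject-specific); fully idiosyncratic hub
  placement is not modeled.
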