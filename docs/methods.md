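# Methods

## Model and assumptions

The package treats a multivariate time series (MVTS) as a sample from a
stationary stochastic process and asks, for each k-tuple of variables, how
statistically distinguishable the forward process is from its time reversal.
The ideal quantity is the Kullback–Leibler divergence between forward and
backward path probabilities of the tuple's projected trajectory — zero for a
reversible (equilibrium) process, positive out of equilibrium, and a lower
bound on entropy production. Path probabilities of continuous-valued series
are not directly estimable, so the package uses a graph-based proxy: the
time-directed visibility graph, whose in/out degree asymmetry vanishes for
reversible processes. The tuple-level statistic

    sigma(n1..nk) = JSD( P_in || P_out )

is the Jensen–Shannon divergence between the joint in- and out-degree
distributions of the tuple's layers in the directed multiplex visibility
graph (DMVG). It is a *proxy*, not an entropy-production estimate: it carries
no physical units, is bounded by ln 2, and is meaningful chiefly as a
comparison between tuples measured on the same cohort with the same support.

Assumptions worth stating explicitly:

- **Stationarity within and across trials.** Nodes from all trials are pooled
  into one empirical distribution; trends or strong nonstationarity will
  register as irreversibility.
- **Equispaced sampling** is the default (time indices 1..T); arbitrary
  strictly increasing time stamps are supported because the visibility
  criterion uses the actual times.
- **Undirectedness within the tuple.** sigma says a tuple's joint dynamics
  break time symmetry; it does not orient information flow between the
  tuple's members.

## The visibility construction

Points are joined when the chord between them passes **strictly** above every
intermediate point; a point exactly on the chord blocks visibility. Two
consequences are documented rather than special-cased: runs of equal values
(plateaus) see only their immediate neighbours, and a collinear stretch forms
a path graph. Adjacent points are always visible, so interior nodes have
in- and out-degree at least 1.

Construction uses a per-origin running-maximum-slope scan: j is visible from
i < j iff the chord slope from i to j strictly exceeds every chord slope from
i to an intermediate point. This is an exact algebraic rearrangement of the
criterion (worst-case O(T²), numba-compiled); correctness is pinned in the
test suite against a direct O(T³) evaluation of the criterion on random,
discretised (tie-rich) and irregularly sampled series.

## Degree distributions

- **Boundary nodes.** The first node of a layer has in-degree 0 and the last
  out-degree 0 by construction, not dynamics. Both are excluded from both
  directions by default, so in- and out-distributions share the same pool of
  M = s·(T−2) interior nodes and the support {1..dmax}^k is literal. Setting
  `exclude_boundary=False` pools them and widens the support to {0..dmax}
  so that zero degrees remain representable.
- **Truncation.** A single dmax — the maximum directed degree observed over
  all layers, nodes, samples and both directions, capped at 75 by default —
  is shared by both directions and all tuples of an analysis, so every JSD
  compares distributions on an identical support. Degrees above dmax are
  clipped into the top bin, preserving normalisation; discarding them would
  give in and out different pool sizes.
- **Smoothing.** P ← ½·(N/M) + ½·dmax^{−k} averages the empirical histogram
  with the uniform prior on the truncated support, eliminating zeros so every
  KLD term is finite. Smoothing is mass-preserving and is on by default for
  any divergence computation; it can be disabled, e.g. for the exact
  marginalisation consistency check (marginalising an unsmoothed joint equals
  the directly estimated unsmoothed marginal bin-for-bin; the same identity
  holds for smoothed distributions because the uniform prior marginalises to
  the uniform prior).
- **Sparse storage.** Only occupied bins carry explicit counts; the smoothing
  floor is implicit. KLD/JSD sum over the union of occupied bins and treat
  the unoccupied remainder analytically (both distributions hold the same
  floor there, contributing zero), so a 5-tuple at dmax = 75 never touches
  75⁵ ≈ 2.4·10⁹ bins. Degree vectors are radix-encoded to 1-D integers for
  counting, which is lossless for dmax^k < 2⁶³.

## Divergences and reports

All logarithms are natural (nats); the JSD bound is ln 2 ≈ 0.6931. Level
sweeps report the population SD (ddof = 0) over the C(N,k) tuples, and the
annotation rule is floor(|z|) symbols at |z| ≥ 1 (stars above, daggers
below); the rule is a display convention and configurable in the sense that
the raw z values are always exported alongside. A zero level SD yields no
annotations and sets a flag. The unique-contribution recursion is evaluated
bottom-up on the smoothed sigma values; the reconstruction identity
(sum of eta over all nonempty subsets equals sigma) then holds by
construction and is verified to 1e−10 in tests.

## Surrogates and error bars

The default null shuffles all variables with **one** time permutation per
sample (joint mode), destroying temporal order while preserving the marginal
value distributions and the equal-time cross-correlation exactly; per-layer
independent permutation is available when the instantaneous coupling itself
should be destroyed. Surrogate r of sample s is seeded by SeedSequence
([seed, r, s]), so null distributions are bit-reproducible and independent of
execution order, and the same shuffled draws serve every tuple (results are
identical to per-tuple runs). The observed panels' dmax is reused for all
null draws so observed and null sigmas share a support. Percentile ranks use
strict inequality (ties count against the observed value — conservative).
Defaults of 99 surrogates and a 95th-percentile criterion are package
conventions. Subsampling draws floor(fraction·s) trials without replacement,
recomputes sigma from the cached degree tables, and reports the mean and SD
over repeats.

## Synthetic data

The generators provide ground truth spanning the reversibility axis:

- `gen_iid_gaussian` — exchangeable, hence exactly reversible; the
  calibration baseline.
- `gen_asymmetric_ou` — Euler–Maruyama discretisation (dt = 0.05 by default,
  burn-in of ten relaxation times) of dX = AX dt + σ dW. With isotropic noise
  the process is reversible iff A is symmetric; `rotational_drift(n, eps)`
  (−I plus an antisymmetric nearest-neighbour rotation of strength eps) gives
  a stable one-parameter irreversibility family, and `hierarchical_drift`
  builds a 6-channel template with a weakly reciprocal (near-reversible)
  sensory-like pair driving a cascade of one-way coupled channels.
- `gen_logistic_map_panel` — dissipative chaos (r in the chaotic band,
  1000-step transient discarded), the strongly irreversible positive control.
- `gen_cohort` — participants × trials panels with per-trial seed streams
  SeedSequence([seed, participant, trial]). The default cohort (6 variables,
  51 participants × 15 trials, T = 4500, hierarchical OU) emulates the shape
  of a source-localised neurophysiological study: a handful of regions, many
  short trials, mixed reversible/irreversible channels with asymmetric
  cross-coupling.

What the synthetic fixtures do **not** emulate: 1/f spectra, oscillatory
band structure, measurement noise and cross-talk from source reconstruction,
inter-participant heterogeneity, and nonstationarity across a trial. Passing
tests therefore demonstrate correct and well-calibrated estimation on
processes with known ground truth, not that any particular neural dataset is
irreversible.

## Problem sizes in tests and the acceptance script

Validation runs use deliberately modest sizes chosen to give the relevant
effects comfortable signal-to-noise on a single CPU: calibration cohorts of
10 participants × 5 trials at T = 500 with 49 surrogates over 20 repeats;
detection fixtures of 20 trials at T = 1000–2000 with 99 surrogates; sweep
demonstrations on 6-variable cohorts with the dmax = 75 cap exercising the
sparse high-order path. Larger panels only sharpen the same comparisons.

## Known limitations

- sigma is biased upward for finite samples (smoothing pulls both
  distributions toward uniform but empirical noise dominates); compare tuples
  at the same level and against surrogate nulls rather than across supports
  or cohort sizes.
- dmax truncation discards tail information; with very heavy-tailed degree
  distributions (strong spikes) the clipped top bin can carry noticeable
  mass. The cap is configurable.
- The number of tuples explodes combinatorially in N; the intended regime is
  a coarse parcellation (N of order 10 or less) where every tuple is
  interpretable.
- Visibility graphs are invariant under positive affine maps of the values
  but not under monotone nonlinear transforms; variables should be on scales
  where "large positive fluctuation" is meaningful.
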