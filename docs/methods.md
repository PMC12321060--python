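# Methods

`fatiguenet` implements a pre/post resting-state EEG analysis of cognitive
fatigue: band-limited spectral power, phase-lag functional connectivity,
weighted graph-theory metrics of the resulting networks, and a paired
statistics layer — together with a synthetic cohort generator that provides
ground truth for every stage. This note records the models, the defaults
and why they were chosen, and the places where a convention had to be
decided.

## Montage and regions

Analyses assume 56 scalp channels in extended 10–20 layout, grouped into
ten regions (prefrontal → temporo-parietal) for nodal-metric aggregation.
The region lists are stored verbatim from their published source; two
consequences are surfaced rather than silently repaired:

* the prefrontal row lists F1/FZ/F2, which also belong to the frontal row —
  `validate_montage` reports the overlap as a warning;
* the region tables name only 51 distinct channels; the remaining five
  (FP1, FPZ, FP2, FT7, FT8) are **inferred** standard 10–20 names, marked as
  such in `montage.INFERRED_CHANNELS`.

## Spectral power

Power spectral density is estimated with Welch's method: Hann-tapered
segments, 50 % overlap, constant detrending, one-sided density. The segment
length defaults to 2 s (0.5 Hz resolution) — long enough to resolve the 4 Hz
θ edge, short enough that a 3-minute record averages ~180 segments. Band
power is the rectangle-integral of the density over θ (4–8 Hz), α (8–13 Hz)
or β (13–30 Hz); shared edges are half-open (`[lo, hi)`), so 8 Hz belongs to
α only and 13 Hz to β only. Band powers are reported as `log10` of the
integral: group-level resting EEG band powers are conventionally tabulated
on a log scale (and plausible linear densities would never produce negative
group means). The whole-brain value is the arithmetic mean over all 56
channels.

## Phase-lag connectivity

Each channel is band-pass filtered (4th-order Butterworth, applied
forward–backward so the filter is zero-phase), the instantaneous phase is
taken from the analytic (Hilbert) signal, and one second of filter edge
transient is trimmed from each end before any phase statistic.

Two estimators of pairwise phase-lag coupling ship:

* `paper_formula` (default): `wPLI(i,j) = |Σ_k sin(Δφ_k)| / N` — the
  magnitude of the time-averaged sine of the phase difference. Zero-lag
  coupling contributes nothing (`sin 0 = 0`), a constant lag φ gives
  `|sin φ|`, and the estimate is invariant to channel amplitude scaling and
  common phase rotations.
* `standard_wpli`: the Vinck weighted phase lag index,
  `|E[Im S]| / E[|Im S|]` with `S` the cross-spectrum of the analytic
  signals. This self-normalizing form reaches 1 for any consistent nonzero
  lag.

The two differ in general and neither is asserted to be "the right one";
`paper_formula` is the default and every result is reproducible under
either via a flag. The estimator is evaluated over the full continuous
record (a single sum over samples), not epoch-averaged. All 1 540 unique
pairs are computed once (one complex matrix product for `paper_formula`)
and mirrored into a symmetric 56 × 56 matrix with zero diagonal.

At the default study scale (180 s at 500 Hz, ~89 000 retained samples) the
null level of `paper_formula` for independent channels is ≈ 0.02 with a
maximum over all pairs below 0.1.

## Graph metrics

Connectivity matrices are proportionally thresholded: exactly
`round(p · 1540)` strongest edges are retained with their weights (no
binarization); ties at the cutoff break by lexicographic channel order so
the selection is reproducible. Statistics default to p = 0.25, and a sweep
over 0.10–0.50 in 0.05 steps is available for threshold-dependence curves.

All metrics are weighted, with shortest-path edge length `1/weight`:

* **Eg** — mean of `1/d(i,j)` over ordered pairs (disconnected pairs
  contribute 0);
* **Lp** — mean `d(i,j)` over connected pairs;
* **Cp** — mean Onnela clustering, `C_i = Σ_{j,h}(ŵ_ij ŵ_ih ŵ_jh)^{1/3} /
  (k_i(k_i−1))`. Weights are normalized by the *scale ceiling* (1 for
  wPLI-type weights, the network maximum only if weights exceed 1) rather
  than each network's own maximum: per-network max normalization cancels a
  uniform strengthening of the connections and in practice reverses the
  direction of pre/post clustering changes whenever the strongest edge
  itself strengthens. Ceiling normalization keeps `Cp ∈ [0,1]`, preserves
  `Cp = 1` for an unweighted triangle, and is monotone in coupling strength;
* **Eloc** — mean over nodes of the (Latora–Marchiori) efficiency of the
  node's neighborhood subgraph;
* **Sigma** — small-worldness `(Cp/Cp_rand)/(Lp/Lp_rand)`, with null means
  over seeded degree-preserving (Maslov–Sneppen) rewired surrogates that
  carry the original weights on the rewired edges; 100 surrogates by
  default. For triangle-free graphs the ratio is undefined and `Sigma` is
  NaN;
* **NE** — per-node mean of `1/d(i,j)` to all other nodes; **DC** — the
  node's summed retained weights (strength). Both are also averaged within
  each montage region.

Distances come from Dijkstra's algorithm (SciPy sparse graph routines) and
are fuzz-tested against a brute-force Floyd–Warshall enumeration.

## Statistics

Every comparison is paired (same subjects pre and post). The branch between
the paired t-test and the Wilcoxon signed-rank test is a pure function of a
normality gate on the paired differences, at 0.05: Shapiro–Wilk for network
metrics, the Lilliefors-corrected Kolmogorov–Smirnov test for band powers
(the estimated-parameter K-S variant that standard statistics packages
report). Samples of n ≤ 3 are "not evaluated" and routed to the
nonparametric branch; in the pipeline the same convention applies to
regions with ≤ 3 channels.

Effect sizes: Cohen's `d = M_diff / S_diff` on the parametric branch
(converted to `r = d/√(d²+4)` for cross-family comparison) and `r = Z/√N`
on the signed-rank branch, `Z` being the continuity-corrected
normal-approximation statistic. The literal form `r = Z/N` sometimes seen
in print cannot produce effect sizes of the usual magnitude and is
available only behind `wilcoxon_r="z_over_n"` for audit. Wilcoxon p-values
use the exact distribution below 20 informative pairs (without ties) and
the normal approximation otherwise. All tests are two-sided.

Bonferroni families: the three band tests (α′ = 0.05/3 ≈ 0.0167), the five
global metrics (α′ = 0.01), and the local metrics with m = 10
(α′ = 0.005). Spearman rank correlations relate per-subject metric changes
(Eg, Eloc, Lp, Cp, and regional NE) to the change in the VAS-F total
score, defined here as `(fatigue + (100 − energy))/2` on the 0–100 scale —
the two subscales point in opposite directions, so this combination rises
monotonically with overall fatigue.

The pipeline selects the "sensitive band" as the one with the largest |r|
across the three band tests (exact ties fall back to θ < α < β order with a
warning) and builds connectivity networks only in that band.

## Synthetic cohorts

The generator emulates paired 56-channel resting recordings (defaults:
48 subjects, 180 s at 500 Hz). Each channel is a sum of:

* `1/f^β` Gaussian background noise (β = 1), giving realistic broadband
  spectra without committing to a head model;
* per-band oscillations built from band-pass-filtered white noise — not
  pure sinusoids, whose constant instantaneous phase would make phase
  metrics degenerate — with variance set by the configured (pre, post)
  band levels;
* shared carriers for coupled channel groups: each member mixes the group
  carrier (rotated by a constant per-position phase lag) against its own
  independent oscillation as `√(1−s²)·independent + s·carrier`, so a fully
  coupled pair at lag φ has phase-lag coupling `|sin φ|` and `s = 0`
  recovers independence.

Default fatigue signatures (chosen once to mirror the study conditions the
pipeline is meant to detect): oscillation variance rises in every band —
θ 1.0 → 1.2, α 1.0 → 2.2, β 0.5 → 0.55 — so that, after the log transform
and with per-condition log-normal level jitter (σ = 0.15) plus per-subject
jitter (σ = 0.2), the α effect size is by far the largest and β sits near
the moderate-effect boundary; and α-band coupling strength rises 0.3 → 0.6
in four groups covering the frontal, fronto-central, central and
centro-parietal regions (incremental lag 0.5 rad). Per-channel amplitudes
are jittered ±20 %, which must not (and does not) move any phase metric.
VAS-F scores are drawn per subject and condition from the configured means
and SDs on a 0–100 scale (fatigue ≈ 11 → 81, energy ≈ 42 → 20). A printed
10-cm scale description would imply 0–10, but the reported magnitudes are
0–100; the generator follows the magnitudes.

Determinism: all draws flow from one root seed through named substreams
(per-subject, per-recording, scores), so identical configurations give
bit-identical cohorts while subjects and conditions remain independent.
Recordings are generated lazily on access; a full cohort is never held in
memory.

What the generator does *not* emulate: volume conduction and field spread
(beyond the zero-lag insensitivity built into the estimator), eye/muscle
artifacts, non-stationarity within a recording, and realistic inter-region
correlation structure outside the configured coupling groups. Passing
recovery tests therefore demonstrate that the pipeline detects the modelled
signatures at realistic noise levels — not that real fatigue EEG must
behave this way.

## Problem sizes in the test suite

Cohort-level tests (signature recovery and no-effect type-I control) run on
scaled conditions — 10 subjects, 30 s records at 250 Hz, 10 replicate
cohorts, 8 rewired surrogates per Sigma — which keep the full suite to a
few minutes on one CPU while leaving every effect detectable by a wide
margin (the injected α contrast has d ≈ 3–4 at this scale). Estimator
properties that need long records (the null wPLI bound, coupled-entry
dominance) use single recordings at up to 180 s / 500 Hz.

## Numerical details and edge cases

* Welch on an all-zero signal returns an all-zero density; non-finite
  samples are rejected.
* `log10` band power of a zero-power band is −inf by construction (NumPy
  divide semantics), never an exception.
* Thresholding requires `0 < p ≤ 1`; an empty graph raises on global
  metrics; isolated nodes have NE = DC = 0; disconnected pairs contribute 0
  to efficiency and are excluded from Lp.
* Degenerate paired samples (all-zero differences) raise rather than
  returning a meaningless test.
* Spearman correlation on constant input raises (undefined ranks).
* The wPLI matrix is clipped to [0, 1] and symmetrized against round-off
  before validation.

## Known limitations

* The pipeline assumes cleaned EEG; no artifact handling is provided.
* Statistics are evaluated at a single sparsity by default; the sweep is
  descriptive. Whether single-threshold or area-under-curve testing is
  preferable is left to the user.
* `Sigma` from 100 weight-carrying rewires is a conventional, not unique,
  small-world normalization; other null models (weight shuffles,
  strength-preserving rewires) would give different absolute values.
* Effect sizes of the nonparametric branch depend on the normal
  approximation for Z even when the p-value is exact.
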