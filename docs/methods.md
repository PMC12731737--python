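# Methods

## Problem and model

`entroseg` performs bi-level thresholding of grayscale images: a single
gray-level cutoff `t` splits the pixels into a background class A (levels
`0..t`) and a foreground class B (levels `t+1..L`), producing a binary
segmentation. All criteria operate on the image histogram alone. With
`p_0..p_L` the level probabilities, class masses `P_A = Σ_{i≤t} p_i`,
`P_B = 1 − P_A`, and renormalized class distributions `p_i/P_A`, `p_i/P_B`,
the implemented selection rules are:

| method        | objective maximized over t |
|---------------|----------------------------|
| `shannon`     | `S(A) + S(B)` (Kapur) |
| `tsallis`     | `S_q(A) + S_q(B) + (1−q) S_q(A) S_q(B)` (Albuquerque) |
| `masi`        | `S_r(A) + S_r(B)` (Nie et al.) |
| `linou`       | form 1 `min(S(A), S_q(B))`; form 2 `min(S_q(A), S(B))` (Lin & Ou) |
| `maxmin_masi` | form 1 `min(S(A), S_r(B))`; form 2 `min(S_r(A), S(B))` |

where `S` is Shannon entropy, `S_q = (Σ p_i^q − 1)/(1 − q)` is Tsallis
entropy and `S_r = ln(1 + (1−r) S)/(1−r)` is Masi entropy. The max–min
forms trade off the two class entropies instead of summing them: Shannon
on one class captures short-range pixel correlation, the nonextensive
entropy on the other captures long-range correlation, and maximizing the
smaller of the two balances the information in both regions. Form 2
(entropies interleaved) is for images whose *background* carries the
weaker long-range correlation, e.g. a sharply peaked background mode.

All logarithms are natural. `0·ln 0 := 0`, and zero-probability levels are
dropped before exponentiation so `p^q` is well defined for `q ≤ 0`.

### Masi domain

`S_r` exists only where `1 + (1−r) S > 0`. For `r < 1` this always holds;
for `r > 1` it requires `S < 1/(r−1)`, so on histograms with high class
entropy (wide modes, near-uniform regions) many or all `(t, r)` candidates
are invalid. Invalidity is carried as a value state, not an exception:
the search excludes invalid candidates from the argmax but keeps them,
flagged, in the exported objective trace, and raises only when *no*
candidate is valid. Parameters within `1e−6` of 1 are routed to the
Shannon limit instead of evaluating the ill-conditioned `1/(1−r)` form.

### Conventions

- Levels are 0-based `0..L`; candidate thresholds are `t ∈ {0..L−1}` with
  both classes non-empty (decided on exact integer counts). Level `t`
  itself belongs to the background.
- Foreground = pixels strictly above `t` (bright objects); `invert`
  options cover dark objects.
- Tie-break: the smallest maximizing `t` (and the smallest parameter in
  grid searches). A deterministic rule is required for exact
  reproducibility; nothing in the theory prefers one tie member.
- RGB input is converted with BT.601 luma (0.299 R + 0.587 G + 0.114 B),
  round-half-up — a fixed, documented choice.

### Implementation note

The per-`t` class entropies are computed for all candidates at once from
cumulative sums (`S_A(t) = ln P_A − (Σ_{i≤t} p_i ln p_i)/P_A`, Tsallis from
cumulative `p^q`, Masi as a pointwise transform of the Shannon curve), so
a full landscape costs O(L) per parameter value. The test suite checks
every criterion against an independent long-double brute-force loop over
explicitly normalized class distributions.

## Parameter search

Two routes select the entropic parameter:

1. **Grid search** (`grid_search_param`): score each grid value by the
   misclassification error (ME) of its binarization against a ground-truth
   mask; return the minimizer (smallest on ties). The conventional grids
   are `q ∈ [0.1, 0.9]` step 0.1 and `r ∈ [0.7, 1.7]` step 0.1 (excluding
   1). An optional single bisection pass (`refine=True`) samples the
   midpoints around the best coarse cell, replacing ad-hoc manual
   oversampling.

2. **Simulated annealing** (`run_algorithm1`): a stochastic walk over `r`
   wrapped around the max–min criterion. Each step perturbs the accepted
   parameter, `r_j = r̂ + U(−d, d)` (resampled, up to 100 draws, if
   `r_j ≤ 0`), re-solves the exhaustive threshold search, scores the
   binarization, and accepts or rejects Metropolis-style under geometric
   cooling `T ← T·α`. With ground truth the score is ME (minimized;
   worsening moves accepted with probability `exp(−ΔE/T)`); without it the
   score is the uniformity measure UM (maximized; `exp(ΔUM/T)`, ΔUM < 0).
   The run exits early once ME ≤ `e_ref` (default 0) or UM ≥ `um_ref`
   (default 1). If the form-1 objective finishes its schedule without
   reaching the reference, the whole schedule is repeated with the form-2
   objective and the better result is returned. `fix_par=0` disables the
   walk entirely (fixed-parameter segmentation). A `masi_only` variant
   (`run_algorithm_a1`) swaps the inner criterion for the plain Masi sum,
   for ablation.

Defaults (also the CLI/YAML defaults): `r_init=1.5`, `d=0.1`,
`T_initial=100`, `T_min=1e−3`, `cooling=0.99`, `markov_length=20`,
`max_iter=100`, `e_ref=0`, `um_ref=1`. The inner loop evaluates
`markov_length − 1` candidates per temperature level (the loop bound is
`j < markov_length`, kept literally); with `T_initial=100`, `cooling=0.99`
and `max_iter=100` the run is iteration-bounded (T only falls to ≈ 36.6),
giving at most `100 × 19` scored candidates per form.

Design choices where the procedure was genuinely open:

- **Acceptance baseline.** A candidate is compared, by default, with the
  score of the currently accepted parameter — standard annealing. A
  `strict_paper` switch instead compares with the *previous candidate's*
  score even if that candidate was rejected; both are provided so either
  convention can be audited.
- **Best-so-far bookkeeping.** The returned `(t, r̂, score)` is the best
  seen anywhere in the run, not the final accepted state; the best-so-far
  trace is therefore non-increasing (ME) / non-decreasing (UM) by
  construction.
- **Invalid initial parameter.** If even the initial `r` admits no valid
  threshold, the candidate is logged as rejected and the walk proceeds
  (the first valid candidate found is accepted unconditionally); the run
  fails explicitly only if no valid candidate ever appears. With
  `fix_par=0` there is no walk to recover with, so the error propagates.
- **Determinism.** One seeded generator per run drives perturbations and
  acceptance draws; identical `(image, config, ground truth, seed)` give
  bit-identical results.

## Accuracy metrics

ME (fraction of pixels whose label disagrees with ground truth), Jaccard
similarity of the foregrounds in percent, relative foreground area error
`||F_GT|−|F_T||/max(|F_GT|,|F_T|)`, precision/recall and the weighted
harmonic mean `F_α = (1+α)PR/(αP+R)` with α = 0.5 by default. Without
ground truth, the uniformity measure

    UM = 1 − 2 (s₁ + s₂) / (N·M·(I_max − I_min)²)

with `s_i` the *sum* of squared deviations from region i's mean intensity.
Reading `s_i` as a sum (rather than a mean-normalized variance) is what
makes the `N·M` denominator normalize UM into a bounded score — the
classical form of the measure; `literal_variance=True` exposes the other
reading. Guards: a constant image scores UM = 1; an empty region
contributes 0. Empty-set conventions for the ground-truth metrics are the
continuity limits (JS with both foregrounds empty = 100, RAE with both
empty = 0, F with empty prediction = 0).

## Pixel-graph validation

The image is a 4-connected graph with normalized contrast weights
`w_ij ∝ exp(−β (I_i − I_j)²)`, intensities rescaled to `[0,1]` first so β
(default 10) has an image-depth-independent meaning. A threshold induces
the partition `S_t = {pixels ≤ t}` with cut, volumes and isoperimetric
ratio `h(S_t) = cut/min(vol S, vol S̄)`. Substituting class entropies for
the volumes and using `cut ≤ 1` (forced by weight normalization) bounds
the entropy ratio by `1/min(S_A, S_r_B)` — minimizing that bound is
maximizing the min-entropy, i.e. exactly the max–min criterion. The
module checks the literal inequalities per `t` and reports both the
min-entropy argmax (which must agree with the criterion's threshold) and
the minimum-ratio threshold. It does not attempt to *solve* the
isoperimetric partitioning problem, and the entropy-for-volume
substitution itself is heuristic — only its consequences are tested.
Intended for small images: the cut loop touches every edge per candidate.

## Synthetic fixtures

`make_bimodal` draws per-pixel intensities from two normal laws
(background/foreground), rounds and clamps to `[0, L]`, with rectangle,
disk or half-plane foreground geometry and exact ground truth. The default
spec — 128×128, modes 60/190, stddev 15, foreground fraction 0.25 — gives
two well-separated populations (> 4σ apart) with a nearly empty histogram
valley: the regime the entropy criteria assume. `add_gaussian_noise`
perturbs on the unit intensity scale (a σ grid like 0.02..0.20 is
meaningful there; per-gray-level σ would make those values sub-quantal).

What the fixtures do *not* emulate: spatial intensity correlation within
regions, sensor noise statistics (fixed-pattern, shot noise), skewed or
multimodal histograms, and natural-scene content. Passing tests on these
fixtures demonstrate correctness of the machinery and recovery in the
idealized bimodal regime, not field performance on IR/NDT imagery.

Note the interaction between mode width and the Masi domain: with stddev
15 the class entropies are ≈ 4 nats, so at `r = 1.5` the Masi *sum*
criterion (which needs both classes valid) has an empty candidate set and
the `masi_only` annealer cannot start — an honest property of the method,
exercised in the tests. The max–min criterion only needs one Masi term
valid and is unaffected. Fixtures for the `masi_only` variant therefore
use tighter modes (stddev 1.5, class entropy ≈ 1.8 < 1/(r−1) = 2).

## Experiment protocols

- `sensitivity_sweep`: ME at fixed `r_k = r̂ + kΔr`, k ∈ [−3, 3],
  Δr = 0.01; reports ΔME(k) = |ME(k) − ME(0)|.
- `convergence_test`: chains annealing runs, feeding each returned r̂ to
  the next run as the initial guess, until ME = 0 or the restart budget.
- `noise_sweep`: mean ME over seeded noisy replicates per σ.
- `repeated_run_ablation`: n seeded runs, reporting (r̂, ME, UM) per run
  and the r̂ envelope.

All runners are pure functions of their inputs and seeds; reports embed
their configuration and are regenerable bit-identically.

## Problem sizes

The shipped tests and the acceptance script use the 128×128 fixture for
annealing runs (a run costs well under a second), 32–64-level random
histograms for oracle-equivalence checks (200 per criterion), 8×8 images
for graph checks (50 seeds), 10 annealing repeats for the spread study and
5 replicates per noise level — sizes at which every check is exact or
statistically stable while the whole suite completes in seconds.

## Known limitations

- Bi-level only; no multilevel extension.
- The annealer offers no guarantee of reaching `e_ref`/`um_ref`; on hard
  inputs the result is the best-so-far state after the schedule.
- UM is a weak guide when both regions are internally smooth but wrongly
  placed; UM-guided runs can settle on a different threshold than
  ME-guided ones (the shipped example does).
- `isocheck` is O(edges × levels) and meant for small images.
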