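# Methods

## Model and decoding

The shifting level model treats an ordered log2-ratio signal as an
unobserved piecewise-constant mean observed through Gaussian white noise.
The mean level m_i either persists (probability 1 − η) or, with probability
η, resamples from N(μ, σ²_m); the observation is x_i = m_i + ε_i with
ε_i ~ N(0, σ²_ε). The model is a hidden Markov model once the continuous
level is discretized, and the package decodes the joint
maximum-a-posteriori level path by the Viterbi algorithm.

**State space.** The continuous level process is embedded on a grid of K
candidate levels placed at the data quantiles between 0.005 and 0.995
(default K = 41). A quantile grid puts resolution where the data mass is
while still reaching the outlying levels created by real events, and it
makes the decoder equivariant under adding a constant to the profile.
Duplicate quantiles (heavily tied data) are dropped, shrinking the grid;
fewer than two distinct levels marks the profile degenerate and the
segmentation short-circuits to a single segment. The level prior π is the
N(μ, σ²_m) density evaluated at the grid, renormalized, and floored at
1e-12 so every level remains reachable in log space.

**Transitions.** A jump lands on level k with probability π_k independent
of the origin, giving the rank-one-plus-diagonal matrix
A[j,k] = (1 − η)1[j=k] + η π_k. The heterogeneous model replaces the scalar
η by η(d_i) = θ + (1 − θ)·exp(log(θ)·d_Norm/d_i), evaluated per step from
the gap d_i = start_i − end_{i−1} (floored at 0) between consecutive
windows. The rewritten exponent is algebraically identical to the form with
1/(d/d_Norm) but needs no special case at d = 0: in IEEE arithmetic
d_Norm/0 = ∞, log(θ)·∞ = −∞ and exp(−∞) = 0, which is exactly the analytic
limit η(0) = θ. Gap distance (rather than center-to-center) was chosen so
that densely tiled profiles have d_i = 0 throughout and the heterogeneous
chain reduces bit-identically to the homogeneous one — both models share a
single decoding kernel that consumes a per-step η vector, so the reduction
is structural, not numerical luck.

**Viterbi kernel.** The stay-or-jump structure lets each recursion step be
computed in O(K) instead of O(K²): the best predecessor of state k is
either k itself or the globally best jump origin. Ties are resolved by a
precise rule — among all maximum-probability paths, the lexicographically
smallest level-index sequence is returned — implemented as a backward
dynamic program over suffix scores followed by a greedy forward
reconstruction that takes the lowest index attaining the optimum at each
position. The test suite verifies the decoder, including the tie-break,
against exhaustive enumeration of all K^N paths on hundreds of random small
instances for both the homogeneous and heterogeneous chains.

**Segments and calls.** The decoded path is run-length collapsed; each
segment's reported mean is the empirical mean of its windows' observed
values rather than the grid level, since the grid is a discretization
artifact and the empirical mean is the natural level estimate given the
breakpoints. Optionally, segments shorter than `min_seg_windows` are merged
into the neighbor with the closer mean (left on exact ties; shortest
offender first; means recomputed after each merge); the default of 1
performs no merging so the raw model output is visible. CNV calls classify
segment means against thresholds (loss ≤ −0.5, gain ≥ +0.3 by default,
bracketing the theoretical one-copy −1 and three-copy +0.585 levels with a
noise margin) and merge adjacent same-state altered segments.

## Parameter estimation

A single moment-based pass, chosen for reproducibility over full
Baum-Welch:

* **μ** — median of the values.
* **σ²_ε** — squared robust scale of first differences divided by 2:
  (1.4826·MAD(Δx))²/2. Within segments Δx is pure noise with variance
  2σ²_ε, and the MAD ignores the rare large differences at true shifts;
  this is the standard changepoint noise estimator. If the MAD vanishes on
  tied data, the raw variance of the differences is used; zero variance
  marks the profile degenerate.
* **ω** (default 0.3) — the assumed noise share of the total variance, so
  σ²_m = σ²_ε·(1 − ω)/ω. ω only shapes the level prior's spread (and hence
  the mild prior penalty on extreme levels); anchoring σ²_ε to the
  first-difference scale rather than deriving it from ω keeps the noise
  model calibrated regardless of how many events the profile contains. An
  early variant that assigned σ²_ε = ω·(first-difference variance)
  systematically underestimated the noise by the factor ω and produced
  spurious segments on event-free profiles; the current scheme fixes that
  while preserving ω's meaning as a variance split.
* **η** (default 1e-5) — held fixed, not re-estimated: jumps are rare by
  assumption and η is the user's sensitivity dial (it is the swept
  parameter in the ROC construction). θ for the heterogeneous model
  defaults to the same 1e-5, with d_Norm = 100 kb.
* An optional iterative mode (`fit(reestimate=True)`) re-estimates σ²_ε
  from the Viterbi residuals until the change is below 1e-6 relative or 20
  iterations — useful when the first-difference scale is inflated by
  extremely dense breakpoints, but off by default so results are a pure
  function of the single-pass estimates.

## Normalization

Raw window read counts are corrected by the stratified-median scheme:
windows are binned by GC fraction (bin width 0.01), each stratum with at
least 20 usable windows is rescaled by global-median/stratum-median, and
windows with mappability below 0.5 are excluded outright (indices recorded
so segments map back to genomic coordinates). Corrected counts are
log2-transformed against the global median (zero counts floored at half a
read and flagged), and the log2 profile is median-centered by default so
the diploid baseline sits at 0. The correction preserves the global median
by construction and is exactly the identity when no GC trend exists.

## Synthetic data

The simulator generates one synthetic chromosome of 10 000 contiguous
windows (defaults) with a single embedded event of N windows: background
windows draw from N(0, σ²) and event windows from N(shift, σ²), with shift
−1 (one-copy loss) or +log2(3/2) (three-copy gain) — the theoretical
diploid log2 levels. The event is placed uniformly at random with at least
one background window per flank. `coverage_noise_sd` ties σ to a sequencing
design via the delta method: λ = coverage·window_bp/read_length expected
reads per window gives sd(log2 C) ≈ 1/(ln 2·√λ), flagged when λ < 10 where
the Poisson-to-normal approximation degrades. Sparse (exome-like) profiles
add log-uniform [1, max_gap] bp gaps between windows, drawn from a
dedicated random stream so window values are identical with and without
gaps at a fixed seed.

What the generator does **not** emulate: GC and mappability bias (the
normalization tests inject their own), correlated noise and wave artifacts
of real read depth, heavy-tailed count noise at low coverage, multiple
overlapping events, and allele-specific signals. Passing tests therefore
demonstrate correctness of the decoding and scoring machinery under the
model's own assumptions — Gaussian noise around piecewise-constant levels —
not robustness to every artifact of real sequencing data.

## Evaluation

Breakpoint accuracy is the window distance between each true breakpoint
and its nearest prediction (and symmetrically for predictions). Because
Viterbi emits hard calls with no per-breakpoint score, ROC operating points
are generated by sweeping the jump probability (η, or θ for the
heterogeneous model): at each value, TPR is the fraction of true
breakpoints matched within a tolerance (default 2 windows) and FPR divides
unmatched predictions by the number of eligible negative positions
(windows not within tolerance of any true breakpoint). The curve is
anchored at (0,0) and (1,1) and integrated by trapezoid, so a segmenter
that never predicts scores exactly 0.5. Interval-level scoring uses the
any-overlap rule — one shared base pair makes a call a true positive — with
an optional (default-on) requirement that the call's copy direction match
the truth; metrics are stratified into Small (< 20 kb), Medium (20–100 kb)
and Large (≥ 100 kb) event classes, with FP calls classified by their own
length since they overlap no truth interval.

## Numerical choices and problem sizes

All decoding is in log space; log(1 − η(1 − π_j)) uses `log1p`. The
acceptance script and test suite run at the documented study conditions —
10 000-window profiles, 100-replicate batches, a 100-window one-copy event
at noise sd 0.2 (the 20x/1000 bp regime), exhaustive-enumeration checks at
N ≤ 8, K ≤ 4 — sizes at which a full run completes in a few minutes on one
core while the Monte-Carlo rates retain ~±3% binomial resolution.

## Known limitations

* Single-sample, single-signal segmentation only; no joint multi-sample
  decoding.
* η/θ are fixed, not learned; a poor choice shifts the
  sensitivity/specificity balance (small d_Norm in particular raises false
  positives on sparse data).
* The discretized grid caps level resolution at the quantile spacing;
  events rarer than ~0.5% of windows may lack a dedicated grid level near
  their true mean and decode to the nearest available level (breakpoints
  are typically still correct; the reported empirical mean is unaffected).
* Emission variance is global; per-window variances (e.g. exome capture
  efficiency) are not modeled.
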