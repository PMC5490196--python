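"""Homogeneous shifting level model (SLM) segmentation.

The shifting level model describes an ordered noisy signal x_1..x_N as

    x_i = m_i + eps_i,        eps_i ~ N(0, sigma2_eps)
    m_i = (1 - z_{i-1}) m_{i-1} + z_{i-1} (mu + delta_i),
                              delta_i ~ N(0, sigma2_m),  Pr(z_i = 1) = eta

i.e. an unobserved piecewise-constant mean level that, with small jump
probability eta, resamples from N(mu, sigma2_m), observed through white
noise.  This is a hidden Markov model once the continuous level process is
discretized onto a grid of K candidate levels: jumps land on grid level k
with probability proportional to the level prior pi_k, independent of the
origin, so the transition matrix is the rank-one-plus-diagonal

    A[j, k] = (1 - eta) * 1[j = k] + eta * pi_k.

Viterbi decoding of that HMM yields the segmentation.  The decoder below
exploits the rank-one structure for an O(N*K) recursion and defines ties
exactly: among all maximum-probability paths it returns the
lexicographically smallest index sequence (backward dynamic program, then
greedy forward reconstruction picking the lowest level index that attains
the optimum at each position).

Parameter estimation is moment-based and robust: mu is the median, the
total variance comes from the MAD of first differences (insensitive to the
level shifts themselves), and the variance-split fraction omega apportions
it between noise (sigma2_eps = omega * sigma2) and level spread
(sigma2_m = (1 - omega) * sigma2).  An optional iterative mode re-estimates
sigma2_eps from Viterbi residuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .profiles import (
    CNVCall,
    CopyState,
    GenomicProfile,
    Scale,
    Segment,
    Segmentation,
)

__all__ = [
    "SLMParameters",
    "LevelGrid",
    "TransitionModel",
    "estimate_parameters",
    "build_transition_matrix",
    "viterbi_decode",
    "slm_segment",
    "call_cnvs",
    "ShiftingLevelModel",
    "SegmentationResults",
]

DEFAULT_OMEGA = 0.3
DEFAULT_ETA = 1e-5
DEFAULT_N_LEVELS = 41
DEFAULT_LOSS_THRESHOLD = -0.5
DEFAULT_GAIN_THRESHOLD = 0.3


@dataclass
class SLMParameters:
    """Global model parameters (log2 units).

    ``degenerate`` is set when the profile carries no usable scale (constant
    input); segmentation then short-circuits to a single segment.
    """

    mu: float
    sigma2_m: float
    sigma2_eps: float
    eta: float
    omega: float
    n_levels: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate:
            if self.sigma2_m <= 0 or self.sigma2_eps <= 0:
                raise ValueError("variances must be strictly positive")
        if not 0 < self.eta < 1:
            raise ValueError("eta must lie in (0, 1)")
        if not 0 < self.omega < 1:
            raise ValueError("omega must lie in (0, 1)")
        if self.n_levels < 2:
            raise ValueError("need at least 2 candidate levels")


@dataclass
class LevelGrid:
    """Discretized candidate mean levels and their prior."""

    levels: np.ndarray
    prior: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.float64)
        self.prior = np.asarray(self.prior, dtype=np.float64)
        if len(self.levels) != len(self.prior):
            raise ValueError("levels and prior must have equal length")
        if np.any(np.diff(self.levels) <= 0):
            raise ValueError("levels must be strictly ascending")
        if np.any(self.prior <= 0) or not math.isclose(float(self.prior.sum()), 1.0,
                                                       rel_tol=0, abs_tol=1e-9):
            raise ValueError("prior must be strictly positive and sum to 1")

    @property
    def K(self) -> int:
        return len(self.levels)


@dataclass
class TransitionModel:
    """Stay-or-jump transition structure: per-step jump probability and jump-target prior.

    ``etas`` is either a scalar (homogeneous chain) or a length N-1 vector of
    per-step jump probabilities (heterogeneous chain).
    """

    prior: np.ndarray
    etas: float | np.ndarray

    def step_etas(self, n_steps: int) -> np.ndarray:
        if np.isscalar(self.etas):
            return np.full(n_steps, float(self.etas))
        etas = np.asarray(self.etas, dtype=np.float64)
        if len(etas) != n_steps:
            raise ValueError(f"expected {n_steps} step probabilities, got {len(etas)}")
        return etas

    def matrix(self, step: int = 0) -> np.ndarray:
        eta = float(self.etas) if np.isscalar(self.etas) else float(self.etas[step])
        return _stay_jump_matrix(self.prior, eta)


def _stay_jump_matrix(prior: np.ndarray, eta: float) -> np.ndarray:
    K = len(prior)
    return (1.0 - eta) * np.eye(K) + eta * np.tile(prior, (K, 1))


def build_transition_matrix(grid: LevelGrid, eta: float) -> np.ndarray:
    """Dense K x K matrix A[j,k] = (1-eta) 1[j=k] + eta pi_k (each row sums to 1)."""
    if not 0 <= eta <= 1:
        raise ValueError("eta must lie in [0, 1]")
    return _stay_jump_matrix(grid.prior, eta)


def estimate_parameters(
    profile: GenomicProfile | np.ndarray,
    omega: float = DEFAULT_OMEGA,
    eta: float = DEFAULT_ETA,
    n_levels: int = DEFAULT_N_LEVELS,
) -> tuple[SLMParameters, LevelGrid | None]:
    """Moment-based parameter estimates and data-quantile level grid.

    * mu = median of the values.
    * sigma2_eps = (1.4826 * MAD of first differences)^2 / 2 — the first
      difference of the signal doubles the noise variance but is immune to
      the piecewise-constant mean, and the MAD ignores the rare large
      differences caused by true shifts; this is the standard changepoint
      noise estimator.
    * omega is the noise share of the total variance
      (sigma2_eps = omega * sigma2_total), so
      sigma2_m = sigma2_eps * (1 - omega) / omega.
    * grid levels = ``n_levels`` quantiles of the data between 0.005 and
      0.995, deduplicated (a collapsed grid simply has fewer levels).
    * prior pi_k proportional to the N(mu, sigma2_m) density at each level.

    A constant profile (zero robust scale and zero variance) returns a
    parameter set flagged degenerate with ``grid = None``.
    """
    values = profile.values if isinstance(profile, GenomicProfile) else np.asarray(profile, float)
    if not np.all(np.isfinite(values)):
        raise ValueError("profile contains non-finite values; filter before segmentation")
    mu = float(np.median(values))

    if len(values) < 2:
        return SLMParameters(mu, 1.0, 1.0, eta, omega, n_levels, degenerate=True), None
    diffs = np.diff(values)
    mad = float(np.median(np.abs(diffs - np.median(diffs))))
    scale = 1.4826 * mad
    sigma2_eps = scale * scale / 2.0
    if sigma2_eps == 0.0:
        # MAD can vanish on heavily tied data; fall back to the raw variance
        sigma2_eps = float(np.var(diffs)) / 2.0
    if sigma2_eps == 0.0:
        return SLMParameters(mu, 1.0, 1.0, eta, omega, n_levels, degenerate=True), None

    sigma2_m = sigma2_eps * (1.0 - omega) / omega

    qs = np.linspace(0.005, 0.995, n_levels)
    levels = np.unique(np.quantile(values, qs))
    if len(levels) < 2:
        return SLMParameters(mu, sigma2_m, sigma2_eps, eta, omega, n_levels,
                             degenerate=True), None
    # prior ~ level-process density, computed via softmax for underflow
    # safety and floored so every level stays reachable in log space
    logp = -((levels - mu) ** 2) / (2.0 * sigma2_m)
    logp -= logp.max()
    prior = np.exp(logp)
    prior /= prior.sum()
    prior = np.maximum(prior, 1e-12)
    prior /= prior.sum()
    params = SLMParameters(mu, sigma2_m, sigma2_eps, eta, omega, n_levels)
    return params, LevelGrid(levels, prior)


def _log_emissions(values: np.ndarray, levels: np.ndarray, sigma2_eps: float) -> np.ndarray:
    const = -0.5 * math.log(2.0 * math.pi * sigma2_eps)
    resid = values[:, None] - levels[None, :]
    return const - resid * resid / (2.0 * sigma2_eps)


def viterbi_decode(
    values: np.ndarray,
    grid: LevelGrid,
    transition: TransitionModel,
    sigma2_eps: float,
) -> np.ndarray:
    """Joint MAP level-index path of the discretized shifting level model.

    Maximizes  log pi(s_1) + sum_i log A_i[s_{i-1}, s_i]
               + sum_i log N(x_i; level_{s_i}, sigma2_eps)
    in log space.  Among tied optima the lexicographically smallest index
    sequence is returned (lower level index wins at the earliest position).

    The recursion uses the stay-or-jump structure: the best predecessor of
    state k is either k itself (stay) or the globally best jump origin, so
    each step costs O(K) instead of O(K^2).
    """
    values = np.asarray(values, dtype=np.float64)
    if sigma2_eps <= 0 or not np.isfinite(sigma2_eps):
        raise ValueError("sigma2_eps must be positive and finite")
    N, K = len(values), grid.K
    log_pi = np.log(grid.prior)
    loge = _log_emissions(values, grid.levels, sigma2_eps)
    if N == 1:
        return np.array([int(np.argmax(log_pi + loge[0]))])

    etas = transition.step_etas(N - 1)
    if np.any((etas <= 0) | (etas >= 1)):
        raise ValueError("step jump probabilities must lie in (0, 1)")
    # per-step log transition pieces; computed identically for the
    # homogeneous and heterogeneous chains so the reduction is bit-exact
    log_stay = np.log1p(-etas[:, None] * (1.0 - grid.prior[None, :]))  # (N-1, K)
    log_jump = np.log(etas)[:, None] + log_pi[None, :]                 # (N-1, K)

    # backward DP: V[t, j] = best score of the suffix t..N-1 given state j at t
    V = np.empty((N, K))
    V[N - 1] = loge[N - 1]
    for t in range(N - 2, -1, -1):
        nxt = V[t + 1]
        best_jump = np.max(log_jump[t] + nxt)
        V[t] = loge[t] + np.maximum(log_stay[t] + nxt, best_jump)

    # greedy forward reconstruction: lowest index attaining the optimum
    path = np.empty(N, dtype=np.int64)
    path[0] = int(np.argmax(log_pi + V[0]))
    for t in range(1, N):
        prev = path[t - 1]
        cand = log_jump[t - 1] + V[t]
        cand[prev] = log_stay[t - 1, prev] + V[t, prev]
        path[t] = int(np.argmax(cand))
    return path


def _collapse_path(values: np.ndarray, path: np.ndarray) -> Segmentation:
    """Collapse a level-index path into segments with empirical means."""
    change = np.flatnonzero(path[1:] != path[:-1]) + 1
    bounds = np.concatenate(([0], change, [len(path)]))
    segments = []
    levels = np.empty(len(path))
    for a, b in zip(bounds[:-1], bounds[1:]):
        mean = float(np.mean(values[a:b]))
        segments.append(Segment(int(a), int(b - 1), mean))
        levels[a:b] = mean
    return Segmentation(levels, segments, [int(c) for c in change])


def _merge_short_segments(
    values: np.ndarray, seg: Segmentation, min_seg_windows: int
) -> Segmentation:
    """Absorb segments shorter than ``min_seg_windows`` into the nearer-mean neighbor.

    The shortest offending segment is merged first; exact mean ties go left.
    Means are recomputed from the observed values after every merge.
    """
    if min_seg_windows <= 1:
        return seg
    segs = list(seg.segments)
    while len(segs) > 1:
        lengths = [s.n_windows for s in segs]
        short = [i for i, L in enumerate(lengths) if L < min_seg_windows]
        if not short:
            break
        i = min(short, key=lambda j: (lengths[j], j))
        left = segs[i - 1] if i > 0 else None
        right = segs[i + 1] if i + 1 < len(segs) else None
        if left is not None and right is not None:
            dl = abs(segs[i].mean_level - left.mean_level)
            dr = abs(segs[i].mean_level - right.mean_level)
            into_left = dl <= dr
        else:
            into_left = left is not None
        if into_left:
            a, b = segs[i - 1].start_index, segs[i].end_index
            merged = Segment(a, b, float(np.mean(values[a:b + 1])))
            segs[i - 1:i + 1] = [merged]
        else:
            a, b = segs[i].start_index, segs[i + 1].end_index
            merged = Segment(a, b, float(np.mean(values[a:b + 1])))
            segs[i:i + 2] = [merged]
    levels = np.empty(len(values))
    for s in segs:
        levels[s.start_index:s.end_index + 1] = s.mean_level
    breakpoints = [s.start_index for s in segs[1:]]
    return Segmentation(levels, segs, breakpoints)


def _single_segment(values: np.ndarray) -> Segmentation:
    mean = float(np.mean(values))
    levels = np.full(len(values), mean)
    return Segmentation(levels, [Segment(0, len(values) - 1, mean)], [])


def call_cnvs(
    seg: Segmentation,
    profile: GenomicProfile,
    loss_threshold: float = DEFAULT_LOSS_THRESHOLD,
    gain_threshold: float = DEFAULT_GAIN_THRESHOLD,
) -> list[CNVCall]:
    """Classify segments as LOSS / NEUTRAL / GAIN and merge adjacent same-state altered runs.

    A segment with mean <= ``loss_threshold`` is a LOSS, >= ``gain_threshold``
    a GAIN, otherwise NEUTRAL.  Consecutive altered segments in the same state
    are merged into one call whose mean is the window-count-weighted mean.
    Only altered (non-neutral) calls are returned.
    """
    if not loss_threshold < 0 < gain_threshold:
        raise ValueError("thresholds must satisfy loss < 0 < gain")
    calls: list[CNVCall] = []
    run: list[Segment] = []
    run_state: CopyState | None = None

    def flush() -> None:
        if not run:
            return
        start = int(profile.starts[run[0].start_index])
        end = int(profile.ends[run[-1].end_index])
        w = np.array([s.n_windows for s in run], dtype=float)
        means = np.array([s.mean_level for s in run])
        calls.append(CNVCall(profile.chrom, start, end, run_state,
                             float(np.sum(w * means) / np.sum(w))))

    for s in seg.segments:
        if s.mean_level <= loss_threshold:
            state = CopyState.LOSS
        elif s.mean_level >= gain_threshold:
            state = CopyState.GAIN
        else:
            state = CopyState.NEUTRAL
        if state is CopyState.NEUTRAL:
            flush()
            run, run_state = [], None
        elif state is run_state:
            run.append(s)
        else:
            flush()
            run, run_state = [s], state
    flush()
    return calls


class SegmentationResults:
    """Fitted segmentation: decoded levels, segments, parameters and diagnostics.

    Returned by :meth:`ShiftingLevelModel.fit`; also the result type of the
    heterogeneous model.
    """

    def __init__(
        self,
        model: "ShiftingLevelModel",
        params: SLMParameters,
        grid: LevelGrid | None,
        segmentation: Segmentation,
        n_iter: int = 0,
    ) -> None:
        self.model = model
        self.profile = model.profile
        self.params = params
        self.grid = grid
        self.segmentation = segmentation
        self.n_iter = n_iter

    # -- convenience views -------------------------------------------------
    @property
    def levels(self) -> np.ndarray:
        return self.segmentation.levels

    @property
    def segments(self) -> list[Segment]:
        return self.segmentation.segments

    @property
    def breakpoints(self) -> list[int]:
        return self.segmentation.breakpoints

    @property
    def n_segments(self) -> int:
        return self.segmentation.n_segments

    @property
    def resid(self) -> np.ndarray:
        """Observed minus decoded level, per window."""
        return self.profile.values - self.levels

    def call_cnvs(
        self,
        loss_threshold: float = DEFAULT_LOSS_THRESHOLD,
        gain_threshold: float = DEFAULT_GAIN_THRESHOLD,
    ) -> list[CNVCall]:
        return call_cnvs(self.segmentation, self.profile, loss_threshold, gain_threshold)

    def to_frame(self) -> pd.DataFrame:
        """Segment table with genomic coordinates."""
        p = self.profile
        rows = [
            {
                "chrom": p.chrom,
                "start": int(p.starts[s.start_index]),
                "end": int(p.ends[s.end_index]),
                "start_index": s.start_index,
                "end_index": s.end_index,
                "n_windows": s.n_windows,
                "mean_level": s.mean_level,
            }
            for s in self.segments
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable fit summary (parameters, then the segment table)."""
        p = self.params
        lines = [
            f"{type(self.model).__name__} segmentation",
            "=" * 46,
            f"windows:      {len(self.profile)}",
            f"segments:     {self.n_segments}",
            f"breakpoints:  {len(self.breakpoints)}",
            f"mu:           {p.mu:.6g}",
            f"sigma2_m:     {p.sigma2_m:.6g}",
            f"sigma2_eps:   {p.sigma2_eps:.6g}",
            f"omega:        {p.omega:.6g}",
            f"grid levels:  {0 if self.grid is None else self.grid.K}",
            f"degenerate:   {p.degenerate}",
            "-" * 46,
            f"{'chrom':<8}{'start':>10}{'end':>10}{'n_win':>7}  mean_level",
        ]
        df = self.to_frame()
        for _, r in df.iterrows():
            lines.append(
                f"{r['chrom']:<8}{r['start']:>10}{r['end']:>10}{r['n_windows']:>7}  "
                f"{r['mean_level']:+.4f}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the observed profile with the decoded mean level overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        mids = (self.profile.starts + self.profile.ends) / 2
        ax.plot(mids, self.profile.values, ".", ms=2, color="0.6", label="observed")
        ax.plot(mids, self.levels, "-", color="C1", lw=1.5, label="decoded level")
        ax.set_xlabel(f"{self.profile.chrom} position (bp)")
        ax.set_ylabel("log2 ratio")
        ax.legend(loc="best", frameon=False)
        return ax


class ShiftingLevelModel:
    """Homogeneous shifting level model for one log2-ratio profile.

    Parameters
    ----------
    profile : GenomicProfile
        Log2-ratio profile of one chromosome.
    omega : float in (0, 1)
        Fraction of the total variance assigned to white noise
        (sigma2_eps = omega * sigma2_total).
    eta : float in (0, 1)
        Jump probability of the level process per step.  Smaller values
        demand stronger evidence for a breakpoint.
    n_levels : int >= 2
        Size of the discretized level grid (data quantiles).
    min_seg_windows : int
        Segments shorter than this are merged into the nearer-mean
        neighbor after decoding (1 = no merging).
    """

    def __init__(
        self,
        profile: GenomicProfile,
        omega: float = DEFAULT_OMEGA,
        eta: float = DEFAULT_ETA,
        n_levels: int = DEFAULT_N_LEVELS,
        min_seg_windows: int = 1,
    ) -> None:
        if profile.scale is not Scale.LOG2RATIO:
            raise ValueError("segmentation expects a LOG2RATIO profile; normalize first")
        if not 0 < eta < 1:
            raise ValueError("eta must lie in (0, 1)")
        self.profile = profile
        self.omega = omega
        self.eta = eta
        self.n_levels = n_levels
        self.min_seg_windows = min_seg_windows

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        chrom_col: str = "chrom",
        start_col: str = "start",
        end_col: str = "end",
        value_col: str = "value",
        **kwargs,
    ) -> "ShiftingLevelModel":
        """Build from a tidy per-window DataFrame (one chromosome)."""
        chroms = df[chrom_col].unique()
        if len(chroms) != 1:
            raise ValueError("from_dataframe expects exactly one chromosome")
        profile = GenomicProfile(
            str(chroms[0]),
            df[start_col].to_numpy(np.int64),
            df[end_col].to_numpy(np.int64),
            df[value_col].to_numpy(np.float64),
            Scale.LOG2RATIO,
        )
        return cls(profile, **kwargs)

    # hook overridden by the heterogeneous model
    def _step_etas(self, n_steps: int) -> np.ndarray:
        return np.full(n_steps, float(self.eta))

    def fit(
        self,
        reestimate: bool = False,
        max_iter: int = 20,
        tol: float = 1e-6,
    ) -> SegmentationResults:
        """Estimate parameters, decode the MAP path, and collapse it to segments.

        With ``reestimate=True`` the noise variance is re-estimated from the
        Viterbi residuals and decoding repeats until sigma2_eps changes by
        less than ``tol`` (relative) or ``max_iter`` iterations.
        """
        values = self.profile.values
        params, grid = estimate_parameters(values, self.omega, self.eta, self.n_levels)
        if params.degenerate:
            return SegmentationResults(self, params, grid, _single_segment(values))

        n_steps = len(values) - 1
        transition = TransitionModel(grid.prior, self._step_etas(n_steps))
        sigma2_eps = params.sigma2_eps
        n_iter = 0
        path = viterbi_decode(values, grid, transition, sigma2_eps)
        if reestimate:
            for n_iter in range(1, max_iter + 1):
                resid = values - grid.levels[path]
                new = float(np.var(resid))
                if new <= 0:
                    break
                if abs(new - sigma2_eps) <= tol * sigma2_eps:
                    sigma2_eps = new
                    break
                sigma2_eps = new
                path = viterbi_decode(values, grid, transition, sigma2_eps)
            params = replace(params, sigma2_eps=sigma2_eps)

        seg = _collapse_path(values, path)
        seg = _merge_short_segments(values, seg, self.min_seg_windows)
        return SegmentationResults(self, params, grid, seg, n_iter)


def slm_segment(
    profile: GenomicProfile,
    omega: float = DEFAULT_OMEGA,
    eta: float = DEFAULT_ETA,
    n_levels: int = DEFAULT_N_LEVELS,
    min_seg_windows: int = 1,
) -> Segmentation:
    """Functional one-shot SLM segmentation (see :class:`ShiftingLevelModel`)."""
    return ShiftingLevelModel(
        profile, omega=omega, eta=eta, n_levels=n_levels,
        min_seg_windows=min_seg_windows,
    ).fit().segmentation
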