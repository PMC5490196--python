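"""Synthetic copy-number profiles with known truth.

Each simulated profile is one synthetic chromosome of ``total_windows``
contiguous (or, in sparse mode, gap-separated) windows on the log2-ratio
scale: diploid background windows draw from N(0, noise_sd^2) and a single
embedded event of ``n_altered`` windows draws from N(shift, noise_sd^2),
where the shift is the theoretical diploid log2 level of the event class
(-1 for a one-copy loss, +log2(3/2) ~ +0.585 for a three-copy gain).  The
event is placed uniformly at random with at least one background window on
each flank, and the truth (interval, breakpoints, copy state, shift) is
returned alongside the profile.

The noise level can be tied to a sequencing design through
:func:`coverage_noise_sd`, which maps fold-coverage and window size to the
log2-scale standard deviation of a Poisson read count via the delta method.

Randomness is fully determined by the config seed.  Event placement, window
values and sparse gaps draw from three independent child streams of that
seed, so the same seed yields identical values whether or not gaps are
simulated.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .profiles import CopyState, GenomicProfile, Scale

__all__ = [
    "EventType",
    "SimulationConfig",
    "TruthSet",
    "simulate_profile",
    "simulate_sparse_profile",
    "coverage_noise_sd",
    "LowCoverageWarning",
]

READ_LENGTH_BP = 100
ONE_COPY_SHIFT = -1.0
THREE_COPY_SHIFT = float(np.log2(1.5))


class LowCoverageWarning(UserWarning):
    """Expected reads per window too small for the Gaussian log2 approximation."""


class EventType(enum.Enum):
    ONE_COPY = "one-copy"
    THREE_COPY = "three-copy"

    @property
    def shift(self) -> float:
        return ONE_COPY_SHIFT if self is EventType.ONE_COPY else THREE_COPY_SHIFT

    @property
    def copy_state(self) -> CopyState:
        return CopyState.LOSS if self is EventType.ONE_COPY else CopyState.GAIN


@dataclass
class SimulationConfig:
    """Recipe for one synthetic profile.

    ``n_altered = 0`` produces a pure-noise (event-free) profile.
    ``max_gap > 0`` enables the sparse gap model: inter-window gaps are drawn
    log-uniformly on [1, max_gap] bp (sparse exon-like spacing).
    """

    total_windows: int = 10_000
    n_altered: int = 0
    event_type: EventType = EventType.ONE_COPY
    noise_sd: float = 0.2
    window_bp: int = 1000
    seed: int = 0
    max_gap: float = 0.0
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if self.total_windows < 1:
            raise ValueError("total_windows must be >= 1")
        if not 0 <= self.n_altered < self.total_windows:
            raise ValueError("need 0 <= n_altered < total_windows")
        if self.n_altered > 0 and self.n_altered > self.total_windows - 2:
            raise ValueError("event needs at least one background window on each flank")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        if self.window_bp < 1:
            raise ValueError("window_bp must be >= 1")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


@dataclass
class TruthSet:
    """Ground truth of a simulated profile.

    ``interval`` is the altered window-index range (inclusive) or None for an
    event-free profile; ``breakpoints`` are the window indices where the true
    mean changes (first altered window and first window after the event);
    ``gap_at_breakpoints`` records the genomic gap (bp) immediately preceding
    each true breakpoint, for sparse profiles.
    """

    interval: tuple[int, int] | None
    breakpoints: list[int]
    copy_state: CopyState | None
    shift: float
    bp_interval: tuple[int, int] | None = None
    gap_at_breakpoints: list[float] = field(default_factory=list)


def _streams(seed: int) -> tuple[np.random.Generator, ...]:
    ss = np.random.SeedSequence(seed)
    return tuple(np.random.default_rng(s) for s in ss.spawn(3))


def _simulate(config: SimulationConfig, with_gaps: bool) -> tuple[GenomicProfile, TruthSet]:
    place_rng, value_rng, gap_rng = _streams(config.seed)
    n, k = config.total_windows, config.n_altered

    if k > 0:
        start_idx = int(place_rng.integers(1, n - k))  # flanks >= 1 window each
    else:
        start_idx = -1

    values = value_rng.normal(0.0, config.noise_sd, n)
    shift = config.event_type.shift if k > 0 else 0.0
    if k > 0:
        values[start_idx:start_idx + k] += shift

    if with_gaps and config.max_gap > 0:
        gaps = np.floor(
            stats.loguniform.rvs(1.0, config.max_gap, size=n - 1, random_state=gap_rng)
        ).astype(np.int64) if n > 1 else np.zeros(0, dtype=np.int64)
    else:
        gaps = np.zeros(max(n - 1, 0), dtype=np.int64)

    starts = np.empty(n, dtype=np.int64)
    starts[0] = 0
    if n > 1:
        starts[1:] = np.cumsum(config.window_bp + gaps)
    ends = starts + config.window_bp
    profile = GenomicProfile(config.chrom, starts, ends, values, Scale.LOG2RATIO)

    if k > 0:
        bkpts = [start_idx, start_idx + k]
        truth = TruthSet(
            interval=(start_idx, start_idx + k - 1),
            breakpoints=bkpts,
            copy_state=config.event_type.copy_state,
            shift=shift,
            bp_interval=(int(starts[start_idx]), int(ends[start_idx + k - 1])),
            gap_at_breakpoints=[float(gaps[b - 1]) if b >= 1 else 0.0 for b in bkpts],
        )
    else:
        truth = TruthSet(None, [], None, 0.0)
    return profile, truth


def simulate_profile(config: SimulationConfig) -> tuple[GenomicProfile, TruthSet]:
    """Dense profile: windows tile the chromosome contiguously at ``window_bp``."""
    return _simulate(config, with_gaps=False)


def simulate_sparse_profile(config: SimulationConfig) -> tuple[GenomicProfile, TruthSet]:
    """Sparse profile: consecutive windows separated by log-uniform [1, max_gap] bp gaps.

    With ``max_gap = 0`` this reduces exactly to :func:`simulate_profile`;
    window values are identical either way for a given seed (gaps draw from
    their own stream), only the coordinates differ.
    """
    return _simulate(config, with_gaps=True)


def coverage_noise_sd(
    coverage: float, window_bp: int, read_length: int = READ_LENGTH_BP
) -> float:
    """log2-scale noise sd implied by a sequencing design.

    The expected read count per window is lambda = coverage * window_bp /
    read_length; a Poisson(lambda) count C has, by the delta method,
    sd(log2 C) ~ 1 / (ln 2 * sqrt(lambda)).  Emits
    :class:`LowCoverageWarning` when lambda < 10, where the Gaussian
    approximation of the Poisson becomes poor.
    """
    if coverage <= 0 or window_bp <= 0 or read_length <= 0:
        raise ValueError("coverage, window_bp and read_length must be positive")
    lam = coverage * window_bp / read_length
    if lam < 10:
        warnings.warn(
            f"expected reads per window lambda={lam:.3g} < 10; "
            "log2-normal noise approximation is poor",
            LowCoverageWarning,
            stacklevel=2,
        )
    return 1.0 / (math.log(2.0) * math.sqrt(lam))
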