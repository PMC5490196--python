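"""Read-count normalization: GC/mappability correction and log2 transform.

Raw window read counts carry systematic biases: GC-rich or GC-poor windows
are under-amplified, and windows with poor mappability lose reads.  The
correction used here is the standard stratified-median scheme: counts are
binned by GC fraction, each stratum is rescaled so its median matches the
global median, and low-mappability windows are excluded outright.  The
corrected counts are then log2-transformed against a diploid reference
(the global median by default), giving the log2-ratio profile that the
segmentation models consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .profiles import GenomicProfile, Scale


class NormalizationError(ValueError):
    """Degenerate input: all windows excluded or zero global median."""


@dataclass
class WindowCovariates:
    """Per-window GC fraction and mappable fraction, both in [0, 1]."""

    gc: np.ndarray
    mappability: np.ndarray

    def __post_init__(self) -> None:
        self.gc = np.asarray(self.gc, dtype=np.float64)
        self.mappability = np.asarray(self.mappability, dtype=np.float64)
        if len(self.gc) != len(self.mappability):
            raise ValueError("gc and mappability must have equal length")
        for name, arr in (("gc", self.gc), ("mappability", self.mappability)):
            if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
                raise ValueError(f"{name} values must lie in [0, 1]")


@dataclass
class CorrectionResult:
    """GC-corrected counts plus the excluded-window mask and per-window factors."""

    counts: np.ndarray
    excluded: np.ndarray  # True where mappability < map_min
    factors: np.ndarray


@dataclass
class Log2Result:
    """log2-ratio values plus a flag marking zero-count windows floored by pseudo-count."""

    values: np.ndarray
    zero_flagged: np.ndarray


# strata thinner than this inherit the global median (no correction)
MIN_STRATUM_WINDOWS = 20


def gc_mappability_correct(
    counts: np.ndarray,
    cov: WindowCovariates,
    gc_bin_width: float = 0.01,
    map_min: float = 0.5,
) -> CorrectionResult:
    """Rescale counts so every GC stratum's median matches the global median.

    Windows with mappability below ``map_min`` are flagged excluded and left
    uncorrected (they should be dropped before segmentation).  Strata holding
    fewer than ``MIN_STRATUM_WINDOWS`` usable windows inherit the global
    median, i.e. receive no correction.  The construction preserves the
    global median of the usable windows.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if np.any(counts < 0):
        raise ValueError("read counts must be non-negative")
    if len(counts) != len(cov.gc):
        raise ValueError("counts and covariates must have equal length")
    if not 0 < gc_bin_width <= 1:
        raise ValueError("gc_bin_width must lie in (0, 1]")

    excluded = cov.mappability < map_min
    usable = ~excluded
    if not usable.any():
        raise NormalizationError("all windows excluded by the mappability filter")
    global_median = float(np.median(counts[usable]))
    if global_median == 0:
        raise NormalizationError("global median count is zero; profile is degenerate")

    bins = np.minimum((cov.gc / gc_bin_width).astype(np.int64),
                      int(np.ceil(1.0 / gc_bin_width)) - 1)
    factors = np.ones_like(counts)
    for b in np.unique(bins[usable]):
        in_bin = usable & (bins == b)
        if in_bin.sum() < MIN_STRATUM_WINDOWS:
            continue
        stratum_median = float(np.median(counts[in_bin]))
        if stratum_median > 0:
            factors[in_bin] = global_median / stratum_median
    corrected = counts * factors
    return CorrectionResult(corrected, excluded, factors)


def log2_transform(
    counts: np.ndarray,
    reference: float | np.ndarray | None = None,
) -> Log2Result:
    """log2(count / reference) per window, with half-count flooring of zeros.

    ``reference`` is the expected diploid count: a scalar, a per-window
    vector, or None to use the global median of ``counts``.  Zero counts are
    replaced by 0.5 (half a read) before the transform so deletions stay
    visible as strongly negative finite values; those windows are flagged.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if np.any(counts < 0):
        raise ValueError("read counts must be non-negative")
    if reference is None:
        reference = float(np.median(counts))
    reference = np.asarray(reference, dtype=np.float64)
    if np.any(reference <= 0):
        raise ValueError("reference must be strictly positive")
    zero_flagged = counts == 0
    floored = np.where(zero_flagged, 0.5, counts)
    return Log2Result(np.log2(floored / reference), zero_flagged)


def normalize_profile(
    profile: GenomicProfile,
    cov: WindowCovariates | None = None,
    gc_bin_width: float = 0.01,
    map_min: float = 0.5,
    reference: float | None = None,
    center: bool = True,
) -> tuple[GenomicProfile, np.ndarray]:
    """Full RC -> log2-ratio pipeline for one profile.

    Applies GC/mappability correction (when covariates are available), drops
    excluded windows, log2-transforms against ``reference`` (global median of
    corrected counts by default) and, with ``center=True``, median-centers the
    log2 values so the diploid baseline sits at 0.

    Returns the normalized LOG2RATIO profile and the integer indices of the
    kept windows in the original profile (so segments can be mapped back).
    """
    if profile.scale is not Scale.RC:
        raise ValueError("normalize_profile expects a read-count (RC) profile")
    counts = profile.values
    if cov is None and profile.gc is not None and profile.mappability is not None:
        cov = WindowCovariates(profile.gc, profile.mappability)
    if cov is not None:
        res = gc_mappability_correct(counts, cov, gc_bin_width, map_min)
        kept = ~res.excluded
        counts = res.counts[kept]
    else:
        kept = np.ones(len(profile), dtype=bool)
    log2 = log2_transform(counts, reference)
    values = log2.values
    if center:
        values = values - np.median(values)
    out = profile.subset(kept).replace_values(values, Scale.LOG2RATIO)
    return out, np.flatnonzero(kept)
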