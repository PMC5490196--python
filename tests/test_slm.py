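"""Homogeneous SLM: estimation, transition structure, Viterbi, segmentation."""

import numpy as np
import pytest

from slmcnv import (
    CopyState,
    LevelGrid,
    ShiftingLevelModel,
    SimulationConfig,
    TransitionModel,
    build_transition_matrix,
    call_cnvs,
    estimate_parameters,
    simulate_profile,
    slm_segment,
    viterbi_decode,
)
from slmcnv.profiles import Segment, Segmentation
from slmcnv.slm import _merge_short_segments

from conftest import brute_force_viterbi, dense_profile, random_instance


# ---------------------------------------------------------------- estimation

def test_estimate_iid_noise_recovers_mu_and_sigma2_eps():
    rng = np.random.default_rng(11)
    values = rng.normal(0.0, 0.2, 10_000)  # variance 0.04, no shifts
    params, grid = estimate_parameters(values)
    assert abs(params.mu) < 0.01
    assert params.sigma2_eps == pytest.approx(0.04, rel=0.15)
    assert grid is not None and grid.K >= 2


def test_estimate_constant_profile_degenerate():
    params, grid = estimate_parameters(np.full(100, 0.3))
    assert params.degenerate and params.mu == 0.3 and grid is None


def test_grid_covers_both_levels_of_two_level_profile():
    values = np.concatenate([np.full(500, -1.0), np.full(500, 0.0)])
    rng = np.random.default_rng(0)
    values = values + rng.normal(0, 1e-3, 1000)  # break ties in the quantiles
    _, grid = estimate_parameters(values)
    step = np.max(np.diff(grid.levels))
    assert np.min(np.abs(grid.levels - (-1.0))) <= step
    assert np.min(np.abs(grid.levels - 0.0)) <= step


def test_estimate_rejects_nonfinite():
    with pytest.raises(ValueError):
        estimate_parameters(np.array([0.0, np.nan, 0.1]))


# ------------------------------------------------------------- transitions

def test_transition_matrix_eta_zero_is_identity():
    grid = LevelGrid([-1.0, 0.0, 0.5], [0.2, 0.5, 0.3])
    assert np.array_equal(build_transition_matrix(grid, 0.0), np.eye(3))


def test_transition_matrix_eta_one_rows_equal_prior():
    grid = LevelGrid([-1.0, 0.0, 0.5, 1.0], np.full(4, 0.25))
    A = build_transition_matrix(grid, 1.0)
    assert np.allclose(A, 0.25)


def test_transition_matrix_hand_evaluated():
    grid = LevelGrid([-1.0, 0.0], [0.5, 0.5])
    A = build_transition_matrix(grid, 0.1)
    assert np.allclose(A, [[0.95, 0.05], [0.05, 0.95]])


def test_transition_rows_sum_to_one_and_diagonal_bound(rng):
    for _ in range(20):
        K = int(rng.integers(2, 8))
        prior = rng.dirichlet(np.ones(K))
        prior = np.maximum(prior, 1e-9)
        prior /= prior.sum()
        levels = np.sort(rng.normal(0, 1, K))
        if np.any(np.diff(levels) <= 0):
            continue
        eta = float(rng.uniform(0.001, 0.999))
        A = build_transition_matrix(LevelGrid(levels, prior), eta)
        assert np.allclose(A.sum(axis=1), 1.0)
        assert np.all(np.diag(A) >= (1 - eta) - 1e-15)


# ------------------------------------------------------------------ viterbi

def test_viterbi_flat_signal_single_level():
    grid = LevelGrid([-1.0, 0.0, 0.585], [0.2, 0.6, 0.2])
    path = viterbi_decode(np.zeros(6), grid, TransitionModel(grid.prior, 0.1), 0.04)
    assert np.array_equal(path, np.ones(6) * 1)


def test_viterbi_clean_step_breakpoint_matches_enumeration():
    values = np.array([0.0, 0.0, 0.0, -1.0, -1.0, -1.0])
    grid = LevelGrid([-1.0, 0.0], [0.5, 0.5])
    sigma2 = 0.05**2
    path = viterbi_decode(values, grid, TransitionModel(grid.prior, 0.01), sigma2)
    A = np.stack([build_transition_matrix(grid, 0.01)] * 5)
    oracle = brute_force_viterbi(values, grid, A, sigma2)
    assert np.array_equal(path, oracle)
    assert np.array_equal(path, [1, 1, 1, 0, 0, 0])


def test_viterbi_tie_breaks_to_lower_level_index():
    # symmetric grid, all-zero data, uniform prior: the all-at-level-0 and
    # all-at-level-1 paths score identically; lexicographic rule picks 0
    grid = LevelGrid([-0.5, 0.5], [0.5, 0.5])
    path = viterbi_decode(np.zeros(5), grid, TransitionModel(grid.prior, 0.2), 0.1)
    assert np.array_equal(path, np.zeros(5))


@pytest.mark.parametrize("heterogeneous", [False, True])
def test_viterbi_equals_exhaustive_enumeration(heterogeneous):
    rng = np.random.default_rng(42 + int(heterogeneous))
    for _ in range(60):
        values, grid, etas, sigma2 = random_instance(rng, heterogeneous)
        path = viterbi_decode(values, grid, TransitionModel(grid.prior, etas), sigma2)
        A = np.stack([build_transition_matrix(grid, e) for e in etas])
        oracle = brute_force_viterbi(values, grid, A, sigma2)
        assert np.array_equal(path, oracle)


def test_viterbi_rejects_zero_noise_variance():
    grid = LevelGrid([0.0, 1.0], [0.5, 0.5])
    with pytest.raises(ValueError):
        viterbi_decode(np.zeros(4), grid, TransitionModel(grid.prior, 0.1), 0.0)


# ------------------------------------------------------------- segmentation

def test_segment_recovers_simulated_event():
    profile, truth = simulate_profile(
        SimulationConfig(total_windows=10_000, n_altered=100, noise_sd=0.2, seed=1)
    )
    seg = slm_segment(profile)
    assert seg.n_segments == 3
    assert abs(seg.breakpoints[0] - truth.breakpoints[0]) <= 2
    assert abs(seg.breakpoints[1] - truth.breakpoints[1]) <= 2
    # reported means are empirical means of the observed windows
    mid = seg.segments[1]
    assert mid.mean_level == pytest.approx(
        float(np.mean(profile.values[mid.start_index:mid.end_index + 1]))
    )


def test_constant_profile_single_segment():
    seg = slm_segment(dense_profile(np.full(50, 0.3)))
    assert seg.n_segments == 1 and seg.segments[0].mean_level == pytest.approx(0.3)


def test_tiny_eta_suppresses_all_breakpoints():
    rng = np.random.default_rng(7)
    profile = dense_profile(rng.normal(0, 0.2, 2000))
    seg = slm_segment(profile, eta=1e-12)
    assert seg.n_segments == 1


def test_breakpoint_count_monotone_in_eta():
    # fixed profile, fixed grid and variances: decreasing eta never adds breakpoints
    profile, _ = simulate_profile(
        SimulationConfig(total_windows=3000, n_altered=60, noise_sd=0.3, seed=9)
    )
    params, grid = estimate_parameters(profile.values)
    counts = []
    for eta in (1e-2, 1e-4, 1e-6, 1e-9):
        path = viterbi_decode(profile.values, grid,
                              TransitionModel(grid.prior, eta), params.sigma2_eps)
        counts.append(int(np.sum(path[1:] != path[:-1])))
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_shift_equivariance():
    # adding a constant shifts segment means by that constant and leaves
    # breakpoints unchanged (the level grid is data-derived)
    profile, _ = simulate_profile(
        SimulationConfig(total_windows=4000, n_altered=80, noise_sd=0.2, seed=21)
    )
    c = 0.7
    shifted = profile.replace_values(profile.values + c, profile.scale)
    a = slm_segment(profile)
    b = slm_segment(shifted)
    assert a.breakpoints == b.breakpoints
    means_a = [s.mean_level for s in a.segments]
    means_b = [s.mean_level for s in b.segments]
    assert np.allclose(np.array(means_b) - np.array(means_a), c, atol=1e-9)


def test_min_seg_windows_merges_into_nearer_neighbor():
    values = np.array([0.0] * 5 + [0.4] * 2 + [0.5] * 5)
    seg = Segmentation(
        np.array([0.0] * 5 + [0.4] * 2 + [0.5] * 5),
        [Segment(0, 4, 0.0), Segment(5, 6, 0.4), Segment(7, 11, 0.5)],
        [5, 7],
    )
    merged = _merge_short_segments(values, seg, min_seg_windows=3)
    assert merged.n_segments == 2
    assert merged.segments[0].n_windows == 5  # short run absorbed to the right
    assert merged.segments[1].mean_level == pytest.approx(np.mean(values[5:]))


def test_reestimation_iterates_and_keeps_segmentation_sane():
    profile, truth = simulate_profile(
        SimulationConfig(total_windows=5000, n_altered=100, noise_sd=0.2, seed=3)
    )
    res = ShiftingLevelModel(profile).fit(reestimate=True)
    assert res.n_iter >= 1
    assert res.params.sigma2_eps == pytest.approx(0.04, rel=0.3)
    assert res.n_segments == 3


# ---------------------------------------------------------------- CNV calls

def test_call_cnvs_threshold_classes():
    p = dense_profile(np.zeros(9))
    seg = Segmentation(
        np.array([-0.9] * 3 + [0.02] * 3 + [0.55] * 3),
        [Segment(0, 2, -0.9), Segment(3, 5, 0.02), Segment(6, 8, 0.55)],
        [3, 6],
    )
    calls = call_cnvs(seg, p, -0.5, 0.3)
    assert [c.copy_state for c in calls] == [CopyState.LOSS, CopyState.GAIN]
    assert calls[0].start == 0 and calls[0].end == 300


def test_call_cnvs_all_neutral_empty():
    p = dense_profile(np.zeros(4))
    seg = Segmentation.from_levels(np.array([0.1, 0.1, -0.2, -0.2]))
    assert call_cnvs(seg, p) == []


def test_call_cnvs_merges_adjacent_same_state():
    p = dense_profile(np.zeros(6))
    seg = Segmentation(
        np.array([-0.8] * 3 + [-1.1] * 3),
        [Segment(0, 2, -0.8), Segment(3, 5, -1.1)],
        [3],
    )
    calls = call_cnvs(seg, p)
    assert len(calls) == 1
    assert calls[0].copy_state is CopyState.LOSS
    assert calls[0].start == 0 and calls[0].end == 600
    assert calls[0].mean_level == pytest.approx((-0.8 - 1.1) / 2)


def test_results_summary_and_frame():
    profile, _ = simulate_profile(
        SimulationConfig(total_windows=2000, n_altered=50, noise_sd=0.2, seed=2)
    )
    res = ShiftingLevelModel(profile).fit()
    text = res.summary()
    assert "segments" in text and profile.chrom in text
    df = res.to_frame()
    assert df["n_windows"].sum() == len(profile)
    assert len(res.resid) == len(profile)


def test_results_plot_smoke():
    import matplotlib
    matplotlib.use("Agg")
    profile, _ = simulate_profile(
        SimulationConfig(total_windows=500, n_altered=30, noise_sd=0.2, seed=6)
    )
    ax = ShiftingLevelModel(profile).fit().plot()
    assert ax.get_ylabel() == "log2 ratio"
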