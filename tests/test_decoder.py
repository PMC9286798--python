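"""Regularized Fisher discriminant, LOO Az, shrinkage search, sliding grid."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import middecode as md
from middecode.decoder import _loo_scores_direct, _loo_scores_downdate
from conftest import (
    SMALL_LAMBDA_GRID,
    oracle_auc,
    oracle_fisher_weights,
    oracle_loo_az,
    oracle_loo_scores,
    small_eeg_config,
)


def _epochs_from_array(data, srate=256.0, t0=-500.0):
    times = t0 + 1000.0 / srate * np.arange(data.shape[2])
    return md.EpochSet(data=data, channel_labels=[f"c{i}" for i in
                                                  range(data.shape[1])],
                       srate_hz=srate, times_ms=times)


# --------------------------------------------------------------- windowing


def test_window_average_of_constant_and_ramp(rng):
    n = 641
    const = np.full((3, 2, n), 4.2)
    ep = _epochs_from_array(const)
    assert np.allclose(md.window_average(ep, 450.0), 4.2)
    # linear ramp: for a center on the sample grid the closed window is
    # symmetric, so the window mean equals the ramp value at the center
    ramp = np.tile(ep.times_ms, (2, 3, 1)).transpose(1, 0, 2)
    epr = _epochs_from_array(ramp)
    center = float(epr.times_ms[300])
    got = md.window_average(epr, center, 60.0)
    assert np.allclose(got, center)


def test_window_sample_count_follows_closed_interval_rule():
    ep = _epochs_from_array(np.zeros((1, 1, 641)))
    half = 30.0
    # every window fully inside the epoch span covers 15 or 16 sample
    # centers depending on grid alignment (60 ms at 256 Hz spans 15.36)
    for center in np.arange(-200.0, 1970.0 + 1e-9, 10.0):
        mask = (ep.times_ms >= center - half - 1e-9) & (
            ep.times_ms <= center + half + 1e-9
        )
        assert mask.sum() in (15, 16)


def test_empty_window_raises():
    ep = _epochs_from_array(np.zeros((1, 1, 641)))
    with pytest.raises(ValueError):
        md.window_average(ep, 5000.0, 60.0)


# ------------------------------------------------------------- shrinkage


def test_shrinkage_limits_and_hand_example():
    s = np.diag([2.0, 4.0])
    assert np.allclose(md.regularize_covariance(s, 0.0), s)
    assert np.allclose(md.regularize_covariance(s, 1.0), 3.0 * np.eye(2))
    with pytest.raises(ValueError):
        md.regularize_covariance(np.array([[1.0, 2.0], [0.0, 1.0]]), 0.5)
    with pytest.raises(ValueError):
        md.regularize_covariance(s, 1.5)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.integers(2, 8), st.floats(0.0, 1.0), st.integers(0, 10**6))
def test_shrinkage_preserves_trace_on_random_spd(d, lam, seed):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((d, d + 2))
    s = a @ a.T
    st_ = md.regularize_covariance(s, lam)
    assert abs(np.trace(st_) - np.trace(s)) < 1e-10 * max(np.trace(s), 1.0)
    assert np.allclose(st_, st_.T)


# ------------------------------------------------------------- Fisher fit


def test_whitened_toy_weights_solve_hand_example():
    # class covariances diag(1,4) exactly (ddof=1), means (0,0) vs (1,0)
    base = np.array(
        [[np.sqrt(1.5), 0.0], [-np.sqrt(1.5), 0.0],
         [0.0, np.sqrt(6.0)], [0.0, -np.sqrt(6.0)]]
    )
    x1 = base
    x2 = base + np.array([1.0, 0.0])
    fit = md.fit_fisher(x1, x2, lam=0.0)
    assert np.allclose(fit.s_common, np.diag([1.0, 4.0]))
    assert np.allclose(fit.w, [1.0, 0.0])
    # S_c = I case: w equals the mean difference exactly
    fit2 = md.fit_fisher(x1 / np.array([1.0, 2.0]), x2 / np.array([1.0, 2.0]),
                         lam=0.0)
    assert np.allclose(fit2.s_common, np.eye(2))
    assert np.allclose(fit2.w, [1.0, 0.0])


def test_fisher_direction_maximizes_class_separation_criterion():
    base = np.array(
        [[np.sqrt(1.5), 0.0], [-np.sqrt(1.5), 0.0],
         [0.0, np.sqrt(6.0)], [0.0, -np.sqrt(6.0)]]
    )
    x1, x2 = base, base + np.array([1.0, 0.0])
    fit = md.fit_fisher(x1, x2, lam=0.0)
    dm = x2.mean(0) - x1.mean(0)
    sc = fit.s_common

    def crit(u):
        return (u @ dm) ** 2 / (u @ sc @ u)

    best = crit(fit.w / np.linalg.norm(fit.w))
    for theta in np.linspace(0, np.pi, 3600, endpoint=False):
        u = np.array([np.cos(theta), np.sin(theta)])
        assert crit(u) <= best + 1e-12


def test_identical_means_give_zero_weights(rng):
    x = rng.standard_normal((10, 4))
    fit = md.fit_fisher(x, x, lam=0.3)
    assert np.allclose(fit.w, 0.0)


# ---------------------------------------------------------------- LOO Az


@pytest.mark.parametrize("seed", range(8))
def test_loo_az_matches_brute_force_on_small_fixtures(seed):
    """Oracle equivalence on <= 8-trial fixtures, all shrinkage levels,
    including the singular D >= N case."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 9))
    d = int(rng.integers(2, 10))  # sometimes D >= N: singular at lambda 0
    x = rng.standard_normal((n, d))
    labels = np.zeros(n, bool)
    labels[: max(2, n // 2)] = True
    rng.shuffle(labels)
    if labels.sum() < 2 or (~labels).sum() < 2:
        labels[:2] = True
        labels[2:] = False
    for lam in (0.0, 0.17, 0.5, 1.0):
        assert md.loo_az(x, labels, lam) == pytest.approx(
            oracle_loo_az(x, labels, lam), abs=1e-12
        )


def test_printed_six_trial_fixture_matches_enumerated_loo():
    """3-vs-3 fixture small enough to audit by hand; the oracle refits all
    six leave-outs independently."""
    x = np.array(
        [[1.0, 0.2], [0.8, -0.1], [1.3, 0.4],
         [-0.9, 0.1], [-1.1, -0.3], [-0.7, 0.2]]
    )
    labels = np.array([True, True, True, False, False, False])
    scores = md.loo_scores(x, labels, np.array([0.2]))[0]
    assert np.allclose(scores, oracle_loo_scores(x, labels, 0.2))
    az = md.rank_auc(scores, labels)
    assert az == pytest.approx(oracle_loo_az(x, labels, 0.2), abs=1e-12)
    assert az == 1.0  # well-separated printed clouds


def test_fast_and_direct_loo_paths_agree(rng):
    for _ in range(5):
        n, d = int(rng.integers(8, 30)), int(rng.integers(2, 12))
        x = rng.standard_normal((n, d))
        labels = rng.random(n) < 0.5
        if labels.sum() < 2 or (~labels).sum() < 2:
            continue
        lams = np.array([0.02, 0.3, 0.9])
        fast = _loo_scores_downdate(x, labels, lams)
        direct = _loo_scores_direct(x, labels, lams)
        assert fast is not None
        assert np.allclose(fast, direct, rtol=1e-7, atol=1e-9)


def test_rank_auc_matches_pair_counting_with_ties(rng):
    scores = np.array([0.1, 0.1, 0.5, 0.7, 0.7, 0.7, 0.9])
    labels = np.array([False, True, False, True, False, True, True])
    assert md.rank_auc(scores, labels) == pytest.approx(
        oracle_auc(scores, labels)
    )


def test_separated_clouds_reach_az_one(rng):
    x = np.vstack([rng.standard_normal((10, 3)),
                   rng.standard_normal((10, 3)) + 50.0])
    labels = np.arange(20) >= 10
    assert md.loo_az(x, labels, 0.1) == 1.0


def test_label_flip_symmetries(rng):
    x = rng.standard_normal((24, 5))
    x[:12] += 0.4
    labels = np.arange(24) < 12
    scores = md.loo_scores(x, labels, np.array([0.1]))[0]
    # at fixed scores, relabelling mirrors the AUC around chance
    assert md.rank_auc(scores, labels) + md.rank_auc(scores, ~labels) == (
        pytest.approx(1.0, abs=1e-12)
    )
    # the refit pipeline is label-symmetric: flipping the labels flips the
    # weight vector, so the held-out Az is unchanged
    az = md.loo_az(x, labels, 0.1)
    az_flip = md.loo_az(x, ~labels, 0.1)
    assert az_flip == pytest.approx(az, abs=1e-12)
    assert 0.0 <= az <= 1.0


def test_permuted_labels_center_az_at_chance(rng):
    x = rng.standard_normal((60, 4))
    azs = []
    for _ in range(60):
        labels = np.zeros(60, bool)
        labels[rng.permutation(60)[:30]] = True
        azs.append(md.loo_az(x, labels, 0.2))
    assert abs(np.mean(azs) - 0.5) < 0.03


def test_single_class_is_rejected(rng):
    x = rng.standard_normal((6, 3))
    with pytest.raises(ValueError):
        md.loo_az(x, np.ones(6, bool), 0.1)
    with pytest.raises(ValueError):
        md.rank_auc(np.arange(6.0), np.ones(6, bool))


# --------------------------------------------------------- lambda search


def test_default_grid_has_101_candidates(rng):
    x = rng.standard_normal((12, 3))
    x[:6] += 1.0
    labels = np.arange(12) < 6
    lam, az, az_all = md.optimize_lambda(x, labels)
    assert az_all.size == 101
    assert az == az_all.max()


def test_ties_break_toward_stronger_shrinkage():
    # one-dimensional data: shrinkage cannot change the ranking, all Az tie
    rng = np.random.default_rng(0)
    x = rng.standard_normal((14, 1))
    x[:7] += 2.0
    labels = np.arange(14) < 7
    lam, _, az_all = md.optimize_lambda(x, labels)
    assert np.allclose(az_all, az_all[0])
    assert lam == 1.0


def test_collinear_high_dimensional_noise_prefers_shrinkage(rng):
    """With D >> N and strongly collinear noise, the grid search picks
    lambda > 0 in a clear majority of runs."""
    wins = 0
    n_runs = 20
    for s in range(n_runs):
        r = np.random.default_rng(s)
        n, d = 16, 30
        q, _ = np.linalg.qr(r.standard_normal((d, d)))
        scale = np.sqrt(np.logspace(0, -2, d))  # condition number 100
        x = r.standard_normal((n, d)) @ (q * scale).T
        labels = np.arange(n) < n // 2
        shift = r.standard_normal(d)
        x[labels] += 0.3 * shift / np.linalg.norm(shift)
        lam, _, _ = md.optimize_lambda(
            x, labels, np.round(np.arange(0, 1.01, 0.05), 2)
        )
        wins += lam > 0
    assert wins > n_runs / 2


def test_invalid_grid_rejected(rng):
    x = rng.standard_normal((8, 2))
    labels = np.arange(8) < 4
    with pytest.raises(ValueError):
        md.optimize_lambda(x, labels, np.array([]))
    with pytest.raises(ValueError):
        md.optimize_lambda(x, labels, np.array([-0.1, 0.5]))


# ------------------------------------------------------- sliding analysis


def test_default_grid_yields_221_windows(la_participant):
    assert md.SlidingWindowSpec().centers_ms().size == 221


def test_sliding_analysis_on_zero_noise_data():
    cfg = small_eeg_config(seed=3, noise_sd_uv=0.0, stv_sd_uv=0.5)
    trials = md.simulate_task(md.TaskConfig(seed=3), md.AgentModel())
    ep, tr, _ = md.simulate_eeg(trials, cfg)
    labels, mask = md.contrast_labels(tr, "valence")
    ep = ep.select_trials(np.flatnonzero(mask))
    res = md.sliding_analysis(
        ep, labels, md.SlidingWindowSpec(step_ms=100.0), SMALL_LAMBDA_GRID
    )
    # with the noise off, every window overlapping the planted kernel's
    # support (450 +- 3 sd, i.e. 270-630 ms, widened by the 30 ms half
    # window) separates the classes perfectly; all others sit at chance
    assert res.az[np.searchsorted(res.centers_ms, 450.0)] == 1.0
    perfect = res.centers_ms[res.valid & (res.az == 1.0)]
    assert perfect.size > 0
    assert perfect.min() >= 240.0 and perfect.max() <= 660.0
    outside = res.valid & ((res.centers_ms < 240.0) | (res.centers_ms > 660.0))
    assert np.allclose(res.az[outside], 0.5)


def test_sliding_analysis_invariant_to_common_scaling(la_participant):
    p = la_participant
    labels, mask = md.contrast_labels(p.trials, "valence")
    ep = p.epochs.select_trials(np.flatnonzero(mask))
    spec = md.SlidingWindowSpec(start_ms=300.0, stop_ms=600.0, step_ms=50.0)
    res1 = md.sliding_analysis(ep, labels, spec, SMALL_LAMBDA_GRID)
    scaled = ep.copy()
    scaled.data = scaled.data * 3.7
    res2 = md.sliding_analysis(scaled, labels, spec, SMALL_LAMBDA_GRID)
    assert np.allclose(res1.az, res2.az)
    assert np.allclose(res1.lam, res2.lam)


def test_out_of_span_windows_are_skipped_not_fatal(rng):
    ep = _epochs_from_array(rng.standard_normal((8, 3, 257)), srate=256.0,
                            t0=-100.0)
    labels = np.arange(8) < 4
    spec = md.SlidingWindowSpec(start_ms=-200.0, stop_ms=1500.0, step_ms=100.0)
    res = md.sliding_analysis(ep, labels, spec, SMALL_LAMBDA_GRID)
    assert (~res.valid).any() and res.valid.any()
    assert np.isnan(res.az[~res.valid]).all()


def test_sliding_result_round_trips_through_hdf5(tmp_path, rng):
    ep = _epochs_from_array(rng.standard_normal((10, 3, 641)))
    labels = np.arange(10) < 5
    res = md.sliding_analysis(
        ep, labels, md.SlidingWindowSpec(step_ms=500.0), SMALL_LAMBDA_GRID
    )
    path = tmp_path / "res.h5"
    res.to_hdf5(path)
    back = md.SlidingResult.from_hdf5(path)
    assert np.array_equal(back.az, res.az, equal_nan=True)
    assert np.array_equal(back.y, res.y, equal_nan=True)
    assert back.n_pos == res.n_pos
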