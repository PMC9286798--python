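"""Permutation-based significance of discriminator performance and forward
models.

The null distribution of Az is built by randomly permuting trial labels and
re-running the *entire* decoding pipeline at the evaluated windows --
including the shrinkage grid search -- so that the selection optimism of
choosing lambda on the evaluation trials is present in the null exactly as it
is in the observed statistic.  The significance threshold is the empirical
(1 - alpha) quantile of the null draws, either pooled across windows into a
single threshold (the default, matching the single dotted significance line
convention for Az time courses) or per window.

Forward models translate the discriminant's backward weights into an
interpretable scalp topography: a = X y / (y' y), the channel pattern whose
amplitude time course best explains the data through the discriminating
component y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decoder import DEFAULT_LAMBDA_GRID, optimize_lambda, window_average
from .io import EpochSet, SlidingResult


@dataclass
class PermutationNull:
    """Label-permutation null for windowed Az values."""

    null_az: np.ndarray            # (n_perm, n_windows)
    centers_ms: np.ndarray
    alpha: float
    pooling_mode: str              # "pooled" | "per_window"
    threshold: np.ndarray          # scalar array (pooled) or per-window

    def threshold_at(self, n_windows: int) -> np.ndarray:
        t = np.atleast_1d(self.threshold)
        if t.size == 1:
            return np.full(n_windows, float(t[0]))
        if t.size != n_windows:
            raise ValueError("per-window threshold does not match curve grid")
        return t


def _empirical_threshold(draws: np.ndarray, alpha: float) -> float:
    """k-th largest draw with k = floor(alpha * n): the largest value t such
    that a strictly greater observation has empirical p < alpha."""
    draws = np.sort(np.asarray(draws, dtype=float).ravel())
    k = max(int(np.floor(alpha * draws.size)), 1)
    return float(draws[-k])


def permutation_threshold(
    x: EpochSet | np.ndarray,
    labels: np.ndarray,
    centers_ms: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    width_ms: float = 60.0,
    pooling_mode: str = "pooled",
    seed: int | None = 0,
) -> PermutationNull:
    """Null Az distribution over the probe windows.

    ``x`` may be an EpochSet (vectors computed per window) or a pre-computed
    array of window-averaged vectors with shape (n_windows, n_trials,
    n_channels).
    """
    if n_perm < 20:
        raise ValueError("n_perm < 20 gives a meaningless quantile")
    if pooling_mode not in ("pooled", "per_window"):
        raise ValueError(f"unknown pooling_mode {pooling_mode!r}")
    labels = np.asarray(labels, dtype=bool)
    centers_ms = np.atleast_1d(np.asarray(centers_ms, dtype=float))
    if isinstance(x, EpochSet):
        vectors = np.stack([window_average(x, c, width_ms) for c in centers_ms])
    else:
        vectors = np.asarray(x, dtype=float)
        if vectors.ndim != 3 or vectors.shape[0] != centers_ms.size:
            raise ValueError("vectors must be (n_windows, n_trials, n_channels)")
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, centers_ms.size))
    for p in range(n_perm):
        perm = rng.permutation(labels)
        for i in range(centers_ms.size):
            _, null[p, i], _ = optimize_lambda(vectors[i], perm, lambda_grid)
    if pooling_mode == "pooled":
        threshold = np.asarray([_empirical_threshold(null, alpha)])
    else:
        threshold = np.asarray(
            [_empirical_threshold(null[:, i], alpha) for i in range(centers_ms.size)]
        )
    return PermutationNull(
        null_az=null, centers_ms=centers_ms, alpha=alpha,
        pooling_mode=pooling_mode, threshold=threshold,
    )


def peak_window(result: SlidingResult, tol: float = 0.02) -> int:
    """Index of the representative peak window of an Az curve.

    Az curves from strong components plateau near their maximum; the
    representative window is the center of the contiguous run of windows
    within ``tol`` of the maximum that contains the argmax (the midpoint of
    the maximal-discrimination region), rather than the run's first window.
    """
    az = np.where(result.valid, result.az, -np.inf)
    if not np.isfinite(az).any():
        raise ValueError("no valid windows in the curve")
    k = int(np.argmax(az))
    near = az >= az[k] - tol
    lo = k
    while lo > 0 and near[lo - 1]:
        lo -= 1
    hi = k
    while hi < az.size - 1 and near[hi + 1]:
        hi += 1
    return (lo + hi) // 2


def forward_model(vectors: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Forward-model scalp map a = X y / (y' y) at one window.

    ``vectors`` is (n_trials, n_channels) window-averaged data, ``y`` the
    per-trial component amplitudes at that window.
    """
    y = np.asarray(y, dtype=float)
    vectors = np.asarray(vectors, dtype=float)
    if y.ndim != 1 or vectors.shape[0] != y.size:
        raise ValueError("y must be one value per trial")
    yy = float(y @ y)
    if yy == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("forward model undefined: component has zero variance")
    return (vectors.T @ y) / yy


def peak_forward_map(
    x: EpochSet, result: SlidingResult, tol: float = 0.02,
    width_ms: float = 60.0,
) -> tuple[np.ndarray, int]:
    """Forward map of the peak component: per-window maps averaged over the
    contiguous near-maximum plateau of the Az curve.

    Averaging across the maximal-discrimination region mirrors the windowed
    averaging used for the component amplitudes themselves and suppresses
    per-window estimation noise in the map.  Returns ``(map, peak_index)``.
    """
    k = peak_window(result, tol)
    az = np.where(result.valid, result.az, -np.inf)
    near = az >= az[int(np.argmax(az))] - tol
    lo = k
    while lo > 0 and near[lo - 1]:
        lo -= 1
    hi = k
    while hi < az.size - 1 and near[hi + 1]:
        hi += 1
    maps = [
        forward_model(window_average(x, result.centers_ms[i], width_ms),
                      result.y[i])
        for i in range(lo, hi + 1)
    ]
    return np.mean(maps, axis=0), k


def forward_model_curve(x: EpochSet, result: SlidingResult,
                        width_ms: float = 60.0) -> np.ndarray:
    """Forward map at every valid window of a sliding result
    (n_windows, n_channels; NaN rows where invalid)."""
    maps = np.full((result.centers_ms.size, x.n_channels), np.nan)
    for i, c in enumerate(result.centers_ms):
        if not result.valid[i]:
            continue
        maps[i] = forward_model(window_average(x, c, width_ms), result.y[i])
    return maps


def significant_intervals(
    result: SlidingResult, null: PermutationNull
) -> list[tuple[float, float]]:
    """Maximal runs of consecutive windows with Az above threshold, as
    [start_ms, end_ms] intervals extended half a grid step on each side."""
    centers = result.centers_ms
    if centers.size != null.centers_ms.size or not np.allclose(
        centers, null.centers_ms
    ):
        raise ValueError("curve and null are on different window grids")
    thr = null.threshold_at(centers.size)
    sig = result.valid & (result.az > thr)
    if centers.size > 1:
        half_step = float(np.median(np.diff(centers))) / 2.0
    else:
        half_step = 5.0
    intervals: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(sig):
        if flag and start is None:
            start = centers[i]
        if not flag and start is not None:
            intervals.append((start - half_step, centers[i - 1] + half_step))
            start = None
    if start is not None:
        intervals.append((start - half_step, centers[-1] + half_step))
    return intervals
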