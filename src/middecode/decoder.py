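"""Sliding-window regularized Fisher discriminant with leave-one-out Az.

For each 60-ms training window centered on a grid of onset times, the EEG is
averaged over samples within the window, giving one channel vector per trial.
A Fisher linear discriminant with shrinkage-regularized class covariances

    S~_i = (1 - lambda) S_i + lambda nu_i I,   nu_i = trace(S_i) / D

is fitted on the common matrix S_c = (S~_1 + S~_2) / 2, and the weight vector
w solves S_c w = m_2 - m_1.  Per-trial discriminating-component amplitudes
are y_i = w' x_i; discrimination performance is the area under the ROC curve
(Az) of the held-out y values under trial-level leave-one-out (LOO)
cross-validation.  The shrinkage strength lambda is chosen per window by grid
search on the LOO Az.

Leave-one-out refits are exact: removing trial k from its class is a rank-one
downdate of that class's covariance, so each held-out weight vector is
obtained by a Sherman-Morrison solve in the eigenbasis of a per-class base
matrix (all lambda values share one eigendecomposition).  A from-scratch
batched-eigendecomposition path with pseudo-inverse semantics backs this up
for degenerate inputs (e.g. lambda = 0 with more channels than trials).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .io import EpochSet, SlidingResult

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)


@dataclass
class SlidingWindowSpec:
    """Training-window geometry: 60-ms windows on a -200..2000 ms grid.

    ``placement`` controls whether a grid time tau is the window *center*
    (symmetric sum over tau +- width/2, the default) or the window *onset*.
    """

    width_ms: float = 60.0
    start_ms: float = -200.0
    stop_ms: float = 2000.0
    step_ms: float = 10.0
    placement: str = "center"

    def centers_ms(self) -> np.ndarray:
        grid = np.arange(self.start_ms, self.stop_ms + 1e-9, self.step_ms)
        if self.placement == "center":
            return grid
        if self.placement == "onset":
            return grid + self.width_ms / 2.0
        raise ValueError(f"unknown placement {self.placement!r}")


@dataclass
class FisherDiscriminant:
    """Fitted discriminant at one window."""

    w: np.ndarray
    lam: float
    m1: np.ndarray
    m2: np.ndarray
    s_common: np.ndarray
    window_center_ms: float | None = None


def window_average(
    x: EpochSet, center_ms: float, width_ms: float = 60.0
) -> np.ndarray:
    """Per-trial channel vectors: mean over samples with centers inside
    [center - width/2, center + width/2] (closed interval)."""
    half = width_ms / 2.0
    tol = 1e-9 * max(1.0, abs(center_ms))
    mask = (x.times_ms >= center_ms - half - tol) & (
        x.times_ms <= center_ms + half + tol
    )
    if not mask.any():
        raise ValueError(
            f"window {center_ms}+-{half} ms contains no samples of the epoch grid"
        )
    return x.data[:, :, mask].mean(axis=2)


def regularize_covariance(s: np.ndarray, lam: float) -> np.ndarray:
    """Shrink a covariance toward the scaled identity, preserving its trace."""
    s = np.asarray(s, dtype=float)
    d = s.shape[0]
    if s.shape != (d, d):
        raise ValueError("S must be square")
    if not np.allclose(s, s.T, atol=1e-8 * max(1.0, np.abs(s).max())):
        raise ValueError("S must be symmetric")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    nu = np.trace(s) / d
    return (1.0 - lam) * s + lam * nu * np.eye(d)


def _class_cov(x: np.ndarray) -> np.ndarray:
    n, d = x.shape
    if n < 2:
        return np.zeros((d, d))
    xc = x - x.mean(axis=0)
    return (xc.T @ xc) / (n - 1)


def fit_fisher(
    x1: np.ndarray, x2: np.ndarray, lam: float,
    window_center_ms: float | None = None,
) -> FisherDiscriminant:
    """Fit the regularized Fisher discriminant to two classes of vectors.

    ``x1``/``x2`` are (n_trials, n_channels); class 2 is the positive class
    (w points from m1 toward m2).  If the common matrix is singular (e.g.
    lambda = 0 with D >= N) the system is solved with a pseudo-inverse and a
    warning is logged.
    """
    x1, x2 = np.atleast_2d(np.asarray(x1, float)), np.atleast_2d(np.asarray(x2, float))
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("need at least 2 trials per class")
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    s_common = 0.5 * (
        regularize_covariance(_class_cov(x1), lam)
        + regularize_covariance(_class_cov(x2), lam)
    )
    dm = m2 - m1
    # solve in the eigenbasis with small eigenvalues zeroed: equals the exact
    # solve when S_c is well conditioned and the pseudo-inverse otherwise
    # (lambda = 0 with rank-deficient data, e.g. after average referencing)
    evals, evecs = np.linalg.eigh(s_common)
    tol = 1e-10 * max(float(evals.max()), 0.0)
    keep = evals > tol
    if not keep.all():
        logger.warning(
            "rank-deficient common covariance (lambda=%g, rank %d/%d); "
            "using pseudo-inverse", lam, int(keep.sum()), s_common.shape[0],
        )
    inv = np.where(keep, 1.0 / np.where(keep, evals, 1.0), 0.0)
    w = evecs @ (inv * (evecs.T @ dm))
    return FisherDiscriminant(w=w, lam=lam, m1=m1, m2=m2, s_common=s_common,
                              window_center_ms=window_center_ms)


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney with ties counted 1/2).

    ``labels`` is boolean; True marks the positive class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined with a single class")
    r = rankdata(scores)
    return float((r[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _rank_auc_rows(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """AUC of each row of ``scores`` against boolean ``labels``."""
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    r = rankdata(scores, axis=1)
    return (r[:, labels].sum(axis=1) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


# ---------------------------------------------------------------------------
# leave-one-out machinery


def _loo_scores_direct(
    x: np.ndarray, labels: np.ndarray, lams: np.ndarray
) -> np.ndarray:
    """Reference LOO path: rebuild class statistics per left-out trial and
    solve in the eigenbasis of the (unregularized) common matrix; reciprocal
    eigenvalues below tolerance are zeroed (pseudo-inverse semantics)."""
    n, d = x.shape
    lams = np.asarray(lams, dtype=float)
    a_mats = np.empty((n, d, d))
    dms = np.empty((n, d))
    for k in range(n):
        keep = np.ones(n, dtype=bool)
        keep[k] = False
        x1 = x[keep & ~labels]
        x2 = x[keep & labels]
        m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
        a_mats[k] = 0.5 * (_class_cov(x1) + _class_cov(x2))
        dms[k] = m2 - m1
    # S_c(lambda) = (1-lambda) A + lambda * (trace(A)/D) I shares A's eigenbasis
    c = np.trace(a_mats, axis1=1, axis2=2) / d
    evals, evecs = np.linalg.eigh(a_mats)
    dm_t = np.einsum("kij,ki->kj", evecs, dms)
    x_t = np.einsum("kij,ki->kj", evecs, x)
    denom = (1.0 - lams[:, None, None]) * evals[None] + (
        lams[:, None, None] * c[None, :, None]
    )
    tol = 1e-12 * np.maximum(np.abs(denom).max(axis=2, keepdims=True), 1e-300)
    inv = np.where(np.abs(denom) > tol, 1.0 / np.where(denom == 0, 1.0, denom), 0.0)
    return np.einsum("kj,lkj,kj->lk", dm_t, inv, x_t)


def _loo_scores_downdate(
    x: np.ndarray, labels: np.ndarray, lams: np.ndarray
) -> np.ndarray | None:
    """Fast exact LOO via rank-one covariance downdate + Sherman-Morrison.

    Returns None when a near-singular configuration is detected, in which
    case the caller falls back to the direct path.
    """
    n, d = x.shape
    lams = np.asarray(lams, dtype=float)
    scores = np.empty((lams.size, n))
    for cls in (False, True):
        idx = np.flatnonzero(labels == cls)
        xa = x[idx]            # class being left out from
        xb = x[labels != cls]  # fixed other class
        na = len(xa)
        ma, mb = xa.mean(axis=0), xb.mean(axis=0)
        sa, sb = _class_cov(xa), _class_cov(xb)
        nu_b = np.trace(sb) / d
        if na > 2:
            a_coef = (na - 1.0) / (na - 2.0)
            b_coef = na / ((na - 1.0) * (na - 2.0))
        else:  # leaving one of 2 trials: remaining class covariance undefined -> 0
            a_coef = 0.0
            b_coef = 0.0
        base = 0.5 * (a_coef * sa + sb)
        evals, evecs = np.linalg.eigh(base)
        evals = np.maximum(evals, 0.0)
        dvec = xa - ma                                   # (na, d)
        q = np.einsum("kd,kd->k", dvec, dvec)            # |d_k|^2
        m_loo = (na * ma - xa) / (na - 1.0)              # leave-out class mean
        dm = (mb - m_loo) if not cls else (m_loo - mb)   # m2 - m1, class2 positive
        d_t = dvec @ evecs
        r_t = dm @ evecs
        x_t = xa @ evecs
        # diagonal part: (1-lam) evals + lam * (nu'_a + nu_b)/2 with
        # nu'_a = a_coef*nu_a - b_coef*|d_k|^2/D
        shift = 0.5 * (a_coef * np.trace(sa) / d + nu_b) - 0.5 * b_coef * q / d
        diag = (1.0 - lams[:, None, None]) * evals[None, None, :] + (
            lams[:, None, None] * shift[None, :, None]
        )  # (L, na, D)
        scale = max(float(np.abs(diag).max()), 1e-300)
        if np.any(diag <= 1e-10 * scale):
            return None
        beta = 0.5 * (1.0 - lams) * b_coef               # (L,)
        p = r_t[None] / diag                             # (L, na, D)
        s_vec = d_t[None] / diag
        g = np.einsum("kd,lkd->lk", d_t, s_vec)
        den = 1.0 - beta[:, None] * g
        if np.any(np.abs(den) <= 1e-10):
            return None
        coef = beta[:, None] * np.einsum("kd,lkd->lk", d_t, p) / den
        w_t = p + coef[:, :, None] * s_vec
        scores[:, idx] = np.einsum("lkd,kd->lk", w_t, x_t)
    return scores


def loo_scores(
    x: np.ndarray, labels: np.ndarray, lams: np.ndarray
) -> np.ndarray:
    """Held-out discriminating-component amplitude of every trial, for every
    shrinkage value: shape (n_lambdas, n_trials)."""
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("leave-one-out needs at least 2 trials per class")
    # (numerically) constant vectors carry no class information; amplified
    # rounding noise must not masquerade as discrimination
    spread = np.abs(x - x.mean(axis=0)).max()
    if spread <= 1e-9 * max(1.0, np.abs(x).max()):
        return np.zeros((np.asarray(lams).size, x.shape[0]))
    out = _loo_scores_downdate(x, labels, lams)
    if out is None:
        logger.info("near-singular LOO system; using direct pseudo-inverse path")
        out = _loo_scores_direct(x, labels, lams)
    return out


def loo_az(x: np.ndarray, labels: np.ndarray, lam: float) -> float:
    """Leave-one-out Az at a single shrinkage value."""
    scores = loo_scores(x, labels, np.asarray([lam]))
    return rank_auc(scores[0], labels)


def optimize_lambda(
    x: np.ndarray,
    labels: np.ndarray,
    grid: np.ndarray = DEFAULT_LAMBDA_GRID,
) -> tuple[float, float, np.ndarray]:
    """Grid-search the shrinkage maximizing LOO Az.

    Returns ``(lambda*, az*, az_per_lambda)``; ties are broken toward the
    larger (more regularized) lambda.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or grid.min() < 0 or grid.max() > 1:
        raise ValueError("lambda grid must be non-empty within [0, 1]")
    labels = np.asarray(labels, dtype=bool)
    scores = loo_scores(x, labels, grid)
    az = _rank_auc_rows(scores, labels)
    best = np.flatnonzero(az >= az.max() - 1e-12)[-1]
    return float(grid[best]), float(az[best]), az


def sliding_analysis(
    x: EpochSet,
    labels: np.ndarray,
    spec: SlidingWindowSpec | None = None,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
) -> SlidingResult:
    """Run the windowed discriminant over the full grid.

    ``labels`` is boolean per trial (True = positive class, e.g. gain in the
    valence contrast).  Windows that fall outside the epoch span, or where
    either class has fewer than 2 trials, are recorded as invalid (NaN) and
    skipped with a log entry.
    """
    spec = spec or SlidingWindowSpec()
    labels = np.asarray(labels, dtype=bool)
    if labels.size != x.n_trials:
        raise ValueError("labels length does not match trial count")
    centers = spec.centers_ms()
    n_w, n_t, n_c = centers.size, x.n_trials, x.n_channels
    az = np.full(n_w, np.nan)
    lam = np.full(n_w, np.nan)
    weights = np.full((n_w, n_c), np.nan)
    y = np.full((n_w, n_t), np.nan)
    valid = np.zeros(n_w, dtype=bool)
    half = spec.width_ms / 2.0
    t0, t1 = x.times_ms[0], x.times_ms[-1]
    enough = labels.sum() >= 2 and (~labels).sum() >= 2
    for i, c in enumerate(centers):
        if c - half < t0 - 1e-9 or c + half > t1 + 1e-9:
            logger.info("window %.0f ms exceeds epoch span; skipped", c)
            continue
        if not enough:
            continue
        vecs = window_average(x, c, spec.width_ms)
        lam_star, az_star, _ = optimize_lambda(vecs, labels, lambda_grid)
        fit = fit_fisher(vecs[~labels], vecs[labels], lam_star, window_center_ms=c)
        az[i], lam[i] = az_star, lam_star
        weights[i] = fit.w
        y[i] = vecs @ fit.w
        valid[i] = True
    return SlidingResult(
        centers_ms=centers, az=az, lam=lam, weights=weights, y=y,
        labels=labels, valid=valid,
        n_pos=int(labels.sum()), n_neg=int((~labels).sum()),
        channel_labels=list(x.channel_labels),
    )


def contrast_labels(trials, contrast: str) -> tuple[np.ndarray, np.ndarray]:
    """Boolean labels and row-mask for a named contrast.

    ``valence``: gain (positive) vs loss, neutral trials excluded.
    ``salience``: incentive (positive) vs neutral, all trials retained.
    Returns ``(labels_for_retained_trials, retained_row_mask)``.
    """
    cond = np.asarray(trials["condition"])
    if contrast == "valence":
        mask = cond != "neutral"
        return (cond[mask] == "gain"), mask
    if contrast == "salience":
        mask = np.ones(cond.size, dtype=bool)
        return (cond != "neutral"), mask
    raise ValueError(f"unknown contrast {contrast!r}")
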