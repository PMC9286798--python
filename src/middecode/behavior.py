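"""Linking single-trial EEG variability (STV) to behaviour.

Three pieces:

* RT-distribution matching for the salience contrast -- incentive trials are
  subsampled so their reaction-time distribution matches the neutral trials'
  (Gaussian density acceptance sampling), removing motor-preparation
  confounds before decoding incentive vs neutral.
* STV extraction -- the per-trial discriminating-component amplitude averaged
  over a time window (e.g. the 400-550 ms valence window).
* A two-stage regression: per participant, ordinary least squares of RT on
  {1, STV, trial order, trial outcome}; at the group level, a one-tailed
  one-sample t test on the per-participant STV coefficients in the
  hypothesized direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import SlidingResult


class MatchingError(RuntimeError):
    """Raised when RT-distribution matching cannot reach tolerance."""

    def __init__(self, message: str, diagnostics: dict):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass
class MatchResult:
    incentive_index: np.ndarray    # trial-table row positions
    neutral_index: np.ndarray
    diagnostics: dict


def _match_diagnostics(rt_inc: np.ndarray, rt_neu: np.ndarray) -> dict:
    pooled_sd = np.sqrt(0.5 * (rt_inc.var(ddof=1) + rt_neu.var(ddof=1)))
    smd = (rt_inc.mean() - rt_neu.mean()) / pooled_sd if pooled_sd > 0 else 0.0
    var_ratio = (
        rt_inc.var(ddof=1) / rt_neu.var(ddof=1) if rt_neu.var(ddof=1) > 0 else np.inf
    )
    ks = stats.ks_2samp(rt_inc, rt_neu)
    return {
        "mean_rt": {"incentive": float(rt_inc.mean()), "neutral": float(rt_neu.mean())},
        "var_rt": {"incentive": float(rt_inc.var(ddof=1)),
                   "neutral": float(rt_neu.var(ddof=1))},
        "standardized_mean_difference": float(smd),
        "variance_ratio": float(var_ratio),
        "ks_statistic": float(ks.statistic),
        "n_per_set": int(len(rt_inc)),
    }


def match_rt_distributions(
    trials: pd.DataFrame,
    seed: int | None = 0,
    smd_tolerance: float = 0.1,
    var_ratio_bounds: tuple[float, float] = (0.8, 1.25),
    max_attempts: int = 50,
) -> MatchResult:
    """Select incentive trials whose RTs match the neutral RT distribution.

    Responded incentive and neutral trials are paired 1:1 by greedy
    nearest-neighbor matching on RT (globally closest pairs first), pairs
    whose RT difference exceeds a caliper of 0.25 neutral standard
    deviations are discarded, and the worst remaining pairs are pruned one
    at a time (up to ``max_attempts``) until the standardized mean
    difference is below ``smd_tolerance`` and the variance ratio falls
    within ``var_ratio_bounds``.  Identical distributions pair almost
    perfectly, so nearly ``min(n)`` trials are retained per side; a planted
    incentive speeding is corrected by dropping the unmatched neutral tail.
    Equal counts in both sets and a never-increased mean RT gap hold by
    construction.  ``seed`` breaks ties among equally close pairs.
    """
    rt = trials["rt_ms"].to_numpy(dtype=float)
    cond = trials["condition"].to_numpy()
    responded = np.isfinite(rt)
    inc_idx = np.flatnonzero((cond != "neutral") & responded)
    neu_idx = np.flatnonzero((cond == "neutral") & responded)
    if len(inc_idx) < 10 or len(neu_idx) < 10:
        raise ValueError("need at least 10 responded trials per side to match")
    rng = np.random.default_rng(seed)
    sd_n = rt[neu_idx].std(ddof=1)
    caliper = 0.25 * sd_n

    # greedy globally-closest bipartite pairing on RT
    d = np.abs(rt[inc_idx][:, None] - rt[neu_idx][None, :])
    flat = np.argsort(d + 1e-12 * rng.random(d.shape), axis=None, kind="stable")
    used_i = np.zeros(len(inc_idx), bool)
    used_n = np.zeros(len(neu_idx), bool)
    pairs: list[tuple[int, int, float]] = []
    for f in flat:
        i, j = divmod(int(f), len(neu_idx))
        if used_i[i] or used_n[j]:
            continue
        if d[i, j] > caliper:
            break  # distances are visited in increasing order
        used_i[i] = used_n[j] = True
        pairs.append((i, j, float(d[i, j])))
        if used_i.all() or used_n.all():
            break

    last_diag = _match_diagnostics(rt[inc_idx], rt[neu_idx])
    pairs.sort(key=lambda p: p[2])  # best first; prune from the tail
    for _ in range(max_attempts + 1):
        if len(pairs) < 10:
            raise MatchingError(
                "RT matching cannot reach tolerance with >= 10 pairs",
                last_diag,
            )
        sel_inc = inc_idx[[p[0] for p in pairs]]
        sel_neu = neu_idx[[p[1] for p in pairs]]
        diag = _match_diagnostics(rt[sel_inc], rt[sel_neu])
        last_diag = diag
        ok = (
            abs(diag["standardized_mean_difference"]) < smd_tolerance
            and var_ratio_bounds[0] <= diag["variance_ratio"] <= var_ratio_bounds[1]
        )
        if ok:
            return MatchResult(
                incentive_index=np.sort(sel_inc),
                neutral_index=np.sort(sel_neu),
                diagnostics=diag,
            )
        pairs = pairs[:-1]
    raise MatchingError(
        f"RT matching failed after pruning {max_attempts} pairs", last_diag
    )


@dataclass
class STVRecord:
    """Per-trial component amplitude averaged over a time window."""

    stv: np.ndarray
    window_ms: tuple[float, float]
    contrast: str = "valence"


def extract_stv(
    result: SlidingResult, window_ms: tuple[float, float], contrast: str = "valence"
) -> STVRecord:
    """Mean of the discriminating component over all valid window centers
    inside ``window_ms`` (closed interval)."""
    lo, hi = window_ms
    mask = (
        (result.centers_ms >= lo - 1e-9)
        & (result.centers_ms <= hi + 1e-9)
        & result.valid
    )
    if not mask.any():
        raise ValueError(
            f"no evaluated window centers inside [{lo}, {hi}] ms"
        )
    return STVRecord(
        stv=result.y[mask].mean(axis=0), window_ms=(float(lo), float(hi)),
        contrast=contrast,
    )


@dataclass
class ParticipantRegression:
    params: pd.Series
    bse: pd.Series
    n_trials: int
    n_dropped: int
    model: object = field(repr=False, default=None)

    @property
    def beta_stv(self) -> float:
        return float(self.params["stv"])


def fit_rt_regression(
    trials: pd.DataFrame, stv: STVRecord, trial_mask: np.ndarray | None = None
) -> ParticipantRegression:
    """OLS of RT on {intercept, STV, trial order, trial outcome (+1/-1)}.

    ``trial_mask`` maps the STV values onto rows of the trial table when the
    decoded contrast used a subset of trials (e.g. valence excludes
    neutrals).  Trials without a response are dropped (RT undefined).
    """
    sub = trials if trial_mask is None else trials.loc[np.asarray(trial_mask)]
    sub = sub.reset_index(drop=True)
    if len(sub) != stv.stv.size:
        raise ValueError("STV length does not match selected trials")
    design = pd.DataFrame(
        {
            "stv": stv.stv,
            "trial_order": sub["trial_index"].to_numpy(dtype=float),
            "trial_outcome": sub["outcome"].to_numpy(dtype=float),
        }
    )
    rt = sub["rt_ms"].to_numpy(dtype=float)
    ok = np.isfinite(rt)
    n_dropped = int((~ok).sum())
    if ok.sum() < 10:
        raise ValueError("need at least 10 responded trials for the regression")
    xmat = sm.add_constant(design.loc[ok], has_constant="add")
    nonconst = [c for c in ("stv", "trial_order", "trial_outcome")
                if np.ptp(xmat[c].to_numpy()) == 0]
    if nonconst:
        raise ValueError(f"constant regressor column(s): {nonconst}")
    rank = np.linalg.matrix_rank(xmat.to_numpy())
    if rank < xmat.shape[1]:
        corr = np.corrcoef(xmat.to_numpy().T[1:])
        pairs = [
            (xmat.columns[1:][i], xmat.columns[1:][j])
            for i in range(corr.shape[0])
            for j in range(i + 1, corr.shape[0])
            if abs(corr[i, j]) > 0.999
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {pairs}")
    fit = sm.OLS(rt[ok], xmat).fit()
    return ParticipantRegression(
        params=fit.params, bse=fit.bse, n_trials=int(ok.sum()),
        n_dropped=n_dropped, model=fit,
    )


@dataclass
class GroupTestResult:
    t: float
    df: int
    p: float
    direction: str
    n: int
    mean_beta: float
    note: str = ""


def group_beta_test(betas: np.ndarray, direction: str = "negative") -> GroupTestResult:
    """One-tailed one-sample t test that the per-participant STV coefficients
    have mean below (``negative``) or above (``positive``) zero."""
    betas = np.asarray(betas, dtype=float)
    n = betas.size
    if n < 3:
        raise ValueError("need at least 3 participants")
    if direction not in ("negative", "positive"):
        raise ValueError("direction must be 'negative' or 'positive'")
    mean = float(betas.mean())
    sd = float(betas.std(ddof=1))
    if sd == 0.0:
        # all coefficients identical: no sampling variability to test against
        return GroupTestResult(
            t=0.0 if mean == 0.0 else np.inf * np.sign(mean),
            df=n - 1, p=1.0 if mean == 0.0 else (0.0 if (
                (mean < 0) == (direction == "negative")) else 1.0),
            direction=direction, n=n, mean_beta=mean,
            note="degenerate: zero variance across participants",
        )
    alternative = "less" if direction == "negative" else "greater"
    res = stats.ttest_1samp(betas, 0.0, alternative=alternative)
    return GroupTestResult(
        t=float(res.statistic), df=n - 1, p=float(res.pvalue),
        direction=direction, n=n, mean_beta=mean,
    )
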