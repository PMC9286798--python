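"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive everything from first principles
(explicit per-leave-out refits, pair-counting AUC, normal-equation solves)
so they share no code path with the package implementation they check.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import middecode as md


# ---------------------------------------------------------------------------
# independent oracles


def oracle_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by explicit pair counting, ties counted 1/2."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins) / (len(pos) * len(neg))


def oracle_fisher_weights(x1: np.ndarray, x2: np.ndarray, lam: float) -> np.ndarray:
    """Regularized Fisher weights via explicit pinv of the common matrix."""
    def cov(x):
        if len(x) < 2:
            return np.zeros((x.shape[1], x.shape[1]))
        xc = x - x.mean(axis=0)
        return xc.T @ xc / (len(x) - 1)

    def reg(s):
        d = s.shape[0]
        return (1 - lam) * s + lam * (np.trace(s) / d) * np.eye(d)

    sc = 0.5 * (reg(cov(x1)) + reg(cov(x2)))
    return np.linalg.pinv(sc, hermitian=True) @ (x2.mean(axis=0) - x1.mean(axis=0))


def oracle_loo_scores(x: np.ndarray, labels: np.ndarray, lam: float) -> np.ndarray:
    """Leave-one-out component amplitudes by refitting every fold."""
    scores = np.empty(len(x))
    for k in range(len(x)):
        keep = np.ones(len(x), bool)
        keep[k] = False
        w = oracle_fisher_weights(x[keep & ~labels], x[keep & labels], lam)
        scores[k] = w @ x[k]
    return scores


def oracle_loo_az(x: np.ndarray, labels: np.ndarray, lam: float) -> float:
    return oracle_auc(oracle_loo_scores(x, labels, lam), labels)


# ---------------------------------------------------------------------------
# fixtures


SMALL_LAMBDA_GRID = np.array([0.01, 0.05, 0.1, 0.2, 0.4])


def small_eeg_config(**overrides) -> md.EEGGenConfig:
    """Reduced-resolution generator config for fast tests."""
    base = md.EEGGenConfig(n_channels=16, srate_hz=128.0)
    return dataclasses.replace(base, **overrides)


def small_cohort_spec(seed: int = 0, n_per_group: int = 22) -> md.CohortSpec:
    spec = md.CohortSpec(n_per_group=n_per_group, seed=seed)
    spec.eeg = small_eeg_config()
    return spec


@pytest.fixture(scope="session")
def la_participant() -> md.Participant:
    """One LA-like participant at full default resolution (64 ch, 256 Hz)."""
    return md.simulate_participant(md.CohortSpec(), md.la_like_preset(), seed=11)


@pytest.fixture(scope="session")
def ha_participant() -> md.Participant:
    """A no-valence-effect participant (null data for the valence contrast)."""
    return md.simulate_participant(md.CohortSpec(), md.ha_like_preset(), seed=23)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
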