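"""Monetary incentive delay (MID) task simulation.

On each trial a cue (gain / loss / neutral) is shown, a jittered anticipation
delay follows, and the participant makes a speeded response to a briefly
presented target.  An adaptive staircase shortens the target's response
interval when the running success rate of that trial type exceeds the design
target (66% hits) and lengthens it when the rate falls below, clamping
subjective difficulty across participants.  The simulated agent responds with
condition-dependent Gaussian reaction times and an occasional lapse
(no response).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CONDITIONS, validate_trial_table


@dataclass
class TaskConfig:
    """MID task structure and staircase parameters.

    Timing fields mirror the task design: 250 ms cue, 2000-2500 ms jittered
    anticipation delay, variable-duration target clipped to 100-1250 ms,
    1200 ms post-target blank, 1000 ms feedback, 2000 ms inter-trial interval.
    The staircase's initial duration and step size are free design parameters
    (500 ms and 25 ms by default).
    """

    n_trials_per_condition: int = 48
    target_hit_rate: float = 0.66
    target_duration_bounds_ms: tuple[float, float] = (100.0, 1250.0)
    initial_target_duration_ms: float = 500.0
    staircase_step_ms: float = 25.0
    n_practice_trials: int = 30
    cue_duration_ms: float = 250.0
    anticipation_delay_ms: tuple[float, float] = (2000.0, 2500.0)
    post_target_blank_ms: float = 1200.0
    feedback_ms: float = 1000.0
    iti_ms: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.target_duration_bounds_ms
        if self.n_trials_per_condition < 1:
            raise ValueError("n_trials_per_condition must be >= 1")
        if not 0.0 < self.target_hit_rate < 1.0:
            raise ValueError("target_hit_rate must lie strictly in (0, 1)")
        if not 0.0 < lo < hi:
            raise ValueError("target duration bounds must be ordered and positive")
        if self.initial_target_duration_ms <= 0 or self.staircase_step_ms <= 0:
            raise ValueError("durations and step size must be positive")


@dataclass
class AgentModel:
    """Simulated participant: Gaussian RTs per condition plus a lapse rate.

    Default presets encode incentive speeding: responses to incentive (gain,
    loss) cues are faster on average than to neutral cues.
    """

    rt_mean_ms: dict = field(
        default_factory=lambda: {"gain": 280.0, "loss": 285.0, "neutral": 330.0}
    )
    rt_sd_ms: dict = field(
        default_factory=lambda: {"gain": 60.0, "loss": 60.0, "neutral": 70.0}
    )
    lapse_rate: float = 0.02

    def __post_init__(self) -> None:
        for cond in CONDITIONS:
            if cond not in self.rt_mean_ms or cond not in self.rt_sd_ms:
                raise ValueError(f"agent missing RT parameters for {cond!r}")
            if self.rt_sd_ms[cond] <= 0:
                raise ValueError("rt_sd_ms must be positive")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must lie in [0, 1]")


class _Staircase:
    """Per-condition staircase on the running success rate."""

    def __init__(self, config: TaskConfig) -> None:
        self.duration = float(config.initial_target_duration_ms)
        self.lo, self.hi = config.target_duration_bounds_ms
        self.step = config.staircase_step_ms
        self.target = config.target_hit_rate
        self.n = 0
        self.hits = 0
        self.duration = float(np.clip(self.duration, self.lo, self.hi))

    def record(self, hit: bool) -> None:
        self.n += 1
        self.hits += int(hit)
        rate = self.hits / self.n
        if rate > self.target:
            self.duration -= self.step
        elif rate < self.target:
            self.duration += self.step
        self.duration = float(np.clip(self.duration, self.lo, self.hi))

    def reset_counts(self) -> None:
        self.n = 0
        self.hits = 0


def _run_block(
    conditions: np.ndarray,
    stairs: dict[str, _Staircase],
    agent: AgentModel,
    rng: np.random.Generator,
) -> list[dict]:
    rows = []
    for i, cond in enumerate(conditions, start=1):
        st = stairs[cond]
        duration = st.duration
        if rng.random() < agent.lapse_rate:
            rt = np.nan
        else:
            rt = max(rng.normal(agent.rt_mean_ms[cond], agent.rt_sd_ms[cond]), 1.0)
        hit = bool(np.isfinite(rt) and rt <= duration)
        st.record(hit)
        rows.append(
            {
                "trial_index": i,
                "condition": cond,
                "rt_ms": rt,
                "outcome": 1 if hit else -1,
                "target_duration_ms": duration,
            }
        )
    return rows


def simulate_task(config: TaskConfig, agent: AgentModel) -> pd.DataFrame:
    """Simulate one participant's session; return the per-trial table.

    The returned table has exactly ``3 * n_trials_per_condition`` rows in
    randomized order.  A practice block (not returned) warms up the staircase
    durations; running-rate counters restart at the main block so the
    staircase regulates the main block's own success rate.
    """
    rng = np.random.default_rng(config.seed)
    stairs = {cond: _Staircase(config) for cond in CONDITIONS}

    if config.n_practice_trials > 0:
        practice = rng.permutation(
            np.array(CONDITIONS * (config.n_practice_trials // 3 + 1))[
                : config.n_practice_trials
            ]
        )
        _run_block(practice, stairs, agent, rng)
        for st in stairs.values():
            st.reset_counts()

    main = rng.permutation(
        np.array([c for c in CONDITIONS for _ in range(config.n_trials_per_condition)])
    )
    rows = _run_block(main, stairs, agent, rng)
    trials = pd.DataFrame(rows)
    return validate_trial_table(trials)


def hit_rate(trials: pd.DataFrame) -> float:
    """Fraction of hits (+1 outcomes) in a trial table."""
    return float((trials["outcome"] == 1).mean())
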