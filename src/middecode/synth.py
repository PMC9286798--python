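"""Synthetic epoched EEG with planted valence and salience components.

Each cue-locked epoch is a linear superposition

    x_i(t) = a_V(i) * topo_V * k_V(t) + a_S(i) * topo_S * k_S(t) + noise_i(t)

with a parietal valence component (smooth bump around 450 ms whose class
amplitude is +g for gain cues and -g for loss cues, plus zero-mean trial-level
variability, "STV") and a fronto-central salience component (a late ramp over
the pre-target interval, present on incentive trials only).  Noise is
spatially correlated Gaussian mixed with a 1/f temporal component, so that
channel covariance is genuinely ill-conditioned and covariance shrinkage in
the discriminant is beneficial.  Optionally, reaction times are re-generated
from the planted valence STV through a linear link with negative slope
(stronger single-trial valence signalling -> faster responses).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import montage
from .io import EpochSet, write_trial_table
from .task import AgentModel, TaskConfig, simulate_task


@dataclass
class ComponentSpec:
    """One planted spatio-temporal component."""

    peak_electrode: str
    topo_sigma_m: float = 0.06
    kernel: str = "bump"            # "bump" (Gaussian in time) or "ramp"
    center_ms: float = 450.0        # bump center
    width_ms: float = 60.0          # bump sd; support truncated at +-3 sd
    ramp_ms: tuple[float, float] = (1300.0, 2000.0)
    amplitude_uv: float = 4.0


@dataclass
class RTLink:
    """RT = beta0 + beta1 * STV + residual noise (enabled per config)."""

    enabled: bool = True
    beta0_ms: float = 320.0
    beta1_ms_per_uv: float = -15.0
    residual_sd_ms: float = 60.0


@dataclass
class EEGGenConfig:
    n_channels: int = 64
    srate_hz: float = 256.0
    epoch_span_ms: tuple[float, float] = (-500.0, 2000.0)
    valence: ComponentSpec = field(
        default_factory=lambda: ComponentSpec(
            peak_electrode="Pz", kernel="bump", amplitude_uv=10.0
        )
    )
    salience: ComponentSpec = field(
        default_factory=lambda: ComponentSpec(peak_electrode="FCz", kernel="ramp")
    )
    stv_sd_uv: float = 4.0
    noise_sd_uv: float = 4.0
    pink_weight: float = 0.5        # share of 1/f noise in the temporal mix
    spatial_rank: int = 0           # 0 -> n_channels // 2 mixing factors
    rt_link: RTLink = field(default_factory=RTLink)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stv_sd_uv < 0 or self.noise_sd_uv < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0.0 <= self.pink_weight <= 1.0:
            raise ValueError("pink_weight must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted quantities, returned for recovery diagnostics and tests."""

    topo_valence: np.ndarray
    topo_salience: np.ndarray
    kernel_valence: np.ndarray
    kernel_salience: np.ndarray
    stv_uv: np.ndarray              # per-trial valence STV draw
    valence_amp_uv: np.ndarray      # per-trial total valence amplitude
    salience_amp_uv: np.ndarray


def epoch_times_ms(config: EEGGenConfig) -> np.ndarray:
    """Uniform sample grid over the epoch span, inclusive of both endpoints."""
    t0, t1 = config.epoch_span_ms
    step = 1000.0 / config.srate_hz
    n = int(round((t1 - t0) / step)) + 1
    return t0 + step * np.arange(n)


def _temporal_kernel(spec: ComponentSpec, times_ms: np.ndarray) -> np.ndarray:
    if spec.kernel == "bump":
        z = (times_ms - spec.center_ms) / spec.width_ms
        k = np.exp(-0.5 * z**2)
        k[np.abs(z) > 3.0] = 0.0
        return k
    if spec.kernel == "ramp":
        a, b = spec.ramp_ms
        k = np.clip((times_ms - a) / (b - a), 0.0, None)
        k[times_ms < a] = 0.0
        return np.clip(k, 0.0, 1.0)
    raise ValueError(f"unknown kernel {spec.kernel!r}")


def _noise(
    rng: np.random.Generator,
    n_trials: int,
    n_samples: int,
    config: EEGGenConfig,
    mixing: np.ndarray,
) -> np.ndarray:
    from scipy.fft import irfft, next_fast_len

    n_sources = mixing.shape[1]
    white = rng.standard_normal((n_trials, n_sources, n_samples))
    if config.pink_weight > 0:
        # 1/f noise synthesized in the frequency domain at an FFT-friendly
        # padded length (the epoch length itself may be prime)
        n_fft = next_fast_len(n_samples, real=True)
        nf = n_fft // 2 + 1
        spec = rng.standard_normal((n_trials, n_sources, nf)) + 1j * rng.standard_normal(
            (n_trials, n_sources, nf)
        )
        freqs = np.fft.rfftfreq(n_fft, d=1.0 / config.srate_hz)
        shaping = np.zeros_like(freqs)
        shaping[1:] = freqs[1:] ** -0.5
        pink = irfft(spec * shaping, n=n_fft)[..., :n_samples]
        pink /= max(pink.std(), 1e-12)
        w = config.pink_weight
        mix = (1 - w) * white + w * pink
        mix /= np.sqrt((1 - w) ** 2 + w**2)
    else:
        mix = white
    # spatial correlation: channels = mixing @ sources (one large matmul)
    flat = mix.transpose(1, 0, 2).reshape(n_sources, n_trials * n_samples)
    out = (mixing @ flat).reshape(-1, n_trials, n_samples).transpose(1, 0, 2)
    return config.noise_sd_uv * np.ascontiguousarray(out)


def _spatial_mixing(rng: np.random.Generator, n_channels: int, rank: int) -> np.ndarray:
    """Random mixing with unit average channel variance and reduced rank."""
    rank = rank if rank > 0 else max(n_channels // 2, 1)
    g = rng.standard_normal((n_channels, rank)) / np.sqrt(rank)
    m = np.hstack([g, 0.35 * np.eye(n_channels)])
    row_power = np.sqrt(np.mean(np.sum(m**2, axis=1)))
    return m / row_power


def simulate_eeg(
    trials: pd.DataFrame, config: EEGGenConfig
) -> tuple[EpochSet, pd.DataFrame, GroundTruth]:
    """Generate one participant's cue-locked epochs for a trial table.

    Returns the epochs, a trial table (with RTs and outcomes re-derived from
    the valence STV when the RT link is enabled), and the planted ground
    truth.
    """
    if len(trials) == 0:
        raise ValueError("trial table is empty")
    rng = np.random.default_rng(config.seed)
    labels = montage.channel_labels(config.n_channels)
    times = epoch_times_ms(config)
    n_trials, n_channels, n_samples = len(trials), len(labels), times.size

    topo_v = montage.gaussian_topography(
        labels, config.valence.peak_electrode, config.valence.topo_sigma_m
    )
    topo_s = montage.gaussian_topography(
        labels, config.salience.peak_electrode, config.salience.topo_sigma_m
    )
    kern_v = _temporal_kernel(config.valence, times)
    kern_s = _temporal_kernel(config.salience, times)

    cond = trials["condition"].to_numpy()
    sign = np.where(cond == "gain", 1.0, np.where(cond == "loss", -1.0, 0.0))
    stv = rng.normal(0.0, config.stv_sd_uv, size=n_trials)
    amp_v = sign * config.valence.amplitude_uv + stv
    amp_s = np.where(cond == "neutral", 0.0, config.salience.amplitude_uv)

    mixing = _spatial_mixing(rng, n_channels, config.spatial_rank)
    data = _noise(rng, n_trials, n_samples, config, mixing)
    data += amp_v[:, None, None] * topo_v[None, :, None] * kern_v[None, None, :]
    data += amp_s[:, None, None] * topo_s[None, :, None] * kern_s[None, None, :]

    out_trials = trials.copy().reset_index(drop=True)
    if config.rt_link.enabled:
        link = config.rt_link
        rt = link.beta0_ms + link.beta1_ms_per_uv * stv + rng.normal(
            0.0, link.residual_sd_ms, size=n_trials
        )
        rt = np.maximum(rt, 1.0)
        missing = ~np.isfinite(out_trials["rt_ms"].to_numpy(dtype=float))
        rt[missing] = np.nan
        out_trials["rt_ms"] = rt
        out_trials["outcome"] = np.where(
            np.isfinite(rt) & (rt <= out_trials["target_duration_ms"]), 1, -1
        )

    epochs = EpochSet(
        data=data,
        channel_labels=list(labels),
        srate_hz=config.srate_hz,
        times_ms=times,
        lock_event="cue",
        reference_state="raw",
    )
    truth = GroundTruth(
        topo_valence=topo_v,
        topo_salience=topo_s,
        kernel_valence=kern_v,
        kernel_salience=kern_s,
        stv_uv=stv,
        valence_amp_uv=amp_v,
        salience_amp_uv=amp_s,
    )
    return epochs, out_trials, truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class GroupPreset:
    """Parameter overrides defining a simulated group."""

    name: str
    valence_amplitude_uv: float
    salience_amplitude_uv: float
    rt_beta1_ms_per_uv: float


def la_like_preset() -> GroupPreset:
    """Low-alcohol-like group: intact valence signalling, negative RT link."""
    return GroupPreset("LA", valence_amplitude_uv=10.0,
                       salience_amplitude_uv=4.0, rt_beta1_ms_per_uv=-15.0)


def ha_like_preset() -> GroupPreset:
    """High-alcohol-like group: absent valence component, elevated salience."""
    return GroupPreset("HA", valence_amplitude_uv=0.0,
                       salience_amplitude_uv=6.0, rt_beta1_ms_per_uv=0.0)


@dataclass
class CohortSpec:
    n_per_group: int = 22
    seed: int = 0
    la: GroupPreset = field(default_factory=la_like_preset)
    ha: GroupPreset = field(default_factory=ha_like_preset)
    task: TaskConfig = field(default_factory=TaskConfig)
    agent: AgentModel = field(default_factory=AgentModel)
    eeg: EEGGenConfig = field(default_factory=EEGGenConfig)


@dataclass
class Participant:
    participant_id: str
    group: str
    seed: int
    epochs: EpochSet
    trials: pd.DataFrame
    truth: GroundTruth


def participant_config(
    spec: CohortSpec, preset: GroupPreset, seed: int
) -> tuple[TaskConfig, EEGGenConfig]:
    task = dataclasses.replace(spec.task, seed=seed)
    eeg = dataclasses.replace(
        spec.eeg,
        seed=seed + 1,
        valence=dataclasses.replace(
            spec.eeg.valence, amplitude_uv=preset.valence_amplitude_uv
        ),
        salience=dataclasses.replace(
            spec.eeg.salience, amplitude_uv=preset.salience_amplitude_uv
        ),
        rt_link=dataclasses.replace(
            spec.eeg.rt_link, beta1_ms_per_uv=preset.rt_beta1_ms_per_uv
        ),
    )
    return task, eeg


def _participant_seeds(spec: CohortSpec) -> list[int]:
    ss = np.random.SeedSequence(spec.seed)
    return [int(s) % (2**31) for s in ss.generate_state(2 * spec.n_per_group)]


def simulate_participant(spec: CohortSpec, preset: GroupPreset, seed: int,
                         participant_id: str = "p000") -> Participant:
    task_cfg, eeg_cfg = participant_config(spec, preset, seed)
    trials = simulate_task(task_cfg, spec.agent)
    epochs, trials, truth = simulate_eeg(trials, eeg_cfg)
    return Participant(participant_id, preset.name, seed, epochs, trials, truth)


def simulate_cohort(spec: CohortSpec) -> list[Participant]:
    """Simulate ``2 * n_per_group`` participants (LA-like then HA-like)."""
    seeds = _participant_seeds(spec)
    cohort = []
    for g, preset in enumerate((spec.la, spec.ha)):
        for i in range(spec.n_per_group):
            pid = f"{preset.name.lower()}{i:03d}"
            cohort.append(
                simulate_participant(
                    spec, preset, seeds[g * spec.n_per_group + i], pid
                )
            )
    return cohort


def generate_cohort(spec: CohortSpec, out_dir, overwrite: bool = False) -> Path:
    """Persist a cohort to ``out_dir``; returns the manifest path.

    Layout: one ``<id>_epochs.h5`` and ``<id>_trials.tsv`` per participant,
    plus ``manifest.json`` recording group labels and per-participant seeds.
    Refuses to clobber an existing manifest unless ``overwrite`` is set.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"{manifest_path} exists; pass overwrite=True to replace it"
        )
    records = []
    for p in simulate_cohort(spec):
        epochs_file = f"{p.participant_id}_epochs.h5"
        trials_file = f"{p.participant_id}_trials.tsv"
        p.epochs.to_hdf5(out_dir / epochs_file)
        write_trial_table(p.trials, out_dir / trials_file)
        records.append(
            {
                "id": p.participant_id,
                "group": p.group,
                "seed": p.seed,
                "epochs": epochs_file,
                "trials": trials_file,
            }
        )
    manifest = {
        "n_per_group": spec.n_per_group,
        "seed": spec.seed,
        "participants": records,
    }
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest_path
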