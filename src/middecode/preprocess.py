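"""Deterministic preprocessing chain applied before discriminant analysis.

The chain mirrors a conventional scalp-EEG pipeline: 0.1-95 Hz band-pass,
50 Hz mains notch, common average reference, cue-locked epoching from -500 to
2000 ms, and a final 30 Hz low-pass.  All filters are zero-phase
(forward-backward) IIR filters, so the chain is linear and phase-preserving.
A simple amplitude-threshold epoch rejector is provided in place of
statistical artifact-rejection toolchains (off by default; synthetic data
contain no artifacts).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import EpochSet

logger = logging.getLogger(__name__)


@dataclass
class FilterSpec:
    """Band-pass, notch and final low-pass cutoffs (Hz)."""

    band_pass_hz: tuple[float, float] | None = (0.1, 95.0)
    notch_hz: float | None = 50.0
    final_lowpass_hz: float | None = 30.0
    order: int = 4
    notch_q: float = 35.0

    def validate(self, srate_hz: float) -> None:
        nyq = srate_hz / 2.0
        cutoffs = []
        if self.band_pass_hz is not None:
            lo, hi = self.band_pass_hz
            if not 0 < lo < hi:
                raise ValueError("band-pass cutoffs must satisfy 0 < low < high")
            cutoffs.append(hi)
        if self.notch_hz is not None:
            cutoffs.append(self.notch_hz)
        if self.final_lowpass_hz is not None:
            cutoffs.append(self.final_lowpass_hz)
        if any(c >= nyq for c in cutoffs):
            raise ValueError(
                f"filter cutoff at or above Nyquist ({nyq} Hz) for srate {srate_hz}"
            )


def _filtfilt_last_axis(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    padlen = min(3 * (2 * sos.shape[0] + 1), x.shape[-1] - 1)
    return signal.sosfiltfilt(sos, x, axis=-1, padlen=padlen)


def apply_filters(x, spec: FilterSpec, srate_hz: float | None = None):
    """Zero-phase filtering along the sample axis; shape preserved.

    ``x`` may be an :class:`EpochSet` (srate taken from it) or a plain array
    with time as the last axis (``srate_hz`` then required).
    """
    if isinstance(x, EpochSet):
        out = x.copy()
        out.data = apply_filters(out.data, spec, out.srate_hz)
        return out
    if srate_hz is None:
        raise ValueError("srate_hz required for array input")
    spec.validate(srate_hz)
    data = np.asarray(x, dtype=float)
    if spec.band_pass_hz is not None:
        sos = signal.butter(
            spec.order, spec.band_pass_hz, btype="bandpass", fs=srate_hz, output="sos"
        )
        data = _filtfilt_last_axis(sos, data)
    if spec.notch_hz is not None:
        b, a = signal.iirnotch(spec.notch_hz, spec.notch_q, fs=srate_hz)
        padlen = min(3 * max(len(a), len(b)), data.shape[-1] - 1)
        data = signal.filtfilt(b, a, data, axis=-1, padlen=padlen)
    if spec.final_lowpass_hz is not None:
        sos = signal.butter(
            spec.order, spec.final_lowpass_hz, btype="lowpass", fs=srate_hz,
            output="sos",
        )
        data = _filtfilt_last_axis(sos, data)
    return data


def average_reference(x: EpochSet) -> EpochSet:
    """Common average reference: subtract the mean across scalp channels.

    Idempotent; re-referencing an already average-referenced set warns and
    returns an identical copy.
    """
    out = x.copy()
    if x.reference_state == "average":
        warnings.warn("EpochSet is already average-referenced", stacklevel=2)
    out.data = out.data - out.data.mean(axis=1, keepdims=True)
    out.reference_state = "average"
    return out


def epoch_and_baseline(
    continuous: np.ndarray,
    events_sample: np.ndarray,
    srate_hz: float,
    channel_labels: list[str],
    span_ms: tuple[float, float] = (-500.0, 2000.0),
    baseline_ms: tuple[float, float] | None = (-200.0, 0.0),
    lock_event: str = "cue",
) -> EpochSet:
    """Cut epochs around event samples and subtract the per-channel baseline.

    ``continuous`` is (channel, sample).  Events whose epoch would overrun the
    record are dropped with a log entry.  When ``baseline_ms`` is None no
    baseline correction is applied.
    """
    continuous = np.asarray(continuous, dtype=float)
    step = 1000.0 / srate_hz
    i0 = int(round(span_ms[0] / step))
    i1 = int(round(span_ms[1] / step))
    times = step * np.arange(i0, i1 + 1)
    n_samples = continuous.shape[1]
    epochs = []
    for ev in np.asarray(events_sample, dtype=int):
        if ev + i0 < 0 or ev + i1 >= n_samples:
            logger.info("dropping event at sample %d: epoch exceeds record", ev)
            continue
        epochs.append(continuous[:, ev + i0 : ev + i1 + 1])
    if not epochs:
        raise ValueError("no events yielded a complete epoch")
    data = np.stack(epochs)
    if baseline_ms is not None:
        mask = (times >= baseline_ms[0]) & (times <= baseline_ms[1])
        if not mask.any():
            raise ValueError("baseline window contains no samples")
        data = data - data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochSet(
        data=data,
        channel_labels=list(channel_labels),
        srate_hz=srate_hz,
        times_ms=times,
        lock_event=lock_event,
        reference_state="raw",
    )


def read_continuous_edf(path) -> tuple[np.ndarray, float, list[str]]:
    """Read a continuous EDF/BDF recording (microvolts, channel x sample).

    Thin wrapper over mne's reader for interoperability with acquisition
    systems; returns ``(data_uv, srate_hz, channel_names)`` ready for
    :func:`epoch_and_baseline`.
    """
    import mne

    path = str(path)
    if path.lower().endswith(".bdf"):
        raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)


def reject_epochs_by_amplitude(
    x: EpochSet, threshold_uv: float
) -> tuple[EpochSet, np.ndarray]:
    """Drop epochs whose absolute amplitude exceeds ``threshold_uv`` anywhere.

    Returns the reduced set and the boolean keep-mask (for aligning trial
    tables).
    """
    if threshold_uv <= 0:
        raise ValueError("threshold_uv must be positive")
    keep = np.abs(x.data).max(axis=(1, 2)) <= threshold_uv
    out = dataclasses.replace(x, data=x.data[keep])
    if not keep.all():
        logger.info("rejected %d/%d epochs above %.1f uV",
                    (~keep).sum(), keep.size, threshold_uv)
    return out, keep
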