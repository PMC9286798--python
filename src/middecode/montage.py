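"""10-10 scalp montage helpers.

Channel labels and 3-D electrode positions come from the standard Biosemi
64-channel layout (10-10 nomenclature), which includes the parietal
(P1, P2, POz, Pz), fronto-central (FC1, FC2, FCz, Fz) and central
(C1, C2, Cz, FCz) groups used by the ERP analyses.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


@lru_cache(maxsize=1)
def _full_montage() -> tuple[tuple[str, ...], np.ndarray]:
    import mne

    mont = mne.channels.make_standard_montage("biosemi64")
    pos = mont.get_positions()["ch_pos"]
    names = tuple(mont.ch_names)
    xyz = np.asarray([pos[ch] for ch in names], dtype=float)
    return names, xyz


def channel_labels(n_channels: int = 64) -> list[str]:
    """Return ``n_channels`` 10-10 labels spread evenly over the 64-channel cap."""
    names, _ = _full_montage()
    if not 1 <= n_channels <= len(names):
        raise ValueError(f"n_channels must be in [1, {len(names)}], got {n_channels}")
    idx = _subset_indices(n_channels)
    return [names[i] for i in idx]


def channel_positions(labels: list[str] | tuple[str, ...]) -> np.ndarray:
    """3-D head-frame positions (metres) for the given 10-10 labels."""
    names, xyz = _full_montage()
    lookup = {ch: i for i, ch in enumerate(names)}
    missing = [ch for ch in labels if ch not in lookup]
    if missing:
        raise KeyError(f"unknown montage label(s): {missing}")
    return xyz[[lookup[ch] for ch in labels]]


def _subset_indices(n_channels: int) -> np.ndarray:
    if n_channels == 64:
        return np.arange(64)
    return np.unique(np.linspace(0, 63, n_channels).round().astype(int))


def gaussian_topography(
    labels: list[str] | tuple[str, ...], peak: str, sigma_m: float = 0.06
) -> np.ndarray:
    """Unit-norm spatial pattern peaked at electrode ``peak``.

    The pattern falls off as a Gaussian of inter-electrode euclidean distance,
    a conventional stand-in for the smooth scalp projection of a focal
    cortical source.
    """
    xyz = channel_positions(labels)
    names, full_xyz = _full_montage()
    try:
        center = full_xyz[names.index(peak)]
    except ValueError as err:
        raise KeyError(f"unknown montage label: {peak!r}") from err
    d = np.linalg.norm(xyz - center, axis=1)
    topo = np.exp(-0.5 * (d / sigma_m) ** 2)
    return topo / np.linalg.norm(topo)
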