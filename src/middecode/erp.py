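"""Classical ERP window measures and the between-group comparison of Az
time courses.

ERP components are quantified as mean amplitudes over fixed windows and
electrode groups (cue-P3a 250-400 ms and cue-P3b 400-550 ms over P1, P2,
POz, Pz; P2 160-210 ms and N2 210-310 ms over FC1, FC2, FCz, Fz; CNV
1800-2000 ms over C1, C2, Cz, FCz).  Group-level ANOVAs and Tukey post-hocs
are thin wrappers over stock routines (pingouin).

Group Az curves are compared with a nonparametric cluster-mass permutation
test: per-timepoint one-tailed unpaired t statistics are thresholded at the
alpha-level critical t, supra-threshold runs form clusters whose summed t is
compared against the permutation distribution of the maximum cluster mass
under random group relabelings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import EpochSet

ELECTRODE_GROUPS = {
    "parietal": ["P1", "P2", "POz", "Pz"],
    "frontal": ["FC1", "FC2", "FCz", "Fz"],
    "central": ["C1", "C2", "Cz", "FCz"],
}


@dataclass
class ERPComponentSpec:
    name: str
    electrode_group: list[str]
    window_ms: tuple[float, float]


STANDARD_COMPONENTS = {
    "P2": ERPComponentSpec("P2", ELECTRODE_GROUPS["frontal"], (160.0, 210.0)),
    "N2": ERPComponentSpec("N2", ELECTRODE_GROUPS["frontal"], (210.0, 310.0)),
    "cueP3a": ERPComponentSpec("cueP3a", ELECTRODE_GROUPS["parietal"], (250.0, 400.0)),
    "cueP3b": ERPComponentSpec("cueP3b", ELECTRODE_GROUPS["parietal"], (400.0, 550.0)),
    "CNV": ERPComponentSpec("CNV", ELECTRODE_GROUPS["central"], (1800.0, 2000.0)),
}


def erp_window_means(
    x: EpochSet, trials: pd.DataFrame, spec: ERPComponentSpec
) -> dict[str, float]:
    """Mean amplitude (microvolts) per condition: averaged over that
    condition's trials, the component's electrodes, and the window samples."""
    ch = x.channel_index(spec.electrode_group)
    lo, hi = spec.window_ms
    tmask = (x.times_ms >= lo - 1e-9) & (x.times_ms <= hi + 1e-9)
    if not tmask.any():
        raise ValueError(f"window {spec.window_ms} outside epoch span")
    cond = trials["condition"].to_numpy()
    out = {}
    for c in pd.unique(cond):
        rows = np.flatnonzero(cond == c)
        if rows.size == 0:
            raise ValueError(f"no trials in condition {c!r}")
        out[str(c)] = float(x.data[np.ix_(rows, ch)][:, :, tmask].mean())
    return out


def erp_condition_table(
    participants: list[tuple[str, str, EpochSet, pd.DataFrame]],
    components: dict[str, ERPComponentSpec] | None = None,
) -> pd.DataFrame:
    """Long-format table (participant, group, component, condition,
    amplitude_uv) for downstream ANOVAs."""
    components = components or STANDARD_COMPONENTS
    rows = []
    for pid, group, epochs, trials in participants:
        for name, spec in components.items():
            for cond, amp in erp_window_means(epochs, trials, spec).items():
                rows.append(
                    {"participant": pid, "group": group, "component": name,
                     "condition": cond, "amplitude_uv": amp}
                )
    return pd.DataFrame(rows)


def condition_rm_anova(table: pd.DataFrame, component: str) -> pd.DataFrame:
    """Repeated-measures ANOVA of amplitude on condition (stock routine)."""
    import pingouin as pg

    sub = table[table["component"] == component]
    return pg.rm_anova(
        data=sub, dv="amplitude_uv", within="condition", subject="participant",
        correction=True,
    )


def mixed_group_anova(table: pd.DataFrame, component: str) -> pd.DataFrame:
    """Mixed ANOVA: condition (within) x group (between) (stock routine)."""
    import pingouin as pg

    sub = table[table["component"] == component]
    return pg.mixed_anova(
        data=sub, dv="amplitude_uv", within="condition", subject="participant",
        between="group", correction=True,
    )


def condition_tukey(table: pd.DataFrame, component: str) -> pd.DataFrame:
    """Tukey HSD pairwise condition comparison (stock routine)."""
    import pingouin as pg

    sub = table[table["component"] == component]
    return pg.pairwise_tukey(data=sub, dv="amplitude_uv", between="condition")


def difference_wave(
    x: EpochSet, trials: pd.DataFrame, cond_a: str, cond_b: str
) -> np.ndarray:
    """Trial-mean(cond_a) - trial-mean(cond_b), per channel and sample."""
    cond = trials["condition"].to_numpy()
    a = np.flatnonzero(cond == cond_a)
    b = np.flatnonzero(cond == cond_b)
    if a.size == 0 or b.size == 0:
        raise ValueError(f"empty condition among ({cond_a!r}, {cond_b!r})")
    return x.data[a].mean(axis=0) - x.data[b].mean(axis=0)


@dataclass
class GroupAzComparison:
    centers_ms: np.ndarray
    t: np.ndarray
    critical_t: float
    clusters: list[dict] = field(default_factory=list)
    tail: str = "greater"
    n_perm: int = 0

    @property
    def significant_clusters(self) -> list[dict]:
        return [c for c in self.clusters if c["cluster_p"] < 0.05]


def _unpaired_t_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per column; a, b are (participants, W)."""
    n1, n2 = a.shape[0], b.shape[0]
    v1 = a.var(axis=0, ddof=1)
    v2 = b.var(axis=0, ddof=1)
    sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    denom = sp * np.sqrt(1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, (a.mean(axis=0) - b.mean(axis=0)) / denom, 0.0)


def _clusters_from_t(tvals: np.ndarray, crit: float) -> list[tuple[int, int, float]]:
    """(start, stop inclusive, mass) of maximal supra-threshold runs."""
    above = tvals > crit
    out = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        if not flag and start is not None:
            out.append((start, i - 1, float(tvals[start:i].sum())))
            start = None
    if start is not None:
        out.append((start, len(tvals) - 1, float(tvals[start:].sum())))
    return out


def compare_az_curves(
    az_group1: np.ndarray,
    az_group2: np.ndarray,
    centers_ms: np.ndarray,
    window_ms: tuple[float, float] | None = None,
    tail: str = "greater",
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = 0,
) -> GroupAzComparison:
    """Cluster-mass permutation comparison of per-participant Az curves.

    ``az_group1``/``az_group2`` are (n_participants, n_windows).  ``tail``
    'greater' tests group1 > group2 per timepoint; 'less' the reverse.
    Cluster p values are the fraction of group-relabeling draws whose maximum
    cluster mass reaches the observed cluster's mass (add-one estimator).
    """
    if az_group1.shape[0] < 2 or az_group2.shape[0] < 2:
        raise ValueError("need at least 2 participants per group")
    if n_perm < 100:
        raise ValueError("n_perm < 100 is too few for cluster p values")
    if tail not in ("greater", "less"):
        raise ValueError("tail must be 'greater' or 'less'")
    centers_ms = np.asarray(centers_ms, dtype=float)
    a = np.asarray(az_group1, dtype=float)
    b = np.asarray(az_group2, dtype=float)
    if window_ms is not None:
        lo, hi = window_ms
        keep = (centers_ms >= lo - 1e-9) & (centers_ms <= hi + 1e-9)
        if not keep.any():
            raise ValueError("no window centers inside the comparison window")
        centers_ms, a, b = centers_ms[keep], a[:, keep], b[:, keep]
    sign = 1.0 if tail == "greater" else -1.0
    n1, n2 = a.shape[0], b.shape[0]
    crit = float(stats.t.ppf(1.0 - alpha, df=n1 + n2 - 2))
    tobs = sign * _unpaired_t_rows(a, b)
    clusters = _clusters_from_t(tobs, crit)

    pooled = np.vstack([a, b])
    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        order = rng.permutation(n1 + n2)
        tp = sign * _unpaired_t_rows(pooled[order[:n1]], pooled[order[n1:]])
        cl = _clusters_from_t(tp, crit)
        null_max[p] = max((m for _, _, m in cl), default=0.0)

    out_clusters = []
    if centers_ms.size > 1:
        half = float(np.median(np.diff(centers_ms))) / 2.0
    else:
        half = 5.0
    for i0, i1, mass in clusters:
        cluster_p = float((1 + np.sum(null_max >= mass)) / (1 + n_perm))
        out_clusters.append(
            {
                "start_ms": float(centers_ms[i0] - half),
                "end_ms": float(centers_ms[i1] + half),
                "mass": mass,
                "cluster_p": cluster_p,
            }
        )
    # t is reported in the tested direction (positive = evidence for the tail)
    return GroupAzComparison(
        centers_ms=centers_ms, t=tobs, critical_t=crit,
        clusters=out_clusters, tail=tail, n_perm=n_perm,
    )
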