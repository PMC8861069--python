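"""Statistical comparison machinery for real and generated ERPs.

Covers the standard ERP quantification route (window means at named
electrodes, 2x2 repeated-measures ANOVA with partial eta², Bonferroni
paired post-hocs), paired effect sizes, default-prior (JZS) Bayesian paired
t-tests per sample, and the spatiotemporal cluster-based permutation test
with its 50-ms epoch aggregation.

The cluster test follows the usual max-statistic recipe for paired designs:
per-sample dependent t values, a two-sided t-quantile entry threshold,
clusters connected under channel adjacency x temporal contiguity with a
minimum-simultaneous-neighbor constraint, cluster mass = summed t, and a
null distribution of the maximum |mass| over random per-subject sign flips
of the condition difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy import sparse
from scipy import stats as sst
from scipy.sparse.csgraph import connected_components

from .datasets import ChannelLayout, ERPDataset, window_slice


@dataclass(frozen=True)
class ComponentWindows:
    """Canonical quantification windows (ms) and electrode sets."""

    p1: tuple[float, float] = (90.0, 110.0)
    n1: tuple[float, float] = (150.0, 170.0)
    n2: tuple[float, float] = (250.0, 280.0)
    p3_frontocentral: tuple[float, float] = (375.0, 400.0)
    p3_parietal: tuple[float, float] = (375.0, 400.0)
    bf_n2_window: tuple[float, float] = (271.0, 291.0)
    bf_p3_cluster_window: tuple[float, float] = (350.0, 400.0)
    electrodes_p1_n1: tuple = ("P7", "P8")
    electrode_n2: str = "Cz"
    electrode_p3_frontocentral: str = "FC1"
    electrode_p3_parietal: str = "P1"
    pooled_electrodes: tuple = ("Cz", "FCz", "FC1", "FC2", "FC3", "FC4")


def window_mean(dataset: ERPDataset, window_ms: tuple[float, float],
                electrodes) -> dict[str, np.ndarray]:
    """Mean activity over a half-open window and electrode set.

    Returns one per-subject vector per condition.
    """
    if isinstance(electrodes, str):
        electrodes = [electrodes]
    if len(electrodes) == 0:
        raise ValueError("empty electrode set")
    idx = [dataset.layout.index(e) for e in electrodes]
    sl = window_slice(window_ms, dataset.fs, dataset.t0_ms)
    if sl.start < 0 or sl.stop > dataset.n_times or sl.stop <= sl.start:
        raise ValueError(f"window {window_ms} outside the {dataset.t0_ms}-ms-anchored axis")
    return {
        cond: arr[:, idx, sl].mean(axis=(1, 2)) for cond, arr in dataset.data.items()
    }


# ---------------------------------------------------------------------------
# repeated-measures ANOVA (2x2 within-subject) and effect sizes


@dataclass(frozen=True)
class EffectResult:
    F: float
    p: float
    eta_p2: float
    df: tuple[int, int]


def _contrast_effect(c: np.ndarray) -> EffectResult:
    n = c.size
    ss_eff = n * c.mean() ** 2
    ss_err = float(np.sum((c - c.mean()) ** 2))
    if ss_err == 0:
        f = np.inf if ss_eff > 0 else 0.0
    else:
        f = ss_eff / (ss_err / (n - 1))
    p = float(sst.f.sf(f, 1, n - 1)) if np.isfinite(f) else 0.0
    eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
    return EffectResult(float(f), p, float(eta), (1, n - 1))


def rm_anova_2x2(a1b1, a1b2, a2b1, a2b2) -> dict[str, EffectResult]:
    """2x2 fully within-subject ANOVA via difference contrasts.

    Factor A varies across the first index (a1 vs a2), factor B across the
    second. For two-level factors each effect's F equals the squared paired
    t of its contrast, and partial eta² = SS_effect / (SS_effect +
    SS_effect x subject).
    """
    cells = [np.asarray(c, dtype=float) for c in (a1b1, a1b2, a2b1, a2b2)]
    n = cells[0].size
    if n < 2 or any(c.size != n for c in cells):
        raise ValueError("need >= 2 subjects with complete cells")
    y11, y12, y21, y22 = cells
    return {
        "A": _contrast_effect((y21 + y22) / 2 - (y11 + y12) / 2),
        "B": _contrast_effect((y12 + y22) / 2 - (y11 + y21) / 2),
        "AxB": _contrast_effect((y11 - y12 - y21 + y22) / 2),
    }


def bonferroni_posthoc(pairs: list[tuple[np.ndarray, np.ndarray]]) -> list[tuple[float, float]]:
    """Paired t-tests with Bonferroni-corrected p, one per pair."""
    out = []
    for x, y in pairs:
        t, p = sst.ttest_rel(x, y)
        out.append((float(t), float(min(1.0, p * len(pairs)))))
    return out


def paired_cohens_d(x, y) -> float:
    """d_z = mean(x - y) / sd(x - y), sample SD with n - 1."""
    diff = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if diff.size < 2:
        raise ValueError("need >= 2 pairs")
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError("zero difference SD: effect size undefined")
    return float(diff.mean() / sd)


# ---------------------------------------------------------------------------
# JZS Bayes factor for the paired t-test


def bf10_from_t(t: float, n: int, prior_scale: float = 0.707) -> float:
    """Default-prior (JZS) Bayes factor from a paired-t statistic.

    Cauchy prior with the given scale on the standardized effect, expressed
    through the usual scale mixture of normals and integrated numerically.
    """
    if not np.isfinite(t):
        raise ValueError("non-finite t")
    df = n - 1
    r2 = prior_scale**2

    def integrand(g):
        a = 1.0 + n * g * r2
        return (
            a**-0.5
            * (1.0 + t**2 / (a * df)) ** (-(df + 1) / 2)
            * (2 * np.pi) ** -0.5
            * g**-1.5
            * np.exp(-1.0 / (2 * g))
        )

    num, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    den = (1.0 + t**2 / df) ** (-(df + 1) / 2)
    return float(num / den)


def bf10_paired(x, y, prior_scale: float = 0.707) -> tuple[float, float]:
    """(BF10, BF01) for a two-sided paired comparison."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or x.shape != y.shape:
        raise ValueError("need >= 2 complete pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite input")
    t, _ = sst.ttest_rel(x, y)
    bf10 = bf10_from_t(float(t), x.size, prior_scale)
    return bf10, 1.0 / bf10


def clamp_bf(bf: float, cap: float = 30.0) -> float:
    """Display convention: Bayes factors above the cap are shown at the cap."""
    return min(bf, cap)


def bf_trace(real: np.ndarray, generated: np.ndarray,
             prior_scale: float = 0.707) -> dict[str, np.ndarray]:
    """Per-sample BF10/BF01 and Cohen's d for pooled-electrode signals.

    ``real``/``generated``: (n_subjects, n_times) pooled signals.
    """
    n, n_t = real.shape
    bf10 = np.empty(n_t)
    d = np.empty(n_t)
    for j in range(n_t):
        t, _ = sst.ttest_rel(generated[:, j], real[:, j])
        bf10[j] = bf10_from_t(float(t), n, prior_scale)
        diff = generated[:, j] - real[:, j]
        sd = diff.std(ddof=1)
        d[j] = diff.mean() / sd if sd > 0 else 0.0
    return {"bf10": bf10, "bf01": 1.0 / bf10, "d": d}


# ---------------------------------------------------------------------------
# cluster-based permutation test


@dataclass(frozen=True)
class PermutationConfig:
    n_draws: int = 1000
    alpha: float = 0.05
    min_neighbor_channels: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class Cluster:
    channels: np.ndarray  # per-sample channel indices
    times: np.ndarray  # per-sample time indices
    sign: int
    mass: float
    p: float


@dataclass
class ClusterResult:
    t_map: np.ndarray  # (n_ch, n_t)
    threshold: float
    clusters: list[Cluster]
    sig_mask: np.ndarray  # (n_ch, n_t) boolean, significant clusters only
    alpha: float
    n_draws: int
    times_ms: np.ndarray
    channel_names: list[str]
    null_max_mass: np.ndarray = field(default=None, repr=False)

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p < self.alpha]


def paired_t_map(diffs: np.ndarray) -> np.ndarray:
    """Closed-form dependent t per (channel, timepoint); 0 where SD is 0."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(sd > 0, t, 0.0)


class _ClusterEngine:
    """Precomputed spatiotemporal graph for repeated cluster searches."""

    def __init__(self, adjacency: np.ndarray, n_times: int, min_neighbor_channels: int):
        self.adj = adjacency.astype(float)
        self.min_nb = min_neighbor_channels
        n_ch = adjacency.shape[0]
        self.n_ch, self.n_t = n_ch, n_times
        self.n_nodes = n_ch * n_times
        # all potential edges on the (channel, time) grid, flat index = ch * n_t + t
        ch_idx = np.arange(n_ch)[:, None]
        t_idx = np.arange(n_times - 1)[None, :]
        temp1 = (ch_idx * n_times + t_idx).ravel()
        temp2 = temp1 + 1
        a, b = np.nonzero(np.triu(adjacency, 1))
        sp1 = (a[:, None] * n_times + np.arange(n_times)[None, :]).ravel()
        sp2 = (b[:, None] * n_times + np.arange(n_times)[None, :]).ravel()
        self.e1 = np.concatenate([temp1, sp1])
        self.e2 = np.concatenate([temp2, sp2])

    def mask(self, t_map: np.ndarray, threshold: float) -> np.ndarray:
        """Suprathreshold samples surviving the minimum-neighbor rule.

        Returns an int8 map: +1 / -1 for retained positive / negative
        samples, 0 elsewhere.
        """
        pos = t_map > threshold
        neg = t_map < -threshold
        if self.min_nb > 0:
            pos &= self.adj @ pos >= self.min_nb
            neg &= self.adj @ neg >= self.min_nb
        return pos.astype(np.int8) - neg.astype(np.int8)

    def _labels(self, signed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        flat = signed.ravel()
        sel = (flat[self.e1] == flat[self.e2]) & (flat[self.e1] != 0)
        g = sparse.coo_matrix(
            (np.ones(int(sel.sum())), (self.e1[sel], self.e2[sel])),
            shape=(self.n_nodes, self.n_nodes),
        )
        _, labels = connected_components(g, directed=False)
        return labels, flat

    def clusters(self, t_map: np.ndarray, threshold: float):
        """All clusters as (member flat indices, sign, mass)."""
        signed = self.mask(t_map, threshold)
        if not signed.any():
            return []
        labels, flat = self._labels(signed)
        members = labels[flat != 0]
        out = []
        for lab in np.unique(members):
            nodes = np.flatnonzero((labels == lab) & (flat != 0))
            mass = float(t_map.ravel()[nodes].sum())
            out.append((nodes, int(np.sign(mass)), mass))
        return out

    def max_mass(self, t_map: np.ndarray, threshold: float) -> float:
        signed = self.mask(t_map, threshold)
        if not signed.any():
            return 0.0
        labels, flat = self._labels(signed)
        active = flat != 0
        masses = np.bincount(labels[active], weights=t_map.ravel()[active])
        counts = np.bincount(labels[active])
        return float(np.abs(masses[counts > 0]).max())


def cluster_permutation(
    real: ERPDataset,
    generated: ERPDataset,
    config: PermutationConfig = PermutationConfig(),
    condition: str | None = None,
    adjacency: np.ndarray | None = None,
) -> ClusterResult:
    """Spatiotemporal cluster permutation test of real vs generated signals.

    Datasets must be paired by subject and share the channel layout. The
    null distribution is the maximum |cluster mass| over random per-subject
    sign flips of the paired difference; cluster p-values use added-one
    smoothing, so the attainable floor is 1 / (n_draws + 1).
    """
    if real.subjects != generated.subjects:
        raise ValueError("datasets are not paired: subject lists differ")
    if condition is None:
        shared = [c for c in generated.conditions if c in real.conditions]
        if len(shared) != 1:
            raise ValueError("condition is ambiguous; pass it explicitly")
        condition = shared[0]
    diffs = generated.data[condition] - real.data[condition]
    n, n_ch, n_t = diffs.shape
    if adjacency is None:
        adjacency = real.layout.adjacency()
    engine = _ClusterEngine(adjacency, n_t, config.min_neighbor_channels)
    threshold = float(sst.t.ppf(1.0 - config.alpha / 2.0, n - 1))
    t_map = paired_t_map(diffs)
    observed = engine.clusters(t_map, threshold)

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 51]))
    flat = diffs.reshape(n, -1)
    sq_mean = (flat**2).mean(axis=0)
    null = np.zeros(config.n_draws)
    signs = rng.integers(0, 2, size=(config.n_draws, n)) * 2 - 1
    for i in range(config.n_draws):
        mean = signs[i] @ flat / n
        var = (sq_mean - mean**2) * n / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = mean / np.sqrt(var / n)
        t_perm = np.where(var > 0, t_perm, 0.0).reshape(n_ch, n_t)
        null[i] = engine.max_mass(t_perm, threshold)

    clusters = []
    sig_mask = np.zeros((n_ch, n_t), dtype=bool)
    for nodes, sign, mass in observed:
        p = float((1 + np.sum(null >= abs(mass))) / (config.n_draws + 1))
        cl = Cluster(nodes // n_t, nodes % n_t, sign, mass, p)
        clusters.append(cl)
        if p < config.alpha:
            sig_mask[cl.channels, cl.times] = True
    clusters.sort(key=lambda c: -abs(c.mass))
    return ClusterResult(
        t_map, threshold, clusters, sig_mask, config.alpha, config.n_draws,
        real.times_ms, list(real.layout.names), null,
    )


# ---------------------------------------------------------------------------
# 50-ms epoch aggregation


@dataclass
class EpochAggregate:
    grid: np.ndarray  # (n_ch, n_epochs) boolean
    epoch_edges_ms: np.ndarray  # (n_epochs + 1,)
    n_significant: int
    n_epochs: int
    note: str = ""


def aggregate_epochs(result: ClusterResult, step_ms: float = 50.0) -> EpochAggregate:
    """Temporal aggregation of significant-cluster membership.

    An (electrode, epoch) cell is flagged if any constituent sample belongs
    to a significant cluster; an epoch counts as significant if any
    electrode is flagged. A 0-1000 ms axis at 50 ms steps gives 20 epochs.
    """
    n_ch, n_t = result.sig_mask.shape
    fs = 1000.0 / (result.times_ms[1] - result.times_ms[0])
    t0 = result.times_ms[0]
    total_ms = n_t * 1000.0 / fs
    n_epochs = int(round(total_ms / step_ms))
    note = ""
    if abs(step_ms * fs / 1000.0 - round(step_ms * fs / 1000.0)) > 1e-9:
        note = (
            f"step {step_ms} ms is not a whole number of samples at {fs:g} Hz; "
            "epoch boundaries snap to the nearest earlier sample"
        )
    edges = np.array([
        int(np.floor(k * step_ms * fs / 1000.0)) for k in range(n_epochs + 1)
    ])
    edges[-1] = n_t
    grid = np.zeros((n_ch, n_epochs), dtype=bool)
    for k in range(n_epochs):
        grid[:, k] = result.sig_mask[:, edges[k] : edges[k + 1]].any(axis=1)
    return EpochAggregate(
        grid,
        t0 + edges * 1000.0 / fs,
        int(grid.any(axis=0).sum()),
        n_epochs,
        note,
    )


def cluster_table(result: ClusterResult):
    """Per-cluster summary as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for i, c in enumerate(result.clusters):
        rows.append({
            "cluster": i,
            "sign": c.sign,
            "mass": c.mass,
            "p": c.p,
            "n_samples": c.channels.size,
            "t_min_ms": result.times_ms[c.times.min()],
            "t_max_ms": result.times_ms[c.times.max()],
            "channels": ",".join(sorted({result.channel_names[j] for j in c.channels})),
        })
    return pd.DataFrame(rows)
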