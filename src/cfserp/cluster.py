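"""Factorial mass-univariate F-maps and spatiotemporal cluster-mass
permutation tests.

At every channel x time point a repeated-measures ANOVA F statistic is
computed for the requested effect of a 2 (expression) x 3 (contrast)
within-subject design.  Supra-threshold points (parametric F quantile at the
cluster-forming alpha) are merged into spatiotemporal clusters — neighbors
are the same channel at adjacent time samples or spatially adjacent channels
at the same sample; diagonal connectivity is off by default and clusters
need at least two points.  The cluster mass sum(F) is referred to the
permutation null distribution of the maximum cluster mass.

Permutation schemes: main effects permute the levels of the tested factor
within each subject after averaging over the other factor; the interaction
permutes cell labels within each subject after removing both estimated
grand-level main effects (ter Braak-style residual permutation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .preproc import ConditionMeans

__all__ = [
    "FMap",
    "ClusterResult",
    "rm_fmap",
    "fmap_from_cells",
    "find_clusters",
    "cbp_test",
    "extract_cluster_average",
    "cluster_table",
]

EFFECTS = ("expression", "contrast", "interaction")


@dataclass
class FMap:
    """Channel x time F statistics for one effect, with degrees of freedom."""

    values: np.ndarray
    df_effect: int
    df_error: int
    effect: str
    times: np.ndarray
    channel_names: list[str]

    def critical_value(self, alpha: float = 0.05) -> float:
        return float(f_dist.ppf(1 - alpha, self.df_effect, self.df_error))


@dataclass
class ClusterResult:
    """A connected supra-threshold set of (channel, time) points."""

    channels: np.ndarray  # member channel indices
    samples: np.ndarray  # member time-sample indices (aligned with channels)
    mass: float
    effect: str
    times: np.ndarray  # time axis of the analysis window (ms)
    p_raw: float | None = None
    p_corrected: float | None = None
    peak_f: float = np.nan
    peak_time: float = np.nan

    @property
    def n_points(self) -> int:
        return len(self.channels)

    @property
    def t_start(self) -> float:
        return float(self.times[self.samples.min()])

    @property
    def t_end(self) -> float:
        return float(self.times[self.samples.max()])

    @property
    def members(self) -> set[tuple[int, int]]:
        return set(zip(self.channels.tolist(), self.samples.tolist()))


# ---------------------------------------------------------------------------
# repeated-measures F maps (vectorized over channel x time)


def _oneway_rm_f(Y: np.ndarray) -> tuple[np.ndarray, int, int]:
    """One-way within-subject F over trailing axes; Y is (S, K, ...)."""
    S, K = Y.shape[:2]
    grand = Y.mean((0, 1))
    mk = Y.mean(0)
    ms = Y.mean(1)
    ss_k = S * ((mk - grand) ** 2).sum(0)
    resid = Y - mk[None] - ms[:, None] + grand
    ss_err = (resid**2).sum((0, 1))
    df_k, df_err = K - 1, (K - 1) * (S - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_k / df_k) / (ss_err / df_err)
    return np.nan_to_num(F, nan=0.0, posinf=0.0), df_k, df_err


def _interaction_rm_f(Y: np.ndarray) -> tuple[np.ndarray, int, int]:
    """A x B interaction F of a fully within-subject design; Y is (S, A, B, ...)."""
    S, A, B = Y.shape[:3]
    grand = Y.mean((0, 1, 2))
    ma = Y.mean((0, 2))
    mb = Y.mean((0, 1))
    ms = Y.mean((1, 2))
    mab = Y.mean(0)
    msa = Y.mean(2)
    msb = Y.mean(1)
    ss_ab = S * ((mab - ma[:, None] - mb[None] + grand) ** 2).sum((0, 1))
    resid = (
        Y
        - mab[None]
        - msa[:, :, None]
        - msb[:, None]
        + ma[None, :, None]
        + mb[None, None]
        + ms[:, None, None]
        - grand
    )
    ss_err = (resid**2).sum((0, 1, 2))
    df_ab = (A - 1) * (B - 1)
    df_err = (A - 1) * (B - 1) * (S - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_ab / df_ab) / (ss_err / df_err)
    return np.nan_to_num(F, nan=0.0, posinf=0.0), df_ab, df_err


def _effect_f(Y: np.ndarray, effect: str) -> tuple[np.ndarray, int, int]:
    """F-map for one effect from Y = (S, A, B, channel, time).

    Main effects use the collapsed one-way form, which is algebraically
    identical to the two-way main-effect F in a balanced design (the error
    term of a main effect depends only on subject x level means).
    """
    if effect == "expression":
        return _oneway_rm_f(Y.mean(2))
    if effect == "contrast":
        return _oneway_rm_f(Y.mean(1))
    if effect == "interaction":
        return _interaction_rm_f(Y)
    raise ValueError(f"effect must be one of {EFFECTS}, got {effect!r}")


def fmap_from_cells(
    Y: np.ndarray,
    effect: str,
    times: np.ndarray | None = None,
    channel_names: list[str] | None = None,
) -> FMap:
    """F-map from a raw (subject, A, B, channel, time) array."""
    if Y.ndim != 5:
        raise ValueError("Y must be subject x A x B x channel x time")
    if Y.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    F, df_e, df_r = _effect_f(np.asarray(Y, dtype=np.float64), effect)
    n_ch, n_t = Y.shape[3], Y.shape[4]
    return FMap(
        values=F,
        df_effect=df_e,
        df_error=df_r,
        effect=effect,
        times=times if times is not None else np.arange(n_t, dtype=float),
        channel_names=channel_names or [f"ch{i}" for i in range(n_ch)],
    )


def rm_fmap(cond_means: ConditionMeans, effect: str, cfs: bool) -> FMap:
    """Mass-univariate repeated-measures F-map for one visibility condition.

    ``cond_means`` should already be restricted to the analysis window and
    channel region of interest (see :meth:`ConditionMeans.select`).
    """
    Y = cond_means.factorial_view(cfs)
    return fmap_from_cells(
        Y, effect, times=cond_means.times, channel_names=cond_means.channel_names
    )


# ---------------------------------------------------------------------------
# clustering


def _connected_components(
    supra: np.ndarray, adjacency: np.ndarray
) -> list[list[tuple[int, int]]]:
    """BFS connected components of supra-threshold (channel, time) points.

    Neighbors: (same channel, time +- 1) and (adjacent channel, same time).
    """
    points = list(zip(*np.nonzero(supra)))
    point_set = set(points)
    seen: set[tuple[int, int]] = set()
    comps = []
    for p in points:
        if p in seen:
            continue
        comp = []
        stack = [p]
        seen.add(p)
        while stack:
            ch, t = stack.pop()
            comp.append((ch, t))
            for q in ((ch, t - 1), (ch, t + 1)):
                if q in point_set and q not in seen:
                    seen.add(q)
                    stack.append(q)
            for nb in np.flatnonzero(adjacency[ch]):
                q = (int(nb), t)
                if q in point_set and q not in seen:
                    seen.add(q)
                    stack.append(q)
        comps.append(comp)
    return comps


def find_clusters(
    fmap: FMap,
    f_crit: float,
    adjacency: np.ndarray,
    min_size: int = 2,
) -> list[ClusterResult]:
    """Spatiotemporal clusters of F-values strictly exceeding ``f_crit``.

    ``adjacency`` is the channel-by-channel boolean neighbor matrix of the
    channels in the F-map.  Components smaller than ``min_size`` points are
    discarded ("two or more neighboring sensors").  Returned clusters are
    sorted by decreasing mass.
    """
    F = fmap.values
    if adjacency.shape != (F.shape[0], F.shape[0]):
        raise ValueError("adjacency must match the F-map's channel count")
    supra = F > f_crit
    out = []
    for comp in _connected_components(supra, adjacency):
        if len(comp) < min_size:
            continue
        ch = np.array([c for c, _ in comp])
        ts = np.array([t for _, t in comp])
        fv = F[ch, ts]
        k = int(np.argmax(fv))
        out.append(
            ClusterResult(
                channels=ch,
                samples=ts,
                mass=float(fv.sum()),
                effect=fmap.effect,
                times=fmap.times,
                peak_f=float(fv[k]),
                peak_time=float(fmap.times[ts[k]]),
            )
        )
    out.sort(key=lambda c: -c.mass)
    return out


def _max_cluster_mass(
    F: np.ndarray, f_crit: float, adjacency: np.ndarray, min_size: int
) -> float:
    supra = F > f_crit
    best = 0.0
    for comp in _connected_components(supra, adjacency):
        if len(comp) < min_size:
            continue
        m = sum(F[c, t] for c, t in comp)
        best = max(best, m)
    return best


# ---------------------------------------------------------------------------
# permutation test


def _permute_main(C: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute factor levels within each subject; C is (S, K, ch, t)."""
    S, K = C.shape[:2]
    out = np.empty_like(C)
    for s in range(S):
        out[s] = C[s, rng.permutation(K)]
    return out


def cbp_test(
    cond_means: ConditionMeans,
    effect: str,
    cfs: bool,
    adjacency: np.ndarray,
    n_perm: int = 5000,
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    n_windows: int = 2,
    min_size: int = 2,
    seed: int = 0,
    estimator: str = "add_one",
) -> list[ClusterResult]:
    """Cluster-mass permutation test for one effect in one visibility condition.

    Observed clusters are scored against the permutation distribution of the
    maximum cluster mass.  ``p_raw = (1 + #{null >= mass}) / (1 + n_perm)``
    (``estimator="proportion"`` uses the plain fraction), and
    ``p_corrected = min(1, n_windows * p_raw)`` corrects for running the
    analysis in ``n_windows`` separate time windows.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    fmap = rm_fmap(cond_means, effect, cfs)
    f_crit = fmap.critical_value(cluster_alpha)
    observed = find_clusters(fmap, f_crit, adjacency, min_size)

    Y = cond_means.factorial_view(cfs).astype(np.float64)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)

    if effect in ("expression", "contrast"):
        C = Y.mean(2) if effect == "expression" else Y.mean(1)
        for b in range(n_perm):
            F, _, _ = _oneway_rm_f(_permute_main(C, rng))
            null_max[b] = _max_cluster_mass(F, f_crit, adjacency, min_size)
    else:
        S, A, B = Y.shape[:3]
        grand = Y.mean((0, 1, 2))
        ma = Y.mean((0, 2))
        mb = Y.mean((0, 1))
        W = Y - ma[None, :, None] - mb[None, None] + grand
        Wf = W.reshape(S, A * B, *Y.shape[3:])
        for b in range(n_perm):
            Wp = _permute_main(Wf, rng).reshape(Y.shape)
            F, _, _ = _interaction_rm_f(Wp)
            null_max[b] = _max_cluster_mass(F, f_crit, adjacency, min_size)

    for cl in observed:
        exceed = int((null_max >= cl.mass).sum())
        if estimator == "add_one":
            cl.p_raw = (1 + exceed) / (1 + n_perm)
        elif estimator == "proportion":
            cl.p_raw = exceed / n_perm
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
        cl.p_corrected = min(1.0, n_windows * cl.p_raw)
    return observed


def extract_cluster_average(
    cond_means: ConditionMeans, cluster: ClusterResult
) -> np.ndarray:
    """Mean voltage over the cluster's (channel, time) points.

    Returns a (subject, cell) array aligned with ``cond_means.cells``; used
    to unpack significant interactions with follow-up tests on scalars.
    """
    if cluster.n_points == 0:
        raise ValueError("empty cluster")
    n_ch, n_t = cond_means.data.shape[2:]
    if cluster.channels.max() >= n_ch or cluster.samples.max() >= n_t:
        raise ValueError("cluster members outside the data extent")
    return cond_means.data[:, :, cluster.channels, cluster.samples].mean(axis=-1)


def cluster_table(clusters: list[ClusterResult]) -> pd.DataFrame:
    """Tidy per-cluster summary table."""
    return pd.DataFrame(
        {
            "effect": [c.effect for c in clusters],
            "mass": [c.mass for c in clusters],
            "p_raw": [c.p_raw for c in clusters],
            "p_corrected": [c.p_corrected for c in clusters],
            "t_start": [c.t_start for c in clusters],
            "t_end": [c.t_end for c in clusters],
            "peak_time": [c.peak_time for c in clusters],
            "n_points": [c.n_points for c in clusters],
        }
    )
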