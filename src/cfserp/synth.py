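"""Synthetic study generator: trial schedules, an SDT observer, and ERP epochs.

This module emulates a within-subject continuous-flash-suppression (CFS)
experiment on emotional faces: a 2 (expression: fearful/neutral) x 3
(contrast: low/medium/high) x 2 (CFS/noCFS) design plus one catch condition
per visibility condition.  Behavioral responses come from an equal-variance
Gaussian signal-detection observer whose sensitivity depends on contrast and
suppression; epochs are multi-channel voltage arrays carrying a contrast main
effect, an early posterior expression effect, a late centro-parietal effect,
and a contrast-dependent expression effect under CFS whose sign inverts at
low contrast.

Everything is deterministic given a seed: identical seeds yield bit-identical
schedules, responses and epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

EXPRESSIONS = ("fearful", "neutral")
MAIN_LEVELS = ("low", "medium", "high")
CATCH = "catch"

__all__ = [
    "Condition",
    "TrialSchedule",
    "ObserverParams",
    "EffectSpec",
    "SensorGraph",
    "EpochSet",
    "make_calibration_schedule",
    "make_main_schedule",
    "simulate_observer",
    "make_layout",
    "simulate_epochs",
    "roi_mask",
]


@dataclass(frozen=True)
class Condition:
    """A single experimental cell.

    ``expression`` is ``"fearful"``, ``"neutral"`` or ``"none"`` (catch);
    ``contrast_level`` is a key into the schedule's contrast map, with
    ``"catch"`` reserved for face-absent trials; ``cfs`` flags suppression.
    The invariant ``expression == "none"  <=>  contrast_level == "catch"``
    is enforced at construction.
    """

    expression: str
    contrast_level: str
    cfs: bool

    def __post_init__(self) -> None:
        if (self.expression == "none") != (self.contrast_level == CATCH):
            raise ValueError(
                f"catch trials must have expression='none' and level='catch'; "
                f"got {self.expression!r}/{self.contrast_level!r}"
            )

    @property
    def is_catch(self) -> bool:
        return self.contrast_level == CATCH


SCHEDULE_COLUMNS = [
    "trial",
    "block",
    "expression",
    "contrast_level",
    "contrast_value",
    "cfs",
    "prompt",
]


@dataclass
class TrialSchedule:
    """Ordered trial conditions plus the contrast map used to realize them.

    ``table`` has one row per trial with columns ``trial, block, expression,
    contrast_level, contrast_value, cfs, prompt``; ``contrasts`` maps level
    name to Michelson-style contrast in (0, 1].
    """

    table: pd.DataFrame
    contrasts: dict[str, float]
    seed: int | None = None

    @property
    def n_trials(self) -> int:
        return len(self.table)

    def condition_of(self, row) -> Condition:
        return Condition(row.expression, row.contrast_level, bool(row.cfs))

    def condition_counts(self) -> pd.Series:
        return self.table.groupby(
            ["expression", "contrast_level", "cfs"], observed=True
        ).size()

    def blocks(self) -> list[pd.DataFrame]:
        return [g for _, g in self.table.groupby("block")]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TrialSchedule":
        table = pd.read_csv(path, sep="\t")
        contrasts = (
            table.loc[table.contrast_level != CATCH]
            .groupby("contrast_level")["contrast_value"]
            .first()
            .to_dict()
        )
        return cls(table=table, contrasts=contrasts)


def _assign_blocks(n_trials: int, n_blocks: int) -> np.ndarray:
    if n_trials % n_blocks:
        raise ValueError(
            f"{n_trials} trials cannot be split into {n_blocks} equal blocks"
        )
    return np.repeat(np.arange(1, n_blocks + 1), n_trials // n_blocks)


def make_calibration_schedule(
    n_per_condition: int,
    contrast_values: Sequence[float],
    seed: int,
    n_blocks: int = 4,
) -> TrialSchedule:
    """Method-of-constant-stimuli calibration schedule, always under CFS.

    One condition per contrast value plus one catch condition, each presented
    ``n_per_condition`` times in a seeded random order.  With the defaults of
    the study design (48 repetitions, contrasts 5/15/25/35%) this yields 240
    trials in four blocks of 60.  Face trials alternate fearful and neutral
    expressions; the expression is irrelevant to the detection task.
    """
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be >= 1")
    values = [float(v) for v in contrast_values]
    if len(set(values)) != len(values):
        raise ValueError("contrast values must be distinct")
    if any(not (0 < v <= 1) for v in values):
        raise ValueError("contrast values must lie in (0, 1]")

    levels = [f"c{v:g}" for v in values]
    contrasts = dict(zip(levels, values))

    rows = []
    for lev, val in contrasts.items():
        for k in range(n_per_condition):
            rows.append((EXPRESSIONS[k % 2], lev, val))
    rows += [("none", CATCH, 0.0)] * n_per_condition

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]

    n = len(rows)
    blocks = (
        _assign_blocks(n, n_blocks) if n % n_blocks == 0 else np.ones(n, dtype=int)
    )
    table = pd.DataFrame(
        {
            "trial": np.arange(n),
            "block": blocks,
            "expression": [r[0] for r in rows],
            "contrast_level": [r[1] for r in rows],
            "contrast_value": [r[2] for r in rows],
            "cfs": True,
            "prompt": True,  # every calibration trial is answered
        }
    )
    return TrialSchedule(table=table, contrasts=contrasts, seed=seed)


def make_main_schedule(
    n_per_condition: int = 60,
    contrasts: Mapping[str, float] | None = None,
    n_blocks: int = 7,
    prompt_fraction: float = 1 / 3,
    seed: int = 0,
) -> TrialSchedule:
    """Main-experiment schedule: 14 conditions x ``n_per_condition`` trials.

    Conditions are 2 expressions x 3 contrast levels x 2 visibility plus one
    catch condition per visibility.  Defaults give 840 trials in seven blocks
    of 120, with a response prompt on a randomly chosen third of trials.
    """
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be >= 1")
    if contrasts is None:
        contrasts = {"low": 0.01, "medium": 0.02, "high": 0.32}
    if set(contrasts) != set(MAIN_LEVELS):
        raise ValueError(f"contrasts must map exactly {MAIN_LEVELS}")

    rows = []
    for cfs in (True, False):
        for lev in MAIN_LEVELS:
            for expr in EXPRESSIONS:
                rows += [(expr, lev, float(contrasts[lev]), cfs)] * n_per_condition
        rows += [("none", CATCH, 0.0, cfs)] * n_per_condition

    n = len(rows)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    rows = [rows[i] for i in order]

    blocks = _assign_blocks(n, n_blocks)
    n_prompts = int(round(prompt_fraction * n))
    prompt = np.zeros(n, dtype=bool)
    prompt[rng.choice(n, size=n_prompts, replace=False)] = True

    table = pd.DataFrame(
        {
            "trial": np.arange(n),
            "block": blocks,
            "expression": [r[0] for r in rows],
            "contrast_level": [r[1] for r in rows],
            "contrast_value": [r[2] for r in rows],
            "cfs": [r[3] for r in rows],
            "prompt": prompt,
        }
    )
    return TrialSchedule(table=table, contrasts=dict(contrasts), seed=seed)


# ---------------------------------------------------------------------------
# SDT observer


@dataclass
class ObserverParams:
    """Equal-variance Gaussian SDT observer.

    Under CFS, detection sensitivity is linear in contrast,
    ``d' = detect_intercept_cfs + detect_slope_cfs * contrast`` clamped at 0,
    so that with the default calibration line (slope 10, intercept -0.2) the
    calibrated low and medium contrasts sit at chance and the high contrast
    breaks suppression at d' = 3.  Without CFS, sensitivity is given per
    named level by ``detect_curve_nocfs`` (graded, all well above chance).
    Fearful faces gain ``emotion_boost_high`` d' units at high contrast.
    Discrimination (fearful vs. neutral, 2AFC) runs at
    ``discrim_fraction`` x detection sensitivity with its own criterion.
    """

    detect_intercept_cfs: float = -0.2
    detect_slope_cfs: float = 10.0
    detect_curve_nocfs: dict[str, float] = field(
        default_factory=lambda: {"low": 1.5, "medium": 2.5, "high": 3.5}
    )
    discrim_fraction: float = 0.8
    criterion: float = 0.5
    discrim_criterion: float = 0.0
    emotion_boost_high: float = 0.5

    def detection_dprime(
        self, contrast_level: str, contrast_value: float, cfs: bool, expression: str
    ) -> float:
        if contrast_level == CATCH:
            return 0.0
        if cfs:
            d = self.detect_intercept_cfs + self.detect_slope_cfs * contrast_value
        else:
            d = self.detect_curve_nocfs.get(contrast_level)
            if d is None:
                # calibration-style numeric level without CFS: fall back to line
                d = self.detect_intercept_cfs + self.detect_slope_cfs * contrast_value
        if expression == "fearful" and contrast_level == "high":
            d += self.emotion_boost_high
        if not np.isfinite(d):
            raise ValueError("non-finite sensitivity")
        return max(d, 0.0)


def simulate_observer(
    schedule: TrialSchedule, params: ObserverParams, seed: int
) -> pd.DataFrame:
    """Simulate detection and discrimination responses for every trial.

    Detection: face trials draw internal evidence from N(d', 1), catch trials
    from N(0, 1); the observer reports "anything else" (key 2) iff the sample
    exceeds the criterion.  Discrimination (prompt trials only): a 2AFC
    decision from N(+-d'_disc/2, 1), reporting fearful (key 2) iff the sample
    exceeds the discrimination criterion; on catch trials the guess is
    unbiased.  Returns the schedule table with ``detect_resp`` and
    ``discrim_resp`` columns (1/2 key codes; discrim_resp is <NA> without a
    prompt).
    """
    t = schedule.table
    rng = np.random.default_rng(seed)
    d = np.array(
        [
            params.detection_dprime(
                r.contrast_level, r.contrast_value, bool(r.cfs), r.expression
            )
            for r in t.itertuples()
        ]
    )
    evidence = rng.standard_normal(len(t)) + d
    detect = np.where(evidence > params.criterion, 2, 1)

    d_disc = params.discrim_fraction * d
    signed = np.where(t.expression.to_numpy() == "fearful", 0.5, -0.5) * d_disc
    signed[t.contrast_level.to_numpy() == CATCH] = 0.0
    disc_evidence = rng.standard_normal(len(t)) + signed
    discrim = np.where(disc_evidence > params.discrim_criterion, 2, 1)

    out = t.copy()
    out["detect_resp"] = detect
    out["discrim_resp"] = pd.array(discrim, dtype="Int64")
    out.loc[~out.prompt.astype(bool), "discrim_resp"] = pd.NA
    return out


# ---------------------------------------------------------------------------
# Sensor layout


@dataclass
class SensorGraph:
    """Channel positions on the unit upper hemisphere plus spatial adjacency.

    Adjacency is the symmetric, irreflexive relation ``chord distance <
    neighbor_distance``; it drives both spatiotemporal clustering and bad-
    channel interpolation.
    """

    positions: np.ndarray  # (n_channels, 3)
    adjacency: np.ndarray  # (n_channels, n_channels) bool
    names: list[str]
    neighbor_distance: float

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def neighbors(self, ch: int) -> np.ndarray:
        return np.flatnonzero(self.adjacency[ch])

    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)


def make_layout(
    n_channels: int = 64, neighbor_distance: float | None = None
) -> SensorGraph:
    """Quasi-uniform Fibonacci layout on the upper unit hemisphere.

    The +y axis points to the front of the head, -y occipital, +z vertex.
    When ``neighbor_distance`` is omitted it is set to 1.5x the median
    nearest-neighbor chord distance, which keeps every channel connected at
    any channel count.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    if neighbor_distance is not None and neighbor_distance <= 0:
        raise ValueError("neighbor_distance must be positive")
    i = np.arange(n_channels)
    z = (i + 0.5) / n_channels  # heights in (0, 1): upper hemisphere
    r = np.sqrt(1.0 - z**2)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    if neighbor_distance is None:
        nn = np.where(np.eye(n_channels, dtype=bool), np.inf, dist).min(axis=1)
        neighbor_distance = 1.5 * float(np.median(nn))
    adj = dist < neighbor_distance
    np.fill_diagonal(adj, False)
    names = [f"E{k + 1:03d}" for k in i]
    return SensorGraph(
        positions=pos, adjacency=adj, names=names, neighbor_distance=neighbor_distance
    )


def roi_mask(layout: SensorGraph, region: str) -> np.ndarray:
    """Boolean channel mask for a named scalp region.

    ``posterior`` — occipito-temporal third of the cap (y < -0.25), the early-
    negativity analysis region; ``central`` — centro-parietal channels near
    the vertex (z > 0.70), the late-positivity region; ``all`` — everything.
    """
    y, z = layout.positions[:, 1], layout.positions[:, 2]
    if region == "posterior":
        return y < -0.25
    if region == "central":
        return z > 0.70
    if region == "all":
        return np.ones(layout.n_channels, dtype=bool)
    raise ValueError(f"unknown region {region!r}")


# ---------------------------------------------------------------------------
# ERP generator


@dataclass
class EffectSpec:
    """Ground-truth ERP effect structure and noise model.

    Two spatiotemporal templates with unit maximum weight: an early posterior
    component (Gaussian time course centered at 220 ms, SD 40 ms, loaded on
    occipital channels) and a late centro-parietal component (450 ms, SD
    120 ms).  ``contrast_gain`` scales both templates per contrast level (the
    contrast main effect, in μV).  ``expression_amplitude_early/late`` give
    the additional amplitude on fearful trials per (contrast level, cfs), in
    μV; negative = larger negativity for fearful.  The defaults realize the
    qualitative study pattern: without CFS a uniform -0.8 μV early fearful
    effect and +0.8 μV late; with CFS the early effect inverts at low
    contrast (+0.5 μV) and grows with contrast (-0.5, -0.8 μV), while the
    late effect exists only at high contrast (+0.5 μV).

    Noise is AR(1) over time with a spatially exponentially correlated
    innovation across channels, plus a per-(subject, channel) DC offset.
    """

    early_center_ms: float = 220.0
    early_width_ms: float = 40.0
    late_center_ms: float = 450.0
    late_width_ms: float = 120.0
    early_seed: tuple[float, float, float] = (0.0, -0.90, 0.44)
    late_seed: tuple[float, float, float] = (0.0, -0.20, 0.98)
    spatial_spread: float = 0.55  # Gaussian width of template channel weights
    contrast_gain: dict[str, float] = field(
        default_factory=lambda: {"low": 2.0, "medium": 4.0, "high": 8.0}
    )
    expression_amplitude_early: dict[tuple[str, bool], float] = field(
        default_factory=lambda: {
            ("low", True): +0.5,
            ("medium", True): -0.5,
            ("high", True): -0.8,
            ("low", False): -0.8,
            ("medium", False): -0.8,
            ("high", False): -0.8,
        }
    )
    expression_amplitude_late: dict[tuple[str, bool], float] = field(
        default_factory=lambda: {
            ("low", True): 0.0,
            ("medium", True): 0.0,
            ("high", True): +0.5,
            ("low", False): +0.8,
            ("medium", False): +0.8,
            ("high", False): +0.8,
        }
    )
    subject_sd: float = 1.0
    trial_noise_sd: float = 4.0
    spatial_corr_length: float = 0.4
    temporal_ar_coefficient: float = 0.985

    def __post_init__(self) -> None:
        if self.subject_sd < 0 or self.trial_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")

    def zeroed(self) -> "EffectSpec":
        """Copy with all expression amplitudes set to zero (null generator)."""
        return replace(
            self,
            expression_amplitude_early={
                k: 0.0 for k in self.expression_amplitude_early
            },
            expression_amplitude_late={k: 0.0 for k in self.expression_amplitude_late},
        )


def _unit_gaussian(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / width) ** 2)


def build_templates(
    spec: EffectSpec, layout: SensorGraph, times_ms: np.ndarray
) -> dict[str, np.ndarray]:
    """Channel weights and time courses of both templates, unit peak each."""
    out = {}
    for name, seed, c, w in [
        ("early", spec.early_seed, spec.early_center_ms, spec.early_width_ms),
        ("late", spec.late_seed, spec.late_center_ms, spec.late_width_ms),
    ]:
        seed = np.asarray(seed, dtype=float)
        seed = seed / np.linalg.norm(seed)
        d = np.linalg.norm(layout.positions - seed, axis=1)
        cw = np.exp(-0.5 * (d / spec.spatial_spread) ** 2)
        cw /= np.abs(cw).max()
        tc = _unit_gaussian(times_ms, c, w)
        tc[times_ms < 0] = 0.0
        out[name] = (cw, tc)
    return out


def default_times(sampling_rate: float = 500.0, tmin_ms: float = -200.0,
                  tmax_ms: float = 600.0) -> np.ndarray:
    """Half-open epoch time grid [tmin, tmax) in ms; onset at index tmin/dt."""
    dt = 1000.0 / sampling_rate
    n = int(round((tmax_ms - tmin_ms) / dt))
    return tmin_ms + dt * np.arange(n)


@dataclass
class EpochSet:
    """Trial-resolved voltages: subject x trial x channel x time, in μV."""

    data: np.ndarray
    times: np.ndarray  # ms
    labels: pd.DataFrame  # one row per trial (schedule table)
    sampling_rate: float
    channel_names: list[str]
    baseline_window: tuple[float, float] = (-200.0, 0.0)

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be subject x trial x channel x time")
        if self.data.shape[1] != len(self.labels):
            raise ValueError("labels must align 1:1 with trials")
        if self.data.shape[3] != len(self.times):
            raise ValueError("time axis mismatch")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    def copy_with(self, data: np.ndarray) -> "EpochSet":
        return EpochSet(
            data=data,
            times=self.times,
            labels=self.labels,
            sampling_rate=self.sampling_rate,
            channel_names=list(self.channel_names),
            baseline_window=self.baseline_window,
        )


def simulate_epochs(
    schedule: TrialSchedule,
    effects: EffectSpec,
    layout: SensorGraph,
    n_subjects: int,
    seed: int,
    sampling_rate: float = 500.0,
    dtype=np.float32,
) -> EpochSet:
    """Generate epochs for every subject and trial of a schedule.

    voltage = subject DC offset
            + contrast_gain[level] * (early + late templates)
            + fearful-only expression amplitudes * templates
            + AR(1)-in-time, spatially correlated noise.

    Catch trials carry noise (and offset) only.  Deterministic given ``seed``:
    subject streams are spawned from a single SeedSequence.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    times = default_times(sampling_rate)
    n_times = len(times)
    t = schedule.table
    n_trials = len(t)
    n_ch = layout.n_channels

    tmpl = build_templates(effects, layout, times)
    early = np.outer(tmpl["early"][0], tmpl["early"][1])  # ch x time
    late = np.outer(tmpl["late"][0], tmpl["late"][1])

    # per-trial deterministic signal (independent of subject), built per cell
    signal = np.zeros((n_trials, n_ch, n_times), dtype=dtype)
    levels = t.contrast_level.to_numpy()
    exprs = t.expression.to_numpy()
    cfs = t.cfs.to_numpy().astype(bool)
    for lev in np.unique(levels):
        if lev == CATCH:
            continue
        gain = effects.contrast_gain.get(lev, 0.0)
        base = gain * (early + late)
        for v in (True, False):
            for expr in np.unique(exprs[levels == lev]):
                rows = (levels == lev) & (cfs == v) & (exprs == expr)
                if not rows.any():
                    continue
                s = base
                if expr == "fearful":
                    key = (lev, v)
                    s = (
                        base
                        + effects.expression_amplitude_early.get(key, 0.0) * early
                        + effects.expression_amplitude_late.get(key, 0.0) * late
                    )
                signal[rows] = s.astype(dtype)

    # spatial correlation factor (Cholesky of exponential kernel)
    if effects.spatial_corr_length > 0:
        diff = layout.positions[:, None, :] - layout.positions[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        K = np.exp(-dist / effects.spatial_corr_length)
        K[np.diag_indices_from(K)] += 1e-9
        L = np.linalg.cholesky(K)
    else:
        L = np.eye(n_ch)

    a = effects.temporal_ar_coefficient
    # scale so the stationary marginal SD equals trial_noise_sd
    innov_sd = effects.trial_noise_sd * np.sqrt(max(1.0 - a * a, np.finfo(float).tiny))

    ss = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(n_subjects)]

    L32 = L.astype(dtype)
    b32 = np.array([1.0], dtype=dtype)
    a32 = np.array([1.0, -a], dtype=dtype)
    data = np.empty((n_subjects, n_trials, n_ch, n_times), dtype=dtype)
    for s_idx, rng in enumerate(streams):
        offset = rng.normal(0.0, effects.subject_sd, size=(n_ch, 1)).astype(dtype)
        out = data[s_idx]
        out[:] = signal
        out += offset
        if effects.trial_noise_sd > 0:
            white = rng.standard_normal((n_trials, n_ch, n_times), dtype=np.float32)
            white *= np.float32(innov_sd)
            noise = lfilter(b32, a32, white.astype(dtype, copy=False), axis=-1)
            out += np.matmul(L32, noise)  # batched over trials

    return EpochSet(
        data=data,
        times=times,
        labels=t,
        sampling_rate=sampling_rate,
        channel_names=list(layout.names),
    )


def inject_amplitude_spikes(
    epochs: EpochSet, rate: float, amplitude: float, seed: int
) -> tuple[EpochSet, np.ndarray]:
    """Inject single-sample amplitude spikes into a random fraction of trials.

    Exists purely to exercise artifact rejection; returns the modified copy
    and a (subject, trial) boolean mask of spiked trials.
    """
    rng = np.random.default_rng(seed)
    data = epochs.data.copy()
    mask = rng.random((epochs.n_subjects, epochs.n_trials)) < rate
    for s, tr in zip(*np.nonzero(mask)):
        ch = rng.integers(epochs.n_channels)
        tp = rng.integers(data.shape[3])
        data[s, tr, ch, tp] += amplitude
    return epochs.copy_with(data), mask
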