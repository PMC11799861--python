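"""Epoch preprocessing: reference, baseline, artifact rejection,
interpolation, condition averaging, filtering, and downsampling.

The pipeline order is fixed (and logged by the orchestrator):
average reference -> baseline -> artifact rejection -> bad-channel
interpolation -> per-condition trial averaging -> zero-phase low-pass ->
decimation.  Rejection applies three per-trial criteria over all channels:
absolute amplitude (default 120 μV), successive-sample gradient (default
5 μV/sample at the native rate), and flat signal (SD of the gradient at or
below 0.01 μV/sample).  Thresholds are inclusive: a value exactly at a bound
violates it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .synth import EXPRESSIONS, MAIN_LEVELS, EpochSet, SensorGraph

__all__ = [
    "RejectionCriteria",
    "RejectionLog",
    "ConditionMeans",
    "baseline_correct",
    "reject_artifacts",
    "interpolate_channels",
    "rereference_average",
    "average_filter_downsample",
    "preprocess",
]


@dataclass
class RejectionCriteria:
    """Artifact-rejection thresholds, all in μV (gradient per sample)."""

    amp_threshold: float = 120.0
    gradient_threshold: float = 5.0
    flat_threshold: float = 0.01

    def __post_init__(self) -> None:
        if min(self.amp_threshold, self.gradient_threshold, self.flat_threshold) <= 0:
            raise ValueError("all thresholds must be > 0")


@dataclass
class RejectionLog:
    """Per-criterion rejection counts over subject x trial."""

    n_total: int
    n_amplitude: int
    n_gradient: int
    n_flat: int
    n_rejected: int

    @property
    def fraction_rejected(self) -> float:
        return self.n_rejected / self.n_total if self.n_total else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "criterion": ["amplitude", "gradient", "flat", "any"],
                "n": [self.n_amplitude, self.n_gradient, self.n_flat, self.n_rejected],
                "n_total": self.n_total,
            }
        )


def baseline_correct(epochs: EpochSet, window: tuple[float, float] | None = None) -> EpochSet:
    """Subtract the mean over the baseline window per trial and channel."""
    if window is None:
        window = epochs.baseline_window
    lo, hi = window
    sel = (epochs.times >= lo) & (epochs.times < hi)
    if not sel.any():
        raise ValueError(f"baseline window {window} contains no samples")
    base = epochs.data[..., sel].mean(axis=-1, keepdims=True)
    return epochs.copy_with(epochs.data - base)


def reject_artifacts(
    epochs: EpochSet, criteria: RejectionCriteria | None = None
) -> tuple[np.ndarray, RejectionLog]:
    """Mark trials violating any criterion on any channel.

    Returns ``(keep, log)`` where ``keep`` is a (subject, trial) boolean mask.
    A trial is rejected when, on at least one channel, max|v| >= amp
    threshold, or max|Δv| >= gradient threshold, or SD(Δv) <= flat threshold
    (Δ = successive-sample difference).
    """
    if criteria is None:
        criteria = RejectionCriteria()
    x = epochs.data
    amp = np.abs(x).max(axis=-1)  # S x T x C
    grad = np.diff(x, axis=-1)
    gmax = np.abs(grad).max(axis=-1)
    gsd = grad.std(axis=-1)
    bad_amp = (amp >= criteria.amp_threshold).any(axis=-1)
    bad_grad = (gmax >= criteria.gradient_threshold).any(axis=-1)
    bad_flat = (gsd <= criteria.flat_threshold).any(axis=-1)
    bad = bad_amp | bad_grad | bad_flat
    log = RejectionLog(
        n_total=bad.size,
        n_amplitude=int(bad_amp.sum()),
        n_gradient=int(bad_grad.sum()),
        n_flat=int(bad_flat.sum()),
        n_rejected=int(bad.sum()),
    )
    return ~bad, log


def interpolate_channels(
    epochs: EpochSet, bad_channels, graph: SensorGraph
) -> EpochSet:
    """Replace bad channels by the inverse-distance-weighted mean of their
    good graph neighbors.

    A deliberate simplification of spherical-spline interpolation that is
    exact for locally constant fields and accurate for smooth ones on the
    synthetic layouts used here.  Raises if a bad channel has no good
    neighbor.
    """
    bad = sorted(set(int(b) for b in np.atleast_1d(bad_channels)))
    data = epochs.data.copy()
    bad_set = set(bad)
    for ch in bad:
        nb = [n for n in graph.neighbors(ch) if n not in bad_set]
        if not nb:
            raise ValueError(f"bad channel {ch} has no good neighbor")
        d = np.linalg.norm(
            graph.positions[nb] - graph.positions[ch], axis=1
        )
        w = 1.0 / np.maximum(d, 1e-12)
        w /= w.sum()
        data[:, :, ch, :] = np.einsum("n,stnx->stx", w, data[:, :, nb, :])
    return epochs.copy_with(data)


def rereference_average(epochs: EpochSet) -> EpochSet:
    """Re-reference to the average: channel mean becomes 0 at every sample."""
    if epochs.n_channels < 2:
        raise ValueError("average reference needs >= 2 channels")
    return epochs.copy_with(
        epochs.data - epochs.data.mean(axis=2, keepdims=True)
    )


def face_cells(cfs_values=(True, False)) -> list[tuple[str, str, bool]]:
    """Canonical ordering of the 12 face cells: cfs x contrast x expression."""
    return [
        (expr, lev, cfs)
        for cfs in cfs_values
        for lev in MAIN_LEVELS
        for expr in EXPRESSIONS
    ]


@dataclass
class ConditionMeans:
    """Per-subject condition-average waveforms: subject x cell x channel x time."""

    data: np.ndarray
    cells: list[tuple[str, str, bool]]  # (expression, contrast_level, cfs)
    times: np.ndarray
    sampling_rate: float
    channel_names: list[str]
    n_trials_per_cell: np.ndarray | None = None  # subject x cell

    def __post_init__(self) -> None:
        if self.data.ndim != 4 or self.data.shape[1] != len(self.cells):
            raise ValueError("data must be subject x cell x channel x time")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    def cell_index(self, expression: str, level: str, cfs: bool) -> int:
        return self.cells.index((expression, level, cfs))

    def factorial_view(self, cfs: bool) -> np.ndarray:
        """View as subject x expression(2) x contrast(3) x channel x time."""
        idx = [
            [self.cell_index(e, l, cfs) for l in MAIN_LEVELS] for e in EXPRESSIONS
        ]
        return self.data[:, np.asarray(idx), :, :]

    def select(
        self,
        window: tuple[float, float] | None = None,
        channels: np.ndarray | None = None,
    ) -> "ConditionMeans":
        """Restrict to a closed time window [tmin, tmax] and/or channel mask."""
        data, times, names = self.data, self.times, self.channel_names
        if channels is not None:
            channels = np.asarray(channels)
            if channels.dtype == bool:
                channels = np.flatnonzero(channels)
            data = data[:, :, channels, :]
            names = [names[i] for i in channels]
        if window is not None:
            lo, hi = window
            sel = (times >= lo) & (times <= hi)
            if not sel.any():
                raise ValueError(f"window {window} contains no samples")
            data = data[..., sel]
            times = times[sel]
        return ConditionMeans(
            data=data,
            cells=list(self.cells),
            times=times,
            sampling_rate=self.sampling_rate,
            channel_names=names,
            n_trials_per_cell=self.n_trials_per_cell,
        )


def lowpass_sos(lp_cutoff: float, sampling_rate: float, order: int = 4):
    return butter(order, lp_cutoff, btype="low", fs=sampling_rate, output="sos")


def average_filter_downsample(
    epochs: EpochSet,
    keep: np.ndarray | None = None,
    lp_cutoff: float = 25.0,
    target_rate: float = 125.0,
    filter_order: int = 4,
) -> ConditionMeans:
    """Average face trials per condition, low-pass, and decimate.

    Per subject and face cell the kept trials are averaged; the averages get
    a zero-phase 4th-order Butterworth low-pass (asymptotic roll-off -24
    dB/octave per pass) at ``lp_cutoff`` Hz, then decimation from the native
    rate to ``target_rate`` by integer stride.  Raises if any subject has an
    empty cell after rejection.
    """
    t = epochs.labels
    factor = epochs.sampling_rate / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("target_rate must divide the native sampling rate")
    factor = int(round(factor))
    if keep is None:
        keep = np.ones((epochs.n_subjects, epochs.n_trials), dtype=bool)

    cfs_present = sorted(t.cfs.unique(), reverse=True)
    cells = face_cells(tuple(bool(c) for c in cfs_present))
    n_cells = len(cells)
    S = epochs.n_subjects
    means = np.zeros((S, n_cells, epochs.n_channels, len(epochs.times)))
    counts = np.zeros((S, n_cells), dtype=int)
    expr = t.expression.to_numpy()
    lev = t.contrast_level.to_numpy()
    cfs = t.cfs.to_numpy().astype(bool)
    for ci, (e, l, v) in enumerate(cells):
        cell_mask = (expr == e) & (lev == l) & (cfs == v)
        for s in range(S):
            rows = cell_mask & keep[s]
            n = int(rows.sum())
            if n == 0:
                raise ValueError(
                    f"subject {s}: no trials left in cell {(e, l, v)}"
                )
            counts[s, ci] = n
            means[s, ci] = epochs.data[s, rows].mean(axis=0)

    sos = lowpass_sos(lp_cutoff, epochs.sampling_rate, filter_order)
    filtered = sosfiltfilt(sos, means, axis=-1)
    out = filtered[..., ::factor]
    times = epochs.times[::factor]
    return ConditionMeans(
        data=out,
        cells=cells,
        times=times,
        sampling_rate=target_rate,
        channel_names=list(epochs.channel_names),
        n_trials_per_cell=counts,
    )


def preprocess(
    epochs: EpochSet,
    criteria: RejectionCriteria | None = None,
    bad_channels=(),
    graph: SensorGraph | None = None,
    lp_cutoff: float = 25.0,
    target_rate: float = 125.0,
) -> tuple[ConditionMeans, RejectionLog]:
    """Full cleaning chain in the fixed order.

    reference -> baseline -> reject -> interpolate -> average -> filter ->
    downsample.  ``bad_channels`` (if any) require ``graph``.
    """
    x = rereference_average(epochs)
    x = baseline_correct(x)
    keep, log = reject_artifacts(x, criteria)
    if len(tuple(bad_channels)):
        if graph is None:
            raise ValueError("bad-channel interpolation requires a SensorGraph")
        x = interpolate_channels(x, bad_channels, graph)
    cm = average_filter_downsample(x, keep, lp_cutoff=lp_cutoff, target_rate=target_rate)
    return cm, log
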