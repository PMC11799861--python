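"""Signal-detection analysis and contrast calibration.

Implements the behavioral side of the study: d' and criterion from
hit/false-alarm counts, the linear d'-vs-contrast calibration that yields the
individual low/medium/high contrasts, the between-block recalibration rule
(reduce low and medium contrasts by 20% when the pooled d' of the preceding
block exceeds 0.3), and the participant-exclusion rule (medium-contrast CFS
detection d' > 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .synth import CATCH

__all__ = [
    "SDTCounts",
    "CalibrationResult",
    "CalibrationError",
    "dprime",
    "detection_counts",
    "discrimination_counts",
    "fit_contrast_levels",
    "recalibrate_block",
    "exclusion_check",
]


class CalibrationError(RuntimeError):
    """Raised when no monotone contrast calibration is possible.

    Mirrors the experimental failure mode in which the fitted line is flat or
    decreasing (``reason="slope"``) or the d'=0 intercept falls at
    non-positive contrast (``reason="medium"``, stimuli visible throughout
    the tested range); the caller is expected to re-run with a contrast grid
    shifted in the indicated direction.
    """

    def __init__(self, message: str, reason: str = "slope") -> None:
        super().__init__(message)
        self.reason = reason


@dataclass(frozen=True)
class SDTCounts:
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self) -> None:
        if min(self.hits, self.misses, self.false_alarms, self.correct_rejections) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_signal(self) -> int:
        return self.hits + self.misses

    @property
    def n_noise(self) -> int:
        return self.false_alarms + self.correct_rejections

    def pooled_with(self, other: "SDTCounts") -> "SDTCounts":
        return SDTCounts(
            self.hits + other.hits,
            self.misses + other.misses,
            self.false_alarms + other.false_alarms,
            self.correct_rejections + other.correct_rejections,
        )


def _rates(counts: SDTCounts, correction: str) -> tuple[float, float]:
    nS, nN = counts.n_signal, counts.n_noise
    if nS == 0 or nN == 0:
        raise ValueError("need at least one signal and one noise trial")
    if correction == "loglinear":
        h = (counts.hits + 0.5) / (nS + 1)
        f = (counts.false_alarms + 0.5) / (nN + 1)
        return h, f
    h = counts.hits / nS
    f = counts.false_alarms / nN
    if correction == "rate_clamp":
        h = min(max(h, 1 / (2 * nS)), 1 - 1 / (2 * nS))
        f = min(max(f, 1 / (2 * nN)), 1 - 1 / (2 * nN))
    elif correction == "none":
        if h in (0.0, 1.0) or f in (0.0, 1.0):
            raise ValueError(
                "extreme rate with correction='none' gives non-finite z; "
                "use 'rate_clamp' or 'loglinear'"
            )
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return h, f


def dprime(counts: SDTCounts, correction: str = "rate_clamp") -> tuple[float, float]:
    """Sensitivity d' = z(H) - z(F) and criterion c = -(z(H)+z(F))/2.

    ``correction`` handles proportions of exactly 0 or 1 before the normal
    quantile transform: ``rate_clamp`` replaces them by 1/(2N) and 1-1/(2N),
    ``loglinear`` adds 0.5/1 to all cells, ``none`` raises.
    """
    h, f = _rates(counts, correction)
    zh, zf = norm.ppf(h), norm.ppf(f)
    return zh - zf, -(zh + zf) / 2


def detection_counts(
    responses: pd.DataFrame,
    face_mask: np.ndarray | None = None,
    catch_mask: np.ndarray | None = None,
) -> SDTCounts:
    """Tally detection hits/FAs from a response table.

    A hit is key 2 ("anything else") on a face trial; a false alarm is key 2
    on a catch trial.  ``face_mask``/``catch_mask`` restrict which rows count
    as signal and noise (e.g. one condition's faces vs. the same visibility
    condition's catch trials); by default all faces and all catches are used.
    """
    is_catch = responses.contrast_level.to_numpy() == CATCH
    face = ~is_catch if face_mask is None else np.asarray(face_mask) & ~is_catch
    catch = is_catch if catch_mask is None else np.asarray(catch_mask) & is_catch
    yes = responses.detect_resp.to_numpy() == 2
    return SDTCounts(
        hits=int((face & yes).sum()),
        misses=int((face & ~yes).sum()),
        false_alarms=int((catch & yes).sum()),
        correct_rejections=int((catch & ~yes).sum()),
    )


def discrimination_counts(
    responses: pd.DataFrame, mask: np.ndarray | None = None
) -> SDTCounts:
    """Tally 2AFC discrimination responses (fearful = signal) on prompt trials."""
    t = responses
    valid = t.prompt.to_numpy().astype(bool) & (t.contrast_level.to_numpy() != CATCH)
    if mask is not None:
        valid &= np.asarray(mask)
    fearful = t.expression.to_numpy() == "fearful"
    said_fearful = t.discrim_resp.to_numpy(dtype=float) == 2
    return SDTCounts(
        hits=int((valid & fearful & said_fearful).sum()),
        misses=int((valid & fearful & ~said_fearful).sum()),
        false_alarms=int((valid & ~fearful & said_fearful).sum()),
        correct_rejections=int((valid & ~fearful & ~said_fearful).sum()),
    )


@dataclass
class CalibrationResult:
    """Fitted d'-vs-contrast line and derived stimulus levels.

    The medium contrast is the d'=0 intercept of the line, the high contrast
    the d'=3 point, and the low contrast is exactly half the medium.
    """

    slope: float
    intercept: float
    c_low: float
    c_medium: float
    c_high: float
    contrasts: list[float] = field(default_factory=list)
    dprimes: list[float] = field(default_factory=list)

    @property
    def levels(self) -> dict[str, float]:
        return {"low": self.c_low, "medium": self.c_medium, "high": self.c_high}

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "c_low": self.c_low,
            "c_medium": self.c_medium,
            "c_high": self.c_high,
            "contrasts": list(self.contrasts),
            "dprimes": list(self.dprimes),
        }


def fit_contrast_levels(contrasts, dprimes) -> CalibrationResult:
    """OLS line d' = intercept + slope * contrast, inverted at d' = 0 and 3.

    Raises :class:`CalibrationError` when the slope is non-positive (flat or
    inverted psychometric data) or when the implied medium contrast is not a
    usable stimulus value in (0, 1].
    """
    c = np.asarray(contrasts, dtype=float)
    d = np.asarray(dprimes, dtype=float)
    if c.shape != d.shape or c.ndim != 1:
        raise ValueError("contrasts and dprimes must be equal-length 1-D")
    if len(np.unique(c)) < 2:
        raise ValueError("need at least 2 distinct contrasts")
    slope, intercept = np.polyfit(c, d, 1)
    if slope <= 0:
        raise CalibrationError(
            f"non-positive slope {slope:.3g}: calibration failed", reason="slope"
        )
    c_medium = -intercept / slope
    c_high = (3.0 - intercept) / slope
    if not (0 < c_medium <= 1):
        raise CalibrationError(
            f"medium contrast {c_medium:.3g} outside (0, 1]: re-run with an "
            "adjusted contrast grid",
            reason="medium",
        )
    return CalibrationResult(
        slope=float(slope),
        intercept=float(intercept),
        c_low=c_medium / 2,
        c_medium=float(c_medium),
        c_high=float(c_high),
        contrasts=list(c),
        dprimes=list(d),
    )


def recalibrate_block(
    block_responses: pd.DataFrame,
    current_contrasts: dict[str, float],
    criterion: float = 0.3,
    reduction: float = 0.2,
    correction: str = "rate_clamp",
) -> tuple[dict[str, float], float]:
    """Between-block contrast adjustment rule.

    Pools hits over low- and medium-contrast CFS face trials and false alarms
    over CFS catch trials of the block (pooled counts, not averaged d'); if
    the pooled d' strictly exceeds ``criterion`` both the low and medium
    contrasts are multiplied by ``1 - reduction``.  The high contrast never
    changes.  Returns (new contrast map, pooled d').
    """
    t = block_responses
    cfs = t.cfs.to_numpy().astype(bool)
    lev = t.contrast_level.to_numpy()
    face_mask = cfs & np.isin(lev, ["low", "medium"])
    catch_mask = cfs & (lev == CATCH)
    if not catch_mask.any():
        raise ValueError("block has no CFS catch trials: no false-alarm estimate")
    if not face_mask.any():
        raise ValueError("block has no low/medium CFS face trials")
    counts = detection_counts(t, face_mask=face_mask, catch_mask=catch_mask)
    d, _ = dprime(counts, correction)
    new = dict(current_contrasts)
    if d > criterion:
        new["low"] = new["low"] * (1 - reduction)
        new["medium"] = new["medium"] * (1 - reduction)
    return new, d


def exclusion_check(
    medium_cfs_dprime: float, dprime_limit: float = 1.0
) -> tuple[bool, str]:
    """Post-hoc participant inclusion rule.

    Excludes (returns ``(False, reason)``) iff the medium-contrast CFS
    detection d' strictly exceeds ``dprime_limit`` — i.e. the calibration
    failed to keep medium-contrast stimuli nonconscious.
    """
    if medium_cfs_dprime > dprime_limit:
        return False, (
            f"medium-contrast CFS detection d' = {medium_cfs_dprime:.3g} > "
            f"{dprime_limit:g}: calibration unsuccessful"
        )
    return True, "included"
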