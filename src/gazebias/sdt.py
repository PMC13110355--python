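"""Equal-variance signal-detection indices, trial scoring, and the
gaze-residualization analysis.

d' = Phi^-1(H) - Phi^-1(F) and c = -(Phi^-1(H) + Phi^-1(F))/2 are computed
per (participant x value location).  Extreme rates (0 or 1) are handled by
the log-linear correction: 0.5 added to every cell, 1 to every denominator.

``residualize_dprime`` tests whether a sensitivity difference between the
high- and low-value locations survives controlling for gaze: d' is regressed
on the mean vertical saccade endpoint separately per location, and the
paired comparison is repeated on the residuals.  A reduction test compares
the raw per-participant d' difference against the residual difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .inferential import TTestResult, t_test

__all__ = ["SDTCounts", "SDTResult", "dprime_criterion", "score_trial",
           "ResidualizationResult", "residualize_dprime"]


@dataclass(frozen=True)
class SDTCounts:
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self):
        for name in ("hits", "misses", "false_alarms", "correct_rejections"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_signal(self) -> int:
        return self.hits + self.misses

    @property
    def n_noise(self) -> int:
        return self.false_alarms + self.correct_rejections


@dataclass(frozen=True)
class SDTResult:
    dprime: float
    criterion: float
    corrected: bool


def dprime_criterion(counts: SDTCounts, correction: str = "log_linear") -> SDTResult:
    """Sensitivity and criterion from hit/false-alarm counts.

    correction: "none" (error on extreme rates) or "log_linear" (+0.5 per
    cell applied when any rate is 0 or 1), or "always" to apply the
    correction unconditionally.
    """
    if counts.n_signal == 0 or counts.n_noise == 0:
        raise ValueError("need at least one signal and one noise trial")
    h = counts.hits / counts.n_signal
    f = counts.false_alarms / counts.n_noise
    extreme = h in (0.0, 1.0) or f in (0.0, 1.0)
    corrected = False
    if correction == "always" or (correction == "log_linear" and extreme):
        h = (counts.hits + 0.5) / (counts.n_signal + 1)
        f = (counts.false_alarms + 0.5) / (counts.n_noise + 1)
        corrected = True
    elif extreme:
        raise ValueError(
            f"hit rate {h} / false-alarm rate {f} is extreme; "
            "use the log-linear correction")
    zh, zf = stats.norm.ppf(h), stats.norm.ppf(f)
    return SDTResult(dprime=float(zh - zf), criterion=float(-(zh + zf) / 2.0),
                     corrected=corrected)


def score_trial(response_present: bool, digit_present: bool,
                digit_value: int | None = None) -> int:
    """Points for one digit-detection trial.

    Correct "absent" -> +5; correct "present" -> the digit's value;
    any incorrect response -> -5.  (500 points convert to 1 EUR.)
    """
    if digit_present:
        if digit_value is None:
            raise ValueError("digit_value required when a digit is present")
        if digit_value not in {1, 2, 3, 4, 6, 7, 8, 9}:
            raise ValueError(f"inadmissible digit value {digit_value}")
        return int(digit_value) if response_present else -5
    if digit_value is not None:
        raise ValueError("digit_value given but no digit present")
    return 5 if not response_present else -5


@dataclass(frozen=True)
class ResidualizationResult:
    residual_high: np.ndarray
    residual_low: np.ndarray
    slopes: tuple[float, float]           # (high, low) regression slopes
    intercepts: tuple[float, float]
    residual_test: TTestResult            # paired test, residual_high vs residual_low
    raw_test: TTestResult                 # paired test on raw d' values
    reduction_test: TTestResult           # paired test on (raw diff - residual diff)


def residualize_dprime(dprime_high: np.ndarray, dprime_low: np.ndarray,
                       endpoints: np.ndarray, sides: str = "two-sided",
                       compute_bf: bool = True) -> ResidualizationResult:
    """Compare d' between value locations after regressing out gaze endpoints.

    ``endpoints`` are per-participant mean vertical saccade endpoints with
    the sign convention positive = toward the high-value location.  Each
    location's d' is regressed on the endpoint (OLS with intercept); the
    location comparison is then repeated on the residuals, and a reduction
    test asks whether the per-participant difference shrank.
    """
    dh = np.asarray(dprime_high, float)
    dl = np.asarray(dprime_low, float)
    ep = np.asarray(endpoints, float)
    if not (dh.shape == dl.shape == ep.shape):
        raise ValueError("inputs must have identical shapes")
    if dh.size < 3:
        raise ValueError("need at least 3 participants")
    if np.ptp(ep) == 0:
        raise ValueError("endpoints are constant; regression is degenerate")

    fits = [stats.linregress(ep, d) for d in (dh, dl)]
    res_h = dh - (fits[0].intercept + fits[0].slope * ep)
    res_l = dl - (fits[1].intercept + fits[1].slope * ep)
    raw = t_test(dh, dl, paired=True, sides=sides, compute_bf=compute_bf)
    residual = t_test(res_h, res_l, paired=True, sides=sides,
                      compute_bf=compute_bf)
    reduction = t_test((dh - dl) - (res_h - res_l), sides=sides,
                       compute_bf=compute_bf)
    return ResidualizationResult(
        residual_high=res_h, residual_low=res_l,
        slopes=(float(fits[0].slope), float(fits[1].slope)),
        intercepts=(float(fits[0].intercept), float(fits[1].intercept)),
        residual_test=residual, raw_test=raw, reduction_test=reduction)
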