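"""Bayesian adaptive contrast staircase (QUEST) and the attentional imbalance score.

The staircase maintains a discretized posterior over the log10 Michelson
contrast threshold of an assumed Weibull psychometric function.  Trial
placement and the final threshold readout both use the posterior mean,
mapped back to linear contrast and clamped to the admissible stimulus range
(0.01-0.9 Michelson by default).  The prior is Gaussian in log10 contrast,
centred at log10(0.2) with an sd of 0.3 log-units.

The attentional imbalance compares the two per-location thresholds as a
normalized difference, positive when the low-value location has the higher
(worse) threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "WeibullShape",
    "QuestState",
    "quest_init",
    "quest_update",
    "quest_next",
    "quest_estimate",
    "attentional_imbalance",
    "weibull_p_correct",
]


@dataclass(frozen=True)
class WeibullShape:
    """Assumed psychometric shape for the staircase likelihood.

    beta: Weibull slope; gamma: guess rate (0.5 for 2AFC orientation
    discrimination); delta: lapse rate.
    """

    beta: float = 3.5
    gamma: float = 0.5
    delta: float = 0.02


def weibull_p_correct(log_intensity: np.ndarray, log_threshold: np.ndarray,
                      shape: WeibullShape) -> np.ndarray:
    """Watson-Pelli Weibull in log10 units: P(correct | threshold)."""
    x = np.asarray(log_intensity, dtype=float)
    t = np.asarray(log_threshold, dtype=float)
    core = 1.0 - (1.0 - shape.gamma) * np.exp(-np.power(10.0, shape.beta * (x - t)))
    return shape.delta * shape.gamma + (1.0 - shape.delta) * core


@dataclass(frozen=True)
class QuestState:
    grid: np.ndarray                 # log10-contrast support
    prior: np.ndarray                # density on grid (sums to 1)
    posterior: np.ndarray            # density on grid (sums to 1)
    shape: WeibullShape
    clamp: tuple[float, float]       # admissible linear-contrast range
    history: tuple[tuple[float, bool], ...] = field(default_factory=tuple)

    def to_json(self) -> str:
        """Serialize for trial-by-trial replay."""
        return json.dumps({
            "grid": self.grid.tolist(),
            "prior": self.prior.tolist(),
            "posterior": self.posterior.tolist(),
            "shape": {"beta": self.shape.beta, "gamma": self.shape.gamma,
                      "delta": self.shape.delta},
            "clamp": list(self.clamp),
            "history": [[i, bool(c)] for i, c in self.history],
        })

    @classmethod
    def from_json(cls, s: str) -> "QuestState":
        d = json.loads(s)
        return cls(grid=np.asarray(d["grid"]), prior=np.asarray(d["prior"]),
                   posterior=np.asarray(d["posterior"]),
                   shape=WeibullShape(**d["shape"]),
                   clamp=tuple(d["clamp"]),
                   history=tuple((i, bool(c)) for i, c in d["history"]))


def quest_init(prior_mean: float = 0.2, prior_sd: float = 0.3,
               clamp: tuple[float, float] = (0.01, 0.9),
               grid: np.ndarray | None = None,
               n_grid: int = 300,
               shape: WeibullShape | None = None) -> QuestState:
    """Fresh staircase state.

    ``prior_mean`` is a linear Michelson contrast; ``prior_sd`` is in log10
    units (the staircase's analysis space).  The grid spans the clamp range
    widened by 3 prior sds so the posterior is never artificially truncated
    at the stimulus limits.
    """
    lo, hi = clamp
    if not (0.0 < lo < hi < 1.0):
        raise ValueError(f"clamp must satisfy 0 < lo < hi < 1, got {clamp}")
    if prior_mean <= 0:
        raise ValueError("prior_mean must be a positive contrast")
    if grid is None:
        grid = np.linspace(np.log10(lo) - 3 * prior_sd,
                           np.log10(hi) + 3 * prior_sd, n_grid)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    logp = -0.5 * ((grid - np.log10(prior_mean)) / prior_sd) ** 2
    prior = np.exp(logp - logp.max())
    prior /= prior.sum()
    return QuestState(grid=grid, prior=prior, posterior=prior.copy(),
                      shape=shape or WeibullShape(), clamp=(lo, hi))


def quest_update(state: QuestState, intensity: float, correct: bool) -> QuestState:
    """Pointwise Bayes step for one observed trial.

    posterior ∝ posterior × likelihood of the binary outcome at ``intensity``
    under each candidate threshold on the grid.
    """
    if not isinstance(correct, (bool, np.bool_)):
        raise TypeError("outcome must be a boolean")
    if intensity <= 0:
        raise ValueError("intensity must be a positive contrast")
    p_correct = weibull_p_correct(np.log10(intensity), state.grid, state.shape)
    like = p_correct if correct else 1.0 - p_correct
    post = state.posterior * like
    total = post.sum()
    if total <= 0:
        raise FloatingPointError("posterior collapsed to zero mass")
    post = post / total
    return replace(state, posterior=post,
                   history=state.history + ((float(intensity), bool(correct)),))


def quest_estimate(state: QuestState) -> float:
    """Threshold readout: posterior mean in log10 contrast, reported linear."""
    return float(10.0 ** np.dot(state.posterior, state.grid))


def quest_next(state: QuestState) -> float:
    """Next trial placement: posterior-mean threshold, clamped to the range."""
    lo, hi = state.clamp
    return float(np.clip(quest_estimate(state), lo, hi))


def attentional_imbalance(m_low: float, m_high: float) -> float:
    """Normalized threshold difference (m_low - m_high)/(m_low + m_high).

    Positive values indicate higher thresholds (worse contrast sensitivity)
    at the low-value location.  Bounded in (-1, 1) for positive inputs.
    """
    if m_low <= 0 or m_high <= 0:
        raise ValueError("thresholds must be positive contrasts")
    return (m_low - m_high) / (m_low + m_high)
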