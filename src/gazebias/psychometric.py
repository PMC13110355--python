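"""Psychometric and oculometric function fitting and PSE-based bias indices.

The response model is a cumulative Gaussian with guess and lapse asymptotes,

    psi(x) = gamma + (1 - gamma - lambda) * Phi((x - mu) / sigma),

fit by penalized maximum likelihood (weak Beta(1, 19) priors on gamma and
lambda stabilize small samples), with multi-start L-BFGS-B.  The point of
subjective equality (PSE) is defined as mu, the level where the *unscaled*
sigmoid crosses 0.5 — robust to asymmetric asymptotes and invariant under
lapses.

Bias indices for the pursuit/report dissociation design compare the PSE
difference between stimulus orders in the rewarded (biased) block against
the same difference in the unbiased block, signed so that positive values
mean the observer favored the highly rewarded stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["BinnedResponses", "PsychometricFit", "fit_psychometric", "pse",
           "bias_index", "pse_difference_exp4", "bin_trials", "psi"]


@dataclass(frozen=True)
class BinnedResponses:
    """Binary responses aggregated per stimulus level.

    levels: stimulus values (deg/s for speed comparison, face-proportion
    for composite images); n: trials per level; k: count of "comparison
    faster" (or "face") responses per level.
    """

    levels: np.ndarray
    n: np.ndarray
    k: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "levels", np.asarray(self.levels, float))
        object.__setattr__(self, "n", np.asarray(self.n, int))
        object.__setattr__(self, "k", np.asarray(self.k, int))
        if not (self.levels.shape == self.n.shape == self.k.shape):
            raise ValueError("levels, n, k must have identical shapes")
        if np.any(self.k < 0) or np.any(self.k > self.n):
            raise ValueError("need 0 <= k <= n at every level")
        if np.unique(self.levels[self.n > 0]).size < 3:
            raise ValueError("need >= 3 distinct levels with trials")


def bin_trials(levels, responses) -> BinnedResponses:
    """Aggregate trial-level (level, binary response) pairs."""
    levels = np.asarray(levels, float)
    responses = np.asarray(responses)
    uniq = np.unique(levels)
    n = np.array([np.sum(levels == u) for u in uniq])
    k = np.array([np.sum(responses[levels == u]) for u in uniq])
    return BinnedResponses(levels=uniq, n=n, k=k)


@dataclass(frozen=True)
class PsychometricFit:
    mu: float
    sigma: float
    gamma: float
    lam: float
    loglik: float
    converged: bool
    pse: float
    pse_ci: tuple[float, float] | None = None
    message: str = ""


def psi(x, mu, sigma, gamma, lam):
    """Lapse-scaled cumulative-Gaussian response probability."""
    return gamma + (1.0 - gamma - lam) * stats.norm.cdf((np.asarray(x, float) - mu) / sigma)


_ASYMPTOTE_MAX = 0.1


def _nll(params, data: BinnedResponses, fix_asymptotes: bool, penalized: bool):
    if fix_asymptotes:
        mu, sigma = params
        gamma = lam = 0.0
    else:
        mu, sigma, gamma, lam = params
    p = np.clip(psi(data.levels, mu, sigma, gamma, lam), 1e-12, 1 - 1e-12)
    ll = np.sum(data.k * np.log(p) + (data.n - data.k) * np.log1p(-p))
    if penalized and not fix_asymptotes:
        # Beta(1, 19) prior on gamma/_ASYMPTOTE_MAX and lambda/_ASYMPTOTE_MAX
        for a in (gamma, lam):
            ll += 18.0 * np.log1p(-min(a / _ASYMPTOTE_MAX, 1 - 1e-12))
    return -ll


def fit_psychometric(data: BinnedResponses, fix_asymptotes: bool = False,
                     penalized: bool = True, n_boot_ci: int = 0,
                     ci_seed: int = 0) -> PsychometricFit:
    """Penalized-ML cumulative-Gaussian fit with multi-start optimization.

    Degenerate data (all responses 0 or all 1, or no dependence on level)
    yield ``converged=False`` with boundary diagnostics rather than a
    silent number.  ``n_boot_ci`` > 0 adds a parametric-bootstrap 95% CI on
    the PSE.
    """
    total_k, total_n = int(data.k.sum()), int(data.n.sum())
    span = float(data.levels.max() - data.levels.min())
    if total_k == 0 or total_k == total_n:
        return PsychometricFit(mu=np.nan, sigma=np.nan, gamma=np.nan,
                               lam=np.nan, loglik=np.nan, converged=False,
                               pse=np.nan, message="all responses identical")

    sig_lo, sig_hi = span * 1e-3, span * 10.0
    mu_lo = float(data.levels.min()) - span
    mu_hi = float(data.levels.max()) + span
    if fix_asymptotes:
        bounds = [(mu_lo, mu_hi), (sig_lo, sig_hi)]
    else:
        bounds = [(mu_lo, mu_hi), (sig_lo, sig_hi),
                  (0.0, _ASYMPTOTE_MAX), (0.0, _ASYMPTOTE_MAX)]

    # deterministic multi-start: spread mu over the level range, sigma coarse/fine
    props = data.k / np.maximum(data.n, 1)
    mu0 = float(np.interp(0.5, props, data.levels)) if np.any(np.diff(props) > 0) \
        else float(np.median(data.levels))
    starts = [
        (mu0, span / 4),
        (float(np.percentile(data.levels, 25)), span / 4),
        (float(np.median(data.levels)), span / 2),
        (float(np.percentile(data.levels, 75)), span / 4),
        (mu0, span),
    ]
    best = None
    for m, s in starts:
        x0 = (m, s) if fix_asymptotes else (m, s, 0.02, 0.02)
        res = optimize.minimize(_nll, x0, args=(data, fix_asymptotes, penalized),
                                method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    if fix_asymptotes:
        mu, sigma = best.x
        gamma = lam = 0.0
    else:
        mu, sigma, gamma, lam = best.x
    loglik = -_nll(best.x, data, fix_asymptotes, penalized=False)
    # honesty of convergence: reject boundary sigma (flat or step-degenerate data)
    interior = sig_lo * 1.5 < sigma < sig_hi * 0.75 and mu_lo < mu < mu_hi
    converged = bool(best.success and interior)
    message = "" if converged else f"boundary or optimizer failure: {best.message}"

    ci = None
    if converged and n_boot_ci > 0:
        rng = np.random.default_rng(ci_seed)
        boots = []
        p_hat = psi(data.levels, mu, sigma, gamma, lam)
        for _ in range(n_boot_ci):
            kb = rng.binomial(data.n, p_hat)
            try:
                fb = fit_psychometric(
                    BinnedResponses(data.levels, data.n, kb),
                    fix_asymptotes=fix_asymptotes, penalized=penalized)
            except ValueError:
                continue
            if fb.converged:
                boots.append(fb.mu)
        if len(boots) >= max(10, n_boot_ci // 2):
            ci = (float(np.percentile(boots, 2.5)),
                  float(np.percentile(boots, 97.5)))
    return PsychometricFit(mu=float(mu), sigma=float(sigma), gamma=float(gamma),
                           lam=float(lam), loglik=float(loglik),
                           converged=converged, pse=float(mu), pse_ci=ci,
                           message=message)


def pse(fit: PsychometricFit) -> float:
    """PSE of a converged fit: mu, where the unscaled sigmoid crosses 0.5."""
    if not fit.converged:
        raise ValueError(f"fit did not converge: {fit.message}")
    return fit.mu


def bias_index(pse_o1_unbiased: float, pse_o2_unbiased: float,
               pse_o1_biased: float, pse_o2_biased: float,
               reward_order: str) -> float:
    """PSE-difference bias index, positive when favoring the rewarded stimulus.

    o1/o2 denote functions fit with the standard stimulus first/second, so
    the comparison sits in the second/first interval respectively.  The
    index is

        s * [(pse_o1_biased - pse_o2_biased)
             - (pse_o1_unbiased - pse_o2_unbiased)]

    with s = +1 when the rewarded response is "first faster" and s = -1 when
    it is "second faster".  Truth table: an observer shifting its reports
    toward interval r raises the PSE of the order whose comparison occupies
    the non-rewarded interval and lowers the other, so the bracketed
    difference is positive for r = first; the sign flip makes r = second
    positive as well.
    """
    for v in (pse_o1_unbiased, pse_o2_unbiased, pse_o1_biased, pse_o2_biased):
        if not np.isfinite(v):
            raise ValueError("all four PSEs must be finite (converged fits)")
    if reward_order not in ("first", "second"):
        raise ValueError("reward_order must be 'first' or 'second'")
    s = 1.0 if reward_order == "first" else -1.0
    return s * ((pse_o1_biased - pse_o2_biased)
                - (pse_o1_unbiased - pse_o2_unbiased))


def pse_difference_exp4(fit_eyes: PsychometricFit,
                        fit_house: PsychometricFit) -> float:
    """PSE(house fixation) - PSE(eye fixation), in face-proportion units.

    Positive means less face signal was needed for subjective equality when
    fixating between the eyes.
    """
    return pse(fit_house) - pse(fit_eyes)
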