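"""Group-level statistics in the study's reporting style.

t-tests (one-sample, paired, independent) with Cohen's d and a 95% CI from
noncentral-t inversion; default-prior (JZS) Bayes factors by direct
quadrature over the Cauchy effect-size prior; simple linear regression with
standardized slope; Wilcoxon signed-rank; and scoring of the Comprehensive
Relative Autonomy Index (C-RAI) motivation-quality questionnaire with
Cronbach's alpha reliability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

__all__ = [
    "TTestResult", "t_test", "jzs_bf10", "linregress",
    "wilcoxon_signed_rank", "CRAIScores", "crai_score", "cronbach_alpha",
    "CRAI_SUBSCALES",
]

_SIDES = {"two-sided", "greater", "less"}


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    sides: str
    cohens_d: float
    d_ci_95: tuple[float, float]
    bf10: float | None
    n1: int
    n2: int | None = None
    paired: bool = False

    def report(self) -> str:
        """One-line summary mirroring the field's reporting format."""
        s = (f"t({self.df:g}) = {self.t:.2f}, p = {self.p:.3g} ({self.sides}), "
             f"d = {self.cohens_d:.2f}, 95% CI [{self.d_ci_95[0]:.2f}, "
             f"{self.d_ci_95[1]:.2f}]")
        if self.bf10 is not None:
            s += f", BF10 = {self.bf10:.3g}"
        return s


def _d_ci_from_t(t: float, df: float, scale: float) -> tuple[float, float]:
    """95% CI for Cohen's d by inverting the noncentral-t CDF.

    ``scale`` maps the noncentrality parameter to d (d = ncp / scale).
    """
    from scipy.optimize import brentq

    def f(nc, target):
        c = stats.nct.cdf(t, df, nc)
        return (c if math.isfinite(c) else (1.0 if nc < t else 0.0)) - target

    def solve(target_cdf: float) -> float:
        # nct.cdf is decreasing in ncp; expand the bracket until it straddles
        half = 4.0 + abs(t)
        for _ in range(8):
            lo, hi = t - half, t + half
            if f(lo, target_cdf) > 0 > f(hi, target_cdf):
                return brentq(f, lo, hi, args=(target_cdf,), xtol=1e-8)
            half *= 2
        return math.nan
    ncp_lo = solve(0.975)   # lower d bound: ncp with upper-tail coverage
    ncp_hi = solve(0.025)
    return (ncp_lo / scale, ncp_hi / scale)


def t_test(a, b=None, paired: bool = False, sides: str = "two-sided",
           mu0: float = 0.0, compute_bf: bool = True,
           rscale: float = math.sqrt(2) / 2) -> TTestResult:
    """t-test with effect size, CI, and (optionally) a default-prior BF10.

    One-sample when ``b`` is None (against ``mu0``); paired when
    ``paired=True`` (reduces to a one-sample test on the differences);
    independent two-sample (pooled variance) otherwise.  Cohen's d is
    mean/sd for the one-sample/paired cases and the pooled-sd standardized
    difference for the independent case; its 95% CI comes from
    noncentral-t inversion.
    """
    if sides not in _SIDES:
        raise ValueError(f"sides must be one of {_SIDES}")
    a = np.asarray(a, dtype=float)
    if b is not None:
        b = np.asarray(b, dtype=float)
    if paired:
        if b is None or a.shape != b.shape:
            raise ValueError("paired test requires two equal-length samples")
        a, b = a - b, None
        mu0 = 0.0
    n2 = None
    if b is None:
        n1 = a.size
        if n1 < 2:
            raise ValueError("need n >= 2")
        sd = a.std(ddof=1)
        if sd == 0:
            if a.mean() == mu0:
                # e.g. a paired test of a sample against itself
                return TTestResult(t=0.0, df=float(n1 - 1),
                                   p=1.0 if sides == "two-sided" else 0.5,
                                   sides=sides, cohens_d=0.0, d_ci_95=(0.0, 0.0),
                                   bf10=None, n1=n1, n2=None, paired=paired)
            raise ValueError("zero variance sample")
        d = float((a.mean() - mu0) / sd)
        scale = math.sqrt(n1)
        t = d * scale
        df = n1 - 1
        n_eff = n1
    else:
        n1, n2 = a.size, b.size
        if min(n1, n2) < 2:
            raise ValueError("need n >= 2 per group")
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
        if sp2 == 0:
            raise ValueError("zero pooled variance")
        d = float((a.mean() - b.mean()) / math.sqrt(sp2))
        scale = math.sqrt(n1 * n2 / (n1 + n2))
        t = d * scale
        n_eff = n1 * n2 / (n1 + n2)

    if sides == "two-sided":
        p = 2 * stats.t.sf(abs(t), df)
    elif sides == "greater":
        p = stats.t.sf(t, df)
    else:
        p = stats.t.cdf(t, df)
    bf = jzs_bf10(t, n1, n2, rscale=rscale, sides=sides) if compute_bf else None
    return TTestResult(t=float(t), df=float(df), p=float(p), sides=sides,
                       cohens_d=d, d_ci_95=_d_ci_from_t(t, df, scale),
                       bf10=bf, n1=n1, n2=n2, paired=paired)


def jzs_bf10(t: float, n1: int, n2: int | None = None,
             rscale: float = math.sqrt(2) / 2, sides: str = "two-sided",
             rtol: float = 1e-8) -> float:
    """Jeffreys-Zellner-Siow Bayes factor for a t statistic.

    The alternative places a Cauchy(0, rscale) prior on the standardized
    effect delta; the marginal likelihood is the noncentral-t density
    integrated over that prior, divided by the central-t density under the
    null.  One-sample/paired when ``n2`` is None, else independent
    two-sample with effective n = n1*n2/(n1+n2).  Directional hypotheses
    (``sides`` "greater"/"less") truncate the prior to the hypothesized
    half-line (doubling its density there), matching the one-sided default
    Bayes factors of common stats suites.
    """
    if sides not in _SIDES:
        raise ValueError(f"sides must be one of {_SIDES}")
    if not math.isfinite(t):
        raise ValueError("t must be finite")
    # scipy's noncentral-t machinery breaks down for very large |t|; the BF
    # there is astronomically decisive, so saturate at |t| = 37 (monotone).
    t = float(np.clip(t, -37.0, 37.0))
    if n2 is None:
        if n1 < 2:
            raise ValueError("need n >= 2")
        df, n_eff = n1 - 1, float(n1)
    else:
        if min(n1, n2) < 2:
            raise ValueError("need n >= 2 per group")
        df, n_eff = n1 + n2 - 2, n1 * n2 / (n1 + n2)
    sq = math.sqrt(n_eff)

    # integrate in a log-rescaled form so large |t| cannot underflow
    center = t / sq
    log_peak = (stats.nct.logpdf(t, df, t)
                + stats.cauchy.logpdf(center, 0.0, rscale))
    if not math.isfinite(log_peak):
        log_peak = 0.0

    def integrand(delta: float) -> float:
        lg = (stats.nct.logpdf(t, df, delta * sq)
              + stats.cauchy.logpdf(delta, 0.0, rscale)) - log_peak
        return math.exp(lg) if math.isfinite(lg) else 0.0

    width = max(rscale, 4.0 / sq, abs(center) / 4.0)
    lo, hi = min(0.0, center) - 8 * width, max(0.0, center) + 8 * width
    if sides == "two-sided":
        segments = ((-np.inf, lo), (lo, min(center, 0.0)),
                    (min(center, 0.0), max(center, 0.0)),
                    (max(center, 0.0), hi), (hi, np.inf))
        scale = 1.0
    elif sides == "greater":
        segments = ((0.0, max(center, 0.0)), (max(center, 0.0), hi),
                    (hi, np.inf))
        scale = 2.0
    else:
        segments = ((-np.inf, lo), (lo, min(center, 0.0)),
                    (min(center, 0.0), 0.0))
        scale = 2.0
    pieces = [integrate.quad(integrand, a, b, epsrel=rtol, limit=200)
              for a, b in segments]
    marg = scale * sum(p[0] for p in pieces)
    err = scale * sum(p[1] for p in pieces)
    if not math.isfinite(marg) or marg <= 0 or (err > 0 and err / marg > 1e-3):
        raise ArithmeticError(
            f"BF quadrature failed to converge (value={marg}, abserr={err})")
    log_bf = math.log(marg) + log_peak - stats.t.logpdf(t, df)
    return float(math.exp(log_bf)) if log_bf < 700 else math.inf


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    beta_std: float
    F: float
    p: float
    r: float
    df: int


def linregress(y, x) -> RegressionResult:
    """Simple OLS of y on x with a standardized slope and slope F-test."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    if y.shape != x.shape or y.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    fit = stats.linregress(x, y)
    sy = y.std(ddof=1)
    beta_std = fit.slope * x.std(ddof=1) / sy if sy > 0 else math.nan
    df = y.size - 2
    tstat = fit.slope / fit.stderr if fit.stderr > 0 else math.inf
    return RegressionResult(slope=float(fit.slope), intercept=float(fit.intercept),
                            beta_std=float(beta_std), F=float(tstat ** 2),
                            p=float(fit.pvalue), r=float(fit.rvalue), df=df)


def wilcoxon_signed_rank(sample, mu0: float = 0.0, sides: str = "two-sided",
                         exact_max_n: int = 25) -> dict:
    """Wilcoxon signed-rank test against ``mu0``.

    Zero differences are dropped (Wilcoxon's original treatment).  The exact
    null distribution is enumerated for n <= ``exact_max_n``; the normal
    approximation is used beyond that.
    """
    d = np.asarray(sample, float) - mu0
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    method = "exact" if d.size <= exact_max_n else "approx"
    alt = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[sides]
    res = stats.wilcoxon(d, alternative=alt, method=method)
    return {"W": float(res.statistic), "p": float(res.pvalue),
            "n": int(d.size), "method": method, "sides": sides}


# C-RAI: 24 items, four per subscale.  The first three subscales compose the
# autonomous scale, the last three the controlled scale.
CRAI_SUBSCALES = ("INT", "IDE", "IJP", "EXT", "AMO", "IJN")


@dataclass(frozen=True)
class CRAIScores:
    subscales: dict                 # subscale name -> per-participant means
    autonomous: np.ndarray
    controlled: np.ndarray
    self_concordance_raw: np.ndarray
    self_concordance_z: np.ndarray


def crai_score(items: np.ndarray, scale_bounds: tuple[float, float] = (1, 7),
               composite: str = "mean") -> CRAIScores:
    """Score the 24-item C-RAI for a sample of participants.

    ``items``: (n_participants, 24) response matrix, columns ordered by
    subscale (INT, IDE, IJP, EXT, AMO, IJN; 4 items each).  Self-concordance
    is the autonomous minus the controlled composite; composites are means
    of subscale means by default (``composite="sum"`` uses sums).  Raw
    self-concordance is z-standardized across the supplied sample.
    """
    items = np.asarray(items, float)
    if items.ndim != 2 or items.shape[1] != 24:
        raise ValueError("expected an (n, 24) item matrix")
    if np.isnan(items).any():
        raise ValueError("missing item responses; no imputation is performed")
    lo, hi = scale_bounds
    if items.min() < lo or items.max() > hi:
        raise ValueError(f"item responses outside scale bounds [{lo}, {hi}]")
    means = {name: items[:, 4 * i:4 * i + 4].mean(axis=1)
             for i, name in enumerate(CRAI_SUBSCALES)}
    agg = (lambda cols: np.mean(cols, axis=0)) if composite == "mean" \
        else (lambda cols: np.sum(cols, axis=0))
    autonomous = agg([means[s] for s in CRAI_SUBSCALES[:3]])
    controlled = agg([means[s] for s in CRAI_SUBSCALES[3:]])
    raw = autonomous - controlled
    sd = raw.std(ddof=1) if raw.size > 1 else 0.0
    if sd == 0:
        raise ValueError("zero variance in self-concordance; cannot z-score")
    z = (raw - raw.mean()) / sd
    return CRAIScores(subscales=means, autonomous=autonomous,
                      controlled=controlled, self_concordance_raw=raw,
                      self_concordance_z=z)


def cronbach_alpha(item_matrix: np.ndarray) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum(item variances)/variance(total))."""
    m = np.asarray(item_matrix, float)
    if m.ndim != 2 or m.shape[1] < 2 or m.shape[0] < 2:
        raise ValueError("need >= 2 items and >= 2 respondents")
    k = m.shape[1]
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance")
    return float(k / (k - 1) * (1 - m.var(axis=0, ddof=1).sum() / total_var))
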