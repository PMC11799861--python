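"""Follow-up inference: repeated-measures ANOVA with Greenhouse–Geisser
correction, t tests, Holm adjustment, and default Bayes factors.

The JZS Bayes factor places a Cauchy prior (scale ``rscale``, default
sqrt(2)/2) on the standardized effect size and integrates it out
numerically; BF10 > 1 favors the alternative, BF01 = 1/BF10 the null.  The
correlation Bayes factor uses the exact sampling distribution of Pearson's r
with a stretched-beta prior on the population correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special
from scipy.stats import beta as beta_dist
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

__all__ = [
    "TestResult",
    "rm_anova",
    "ttest",
    "jzs_bf",
    "holm",
    "correlation_bf",
    "bf_label",
]


@dataclass
class TestResult:
    """One inferential test: statistic, dfs, p, and optional BF/epsilon."""

    effect: str
    statistic: float
    df: tuple[float, ...]
    p: float
    p_adjusted: float | None = None
    bf10: float | None = None
    epsilon_hat: float | None = None

    @property
    def bf01(self) -> float | None:
        return None if self.bf10 is None else 1.0 / self.bf10


def bf_label(bf10: float) -> str:
    """Descriptive evidence category for a BF10 (conventional cutpoints)."""
    bf = bf10 if bf10 >= 1 else 1 / bf10
    side = "alternative" if bf10 >= 1 else "null"
    if bf < 3:
        strength = "anecdotal"
    elif bf < 10:
        strength = "moderate"
    elif bf < 30:
        strength = "strong"
    elif bf < 100:
        strength = "very strong"
    else:
        strength = "extreme"
    return f"{strength} evidence for {side}"


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrasts spanning the difference space."""
    H = np.linalg.qr(np.column_stack([np.ones(k), np.eye(k, k - 1)]))[0]
    return H[:, 1:].T


def _gg_epsilon(scores: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from subject x level scores.

    Box's epsilon of the covariance of the (k-1) orthonormal contrast
    variables: eps = tr(M)^2 / ((k-1) tr(M^2)).  Bounded below by 1/(k-1).
    """
    k = scores.shape[1]
    if k < 3:
        return 1.0
    C = _orthonormal_contrasts(k)
    S = np.cov(scores, rowvar=False)
    M = C @ S @ C.T
    eps = np.trace(M) ** 2 / ((k - 1) * np.trace(M @ M))
    return float(min(1.0, max(eps, 1.0 / (k - 1))))


def _rm_effect(scores: np.ndarray, name: str) -> TestResult:
    """One-way within-subject effect from subject x level scores."""
    S, K = scores.shape
    grand = scores.mean()
    mk = scores.mean(0)
    ms = scores.mean(1)
    ss_k = S * ((mk - grand) ** 2).sum()
    resid = scores - mk[None] - ms[:, None] + grand
    ss_err = (resid**2).sum()
    df1, df2 = K - 1, (K - 1) * (S - 1)
    F = (ss_k / df1) / (ss_err / df2) if ss_err > 0 else np.inf
    eps = _gg_epsilon(scores)
    p = float(f_dist.sf(F, eps * df1, eps * df2)) if np.isfinite(F) else 0.0
    return TestResult(
        effect=name, statistic=float(F), df=(df1, df2), p=p, epsilon_hat=eps
    )


def rm_anova(
    data: np.ndarray,
    design: tuple[int, ...],
    factor_names: tuple[str, ...] | None = None,
) -> list[TestResult]:
    """Fully within-subject ANOVA on subject x cell scalars.

    ``design`` is ``(a,)`` for one factor or ``(a, b)`` for two crossed
    factors; the cell axis must be ordered with the second factor fastest.
    GG-corrected p-values are reported whenever an effect has >= 2 numerator
    df (for 2-level effects epsilon is exactly 1).  The interaction epsilon
    is computed on the (a-1)(b-1) interaction contrast variables.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be subject x cell")
    if np.isnan(X).any():
        raise ValueError("incomplete cells (NaN) are not supported")
    if X.shape[0] < 3:
        raise ValueError("need >= 3 subjects")
    if X.shape[1] != int(np.prod(design)):
        raise ValueError("cell count does not match design")

    if len(design) == 1:
        name = factor_names[0] if factor_names else "factor"
        return [_rm_effect(X, name)]
    if len(design) != 2:
        raise ValueError("only one- and two-factor designs are supported")

    a, b = design
    names = factor_names or ("A", "B")
    Y = X.reshape(-1, a, b)
    out = [
        _rm_effect(Y.mean(2), names[0]),
        _rm_effect(Y.mean(1), names[1]),
    ]

    # interaction: project cells onto the interaction contrast space
    Ca, Cb = _orthonormal_contrasts(a), _orthonormal_contrasts(b)
    Cab = np.kron(Ca, Cb)  # (a-1)(b-1) x ab
    Z = X @ Cab.T  # subject x interaction contrasts
    S = X.shape[0]
    df1 = (a - 1) * (b - 1)
    df2 = df1 * (S - 1)
    zbar = Z.mean(0)
    ss_int = S * (zbar**2).sum()
    ss_err = ((Z - zbar) ** 2).sum()
    F = (ss_int / df1) / (ss_err / df2) if ss_err > 0 else np.inf
    M = np.cov(Z, rowvar=False)
    M = np.atleast_2d(M)
    eps = float(
        min(1.0, max(np.trace(M) ** 2 / (df1 * np.trace(M @ M)), 1.0 / df1))
    )
    p = float(f_dist.sf(F, eps * df1, eps * df2)) if np.isfinite(F) else 0.0
    out.append(
        TestResult(
            effect=f"{names[0]}:{names[1]}",
            statistic=float(F),
            df=(df1, df2),
            p=p,
            epsilon_hat=eps,
        )
    )
    return out


# ---------------------------------------------------------------------------
# t tests


def ttest(
    values_a,
    values_b=None,
    kind: str = "one_sample",
    popmean: float = 0.0,
    effect: str = "",
) -> TestResult:
    """Two-sided t test; df = n-1 (one-sample/paired) or n1+n2-2 (pooled)."""
    x = np.asarray(values_a, dtype=float)
    if kind == "paired":
        if values_b is None:
            raise ValueError("paired test needs two samples")
        y = np.asarray(values_b, dtype=float)
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        x, kind = x - y, "one_sample"
    if kind == "one_sample":
        n = len(x)
        if n < 2:
            raise ValueError("need n >= 2")
        se = x.std(ddof=1) / math.sqrt(n)
        diff = x.mean() - popmean
        t = diff / se if se > 0 else math.copysign(math.inf, diff) if diff else 0.0
        df = n - 1
    elif kind == "independent":
        y = np.asarray(values_b, dtype=float)
        n1, n2 = len(x), len(y)
        if min(n1, n2) < 2:
            raise ValueError("need n >= 2 per sample")
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        diff = x.mean() - y.mean()
        t = diff / se if se > 0 else math.copysign(math.inf, diff) if diff else 0.0
    else:
        raise ValueError(f"unknown kind {kind!r}")
    p = float(2 * t_dist.sf(abs(t), df)) if math.isfinite(t) else 0.0
    if t == 0.0:
        p = 1.0
    return TestResult(effect=effect, statistic=float(t), df=(df,), p=p)


# ---------------------------------------------------------------------------
# JZS Bayes factor


def _jzs_effective(t: float, n1: int, n2: int | None, kind: str) -> tuple[float, float]:
    if kind in ("one_sample", "paired"):
        if n1 < 2:
            raise ValueError("need n >= 2")
        return float(n1), float(n1 - 1)
    if kind == "independent":
        if n2 is None or min(n1, n2) < 2:
            raise ValueError("independent test needs two group sizes >= 2")
        return n1 * n2 / (n1 + n2), float(n1 + n2 - 2)
    raise ValueError(f"unknown kind {kind!r}")


def jzs_bf(
    t: float,
    n1: int,
    n2: int | None = None,
    kind: str = "one_sample",
    rscale: float = 0.707,
) -> float:
    """Jeffreys–Zellner–Siow default Bayes factor BF10 for a t statistic.

    Marginalizes the Cauchy(0, rscale) prior on standardized effect size via
    the equivalent scale mixture: g ~ InverseGamma(1/2, rscale^2/2),

        BF10 = E_g[(1+Ng)^(-1/2) (1 + t^2/((1+Ng) v))^(-(v+1)/2)]
               / (1 + t^2/v)^(-(v+1)/2),

    with effective sample size N (n for one-sample/paired, n1 n2/(n1+n2)
    for independent groups) and v degrees of freedom.  Computed in log space
    by adaptive quadrature; raises on non-convergence.
    """
    if not math.isfinite(t):
        raise ValueError("t must be finite")
    N, nu = _jzs_effective(t, n1, n2, kind)
    r2 = rscale * rscale
    log_den = -(nu + 1) / 2 * math.log1p(t * t / nu)

    def integrand(g: float) -> float:
        if g <= 0:
            return 0.0
        log_lik = (
            -0.5 * math.log1p(N * g)
            - (nu + 1) / 2 * math.log1p(t * t / ((1 + N * g) * nu))
        )
        log_prior = (
            0.5 * math.log(r2 / 2)
            - special.gammaln(0.5)
            - 1.5 * math.log(g)
            - r2 / (2 * g)
        )
        return math.exp(log_lik + log_prior - log_den)

    # map g = u/(1-u) onto (0, 1) so adaptive quadrature sees finite bounds
    def transformed(u: float) -> float:
        if u <= 0.0 or u >= 1.0:
            return 0.0
        g = u / (1 - u)
        return integrand(g) / (1 - u) ** 2

    val, err = integrate.quad(transformed, 0.0, 1.0, limit=300)
    if not math.isfinite(val) or val <= 0 or err > 1e-6 * max(val, 1e-12):
        raise RuntimeError(
            f"JZS integration did not converge (value={val!r}, abserr={err!r})"
        )
    return float(val)


# ---------------------------------------------------------------------------
# Holm correction


def holm(pvals) -> np.ndarray:
    """Step-down Holm adjustment with monotonicity enforcement, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-D")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


# ---------------------------------------------------------------------------
# correlation Bayes factor


def _log_r_kernel(rho: float, r: float, n: int) -> float:
    """rho-dependent part of the exact sampling density of Pearson's r."""
    h = special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2)
    return (
        (n - 1) / 2 * math.log1p(-rho * rho)
        - (n - 1.5) * math.log1p(-rho * r)
        + math.log(h)
    )


def correlation_bf(x, y, rscale: float = 1 / 3) -> tuple[float, float, float]:
    """Pearson r, two-sided p, and a default correlation Bayes factor.

    The alternative places a stretched-beta prior on the population
    correlation: rho = 2u - 1 with u ~ Beta(1/rscale, 1/rscale), so smaller
    ``rscale`` concentrates mass near zero ("medium" width 1/3 by default).
    BF10 is the ratio of the marginal likelihood of the observed r under
    this prior to its likelihood at rho = 0, by adaptive quadrature.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need two equal-length samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    tstat = r * math.sqrt((n - 2) / max(1 - r * r, 1e-300))
    p = float(2 * t_dist.sf(abs(tstat), n - 2))
    if 1 - r * r < 1e-12:
        # perfect correlation: the marginal likelihood ratio diverges
        return r, p, math.inf

    a = 1.0 / rscale
    log_k0 = _log_r_kernel(0.0, r, n)

    def integrand(rho: float) -> float:
        dens = beta_dist.pdf((rho + 1) / 2, a, a) / 2
        return math.exp(_log_r_kernel(rho, r, n) - log_k0) * dens

    bf10, err = integrate.quad(integrand, -1, 1, limit=200)
    if not math.isfinite(bf10) or bf10 <= 0:
        raise RuntimeError("correlation BF integration failed")
    return r, p, float(bf10)
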