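"""Maximum-likelihood fits and model selection for run/flight length samples.

Five candidate length distributions are fit on the common support
``[xmin, inf)`` (densities truncated and renormalized at xmin, so their
likelihoods are comparable):

===========================  =====================================================
model                        density on [xmin, inf)
===========================  =====================================================
lognormal(mu, sigma)         LN(x; mu, sigma) / S_LN(xmin; mu, sigma)
power_law(gamma)             (gamma - 1)/xmin * (x/xmin)^(-gamma)
truncated_power_law(g, lam)  x^(-g) exp(-lam x) / Z(g, lam, xmin)
stretched_exponential(l, b)  l b x^(b-1) exp(-l x^b) / exp(-l xmin^b)
exponential(lam)             lam exp(-lam (x - xmin))
===========================  =====================================================

Exponential and power-law estimates are the closed-form MLEs; the other three
are obtained numerically (multi-start Nelder-Mead from moment-based initial
values).  Candidates are compared by Akaike weights
w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2) with Delta_i = AIC_i - min AIC,
AIC = 2k - 2 loglik.  The module also provides empirical CCDFs (survival
functions), samplers for all five models, and the two-sample tests used to
compare length distributions between groups (two-sample Cramér-von Mises for
pooled length samples, Wilcoxon-Mann-Whitney for unpaired per-cell summaries
and the two-tailed paired t-test for matched cargo-bearing/free comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, special, stats

__all__ = [
    "MODELS",
    "ModelFit",
    "ModelComparison",
    "TestResult",
    "FitError",
    "ccdf",
    "fit_exponential",
    "fit_power_law",
    "fit_numeric",
    "fit_all",
    "akaike_weights",
    "sample_lengths",
    "cvm_two_sample",
    "group_test",
]

MODELS = (
    "lognormal",
    "power_law",
    "truncated_power_law",
    "stretched_exponential",
    "exponential",
)

_N_PARAMS = {
    "lognormal": 2,
    "power_law": 1,
    "truncated_power_law": 2,
    "stretched_exponential": 2,
    "exponential": 1,
}


class FitError(RuntimeError):
    """Raised when an MLE cannot be computed (degenerate sample or optimizer
    failure); carries the optimizer diagnostics in its message."""


@dataclass
class ModelFit:
    """One model's MLE on one length sample."""

    model: str
    params: dict
    xmin: float
    loglik: float
    n: int
    k: int = field(init=False)

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        self.k = _N_PARAMS[self.model]
        if not np.isfinite(self.loglik):
            raise FitError(f"{self.model}: non-finite log-likelihood")

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik


@dataclass
class ModelComparison:
    """Akaike-weight comparison of several fits on the same sample."""

    fits: dict
    weights: dict
    winner: str


def ccdf(values) -> tuple[np.ndarray, np.ndarray]:
    """Empirical complementary CDF (survival function).

    Returns the sorted values and P(X >= x) at each of them; ties share the
    same survival probability.  Non-increasing, starting at 1 and ending at
    (multiplicity of the maximum)/n.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    x = np.sort(values)
    n = x.size
    # P(X >= x_i) = (n - #{values strictly below x_i}) / n
    below = np.searchsorted(x, x, side="left")
    surv = (n - below) / n
    return x, surv


# ---------------------------------------------------------------------------
# log-likelihoods on [xmin, inf)


def _check_sample(values, xmin):
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    if np.any(values <= 0):
        raise ValueError("lengths must be positive")
    if xmin is None:
        xmin = float(np.min(values))
    if np.any(values < xmin - 1e-12):
        raise ValueError("all values must be >= xmin")
    return values, float(xmin)


def _loglik_lognormal(x, xmin, mu, sigma):
    if sigma <= 0:
        return -np.inf
    dist = stats.lognorm(s=sigma, scale=np.exp(mu))
    tail = dist.sf(xmin) if xmin > 0 else 1.0
    if tail <= 0:
        return -np.inf
    return float(np.sum(dist.logpdf(x)) - x.size * np.log(tail))


def _loglik_stretched_exponential(x, xmin, lam, beta):
    if lam <= 0 or beta <= 0:
        return -np.inf
    return float(
        np.sum(np.log(lam * beta) + (beta - 1.0) * np.log(x) - lam * x**beta)
        + x.size * lam * xmin**beta
    )


def _loglik_exponential(x, xmin, lam):
    if lam <= 0:
        return -np.inf
    return float(x.size * np.log(lam) - lam * np.sum(x - xmin))


def _loglik_power_law(x, xmin, gamma):
    if gamma <= 1 or xmin <= 0:
        return -np.inf
    return float(
        x.size * (np.log(gamma - 1.0) - np.log(xmin)) - gamma * np.sum(np.log(x / xmin))
    )


def _upper_gamma(s: float, z: float) -> float:
    """Upper incomplete gamma Gamma(s, z) for real s (including s <= 0), z > 0.

    For s <= 0 scipy's regularized gammaincc is unavailable; the recurrence
    Gamma(s, z) = (Gamma(s+1, z) - z^s e^-z) / s continues it downward.
    """
    if z <= 0:
        return np.inf
    m = int(np.ceil(max(0.0, 1.0 - s)))
    s_top = s + m
    val = special.gammaincc(s_top, z) * special.gamma(s_top) if s_top > 0 else special.exp1(z)
    for k in range(m):
        sk = s_top - 1 - k
        val = (val - z**sk * np.exp(-z)) / sk if sk != 0 else special.exp1(z)
    return float(val)


def _log_norm_tpl(gamma, lam, xmin):
    """log of Z = int_xmin^inf x^-gamma e^-lam x dx = lam^(gamma-1) Gamma(1-gamma, lam*xmin)."""
    if lam <= 0 or xmin <= 0:
        return np.inf
    val = _upper_gamma(1.0 - gamma, lam * xmin)
    if np.isfinite(val) and val > 0:
        return float((gamma - 1.0) * np.log(lam) + np.log(val))

    # recurrence can cancel catastrophically for large lam*xmin; fall back to
    # direct integration of the well-scaled integrand g(u) = (x/xmin)^-g e^-lam(x-xmin)
    def g(u):
        return np.exp(-gamma * np.log(u) - lam * xmin * (u - 1.0))

    val, _ = integrate.quad(g, 1.0, np.inf, limit=200)
    if not np.isfinite(val) or val <= 0:
        return np.inf
    return float(np.log(val) + (1.0 - gamma) * np.log(xmin) - lam * xmin)


def _loglik_truncated_power_law(x, xmin, gamma, lam):
    lz = _log_norm_tpl(gamma, lam, xmin)
    if not np.isfinite(lz):
        return -np.inf
    return float(-gamma * np.sum(np.log(x)) - lam * np.sum(x) - x.size * lz)


# ---------------------------------------------------------------------------
# fits


def fit_exponential(values, xmin: float | None = None) -> ModelFit:
    """Closed-form MLE of the shifted exponential: lambda = 1/mean(x - xmin)."""
    x, xmin = _check_sample(values, xmin)
    m = float(np.mean(x - xmin))
    if m <= 0:
        raise FitError("exponential: sample mean equals xmin (zero-variance sample)")
    lam = 1.0 / m
    return ModelFit(
        model="exponential",
        params={"lambda": lam},
        xmin=xmin,
        loglik=_loglik_exponential(x, xmin, lam),
        n=x.size,
    )


def fit_power_law(values, xmin: float | None = None) -> ModelFit:
    """Closed-form (Hill) MLE of the power law: gamma = 1 + n / sum ln(x/xmin)."""
    x, xmin = _check_sample(values, xmin)
    if xmin <= 0:
        raise ValueError("power law requires xmin > 0")
    s = float(np.sum(np.log(x / xmin)))
    if s <= 0:
        raise FitError("power law: all values at xmin; exponent estimate diverges")
    gamma = 1.0 + x.size / s
    return ModelFit(
        model="power_law",
        params={"gamma": gamma},
        xmin=xmin,
        loglik=_loglik_power_law(x, xmin, gamma),
        n=x.size,
    )


def _numeric_mle(nll, starts, names):
    best = None
    diagnostics = []
    for s0 in starts:
        res = optimize.minimize(
            nll, np.asarray(s0, dtype=float), method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000, "maxfev": 10000},
        )
        diagnostics.append(f"start={s0} -> success={res.success} fun={res.fun:.6g}")
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("numeric MLE failed: " + "; ".join(diagnostics))
    return dict(zip(names, best.x)), -float(best.fun)


def fit_numeric(values, model: str, xmin: float | None = None, n_min: int = 10) -> ModelFit:
    """Numerical MLE for lognormal, stretched-exponential or truncated power law.

    Optimization is multi-start Nelder-Mead from moment-based initial values;
    rate/scale parameters are optimized on a log scale to stay positive.
    """
    x, xmin = _check_sample(values, xmin)
    if x.size < n_min:
        raise ValueError(f"need at least {n_min} values for a numeric fit")
    logx = np.log(x)

    if model == "lognormal":
        mu0, sg0 = float(np.mean(logx)), float(np.std(logx))
        sg0 = max(sg0, 1e-3)

        def nll(p):
            return -_loglik_lognormal(x, xmin, p[0], np.exp(p[1]))

        starts = [(mu0, np.log(sg0)), (mu0 - 0.5, np.log(sg0 * 1.5))]
        params, ll = _numeric_mle(nll, starts, ("mu", "log_sigma"))
        out = {"mu": params["mu"], "sigma": float(np.exp(params["log_sigma"]))}

    elif model == "stretched_exponential":
        lam0 = 1.0 / float(np.mean(x))

        def nll(p):
            return -_loglik_stretched_exponential(x, xmin, np.exp(p[0]), np.exp(p[1]))

        starts = [(np.log(lam0), 0.0), (np.log(lam0), np.log(0.5))]
        params, ll = _numeric_mle(nll, starts, ("log_lambda", "log_beta"))
        out = {"lambda": float(np.exp(params["log_lambda"])),
               "beta": float(np.exp(params["log_beta"]))}

    elif model == "truncated_power_law":
        try:
            g0 = min(fit_power_law(x, xmin).params["gamma"], 3.0)
        except FitError:
            g0 = 1.5
        lam0 = 1.0 / float(np.mean(x))

        def nll(p):
            return -_loglik_truncated_power_law(x, xmin, p[0], np.exp(p[1]))

        starts = [(g0, np.log(lam0)), (1.2, np.log(lam0)), (0.5, np.log(lam0 * 2.0))]
        params, ll = _numeric_mle(nll, starts, ("gamma", "log_lambda"))
        out = {"gamma": params["gamma"], "lambda": float(np.exp(params["log_lambda"]))}

    else:
        raise ValueError(
            f"model {model!r} has a closed-form MLE or is unknown; "
            "use fit_exponential/fit_power_law for the analytic cases"
        )

    return ModelFit(model=model, params=out, xmin=xmin, loglik=ll, n=x.size)


def fit_all(values, xmin: float | None = None) -> dict:
    """Fit all five candidate models on a common xmin (default: sample minimum)."""
    x, xmin = _check_sample(values, xmin)
    fits = {}
    fits["lognormal"] = fit_numeric(x, "lognormal", xmin)
    fits["power_law"] = fit_power_law(x, xmin)
    fits["truncated_power_law"] = fit_numeric(x, "truncated_power_law", xmin)
    fits["stretched_exponential"] = fit_numeric(x, "stretched_exponential", xmin)
    fits["exponential"] = fit_exponential(x, xmin)
    return fits


def akaike_weights(fits) -> ModelComparison:
    """Akaike weights over >= 2 fits of the same sample and xmin."""
    if isinstance(fits, dict):
        fits = list(fits.values())
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    n0, x0 = fits[0].n, fits[0].xmin
    for f in fits[1:]:
        if f.n != n0 or not np.isclose(f.xmin, x0):
            raise ValueError("fits were not computed on the same sample / xmin")
    aics = np.array([f.aic for f in fits])
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    weights = {f.model: float(wi) for f, wi in zip(fits, w)}
    winner = max(weights, key=weights.get)
    return ModelComparison(fits={f.model: f for f in fits}, weights=weights, winner=winner)


# ---------------------------------------------------------------------------
# samplers (inverse-CDF on [xmin, inf); rejection for the truncated power law)


def sample_lengths(model: str, params: dict, n: int, rng, xmin: float = 0.0) -> np.ndarray:
    """Draw n lengths from one of the five models, truncated at xmin."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    u = rng.uniform(size=n)
    if model == "lognormal":
        dist = stats.lognorm(s=params["sigma"], scale=np.exp(params["mu"]))
        if xmin <= 0:
            return dist.ppf(u)
        f0 = dist.cdf(xmin)
        return dist.ppf(f0 + u * (1.0 - f0))
    if model == "exponential":
        return xmin - np.log1p(-u) / params["lambda"]
    if model == "stretched_exponential":
        lam, beta = params["lambda"], params["beta"]
        return ((lam * xmin**beta - np.log1p(-u)) / lam) ** (1.0 / beta)
    if model == "power_law":
        if xmin <= 0:
            raise ValueError("power law requires xmin > 0")
        return xmin * (1.0 - u) ** (-1.0 / (params["gamma"] - 1.0))
    if model == "truncated_power_law":
        if xmin <= 0:
            raise ValueError("truncated power law requires xmin > 0")
        gamma, lam = params["gamma"], params["lambda"]
        # rejection from the pure power law when gamma > 1, else from the
        # shifted exponential, with the complementary factor as acceptance
        out = np.empty(n)
        got = 0
        while got < n:
            m = max(n - got, 1000)
            if gamma > 1.0:
                cand = sample_lengths("power_law", {"gamma": gamma}, m, rng, xmin)
                acc = rng.uniform(size=m) < np.exp(-lam * (cand - xmin))
            else:
                cand = sample_lengths("exponential", {"lambda": lam}, m, rng, xmin)
                acc = rng.uniform(size=m) < (cand / xmin) ** (-gamma)
            cand = cand[acc]
            take = min(cand.size, n - got)
            out[got : got + take] = cand[:take]
            got += take
        return out
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# two-sample tests


@dataclass
class TestResult:
    name: str
    statistic: float
    pvalue: float


def cvm_two_sample(a, b, method: str = "asymptotic", n_perm: int = 2000, rng=None) -> TestResult:
    """Two-sample Cramér-von Mises test (symmetric, rank-based).

    ``method='asymptotic'`` uses the large-sample null; ``'permutation'``
    recomputes the statistic under ``n_perm`` pooled shuffles (for small n).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need n >= 2")
    res = stats.cramervonmises_2samp(a, b, method="asymptotic")
    stat = float(res.statistic)
    if method == "asymptotic":
        p = float(res.pvalue)
    elif method == "permutation":
        rng = np.random.default_rng(rng)
        pool = np.concatenate([a, b])
        count = 0
        for _ in range(n_perm):
            rng.shuffle(pool)
            s = stats.cramervonmises_2samp(pool[: a.size], pool[a.size :],
                                           method="asymptotic").statistic
            if s >= stat:
                count += 1
        p = (count + 1) / (n_perm + 1)
    else:
        raise ValueError("method must be 'asymptotic' or 'permutation'")
    return TestResult(name="cramer_von_mises_2s", statistic=stat, pvalue=float(np.clip(p, 0, 1)))


def group_test(a, b, paired: bool = False, ids_a=None, ids_b=None) -> TestResult:
    """Between-group test on per-cell summaries.

    Unpaired comparisons use the Wilcoxon-Mann-Whitney test; matched
    comparisons (e.g. cargo-bearing vs cargo-free tracks of the same cells)
    use the two-tailed paired Student t-test and require matched cell ids.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal-length samples")
        if ids_a is not None or ids_b is not None:
            if ids_a is None or ids_b is None or list(ids_a) != list(ids_b):
                raise ValueError("paired test requires matched cell ids")
        diff = a - b
        if np.allclose(diff, 0.0):
            return TestResult(name="paired_t_two_tailed", statistic=0.0, pvalue=1.0)
        res = stats.ttest_rel(a, b)
        return TestResult(
            name="paired_t_two_tailed", statistic=float(res.statistic), pvalue=float(res.pvalue)
        )
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return TestResult(
        name="wilcoxon_mann_whitney", statistic=float(res.statistic), pvalue=float(res.pvalue)
    )
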