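"""Trap-scale catch models: counts vs. urbanization with landscape random effects.

Per-trap species richness or total abundance y_ij (trap j in landscape
i) is modelled as a count GLMM with a log link,

    y_ij ~ Poisson(mu_ij)  or  NegBin(mu_ij, theta)
    log mu_ij = alpha + beta * urbanization_index_ij + u_i
    u_i ~ Normal(0, sigma_u^2)

Richness models default to the Poisson family and abundance models to
the negative binomial (counts of pooled individuals are strongly
overdispersed).  The marginal likelihood integrates the landscape
random intercept by Gauss-Hermite quadrature — exact enough for a
one-dimensional random effect — and is maximised with L-BFGS-B.
Inference on the urbanization effect is a likelihood-ratio test against
the intercept + random-intercept null (df = 1), the protocol used for
all reported chi-square statistics; Wald standard errors come from a
finite-difference Hessian at the optimum.

The negative binomial uses the (mu, theta) parameterisation with
Var(y) = mu + mu^2/theta; theta is profiled on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .data_model import AbundanceMatrix, IncidenceMatrix

Family = Literal["poisson", "negative_binomial"]

_DEFAULT_FAMILY = {"species_richness": "poisson", "abundance": "negative_binomial"}


@dataclass(frozen=True)
class CatchModelSpec:
    """What to model: response, community subset, and count family."""

    response: Literal["species_richness", "abundance"]
    subset: Literal["native", "non_native", "all"] = "all"
    family: Family | None = None

    def resolved_family(self) -> Family:
        return self.family or _DEFAULT_FAMILY[self.response]


@dataclass
class CatchModelFit:
    slope: float
    slope_se: float
    intercept: float
    sigma_u: float
    dispersion: float | None  # NB theta; None for poisson
    loglik: float
    null_loglik: float
    lrt_chi2: float
    lrt_p: float
    converged: bool
    n_obs: int
    n_groups: int
    family: str
    overdispersion_ratio: float  # Pearson chi2 / residual df at the optimum
    message: str = ""

    @property
    def slope_ci95(self) -> tuple[float, float]:
        half = 1.959963984540054 * self.slope_se
        return (self.slope - half, self.slope + half)


def trap_responses(
    matrices: dict[str, tuple[AbundanceMatrix, IncidenceMatrix]]
) -> pd.DataFrame:
    """Per-trap richness and abundance from per-landscape matrix pairs.

    Zero-catch traps yield (0, 0): they stay in the model as genuine
    observations of an empty sampling unit.
    """
    rows = []
    for lid, (ab, inc) in matrices.items():
        richness = inc.values.sum(axis=0) if inc.n_species else np.zeros(inc.n_traps, int)
        abundance = ab.values.sum(axis=0) if ab.species_ids else np.zeros(len(ab.trap_ids), int)
        for j, tid in enumerate(inc.trap_ids):
            rows.append(
                {
                    "trap_id": tid,
                    "landscape_id": lid,
                    "richness": int(richness[j]),
                    "abundance": int(abundance[j]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# marginal likelihood


def _count_logpmf(y: np.ndarray, mu: np.ndarray, family: str, theta: float) -> np.ndarray:
    if family == "poisson":
        return y * np.log(mu) - mu - special.gammaln(y + 1)
    # negative binomial, mean mu, size theta
    return (
        special.gammaln(y + theta)
        - special.gammaln(theta)
        - special.gammaln(y + 1)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    )


class _MixedCountModel:
    """Marginal log-likelihood of the random-intercept count model.

    The one-dimensional random-effect integral per group is evaluated by
    adaptive Gauss-Hermite quadrature: nodes are recentred at each
    group's posterior mode and rescaled by the Laplace curvature, so a
    modest node count stays accurate even when the conditional posterior
    is much narrower than the random-effect prior.
    """

    def __init__(
        self,
        y: np.ndarray,
        x: np.ndarray,
        groups: np.ndarray,
        family: Family,
        n_quad: int = 15,
    ):
        self.y = np.asarray(y, dtype=np.float64)
        self.x = np.asarray(x, dtype=np.float64)
        if (self.y < 0).any() or not np.allclose(self.y, np.round(self.y)):
            raise ValueError("responses must be nonnegative integers")
        codes, uniques = pd.factorize(np.asarray(groups))
        self.group_idx = codes
        self.n_groups = len(uniques)
        self.family = family
        nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
        self.z = nodes
        self.logw = np.log(weights)

    def _group_sum(self, values: np.ndarray) -> np.ndarray:
        out = np.zeros(self.n_groups)
        np.add.at(out, self.group_idx, values)
        return out

    def _posterior_mode(
        self, eta: np.ndarray, sigma: float, theta: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """Newton mode and curvature of each group's joint log-density in u."""
        u = np.zeros(self.n_groups)
        inv_var = 1.0 / sigma**2
        curv = np.full(self.n_groups, -inv_var)
        for _ in range(60):
            mu = np.exp(np.clip(eta + u[self.group_idx], -700, 50))
            if self.family == "poisson":
                d1 = self.y - mu
                d2 = -mu
            else:
                d1 = (self.y - mu) * theta / (theta + mu)
                d2 = -theta * mu * (theta + self.y) / (theta + mu) ** 2
            grad = self._group_sum(d1) - u * inv_var
            curv = self._group_sum(d2) - inv_var
            step = np.clip(grad / curv, -2.0, 2.0)
            u = u - step
            if np.max(np.abs(step)) < 1e-10:
                break
        return u, curv

    def loglik(self, a: float, b: float, sigma: float, theta: float) -> float:
        eta = a + b * self.x  # (n,)
        if sigma < 1e-8:  # degenerate: no random effect
            mu = np.exp(np.clip(eta, -700, 50))
            return float(_count_logpmf(self.y, mu, self.family, theta).sum())
        mode, curv = self._posterior_mode(eta, sigma, theta)
        scale = 1.0 / np.sqrt(-curv)  # (G,)
        # (G, q) random-effect evaluation points
        upts = mode[:, None] + np.sqrt(2.0) * scale[:, None] * self.z[None, :]
        lp = _count_logpmf(
            self.y[:, None],
            np.exp(np.clip(eta[:, None] + upts[self.group_idx, :], -700, 50)),
            self.family,
            theta,
        )
        group_lp = np.zeros((self.n_groups, lp.shape[1]))
        np.add.at(group_lp, self.group_idx, lp)
        log_prior = -0.5 * np.log(2 * np.pi) - np.log(sigma) - 0.5 * (upts / sigma) ** 2
        h = group_lp + log_prior + self.z[None, :] ** 2 + self.logw[None, :]
        per_group = (
            0.5 * np.log(2.0) + np.log(scale) + special.logsumexp(h, axis=1)
        )
        return float(per_group.sum())


def _fit_mixed_count(
    y: np.ndarray,
    x: np.ndarray,
    groups: np.ndarray,
    family: Family,
    include_slope: bool = True,
    n_quad: int = 15,
    force_sigma_zero: bool = False,
) -> dict:
    """Maximise the marginal likelihood; returns parameters and loglik.

    The covariate is centred and scaled internally (better conditioning
    for the quasi-Newton line search); reported intercept/slope are on
    the original scale, while ``params``/``nll`` stay in fitting space.
    """
    x = np.asarray(x, dtype=np.float64)
    x_loc = float(np.mean(x))
    x_scale = float(np.std(x)) or 1.0
    xs = (x - x_loc) / x_scale
    model = _MixedCountModel(y, xs, groups, family, n_quad=n_quad)
    ybar = max(float(np.mean(y)), 0.1)
    a0 = np.log(ybar)
    theta_free = family == "negative_binomial"

    def unpack(p: np.ndarray) -> tuple[float, float, float, float]:
        a = p[0]
        b = p[1] if include_slope else 0.0
        k = 2 if include_slope else 1
        sigma = 0.0 if force_sigma_zero else np.exp(p[k])
        if not force_sigma_zero:
            k += 1
        theta = np.exp(p[k]) if theta_free else 1.0
        return a, b, sigma, theta

    def nll(p: np.ndarray) -> float:
        a, b, sigma, theta = unpack(p)
        with np.errstate(over="ignore"):
            ll = model.loglik(a, b, sigma, theta)
        return -ll if np.isfinite(ll) else 1e12

    p0 = [a0] + ([0.0] if include_slope else [])
    bounds: list[tuple[float, float]] = [(-30, 30)] + ([(-5, 5)] if include_slope else [])
    if not force_sigma_zero:
        p0.append(np.log(0.3))
        bounds.append((-7.0, 3.0))
    if theta_free:
        p0.append(0.0)
        bounds.append((-7.0, 7.0))
    res = optimize.minimize(
        nll, np.asarray(p0), method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-11},
    )
    if not res.success:  # polish with a derivative-free pass from the BFGS point
        res2 = optimize.minimize(nll, res.x, method="Nelder-Mead",
                                 options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        if res2.fun <= res.fun:
            res = res2
    a, b, sigma, theta = unpack(res.x)
    return {
        "params": res.x,
        "a": a - b * x_loc / x_scale,
        "b": b / x_scale,
        "x_scale": x_scale,
        "sigma": sigma,
        "theta": theta if theta_free else None,
        "loglik": -float(res.fun),
        "converged": bool(res.success),
        "message": str(res.message),
        "nll": nll,
        "model": model,
    }


def _slope_se(nll, p_opt: np.ndarray, slope_pos: int = 1) -> float:
    """Wald SE of the slope from a central finite-difference Hessian."""
    n = p_opt.size
    h = 1e-4 * np.maximum(1.0, np.abs(p_opt))
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            pp = p_opt.copy(); pp[i] += h[i]; pp[j] += h[j]; fpp = nll(pp)
            pm = p_opt.copy(); pm[i] += h[i]; pm[j] -= h[j]; fpm = nll(pm)
            mp = p_opt.copy(); mp[i] -= h[i]; mp[j] += h[j]; fmp = nll(mp)
            mm = p_opt.copy(); mm[i] -= h[i]; mm[j] -= h[j]; fmm = nll(mm)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        var = cov[slope_pos, slope_pos]
        return float(np.sqrt(var)) if var > 0 else np.nan
    except np.linalg.LinAlgError:
        return np.nan


def _pearson_overdispersion(
    y: np.ndarray, x: np.ndarray, groups: np.ndarray, fit: dict, family: str
) -> float:
    """Pearson chi2 / df with group means plugged in (conditional residuals)."""
    # empirical-Bayes-free shortcut: use marginal mean exp(a + b x + sigma^2/2)
    mu = np.exp(fit["a"] + fit["b"] * x + 0.5 * fit["sigma"] ** 2)
    theta = fit["theta"]
    var = mu + (mu**2 / theta if theta else 0.0)
    df = max(y.size - (3 if theta is None else 4), 1)
    return float(np.sum((y - mu) ** 2 / var) / df)


def fit_catch_glmm(
    spec: CatchModelSpec,
    data: pd.DataFrame,
    n_quad: int = 15,
) -> CatchModelFit:
    """Fit the catch model described by ``spec`` on a per-trap table.

    ``data`` needs columns ``urbanization_index``, ``landscape_id`` and
    the response (``richness`` or ``abundance``).  Non-convergence is
    reported in the fit's flags, never silently.
    """
    col = "richness" if spec.response == "species_richness" else "abundance"
    if col not in data.columns:
        raise ValueError(f"data lacks a {col!r} column")
    y = data[col].to_numpy()
    x = data["urbanization_index"].to_numpy(dtype=float)
    groups = data["landscape_id"].to_numpy()
    family = spec.resolved_family()

    full = _fit_mixed_count(y, x, groups, family, include_slope=True, n_quad=n_quad)
    null = _fit_mixed_count(y, x, groups, family, include_slope=False, n_quad=n_quad)
    chi2 = max(0.0, 2.0 * (full["loglik"] - null["loglik"]))
    se = _slope_se(full["nll"], full["params"], slope_pos=1) / full["x_scale"]
    return CatchModelFit(
        slope=full["b"],
        slope_se=se,
        intercept=full["a"],
        sigma_u=full["sigma"],
        dispersion=full["theta"],
        loglik=full["loglik"],
        null_loglik=null["loglik"],
        lrt_chi2=chi2,
        lrt_p=float(stats.chi2.sf(chi2, df=1)),
        converged=full["converged"] and null["converged"],
        n_obs=int(y.size),
        n_groups=int(pd.unique(groups).size),
        family=family,
        overdispersion_ratio=_pearson_overdispersion(y, x, groups, full, family),
        message="; ".join(m for m in (full["message"], null["message"]) if m),
    )


def simulate_from_model(
    x: np.ndarray,
    groups: np.ndarray,
    intercept: float,
    slope: float,
    sigma_u: float,
    family: Family = "poisson",
    theta: float = 1.0,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Draw per-trap counts from the random-intercept count model.

    The simulation side of the calibration harness: data generated here
    and refit with :func:`fit_catch_glmm` should recover ``slope`` with
    nominal Wald coverage, and under ``slope = 0`` the likelihood-ratio
    test should reject at its nominal level.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    x = np.asarray(x, dtype=float)
    codes, uniques = pd.factorize(np.asarray(groups))
    u = rng.normal(0.0, sigma_u, size=len(uniques))
    mu = np.exp(intercept + slope * x + u[codes])
    if family == "poisson":
        return rng.poisson(mu)
    lam = rng.gamma(shape=theta, scale=mu / theta)
    return rng.poisson(lam)


def fit_fixed_effects_glm(
    y: np.ndarray, x: np.ndarray, family: Family = "poisson"
) -> tuple[float, float]:
    """Plain (no random effect) count GLM fit of the same mean model.

    Returns (intercept, slope).  Used to cross-check that forcing the
    random-intercept variance to zero collapses the mixed model onto
    ordinary regression.
    """
    groups = np.zeros(len(np.asarray(y)), dtype=int)
    fit = _fit_mixed_count(
        np.asarray(y), np.asarray(x), groups, family,
        include_slope=True, force_sigma_zero=True,
    )
    return fit["a"], fit["b"]
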