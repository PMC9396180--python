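"""Model configuration, likelihoods, concentration, and maximum-likelihood fitting.

For Poisson counts the site totals ``N_i`` are nuisance parameters that can
be concentrated out of the likelihood analytically: at any value of the
seasonal-curve parameters the conditional maximiser is the scaled site total

    N_hat_i = sum_j y_ij / sum_j a_ij        (observed occasions only),

so the optimiser works on the concentrated (profile) log-likelihood over the
curve parameters alone.  For negative-binomial and zero-inflated-Poisson
counts no closed form exists, and fitting alternates between maximising over
the link-scale vector theta with the ``N_i`` held fixed and updating each
``N_i`` by a one-dimensional search with theta held fixed, until the joint
log-likelihood stops improving.

AIC counts only the theta coefficients, never the concentrated site totals.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import betaln, gammaln, xlogy
from statsmodels.tools.numdiff import approx_hess

from .curves import _emergence_matrix, _mixture_matrix, _stopover_recursion, spline_basis
from .data_model import SurveyData
from .links import ConfigurationError, FormulaSpec, LinkParams, ParameterMapper, SiteParams

__all__ = [
    "ModelConfig", "FittedModel", "ConvergenceError",
    "concentrate_site_total", "poisson_concentrated_loglik",
    "nb_loglik", "zip_loglik", "fit_gai", "aic", "summary",
]

log = logging.getLogger(__name__)

_BIG = 1e12  # optimiser-safe stand-in for an infinite penalty


class ConvergenceError(RuntimeError):
    """The optimiser failed to converge to a usable optimum."""


@dataclass
class ModelConfig:
    """Configuration of one generalized-abundance-index model.

    Parameters
    ----------
    family
        ``"mixture"``, ``"stopover"`` or ``"spline"`` seasonal curve.
    B
        Number of broods (mixture/stopover); ignored for splines.
    distribution
        Count distribution: ``"poisson"``, ``"nb"`` (negative binomial with
        variance ``lambda (1 + lambda / r)``) or ``"zip"`` (zero-inflated
        Poisson with extra-zero probability psi).
    sigma_mode
        ``"shared"`` for one flight-period standard deviation across broods,
        ``"per_brood"`` for individual sigmas.
    formulas
        Covariate formulas for mu / sigma / w linear predictors.
    spline_df, spline_degree
        B-spline basis dimension and degree for the spline family.
    normalise_mixture
        Rescale mixture ordinates to sum to one over the occasions (the
        spline convention); off by default, where they are raw densities.
    beta_method
        How emergence proportions handle the season edges (stopover only):
        ``"tail"`` absorbs the Normal tails into the first and last visits,
        ``"rescale"`` divides interval masses by their total.
    fix_r, fix_psi
        Freeze the dispersion / zero-inflation parameter at a constant
        instead of estimating it (it then leaves theta and the AIC count).
    standardize
        Centre and scale covariates internally (default).
    maxiter, tol, n_starts, seed
        Optimiser budget, outer-loop tolerance for the iterative NB/ZIP
        scheme, number of random multi-starts, and the seed that makes the
        multi-start perturbations reproducible.
    """

    family: str = "mixture"
    B: int = 1
    distribution: str = "poisson"
    sigma_mode: str = "shared"
    formulas: FormulaSpec | None = None
    spline_df: int = 10
    spline_degree: int = 3
    normalise_mixture: bool = False
    beta_method: str = "tail"
    fix_r: float | None = None
    fix_psi: float | None = None
    standardize: bool = True
    maxiter: int = 1000
    tol: float = 1e-6
    n_starts: int = 1
    seed: int | None = None

    def __post_init__(self):
        if self.family not in ("mixture", "stopover", "spline"):
            raise ConfigurationError(f"unknown curve family {self.family!r}")
        if self.distribution not in ("poisson", "nb", "zip"):
            raise ConfigurationError(f"unknown count distribution {self.distribution!r}")
        if self.sigma_mode not in ("shared", "per_brood"):
            raise ConfigurationError(f"unknown sigma_mode {self.sigma_mode!r}")
        if self.B < 1:
            raise ConfigurationError("B must be at least 1")
        if self.family == "spline":
            if self.formulas is not None:
                raise ConfigurationError("the spline family does not take covariate formulas")
            if self.spline_df < self.spline_degree + 1:
                raise ConfigurationError("spline_df must be at least degree + 1")
        if isinstance(self.formulas, dict):
            self.formulas = FormulaSpec(**self.formulas)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


# ---------------------------------------------------------------------------
# curve matrix

def curve_matrix(theta, mapper: ParameterMapper, config: ModelConfig,
                 t: np.ndarray, n_sites: int) -> np.ndarray:
    """Fitted seasonal pattern ``a_ij`` (S x T) at a link-scale vector."""
    sp = mapper.to_natural(theta)
    return _curve_from_site_params(sp, config, t, n_sites)


def _curve_from_site_params(sp: SiteParams, config: ModelConfig,
                            t: np.ndarray, n_sites: int) -> np.ndarray:
    if config.family == "spline":
        X = spline_basis(t, config.spline_df, config.spline_degree)
        s = X @ sp.spline_coefs
        s = s - s.max()
        e = np.exp(s)
        a = e / e.sum()
        return np.repeat(a[None, :], n_sites, axis=0)
    mu, sigma, w = sp.mu, sp.sigma, sp.w
    if mu.shape[0] == 1 and n_sites > 1:
        mu = np.repeat(mu, n_sites, axis=0)
        sigma = np.repeat(sigma, n_sites, axis=0)
        w = np.repeat(w, n_sites, axis=0)
    if config.family == "mixture":
        a = _mixture_matrix(t, mu, sigma, w)
        if config.normalise_mixture:
            a = a / a.sum(axis=1, keepdims=True)
        return a
    beta = _emergence_matrix(t, mu, sigma, w, config.beta_method)
    return _stopover_recursion(beta, sp.phi)


# ---------------------------------------------------------------------------
# concentration and likelihood kernels

def concentrate_site_total(y, a) -> float:
    """Conditional ML site total ``sum y / sum a`` over observed occasions."""
    y = np.asarray(y, dtype=float)
    a = np.asarray(a, dtype=float)
    obs = ~np.isnan(y)
    if not obs.any():
        raise ValueError("cannot concentrate a site with no observed occasions")
    asum = a[obs].sum()
    if asum <= 0:
        raise ValueError("curve mass over observed occasions is zero")
    return float(y[obs].sum() / asum)


def _concentrate_all(counts: np.ndarray, a: np.ndarray) -> np.ndarray:
    obs = ~np.isnan(counts)
    ysum = np.where(obs, counts, 0.0).sum(axis=1)
    asum = np.where(obs, a, 0.0).sum(axis=1)
    if np.any(asum <= 0):
        raise ValueError("curve mass over observed occasions is zero for some site")
    return ysum / asum


def _poisson_terms(y, lam):
    return xlogy(y, lam) - lam - gammaln(y + 1.0)


def _nb_terms(y, lam, r):
    # mean lam, variance lam (1 + lam / r); Poisson recovered as r -> inf.
    # The binomial coefficient is written via betaln (gammaln(y+r) - gammaln(r)
    # cancels catastrophically for huge r) and the r log(r / (r+lam)) factor
    # via log1p, so the Poisson limit is numerically clean.
    lr = lam + r
    comb = np.where(y > 0, -betaln(r, y + 1.0) - np.log(y + r), 0.0)
    return comb + r * np.log1p(-lam / lr) + xlogy(y, lam) - xlogy(y, lr)


def _zip_terms(y, lam, psi):
    pois = _poisson_terms(y, lam)
    with np.errstate(divide="ignore"):
        zero = np.log(psi + (1.0 - psi) * np.exp(-lam))
    return np.where(y == 0, zero, np.log1p(-psi) + pois)


def _masked_total(terms: np.ndarray, obs: np.ndarray) -> float:
    total = terms[obs].sum()
    return float(total) if np.isfinite(total) else -np.inf


def poisson_concentrated_loglik(theta, data: SurveyData, config: ModelConfig,
                                mapper: ParameterMapper | None = None) -> float:
    """Profile Poisson log-likelihood with site totals concentrated out."""
    mapper = mapper or ParameterMapper(config, data.covariates)
    th = theta.theta if isinstance(theta, LinkParams) else np.asarray(theta, dtype=float)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        a = curve_matrix(th, mapper, config, data.occasions, data.S)
        if not np.all(np.isfinite(a)) or np.any(a < 0):
            return -np.inf
        obs = data.observed
        ysum = np.where(obs, np.nan_to_num(data.counts), 0.0).sum(axis=1)
        asum = np.where(obs, a, 0.0).sum(axis=1)
        if np.any((asum <= 0) & (ysum > 0)):
            return -np.inf  # degenerate theta: no curve mass where counts exist
        N = np.divide(ysum, asum, out=np.zeros_like(ysum), where=asum > 0)
        lam = N[:, None] * a
        terms = _poisson_terms(np.nan_to_num(data.counts), lam)
    return _masked_total(terms, data.observed)


def _dist_loglik(theta, N, data, config, mapper, kind: str) -> float:
    th = theta.theta if isinstance(theta, LinkParams) else np.asarray(theta, dtype=float)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        sp = mapper.to_natural(th)
        a = _curve_from_site_params(sp, config, data.occasions, data.S)
        if not np.all(np.isfinite(a)) or np.any(a < 0):
            return -np.inf
        lam = np.asarray(N, dtype=float)[:, None] * a
        y = np.nan_to_num(data.counts)
        if kind == "nb":
            r = sp.r
            if r is None or r <= 0 or not np.isfinite(r):
                return -np.inf
            terms = _nb_terms(y, lam, r)
        elif kind == "zip":
            psi = sp.psi
            if psi is None or not (0.0 <= psi < 1.0):
                return -np.inf
            terms = _zip_terms(y, lam, psi)
        else:
            terms = _poisson_terms(y, lam)
    return _masked_total(terms, data.observed)


def nb_loglik(theta, N, data: SurveyData, config: ModelConfig,
              mapper: ParameterMapper | None = None) -> float:
    """Negative-binomial log-likelihood at fixed site totals ``N``."""
    mapper = mapper or ParameterMapper(config, data.covariates)
    return _dist_loglik(theta, N, data, config, mapper, "nb")


def zip_loglik(theta, N, data: SurveyData, config: ModelConfig,
               mapper: ParameterMapper | None = None) -> float:
    """Zero-inflated-Poisson log-likelihood at fixed site totals ``N``."""
    mapper = mapper or ParameterMapper(config, data.covariates)
    return _dist_loglik(theta, N, data, config, mapper, "zip")


# ---------------------------------------------------------------------------
# fitted model container

@dataclass
class FittedModel:
    """Result of :func:`fit_gai`."""

    config: ModelConfig
    mapper: ParameterMapper
    theta_hat: np.ndarray
    loglik: float
    site_totals: np.ndarray
    a_matrix: np.ndarray
    vcov: np.ndarray | None
    converged: bool
    diagnostics: dict = field(default_factory=dict)
    data: SurveyData | None = None

    @property
    def n_params(self) -> int:
        return self.theta_hat.size

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def param_names(self) -> list[str]:
        return self.mapper.param_names

    @property
    def se(self) -> np.ndarray | None:
        if self.vcov is None:
            return None
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))

    def fitted_lambda(self) -> np.ndarray:
        """Expected count matrix ``N_hat_i * a_ij``."""
        return self.site_totals[:, None] * self.a_matrix

    def to_json(self, path=None) -> str:
        doc = {
            "config": self.config.to_dict(),
            "param_names": self.param_names,
            "theta_hat": self.theta_hat.tolist(),
            "vcov": None if self.vcov is None else self.vcov.tolist(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "aic": self.aic,
            "site_totals": self.site_totals.tolist(),
            "converged": self.converged,
            "diagnostics": self.diagnostics,
        }
        text = json.dumps(doc, indent=2,
                          default=lambda o: o.item() if hasattr(o, "item") else str(o))
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source, data: SurveyData) -> "FittedModel":
        """Rebuild a fit from its JSON document plus the survey it was fit to."""
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        cfg_d = doc["config"]
        if cfg_d.get("formulas"):
            cfg_d["formulas"] = FormulaSpec(**cfg_d["formulas"])
        config = ModelConfig(**cfg_d)
        mapper = ParameterMapper(config, data.covariates)
        theta = np.asarray(doc["theta_hat"], dtype=float)
        a = curve_matrix(theta, mapper, config, data.occasions, data.S)
        return cls(
            config=config, mapper=mapper, theta_hat=theta,
            loglik=float(doc["loglik"]),
            site_totals=np.asarray(doc["site_totals"], dtype=float),
            a_matrix=a,
            vcov=None if doc["vcov"] is None else np.asarray(doc["vcov"], dtype=float),
            converged=bool(doc["converged"]), diagnostics=doc.get("diagnostics", {}),
            data=data)


def aic(fit: FittedModel) -> float:
    """Akaike information criterion ``2 n - 2 loglik`` (n excludes site totals)."""
    return fit.aic


def summary(fit: FittedModel) -> pd.DataFrame:
    """Link-scale estimates with standard errors from the numerical Hessian."""
    se = fit.se
    return pd.DataFrame({
        "parameter": fit.param_names,
        "estimate": fit.theta_hat,
        "se": np.full(fit.n_params, np.nan) if se is None else se,
    })


# ---------------------------------------------------------------------------
# starting values

def auto_start(data: SurveyData, config: ModelConfig,
               mapper: ParameterMapper) -> np.ndarray:
    """Data-driven natural-scale starting guesses mapped to the link scale.

    Brood means start at count-weighted quantiles ``(b - 0.5) / B`` of the
    occasion axis, flight-period sigma at ``T / (4B)``, weights equal,
    ``phi = 0.5``, ``r = 1``, ``psi = 0.1``.
    """
    if config.family == "spline":
        return mapper.from_natural({"r": 1.0, "psi": 0.1})
    t = data.occasions
    obs = data.observed
    tot = np.where(obs, np.nan_to_num(data.counts), 0.0).sum(axis=0)
    B = config.B
    if tot.sum() > 0:
        cum = np.cumsum(tot) / tot.sum()
        mu0 = np.interp((np.arange(B) + 0.5) / B, cum, t)
    else:
        mu0 = np.quantile(t, (np.arange(B) + 0.5) / B)
    # enforce strict ordering for degenerate count patterns
    for b in range(1, B):
        mu0[b] = max(mu0[b], mu0[b - 1] + 0.5)
    sigma0 = max(data.T / (4.0 * B), 0.5)
    values = {"mu": mu0, "sigma": sigma0, "w": np.full(B, 1.0 / B),
              "phi": 0.5, "r": 1.0, "psi": 0.1}
    return mapper.from_natural(values)


# ---------------------------------------------------------------------------
# optimisation

def _maximize(objective, x0, maxiter):
    def neg(x):
        v = objective(x)
        return _BIG if not np.isfinite(v) else -v
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = minimize(neg, x0, method="L-BFGS-B",
                       options={"maxiter": maxiter, "maxfun": 20 * maxiter})
    return res


def _update_site_totals(theta, N, data, config, mapper, kind) -> np.ndarray:
    """One-dimensional refinement of each N_i with theta fixed (NB/ZIP step)."""
    sp = mapper.to_natural(theta)
    a = _curve_from_site_params(sp, config, data.occasions, data.S)
    obs = data.observed
    y = np.nan_to_num(data.counts)
    N = np.array(N, dtype=float)
    for i in range(data.S):
        oi = obs[i]
        ysum = y[i, oi].sum()
        if ysum == 0:
            N[i] = 0.0
            continue
        asum = a[i, oi].sum()
        hi = 10.0 * ysum / max(asum, 1e-12)

        def site_neg(logN):
            lam = np.exp(logN) * a[i, oi]
            if kind == "nb":
                terms = _nb_terms(y[i, oi], lam, sp.r)
            elif kind == "zip":
                terms = _zip_terms(y[i, oi], lam, sp.psi)
            else:
                terms = _poisson_terms(y[i, oi], lam)
            t = terms.sum()
            return _BIG if not np.isfinite(t) else -t

        res = minimize_scalar(site_neg, bounds=(np.log(1e-6), np.log(hi)),
                              method="bounded", options={"xatol": 1e-8})
        N[i] = float(np.exp(res.x))
    return N


def _nearest_pd(H: np.ndarray) -> tuple[np.ndarray, bool]:
    Hs = 0.5 * (H + H.T)
    vals, vecs = np.linalg.eigh(Hs)
    if np.all(vals > 0):
        return Hs, False
    floor = max(abs(vals).max() * 1e-10, 1e-12)
    vals = np.clip(vals, floor, None)
    return (vecs * vals) @ vecs.T, True


def _hessian_vcov(objective, theta_hat) -> tuple[np.ndarray | None, dict]:
    diag: dict = {}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            H = approx_hess(theta_hat, lambda x: -objective(x))
        if not np.all(np.isfinite(H)):
            raise FloatingPointError("non-finite Hessian")
        H, repaired = _nearest_pd(H)
        if repaired:
            diag["hessian_repaired"] = True
            log.warning("Hessian not positive definite; nearest-PD repair applied")
        return np.linalg.inv(H), diag
    except Exception as exc:  # pragma: no cover
        diag["vcov_error"] = str(exc)
        return None, diag


def fit_gai(data: SurveyData, config: ModelConfig,
            start: LinkParams | np.ndarray | None = None) -> FittedModel:
    """Fit a generalized abundance index model by maximum likelihood.

    Poisson models maximise the concentrated log-likelihood directly.
    Negative-binomial and zero-inflated-Poisson models first fit the curve
    parameters under the Poisson profile to initialise the site totals, then
    alternate full-theta maximisation with per-site total updates until the
    log-likelihood gain drops below ``config.tol``.

    The variance matrix of theta_hat comes from the inverse finite-difference
    Hessian of the objective at the optimum; if the optimiser fails the
    result is flagged and the variance matrix withheld.
    """
    mapper = ParameterMapper(config, data.covariates)
    if start is None:
        x0 = auto_start(data, config, mapper)
    else:
        x0 = start.theta if isinstance(start, LinkParams) else np.asarray(start, dtype=float)
        if x0.size != mapper.n_params:
            raise ConfigurationError(
                f"starting vector has {x0.size} entries; layout needs {mapper.n_params}")

    starts = [x0]
    if config.n_starts > 1:
        rng = np.random.default_rng(config.seed)
        starts += [x0 + rng.normal(scale=0.5, size=x0.size)
                   for _ in range(config.n_starts - 1)]

    diagnostics: dict = {}

    if config.distribution == "poisson":
        profile = lambda th: poisson_concentrated_loglik(th, data, config, mapper)
        best = None
        for s in starts:
            res = _maximize(profile, s, config.maxiter)
            if best is None or -res.fun > -best.fun or (
                    np.isclose(res.fun, best.fun) and
                    np.linalg.norm(res.x) < np.linalg.norm(best.x)):
                best = res
        theta_hat = best.x
        loglik = -best.fun
        converged = bool(best.success and np.isfinite(loglik))
        a = curve_matrix(theta_hat, mapper, config, data.occasions, data.S)
        N = _concentrate_all(data.counts, a)
        objective = profile
        diagnostics["optimizer_message"] = str(best.message)
    else:
        kind = config.distribution
        # stage 1: Poisson profile on the curve parameters for initial totals
        dist_idx = np.concatenate([mapper.block_indices("r"),
                                   mapper.block_indices("psi")]).astype(int)
        curve_idx = np.setdiff1d(np.arange(mapper.n_params), dist_idx)
        pois_cfg = ModelConfig(**{**config.to_dict(), "distribution": "poisson",
                                  "formulas": config.formulas})
        pois_mapper = ParameterMapper(pois_cfg, data.covariates)

        best = None
        for s in starts:
            res = _maximize(
                lambda tc: poisson_concentrated_loglik(tc, data, pois_cfg, pois_mapper),
                s[curve_idx], config.maxiter)
            if best is None or -res.fun > -best.fun:
                best = res
        theta = x0.copy()
        theta[curve_idx] = best.x
        a0 = curve_matrix(best.x, pois_mapper, pois_cfg, data.occasions, data.S)
        N = _concentrate_all(data.counts, a0)

        objective = lambda th: _dist_loglik(th, N, data, config, mapper, kind)
        ll = objective(theta)
        n_outer = 0
        converged = False
        for n_outer in range(1, 101):
            res = _maximize(objective, theta, config.maxiter)
            theta = res.x
            N = _update_site_totals(theta, N, data, config, mapper, kind)
            new_ll = objective(theta)
            if not np.isfinite(new_ll):
                break
            if new_ll - ll < config.tol and n_outer >= 2:
                ll = max(new_ll, ll)
                converged = True
                break
            ll = new_ll
        theta_hat = theta
        loglik = ll
        diagnostics["outer_iterations"] = n_outer
        a = curve_matrix(theta_hat, mapper, config, data.occasions, data.S)

    vcov = None
    if converged:
        vcov, hdiag = _hessian_vcov(objective, theta_hat)
        diagnostics.update(hdiag)
    else:
        log.warning("fit did not converge; variance matrix withheld")
        diagnostics["converged"] = False

    return FittedModel(config=config, mapper=mapper, theta_hat=theta_hat,
                       loglik=float(loglik), site_totals=np.asarray(N, dtype=float),
                       a_matrix=a, vcov=vcov, converged=converged,
                       diagnostics=diagnostics, data=data)
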