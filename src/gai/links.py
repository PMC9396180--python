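"""Link-scale parameterisation with covariate design matrices.

The optimiser works on an unconstrained flat vector ``theta``.  This module
owns the bidirectional map between ``theta`` and the natural-scale per-site
brood parameters, enforcing the constraints by construction:

* ordered brood means — ``mu_1 = exp(eta)`` and ``mu_b = mu_{b-1} +
  exp(eta_b)`` for later broods (log link on the first mean and on the
  increments ``mu_d``);
* positive standard deviations — log link;
* simplex brood weights — multinomial-logistic transform with the last
  brood as reference, so ``sum_b w_b = 1`` always;
* survival ``phi`` and zero-inflation ``psi`` — logistic link;
* negative-binomial dispersion ``r`` — log link.

Each linear predictor is ``X eta`` with a per-site design matrix built from
a small formula grammar ("northing + northing^2"; intercept implicit,
``I(x^2)`` also accepted).  Covariates are centred and scaled to unit
standard deviation internally by default; the scaling is stored so natural
scale predictions can be requested at covariate values on the original
scale.

theta layout (deterministic): mu1 coefficients; mu-increment coefficients
for broods 2..B; sigma coefficients (one block, or B blocks per brood);
weight coefficients for broods 1..B-1; then scalar phi (stopover), r
(negative binomial), psi (zero-inflated Poisson) unless fixed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FormulaSpec", "LinkParams", "SiteParams", "ParameterMapper",
    "parse_formula", "build_design", "theta_to_site_params",
    "transform_starting_values", "transform_output",
]


class ConfigurationError(ValueError):
    """Model configuration is inconsistent with the data."""


# ---------------------------------------------------------------------------
# formulas

_TERM_RE = re.compile(r"^(?:I\()?\s*([A-Za-z_][A-Za-z0-9_.]*)\s*(?:\^\s*(\d+))?\s*\)?$")


def parse_formula(formula: str | None) -> list[tuple[str, int]]:
    """Parse ``"~ northing + I(northing^2)"`` into ``[(name, power), ...]``.

    The intercept is always implicit; ``"1"``, ``""`` and ``None`` denote an
    intercept-only predictor.
    """
    if formula is None:
        return []
    s = formula.strip().lstrip("~").strip()
    if s in ("", "1"):
        return []
    terms = []
    for raw in s.split("+"):
        raw = raw.strip()
        if raw == "1":
            continue
        m = _TERM_RE.match(raw)
        if not m:
            raise ConfigurationError(f"cannot parse formula term {raw!r}")
        terms.append((m.group(1), int(m.group(2) or 1)))
    return terms


@dataclass
class FormulaSpec:
    """Covariate formulas for the mean, standard deviation and weight
    predictors; each either one shared formula string or a list with one
    formula per brood."""

    mu: str | list[str] | None = None
    sigma: str | list[str] | None = None
    w: str | list[str] | None = None

    def for_brood(self, family: str, b: int, B: int) -> str | None:
        spec = getattr(self, family)
        if spec is None or isinstance(spec, str):
            return spec
        if len(spec) != B:
            raise ConfigurationError(
                f"{family} formula list has {len(spec)} entries for B={B}")
        return spec[b]


def build_design(formula, covariates: pd.DataFrame | None,
                 scaling: dict | None = None) -> np.ndarray:
    """Design matrix with leading intercept column for one linear predictor.

    *formula* is a string or pre-parsed term list; *scaling* maps covariate
    name to ``(centre, scale)`` applied before raising to the term's power.
    """
    terms = parse_formula(formula) if isinstance(formula, (str, type(None))) else formula
    n = 1 if covariates is None else len(covariates)
    cols = [np.ones(n)]
    for name, power in terms:
        if covariates is None or name not in covariates.columns:
            raise ConfigurationError(f"unknown covariate {name!r}")
        x = covariates[name].to_numpy(dtype=float)
        if scaling and name in scaling:
            centre, scale = scaling[name]
            x = (x - centre) / scale
        cols.append(x ** power)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# parameter containers

@dataclass
class LinkParams:
    """Flat link-scale parameter vector with its layout record."""

    theta: np.ndarray
    names: list[str]

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.size != len(self.names):
            raise ConfigurationError(
                f"theta has {self.theta.size} entries but layout names {len(self.names)}")

    def __len__(self) -> int:
        return self.theta.size


@dataclass
class SiteParams:
    """Natural-scale parameters resolved per site (rows) and brood (columns)."""

    mu: np.ndarray | None = None       # (S, B)
    sigma: np.ndarray | None = None    # (S, B)
    w: np.ndarray | None = None        # (S, B)
    phi: float | None = None
    r: float | None = None
    psi: float | None = None
    spline_coefs: np.ndarray | None = None  # full vector incl. pinned zero


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


class ParameterMapper:
    """Build designs from a model configuration and map theta <-> natural scale.

    Parameters
    ----------
    config
        A model configuration exposing ``family``, ``B``, ``distribution``,
        ``sigma_mode``, ``formulas``, ``spline_df``, ``spline_degree``,
        ``standardize``, ``fix_r``, ``fix_psi``.
    covariates
        Per-site covariate table (or ``None`` for intercept-only models).
    """

    def __init__(self, config, covariates: pd.DataFrame | None = None):
        self.config = config
        self.covariates = covariates
        self.scaling: dict[str, tuple[float, float]] = {}
        if covariates is not None and getattr(config, "standardize", True):
            for c in covariates.columns:
                x = covariates[c].to_numpy(dtype=float)
                sd = float(np.std(x))
                self.scaling[c] = (float(np.mean(x)), sd if sd > 0 else 1.0)
        self.blocks: list[dict] = []  # {kind, brood, formula, ncol, colnames}
        self._build_layout()
        self._X_cache = self._designs(covariates)

    # -- layout ---------------------------------------------------------
    def _add_block(self, kind: str, label: str, formula=None, ncol: int | None = None):
        if formula is not None or ncol is None:
            terms = parse_formula(formula)
            ncol = 1 + len(terms)
            colnames = ["intercept"] + [f"{n}^{p}" if p > 1 else n for n, p in terms]
        else:
            colnames = [str(k) for k in range(ncol)]
        self.blocks.append({"kind": kind, "label": label, "formula": formula,
                            "ncol": ncol, "colnames": colnames})

    def _build_layout(self):
        cfg = self.config
        B = cfg.B
        if cfg.family == "spline":
            K = cfg.spline_df
            self._add_block("spline", "spline", ncol=K - 1)
        else:
            f = cfg.formulas or FormulaSpec()
            self._add_block("mu1", "mu1", f.for_brood("mu", 0, B))
            for b in range(1, B):
                self._add_block("mud", f"mud{b + 1}", f.for_brood("mu", b, B))
            if getattr(cfg, "sigma_mode", "shared") == "per_brood" and B > 1:
                for b in range(B):
                    self._add_block("sigma", f"sigma{b + 1}", f.for_brood("sigma", b, B))
            else:
                self._add_block("sigma", "sigma", f.for_brood("sigma", 0, B))
            for b in range(B - 1):
                self._add_block("w", f"w{b + 1}", f.for_brood("w", b, B))
            if cfg.family == "stopover":
                self._add_block("phi", "phi", None)
        if cfg.distribution == "nb" and getattr(cfg, "fix_r", None) is None:
            self._add_block("r", "r", None)
        if cfg.distribution == "zip" and getattr(cfg, "fix_psi", None) is None:
            self._add_block("psi", "psi", None)

    def _designs(self, covariates) -> list[np.ndarray | None]:
        out = []
        for blk in self.blocks:
            if blk["kind"] == "spline":
                out.append(None)
            else:
                out.append(build_design(blk["formula"], covariates, self.scaling))
        return out

    @property
    def n_params(self) -> int:
        return sum(b["ncol"] for b in self.blocks)

    @property
    def param_names(self) -> list[str]:
        names = []
        for blk in self.blocks:
            if blk["ncol"] == 1 and blk["kind"] in ("phi", "r", "psi"):
                names.append(blk["label"])
            elif blk["kind"] == "spline":
                names.extend(f"spline:{k + 1}" for k in range(blk["ncol"]))
            else:
                names.extend(f"{blk['label']}:{c}" for c in blk["colnames"])
        return names

    def _split(self, theta: np.ndarray) -> list[np.ndarray]:
        theta = np.asarray(theta, dtype=float)
        if theta.size != self.n_params:
            raise ConfigurationError(
                f"theta length {theta.size} does not match layout ({self.n_params})")
        out, k = [], 0
        for blk in self.blocks:
            out.append(theta[k:k + blk["ncol"]])
            k += blk["ncol"]
        return out

    def block_indices(self, kind: str) -> np.ndarray:
        """Flat theta indices belonging to blocks of the given kind."""
        idx, k = [], 0
        for blk in self.blocks:
            if blk["kind"] == kind:
                idx.extend(range(k, k + blk["ncol"]))
            k += blk["ncol"]
        return np.asarray(idx, dtype=int)

    # -- theta -> natural -----------------------------------------------
    def to_natural(self, theta, covariates: pd.DataFrame | None = "training") -> SiteParams:
        """Resolve per-site natural-scale parameters at the given covariate
        rows (default: the table the mapper was built with)."""
        cfg = self.config
        if isinstance(covariates, str):
            designs = self._X_cache
            n = 1 if self.covariates is None else len(self.covariates)
        else:
            designs = self._designs(covariates)
            n = 1 if covariates is None else len(covariates)
        parts = self._split(theta)
        sp = SiteParams()
        if cfg.family == "spline":
            sp.spline_coefs = np.concatenate([[0.0], parts[0]])
        else:
            B = cfg.B
            mu_cols, sig_cols, w_eta = [], [], []
            for blk, eta, X in zip(self.blocks, parts, designs):
                kind = blk["kind"]
                if kind == "mu1":
                    mu_cols.append(np.exp(X @ eta))
                elif kind == "mud":
                    mu_cols.append(mu_cols[-1] + np.exp(X @ eta))
                elif kind == "sigma":
                    sig_cols.append(np.exp(X @ eta))
                elif kind == "w":
                    w_eta.append(X @ eta)
                elif kind == "phi":
                    sp.phi = float(_expit(eta[0]))
            sp.mu = np.column_stack(mu_cols)
            sp.sigma = (np.column_stack(sig_cols) if len(sig_cols) == B
                        else np.repeat(sig_cols[0][:, None], B, axis=1))
            if B == 1:
                sp.w = np.ones((n, 1))
            else:
                E = np.exp(np.column_stack(w_eta + [np.zeros(n)]))
                sp.w = E / E.sum(axis=1, keepdims=True)
        for blk, eta in zip(self.blocks, parts):
            if blk["kind"] == "r":
                sp.r = float(np.exp(eta[0]))
            elif blk["kind"] == "psi":
                sp.psi = float(_expit(eta[0]))
        if getattr(cfg, "fix_r", None) is not None:
            sp.r = float(cfg.fix_r)
        if getattr(cfg, "fix_psi", None) is not None:
            sp.psi = float(cfg.fix_psi)
        return sp

    # -- natural -> theta (intercepts only) ------------------------------
    def from_natural(self, values: dict) -> np.ndarray:
        """Invert the links at intercept level: covariate coefficients are
        zero, intercepts reproduce the supplied natural-scale values.

        *values* holds ``mu`` (length B, strictly increasing), ``sigma``
        (scalar or length B), ``w`` (length B summing to one), and for the
        relevant models ``phi``, ``r``, ``psi``; for splines,
        ``spline_coefs`` (length df, leading entry ignored).
        """
        cfg = self.config
        theta = np.zeros(self.n_params)
        k = 0
        if cfg.family != "spline":
            mu = np.atleast_1d(np.asarray(values["mu"], dtype=float))
            if mu.size != cfg.B:
                raise ConfigurationError(f"need {cfg.B} brood means, got {mu.size}")
            if cfg.B > 1 and not np.all(np.diff(mu) > 0):
                raise ConfigurationError(
                    f"brood means must be sorted increasing before transforming: {mu}")
            sigma = np.atleast_1d(np.asarray(values["sigma"], dtype=float))
            w = np.atleast_1d(np.asarray(values.get("w", [1.0]), dtype=float))
        for blk in self.blocks:
            kind, ncol = blk["kind"], blk["ncol"]
            if kind == "spline":
                sc = np.asarray(values.get("spline_coefs", np.zeros(ncol + 1)), dtype=float)
                theta[k:k + ncol] = sc[1:] - sc[0]
            elif kind == "mu1":
                theta[k] = np.log(mu[0])
            elif kind == "mud":
                b = int(blk["label"][3:]) - 1
                theta[k] = np.log(mu[b] - mu[b - 1])
            elif kind == "sigma":
                if blk["label"] == "sigma":
                    theta[k] = np.log(sigma[0])
                else:
                    b = int(blk["label"][5:]) - 1
                    theta[k] = np.log(sigma[b] if sigma.size > 1 else sigma[0])
            elif kind == "w":
                b = int(blk["label"][1:]) - 1
                theta[k] = np.log(w[b]) - np.log(w[-1])
            elif kind == "phi":
                theta[k] = _logit(float(values["phi"]))
            elif kind == "r":
                theta[k] = np.log(float(values.get("r", 1.0)))
            elif kind == "psi":
                theta[k] = _logit(float(values.get("psi", 0.1)))
            k += ncol
        return theta


# ---------------------------------------------------------------------------
# module-surface wrappers

def theta_to_site_params(theta, mapper: ParameterMapper,
                         covariates: pd.DataFrame | None = "training") -> SiteParams:
    """Natural-scale per-site parameters for a link-scale vector."""
    th = theta.theta if isinstance(theta, LinkParams) else theta
    return mapper.to_natural(th, covariates)


def transform_starting_values(values: dict, config,
                              covariates: pd.DataFrame | None = None) -> LinkParams:
    """Turn natural-scale starting guesses into a link-scale vector.

    Covariate coefficients start at zero; the round trip through
    :func:`theta_to_site_params` recovers the guesses exactly.
    """
    mapper = ParameterMapper(config, covariates)
    return LinkParams(mapper.from_natural(values), mapper.param_names)


def _natural_frame(sp: SiteParams, index, family: str) -> pd.DataFrame:
    cols = {}
    if sp.mu is not None:
        B = sp.mu.shape[1]
        for b in range(B):
            cols[f"mu_{b + 1}"] = sp.mu[:, b]
            cols[f"sigma_{b + 1}"] = sp.sigma[:, b]
        for b in range(B):
            cols[f"w_{b + 1}"] = sp.w[:, b]
    if sp.phi is not None:
        cols["phi"] = sp.phi
        cols["mean_lifespan"] = 1.0 / (1.0 - sp.phi)
    if sp.r is not None:
        cols["r"] = sp.r
    if sp.psi is not None:
        cols["psi"] = sp.psi
    return pd.DataFrame(cols, index=index)


def transform_output(fit, covariate_values: dict | pd.DataFrame | None = None) -> pd.DataFrame:
    """Natural-scale parameter table for a fitted model.

    With no arguments, one row per site at the observed covariate values.
    *covariate_values* (original, unstandardised scale) gives custom rows,
    e.g. a northing grid for plotting phenology profiles.
    """
    mapper: ParameterMapper = fit.mapper
    if covariate_values is None:
        sp = mapper.to_natural(fit.theta_hat)
        index = (pd.Index(mapper.covariates.index) if mapper.covariates is not None
                 else pd.RangeIndex(1))
        cov_df = mapper.covariates
    else:
        cov_df = (covariate_values if isinstance(covariate_values, pd.DataFrame)
                  else pd.DataFrame(covariate_values))
        needed = {n for blk in mapper.blocks
                  for n, _ in parse_formula(blk["formula"])}
        missing = needed - set(cov_df.columns)
        if missing:
            raise ConfigurationError(f"covariate values required for {sorted(missing)}")
        sp = mapper.to_natural(fit.theta_hat, cov_df)
        index = cov_df.index
    out = _natural_frame(sp, index, fit.config.family)
    if cov_df is not None and covariate_values is not None:
        out = pd.concat([cov_df.reset_index(drop=True),
                         out.reset_index(drop=True)], axis=1)
    return out
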