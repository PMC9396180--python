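"""Bootstrap uncertainty for fitted abundance-index models.

Two flavours are provided.  The parametric bootstrap resamples the
link-scale parameter vector from its asymptotic Normal approximation
``theta* ~ MVN(theta_hat, vcov)``; it is cheap and is what the headline
confidence intervals (e.g. on survival phi or on derived life span) use.
The non-parametric bootstrap resamples whole sites with replacement —
covariates travel with their site — and refits the model for every
replicate, which is robust to misspecified variance but costs one fit per
draw.  Intervals are percentile intervals, which are equivariant under
monotone transformations, so link-scale intervals can be pushed through the
inverse links without distortion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import SurveyData
from .likelihood import FittedModel, ModelConfig, fit_gai
from .links import ParameterMapper

__all__ = [
    "BootstrapResult", "parametric_bootstrap", "nonparametric_bootstrap",
    "transform_bootstrap_parameters",
]

log = logging.getLogger(__name__)


def _tail_probs(level: float) -> np.ndarray:
    """(alpha/2, 1 - alpha/2), rounded so e.g. 1 - 0.95 cannot drift above
    0.05 by a float epsilon and shift the selected order statistic."""
    alpha = 1.0 - level
    return np.round([alpha / 2.0, 1.0 - alpha / 2.0], 12)


@dataclass
class BootstrapResult:
    """Link-scale bootstrap draws with percentile intervals."""

    draws: np.ndarray            # R x n_params
    method: str                  # "parametric" | "nonparametric"
    level: float
    param_names: list[str]
    failures: int = 0
    seed: int | None = None

    def __post_init__(self):
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 2 or self.draws.shape[0] < 1:
            raise ValueError("need at least one bootstrap draw")

    @property
    def R(self) -> int:
        return self.draws.shape[0]

    def intervals(self) -> pd.DataFrame:
        """Percentile interval per parameter on the link scale.

        Quantiles are order statistics (``inverted_cdf``), so intervals are
        exactly equivariant under monotone transformations of a parameter.
        """
        q = _tail_probs(self.level)
        lo, hi = np.quantile(self.draws, q, axis=0, method="inverted_cdf")
        return pd.DataFrame({"parameter": self.param_names, "lower": lo, "upper": hi})

    def se(self) -> np.ndarray:
        """Bootstrap standard error per link-scale parameter."""
        return self.draws.std(axis=0, ddof=1)


def parametric_bootstrap(fit: FittedModel, R: int = 1000, level: float = 0.95,
                         seed: int | None = None) -> BootstrapResult:
    """Draw ``theta*`` from the asymptotic Normal distribution of the MLE."""
    if fit.vcov is None:
        raise ValueError(
            "fit has no variance matrix; use the nonparametric bootstrap instead")
    if R < 1:
        raise ValueError("R must be at least 1")
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(fit.theta_hat, fit.vcov, size=R,
                                    method="svd")
    return BootstrapResult(draws=draws, method="parametric", level=level,
                           param_names=fit.param_names, seed=seed)


def nonparametric_bootstrap(data: SurveyData, config: ModelConfig,
                            fit: FittedModel, R: int = 200, level: float = 0.95,
                            seed: int | None = None, cold_start: bool = False,
                            indices: np.ndarray | None = None) -> BootstrapResult:
    """Refit the model on site resamples drawn with replacement.

    Refits start from ``theta_hat`` (warm start) unless ``cold_start``.
    Replicates whose refit does not converge are dropped and counted in
    ``failures``; more than 50 % failures is an error.  ``indices`` fixes
    the resampling matrix (R x S) explicitly, mainly for testing.
    """
    if data.S < 2:
        raise ValueError("site bootstrap needs at least two sites")
    if R < 1:
        raise ValueError("R must be at least 1")
    rng = np.random.default_rng(seed)
    draws, failures = [], 0
    for rep in range(R):
        idx = (indices[rep] if indices is not None
               else rng.integers(0, data.S, size=data.S))
        sub = data.subset_sites(idx)
        try:
            refit = fit_gai(sub, config,
                            start=None if cold_start else fit.theta_hat)
            if not refit.converged:
                raise RuntimeError("refit did not converge")
            draws.append(refit.theta_hat)
        except Exception as exc:
            failures += 1
            log.debug("bootstrap replicate %d failed: %s", rep, exc)
    if failures > 0.5 * R or not draws:
        raise RuntimeError(
            f"nonparametric bootstrap failed: {failures}/{R} replicates did not "
            "converge; consider cold_start=True or a simpler model")
    return BootstrapResult(draws=np.asarray(draws), method="nonparametric",
                           level=level, param_names=fit.param_names,
                           failures=failures, seed=seed)


def transform_bootstrap_parameters(result: BootstrapResult, fit: FittedModel,
                                   covariate_values: dict | pd.DataFrame | None = None,
                                   ) -> pd.DataFrame:
    """Natural-scale percentile intervals from link-scale bootstrap draws.

    Each draw is pushed through the inverse links at the requested covariate
    values (original scale; default one representative row at the observed
    covariate mean), and percentile intervals of the transformed draws are
    reported per natural-scale quantity, including derived mean life span
    for stopover models.
    """
    mapper: ParameterMapper = fit.mapper
    if covariate_values is None:
        if mapper.covariates is not None:
            cov_df = pd.DataFrame({c: [float(mapper.covariates[c].mean())]
                                   for c in mapper.covariates.columns})
        else:
            cov_df = None
    else:
        cov_df = (covariate_values if isinstance(covariate_values, pd.DataFrame)
                  else pd.DataFrame(covariate_values))

    from .links import _natural_frame  # late import to avoid cycle at module load
    frames = []
    for draw in result.draws:
        sp = mapper.to_natural(draw, cov_df)
        frames.append(_natural_frame(sp, None, fit.config.family))
    stacked = pd.concat(frames, keys=range(result.R))

    q = _tail_probs(result.level)
    rows = []
    n_rows = len(frames[0])
    point_sp = mapper.to_natural(fit.theta_hat, cov_df)
    point = _natural_frame(point_sp, None, fit.config.family)
    for row in range(n_rows):
        sub = stacked.xs(row, level=1)
        for colname in sub.columns:
            lo, hi = np.quantile(sub[colname].to_numpy(), q,
                                 method="inverted_cdf")
            rec = {"row": row, "parameter": colname,
                   "estimate": float(point.iloc[row][colname]),
                   "lower": float(lo), "upper": float(hi)}
            if cov_df is not None:
                for c in cov_df.columns:
                    rec[c] = float(cov_df.iloc[row][c])
            rows.append(rec)
    return pd.DataFrame(rows)
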