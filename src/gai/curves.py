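"""Seasonal-pattern curves: Normal mixtures, the stopover model, B-splines.

The expected count at site *i* and occasion *j* factorises as
``lambda_ij = N_i * a_ij`` where ``a_ij`` describes within-season variation.
Three descriptions of ``a`` are provided:

* **mixture** — a weighted sum of B Normal probability densities over the
  occasion axis, one component per brood; the density integrates to one over
  continuous time, so the discrete ``a_j`` are raw density ordinates.
* **stopover** — a mechanistic model: individuals emerge at visit ``d`` with
  probability ``beta_{d-1}`` (areas under a Normal mixture between visits,
  summing to one) and persist between consecutive visits with constant
  survival probability ``phi``; mean adult life span is ``1/(1-phi)``
  inter-visit intervals.
* **spline** — a flexible shared curve: softmax of a B-spline score, scaled
  to sum to one over the occasions.

Public operations work on single parameter sets; the module-private
vectorised kernels (``_mixture_matrix`` etc.) take per-site parameter arrays
and are what the likelihood code calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.special import ndtr  # fast Normal CDF

__all__ = [
    "BroodParams", "StopoverParams", "SplineParams",
    "mixture_curve", "emergence_proportions", "stopover_curve",
    "mean_lifespan", "spline_curve", "spline_basis",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)


class InvariantError(ValueError):
    """A natural-scale parameter constraint is violated."""


@dataclass
class BroodParams:
    """Natural-scale parameters of a B-component Normal brood mixture.

    ``means`` must be strictly increasing (brood order within the season),
    ``sds`` positive, and ``weights`` a point in the open simplex.
    """

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.means = np.atleast_1d(np.asarray(self.means, dtype=float))
        self.sds = np.atleast_1d(np.asarray(self.sds, dtype=float))
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if self.sds.shape != self.means.shape and self.sds.size == 1:
            self.sds = np.full_like(self.means, self.sds[0])
        B = self.means.size
        if self.sds.size != B or self.weights.size != B:
            raise InvariantError("means, sds, weights must have one entry per brood")
        if B > 1 and not np.all(np.diff(self.means) > 0):
            raise InvariantError(f"brood means must be strictly increasing: {self.means}")
        if np.any(self.sds <= 0):
            raise InvariantError("brood standard deviations must be positive")
        if np.any(self.weights <= 0) or not np.isclose(self.weights.sum(), 1.0):
            raise InvariantError("brood weights must be positive and sum to one")

    @property
    def B(self) -> int:
        return self.means.size


@dataclass
class StopoverParams:
    """Brood mixture for emergence timing plus between-visit survival phi."""

    brood: BroodParams
    phi: float

    def __post_init__(self):
        if not (0.0 < self.phi < 1.0):
            raise InvariantError(f"phi must lie in (0, 1): {self.phi}")


@dataclass
class SplineParams:
    """Coefficients for the softmax-normalised spline curve.

    ``coefficients`` includes the pinned leading zero used for
    identifiability.  ``basis`` overrides the B-spline design matrix (used
    for testing with custom bases); otherwise a cubic B-spline basis with
    equally spaced interior knots is built from ``degree`` and ``df``.
    """

    coefficients: np.ndarray
    degree: int = 3
    df: int | None = None
    basis: np.ndarray | None = None

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        K = self.coefficients.size
        if self.basis is None and K < self.degree + 1:
            raise InvariantError(
                f"need at least degree+1={self.degree + 1} basis coefficients, got {K}")


# ---------------------------------------------------------------------------
# single-parameter-set operations

def mixture_curve(t, p: BroodParams, normalise: bool = False) -> np.ndarray:
    """Evaluate the Normal-mixture seasonal curve at occasion times *t*.

    Returns raw mixture density ordinates (integrating to one over
    continuous time); with ``normalise`` the values are rescaled to sum to
    one over the supplied occasions instead.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    a = _mixture_matrix(t, p.means[None], p.sds[None], p.weights[None])[0]
    if normalise:
        a = a / a.sum()
    return a


def emergence_proportions(t, p: BroodParams, method: str = "tail") -> np.ndarray:
    """Per-visit emergence probabilities beta under a Normal-mixture kernel.

    ``beta[d-1]`` is the mixture mass between visits ``t_{d-1}`` and ``t_d``.
    With ``method="tail"`` (default) the first and last visits absorb the
    lower and upper Normal tails, so the vector sums to one exactly.  With
    ``method="rescale"`` the mass over ``[t_1 - (t_2 - t_1), t_T]`` is
    computed on intervals and divided by its total.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if t.size < 2:
        raise InvariantError("emergence proportions need at least two occasions")
    return _emergence_matrix(t, p.means[None], p.sds[None], p.weights[None], method)[0]


def stopover_curve(beta, phi: float) -> np.ndarray:
    """Expected availability ``a_j = sum_{d<=j} beta_{d-1} phi^{j-d}``.

    Boundary survival values 0 and 1 are permitted (no survivors / nobody
    leaves); *beta* must sum to one.
    """
    beta = np.asarray(beta, dtype=float)
    if not np.isclose(beta.sum(), 1.0):
        raise InvariantError(f"emergence proportions must sum to one: sum={beta.sum()}")
    if not (0.0 <= phi <= 1.0):
        raise InvariantError(f"phi must lie in [0, 1]: {phi}")
    return _stopover_recursion(beta[None], phi)[0]


def mean_lifespan(phi: float) -> float:
    """Mean adult life span ``1/(1-phi)`` in inter-visit intervals."""
    if not (0.0 <= phi < 1.0):
        raise InvariantError(f"life span undefined for phi={phi}")
    return 1.0 / (1.0 - phi)


def spline_basis(t, df: int = 10, degree: int = 3) -> np.ndarray:
    """B-spline design matrix over *t* with *df* basis functions.

    Interior knots are equally spaced over the span of *t*; boundary knots
    are repeated ``degree + 1`` times (clamped spline).
    """
    t = np.asarray(t, dtype=float)
    if df < degree + 1:
        raise InvariantError(f"df must be at least degree+1={degree + 1}")
    n_interior = df - degree - 1
    lo, hi = t.min(), t.max()
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    return BSpline.design_matrix(t, knots, degree).toarray()


def spline_curve(t, p: SplineParams) -> np.ndarray:
    """Softmax-normalised spline curve; always sums to one over *t*."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if p.basis is not None:
        X = np.asarray(p.basis, dtype=float)
    else:
        X = spline_basis(t, df=p.df or p.coefficients.size, degree=p.degree)
    if X.shape != (t.size, p.coefficients.size):
        raise InvariantError(
            f"basis shape {X.shape} incompatible with {t.size} occasions and "
            f"{p.coefficients.size} coefficients")
    s = X @ p.coefficients
    s = s - s.max()
    e = np.exp(s)
    return e / e.sum()


# ---------------------------------------------------------------------------
# vectorised kernels over per-site parameter arrays (S x B)

def _mixture_matrix(t, mu, sigma, w) -> np.ndarray:
    """Mixture density ordinates; mu/sigma/w are (S, B), t is (T,) -> (S, T)."""
    z = (t[None, None, :] - mu[:, :, None]) / sigma[:, :, None]
    dens = np.exp(-0.5 * z * z) / (sigma[:, :, None] * _SQRT2PI)
    return np.einsum("sb,sbt->st", w, dens)


def _emergence_matrix(t, mu, sigma, w, method: str = "tail") -> np.ndarray:
    """Per-site emergence proportions; (S, B) params, (T,) times -> (S, T)."""
    if method == "tail":
        # CDF at interior cut points t_1..t_{T-1}; tails absorbed at the ends
        F = ndtr((t[None, None, :-1] - mu[:, :, None]) / sigma[:, :, None])
        Fmix = np.einsum("sb,sbt->st", w, F)
        S, T = Fmix.shape[0], t.size
        beta = np.empty((S, T))
        beta[:, 0] = Fmix[:, 0]
        beta[:, 1:-1] = np.diff(Fmix, axis=1)
        beta[:, -1] = 1.0 - Fmix[:, -1]
        return beta
    if method == "rescale":
        edges = np.concatenate([[t[0] - (t[1] - t[0])], t])
        F = ndtr((edges[None, None, :] - mu[:, :, None]) / sigma[:, :, None])
        Fmix = np.einsum("sb,sbt->st", w, F)
        raw = np.diff(Fmix, axis=1)
        return raw / raw.sum(axis=1, keepdims=True)
    raise ValueError(f"unknown emergence normalisation {method!r}")


def _stopover_recursion(beta, phi) -> np.ndarray:
    """a_{.,j} = phi * a_{.,j-1} + beta_{.,j} column by column."""
    S, T = beta.shape
    a = np.empty_like(beta)
    a[:, 0] = beta[:, 0]
    for j in range(1, T):
        a[:, j] = phi * a[:, j - 1] + beta[:, j]
    return a
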