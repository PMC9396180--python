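"""Containers and I/O for seasonal count survey data.

A survey records counts of a seasonal population (e.g. adult butterflies on
weekly transect walks) at ``S`` sites over ``T`` occasions within one season.
Counts live in an ``S x T`` matrix with ``NaN`` marking occasions a site was
not visited; site-level covariates (such as northing) travel alongside in a
small table.  The long "tidy" file format is one row per realised visit:
``site,occasion,count[,covariate...]``; occasions absent from the file are
missing visits, an explicit 0 is a true zero count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SurveyData", "ValidationError", "load_survey", "extract_counts", "write_survey"]

log = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Raised when survey data violate a structural invariant."""


@dataclass
class SurveyData:
    """Site x occasion count matrix with optional site-level covariates.

    Parameters
    ----------
    sites
        Ordered site identifiers, length ``S``.
    occasions
        Strictly increasing visit times ``t_j`` (length ``T``); by default
        week numbers ``1..T``.
    counts
        ``S x T`` float array of non-negative integer counts, ``NaN`` where a
        site was not visited.
    covariates
        Optional per-site table (indexed like ``sites``) of numeric covariates.
    """

    sites: list
    occasions: np.ndarray
    counts: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self):
        self.sites = list(self.sites)
        self.occasions = np.asarray(self.occasions, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D site x occasion array")
        S, T = self.counts.shape
        if len(self.sites) != S:
            raise ValidationError(f"{len(self.sites)} sites but {S} count rows")
        if len(self.occasions) != T:
            raise ValidationError(f"{len(self.occasions)} occasions but {T} count columns")
        if len(set(map(str, self.sites))) != S:
            raise ValidationError("site identifiers must be unique")
        if T >= 2 and not np.all(np.diff(self.occasions) > 0):
            raise ValidationError("occasions must be strictly increasing")
        obs = ~np.isnan(self.counts)
        vals = self.counts[obs]
        if np.any(vals < 0):
            raise ValidationError("counts must be non-negative")
        if np.any(vals != np.round(vals)):
            raise ValidationError("counts must be integers (use load_survey(strict=False) to round)")
        if np.any(~obs.any(axis=1)):
            bad = [s for s, ok in zip(self.sites, obs.any(axis=1)) if not ok]
            raise ValidationError(f"each site has at least one non-missing count; all missing: {bad}")
        if self.covariates is not None:
            if len(self.covariates) != S:
                raise ValidationError("covariate table must have one row per site")
            self.covariates = self.covariates.copy()
            self.covariates.index = pd.Index(self.sites)
            nonnum = [c for c in self.covariates.columns
                      if not np.issubdtype(self.covariates[c].dtype, np.number)]
            if nonnum:
                raise ValidationError(f"covariates must be numeric: {nonnum}")

    # -- basic geometry -------------------------------------------------
    @property
    def S(self) -> int:
        return self.counts.shape[0]

    @property
    def T(self) -> int:
        return self.counts.shape[1]

    @property
    def observed(self) -> np.ndarray:
        """Boolean ``S x T`` mask of realised visits."""
        return ~np.isnan(self.counts)

    def site_totals(self) -> np.ndarray:
        """Raw sum of observed counts per site."""
        return np.nansum(self.counts, axis=1)

    def subset_sites(self, indices, rename: bool = True) -> "SurveyData":
        """Return a survey containing ``sites[i]`` for each ``i`` in *indices*.

        Repeated indices are allowed (site bootstrap); with ``rename`` the
        duplicates get unique ``name#k`` identifiers.
        """
        indices = list(indices)
        names = []
        seen: dict = {}
        for i in indices:
            base = self.sites[i]
            k = seen.get(base, 0)
            seen[base] = k + 1
            names.append(f"{base}#{k}" if (rename and k) else base)
        cov = None
        if self.covariates is not None:
            cov = self.covariates.iloc[indices].copy()
            cov.index = pd.Index(names)
        return SurveyData(names, self.occasions.copy(), self.counts[indices].copy(), cov)


def _occasion_grid(values: np.ndarray) -> np.ndarray:
    """Shared occasion axis: consecutive integers when occasions are integer
    labels (so unvisited interior weeks exist as missing columns), otherwise
    the sorted unique visit times."""
    uniq = np.unique(values)
    if np.allclose(uniq, np.round(uniq)):
        lo, hi = int(round(uniq.min())), int(round(uniq.max()))
        return np.arange(lo, hi + 1, dtype=float)
    return uniq.astype(float)


def load_survey(source, covariate_columns=None, strict: bool = True) -> SurveyData:
    """Read a long-format survey table into a :class:`SurveyData`.

    Parameters
    ----------
    source
        CSV path (header row ``site,occasion,count[,...]``) or an equivalent
        :class:`pandas.DataFrame`.
    covariate_columns
        Names of site-level covariate columns to carry along; each must be
        constant within a site.
    strict
        When ``True`` (default) non-integer counts are an error; otherwise
        they are rounded with a logged warning (e.g. for averaged counts).

    Sites keep first-appearance order; occasions become a shared sorted axis
    and absent (site, occasion) pairs become missing counts.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)
    required = {"site", "occasion", "count"}
    if not required.issubset(df.columns):
        raise ValidationError(f"input must have columns {sorted(required)}; got {list(df.columns)}")
    covariate_columns = list(covariate_columns or [])
    missing_cov = [c for c in covariate_columns if c not in df.columns]
    if missing_cov:
        raise ValidationError(f"covariate columns not in table: {missing_cov}")

    dup = df.duplicated(subset=["site", "occasion"], keep=False)
    if dup.any():
        pair = df.loc[dup, ["site", "occasion"]].iloc[0]
        raise ValidationError(
            f"duplicate site-occasion pair: ({pair['site']}, {pair['occasion']})")

    occ_vals = pd.to_numeric(df["occasion"], errors="coerce")
    if occ_vals.isna().any():
        raise ValidationError("occasion values must be numeric")
    counts = pd.to_numeric(df["count"], errors="coerce")  # NA/empty -> missing visit
    valid = ~counts.isna()
    if (counts[valid] < 0).any():
        bad = df.loc[valid & (counts < 0)].iloc[0]
        raise ValidationError(f"negative count at ({bad['site']}, {bad['occasion']})")
    nonint = valid & (counts != np.round(counts))
    if nonint.any():
        if strict:
            bad = df.loc[nonint].iloc[0]
            raise ValidationError(
                f"non-integer count at ({bad['site']}, {bad['occasion']}); "
                "pass strict=False to round")
        log.warning("rounding %d non-integer counts to nearest integer", int(nonint.sum()))
        counts = counts.round()

    sites = list(dict.fromkeys(df["site"]))  # first-appearance order
    occasions = _occasion_grid(occ_vals.to_numpy())
    occ_index = {t: j for j, t in enumerate(occasions)}
    site_index = {s: i for i, s in enumerate(sites)}

    mat = np.full((len(sites), len(occasions)), np.nan)
    for s, t, y in zip(df["site"], occ_vals, counts):
        if not np.isnan(y):
            mat[site_index[s], occ_index[float(t)]] = y

    cov = None
    if covariate_columns:
        rows = {}
        for c in covariate_columns:
            per_site = df.groupby("site", sort=False)[c].nunique(dropna=False)
            varying = per_site[per_site > 1]
            if len(varying):
                raise ValidationError(
                    f"covariate '{c}' varies within site {varying.index[0]}")
            rows[c] = df.groupby("site", sort=False)[c].first().reindex(sites)
        cov = pd.DataFrame(rows, index=pd.Index(sites))
    return SurveyData(sites, occasions, mat, cov)


def extract_counts(data: SurveyData) -> pd.DataFrame:
    """Wide site x occasion count table (``NaN`` = missing visit)."""
    return pd.DataFrame(data.counts, index=pd.Index(data.sites, name="site"),
                        columns=data.occasions)


def write_survey(data: SurveyData, path) -> None:
    """Write long-format CSV (observed cells only) that round-trips through
    :func:`load_survey`."""
    obs = data.observed
    recs = []
    for i, s in enumerate(data.sites):
        for j in np.flatnonzero(obs[i]):
            rec = {"site": s, "occasion": data.occasions[j],
                   "count": int(data.counts[i, j])}
            if data.covariates is not None:
                rec.update(data.covariates.iloc[i].to_dict())
            recs.append(rec)
    pd.DataFrame(recs).to_csv(path, index=False)
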