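"""Longitudinal statistics on abundance / replication-rate tables.

Covers the statistical layer of the pipeline: the centered log-ratio (CLR)
transform, gap-gated day-to-day deltas and their regression-to-the-mean
diagnostic, per-taxon log2(PTR)–CLR regressions, Benjamini–Hochberg FDR,
Fisher's meta-analytic p-value combination, augmented Dickey–Fuller
stationarity screening, donor-level mean-vs-mean regression and a
taxonomy-covariate-adjusted regression.

Orientation convention: per-taxon regressions fit CLR abundance as the
response against log2(PTR) (Pearson r, which carries the sign conclusions,
is symmetric); the covariate-adjusted cohort model fits log2(PTR) against
CLR plus group indicators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio.stats.composition import clr as _skbio_clr
from statsmodels.stats.multitest import multipletests
from statsmodels.tsa.stattools import adfuller
import statsmodels.formula.api as smf

__all__ = [
    "TaxonSeries",
    "RegressionResult",
    "StationarityResult",
    "clr_transform",
    "compute_deltas",
    "delta_abundance_stats",
    "ptr_abundance_regression",
    "bh_adjust",
    "fisher_combine",
    "adf_stationarity",
    "donor_mean_regression",
    "covariate_adjusted_regression",
]


@dataclass
class TaxonSeries:
    """One taxon's longitudinal record within a donor.

    days are strictly increasing integer collection days; clr is the
    CLR-transformed abundance per day; log2ptr the log2 peak-to-trough
    ratio per day with NaN for missing estimates.  Summary means are
    computed on access, never stored.
    """

    taxon: str
    donor: str
    days: np.ndarray
    clr: np.ndarray
    log2ptr: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.clr = np.asarray(self.clr, dtype=float)
        self.log2ptr = np.asarray(self.log2ptr, dtype=float)
        if not (len(self.days) == len(self.clr) == len(self.log2ptr)):
            raise ValueError(f"{self.taxon}: days/clr/log2ptr lengths differ")
        if len(self.days) > 1 and np.any(np.diff(self.days) <= 0):
            raise ValueError(f"{self.taxon}: days must be strictly increasing")

    @property
    def mu(self) -> float:
        """Mean CLR abundance over all days."""
        return float(np.mean(self.clr)) if len(self.clr) else float("nan")

    @property
    def mean_log2ptr(self) -> float:
        """Mean of the available (non-missing) log2(PTR) values."""
        vals = self.log2ptr[~np.isnan(self.log2ptr)]
        return float(np.mean(vals)) if len(vals) else float("nan")


@dataclass
class RegressionResult:
    """OLS fit plus Pearson correlation for one taxon or one donor.

    q (the FDR-adjusted p) is filled by a batch step such as
    :func:`phaseflow.classify.classify_donor`; it is None until then.
    """

    slope: float
    intercept: float
    pearson_r: float
    p: float
    n: int
    q: float | None = field(default=None)


class StationarityResult(tuple):
    """(p, stationary) pair from the ADF unit-root test."""

    __slots__ = ()

    def __new__(cls, p: float, stationary: bool):
        return super().__new__(cls, (float(p), bool(stationary)))

    @property
    def p(self) -> float:
        return self[0]

    @property
    def stationary(self) -> bool:
        return self[1]


def clr_transform(counts, pseudocount: float = 0.5):
    """Centered log-ratio transform of a taxa × samples count table.

    Each sample (column) is transformed independently: ln(count + pseudocount)
    minus the mean of ln(count + pseudocount) over all taxa in that sample,
    so each column sums to zero.  Accepts a DataFrame (returned as a
    DataFrame with the same labels) or a 2-D array.
    """
    is_df = isinstance(counts, pd.DataFrame)
    mat = counts.to_numpy(dtype=float) if is_df else np.asarray(counts, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("need a 2-D table with at least 2 taxa per sample")
    if np.any(mat < 0):
        raise ValueError("counts must be non-negative")
    totals = mat.sum(axis=0)
    if np.any(totals == 0):
        j = int(np.argmax(totals == 0))
        name = counts.columns[j] if is_df else j
        raise ValueError(f"sample {name!r} has all-zero counts")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if np.any(mat + pseudocount == 0):
        raise ValueError("zero counts need a positive pseudocount")
    out = _skbio_clr((mat + pseudocount).T).T
    if is_df:
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out


def compute_deltas(series: TaxonSeries, max_gap: int = 3) -> np.ndarray:
    """Gap-gated (abundance, delta) pairs from consecutive samples.

    For each consecutive pair of collection days with gap strictly less than
    ``max_gap`` days, emits (clr at t, clr at t+1 minus clr at t).  Pairs
    violating the gate are dropped, never interpolated.  Returns an (m, 2)
    array (possibly empty).
    """
    if len(series.days) < 2:
        return np.empty((0, 2))
    gaps = np.diff(series.days)
    keep = np.nonzero(gaps < max_gap)[0]
    pairs = np.column_stack([series.clr[keep], series.clr[keep + 1] - series.clr[keep]])
    return pairs


def _linfit(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p=float(res.pvalue),
        n=len(x),
    )


def delta_abundance_stats(pairs: np.ndarray) -> RegressionResult | None:
    """Pearson correlation and OLS fit of delta on abundance.

    The regression-to-the-mean diagnostic: under stationary sampling around a
    fixed carrying capacity this correlation is negative.  Returns None for
    fewer than 3 pairs or zero abundance variance.
    """
    pairs = np.asarray(pairs, dtype=float)
    if len(pairs) < 3:
        return None
    x, d = pairs[:, 0], pairs[:, 1]
    if np.ptp(x) == 0 or np.ptp(d) == 0:
        return None
    return _linfit(x, d)


def ptr_abundance_regression(series: TaxonSeries, min_points: int = 5) -> RegressionResult | None:
    """Per-taxon OLS of CLR abundance (response) against log2(PTR).

    Only days with both measurements present are used; a taxon needs strictly
    more than ``min_points`` matched days to be eligible.  Returns None
    (ineligible / degenerate marker) rather than raising, so donor-level
    batches can carry ineligible taxa through.
    """
    mask = ~np.isnan(series.log2ptr) & ~np.isnan(series.clr)
    if int(mask.sum()) <= min_points:
        return None
    x = series.log2ptr[mask]
    y = series.clr[mask]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return _linfit(x, y)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_combine(pvalues) -> float:
    """Fisher's method: X = -2 Σ ln p_i against chi-square with 2k df."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0):
        raise ValueError("p = 0 gives an infinite Fisher statistic; p-values must be in (0, 1]")
    if np.any(p > 1):
        raise ValueError("p-values must be in (0, 1]")
    return float(sps.combine_pvalues(p, method="fisher")[1])


def adf_stationarity(values, threshold: float = 0.1) -> StationarityResult | None:
    """Augmented Dickey–Fuller unit-root test with automatic (AIC) lag order.

    The null is a unit root, so a significant p-value indicates stationarity;
    the flag is p < ``threshold`` (default 0.1).  Series shorter than 20
    points, with missing values, or constant yield None.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 20 or np.any(np.isnan(x)) or np.ptp(x) == 0:
        return None
    p = float(adfuller(x, autolag="AIC")[1])
    return StationarityResult(p, p < threshold)


def donor_mean_regression(series_list, min_points: int = 5) -> RegressionResult | None:
    """Across-taxon OLS of mean CLR abundance on mean log2(PTR) within a donor.

    Uses taxa eligible for the per-taxon regression (more than ``min_points``
    matched days).  The donor-level p-values produced here are the inputs to
    :func:`fisher_combine`.  Returns None with fewer than 3 eligible taxa.
    """
    eligible = [s for s in series_list if ptr_abundance_regression(s, min_points) is not None]
    if len(eligible) < 3:
        return None
    x = np.array([s.mean_log2ptr for s in eligible])
    y = np.array([s.mu for s in eligible])
    if np.ptp(x) == 0:
        return None
    return _linfit(x, y)


def covariate_adjusted_regression(
    rows: pd.DataFrame, group_col: str = "group", min_group_rows: int = 3
) -> tuple[float, float]:
    """Taxonomy-adjusted association between log2(PTR) and CLR abundance.

    OLS of log2ptr on clr plus group (e.g. class- or species-level) indicator
    terms, over pooled rows with columns 'clr', 'log2ptr' and ``group_col``.
    Groups with fewer than ``min_group_rows`` rows are dropped.  Returns the
    CLR coefficient and its p-value; with a single usable group, falls back
    to the simple regression with a warning.
    """
    df = rows[["clr", "log2ptr", group_col]].dropna().copy()
    counts = df[group_col].value_counts()
    df = df[df[group_col].isin(counts[counts >= min_group_rows].index)]
    n_groups = df[group_col].nunique()
    if len(df) < 3:
        raise ValueError("too few rows after group filtering")
    if n_groups < 2:
        warnings.warn(
            "fewer than 2 usable groups; falling back to unadjusted regression",
            UserWarning,
            stacklevel=2,
        )
        fit = smf.ols("log2ptr ~ clr", data=df).fit()
    else:
        df = df.rename(columns={group_col: "grp"})
        fit = smf.ols("log2ptr ~ clr + C(grp)", data=df).fit()
    return float(fit.params["clr"]), float(fit.pvalues["clr"])
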