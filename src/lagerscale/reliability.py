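"""Scale-screening diagnostics for multi-item Likert scales.

Before any weighting, each multi-item rating scale is screened for internal
consistency (Cronbach's alpha), sampling adequacy (Kaiser-Meyer-Olkin), and
sufficient inter-item correlation (Bartlett's test of sphericity).  All three
are defined on product-moment (Pearson) correlations of the item scores;
respondents with any missing item in a scale are dropped (complete cases),
mirroring the valid-case screening a survey analysis applies instead of
imputing.

Conventional benchmarks: alpha >= 0.70 satisfactory, KMO >= 0.70 good,
Bartlett p < 0.05 suitable for structure detection.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io import RatingsTable, ValidationError

__all__ = [
    "cronbach_alpha",
    "kmo_statistic",
    "kmo_from_correlation",
    "bartlett_sphericity",
    "bartlett_from_correlation",
    "ReliabilityReport",
    "reliability_report",
]


def _complete_matrix(items) -> np.ndarray:
    x = pd.DataFrame(items).astype(float).dropna(axis=0, how="any").to_numpy()
    return x


def cronbach_alpha(items) -> float:
    """Cronbach's alpha of a respondent x item score matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of row totals),
    with sample (ddof=1) variances.  May be negative; equals 1 only when items
    are perfectly consistent.
    """
    x = _complete_matrix(items)
    n, k = x.shape
    if k < 2:
        raise ValidationError("Cronbach's alpha requires at least 2 items")
    if n < 3:
        raise ValidationError("Cronbach's alpha requires at least 3 complete cases")
    item_var = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValidationError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def _correlation(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        const = list(np.where(sd == 0)[0])
        raise ValidationError(f"constant items at positions {const}; remove them")
    return np.corrcoef(x, rowvar=False)


def kmo_from_correlation(r: np.ndarray) -> tuple[float, np.ndarray]:
    """KMO from a correlation matrix: overall value and per-item values.

    The anti-image partial correlations q_ij are read off the inverse of R:
    q_ij = -inv(R)_ij / sqrt(inv(R)_ii * inv(R)_jj).  KMO compares squared raw
    correlations with squared partials; values near 1 mean the correlation
    structure is dominated by common variance.
    """
    r = np.asarray(r, dtype=float)
    try:
        rinv = np.linalg.inv(r)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "singular correlation matrix; remove redundant items"
        ) from exc
    d = np.sqrt(np.outer(np.diag(rinv), np.diag(rinv)))
    q = -rinv / d
    off = ~np.eye(r.shape[0], dtype=bool)
    r2 = r[off] ** 2
    q2 = q[off] ** 2
    overall = float(r2.sum() / (r2.sum() + q2.sum()))
    r2_item = (r**2 * off).sum(axis=0)
    q2_item = (q**2 * off).sum(axis=0)
    per_item = r2_item / (r2_item + q2_item)
    return overall, per_item


def kmo_statistic(items) -> tuple[float, np.ndarray]:
    """KMO sampling-adequacy statistic of a respondent x item matrix."""
    x = _complete_matrix(items)
    n, k = x.shape
    if n <= k:
        raise ValidationError("KMO requires more respondents than items")
    return kmo_from_correlation(_correlation(x))


def bartlett_from_correlation(r: np.ndarray, n: int) -> tuple[float, int, float]:
    """Bartlett's sphericity test from a correlation matrix and sample size.

    chi2 = -(n - 1 - (2k + 5)/6) * ln det(R), df = k(k-1)/2; the null is that
    R is the identity (items uncorrelated).
    """
    r = np.asarray(r, dtype=float)
    k = r.shape[0]
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise ValidationError("correlation matrix is not positive definite")
    stat = -(n - 1 - (2 * k + 5) / 6.0) * logdet
    df = k * (k - 1) // 2
    p = float(chi2.sf(stat, df))
    return float(stat), df, p


def bartlett_sphericity(items) -> tuple[float, int, float]:
    """Bartlett's test of sphericity on a respondent x item matrix."""
    x = _complete_matrix(items)
    n, k = x.shape
    if n <= k:
        raise ValidationError("Bartlett's test requires more respondents than items")
    return bartlett_from_correlation(_correlation(x), n)


@dataclass
class ReliabilityReport:
    """Screening statistics per multi-item scale."""

    table: pd.DataFrame  # index: scale; columns: alpha, kmo, chi2, df, p, n, k

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def reliability_report(ratings: RatingsTable) -> ReliabilityReport:
    """Screen every dimension's sub-attribute scale of a ratings table."""
    h = ratings.hierarchy
    rows = {}
    for d in h.dimensions:
        items = ratings.data[list(h.children[d])].astype(float)
        complete = items.dropna(axis=0, how="any")
        alpha = cronbach_alpha(complete)
        kmo, _ = kmo_statistic(complete)
        stat, df, p = bartlett_sphericity(complete)
        rows[d] = {
            "alpha": alpha,
            "kmo": kmo,
            "bartlett_chi2": stat,
            "bartlett_df": df,
            "bartlett_p": p,
            "n": len(complete),
            "k": items.shape[1],
        }
    return ReliabilityReport(table=pd.DataFrame(rows).T)
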