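"""Core weighting computation: ratings-driven AHP, entropy weights,
subjective-objective fusion, and drinking-frequency cohort aggregation.

The subjective layer departs from classical expert AHP: per-cohort attribute
means on the 1-5 Likert scale are min-max normalized and mapped linearly onto
Saaty's 1-9 intensity scale, v = 1 + 8*(m - min)/(max - min).  The pairwise
comparison matrix is then the ratio matrix a_ij = v_i / v_j, which is
perfectly consistent (CR = 0) and whose principal eigenvector is simply
w = v / sum(v).  The objective layer is the entropy weight method on the raw
respondent x attribute matrix: attributes whose scores are more dispersed
(lower Shannon entropy of the column-normalized score distribution) carry
more information and receive larger weights.

The two layers are fused as a fixed convex combination (default 0.7 AHP /
0.3 EWM, a ratio set by Delphi expert consultation), and per-cohort weights
are aggregated market-wide with population coefficients C_i = f_i N_i / sum
(f = representative drinking occasions per month, N = cohort size).

Note on the aggregation layer: the aggregation formula is stated over the
fused composite weights, but the published comprehensive figures arise from
aggregating the per-cohort AHP layer; the default follows the published
arithmetic (``aggregate_layer='ahp'``) and ``'composite'`` gives the formula
as stated.  See docs/methods.md.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    AttributeHierarchy,
    PipelineConfig,
    RatingsTable,
    ValidationError,
    attribute_means,
)

__all__ = [
    "WeightVector",
    "SaatyMapping",
    "PairwiseMatrix",
    "CohortCoefficients",
    "minmax_to_saaty",
    "ahp_weights_from_values",
    "consistency_ratio",
    "entropy_weights",
    "fuse_weights",
    "cohort_coefficients",
    "aggregate_cohorts",
    "compute_weight_tables",
]

logger = logging.getLogger("lagerscale")

#: Saaty's random consistency index by matrix order.
RANDOM_INDEX = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24,
                7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49}

_NORM_TOL = 1e-9


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class WeightVector:
    """Named nonnegative weights over the attributes of one hierarchy level.

    ``layer`` tags provenance (ahp | ewm | composite | comprehensive);
    ``level`` is ``'dimension'`` or the parent dimension's name for a
    sub-attribute vector; ``cohort`` is a cohort label or ``'all'``.
    Normalized vectors sum to 1 within 1e-9; ``normalized=False`` marks
    intermediate vectors (e.g. after exclusions) that intentionally do not.
    """

    weights: pd.Series
    layer: str = "ahp"
    level: str = "dimension"
    cohort: str = "all"
    normalized: bool = True

    def __post_init__(self):
        self.weights = pd.Series(self.weights, dtype=float)
        if (self.weights < -_NORM_TOL).any():
            raise ValidationError("weights must be nonnegative")
        if self.normalized and abs(self.weights.sum() - 1.0) > _NORM_TOL:
            raise ValidationError(
                f"weights sum to {self.weights.sum()!r}, expected 1"
            )

    @property
    def attributes(self) -> tuple[str, ...]:
        return tuple(self.weights.index)

    def __getitem__(self, attribute: str) -> float:
        return float(self.weights[attribute])

    def as_percent(self, decimals: int = 2) -> pd.Series:
        return (self.weights * 100).round(decimals)


@dataclass(frozen=True)
class SaatyMapping:
    """Attribute means mapped onto the 1-9 AHP intensity scale."""

    means: pd.Series
    values: pd.Series
    vmin: float
    vmax: float


@dataclass(frozen=True)
class PairwiseMatrix:
    """Reciprocal pairwise-comparison matrix with its attribute labels."""

    matrix: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        a = np.asarray(self.matrix, dtype=float)
        n = a.shape[0]
        if a.shape != (n, n):
            raise ValidationError("pairwise matrix must be square")
        if not np.allclose(np.diag(a), 1.0):
            raise ValidationError("pairwise matrix diagonal must be 1")
        if not np.allclose(a * a.T, 1.0, atol=1e-8):
            raise ValidationError("pairwise matrix must be reciprocal")
        object.__setattr__(self, "matrix", a)


@dataclass(frozen=True)
class CohortCoefficients:
    """Population coefficients C_i = f_i N_i / sum(f_j N_j) per cohort."""

    frequency_factors: pd.Series
    sizes: pd.Series
    contributions: pd.Series
    coefficients: pd.Series

    @property
    def cohorts(self) -> tuple[str, ...]:
        return tuple(self.coefficients.index)


# ---------------------------------------------------------------------------
# AHP layer
# ---------------------------------------------------------------------------

def minmax_to_saaty(means: pd.Series | Mapping[str, float]) -> SaatyMapping:
    """Map attribute means onto [1, 9]: v = 1 + 8*(m - min)/(max - min).

    All-equal means degenerate to the scale midpoint 5 (uniform importance),
    with a warning.
    """
    m = pd.Series(means, dtype=float)
    if len(m) < 2:
        raise ValidationError("Saaty mapping needs at least 2 attributes")
    vmin, vmax = float(m.min()), float(m.max())
    if vmax == vmin:
        warnings.warn(
            "all attribute means equal; mapping every value to mid-scale 5",
            stacklevel=2,
        )
        v = pd.Series(5.0, index=m.index)
    else:
        v = 1.0 + 8.0 * (m - vmin) / (vmax - vmin)
    return SaatyMapping(means=m, values=v, vmin=vmin, vmax=vmax)


def ahp_weights_from_values(
    mapping: SaatyMapping, cohort: str = "all", level: str = "dimension"
) -> tuple[WeightVector, PairwiseMatrix]:
    """AHP weights from mapped 1-9 values via the ratio comparison matrix.

    a_ij = v_i / v_j (clipped to Saaty's [1/9, 9] band) is consistent by
    construction, so the principal eigenvector is v itself and the weights
    are w = v / sum(v).
    """
    v = mapping.values.to_numpy()
    a = np.clip(np.outer(v, 1.0 / v), 1.0 / 9.0, 9.0)
    np.fill_diagonal(a, 1.0)
    w = pd.Series(v / v.sum(), index=mapping.values.index)
    vec = WeightVector(weights=w, layer="ahp", level=level, cohort=cohort)
    return vec, PairwiseMatrix(matrix=a, labels=tuple(mapping.values.index))


def consistency_ratio(matrix: PairwiseMatrix) -> float:
    """Saaty consistency ratio CR = CI / RI, CI = (lambda_max - n)/(n - 1).

    lambda_max is the principal eigenvalue of the reciprocal matrix; ratio
    matrices built from a value vector give CR = 0 exactly.  Orders 1-2 are
    consistent by definition.
    """
    a = matrix.matrix
    n = a.shape[0]
    if n > 10:
        raise ValidationError("random-index table covers orders up to 10")
    if n <= 2:
        return 0.0
    eigvals = np.linalg.eigvals(a)
    lam = float(np.max(eigvals.real))
    ci = (lam - n) / (n - 1)
    return float(ci / RANDOM_INDEX[n])


# ---------------------------------------------------------------------------
# Entropy layer
# ---------------------------------------------------------------------------

def entropy_weights(
    ratings: pd.DataFrame, cohort: str = "all", level: str = "dimension"
) -> WeightVector:
    """Entropy-method weights of a respondent x attribute score matrix.

    Columns are normalized to distributions p_ij = x_ij / sum_i x_ij; the
    Shannon entropy e_j = -(1/ln n) sum p ln p (0 ln 0 = 0) yields divergence
    d_j = 1 - e_j and weights w_j = d_j / sum d.  A constant column carries no
    information (e = 1, weight 0); if every column is constant the weights
    degenerate to uniform, with a warning.
    """
    x = pd.DataFrame(ratings).astype(float).dropna(axis=0, how="any")
    if (x.to_numpy() < 0).any():
        raise ValidationError("entropy weights require nonnegative ratings")
    n = len(x)
    if n < 2:
        raise ValidationError("entropy weights require at least 2 respondents")
    arr = x.to_numpy()
    colsum = arr.sum(axis=0)
    if np.any(colsum == 0):
        # all-zero column: no information, treated like a constant column
        colsum = np.where(colsum == 0, 1.0, colsum)
    p = arr / colsum
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    e = -plogp.sum(axis=0) / np.log(n)
    d = 1.0 - e
    d = np.where(np.abs(d) < 1e-12, 0.0, d)
    if d.sum() == 0:
        warnings.warn(
            "every column has zero dispersion; entropy weights fall back "
            "to uniform",
            stacklevel=2,
        )
        w = np.full(arr.shape[1], 1.0 / arr.shape[1])
    else:
        w = d / d.sum()
    return WeightVector(
        weights=pd.Series(w, index=x.columns), layer="ewm",
        level=level, cohort=cohort,
    )


# ---------------------------------------------------------------------------
# Fusion and aggregation
# ---------------------------------------------------------------------------

def fuse_weights(
    w_subj: WeightVector, w_obj: WeightVector, alpha: float = 0.7
) -> WeightVector:
    """Convex fusion w = alpha*subjective + (1-alpha)*objective."""
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError("alpha must lie in [0, 1]")
    if w_subj.attributes != w_obj.attributes:
        raise ValidationError(
            f"attribute sets differ: {w_subj.attributes} vs {w_obj.attributes}"
        )
    w = alpha * w_subj.weights + (1.0 - alpha) * w_obj.weights
    return WeightVector(
        weights=w, layer="composite", level=w_subj.level, cohort=w_subj.cohort
    )


def cohort_coefficients(
    frequency_factors: Mapping[str, float] | pd.Series,
    sizes: Mapping[str, int] | pd.Series,
) -> CohortCoefficients:
    """Population coefficients from frequency factors and cohort sizes."""
    f = pd.Series(frequency_factors, dtype=float)
    n = pd.Series(sizes, dtype=float).reindex(f.index)
    if n.isna().any():
        raise ValidationError("every cohort needs both a factor and a size")
    if (f <= 0).any():
        raise ValidationError("frequency factors must be positive")
    if (n <= 0).any():
        empty = list(n.index[n <= 0])
        raise ValidationError(f"empty cohorts: {empty}")
    m = f * n
    c = m / m.sum()
    return CohortCoefficients(
        frequency_factors=f, sizes=n.astype(int), contributions=m, coefficients=c
    )


def aggregate_cohorts(
    weights: Sequence[WeightVector] | Mapping[str, WeightVector],
    coefficients: CohortCoefficients,
) -> WeightVector:
    """Market-wide weights W_a = sum_k C_k W_k,a across cohorts.

    All cohort vectors must share the attribute set, level, and layer (mixing
    layers silently would blur subjective and objective weights).  Rounding
    drift beyond 1e-9 is renormalized.
    """
    if isinstance(weights, Mapping):
        vecs = {c: weights[c] for c in coefficients.cohorts}
    else:
        vecs = {v.cohort: v for v in weights}
        missing = set(coefficients.cohorts) - set(vecs)
        if missing:
            raise ValidationError(f"no weight vector for cohorts {sorted(missing)}")
    layers = {v.layer for v in vecs.values()}
    if len(layers) != 1:
        raise ValidationError(f"cannot aggregate mixed layers: {sorted(layers)}")
    first = vecs[coefficients.cohorts[0]]
    for v in vecs.values():
        if v.attributes != first.attributes:
            raise ValidationError("cohort vectors cover different attributes")
        if v.level != first.level:
            raise ValidationError("cohort vectors are at different levels")
    total = sum(
        float(coefficients.coefficients[c]) * vecs[c].weights
        for c in coefficients.cohorts
    )
    s = total.sum()
    if abs(s - 1.0) > _NORM_TOL:
        total = total / s
    return WeightVector(
        weights=total, layer="comprehensive", level=first.level, cohort="all"
    )


# ---------------------------------------------------------------------------
# Full per-cohort computation
# ---------------------------------------------------------------------------

def _dimension_matrix(
    data: pd.DataFrame, hierarchy: AttributeHierarchy
) -> pd.DataFrame:
    """Respondent x dimension scores (mean over the dimension's items)."""
    return pd.DataFrame(
        {
            d: data[list(hierarchy.children[d])].astype(float).mean(axis=1)
            for d in hierarchy.dimensions
        }
    )


def compute_weight_tables(
    ratings: RatingsTable, config: PipelineConfig
) -> pd.DataFrame:
    """Run the full weighting engine on a ratings table.

    For every cohort and every level (the dimension level plus each
    dimension's sub-attribute set) computes AHP, EWM, and composite weights;
    then aggregates across cohorts into comprehensive weights with
    coefficients from the configured frequency factors and observed cohort
    sizes.  Returns a tidy frame with columns
    ``cohort, level, attribute, layer, weight``.
    """
    h = config.hierarchy
    means = attribute_means(ratings, level="sub-attribute")
    dim_means = attribute_means(ratings, level="dimension")

    sizes = ratings.cohort_sizes()
    if (sizes < 2).any():
        raise ValidationError(
            f"every cohort needs >= 2 respondents; sizes: {sizes.to_dict()}"
        )
    coeff = cohort_coefficients(
        {c.label: c.frequency_factor for c in config.cohorts}, sizes
    )
    logger.info(
        "cohort coefficients: %s",
        {k: round(v, 4) for k, v in coeff.coefficients.items()},
    )

    levels: list[tuple[str, tuple[str, ...]]] = [("dimension", h.dimensions)]
    levels += [(d, h.children[d]) for d in h.dimensions]

    rows = []
    per_cohort: dict[tuple[str, str], dict[str, WeightVector]] = {}
    for cohort in ratings.cohorts:
        data = ratings.subset(cohort)
        dim_scores = _dimension_matrix(data, h)
        for level, attrs in levels:
            if level == "dimension":
                m = dim_means.slice(cohort, attrs)
                matrix = dim_scores
            else:
                m = means.slice(cohort, attrs)
                matrix = data[list(attrs)]
            ahp, _ = ahp_weights_from_values(
                minmax_to_saaty(m), cohort=cohort, level=level
            )
            ewm = entropy_weights(matrix, cohort=cohort, level=level)
            composite = fuse_weights(ahp, ewm, alpha=config.fusion_alpha)
            per_cohort[(cohort, level)] = {
                "ahp": ahp, "ewm": ewm, "composite": composite,
            }
            for layer, vec in per_cohort[(cohort, level)].items():
                for a, w in vec.weights.items():
                    rows.append(
                        {"cohort": cohort, "level": level, "attribute": a,
                         "layer": layer, "weight": float(w)}
                    )

    logger.info(
        "aggregating the %r layer across cohorts (formula-as-stated would "
        "use 'composite')", config.aggregate_layer,
    )
    for level, attrs in levels:
        vecs = {
            c: per_cohort[(c, level)][config.aggregate_layer]
            for c in ratings.cohorts
        }
        comp = aggregate_cohorts(vecs, coeff)
        for a, w in comp.weights.items():
            rows.append(
                {"cohort": "all", "level": level, "attribute": a,
                 "layer": "comprehensive", "weight": float(w)}
            )
    return pd.DataFrame(rows)
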