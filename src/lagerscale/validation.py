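"""Scoring of tasting sessions and concordance with consumer preference.

A professional panel scores each sample either attribute-by-attribute under
the consumer-oriented scale (composite = weighted average with the scale's
fractional weights, then averaged over assessors) or with a single overall
score under the existing industry scale.  A consumer panel supplies 9-point
hedonic liking scores.  Samples are ranked (rank 1 = best, average ranks on
ties) and agreement between the professional and consumer rankings is
quantified with Kendall's tau-b and Spearman's rho — with four samples no
significance testing is meaningful, so only the coefficients are reported.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import TastingSession, ValidationError
from .scale import ScaleDefinition

__all__ = [
    "ValidationReport",
    "weighted_score",
    "session_composites",
    "mean_hedonic",
    "rank_descending",
    "kendall_tau",
    "spearman_rho",
    "validate_scale",
]


def weighted_score(
    panel_scores: pd.DataFrame, scale: ScaleDefinition
) -> float:
    """Composite score of one sample: mean over assessors of per-assessor
    weighted attribute scores (equivalently, the weighted mean attribute
    score, by linearity — computed per assessor for diagnostics)."""
    w = scale.fractional_weights()
    pivot = panel_scores.pivot_table(
        index="assessor", columns="attribute", values="score", aggfunc="first"
    )
    missing_attrs = [a for a in w.index if a not in pivot.columns]
    if missing_attrs:
        raise ValidationError(f"no scores for scale attributes {missing_attrs}")
    block = pivot[list(w.index)]
    if block.isna().any().any():
        holes = [
            f"{assessor}:{attr}"
            for assessor, row in block.iterrows()
            for attr, v in row.items()
            if pd.isna(v)
        ]
        raise ValidationError(f"missing attribute scores: {holes}")
    per_assessor = block.to_numpy() @ w.to_numpy()
    return float(per_assessor.mean())


def session_composites(
    session: TastingSession, scale: ScaleDefinition | None = None
) -> pd.Series:
    """Per-sample professional composite scores.

    With a scale: weighted attribute averages.  Without one (the existing
    industry scale): the mean of the single ``overall`` score per assessor.
    """
    out = {}
    for sample in session.samples:
        rows = session.panel_scores[session.panel_scores["sample"] == sample]
        if scale is None:
            out[sample] = float(rows["score"].mean())
        else:
            out[sample] = weighted_score(rows, scale)
    return pd.Series(out, name="composite")


def mean_hedonic(session: TastingSession) -> pd.Series:
    """Per-sample mean consumer liking."""
    h = session.hedonic_scores
    if h.empty:
        raise ValidationError("session has no hedonic scores")
    means = h.groupby("sample")["score"].mean()
    empty = [s for s in session.samples if s not in means.index]
    if empty:
        raise ValidationError(f"no consumer scores for samples {empty}")
    return means.reindex(list(session.samples)).astype(float)


def rank_descending(scores: pd.Series | np.ndarray) -> pd.Series:
    """Ranks with 1 = highest score; ties get the average rank."""
    s = pd.Series(scores, dtype=float)
    if len(s) < 2:
        raise ValidationError("ranking needs at least 2 samples")
    return s.rank(ascending=False, method="average")


def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValidationError("inputs must be equal-length vectors of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("rank correlation undefined for constant input")
    return x, y


def kendall_tau(x, y) -> float:
    """Kendall's tau-b (tie-corrected); equals tau-a when there are no ties."""
    x, y = _check_pair(x, y)
    tau = stats.kendalltau(x, y, variant="b").statistic
    return float(tau)


def spearman_rho(x, y) -> float:
    """Spearman's rho: Pearson correlation of tie-averaged ranks."""
    x, y = _check_pair(x, y)
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


@dataclass
class ValidationReport:
    """Concordance of one professional scoring route with consumer liking."""

    scale_id: str
    professional_scores: pd.Series
    consumer_scores: pd.Series
    professional_ranking: pd.Series
    consumer_ranking: pd.Series
    kendall_tau: float
    spearman_rho: float

    def to_dict(self) -> dict:
        return {
            "scale_id": self.scale_id,
            "professional_scores": {
                k: float(v) for k, v in self.professional_scores.items()
            },
            "consumer_scores": {
                k: float(v) for k, v in self.consumer_scores.items()
            },
            "professional_ranking": {
                k: float(v) for k, v in self.professional_ranking.items()
            },
            "consumer_ranking": {
                k: float(v) for k, v in self.consumer_ranking.items()
            },
            "kendall_tau": self.kendall_tau,
            "spearman_rho": self.spearman_rho,
        }


def _report(
    scale_id: str, professional: pd.Series, consumer: pd.Series
) -> ValidationReport:
    pro_rank = rank_descending(professional)
    con_rank = rank_descending(consumer)
    return ValidationReport(
        scale_id=scale_id,
        professional_scores=professional,
        consumer_scores=consumer,
        professional_ranking=pro_rank,
        consumer_ranking=con_rank,
        kendall_tau=kendall_tau(professional, consumer),
        spearman_rho=spearman_rho(professional, consumer),
    )


def validate_scale(
    session_new: TastingSession,
    session_old: TastingSession,
    scale: ScaleDefinition,
) -> tuple[ValidationReport, ValidationReport]:
    """Score both sessions and compare each against consumer liking.

    The new-scale session carries per-attribute panel scores; the old-scale
    session a single overall score per assessor.  Both sessions must cover
    the same samples; the consumer panel is shared (taken from the new-scale
    session, or from the old one if the new session has no hedonic block).
    """
    if set(session_new.samples) != set(session_old.samples):
        raise ValidationError(
            f"sample sets differ: {sorted(session_new.samples)} vs "
            f"{sorted(session_old.samples)}"
        )
    hedonic_source = (
        session_new if not session_new.hedonic_scores.empty else session_old
    )
    consumer = mean_hedonic(hedonic_source)

    new_scores = session_composites(session_new, scale)
    old_scores = session_composites(session_old, scale=None)
    order = list(session_new.samples)
    return (
        _report(session_new.scale_id, new_scores.reindex(order), consumer.reindex(order)),
        _report(session_old.scale_id, old_scores.reindex(order), consumer.reindex(order)),
    )
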