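"""End-to-end orchestration: simulate -> reliability -> weights ->
build-scale -> validate -> report.

Two entry modes exist.  ``run_pipeline`` computes everything from a raw (or
synthetic) ratings table.  ``run_published_pipeline`` starts instead from the
printed comprehensive weight tables of the original study — the raw survey
was never deposited, so this is the route that reproduces the published
scale and validation numbers exactly.

Every artifact bundle is deterministic given config + seed and is stamped
with a hash of the canonical config serialization and the package version.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import PipelineConfig, RatingsTable, TastingSession
from .published import (
    CONSUMER_HEDONIC_MEANS,
    NEW_SCALE_PROFESSIONAL_SCORES,
    OLD_SCALE_PROFESSIONAL_SCORES,
    comprehensive_dimension_vector,
    comprehensive_sub_vectors,
)
from .reliability import reliability_report
from .scale import ScaleDefinition, build_scale
from .simulate import SurveyConfig, TastingConfig, generate_survey, generate_tasting
from .validation import (
    ValidationReport,
    _report,
    validate_scale,
)
from .weighting import WeightVector, compute_weight_tables

__all__ = ["PipelineResult", "run_pipeline", "run_published_pipeline", "config_hash"]

logger = logging.getLogger("lagerscale")


def _percent_column(weights: pd.DataFrame) -> pd.Series:
    """Display percents at 2 decimals, sum-preserving per weight vector.

    Independent half-up rounding can drift a 9-attribute vector by several
    hundredths, so each (cohort, level, layer) group is rounded by largest
    remainder at 0.01-percent resolution to total exactly 100.00.
    """
    out = pd.Series(0.0, index=weights.index)
    for _, idx in weights.groupby(["cohort", "level", "layer"]).groups.items():
        w = weights.loc[idx, "weight"]
        scaled = w * 10000.0
        floors = np.floor(scaled)
        shortfall = int(round(10000 - floors.sum()))
        remainders = scaled - floors
        order = remainders.sort_values(ascending=False).index
        floors.loc[order[:shortfall]] += 1
        out.loc[idx] = floors / 100.0
    return out


def config_hash(config: PipelineConfig) -> str:
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    """Artifact bundle of one pipeline run."""

    weights: pd.DataFrame
    scale: ScaleDefinition
    reliability: pd.DataFrame | None = None
    validation: tuple[ValidationReport, ValidationReport] | None = None
    config_hash: str = ""
    version: str = __version__

    def write(self, outdir: str | Path) -> None:
        """Persist the bundle as CSV/JSON under *outdir*."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stamp = {"config_hash": self.config_hash, "version": self.version}

        weights = self.weights.copy()
        weights["percent"] = _percent_column(weights)
        weights.to_csv(outdir / "weights.csv", index=False)

        scale_doc = {**stamp, **self.scale.to_dict()}
        (outdir / "scale.json").write_text(
            json.dumps(scale_doc, indent=2, sort_keys=True) + "\n"
        )
        if self.reliability is not None:
            self.reliability.to_csv(outdir / "reliability.csv")
        if self.validation is not None:
            new, old = self.validation
            doc = {**stamp, "new_scale": new.to_dict(), "existing_scale": old.to_dict()}
            (outdir / "validation.json").write_text(
                json.dumps(doc, indent=2, sort_keys=True) + "\n"
            )


def _scale_inputs_from_table(
    weights: pd.DataFrame, config: PipelineConfig
) -> tuple[dict[str, WeightVector], WeightVector, dict[str, dict[str, float]]]:
    """Slice a tidy weight table into build_scale inputs."""
    h = config.hierarchy
    comp = weights[(weights["layer"] == "comprehensive")]
    dim_rows = comp[comp["level"] == "dimension"].set_index("attribute")["weight"]
    dim_vec = WeightVector(
        weights=dim_rows, layer="comprehensive", level="dimension", cohort="all"
    )
    sub_vecs = {}
    tiebreak: dict[str, dict[str, float]] = {}
    for d in h.dimensions:
        rows = comp[comp["level"] == d].set_index("attribute")["weight"]
        if len(rows):
            sub_vecs[d] = WeightVector(
                weights=rows, layer="comprehensive", level=d, cohort="all"
            )
        ahp_rows = weights[
            (weights["layer"] == "ahp") & (weights["level"] == d)
        ]
        if len(ahp_rows):
            # pooled pre-merge AHP weight per attribute, for rank-k tie-breaks
            tiebreak[d] = (
                ahp_rows.groupby("attribute")["weight"].mean().to_dict()
            )
    return sub_vecs, dim_vec, tiebreak


def run_pipeline(
    config: PipelineConfig,
    ratings: RatingsTable | None = None,
    tasting_new: TastingSession | None = None,
    tasting_old: TastingSession | None = None,
    with_reliability: bool = True,
) -> PipelineResult:
    """Full computation from a ratings table (synthesized when absent)."""
    if ratings is None:
        logger.info("no ratings supplied; generating a synthetic survey")
        ratings = generate_survey(
            SurveyConfig(hierarchy=config.hierarchy, seed=config.seed)
        )
    rel = reliability_report(ratings).to_frame() if with_reliability else None
    weights = compute_weight_tables(ratings, config)
    sub_vecs, dim_vec, tiebreak = _scale_inputs_from_table(weights, config)
    scale = build_scale(
        sub_vecs, dim_vec, config.hierarchy, k=config.top_k,
        ahp_tiebreak=tiebreak,
    )

    validation = None
    if tasting_new is None and tasting_old is None:
        truth = _default_tasting_truth(scale)
        tasting_new = generate_tasting(
            TastingConfig(
                attributes=scale.attributes,
                true_intensity=truth["intensity"],
                true_hedonic=truth["hedonic"],
                scale_id="consumer",
                seed=config.seed,
            )
        )
        tasting_old = generate_tasting(
            TastingConfig(
                attributes=("overall",),
                true_intensity=truth["overall"],
                true_hedonic={},
                scale_id="existing",
                seed=config.seed + 1,
            )
        )
        tasting_old.hedonic_scores = tasting_old.hedonic_scores.iloc[0:0]
    if tasting_new is not None and tasting_old is not None:
        validation = validate_scale(tasting_new, tasting_old, scale)

    return PipelineResult(
        weights=weights,
        scale=scale,
        reliability=rel,
        validation=validation,
        config_hash=config_hash(config),
    )


def _default_tasting_truth(scale: ScaleDefinition) -> dict:
    """Planted truth for the demo tasting: four samples of graded quality."""
    quality = {"YJ": 7.5, "BW": 6.5, "HR": 6.0, "QD": 4.8}
    intensity = {
        (s, a): min(9.0, max(1.0, q))
        for s, q in quality.items()
        for a in scale.attributes
    }
    overall = {(s, "overall"): q for s, q in quality.items()}
    return {"intensity": intensity, "overall": overall, "hedonic": quality}


def run_published_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Reproduce the published scale and validation from printed tables.

    Builds the scale from the printed comprehensive weights and computes the
    rank-concordance reports from the printed professional and consumer
    scores.
    """
    config = config or PipelineConfig()
    sub_vecs = comprehensive_sub_vectors()
    dim_vec = comprehensive_dimension_vector()
    scale = build_scale(sub_vecs, dim_vec, config.hierarchy, k=config.top_k)

    samples = list(NEW_SCALE_PROFESSIONAL_SCORES)
    consumer = pd.Series(CONSUMER_HEDONIC_MEANS, dtype=float).reindex(samples)
    new = _report(
        "consumer",
        pd.Series(NEW_SCALE_PROFESSIONAL_SCORES, dtype=float).reindex(samples),
        consumer,
    )
    old = _report(
        "existing",
        pd.Series(OLD_SCALE_PROFESSIONAL_SCORES, dtype=float).reindex(samples),
        consumer,
    )

    rows = []
    for d, vec in sub_vecs.items():
        for a, w in vec.weights.items():
            rows.append(
                {"cohort": "all", "level": d, "attribute": a,
                 "layer": "comprehensive", "weight": float(w)}
            )
    for a, w in dim_vec.weights.items():
        rows.append(
            {"cohort": "all", "level": "dimension", "attribute": a,
             "layer": "comprehensive", "weight": float(w)}
        )
    return PipelineResult(
        weights=pd.DataFrame(rows),
        scale=scale,
        validation=(new, old),
        config_hash=config_hash(config),
    )
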