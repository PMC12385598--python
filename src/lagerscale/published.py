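"""Reference weight tables and tasting scores of the pale-lager consumer
study this package reimplements.

The study's raw survey and panel data were not deposited; its printed
per-cohort and market-wide weight tables, population coefficients, and
validation tasting scores are, however, sufficient to re-run everything from
the fusion step onward.  This module ships those printed values so the late
pipeline stages (fusion, cohort aggregation, scale construction, validation)
can be reproduced and checked without the raw data.

All weights are in percent, exactly as printed (rows may sum to 100 +/- 0.01
from the source's own rounding).
"""
from __future__ import annotations

import pandas as pd

from .weighting import CohortCoefficients, WeightVector

__all__ = [
    "COHORT_DIMENSION_WEIGHTS",
    "COMPREHENSIVE_DIMENSION_WEIGHTS",
    "COMPREHENSIVE_SUB_WEIGHTS",
    "POPULATION_COEFFICIENTS",
    "NEW_SCALE_PROFESSIONAL_SCORES",
    "OLD_SCALE_PROFESSIONAL_SCORES",
    "CONSUMER_HEDONIC_MEANS",
    "FINAL_SCALE_WEIGHTS",
    "published_coefficients",
    "comprehensive_dimension_vector",
    "comprehensive_sub_vectors",
    "cohort_ahp_dimension_vectors",
]

#: Per-cohort dimension-level weights (percent) by layer.  The low-frequency
#: cohort's taste and appearance AHP/EWM shares were never printed; only the
#: layers needed to reproduce the published arithmetic are included.
COHORT_DIMENSION_WEIGHTS: dict[str, dict[str, dict[str, float]]] = {
    "low": {
        "ahp": {"drinking_sensation": 65.32, "aroma": 7.26},
        "ewm": {"drinking_sensation": 25.19, "aroma": 28.58},
        "composite": {
            "drinking_sensation": 53.28,
            "taste": 17.06,
            "appearance": 16.01,
            "aroma": 13.66,
        },
    },
    "mid": {
        "ahp": {
            "drinking_sensation": 38.59,
            "appearance": 31.65,
            "taste": 25.49,
            "aroma": 4.29,
        },
        "ewm": {
            "drinking_sensation": 26.51,
            "appearance": 19.30,
            "taste": 25.77,
            "aroma": 28.42,
        },
        "composite": {
            "drinking_sensation": 34.97,
            "appearance": 27.95,
            "taste": 25.57,
            "aroma": 11.53,
        },
    },
    "high": {
        "ahp": {
            "aroma": 49.49,
            "taste": 31.40,
            "drinking_sensation": 13.61,
            "appearance": 5.50,
        },
        "ewm": {
            "aroma": 24.76,
            "taste": 22.52,
            "drinking_sensation": 25.61,
            "appearance": 27.11,
        },
        "composite": {
            "aroma": 42.07,
            "taste": 28.98,
            "drinking_sensation": 16.90,
            "appearance": 10.34,
        },
    },
}

#: Market-wide comprehensive dimension weights (percent).
COMPREHENSIVE_DIMENSION_WEIGHTS = {
    "drinking_sensation": 30.92,
    "taste": 26.60,
    "aroma": 24.77,
    "appearance": 17.71,
}

#: Market-wide comprehensive sub-attribute weights (percent) per dimension.
#: Appearance sub-attributes carry no published tertiary weights.
COMPREHENSIVE_SUB_WEIGHTS: dict[str, dict[str, float]] = {
    "aroma": {
        "malt": 25.88,
        "floral": 20.02,
        "fermentation": 20.31,
        "sweet_aroma": 18.61,
        "fruit": 10.35,
        "hop": 4.83,
    },
    "taste": {
        "astringency": 27.59,
        "sweetness": 26.70,
        "bitterness": 21.92,
        "umami": 13.47,
        "sourness": 10.33,
    },
    "drinking_sensation": {
        "persistence": 15.53,
        "alcohol_warmth": 15.45,
        "body_coordination": 14.36,
        "smoothness": 12.83,
        "aftertaste": 11.81,
        "refreshment": 9.99,
        "fullness": 8.59,
        "foam_fineness": 5.94,
        "prickliness": 5.51,
    },
}

#: Population coefficients C_i (frequency factors 2/6/14; exact cohort sizes
#: were not printed, so the coefficients are taken as printed constants).
POPULATION_COEFFICIENTS = {"low": 0.1285, "mid": 0.4269, "high": 0.4446}

#: Validation tasting: professional composites under the new scale.
NEW_SCALE_PROFESSIONAL_SCORES = {"YJ": 6.61, "HR": 5.80, "BW": 5.75, "QD": 3.98}

#: Professional scores under the existing industry scale.
OLD_SCALE_PROFESSIONAL_SCORES = {"YJ": 6.20, "HR": 5.03, "BW": 5.63, "QD": 6.40}

#: Consumer mean hedonic liking per sample.
CONSUMER_HEDONIC_MEANS = {"YJ": 7.43, "HR": 5.97, "BW": 6.47, "QD": 4.83}

#: The published final nine-attribute scale (percent).
FINAL_SCALE_WEIGHTS = {
    "aftertaste_persistence": 18.84,
    "astringency": 11.70,
    "fruity_fermentation": 11.34,
    "sweetness": 11.32,
    "body_coordination": 9.89,
    "malt": 9.57,
    "bitterness": 9.30,
    "hop_flower": 9.19,
    "smoothness": 8.84,
}


def published_coefficients() -> CohortCoefficients:
    """The printed population coefficients as a CohortCoefficients object.

    Sizes are unknown; contributions are stored proportional to the printed
    coefficients (factors 2/6/14 imply relative sizes, not absolute counts).
    """
    c = pd.Series(POPULATION_COEFFICIENTS, dtype=float)
    c = c / c.sum()
    f = pd.Series({"low": 2.0, "mid": 6.0, "high": 14.0})
    implied_sizes = (c / f) / (c / f).sum()
    return CohortCoefficients(
        frequency_factors=f,
        sizes=implied_sizes,
        contributions=c,
        coefficients=c,
    )


def comprehensive_dimension_vector() -> WeightVector:
    """Comprehensive dimension weights as a fraction-valued vector."""
    w = pd.Series(COMPREHENSIVE_DIMENSION_WEIGHTS, dtype=float) / 100.0
    return WeightVector(
        weights=w / w.sum(), layer="comprehensive", level="dimension",
        cohort="all",
    )


def comprehensive_sub_vectors() -> dict[str, WeightVector]:
    """Comprehensive sub-attribute weights per dimension, as fractions."""
    out = {}
    for dim, table in COMPREHENSIVE_SUB_WEIGHTS.items():
        w = pd.Series(table, dtype=float) / 100.0
        out[dim] = WeightVector(
            weights=w / w.sum(), layer="comprehensive", level=dim, cohort="all"
        )
    return out


def cohort_ahp_dimension_vectors() -> dict[str, pd.Series]:
    """Printed per-cohort AHP dimension weights (percent), as Series.

    The low-frequency cohort's taste and appearance shares were not printed;
    the returned low-cohort series contains only the published entries.
    """
    return {
        c: pd.Series(COHORT_DIMENSION_WEIGHTS[c]["ahp"], dtype=float)
        for c in COHORT_DIMENSION_WEIGHTS
    }
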