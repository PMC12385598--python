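"""Data model and file I/O for questionnaire ratings, attribute hierarchies,
and tasting sessions.

The attribute hierarchy is the coordinate system of the whole analysis: four
sensory dimensions (appearance, aroma, taste, drinking sensation), each broken
into sub-attributes, plus a merge map (perceptually similar attributes that are
consolidated before scale construction) and an exclusion list (attributes or
whole dimensions dropped from the final scale).

File formats are deliberately plain: UTF-8 comma-separated CSV with a mandatory
header and ``NA`` marking missing ratings, and a single YAML configuration file
holding the hierarchy and every pipeline constant, so a run is reproducible
from config + ratings alone.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "ValidationError",
    "ConfigError",
    "AttributeHierarchy",
    "RatingsTable",
    "MeanSummary",
    "TastingSession",
    "CohortDefinition",
    "PipelineConfig",
    "DEFAULT_HIERARCHY",
    "DEFAULT_COHORTS",
    "default_config",
    "load_config",
    "save_config",
    "load_ratings",
    "write_ratings",
    "load_tasting",
    "write_tasting",
    "attribute_means",
]

MISSING_TOKEN = "NA"


class SchemaError(ValueError):
    """A file or table does not match the expected schema."""


class ValidationError(ValueError):
    """Values violate the declared constraints (bounds, labels, counts)."""


class ConfigError(ValueError):
    """The pipeline configuration is internally inconsistent."""


# ---------------------------------------------------------------------------
# Attribute hierarchy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AttributeHierarchy:
    """Dimension -> sub-attribute tree plus merge map and exclusions.

    Parameters
    ----------
    dimensions
        Ordered dimension names.
    children
        Mapping dimension -> ordered list of sub-attribute names.
    merge_map
        Mapping merged-name -> list of source sub-attributes.  Each source may
        appear in at most one merge group; merged names must not collide with
        any existing name.
    exclusions
        Attribute or dimension names excluded from scale construction.
    """

    dimensions: tuple[str, ...]
    children: Mapping[str, tuple[str, ...]]
    merge_map: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    exclusions: tuple[str, ...] = ()

    def __post_init__(self):
        children = {d: tuple(self.children[d]) for d in self.dimensions}
        object.__setattr__(self, "dimensions", tuple(self.dimensions))
        object.__setattr__(self, "children", children)
        object.__setattr__(
            self, "merge_map", {m: tuple(s) for m, s in self.merge_map.items()}
        )
        object.__setattr__(self, "exclusions", tuple(self.exclusions))
        self._validate()

    def _validate(self) -> None:
        if set(self.children) != set(self.dimensions):
            raise ConfigError("children keys must equal the dimension list")
        seen: dict[str, str] = {}
        for d in self.dimensions:
            for a in self.children[d]:
                if a in seen:
                    raise ConfigError(
                        f"sub-attribute {a!r} appears under both "
                        f"{seen[a]!r} and {d!r}"
                    )
                if a in self.children:
                    raise ConfigError(f"{a!r} is both a dimension and a sub-attribute")
                seen[a] = d
        merged_sources: set[str] = set()
        for merged, sources in self.merge_map.items():
            if merged in seen or merged in self.children:
                raise ConfigError(f"merged name {merged!r} collides with the hierarchy")
            for s in sources:
                if s not in seen:
                    raise ConfigError(f"merge source {s!r} not in the hierarchy")
                if s in merged_sources:
                    raise ConfigError(f"merge source {s!r} used in two merge groups")
                merged_sources.add(s)
            if len({seen[s] for s in sources}) != 1:
                raise ConfigError(
                    f"merge group {merged!r} spans multiple dimensions"
                )

    @property
    def attributes(self) -> tuple[str, ...]:
        """All sub-attributes in hierarchy order."""
        return tuple(a for d in self.dimensions for a in self.children[d])

    def dimension_of(self, attribute: str) -> str:
        for d in self.dimensions:
            if attribute in self.children[d]:
                return d
        raise KeyError(attribute)

    def merged_children(self, dimension: str) -> tuple[str, ...]:
        """Sub-attributes of *dimension* after applying the merge map."""
        out: list[str] = []
        added: set[str] = set()
        source_to_merged = {
            s: m for m, sources in self.merge_map.items() for s in sources
        }
        for a in self.children[dimension]:
            m = source_to_merged.get(a)
            if m is None:
                out.append(a)
            elif m not in added:
                out.append(m)
                added.add(m)
        return tuple(out)

    def to_dict(self) -> dict:
        return {
            "dimensions": {d: list(self.children[d]) for d in self.dimensions},
            "merge_map": {m: list(s) for m, s in self.merge_map.items()},
            "exclusions": list(self.exclusions),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AttributeHierarchy":
        dims = d["dimensions"]
        return cls(
            dimensions=tuple(dims),
            children={k: tuple(v) for k, v in dims.items()},
            merge_map={k: tuple(v) for k, v in d.get("merge_map", {}).items()},
            exclusions=tuple(d.get("exclusions", ())),
        )


#: Default pale-lager hierarchy.  Appearance sub-attributes carry no published
#: tertiary weights and the dimension is excluded from the final scale; foam
#: fineness sits under drinking sensation, where the weight tables place it.
DEFAULT_HIERARCHY = AttributeHierarchy(
    dimensions=("appearance", "aroma", "taste", "drinking_sensation"),
    children={
        "appearance": ("beer_color", "clarity", "foam_abundance"),
        "aroma": ("malt", "hop", "fruit", "floral", "sweet_aroma", "fermentation"),
        "taste": ("sourness", "sweetness", "bitterness", "umami", "astringency"),
        "drinking_sensation": (
            "smoothness",
            "fullness",
            "refreshment",
            "body_coordination",
            "prickliness",
            "alcohol_warmth",
            "aftertaste",
            "persistence",
            "foam_fineness",
        ),
    },
    merge_map={
        "hop_flower": ("hop", "floral"),
        "fruity_fermentation": ("fruit", "fermentation"),
        "aftertaste_persistence": ("aftertaste", "persistence"),
    },
    exclusions=("alcohol_warmth", "appearance"),
)


# ---------------------------------------------------------------------------
# Cohorts and pipeline configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortDefinition:
    """A drinking-frequency band with its Delphi frequency factor.

    ``frequency_factor`` is the representative occasions-per-month value used
    to weight the cohort's contribution when aggregating weights market-wide.
    """

    label: str
    min_occasions: int
    max_occasions: int | None  # None = open-ended
    frequency_factor: float


DEFAULT_COHORTS = (
    CohortDefinition("low", 1, 3, 2.0),
    CohortDefinition("mid", 4, 8, 6.0),
    CohortDefinition("high", 9, None, 14.0),
)


@dataclass
class PipelineConfig:
    """Every tunable of the analysis in one reproducible object."""

    hierarchy: AttributeHierarchy = DEFAULT_HIERARCHY
    cohorts: tuple[CohortDefinition, ...] = DEFAULT_COHORTS
    fusion_alpha: float = 0.7          # subjective (AHP) share in the fusion
    aggregate_layer: str = "ahp"       # which per-cohort layer feeds aggregation
    top_k: int = 3                     # sub-attributes retained per dimension
    survey_scale: tuple[int, int] = (1, 5)
    tasting_scale: tuple[int, int] = (1, 9)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.fusion_alpha <= 1.0:
            raise ConfigError("fusion_alpha must lie in [0, 1]")
        if self.aggregate_layer not in ("ahp", "composite"):
            raise ConfigError("aggregate_layer must be 'ahp' or 'composite'")
        if self.top_k < 1:
            raise ConfigError("top_k must be >= 1")
        labels = [c.label for c in self.cohorts]
        if len(set(labels)) != len(labels):
            raise ConfigError("cohort labels must be unique")

    @property
    def cohort_labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.cohorts)

    def to_dict(self) -> dict:
        return {
            "hierarchy": self.hierarchy.to_dict(),
            "cohorts": [
                {
                    "label": c.label,
                    "min_occasions": c.min_occasions,
                    "max_occasions": c.max_occasions,
                    "frequency_factor": c.frequency_factor,
                }
                for c in self.cohorts
            ],
            "fusion_alpha": self.fusion_alpha,
            "aggregate_layer": self.aggregate_layer,
            "top_k": self.top_k,
            "survey_scale": list(self.survey_scale),
            "tasting_scale": list(self.tasting_scale),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        kwargs: dict = {}
        if "hierarchy" in d:
            kwargs["hierarchy"] = AttributeHierarchy.from_dict(d["hierarchy"])
        if "cohorts" in d:
            kwargs["cohorts"] = tuple(
                CohortDefinition(
                    label=c["label"],
                    min_occasions=c["min_occasions"],
                    max_occasions=c.get("max_occasions"),
                    frequency_factor=c["frequency_factor"],
                )
                for c in d["cohorts"]
            )
        for key in ("fusion_alpha", "aggregate_layer", "top_k", "seed"):
            if key in d:
                kwargs[key] = d[key]
        for key in ("survey_scale", "tasting_scale"):
            if key in d:
                kwargs[key] = tuple(d[key])
        return cls(**kwargs)


def default_config() -> PipelineConfig:
    return PipelineConfig()


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Ratings table
# ---------------------------------------------------------------------------

@dataclass
class RatingsTable:
    """Respondent x sub-attribute Likert matrix with cohort labels.

    ``data`` holds one row per respondent: a ``respondent_id`` column, a
    ``cohort`` column, one nullable-integer column per sub-attribute, and any
    extra demographic columns.  Missing ratings are ``pd.NA`` in memory and
    ``NA`` on disk — never silently zero.
    """

    data: pd.DataFrame
    hierarchy: AttributeHierarchy
    cohorts: tuple[str, ...] = tuple(c.label for c in DEFAULT_COHORTS)
    scale: tuple[int, int] = (1, 5)

    def __post_init__(self):
        self.validate()

    @property
    def attributes(self) -> tuple[str, ...]:
        return self.hierarchy.attributes

    @property
    def n(self) -> int:
        return len(self.data)

    def validate(self) -> None:
        df = self.data
        required = ["respondent_id", "cohort"]
        missing_cols = [c for c in required if c not in df.columns]
        if missing_cols:
            raise SchemaError(f"missing required columns: {missing_cols}")
        missing_attrs = [a for a in self.attributes if a not in df.columns]
        if missing_attrs:
            raise SchemaError(f"missing attribute columns: {missing_attrs}")

        lo, hi = self.scale
        bad_rows: list[int] = []
        for a in self.attributes:
            col = pd.to_numeric(df[a], errors="coerce")
            notna = col.notna()
            ok = (
                (col >= lo) & (col <= hi) & (col == col.round())
            ) | ~notna
            bad = df.index[~ok & notna]
            bad_rows.extend(int(i) for i in bad)
        if bad_rows:
            rows = sorted(set(bad_rows))
            raise ValidationError(
                f"ratings outside [{lo}, {hi}] or non-integer in rows {rows}"
            )

        unknown = set(df["cohort"].unique()) - set(self.cohorts)
        if unknown:
            raise ValidationError(f"unknown cohort labels: {sorted(unknown)}")
        # normalize attribute storage to nullable Int64
        for a in self.attributes:
            self.data[a] = pd.to_numeric(df[a], errors="coerce").astype("Int64")

    def cohort_sizes(self) -> pd.Series:
        return self.data["cohort"].value_counts().reindex(self.cohorts, fill_value=0)

    def subset(self, cohort: str) -> pd.DataFrame:
        """Rows of one cohort ('all' pools every respondent)."""
        if cohort == "all":
            return self.data
        if cohort not in self.cohorts:
            raise KeyError(cohort)
        return self.data[self.data["cohort"] == cohort]

    def __eq__(self, other) -> bool:
        if not isinstance(other, RatingsTable):
            return NotImplemented
        if self.hierarchy != other.hierarchy or self.cohorts != other.cohorts:
            return False
        cols = ["respondent_id", "cohort", *self.attributes]
        a = self.data[cols].reset_index(drop=True)
        b = other.data[cols].reset_index(drop=True)
        return a.equals(b)


def load_ratings(
    path: str | Path,
    hierarchy: AttributeHierarchy = DEFAULT_HIERARCHY,
    cohorts: Sequence[str] = tuple(c.label for c in DEFAULT_COHORTS),
    scale: tuple[int, int] = (1, 5),
) -> RatingsTable:
    """Read a ratings CSV and validate it against the hierarchy.

    The header must name ``respondent_id``, ``cohort``, and one column per
    sub-attribute; extra columns are kept as demographics.  Errors name the
    offending rows (0-based data rows, excluding the header).
    """
    df = pd.read_csv(path, na_values=[MISSING_TOKEN], keep_default_na=False)
    return RatingsTable(
        data=df, hierarchy=hierarchy, cohorts=tuple(cohorts), scale=scale
    )


def write_ratings(table: RatingsTable, path: str | Path) -> None:
    cols = ["respondent_id", "cohort", *table.attributes]
    extra = [c for c in table.data.columns if c not in cols]
    out = table.data[cols + extra].copy()
    out.to_csv(path, index=False, na_rep=MISSING_TOKEN)


# ---------------------------------------------------------------------------
# Mean / SD summaries
# ---------------------------------------------------------------------------

@dataclass
class MeanSummary:
    """Per-(cohort, attribute) mean, sample SD (ddof=1), and count.

    ``table`` is indexed by (cohort, attribute); the pooled rows use cohort
    label ``'all'``.
    """

    table: pd.DataFrame
    level: str  # 'sub-attribute' or 'dimension'

    def slice(self, cohort: str, attributes: Iterable[str]) -> pd.Series:
        """Means for one cohort over an ordered attribute set."""
        attrs = list(attributes)
        sub = self.table.loc[cohort]
        missing = [a for a in attrs if a not in sub.index]
        if missing:
            raise KeyError(f"no summary for attributes {missing} in cohort {cohort!r}")
        return sub.loc[attrs, "mean"]


def attribute_means(
    ratings: RatingsTable, level: str = "sub-attribute"
) -> MeanSummary:
    """Per-cohort and pooled mean/SD/n at sub-attribute or dimension level.

    A respondent's dimension score is the mean of their non-missing ratings on
    that dimension's sub-attributes.  Missing values are excluded pairwise; an
    attribute with fewer than 2 ratings in any cohort is an error.
    """
    if level not in ("sub-attribute", "dimension"):
        raise ValueError("level must be 'sub-attribute' or 'dimension'")
    h = ratings.hierarchy
    if level == "sub-attribute":
        frame = ratings.data[list(h.attributes)].astype(float)
    else:
        frame = pd.DataFrame(
            {
                d: ratings.data[list(h.children[d])].astype(float).mean(axis=1)
                for d in h.dimensions
            }
        )
    frame = frame.assign(cohort=ratings.data["cohort"].values)

    rows = []
    groups = [("all", frame)] + [
        (c, frame[frame["cohort"] == c]) for c in ratings.cohorts
    ]
    for cohort, g in groups:
        for a in frame.columns.drop("cohort"):
            col = g[a].dropna()
            n = len(col)
            if n == 0:
                raise ValidationError(
                    f"attribute {a!r} has no ratings in cohort {cohort!r}"
                )
            if n < 2:
                raise ValidationError(
                    f"attribute {a!r} has fewer than 2 ratings in cohort {cohort!r}"
                )
            rows.append(
                {
                    "cohort": cohort,
                    "attribute": a,
                    "mean": float(col.mean()),
                    "sd": float(col.std(ddof=1)),
                    "n": n,
                }
            )
    table = pd.DataFrame(rows).set_index(["cohort", "attribute"])
    return MeanSummary(table=table, level=level)


# ---------------------------------------------------------------------------
# Tasting sessions
# ---------------------------------------------------------------------------

@dataclass
class TastingSession:
    """Blind-tasting data: panel intensity scores and consumer hedonic scores.

    ``panel_scores`` is long form (assessor, sample, attribute, score) with
    integer intensities on the tasting scale; an existing-scale session uses
    the single attribute ``'overall'``.  ``hedonic_scores`` is
    (consumer, sample, score) liking on the same 1-9 scale.
    """

    panel_scores: pd.DataFrame
    hedonic_scores: pd.DataFrame
    scale_id: str = "unnamed"
    score_range: tuple[int, int] = (1, 9)

    def __post_init__(self):
        self.validate()

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.panel_scores["sample"]))

    @property
    def attributes(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.panel_scores["attribute"]))

    def validate(self) -> None:
        for name, df, cols in (
            ("panel_scores", self.panel_scores, ["assessor", "sample", "attribute", "score"]),
            ("hedonic_scores", self.hedonic_scores, ["consumer", "sample", "score"]),
        ):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise SchemaError(f"{name} missing columns {missing}")
            lo, hi = self.score_range
            s = df["score"]
            if ((s < lo) | (s > hi) | (s != s.round())).any():
                raise ValidationError(
                    f"{name}: scores must be integers in [{lo}, {hi}]"
                )
        # complete block: every assessor scores every (sample, attribute)
        counts = self.panel_scores.groupby(["assessor"]).size()
        expected = len(self.samples) * len(self.attributes)
        bad = counts[counts != expected]
        if len(bad):
            raise ValidationError(
                f"incomplete panel block for assessors {list(bad.index)}"
            )


def load_tasting(
    path: str | Path, scale_id: str = "unnamed", score_range: tuple[int, int] = (1, 9)
) -> TastingSession:
    """Read a long-form tasting CSV.

    Columns: ``assessor_id, role, sample, attribute, score`` with
    ``role in {panel, consumer}``; consumer rows use attribute ``hedonic``.
    """
    df = pd.read_csv(path, na_values=[MISSING_TOKEN], keep_default_na=False)
    required = ["assessor_id", "role", "sample", "attribute", "score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"tasting file missing columns {missing}")
    bad_roles = set(df["role"].unique()) - {"panel", "consumer"}
    if bad_roles:
        raise ValidationError(f"unknown roles: {sorted(bad_roles)}")
    panel = df[df["role"] == "panel"].rename(columns={"assessor_id": "assessor"})
    cons = df[df["role"] == "consumer"].rename(columns={"assessor_id": "consumer"})
    return TastingSession(
        panel_scores=panel[["assessor", "sample", "attribute", "score"]].reset_index(drop=True),
        hedonic_scores=cons[["consumer", "sample", "score"]].reset_index(drop=True),
        scale_id=scale_id,
        score_range=score_range,
    )


def write_tasting(session: TastingSession, path: str | Path) -> None:
    panel = session.panel_scores.rename(columns={"assessor": "assessor_id"}).assign(
        role="panel"
    )
    cons = session.hedonic_scores.rename(columns={"consumer": "assessor_id"}).assign(
        role="consumer", attribute="hedonic"
    )
    cols = ["assessor_id", "role", "sample", "attribute", "score"]
    pd.concat([panel[cols], cons[cols]]).to_csv(path, index=False)
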