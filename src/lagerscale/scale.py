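"""Construction of the consumer-oriented sensory evaluation scale.

Starting from comprehensive weights at both hierarchy levels, the scale is
built in a fixed order: perceptually similar sub-attributes are merged (their
weights summed), configured attributes or whole dimensions are excluded, the
top-k (default 3) sub-attributes per retained dimension are selected, and a
three-step standardization is applied — local normalization within each
dimension, multiplication by the dimension's weight, and global normalization
so the scale sums to 100%.  Display weights are finally converted to integer
percentages summing to exactly 100 by the largest-remainder method.

Merging happens before top-k selection: a merged attribute competes for a
top-3 slot with its combined weight, which is what lets a pairing of two
mid-ranked aromas outrank either source alone.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .io import AttributeHierarchy, ValidationError
from .weighting import WeightVector

__all__ = [
    "ScaleDefinition",
    "SCORE_ANCHORS",
    "merge_attributes",
    "apply_exclusions",
    "top_k_local_normalize",
    "integrate_and_globalize",
    "integerize",
    "build_scale",
]

logger = logging.getLogger("lagerscale")

#: Intensity anchors of the 9-point attribute scale.
SCORE_ANCHORS = {1: "extremely weak", 9: "extremely strong"}


@dataclass
class ScaleDefinition:
    """The final evaluation scale.

    ``table`` has one row per scale attribute, ordered by descending weight:
    fractional weight (sums to 1), integer percent (sums to exactly 100), the
    source dimension, and the source sub-attributes behind any merge.
    """

    table: pd.DataFrame
    scale_id: str = "consumer"
    anchors: Mapping[int, str] = field(default_factory=lambda: dict(SCORE_ANCHORS))

    def __post_init__(self):
        frac = self.table["weight"]
        if abs(frac.sum() - 1.0) > 1e-9:
            raise ValidationError("fractional scale weights must sum to 1")
        if int(self.table["integer_weight"].sum()) != 100:
            raise ValidationError("integer scale weights must sum to 100")

    @property
    def attributes(self) -> tuple[str, ...]:
        return tuple(self.table["attribute"])

    def fractional_weights(self) -> pd.Series:
        return pd.Series(
            self.table["weight"].values, index=self.table["attribute"]
        )

    def to_dict(self) -> dict:
        return {
            "scale_id": self.scale_id,
            "anchors": {int(k): v for k, v in self.anchors.items()},
            "attributes": self.table.to_dict(orient="records"),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScaleDefinition":
        return cls(
            table=pd.DataFrame(d["attributes"]),
            scale_id=d.get("scale_id", "consumer"),
            anchors={int(k): v for k, v in d.get("anchors", SCORE_ANCHORS).items()},
        )


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------

def merge_attributes(
    w: WeightVector, merge_map: Mapping[str, Sequence[str]]
) -> WeightVector:
    """Sum the weights of each merge group into its merged attribute.

    Total weight is conserved; attributes outside any group pass through in
    their original order, the merged name taking the position of its first
    source.
    """
    relevant = {
        m: tuple(srcs) for m, srcs in merge_map.items()
        if any(s in w.weights.index for s in tuple(srcs))
    }
    for m, srcs in relevant.items():
        missing = [s for s in srcs if s not in w.weights.index]
        if missing:
            raise ValidationError(
                f"merge group {m!r}: source attributes {missing} absent"
            )
    source_to_merged = {s: m for m, srcs in relevant.items() for s in srcs}
    out: dict[str, float] = {}
    for a, val in w.weights.items():
        m = source_to_merged.get(a)
        if m is None:
            out[a] = out.get(a, 0.0) + float(val)
        else:
            out[m] = out.get(m, 0.0) + float(val)
    return WeightVector(
        weights=pd.Series(out), layer=w.layer, level=w.level,
        cohort=w.cohort, normalized=w.normalized,
    )


def apply_exclusions(
    w: WeightVector, exclusions: Sequence[str]
) -> WeightVector:
    """Drop excluded attributes without renormalizing.

    Renormalization is deferred to the three-step standardization.  Excluding
    a name that is not present is a warning, not an error.
    """
    present = [e for e in exclusions if e in w.weights.index]
    absent = [e for e in exclusions if e not in w.weights.index]
    if absent:
        warnings.warn(f"exclusions not present, ignored: {absent}", stacklevel=2)
    kept = w.weights.drop(present)
    if len(kept) == 0:
        warnings.warn(
            f"all attributes of level {w.level!r} excluded", stacklevel=2
        )
    return WeightVector(
        weights=kept, layer=w.layer, level=w.level, cohort=w.cohort,
        normalized=False,
    )


def top_k_local_normalize(
    w: WeightVector, k: int = 3, tiebreak: Mapping[str, float] | None = None
) -> WeightVector:
    """Keep the k largest attributes and rescale them to sum to 1.

    A tie at rank k is broken by the larger value in ``tiebreak`` (the
    pre-merge AHP weights, when available), then lexicographically — the
    selection is deterministic either way.
    """
    if len(w.weights) < k:
        raise ValidationError(
            f"dimension {w.level!r} has {len(w.weights)} attributes, "
            f"needs at least k={k}"
        )
    tb = tiebreak or {}
    order = sorted(
        w.weights.index,
        key=lambda a: (-w.weights[a], -tb.get(a, 0.0), a),
    )
    top = order[:k]
    kept = w.weights.loc[top]
    total = kept.sum()
    if total == 0:
        raise ValidationError(f"top-{k} weights of {w.level!r} are all zero")
    return WeightVector(
        weights=kept / total, layer=w.layer, level=w.level, cohort=w.cohort
    )


def integrate_and_globalize(
    locals_: Mapping[str, WeightVector], dim_weights: WeightVector
) -> pd.DataFrame:
    """Weighted integration then global normalization.

    Each dimension's local weights are multiplied by that dimension's weight
    and the products are renormalized so the scale sums to 1.  Returns a frame
    with columns ``attribute, dimension, weight`` ordered by descending
    weight.
    """
    rows = []
    for dim, local in locals_.items():
        if dim not in dim_weights.weights.index:
            raise ValidationError(f"no dimension weight for {dim!r}")
        dw = float(dim_weights.weights[dim])
        for a, lw in local.weights.items():
            rows.append(
                {"attribute": a, "dimension": dim, "weight": float(lw) * dw}
            )
    df = pd.DataFrame(rows)
    df["weight"] = df["weight"] / df["weight"].sum()
    return df.sort_values(
        ["weight", "attribute"], ascending=[False, True]
    ).reset_index(drop=True)


def integerize(fractions: pd.Series | Mapping[str, float]) -> pd.Series:
    """Integer percentages summing to 100 by the largest-remainder method.

    Each fraction gets floor(100*f); the shortfall goes one point at a time to
    the largest fractional remainders, ties broken by larger fraction then
    lexicographic attribute name.
    """
    f = pd.Series(fractions, dtype=float)
    if abs(f.sum() - 1.0) > 1e-6:
        raise ValidationError(f"fractions sum to {f.sum()}, expected 1")
    scaled = 100.0 * f
    floors = scaled.apply(math.floor).astype(int)
    shortfall = 100 - int(floors.sum())
    remainders = scaled - floors
    order = sorted(
        f.index, key=lambda a: (-remainders[a], -f[a], str(a))
    )
    out = floors.copy()
    for a in order[:shortfall]:
        out[a] += 1
    return out


# ---------------------------------------------------------------------------
# Full construction
# ---------------------------------------------------------------------------

def build_scale(
    sub_weights: Mapping[str, WeightVector],
    dim_weights: WeightVector,
    hierarchy: AttributeHierarchy,
    k: int = 3,
    ahp_tiebreak: Mapping[str, Mapping[str, float]] | None = None,
    scale_id: str = "consumer",
) -> ScaleDefinition:
    """Merge -> exclude -> top-k -> three-step standardization -> integerize.

    Parameters
    ----------
    sub_weights
        Comprehensive sub-attribute weight vector per dimension.
    dim_weights
        Comprehensive dimension weights.
    hierarchy
        Supplies the merge map and exclusion list; a dimension name in the
        exclusion list drops the whole dimension.
    ahp_tiebreak
        Optional per-dimension pre-merge AHP weights used only to break exact
        ties at rank k.
    """
    excluded_dims = [e for e in hierarchy.exclusions if e in hierarchy.dimensions]
    attr_exclusions = [e for e in hierarchy.exclusions if e not in excluded_dims]
    if excluded_dims:
        logger.info("dimensions excluded from the scale: %s", excluded_dims)

    locals_: dict[str, WeightVector] = {}
    provenance: dict[str, list[str]] = {}
    for dim in dim_weights.weights.index:
        if dim in excluded_dims:
            continue
        if dim not in sub_weights:
            raise ValidationError(f"no sub-attribute weights for {dim!r}")
        merged = merge_attributes(sub_weights[dim], hierarchy.merge_map)
        local_exclusions = [e for e in attr_exclusions if e in merged.weights.index]
        filtered = apply_exclusions(merged, local_exclusions)
        tb = dict((ahp_tiebreak or {}).get(dim, {}))
        locals_[dim] = top_k_local_normalize(filtered, k=k, tiebreak=tb)
        for a in locals_[dim].attributes:
            provenance[a] = list(hierarchy.merge_map.get(a, (a,)))

    retained_dims = pd.Series(
        {d: float(dim_weights.weights[d]) for d in locals_}
    )
    dim_vec = WeightVector(
        weights=retained_dims, layer=dim_weights.layer,
        level="dimension", cohort=dim_weights.cohort, normalized=False,
    )
    table = integrate_and_globalize(locals_, dim_vec)
    ints = integerize(table.set_index("attribute")["weight"])
    table["integer_weight"] = table["attribute"].map(ints).astype(int)
    table["sources"] = table["attribute"].map(provenance)
    return ScaleDefinition(table=table, scale_id=scale_id)
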