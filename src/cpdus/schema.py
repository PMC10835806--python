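"""The 42-trait schema used throughout the package.

Traits F1-F10 describe the whole flower (shape, size, openness), F11-F26 the
outer perianth whorl and F27-F42 the inner whorl.  Fourteen of the traits are
image-derived descriptors that go beyond the classical DUS guideline set
(contour perimeter/area, equal-circle area, concavity, circularity,
compactness, whorl areas and the full secondary-colour description of the
outer perianth); the remaining 28 correspond to guideline characteristics.

Categorical traits are stored as small integer codes; the code tables live in
this module so that extraction, synthesis and reporting agree on them.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "TraitDef",
    "TRAIT_SCHEMA",
    "TRAIT_IDS",
    "NOVEL_TRAITS",
    "DUS_TRAITS",
    "FEATURE_GROUPS",
    "SHAPE_CODES",
    "APEX_SHAPE_CODES",
    "APEX_STATE_CODES",
    "MARGIN_CODES",
    "POSITION_CODES",
    "DISTRIBUTION_CODES",
    "trait_def",
    "schema_frame",
]


@dataclass(frozen=True)
class TraitDef:
    """One trait: identifier, human name, flower part, measurement scale."""

    id: str
    name: str
    part: str  # overall | outer | inner
    scale: str  # nominal | ordinal | continuous
    novel: bool = False


# Integer code tables for categorical/ordinal states.
SHAPE_CODES = {"broad_elliptic": 1, "elliptic": 2, "narrow_elliptic": 3}
APEX_SHAPE_CODES = {"acute": 1, "obtuse": 2, "rounded": 3}
APEX_STATE_CODES = {"reflexed": 1, "straight": 2, "incurved": 3}
MARGIN_CODES = {"entire": 1, "undulate": 2}
POSITION_CODES = {"separated": 1, "touching": 2, "overlapping": 3}
DISTRIBUTION_CODES = {"none": 0, "basal": 1, "marginal": 2, "striped": 3, "full": 4}

_T = TraitDef
TRAIT_SCHEMA: tuple[TraitDef, ...] = (
    _T("F1", "Flower type", "overall", "nominal"),
    _T("F2", "Maximum diameter", "overall", "continuous"),
    _T("F3", "Perimeter", "overall", "continuous", True),
    _T("F4", "Area", "overall", "continuous", True),
    _T("F5", "Equal circle area", "overall", "continuous", True),
    _T("F6", "Concave-convex ratio", "overall", "continuous", True),
    _T("F7", "Circularity", "overall", "continuous", True),
    _T("F8", "Compactness", "overall", "continuous", True),
    _T("F9", "Outer perianth position relationship", "overall", "ordinal"),
    _T("F10", "Outer perianth extension angle", "overall", "continuous"),
    _T("F11", "Number of outer perianth", "outer", "continuous"),
    _T("F12", "Minimum rectangular length of outer perianth", "outer", "continuous"),
    _T("F13", "Minimum rectangular width of outer perianth", "outer", "continuous"),
    _T("F14", "Outer perianth shape", "outer", "ordinal"),
    _T("F15", "Outer perianth area", "outer", "continuous", True),
    _T("F16", "Outer perianth apex shape", "outer", "ordinal"),
    _T("F17", "Outer perianth apex state", "outer", "ordinal"),
    _T("F18", "Outer perianth marginal state", "outer", "ordinal"),
    _T("F19", "Average R value of outer perianth main color", "outer", "continuous"),
    _T("F20", "Average G value of outer perianth main color", "outer", "continuous"),
    _T("F21", "Average B value of outer perianth main color", "outer", "continuous"),
    _T("F22", "Average R value of outer perianth secondary color", "outer", "continuous", True),
    _T("F23", "Average G value of outer perianth secondary color", "outer", "continuous", True),
    _T("F24", "Average B value of outer perianth secondary color", "outer", "continuous", True),
    _T("F25", "Percentage of secondary color area of outer perianth", "outer", "continuous", True),
    _T("F26", "Whether the outer perianth is polychromatic", "outer", "ordinal", True),
    _T("F27", "Number of inner perianth", "inner", "continuous"),
    _T("F28", "Minimum rectangular length of inner perianth", "inner", "continuous"),
    _T("F29", "Minimum rectangular width of inner perianth", "inner", "continuous", True),
    _T("F30", "Inner perianth shape", "inner", "ordinal"),
    _T("F31", "Inner perianth area", "inner", "continuous", True),
    _T("F32", "Inner perianth apex shape", "inner", "ordinal"),
    _T("F33", "Inner perianth apex state", "inner", "ordinal"),
    _T("F34", "Average R value of inner perianth main color", "inner", "continuous"),
    _T("F35", "Average G value of inner perianth main color", "inner", "continuous"),
    _T("F36", "Average B value of inner perianth main color", "inner", "continuous"),
    _T("F37", "Average R value of inner perianth secondary color", "inner", "continuous"),
    _T("F38", "Average G value of inner perianth secondary color", "inner", "continuous"),
    _T("F39", "Average B value of inner perianth secondary color", "inner", "continuous"),
    _T("F40", "Percentage of secondary color area of inner perianth", "inner", "continuous"),
    _T("F41", "Whether the inner perianth is polychromatic", "inner", "ordinal"),
    _T("F42", "Inner perianth secondary color distribution type", "inner", "nominal"),
)

TRAIT_IDS: tuple[str, ...] = tuple(t.id for t in TRAIT_SCHEMA)
NOVEL_TRAITS: tuple[str, ...] = tuple(t.id for t in TRAIT_SCHEMA if t.novel)
DUS_TRAITS: tuple[str, ...] = tuple(t.id for t in TRAIT_SCHEMA if not t.novel)

#: Benchmark feature groups: the full set, the guideline (non-novel) subset
#: and the three flower parts.
FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "all": TRAIT_IDS,
    "dus": DUS_TRAITS,
    "entirety": tuple(t.id for t in TRAIT_SCHEMA if t.part == "overall"),
    "outer": tuple(t.id for t in TRAIT_SCHEMA if t.part == "outer"),
    "inner": tuple(t.id for t in TRAIT_SCHEMA if t.part == "inner"),
}

_BY_ID = {t.id: t for t in TRAIT_SCHEMA}


def trait_def(trait_id: str) -> TraitDef:
    """Look up one trait definition by id (``"F7"`` ...)."""
    return _BY_ID[trait_id]


def schema_frame():
    """The schema as a :class:`pandas.DataFrame` (one row per trait)."""
    import pandas as pd

    return pd.DataFrame([vars(t) for t in TRAIT_SCHEMA]).set_index("id")
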