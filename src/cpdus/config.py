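"""Tunable thresholds and defaults, collected in one place.

All decision thresholds used by the trait extractor (shape-class cut points,
polychromatic rules, apex-angle bins ...) live here rather than being buried
in code, so a user can adapt them to another crop's DUS guideline without
touching the extraction logic.  ``ExtractionConfig.from_yaml`` accepts a YAML
mapping with any subset of the fields.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["ExtractionConfig", "DEFAULT_CONFIG"]


@dataclass
class ExtractionConfig:
    # -- imaging --------------------------------------------------------
    polarity: str = "auto"  # auto | dark_bg | light_bg
    binarize_method: str = "otsu"  # otsu | fixed
    fixed_threshold: int = 128
    close_radius: int = 2

    # -- perianth counting ---------------------------------------------
    angular_bins: int = 360
    profile_smooth_window: int = 13  # bins, circular moving average
    flat_profile_rel_range: float = 0.04  # below this ρ(θ) is "no petal structure"

    # -- petal shape classes (min-rect aspect ratio length/width) -------
    narrow_aspect: float = 3.0  # >= -> narrow elliptic
    broad_aspect: float = 1.5  # <  -> broad elliptic

    # -- apex classification --------------------------------------------
    apex_acute_deg: float = 60.0  # turning angle at tip below -> acute
    apex_rounded_deg: float = 120.0  # above -> rounded
    apex_arc_fraction: float = 0.08  # contour arc offset used to measure the tip angle
    apex_state_offset: float = 0.15  # |lateral tip offset|/length above -> curved

    # -- margin ----------------------------------------------------------
    margin_hf_energy: float = 0.02  # HF share of ρ(θ) spectrum above -> undulate

    # -- petal position relationship (angular coverage of the whorl) -----
    position_separated: float = 0.80  # coverage below -> separated
    position_touching: float = 1.05  # coverage below -> touching, else overlapping

    # -- flower type (extension-angle bins, degrees) ----------------------
    extension_bins: tuple = (70.0, 110.0)

    # -- secondary colour -------------------------------------------------
    poly_min_pct: float = 5.0  # secondary area percentage
    poly_min_rgb_dist: float = 30.0  # Euclidean RGB distance between clusters
    # A band painted at the base (rim) concentrates the secondary pixels at
    # low (high) normalised radius; stripes span the whole radial range.  In
    # area measure the radius of a uniform region distributes like 2r, which
    # puts the class means near 2/3*sqrt(f), 2/3 and 0.9 — hence these cuts.
    dist_basal_rmax: float = 0.55  # mean normalised radius below -> basal
    dist_marginal_rmin: float = 0.75  # above -> marginal
    dist_striped_sd: float = 0.21  # sd of normalised radius above -> striped
    dist_full_pct: float = 60.0  # secondary percentage above -> full

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExtractionConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


DEFAULT_CONFIG = ExtractionConfig()
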