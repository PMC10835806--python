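"""Seedable synthetic flower renderer with ground-truth trait vectors.

Real DUS image sets (thousands of studio photographs of cultivar flowers)
are rarely redistributable, so this module fabricates one: each variety is an
archetype (petal counts, petal geometry, base/secondary colour, secondary
placement, openness angle) from which individual flowers are realised with
controlled jitter and rendered in the four standard views — front, outer
perianth whorl, inner perianth whorl and side profile — on near-uniform dark
or light backgrounds.

Varieties belong to one of three colour groups that mimic the classical
wintersweet classification: ``concolor`` (inner perianth plain, no secondary
colour), ``intermedius`` (small purple secondary fraction) and ``patens``
(large purple fraction).

Petals are painted as rotated superellipse lobes around a centre, so every
rendered quantity (painted area, secondary-pixel fraction, petal count,
realised petal dimensions) is known exactly and recorded as ground truth;
the trait extractor is tested against these records.  Rendering is fully
deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.spatial import ConvexHull
from skimage import measure

from .schema import (
    APEX_SHAPE_CODES,
    APEX_STATE_CODES,
    DISTRIBUTION_CODES,
    MARGIN_CODES,
    POSITION_CODES,
    SHAPE_CODES,
    TRAIT_IDS,
)

__all__ = [
    "VarietySpec",
    "FlowerRealization",
    "RenderedSample",
    "sample_variety_specs",
    "render_sample",
    "render_flower",
    "generate_dataset",
    "sample_trait_table",
    "planted_table",
    "GROUPS",
    "VIEWS",
    "BACKGROUNDS",
]

GROUPS = ("concolor", "intermedius", "patens")
VIEWS = ("front", "outer", "inner", "side")
BACKGROUNDS = {"dark": (30, 30, 30), "light": (235, 235, 235)}

#: Canvas size the archetype pixel dimensions refer to; other render sizes rescale.
REFERENCE_SIZE = 512
#: Inner whorl linear scale relative to the outer whorl.
INNER_SCALE = 0.55
#: Superellipse tip exponents per apex type (lower = sharper tip).
APEX_EXPONENT = {"acute": 1.3, "obtuse": 2.0, "rounded": 2.8}

# Thresholds shared with the extractor's defaults (see cpdus.config).
_POLY_MIN_PCT = 5.0
_POLY_MIN_DIST = 30.0
_FULL_PCT = 60.0
_EXT_BINS = (70.0, 110.0)
_COVER_SEPARATED = 0.80
_COVER_TOUCHING = 1.05

#: Flower radiance factor for light-background shots: white backgrounds are
#: photographed at a shorter exposure, so the flower renders darker while the
#: background stays near-white.  Keeps the silhouette luma-separable.
LIGHT_BG_EXPOSURE = 0.55


def _exposed(rgb: tuple[int, int, int], background: str) -> tuple[int, int, int]:
    if background == "light":
        return tuple(int(round(v * LIGHT_BG_EXPOSURE)) for v in rgb)
    return tuple(int(v) for v in rgb)


@dataclass
class VarietySpec:
    """Archetype parameters of one synthetic variety.

    Pixel dimensions refer to a 512 px canvas and are rescaled when rendering
    at a different size.
    """

    variety_id: int
    group: str
    outer_count_mean: float
    inner_count_mean: float
    petal_length_px: float
    petal_width_px: float
    petal_aspect_jitter: float
    base_rgb: tuple[int, int, int]
    secondary_rgb: tuple[int, int, int]
    inner_secondary_fraction: float
    outer_secondary_fraction: float
    secondary_distribution: str  # basal | marginal | striped | full
    apex_type: str  # acute | obtuse | rounded
    extension_angle_deg: float
    pixel_noise_sd: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.group == "concolor" and self.inner_secondary_fraction != 0:
            raise ValueError("concolor varieties have no inner secondary colour")
        for f in (self.inner_secondary_fraction, self.outer_secondary_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("secondary fractions must lie in [0, 1]")
        if self.outer_count_mean < 3 or self.inner_count_mean < 3:
            raise ValueError("petal count means must be >= 3")
        if not 0.0 < self.extension_angle_deg < 180.0:
            raise ValueError("extension angle must lie in (0, 180) degrees")
        if self.pixel_noise_sd < 0:
            raise ValueError("pixel noise sd must be >= 0")


@dataclass
class FlowerRealization:
    """Per-flower realised parameters drawn around the variety archetype."""

    n_outer: int
    n_inner: int
    outer_length: float  # px at render size
    outer_width: float
    inner_length: float
    inner_width: float
    extension_deg: float
    phase_outer: float  # whorl rotation, radians
    phase_inner: float


@dataclass
class RenderedSample:
    """Four rendered views of one flower plus its ground-truth trait vector."""

    variety_id: int
    flower_id: int
    images: dict[str, np.ndarray]
    masks: dict[str, np.ndarray]
    truth: dict[str, float]
    realization: FlowerRealization
    background: str = "dark"

    def __post_init__(self) -> None:
        missing = set(VIEWS) - set(self.images)
        if missing:
            raise ValueError(f"missing views: {sorted(missing)}")


def sample_variety_specs(n_varieties: int, seed: int) -> list[VarietySpec]:
    """Draw ``n_varieties`` distinct variety archetypes, deterministically.

    Colour groups are assigned round-robin so all three are represented as
    soon as ``n_varieties >= 3``.
    """
    if n_varieties < 2:
        raise ValueError("need at least 2 varieties")
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_varieties):
        group = GROUPS[i % 3]
        if group == "concolor":
            inner_frac = 0.0
            outer_frac = 0.0
        elif group == "intermedius":
            inner_frac = float(rng.uniform(0.10, 0.35))
            outer_frac = 0.0 if rng.random() < 0.5 else float(rng.uniform(0.08, 0.20))
        else:  # patens
            inner_frac = float(rng.uniform(0.55, 0.85))
            outer_frac = float(rng.uniform(0.10, 0.30))
        length = float(rng.uniform(120, 180))
        aspect = float(rng.uniform(1.3, 4.2))
        specs.append(
            VarietySpec(
                variety_id=i + 1,
                group=group,
                outer_count_mean=float(rng.uniform(5.0, 9.0)),
                inner_count_mean=float(rng.uniform(3.0, 6.0)),
                petal_length_px=length,
                petal_width_px=length / aspect,
                petal_aspect_jitter=0.04,
                base_rgb=(
                    int(rng.integers(210, 256)),
                    int(rng.integers(150, 226)),
                    int(rng.integers(10, 91)),
                ),
                secondary_rgb=(
                    int(rng.integers(170, 221)),
                    int(rng.integers(60, 111)),
                    int(rng.integers(120, 181)),
                ),
                inner_secondary_fraction=inner_frac,
                outer_secondary_fraction=outer_frac,
                secondary_distribution=str(rng.choice(["basal", "marginal", "striped"])),
                apex_type=str(rng.choice(list(APEX_EXPONENT))),
                extension_angle_deg=float(rng.uniform(60, 150)),
                pixel_noise_sd=5.0,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# painting primitives
# ---------------------------------------------------------------------------


def _grid(size: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - c, xx - c
    return dy, dx, np.hypot(dy, dx), np.arctan2(dy, dx)


def _whorl_mask(
    size: int,
    n_petals: int,
    length: float,
    width: float,
    apex_p: float,
    phase: float,
) -> np.ndarray:
    """Paint ``n_petals`` superellipse lobes radiating from the centre."""
    dy, dx, r, _ = _grid(size)
    # central receptacle disk keeps the whorl a single connected region
    mask = r <= max(3.0, 0.12 * length)
    a, b = length / 2.0, width / 2.0
    for k in range(n_petals):
        theta = phase + 2.0 * math.pi * k / n_petals
        ct, st = math.cos(theta), math.sin(theta)
        u = dx * ct + dy * st  # along the petal axis
        v = -dx * st + dy * ct  # across it
        with np.errstate(invalid="ignore"):
            member = (np.abs(u - a) / a) ** apex_p + (v / b) ** 2 <= 1.0
        mask |= member
    return mask


def _radial_norm(mask: np.ndarray, n_bins: int = 720) -> np.ndarray:
    """Normalised radial position r/rho(theta) of each foreground pixel."""
    size = mask.shape[0]
    dy, dx, r, phi = _grid(size)
    bins = ((phi % (2 * math.pi)) / (2 * math.pi) * n_bins).astype(int) % n_bins
    rho = np.zeros(n_bins)
    np.maximum.at(rho, bins[mask], r[mask])
    rho = np.maximum(rho, 1e-9)
    out = np.zeros_like(r)
    out[mask] = r[mask] / rho[bins[mask]]
    return out


def _secondary_mask(
    mask: np.ndarray,
    fraction: float,
    distribution: str,
    n_petals: int,
    phase: float,
) -> np.ndarray:
    """Choose which foreground pixels receive the secondary colour.

    Basal/marginal placement uses the quantile of the normalised radial
    position, so the painted fraction equals the target almost exactly;
    stripes are angular sectors radiating from the centre.
    """
    sec = np.zeros_like(mask)
    if fraction <= 0 or not mask.any():
        return sec
    if fraction >= 1 or distribution == "full":
        sec[mask] = True
        return sec
    if distribution in ("basal", "marginal"):
        rnorm = _radial_norm(mask)
        vals = rnorm[mask]
        if distribution == "basal":
            sec[mask] = vals <= np.quantile(vals, fraction)
        else:
            sec[mask] = vals >= np.quantile(vals, 1.0 - fraction)
    elif distribution == "striped":
        size = mask.shape[0]
        _, _, _, phi = _grid(size)
        n_stripes = max(2 * n_petals, 6)
        t = ((phi - phase) % (2 * math.pi)) / (2 * math.pi) * n_stripes
        sec = mask & ((t % 1.0) < fraction)
    else:
        raise ValueError(f"unknown secondary distribution {distribution!r}")
    return sec


def _compose(
    size: int,
    layers: list[tuple[np.ndarray, tuple[int, int, int]]],
    background: str,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    img = np.empty((size, size, 3), dtype=np.float64)
    img[:] = BACKGROUNDS[background]
    for mask, rgb in layers:
        img[mask] = rgb
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _sector_mask(size: int, angle_deg: float, radius: float) -> np.ndarray:
    """Upward-opening filled circular sector, apex near the bottom."""
    apex = (0.85 * (size - 1), (size - 1) / 2.0)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - apex[0], xx - apex[1]
    r = np.hypot(dy, dx)
    phi = np.arctan2(dy, dx)  # up is -pi/2 (y grows downward)
    half = math.radians(angle_deg) / 2.0
    dev = np.abs((phi + math.pi / 2 + math.pi) % (2 * math.pi) - math.pi)
    return (r <= radius) & (dev <= half)


# ---------------------------------------------------------------------------
# truth measurement (independent of the cpdus.imaging chain)
# ---------------------------------------------------------------------------


def _mask_geometry(mask: np.ndarray) -> dict[str, float]:
    """Pixel-count / convex-hull geometry of a painted silhouette.

    Deliberately avoids the contour-tracing code under test: area is the
    pixel count, the hull comes from all foreground pixel centres and the
    perimeter is the Crofton estimate.
    """
    pts = np.argwhere(mask).astype(float)
    area = float(mask.sum())
    hull = ConvexHull(pts)
    hv = pts[hull.vertices]
    d2 = ((hv[:, None, :] - hv[None, :, :]) ** 2).sum(-1)
    feret = float(np.sqrt(d2.max()))
    perimeter = float(measure.perimeter_crofton(mask, directions=4))
    return {
        "area": area,
        "perimeter": perimeter,
        "feret": feret,
        "hull_area": float(hull.volume),
    }


def _position_code(n: int, length: float, width: float) -> int:
    coverage = n * 2.0 * math.atan2(width, length) / (2.0 * math.pi)
    if coverage < _COVER_SEPARATED:
        return POSITION_CODES["separated"]
    if coverage < _COVER_TOUCHING:
        return POSITION_CODES["touching"]
    return POSITION_CODES["overlapping"]


def _extension_bin(angle: float) -> int:
    return int(np.searchsorted(_EXT_BINS, angle, side="right"))


def _shape_code(aspect: float) -> int:
    if aspect >= 3.0:
        return SHAPE_CODES["narrow_elliptic"]
    if aspect >= 1.5:
        return SHAPE_CODES["elliptic"]
    return SHAPE_CODES["broad_elliptic"]


_COMPLEMENT_PLACEMENT = {"basal": "marginal", "marginal": "basal", "striped": "striped", "full": "full"}


def _colour_truth(
    pct_painted: float, base: tuple, paint: tuple, distribution: str
) -> tuple[tuple, tuple, float, int, int]:
    """Realised colour description under the smaller-cluster convention.

    The extractor reports the larger colour cluster as "main" and the
    smaller as "secondary", so when more than half the whorl is painted the
    roles swap: the paint colour becomes the main colour and the unpainted
    base occupies the complementary placement (a basal paint band leaves a
    marginal base remnant, and vice versa).  Returns
    ``(main_rgb, secondary_rgb, secondary_pct, polychromatic, code)``.
    """
    if pct_painted > 50.0:
        main, sec = tuple(paint), tuple(base)
        pct = 100.0 - pct_painted
        placement = _COMPLEMENT_PLACEMENT[distribution]
    else:
        main, sec = tuple(base), tuple(paint)
        pct = pct_painted
        placement = distribution
    dist = float(np.linalg.norm(np.subtract(main, sec, dtype=float)))
    poly = int(pct >= _POLY_MIN_PCT and dist >= _POLY_MIN_DIST)
    if not poly:
        return main, main, 0.0, 0, DISTRIBUTION_CODES["none"]
    code = DISTRIBUTION_CODES["full"] if pct > _FULL_PCT else DISTRIBUTION_CODES[placement]
    return main, sec, pct, 1, code


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _realize(spec: VarietySpec, rng: np.random.Generator, scale: float) -> FlowerRealization:
    j = spec.petal_aspect_jitter
    length = spec.petal_length_px * float(np.clip(1 + j * rng.standard_normal(), 0.8, 1.2))
    width = spec.petal_width_px * float(np.clip(1 + j * rng.standard_normal(), 0.8, 1.2))
    return FlowerRealization(
        n_outer=max(3, int(round(spec.outer_count_mean + 0.7 * rng.standard_normal()))),
        n_inner=max(3, int(round(spec.inner_count_mean + 0.5 * rng.standard_normal()))),
        outer_length=length * scale,
        outer_width=width * scale,
        inner_length=length * INNER_SCALE * scale,
        inner_width=width * INNER_SCALE * scale,
        extension_deg=float(np.clip(spec.extension_angle_deg + 3.0 * rng.standard_normal(), 10, 175)),
        phase_outer=float(rng.uniform(0, 2 * math.pi)),
        phase_inner=float(rng.uniform(0, 2 * math.pi)),
    )


def render_sample(
    spec: VarietySpec,
    rng: np.random.Generator,
    flower_id: int = 0,
    size: int = 512,
    background: str = "dark",
) -> RenderedSample:
    """Render all four views of one flower and assemble its ground truth."""
    scale = size / REFERENCE_SIZE
    real = _realize(spec, rng, scale)
    apex_p = APEX_EXPONENT[spec.apex_type]

    outer_whorl = _whorl_mask(size, real.n_outer, real.outer_length, real.outer_width, apex_p, real.phase_outer)
    inner_whorl = _whorl_mask(size, real.n_inner, real.inner_length, real.inner_width, apex_p, real.phase_inner)

    outer_sec = _secondary_mask(
        outer_whorl, spec.outer_secondary_fraction, spec.secondary_distribution, real.n_outer, real.phase_outer
    )
    inner_sec = _secondary_mask(
        inner_whorl, spec.inner_secondary_fraction, spec.secondary_distribution, real.n_inner, real.phase_inner
    )

    side_mask = _sector_mask(size, real.extension_deg, min(0.62 * size, 1.35 * real.outer_length))

    base = _exposed(spec.base_rgb, background)
    secondary = _exposed(spec.secondary_rgb, background)
    images = {
        "front": _compose(
            size,
            [(outer_whorl, base), (outer_sec, secondary),
             (inner_whorl, base), (inner_whorl & inner_sec, secondary)],
            background, spec.pixel_noise_sd, rng,
        ),
        "outer": _compose(
            size, [(outer_whorl, base), (outer_sec, secondary)],
            background, spec.pixel_noise_sd, rng,
        ),
        "inner": _compose(
            size, [(inner_whorl, base), (inner_sec, secondary)],
            background, spec.pixel_noise_sd, rng,
        ),
        "side": _compose(size, [(side_mask, base)], background, spec.pixel_noise_sd, rng),
    }
    masks = {
        "front": outer_whorl | inner_whorl,
        "outer": outer_whorl,
        "inner": inner_whorl,
        "side": side_mask,
    }

    # ---- ground truth -----------------------------------------------------
    geom = _mask_geometry(masks["front"])
    pos = _position_code(real.n_outer, real.outer_length, real.outer_width)
    out_pct = 100.0 * outer_sec.sum() / max(outer_whorl.sum(), 1)
    in_pct = 100.0 * inner_sec.sum() / max(inner_whorl.sum(), 1)
    o_main, o_sec_rgb, o_pct, o_poly, _ = _colour_truth(out_pct, base, secondary, spec.secondary_distribution)
    i_main, i_sec_rgb, i_pct, i_poly, i_code = _colour_truth(in_pct, base, secondary, spec.secondary_distribution)

    truth: dict[str, float] = {
        "F1": float(3 * _extension_bin(real.extension_deg) + pos),
        "F2": geom["feret"],
        "F3": geom["perimeter"],
        "F4": geom["area"],
        "F5": math.pi * (geom["feret"] / 2.0) ** 2,
        "F6": geom["area"] / geom["hull_area"],
        "F7": 4.0 * math.pi * geom["area"] / geom["perimeter"] ** 2,
        "F8": geom["perimeter"] ** 2 / geom["area"],
        "F9": float(pos),
        "F10": real.extension_deg,
        "F11": float(real.n_outer),
        "F12": real.outer_length,
        "F13": real.outer_width,
        "F14": float(_shape_code(real.outer_length / real.outer_width)),
        "F15": float(outer_whorl.sum()),
        "F16": float(APEX_SHAPE_CODES[spec.apex_type]),
        "F17": float(APEX_STATE_CODES["straight"]),
        "F18": float(MARGIN_CODES["entire"]),
        "F19": float(o_main[0]),
        "F20": float(o_main[1]),
        "F21": float(o_main[2]),
        "F22": float(o_sec_rgb[0]),
        "F23": float(o_sec_rgb[1]),
        "F24": float(o_sec_rgb[2]),
        "F25": o_pct,
        "F26": float(o_poly),
        "F27": float(real.n_inner),
        "F28": real.inner_length,
        "F29": real.inner_width,
        "F30": float(_shape_code(real.inner_length / real.inner_width)),
        "F31": float(inner_whorl.sum()),
        "F32": float(APEX_SHAPE_CODES[spec.apex_type]),
        "F33": float(APEX_STATE_CODES["straight"]),
        "F34": float(i_main[0]),
        "F35": float(i_main[1]),
        "F36": float(i_main[2]),
        "F37": float(i_sec_rgb[0]),
        "F38": float(i_sec_rgb[1]),
        "F39": float(i_sec_rgb[2]),
        "F40": i_pct,
        "F41": float(i_poly),
        "F42": float(i_code),
    }
    return RenderedSample(spec.variety_id, flower_id, images, masks, truth, real, background)


def render_flower(
    spec: VarietySpec,
    view: str,
    rng: np.random.Generator,
    size: int = 512,
    background: str = "dark",
) -> tuple[np.ndarray, np.ndarray, dict[str, float]]:
    """Render a single view; returns ``(image, mask, truth)``.

    Convenience wrapper over :func:`render_sample` (the realisation is drawn
    once, so the truth dict is consistent with the returned view).
    """
    if view not in VIEWS:
        raise ValueError(f"view must be one of {VIEWS}")
    sample = render_sample(spec, rng, size=size, background=background)
    return sample.images[view], sample.masks[view], sample.truth


def generate_dataset(
    n_varieties: int,
    n_per_variety: int,
    seed: int,
    out_dir: str | Path,
    size: int = 512,
) -> pd.DataFrame:
    """Write a full synthetic image set plus manifest and ground-truth CSVs.

    Produces ``n_varieties * n_per_variety * 4`` PNGs under
    ``out_dir/images/``, a ``manifest.csv`` (path, variety_id, flower_id,
    view) and a ``truth.csv`` with one ground-truth row per flower.
    Backgrounds alternate between the dark and light variants per flower.
    Returns the manifest frame.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    specs = sample_variety_specs(n_varieties, seed)
    rng = np.random.default_rng(seed + 1)

    manifest_rows, truth_rows = [], []
    for spec in specs:
        for f in range(n_per_variety):
            background = "dark" if f % 2 == 0 else "light"
            sample = render_sample(spec, rng, flower_id=f + 1, size=size, background=background)
            for view in VIEWS:
                name = f"v{spec.variety_id:03d}_f{f + 1:03d}_{view}.png"
                Image.fromarray(sample.images[view]).save(img_dir / name)
                manifest_rows.append(
                    {"path": f"images/{name}", "variety_id": spec.variety_id,
                     "flower_id": f + 1, "view": view}
                )
            truth_rows.append(
                {"variety_id": spec.variety_id, "flower_id": f + 1,
                 **{k: sample.truth[k] for k in TRAIT_IDS}}
            )

    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out_dir / "truth.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# render-free trait tables (for classifier / selection experiments)
# ---------------------------------------------------------------------------


def _analytic_truth(spec: VarietySpec, rng: np.random.Generator) -> dict[str, float]:
    """One trait vector drawn directly from the archetype, without rendering.

    Geometry is approximated analytically (petal lobes treated as ellipses;
    whorl area discounted for overlap) and measurement noise is added to the
    continuous traits, so tables of thousands of flowers are cheap.  Values
    follow the same schema and units as rendered ground truth but are not
    pixel-exact.
    """
    real = _realize(spec, rng, 1.0)
    lobe = math.pi * (real.outer_length / 2) * (real.outer_width / 2)
    cover = real.n_outer * 2 * math.atan2(real.outer_width, real.outer_length) / (2 * math.pi)
    overlap = 1.0 / max(1.0, cover)  # crude discount once petals overlap
    area_outer = real.n_outer * lobe * overlap
    lobe_i = math.pi * (real.inner_length / 2) * (real.inner_width / 2)
    cover_i = real.n_inner * 2 * math.atan2(real.inner_width, real.inner_length) / (2 * math.pi)
    area_inner = real.n_inner * lobe_i / max(1.0, cover_i)
    area = area_outer + 0.35 * area_inner
    feret = 2.0 * real.outer_length
    # silhouette perimeter ~ scalloped circle; lengthens as petals separate
    perimeter = 2 * math.pi * real.outer_length * (1.0 + 0.5 / max(cover, 0.4))
    hull_area = math.pi * real.outer_length**2

    pos = _position_code(real.n_outer, real.outer_length, real.outer_width)
    out_pct = 100.0 * spec.outer_secondary_fraction
    in_pct = 100.0 * spec.inner_secondary_fraction
    o_main, o_rgb, o_pct, o_poly, _ = _colour_truth(out_pct, spec.base_rgb, spec.secondary_rgb, spec.secondary_distribution)
    i_main, i_rgb, i_pct, i_poly, i_code = _colour_truth(in_pct, spec.base_rgb, spec.secondary_rgb, spec.secondary_distribution)

    noise = lambda s: float(rng.normal(0, s))  # noqa: E731
    rel = lambda x, cv=0.02: x * float(1 + cv * rng.standard_normal())  # noqa: E731
    row = {
        "F1": float(3 * _extension_bin(real.extension_deg) + pos),
        "F2": rel(feret),
        "F3": rel(perimeter, 0.03),
        "F4": rel(area, 0.03),
        "F5": rel(math.pi * (feret / 2) ** 2, 0.03),
        "F6": float(np.clip(rel(min(area / hull_area, 1.0), 0.03), 0.05, 1.0)),
        "F7": float(np.clip(rel(4 * math.pi * area / perimeter**2, 0.03), 0.05, 1.1)),
        "F8": rel(perimeter**2 / area, 0.03),
        "F9": float(pos),
        "F10": real.extension_deg,
        "F11": float(real.n_outer),
        "F12": rel(real.outer_length),
        "F13": rel(real.outer_width),
        "F14": float(_shape_code(real.outer_length / real.outer_width)),
        "F15": rel(area_outer, 0.03),
        "F16": float(APEX_SHAPE_CODES[spec.apex_type]),
        "F17": float(APEX_STATE_CODES["straight"]),
        "F18": float(MARGIN_CODES["entire"]),
        "F19": float(np.clip(o_main[0] + noise(3), 0, 255)),
        "F20": float(np.clip(o_main[1] + noise(3), 0, 255)),
        "F21": float(np.clip(o_main[2] + noise(3), 0, 255)),
        "F22": float(np.clip(o_rgb[0] + noise(3), 0, 255)),
        "F23": float(np.clip(o_rgb[1] + noise(3), 0, 255)),
        "F24": float(np.clip(o_rgb[2] + noise(3), 0, 255)),
        "F25": float(np.clip(o_pct + (noise(1.5) if o_poly else 0.0), 0, 100)),
        "F26": float(o_poly),
        "F27": float(real.n_inner),
        "F28": rel(real.inner_length),
        "F29": rel(real.inner_width),
        "F30": float(_shape_code(real.inner_length / real.inner_width)),
        "F31": rel(area_inner, 0.03),
        "F32": float(APEX_SHAPE_CODES[spec.apex_type]),
        "F33": float(APEX_STATE_CODES["straight"]),
        "F34": float(np.clip(i_main[0] + noise(3), 0, 255)),
        "F35": float(np.clip(i_main[1] + noise(3), 0, 255)),
        "F36": float(np.clip(i_main[2] + noise(3), 0, 255)),
        "F37": float(np.clip(i_rgb[0] + noise(3), 0, 255)),
        "F38": float(np.clip(i_rgb[1] + noise(3), 0, 255)),
        "F39": float(np.clip(i_rgb[2] + noise(3), 0, 255)),
        "F40": float(np.clip(i_pct + (noise(1.5) if i_poly else 0.0), 0, 100)),
        "F41": float(i_poly),
        "F42": float(i_code),
    }
    return row


def sample_trait_table(
    n_varieties: int = 23,
    n_per_variety: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """A labelled trait table drawn from variety archetypes without rendering.

    The default size mirrors a realistic DUS study (23 varieties x 100
    flowers).  Columns are F1..F42 plus ``variety_id`` and ``flower_id``.
    """
    specs = sample_variety_specs(n_varieties, seed)
    rng = np.random.default_rng(seed + 1)
    rows = []
    for spec in specs:
        for f in range(n_per_variety):
            rows.append(
                {**_analytic_truth(spec, rng), "variety_id": spec.variety_id, "flower_id": f + 1}
            )
    return pd.DataFrame(rows)


def planted_table(
    n_samples: int = 300,
    n_classes: int = 5,
    n_informative: int = 2,
    n_noise: int = 4,
    n_collinear: int = 0,
    class_sep: float = 3.0,
    seed: int = 0,
    scheme: str = "circle",
    collinear_source: str = "informative",
) -> tuple[pd.DataFrame, list[str]]:
    """A trait-style table where only a known subset of columns carries signal.

    With ``scheme="circle"`` class centres sit equally spaced on a circle of
    radius ``class_sep`` in the first two informative dimensions (on a line
    if there is only one), with unit Gaussian scatter, so classes are
    separable by construction.  With ``scheme="onehot"`` (requires
    ``n_classes <= n_informative + 1``) class k's centre is ``class_sep``
    along informative axis k (the last class sits at the origin), which makes
    every informative column individually essential: dropping axis k
    collapses class k onto the origin class.  Noise columns are pure
    standard normals; collinear columns are noisy copies of informative ones
    (cycled).  Columns are named T1..Td (they are abstract model-level
    features, not schema traits); returns
    ``(table, informative_column_names)``.
    """
    rng = np.random.default_rng(seed)
    y = np.repeat(np.arange(1, n_classes + 1), int(np.ceil(n_samples / n_classes)))[:n_samples]
    d = n_informative + n_noise + n_collinear
    X = np.empty((n_samples, d))
    centers = np.zeros((n_classes, n_informative))
    if scheme == "onehot":
        if n_classes > n_informative + 1:
            raise ValueError("onehot scheme needs n_classes <= n_informative + 1")
        for k in range(min(n_classes, n_informative)):
            centers[k, k] = class_sep
    elif scheme != "circle":
        raise ValueError(f"unknown scheme {scheme!r}")
    elif n_informative == 1:
        centers[:, 0] = class_sep * (np.arange(n_classes) - (n_classes - 1) / 2.0)
    else:
        ang = 2 * math.pi * np.arange(n_classes) / n_classes + rng.uniform(0, 2 * math.pi)
        centers[:, 0] = class_sep * np.cos(ang)
        centers[:, 1] = class_sep * np.sin(ang)
        if n_informative > 2:
            centers[:, 2:] = rng.normal(0, class_sep / 2.0, size=(n_classes, n_informative - 2))
    X[:, :n_informative] = centers[y - 1] + rng.standard_normal((n_samples, n_informative))
    X[:, n_informative : n_informative + n_noise] = rng.standard_normal((n_samples, n_noise))
    # collinear columns copy informative traits (redundant signal carriers,
    # interchangeable with their sources) or noise traits (pure redundancy;
    # keeps the informative set uniquely essential)
    for j in range(n_collinear):
        if collinear_source == "informative":
            src = j % n_informative
        elif collinear_source == "noise":
            if n_noise == 0:
                raise ValueError("collinear_source='noise' needs noise columns")
            src = n_informative + j % n_noise
        else:
            raise ValueError(f"unknown collinear_source {collinear_source!r}")
        X[:, n_informative + n_noise + j] = X[:, src] + 0.05 * rng.standard_normal(n_samples)
    cols = [f"T{i + 1}" for i in range(d)]
    table = pd.DataFrame(X, columns=cols)
    table["variety_id"] = y
    table["flower_id"] = np.arange(1, n_samples + 1)
    return table, cols[:n_informative]
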