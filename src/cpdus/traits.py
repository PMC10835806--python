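"""Quantification of the 42 flower traits from the four standard views.

One flower is described by a single 42-entry trait vector: whole-flower
geometry and openness from the front and side views, then per-whorl traits
(petal count, petal min-rect dimensions and shape class, apex descriptors,
margin state, main/secondary colour statistics) from the outer- and
inner-perianth views.  All decision thresholds come from
:class:`cpdus.config.ExtractionConfig`.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import find_peaks
from scipy.spatial import ConvexHull
from skimage.color import rgb2hsv
from sklearn.cluster import KMeans

from .config import DEFAULT_CONFIG, ExtractionConfig
from .imaging import ContourPath, binarize, extract_contours, flower_mask, to_grayscale
from .schema import (
    APEX_SHAPE_CODES,
    APEX_STATE_CODES,
    DISTRIBUTION_CODES,
    MARGIN_CODES,
    POSITION_CODES,
    SHAPE_CODES,
    TRAIT_IDS,
    trait_def,
)

__all__ = [
    "geometry_traits",
    "count_perianths",
    "color_traits",
    "categorical_traits",
    "extract_all",
    "extract_table",
]


# ---------------------------------------------------------------------------
# geometry descriptors
# ---------------------------------------------------------------------------


def _min_area_rect(hull_pts: np.ndarray) -> tuple[float, float]:
    """Rotating-calipers minimum-area enclosing rectangle (length >= width)."""
    best = (math.inf, 0.0, 0.0)
    n = len(hull_pts)
    for i in range(n):
        edge = hull_pts[(i + 1) % n] - hull_pts[i]
        norm = np.hypot(*edge)
        if norm < 1e-12:
            continue
        u = edge / norm
        v = np.array([-u[1], u[0]])
        pu = hull_pts @ u
        pv = hull_pts @ v
        w, h = pu.max() - pu.min(), pv.max() - pv.min()
        if w * h < best[0]:
            best = (w * h, w, h)
    _, w, h = best
    return (max(w, h), min(w, h))


def geometry_traits(contour: ContourPath) -> dict[str, float]:
    """Shape descriptors of one closed contour.

    Returns max (Feret) diameter, perimeter, area, equal-circle area
    (pi * (Feret/2)^2), solidity (area / convex-hull area), circularity
    (4*pi*A/P^2), compactness (P^2/A) and the minimum-area rotated
    rectangle's length and width.
    """
    pts = contour.vertices
    hull = ConvexHull(pts)
    hv = pts[hull.vertices]
    d2 = ((hv[:, None, :] - hv[None, :, :]) ** 2).sum(-1)
    feret = float(np.sqrt(d2.max()))
    length, width = _min_area_rect(hv)
    area, perim = contour.area, contour.perimeter
    return {
        "max_diameter": feret,
        "perimeter": perim,
        "area": area,
        "equal_circle_area": math.pi * (feret / 2.0) ** 2,
        "solidity": area / float(hull.volume),
        "circularity": 4.0 * math.pi * area / perim**2,
        "compactness": perim**2 / area,
        "min_rect_length": length,
        "min_rect_width": width,
    }


# ---------------------------------------------------------------------------
# angular radius profile and perianth counting
# ---------------------------------------------------------------------------


def _radius_profile(mask: np.ndarray, n_bins: int, smooth: int) -> np.ndarray:
    """rho(theta): max centroid-to-pixel distance per angular bin, smoothed."""
    pts = np.argwhere(mask).astype(float)
    cy, cx = pts.mean(axis=0)
    dy, dx = pts[:, 0] - cy, pts[:, 1] - cx
    r = np.hypot(dy, dx)
    phi = np.arctan2(dy, dx) % (2 * math.pi)
    bins = np.minimum((phi / (2 * math.pi) * n_bins).astype(int), n_bins - 1)
    rho = np.zeros(n_bins)
    np.maximum.at(rho, bins, r)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        rho = np.convolve(np.concatenate([rho[-smooth:], rho, rho[:smooth]]), kernel, mode="same")[
            smooth:-smooth
        ]
    return rho


def count_perianths(
    mask: np.ndarray, config: ExtractionConfig = DEFAULT_CONFIG
) -> tuple[int, bool]:
    """Count petal lobes as peaks of the angular radius profile.

    Returns ``(count, confident)``.  A near-circular profile (relative range
    below ``config.flat_profile_rel_range``) has no petal structure; the
    count defaults to 1 with ``confident=False``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    rho = _radius_profile(mask, config.angular_bins, config.profile_smooth_window)
    lo, hi = rho.min(), rho.max()
    if hi <= 0 or (hi - lo) / hi < config.flat_profile_rel_range:
        return 1, False
    height = (lo + hi) / 2.0
    tiled = np.concatenate([rho, rho, rho])
    n = len(rho)
    # petals subtend at least ~12 degrees; demand that much separation and a
    # prominence well above pixel jitter
    peaks, _ = find_peaks(
        tiled, height=height, distance=max(4, n // 30), prominence=0.08 * (hi - lo)
    )
    count = int(np.sum((peaks >= n) & (peaks < 2 * n)))
    if count == 0:
        return 1, False
    return count, True


# ---------------------------------------------------------------------------
# colour description
# ---------------------------------------------------------------------------


def _hsv_embed(rgb: np.ndarray) -> np.ndarray:
    """Map RGB pixels to (S cos H, S sin H, V): hue made continuous."""
    hsv = rgb2hsv(rgb[None, :, :] / 255.0)[0]
    ang = hsv[:, 0] * 2 * math.pi
    return np.column_stack([hsv[:, 1] * np.cos(ang), hsv[:, 1] * np.sin(ang), hsv[:, 2]])


def _normalized_radius(mask: np.ndarray, select: np.ndarray) -> tuple[float, float]:
    """Mean and sd of r/rho(theta) over the ``select`` pixels of ``mask``."""
    coords = np.argwhere(mask)
    pts = coords.astype(float)
    cy, cx = pts.mean(axis=0)
    n_bins = 720
    dy, dx = pts[:, 0] - cy, pts[:, 1] - cx
    r = np.hypot(dy, dx)
    phi = np.arctan2(dy, dx) % (2 * math.pi)
    bins = np.minimum((phi / (2 * math.pi) * n_bins).astype(int), n_bins - 1)
    rho = np.zeros(n_bins)
    np.maximum.at(rho, bins, r)
    rho = np.maximum(rho, 1e-9)
    rnorm = r / rho[bins]
    flat_sel = select[tuple(coords.T)]
    vals = rnorm[flat_sel]
    return float(vals.mean()), float(vals.std())


def color_traits(
    img: np.ndarray, mask: np.ndarray, config: ExtractionConfig = DEFAULT_CONFIG
) -> dict[str, float | tuple]:
    """Dominant/secondary colour of the masked region by 2-way quantisation.

    Foreground pixels are clustered (k=2) in a hue-circular HSV embedding;
    the larger cluster is the main colour.  The region counts as
    polychromatic only if the smaller cluster holds at least
    ``poly_min_pct`` percent of the pixels *and* the clusters are at least
    ``poly_min_rgb_dist`` apart in RGB; otherwise the secondary colour is
    reported equal to the main one with a zero percentage.  The secondary
    distribution class comes from the mean normalised radial position of the
    secondary pixels (basal near the centre, marginal near the rim, striped
    in between, full above ``dist_full_pct`` percent).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    rgb = np.asarray(img, dtype=float)[mask]
    emb = _hsv_embed(rgb)
    # subsample for the fit only; labels are predicted for every pixel
    rng = np.random.default_rng(0)
    fit_idx = rng.choice(len(emb), size=min(len(emb), 20000), replace=False)
    km = KMeans(n_clusters=2, n_init=3, random_state=0).fit(emb[fit_idx])
    labels = km.predict(emb)
    sizes = np.bincount(labels, minlength=2)
    main_lab = int(np.argmax(sizes))
    sec_lab = 1 - main_lab
    main_rgb = tuple(float(x) for x in rgb[labels == main_lab].mean(axis=0))
    if sizes[sec_lab] > 0:
        sec_rgb = tuple(float(x) for x in rgb[labels == sec_lab].mean(axis=0))
    else:
        sec_rgb = main_rgb
    pct = 100.0 * sizes[sec_lab] / sizes.sum()
    dist = float(np.linalg.norm(np.subtract(main_rgb, sec_rgb)))
    poly = int(pct >= config.poly_min_pct and dist >= config.poly_min_rgb_dist)
    if not poly:
        return {
            "main_rgb": main_rgb,
            "secondary_rgb": main_rgb,
            "secondary_pct": 0.0,
            "polychromatic": 0,
            "distribution_type": DISTRIBUTION_CODES["none"],
        }
    if pct > config.dist_full_pct:
        code = DISTRIBUTION_CODES["full"]
    else:
        sel = np.zeros_like(mask)
        sel[mask] = labels == sec_lab
        rbar, rsd = _normalized_radius(mask, sel)
        # stripes span the full radial range; bands concentrate it
        if rsd > config.dist_striped_sd:
            code = DISTRIBUTION_CODES["striped"]
        elif rbar < config.dist_basal_rmax:
            code = DISTRIBUTION_CODES["basal"]
        elif rbar > config.dist_marginal_rmin:
            code = DISTRIBUTION_CODES["marginal"]
        else:
            code = DISTRIBUTION_CODES["striped"]
    return {
        "main_rgb": main_rgb,
        "secondary_rgb": sec_rgb,
        "secondary_pct": float(pct),
        "polychromatic": poly,
        "distribution_type": code,
    }


# ---------------------------------------------------------------------------
# petal-level shape: lobe isolation, min-rect, apex, margin
# ---------------------------------------------------------------------------


def _isolate_lobe(mask: np.ndarray, config: ExtractionConfig) -> np.ndarray | None:
    """Cut out the angular sector holding the tallest petal lobe."""
    rho = _radius_profile(mask, config.angular_bins, config.profile_smooth_window)
    n = len(rho)
    lo, hi = rho.min(), rho.max()
    if hi <= 0 or (hi - lo) / hi < config.flat_profile_rel_range:
        return None
    peak = int(np.argmax(rho))
    # walk to the valleys on each side of the peak
    left = peak
    for _ in range(n):
        nxt = (left - 1) % n
        if rho[nxt] > rho[left]:
            break
        left = nxt
    right = peak
    for _ in range(n):
        nxt = (right + 1) % n
        if rho[nxt] > rho[right]:
            break
        right = nxt
    if left == right:
        return None
    pts = np.argwhere(mask).astype(float)
    cy, cx = pts.mean(axis=0)
    yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    phi = np.arctan2(yy - cy, xx - cx) % (2 * math.pi)
    bins = np.minimum((phi / (2 * math.pi) * n).astype(int), n - 1)
    if left <= right:
        sector = (bins >= left) & (bins <= right)
    else:
        sector = (bins >= left) | (bins <= right)
    lobe = mask & sector
    labels, k = ndimage.label(lobe)
    if k == 0:
        return None
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, k + 1))
    return labels == (1 + int(np.argmax(sizes)))


def _petal_shape(
    mask: np.ndarray, config: ExtractionConfig
) -> dict[str, float] | None:
    """Length/width/apex descriptors of one representative petal lobe."""
    lobe = _isolate_lobe(mask, config)
    if lobe is None:
        contours = extract_contours(mask)
        if not contours:
            return None
        g = geometry_traits(contours[0])
        return {
            "length": g["min_rect_length"],
            "width": g["min_rect_width"],
            "apex_angle": 180.0,
            "tip_offset": 0.0,
        }
    contours = extract_contours(lobe)
    if not contours:
        return None
    contour = contours[0]
    g = geometry_traits(contour)
    pts = np.argwhere(mask).astype(float)
    center = pts.mean(axis=0)
    verts = contour.vertices
    dists = np.hypot(*(verts - center).T)
    tip_i = int(np.argmax(dists))
    # turning angle at the tip, measured between points an arc offset away
    m = len(verts)
    off = max(2, int(config.apex_arc_fraction * m))
    a = verts[(tip_i - off) % m] - verts[tip_i]
    b = verts[(tip_i + off) % m] - verts[tip_i]
    cosang = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b) + 1e-12)
    apex_angle = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
    # lateral tip offset relative to the centre->lobe-centroid axis
    lobe_c = np.argwhere(lobe).mean(axis=0)
    axis = lobe_c - center
    axis /= np.linalg.norm(axis) + 1e-12
    rel = verts[tip_i] - center
    lateral = abs(rel[0] * axis[1] - rel[1] * axis[0])
    return {
        "length": g["min_rect_length"],
        "width": g["min_rect_width"],
        "apex_angle": apex_angle,
        "tip_offset": float(lateral / (g["min_rect_length"] + 1e-12)),
    }


def _shape_code(aspect: float, config: ExtractionConfig) -> int:
    if aspect >= config.narrow_aspect:
        return SHAPE_CODES["narrow_elliptic"]
    if aspect >= config.broad_aspect:
        return SHAPE_CODES["elliptic"]
    return SHAPE_CODES["broad_elliptic"]


def _apex_shape_code(angle: float, config: ExtractionConfig) -> int:
    if angle < config.apex_acute_deg:
        return APEX_SHAPE_CODES["acute"]
    if angle <= config.apex_rounded_deg:
        return APEX_SHAPE_CODES["obtuse"]
    return APEX_SHAPE_CODES["rounded"]


def _apex_state_code(tip_offset: float, config: ExtractionConfig) -> int:
    # the silhouette does not tell incurved from reflexed; any strong lateral
    # deflection is scored incurved, otherwise straight
    if tip_offset > config.apex_state_offset:
        return APEX_STATE_CODES["incurved"]
    return APEX_STATE_CODES["straight"]


def margin_state(
    mask: np.ndarray, petal_count: int, config: ExtractionConfig = DEFAULT_CONFIG
) -> int:
    """Entire vs undulate margin from the high-frequency share of rho(theta).

    Energy in angular harmonics above 2.5x the petal frequency, relative to
    the total non-DC energy.  A circle has none and scores entire.
    """
    rho = _radius_profile(mask, config.angular_bins, 3)
    # a near-circular profile has no margin structure at all, only jitter
    if (rho.max() - rho.min()) / max(rho.max(), 1e-9) < config.flat_profile_rel_range:
        return MARGIN_CODES["entire"]
    spec = np.abs(np.fft.rfft(rho - rho.mean())) ** 2
    total = spec.sum()
    if total <= 1e-12:
        return MARGIN_CODES["entire"]
    cutoff = max(int(2.5 * max(petal_count, 1)), 3)
    hf = spec[cutoff:].sum()
    return MARGIN_CODES["undulate"] if hf / total > config.margin_hf_energy else MARGIN_CODES["entire"]


def extension_angle(side_mask: np.ndarray) -> float:
    """Opening angle (degrees) subtended at the basal point of a side view."""
    pts = np.argwhere(side_mask).astype(float)
    if len(pts) == 0:
        raise ValueError("empty side mask")
    ymax = pts[:, 0].max()
    basal = pts[pts[:, 0] >= ymax - 1]
    by, bx = basal[:, 0].max(), basal[:, 1].mean()
    dy, dx = by - pts[:, 0], pts[:, 1] - bx  # dy >= 0 upward
    r = np.hypot(dy, dx)
    keep = r > 0.2 * r.max()
    phi = np.degrees(np.arctan2(dy[keep], dx[keep]))
    return float(phi.max() - phi.min())


def _position_from_petals(n: int, length: float, width: float, config: ExtractionConfig) -> int:
    coverage = n * 2.0 * math.atan2(width, length) / (2.0 * math.pi)
    if coverage < config.position_separated:
        return POSITION_CODES["separated"]
    if coverage < config.position_touching:
        return POSITION_CODES["touching"]
    return POSITION_CODES["overlapping"]


def categorical_traits(
    outer_mask: np.ndarray,
    side_mask: np.ndarray | None,
    config: ExtractionConfig = DEFAULT_CONFIG,
) -> dict[str, float]:
    """Whole-flower categorical codes: position, extension angle, flower type."""
    count, _ = count_perianths(outer_mask, config)
    petal = _petal_shape(outer_mask, config)
    if petal is None:
        pos = POSITION_CODES["overlapping"]
    else:
        pos = _position_from_petals(count, petal["length"], petal["width"], config)
    if side_mask is not None and side_mask.any():
        ext = extension_angle(side_mask)
    else:
        ext = float("nan")
    ext_bin = int(np.searchsorted(np.asarray(config.extension_bins), ext, side="right")) if np.isfinite(ext) else 1
    return {"position": float(pos), "extension_angle": ext, "flower_type": float(3 * ext_bin + pos)}


# ---------------------------------------------------------------------------
# per-view fusion
# ---------------------------------------------------------------------------


def _whorl_traits(
    img: np.ndarray,
    mask: np.ndarray,
    prefix_ids: list[str],
    config: ExtractionConfig,
    colour_mask: np.ndarray | None = None,
) -> dict[str, float]:
    """The 16 per-whorl traits (count, petal shape, apex, margin, colour).

    ``colour_mask`` restricts the colour statistics to pixels that were
    foreground before morphological closing: gap fill annexed by the closing
    is background-coloured and would contaminate the clusters.
    """
    count, _ = count_perianths(mask, config)
    petal = _petal_shape(mask, config)
    if petal is None:
        petal = {"length": float("nan"), "width": float("nan"), "apex_angle": 180.0, "tip_offset": 0.0}
    cmask = mask if colour_mask is None else (mask & colour_mask)
    if not cmask.any():
        cmask = mask
    colour = color_traits(img, cmask, config)
    ids = prefix_ids
    out = {
        ids[0]: float(count),
        ids[1]: petal["length"],
        ids[2]: petal["width"],
        ids[3]: float(_shape_code(petal["length"] / max(petal["width"], 1e-9), config)),
        ids[4]: float(mask.sum()),
        ids[5]: float(_apex_shape_code(petal["apex_angle"], config)),
        ids[6]: float(_apex_state_code(petal["tip_offset"], config)),
    }
    out.update(
        {
            ids[7]: colour["main_rgb"][0],
            ids[8]: colour["main_rgb"][1],
            ids[9]: colour["main_rgb"][2],
            ids[10]: colour["secondary_rgb"][0],
            ids[11]: colour["secondary_rgb"][1],
            ids[12]: colour["secondary_rgb"][2],
            ids[13]: colour["secondary_pct"],
            ids[14]: float(colour["polychromatic"]),
            ids[15]: float(colour["distribution_type"]),
        }
    )
    return out


_OUTER_IDS = ["F11", "F12", "F13", "F14", "F15", "F16", "F17",
              "F19", "F20", "F21", "F22", "F23", "F24", "F25", "F26", "F18_placeholder"]
_INNER_IDS = ["F27", "F28", "F29", "F30", "F31", "F32", "F33",
              "F34", "F35", "F36", "F37", "F38", "F39", "F40", "F41", "F42"]


def extract_all(
    images: dict[str, np.ndarray], config: ExtractionConfig = DEFAULT_CONFIG
) -> pd.Series:
    """Fuse the four views of one flower into a 42-trait vector.

    ``images`` maps view names (``front``, ``outer``, ``inner``, ``side``) to
    RGB arrays.  The front view is required; traits whose source view is
    missing come back as NaN (table-level imputation fills them later).
    """
    if "front" not in images:
        raise ValueError("the front view is required")
    masks = {
        v: flower_mask(
            img,
            polarity=config.polarity,
            method=config.binarize_method,
            threshold=config.fixed_threshold,
            close_radius=config.close_radius,
        )
        for v, img in images.items()
    }
    # pre-closing masks: colour statistics must not include annexed gap fill
    raw_masks = {
        v: binarize(
            to_grayscale(img), polarity=config.polarity,
            method=config.binarize_method, threshold=config.fixed_threshold,
        )
        for v, img in images.items()
    }
    values: dict[str, float] = {t: float("nan") for t in TRAIT_IDS}

    front = masks["front"]
    contours = extract_contours(front)
    if not contours:
        raise ValueError("front view segmentation produced no contour")
    g = geometry_traits(contours[0])
    values.update(
        {
            "F2": g["max_diameter"],
            "F3": g["perimeter"],
            "F4": g["area"],
            "F5": g["equal_circle_area"],
            "F6": g["solidity"],
            "F7": g["circularity"],
            "F8": g["compactness"],
        }
    )

    ref_for_cat = masks.get("outer", front)
    cat = categorical_traits(ref_for_cat, masks.get("side"), config)
    values["F9"] = cat["position"]
    values["F10"] = cat["extension_angle"]
    values["F1"] = cat["flower_type"]

    if "outer" in images and masks["outer"].any():
        outer = _whorl_traits(images["outer"], masks["outer"], _OUTER_IDS, config,
                              colour_mask=raw_masks["outer"])
        outer.pop("F18_placeholder", None)  # the outer whorl has no distribution trait
        values.update(outer)
        count = int(values["F11"])
        values["F18"] = float(margin_state(masks["outer"], count, config))
    if "inner" in images and masks["inner"].any():
        values.update(_whorl_traits(images["inner"], masks["inner"], _INNER_IDS, config,
                                    colour_mask=raw_masks["inner"]))

    return pd.Series(values, index=list(TRAIT_IDS), dtype=float)


def _impute(table: pd.DataFrame) -> pd.DataFrame:
    """Fill missing traits with the variety mean (mode for categoricals)."""
    out = table.copy()
    for col in TRAIT_IDS:
        if not out[col].isna().any():
            continue
        scale = trait_def(col).scale
        if scale == "continuous":
            fill = out.groupby("variety_id")[col].transform("mean")
        else:
            fill = out.groupby("variety_id")[col].transform(
                lambda s: s.mode().iloc[0] if not s.mode().empty else np.nan
            )
        out[col] = out[col].fillna(fill).fillna(out[col].mean())
    return out


def extract_table(
    manifest: pd.DataFrame | str | Path,
    root: str | Path | None = None,
    config: ExtractionConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Extract a trait table from an image manifest.

    ``manifest`` is a frame (or CSV path) with columns ``path``,
    ``variety_id``, ``flower_id`` and ``view``; image paths are resolved
    against ``root`` (defaults to the manifest's directory).  Returns one row
    per flower with columns F1..F42, ``variety_id`` and ``flower_id``.
    Unreadable flowers are skipped with a warning; missing individual traits
    are imputed from the variety.
    """
    from PIL import Image

    if not isinstance(manifest, pd.DataFrame):
        path = Path(manifest)
        if root is None:
            root = path.parent
        manifest = pd.read_csv(path)
    root = Path(root) if root is not None else Path(".")

    rows = []
    for (vid, fid), grp in manifest.groupby(["variety_id", "flower_id"], sort=True):
        images = {}
        for _, rec in grp.iterrows():
            try:
                images[rec["view"]] = np.asarray(Image.open(root / rec["path"]).convert("RGB"))
            except OSError as exc:  # unreadable file
                warnings.warn(f"skipping unreadable image {rec['path']}: {exc}", stacklevel=2)
        try:
            vec = extract_all(images, config)
        except ValueError as exc:
            warnings.warn(f"skipping flower variety={vid} flower={fid}: {exc}", stacklevel=2)
            continue
        rows.append({**vec.to_dict(), "variety_id": vid, "flower_id": fid})
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    return _impute(table)
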