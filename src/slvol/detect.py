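"""Laser-dot detection: HSV gate, cosine-similarity mask, luminance mask,
border cleanup, mask merge, reflection elimination and centre-dot search.

The cascade isolates the projected green laser dots in a food photograph.
Three independent binary masks are combined by pixelwise conjunction:

* an HSV gate keeping hue in [90, 180] degrees and saturation >= 90 %,
* a cosine-similarity mask against a reference colour (pure green
  (0, 255, 0) by default), thresholded on the RGB-vector cosine,
* a luminance mask: the BT.709 luminance (L = 0.2126 R + 0.7152 G +
  0.0722 B) minus its morphological opening by a disk, thresholded to
  retain only small bright blobs.

Components touching the image border band are removed, remaining
components become sub-pixel (luminance-weighted) centroids, clusters of
mutually close dots collapse to their brightest member (laser
reflections), and the brightest surviving dot is flagged as the grid
centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.morphology import disk

from .geometry import SlvolError

__all__ = [
    "InvalidImageError",
    "InvalidConfigError",
    "InvalidEditError",
    "NoDotsFoundError",
    "MaskCascadeConfig",
    "LaserDot",
    "hsv_filter",
    "cosine_similarity_mask",
    "luminance",
    "luminance_mask",
    "eliminate_border",
    "merge_masks",
    "extract_dots",
    "eliminate_reflections",
    "find_center_dot",
    "manual_correction",
    "detect_dots",
]

_EPS_DEG = 1e-9


class InvalidImageError(SlvolError):
    pass


class InvalidConfigError(SlvolError):
    pass


class InvalidEditError(SlvolError):
    pass


class NoDotsFoundError(SlvolError):
    pass


@dataclass
class MaskCascadeConfig:
    hue_min_deg: float = 90.0
    hue_max_deg: float = 180.0
    saturation_min_pct: float = 90.0
    similarity_reference_rgb: tuple = (0.0, 255.0, 0.0)
    similarity_threshold: float = 0.9
    luminance_threshold: float = 0.6       # fraction of the max residual
    luminance_floor: float = 1.0           # absolute residual floor, 0..255
    opening_disk_radius_px: int = 5
    border_erosion_radius_px: int = 8
    min_area_px: int = 3
    min_separation_px: float = 12.0
    refine_reference: bool = False
    refine_max_iter: int = 5

    def __post_init__(self):
        if not 0.0 <= self.hue_min_deg < self.hue_max_deg <= 360.0:
            raise InvalidConfigError("hue bounds must satisfy 0 <= min < max <= 360")
        if not 0.0 <= self.saturation_min_pct <= 100.0:
            raise InvalidConfigError("saturation bound must be a percentage")
        if not 0.0 < self.similarity_threshold <= 1.0:
            raise InvalidConfigError("similarity threshold must be in (0, 1]")
        if not 0.0 < self.luminance_threshold <= 1.0:
            raise InvalidConfigError("luminance threshold must be in (0, 1]")


@dataclass
class LaserDot:
    x_px: float
    y_px: float
    peak_luminance: float
    area_px: int
    is_center: bool = False
    provenance: str = "auto"


def _check_rgb(image):
    img = np.asarray(image, float)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise InvalidImageError("expected a 3-channel RGB image")
    return img


def hsv_filter(image, cfg: MaskCascadeConfig) -> np.ndarray:
    """Binary mask of pixels with laser-like hue and saturation."""
    img = _check_rgb(image)
    hsv = rgb2hsv(img / 255.0)
    hue = hsv[..., 0] * 360.0
    sat = hsv[..., 1] * 100.0
    return (
        (hue >= cfg.hue_min_deg - _EPS_DEG)
        & (hue <= cfg.hue_max_deg + _EPS_DEG)
        & (sat >= cfg.saturation_min_pct - _EPS_DEG)
    )


def cosine_similarity_mask(image, reference_rgb, threshold) -> np.ndarray:
    """Mask of pixels whose RGB vector points near the reference colour.

    Black pixels (zero vectors) have no direction and are always rejected.
    """
    img = _check_rgb(image)
    ref = np.asarray(reference_rgb, float)
    nref = np.linalg.norm(ref)
    if nref == 0:
        raise InvalidConfigError("similarity reference must be a nonzero vector")
    norms = np.linalg.norm(img, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = (img @ ref) / (norms * nref)
    return np.where(norms > 0, cos, -1.0) >= threshold


def luminance(image) -> np.ndarray:
    """Per-pixel BT.709 luminance, same scale as the input channels."""
    img = _check_rgb(image)
    return img @ np.array([0.2126, 0.7152, 0.0722])


def _luminance_residual(image, cfg: MaskCascadeConfig) -> np.ndarray:
    """Luminance minus its morphological opening by a disk: the small
    bright blobs that survive background removal."""
    if cfg.opening_disk_radius_px < 1:
        raise InvalidConfigError("opening disk radius must be at least 1 px")
    lum = luminance(image)
    fp = disk(cfg.opening_disk_radius_px).astype(bool)
    opened = ndimage.grey_opening(lum, footprint=fp)
    return lum - opened


def luminance_mask(image, cfg: MaskCascadeConfig) -> np.ndarray:
    """Small bright blobs: luminance minus its opening by a disk, thresholded.

    Opening (erosion then dilation) removes structures smaller than the
    disk, so the residual is large only at compact bright spots; diffuse
    background and straight edges leave no residual.
    """
    residual = _luminance_residual(image, cfg)
    mx = residual.max()
    thr = max(cfg.luminance_threshold * mx, cfg.luminance_floor)
    return residual >= thr


def eliminate_border(mask, radius_px: int) -> np.ndarray:
    """Drop connected components that touch the image-border band."""
    mask = np.asarray(mask, bool)
    if radius_px <= 0:
        return mask.copy()
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask.copy()
    band = np.zeros_like(mask)
    r = int(radius_px)
    band[:r, :] = band[-r:, :] = True
    band[:, :r] = band[:, -r:] = True
    touching = np.unique(labels[band & mask])
    touching = touching[touching > 0]
    out = mask.copy()
    out[np.isin(labels, touching)] = False
    return out


def merge_masks(hsv_mask, cosine_mask, luminance_mask) -> np.ndarray:
    """Pixelwise conjunction of the three cascade masks."""
    a, b, c = (np.asarray(m, bool) for m in (hsv_mask, cosine_mask, luminance_mask))
    if not (a.shape == b.shape == c.shape):
        raise InvalidImageError("mask shapes differ")
    return a & b & c


def extract_dots(merged_mask, luminance_map, min_area_px: int = 3, *,
                 weight_map=None, pad_px: int = 4) -> list:
    """Luminance-weighted sub-pixel centroid per connected component.

    ``weight_map`` (default: the luminance map) supplies the centroid
    weights; passing the background-subtracted residual sharpens the
    sub-pixel estimate because the flat background no longer pulls the
    centroid toward the mask's geometric centre.  The weighting window is
    the component dilated by ``pad_px`` so the splat's skirt contributes.

    Components much larger than the typical dot (a reflection satellite
    blended into its parent) are re-centroided on a small window around
    their peak, where the brighter parent dominates.
    """
    mask = np.asarray(merged_mask, bool)
    lum = np.asarray(luminance_map, float)
    w_map = lum if weight_map is None else np.asarray(weight_map, float)
    h, wd = mask.shape
    labels, n = ndimage.label(mask)
    dots = []
    if n == 0:
        return dots
    slices = ndimage.find_objects(labels)
    for k, sl in enumerate(slices, start=1):
        comp = labels[sl] == k
        area = int(comp.sum())
        if area < min_area_px:
            continue
        y0 = max(sl[0].start - pad_px, 0)
        y1 = min(sl[0].stop + pad_px, h)
        x0 = max(sl[1].start - pad_px, 0)
        x1 = min(sl[1].stop + pad_px, wd)
        win = np.zeros((y1 - y0, x1 - x0), bool)
        win[sl[0].start - y0:sl[0].stop - y0, sl[1].start - x0:sl[1].stop - x0] = comp
        if pad_px:
            win = ndimage.binary_dilation(win, iterations=pad_px)
            win &= (labels[y0:y1, x0:x1] == k) | (labels[y0:y1, x0:x1] == 0)
        w = np.where(win, np.clip(w_map[y0:y1, x0:x1], 0.0, None), 0.0)
        tot = w.sum()
        if tot <= 0:
            continue
        ys, xs = np.mgrid[y0:y1, x0:x1]
        dots.append(
            LaserDot(
                x_px=float((w * xs).sum() / tot),
                y_px=float((w * ys).sum() / tot),
                peak_luminance=float(np.where(comp, lum[sl], 0.0).max()),
                area_px=area,
            )
        )
    if len(dots) >= 5:
        med_area = float(np.median([d.area_px for d in dots]))
        for d in dots:
            if d.area_px <= 1.6 * med_area:
                continue
            # blended blob: re-centroid around the peak of the weight map
            x0 = max(int(d.x_px) - 6, 0)
            x1 = min(int(d.x_px) + 7, mask.shape[1])
            y0 = max(int(d.y_px) - 6, 0)
            y1 = min(int(d.y_px) + 7, mask.shape[0])
            patch = np.clip(w_map[y0:y1, x0:x1], 0.0, None)
            py, px = np.unravel_index(np.argmax(patch), patch.shape)
            ys, xs = np.mgrid[y0:y1, x0:x1]
            keep = (ys - (y0 + py)) ** 2 + (xs - (x0 + px)) ** 2 <= 16.0
            w2 = np.where(keep, patch, 0.0)
            if w2.sum() > 0:
                d.x_px = float((w2 * xs).sum() / w2.sum())
                d.y_px = float((w2 * ys).sum() / w2.sum())
    return dots


def eliminate_reflections(dots, min_separation_px: float) -> list:
    """Collapse clusters of dots closer than the separation threshold.

    Within each single-linkage cluster the brightest dot survives; exact
    brightness ties go to the dot nearest the cluster centroid.
    """
    if len(dots) <= 1:
        return list(dots)
    pos = np.array([[d.x_px, d.y_px] for d in dots])
    from scipy.spatial import cKDTree

    tree = cKDTree(pos)
    pairs = tree.query_pairs(min_separation_px, output_type="ndarray")
    parent = list(range(len(dots)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in pairs:
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[ra] = rb
    clusters: dict[int, list[int]] = {}
    for k in range(len(dots)):
        clusters.setdefault(find(k), []).append(k)
    out = []
    for members in clusters.values():
        if len(members) == 1:
            out.append(dots[members[0]])
            continue
        peaks = np.array([dots[m].peak_luminance for m in members])
        best = peaks.max()
        tied = [m for m, p in zip(members, peaks) if p >= best - 1e-9]
        if len(tied) == 1:
            out.append(dots[tied[0]])
        else:
            centroid = pos[members].mean(axis=0)
            d2 = [np.sum((pos[m] - centroid) ** 2) for m in tied]
            out.append(dots[tied[int(np.argmin(d2))]])
    out.sort(key=lambda d: (d.y_px, d.x_px))
    return out


def find_center_dot(dots, image_shape=None) -> LaserDot:
    """Flag and return the brightest dot as the grid centre.

    Brightness ties break toward the image centre (or the dot centroid
    when the image size is unknown).
    """
    if not dots:
        raise NoDotsFoundError("no dots to search for a centre")
    peaks = np.array([d.peak_luminance for d in dots])
    best = peaks.max()
    tied = [d for d, p in zip(dots, peaks) if p >= best - 1e-9]
    if len(tied) > 1:
        if image_shape is not None:
            cx, cy = image_shape[1] / 2.0, image_shape[0] / 2.0
        else:
            cx = float(np.mean([d.x_px for d in dots]))
            cy = float(np.mean([d.y_px for d in dots]))
        tied.sort(key=lambda d: (d.x_px - cx) ** 2 + (d.y_px - cy) ** 2)
    center = tied[0]
    for d in dots:
        d.is_center = d is center
    return center


def manual_correction(dots, user_edits, image_shape=None) -> list:
    """Apply a file-driven edit list: add / remove / move dots.

    Each edit is a mapping with an ``op`` key: ``{"op": "add", "x":, "y":}``,
    ``{"op": "remove", "id":}`` or ``{"op": "move", "id":, "x":, "y":}``.
    Ids index the current dot list.  Edited dots carry provenance
    ``"manual"``.
    """
    out = [
        LaserDot(d.x_px, d.y_px, d.peak_luminance, d.area_px, d.is_center, d.provenance)
        for d in dots
    ]

    def check_xy(x, y):
        if image_shape is not None:
            h, w = image_shape[:2]
            if not (0 <= x < w and 0 <= y < h):
                raise InvalidEditError(f"edit position ({x}, {y}) outside image")

    for edit in user_edits:
        op = edit.get("op")
        if op == "add":
            x, y = float(edit["x"]), float(edit["y"])
            check_xy(x, y)
            out.append(LaserDot(x, y, peak_luminance=float(edit.get("peak", 0.0)),
                                area_px=int(edit.get("area", 1)), provenance="manual"))
        elif op in ("remove", "move"):
            idx = int(edit["id"])
            if not 0 <= idx < len(out):
                raise InvalidEditError(f"edit references missing dot id {idx}")
            if op == "remove":
                out.pop(idx)
            else:
                x, y = float(edit["x"]), float(edit["y"])
                check_xy(x, y)
                out[idx].x_px = x
                out[idx].y_px = y
                out[idx].provenance = "manual"
        else:
            raise InvalidEditError(f"unknown edit op {op!r}")
    return out


@dataclass
class CascadeResult:
    dots: list
    center: LaserDot | None
    masks: dict = field(default_factory=dict)
    reference_rgb: tuple = (0.0, 255.0, 0.0)


def _refine_reference(img, cfg, hsv_m, lum_map, lmask):
    """Iteratively re-estimate the laser colour from the brightest retained
    pixels until the retained-pixel count stabilises."""
    ref = np.asarray(cfg.similarity_reference_rgb, float)
    prev = -1
    for _ in range(cfg.refine_max_iter):
        cos_m = cosine_similarity_mask(img, ref, cfg.similarity_threshold)
        merged = merge_masks(hsv_m, cos_m, lmask)
        count = int(merged.sum())
        if count == 0:
            break
        vals = lum_map[merged]
        cut = np.quantile(vals, 0.9)
        sel = merged & (lum_map >= cut)
        if sel.sum() >= 3:
            ref = img[sel].mean(axis=0)
        if prev >= 0 and abs(count - prev) <= max(1, 0.01 * prev):
            break
        prev = count
    return ref


def detect_dots(image, cfg: MaskCascadeConfig | None = None, *,
                keep_masks: bool = False) -> CascadeResult:
    """Run the full mask cascade on one frame."""
    cfg = cfg or MaskCascadeConfig()
    img = _check_rgb(image)
    hsv_m = hsv_filter(img, cfg)
    lum_map = luminance(img)
    residual = _luminance_residual(img, cfg)
    mx = residual.max()
    lmask = residual >= max(cfg.luminance_threshold * mx, cfg.luminance_floor)
    ref = tuple(np.asarray(cfg.similarity_reference_rgb, float))
    if cfg.refine_reference:
        ref = tuple(_refine_reference(img, cfg, hsv_m, lum_map, lmask))
    cos_m = cosine_similarity_mask(img, ref, cfg.similarity_threshold)
    merged = merge_masks(hsv_m, cos_m, lmask)
    cleaned = eliminate_border(merged, cfg.border_erosion_radius_px)
    dots = extract_dots(cleaned, lum_map, cfg.min_area_px, weight_map=residual)
    dots = eliminate_reflections(dots, cfg.min_separation_px)
    center = None
    if dots:
        center = find_center_dot(dots, image_shape=img.shape)
    masks = {}
    if keep_masks:
        masks = {"hsv": hsv_m, "cosine": cos_m, "luminance": lmask,
                 "merged": merged, "cleaned": cleaned}
    return CascadeResult(dots=dots, center=center, masks=masks, reference_rgb=ref)
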