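"""Punctate-signal segmentation and per-capillary relative areas.

The per-capillary feature of interest is the *relative area*: the fraction
of an ROI's pixel raster covered by segmented punctate mRNA signal in one
channel.  Spots are isolated with a deterministic operator — white top-hat
(suppresses structures wider than the spot scale), a global threshold
(Otsu or fixed) on the ROI crop, and a connected-component size filter —
applied identically to both channels.

Rasterization rule: a pixel belongs to an ROI iff its center lies inside
the polygon (even-odd rule for simple polygons), which makes every
relative area an exact ratio of integer pixel counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk, white_tophat

from .annotation_io import AnnotationSet

__all__ = [
    "SpotParams",
    "CapillaryFeatures",
    "segment_spots",
    "relative_area",
    "quantify_capillaries",
    "rasterize_roi",
]


class DegenerateROIError(ValueError):
    """ROI rasterizes to zero pixels."""


@dataclass(frozen=True)
class SpotParams:
    """Spot-detector settings shared by both channels."""

    tophat_radius_px: float = 3.0
    threshold_method: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float = 0.5
    min_spot_area_px: int = 3
    max_spot_area_px: int = 400

    def validate(self) -> None:
        if self.tophat_radius_px <= 0:
            raise ValueError("tophat_radius_px must be positive")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if not 0.0 < self.fixed_threshold < 1.0:
            raise ValueError("fixed_threshold must lie in (0, 1)")
        if not 0 < self.min_spot_area_px <= self.max_spot_area_px:
            raise ValueError("min_spot_area_px must be in [1, max_spot_area_px]")


@dataclass
class CapillaryFeatures:
    """Per-ROI marker features; distance and category are filled downstream."""

    id: str
    rel_area_cd31: float
    rel_area_emcn: float
    roi_area_um2: float
    min_dist_um: float = float("nan")
    category: str | None = None


def rasterize_roi(roi_polygon: np.ndarray, image_shape: tuple[int, int]):
    """Boolean crop raster and its (y0, x0) offset; pixel-center-inside rule."""
    from matplotlib.path import Path

    h, w = image_shape
    poly = np.asarray(roi_polygon, float)
    x0 = max(int(np.floor(poly[:, 0].min())), 0)
    x1 = min(int(np.ceil(poly[:, 0].max())) + 1, w)
    y0 = max(int(np.floor(poly[:, 1].min())), 0)
    y1 = min(int(np.ceil(poly[:, 1].max())) + 1, h)
    if x1 <= x0 or y1 <= y0:
        raise DegenerateROIError("degenerate ROI: rasterizes to zero pixels")
    xs, ys = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    # closed=True consumes the final vertex as the closing point, so repeat it
    ring = np.vstack([poly, poly[:1]])
    inside = Path(ring, closed=True).contains_points(
        np.column_stack([xs.ravel(), ys.ravel()]))
    mask = inside.reshape(y1 - y0, x1 - x0)
    if not mask.any():
        raise DegenerateROIError("degenerate ROI: rasterizes to zero pixels")
    return mask, (y0, x0)


def _tophat_and_threshold(channel_image: np.ndarray, params: SpotParams):
    """Whole-channel white top-hat and its global threshold.

    The threshold is set once per channel on the full section (Otsu over
    the top-hat response, or the fixed value), mirroring a single trained
    classifier applied everywhere; per-ROI thresholds would be dominated
    by background noise in spot-free capillaries.
    """
    filtered = white_tophat(np.asarray(channel_image, np.float64),
                            footprint=disk(int(round(params.tophat_radius_px))))
    if params.threshold_method == "fixed":
        return filtered, params.fixed_threshold
    if np.ptp(filtered) == 0:  # constant response: nothing punctate anywhere
        return filtered, None
    return filtered, float(threshold_otsu(filtered))


def _segment_crop(filtered: np.ndarray, threshold: float | None,
                  roi_mask: np.ndarray, origin: tuple[int, int],
                  params: SpotParams) -> np.ndarray:
    """Spot mask on the ROI crop (same shape as ``roi_mask``)."""
    if threshold is None:
        return np.zeros_like(roi_mask)
    y0, x0 = origin
    hh, ww = roi_mask.shape
    # restrict to the ROI raster before size filtering
    local = (filtered[y0:y0 + hh, x0:x0 + ww] > threshold) & roi_mask
    labels, n = ndimage.label(local)
    if n == 0:
        return local
    sizes = ndimage.sum_labels(np.ones_like(local, np.int64), labels, np.arange(1, n + 1))
    keep = (sizes >= params.min_spot_area_px) & (sizes <= params.max_spot_area_px)
    return keep[labels - 1] & (labels > 0)


def segment_spots(channel_image: np.ndarray, roi_polygon: np.ndarray,
                  params: SpotParams | None = None) -> np.ndarray:
    """Binary spot mask (full image shape), nonzero only inside the ROI raster.

    White top-hat with radius ``tophat_radius_px`` precedes thresholding
    (the threshold is global to the channel); connected components outside
    ``[min_spot_area_px, max_spot_area_px]`` are removed.  Raises
    :class:`DegenerateROIError` for zero-pixel ROIs.
    """
    params = params or SpotParams()
    params.validate()
    roi_mask, origin = rasterize_roi(roi_polygon, channel_image.shape)
    filtered, threshold = _tophat_and_threshold(channel_image, params)
    local = _segment_crop(filtered, threshold, roi_mask, origin, params)
    out = np.zeros(channel_image.shape, bool)
    y0, x0 = origin
    out[y0:y0 + roi_mask.shape[0], x0:x0 + roi_mask.shape[1]] = local
    return out


def relative_area(spot_mask: np.ndarray, roi_polygon: np.ndarray) -> float:
    """(spot pixels) / (ROI raster pixels) — an exact rational in [0, 1]."""
    roi_mask, (y0, x0) = rasterize_roi(roi_polygon, spot_mask.shape)
    roi_px = int(roi_mask.sum())
    full = np.zeros(spot_mask.shape, bool)
    full[y0:y0 + roi_mask.shape[0], x0:x0 + roi_mask.shape[1]] = roi_mask
    spot_mask = np.asarray(spot_mask, bool)
    if (spot_mask & ~full).any():
        raise ValueError("spot mask extends outside the ROI raster")
    return int(spot_mask.sum()) / roi_px


def quantify_capillaries(channel_images: dict[str, np.ndarray],
                         annotations: AnnotationSet,
                         params: SpotParams | None = None) -> list[CapillaryFeatures]:
    """One :class:`CapillaryFeatures` row per ROI, in annotation order.

    ``channel_images`` must contain ``"CD31"`` and ``"EMCN"``; both are
    quantified with the same ``params``.  ``min_dist_um`` is left NaN for
    :mod:`~vesselzoner.spatial_analysis` to fill.
    """
    params = params or SpotParams()
    params.validate()
    for name in ("CD31", "EMCN"):
        if name not in channel_images:
            raise ValueError(f"channel missing: {name}")
    annotations.validate()
    px2 = annotations.pixel_size_um ** 2
    prepared = {name: _tophat_and_threshold(channel_images[name], params)
                for name in ("CD31", "EMCN")}
    rows: list[CapillaryFeatures] = []
    for rid, poly in annotations.capillary_rois:
        roi_mask, origin = rasterize_roi(poly, channel_images["CD31"].shape)
        roi_px = int(roi_mask.sum())
        rel = {}
        for name in ("CD31", "EMCN"):
            filtered, threshold = prepared[name]
            local = _segment_crop(filtered, threshold, roi_mask, origin, params)
            rel[name] = int(local.sum()) / roi_px
        rows.append(CapillaryFeatures(
            id=rid,
            rel_area_cd31=rel["CD31"],
            rel_area_emcn=rel["EMCN"],
            roi_area_um2=roi_px * px2,
        ))
    return rows
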