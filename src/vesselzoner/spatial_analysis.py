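"""Distances to the bone bed, per-category distance profiles, KS tests,
section registration, and OSX proximity enrichment.

All distances are minimal Euclidean distances between a capillary ROI and
the bone-bed polyline (exact segment-to-segment geometry, 0 when they
touch), expressed in µm; summaries are reported in mm.  Per-category
distance distributions are smoothed with a Gaussian KDE (Scott bandwidth)
reflected at zero, mirroring violin-style profiles.  Distribution pairs
are compared with the two-sample Kolmogorov–Smirnov test (asymptotic
p-value, significance at p <= 0.05).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import special
from shapely.geometry import LineString, Polygon

from .annotation_io import AnnotationSet
from .spot_quantification import CapillaryFeatures

__all__ = [
    "CategoryProfile",
    "SimilarityTransform",
    "min_distance_to_bonebed",
    "fill_min_distances",
    "distance_profile",
    "ks_two_sample",
    "register_sections",
    "osx_proximity_enrichment",
]

logger = logging.getLogger(__name__)


def min_distance_to_bonebed(roi_polygon: np.ndarray, bone_bed: np.ndarray,
                            pixel_size_um: float) -> float:
    """Minimal distance (µm) between the ROI and the bed polyline; 0 if touching."""
    poly = np.asarray(roi_polygon, float)
    bed = np.asarray(bone_bed, float)
    if len(poly) < 3 or len(bed) < 2:
        raise ValueError("empty geometry")
    return float(Polygon(poly).distance(LineString(bed)) * pixel_size_um)


def fill_min_distances(features: list[CapillaryFeatures],
                       annotations: AnnotationSet) -> list[CapillaryFeatures]:
    """Fill ``min_dist_um`` for every feature row from the annotation geometry."""
    polys = dict(annotations.capillary_rois)
    bed = LineString(annotations.bone_bed)
    out = []
    for f in features:
        if f.id not in polys:
            raise ValueError(f"no ROI annotation for capillary {f.id}")
        d = Polygon(polys[f.id]).distance(bed) * annotations.pixel_size_um
        out.append(replace(f, min_dist_um=float(d)))
    return out


@dataclass
class CategoryProfile:
    """Distance sample and reflected-KDE profile for one capillary category."""

    category: str
    distances_um: np.ndarray
    kde_support_um: np.ndarray
    kde_density_per_um: np.ndarray
    mean_um: float
    sem_um: float
    degenerate: bool = False

    @property
    def mean_mm(self) -> float:
        return self.mean_um / 1000.0

    @property
    def sem_mm(self) -> float:
        return self.sem_um / 1000.0

    def mode_um(self) -> float:
        return float(self.kde_support_um[np.argmax(self.kde_density_per_um)])


def _profile_one(category: str, d: np.ndarray, grid_size: int) -> CategoryProfile:
    d = np.asarray(d, float)
    mean = float(d.mean())
    sem = float(d.std(ddof=1) / np.sqrt(len(d))) if len(d) > 1 else 0.0
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        # all distances identical: degenerate, delta-like profile
        support = np.array([d[0]])
        dens = np.array([1.0])
        return CategoryProfile(category, d, support, dens, mean, 0.0, degenerate=True)
    h = sd * len(d) ** (-1.0 / 5.0)  # Scott, d = 1
    support = np.linspace(0.0, d.max() + 3 * h, grid_size)
    inv = 1.0 / (np.sqrt(2 * np.pi) * h * len(d))
    # boundary reflection at 0 keeps all mass on the nonnegative axis
    dens = inv * (
        np.exp(-0.5 * ((support[:, None] - d[None, :]) / h) ** 2)
        + np.exp(-0.5 * ((support[:, None] + d[None, :]) / h) ** 2)
    ).sum(axis=1)
    return CategoryProfile(category, d, support, dens, mean, sem)


def distance_profile(features, categories=("HH", "HL", "LH", "LL"),
                     grid_size: int = 512) -> list[CategoryProfile]:
    """Per-category distance distributions (KDE reflected at 0).

    Categories with fewer than 2 members are omitted with a warning.
    Accepts a list of :class:`CapillaryFeatures` or a feature DataFrame.
    """
    if isinstance(features, pd.DataFrame):
        cats = features["category"].to_numpy(str)
        dists = features["min_dist_um"].to_numpy(float)
    else:
        cats = np.array([f.category for f in features], str)
        dists = np.array([f.min_dist_um for f in features], float)
    if np.isnan(dists).any():
        raise ValueError("min_dist_um not filled for all capillaries")
    profiles = []
    for c in categories:
        d = dists[cats == c]
        if len(d) < 2:
            logger.warning("category %s has %d member(s); profile omitted", c, len(d))
            continue
        profiles.append(_profile_one(c, d, grid_size))
    return profiles


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test.

    D is the exact supremum of |ECDF_x - ECDF_y| over the pooled sample;
    the p-value comes from the asymptotic Kolmogorov distribution with
    effective size n_x n_y / (n_x + n_y), using Stephens' finite-sample
    argument correction so the test holds its nominal size at moderate n.
    """
    x = np.sort(np.asarray(x, float).ravel())
    y = np.sort(np.asarray(y, float).ravel())
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    # integer ECDF counts keep D an exact rational (count / (n_x * n_y))
    cx = np.searchsorted(x, pooled, side="right").astype(np.int64)
    cy = np.searchsorted(y, pooled, side="right").astype(np.int64)
    d = int(np.max(np.abs(cx * y.size - cy * x.size))) / (x.size * y.size)
    en = np.sqrt(x.size * y.size / (x.size + y.size))
    p = float(special.kolmogorov((en + 0.12 + 0.11 / en) * d))
    return d, float(np.clip(p, np.finfo(float).tiny, 1.0))


@dataclass
class SimilarityTransform:
    """Least-squares rotation + isotropic scale + translation between sections."""

    rotation_rad: float
    scale: float
    translation: np.ndarray
    rmse: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float).reshape(-1, 2)
        c, s = np.cos(self.rotation_rad), np.sin(self.rotation_rad)
        R = np.array([[c, -s], [s, c]])
        return pts @ (self.scale * R).T + self.translation


def register_sections(landmarks_src, landmarks_dst) -> SimilarityTransform:
    """Fit the similarity transform mapping source landmarks onto targets.

    Uses the least-squares (Umeyama) solution over >= 2 paired landmarks,
    as used to merge adjacent 4-µm sections via morphological landmarks.
    """
    from skimage.transform import SimilarityTransform as _SkSim

    src = np.asarray(landmarks_src, float).reshape(-1, 2)
    dst = np.asarray(landmarks_dst, float).reshape(-1, 2)
    if src.shape != dst.shape or len(src) < 2:
        raise ValueError("need >= 2 paired landmarks of identical shape")
    if np.allclose(src, src[0]):
        raise ValueError("degenerate landmarks: all source points coincide")
    if hasattr(_SkSim, "from_estimate"):
        tf = _SkSim.from_estimate(src, dst)
        if not tf or not np.all(np.isfinite(tf.params)):
            raise ValueError("similarity transform estimation failed")
    else:  # older scikit-image
        tf = _SkSim(dimensionality=2)
        if not tf.estimate(src, dst) or not np.all(np.isfinite(tf.params)):
            raise ValueError("similarity transform estimation failed")
    residual = tf(src) - dst
    rmse = float(np.sqrt(np.mean(np.sum(residual ** 2, axis=1))))
    return SimilarityTransform(
        rotation_rad=float(tf.rotation),
        scale=float(tf.scale),
        translation=np.asarray(tf.translation, float),
        rmse=rmse,
    )


def osx_proximity_enrichment(features, annotations: AnnotationSet,
                             osx_points: np.ndarray,
                             radius_um: float = 100.0) -> float:
    """OSX point density near HH capillaries relative to near LL capillaries.

    Each category's neighborhood is the union of its ROIs dilated by
    ``radius_um``, minus all capillary ROIs themselves; the returned ratio
    is (points per µm² in the HH neighborhood) / (same for LL).  The
    default radius (100 µm) is the scale at which osteoprogenitor foci are
    described around high-expressing capillaries.
    """
    import shapely

    if radius_um <= 0:
        raise ValueError("radius_um must be positive")
    if isinstance(features, pd.DataFrame):
        cat_of = dict(zip(features["id"].astype(str), features["category"].astype(str)))
    else:
        cat_of = {f.id: f.category for f in features}
    polys = {rid: Polygon(p) for rid, p in annotations.capillary_rois}
    by_cat = {"HH": [], "LL": []}
    for rid, poly in polys.items():
        c = cat_of.get(rid)
        if c in by_cat:
            by_cat[c].append(poly)
    if not by_cat["HH"] or not by_cat["LL"]:
        raise ValueError("need at least one HH and one LL capillary")
    pts = np.asarray(osx_points, float).reshape(-1, 2)
    radius_px = radius_um / annotations.pixel_size_um
    all_rois = shapely.unary_union(list(polys.values()))
    px2 = annotations.pixel_size_um ** 2

    dens = {}
    for c in ("HH", "LL"):
        region = shapely.unary_union([p.buffer(radius_px) for p in by_cat[c]])
        region = region.difference(all_rois)
        area_um2 = region.area * px2
        if area_um2 <= 0:
            raise ValueError(f"zero neighborhood area for category {c}")
        if len(pts):
            inside = shapely.contains_xy(region, pts[:, 0], pts[:, 1])
            n_in = int(inside.sum())
        else:
            n_in = 0
        dens[c] = n_in / area_um2
    if dens["LL"] == 0:
        raise ValueError("no OSX points in the LL neighborhood: enrichment undefined")
    return dens["HH"] / dens["LL"]
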