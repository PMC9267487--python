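"""Synthetic two-channel mRNA-hybridization histology scenes with planted truth.

A *scene* emulates one entire cylinder cross-section of a calvarial
bone-augmentation biopsy imaged after punctate in-situ hybridization:

* a bone-bed polyline spanning the section width (the native calvarial
  surface; all heights are measured from it, positive upward);
* elliptical capillary ROIs scattered above the bed, each carrying a true
  expression category — HH, HL, LH, LL for CD31 high/low × EMCN high/low —
  with CD31-high/EMCN-high ("type-H-like") capillaries concentrated in a
  band between the new-bone front and the granulation-tissue front, and the
  dominant low/low population concentrated near the bed;
* per-capillary true relative signal areas (fraction of ROI area covered by
  punctate signal) drawn from the category means;
* an OSX (Osterix, osteoprogenitor marker) point process whose intensity is
  multiplied by a configurable factor near HH capillaries;
* optionally rendered CD31 / EMCN / OSX channel images in which each
  capillary contains non-overlapping disk-shaped "spots" realizing its true
  relative area up to one spot-area quantum, plus Gaussian background noise.

Coordinates are 0-based pixels, x rightward, y downward; the bone bed sits
at large y, so height above the bed is ``(y_bed(x) - y) * pixel_size_um``.
Internal distances are µm; reports use mm.  Everything is reproducible from
``SceneConfig.seed`` alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon
from shapely.strtree import STRtree

__all__ = [
    "SceneConfig",
    "GroundTruthCapillary",
    "Scene",
    "generate_scene",
    "render_channels",
    "ground_truth_table",
    "scene_annotations",
    "zone_masks",
    "write_scene",
    "CATEGORIES",
]

CATEGORIES = ("HH", "HL", "LH", "LL")

# seed-stream tags so each stage draws from an independent substream
_STREAM_GEOMETRY = 1
_STREAM_AREAS = 2
_STREAM_OSX = 3
_STREAM_RENDER = 4


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic section (defaults ≈ a 2-week biopsy).

    The default frame is a 5 × 8 mm cross-section at 4 µm/px.  Zone fronts
    follow the 2-week geometry of the emulated model: new bone reaching
    ~0.7 mm and granulation tissue ~2.5 mm above the bed, with the
    CD31-high/EMCN-high band centered at 2.0 mm (inside the osteogenic
    zone) and the low/low population at 0.8 mm.
    """

    image_width_px: int = 1250
    image_height_px: int = 2000
    pixel_size_um: float = 4.0
    n_capillaries: int = 269
    frac_high_high: float = 0.15
    frac_high_low: float = 0.05
    frac_low_high: float = 0.05
    rel_area_low_mean: float = 0.05
    rel_area_high_mean: float = 0.25
    rel_area_sd: float = 0.03
    spot_radius_px: float = 1.5
    background_noise_sd: float = 0.02
    bone_front_mm: float = 0.7
    granulation_front_mm: float = 2.5
    highhigh_band_center_mm: float = 2.0
    highhigh_band_sd_mm: float = 0.5
    lowlow_center_mm: float = 0.8
    lowlow_sd_mm: float = 0.5
    n_osx_spots: int = 2000
    osx_enrichment_radius_um: float = 100.0
    osx_enrichment_factor: float = 3.0
    capillary_radius_um_min: float = 20.0
    capillary_radius_um_max: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        """Raise ``ValueError`` naming the offending field."""
        def _positive(name):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

        for name in (
            "image_width_px", "image_height_px", "pixel_size_um",
            "rel_area_sd", "spot_radius_px", "highhigh_band_center_mm",
            "highhigh_band_sd_mm", "lowlow_center_mm", "lowlow_sd_mm",
            "osx_enrichment_radius_um", "osx_enrichment_factor",
            "capillary_radius_um_min", "capillary_radius_um_max",
        ):
            _positive(name)
        if self.n_capillaries < 0:
            raise ValueError("n_capillaries must be nonnegative")
        if self.n_osx_spots < 0:
            raise ValueError("n_osx_spots must be nonnegative")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be nonnegative")
        for name in ("frac_high_high", "frac_high_low", "frac_low_high"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frac_high_high + self.frac_high_low + self.frac_low_high > 1.0 + 1e-12:
            raise ValueError("frac_high_high + frac_high_low + frac_low_high exceeds 1")
        for name in ("rel_area_low_mean", "rel_area_high_mean"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not self.rel_area_high_mean > self.rel_area_low_mean:
            raise ValueError("rel_area_high_mean must exceed rel_area_low_mean")
        if not 0.0 <= self.bone_front_mm < self.granulation_front_mm:
            raise ValueError("bone_front_mm must be nonnegative and below granulation_front_mm")
        height_mm = self.image_height_px * self.pixel_size_um / 1000.0
        for name in ("granulation_front_mm", "highhigh_band_center_mm", "lowlow_center_mm"):
            if getattr(self, name) >= height_mm:
                raise ValueError(f"{name} does not fit inside the image height ({height_mm:g} mm)")
        if self.capillary_radius_um_max < self.capillary_radius_um_min:
            raise ValueError("capillary_radius_um_max must be >= capillary_radius_um_min")

    @property
    def category_fractions(self) -> dict[str, float]:
        ll = 1.0 - self.frac_high_high - self.frac_high_low - self.frac_low_high
        return {"HH": self.frac_high_high, "HL": self.frac_high_low,
                "LH": self.frac_low_high, "LL": ll}


@dataclass
class GroundTruthCapillary:
    """One planted capillary: polygon, category and true feature values."""

    id: str
    polygon: np.ndarray  # (n, 2) closed-by-convention simple polygon, pixel coords
    true_category: str
    true_rel_area_cd31: float
    true_rel_area_emcn: float
    true_dist_um: float


@dataclass
class Scene:
    """A generated section: ground truth plus (optionally) rendered channels."""

    config: SceneConfig
    capillaries: list[GroundTruthCapillary]
    bone_bed: np.ndarray  # (m, 2) polyline spanning the full image width
    osx_points: np.ndarray  # (k, 2)
    channel_images: dict[str, np.ndarray] | None = None


def _bed_polyline(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Gently undulating bed near the bottom of the frame, spanning full width."""
    w, h = config.image_width_px, config.image_height_px
    amplitude = min(0.01 * h, 20.0)
    base = h - 1 - 2.0 * amplitude - 4.0
    xs = np.linspace(0.0, w - 1.0, 65)
    phase = rng.uniform(0, 2 * np.pi)
    ys = base + amplitude * np.sin(2 * np.pi * xs / w + phase)
    return np.column_stack([xs, ys])


def _bed_y_at(bed: np.ndarray, x: np.ndarray | float) -> np.ndarray | float:
    order = np.argsort(bed[:, 0])
    return np.interp(x, bed[order, 0], bed[order, 1])


def _ellipse(cx, cy, a, b, angle, n=32) -> np.ndarray:
    phi = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    x = a * np.cos(phi)
    y = b * np.sin(phi)
    c, s = np.cos(angle), np.sin(angle)
    return np.column_stack([cx + c * x - s * y, cy + s * x + c * y])


def _draw_height_mm(category: str, config: SceneConfig, rng: np.random.Generator,
                    lo_mm: float, hi_mm: float) -> float:
    """Height above the bed for one capillary center, truncated to [lo, hi]."""
    for _ in range(1000):
        if category == "HH":
            h = rng.normal(config.highhigh_band_center_mm, config.highhigh_band_sd_mm)
        elif category == "LL":
            h = rng.normal(config.lowlow_center_mm, config.lowlow_sd_mm)
        else:  # HL / LH: spread over the colonized region
            h = rng.uniform(lo_mm, config.granulation_front_mm)
        if lo_mm <= h <= hi_mm:
            return h
    raise RuntimeError("could not draw a capillary height inside the frame")


def generate_scene(config: SceneConfig) -> Scene:
    """Plant capillaries, the bone bed and OSX points; channels stay unrendered.

    HH capillary centers follow a normal law in height centered at
    ``highhigh_band_center_mm``; LL centers one at ``lowlow_center_mm``.
    Per-capillary true relative areas are drawn from the category's channel
    means with sd ``rel_area_sd``.  OSX intensity is multiplied by
    ``osx_enrichment_factor`` within ``osx_enrichment_radius_um`` of an HH
    capillary (outside the ROI itself).  Fully reproducible from the seed.
    """
    config.validate()
    rng_geo = np.random.Generator(np.random.Philox(
        np.random.SeedSequence([config.seed, _STREAM_GEOMETRY])))
    rng_area = np.random.Generator(np.random.Philox(
        np.random.SeedSequence([config.seed, _STREAM_AREAS])))
    rng_osx = np.random.Generator(np.random.Philox(
        np.random.SeedSequence([config.seed, _STREAM_OSX])))

    bed = _bed_polyline(config, rng_geo)
    bed_line = LineString(bed)
    px = config.pixel_size_um
    w, h = config.image_width_px, config.image_height_px

    fracs = config.category_fractions
    cats = rng_geo.choice(CATEGORIES, size=config.n_capillaries,
                          p=[fracs[c] for c in CATEGORIES])

    r_lo = config.capillary_radius_um_min / px
    r_hi = config.capillary_radius_um_max / px
    max_r_mm = config.capillary_radius_um_max / 1000.0

    capillaries: list[GroundTruthCapillary] = []
    placed: list[Polygon] = []
    placed_r: list[float] = []
    centers: list[tuple[float, float]] = []

    for i, cat in enumerate(cats):
        for attempt in range(500):
            a = rng_geo.uniform(r_lo, r_hi)
            b = rng_geo.uniform(r_lo, a)  # semi-minor <= semi-major
            angle = rng_geo.uniform(0, np.pi)
            margin = a + 2.0
            cx = rng_geo.uniform(margin, w - 1 - margin)
            lo_mm = max_r_mm + 0.02
            hi_mm = (_bed_y_at(bed, cx) - margin) * px / 1000.0
            hh = _draw_height_mm(cat, config, rng_geo, lo_mm, hi_mm)
            cy = _bed_y_at(bed, cx) - hh * 1000.0 / px
            if cy < margin:
                continue
            poly = _ellipse(cx, cy, a, b, angle)
            shp = Polygon(poly)
            # reject overlaps with already placed capillaries (cheap prefilter)
            ok = True
            for j, (ox, oy) in enumerate(centers):
                if (ox - cx) ** 2 + (oy - cy) ** 2 < (placed_r[j] + a + 2.0) ** 2:
                    if shp.distance(placed[j]) < 2.0:
                        ok = False
                        break
            if ok:
                break
        else:
            raise RuntimeError("could not place capillary without overlap; "
                               "reduce n_capillaries or capillary radii")
        placed.append(shp)
        placed_r.append(a)
        centers.append((cx, cy))
        rel = {}
        for channel, state in (("cd31", cat[0]), ("emcn", cat[1])):
            mean = config.rel_area_high_mean if state == "H" else config.rel_area_low_mean
            rel[channel] = float(np.clip(rng_area.normal(mean, config.rel_area_sd), 0.0, 0.6))
        capillaries.append(GroundTruthCapillary(
            id=f"cap{i:04d}",
            polygon=poly,
            true_category=str(cat),
            true_rel_area_cd31=rel["cd31"],
            true_rel_area_emcn=rel["emcn"],
            true_dist_um=float(shp.distance(bed_line) * px),
        ))

    osx = _sample_osx_points(config, capillaries, rng_osx)
    return Scene(config=config, capillaries=capillaries, bone_bed=bed, osx_points=osx)


def _sample_osx_points(config: SceneConfig, capillaries: list[GroundTruthCapillary],
                       rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample OSX points with enriched intensity near HH capillaries."""
    import shapely

    n = config.n_osx_spots
    if n == 0:
        return np.empty((0, 2))
    w, h = config.image_width_px, config.image_height_px
    radius_px = config.osx_enrichment_radius_um / config.pixel_size_um
    hh_polys = [Polygon(c.polygon) for c in capillaries if c.true_category == "HH"]
    if hh_polys:
        enriched = shapely.unary_union([p.buffer(radius_px) for p in hh_polys])
        enriched = enriched.difference(shapely.unary_union(hh_polys))
    else:
        enriched = None
    factor = config.osx_enrichment_factor

    points: list[np.ndarray] = []
    got = 0
    for _ in range(200):
        m = max(4 * n, 256)
        cand = np.column_stack([rng.uniform(0, w - 1, m), rng.uniform(0, h - 1, m)])
        if enriched is not None and factor != 1.0:
            inside = shapely.contains_xy(enriched, cand[:, 0], cand[:, 1])
            weight = np.where(inside, factor, 1.0)
        else:
            weight = np.ones(m)
        accept = rng.uniform(0, factor if factor >= 1 else 1.0, m) < weight
        sel = cand[accept]
        points.append(sel)
        got += len(sel)
        if got >= n:
            break
    out = np.concatenate(points)[:n]
    return out


def _disk_offsets(radius_px: float) -> np.ndarray:
    r = int(np.ceil(radius_px))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    keep = dx ** 2 + dy ** 2 <= radius_px ** 2
    return np.column_stack([dy[keep], dx[keep]])  # (k, 2) as (dy, dx)


def _roi_raster(polygon: np.ndarray, width: int, height: int):
    """Crop-local boolean raster of pixels whose centers fall inside the polygon."""
    from matplotlib.path import Path

    x0 = max(int(np.floor(polygon[:, 0].min())), 0)
    x1 = min(int(np.ceil(polygon[:, 0].max())) + 1, width)
    y0 = max(int(np.floor(polygon[:, 1].min())), 0)
    y1 = min(int(np.ceil(polygon[:, 1].max())) + 1, height)
    if x1 <= x0 or y1 <= y0:
        return np.zeros((0, 0), bool), (0, 0)
    xs, ys = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    ring = np.vstack([polygon, polygon[:1]])
    inside = Path(ring, closed=True).contains_points(pts)
    return inside.reshape(y1 - y0, x1 - x0), (y0, x0)


def render_channels(scene: Scene) -> Scene:
    """Paint punctate spots into CD31/EMCN/OSX channels; returns a new Scene.

    Per capillary and channel, ``round(true_rel_area * roi_px / spot_px)``
    non-overlapping disks of radius ``spot_radius_px`` are placed fully
    inside the ROI raster, so the painted in-ROI fraction is within one
    spot-area quantum of the planted truth.  Gaussian background noise of
    sd ``background_noise_sd`` is added and values are clipped to [0, 1].
    Rendering twice from the same scene yields identical images.
    """
    config = scene.config
    rng = np.random.Generator(np.random.Philox(
        np.random.SeedSequence([config.seed, _STREAM_RENDER])))
    w, h = config.image_width_px, config.image_height_px
    offsets = _disk_offsets(config.spot_radius_px)
    spot_px = len(offsets)
    reach = int(np.ceil(config.spot_radius_px))

    images = {name: np.zeros((h, w), np.float32) for name in ("CD31", "EMCN", "OSX")}

    from scipy.ndimage import binary_erosion

    footprint = np.zeros((2 * reach + 1, 2 * reach + 1), bool)
    footprint[offsets[:, 0] + reach, offsets[:, 1] + reach] = True

    for cap in scene.capillaries:
        mask, (y0, x0) = _roi_raster(cap.polygon, w, h)
        roi_px = int(mask.sum())
        if roi_px == 0:
            continue
        eligible = binary_erosion(mask, structure=footprint, border_value=0)
        for channel, target in (("CD31", cap.true_rel_area_cd31),
                                ("EMCN", cap.true_rel_area_emcn)):
            n_spots = int(round(target * roi_px / spot_px))
            if n_spots == 0:
                continue
            centers = np.argwhere(eligible)
            if len(centers) == 0:
                raise ValueError(
                    f"relative area {target:.3f} unreachable in ROI {cap.id}: "
                    "no room for spots; use a smaller spot_radius_px")
            painted = np.zeros_like(mask)
            placed = 0
            attempts = 0
            max_attempts = max(50, 10 * n_spots)
            while placed < n_spots and attempts < max_attempts:
                attempts += 1
                cy, cx = centers[rng.integers(len(centers))]
                yy = cy + offsets[:, 0]
                xx = cx + offsets[:, 1]
                if painted[yy, xx].any():
                    continue
                painted[yy, xx] = True
                placed += 1
            if placed < n_spots:
                raise ValueError(
                    f"relative area {target:.3f} unreachable without spot overlap "
                    f"in ROI {cap.id}; use a smaller spot_radius_px")
            img = images[channel]
            sub = img[y0:y0 + mask.shape[0], x0:x0 + mask.shape[1]]
            sub[painted] = 1.0

    # OSX points: overlapping stamps allowed, channel is not area-quantified
    osx = images["OSX"]
    for x, y in scene.osx_points:
        cy, cx = int(round(y)), int(round(x))
        yy = cy + offsets[:, 0]
        xx = cx + offsets[:, 1]
        keep = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
        osx[yy[keep], xx[keep]] = 1.0

    if config.background_noise_sd > 0:
        for name in ("CD31", "EMCN", "OSX"):
            images[name] = images[name] + rng.normal(
                0.0, config.background_noise_sd, (h, w)).astype(np.float32)
    for name in ("CD31", "EMCN", "OSX"):
        images[name] = np.clip(images[name], 0.0, 1.0)

    return dataclasses.replace(scene, channel_images=images)


def ground_truth_table(scene: Scene) -> pd.DataFrame:
    """Planted truth as a table: id, category, relative areas, distance (µm)."""
    return pd.DataFrame({
        "id": [c.id for c in scene.capillaries],
        "true_category": [c.true_category for c in scene.capillaries],
        "true_rel_area_cd31": [c.true_rel_area_cd31 for c in scene.capillaries],
        "true_rel_area_emcn": [c.true_rel_area_emcn for c in scene.capillaries],
        "true_dist_um": [c.true_dist_um for c in scene.capillaries],
    })


def scene_annotations(scene: Scene):
    """The scene's geometry as an :class:`~vesselzoner.annotation_io.AnnotationSet`."""
    from .annotation_io import AnnotationSet

    return AnnotationSet(
        capillary_rois=[(c.id, c.polygon.copy()) for c in scene.capillaries],
        bone_bed=scene.bone_bed.copy(),
        landmarks=None,
        pixel_size_um=scene.config.pixel_size_um,
    )


def zone_masks(scene: Scene) -> dict[str, np.ndarray]:
    """Boolean zone masks from the planted fronts.

    ``bone`` is the slab between the bed and ``bone_front_mm`` (stands in
    for a new-bone label), ``granulation`` everything above
    ``granulation_front_mm``, ``cylinder`` the whole region above the bed.
    """
    cfg = scene.config
    w, h = cfg.image_width_px, cfg.image_height_px
    cols = np.arange(w)
    bed_y = np.asarray(_bed_y_at(scene.bone_bed, cols))
    rows = np.arange(h)[:, None]
    height_mm = (bed_y[None, :] - rows) * cfg.pixel_size_um / 1000.0
    return {
        "bone": (height_mm >= 0) & (height_mm <= cfg.bone_front_mm),
        "granulation": (height_mm >= cfg.granulation_front_mm),
        "cylinder": height_mm >= 0,
    }


def write_scene(scene: Scene, outdir) -> dict[str, str]:
    """Write channel TIFFs (16-bit), GeoJSON annotations, truth CSV and config YAML."""
    import pathlib

    import tifffile
    import yaml

    from .annotation_io import save_annotations

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    if scene.channel_images is not None:
        for name, img in scene.channel_images.items():
            p = outdir / f"{name.lower()}.tif"
            tifffile.imwrite(p, (np.clip(img, 0, 1) * 65535).astype(np.uint16))
            paths[name] = str(p)
    ann_path = outdir / "annotations.geojson"
    save_annotations(scene_annotations(scene), ann_path)
    paths["annotations"] = str(ann_path)
    truth_path = outdir / "ground_truth.csv"
    ground_truth_table(scene).to_csv(truth_path, index=False)
    paths["ground_truth"] = str(truth_path)
    cfg_path = outdir / "scene_config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(scene.config), fh, sort_keys=True)
    paths["config"] = str(cfg_path)
    return paths
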