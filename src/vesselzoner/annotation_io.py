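"""Reading and writing ROI annotations (GeoJSON), images and feature tables.

Annotations follow the QuPath export convention: a GeoJSON
FeatureCollection where each capillary ROI is a ``Polygon`` feature with
properties ``{"class": "capillary", "id": ...}`` and the bone bed is a
single ``LineString`` feature with ``{"class": "bone_bed"}``.  Coordinates
are stored in pixel units; the µm-per-pixel scale travels in a top-level
``pixel_size_um`` property.  QuPath's nested ``classification.name``
property is also accepted on load.

Feature tables are plain CSV (comma, UTF-8, "." decimal, no index) with
header ``id,rel_area_cd31,rel_area_emcn,min_dist_um,category``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

__all__ = [
    "AnnotationSet",
    "load_annotations",
    "save_annotations",
    "save_features",
    "load_features",
    "load_channel_images",
]

FEATURE_COLUMNS = ["id", "rel_area_cd31", "rel_area_emcn", "min_dist_um", "category"]


@dataclass
class AnnotationSet:
    """Capillary ROIs, the bone bed, optional landmarks, and the pixel scale."""

    capillary_rois: list[tuple[str, np.ndarray]]
    bone_bed: np.ndarray
    landmarks: list[tuple[str, np.ndarray]] | None = None
    pixel_size_um: float = 1.0

    def validate(self) -> None:
        ids = [i for i, _ in self.capillary_rois]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValueError(f"duplicate ROI ids: {', '.join(dupes)}")
        if self.bone_bed is None or len(self.bone_bed) < 2:
            raise ValueError("bone_bed annotation missing")
        for rid, poly in self.capillary_rois:
            if len(poly) < 3:
                raise ValueError(f"ROI {rid} has fewer than 3 vertices")
            if not Polygon(poly).is_valid:
                raise ValueError(f"ROI {rid} polygon is not simple")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")


def _feature_class(feature: dict) -> str | None:
    props = feature.get("properties") or {}
    if "class" in props:
        return props["class"]
    cls = props.get("classification")
    if isinstance(cls, dict):
        return cls.get("name")
    if isinstance(cls, str):
        return cls
    return None


def _close_ring(coords: np.ndarray) -> np.ndarray:
    if not np.array_equal(coords[0], coords[-1]):
        return coords
    return coords[:-1]


def load_annotations(path) -> AnnotationSet:
    """Parse a GeoJSON FeatureCollection into an :class:`AnnotationSet`.

    Unclosed polygons are closed implicitly (the closing vertex, if present,
    is dropped; polygons are treated as closed rings).  Raises ``ValueError``
    when the bone bed is missing or duplicated, ids repeat, or a polygon is
    non-simple.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    rois: list[tuple[str, np.ndarray]] = []
    beds: list[np.ndarray] = []
    landmarks: list[tuple[str, np.ndarray]] = []
    anon = 0
    for feature in doc.get("features", []):
        cls = (_feature_class(feature) or "").lower()
        geom = feature.get("geometry") or {}
        gtype = geom.get("type")
        props = feature.get("properties") or {}
        if cls == "bone_bed":
            if gtype != "LineString":
                raise ValueError("bone_bed feature must be a LineString")
            beds.append(np.asarray(geom["coordinates"], float))
        elif cls == "capillary":
            if gtype != "Polygon":
                raise ValueError("capillary feature must be a Polygon")
            rid = props.get("id")
            if rid is None:
                rid = f"roi{anon:04d}"
                anon += 1
            coords = _close_ring(np.asarray(geom["coordinates"][0], float))
            rois.append((str(rid), coords))
        elif cls == "landmark":
            landmarks.append((str(props.get("label", f"lm{len(landmarks)}")),
                              np.asarray(geom["coordinates"], float)))
        # other classes are ignored
    if len(beds) == 0:
        raise ValueError("bone_bed annotation missing")
    if len(beds) > 1:
        raise ValueError(f"expected exactly one bone_bed, found {len(beds)}")
    aset = AnnotationSet(
        capillary_rois=rois,
        bone_bed=beds[0],
        landmarks=landmarks or None,
        pixel_size_um=float(doc.get("pixel_size_um", 1.0)),
    )
    aset.validate()
    return aset


def save_annotations(aset: AnnotationSet, path) -> None:
    """Write an :class:`AnnotationSet` as GeoJSON (vertex-exact round trip)."""
    aset.validate()
    features = []
    for rid, poly in aset.capillary_rois:
        ring = [list(map(float, p)) for p in poly]
        ring.append(ring[0])
        features.append({
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": {"class": "capillary", "id": rid},
        })
    features.append({
        "type": "Feature",
        "geometry": {"type": "LineString",
                     "coordinates": [list(map(float, p)) for p in aset.bone_bed]},
        "properties": {"class": "bone_bed"},
    })
    for label, pt in aset.landmarks or []:
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": list(map(float, pt))},
            "properties": {"class": "landmark", "label": label},
        })
    doc = {"type": "FeatureCollection",
           "pixel_size_um": float(aset.pixel_size_um),
           "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def save_features(table, path) -> None:
    """Write per-capillary features to CSV.

    Accepts a pandas DataFrame or a list of
    :class:`~vesselzoner.spot_quantification.CapillaryFeatures`.
    """
    df = _as_frame(table)
    # %.17g guarantees a bit-exact float64 round trip through the CSV
    df.to_csv(path, index=False, float_format="%.17g")


def load_features(path) -> pd.DataFrame:
    """Read a feature CSV, raising ``ValueError`` naming any missing column."""
    df = pd.read_csv(path, dtype={"id": str, "category": str},
                     float_precision="round_trip")
    for col in FEATURE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"feature table missing column '{col}'")
    return df


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"feature table missing column '{missing[0]}'")
        return table[FEATURE_COLUMNS + [c for c in table.columns if c not in FEATURE_COLUMNS]]
    rows = []
    for f in table:
        rows.append({
            "id": f.id,
            "rel_area_cd31": f.rel_area_cd31,
            "rel_area_emcn": f.rel_area_emcn,
            "min_dist_um": f.min_dist_um,
            "category": f.category,
        })
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def load_channel_images(paths: dict[str, str]) -> dict[str, np.ndarray]:
    """Load single-channel TIFF/PNG images, rescaled to float in [0, 1]."""
    import tifffile
    from imageio.v3 import imread

    out = {}
    for name, p in paths.items():
        p = str(p)
        if p.lower().endswith((".tif", ".tiff")):
            arr = tifffile.imread(p)
        else:
            arr = imread(p)
        arr = np.asarray(arr)
        if arr.ndim != 2:
            raise ValueError(f"channel {name}: expected a single-channel 2D image")
        if np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
        out[name] = arr.astype(np.float64)
    return out
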