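"""GeoJSON / CSV round trips must be lossless."""

import json

import numpy as np
import pandas as pd
import pytest

from vesselzoner.annotation_io import (AnnotationSet, load_annotations,
                                       load_features, save_annotations,
                                       save_features)
from vesselzoner.spot_quantification import CapillaryFeatures
from vesselzoner.synthetic_histology import scene_annotations


def _write(doc, path):
    with open(path, "w") as fh:
        json.dump(doc, fh)


def _simple_doc(n_rois=3, beds=1, ids=None):
    features = []
    for i in range(n_rois):
        rid = ids[i] if ids else f"c{i}"
        ring = [[10.0 + 20 * i, 10.0], [30.0 + 20 * i, 10.0],
                [30.0 + 20 * i, 30.0], [10.0 + 20 * i, 30.0],
                [10.0 + 20 * i, 10.0]]
        features.append({"type": "Feature",
                         "geometry": {"type": "Polygon", "coordinates": [ring]},
                         "properties": {"class": "capillary", "id": rid}})
    for _ in range(beds):
        features.append({"type": "Feature",
                         "geometry": {"type": "LineString",
                                      "coordinates": [[0.0, 90.0], [99.0, 95.0]]},
                         "properties": {"class": "bone_bed"}})
    return {"type": "FeatureCollection", "pixel_size_um": 2.0, "features": features}


def test_load_counts_rois(tmp_path):
    p = tmp_path / "a.geojson"
    _write(_simple_doc(), p)
    aset = load_annotations(p)
    assert len(aset.capillary_rois) == 3
    assert aset.pixel_size_um == 2.0


def test_missing_bone_bed_is_an_error(tmp_path):
    p = tmp_path / "a.geojson"
    _write(_simple_doc(beds=0), p)
    with pytest.raises(ValueError, match="bone_bed annotation missing"):
        load_annotations(p)


def test_multiple_bone_beds_are_an_error(tmp_path):
    p = tmp_path / "a.geojson"
    _write(_simple_doc(beds=2), p)
    with pytest.raises(ValueError, match="exactly one bone_bed"):
        load_annotations(p)


def test_duplicate_ids_are_listed(tmp_path):
    p = tmp_path / "a.geojson"
    _write(_simple_doc(ids=["x", "x", "y"]), p)
    with pytest.raises(ValueError, match="duplicate ROI ids: x"):
        load_annotations(p)


def test_non_simple_polygon_names_the_id(tmp_path):
    doc = _simple_doc(n_rois=1, ids=["bowtie"])
    doc["features"][0]["geometry"]["coordinates"] = [[
        [0.0, 0.0], [10.0, 10.0], [10.0, 0.0], [0.0, 10.0], [0.0, 0.0]]]
    p = tmp_path / "a.geojson"
    _write(doc, p)
    with pytest.raises(ValueError, match="bowtie"):
        load_annotations(p)


def test_qupath_nested_classification_accepted(tmp_path):
    doc = _simple_doc(n_rois=1)
    doc["features"][0]["properties"] = {"classification": {"name": "capillary"},
                                        "id": "q1"}
    p = tmp_path / "a.geojson"
    _write(doc, p)
    assert load_annotations(p).capillary_rois[0][0] == "q1"


def test_annotation_round_trip_is_vertex_exact(tiny_scene, tmp_path):
    aset = scene_annotations(tiny_scene)
    aset.landmarks = [("lm0", np.array([3.25, 7.5])), ("lm1", np.array([90.0, 12.0]))]
    p = tmp_path / "rt.geojson"
    save_annotations(aset, p)
    back = load_annotations(p)
    assert back.pixel_size_um == aset.pixel_size_um
    assert len(back.capillary_rois) == len(aset.capillary_rois)
    for (ida, pa), (idb, pb) in zip(aset.capillary_rois, back.capillary_rois):
        assert ida == idb
        assert np.array_equal(pa, pb)
    assert np.array_equal(back.bone_bed, aset.bone_bed)
    assert [l for l, _ in back.landmarks] == ["lm0", "lm1"]


def test_empty_feature_table_writes_header_only(tmp_path):
    p = tmp_path / "f.csv"
    save_features([], p)
    assert p.read_text().strip() == "id,rel_area_cd31,rel_area_emcn,min_dist_um,category"


def test_feature_round_trip_preserves_values(tmp_path):
    rows = [CapillaryFeatures(id="a", rel_area_cd31=0.25, rel_area_emcn=0.10,
                              roi_area_um2=100.0, min_dist_um=123.456, category="HH")]
    p = tmp_path / "f.csv"
    save_features(rows, p)
    back = load_features(p)
    assert back.loc[0, "rel_area_cd31"] == 0.25
    assert back.loc[0, "rel_area_emcn"] == 0.10
    assert back.loc[0, "category"] == "HH"


def test_corpus_scale_table_round_trips(tmp_path):
    """A full-corpus-sized table (7255 capillaries) survives the round trip."""
    rng = np.random.default_rng(0)
    n = 7255
    df = pd.DataFrame({
        "id": [f"c{i}" for i in range(n)],
        "rel_area_cd31": rng.uniform(0, 1, n),
        "rel_area_emcn": rng.uniform(0, 1, n),
        "min_dist_um": rng.uniform(0, 8000, n),
        "category": rng.choice(["HH", "HL", "LH", "LL"], n),
    })
    p = tmp_path / "big.csv"
    save_features(df, p)
    back = load_features(p)
    assert len(back) == n
    assert np.array_equal(back["rel_area_cd31"].to_numpy(),
                          df["rel_area_cd31"].to_numpy())
    assert np.array_equal(back["min_dist_um"].to_numpy(), df["min_dist_um"].to_numpy())


def test_missing_column_is_named(tmp_path):
    p = tmp_path / "f.csv"
    p.write_text("id,rel_area_cd31\nx,0.1\n")
    with pytest.raises(ValueError, match="min_dist_um|rel_area_emcn"):
        load_features(p)
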