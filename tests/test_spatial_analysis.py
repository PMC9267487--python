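"""Distances, distance profiles, KS tests, registration, OSX enrichment."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from vesselzoner.annotation_io import AnnotationSet
from vesselzoner.spatial_analysis import (distance_profile, ks_two_sample,
                                          min_distance_to_bonebed,
                                          osx_proximity_enrichment,
                                          register_sections)
from vesselzoner.spot_quantification import CapillaryFeatures


# ---------------------------------------------------------------- distances

def brute_force_min_distance(polygon, polyline, step=0.01):
    """Dense boundary sampling oracle: exact point-to-segment per sample."""
    poly = np.vstack([polygon, polygon[:1]])
    samples = []
    for a, b in zip(poly[:-1], poly[1:]):
        n = max(int(np.ceil(np.linalg.norm(b - a) / step)), 1)
        t = np.linspace(0, 1, n + 1)[:, None]
        samples.append(a + t * (b - a))
    pts = np.vstack(samples)
    best = np.inf
    for a, b in zip(polyline[:-1], polyline[1:]):
        ab = b - a
        denom = ab @ ab
        t = np.clip((pts - a) @ ab / denom, 0, 1) if denom > 0 else np.zeros(len(pts))
        proj = a + t[:, None] * ab
        best = min(best, float(np.sqrt(((pts - proj) ** 2).sum(1)).min()))
    return best


def test_touching_roi_has_zero_distance():
    poly = np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]])
    bed = np.array([[-5.0, 10.0], [20.0, 10.0]])
    assert min_distance_to_bonebed(poly, bed, 2.0) == 0.0


def test_square_above_flat_bed_analytic():
    # unit square whose bottom edge sits 10 px above a horizontal bed, 2 um/px
    poly = np.array([[3.0, 39.0], [4.0, 39.0], [4.0, 40.0], [3.0, 40.0]])
    bed = np.array([[0.0, 50.0], [100.0, 50.0]])
    assert min_distance_to_bonebed(poly, bed, 2.0) == pytest.approx(20.0)


def test_empty_geometry_raises():
    with pytest.raises(ValueError, match="empty geometry"):
        min_distance_to_bonebed(np.zeros((2, 2)), np.zeros((2, 2)), 1.0)


def test_distance_matches_dense_sampling_oracle():
    rng = np.random.default_rng(8)
    for _ in range(20):
        c = rng.uniform(20, 80, 2)
        r = rng.uniform(2, 8)
        phi = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        poly = c + np.column_stack([r * np.cos(phi), 0.6 * r * np.sin(phi)])
        xs = np.linspace(0, 100, 6)
        bed = np.column_stack([xs, rng.uniform(85, 95, 6)])
        ours = min_distance_to_bonebed(poly, bed, 1.0)
        oracle = brute_force_min_distance(poly, bed)
        assert abs(ours - oracle) <= 0.02


def test_distance_invariant_under_rigid_motion():
    poly = np.array([[3.0, 30.0], [8.0, 31.0], [6.0, 36.0]])
    bed = np.array([[0.0, 50.0], [50.0, 52.0]])
    d0 = min_distance_to_bonebed(poly, bed, 1.0)
    th = 0.7
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    shift = np.array([12.0, -4.0])
    assert min_distance_to_bonebed(poly @ R.T + shift, bed @ R.T + shift,
                                   1.0) == pytest.approx(d0)


# ----------------------------------------------------------------- profiles

def _feats(cats_dists):
    return [CapillaryFeatures(id=f"c{i}", rel_area_cd31=0, rel_area_emcn=0,
                              roi_area_um2=1.0, min_dist_um=d, category=c)
            for i, (c, d) in enumerate(cats_dists)]


def test_degenerate_profile_flagged():
    profiles = distance_profile(_feats([("LL", 500.0)] * 5), categories=("LL",))
    p = profiles[0]
    assert p.degenerate and p.mean_um == 500.0 and p.sem_um == 0.0


def test_small_category_omitted_with_warning(caplog):
    feats = _feats([("LL", 100.0), ("LL", 200.0), ("LL", 150.0), ("HH", 900.0)])
    with caplog.at_level("WARNING"):
        profiles = distance_profile(feats)
    assert [p.category for p in profiles] == ["LL"]
    assert "HH" in caplog.text


def test_profile_density_normalized_and_mean_in_range():
    rng = np.random.default_rng(9)
    d = np.abs(rng.normal(2000, 500, 300))
    profiles = distance_profile(_feats([("HH", v) for v in d]), categories=("HH",))
    p = profiles[0]
    integral = np.trapezoid(p.kde_density_per_um, p.kde_support_um)
    assert abs(integral - 1.0) < 0.01
    assert d.min() <= p.mean_um <= d.max()
    assert (p.kde_density_per_um >= 0).all()


# ----------------------------------------------------------------------- KS

def ks_oracle_d(x, y):
    """Exhaustive ECDF sup-difference via integer counts (exact)."""
    best = 0
    for v in list(x) + list(y):
        fx = sum(1 for u in x if u <= v) * len(y)
        fy = sum(1 for u in y if u <= v) * len(x)
        best = max(best, abs(fx - fy))
    return best / (len(x) * len(y))


def test_ks_trivial_cases():
    d, p = ks_two_sample([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
    assert d == 0.0 and p == 1.0
    d, _ = ks_two_sample([1, 2, 3], [4, 5, 6])
    assert d == 1.0
    d, _ = ks_two_sample([1, 3], [2, 4])
    assert d == 0.5


def test_ks_statistic_matches_enumeration_and_scipy():
    rng = np.random.default_rng(10)
    for _ in range(50):
        x = rng.normal(0, 1, rng.integers(1, 51))
        y = rng.normal(0.4, 1.3, rng.integers(1, 51))
        d, _ = ks_two_sample(x, y)
        assert d == pytest.approx(ks_oracle_d(x, y), abs=1e-12)
        assert d == pytest.approx(ks_2samp(x, y).statistic, abs=1e-12)


def test_ks_invariances():
    rng = np.random.default_rng(11)
    x = rng.normal(0, 1, 40)
    y = rng.normal(0.5, 1, 60)
    d, p = ks_two_sample(x, y)
    d_swap, p_swap = ks_two_sample(y, x)
    assert (d, p) == (d_swap, p_swap)
    # strictly monotone transform of both samples leaves D unchanged
    d_t, _ = ks_two_sample(np.exp(x), np.exp(y))
    assert d_t == pytest.approx(d, abs=1e-12)


def test_ks_empty_sample_raises():
    with pytest.raises(ValueError, match="empty sample"):
        ks_two_sample([], [1.0])


# -------------------------------------------------------------- registration

def umeyama_oracle(src, dst):
    """Closed-form similarity fit, independent of the implementation path."""
    mu_s, mu_d = src.mean(0), dst.mean(0)
    sc, dc = src - mu_s, dst - mu_d
    cov = dc.T @ sc / len(src)
    U, S, Vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, d])
    R = U @ D @ Vt
    scale = np.trace(np.diag(S) @ D) / sc.var(0).sum()
    t = mu_d - scale * R @ mu_s
    return R, scale, t


def test_identity_and_translation():
    src = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    tf = register_sections(src, src)
    assert tf.rmse == pytest.approx(0.0, abs=1e-12)
    assert tf.scale == pytest.approx(1.0)
    tf = register_sections(src, src + np.array([5.0, 0.0]))
    assert tf.translation == pytest.approx([5.0, 0.0])
    assert tf.rotation_rad == pytest.approx(0.0, abs=1e-12)


def test_planted_similarity_recovered_and_matches_oracle():
    rng = np.random.default_rng(12)
    src = rng.uniform(0, 100, (6, 2))
    th, s, t = 0.3, 1.2, np.array([5.0, 7.0])
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    dst = src @ (s * R).T + t
    tf = register_sections(src, dst)
    assert tf.rotation_rad == pytest.approx(th, abs=1e-9)
    assert tf.scale == pytest.approx(s, abs=1e-9)
    assert tf.rmse < 1e-9
    R_o, s_o, t_o = umeyama_oracle(src, dst)
    assert s_o == pytest.approx(tf.scale, abs=1e-9)
    assert np.allclose(tf.apply(src), src @ (s_o * R_o).T + t_o, atol=1e-9)


def test_degenerate_landmarks_raise():
    src = np.tile([[1.0, 1.0]], (4, 1))
    with pytest.raises(ValueError, match="degenerate landmarks"):
        register_sections(src, src + 1.0)


# ----------------------------------------------------------- OSX enrichment

def _square_annotations(centers, half=3.0, pixel_size=1.0):
    rois = []
    for i, (cx, cy) in enumerate(centers):
        rois.append((f"c{i}", np.array([[cx - half, cy - half], [cx + half, cy - half],
                                        [cx + half, cy + half], [cx - half, cy + half]])))
    return AnnotationSet(capillary_rois=rois,
                         bone_bed=np.array([[0.0, 199.0], [199.0, 199.0]]),
                         pixel_size_um=pixel_size)


def test_enrichment_requires_both_categories_and_points():
    aset = _square_annotations([(50, 50), (150, 150)])
    feats = _feats([("HH", 0.0), ("HH", 0.0)])
    with pytest.raises(ValueError, match="HH and .*LL|LL"):
        osx_proximity_enrichment(feats, aset, np.zeros((0, 2)))
    feats = _feats([("HH", 0.0), ("LL", 0.0)])
    with pytest.raises(ValueError, match="no OSX points"):
        osx_proximity_enrichment(feats, aset, np.zeros((0, 2)))


def test_uniform_points_give_unit_ratio():
    rng = np.random.default_rng(13)
    aset = _square_annotations([(50, 50), (150, 150)])
    feats = _feats([("HH", 0.0), ("LL", 0.0)])
    ratios = [osx_proximity_enrichment(
        feats, aset, rng.uniform(0, 199, (4000, 2)), radius_um=30)
        for _ in range(10)]
    assert abs(np.mean(ratios) - 1.0) < 0.1
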