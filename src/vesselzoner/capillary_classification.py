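"""Quadrant gating of capillaries on the CD31–EMCN relative-area plane.

Capillaries are assigned to four categories (HH, HL, LH, LL — CD31
high/low × EMCN high/low) by a *threshold cross*: one threshold per
marker, with ``>= threshold`` counting as High.  In the emulated workflow
the cross is placed by an operator "at the limit of the denser core" of a
density-colored scatter plot, such that most of the capillary density
stays in the Low/Low quadrant.  This module makes that rule algorithmic:

1.  estimate the 2-D kernel density of the feature cloud (Gaussian
    product kernel, per-axis bandwidth = Scott's factor ``N**(-1/6)``
    times a robust scale ``min(sd, IQR/1.349)``, on a 256×256 grid);
2.  grow the density superlevel set connected to the global mode,
    lowering the level until the component holds ``core_mass`` of the
    sample points — or until it would merge with a second density
    cluster holding a non-negligible share of the sample (the "limit of
    the denser core");
3.  place the thresholds at the component's maximal extent along each
    axis.

If the mode component cannot reach a usable mass (fragmented density),
per-axis quantiles at ``core_mass`` are used and the result is flagged.
A manual mode records operator-chosen thresholds verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label

from .spot_quantification import CapillaryFeatures

__all__ = [
    "Density2D",
    "ThresholdCross",
    "estimate_density_2d",
    "place_thresholds",
    "manual_cross",
    "classify_capillaries",
    "classify_xy",
]

_MIN_POINTS = 10


@dataclass
class Density2D:
    """KDE on a regular grid; ``density[i, j]`` is f(x[i], y[j])."""

    x: np.ndarray
    y: np.ndarray
    density: np.ndarray
    bandwidth: tuple[float, float]

    def integral(self) -> float:
        dx = self.x[1] - self.x[0] if len(self.x) > 1 else 1.0
        dy = self.y[1] - self.y[0] if len(self.y) > 1 else 1.0
        return float(self.density.sum() * dx * dy)


@dataclass(frozen=True)
class ThresholdCross:
    """The gating cross on the (CD31, EMCN) relative-area plane."""

    t_cd31: float
    t_emcn: float
    method: str  # "auto" | "manual"
    core_mass: float | None = None
    bandwidth: tuple[float, float] | None = None
    fallback: bool = False
    core_mass_achieved: float | None = None


def _feature_xy(features) -> np.ndarray:
    """Coerce list/DataFrame/array feature input to an (N, 2) float array."""
    if isinstance(features, pd.DataFrame):
        return features[["rel_area_cd31", "rel_area_emcn"]].to_numpy(float)
    if len(features) and isinstance(features[0], CapillaryFeatures):
        return np.array([[f.rel_area_cd31, f.rel_area_emcn] for f in features], float)
    return np.asarray(features, float).reshape(-1, 2)


def _robust_scale(v: np.ndarray) -> float:
    sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    q75, q25 = np.percentile(v, [75, 25])
    iqr = (q75 - q25) / 1.349
    scales = [s for s in (sd, iqr) if s > 0]
    return min(scales) if scales else 0.0


def _bandwidths(xy: np.ndarray) -> tuple[float, float]:
    n = len(xy)
    factor = n ** (-1.0 / 6.0)  # Scott's factor for d = 2
    out = []
    for j in (0, 1):
        scale = _robust_scale(xy[:, j])
        # floor guards against exactly- or numerically-degenerate axes
        tiny = 1e-9 * max(abs(float(xy[:, j].mean())), 1.0)
        out.append(max(scale, tiny) * factor)
    return out[0], out[1]


def estimate_density_2d(features, grid_size: int = 256,
                        bandwidth: tuple[float, float] | None = None) -> Density2D:
    """Gaussian-product KDE of the feature cloud on a regular grid.

    The grid covers the data range padded by 3 bandwidths per axis, so the
    quadrature integral of the returned density is 1 to within ~1%.
    Requires at least 10 points.
    """
    xy = _feature_xy(features)
    if len(xy) < _MIN_POINTS:
        raise ValueError("insufficient capillaries for density estimation (need >= 10)")
    hx, hy = bandwidth if bandwidth is not None else _bandwidths(xy)
    gx = np.linspace(xy[:, 0].min() - 3 * hx, xy[:, 0].max() + 3 * hx, grid_size)
    gy = np.linspace(xy[:, 1].min() - 3 * hy, xy[:, 1].max() + 3 * hy, grid_size)
    # separable kernel: density = Gx @ Gy.T / N with Gx (nx, N), Gy (ny, N)
    inv_sqrt2pi = 1.0 / np.sqrt(2 * np.pi)
    Gx = inv_sqrt2pi / hx * np.exp(-0.5 * ((gx[:, None] - xy[None, :, 0]) / hx) ** 2)
    Gy = inv_sqrt2pi / hy * np.exp(-0.5 * ((gy[:, None] - xy[None, :, 1]) / hy) ** 2)
    density = Gx @ Gy.T / len(xy)
    return Density2D(x=gx, y=gy, density=density, bandwidth=(hx, hy))


def _bin_points(xy: np.ndarray, grid: Density2D) -> np.ndarray:
    """Sample-point counts per grid cell (same shape as the density)."""
    def _idx(vals, centers):
        dx = centers[1] - centers[0] if len(centers) > 1 else 1.0
        edges = np.concatenate([[centers[0] - dx / 2], centers + dx / 2])
        return np.clip(np.searchsorted(edges, vals, side="right") - 1,
                       0, len(centers) - 1)

    ix = _idx(xy[:, 0], grid.x)
    iy = _idx(xy[:, 1], grid.y)
    counts = np.zeros(grid.density.shape, np.int64)
    np.add.at(counts, (ix, iy), 1)
    return counts


def _core_component(grid: Density2D, counts: np.ndarray, core_mass: float,
                    min_cluster_frac: float, n_levels: int = 160):
    """Superlevel-set component of the global mode.

    Lowers the level through density quantiles until the component holds
    ``core_mass`` of the sample, stopping early if it would absorb another
    cluster holding at least ``min_cluster_frac`` of the sample.  Returns
    ``(component_mask, mass_fraction, merged_early)``.
    """
    dens = grid.density
    total = counts.sum()
    mode = np.unravel_index(int(np.argmax(dens)), dens.shape)
    positive = dens[dens > 0]
    levels = np.quantile(positive, np.linspace(1.0, 0.0, n_levels))
    levels = np.unique(levels)[::-1]  # descending

    prev_labels = None
    prev_mode_lab = None
    prev_mass = 0.0
    prev_mask = None
    for lam in levels:
        labels = cc_label(dens >= lam, connectivity=2)
        mode_lab = labels[mode]
        if mode_lab == 0:
            continue
        comp = labels == mode_lab
        if prev_labels is not None:
            # did the mode component swallow a previously separate cluster?
            prev_in_comp = np.unique(prev_labels[comp])
            for q in prev_in_comp:
                if q == 0 or q == prev_mode_lab:
                    continue
                other_mass = counts[prev_labels == q].sum() / total
                if other_mass >= min_cluster_frac:
                    return prev_mask, prev_mass, True
        mass = counts[comp].sum() / total
        if mass >= core_mass:
            return comp, float(mass), False
        prev_labels, prev_mode_lab = labels, mode_lab
        prev_mask, prev_mass = comp, float(mass)
    return prev_mask, float(prev_mass), False


def place_thresholds(features, core_mass: float = 0.75, grid_size: int = 256,
                     min_cluster_frac: float = 0.02) -> ThresholdCross:
    """Automatic cross placement at the limit of the denser core.

    The thresholds are the maxima of the mode-connected density core's
    extent along each axis (plus half a grid cell, clipped to the data
    range), which leaves the fitted sample's plurality — in practice a
    majority — in the Low/Low quadrant.  Falls back to per-axis quantiles
    at ``core_mass`` (``fallback=True``) when the density core fragments.
    """
    if not 0.0 < core_mass < 1.0:
        raise ValueError("core_mass must lie in (0, 1)")
    xy = _feature_xy(features)
    if len(xy) < _MIN_POINTS:
        raise ValueError("insufficient capillaries for density estimation (need >= 10)")
    grid = estimate_density_2d(xy, grid_size=grid_size)
    counts = _bin_points(xy, grid)
    comp, mass, merged = _core_component(grid, counts, core_mass, min_cluster_frac)

    def _quantile_cross() -> ThresholdCross:
        tq = np.quantile(xy, core_mass, axis=0)
        return ThresholdCross(
            t_cd31=float(tq[0]), t_emcn=float(tq[1]), method="auto",
            core_mass=core_mass, bandwidth=grid.bandwidth,
            fallback=True, core_mass_achieved=float(mass))

    if comp is None or (merged and mass < 0.35):
        return _quantile_cross()
    dx = grid.x[1] - grid.x[0]
    dy = grid.y[1] - grid.y[0]
    ix, iy = np.nonzero(comp)
    t_cd31 = min(float(grid.x[ix.max()] + dx / 2), float(xy[:, 0].max()))
    t_emcn = min(float(grid.y[iy.max()] + dy / 2), float(xy[:, 1].max()))
    cross = ThresholdCross(
        t_cd31=t_cd31, t_emcn=t_emcn, method="auto", core_mass=core_mass,
        bandwidth=grid.bandwidth, fallback=False, core_mass_achieved=float(mass))
    # the fitted sample must keep LL as (at least) the plurality category
    cats = classify_xy(xy, cross)
    counts_by = {c: int((cats == c).sum()) for c in ("HH", "HL", "LH", "LL")}
    if counts_by["LL"] < max(counts_by.values()) or counts_by["LL"] < len(xy) / 2:
        return _quantile_cross()
    return cross


def manual_cross(t_cd31: float, t_emcn: float) -> ThresholdCross:
    """Operator-chosen thresholds, echoed verbatim."""
    return ThresholdCross(t_cd31=float(t_cd31), t_emcn=float(t_emcn), method="manual")


def classify_xy(xy: np.ndarray, cross: ThresholdCross) -> np.ndarray:
    """Category labels for an (N, 2) array of (CD31, EMCN) relative areas."""
    xy = np.asarray(xy, float).reshape(-1, 2)
    if not (np.isfinite(cross.t_cd31) and np.isfinite(cross.t_emcn)):
        raise ValueError("cross thresholds must be finite")
    hi_cd = xy[:, 0] >= cross.t_cd31
    hi_em = xy[:, 1] >= cross.t_emcn
    out = np.full(len(xy), "LL", dtype=object)
    out[hi_cd & hi_em] = "HH"
    out[hi_cd & ~hi_em] = "HL"
    out[~hi_cd & hi_em] = "LH"
    return out.astype(str)


def classify_capillaries(features, cross: ThresholdCross):
    """Fill the ``category`` field; ties (== threshold) count as High.

    Accepts and returns a list of :class:`CapillaryFeatures` (new list,
    inputs untouched) or a DataFrame (copy with ``category`` column set).
    """
    if isinstance(features, pd.DataFrame):
        out = features.copy()
        out["category"] = classify_xy(_feature_xy(features), cross)
        return out
    cats = classify_xy(_feature_xy(features), cross)
    return [replace(f, category=str(c)) for f, c in zip(features, cats)]
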