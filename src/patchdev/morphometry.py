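"""Point-pattern and laminar quantification.

Cell densities (count / area in cells/mm^2), dorsoventral partition of a
region into equal-extent dorsal / intermediate / ventral thirds, age-group
density trajectories, the dorsoventral extent fraction of a marker along a
band, cortical layer widths from boundary polylines, and the two-tailed
Mann-Whitney U test used for all group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon

from .image import GeometryError, Image2D, ROI

__all__ = [
    "PointPattern",
    "DensityEstimate",
    "PartitionProportions",
    "ExtentFraction",
    "LayerProfile",
    "GroupComparison",
    "cell_density",
    "dv_partition",
    "density_trajectory",
    "marker_extent_fraction",
    "layer_widths",
    "mann_whitney_two_tailed",
    "read_point_table",
    "write_point_table",
]

THIRD_LABELS = ("dorsal", "intermediate", "ventral")


@dataclass
class PointPattern:
    """Annotated cell positions (um) inside a region polygon (um)."""

    points: np.ndarray  # (n, 2) of (x_um, y_um)
    marker: str
    region: Polygon
    region_area_mm2: float
    dv_axis: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.region_area_mm2 <= 0:
            raise GeometryError("region area must be positive")
        computed = self.region.area / 1e6
        if abs(computed - self.region_area_mm2) > 1e-3 * self.region_area_mm2:
            raise GeometryError(
                f"declared area {self.region_area_mm2} mm^2 differs from polygon "
                f"area {computed} mm^2 by more than 0.1%"
            )

    @property
    def count(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class DensityEstimate:
    count: int
    area_mm2: float
    density: float  # always count / area_mm2

    @classmethod
    def from_count(cls, count: int, area_mm2: float) -> "DensityEstimate":
        if area_mm2 <= 0:
            raise GeometryError("zero-area region")
        return cls(count=count, area_mm2=area_mm2, density=count / area_mm2)


@dataclass
class PartitionProportions:
    """Per-third density estimates and density-normalized proportions."""

    thirds: dict[str, DensityEstimate]
    proportions: dict[str, float]


@dataclass(frozen=True)
class ExtentFraction:
    """Fraction of a band's dorsoventral length covered by a marker."""

    fraction: float
    band_length_um: float
    threshold: float
    n_slabs: int
    islands_ventral: int = 0  # suprathreshold slabs beyond the dorsal run


@dataclass
class LayerProfile:
    """Ordered laminar boundary polylines (um), pia first, white matter last."""

    boundaries: Sequence[np.ndarray]  # each (k, 2) polyline
    boundary_names: Sequence[str]
    sample_positions: Mapping[str, tuple[float, float]]  # anchor points on the pia
    widths: Optional[pd.DataFrame] = None


@dataclass(frozen=True)
class GroupComparison:
    u_statistic: float
    p_value: float
    n_a: int
    n_b: int
    method: str  # "exact" or "normal_approx"


def cell_density(pp: PointPattern) -> DensityEstimate:
    """Cells per mm^2: exact arithmetic on the count and polygon area."""
    return DensityEstimate.from_count(pp.count, pp.region_area_mm2)


def _dv_strip(region: Polygon, ax: np.ndarray, t_lo: float, t_hi: float) -> Polygon:
    """Intersection of the region with the slab t_lo <= (p . ax) <= t_hi."""
    # build a rectangle in the rotated frame where ax is +x, then intersect
    perp = np.array([-ax[1], ax[0]])
    verts = np.asarray(region.exterior.coords)
    s = verts @ perp
    s_lo, s_hi = s.min() - 1.0, s.max() + 1.0
    corners = [
        t_lo * ax + s_lo * perp, t_hi * ax + s_lo * perp,
        t_hi * ax + s_hi * perp, t_lo * ax + s_hi * perp,
    ]
    return region.intersection(Polygon([tuple(c) for c in corners]))


def dv_partition(pp: PointPattern, dv_axis: Optional[tuple[float, float]] = None,
                 ) -> PartitionProportions:
    """Split a pattern into dorsal / intermediate / ventral equal-extent thirds.

    Thirds are equal in extent along the dorsoventral axis, not equal in
    area: per-third densities use the geometric area of region-and-slab, and
    proportions normalize those densities so they sum to one.
    """
    ax = np.asarray(dv_axis if dv_axis is not None else pp.dv_axis, dtype=float)
    norm = np.hypot(*ax)
    if norm == 0:
        raise GeometryError("degenerate dorsoventral axis")
    ax = ax / norm
    verts = np.asarray(pp.region.exterior.coords)
    t = verts @ ax
    t0, t1 = float(t.min()), float(t.max())
    if t1 - t0 <= 0:
        raise GeometryError("region has no extent along the dorsoventral axis")
    edges = np.linspace(t0, t1, 4)
    proj = pp.points @ ax if pp.count else np.empty(0)
    thirds: dict[str, DensityEstimate] = {}
    for k, name in enumerate(THIRD_LABELS):
        lo, hi = edges[k], edges[k + 1]
        # top edge of last bin inclusive so every point lands in exactly one bin
        if k < 2:
            inbin = (proj >= lo) & (proj < hi)
        else:
            inbin = (proj >= lo) & (proj <= hi)
        strip = _dv_strip(pp.region, ax, lo, hi)
        thirds[name] = DensityEstimate.from_count(int(inbin.sum()), strip.area / 1e6)
    total = sum(d.density for d in thirds.values())
    if total > 0:
        proportions = {k: d.density / total for k, d in thirds.items()}
    else:
        proportions = {k: float("nan") for k in thirds}
    return PartitionProportions(thirds=thirds, proportions=proportions)


def density_trajectory(groups: Mapping[str, Sequence[DensityEstimate]]) -> pd.DataFrame:
    """Per-age-group mean +/- SD density table, group order preserved."""
    rows = []
    for name, ests in groups.items():
        if len(ests) == 0:
            raise ValueError(f"age group {name!r} has no density estimates")
        d = np.array([e.density for e in ests])
        rows.append({
            "age_group": name, "n": len(ests),
            "mean_density": float(d.mean()),
            "sd_density": float(d.std(ddof=1)) if len(d) > 1 else 0.0,
            "total_count": int(sum(e.count for e in ests)),
        })
    return pd.DataFrame(rows)


def marker_extent_fraction(band_img: Image2D, band_roi: ROI,
                           threshold: Optional[float] = None,
                           n_slabs: int = 100) -> ExtentFraction:
    """Dorsoventral fraction of a band over which a marker is expressed.

    The band is partitioned into ``n_slabs`` (>= 50) equal slabs along the
    ROI's dorsoventral axis; a slab counts as expressing when its mean
    intensity exceeds the threshold (Otsu's split of the band histogram when
    not given). The fraction is the contiguous suprathreshold run from the
    dorsal end over the total slab count, matching a marker front that
    extends progressively ventrally; isolated ventral islands are reported
    separately, never added to the fraction.
    """
    if n_slabs < 50:
        raise ValueError("n_slabs must be >= 50")
    h, w = band_img.shape
    ax = np.asarray(band_roi.dv_axis, dtype=float)
    yy, xx = np.meshgrid(np.arange(h) + 0.5, np.arange(w) + 0.5, indexing="ij")
    proj = (xx * ax[0] + yy * ax[1]) * band_img.pixel_size_um
    m = band_img.valid_mask()
    proj_v = proj[m]
    vals = band_img.pixels[m]
    length = float(proj_v.max() - proj_v.min())
    if length / band_img.pixel_size_um < 50:
        raise GeometryError("band shorter than 50 px along the dorsoventral axis")
    if threshold is None:
        from skimage.filters import threshold_otsu

        threshold = float(threshold_otsu(vals))
    edges = np.linspace(proj_v.min(), proj_v.max(), n_slabs + 1)
    idx = np.clip(np.digitize(proj_v, edges) - 1, 0, n_slabs - 1)
    sums = np.bincount(idx, weights=vals, minlength=n_slabs)
    counts = np.bincount(idx, minlength=n_slabs)
    means = np.divide(sums, counts, out=np.full(n_slabs, np.nan), where=counts > 0)
    above = means > threshold
    run = 0
    for flag in above:
        if flag:
            run += 1
        else:
            break
    islands = int(above[run:].sum())
    return ExtentFraction(fraction=run / n_slabs, band_length_um=length,
                          threshold=float(threshold), n_slabs=n_slabs,
                          islands_ventral=islands)


# --- layer widths -----------------------------------------------------------

def _normal_at(polyline: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """Unit normal of a polyline at the vertex span nearest an anchor point."""
    line = LineString(polyline)
    s = line.project(Point(anchor))
    eps = max(line.length * 1e-4, 1e-9)
    p0 = np.asarray(line.interpolate(max(s - eps, 0.0)).coords[0])
    p1 = np.asarray(line.interpolate(min(s + eps, line.length)).coords[0])
    tang = p1 - p0
    tang = tang / np.hypot(*tang)
    return np.array([-tang[1], tang[0]])


def layer_widths(profile: LayerProfile) -> pd.DataFrame:
    """Layer widths at each sample position, measured along the pia's normal.

    At each anchor the local normal to the pia (first boundary) is cast and
    intersected with every boundary polyline; widths are the distances
    between consecutive intersections, and proportional widths divide by the
    pia-to-white-matter distance. Crossing boundaries raise a geometry error.
    """
    blines = [np.asarray(b, dtype=float) for b in profile.boundaries]
    if len(blines) < 2:
        raise GeometryError("need at least pia and white-matter boundaries")
    names = list(profile.boundary_names)
    span = max(LineString(b).length for b in blines) * 4
    rows = []
    for pos, anchor in profile.sample_positions.items():
        anchor = np.asarray(anchor, dtype=float)
        nrm = _normal_at(blines[0], anchor)
        ray = LineString([tuple(anchor - span * nrm), tuple(anchor + span * nrm)])
        ts = []
        for b in blines:
            inter = ray.intersection(LineString(b))
            if inter.is_empty:
                raise GeometryError(
                    f"normal at {pos!r} does not intersect boundary; "
                    "check boundary ordering and sample position")
            pts = ([inter] if inter.geom_type == "Point"
                   else list(getattr(inter, "geoms", [])))
            cand = [(np.asarray(p.coords[0]) - anchor) @ nrm for p in pts
                    if p.geom_type == "Point"]
            if not cand:
                raise GeometryError(f"non-point intersection at {pos!r}")
            ts.append(min(cand, key=abs))
        ts = np.asarray(ts)
        order = np.sign(ts[-1] - ts[0])
        if order == 0 or np.any(np.diff(ts) * order < 0):
            raise GeometryError(f"boundaries cross along the normal at {pos!r}")
        widths = np.abs(np.diff(ts))
        total = abs(ts[-1] - ts[0])
        for k, wv in enumerate(widths):
            rows.append({
                "position": pos,
                "layer": f"{names[k]}-{names[k + 1]}",
                "width_um": float(wv),
                "proportion": float(wv / total) if total > 0 else float("nan"),
            })
    df = pd.DataFrame(rows)
    profile.widths = df
    return df


# --- Mann-Whitney -----------------------------------------------------------

@lru_cache(maxsize=None)
def _u_counts(n_a: int, n_b: int) -> np.ndarray:
    """Number of rank arrangements giving each U value for group a.

    Standard recursion c(n_a, n_b, u) = c(n_a-1, n_b, u-n_b) +
    c(n_a, n_b-1, u), built bottom-up over a (n_a+1, n_b+1) grid of
    polynomial coefficient arrays.
    """
    max_u = n_a * n_b
    table = np.zeros((n_a + 1, n_b + 1, max_u + 1), dtype=np.float64)
    table[0, :, 0] = 1.0
    table[:, 0, 0] = 1.0
    for i in range(1, n_a + 1):
        for j in range(1, n_b + 1):
            shifted = np.zeros(max_u + 1)
            shifted[j:] = table[i - 1, j, : max_u + 1 - j]
            table[i, j] = shifted + table[i, j - 1]
    return table[n_a, n_b]


def mann_whitney_two_tailed(a: Sequence[float], b: Sequence[float],
                            exact_limit: int = 400) -> GroupComparison:
    """Two-tailed Mann-Whitney U test with midrank tie handling.

    The p value is exact (full enumeration of the U null distribution) when
    ``n_a * n_b <= exact_limit`` and there are no ties across the pooled
    sample; otherwise the normal approximation with tie correction and a
    0.5 continuity correction is used. The reported U is the statistic for
    sample ``a``; the two-tailed p is invariant to swapping the samples.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = pd.Series(pooled).rank(method="average").to_numpy()
    r_a = ranks[:n_a].sum()
    u_a = r_a - n_a * (n_a + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)
    if not has_ties and n_a * n_b <= exact_limit:
        counts = _u_counts(n_a, n_b)
        total = counts.sum()
        u_int = int(round(u_a))
        p_low = counts[: u_int + 1].sum() / total
        p_high = counts[u_int:].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        method = "exact"
    else:
        mu = n_a * n_b / 2.0
        n = n_a + n_b
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            z = max(0.0, abs(u_a - mu) - 0.5) / np.sqrt(sigma2)
            from scipy.stats import norm

            p = float(min(1.0, 2.0 * norm.sf(z)))
        method = "normal_approx"
    return GroupComparison(u_statistic=float(u_a), p_value=float(p),
                           n_a=n_a, n_b=n_b, method=method)


# --- point-table I/O --------------------------------------------------------

def write_point_table(pp: PointPattern, path: str | Path) -> None:
    """Tab-delimited cell table with header ``x_um  y_um  marker  region``."""
    df = pd.DataFrame({
        "x_um": pp.points[:, 0], "y_um": pp.points[:, 1],
        "marker": pp.marker, "region": "region",
    })
    df.to_csv(path, sep="\t", index=False)


def read_point_table(path: str | Path, region: Polygon,
                     dv_axis: tuple[float, float] = (0.0, 1.0)) -> PointPattern:
    """Read a tab-delimited cell table into a PointPattern over ``region``."""
    df = pd.read_csv(path, sep="\t")
    marker = str(df["marker"].iloc[0]) if len(df) else "unknown"
    return PointPattern(points=df[["x_um", "y_um"]].to_numpy(), marker=marker,
                        region=region, region_area_mm2=region.area / 1e6,
                        dv_axis=dv_axis)
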