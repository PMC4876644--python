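"""Seeded synthetic histology: patch lattices, scatter, colocalized channels,
dorsoventral expression fronts and cell point patterns.

Every generator is a pure function of its config (seed included), so each
downstream statistic can be tested against known ground truth without any
micrograph. The generators emulate the statistical structure the analyses
assume, not cell morphology:

* hexagonal (triangular-lattice) layouts of Gaussian-profile patches, the
  geometry of calbindin-positive patch grids in tangential sections;
* homogeneous Poisson scatter, the null geometry of reelin-positive cells;
* a second channel sharing a standardized component with the first at a
  chosen Pearson coefficient, the doublecortin-overlap regimes;
* a band whose marker expression covers a chosen dorsal fraction with a
  sigmoidal front, the wolframin expression gradient;
* inhomogeneous Poisson point patterns in a polygon with a linear
  dorsoventral density gradient, the layer-3 cell-count data.

Intensities are floats in [0, 1] internally; the TIFF writers quantize to
16-bit, a positive affine map that leaves all Pearson statistics unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from shapely.geometry import Point, Polygon

from .image import ConfigurationError, GeometryError, Image2D, ROI, write_image

__all__ = [
    "SynthImageConfig",
    "ColocConfig",
    "GradientConfig",
    "PointPatternConfig",
    "gen_hex_patch_image",
    "gen_square_patch_image",
    "gen_scattered_image",
    "gen_noise_image",
    "gen_coloc_pair",
    "gen_dv_gradient_mask",
    "gen_point_pattern",
    "write_channel",
]

_PATCH_AMPLITUDE = 0.85  # peak intensity of one patch before noise/clipping


@dataclass(frozen=True)
class SynthImageConfig:
    """Geometry and noise settings for patch-image generators.

    ``lattice_spacing_um`` is the center-to-center patch spacing,
    ``patch_sigma_um`` the Gaussian patch radius, ``position_jitter_um`` the
    SD of isotropic Gaussian displacement of each patch center, and
    ``background_noise_sd`` the SD of additive pixel noise (intensity units
    on the [0, 1] scale). ``expected_blob_count``, when set, overrides the
    lattice-equivalent blob density used by the scattered generator.
    """

    width_px: int = 256
    height_px: int = 256
    pixel_size_um: float = 2.0
    lattice_spacing_um: float = 80.0
    patch_sigma_um: float = 12.0
    lattice_orientation_deg: float = 0.0
    position_jitter_um: float = 0.0
    background_noise_sd: float = 0.0
    seed: int = 0
    expected_blob_count: Optional[int] = None

    def validate(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ConfigurationError("image dimensions must be positive")
        if not (self.pixel_size_um > 0):
            raise ConfigurationError("pixel_size_um must be > 0")
        if not (self.lattice_spacing_um > 2 * self.patch_sigma_um):
            raise ConfigurationError(
                "violated invariant lattice_spacing_um > 2*patch_sigma_um: "
                f"{self.lattice_spacing_um} <= 2*{self.patch_sigma_um} (patches not resolvable)"
            )
        if self.lattice_spacing_um / self.pixel_size_um < 6:
            raise ConfigurationError(
                "violated invariant lattice_spacing_um / pixel_size_um >= 6: "
                f"{self.lattice_spacing_um}/{self.pixel_size_um} (spacing not resolvable in pixels)"
            )
        if self.position_jitter_um < 0:
            raise ConfigurationError("position_jitter_um must be >= 0")
        if self.background_noise_sd < 0:
            raise ConfigurationError("background_noise_sd must be >= 0")


@dataclass(frozen=True)
class ColocConfig:
    """Target Pearson coefficient and noise scale for a colocalized channel."""

    target_rho: float = 0.6
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if abs(self.target_rho) > 1:
            raise ConfigurationError(f"|target_rho| must be <= 1, got {self.target_rho}")
        if not (self.noise_sd > 0):
            raise ConfigurationError("noise_sd must be > 0")


@dataclass(frozen=True)
class GradientConfig:
    """Dorsal expression front: covered fraction and sigmoidal edge scale."""

    front_fraction: float = 0.4
    front_softness_um: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.front_fraction <= 1.0):
            raise ConfigurationError(
                f"front_fraction must lie in [0, 1], got {self.front_fraction}"
            )
        if self.front_softness_um < 0:
            raise ConfigurationError("front_softness_um must be >= 0")


@dataclass(frozen=True)
class PointPatternConfig:
    """Inhomogeneous Poisson cell pattern in a polygon.

    ``density_per_mm2`` is the mean density over the dorsoventral extent;
    ``dv_gradient_slope`` is the relative density change per normalized
    dorsoventral unit, i.e. local density = density * (1 + slope*(u - 1/2))
    with u in [0, 1] from dorsal to ventral end of the polygon.
    """

    region_polygon: tuple  # ((x_um, y_um), ...) vertices
    density_per_mm2: float = 1000.0
    dv_gradient_slope: float = 0.0
    dv_axis: tuple[float, float] = (0.0, 1.0)
    seed: int = 0
    marker: str = "calbindin"
    region_name: str = "layer3"

    def polygon(self) -> Polygon:
        poly = Polygon(self.region_polygon)
        if not poly.is_valid or poly.area <= 0:
            raise GeometryError("region_polygon must be a simple polygon with positive area")
        return poly

    def validate(self) -> None:
        self.polygon()
        if self.density_per_mm2 < 0:
            raise ConfigurationError("density_per_mm2 must be >= 0")
        if abs(self.dv_gradient_slope) > 2:
            raise ConfigurationError(
                "dv_gradient_slope beyond +/-2 makes local density negative"
            )


def _render_blobs(centers_px: np.ndarray, shape: tuple[int, int], sigma_px: float) -> np.ndarray:
    """Sum isotropic Gaussian bumps at sub-pixel centers onto a float image."""
    h, w = shape
    img = np.zeros((h, w), dtype=np.float64)
    half = max(2, int(math.ceil(4 * sigma_px)))
    for cx, cy in centers_px:
        x0, x1 = int(math.floor(cx)) - half, int(math.floor(cx)) + half + 1
        y0, y1 = int(math.floor(cy)) - half, int(math.floor(cy)) + half + 1
        x0c, x1c = max(x0, 0), min(x1, w)
        y0c, y1c = max(y0, 0), min(y1, h)
        if x0c >= x1c or y0c >= y1c:
            continue
        xs = np.arange(x0c, x1c) - cx
        ys = np.arange(y0c, y1c) - cy
        g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * sigma_px**2))
        img[y0c:y1c, x0c:x1c] += _PATCH_AMPLITUDE * g
    return img


def _finalize(img: np.ndarray, cfg: SynthImageConfig, rng: np.random.Generator,
              centers_px: np.ndarray, kind: str) -> Image2D:
    if cfg.background_noise_sd > 0:
        img = img + rng.normal(0.0, cfg.background_noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    meta = {"generator": kind, "config": asdict(cfg), "centers_px": np.asarray(centers_px)}
    return Image2D(pixels=img, pixel_size_um=cfg.pixel_size_um, meta=meta)


def _lattice_centers(cfg: SynthImageConfig, basis: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Centers of a 2-vector lattice covering the frame plus a margin."""
    w_um = cfg.width_px * cfg.pixel_size_um
    h_um = cfg.height_px * cfg.pixel_size_um
    margin = cfg.lattice_spacing_um + 4 * cfg.patch_sigma_um
    # enough lattice steps to cover the frame diagonal from a corner anchor
    n = int(math.ceil((math.hypot(w_um, h_um) + 2 * margin) / cfg.lattice_spacing_um)) + 2
    i, j = np.meshgrid(np.arange(-n, n + 1), np.arange(-n, n + 1), indexing="ij")
    pts = i.ravel()[:, None] * basis[0] + j.ravel()[:, None] * basis[1]
    pts = pts + np.array([w_um / 2, h_um / 2])  # anchor one site at frame center
    if cfg.position_jitter_um > 0:
        pts = pts + rng.normal(0.0, cfg.position_jitter_um, size=pts.shape)
    keep = (
        (pts[:, 0] > -margin) & (pts[:, 0] < w_um + margin)
        & (pts[:, 1] > -margin) & (pts[:, 1] < h_um + margin)
    )
    return pts[keep]


def gen_hex_patch_image(cfg: SynthImageConfig) -> Image2D:
    """Gaussian patches on a triangular (hexagonal-neighbor) lattice.

    Each interior patch has six nearest neighbours at the configured spacing;
    centers are jittered by an isotropic Gaussian of SD ``position_jitter_um``
    and pixel noise of SD ``background_noise_sd`` is added. Deterministic for
    a fixed config.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    th = math.radians(cfg.lattice_orientation_deg)
    s = cfg.lattice_spacing_um
    basis = s * np.array([
        [math.cos(th), math.sin(th)],
        [math.cos(th + math.pi / 3), math.sin(th + math.pi / 3)],
    ])
    centers_um = _lattice_centers(cfg, basis, rng)
    centers_px = centers_um / cfg.pixel_size_um
    img = _render_blobs(centers_px, (cfg.height_px, cfg.width_px),
                        cfg.patch_sigma_um / cfg.pixel_size_um)
    return _finalize(img, cfg, rng, centers_px, "hex_patches")


def gen_square_patch_image(cfg: SynthImageConfig) -> Image2D:
    """Gaussian patches on a square lattice (four-fold symmetry control)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    th = math.radians(cfg.lattice_orientation_deg)
    s = cfg.lattice_spacing_um
    basis = s * np.array([
        [math.cos(th), math.sin(th)],
        [-math.sin(th), math.cos(th)],
    ])
    centers_um = _lattice_centers(cfg, basis, rng)
    centers_px = centers_um / cfg.pixel_size_um
    img = _render_blobs(centers_px, (cfg.height_px, cfg.width_px),
                        cfg.patch_sigma_um / cfg.pixel_size_um)
    return _finalize(img, cfg, rng, centers_px, "square_patches")


def gen_scattered_image(cfg: SynthImageConfig) -> Image2D:
    """Gaussian blobs at homogeneous-Poisson positions (aperiodic null).

    The expected blob count is ``expected_blob_count`` when set; otherwise it
    matches the blob density of a hexagonal lattice with the configured
    spacing (2 / (sqrt(3) * spacing^2)), so periodicity is the only feature
    distinguishing this null from :func:`gen_hex_patch_image`.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    w_um = cfg.width_px * cfg.pixel_size_um
    h_um = cfg.height_px * cfg.pixel_size_um
    if cfg.expected_blob_count is not None:
        lam = float(cfg.expected_blob_count)
    else:
        lam = 2.0 / (math.sqrt(3.0) * cfg.lattice_spacing_um**2) * w_um * h_um
    n = rng.poisson(lam)
    centers_um = np.column_stack([rng.uniform(0, w_um, n), rng.uniform(0, h_um, n)])
    centers_px = centers_um / cfg.pixel_size_um
    img = _render_blobs(centers_px, (cfg.height_px, cfg.width_px),
                        cfg.patch_sigma_um / cfg.pixel_size_um)
    return _finalize(img, cfg, rng, centers_px, "scattered")


def gen_noise_image(width_px: int, height_px: int, pixel_size_um: float,
                    seed: int) -> Image2D:
    """Pure pixel-noise image (uniform [0, 1)); independent channels for null
    cross-correlation experiments."""
    rng = np.random.default_rng(seed)
    px = rng.random((height_px, width_px))
    return Image2D(pixels=px, pixel_size_um=pixel_size_um,
                   meta={"generator": "noise", "seed": seed})


def gen_coloc_pair(base: Image2D, cfg: ColocConfig) -> tuple[Image2D, Image2D]:
    """A channel pair with a chosen expected whole-image Pearson coefficient.

    Channel 1 is the base image; channel 2 is
    ``rho * z(base) + sqrt(1 - rho^2) * eps`` with ``z`` the standardized
    image and ``eps`` independent standardized pixel noise, mapped back to
    nonnegative [0, 1] intensities by a positive affine map (which leaves the
    Pearson coefficient untouched). The sample coefficient concentrates on
    ``target_rho`` as the pixel count grows.
    """
    cfg.validate()
    px = base.pixels
    sd = float(px.std())
    if sd == 0:
        raise ValueError("degenerate input: base image is constant, Pearson undefined")
    rng = np.random.default_rng(cfg.seed)
    z = (px - px.mean()) / sd
    eps = rng.normal(0.0, cfg.noise_sd, size=px.shape)
    eps = (eps - eps.mean()) / eps.std()
    rho = cfg.target_rho
    mix = rho * z + math.sqrt(max(0.0, 1.0 - rho * rho)) * eps
    lo, hi = float(mix.min()), float(mix.max())
    ch2 = (mix - lo) / (hi - lo) if hi > lo else np.zeros_like(mix)
    meta = {"generator": "coloc_channel", "config": asdict(cfg)}
    return (
        Image2D(pixels=px.copy(), pixel_size_um=base.pixel_size_um,
                mask=None if base.mask is None else base.mask.copy(),
                meta=dict(base.meta)),
        Image2D(pixels=ch2, pixel_size_um=base.pixel_size_um,
                mask=None if base.mask is None else base.mask.copy(), meta=meta),
    )


def gen_dv_gradient_mask(band: ROI, cfg: GradientConfig,
                         pixel_size_um: float = 2.0) -> Image2D:
    """Marker intensity covering the dorsal ``front_fraction`` of a band ROI.

    Intensity is 1 at the dorsal end and falls to 0 across a logistic front
    of length scale ``front_softness_um`` centred at
    ``front_fraction * band_length``; softness 0 gives a hard step. The image
    covers the ROI bounding box; for polygon ROIs a validity mask marks
    outside pixels.
    """
    cfg.validate()
    x0, y0, x1, y1 = band.bounds()
    h, w = y1 - y0, x1 - x0
    yy, xx = np.meshgrid(np.arange(h) + 0.5, np.arange(w) + 0.5, indexing="ij")
    ax = np.asarray(band.dv_axis, dtype=float)
    # projection (um) of each pixel center onto the dv axis, from the dorsal end
    proj = ((xx + x0) * ax[0] + (yy + y0) * ax[1]) * pixel_size_um
    t = proj - proj.min()
    length = float(t.max())
    front = cfg.front_fraction * length
    if cfg.front_softness_um == 0:
        if cfg.front_fraction <= 0.0:
            px = np.zeros_like(t)
        elif cfg.front_fraction >= 1.0:
            px = np.ones_like(t)
        else:
            px = (t <= front).astype(np.float64)
    else:
        px = 1.0 / (1.0 + np.exp((t - front) / cfg.front_softness_um))
    mask = None
    if band.shape[0] == "polygon":
        from skimage.draw import polygon2mask

        verts = np.asarray(band.shape[1], dtype=float)
        local = np.column_stack([verts[:, 1] - y0, verts[:, 0] - x0])
        mask = polygon2mask((h, w), local)
    meta = {"generator": "dv_gradient", "config": asdict(cfg),
            "band_length_um": length}
    return Image2D(pixels=px, pixel_size_um=pixel_size_um, mask=mask, meta=meta)


def gen_point_pattern(cfg: PointPatternConfig):
    """Seeded inhomogeneous Poisson cell positions inside a polygon.

    Homogeneous candidates at the gradient's maximum density are thinned by
    the linear dorsoventral profile, giving an exact inhomogeneous Poisson
    process whose mean density over the dorsoventral extent equals
    ``density_per_mm2``.
    """
    from .morphometry import PointPattern  # local import to avoid a cycle

    cfg.validate()
    poly = cfg.polygon()
    rng = np.random.default_rng(cfg.seed)
    area_mm2 = poly.area / 1e6  # polygon in um -> mm^2
    ax = np.asarray(cfg.dv_axis, dtype=float)
    verts = np.asarray(poly.exterior.coords)
    tproj = verts @ ax
    t0, t1 = float(tproj.min()), float(tproj.max())
    span = t1 - t0
    slope = cfg.dv_gradient_slope
    lam_max = cfg.density_per_mm2 * (1.0 + abs(slope) / 2.0)
    minx, miny, maxx, maxy = poly.bounds
    box_area_mm2 = (maxx - minx) * (maxy - miny) / 1e6
    n_cand = rng.poisson(lam_max * box_area_mm2)
    pts: list[tuple[float, float]] = []
    if n_cand > 0 and cfg.density_per_mm2 > 0:
        xs = rng.uniform(minx, maxx, n_cand)
        ys = rng.uniform(miny, maxy, n_cand)
        u = ((xs * ax[0] + ys * ax[1]) - t0) / span if span > 0 else np.full(n_cand, 0.5)
        lam = cfg.density_per_mm2 * (1.0 + slope * (u - 0.5))
        accept = rng.uniform(0.0, lam_max, n_cand) < lam
        for x, y, a in zip(xs, ys, accept):
            if a and poly.contains(Point(x, y)):
                pts.append((float(x), float(y)))
    return PointPattern(
        points=np.asarray(pts, dtype=float).reshape(-1, 2),
        marker=cfg.marker,
        region=poly,
        region_area_mm2=area_mm2,
        dv_axis=tuple(ax),
    )


def write_channel(img: Image2D, path: str | Path,
                  config: Optional[object] = None) -> None:
    """Write one channel as 16-bit grayscale TIFF plus a YAML sidecar holding
    the full generator config, seed and pixel size."""
    path = Path(path)
    write_image(img, path, bit_depth=16)
    sidecar = {
        "pixel_size_um": img.pixel_size_um,
        "generator": img.meta.get("generator"),
        "config": asdict(config) if config is not None and not isinstance(config, dict)
        else (config or img.meta.get("config")),
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))
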