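"""Single-channel image container, ROI handling and permitted preprocessing.

Images are plain 2D intensity grids with an explicit physical pixel size; the
anatomical dorsoventral direction is never inferred from image orientation but
carried on each :class:`ROI` as a unit vector. The only intensity preprocessing
offered is a uniform positive linear (gain/offset) adjustment, because every
downstream statistic is a Pearson correlation and therefore invariant to it.

Coordinate convention: row-major arrays, origin at the top-left pixel, x along
columns and y along rows. Pixel coordinates are 0-based and ROI rectangles are
half-open ``[x0, x1) x [y0, y1)`` so paired crops of equal nominal size always
have identical shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import tifffile
import yaml
from PIL import Image as PILImage
from skimage.draw import polygon2mask

__all__ = [
    "Image2D",
    "ROI",
    "FormatError",
    "GeometryError",
    "ConfigurationError",
    "read_image",
    "write_image",
    "extract_roi",
    "linear_adjust",
    "read_rois",
    "write_rois",
]


class FormatError(ValueError):
    """Unsupported image file layout (e.g. RGB where monochrome is required)."""


class GeometryError(ValueError):
    """ROI/polygon geometry violates a precondition."""


class ConfigurationError(ValueError):
    """A configuration value violates its invariant."""


@dataclass
class Image2D:
    """A single-channel intensity grid with physical pixel size.

    Parameters
    ----------
    pixels
        2D float array of finite intensities (arbitrary units).
    pixel_size_um
        Physical size of one pixel in micrometres; must be positive.
    mask
        Optional boolean validity grid of the same shape; ``False`` marks
        pixels excluded from every statistic (e.g. outside a polygon ROI).
    meta
        Free-form provenance (generator config, applied adjustments, ...).
    """

    pixels: np.ndarray
    pixel_size_um: float
    mask: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise FormatError(
                f"Image2D requires a 2D single-channel array, got ndim={self.pixels.ndim}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("Image2D intensities must all be finite")
        if not (self.pixel_size_um > 0):
            raise ConfigurationError(
                f"pixel_size_um must be > 0, got {self.pixel_size_um}"
            )
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape:
                raise GeometryError(
                    f"mask shape {self.mask.shape} != pixel shape {self.pixels.shape}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def valid_mask(self) -> np.ndarray:
        """Boolean validity grid (all-True when no mask is attached)."""
        if self.mask is None:
            return np.ones(self.pixels.shape, dtype=bool)
        return self.mask


@dataclass
class ROI:
    """A rectangular or polygonal region with an anatomical dorsoventral axis.

    ``shape`` is either ``("rect", (x0, y0, x1, y1))`` with half-open pixel
    bounds, or ``("polygon", vertices)`` with an (N, 2) array of ``(x, y)``
    pixel vertices. ``dv_axis`` points dorsal -> ventral in image coordinates
    and must have unit length.
    """

    shape: tuple
    dv_axis: tuple[float, float] = (0.0, 1.0)
    label: str = "whole"
    pair_id: Optional[str] = None

    def __post_init__(self) -> None:
        kind = self.shape[0]
        if kind not in ("rect", "polygon"):
            raise GeometryError(f"unknown ROI shape kind {kind!r}")
        ax = np.asarray(self.dv_axis, dtype=float)
        norm = float(np.hypot(*ax))
        if not np.isclose(norm, 1.0, atol=1e-6):
            raise GeometryError(f"dv_axis must be unit length, |axis|={norm:.6g}")
        if kind == "rect":
            x0, y0, x1, y1 = self.shape[1]
            if not (x1 > x0 and y1 > y0):
                raise GeometryError(f"empty rectangle {self.shape[1]}")
        else:
            verts = np.asarray(self.shape[1], dtype=float)
            if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
                raise GeometryError("polygon needs >= 3 (x, y) vertices")

    def bounds(self) -> tuple[int, int, int, int]:
        """Integer half-open bounding box (x0, y0, x1, y1) in pixels."""
        if self.shape[0] == "rect":
            x0, y0, x1, y1 = self.shape[1]
            return int(x0), int(y0), int(x1), int(y1)
        verts = np.asarray(self.shape[1], dtype=float)
        x0 = int(np.floor(verts[:, 0].min()))
        y0 = int(np.floor(verts[:, 1].min()))
        x1 = int(np.ceil(verts[:, 0].max()))
        y1 = int(np.ceil(verts[:, 1].max()))
        return x0, y0, x1, y1


def read_image(path: str | Path, pixel_size_um: float) -> Image2D:
    """Read a single-channel 8/16-bit TIFF or PNG with intensities preserved.

    No smoothing or rescaling is applied: the stored integer values become the
    float intensities verbatim. The physical pixel size is not stored in the
    files this package writes reliably across tools, so it must be supplied.
    """
    path = Path(path)
    if pixel_size_um is None or not (pixel_size_um > 0):
        raise ConfigurationError("pixel_size_um must be supplied and > 0")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(PILImage.open(path))
    if arr.ndim != 2:
        raise FormatError(
            f"{path.name}: expected a single-channel image, got shape {arr.shape}; "
            "export each channel to its own monochrome file"
        )
    return Image2D(pixels=arr.astype(np.float64), pixel_size_um=float(pixel_size_um))


def write_image(img: Image2D, path: str | Path, bit_depth: int = 16) -> None:
    """Write an image as grayscale 8/16-bit TIFF or PNG.

    Float images are quantized onto the full integer range by a positive
    affine map (harmless to every Pearson statistic); integer-valued images
    within range are stored exactly.
    """
    path = Path(path)
    if bit_depth not in (8, 16):
        raise ConfigurationError("bit_depth must be 8 or 16")
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    top = float(np.iinfo(dtype).max)
    px = img.pixels
    if np.array_equal(px, np.round(px)) and px.min() >= 0 and px.max() <= top:
        data = px.astype(dtype)
    else:
        lo, hi = float(px.min()), float(px.max())
        scale = top / (hi - lo) if hi > lo else 0.0
        data = np.round((px - lo) * scale).astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        PILImage.fromarray(data).save(path)


def extract_roi(img: Image2D, roi: ROI) -> Image2D:
    """Crop an ROI out of an image.

    Rectangles produce a plain crop. Polygons produce the crop of their
    bounding box with a mask marking outside-polygon pixels invalid (composed
    with any pre-existing mask).
    """
    h, w = img.shape
    x0, y0, x1, y1 = roi.bounds()
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        raise GeometryError(
            f"ROI bounds ({x0},{y0})-({x1},{y1}) exceed image shape {(w, h)}"
        )
    crop = img.pixels[y0:y1, x0:x1].copy()
    base_mask = img.mask[y0:y1, x0:x1].copy() if img.mask is not None else None
    if roi.shape[0] == "polygon":
        verts = np.asarray(roi.shape[1], dtype=float)
        # polygon2mask wants (row, col) = (y, x) vertices relative to the crop
        local = np.column_stack([verts[:, 1] - y0, verts[:, 0] - x0])
        poly_mask = polygon2mask(crop.shape, local)
        mask = poly_mask if base_mask is None else (poly_mask & base_mask)
    else:
        mask = base_mask
    meta = dict(img.meta)
    meta["roi"] = {"label": roi.label, "pair_id": roi.pair_id, "bounds": (x0, y0, x1, y1)}
    return Image2D(pixels=crop, pixel_size_um=img.pixel_size_um, mask=mask, meta=meta)


def linear_adjust(img: Image2D, gain: float, offset: float = 0.0) -> Image2D:
    """Uniform linear brightness/contrast adjustment: ``gain * pixels + offset``.

    Gain must be positive: a non-positive gain would flip or destroy the
    correlation structure every downstream statistic relies on.
    """
    if not (gain > 0):
        raise ConfigurationError(f"gain must be > 0, got {gain}")
    meta = dict(img.meta)
    meta.setdefault("adjustments", []).append({"gain": float(gain), "offset": float(offset)})
    return Image2D(
        pixels=gain * img.pixels + offset,
        pixel_size_um=img.pixel_size_um,
        mask=None if img.mask is None else img.mask.copy(),
        meta=meta,
    )


# --- ROI YAML files ---------------------------------------------------------

def _roi_to_dict(name: str, roi: ROI) -> dict:
    kind = roi.shape[0]
    geom = (
        [float(v) for v in roi.shape[1]]
        if kind == "rect"
        else [[float(x), float(y)] for x, y in np.asarray(roi.shape[1], dtype=float)]
    )
    return {
        "name": name,
        "kind": kind,
        "geometry": geom,
        "dv_axis": [float(roi.dv_axis[0]), float(roi.dv_axis[1])],
        "label": roi.label,
        "pair_id": roi.pair_id,
    }


def write_rois(rois: dict[str, ROI], path: str | Path) -> None:
    """Write named ROIs to a human-editable YAML file."""
    entries = [_roi_to_dict(name, roi) for name, roi in rois.items()]
    Path(path).write_text(yaml.safe_dump(entries, sort_keys=False))


def read_rois(path: str | Path) -> dict[str, ROI]:
    """Read a YAML list of named ROIs written by :func:`write_rois`."""
    entries = yaml.safe_load(Path(path).read_text())
    out: dict[str, ROI] = {}
    for e in entries:
        geom: Sequence = e["geometry"]
        shape = ("rect", tuple(geom)) if e["kind"] == "rect" else ("polygon", np.asarray(geom))
        out[e["name"]] = ROI(
            shape=shape,
            dv_axis=tuple(e.get("dv_axis", (0.0, 1.0))),
            label=e.get("label", "whole"),
            pair_id=e.get("pair_id"),
        )
    return out
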