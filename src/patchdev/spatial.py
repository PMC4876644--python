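"""Spatial periodicity and overlap statistics.

The three statistics here quantify the geometry of immunolabeled patch
lattices and the colocalization of marker channels:

* :func:`spatial_autocorrelogram` — the map of Pearson product-moment
  correlations between an image and its shifted copy, computed per lag over
  exactly the overlapping (and mask-valid) pixels, with no smoothing. Lags
  with fewer than ``min_overlap`` overlapping pixels, or with zero variance
  in either window, are flagged invalid rather than zero-filled.
* :func:`grid_score` — the rotational six-fold-symmetry score of an
  autocorrelogram: the annulus containing the six inner peaks is correlated
  with itself rotated by 30/60/90/120/150 degrees and the score is
  ``min(r60, r120) - max(r30, r90, r150)``, bounded in [-2, 2]. Positive
  scores indicate hexagonal arrangement.
* :func:`spatial_crosscorrelation` — the whole-image Pearson coefficient
  between two same-size channels, the colocalization measure, in [-1, 1].

All three are exactly invariant under positive linear (gain/offset)
intensity adjustment of their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import maximum_filter
from scipy.signal import correlate

from .image import GeometryError, Image2D, ROI, extract_roi

__all__ = [
    "Autocorrelogram",
    "GridScoreResult",
    "CrossCorrResult",
    "DegenerateInputError",
    "spatial_autocorrelogram",
    "grid_score",
    "spatial_crosscorrelation",
    "paired_dv_crosscorrelation",
]

ROTATIONS_DEG = (30, 60, 90, 120, 150)


class DegenerateInputError(ValueError):
    """Input has no variance where variance is required."""


@dataclass
class Autocorrelogram:
    """Per-lag Pearson autocorrelation map.

    ``r[i, j]`` is the correlation at lag ``(tau_y, tau_x) = (i - max_lag,
    j - max_lag)``; ``n`` the per-lag overlapping-pixel count; ``valid``
    flags lags with ``n >= min_overlap`` and defined variance. Invalid lags
    hold NaN in ``r``.
    """

    r: np.ndarray
    n: np.ndarray
    valid: np.ndarray
    min_overlap: int
    max_lag: int
    source_shape: tuple[int, int]
    pixel_size_um: float = 1.0

    def lag_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """(tau_x, tau_y) integer lag coordinate grids."""
        lags = np.arange(-self.max_lag, self.max_lag + 1)
        ty, tx = np.meshgrid(lags, lags, indexing="ij")
        return tx, ty


@dataclass
class GridScoreResult:
    """Rotational grid score with the annulus and correlations behind it.

    ``ok`` is False for a flagged "no-periodicity" result (fewer than six
    detectable peaks or a degenerate annulus); then ``score`` is None and
    must not enter group averages.
    """

    ok: bool
    score: Optional[float] = None
    annulus_inner_px: Optional[float] = None
    annulus_outer_px: Optional[float] = None
    rot_corr: dict[int, float] = field(default_factory=dict)
    peak_spacing_px: Optional[float] = None
    peaks_px: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    reason: Optional[str] = None


@dataclass
class CrossCorrResult:
    """Whole-image Pearson coefficient between two marker channels."""

    r: float
    n_pixels: int
    roi_label: str = "whole"
    pair_id: Optional[str] = None
    marker_pair: tuple[str, str] = ("ch1", "ch2")
    unpaired: bool = False


def _corr2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # full 2D cross-correlation sum_x a(x) b(x - tau) via FFT
    return correlate(a, b, mode="full", method="fft")


def spatial_autocorrelogram(img: Image2D, max_lag: int,
                            min_overlap: int = 20) -> Autocorrelogram:
    """Per-lag Pearson autocorrelation of an image with its shifted copy.

    For each lag ``(tau_x, tau_y)`` with ``|tau| <= max_lag`` the Pearson
    product-moment coefficient is computed over exactly the pixels where the
    image and its shifted copy overlap and both are mask-valid::

        r(t) = [n*S_ab - S_a*S_b] /
               sqrt(n*S_aa - S_a^2) / sqrt(n*S_bb - S_b^2)

    with the sums taken over the overlap. Lags where ``n < min_overlap`` or
    either window has zero variance are invalid (NaN), never zero-filled.

    The five correlation sums are evaluated with FFT-based masked
    correlations of the mean-centred image (Pearson is exactly invariant to
    the centring, which only serves numerical conditioning); the result
    matches a naive per-lag evaluation to ~1e-12.
    """
    h, w = img.shape
    if max_lag >= min(h, w):
        raise ValueError(f"max_lag={max_lag} must be < min(image dims)={min(h, w)}")
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    m = img.valid_mask().astype(np.float64)
    px = img.pixels
    nv = m.sum()
    if nv < 2:
        raise DegenerateInputError("fewer than 2 valid pixels")
    mean = (px * m).sum() / nv
    gsd = float(np.sqrt(((px - mean) ** 2 * m).sum() / nv))
    if gsd == 0:
        raise DegenerateInputError("constant image: Pearson autocorrelation undefined")
    f = (px - mean) * m  # centred, zero outside the mask

    n_full = _corr2(m, m)
    s_a = _corr2(f, m)           # sum f(x) over overlap
    s_b = _corr2(m, f)           # sum f(x - tau) over overlap
    s_aa = _corr2(f * f, m)
    s_bb = _corr2(m, f * f)
    s_ab = _corr2(f, f)

    c0, c1 = h - 1, w - 1  # zero-lag index in the full correlation
    sl = (slice(c0 - max_lag, c0 + max_lag + 1), slice(c1 - max_lag, c1 + max_lag + 1))
    n = np.rint(n_full[sl]).astype(np.int64)
    s_a, s_b = s_a[sl], s_b[sl]
    s_aa, s_bb, s_ab = s_aa[sl], s_bb[sl], s_ab[sl]

    var_a = n * s_aa - s_a**2
    var_b = n * s_bb - s_b**2
    # variance threshold: relative to what n pixels of the global SD would give
    var_tol = (n.astype(np.float64) * gsd) ** 2 * 1e-12
    valid = (n >= min_overlap) & (var_a > var_tol) & (var_b > var_tol)
    r = np.full(n.shape, np.nan)
    num = n * s_ab - s_a * s_b
    with np.errstate(invalid="ignore", divide="ignore"):
        den = np.sqrt(np.where(var_a > 0, var_a, np.nan)) * \
              np.sqrt(np.where(var_b > 0, var_b, np.nan))
        r_all = num / den
    r[valid] = np.clip(r_all[valid], -1.0, 1.0)
    return Autocorrelogram(r=r, n=n, valid=valid, min_overlap=min_overlap,
                           max_lag=max_lag, source_shape=(h, w),
                           pixel_size_um=img.pixel_size_um)


# --- grid score -------------------------------------------------------------

def _radial_profile(acorr: Autocorrelogram) -> tuple[np.ndarray, np.ndarray]:
    """Mean valid correlation per integer radial bin."""
    tx, ty = acorr.lag_grids()
    rad = np.rint(np.hypot(tx, ty)).astype(int)
    nbins = rad.max() + 1
    prof = np.full(nbins, np.nan)
    for k in range(nbins):
        sel = (rad == k) & acorr.valid
        if sel.any():
            prof[k] = acorr.r[sel].mean()
    return np.arange(nbins), prof


def _first_local_min(prof: np.ndarray) -> Optional[int]:
    for i in range(1, len(prof) - 1):
        if np.isnan(prof[i - 1]) or np.isnan(prof[i]) or np.isnan(prof[i + 1]):
            continue
        if prof[i] <= prof[i - 1] and prof[i] <= prof[i + 1]:
            return i
    return None


def _find_peaks(acorr: Autocorrelogram, inner_radius: float) -> np.ndarray:
    """Off-center local maxima of r, merged within 2 px.

    Candidates are valid lags above the 97.5th percentile of valid r that are
    maxima of their 3x3 neighbourhood; merging keeps the larger r, ties
    broken toward smaller radius. Returns (k, 2) array of (tau_x, tau_y).
    """
    filled = np.where(acorr.valid, acorr.r, -2.0)
    is_max = (maximum_filter(filled, size=3, mode="constant", cval=-2.0) == filled)
    tx, ty = acorr.lag_grids()
    rad = np.hypot(tx, ty)
    off_center = acorr.valid & (rad > inner_radius)
    if not off_center.any():
        return np.empty((0, 2))
    # percentile over off-center lags so the central peak cannot mask the ring
    thr = np.percentile(acorr.r[off_center], 97.5)
    cand = is_max & off_center & (acorr.r >= thr)
    if not cand.any():
        return np.empty((0, 2))
    pts = np.column_stack([tx[cand], ty[cand]]).astype(float)
    vals = acorr.r[cand]
    radii = rad[cand]
    order = np.lexsort((radii, -vals))  # by descending r, then smaller radius
    kept: list[np.ndarray] = []
    for idx in order:
        p = pts[idx]
        if all(np.hypot(*(p - q)) > 2.0 for q in kept):
            kept.append(p)
    return np.asarray(kept)


def _annulus_rotation_corr(acorr: Autocorrelogram, inner: float, outer: float,
                           angle_deg: float) -> Optional[float]:
    """Pearson correlation between annulus values and the values at
    nearest-neighbour rotated lag positions; invalid lags excluded pairwise."""
    tx, ty = acorr.lag_grids()
    rad = np.hypot(tx, ty)
    ring = (rad >= inner) & (rad <= outer) & acorr.valid
    if ring.sum() < 20:
        return None
    th = np.deg2rad(angle_deg)
    xs, ys = tx[ring], ty[ring]
    rx = np.rint(np.cos(th) * xs - np.sin(th) * ys).astype(int)
    ry = np.rint(np.sin(th) * xs + np.cos(th) * ys).astype(int)
    L = acorr.max_lag
    inb = (np.abs(rx) <= L) & (np.abs(ry) <= L)
    a = acorr.r[ring][inb]
    i, j = ry[inb] + L, rx[inb] + L
    ok = acorr.valid[i, j]
    a, b = a[ok], acorr.r[i[ok], j[ok]]
    if a.size < 20 or a.std() == 0 or b.std() == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def grid_score(acorr: Autocorrelogram) -> GridScoreResult:
    """Rotational six-fold-symmetry score of an autocorrelogram.

    The annulus spans from the first local minimum of the radially averaged
    correlation (excluding the central peak) out to a radius chosen among
    candidates between 1.1x and 2.0x the inner-ring radius to maximize the
    score. The annulus is correlated with itself rotated by 30/60/90/120/150
    degrees (nearest-neighbour lag sampling, invalid lags excluded pairwise)
    and ``score = min(r60, r120) - max(r30, r90, r150)``, in [-2, 2].

    With fewer than six detectable off-center peaks, or a degenerate annulus,
    a flagged no-periodicity result is returned instead of a number.
    """
    _, prof = _radial_profile(acorr)
    imin = _first_local_min(prof)
    if imin is None:
        return GridScoreResult(ok=False, reason="no local minimum in radial profile")
    peaks = _find_peaks(acorr, float(imin))
    if peaks.shape[0] < 6:
        return GridScoreResult(
            ok=False, reason=f"only {peaks.shape[0]} off-center peaks detected",
            peaks_px=peaks)
    radii = np.hypot(peaks[:, 0], peaks[:, 1])
    order = np.argsort(radii)
    six = peaks[order[:6]]
    ring_radius = float(np.median(np.hypot(six[:, 0], six[:, 1])))
    inner = float(imin)
    best: Optional[tuple[float, float, dict[int, float]]] = None
    for mult in np.linspace(1.1, 2.0, 19):
        outer = min(mult * ring_radius, float(acorr.max_lag))
        if outer <= inner + 1:
            continue
        cors = {ang: _annulus_rotation_corr(acorr, inner, outer, ang)
                for ang in ROTATIONS_DEG}
        if any(v is None for v in cors.values()):
            continue
        score = min(cors[60], cors[120]) - max(cors[30], cors[90], cors[150])
        if best is None or score > best[0]:
            best = (score, outer, cors)  # type: ignore[assignment]
    if best is None:
        return GridScoreResult(ok=False, reason="degenerate annulus", peaks_px=peaks)
    score, outer, cors = best
    return GridScoreResult(ok=True, score=float(score), annulus_inner_px=inner,
                           annulus_outer_px=float(outer),
                           rot_corr={k: float(v) for k, v in cors.items()},
                           peak_spacing_px=ring_radius, peaks_px=six)


# --- cross-correlation ------------------------------------------------------

def spatial_crosscorrelation(img1: Image2D, img2: Image2D,
                             roi_label: str = "whole",
                             pair_id: Optional[str] = None,
                             marker_pair: tuple[str, str] = ("ch1", "ch2"),
                             ) -> CrossCorrResult:
    """Whole-image Pearson coefficient between two same-size channels.

    Computed over all jointly mask-valid pixels with no smoothing. Raises on
    shape mismatch or when either channel is constant over the joint support.
    """
    if img1.shape != img2.shape:
        raise GeometryError(f"shape mismatch: {img1.shape} vs {img2.shape}")
    joint = img1.valid_mask() & img2.valid_mask()
    n = int(joint.sum())
    if n < 2:
        raise DegenerateInputError("fewer than 2 jointly valid pixels")
    a = img1.pixels[joint]
    b = img2.pixels[joint]
    if a.std() == 0 or b.std() == 0:
        raise DegenerateInputError("constant channel: Pearson undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    return CrossCorrResult(r=float(np.clip(r, -1.0, 1.0)), n_pixels=n,
                           roi_label=roi_label, pair_id=pair_id,
                           marker_pair=marker_pair)


def paired_dv_crosscorrelation(ch1: Image2D, ch2: Image2D,
                               rois: Sequence[ROI],
                               marker_pair: tuple[str, str] = ("ch1", "ch2"),
                               ) -> list[CrossCorrResult]:
    """Cross-correlation per dorsal/ventral ROI with pairing bookkeeping.

    ROIs sharing a ``pair_id`` form a dorsal/ventral pair and must have
    identical pixel sizes; an ROI whose pair is missing (e.g. section damage
    on one half) is accepted and flagged ``unpaired``.
    """
    by_pair: dict[Optional[str], list[ROI]] = {}
    for roi in rois:
        by_pair.setdefault(roi.pair_id, []).append(roi)
    for pid, group in by_pair.items():
        if pid is None:
            continue
        sizes = set()
        for roi in group:
            x0, y0, x1, y1 = roi.bounds()
            sizes.add((x1 - x0, y1 - y0))
        if len(group) > 1 and len(sizes) > 1:
            raise GeometryError(f"paired ROIs {pid!r} differ in size: {sizes}")
    results = []
    for roi in rois:
        res = spatial_crosscorrelation(
            extract_roi(ch1, roi), extract_roi(ch2, roi),
            roi_label=roi.label, pair_id=roi.pair_id, marker_pair=marker_pair)
        res.unpaired = roi.pair_id is None or len(by_pair[roi.pair_id]) < 2
        results.append(res)
    return results
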