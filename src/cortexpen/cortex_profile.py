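"""Cortex straightening and transverse-profile statistics.

Given rendered super-resolution images of an equatorial cell cortex,
this module detects the cortex ridge in the actin channel, fits a cubic
spline through it, straightens all channels by sampling along the
spline normals, averages transverse profiles in bins along the cortex
(default 200 nm), and measures per-bin peak position, FWHM,
peak-to-peak distance between channels, and the signed cytoplasmic
overhang:

    overhang = 100 * (t_hi - a_hi) / (t_hi - t_lo)

where [a_lo, a_hi] and [t_lo, t_hi] are the actin and target FWHM
intervals on the signed transverse axis (positive toward the
cytoplasm).  Positive overhang means the target layer extends beyond
the actin layer into the cytoplasm; negative means its cytoplasmic edge
is retracted toward the membrane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .smlm_core import RenderedImage

logger = logging.getLogger(__name__)


class ProfileRejected(ValueError):
    """A transverse profile failed a measurement precondition."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def sample_image(image: RenderedImage, points: np.ndarray) -> np.ndarray:
    """Bilinear sample at (x, y) nm points; NaN outside the image."""
    pts = np.atleast_2d(np.asarray(points, float))
    col = (pts[..., 0] - image.origin[0]) / image.pixel_size - 0.5
    row = (pts[..., 1] - image.origin[1]) / image.pixel_size - 0.5
    return ndimage.map_coordinates(
        image.data, [row, col], order=1, mode="constant", cval=np.nan
    )


# ---------------------------------------------------------------------------
# Cortex detection
# ---------------------------------------------------------------------------


@dataclass
class CortexContour:
    """Closed or open cortex centre line with inward (cytoplasm) normals."""

    points: np.ndarray  # (n, 2) nm, ordered
    closed: bool
    normal_sign: float = 1.0  # +1 if left-of-tangent normal points to cytoplasm
    _spline: CubicSpline | None = field(default=None, repr=False)
    _arclen: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, float)
        if len(pts) < 4:
            raise ValueError("need at least 4 contour points for a cubic spline")
        if self.closed:
            pts_ext = np.vstack([pts, pts[:1]])
        else:
            pts_ext = pts
        seg = np.linalg.norm(np.diff(pts_ext, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        bc = "periodic" if self.closed else "not-a-knot"
        self._spline = CubicSpline(s, pts_ext, axis=0, bc_type=bc)
        self._arclen = s
        self.points = pts

    @property
    def length(self) -> float:
        return float(self._arclen[-1])

    def position(self, s: np.ndarray) -> np.ndarray:
        return self._spline(np.asarray(s, float))

    def normal(self, s: np.ndarray) -> np.ndarray:
        """Unit normal pointing toward the cytoplasm."""
        d = self._spline(np.asarray(s, float), 1)
        d = np.atleast_2d(d)
        t = d / np.linalg.norm(d, axis=-1, keepdims=True)
        n = np.stack([-t[..., 1], t[..., 0]], axis=-1)  # left of tangent
        return self.normal_sign * n


def _auto_seed_circle(image: RenderedImage, spacing_nm: float = 100.0) -> np.ndarray:
    """Seed points on a circle fitted to the bright cortex band."""
    data = image.data
    pos = data[data > 0]
    if pos.size < 10:
        raise ValueError("image too dim for automatic cortex seeding")
    # robust scale: bright fiducial-bead spikes must not set the threshold
    scale = np.percentile(pos, 99)
    thr = 0.2 * scale
    rows, cols = np.nonzero(data > thr)
    if len(rows) < 10:
        raise ValueError("image too dim for automatic cortex seeding")
    w = np.minimum(data[rows, cols], scale)
    x = image.x_of_col(cols)
    y = image.y_of_row(rows)
    cx, cy = np.average(x, weights=w), np.average(y, weights=w)
    r = float(np.average(np.hypot(x - cx, y - cy), weights=w))
    n = max(int(np.ceil(2 * np.pi * r / spacing_nm)), 8)
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)])


def detect_cortex(
    actin_image: RenderedImage,
    seed_points: np.ndarray | None = None,
    closed: bool | None = None,
    search_half_width: float = 500.0,
    cytoplasm_offset: float = 400.0,
    cytoplasm_side: str = "auto",
) -> CortexContour:
    """Refine seed points to the transverse intensity ridge and fit a spline.

    Each seed is moved to the (parabolically refined) maximum of the
    actin intensity along the local normal within
    ``+-search_half_width`` nm; seeds whose refinement diverges farther
    than that are dropped.  For synthetic circular cells
    ``seed_points=None`` auto-seeds from a circle fit.  The normal
    orientation (which side is cytoplasm) is decided by comparing the
    mean intensity of the two sides at ``cytoplasm_offset`` nm from the
    ridge, unless forced with ``cytoplasm_side`` ('positive' keeps the
    left-of-tangent normal, 'negative' flips it).
    """
    if seed_points is None:
        seed_points = _auto_seed_circle(actin_image)
        if closed is None:
            closed = True
    closed = bool(closed) if closed is not None else False
    seeds = np.atleast_2d(np.asarray(seed_points, float))

    # local normal direction at each seed from the seed polyline
    nxt = np.roll(seeds, -1, axis=0) if closed else np.vstack([seeds[1:], seeds[-1:] * 2 - seeds[-2:-1]])
    prv = np.roll(seeds, 1, axis=0) if closed else np.vstack([seeds[:1] * 2 - seeds[1:2], seeds[:-1]])
    tang = nxt - prv
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    norm = np.column_stack([-tang[:, 1], tang[:, 0]])

    step = actin_image.pixel_size
    offsets = np.arange(-search_half_width, search_half_width + step, step)
    # average transverse profiles over a short tangential window to tame
    # localization shot noise on the ridge position
    tang_offsets = np.linspace(-40.0, 40.0, 5)
    pts = (
        seeds[:, None, None, :]
        + offsets[None, None, :, None] * norm[:, None, None, :]
        + tang_offsets[None, :, None, None] * tang[:, None, None, :]
    )
    sampled = sample_image(actin_image, pts)
    finite = np.isfinite(sampled)
    vals = np.where(finite, sampled, 0.0).sum(axis=1) / np.maximum(
        finite.sum(axis=1), 1
    )
    vals[~finite.any(axis=1)] = np.nan

    refined = []
    offs = []
    for i in range(len(seeds)):
        v = vals[i]
        if not np.any(np.isfinite(v)):
            continue
        v = np.where(np.isfinite(v), v, 0.0)
        v = ndimage.gaussian_filter1d(v, 2.0, mode="nearest")
        k = int(np.argmax(v))
        if v[k] <= 0:
            logger.warning("seed %d lies over an empty region; dropped", i)
            continue
        off = offsets[k]
        if 0 < k < len(offsets) - 1:
            denom = v[k - 1] - 2 * v[k] + v[k + 1]
            if abs(denom) > 1e-12:
                off += float(np.clip(0.5 * (v[k - 1] - v[k + 1]) / denom, -0.5, 0.5)) * step
        if abs(off) > search_half_width:
            continue
        refined.append(seeds[i] + off * norm[i])
        offs.append(off)
    if len(refined) < 4:
        raise ValueError("fewer than 4 cortex points survived refinement")
    refined = np.asarray(refined)

    if closed:
        # order by angle around the centroid to guarantee a simple closed loop
        c = refined.mean(axis=0)
        ang = np.arctan2(refined[:, 1] - c[1], refined[:, 0] - c[0])
        order = np.argsort(ang)
        refined = refined[order]
        # light circular smoothing of the ridge positions before the spline
        # fit; residual jitter otherwise broadens every straightened profile
        rad = np.hypot(refined[:, 0] - c[0], refined[:, 1] - c[1])
        kernel = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
        kernel /= kernel.sum()
        rad_s = np.convolve(np.concatenate([rad[-2:], rad, rad[:2]]), kernel, mode="valid")
        theta = np.sort(ang)
        refined = np.column_stack(
            [c[0] + rad_s * np.cos(theta), c[1] + rad_s * np.sin(theta)]
        )

    contour = CortexContour(refined, closed=closed)

    if cytoplasm_side == "positive":
        contour.normal_sign = 1.0
    elif cytoplasm_side == "negative":
        contour.normal_sign = -1.0
    elif closed:
        # the cytoplasm is the interior of a closed equatorial contour
        s = np.linspace(0, contour.length, 16, endpoint=False)
        pos = contour.position(s)
        n = contour.normal(s)
        c = refined.mean(axis=0)
        inward = np.mean(np.sum((c - pos) * n, axis=1))
        if inward < 0:
            contour.normal_sign *= -1.0
    else:
        s = np.linspace(0, contour.length, 32, endpoint=False)
        pos = contour.position(s)
        n = contour.normal(s)
        plus = np.nanmean(sample_image(actin_image, pos + cytoplasm_offset * n))
        minus = np.nanmean(sample_image(actin_image, pos - cytoplasm_offset * n))
        # cytoplasm: dimmer than the ridge but brighter than the outside
        if not (plus >= minus):
            contour.normal_sign *= -1.0
    return contour


# ---------------------------------------------------------------------------
# Straightening and binning
# ---------------------------------------------------------------------------


@dataclass
class StraightenedCortex:
    """Channels resampled in (arc position, signed transverse offset) space."""

    arc_positions: np.ndarray  # (n_rows,) nm along the cortex
    axis: np.ndarray  # (n_cols,) signed nm, + toward cytoplasm
    channels: dict[str, np.ndarray]  # each (n_rows, n_cols)
    valid_rows: np.ndarray  # bool (n_rows,)


def straighten(
    images: dict[str, RenderedImage],
    contour: CortexContour,
    half_width_nm: float = 600.0,
    pitch_nm: float | None = None,
) -> StraightenedCortex:
    """Sample every channel along the contour normals.

    Rows are arc positions at the rendering pixel pitch, columns the
    signed transverse axis; sampling is bilinear.  Rows where a normal
    exits any image are flagged invalid and excluded downstream.
    """
    if pitch_nm is None:
        pitch_nm = min(im.pixel_size for im in images.values())
    arcs = np.arange(0.0, contour.length, pitch_nm)
    axis = np.arange(-half_width_nm, half_width_nm + 0.5 * pitch_nm, pitch_nm)
    pos = contour.position(arcs)
    nrm = contour.normal(arcs)
    pts = pos[:, None, :] + axis[None, :, None] * nrm[:, None, :]
    channels = {}
    valid = np.ones(len(arcs), dtype=bool)
    for name, image in images.items():
        vals = sample_image(image, pts)
        valid &= np.all(np.isfinite(vals), axis=1)
        channels[name] = vals
    n_bad = int((~valid).sum())
    if n_bad:
        logger.info("%d straightened rows exit the image and are flagged", n_bad)
    return StraightenedCortex(arcs, axis, channels, valid)


@dataclass
class TransverseProfileBin:
    """Bin-averaged transverse intensity profiles with their measurements."""

    arc_position: float
    axis: np.ndarray
    profiles: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.axis) > 0):
            raise ValueError("transverse axis must be strictly increasing")


def bin_profiles(
    straightened: StraightenedCortex, bin_width_nm: float = 200.0
) -> list[TransverseProfileBin]:
    """Average straightened rows in consecutive bins along the cortex.

    Bins containing any flagged row are excluded; an incomplete
    trailing bin is dropped.
    """
    arcs = straightened.arc_positions
    if len(arcs) < 2:
        raise ValueError("straightened cortex has fewer than 2 rows")
    pitch = arcs[1] - arcs[0]
    rows_per_bin = max(int(round(bin_width_nm / pitch)), 1)
    n_bins = len(arcs) // rows_per_bin
    bins: list[TransverseProfileBin] = []
    for b in range(n_bins):
        sl = slice(b * rows_per_bin, (b + 1) * rows_per_bin)
        if not np.all(straightened.valid_rows[sl]):
            continue
        profiles = {k: v[sl].mean(axis=0) for k, v in straightened.channels.items()}
        bins.append(
            TransverseProfileBin(float(arcs[sl].mean()), straightened.axis, profiles)
        )
    return bins


# ---------------------------------------------------------------------------
# Profile measurements
# ---------------------------------------------------------------------------


@dataclass
class FWHMResult:
    peak_position: float  # nm on the signed axis
    fwhm_lo: float
    fwhm_hi: float
    background: float
    peak_height: float  # above background

    @property
    def fwhm(self) -> float:
        return self.fwhm_hi - self.fwhm_lo


def measure_fwhm(axis: np.ndarray, profile: np.ndarray) -> FWHMResult:
    """Peak position and FWHM of a transverse intensity profile.

    Background is the mean of the medians of the outer 20% of samples
    on each side; the peak is the maximum after background subtraction
    (parabolically refined); half-maximum crossings are located by
    linear interpolation, taking the innermost crossing bracketing the
    peak on each side.
    """
    axis = np.asarray(axis, float)
    y = np.asarray(profile, float)
    if len(axis) != len(y) or len(y) < 5:
        raise ProfileRejected("profile too short")
    if not np.all(np.isfinite(y)):
        raise ProfileRejected("non-finite samples")
    n_edge = max(int(round(0.2 * len(y))), 1)
    background = 0.5 * (np.median(y[:n_edge]) + np.median(y[-n_edge:]))
    ys = y - background
    k = int(np.argmax(ys))
    if k == 0 or k == len(y) - 1:
        raise ProfileRejected("no interior maximum")
    if ys[k] <= 0:
        raise ProfileRejected("peak not above background")
    peak_pos = axis[k]
    peak_h = ys[k]
    denom = ys[k - 1] - 2 * ys[k] + ys[k + 1]
    if abs(denom) > 1e-12:
        frac = 0.5 * (ys[k - 1] - ys[k + 1]) / denom
        frac = float(np.clip(frac, -0.5, 0.5))
        peak_pos = axis[k] + frac * (axis[min(k + 1, len(y) - 1)] - axis[k])
        peak_h = ys[k] - 0.25 * (ys[k - 1] - ys[k + 1]) * frac
    half = 0.5 * peak_h

    lo = hi = None
    for i in range(k, 0, -1):  # innermost crossing left of the peak
        if ys[i - 1] < half <= ys[i]:
            f = (half - ys[i - 1]) / (ys[i] - ys[i - 1])
            lo = axis[i - 1] + f * (axis[i] - axis[i - 1])
            break
    for i in range(k, len(y) - 1):  # innermost crossing right of the peak
        if ys[i + 1] < half <= ys[i]:
            f = (ys[i] - half) / (ys[i] - ys[i + 1])
            hi = axis[i] + f * (axis[i + 1] - axis[i])
            break
    if lo is None or hi is None:
        raise ProfileRejected("half-maximum crossing missing (truncated profile)")
    return FWHMResult(float(peak_pos), float(lo), float(hi), float(background), float(peak_h))


def peak_to_peak(actin: FWHMResult, target: FWHMResult) -> float:
    """Signed peak offset (nm): positive when the target peak is deeper in the cytoplasm."""
    return target.peak_position - actin.peak_position


def overhang(actin: FWHMResult, target: FWHMResult) -> float:
    """Signed cytoplasmic overhang (%) of the target layer beyond the actin layer.

    With FWHM intervals [a_lo, a_hi] (actin) and [t_lo, t_hi] (target)
    on the signed axis whose ``hi`` edges face the cytoplasm:
    ``100 * (t_hi - a_hi) / (t_hi - t_lo)``.  Negative values indicate a
    cytoplasmic edge retracted toward the membrane.
    """
    width = target.fwhm
    if width <= 0:
        raise ProfileRejected("degenerate target FWHM")
    return 100.0 * (target.fwhm_hi - actin.fwhm_hi) / width


def overhang_symmetric(actin: FWHMResult, target: FWHMResult) -> float:
    """Two-sided non-overlap (%) of the target FWHM interval outside the actin interval."""
    width = target.fwhm
    if width <= 0:
        raise ProfileRejected("degenerate target FWHM")
    outside = max(actin.fwhm_lo - target.fwhm_lo, 0.0) + max(
        target.fwhm_hi - actin.fwhm_hi, 0.0
    )
    return 100.0 * outside / width


@dataclass
class OverhangResult:
    """Per-cell summary of the actin/target transverse-profile comparison."""

    mean_actin_fwhm: float
    mean_target_fwhm: float
    mean_peak_to_peak: float
    mean_overhang: float
    n_bins_accepted: int
    n_bins_total: int
    per_bin: list[dict]
    rejections: dict[str, int]


def aggregate_cell(
    bins: list[TransverseProfileBin],
    actin_channel: str = "actin",
    target_channel: str = "target",
    min_bins: int = 3,
    statistic: str = "mean",
) -> OverhangResult:
    """Measure every bin and average accepted bins into per-cell statistics."""
    rows: list[dict] = []
    rejections: dict[str, int] = {}
    for b in bins:
        try:
            a = measure_fwhm(b.axis, b.profiles[actin_channel])
            t = measure_fwhm(b.axis, b.profiles[target_channel])
            rows.append(
                {
                    "arc_position": b.arc_position,
                    "actin_fwhm": a.fwhm,
                    "target_fwhm": t.fwhm,
                    "peak_to_peak": peak_to_peak(a, t),
                    "overhang": overhang(a, t),
                }
            )
        except ProfileRejected as exc:
            rejections[exc.reason] = rejections.get(exc.reason, 0) + 1
    if len(rows) < min_bins:
        raise ValueError(
            f"only {len(rows)} accepted bins (<{min_bins}); cell excluded"
        )
    agg = np.median if statistic == "median" else np.mean
    return OverhangResult(
        mean_actin_fwhm=float(agg([r["actin_fwhm"] for r in rows])),
        mean_target_fwhm=float(agg([r["target_fwhm"] for r in rows])),
        mean_peak_to_peak=float(agg([r["peak_to_peak"] for r in rows])),
        mean_overhang=float(agg([r["overhang"] for r in rows])),
        n_bins_accepted=len(rows),
        n_bins_total=len(bins),
        per_bin=rows,
        rejections=rejections,
    )


def analyze_cortex(
    images: dict[str, RenderedImage],
    actin_channel: str = "actin",
    target_channel: str = "target",
    half_width_nm: float = 600.0,
    bin_width_nm: float = 200.0,
    seed_points: np.ndarray | None = None,
) -> OverhangResult:
    """Convenience pipeline: detect -> straighten -> bin -> aggregate one cell."""
    contour = detect_cortex(images[actin_channel], seed_points=seed_points)
    st = straighten(images, contour, half_width_nm=half_width_nm)
    bins = bin_profiles(st, bin_width_nm=bin_width_nm)
    return aggregate_cell(bins, actin_channel, target_channel)


def curvature_broadening_bound(cell_radius_nm: float, slab_thickness_nm: float) -> float:
    """Worst-case FWHM inflation (nm) from out-of-plane shell curvature.

    For a spherical shell of radius R imaged in a focal slab of the
    given thickness centred on the equator, fluorophores at the slab
    edge project inward by ``R - sqrt(R^2 - (slab/2)^2)``; assuming the
    worst case on both profile edges the measured FWHM can grow by at
    most twice that.
    """
    if slab_thickness_nm < 0:
        raise ValueError("slab thickness must be >= 0")
    if cell_radius_nm <= slab_thickness_nm / 2:
        raise ValueError("cell radius must exceed half the slab thickness")
    half = slab_thickness_nm / 2.0
    return 2.0 * (cell_radius_nm - np.sqrt(cell_radius_nm**2 - half**2))
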