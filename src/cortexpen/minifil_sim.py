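"""Bipolar myosin minifilament detection in two-channel SIM images.

Nonmuscle myosin II assembles into ~300 nm bipolar minifilaments whose
motor heads sit at both ends and whose tails overlap in the middle.
With heads and tails labelled in different channels, a minifilament
appears as two head spots flanking one tail spot.  The pipeline here:

1. homogenize the background (subtract a large-radius Gaussian blur),
2. deconvolve (Richardson-Lucy),
3. threshold at 3x the SD of a cell-free background area and erode
   isolated noise pixels,
4. detect 8-neighbour local maxima refined to 5x5-ROI centroids,
5. pair head peaks separated by 200-400 nm and validate each pair by a
   tail peak within 50 nm of its midpoint.

The in-plane head-to-head distance (projected length ``L_proj``) of a
filament tilted out of plane by an angle theta equals
``L_ref * cos(theta)``, so mean projected lengths convert to mean
membrane angles via ``theta = arccos(L_proj / L_ref)`` and, if every
minifilament contributes to cortical tension in proportion to
``cos(theta)``, an angle change converts to a relative tension change
``100 * (cos(theta_after) / cos(theta_before) - 1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Image conditioning
# ---------------------------------------------------------------------------


def homogenize_background(image: np.ndarray, gaussian_radius_px: float = 500.0) -> np.ndarray:
    """Subtract the large-radius Gaussian blur of the image; clip at zero.

    The blur radius must be much larger than the filament scale so spot
    contrast is preserved while slow background inhomogeneity is
    removed.
    """
    image = np.asarray(image, float)
    background = ndimage.gaussian_filter(image, gaussian_radius_px, mode="nearest")
    return np.clip(image - background, 0.0, None)


def _gaussian_psf(sigma_px: float, radius_factor: float = 4.0) -> np.ndarray:
    r = max(int(np.ceil(radius_factor * sigma_px)), 1)
    ax = np.arange(-r, r + 1)
    g = np.exp(-0.5 * (ax / sigma_px) ** 2)
    psf = np.outer(g, g)
    return psf / psf.sum()


def deconvolve(
    image: np.ndarray, psf_sigma_px: float, iterations: int = 20
) -> np.ndarray:
    """Richardson-Lucy deconvolution with a Gaussian PSF.

    Iterations stop early with a warning if the estimate norm starts
    growing without bound (divergence guard).
    """
    if psf_sigma_px <= 0:
        raise ValueError("psf_sigma_px must be positive")
    image = np.clip(np.asarray(image, float), 0.0, None)
    psf = _gaussian_psf(psf_sigma_px)
    psf_flip = psf[::-1, ::-1]
    # reflect-pad so the truncated kernel at the borders does not drive
    # spurious intensity growth; crop back at the end
    pad = psf.shape[0] // 2
    padded = np.pad(image, pad, mode="reflect")
    est = np.full_like(padded, max(image.mean(), 1e-12))
    prev_norm = np.inf
    for it in range(iterations):
        conv = fftconvolve(est, psf, mode="same")
        ratio = padded / np.maximum(conv, 1e-12)
        est = est * fftconvolve(ratio, psf_flip, mode="same")
        est = np.clip(est, 0.0, None)
        norm = float(np.linalg.norm(est))
        if norm > 10.0 * prev_norm:
            logger.warning("Richardson-Lucy diverging at iteration %d; stopping", it)
            break
        prev_norm = max(norm, 1e-12)
    return est[pad:-pad, pad:-pad] if pad else est


def threshold_and_clean(image: np.ndarray, background_roi: np.ndarray) -> np.ndarray:
    """Zero values below 3x the background-ROI SD and erode isolated pixels.

    ``background_roi`` is a boolean mask (or index tuple) selecting a
    cell-free area; the binary support of the thresholded image is
    eroded with a 3x3 structuring element and surviving intensities are
    retained.
    """
    image = np.asarray(image, float)
    bg = image[background_roi]
    if bg.size == 0:
        raise ValueError("background ROI is empty")
    thr = 3.0 * float(np.std(bg))
    above = image > thr
    support = ndimage.binary_erosion(above, structure=np.ones((3, 3)))
    out = np.where(support, image, 0.0)
    return out


# ---------------------------------------------------------------------------
# Peak detection and pairing
# ---------------------------------------------------------------------------


def detect_peaks(
    image: np.ndarray,
    pixel_size_nm: float,
    roi_half_px: int = 2,
    merge_radius_px: float = 1.0,
) -> np.ndarray:
    """Strict 8-neighbour local maxima refined to 5x5 intensity centroids.

    Returns (n, 2) peak positions in nm (x, y).  Plateaus of exactly
    equal pixels have no strict maximum; the first pixel in scan order
    is kept and flagged in the log.  Refined duplicates within
    ``merge_radius_px`` are merged.
    """
    img = np.asarray(image, float)
    footprint = np.ones((3, 3), bool)
    footprint[1, 1] = False
    neigh_max = ndimage.maximum_filter(img, footprint=footprint, mode="constant", cval=-np.inf)
    strict = (img > neigh_max) & (img > 0)
    # plateau handling: equal-neighbour maxima kept once, in scan order
    plateau = (img == neigh_max) & (img > 0)
    if np.any(plateau):
        labels, n_lab = ndimage.label(plateau)
        if n_lab:
            logger.info("%d intensity plateau(s) resolved by scan order", n_lab)
            for lab in range(1, n_lab + 1):
                rr, cc = np.nonzero(labels == lab)
                strict[rr[0], cc[0]] = True
    peaks = []
    h, w = img.shape
    for r, c in zip(*np.nonzero(strict)):
        r0, r1 = max(r - roi_half_px, 0), min(r + roi_half_px + 1, h)
        c0, c1 = max(c - roi_half_px, 0), min(c + roi_half_px + 1, w)
        roi = img[r0:r1, c0:c1]
        tot = roi.sum()
        if tot <= 0:
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        peaks.append(((cc * roi).sum() / tot, (rr * roi).sum() / tot))
    if not peaks:
        return np.empty((0, 2))
    peaks = np.asarray(peaks)
    # merge refined duplicates within merge_radius_px
    kept: list[np.ndarray] = []
    for p in peaks:
        if kept and np.min(np.linalg.norm(np.asarray(kept) - p, axis=1)) <= merge_radius_px:
            continue
        kept.append(p)
    return (np.asarray(kept) + 0.5) * pixel_size_nm


@dataclass
class MinifilamentRecord:
    """A validated (or candidate) head pair with its tail geometry."""

    head1: np.ndarray  # (x, y) nm
    head2: np.ndarray
    tail: np.ndarray | None
    projected_length: float  # nm
    validated: bool

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (np.asarray(self.head1) + np.asarray(self.head2))


def pair_and_validate(
    green_peaks: np.ndarray,
    red_peaks: np.ndarray,
    d_min: float = 200.0,
    d_max: float = 400.0,
    tail_radius: float = 50.0,
    resolve_conflicts: bool = False,
) -> list[MinifilamentRecord]:
    """All head pairs separated by [d_min, d_max] nm, validated by a nearby tail.

    A candidate is validated iff some red (tail) peak lies within
    ``tail_radius`` nm of the pair midpoint.  By default a head may
    belong to several candidates (all-pairs rule); with
    ``resolve_conflicts`` candidates are accepted greedily by tail
    distance and each head used once.
    """
    green = np.atleast_2d(np.asarray(green_peaks, float)) if len(green_peaks) else np.empty((0, 2))
    red = np.atleast_2d(np.asarray(red_peaks, float)) if len(red_peaks) else np.empty((0, 2))
    records: list[tuple[float, int, int, MinifilamentRecord]] = []
    for i in range(len(green)):
        for j in range(i + 1, len(green)):
            d = float(np.linalg.norm(green[i] - green[j]))
            if not (d_min <= d <= d_max):
                continue
            mid = 0.5 * (green[i] + green[j])
            tail = None
            tail_d = np.inf
            if len(red):
                dists = np.linalg.norm(red - mid, axis=1)
                k = int(np.argmin(dists))
                if dists[k] <= tail_radius:
                    tail = red[k]
                    tail_d = float(dists[k])
            rec = MinifilamentRecord(green[i], green[j], tail, d, tail is not None)
            records.append((tail_d, i, j, rec))
    if not resolve_conflicts:
        return [r for *_, r in records]
    used: set[int] = set()
    out = []
    for tail_d, i, j, rec in sorted(records, key=lambda t: t[0]):
        if not rec.validated or i in used or j in used:
            continue
        used.update((i, j))
        out.append(rec)
    return out


def detect_minifilaments(
    head_image: np.ndarray,
    tail_image: np.ndarray,
    pixel_size_nm: float,
    psf_sigma_nm: float,
    background_roi: np.ndarray,
    gaussian_radius_px: float = 500.0,
    deconvolve_iterations: int = 20,
    d_min: float = 200.0,
    d_max: float = 400.0,
    tail_radius: float = 50.0,
    edge_margin_nm: float | None = None,
) -> list[MinifilamentRecord]:
    """Full detection pipeline on a two-channel SIM image.

    ``edge_margin_nm`` (default ``d_max``) excludes peaks near the image
    border, where the analysis is unreliable.
    """
    margin = d_max if edge_margin_nm is None else edge_margin_nm
    peaks = {}
    for name, img in (("head", head_image), ("tail", tail_image)):
        x = homogenize_background(img, gaussian_radius_px)
        x = deconvolve(x, psf_sigma_nm / pixel_size_nm, deconvolve_iterations)
        x = threshold_and_clean(x, background_roi)
        pts = detect_peaks(x, pixel_size_nm)
        if len(pts):
            lim_x = head_image.shape[1] * pixel_size_nm
            lim_y = head_image.shape[0] * pixel_size_nm
            keep = (
                (pts[:, 0] > margin)
                & (pts[:, 0] < lim_x - margin)
                & (pts[:, 1] > margin)
                & (pts[:, 1] < lim_y - margin)
            )
            pts = pts[keep]
        peaks[name] = pts
    return [
        r
        for r in pair_and_validate(peaks["head"], peaks["tail"], d_min, d_max, tail_radius)
        if r.validated
    ]


# ---------------------------------------------------------------------------
# Length / angle / tension statistics
# ---------------------------------------------------------------------------

L_REF_STRESS_FIBER_NM = 317.0  # mean projected length in stress fibers
L_REF_EM_NM = 330.0  # electron-microscopy minifilament length (alternative)


def projected_length_stats(
    records: list[MinifilamentRecord],
    cell_ids=None,
    min_records: int = 1,
) -> dict:
    """Per-cell mean and SD of validated projected lengths.

    ``cell_ids`` assigns each record to a cell (all one cell if None);
    cells with fewer than ``min_records`` records are flagged.
    """
    if not records:
        raise ValueError("no minifilament records")
    lengths = np.array([r.projected_length for r in records])
    ids = np.zeros(len(records), int) if cell_ids is None else np.asarray(cell_ids)
    out = {}
    for cid in np.unique(ids):
        vals = lengths[ids == cid]
        out[int(cid)] = {
            "mean_nm": float(vals.mean()),
            "sd_nm": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            "n": int(len(vals)),
            "flagged": bool(len(vals) < min_records),
        }
    return out


def angle_from_projection(l_proj_nm: float, l_ref_nm: float = L_REF_STRESS_FIBER_NM) -> float:
    """Out-of-plane angle (degrees) implied by a projected length."""
    if not (0 < l_proj_nm <= l_ref_nm):
        raise ValueError(
            "projected length must be in (0, L_ref]; consider a larger reference length"
        )
    return float(np.degrees(np.arccos(l_proj_nm / l_ref_nm)))


def tension_change_from_angles(theta_before_deg: float, theta_after_deg: float) -> float:
    """Relative cortical-tension change (%) under the equal-contribution cosine model.

    ``100 * (cos(theta_after) / cos(theta_before) - 1)``; at fixed
    reference length this equals the relative change in mean projected
    length.
    """
    for th in (theta_before_deg, theta_after_deg):
        if not (0 <= th < 90):
            raise ValueError("angles must lie in [0, 90) degrees")
    cb = np.cos(np.radians(theta_before_deg))
    ca = np.cos(np.radians(theta_after_deg))
    return float(100.0 * (ca / cb - 1.0))
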