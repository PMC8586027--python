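"""Confocal cortex quantification: segmentation, cortical intensity, thickness fits.

Two parts:

* Image pipeline — rolling-ball background subtraction, two independent
  segmentation routes (empty-region threshold; Sobel edges + watershed),
  per-cell selection of the candidate whose contour carries the highest
  total signal, cortical-band intensity within an 8-px band centred on
  the outline, and correction for unspecific staining via a
  secondary-only control.

* Linescan fitting — the transverse intensity profile across the cortex
  is modelled as a piecewise-constant density (extracellular level
  ``i_out``, cortical level ``i_cort`` over a slab of thickness
  ``h_actin`` starting at the membrane position ``X_m``, cytoplasmic
  level ``i_in``) convolved with a Gaussian PSF of width ``sigma_psf``.
  Myosin is modelled as a step of width ``h_myo`` whose cytoplasmic
  edge is pinned to the cytoplasmic edge of the actin slab; the
  membrane-side gap ``h_actin - h_myo`` is the myosin-free cortex
  length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.special import ndtr
from skimage import feature, filters, morphology, restoration, segmentation

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Background subtraction and segmentation
# ---------------------------------------------------------------------------


def subtract_background_rollingball(image: np.ndarray, radius_px: float = 50.0) -> np.ndarray:
    """Rolling-ball background subtraction; output clipped at zero.

    The ball radius must be large relative to the cortex width (~8 px)
    so the band itself is not absorbed into the background estimate.
    """
    image = np.asarray(image, float)
    background = restoration.rolling_ball(image, radius=radius_px)
    return np.clip(image - background, 0.0, None)


PRESMOOTH_SIGMA_PX = 1.5  # light denoising before either segmentation route
BOUNDARY_ERODE_PX = 2  # pulls mask boundaries back onto the membrane ridge


def segment_threshold(
    image: np.ndarray, empty_region: np.ndarray, min_area_px: int = 500
) -> list[np.ndarray]:
    """Threshold at mean+SD of a cell-free region; return filled candidate masks.

    Deliberately simple (no smoothing): precise at high SNR, ragged at
    low SNR — the edge-based route and the per-cell candidate selection
    compensate there.
    """
    image = np.asarray(image, float)
    bg = image[empty_region]
    if bg.size == 0:
        raise ValueError("empty_region selects no pixels")
    thr = float(np.mean(bg) + np.std(bg))
    binary = ndimage.binary_fill_holes(image > thr)
    labels, n = ndimage.label(binary)
    masks = []
    for lab in range(1, n + 1):
        m = labels == lab
        if m.sum() >= min_area_px:
            masks.append(m)
    return masks


def _remove_small(mask: np.ndarray, min_area_px: int) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_area_px
    keep[0] = False
    return keep[labels]


def segment_edges(image: np.ndarray, min_area_px: int = 500) -> list[np.ndarray]:
    """Sobel edge map -> fill holes -> clean -> watershed split of touching cells."""
    image = ndimage.gaussian_filter(np.asarray(image, float), PRESMOOTH_SIGMA_PX)
    grad = filters.sobel(image)
    if not np.any(grad > 0):
        return []
    try:
        thr = filters.threshold_otsu(grad)
    except ValueError:
        return []
    edges = grad > thr
    edges = morphology.closing(edges, morphology.disk(2))
    filled = ndimage.binary_fill_holes(edges)
    filled = _remove_small(filled, min_area_px)
    filled = morphology.opening(filled, morphology.disk(2))
    # the filled edge band extends ~half its width beyond the true
    # boundary; pull it back onto the gradient ridge
    filled = ndimage.binary_erosion(filled, morphology.disk(BOUNDARY_ERODE_PX))
    if not filled.any():
        return []
    dist = ndimage.distance_transform_edt(filled)
    coords = feature.peak_local_max(
        dist, labels=filled, min_distance=7, exclude_border=False
    )
    markers = np.zeros_like(dist, dtype=int)
    for k, (r, c) in enumerate(coords, start=1):
        markers[r, c] = k
    if markers.max() == 0:
        labels, _ = ndimage.label(filled)
    else:
        labels = segmentation.watershed(-dist, markers, mask=filled)
    masks = []
    outside_mean = float(image[~filled].mean()) if (~filled).any() else 0.0
    outside_sd = float(image[~filled].std()) if (~filled).any() else 0.0
    for lab in range(1, labels.max() + 1):
        m = _remove_small(labels == lab, min_area_px)
        # a genuine cell is brighter inside than the surroundings; lacy
        # pure-noise edge artifacts are not
        if m.any() and float(image[m].mean()) > outside_mean + outside_sd:
            masks.append(m)
    return masks


@dataclass
class CellSegmentation:
    """Winning mask for one cell with its cortex outline and band boundaries."""

    mask: np.ndarray
    centroid: tuple[float, float]  # (row, col)
    outline: np.ndarray  # bool mask of the cortex centre line
    outer_boundary: np.ndarray  # bool mask (dilated boundary)
    inner_boundary: np.ndarray  # bool mask (eroded boundary)
    provenance: str


def _boundary(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask)


def _make_segmentation(mask: np.ndarray, provenance: str) -> CellSegmentation:
    # cortex band edges from dilated (5 px) and eroded (3 px) masks
    outer = _boundary(ndimage.binary_dilation(mask, morphology.disk(5)))
    inner = _boundary(ndimage.binary_erosion(mask, morphology.disk(3)))
    r, c = np.nonzero(mask)
    return CellSegmentation(
        mask=mask,
        centroid=(float(r.mean()), float(c.mean())),
        outline=_boundary(mask),
        outer_boundary=outer,
        inner_boundary=inner,
        provenance=provenance,
    )


def select_best_segmentation(
    image: np.ndarray,
    candidates_by_method: dict[str, list[np.ndarray]],
    grouping_distance_px: float = 20.0,
) -> list[CellSegmentation]:
    """Group candidate masks by centroid and keep the brightest-contour one per cell."""
    entries = []
    # score on a lightly smoothed image: a ragged contour threading bright
    # noise pixels must not outscore an on-ridge contour
    image = ndimage.gaussian_filter(np.asarray(image, float), PRESMOOTH_SIGMA_PX)
    for method, masks in candidates_by_method.items():
        for m in masks:
            r, c = np.nonzero(m)
            if len(r) == 0:
                continue
            outline = _boundary(m)
            # mean rather than total contour intensity: a total rewards
            # long ragged contours over tight on-ridge ones
            score = float(image[outline].mean())
            entries.append(((r.mean(), c.mean()), score, m, method))
    groups: list[list[int]] = []
    for i, (cen, *_rest) in enumerate(entries):
        for g in groups:
            c0 = entries[g[0]][0]
            if np.hypot(cen[0] - c0[0], cen[1] - c0[1]) <= grouping_distance_px:
                g.append(i)
                break
        else:
            groups.append([i])
    out = []
    for g in groups:
        best = max(g, key=lambda i: entries[i][1])
        _, _, mask, method = entries[best]
        out.append(_make_segmentation(mask, method))
    return out


def segment_cells(
    image: np.ndarray,
    empty_region: np.ndarray,
    grouping_distance_px: float = 20.0,
    min_area_px: int = 500,
) -> list[CellSegmentation]:
    """Run both segmentation routes and pick the best candidate per cell."""
    candidates = {
        "threshold": segment_threshold(image, empty_region, min_area_px),
        "edges": segment_edges(image, min_area_px),
    }
    return select_best_segmentation(image, candidates, grouping_distance_px)


def cortical_band_intensity(
    image: np.ndarray, seg: CellSegmentation, band_px: int = 8
) -> float:
    """Mean intensity within a band of ``band_px`` thickness centred on the outline."""
    band = ndimage.binary_dilation(seg.outline, morphology.disk(band_px // 2))
    h, w = image.shape
    rr, cc = np.nonzero(seg.outline)
    if (rr.min() < band_px or cc.min() < band_px
            or rr.max() >= h - band_px or cc.max() >= w - band_px):
        logger.warning("cortical band touches the image border; value flagged partial")
    return float(np.asarray(image, float)[band].mean())


def correct_unspecific(values: np.ndarray, control_values: np.ndarray) -> np.ndarray:
    """Subtract the mean unspecific-staining control signal from each value."""
    control = np.asarray(control_values, float)
    if control.size == 0:
        raise ValueError("control values are empty")
    corrected = np.asarray(values, float) - control.mean()
    if np.any(corrected < 0):
        logger.warning("%d corrected intensity value(s) are negative", int((corrected < 0).sum()))
    return corrected


# ---------------------------------------------------------------------------
# Step-convolution linescan fitting
# ---------------------------------------------------------------------------


def step_convolution_model(
    x: np.ndarray,
    x_m: float,
    h: float,
    i_out: float,
    i_cort: float,
    i_in: float,
    sigma_psf: float,
) -> np.ndarray:
    """Piecewise-constant cortex density convolved with a Gaussian PSF.

    Density is ``i_out`` for x < x_m, ``i_cort`` on [x_m, x_m + h) and
    ``i_in`` beyond; x increases toward the cytoplasm.  With sigma_psf
    <= 0 the unconvolved step profile is returned.
    """
    x = np.asarray(x, float)
    if sigma_psf <= 0:
        return np.where(x < x_m, i_out, np.where(x < x_m + h, i_cort, i_in))
    phi1 = ndtr((x - x_m) / sigma_psf)
    phi2 = ndtr((x - (x_m + h)) / sigma_psf)
    return i_out + (i_cort - i_out) * phi1 + (i_in - i_cort) * phi2


def myosin_step_model(
    x: np.ndarray,
    inner_edge: float,
    h_myo: float,
    i_out: float,
    i_myo: float,
    i_in: float,
    sigma_psf: float,
) -> np.ndarray:
    """Myosin slab of width h_myo whose cytoplasmic edge sits at ``inner_edge``."""
    return step_convolution_model(
        x, inner_edge - h_myo, h_myo, i_out, i_myo, i_in, sigma_psf
    )


@dataclass
class StepConvolutionFit:
    """Fitted membrane position and layer thicknesses from a linescan."""

    x_m: float  # membrane position, nm
    h_actin: float  # actin cortex thickness, nm
    i_out: float
    i_cort: float
    i_in: float
    sigma_psf: float
    residual_rms: float
    h_myo: float | None = None
    i_myo: float | None = None
    clipped: bool = False

    @property
    def myosin_free_length(self) -> float | None:
        if self.h_myo is None:
            return None
        return self.h_actin - self.h_myo


def fit_actin_linescan(
    distances: np.ndarray,
    intensities: np.ndarray,
    sigma_psf: float = 170.0,
    h_starts: np.ndarray | None = None,
    h_bounds: tuple[float, float] = (10.0, 500.0),
) -> StepConvolutionFit:
    """Least-squares step-convolution fit of an actin linescan.

    Free parameters: membrane position ``X_m``, cortex thickness
    ``h_actin``, cortical and intracellular levels; the extracellular
    level is estimated from the extracellular tail.  A multistart over
    ``h in {50, 100, ..., 400}`` nm keeps the best-residual solution;
    ``h_bounds`` restricts the thickness to the physically plausible
    range (the wide-PSF fit is otherwise free to run along the flat
    (h, i_cort) trade-off ridge).  The linescan must cross the cortex
    once with the extracellular side at small x.
    """
    x = np.asarray(distances, float)
    y = np.asarray(intensities, float)
    if sigma_psf <= 0:
        raise ValueError("sigma_psf must be positive")
    if len(x) != len(y) or len(x) < 8:
        raise ValueError("linescan too short")
    n_tail = max(int(0.1 * len(x)), 3)
    i_out0 = float(np.median(y[:n_tail]))
    i_in0 = float(np.median(y[-n_tail:]))
    peak_idx = int(np.argmax(y))
    peak = float(y[peak_idx])
    if h_starts is None:
        h_starts = np.arange(50.0, 401.0, 50.0)

    span = x[-1] - x[0]
    best = None
    for h0 in h_starts:
        p0 = np.array([x[peak_idx] - h0 / 2, h0, peak, i_in0])
        try:
            res = least_squares(
                lambda p: step_convolution_model(x, p[0], p[1], i_out0, p[2], p[3], sigma_psf) - y,
                p0,
                bounds=(
                    [x[0] - span, h_bounds[0], 0.0, 0.0],
                    [x[-1] + span, h_bounds[1], 10 * max(peak, 1e-9), 10 * max(peak, 1e-9)],
                ),
                method="trf",
            )
        except ValueError:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError("step-convolution fit did not converge from any start")
    x_m, h, i_cort, i_in = best.x
    i_out = i_out0
    rms = float(np.sqrt(np.mean(best.fun**2)))
    return StepConvolutionFit(
        x_m=float(x_m), h_actin=float(h), i_out=float(i_out),
        i_cort=float(i_cort), i_in=float(i_in), sigma_psf=float(sigma_psf),
        residual_rms=rms,
    )


def fit_myosin_penetration(
    distances: np.ndarray,
    myosin_intensities: np.ndarray,
    actin_fit: StepConvolutionFit,
    sigma_psf: float | None = None,
) -> StepConvolutionFit:
    """Fit the myosin penetration depth with the cytoplasmic edge pinned to actin.

    The myosin density is a slab of width ``h_myo`` ending at
    ``X_m + h_actin`` (the cytoplasmic edge of the actin cortex); free
    parameters are ``h_myo`` and the three intensity levels.  Returns a
    fit whose ``myosin_free_length`` is ``h_actin - h_myo``; an
    ``h_myo`` exceeding ``h_actin`` is clipped with a warning (full
    penetration).
    """
    x = np.asarray(distances, float)
    y = np.asarray(myosin_intensities, float)
    sigma = actin_fit.sigma_psf if sigma_psf is None else sigma_psf
    inner_edge = actin_fit.x_m + actin_fit.h_actin
    n_tail = max(int(0.1 * len(x)), 3)
    i_out0 = float(np.median(y[:n_tail]))
    i_in0 = float(np.median(y[-n_tail:]))
    peak = float(y.max())
    if peak - max(i_out0, i_in0) <= 0:
        raise RuntimeError("no myosin signal above background; fit rejected")
    span = x[-1] - x[0]

    best = None
    for h0 in np.arange(25.0, actin_fit.h_actin + 26.0, 25.0):
        p0 = np.array([h0, peak, i_in0, i_out0])
        res = least_squares(
            lambda p: myosin_step_model(x, inner_edge, p[0], p[3], p[1], p[2], sigma) - y,
            p0,
            bounds=([1.0, 0.0, 0.0, 0.0], [span, 10 * peak, 10 * peak, 10 * peak]),
            method="trf",
        )
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError("myosin penetration fit did not converge")
    h_myo, i_myo, i_in, i_out = best.x
    clipped = False
    if h_myo > actin_fit.h_actin:
        logger.warning(
            "fitted h_myo %.1f nm exceeds h_actin %.1f nm; clipped (full penetration)",
            h_myo, actin_fit.h_actin,
        )
        h_myo = actin_fit.h_actin
        clipped = True
    rms = float(np.sqrt(np.mean(best.fun**2)))
    return StepConvolutionFit(
        x_m=actin_fit.x_m, h_actin=actin_fit.h_actin, i_out=float(i_out),
        i_cort=actin_fit.i_cort, i_in=float(i_in), sigma_psf=float(sigma),
        residual_rms=rms, h_myo=float(h_myo), i_myo=float(i_myo), clipped=clipped,
    )
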