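"""Synthetic data generators with recorded ground truth.

Every downstream stage of the pipeline is exercised on data produced
here: two-channel SMLM localization tables of an equatorial cell cortex
(with injected drift, chromatic distortion and fiducial beads),
two-channel SIM-like images of bipolar minifilaments, confocal
transverse linescans built from the same step-convolution forward model
the fitter uses, ring-cell confocal images, and AFM force-time curves.
All generators are deterministic given (spec, seed) and return a
ground-truth record alongside the data.

Conventions: continuous coordinates in nm with the origin at the
corner of image pixel (0, 0); the signed transverse axis across the
cortex is positive toward the cytoplasm, so a band's "depth" is its
distance inward from the membrane.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .confocal_quant import myosin_step_model, step_convolution_model
from .smlm_core import AffineTransform2D

logger = logging.getLogger(__name__)

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


# ---------------------------------------------------------------------------
# SMLM cortex scenes
# ---------------------------------------------------------------------------


@dataclass
class BandSpec:
    """A cortical layer: depth of its centre below the membrane, FWHM, count."""

    depth_nm: float  # band centre, nm inward from the membrane (+ = cytoplasm)
    fwhm_nm: float
    n_localizations: int

    def __post_init__(self) -> None:
        if self.fwhm_nm <= 0:
            raise ValueError("band FWHM must be positive")
        if self.n_localizations <= 0:
            raise ValueError("localization count must be positive")

    @property
    def interval(self) -> tuple[float, float]:
        """True FWHM interval on the signed depth axis (+ toward cytoplasm)."""
        return (self.depth_nm - self.fwhm_nm / 2, self.depth_nm + self.fwhm_nm / 2)


def true_overhang(actin: BandSpec, target: BandSpec) -> float:
    """Signed cytoplasmic overhang (%) implied by the two true FWHM intervals.

    ``100 * (t_hi - a_hi) / (t_hi - t_lo)`` with ``hi`` the cytoplasmic
    edge — interval arithmetic on the generative parameters.
    """
    a_lo, a_hi = actin.interval
    t_lo, t_hi = target.interval
    return 100.0 * (t_hi - a_hi) / (t_hi - t_lo)


def linear_drift(n_frames: int, total_nm: tuple[float, float]) -> np.ndarray:
    """Cumulative linear drift reaching ``total_nm`` at the last frame."""
    ramp = np.linspace(0.0, 1.0, n_frames)
    return np.outer(ramp, np.asarray(total_nm, float))


def sinusoidal_drift(
    n_frames: int, amplitude_nm: float, period_frames: float
) -> np.ndarray:
    """Sinusoidal drift of the given amplitude, out of phase between axes."""
    t = np.arange(n_frames)
    w = 2 * np.pi / period_frames
    return np.column_stack(
        [amplitude_nm * np.sin(w * t), amplitude_nm * (1 - np.cos(w * t))]
    )


@dataclass
class CortexSceneSpec:
    """Two-channel equatorial cortex scene for SMLM generation."""

    cell_center: tuple[float, float] = (3000.0, 3000.0)  # nm
    cell_radius: float = 2500.0  # nm (membrane)
    actin_band: BandSpec = field(default_factory=lambda: BandSpec(100.0, 200.0, 15000))
    target_band: BandSpec = field(default_factory=lambda: BandSpec(100.0, 200.0, 15000))
    uncertainty_mean: float = 20.0  # nm
    uncertainty_sd: float = 10.0  # nm, truncated at > 0
    n_frames: int = 20000
    drift: np.ndarray | None = None  # (n_frames, 2) cumulative nm, or None
    chromatic_affine: AffineTransform2D | None = None  # applied to target channel
    beads: np.ndarray | None = None  # (n, 2) nm, always-on fiducials
    bead_jitter_nm: float = 3.0

    def __post_init__(self) -> None:
        if self.cell_radius <= 0:
            raise ValueError("cell radius must be positive")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        if self.drift is not None:
            self.drift = np.asarray(self.drift, float)
            if self.drift.shape != (self.n_frames, 2):
                raise ValueError("drift must have shape (n_frames, 2)")


@dataclass
class CortexGroundTruth:
    actin_band: BandSpec
    target_band: BandSpec
    overhang_percent: float
    peak_to_peak_nm: float
    drift: np.ndarray  # (n_frames, 2)
    chromatic_affine: AffineTransform2D | None
    beads: np.ndarray
    cell_center: tuple[float, float]
    cell_radius: float


ACTIN_CHANNEL = 1
TARGET_CHANNEL = 2


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    out = rng.normal(mean, sd, n)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
    return out


def _band_localizations(
    rng: np.random.Generator, spec: CortexSceneSpec, band: BandSpec, channel: int
) -> pd.DataFrame:
    n = band.n_localizations
    phi = rng.uniform(0, 2 * np.pi, n)
    radius = spec.cell_radius - band.depth_nm  # deeper band -> smaller radius
    r = radius + rng.normal(0.0, band.fwhm_nm / FWHM_PER_SIGMA, n)
    x = spec.cell_center[0] + r * np.cos(phi)
    y = spec.cell_center[1] + r * np.sin(phi)
    unc = _truncated_normal(rng, spec.uncertainty_mean, spec.uncertainty_sd, n)
    x += rng.normal(0.0, unc)
    y += rng.normal(0.0, unc)
    frames = rng.integers(0, spec.n_frames, n)
    return pd.DataFrame(
        {
            "frame": frames,
            "x": x,
            "y": y,
            "uncertainty": unc,
            "intensity": rng.gamma(5.0, 200.0, n),
            "channel": channel,
        }
    )


def _bead_localizations(
    rng: np.random.Generator, spec: CortexSceneSpec, channel: int
) -> pd.DataFrame:
    beads = np.atleast_2d(np.asarray(spec.beads, float))
    n_b = len(beads)
    frames = np.repeat(np.arange(spec.n_frames), n_b)
    pos = np.tile(beads, (spec.n_frames, 1))
    pos = pos + rng.normal(0.0, spec.bead_jitter_nm, pos.shape)
    return pd.DataFrame(
        {
            "frame": frames,
            "x": pos[:, 0],
            "y": pos[:, 1],
            "uncertainty": np.full(len(pos), max(spec.bead_jitter_nm, 1.0)),
            "intensity": np.full(len(pos), 20000.0),
            "channel": channel,
        }
    )


def gen_smlm_cortex(
    spec: CortexSceneSpec, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, CortexGroundTruth]:
    """Generate the two-channel SMLM cortex scene.

    Localizations are drawn on an annular band (uniform angular
    position; Gaussian radial position with the stated FWHM about the
    band centre), each molecule appearing in one random frame with its
    own localization uncertainty (truncated normal) applied as
    positional noise.  Cumulative drift is added per frame, the
    chromatic affine distortion is applied to the target channel only,
    and always-on fiducial beads appear in every frame of both
    channels.  Returns (actin table, target table, ground truth).
    """
    rng = np.random.default_rng(seed)
    drift = spec.drift if spec.drift is not None else np.zeros((spec.n_frames, 2))

    actin = _band_localizations(rng, spec, spec.actin_band, ACTIN_CHANNEL)
    target = _band_localizations(rng, spec, spec.target_band, TARGET_CHANNEL)
    tables = {"actin": actin, "target": target}
    if spec.beads is not None and len(spec.beads):
        tables["actin"] = pd.concat(
            [actin, _bead_localizations(rng, spec, ACTIN_CHANNEL)], ignore_index=True
        )
        tables["target"] = pd.concat(
            [target, _bead_localizations(rng, spec, TARGET_CHANNEL)], ignore_index=True
        )

    for name, tab in tables.items():
        d = drift[tab["frame"].to_numpy(int)]
        tab["x"] = tab["x"].to_numpy(float) + d[:, 0]
        tab["y"] = tab["y"].to_numpy(float) + d[:, 1]
        if name == "target" and spec.chromatic_affine is not None:
            pts = spec.chromatic_affine.apply(tab[["x", "y"]].to_numpy(float))
            tab["x"], tab["y"] = pts[:, 0], pts[:, 1]

    gt = CortexGroundTruth(
        actin_band=spec.actin_band,
        target_band=spec.target_band,
        overhang_percent=true_overhang(spec.actin_band, spec.target_band),
        peak_to_peak_nm=spec.target_band.depth_nm - spec.actin_band.depth_nm,
        drift=drift,
        chromatic_affine=spec.chromatic_affine,
        beads=np.atleast_2d(np.asarray(spec.beads, float)) if spec.beads is not None else np.empty((0, 2)),
        cell_center=spec.cell_center,
        cell_radius=spec.cell_radius,
    )
    return tables["actin"], tables["target"], gt


# ---------------------------------------------------------------------------
# SIM minifilament scenes
# ---------------------------------------------------------------------------


@dataclass
class MinifilSceneSpec:
    """Dumbbell minifilaments over an inhomogeneous background."""

    n_filaments: int = 25
    true_length_nm: float = 317.0
    theta_max_deg: float = 30.0  # out-of-plane angle uniform on [0, theta_max]
    theta_values_deg: np.ndarray | None = None  # explicit angles override the distribution
    pixel_size_nm: float = 40.0
    psf_sigma_nm: float = 60.0
    image_size_px: int = 256
    head_peak: float = 500.0  # photon counts at a head-spot centre
    tail_peak: float = 400.0
    background_offset: float = 20.0
    background_gradient: float = 10.0  # peak-to-peak of the smooth background ramp
    read_noise_sd: float = 3.0
    poisson_noise: bool = True
    edge_margin_nm: float = 500.0  # keep filament centres away from borders
    clear_region_px: int = 48  # structure-free top-left square (noise reference)

    def __post_init__(self) -> None:
        if not (200.0 <= self.true_length_nm <= 400.0):
            raise ValueError("true length must lie in [200, 400] nm")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be positive")
        area_um2 = (self.image_size_px * self.pixel_size_nm / 1000.0) ** 2
        limit = 1.0 / (2 * self.true_length_nm / 1000.0) ** 2
        if self.n_filaments / area_um2 > limit:
            warnings.warn(
                "filament density exceeds 1 per (2L)^2; head pairing may be ambiguous",
                stacklevel=2,
            )


@dataclass
class MinifilamentTruth:
    center_nm: np.ndarray
    phi_deg: float  # in-plane direction
    theta_deg: float  # out-of-plane angle
    projected_length_nm: float
    head1_nm: np.ndarray
    head2_nm: np.ndarray
    detectable: bool  # False when the heads coincide (theta = 90 deg)


def _add_spot(img: np.ndarray, x_nm: float, y_nm: float, peak: float,
              sigma_nm: float, pixel_nm: float) -> None:
    h, w = img.shape
    s_px = sigma_nm / pixel_nm
    cx = x_nm / pixel_nm - 0.5
    cy = y_nm / pixel_nm - 0.5
    r = int(np.ceil(4 * s_px)) + 1
    c0, c1 = max(int(cx) - r, 0), min(int(cx) + r + 1, w)
    r0, r1 = max(int(cy) - r, 0), min(int(cy) + r + 1, h)
    if c1 <= c0 or r1 <= r0:
        return
    cols = np.arange(c0, c1)
    rows = np.arange(r0, r1)
    gx = np.exp(-0.5 * ((cols - cx) / s_px) ** 2)
    gy = np.exp(-0.5 * ((rows - cy) / s_px) ** 2)
    img[r0:r1, c0:c1] += peak * np.outer(gy, gx)


def gen_sim_minifilaments(
    spec: MinifilSceneSpec, seed: int
) -> tuple[np.ndarray, list[MinifilamentTruth]]:
    """Render a two-channel SIM-like image of dumbbell minifilaments.

    Channel 0 (heads): two spots at ``+-(L/2) cos(theta)`` along a
    random in-plane direction from the filament centre; channel 1
    (tail): one spot at the centre.  All spots are Gaussian with the
    PSF sigma; a smooth background ramp, Poisson photon noise and
    Gaussian read noise are added.  Ground truth records the projected
    length ``L cos(theta)`` per filament.
    """
    rng = np.random.default_rng(seed)
    n_px = spec.image_size_px
    img = np.zeros((2, n_px, n_px))
    size_nm = n_px * spec.pixel_size_nm
    m = spec.edge_margin_nm

    if spec.theta_values_deg is not None:
        theta = np.asarray(spec.theta_values_deg, float)
        if len(theta) != spec.n_filaments:
            raise ValueError("theta_values_deg length must equal n_filaments")
    else:
        theta = rng.uniform(0.0, spec.theta_max_deg, spec.n_filaments)
    phi = rng.uniform(0.0, 360.0, spec.n_filaments)
    centers = rng.uniform(m, size_nm - m, size=(spec.n_filaments, 2))
    # keep the noise-reference corner free of structure
    clear_nm = spec.clear_region_px * spec.pixel_size_nm + m
    in_corner = (centers < clear_nm).all(axis=1)
    while np.any(in_corner):
        centers[in_corner] = rng.uniform(m, size_nm - m, size=(int(in_corner.sum()), 2))
        in_corner = (centers < clear_nm).all(axis=1)

    truths: list[MinifilamentTruth] = []
    for c, ph, th in zip(centers, phi, theta):
        l_proj = spec.true_length_nm * np.cos(np.radians(th))
        u = np.array([np.cos(np.radians(ph)), np.sin(np.radians(ph))])
        h1 = c + 0.5 * l_proj * u
        h2 = c - 0.5 * l_proj * u
        for h_pos in (h1, h2):
            _add_spot(img[0], h_pos[0], h_pos[1], spec.head_peak,
                      spec.psf_sigma_nm, spec.pixel_size_nm)
        _add_spot(img[1], c[0], c[1], spec.tail_peak,
                  spec.psf_sigma_nm, spec.pixel_size_nm)
        truths.append(
            MinifilamentTruth(
                center_nm=c, phi_deg=float(ph), theta_deg=float(th),
                projected_length_nm=float(l_proj), head1_nm=h1, head2_nm=h2,
                detectable=bool(l_proj > 1e-9),
            )
        )

    yy, xx = np.mgrid[0:n_px, 0:n_px]
    background = spec.background_offset + spec.background_gradient * (
        xx + yy
    ) / (2.0 * n_px)
    img += background[None]
    if spec.poisson_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if spec.read_noise_sd > 0:
        img += rng.normal(0.0, spec.read_noise_sd, img.shape)
    return img, truths


# ---------------------------------------------------------------------------
# Confocal linescans
# ---------------------------------------------------------------------------


@dataclass
class LinescanSpec:
    """Transverse cortex linescan from the step-convolution forward model."""

    x_m_nm: float = 1000.0  # membrane position
    h_actin_nm: float = 230.0
    h_myo_nm: float = 150.0
    i_out: float = 10.0
    i_cort: float = 100.0
    i_in: float = 40.0
    myo_out: float = 5.0
    myo_peak: float = 80.0
    myo_in: float = 20.0
    psf_sigma_nm: float = 170.0
    noise_sd: float = 0.0
    pitch_nm: float = 20.0
    margin_nm: float = 1000.0

    def __post_init__(self) -> None:
        if self.h_actin_nm <= 0:
            raise ValueError("h_actin must be positive")
        if not (0 < self.h_myo_nm <= self.h_actin_nm):
            raise ValueError("need 0 < h_myo <= h_actin for the aligned-edge model")
        if self.psf_sigma_nm < 0:
            raise ValueError("psf sigma must be >= 0")


@dataclass
class LinescanGroundTruth:
    x_m_nm: float
    h_actin_nm: float
    h_myo_nm: float
    myosin_free_length_nm: float


def gen_linescan(
    spec: LinescanSpec, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, LinescanGroundTruth]:
    """Noisy actin and myosin linescans across the cortex.

    The actin profile is the piecewise-constant density (i_out | i_cort
    | i_in) convolved with the Gaussian PSF; the myosin profile is a
    slab of width ``h_myo`` whose cytoplasmic edge coincides with the
    actin slab's, convolved identically.  x increases toward the
    cytoplasm.
    """
    rng = np.random.default_rng(seed)
    x = np.arange(
        spec.x_m_nm - spec.margin_nm,
        spec.x_m_nm + spec.h_actin_nm + spec.margin_nm + spec.pitch_nm / 2,
        spec.pitch_nm,
    )
    actin = step_convolution_model(
        x, spec.x_m_nm, spec.h_actin_nm, spec.i_out, spec.i_cort, spec.i_in,
        spec.psf_sigma_nm,
    )
    myo = myosin_step_model(
        x, spec.x_m_nm + spec.h_actin_nm, spec.h_myo_nm,
        spec.myo_out, spec.myo_peak, spec.myo_in, spec.psf_sigma_nm,
    )
    if spec.noise_sd > 0:
        actin = actin + rng.normal(0.0, spec.noise_sd, len(x))
        myo = myo + rng.normal(0.0, spec.noise_sd, len(x))
    gt = LinescanGroundTruth(
        spec.x_m_nm, spec.h_actin_nm, spec.h_myo_nm,
        spec.h_actin_nm - spec.h_myo_nm,
    )
    return x, actin, myo, gt


# ---------------------------------------------------------------------------
# AFM force curves
# ---------------------------------------------------------------------------


@dataclass
class ForceCurveSpec:
    """Compression peak, exponential relaxation to a plateau, optional drug transient."""

    baseline_nN: float = 0.2
    peak_nN: float = 25.0
    plateau_nN: float = 12.0
    relax_tau_s: float = 8.0
    compression_time_s: float = 10.0
    drug_time_s: float | None = None
    drug_response: object = None  # callable g(dt_s) -> multiplicative force factor
    duration_s: float = 120.0
    sampling_rate_hz: float = 10.0
    noise_sd_nN: float = 0.0
    z_um: float = 10.0

    def __post_init__(self) -> None:
        if self.plateau_nN <= 0:
            raise ValueError("plateau force must be positive")
        if self.drug_time_s is not None and self.drug_time_s < self.compression_time_s + 30.0:
            raise ValueError("drug addition must come after the relaxation window")


def drug_transient(max_frac: float, final_frac: float, tau_s: float = 60.0):
    """Factor jumping to (1 + max_frac) then decaying to (1 + final_frac)."""

    def g(dt: np.ndarray) -> np.ndarray:
        dt = np.asarray(dt, float)
        return (1 + final_frac) + (max_frac - final_frac) * np.exp(-dt / tau_s)

    return g


def gen_force_curve(spec: ForceCurveSpec, seed: int) -> pd.DataFrame:
    """AFM force-time curve with compression peak, relaxation and drug transient."""
    rng = np.random.default_rng(seed)
    n = int(spec.duration_s * spec.sampling_rate_hz) + 1
    t = np.arange(n) / spec.sampling_rate_hz
    f = np.full(n, spec.baseline_nN)
    after = t >= spec.compression_time_s
    dt = t[after] - spec.compression_time_s
    f[after] = spec.plateau_nN + (spec.peak_nN - spec.plateau_nN) * np.exp(
        -dt / spec.relax_tau_s
    )
    if spec.drug_time_s is not None and spec.drug_response is not None:
        post = t >= spec.drug_time_s
        f[post] = f[post] * spec.drug_response(t[post] - spec.drug_time_s)
    if spec.noise_sd_nN > 0:
        f = f + rng.normal(0.0, spec.noise_sd_nN, n)
    return pd.DataFrame({"time": t, "force": f, "z": np.full(n, spec.z_um)})


# ---------------------------------------------------------------------------
# Confocal ring-cell images
# ---------------------------------------------------------------------------


@dataclass
class ConfocalCellSpec:
    center_px: tuple[float, float]  # (row, col)
    radius_px: float
    cortex_intensity: float  # peak intensity of the cortical band
    band_width_px: float = 8.0  # FWHM of the cortical band profile
    interior_fraction: float = 0.25  # cytoplasmic level relative to the cortex peak


@dataclass
class ConfocalGroundTruth:
    masks: list[np.ndarray]  # filled per-cell disks
    cortex_intensities: list[float]
    cells: list[ConfocalCellSpec]


def gen_confocal_cell_image(
    cells: list[ConfocalCellSpec],
    image_size_px: int = 256,
    background_offset: float = 1.0,
    background_gradient: float = 0.5,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, ConfocalGroundTruth]:
    """Ring-shaped cortical cells over a smooth inhomogeneous background.

    Each cell is a cytoplasmic disk plus a cortical band that peaks at
    the membrane and decays inward over ``band_width_px`` with a
    raised-cosine profile; the outer (extracellular) edge is sharp at
    the membrane (sub-resolution).  Cells must not overlap.
    Ground-truth masks are the membrane-bounded disks; the generative
    peak cortical intensities are recorded.
    """
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            a, b = cells[i], cells[j]
            d = np.hypot(a.center_px[0] - b.center_px[0], a.center_px[1] - b.center_px[1])
            if d < a.radius_px + b.radius_px + a.band_width_px + b.band_width_px:
                raise ValueError(f"cells {i} and {j} overlap")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:image_size_px, 0:image_size_px].astype(float)
    img = background_offset + background_gradient * (xx + yy) / (2.0 * image_size_px)
    masks, intensities = [], []
    for cell in cells:
        d = np.hypot(yy - cell.center_px[0], xx - cell.center_px[1])
        w = cell.band_width_px
        inside = d <= cell.radius_px
        u = np.clip((cell.radius_px - d) / w, 0.0, 1.0)  # 0 at membrane, 1 deep inside
        band = np.cos(0.5 * np.pi * u) ** 2
        img += cell.cortex_intensity * np.where(
            inside, np.maximum(band, cell.interior_fraction), 0.0
        )
        masks.append(inside)
        intensities.append(cell.cortex_intensity)
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, img.shape)
    return img, ConfocalGroundTruth(masks, intensities, list(cells))
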