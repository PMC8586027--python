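"""Cortical tension from parallel-plate AFM compression and drug transients.

A rounded cell compressed between a glass dish and a tipless cantilever
reaches a force plateau F after an initial relaxation.  Neglecting the
small cantilever tilt and adhesion, the force balance at the contact
line gives the cortical tension

    T = F * (r_mid^2 / r_c^2 - 1) / (2 * pi * r_mid)        [nN/um = mN/m]

where r_mid is the radius of the cell's maximum (equatorial)
cross-section and r_c the cell-cantilever contact radius.  Rather than
measuring r_c directly, it is obtained from the equatorial area A_mid
and the compressed cell height h_cell through the contact area

    A_c = A_mid - (pi/4) * h_cell^2,      r_c = sqrt(A_c / pi).

Drug-addition experiments are analysed on the Savitzky-Golay-smoothed
force trace: the mean force in the 20 s before addition is the
baseline, and the mean and maximum forces in the 300 s after addition
are reported normalized to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

logger = logging.getLogger(__name__)


def _as_curve(curve) -> pd.DataFrame:
    df = pd.DataFrame(curve)
    for col in ("time", "force"):
        if col not in df.columns:
            raise ValueError(f"force curve missing column {col!r}")
    t = df["time"].to_numpy(float)
    if not np.all(np.diff(t) > 0):
        raise ValueError("force-curve time must be strictly increasing")
    if not np.all(np.isfinite(df["force"].to_numpy(float))):
        raise ValueError("force values must be finite")
    return df


def extract_plateau(
    curve,
    relax_window_s: tuple[float, float] = (20.0, 30.0),
    t_end: float | None = None,
    flatness_threshold: float = 0.02,
) -> dict:
    """Mean plateau force (nN) after the post-peak relaxation window.

    The compression peak is the global force maximum before the
    plateau; the plateau is averaged from ``relax_window_s[1]`` seconds
    after the peak until ``t_end`` (e.g. the drug-addition time) or the
    end of the curve.  The residual slope over the plateau (nN/s) is
    reported and flagged if above ``flatness_threshold``.
    """
    df = _as_curve(curve)
    t = df["time"].to_numpy(float)
    f = df["force"].to_numpy(float)
    stop = t[-1] if t_end is None else t_end
    k = int(np.argmax(f[t <= stop])) if np.any(t <= stop) else int(np.argmax(f))
    t_peak = t[k]
    start = t_peak + relax_window_s[1]
    sel = (t >= start) & (t <= stop)
    if not np.any(sel):
        raise ValueError("no samples after the relaxation window; cannot extract plateau")
    no_peak = f[k] <= f[sel].mean() * (1 + 1e-9)
    if no_peak:
        logger.warning("no compression peak found; curve treated as already relaxed")
    plateau = float(f[sel].mean())
    slope = float(np.polyfit(t[sel], f[sel], 1)[0]) if sel.sum() > 2 else 0.0
    # non-stationary if the drift across the averaging window exceeds the
    # stated fraction of the plateau force
    span = float(t[sel][-1] - t[sel][0])
    flagged = abs(slope) * span > flatness_threshold * max(abs(plateau), 1e-12)
    if flagged:
        logger.warning("plateau slope %.3g nN/s above threshold; non-stationary", slope)
    return {
        "plateau_nN": plateau,
        "t_peak_s": float(t_peak),
        "peak_nN": float(f[k]),
        "slope_nN_per_s": slope,
        "non_stationary": bool(flagged),
        "no_peak": bool(no_peak),
    }


def measure_h_cell(z_on_cell_um: float, z_on_glass_um: float) -> float:
    """Compressed cell height (um) from cantilever z on the cell vs on glass."""
    h = z_on_cell_um - z_on_glass_um
    if h < 0:
        raise ValueError("negative cell height; check input order (cell z first)")
    return float(h)


def contact_radius(a_mid_um2: float, h_cell_um: float) -> float:
    """Cell-cantilever contact radius (um) from equatorial area and cell height.

    ``A_c = A_mid - (pi/4) h_cell^2`` and ``r_c = sqrt(A_c / pi)``.
    Requires ``A_mid > (pi/4) h_cell^2`` (a compressed cell is wider
    than tall).
    """
    a_c = a_mid_um2 - (np.pi / 4.0) * h_cell_um**2
    if a_c <= 0:
        raise ValueError("A_mid <= (pi/4) h_cell^2: cell taller than wide; geometry invalid")
    return float(np.sqrt(a_c / np.pi))


def tension(f_nN: float, r_mid_um: float, r_c_um: float) -> float:
    """Cortical tension (mN/m) from the parallel-plate force balance."""
    if f_nN < 0:
        raise ValueError("plateau force must be non-negative")
    if not (0 < r_c_um <= r_mid_um):
        raise ValueError("need 0 < r_c <= r_mid")
    return float(f_nN * (r_mid_um**2 / r_c_um**2 - 1.0) / (2.0 * np.pi * r_mid_um))


@dataclass
class TensionResult:
    plateau_nN: float
    r_mid_um: float
    a_mid_um2: float
    h_cell_um: float
    r_c_um: float
    tension_mN_per_m: float


def tension_from_curve(
    curve,
    a_mid_um2: float,
    z_on_cell_um: float,
    z_on_glass_um: float,
    relax_window_s: tuple[float, float] = (20.0, 30.0),
    t_end: float | None = None,
) -> TensionResult:
    """End-to-end: plateau force + geometry -> cortical tension."""
    plateau = extract_plateau(curve, relax_window_s=relax_window_s, t_end=t_end)
    h_cell = measure_h_cell(z_on_cell_um, z_on_glass_um)
    r_c = contact_radius(a_mid_um2, h_cell)
    r_mid = float(np.sqrt(a_mid_um2 / np.pi))
    t_val = tension(plateau["plateau_nN"], r_mid, r_c)
    return TensionResult(
        plateau_nN=plateau["plateau_nN"],
        r_mid_um=r_mid,
        a_mid_um2=float(a_mid_um2),
        h_cell_um=h_cell,
        r_c_um=r_c,
        tension_mN_per_m=t_val,
    )


def drug_response(
    curve,
    t_drug_s: float,
    pre_window_s: float = 20.0,
    post_window_s: float = 300.0,
    savgol_window: int = 21,
    savgol_order: int = 3,
) -> dict:
    """Normalized mean and max force response to drug addition.

    The trace is Savitzky-Golay smoothed; the baseline is the mean
    force over ``[t_drug - pre_window, t_drug]`` and the outputs are
    ``mean(post)/baseline`` and ``max(post)/baseline`` over
    ``[t_drug, t_drug + post_window]``.
    """
    df = _as_curve(curve)
    t = df["time"].to_numpy(float)
    f = df["force"].to_numpy(float)
    if t[0] > t_drug_s - pre_window_s or t[-1] < t_drug_s + post_window_s:
        raise ValueError(
            f"curve must cover [{t_drug_s - pre_window_s:.1f}, "
            f"{t_drug_s + post_window_s:.1f}] s around drug addition"
        )
    win = min(savgol_window, len(f) - (1 - len(f) % 2))
    if win > savgol_order + 1:
        if win % 2 == 0:
            win -= 1
        f = savgol_filter(f, win, savgol_order)
    pre = (t >= t_drug_s - pre_window_s) & (t <= t_drug_s)
    post = (t >= t_drug_s) & (t <= t_drug_s + post_window_s)
    baseline = float(f[pre].mean())
    if baseline == 0:
        raise ValueError("zero baseline force; cannot normalize")
    return {
        "baseline_nN": baseline,
        "normalized_mean": float(f[post].mean() / baseline),
        "normalized_max": float(f[post].max() / baseline),
    }
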