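"""Height, functional, spatial and hybrid areal texture parameters (ISO 25178-2).

All operations expect the S-F surface (form removed, zero mean over valid
points).  Height and functional parameters average over valid points only;
spatial and hybrid parameters require a gap-free grid (see
:func:`microwear.surface_io.fill_nonmeasured`).

Each operation returns ``(params, flags)`` where ``flags`` is a set of short
strings recording degenerate conditions (e.g. a constant surface) instead of
raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal.windows import hann

from .errors import ConfigurationError
from .surface_io import HeightMap


@dataclass
class ParamSettings:
    """Material-ratio and spatial settings of the parameter battery.

    Defaults follow the standard DMTA reporting configuration: Vm/Vv volumes
    split at material ratios p = 10% and q = 80%, Sxp between p = 50% and
    q = 97.5%, the autocorrelation threshold s = 0.2, and the Smr reference
    height 1 µm below the highest peak.
    """

    p_material: float = 10.0
    q_material: float = 80.0
    p_sxp: float = 50.0
    q_sxp: float = 97.5
    p_vvv: float = 80.0
    acf_s: float = 0.2
    smr_cref: float = 1.0

    def __post_init__(self):
        for p, q in ((self.p_material, self.q_material), (self.p_sxp, self.q_sxp)):
            if not (0.0 < p < q < 100.0):
                raise ConfigurationError(f"material ratios must satisfy 0 < p < q < 100, got {p}, {q}")
        if not (0.0 < self.p_vvv < 100.0):
            raise ConfigurationError("p_vvv must lie in (0, 100)")
        if not (0.0 < self.acf_s < 1.0):
            raise ConfigurationError("ACF threshold s must lie in (0, 1)")


# ---------------------------------------------------------------------------
# height parameters
# ---------------------------------------------------------------------------


def height_params(hm: HeightMap) -> tuple[dict, set]:
    """Sq, Ssk, Sku, Sp, Sv, Sz, Sa over the valid points of a levelled surface."""
    z = hm.valid_heights()
    flags: set[str] = set()
    sq = float(np.sqrt(np.mean(z**2)))
    if sq == 0.0:
        flags.add("degenerate_surface")
        return (
            {"Sq": 0.0, "Ssk": 0.0, "Sku": 0.0, "Sp": 0.0, "Sv": 0.0, "Sz": 0.0, "Sa": 0.0},
            flags,
        )
    params = {
        "Sq": sq,
        "Ssk": float(np.mean(z**3) / sq**3),
        "Sku": float(np.mean(z**4) / sq**4),
        "Sp": float(z.max()),
        "Sv": float(-z.min()),
        "Sa": float(np.mean(np.abs(z))),
    }
    params["Sz"] = params["Sp"] + params["Sv"]
    return params, flags


# ---------------------------------------------------------------------------
# bearing (Abbott–Firestone) curve and functional parameters
# ---------------------------------------------------------------------------


class BearingCurve:
    """Empirical areal material-ratio curve of one scan.

    Maps material ratio r (0–100 %) to height c (µm) by linear interpolation
    between the sorted valid heights: the highest point has ratio 0, the
    lowest ratio 100 (at grid resolution).  The inverse lookup
    :meth:`ratio_at` is defined the same way.
    """

    def __init__(self, hm: HeightMap):
        z = np.sort(hm.valid_heights())[::-1]  # descending
        if z.size < 2 or z[0] == z[-1]:
            # still usable (constant surface): flat curve
            pass
        self.heights = z
        self.ratios = np.linspace(0.0, 100.0, z.size)

    def height_at(self, ratio) -> np.ndarray | float:
        """Height c (µm) at material ratio(s) r in percent."""
        return np.interp(ratio, self.ratios, self.heights)

    def ratio_at(self, height) -> np.ndarray | float:
        """Material ratio (%) at height c (µm)."""
        # heights ascending for interp; paired ratios descend from 100 to 0
        h_asc = self.heights[::-1]
        r_desc = self.ratios[::-1]
        return np.interp(height, h_asc, r_desc)


def bearing_curve(hm: HeightMap) -> BearingCurve:
    return BearingCurve(hm)


def functional_params(
    hm: HeightMap, curve: BearingCurve | None = None, settings: ParamSettings | None = None
) -> tuple[dict, set]:
    """Material-ratio parameters Smr, Smc, Sxp and the Vm/Vv volume family.

    Volumes are areal densities (µm³/µm²): Vm(r) is the mean material above
    the cutting plane c(r), Vv(r) the mean void below it; the peak/core/valley
    split uses the configured p/q ratios.
    """
    settings = settings or ParamSettings()
    curve = curve or BearingCurve(hm)
    z = hm.valid_heights()
    flags: set[str] = set()

    def vm(r):
        c = curve.height_at(r)
        return float(np.mean(np.maximum(z - c, 0.0)))

    def vv(r):
        c = curve.height_at(r)
        return float(np.mean(np.maximum(c - z, 0.0)))

    p, q = settings.p_material, settings.q_material
    sp = float(z.max())
    params = {
        "Smc": float(curve.height_at(p)),
        "Smr": float(curve.ratio_at(sp - settings.smr_cref)),
        "Sxp": float(curve.height_at(settings.p_sxp) - curve.height_at(settings.q_sxp)),
        "Vm": vm(p),
        "Vv": vv(p),
        "Vmp": vm(p),
        "Vmc": vm(q) - vm(p),
        "Vvc": vv(p) - vv(settings.p_vvv),
        "Vvv": vv(settings.p_vvv),
    }
    if np.ptp(z) == 0.0:
        flags.add("degenerate_surface")
    return params, flags


# ---------------------------------------------------------------------------
# spatial parameters
# ---------------------------------------------------------------------------


def _autocorrelation(z: np.ndarray) -> np.ndarray:
    """Normalised biased areal ACF (Wiener–Khinchin), centred with fftshift."""
    z0 = z - z.mean()
    F = np.fft.fft2(z0)
    acf = np.fft.ifft2(np.abs(F) ** 2).real
    acf /= acf[0, 0]
    return np.fft.fftshift(acf)


def spatial_params(hm: HeightMap, settings: ParamSettings | None = None) -> tuple[dict, set]:
    """Sal, Str (ACF decay) and Std (spectral lay direction).

    Sal is the shortest distance at which the normalised ACF decays below
    s = 0.2, searched over 360 azimuths at 1° steps with bilinear
    interpolation; Str is that minimum divided by the maximum decay distance
    (decay saturates at the half-field radius when the ACF never crosses s).
    Std is the lay direction: 90° plus the azimuth of the dominant angular
    energy of the Hann-windowed Fourier power spectrum (DC excluded), modulo
    180°, measured counter-clockwise from +x.
    """
    settings = settings or ParamSettings()
    if hm.mask.any():
        raise ValueError("spatial parameters require a gap-free grid; fill masked points first")
    z = hm.heights
    ny, nx = z.shape
    flags: set[str] = set()
    if np.ptp(z) == 0.0:
        flags |= {"degenerate_surface", "std_invalid"}
        return {"Sal": 0.0, "Str": 0.0, "Std": 0.0}, flags

    # --- Sal / Str from the directional ACF decay
    acf = _autocorrelation(z)
    cy, cx = ny // 2, nx // 2
    rmax = min((min(cy, ny - 1 - cy)) * hm.dy, (min(cx, nx - 1 - cx)) * hm.dx)
    dr = 0.5 * min(hm.dx, hm.dy)
    radii = np.arange(0.0, rmax + 0.5 * dr, dr)
    theta = np.deg2rad(np.arange(360.0))
    rows = cy + np.outer(np.sin(theta), radii) / hm.dy
    cols = cx + np.outer(np.cos(theta), radii) / hm.dx
    prof = ndimage.map_coordinates(acf, [rows.ravel(), cols.ravel()], order=1, mode="nearest")
    prof = prof.reshape(360, radii.size)

    s = settings.acf_s
    below = prof < s
    decay = np.full(360, radii[-1])
    hit = below.any(axis=1)
    idx = np.argmax(below, axis=1)  # first radius index below s (>= 1: prof[:,0] = 1)
    i = idx[hit]
    v1 = prof[hit, i - 1]
    v2 = prof[hit, i]
    frac = np.where(v2 != v1, (v1 - s) / (v1 - v2), 1.0)
    decay[hit] = radii[i - 1] + frac * dr
    sal = float(decay.min())
    str_ = float(decay.min() / decay.max()) if decay.max() > 0 else 0.0
    if not hit.all():
        flags.add("acf_saturated")

    # --- Std from the angular energy of the windowed power spectrum
    w = np.outer(hann(ny, sym=False), hann(nx, sym=False))
    P = np.abs(np.fft.fft2((z - z.mean()) * w)) ** 2
    P = np.fft.fftshift(P)
    fy = np.fft.fftshift(np.fft.fftfreq(ny, d=hm.dy))
    fx = np.fft.fftshift(np.fft.fftfreq(nx, d=hm.dx))
    FX, FY = np.meshgrid(fx, fy)
    # exclude DC and the leakage-dominated innermost rings (index radius <= 2)
    iy, ix = np.mgrid[0:ny, 0:nx]
    ring = np.hypot(iy - cy, ix - cx)
    keep = ring > 2.0
    az = np.rad2deg(np.arctan2(FY, FX)) % 180.0
    bins = np.floor(az[keep]).astype(int) % 180
    energy = np.bincount(bins, weights=P[keep], minlength=180)
    dominant = float(np.argmax(energy)) + 0.5  # bin centre
    std = (dominant + 90.0) % 180.0
    return {"Sal": sal, "Str": str_, "Std": std}, flags


# ---------------------------------------------------------------------------
# hybrid parameters
# ---------------------------------------------------------------------------


def hybrid_params(hm: HeightMap) -> tuple[dict, set]:
    """Sdq (RMS gradient, unitless) and Sdr (developed area ratio, %).

    Gradients by central differences (one-sided at the borders).
    """
    if hm.mask.any():
        raise ValueError("hybrid parameters require a gap-free grid; fill masked points first")
    gy, gx = np.gradient(hm.heights, hm.dy, hm.dx)
    g2 = gx**2 + gy**2
    sdq = float(np.sqrt(np.mean(g2)))
    sdr = float(100.0 * np.mean(np.sqrt(1.0 + g2) - 1.0))
    return {"Sdq": sdq, "Sdr": sdr}, set()
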