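"""Layer-line indexing of filament power spectra.

The diffraction pattern of a helical filament concentrates on horizontal
layer lines at axial frequencies l/c, where c is the helical repeat distance.
The indexing chain implemented here mirrors the classical workflow: average
the power spectra of a stack of vertically aligned segments, detect layer
lines as rows of excess radially integrated power, fit the repeat distance c
by least squares over integer indexings, assign Bessel orders from the radial
position of each line's first intensity maximum, and finally solve the
meridional and pitch lines for twist and rise.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import jv

from .simulate import ImageStack
from .symmetry import HelicalSymmetry, RationalRepeat, pitch_units_to_symmetry

__all__ = [
    "PowerSpectrum",
    "LayerLine",
    "average_power_spectrum",
    "detect_layer_lines",
    "fit_repeat",
    "first_maximum_of_bessel",
    "assign_bessel_order",
    "measure_first_maximum",
    "index_spectrum",
    "index_symmetry",
]


@dataclass
class PowerSpectrum:
    """Origin-centred 2D power spectrum of a vertical filament.

    Rows are axial frequency (Å⁻¹), columns radial frequency; the meridian is
    the central column and the equator the central row.  For an (ny, nx) box
    the origin sits at pixel (ny//2, nx//2).
    """

    power: np.ndarray
    axial_step: float  # Å⁻¹ per row
    radial_step: float  # Å⁻¹ per column

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.power.ndim != 2:
            raise ValueError("power must be 2D")
        if np.any(self.power < 0):
            raise ValueError("power values must be non-negative")

    @property
    def origin(self) -> tuple[int, int]:
        return self.power.shape[0] // 2, self.power.shape[1] // 2

    def axial_freqs(self) -> np.ndarray:
        ny = self.power.shape[0]
        return (np.arange(ny) - ny // 2) * self.axial_step

    def radial_freqs(self) -> np.ndarray:
        nx = self.power.shape[1]
        return (np.arange(nx) - nx // 2) * self.radial_step


@dataclass
class LayerLine:
    l: int | None
    height: float  # Å⁻¹, >= 0
    n: int | None = None
    r_first_max: float | None = None

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError("layer-line height must be >= 0")


def average_power_spectrum(stack: ImageStack, axial_pad: int = 2) -> PowerSpectrum:
    """Mean squared Fourier magnitude of a segment stack, origin centred.

    ``axial_pad`` zero-pads images along the filament axis before the FFT,
    sampling the layer-line profiles ``axial_pad`` times more finely than the
    box alone allows (finite-length lines are narrower than one unpadded
    Fourier pixel, which otherwise limits peak localization).
    """
    if len(stack) == 0:
        raise ValueError("empty image stack")
    if axial_pad < 1:
        raise ValueError("axial_pad must be >= 1")
    acc = None
    ny_pad = stack.images.shape[1] * axial_pad
    for img in stack.images:
        ft = np.fft.fftshift(np.fft.fft2(img, s=(ny_pad, img.shape[1])))
        p = np.abs(ft) ** 2
        acc = p if acc is None else acc + p
    acc /= len(stack)
    ny, nx = acc.shape
    return PowerSpectrum(acc, 1.0 / (ny * stack.pixel_size_ang), 1.0 / (nx * stack.pixel_size_ang))


def _axial_profile(ps: PowerSpectrum, r_min_px: int = 2) -> np.ndarray:
    """Radially integrated power per row, excluding a central meridian band."""
    oy, ox = ps.origin
    cols = np.ones(ps.power.shape[1], dtype=bool)
    cols[max(0, ox - r_min_px) : ox + r_min_px + 1] = False
    return ps.power[:, cols].sum(axis=1)


def detect_layer_lines(
    ps: PowerSpectrum,
    min_snr: float = 5.0,
    max_lines: int = 16,
    min_separation_rows: int = 3,
) -> list[float]:
    """Heights (Å⁻¹) of rows with significant off-meridian power.

    A row is significant when its radially integrated power exceeds the local
    background — a rolling median along the axial profile, which follows the
    overall reciprocal-space envelope — by ``min_snr`` times both the robust
    scatter of the background-subtracted profile and the local background
    itself (local contrast; strong low-frequency envelopes would otherwise
    dominate weak high-resolution lines).  Friedel mates are merged and the
    equator is excluded.  ``min_separation_rows`` suppresses secondary maxima
    closer than the finite-length sinc sidelobe distance of a real line.
    """
    from scipy.ndimage import median_filter
    from scipy.signal import find_peaks

    profile = _axial_profile(ps)
    oy = ps.origin[0]
    # merge Friedel mates: symmetrize the profile about the equator
    half = profile[oy + 1 :].copy()
    mates = profile[:oy][::-1]
    half[: len(mates)] += mates[: len(half)]
    bg = median_filter(half, size=min(31, max(3, len(half) // 4)), mode="nearest")
    resid = half - bg
    mad = np.median(np.abs(resid))
    if mad == 0:
        mad = float(np.finfo(float).tiny)
    tiny = max(half.max() * 1e-12, np.finfo(float).tiny)
    contrast = resid / (bg + tiny)
    significant = resid > min_snr * 1.4826 * mad
    peaks, _ = find_peaks(np.where(significant, contrast, 0.0), distance=min_separation_rows)
    peaks = peaks[significant[peaks]]
    # rank by local contrast, keep the strongest, report ascending heights
    peaks = peaks[np.argsort(contrast[peaks])[::-1]][:max_lines]
    heights = []
    for p in sorted(peaks):
        # sub-row refinement by parabolic interpolation on the subtracted profile
        delta = 0.0
        if 1 <= p < len(half) - 1:
            y0, y1, y2 = resid[p - 1], resid[p], resid[p + 1]
            denom = y0 - 2 * y1 + y2
            if denom != 0:
                delta = float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
        heights.append((p + 1 + delta) * ps.axial_step)
    return heights


def fit_repeat(
    heights: list[float],
    max_l: int = 64,
    rel_tol: float = 0.05,
    c_max: float | None = None,
) -> tuple[float, list[int]]:
    """Fit the repeat distance c and integer layer indices to measured heights.

    For each candidate index l0 of the lowest line, indices of the remaining
    lines follow by rounding, and c is refit by least squares
    (1/c = Σ l·h / Σ l²).  The assignment with the smallest residual wins;
    among near-degenerate assignments the one with the smallest c (lowest l0)
    is preferred.  Raises if no indexing fits within ``rel_tol`` relative
    residual per line.
    """
    h = np.asarray(sorted(heights), dtype=float)
    if len(h) < 2:
        raise ValueError("need at least two layer-line heights")
    if np.any(h <= 0):
        raise ValueError("heights must be positive")
    # candidate repeats: every (observed height, integer index) pair proposes
    # c = l / h
    candidates = sorted({l / hi for hi in h for l in range(1, max_l + 1)})
    fits = []
    for c0 in candidates:
        if c_max is not None and c0 > c_max:
            continue  # line spacing below the resolvable limit
        l = np.round(h * c0).astype(int)
        if np.any(l < 1) or np.any(l > max_l) or len(set(l.tolist())) != len(l):
            continue
        inv_c = float(np.dot(l, h) / np.dot(l, l))
        c_fit = 1.0 / inv_c
        resid = float(np.sqrt(np.mean((h - l * inv_c) ** 2)))
        # a repeat of length c can index ARBITRARY heights to within its line
        # spacing (rms 1/(sqrt(12) c)), so judge each candidate against that
        # null: score = resid / (rounding noise) = resid * c * sqrt(12);
        # ties (e.g. exact data, where 2c fits as well as c) go to smaller c
        fits.append((resid * c_fit, c_fit, resid / float(np.mean(h)), l.tolist()))
    if not fits:
        raise ValueError(f"no consistent layer-line indexing with l <= {max_l}")
    fits.sort(key=lambda f: f[1])  # ascending c
    best = None
    for score, c_fit, rel_resid, l in fits:
        if best is None or score < best[0] * (1 - 1e-9) - 1e-15:
            best = (score, c_fit, rel_resid, l)
    _, c, rel_resid, l = best
    if rel_resid > rel_tol:
        raise ValueError(f"no consistent layer-line indexing with l <= {max_l}")
    order = np.argsort(np.argsort(heights))
    return c, [l[i] for i in order]


@functools.lru_cache(maxsize=None)
def first_maximum_of_bessel(n: int, x_max: float | None = None, dx: float = 1e-3) -> float:
    """Position of the first maximum of |J_n| for n >= 0 (0 for n = 0)."""
    if n == 0:
        return 0.0
    if x_max is None:
        x_max = n + 10.0  # the first maximum of J_n lies between n and n+2
    x = np.arange(max(dx, n * 0.3), x_max, dx)
    y = np.abs(jv(n, x))
    i = int(np.argmax(np.diff(y) < 0))  # first downturn
    return float(x[i])


def assign_bessel_order(
    line: LayerLine, filament_radius: float, n_max: int = 10
) -> tuple[int, bool]:
    """Assign |n| from the radial position of the first intensity maximum.

    On a layer line carrying Bessel order n, the first maximum of |J_n(2πRr)|
    falls at 2π·R·r = x_n, the first maximum of J_n.  Returns (|n|, confident);
    ``confident`` is False when the observed maximum lies beyond the position
    predicted for n_max (the order is then reported as n_max).
    """
    if line.r_first_max is None:
        raise ValueError("layer line carries no first-maximum position")
    if filament_radius <= 0:
        raise ValueError("radius must be positive")
    x_obs = 2 * math.pi * line.r_first_max * filament_radius
    peaks = [first_maximum_of_bessel(n) for n in range(n_max + 1)]
    errs = [abs(p - x_obs) for p in peaks]
    n = int(np.argmin(errs))
    confident = x_obs <= peaks[-1] + (peaks[-1] - peaks[-2] if n_max >= 1 else 1.0)
    return n, confident


def measure_first_maximum(
    ps: PowerSpectrum, height: float, r_max: float | None = None
) -> float:
    """Radial position (Å⁻¹) of the intensity maximum on the layer line
    nearest ``height``.

    The profile is averaged over the line's rows (±1) and their Friedel
    mates and symmetrized about the meridian; for a J_n-profile line under a
    decaying envelope the global maximum is the first maximum, and n = 0
    lines peak on the meridian itself (returned as 0 within sub-pixel
    refinement).  ``r_max`` optionally restricts the search radius.
    """
    oy, ox = ps.origin
    ny = ps.power.shape[0]
    row = oy + int(round(height / ps.axial_step))
    rows = [r for r in (row - 1, row, row + 1) if 0 <= r < ny and r != oy]
    rows += [2 * oy - r for r in rows if 0 <= 2 * oy - r < ny and 2 * oy - r != oy]
    band = ps.power[rows].mean(axis=0)
    right = band[ox:]
    left = band[ox::-1]
    m = min(len(right), len(left))
    prof = (right[:m] + left[:m]) / 2
    prof = np.convolve(prof, np.ones(3) / 3, mode="same")
    if r_max is not None:
        m = min(m, max(2, int(r_max / ps.radial_step) + 1))
        prof = prof[:m]
    i = int(np.argmax(prof))
    delta = 0.0
    if 1 <= i < m - 1:
        y0, y1, y2 = prof[i - 1], prof[i], prof[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            delta = float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
    return max(0.0, (i + delta) * ps.radial_step)


def index_spectrum(
    ps: PowerSpectrum,
    filament_radius: float = 25.0,
    handedness: str = "left",
    min_snr: float = 5.0,
    max_l: int = 128,
    n_max: int = 10,
) -> dict:
    """Full indexing chain: detect layer lines, fit the repeat, assign Bessel
    orders, and solve the meridional (n=0) and pitch (n=1) lines for the
    helical symmetry.

    Returns a report dict with the repeat ``c_ang``, the per-line table
    (l, height, |n|, r_first_max), and the solved symmetry / rational repeat.
    """
    # stage 1: fit the repeat on the strongest lines only (robust to spurious
    # weak detections)
    strong = detect_layer_lines(ps, min_snr=min_snr, max_lines=12)
    if len(strong) < 2:
        raise ValueError("fewer than two layer lines detected")
    # repeats whose line spacing falls below ~2 spectral rows are unresolvable
    c_max = 1.0 / (2.0 * ps.axial_step)
    c, _ = fit_repeat(strong, max_l=max_l, c_max=c_max)
    # stage 2: re-detect generously; keep heights consistent with the fitted
    # repeat (inliers within ~half a line spacing), re-index and refine c
    all_heights = detect_layer_lines(ps, min_snr=min_snr, max_lines=40)
    inliers, ls = [], []
    for h in all_heights:
        l = int(round(h * c))
        if 1 <= l <= max_l and abs(h - l / c) < 0.25 / c and l not in ls:
            inliers.append(h)
            ls.append(l)
    h_arr = np.asarray(inliers)
    l_arr = np.asarray(ls)
    c = float(np.dot(l_arr, l_arr) / np.dot(l_arr, h_arr))
    lines = []
    r_search = 1.3 * first_maximum_of_bessel(n_max) / (2 * math.pi * filament_radius)
    for l, h in sorted(zip(ls, inliers)):
        r_first = measure_first_maximum(ps, h, r_max=r_search)
        n, confident = assign_bessel_order(
            LayerLine(l, h, r_first_max=r_first), filament_radius, n_max
        )
        lines.append(LayerLine(l, h, n=n if confident else None, r_first_max=r_first))
    # rank candidate meridional (n=0) and pitch (n=1) lines by integrated row
    # power: the genuine ones are strong, while weak lines near the equator
    # can spuriously peak on the meridian
    profile = _axial_profile(ps)
    oy = ps.origin[0]

    def strength(line: LayerLine) -> float:
        row = int(np.clip(oy + round(line.height / ps.axial_step), 0, len(profile) - 1))
        return float(profile[row])

    meridionals = [ln for ln in lines if ln.n == 0 and ln.l > 0]
    pitch_lines = [ln for ln in lines if ln.n == 1]
    if not pitch_lines:
        raise ValueError("could not identify a pitch (n=1) layer line")
    # the pitch line (height 1/P) is the n=1 line nearest the equator
    l_pitch = min(pitch_lines, key=lambda ln: ln.l).l
    if meridionals:
        l_mer = max(meridionals, key=strength).l
    elif len(pitch_lines) >= 2:
        # the meridional line can be buried by the reciprocal-space envelope;
        # the two lowest n=1 lines are then n=+1 (height 1/P) and n=-1
        # (height 1/rise - 1/P), so their heights sum to 1/rise and their
        # indices to the meridional index
        lo = sorted(pitch_lines, key=lambda ln: ln.l)[:2]
        l_mer = lo[0].l + lo[1].l
    else:
        raise ValueError("could not identify a meridional (n=0) layer line")
    sym, rep = index_symmetry(c, l_mer, l_pitch, handedness)
    return {
        "c_ang": c,
        "lines": lines,
        "symmetry": sym,
        "repeat": rep,
        "l_meridional": l_mer,
        "l_pitch": l_pitch,
    }


def index_symmetry(
    c_ang: float, l_meridional: int, l_pitch: int, handedness: str = "left"
) -> tuple[HelicalSymmetry, RationalRepeat]:
    """Solve the meridional (n=0) and pitch (n=1) layer lines for symmetry.

    The meridional line index gives the rise (c / l_meridional) and hence
    u = l_meridional subunits per repeat; the n=1 pitch line gives
    t = l_pitch turns per repeat.  Handedness cannot be read from a single
    projection power spectrum and must be supplied.
    """
    if not l_meridional > l_pitch >= 1:
        raise ValueError("require l_meridional > l_pitch >= 1")
    g = math.gcd(l_meridional, l_pitch)
    if g != 1:
        import warnings

        warnings.warn(f"(u, t) = ({l_meridional}, {l_pitch}) reduced by gcd {g}", stacklevel=2)
        l_meridional //= g
        l_pitch //= g
    rise = c_ang / l_meridional
    pitch = c_ang / l_pitch
    sym = pitch_units_to_symmetry(pitch, pitch / rise, handedness)
    return sym, RationalRepeat(l_meridional, l_pitch, c_ang)
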