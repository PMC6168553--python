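"""Amplitude-correlation refinement of helical symmetry parameters.

Candidate (pitch, units-per-turn) pairs are scored by correlating an
experimental power spectrum against analytic layer-line spectra computed with
the Cochran–Crick–Vand single-radius helix model: on layer line l (axial
frequency l/c) the amplitude at radial frequency R is the coherent sum of
J_n(2πRr) over the Bessel orders n allowed by the selection rule
l = t·n + u·m.  Finite filament length broadens each line axially by a
sinc² profile of width 1/length.  The refinement evaluates the correlation on
an inclusive rectangular grid of nodes and returns the argmax.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import jv

from .layerlines import PowerSpectrum
from .symmetry import (
    HelicalSymmetry,
    pitch_units_to_symmetry,
    rational_units_per_turn,
    selection_rule_orders,
)

__all__ = [
    "GridSpec",
    "SymmetryGrid",
    "simulate_spectrum",
    "default_mask",
    "amplitude_correlation",
    "grid_refine",
    "GridRefiner",
]


@dataclass(frozen=True)
class GridSpec:
    """Inclusive search grid over pitch (Å) and units per turn."""

    pitch_min: float
    pitch_max: float
    pitch_step: float
    upt_min: float
    upt_max: float
    upt_step: float

    def pitch_values(self) -> np.ndarray:
        n = round((self.pitch_max - self.pitch_min) / self.pitch_step) + 1
        return self.pitch_min + self.pitch_step * np.arange(n)

    def upt_values(self) -> np.ndarray:
        n = round((self.upt_max - self.upt_min) / self.upt_step) + 1
        return self.upt_min + self.upt_step * np.arange(n)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.pitch_values()), len(self.upt_values())


PAPER_GRID = GridSpec(17.2, 17.4, 0.02, 3.4, 3.6, 0.02)
"""11 × 11 grid: pitch 17.2–17.4 Å (step 0.02), units/turn 3.4–3.6 (step 0.02)."""


@dataclass
class SymmetryGrid:
    spec: GridSpec
    surface: np.ndarray  # (n_pitch, n_upt) correlation values

    def __post_init__(self) -> None:
        if self.surface.shape != self.spec.shape:
            raise ValueError("surface shape does not match grid spec")


def simulate_spectrum(
    sym: HelicalSymmetry,
    radius_ang: float,
    length_ang: float,
    shape: tuple[int, int],
    axial_step: float,
    radial_step: float,
    n_max: int = 36,
    max_turns: int = 64,
    envelope_sigma_ang: float | None = None,
) -> PowerSpectrum:
    """Analytic single-radius layer-line power spectrum for a helix.

    The symmetry is rationalized to u subunits in t turns (t <= max_turns);
    layer lines sit at heights l/c with c = u·rise.  ``envelope_sigma_ang``
    applies the reciprocal-space envelope of a real-space Gaussian scatterer
    of that width, for comparison with rendered projections.
    """
    if radius_ang <= 0 or length_ang <= 0:
        raise ValueError("radius and length must be positive")
    rep = rational_units_per_turn(sym.units_per_turn, max_turns)
    u, t = rep.u, rep.t
    c = u * sym.rise_ang
    ny, nx = shape
    Z = (np.arange(ny) - ny // 2) * axial_step
    R = (np.arange(nx) - nx // 2) * radial_step
    z_max = np.abs(Z).max() + 2.0 / length_ang
    l_max = int(math.floor(z_max * c))
    two_pi_Rr = 2 * math.pi * np.abs(R) * radius_ang
    bessel_cache: dict[int, np.ndarray] = {}
    axials, intensities = [], []
    for l in range(0, l_max + 1):
        orders = selection_rule_orders(u, t, l, n_max)
        if not orders:
            continue
        amp = np.zeros(nx)
        for n in orders:
            if abs(n) not in bessel_cache:
                bessel_cache[abs(n)] = jv(abs(n), two_pi_Rr)
            amp += bessel_cache[abs(n)]
        h = l / c
        for sign in (1,) if l == 0 else (1, -1):
            axials.append(np.sinc((Z - sign * h) * length_ang) ** 2)
            intensities.append(amp**2)
    power = np.asarray(axials).T @ np.asarray(intensities)
    if envelope_sigma_ang is not None:
        env = np.exp(
            -4 * math.pi**2 * envelope_sigma_ang**2 * (Z[:, None] ** 2 + R[None, :] ** 2)
        )
        power *= env
    return PowerSpectrum(power, axial_step, radial_step)


def default_mask(shape: tuple[int, int], origin_radius_px: int = 3) -> np.ndarray:
    """Standard correlation mask: everything except the equator row and a
    small disc around the origin (both dominated by low-frequency background)."""
    ny, nx = shape
    mask = np.ones(shape, dtype=bool)
    oy, ox = ny // 2, nx // 2
    mask[oy, :] = False
    yy, xx = np.ogrid[:ny, :nx]
    mask[(yy - oy) ** 2 + (xx - ox) ** 2 <= origin_radius_px**2] = False
    return mask


def amplitude_correlation(
    a: PowerSpectrum, b: PowerSpectrum, mask: np.ndarray | None = None
) -> float:
    """Pearson correlation of square-root amplitudes over a mask."""
    if a.power.shape != b.power.shape:
        raise ValueError(f"shape mismatch: {a.power.shape} vs {b.power.shape}")
    if mask is None:
        mask = default_mask(a.power.shape)
    x = np.sqrt(a.power[mask]).ravel()
    y = np.sqrt(b.power[mask]).ravel()
    x = x - x.mean()
    y = y - y.mean()
    denom = np.linalg.norm(x) * np.linalg.norm(y)
    if denom == 0:
        return 0.0
    return float(np.clip(np.dot(x, y) / denom, -1.0, 1.0))


class GridRefiner:
    """Precomputes model spectra on a symmetry grid for repeated refinement.

    Useful when many experimental spectra (trials) are scored against the same
    grid: node spectra are simulated once and correlation reduces to one
    matrix product per experimental spectrum.
    """

    def __init__(
        self,
        spec: GridSpec,
        radius_ang: float,
        length_ang: float,
        shape: tuple[int, int],
        axial_step: float,
        radial_step: float,
        mask: np.ndarray | None = None,
        handedness: str = "left",
        envelope_sigma_ang: float | None = None,
        n_max: int = 36,
    ):
        self.spec = spec
        self.mask = default_mask(shape) if mask is None else mask
        self.pitches = spec.pitch_values()
        self.upts = spec.upt_values()
        models = []
        for p in self.pitches:
            for q in self.upts:
                sym = pitch_units_to_symmetry(float(p), float(q), handedness)
                ps = simulate_spectrum(
                    sym, radius_ang, length_ang, shape, axial_step, radial_step,
                    n_max=n_max, envelope_sigma_ang=envelope_sigma_ang,
                )
                v = np.sqrt(ps.power[self.mask]).ravel()
                v = v - v.mean()
                nrm = np.linalg.norm(v)
                models.append(v / nrm if nrm > 0 else v)
        self._model_matrix = np.stack(models)  # (n_nodes, n_px)

    def refine(self, experimental: PowerSpectrum) -> tuple[float, float, SymmetryGrid]:
        if experimental.power.shape != self.mask.shape:
            raise ValueError("experimental spectrum shape does not match grid models")
        e = np.sqrt(experimental.power[self.mask]).ravel()
        e = e - e.mean()
        nrm = np.linalg.norm(e)
        if nrm > 0:
            e = e / nrm
        corr = self._model_matrix @ e
        surface = corr.reshape(len(self.pitches), len(self.upts))
        surface = np.clip(surface, -1.0, 1.0)
        best = _argmax_toward_centre(surface)
        return (
            float(self.pitches[best[0]]),
            float(self.upts[best[1]]),
            SymmetryGrid(self.spec, surface),
        )


def _argmax_toward_centre(surface: np.ndarray) -> tuple[int, int]:
    """Argmax of the correlation surface; exact ties go to the node nearest
    the grid centre."""
    flat = surface.ravel()
    m = flat.max()
    ties = np.flatnonzero(flat == m)
    ny, nx = surface.shape
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    iy, ix = np.unravel_index(ties, surface.shape)
    d = (iy - cy) ** 2 + (ix - cx) ** 2
    k = int(ties[np.argmin(d)])
    return k // nx, k % nx


def grid_refine(
    experimental: PowerSpectrum,
    spec: GridSpec,
    radius_ang: float,
    length_ang: float,
    mask: np.ndarray | None = None,
    handedness: str = "left",
    envelope_sigma_ang: float | None = None,
) -> tuple[float, float, SymmetryGrid]:
    """Evaluate the amplitude correlation at every grid node; return the best
    (pitch, units-per-turn) and the full correlation surface."""
    if spec.shape[0] < 1 or spec.shape[1] < 1:
        raise ValueError("empty grid")
    refiner = GridRefiner(
        spec,
        radius_ang,
        length_ang,
        experimental.power.shape,
        experimental.axial_step,
        experimental.radial_step,
        mask=mask,
        handedness=handedness,
        envelope_sigma_ang=envelope_sigma_ang,
    )
    return refiner.refine(experimental)
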