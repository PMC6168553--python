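"""Helical symmetry arithmetic.

A 1-start helix is parameterized either by (twist, rise) — the rotation in
degrees and axial translation in Å applied per subunit — or by
(pitch, units_per_turn), the axial distance of one full 360° turn and the
number of subunits it contains.  The two are related by

    |twist| = 360 / units_per_turn,      rise = pitch / units_per_turn.

Subunit k sits at azimuth ``k * twist`` (right-hand rule about +z) and height
``k * rise`` along +z; a left-handed filament therefore carries negative
twist.  When units_per_turn is close to a rational number u/t the structure
repeats after u subunits in t turns, over a repeat distance c = u * rise, and
layer line l of the diffraction pattern admits Bessel orders n satisfying the
selection rule l = t*n + u*m.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction

__all__ = [
    "HelicalSymmetry",
    "RationalRepeat",
    "SegmentationParams",
    "pitch_units_to_symmetry",
    "symmetry_to_pitch_units",
    "rational_units_per_turn",
    "repeat_distance",
    "asymmetric_units",
    "selection_rule_orders",
]


@dataclass(frozen=True)
class HelicalSymmetry:
    """Twist (deg, signed) and rise (Å) per subunit.

    ``handedness`` is redundant with the sign of twist and is validated
    against it: left-handed helices have negative twist.
    """

    twist_deg: float
    rise_ang: float
    handedness: str = "left"

    def __post_init__(self) -> None:
        if not 0 < abs(self.twist_deg) <= 360:
            raise ValueError(f"twist must satisfy 0 < |twist| <= 360, got {self.twist_deg}")
        if self.rise_ang <= 0:
            raise ValueError(f"rise must be positive, got {self.rise_ang}")
        if self.handedness not in ("left", "right"):
            raise ValueError(f"handedness must be 'left' or 'right', got {self.handedness!r}")
        if (self.handedness == "left") != (self.twist_deg < 0):
            raise ValueError(
                f"handedness {self.handedness!r} inconsistent with twist {self.twist_deg}"
            )

    @property
    def units_per_turn(self) -> float:
        return 360.0 / abs(self.twist_deg)

    @property
    def pitch_ang(self) -> float:
        return self.rise_ang * self.units_per_turn


@dataclass(frozen=True)
class RationalRepeat:
    """u subunits in t turns; repeat distance c = u * rise."""

    u: int
    t: int
    c_ang: float | None = None

    def __post_init__(self) -> None:
        if self.u < 1 or self.t < 1:
            raise ValueError("u and t must be >= 1")
        if math.gcd(self.u, self.t) != 1:
            raise ValueError(f"u={self.u} and t={self.t} must be coprime")

    @property
    def units_per_turn(self) -> float:
        return self.u / self.t


@dataclass(frozen=True)
class SegmentationParams:
    segment_length_ang: float
    step_ang: float
    n_segments: int

    def __post_init__(self) -> None:
        if not 0 < self.step_ang <= self.segment_length_ang:
            raise ValueError("require 0 < step <= segment length")
        if self.n_segments < 0:
            raise ValueError("n_segments must be >= 0")


def pitch_units_to_symmetry(
    pitch_ang: float, units_per_turn: float, handedness: str = "left"
) -> HelicalSymmetry:
    """Convert (pitch, units-per-turn) to (twist, rise)."""
    if pitch_ang <= 0:
        raise ValueError(f"pitch must be positive, got {pitch_ang}")
    if units_per_turn <= 1:
        raise ValueError(f"units_per_turn must exceed 1, got {units_per_turn}")
    twist = 360.0 / units_per_turn
    if handedness == "left":
        twist = -twist
    return HelicalSymmetry(twist, pitch_ang / units_per_turn, handedness)


def symmetry_to_pitch_units(sym: HelicalSymmetry) -> tuple[float, float]:
    """Inverse of :func:`pitch_units_to_symmetry`."""
    return sym.pitch_ang, sym.units_per_turn


def _convergents(x: float, max_den: int):
    """Continued-fraction convergents of x with denominator <= max_den."""
    frac = Fraction(x).limit_denominator(max_den)
    # walk the continued-fraction expansion of x, collecting convergents
    out = []
    a = x
    h0, h1 = 1, int(math.floor(a))
    k0, k1 = 0, 1
    out.append((h1, k1))
    for _ in range(64):
        rem = a - math.floor(a)
        if rem < 1e-12:
            break
        a = 1.0 / rem
        ai = int(math.floor(a))
        h0, h1 = h1, ai * h1 + h0
        k0, k1 = k1, ai * k1 + k0
        if k1 > max_den:
            break
        out.append((h1, k1))
    out.append((frac.numerator, frac.denominator))
    return out


def rational_units_per_turn(units_per_turn: float, max_turns: int) -> RationalRepeat:
    """Best coprime rational approximation u/t to units_per_turn with t <= max_turns.

    Ties in approximation error are resolved toward smaller t.  Continued-fraction
    convergents seed the search; an exhaustive sweep over all t <= max_turns
    guarantees optimality (max_turns is small in practice).
    """
    if units_per_turn <= 1:
        raise ValueError("units_per_turn must exceed 1")
    if max_turns < 1:
        raise ValueError("max_turns must be >= 1")
    best_u, best_t, best_err = None, None, math.inf
    candidates = set(_convergents(units_per_turn, max_turns))
    candidates.update((max(1, round(units_per_turn * t)), t) for t in range(1, max_turns + 1))
    for u, t in sorted(candidates, key=lambda p: p[1]):
        if t > max_turns or t < 1:
            continue
        err = abs(u / t - units_per_turn)
        if err < best_err - 1e-15:
            best_u, best_t, best_err = u, t, err
    g = math.gcd(best_u, best_t)
    return RationalRepeat(best_u // g, best_t // g)


def repeat_distance(u: int, rise_ang: float) -> float:
    """Repeat length c = u * rise (Å)."""
    if u < 1:
        raise ValueError("u must be >= 1")
    if rise_ang <= 0:
        raise ValueError("rise must be positive")
    return u * rise_ang


def asymmetric_units(seg: SegmentationParams, rise_ang: float) -> int:
    """Asymmetric units contributed by a segmented data set after symmetrization.

    Each refinement segment contributes floor(step / rise) unique subunits;
    overlapping parts of consecutive segments are not double-counted.
    """
    if rise_ang <= 0:
        raise ValueError("rise must be positive")
    per_segment = int(seg.step_ang // rise_ang)
    if per_segment == 0:
        warnings.warn(
            "segment step is smaller than the rise: segments contribute no unique subunits",
            stacklevel=2,
        )
    return seg.n_segments * per_segment


def selection_rule_orders(u: int, t: int, l: int, n_max: int) -> list[int]:
    """Bessel orders allowed on layer line l of a (u, t) 1-start helix.

    Returns all n with \\|n\\| <= n_max satisfying l = t*n + u*m for some
    integer m, sorted by \\|n\\| then sign.
    """
    if math.gcd(u, t) != 1:
        raise ValueError(f"u={u}, t={t} must be coprime")
    allowed = [n for n in range(-n_max, n_max + 1) if (l - t * n) % u == 0]
    return sorted(allowed, key=lambda n: (abs(n), n))
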