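"""Seeded generators for every input the pipeline consumes.

All generators take an explicit seed (or a ``numpy.random.Generator``) and are
bit-reproducible.  They emulate, at desk scale, the inputs of a helical
filament study: point/atom filament models with known twist and rise, their
2D projections and layer-line power spectra with additive noise, a toy
CARD-like monomer, paired solution/solid chemical-shift tables with localized
perturbations, and immuno-gold particle annotation tables with a tunable
end-binding preference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .symmetry import HelicalSymmetry

__all__ = [
    "FilamentModel",
    "ImageStack",
    "NoiseModel",
    "make_filament",
    "project_filament",
    "make_toy_monomer",
    "make_shift_tables",
    "make_gold_annotations",
    "make_test_sequence",
    "DEFAULT_PIXEL_SIZE",
    "DEFAULT_BOX",
]

# default image geometry: 1.21 Å/px sampling in 420 px boxes, so that fixture
# spectra are commensurate with typical printed reciprocal-space spacings
DEFAULT_PIXEL_SIZE = 1.21
DEFAULT_BOX = 420


@dataclass
class NoiseModel:
    """Additive white Gaussian noise, optionally with a reciprocal-space
    Gaussian envelope applied to the signal before noise is added."""

    sigma: float = 0.0
    envelope_sigma_px: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")


@dataclass
class FilamentModel:
    """Expanded helical arrangement of point scatterers.

    ``asym_unit`` lists scatterers of one subunit as (radius Å, azimuth deg,
    axial offset Å); ``positions`` holds the expanded Cartesian coordinates,
    one row per scatterer per subunit.
    """

    asym_unit: list[tuple[float, float, float]]
    symmetry: HelicalSymmetry
    length_ang: float
    positions: np.ndarray = field(repr=False, default=None)

    @property
    def n_subunits(self) -> int:
        return int(self.length_ang // self.symmetry.rise_ang)


@dataclass
class ImageStack:
    """Stack of 2D images (filament axis vertical), constant pixel size."""

    images: np.ndarray  # (n, ny, nx)
    pixel_size_ang: float

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        if self.images.ndim == 2:
            self.images = self.images[None]
        if self.images.ndim != 3:
            raise ValueError("images must be a (n, ny, nx) array")
        if self.pixel_size_ang <= 0:
            raise ValueError("pixel size must be positive")

    def __len__(self) -> int:
        return len(self.images)


def make_filament(
    asym_unit: list[tuple[float, float, float]],
    symmetry: HelicalSymmetry,
    length_ang: float,
    phase_deg: float = 0.0,
) -> FilamentModel:
    """Expand one asymmetric unit along a helix of given symmetry.

    Subunit k places each scatterer (r, φ, z) at azimuth φ + phase + k*twist
    and height z + k*rise.  ``length_ang`` must be at least one rise; the
    expanded model has floor(length / rise) subunits.
    """
    if length_ang < symmetry.rise_ang:
        raise ValueError(
            f"length {length_ang} Å is shorter than one rise ({symmetry.rise_ang} Å)"
        )
    if any(r < 0 for r, _, _ in asym_unit):
        raise ValueError("scatterer radii must be >= 0")
    n_sub = int(length_ang // symmetry.rise_ang)
    k = np.arange(n_sub)
    pos = []
    for r, phi, z in asym_unit:
        ang = np.deg2rad(phi + phase_deg + k * symmetry.twist_deg)
        pos.append(np.stack([r * np.cos(ang), r * np.sin(ang), z + k * symmetry.rise_ang], axis=1))
    positions = (
        np.concatenate(pos, axis=0) if pos else np.empty((0, 3))
    )
    return FilamentModel(list(asym_unit), symmetry, length_ang, positions)


def _render_gaussians(
    xy: np.ndarray, box: int, sigma_px: float, amplitudes: np.ndarray | None = None
) -> np.ndarray:
    """Accumulate isotropic 2D Gaussians (σ in px) at (x, y) pixel coords."""
    img = np.zeros((box, box))
    half = max(3, int(math.ceil(4 * sigma_px)))
    amps = np.ones(len(xy)) if amplitudes is None else amplitudes
    grid = np.arange(-half, half + 1)
    for (x, y), a in zip(xy, amps):
        ix, iy = int(round(x)), int(round(y))
        if not (-half <= ix < box + half and -half <= iy < box + half):
            continue
        gx = np.exp(-((grid + ix - x) ** 2) / (2 * sigma_px**2))
        gy = np.exp(-((grid + iy - y) ** 2) / (2 * sigma_px**2))
        x0, x1 = max(0, ix - half), min(box, ix + half + 1)
        y0, y1 = max(0, iy - half), min(box, iy + half + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        img[y0:y1, x0:x1] += a * np.outer(
            gy[y0 - (iy - half) : y1 - (iy - half)], gx[x0 - (ix - half) : x1 - (ix - half)]
        )
    return img


def project_filament(
    model: FilamentModel,
    pixel_size_ang: float = DEFAULT_PIXEL_SIZE,
    box: int = DEFAULT_BOX,
    noise: NoiseModel | None = None,
    scatterer_sigma_px: float = 2.0,
    rng: np.random.Generator | None = None,
) -> ImageStack:
    """Project a filament model along +y onto a (box, box) image.

    Each scatterer is rendered as an isotropic Gaussian of ``scatterer_sigma_px``
    pixels; the filament axis is vertical and centred.  Additive Gaussian noise
    is applied last.
    """
    noise = noise or NoiseModel()
    rng = rng if rng is not None else np.random.default_rng(noise.seed)
    pos = model.positions if model.positions is not None else np.empty((0, 3))
    if len(pos):
        r_needed = 2 * (np.abs(pos[:, 0]).max() + 4 * scatterer_sigma_px * pixel_size_ang)
        if r_needed > box * pixel_size_ang:
            raise ValueError(
                f"box of {box} px at {pixel_size_ang} Å/px cannot contain the filament; "
                f"need at least {int(math.ceil(r_needed / pixel_size_ang))} px"
            )
    cx = box / 2.0
    # centre the box on the filament mid-length (not the atom extent, so that
    # projections of scatterer subsets share one frame)
    z0 = model.length_ang / 2.0
    xy = np.stack(
        [pos[:, 0] / pixel_size_ang + cx, (pos[:, 2] - z0) / pixel_size_ang + cx], axis=1
    ) if len(pos) else np.empty((0, 2))
    img = _render_gaussians(xy, box, scatterer_sigma_px)
    if noise.sigma > 0:
        img = img + rng.normal(0.0, noise.sigma, img.shape)
    return ImageStack(img[None], pixel_size_ang)


def project_segments(
    asym_unit: list[tuple[float, float, float]],
    symmetry: HelicalSymmetry,
    length_ang: float,
    n_segments: int,
    pixel_size_ang: float = DEFAULT_PIXEL_SIZE,
    box: int = DEFAULT_BOX,
    noise: NoiseModel | None = None,
    scatterer_sigma_px: float = 2.0,
) -> ImageStack:
    """Simulate an extracted segment stack: each segment is an independently
    noised projection of the same helix at a random azimuthal phase.

    Random phases emulate segments cut at different points along a filament;
    the power spectrum of every segment shares the same layer-line geometry.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    imgs = []
    for _ in range(n_segments):
        phase = rng.uniform(0.0, 360.0)
        model = make_filament(asym_unit, symmetry, length_ang, phase_deg=phase)
        imgs.append(
            project_filament(
                model, pixel_size_ang, box, NoiseModel(noise.sigma), scatterer_sigma_px, rng=rng
            ).images[0]
        )
    return ImageStack(np.stack(imgs), pixel_size_ang)


# ---------------------------------------------------------------------------
# toy monomer


def make_toy_monomer(
    n_residues: int = 8,
    first_resnum: int = 433,
    radius_ang: float = 10.0,
    domain_radius_ang: float = 7.0,
    rng: np.random.Generator | None = None,
) -> "pd.DataFrame":
    """Small globular toy monomer as an atom table.

    Residues are spread over a sphere of ``domain_radius_ang`` centred at
    cylindrical radius ``radius_ang`` on the x axis (golden-spiral layout),
    each with N, CA, C, O, CB heavy atoms, so that helical expansion at
    single-digit rises produces genuine inter-subunit contacts.  Returned as
    a DataFrame with columns serial, name, resname, resnum, chain, x, y, z,
    element.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    rows = []
    serial = 1
    offsets = {
        "N": (-0.8, 0.6, -0.7),
        "CA": (0.0, 0.0, 0.0),
        "C": (1.0, 0.4, 0.6),
        "O": (1.2, 1.6, 0.8),
        "CB": (0.2, -1.4, 0.8),
    }
    golden = math.pi * (3.0 - math.sqrt(5.0))
    centre = np.array([radius_ang, 0.0, 0.0])
    for i in range(n_residues):
        # golden-spiral point on the sphere
        u = 1.0 - 2.0 * (i + 0.5) / n_residues
        r_xy = math.sqrt(max(0.0, 1.0 - u * u))
        ang = golden * i
        direction = np.array([r_xy * math.cos(ang), r_xy * math.sin(ang), u])
        base = centre + domain_radius_ang * direction
        jitter = rng.normal(0, 0.05, 3)
        for name, off in offsets.items():
            x, y, zz = base + np.array(off) + jitter
            rows.append(
                (serial, name, "ALA", first_resnum + i, "A", x, y, zz, name[0])
            )
            serial += 1
    return pd.DataFrame(
        rows, columns=["serial", "name", "resname", "resnum", "chain", "x", "y", "z", "element"]
    )


# ---------------------------------------------------------------------------
# chemical-shift tables

# representative Cα/Cβ base shifts per residue type (ppm); the generator only
# needs plausible magnitudes, tests never assert these numbers
_BASE_CA = {
    "A": 52.5, "C": 58.2, "D": 54.2, "E": 56.6, "F": 57.7, "G": 45.1, "H": 55.0,
    "I": 61.1, "K": 56.2, "L": 55.1, "M": 55.4, "N": 53.1, "P": 63.3, "Q": 55.7,
    "R": 56.0, "S": 58.3, "T": 61.8, "V": 62.2, "W": 57.5, "Y": 57.9,
}
_BASE_CB = {
    "A": 19.1, "C": 28.0, "D": 41.1, "E": 29.9, "F": 39.6, "H": 29.0, "I": 38.8,
    "K": 33.1, "L": 42.4, "M": 32.9, "N": 38.9, "P": 32.1, "Q": 29.4, "R": 30.9,
    "S": 63.8, "T": 69.8, "V": 32.9, "W": 29.6, "Y": 38.8,
}


def make_shift_tables(
    sequence: str,
    first_resnum: int = 433,
    perturbed_residues: dict[int, tuple[float, float]] | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired solution/solid chemical-shift tables (long format).

    The solid-state table equals the solution table plus the stated per-residue
    (ΔCα, ΔCβ) perturbations plus Gaussian noise of ``noise_sigma`` ppm on every
    solid entry.  Glycines carry no Cβ row.  Tables have columns
    resnum, aa, atom, shift_ppm.
    """
    perturbed_residues = perturbed_residues or {}
    resnums = range(first_resnum, first_resnum + len(sequence))
    valid = set(resnums)
    for rn in perturbed_residues:
        if rn not in valid:
            raise ValueError(f"perturbed residue {rn} outside sequence range")
    rng = np.random.default_rng(seed)
    sol_rows, ssn_rows = [], []
    for rn, aa in zip(resnums, sequence):
        dca, dcb = perturbed_residues.get(rn, (0.0, 0.0))
        ca = _BASE_CA[aa]
        sol_rows.append((rn, aa, "CA", ca))
        ssn_rows.append((rn, aa, "CA", ca + dca + rng.normal(0, noise_sigma)))
        if aa != "G":
            cb = _BASE_CB[aa]
            sol_rows.append((rn, aa, "CB", cb))
            ssn_rows.append((rn, aa, "CB", cb + dcb + rng.normal(0, noise_sigma)))
    cols = ["resnum", "aa", "atom", "shift_ppm"]
    return pd.DataFrame(sol_rows, columns=cols), pd.DataFrame(ssn_rows, columns=cols)


def make_test_sequence() -> tuple[str, int]:
    """Deterministic 108-residue test sequence (numbered 433-540).

    Composition mirrors a CARD construct used for signal counting: 14 Leu,
    6 Thr, 7 Val and 4 Pro, with 5 Leu, 0 Thr, 2 Val and 3 Pro falling in the
    disordered C-terminal tail (residues 512-540), so that masking the tail
    leaves 9/14 L, 6/6 T, 5/7 V and 1/4 P visible.
    """
    filler = "AEQSKDNRHMIFYWG"  # no L/T/V/P
    core = [filler[i % len(filler)] for i in range(79)]   # residues 433..511
    tail = [filler[(i + 7) % len(filler)] for i in range(29)]  # residues 512..540
    for idx, aa in [(5, "L"), (13, "L"), (24, "L"), (36, "L"), (48, "L"),
                    (57, "L"), (63, "L"), (70, "L"), (77, "L"),
                    (8, "T"), (18, "T"), (29, "T"), (41, "T"), (52, "T"), (66, "T"),
                    (3, "V"), (15, "V"), (33, "V"), (45, "V"), (60, "V"),
                    (26, "P")]:
        core[idx] = aa
    for idx, aa in [(2, "L"), (7, "L"), (13, "L"), (19, "L"), (25, "L"),
                    (6, "V"), (16, "V"), (10, "P"), (21, "P"), (27, "P")]:
        tail[idx] = aa
    seq = "".join(core + tail)
    return seq, 433


# ---------------------------------------------------------------------------
# immuno-gold annotations


def make_gold_annotations(
    n_images: int = 20,
    filaments_per_image: int = 5,
    particles_per_filament: float = 2.0,
    end_preference: float = 0.9,
    off_filament_rate: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic immuno-gold particle annotation table.

    Each particle is off-filament with probability ``off_filament_rate``;
    otherwise it lands on a filament end with probability ``end_preference``
    and on the filament body otherwise.  Columns: image_id, particle_id,
    location, filament_id (empty for off-filament particles).
    """
    if not 0 <= end_preference <= 1:
        raise ValueError("end_preference must be in [0, 1]")
    if not 0 <= off_filament_rate <= 1:
        raise ValueError("off_filament_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for img in range(n_images):
        n_particles = rng.poisson(filaments_per_image * particles_per_filament)
        for pid in range(n_particles):
            if rng.random() < off_filament_rate:
                rows.append((img, pid, "off", ""))
                continue
            fid = int(rng.integers(filaments_per_image))
            loc = "on_end" if rng.random() < end_preference else "on_body"
            rows.append((img, pid, loc, f"f{img}_{fid}"))
    return pd.DataFrame(rows, columns=["image_id", "particle_id", "location", "filament_id"])
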