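import numpy as np
import pytest

from helifil.assembly import Structure
from helifil.layerlines import average_power_spectrum
from helifil.refine import PAPER_GRID, GridRefiner
from helifil.simulate import NoiseModel, make_toy_monomer, project_segments
from helifil.symmetry import pitch_units_to_symmetry

# imaging geometry shared by the synthetic-recovery tests
PIXEL_SIZE = 1.21
BOX = 420
FILAMENT_LENGTH = 400.0
SCATTERER_RADIUS = 25.0
BLOB_SIGMA_PX = 2.0


@pytest.fixture(scope="session")
def paper_symmetry():
    """Helical symmetry of the study filament: pitch 17.26 Å, 3.56 units/turn,
    left-handed (twist -101.124°, rise 4.848 Å)."""
    return pitch_units_to_symmetry(17.26, 3.56, "left")


@pytest.fixture(scope="session")
def noiseless_spectrum(paper_symmetry):
    """Averaged power spectrum of a noiseless projected filament segment."""
    stack = project_segments(
        [(SCATTERER_RADIUS, 0.0, 0.0)],
        paper_symmetry,
        FILAMENT_LENGTH,
        1,
        pixel_size_ang=PIXEL_SIZE,
        box=BOX,
        noise=NoiseModel(0.0, seed=7),
    )
    return average_power_spectrum(stack)


@pytest.fixture(scope="session")
def signal_sigma(paper_symmetry):
    """Real-space standard deviation of the noiseless projection; additive
    noise of this sigma gives SNR = 1."""
    stack = project_segments(
        [(SCATTERER_RADIUS, 0.0, 0.0)],
        paper_symmetry,
        FILAMENT_LENGTH,
        1,
        pixel_size_ang=PIXEL_SIZE,
        box=BOX,
        noise=NoiseModel(0.0, seed=7),
    )
    return float(stack.images[0].std())


@pytest.fixture(scope="session")
def paper_grid_refiner(noiseless_spectrum):
    """Model spectra precomputed on the 11x11 refinement grid (shared: the
    precompute dominates the cost of every grid-refinement test)."""
    ps = noiseless_spectrum
    return GridRefiner(
        PAPER_GRID,
        SCATTERER_RADIUS,
        FILAMENT_LENGTH,
        ps.power.shape,
        ps.axial_step,
        ps.radial_step,
        envelope_sigma_ang=BLOB_SIGMA_PX * PIXEL_SIZE,
    )


@pytest.fixture()
def toy_monomer():
    return Structure(make_toy_monomer())
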