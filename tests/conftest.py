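import numpy as np
import pytest

import tfocc

TEST_SEED = 101


def toy_landscape(energies, tau0=1.0, footprint=1):
    """Single-strand landscape from an explicit energy vector."""
    e = np.asarray(energies, dtype=float)[:, None]
    return tfocc.EnergyLandscape(energies=e, tau0=tau0, scaling=1.0,
                                 footprint=footprint)


def single_molecule_config(landscape, dna_length, k_assoc=1.0,
                           move_probs=(0.4, 0.4, 0.1, 0.1), hop_range=5,
                           t_end=1e5, seed=0, footprint=1):
    sp = tfocc.SpeciesParams(name="tf", footprint=footprint, abundance=1,
                             k_assoc=k_assoc, landscape=landscape,
                             move_probs=move_probs, hop_range=hop_range)
    return tfocc.SimConfig(dna_length=dna_length, species=[sp], t_end=t_end,
                           seed=seed)


@pytest.fixture(scope="session")
def design():
    """Default study design (desk scale)."""
    return tfocc.StudyDesign()


@pytest.fixture(scope="session")
def substrate(design):
    """The default 10 kb synthetic substrate at a fixed seed."""
    return design.substrate(TEST_SEED)


@pytest.fixture(scope="session")
def strong_sites(design, substrate):
    return tfocc.select_strong_sites(substrate.landscape, design.strong_fraction)


@pytest.fixture(scope="session")
def ratio_cells(design, substrate):
    """Reduced-scale versions of the three headline abundance/crowding cells.

    Keyed by (abundance, coverage); each value is a CellResult computed
    from 12 hybrid replicates.
    """
    cells = {}
    for abundance, coverage in [(1, 0.26), (10, 0.0), (10, 0.26), (10, 0.55)]:
        t_rep = 1.0e6 if abundance == 1 else 2.0e5
        cells[(abundance, coverage)] = tfocc.run_cell(
            design, substrate, abundance, coverage,
            seed=TEST_SEED + 31 * abundance + int(coverage * 100),
            n_reps=12, t_rep=t_rep)
    return cells


@pytest.fixture(scope="session")
def abundance_cells(design, substrate):
    """Abundance sweep (no crowding) spanning three orders of magnitude."""
    cells = {}
    for abundance in (1, 10, 100, 1000):
        t_rep = max(8.0e5 / abundance, 4.0e4)
        cells[abundance] = tfocc.run_cell(
            design, substrate, abundance, 0.0,
            seed=TEST_SEED + 7 * abundance, n_reps=6, t_rep=t_rep)
    return cells
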