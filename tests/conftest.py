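"""Shared fixtures: small synthetic systems and pre-sampled macrostate grids."""

import numpy as np
import pytest

from qsfr import (
    ConstraintInventory,
    DCMParameters,
    SyntheticSystemSpec,
    build_peptide,
    sample_grid,
)


@pytest.fixture(scope="session")
def helix_spec():
    return SyntheticSystemSpec(sequence="A" * 12, fold_template="helix", n_frames=10)


@pytest.fixture(scope="session")
def helix(helix_spec):
    """12-residue poly-alanine alpha helix with polar hydrogens."""
    return build_peptide(helix_spec)


@pytest.fixture(scope="session")
def helix_inventory(helix):
    return ConstraintInventory.from_conformation(helix)


@pytest.fixture(scope="session")
def chain():
    """Extended 8-residue chain: no H-bonds, fully floppy backbone."""
    spec = SyntheticSystemSpec(sequence="A" * 8, fold_template="coil", n_frames=10)
    return build_peptide(spec)


@pytest.fixture(scope="session")
def chain_inventory(chain):
    return ConstraintInventory.from_conformation(chain)


@pytest.fixture(scope="session")
def helix_grid(helix_inventory):
    """Moderate-resolution sampled grid with mechanical statistics."""
    return sample_grid(
        helix_inventory, params=DCMParameters(), n_samples=40, seed=5,
        collect_mech=True,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
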