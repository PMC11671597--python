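import numpy as np
import pytest

from dartsdeconv import synthetic
from dartsdeconv.coverage import ProteinRecord


@pytest.fixture(scope="session")
def small_proteome() -> list[ProteinRecord]:
    return synthetic.generate_proteome(
        synthetic.ProteomeSpec(n_proteins=10, length_range=(60, 200), seed=11)
    )


@pytest.fixture()
def contact_ensemble():
    """Toy complex: anionic side chain of residue 1 contacts a +1 ligand at
    3 A; residues 2..4 are neutral; no LJ; single noiseless snapshot."""
    spec = synthetic.ToyComplexSpec(
        n_residues=4,
        atoms_per_residue=6,
        ligand_charge=1.0,
        n_snapshots=1,
        seed=0,
        jitter=0.0,
        contact_residue=1,
        residue_charges={1: -1.0},
    )
    return synthetic.generate_toy_complex(spec)


@pytest.fixture()
def jittered_ensemble():
    spec = synthetic.ToyComplexSpec(
        n_residues=5,
        atoms_per_residue=6,
        ligand_charge=1.0,
        n_snapshots=8,
        seed=3,
        jitter=0.15,
        contact_residue=2,
        residue_charges={2: -1.0, 4: 0.5},
        residue_lj={3: (0.2, 3.5)},
    )
    return synthetic.generate_toy_complex(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
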