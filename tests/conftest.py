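import numpy as np
import pytest

from vcdkit.ensemble import Conformer, EnergyRecord, Ensemble


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_conformer(rng, n_atoms=5, label="c", energy=None):
    atoms = (["C", "N", "O", "H"] * n_atoms)[:n_atoms]
    coords = rng.normal(scale=2.0, size=(n_atoms, 3))
    return Conformer(atoms=atoms, coords=coords, energy=energy, label=label)


@pytest.fixture
def toy_ensemble(rng):
    """Three conformers sharing one atom identity, distinct energies."""
    confs = []
    base = rng.normal(scale=2.0, size=(5, 3))
    for k in range(3):
        coords = base + rng.normal(scale=0.8, size=base.shape) * (k > 0)
        rec = EnergyRecord(electronic=-100.0 + 0.002 * k, gibbs=-99.9 + 0.002 * k)
        confs.append(
            Conformer(atoms=["C", "N", "O", "C", "H"], coords=coords, energy=rec, label=f"c{k + 1}")
        )
    return Ensemble(conformers=confs)


@pytest.fixture
def amide_i_sticks():
    """Four amide I bands with the -/+/+/- sign pattern (unit magnitudes)."""
    from vcdkit.spectra import StickSpectrum

    return StickSpectrum(
        modality="VCD",
        frequencies=np.array([1643.0, 1650.0, 1668.0, 1673.0]),
        strengths=np.array([-1.0, +1.0, +1.0, -1.0]),
        conformer_label="1a",
    )
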