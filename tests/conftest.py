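import numpy as np
import pytest

from seventm.structures import Atom, Residue, Structure
from seventm.synthetic import (
    ActivationSpec,
    BundleSpec,
    HelixSpec,
    build_bundle,
    build_ideal_helix,
    bundle_segments,
    simulate_ensemble,
)


def add_noise(structure: Structure, sd: float, rng: np.random.Generator) -> Structure:
    noisy = structure.copy()
    for res in noisy.residues:
        for atom in res.atoms.values():
            atom.coords = atom.coords + rng.normal(0.0, sd, 3)
    return noisy


def make_structure(coords_by_residue, start_author=1, amino_acid="A", generic_start=None) -> Structure:
    """Structure from a list of {atom_name: xyz} dicts."""
    residues = []
    for i, atoms in enumerate(coords_by_residue):
        residues.append(
            Residue(
                author_number=start_author + i,
                amino_acid=amino_acid,
                generic_number=None if generic_start is None else generic_start + i,
                atoms={name: Atom(name, np.asarray(xyz, float)) for name, xyz in atoms.items()},
            )
        )
    return Structure("fixture", residues)


@pytest.fixture(scope="session")
def alpha_helix() -> Structure:
    return build_ideal_helix(HelixSpec(n_residues=20), start_generic=501)


@pytest.fixture(scope="session")
def bulge_helix() -> Structure:
    return build_ideal_helix(HelixSpec(n_residues=24, bulge_positions=(11,)), start_generic=501)


@pytest.fixture(scope="session")
def bundle_pair():
    """A noise-free bundle and a copy with bulges planted in TM2 and TM5."""
    plain = BundleSpec(tuple(HelixSpec(n_residues=29) for _ in range(7)))
    bulged = BundleSpec(
        tuple(
            HelixSpec(n_residues=29, bulge_positions=(14,) if h in (2, 5) else ())
            for h in range(1, 8)
        )
    )
    return build_bundle(plain, "plain"), build_bundle(bulged, "bulged"), bundle_segments(plain)


@pytest.fixture(scope="session")
def small_ensemble():
    """16-structure two-class ensemble with the planted activation motions."""
    spec = BundleSpec(tuple(HelixSpec(n_residues=12) for _ in range(7)), noise_sd=0.1, seed=0)
    structures, labels, truth = simulate_ensemble(
        spec, ActivationSpec(tm6_rotation_deg=30.0, tm3_translation_A=1.0), n_per_class=8, seed=11
    )
    return structures, labels, truth, bundle_segments(spec)
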