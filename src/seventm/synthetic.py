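"""Synthetic backbone generators: ideal helices, seven-helix bundles, and
labelled two-class ensembles with planted activation motions.

Backbones are grown residue by residue from internal coordinates (the NeRF
chain-extension scheme) with standard peptide geometry, so the generated
helices have physically sensible hydrogen-bonding patterns: an α stretch
(φ=−57°, ψ=−47°) produces i→i+4 bonds, a planted π window (φ=−76°,
ψ=−55°, calibrated once against the assignment module and frozen)
produces the i→i+5 pattern that the secondary-structure module
reports as an α-bulge, and a 3₁₀ window (φ≈−49°, ψ≈−26°) produces i→i+3
bonds.

The bundle generator emulates the topology of a Class A GPCR: seven
roughly antiparallel helices on a ring, renumbered helix*100+k, with the
membrane normal along +z and the extracellular side at the top.  Planted
activation motions follow the canonical active/inactive contrast: a rigid
whole-helix rotation of TM6 about a membrane-parallel axis (the cytosolic
end swings outward) and a small translation of TM3 toward the
extracellular side.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import Atom, Residue, Structure, SegmentTable, write_pdb

__all__ = [
    "HelixSpec",
    "BundleSpec",
    "ActivationSpec",
    "ALPHA_DIHEDRALS",
    "PI_DIHEDRALS",
    "THREE_TEN_DIHEDRALS",
    "place_atom",
    "build_ideal_helix",
    "build_bundle",
    "bundle_segments",
    "simulate_ensemble",
    "write_ensemble",
]

# Canonical backbone dihedrals (degrees).
ALPHA_DIHEDRALS = (-57.0, -47.0)
PI_DIHEDRALS = (-76.0, -55.0)
THREE_TEN_DIHEDRALS = (-49.0, -26.0)

# Standard peptide bond lengths (Å) and angles (degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 117.0
ANGLE_C_N_CA = 121.0
ANGLE_CA_C_O = 120.8


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    length: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Place atom ``d`` with bond length ``|c-d|``, angle b-c-d and torsion
    a-b-c-d given (natural-extension reference frame)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = length * np.array(
        [-np.cos(angle), np.cos(torsion) * np.sin(angle), np.sin(torsion) * np.sin(angle)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


@dataclass
class HelixSpec:
    """Recipe for one ideal helix.

    ``bulge_positions`` are 0-based residue indices; a 5-residue window
    starting one residue before each is switched to π dihedrals, planting
    an α-bulge whose i→i+5 bonding the assignment module detects (the
    window width was calibrated once for robust detection under coordinate
    noise and is frozen by a regression test).  Positions must sit at
    least 4 residues from either end so the flanking α context survives.
    """

    n_residues: int = 29
    phi: float = ALPHA_DIHEDRALS[0]
    psi: float = ALPHA_DIHEDRALS[1]
    omega: float = 180.0
    bulge_positions: tuple[int, ...] = ()
    three_ten_positions: tuple[int, ...] = ()
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    prolines_at_bulges: bool = False

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise ValueError("a helix needs at least 4 residues")
        for p in self.bulge_positions:
            if p < 4 or p > self.n_residues - 5:
                raise ValueError(
                    f"bulge position {p} must lie >= 4 residues from either end"
                )

    def dihedral_table(self) -> np.ndarray:
        """(n, 3) array of per-residue (φ, ψ, ω)."""
        table = np.tile([self.phi, self.psi, self.omega], (self.n_residues, 1))
        for p in self.three_ten_positions:
            for i in range(max(p - 1, 0), min(p + 2, self.n_residues)):
                table[i, :2] = THREE_TEN_DIHEDRALS
        for p in self.bulge_positions:
            for i in range(p - 1, min(p + 4, self.n_residues)):
                table[i, :2] = PI_DIHEDRALS
        return table


def _build_backbone(dihedrals: np.ndarray) -> list[dict[str, np.ndarray]]:
    """Grow N/CA/C/O coordinates from the per-residue (φ, ψ, ω) table."""
    n_res = len(dihedrals)
    residues: list[dict[str, np.ndarray]] = []
    # Seed the first three backbone atoms in an arbitrary frame.
    n0 = np.zeros(3)
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = residues[-1]
        psi_prev = dihedrals[i - 1, 1]
        omega_prev = dihedrals[i - 1, 2]
        phi = dihedrals[i, 0]
        n = place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca = place_atom(prev["CA"], prev["C"], n, BOND_N_CA, ANGLE_C_N_CA, omega_prev)
        c = place_atom(prev["C"], n, ca, BOND_CA_C, ANGLE_N_CA_C, phi)
        residues.append({"N": n, "CA": ca, "C": c})
    # Carbonyl oxygens: in the peptide plane, opposite N(i+1) (torsion ψ+180°).
    for i, res in enumerate(residues):
        psi = dihedrals[i, 1]
        res["O"] = place_atom(res["N"], res["CA"], res["C"], BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
    return residues


def build_ideal_helix(spec: HelixSpec, start_generic: int | None = None) -> Structure:
    """Build the helix, oriented along ``spec.axis_direction`` with its Cα
    centroid at ``spec.origin``.  Author numbers run 1..n; generic numbers
    are attached sequentially from ``start_generic`` when given."""
    backbone = _build_backbone(spec.dihedral_table())
    ca = np.array([r["CA"] for r in backbone])
    centroid = ca.mean(axis=0)
    # Principal Cα direction, oriented first -> last residue.
    _, _, vt = np.linalg.svd(ca - centroid)
    axis = vt[0]
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    target = np.asarray(spec.axis_direction, dtype=float)
    target = target / np.linalg.norm(target)
    rot, _ = Rotation.align_vectors(target[None, :], axis[None, :])
    mat = rot.as_matrix()
    origin = np.asarray(spec.origin, dtype=float)

    # The conserved proline sits where the regular helix resumes after the
    # widening — the first residue past the π window.
    proline_sites = {p + 4 for p in spec.bulge_positions} if spec.prolines_at_bulges else set()
    residues: list[Residue] = []
    for i, atoms in enumerate(backbone):
        aa = "P" if i in proline_sites else "A"
        res = Residue(
            author_number=i + 1,
            amino_acid=aa,
            generic_number=None if start_generic is None else start_generic + i,
            atoms={
                name: Atom(name, mat @ (xyz - centroid) + origin)
                for name, xyz in atoms.items()
            },
        )
        residues.append(res)
    return Structure(id="helix", residues=residues)


@dataclass
class BundleSpec:
    """Seven helices on a ring with alternating up/down orientation.

    Odd helices (TM1, 3, 5, 7) run extracellular→cytosolic (axis −z), even
    ones the other way, mirroring the receptor topology where the
    N-terminus is extracellular.  Generic numbers start at helix*100+1.
    """

    helices: tuple[HelixSpec, ...] = field(
        default_factory=lambda: tuple(HelixSpec() for _ in range(7))
    )
    ring_radius: float = 11.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.helices) != 7:
            raise ValueError("a bundle has exactly 7 helices")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def bundle_segments(spec: BundleSpec) -> SegmentTable:
    """Segment table matching the generic numbering laid down by the generator."""
    return SegmentTable(
        {
            f"TM{h}": (h * 100 + 1, h * 100 + spec.helices[h - 1].n_residues)
            for h in range(1, 8)
        }
    )


def build_bundle(spec: BundleSpec, structure_id: str = "bundle") -> Structure:
    """Place the seven helices, renumber, and add seeded isotropic noise."""
    import logging

    rng = np.random.default_rng(spec.seed)
    residues: list[Residue] = []
    author = 0
    for h in range(1, 8):
        hspec = spec.helices[h - 1]
        theta = 2.0 * np.pi * (h - 1) / 7.0
        origin = (spec.ring_radius * np.cos(theta), spec.ring_radius * np.sin(theta), 0.0)
        axis = (0.0, 0.0, -1.0) if h % 2 == 1 else (0.0, 0.0, 1.0)
        placed = HelixSpec(
            n_residues=hspec.n_residues,
            phi=hspec.phi,
            psi=hspec.psi,
            omega=hspec.omega,
            bulge_positions=hspec.bulge_positions,
            three_ten_positions=hspec.three_ten_positions,
            origin=origin,
            axis_direction=axis,
            prolines_at_bulges=hspec.prolines_at_bulges,
        )
        helix = build_ideal_helix(placed, start_generic=h * 100 + 1)
        for res in helix.residues:
            author += 1
            res.author_number = author
            residues.append(res)
    structure = Structure(id=structure_id, residues=residues)
    if spec.noise_sd > 0:
        for res in structure.residues:
            for atom in res.atoms.values():
                atom.coords = atom.coords + rng.normal(0.0, spec.noise_sd, 3)
    ca = structure.ca_array()
    helix_slices = np.repeat(np.arange(7), [h.n_residues for h in spec.helices])
    min_sep = np.inf
    for a in range(7):
        for b in range(a + 1, 7):
            d = np.linalg.norm(ca[helix_slices == a][:, None] - ca[helix_slices == b][None], axis=-1)
            min_sep = min(min_sep, float(d.min()))
    if min_sep < 3.0:
        logging.getLogger(__name__).warning(
            "bundle %s: helices overlap (min inter-helix Cα distance %.2f Å)", structure_id, min_sep
        )
    return structure


@dataclass
class ActivationSpec:
    """Planted activation motions for the active class.

    ``tm6_rotation_deg`` rotates the whole of TM6 about a membrane-parallel
    axis through its Cα midpoint so that the cytosolic end swings outward;
    ``tm3_translation_A`` slides TM3 along the membrane normal toward the
    extracellular side.
    """

    tm6_rotation_deg: float = 30.0
    tm3_translation_A: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tm6_rotation_deg <= 60.0:
            raise ValueError("tm6_rotation_deg must be in [0, 60]")
        if not 0.0 <= self.tm3_translation_A <= 3.0:
            raise ValueError("tm3_translation_A must be in [0, 3]")


def _helix_residues(structure: Structure, helix: int) -> list[Residue]:
    lo, hi = helix * 100 + 1, helix * 100 + 99
    return [r for r in structure.residues if r.generic_number is not None and lo <= r.generic_number <= hi]


def _apply_activation(structure: Structure, activation: ActivationSpec) -> None:
    # TM6: rigid rotation about the ring-tangent axis through the helix midpoint.
    tm6 = _helix_residues(structure, 6)
    ca6 = np.array([r.coords("CA") for r in tm6])
    mid = ca6.mean(axis=0)
    radial = np.array([mid[0], mid[1], 0.0])
    radial = radial / np.linalg.norm(radial)
    tangent = np.cross(np.array([0.0, 0.0, 1.0]), radial)
    rot = Rotation.from_rotvec(np.deg2rad(activation.tm6_rotation_deg) * tangent)
    # Orient the rotation so the cytosolic end (low generic numbers, -z for TM6)
    # moves radially outward.
    cyt_end = ca6[0]
    moved = rot.as_matrix() @ (cyt_end - mid) + mid
    if np.dot(moved - cyt_end, radial) < 0:
        rot = rot.inv()
    mat = rot.as_matrix()
    for res in tm6:
        for atom in res.atoms.values():
            atom.coords = mat @ (atom.coords - mid) + mid
    # TM3: translation along the membrane normal toward the extracellular side (+z).
    shift = np.array([0.0, 0.0, activation.tm3_translation_A])
    for res in _helix_residues(structure, 3):
        for atom in res.atoms.values():
            atom.coords = atom.coords + shift


def simulate_ensemble(
    bundle: BundleSpec,
    activation: ActivationSpec,
    n_per_class: int = 8,
    seed: int = 0,
) -> tuple[list[Structure], dict[str, str], dict]:
    """Generate a labelled two-class ensemble.

    Inactive replicates are the base bundle plus fresh isotropic noise;
    active replicates first receive the planted TM6 rotation and TM3
    translation.  Returns the structures, an id→label map, and the
    ground-truth motion record used by recovery tests.
    """
    if n_per_class < 2:
        raise ValueError("need at least 2 structures per class")
    base = build_bundle(
        BundleSpec(bundle.helices, bundle.ring_radius, noise_sd=0.0, seed=bundle.seed),
        structure_id="base",
    )
    active_base = base.copy()
    _apply_activation(active_base, activation)

    rng = np.random.default_rng(seed)
    structures: list[Structure] = []
    labels: dict[str, str] = {}
    for label, template in (("inactive", base), ("active", active_base)):
        for k in range(n_per_class):
            rep = template.copy()
            rep.id = f"{label}_{k}"
            if bundle.noise_sd > 0:
                for res in rep.residues:
                    for atom in res.atoms.values():
                        atom.coords = atom.coords + rng.normal(0.0, bundle.noise_sd, 3)
            structures.append(rep)
            labels[rep.id] = label
    truth = {
        "tm6_rotation_deg": activation.tm6_rotation_deg,
        "tm3_translation_A": activation.tm3_translation_A,
        "noise_sd": bundle.noise_sd,
        "n_per_class": n_per_class,
        "seed": seed,
    }
    return structures, labels, truth


def write_ensemble(
    structures: list[Structure],
    labels: dict[str, str],
    truth: dict,
    out_dir: str | Path,
) -> None:
    """Write PDB files plus sidecar JSON (labels, ground truth), a labels
    TSV and the generic-number mapping TSV needed to renumber on re-read."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for st in structures:
        write_pdb(st, out / f"{st.id}.pdb")
    with open(out / "mapping.tsv", "w") as fh:
        fh.write("structure_id\tchain\tauthor_number\tinsertion_code\tgeneric_number\n")
        for st in structures:
            for res in st.residues:
                if res.generic_number is not None:
                    fh.write(f"{st.id}_A\tA\t{res.author_number}\t\t{res.generic_number}\n")
    with open(out / "ensemble.json", "w") as fh:
        json.dump({"labels": labels, "ground_truth": truth}, fh, indent=2)
    with open(out / "labels.tsv", "w") as fh:
        fh.write("structure_id\tclass\n")
        for sid, label in labels.items():
            fh.write(f"{sid}\t{label}\n")
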