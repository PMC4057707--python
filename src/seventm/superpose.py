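"""Rigid-body superposition and helix-axis geometry.

Pairing between two receptors is always by generic number — the numbering
scheme exists precisely so that homologous residues share numbers — never
by sequence alignment.  The bulge-skipping variant of the per-helix
superposition drops Cα atoms that sit inside an α-bulge detected in only
one of the two partners, so a helix widening in one structure does not
misregister the fit of the shared residues.

The whole-helix rotation measurement supports the rotation-not-kink
analysis: after a global superposition over all shared Cα atoms, the
principal axes of one helix (or its cytosolic/extracellular half) are
fitted in both structures and the angle between them is reported.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .secondary import assign_secondary_structure, find_alpha_bulges
from .structures import SegmentTable, Structure

__all__ = [
    "RigidTransform",
    "SuperpositionResult",
    "kabsch_superpose",
    "global_superpose",
    "local_helix_superpose",
    "fit_helix_axis",
    "helix_rotation_angle",
    "CYTOSOLIC_END",
]

#: Which end of each TM helix (by generic number) faces the cytosol.  The
#: N-terminus is extracellular, so odd helices run down through the membrane
#: and end cytosolically, even helices the reverse.
CYTOSOLIC_END = {
    "TM1": "high", "TM2": "low", "TM3": "high", "TM4": "low",
    "TM5": "high", "TM6": "low", "TM7": "high",
}


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation plus translation: x ↦ R·x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass(frozen=True)
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_atoms: int
    matched_pairs: tuple[tuple[int, int], ...] = ()
    rank_deficient: bool = False


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid fit of ``coords_b`` onto ``coords_a``.

    Returns the optimal proper rotation (reflections excluded by sign
    correction of the smallest singular value) and the minimised RMSD.
    Collinear point sets are fitted but flagged ``rank_deficient``.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must both be N x 3")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atoms to superpose")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (b - cb).T @ (a - ca)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    transform = RigidTransform(rot, ca - rot @ cb)
    moved = transform.apply(b)
    rmsd = float(np.sqrt(((moved - a) ** 2).sum() / n))
    scale = max(s[0], 1e-12)
    return SuperpositionResult(
        transform=transform,
        rmsd=rmsd,
        n_atoms=n,
        rank_deficient=bool(s[1] / scale < 1e-8),
    )


def _shared_ca(struct_a: Structure, struct_b: Structure, generics) -> tuple[np.ndarray, np.ndarray, list[int]]:
    by_a, by_b = struct_a.by_generic(), struct_b.by_generic()
    shared = [
        g
        for g in generics
        if g in by_a and g in by_b
        and by_a[g].coords("CA") is not None
        and by_b[g].coords("CA") is not None
    ]
    a = np.array([by_a[g].coords("CA") for g in shared]).reshape(-1, 3)
    b = np.array([by_b[g].coords("CA") for g in shared]).reshape(-1, 3)
    return a, b, shared


def global_superpose(struct_a: Structure, struct_b: Structure) -> SuperpositionResult:
    """Superpose ``struct_b`` onto ``struct_a`` over all shared generic-numbered Cα."""
    generics = sorted(set(struct_a.by_generic()) & set(struct_b.by_generic()))
    a, b, shared = _shared_ca(struct_a, struct_b, generics)
    result = kabsch_superpose(a, b)
    return SuperpositionResult(
        result.transform, result.rmsd, result.n_atoms,
        tuple((g, g) for g in shared), result.rank_deficient,
    )


def local_helix_superpose(
    struct_a: Structure,
    struct_b: Structure,
    helix: str,
    segments: SegmentTable,
    skip_unshared_bulges: bool = False,
) -> SuperpositionResult:
    """Superpose one helix of ``struct_b`` onto the same helix of ``struct_a``
    using Cα atoms paired by generic number.

    With ``skip_unshared_bulges``, α-bulges are detected in both structures
    and residues lying inside a bulge present in only one partner are
    excluded from the pairing (two bulges are 'shared' when their generic
    ranges overlap).
    """
    if helix not in segments.segments:
        raise ValueError(f"unknown helix {helix!r}")
    lo, hi = segments.segments[helix]
    generics = list(range(lo, hi + 1))

    if skip_unshared_bulges:
        excluded: set[int] = set()
        bulges_a = _helix_bulge_ranges(struct_a, helix, segments)
        bulges_b = _helix_bulge_ranges(struct_b, helix, segments)
        for own, other in ((bulges_a, bulges_b), (bulges_b, bulges_a)):
            for b_lo, b_hi in own:
                shared = any(o_lo <= b_hi and b_lo <= o_hi for o_lo, o_hi in other)
                if not shared:
                    excluded.update(range(b_lo, b_hi + 1))
        generics = [g for g in generics if g not in excluded]

    a, b, shared = _shared_ca(struct_a, struct_b, generics)
    if len(shared) < 3:
        raise ValueError(f"fewer than 3 shared residues in {helix}")
    result = kabsch_superpose(a, b)
    return SuperpositionResult(
        result.transform, result.rmsd, result.n_atoms,
        tuple((g, g) for g in shared), result.rank_deficient,
    )


def _helix_bulge_ranges(structure: Structure, helix: str, segments: SegmentTable):
    assignment = assign_secondary_structure(structure)
    return [
        (rec.start_generic, rec.end_generic)
        for rec in find_alpha_bulges(assignment, structure, segments)
        if rec.helix == helix
    ]


def fit_helix_axis(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal direction of a Cα cloud, oriented first → last residue.

    Returns (unit axis, centroid).  Needs at least 5 points for the axis of
    a helical turn to be meaningful.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 5:
        raise ValueError("need at least 5 Calpha positions to fit a helix axis")
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    axis = vt[0]
    if np.dot(axis, coords[-1] - coords[0]) < 0:
        axis = -axis
    return axis, centroid


def helix_rotation_angle(
    struct_a: Structure,
    struct_b: Structure,
    helix: str,
    segments: SegmentTable,
    half: str = "whole",
    transform: RigidTransform | None = None,
) -> float:
    """Angle (degrees, in [0, 180]) between the fitted axes of one helix in
    two structures after global superposition.

    ``half`` selects the whole helix or its cytosolic/extracellular half
    (the half nearer the corresponding membrane side by generic number,
    rounded down).  ``transform`` may carry a pre-computed global fit of
    ``struct_b`` onto ``struct_a``; otherwise one is computed over all
    shared generic-numbered Cα atoms.
    """
    if half not in ("whole", "cytosolic", "extracellular"):
        raise ValueError("half must be 'whole', 'cytosolic' or 'extracellular'")
    if helix not in segments.segments:
        raise ValueError(f"unknown helix {helix!r}")
    if transform is None:
        transform = global_superpose(struct_a, struct_b).transform

    lo, hi = segments.segments[helix]
    a, b, shared = _shared_ca(struct_a, struct_b, range(lo, hi + 1))
    if half != "whole":
        n_half = len(shared) // 2
        cyt_high = CYTOSOLIC_END.get(helix, "high") == "high"
        take_high = (half == "cytosolic") == cyt_high
        sel = slice(len(shared) - n_half, None) if take_high else slice(None, n_half)
        a, b = a[sel], b[sel]
    if len(a) < 5:
        raise ValueError(f"selected portion of {helix} has fewer than 5 residues")
    axis_a, _ = fit_helix_axis(a)
    axis_b, _ = fit_helix_axis(transform.apply(b))
    cosang = float(np.clip(np.dot(axis_a, axis_b), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))
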