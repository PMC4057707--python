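"""Hydrogen-bond-based secondary-structure assignment with π-helix preference.

The assignment follows the Kabsch–Sander scheme: an amide hydrogen is
placed on each backbone nitrogen, every CO···HN contact is scored with the
electrostatic energy

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)  kcal/mol,

a bond exists when E < −0.5 kcal/mol, and n-turns (n = 3, 4, 5) are read
off the CO(i)→NH(i+n) bonds.  Two consecutive n-turns make a minimal
helix.  The one deliberate departure from the classic priority order is
the π preference: where 5-turn (π) and 4-turn (α) patterns overlap, the π
code I wins.  A contiguous stretch of I inside a transmembrane helix is
exactly what this package calls an α-bulge — the local widening of a
helix that accommodates one extra residue.  With ``pi_priority=False`` the
classic ordering (H over G over I) is used instead, which reproduces
reference DSSP output.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structures import SegmentTable, Structure, TM_HELICES

__all__ = [
    "HBond",
    "SSAssignment",
    "BulgeRecord",
    "HBOND_ENERGY_CUTOFF",
    "place_amide_hydrogen",
    "hbond_energy",
    "assign_secondary_structure",
    "find_alpha_bulges",
    "find_three_ten_runs",
    "bulge_census",
    "NoDonorHydrogen",
    "IncompleteBackbone",
    "AtomClash",
]

logger = logging.getLogger(__name__)

#: Kabsch–Sander coupling constant, 0.084 e² · 332 kcal·Å/mol.
COUPLING = 0.084 * 332
HBOND_ENERGY_CUTOFF = -0.5
#: Energies are clamped below at this value, as in reference implementations.
MIN_ENERGY = -9.9
#: Cα–Cα screening distance; pairs farther apart cannot form an H-bond.
CA_SCREEN = 9.0
#: Minimal chain separation for a stored bond.
MIN_SEPARATION = 2
#: Bend threshold on the virtual-bond angle Cα(i−2)–Cα(i)–Cα(i+2).
BEND_KAPPA = 70.0


class NoDonorHydrogen(ValueError):
    """Proline (or a fragment-initial residue) has no amide hydrogen."""


class IncompleteBackbone(ValueError):
    """A required backbone atom is missing."""


class AtomClash(ValueError):
    """Donor and acceptor atoms closer than the 0.5 Å clash guard."""


@dataclass(frozen=True)
class HBond:
    """A stored backbone hydrogen bond: NH(donor) → CO(acceptor)."""

    donor_index: int
    acceptor_index: int
    energy: float


@dataclass
class SSAssignment:
    """Per-residue codes plus the turn and H-bond evidence behind them.

    ``codes[i]`` is one of H, G, I, E, B, T, S or blank; ``turn_starts[n]``
    flags residues i where the CO(i)→NH(i+n) bond exists.
    """

    codes: list[str]
    turn_starts: dict[int, np.ndarray]
    hbonds: list[HBond]

    def __len__(self) -> int:
        return len(self.codes)

    def code_string(self) -> str:
        return "".join(self.codes)

    def to_tsv(self, structure: Structure, path: str | Path) -> None:
        donors: dict[int, list[HBond]] = {}
        for hb in self.hbonds:
            donors.setdefault(hb.donor_index, []).append(hb)
        with open(path, "w") as fh:
            fh.write(
                "index\tauthor_number\tgeneric_number\tamino_acid\tcode\t"
                "turn3\tturn4\tturn5\tnh_partners\tnh_energies\n"
            )
            for i, res in enumerate(structure.residues):
                bonds = sorted(donors.get(i, []), key=lambda b: b.energy)
                partners = ",".join(str(b.acceptor_index) for b in bonds)
                energies = ",".join(f"{b.energy:.2f}" for b in bonds)
                fh.write(
                    f"{i}\t{res.author_number}\t{res.generic_number or ''}\t"
                    f"{res.amino_acid}\t{self.codes[i]}\t"
                    f"{int(self.turn_starts[3][i])}\t{int(self.turn_starts[4][i])}\t"
                    f"{int(self.turn_starts[5][i])}\t{partners}\t{energies}\n"
                )


@dataclass(frozen=True)
class BulgeRecord:
    """A maximal π-coded stretch located within a named TM helix."""

    helix: str
    start_generic: int
    end_generic: int
    length: int


def place_amide_hydrogen(prev_residue, residue) -> np.ndarray:
    """Backbone amide H: 1.0 Å from N along the unit vector O(prev)→C(prev)."""
    if residue.amino_acid == "P":
        raise NoDonorHydrogen("proline has no donor hydrogen")
    c, o = prev_residue.coords("C"), prev_residue.coords("O")
    n = residue.coords("N")
    if c is None or o is None or n is None:
        raise IncompleteBackbone("need C and O on the previous residue and N on the donor")
    direction = c - o
    return n + direction / np.linalg.norm(direction)


def hbond_energy(
    n: np.ndarray, h: np.ndarray, c: np.ndarray, o: np.ndarray
) -> float:
    """Kabsch–Sander electrostatic energy of one NH···OC contact, kcal/mol."""
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) <= 0.5:
        raise AtomClash("atoms too close")
    energy = COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return max(energy, MIN_ENERGY)


def _collect_hbonds(structure: Structure) -> list[HBond]:
    """All NH(i)→CO(j) bonds below the cutoff, keeping per residue the two
    best bonds in each role (donor and acceptor), the Kabsch–Sander rule."""
    n_res = len(structure.residues)
    frag = structure.fragment_ids()
    hydrogens: dict[int, np.ndarray] = {}
    for i in range(1, n_res):
        if frag[i] != frag[i - 1]:
            continue
        try:
            hydrogens[i] = place_amide_hydrogen(structure.residues[i - 1], structure.residues[i])
        except (NoDonorHydrogen, IncompleteBackbone):
            continue

    ca = np.array(
        [
            r.coords("CA") if r.coords("CA") is not None else [np.nan] * 3
            for r in structure.residues
        ]
    )
    candidates: list[HBond] = []
    for i, h in hydrogens.items():  # donor NH
        n_atom = structure.residues[i].coords("N")
        for j in range(n_res):  # acceptor CO
            if abs(i - j) < MIN_SEPARATION:
                continue
            c_atom = structure.residues[j].coords("C")
            o_atom = structure.residues[j].coords("O")
            if c_atom is None or o_atom is None:
                continue
            d = ca[i] - ca[j]
            if np.isnan(d).any() or d @ d > CA_SCREEN**2:
                continue
            try:
                e = hbond_energy(n_atom, h, c_atom, o_atom)
            except AtomClash:
                continue
            if e < HBOND_ENERGY_CUTOFF:
                candidates.append(HBond(i, j, e))

    # Each NH keeps its two best acceptors; those bonds define the patterns.
    best_donor: dict[int, list[HBond]] = {}
    for hb in sorted(candidates, key=lambda b: b.energy):
        d = best_donor.setdefault(hb.donor_index, [])
        if len(d) < 2:
            d.append(hb)
    return [hb for bonds in best_donor.values() for hb in bonds]


def _turn_starts(structure: Structure, hbonds: list[HBond]) -> dict[int, np.ndarray]:
    n_res = len(structure.residues)
    frag = structure.fragment_ids()
    bonded = {(hb.acceptor_index, hb.donor_index) for hb in hbonds}
    turns = {n: np.zeros(n_res, dtype=bool) for n in (3, 4, 5)}
    for n in (3, 4, 5):
        for i in range(n_res - n):
            if frag[i] != frag[i + n]:
                continue  # no turn bridges a chain break
            if (i, i + n) in bonded:
                turns[n][i] = True
    return turns


def _bridges(structure: Structure, hbonds: list[HBond]) -> tuple[np.ndarray, np.ndarray]:
    """Kabsch–Sander parallel/antiparallel bridges; returns (is_E, is_B)."""
    n_res = len(structure.residues)
    frag = structure.fragment_ids()
    bonded = {(hb.acceptor_index, hb.donor_index) for hb in hbonds}

    def hb(a: int, b: int) -> bool:  # CO(a) -> NH(b)
        return (a, b) in bonded

    bridges: list[tuple[int, int, str]] = []
    for i in range(1, n_res - 1):
        if frag[i - 1] != frag[i + 1]:
            continue
        for j in range(i + 3, n_res - 1):
            if frag[j - 1] != frag[j + 1]:
                continue
            para = (hb(i - 1, j) and hb(j, i + 1)) or (hb(j - 1, i) and hb(i, j + 1))
            anti = (hb(i, j) and hb(j, i)) or (hb(i - 1, j + 1) and hb(j - 1, i + 1))
            if para:
                bridges.append((i, j, "p"))
            elif anti:
                bridges.append((i, j, "a"))

    in_ladder = np.zeros(n_res, dtype=bool)
    in_bridge = np.zeros(n_res, dtype=bool)
    bridge_set = set(bridges)
    for i, j, kind in bridges:
        in_bridge[i] = in_bridge[j] = True
        partner = (i + 1, j + 1, "p") if kind == "p" else (i + 1, j - 1, "a")
        prev = (i - 1, j - 1, "p") if kind == "p" else (i - 1, j + 1, "a")
        if partner in bridge_set or prev in bridge_set:
            in_ladder[i] = in_ladder[j] = True
    return in_ladder, in_bridge & ~in_ladder


def _bends(structure: Structure) -> np.ndarray:
    n_res = len(structure.residues)
    frag = structure.fragment_ids()
    bend = np.zeros(n_res, dtype=bool)
    for i in range(2, n_res - 2):
        if frag[i - 2] != frag[i + 2]:
            continue
        a = structure.residues[i - 2].coords("CA")
        b = structure.residues[i].coords("CA")
        c = structure.residues[i + 2].coords("CA")
        if a is None or b is None or c is None:
            continue
        u, v = b - a, c - b
        cosang = np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0)
        bend[i] = np.degrees(np.arccos(cosang)) > BEND_KAPPA
    return bend


def assign_secondary_structure(
    structure: Structure, pi_priority: bool = True
) -> SSAssignment:
    """Assign H/G/I/E/B/T/S codes from backbone hydrogen bonding.

    With ``pi_priority`` (the default) overlapping π and α patterns resolve
    to I — the behaviour that turns helix widenings into visible α-bulges.
    Disabling it restores the classic priority (H over G over I).
    """
    n_res = len(structure.residues)
    if n_res < 3:
        raise ValueError("structure too short for secondary-structure assignment")
    complete = np.array([r.has_backbone() for r in structure.residues])
    hbonds = _collect_hbonds(structure)
    turns = _turn_starts(structure, hbonds)
    in_ladder, in_lone_bridge = _bridges(structure, hbonds)
    bend = _bends(structure)

    codes = [" "] * n_res

    def minimal_helix(n: int) -> np.ndarray:
        flag = np.zeros(n_res, dtype=bool)
        starts = turns[n]
        for i in range(1, n_res - n):
            if starts[i] and starts[i - 1]:
                flag[i : i + n] = True
        return flag

    def fill(mask: np.ndarray, code: str) -> None:
        for i in np.flatnonzero(mask):
            codes[i] = code

    def fill_spans(n: int, code: str) -> None:
        # A minimal G/I span is assigned only when every residue of the span
        # is still free (or already carries the same code) — the classic rule.
        starts = turns[n]
        for i in range(1, n_res - n):
            if starts[i] and starts[i - 1]:
                span = range(i, i + n)
                if all(codes[j] in (" ", "T", "S", code) for j in span):
                    for j in span:
                        codes[j] = code

    fill(in_ladder, "E")
    for i in np.flatnonzero(in_lone_bridge):
        if codes[i] == " ":
            codes[i] = "B"
    fill(minimal_helix(4), "H")
    if pi_priority:
        fill(minimal_helix(5), "I")  # π wins over α where patterns overlap
        fill_spans(3, "G")
    else:
        fill_spans(3, "G")
        fill_spans(5, "I")

    # Turns: loop residues inside any single n-turn span.
    for n in (3, 4, 5):
        for i in np.flatnonzero(turns[n]):
            for k in range(1, n):
                if i + k < n_res and codes[i + k] == " ":
                    codes[i + k] = "T"
    for i in np.flatnonzero(bend):
        if codes[i] == " ":
            codes[i] = "S"
    for i in np.flatnonzero(~complete):
        codes[i] = " "
    return SSAssignment(codes=codes, turn_starts=turns, hbonds=hbonds)


def _code_runs(codes: list[str], code: str) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, c in enumerate(codes + [""]):
        if c == code and start is None:
            start = i
        elif c != code and start is not None:
            runs.append((start, i - 1))
            start = None
    return runs


def _runs_to_records(
    runs: list[tuple[int, int]],
    structure: Structure,
    segments: SegmentTable,
) -> list[BulgeRecord]:
    records = []
    for lo, hi in runs:
        span = structure.residues[lo : hi + 1]
        generics = [r.generic_number for r in span if r.generic_number is not None]
        if not generics:
            continue
        # A run overlapping a segment boundary counts for the segment that
        # contains its start residue.
        helix = segments.helix_of(generics[0])
        if helix is None:
            continue
        records.append(
            BulgeRecord(
                helix=helix,
                start_generic=generics[0],
                end_generic=generics[-1],
                length=hi - lo + 1,
            )
        )
    records.sort(key=lambda r: (r.helix, r.start_generic))
    return records


def find_alpha_bulges(
    assignment: SSAssignment, structure: Structure, segments: SegmentTable
) -> list[BulgeRecord]:
    """One record per maximal I run whose start lies inside a TM segment."""
    return _runs_to_records(_code_runs(assignment.codes, "I"), structure, segments)


def find_three_ten_runs(
    assignment: SSAssignment, structure: Structure, segments: SegmentTable
) -> list[BulgeRecord]:
    """Maximal 3₁₀ (G) runs per TM segment — the 'anti-bulge' census."""
    return _runs_to_records(_code_runs(assignment.codes, "G"), structure, segments)


def bulge_census(structures: list[Structure], segments: SegmentTable):
    """α-bulge counts per structure per TM helix as a DataFrame (rows =
    structure ids, columns TM1..TM7).  Per-structure failures are logged and
    reported as missing rows rather than aborting the census."""
    import pandas as pd

    rows = {}
    for st in structures:
        try:
            assignment = assign_secondary_structure(st)
            records = find_alpha_bulges(assignment, st, segments)
        except Exception as exc:  # noqa: BLE001 - census must survive bad entries
            logger.warning("census: skipping %s (%s)", st.id, exc)
            continue
        counts = {h: 0 for h in TM_HELICES}
        for rec in records:
            if rec.helix in counts:
                counts[rec.helix] += 1
        rows[st.id] = counts
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(TM_HELICES)).astype(int)
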