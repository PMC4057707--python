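"""Receptor structure data model and I/O.

The downstream analysis (secondary structure, superposition, distance
features) only ever needs the peptide backbone with dual numbering: the
author residue number from the coordinate file and, where available, the
GPCRDB-style generic number (helix*100 + position, e.g. 733 = helix 7,
position 33).  This module reads PDB/mmCIF files through :mod:`gemmi`,
reduces them to that model, and provides the cleaning, renumbering and
segmentation steps that make heterogeneous receptor structures comparable.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "SegmentTable",
    "StructureError",
    "MissingChainError",
    "MappingError",
    "read_structure",
    "write_pdb",
    "strip_to_receptor",
    "apply_numbering",
    "segment_residues",
    "load_numbering_table",
    "default_segments",
]

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: C(i)->N(i+1) distances above this bound (Å) declare a chain break; a real
#: peptide bond is ~1.33 Å, so 2.5 Å is a generous sanity margin.
CHAIN_BREAK_DISTANCE = 2.5

TM_HELICES = ("TM1", "TM2", "TM3", "TM4", "TM5", "TM6", "TM7")


class StructureError(ValueError):
    """Raised for unreadable or inconsistent structure input."""


class MissingChainError(StructureError):
    """Requested chain is absent from the coordinate file."""


class MappingError(StructureError):
    """Generic-number mapping refers to absent residues or duplicates targets."""


@dataclass
class Atom:
    """A single atom: label, Cartesian coordinates in Å, occupancy, altloc."""

    name: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    """One amino-acid residue with author and (optional) generic numbering."""

    author_number: int
    insertion_code: str = ""
    amino_acid: str = "A"
    generic_number: int | None = None
    atoms: dict[str, Atom] = field(default_factory=dict)

    def coords(self, name: str) -> np.ndarray | None:
        atom = self.atoms.get(name)
        return None if atom is None else atom.coords

    def has_backbone(self) -> bool:
        return all(name in self.atoms for name in BACKBONE_ATOMS)

    @property
    def key(self) -> tuple[int, str]:
        return (self.author_number, self.insertion_code)

    def copy(self) -> "Residue":
        atoms = {n: Atom(a.name, a.coords.copy(), a.occupancy, a.altloc) for n, a in self.atoms.items()}
        return replace(self, atoms=atoms)


@dataclass
class Structure:
    """An ordered chain of residues from one coordinate file."""

    id: str
    residues: list[Residue]
    source_path: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    def copy(self) -> "Structure":
        return Structure(self.id, [r.copy() for r in self.residues], self.source_path)

    def chain_breaks(self) -> set[int]:
        """Indices ``i`` such that the peptide bond between residues ``i`` and
        ``i+1`` is broken (C→N distance above :data:`CHAIN_BREAK_DISTANCE`, or
        either atom missing)."""
        breaks: set[int] = set()
        for i in range(len(self.residues) - 1):
            c = self.residues[i].coords("C")
            n = self.residues[i + 1].coords("N")
            if c is None or n is None or float(np.linalg.norm(n - c)) > CHAIN_BREAK_DISTANCE:
                breaks.add(i)
        return breaks

    def fragment_ids(self) -> np.ndarray:
        """Per-residue fragment label; turn/H-bond patterns never span fragments."""
        breaks = self.chain_breaks()
        ids = np.zeros(len(self.residues), dtype=int)
        frag = 0
        for i in range(1, len(self.residues)):
            if i - 1 in breaks:
                frag += 1
            ids[i] = frag
        return ids

    def by_generic(self) -> dict[int, Residue]:
        return {r.generic_number: r for r in self.residues if r.generic_number is not None}

    def ca_array(self) -> np.ndarray:
        """Cα coordinates of all residues that have one, in sequence order."""
        return np.array([r.coords("CA") for r in self.residues if r.coords("CA") is not None])


@dataclass(frozen=True)
class SegmentTable:
    """Mapping from helix label (TM1..TM7, H8) to an inclusive generic-number range."""

    segments: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        spans = sorted(self.segments.items(), key=lambda kv: kv[1][0])
        for label, (lo, hi) in spans:
            if lo > hi:
                raise StructureError(f"segment {label}: start {lo} > end {hi}")
            if label in TM_HELICES and hi - lo + 1 < 10:
                raise StructureError(f"segment {label}: TM helices must span >= 10 residues")
        for (la, (_, hi_a)), (lb, (lo_b, _)) in zip(spans, spans[1:]):
            if lo_b <= hi_a:
                raise StructureError(f"segments {la} and {lb} overlap")

    def helix_of(self, generic: int) -> str | None:
        for label, (lo, hi) in self.segments.items():
            if lo <= generic <= hi:
                return label
        return None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SegmentTable":
        segments: dict[str, tuple[int, int]] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {name: i for i, name in enumerate(header)}
            for name in ("helix", "generic_start", "generic_end"):
                if name not in idx:
                    raise StructureError(f"segment table {path}: missing column {name!r}")
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                segments[fields[idx["helix"]]] = (
                    int(fields[idx["generic_start"]]),
                    int(fields[idx["generic_end"]]),
                )
        return cls(segments)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("helix\tgeneric_start\tgeneric_end\n")
            for label, (lo, hi) in sorted(self.segments.items(), key=lambda kv: kv[1][0]):
                fh.write(f"{label}\t{lo}\t{hi}\n")


def default_segments() -> SegmentTable:
    """The packaged default transmembrane segment table.

    The ranges are a documented reconstruction anchored on conserved
    generic-number landmarks (DRY at 339–341, P520, W618/P620, NPxxY ending
    at 733); no authoritative boundary list exists for the 203-residue
    common set, so users with their own definitions should supply a table.
    """
    with resources.as_file(resources.files("seventm.data") / "tm_segments.tsv") as p:
        return SegmentTable.from_tsv(p)


# --- reading -----------------------------------------------------------------

def _one_letter(resname: str) -> tuple[str | None, bool]:
    """(parent one-letter code or None, is-amino-acid flag).  Standard
    residues and common modified ones (MSE→M etc.) get a code; other
    amino-acid-like residues return (None, True) so callers can warn."""
    info = gemmi.find_tabulated_residue(resname)
    if info is None or not info.is_amino_acid():
        return None, False
    code = info.one_letter_code.upper()
    return (code if code.isalpha() and code != "X" else None), True


def read_structure(path: str | Path, chain: str, model: int = 1) -> Structure:
    """Read one chain of one model as a cleaned :class:`Structure`.

    Waters, ligands, ions and sugars are excluded; for alternate locations
    the highest-occupancy conformer is kept (ties: first in file order);
    modified standard residues (e.g. MSE) are mapped to their parent amino
    acid, other non-standard residues dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    models = {m.num: m for m in st}
    if model not in models:
        raise StructureError(f"{path}: model {model} not present (available: {sorted(models)})")
    mod = models[model]

    chains = [ch.name for ch in mod]
    target = next((ch for ch in mod if ch.name == chain), None)
    if target is None:
        raise MissingChainError(f"{path}: chain {chain!r} not found; available chains: {chains}")

    residues: list[Residue] = []
    seen: set[tuple[int, str]] = set()
    for res in target:
        aa, is_aa = _one_letter(res.name)
        if aa is None:
            if is_aa:
                logger.warning("%s: dropping non-standard residue %s %s", path.name, res.name, res.seqid)
            continue
        key = (res.seqid.num, (res.seqid.icode or " ").strip())
        if key in seen:
            logger.warning("%s: duplicate residue %s%s, keeping first", path.name, *key)
            continue
        seen.add(key)
        atoms: dict[str, Atom] = {}
        for atom in res:
            if atom.name not in BACKBONE_ATOMS:
                continue
            occ = min(max(float(atom.occ), 0.0), 1.0)
            prev = atoms.get(atom.name)
            if prev is None or occ > prev.occupancy:  # ties keep first in file order
                atoms[atom.name] = Atom(
                    atom.name,
                    np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occ,
                    (atom.altloc or "").strip("\x00"),
                )
        residues.append(Residue(key[0], key[1], aa, atoms=atoms))
    return Structure(id=f"{path.stem}_{chain}", residues=residues, source_path=str(path))


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def write_pdb(structure: Structure, path: str | Path, chain: str = "A") -> None:
    """Write the backbone model as a minimal single-chain PDB file."""
    serial = 0
    with open(path, "w") as fh:
        for res in structure.residues:
            resname = _ONE_TO_THREE.get(res.amino_acid, "ALA")
            for name in BACKBONE_ATOMS:
                atom = res.atoms.get(name)
                if atom is None:
                    continue
                serial += 1
                x, y, z = atom.coords
                element = name[0]
                fh.write(
                    f"ATOM  {serial:5d}  {name:<3s}{resname:>4s} {chain}"
                    f"{res.author_number:4d}{res.insertion_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {element:>2s}\n"
                )
        fh.write("TER\nEND\n")


# --- cleaning and numbering --------------------------------------------------

def strip_to_receptor(structure: Structure, keep_ranges: list[tuple[int, int]]) -> Structure:
    """Keep only residues whose author number lies in one of the inclusive
    ranges; used to cut away fusion partners, G proteins, antibodies etc."""
    for lo, hi in keep_ranges:
        if lo > hi:
            raise StructureError(f"malformed keep range {lo}..{hi}")
    kept = [
        r.copy()
        for r in structure.residues
        if any(lo <= r.author_number <= hi for lo, hi in keep_ranges)
    ]
    if not kept:
        logger.warning("%s: keep ranges removed every residue", structure.id)
    return Structure(structure.id, kept, structure.source_path)


def apply_numbering(
    structure: Structure, mapping: dict[tuple[int, str], int]
) -> Structure:
    """Attach generic numbers; residues absent from the mapping carry none.

    Coordinates and residue count are never changed.  Raises
    :class:`MappingError` if the mapping targets the same generic number
    twice or refers to residues the structure does not contain.
    """
    targets = list(mapping.values())
    if len(set(targets)) != len(targets):
        dupes = sorted({g for g in targets if targets.count(g) > 1})
        raise MappingError(f"duplicate generic-number targets: {dupes}")
    present = {r.key for r in structure.residues}
    missing = sorted(k for k in mapping if k not in present)
    if missing:
        raise MappingError(f"mapping refers to absent residues: {missing}")
    out = structure.copy()
    n_mapped = 0
    for res in out.residues:
        generic = mapping.get(res.key)
        res.generic_number = generic
        if generic is not None:
            n_mapped += 1
    logger.info("%s: %d residues mapped to generic numbers", structure.id, n_mapped)
    return out


def segment_residues(
    structure: Structure, segments: SegmentTable
) -> dict[str, list[Residue]]:
    """Group residues by the helix whose generic-number range contains them."""
    out: dict[str, list[Residue]] = {label: [] for label in segments.segments}
    for res in structure.residues:
        if res.generic_number is None:
            continue
        label = segments.helix_of(res.generic_number)
        if label is not None:
            out[label].append(res)
    return out


def load_numbering_table(path: str | Path) -> "object":
    """Read the TSV mapping table (structure_id, chain, author_number,
    insertion_code, generic_number) into a DataFrame."""
    import pandas as pd

    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"structure_id": str, "chain": str, "insertion_code": str},
        keep_default_na=False,
    )
    required = {"structure_id", "chain", "author_number", "insertion_code", "generic_number"}
    missing = required - set(df.columns)
    if missing:
        raise StructureError(f"numbering table {path}: missing columns {sorted(missing)}")
    return df


def mapping_for(table, structure_id: str, chain: str) -> dict[tuple[int, str], int]:
    """Extract the (author_number, insertion_code) → generic mapping for one chain."""
    rows = table[(table["structure_id"] == structure_id) & (table["chain"] == chain)]
    return {
        (int(r.author_number), str(r.insertion_code).strip()): int(r.generic_number)
        for r in rows.itertuples()
    }
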