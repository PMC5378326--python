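"""PDB structure model and side-chain reference points.

Reads protein crystal structures (e.g. the eGFP structure 4EUL) into a
light-weight residue/atom model and computes, for every residue, the
reference point used by the side-chain weighted contact number: the
geometric center of the side-chain heavy atoms, falling back to the
C-alpha position for glycine (which has no side chain).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

from .exceptions import (
    EmptyStructureError,
    MissingAtomError,
    PDBParseError,
)

logger = logging.getLogger(__name__)

#: Backbone heavy atoms excluded from the side-chain center.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: The twenty standard amino acids (3-letter codes).
STANDARD_AA = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)

ResidueKey = tuple[str, int, str]


@dataclass(frozen=True)
class Atom:
    """A heavy atom with PDB name, element symbol and coordinates in Angstrom."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float)
        )
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name!r}")


@dataclass
class Residue:
    """One residue: author chain/number/insertion-code identity plus its atoms."""

    chain_id: str
    number: int
    insertion_code: str
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.number, self.insertion_code)

    def get_atom(self, name: str) -> Optional[Atom]:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None

    @property
    def side_chain_atoms(self) -> list[Atom]:
        """Heavy atoms outside the peptide backbone (N, CA, C, O, OXT)."""
        return [
            a
            for a in self.atoms
            if a.name not in BACKBONE_ATOMS and a.element not in ("H", "D")
        ]


@dataclass
class Structure:
    """An ordered list of residues, as read from a PDB file."""

    id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def residue_map(self) -> dict[ResidueKey, Residue]:
        return {r.key: r for r in self.residues}

    def find_residues(
        self, number: int, chain: Optional[str] = None
    ) -> list[Residue]:
        """All residues with the given author number (optionally chain-restricted)."""
        return [
            r
            for r in self.residues
            if r.number == number and (chain is None or r.chain_id == chain)
        ]


@dataclass(frozen=True)
class CenterPoint:
    """Side-chain reference point of a residue.

    ``method`` records whether the point is the geometric center of the
    side-chain heavy atoms or the C-alpha fallback (always used for glycine).
    """

    residue_key: ResidueKey
    point: np.ndarray
    method: str  # "sidechain_geometric" | "calpha_fallback"

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        if not np.all(np.isfinite(self.point)):
            raise ValueError("non-finite center point")


def _validate_coordinate_fields(pdb_text: str) -> None:
    # gemmi silently zero-fills malformed coordinates; scan the fixed-width
    # coordinate columns first so the error names the offending line.
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 54:
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fieldtxt = line[lo:hi].strip()
                try:
                    float(fieldtxt)
                except ValueError:
                    raise PDBParseError(
                        f"malformed coordinate field {fieldtxt!r} "
                        f"on line {lineno}: {line.rstrip()}"
                    ) from None


def _select_altloc(atoms: list[Atom]) -> list[Atom]:
    """Keep one copy per atom name: highest occupancy, ties by file order."""
    best: dict[str, Atom] = {}
    for atom in atoms:
        prev = best.get(atom.name)
        if prev is None or atom.occupancy > prev.occupancy:
            best[atom.name] = atom
    # preserve file order of the winners
    winners = set(id(a) for a in best.values())
    return [a for a in atoms if id(a) in winners]


def read_structure(
    pdb_text: str,
    chain: Optional[str] = None,
    include_het: Iterable[str] = (),
) -> Structure:
    """Parse PDB text into a :class:`Structure` of standard amino acids.

    Hydrogens are dropped; for alternate locations the highest-occupancy
    copy is kept (ties broken by file order).  HETATM records are excluded
    unless their residue name appears in ``include_het`` (e.g. ``{"CRO"}``
    to treat a mature GFP chromophore as a pseudo-residue).

    Parameters
    ----------
    pdb_text : str
        Contents of a PDB file (wwPDB v3.3 ATOM/HETATM records).
    chain : str, optional
        If given, restrict to this chain identifier.
    include_het : iterable of str
        Residue names of het groups to include as pseudo-residues.

    Raises
    ------
    EmptyStructureError
        If no residues survive parsing and filtering.
    PDBParseError
        If a coordinate field cannot be parsed.
    """
    _validate_coordinate_fields(pdb_text)
    include_het = set(include_het)
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover
        raise PDBParseError(str(exc)) from exc

    residues: list[Residue] = []
    if len(st) > 0:
        model = st[0]
        for ch in model:
            if chain is not None and ch.name != chain:
                continue
            for res in ch:
                is_het = res.het_flag == "H"
                if is_het and res.name not in include_het:
                    continue
                if not is_het and res.name not in STANDARD_AA:
                    continue
                atoms = []
                for a in res:
                    if a.is_hydrogen():
                        continue
                    altloc = "" if a.altloc == "\0" else a.altloc
                    atoms.append(
                        Atom(
                            name=a.name,
                            element=a.element.name.upper(),
                            position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                            occupancy=round(a.occ, 4),
                            altloc=altloc,
                        )
                    )
                atoms = _select_altloc(atoms)
                if not atoms:
                    continue
                icode = res.seqid.icode.strip()
                residues.append(
                    Residue(
                        chain_id=ch.name,
                        number=res.seqid.num,
                        insertion_code=icode,
                        name=res.name,
                        atoms=atoms,
                    )
                )
    if not residues:
        raise EmptyStructureError(
            "no ATOM records found"
            + (f" for chain {chain!r}" if chain is not None else "")
        )
    return Structure(id=st.name or "structure", residues=residues)


def side_chain_center(residue: Residue) -> CenterPoint:
    """Geometric center of the side-chain heavy atoms of a residue.

    Glycine carries no side chain, so its C-alpha position is used instead;
    the same fallback applies to any residue whose side-chain atoms are
    missing from the model, with ``method`` flagging the fallback.

    Raises
    ------
    MissingAtomError
        If the residue has neither side-chain heavy atoms nor a C-alpha.
    """
    side = residue.side_chain_atoms
    if residue.name != "GLY" and side:
        pts = np.array([a.position for a in side])
        return CenterPoint(
            residue_key=residue.key,
            point=pts.mean(axis=0),
            method="sidechain_geometric",
        )
    ca = residue.get_atom("CA")
    if ca is None:
        raise MissingAtomError(
            f"residue {residue.key} ({residue.name}) has neither side-chain "
            "atoms nor CA"
        )
    if residue.name != "GLY":
        logger.warning(
            "residue %s (%s) lacks side-chain atoms; using CA fallback",
            residue.key,
            residue.name,
        )
    return CenterPoint(
        residue_key=residue.key, point=ca.position, method="calpha_fallback"
    )


def side_chain_centers(structure: Structure) -> list[CenterPoint]:
    """Side-chain centers for every residue of a structure, in file order."""
    return [side_chain_center(r) for r in structure.residues]


def write_pdb(structure: Structure) -> str:
    """Serialize the model back to PDB ATOM-record text (wwPDB v3.3 columns)."""
    lines = []
    serial = 0
    for res in structure.residues:
        for atom in res.atoms:
            serial += 1
            name = atom.name
            # standard alignment: short names of single-letter elements are
            # indented one column
            if len(name) < 4 and len(atom.element) == 1:
                name = f" {name}"
            lines.append(
                f"ATOM  {serial:5d} {name:<4s}{(atom.altloc or ' '):1s}"
                f"{res.name:>3s} {res.chain_id:1s}{res.number:4d}"
                f"{(res.insertion_code or ' '):1s}   "
                f"{atom.position[0]:8.3f}{atom.position[1]:8.3f}"
                f"{atom.position[2]:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2s}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"
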