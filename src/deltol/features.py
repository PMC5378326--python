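"""Per-residue structural features: WCN, ASA, RSA, and the mutant feature table.

The side-chain weighted contact number (WCN) of residue *i* is

    WCN_i = sum_{j != i} 1 / r_ij**2

with r_ij the Euclidean distance between the side-chain geometric centers of
residues *i* and *j* (C-alpha for glycine).  High WCN means a tightly packed
residue.  Solvent-accessible surface area (ASA) is computed with the
Shrake-Rupley rolling-probe method on a deterministic Fibonacci sphere
lattice, and relative solvent accessibility (RSA) normalizes each residue's
ASA by the maximum ASA of that amino acid in an extended Gly-X-Gly
tripeptide (theoretical normalization constants of Tien et al. 2013).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform, pdist

from .exceptions import (
    JoinError,
    MaxASALookupError,
    RadiusLookupError,
    SchemaError,
    SingularDistanceError,
)
from .structure import CenterPoint, ResidueKey, Structure, side_chain_centers

logger = logging.getLogger(__name__)

#: Maximum solvent accessibility (A^2) of residue X in an extended Gly-X-Gly
#: tripeptide; theoretical values of Tien et al. (2013), Table 1.
MAX_ASA_GLY_X_GLY: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

#: Van der Waals radii (A) for heavy elements common in protein structures.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}

SS_CATEGORIES = ("helix", "loop", "sheet")


@dataclass(frozen=True)
class ResidueFeatures:
    """Structural features of one residue: WCN (1/A^2), ASA (A^2), RSA."""

    residue_key: ResidueKey
    wcn: float
    asa: float
    rsa: float


@dataclass(frozen=True)
class MutantRecord:
    """One single-residue deletion mutant and its functional label."""

    mutant_id: str
    position: int
    ss: str
    functional: bool
    chain: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ss not in SS_CATEGORIES:
            raise ValueError(
                f"mutant {self.mutant_id!r}: ss must be one of "
                f"{SS_CATEGORIES}, got {self.ss!r}"
            )


def wcn_sidechain(centers: Sequence[CenterPoint]) -> np.ndarray:
    """Side-chain weighted contact number for each center, in input order.

    Raises
    ------
    SingularDistanceError
        If two centers coincide (1/r**2 undefined), naming the pair.
    """
    if len(centers) < 2:
        raise ValueError("WCN requires at least 2 residues")
    pts = np.array([c.point for c in centers])
    dists = squareform(pdist(pts))
    off_diag = ~np.eye(len(pts), dtype=bool)
    zero = np.argwhere((dists == 0.0) & off_diag)
    if zero.size:
        i, j = zero[0]
        raise SingularDistanceError(
            f"coincident side-chain centers for residues "
            f"{centers[i].residue_key} and {centers[j].residue_key}"
        )
    with np.errstate(divide="ignore"):
        inv2 = 1.0 / dists**2
    np.fill_diagonal(inv2, 0.0)
    return inv2.sum(axis=1)


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` near-uniform points on the unit sphere (golden-angle lattice).

    Deterministic, so ASA values are reproducible bit-for-bit for a fixed
    number of quadrature points.
    """
    i = np.arange(n)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    theta = 2.0 * np.pi * i / phi
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def asa_per_residue(
    structure: Structure,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    radii: Mapping[str, float] = VDW_RADII,
) -> dict[ResidueKey, float]:
    """Shrake-Rupley solvent-accessible surface area per residue (A^2).

    Each atom's sphere of radius ``r_vdw + probe_radius`` is sampled at
    ``n_sphere_points`` lattice points; a point is accessible when it lies
    outside every other atom's expanded sphere.  A residue's ASA is the sum
    over its atoms.

    Raises
    ------
    RadiusLookupError
        For an element with no van der Waals radius in ``radii``.
    """
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    atoms = []  # (residue index, position, expanded radius)
    for ri, res in enumerate(structure.residues):
        for atom in res.atoms:
            try:
                r = radii[atom.element]
            except KeyError:
                raise RadiusLookupError(
                    f"no van der Waals radius for element {atom.element!r} "
                    f"(atom {atom.name!r} in residue {res.key})"
                ) from None
            atoms.append((ri, atom.position, r + probe_radius))
    if not atoms:
        raise ValueError("empty structure")

    owner = np.array([a[0] for a in atoms])
    pos = np.array([a[1] for a in atoms])
    rad = np.array([a[2] for a in atoms])
    sphere = fibonacci_sphere(n_sphere_points)

    tree = cKDTree(pos)
    max_rad = rad.max()
    asa_atom = np.zeros(len(atoms))
    for ai in range(len(atoms)):
        neighbors = tree.query_ball_point(pos[ai], rad[ai] + max_rad)
        neighbors = [j for j in neighbors if j != ai]
        points = pos[ai] + rad[ai] * sphere
        if neighbors:
            npos = pos[neighbors]
            nrad = rad[neighbors]
            d2 = ((points[:, None, :] - npos[None, :, :]) ** 2).sum(axis=2)
            accessible = np.all(d2 > nrad[None, :] ** 2, axis=1)
            n_acc = int(accessible.sum())
        else:
            n_acc = n_sphere_points
        asa_atom[ai] = 4.0 * np.pi * rad[ai] ** 2 * n_acc / n_sphere_points

    result: dict[ResidueKey, float] = {
        res.key: 0.0 for res in structure.residues
    }
    for ai, ri in enumerate(owner):
        result[structure.residues[ri].key] += asa_atom[ai]
    return result


def rsa(
    asa: float,
    residue_name: str,
    table: Mapping[str, float] = MAX_ASA_GLY_X_GLY,
) -> float:
    """Relative solvent accessibility: ASA / max ASA of the amino acid.

    Values above 1 can occur (crystal contacts, normalization choice); they
    are retained but flagged in the run log.
    """
    if asa < 0:
        raise ValueError("asa must be >= 0")
    try:
        max_asa = table[residue_name]
    except KeyError:
        raise MaxASALookupError(
            f"no maximum-ASA value for residue name {residue_name!r}"
        ) from None
    value = asa / max_asa
    if value > 1.0:
        logger.warning(
            "RSA %.3f > 1 for residue type %s (ASA %.1f, max %.1f)",
            value, residue_name, asa, max_asa,
        )
    return value


def compute_residue_features(
    structure: Structure,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> pd.DataFrame:
    """WCN, ASA and RSA for every residue, indexed by (chain, number, icode)."""
    centers = side_chain_centers(structure)
    wcn = wcn_sidechain(centers)
    asa = asa_per_residue(
        structure, probe_radius=probe_radius, n_sphere_points=n_sphere_points
    )
    rows = []
    for res, w in zip(structure.residues, wcn):
        a = asa[res.key]
        rows.append(
            {
                "chain": res.chain_id,
                "number": res.number,
                "icode": res.insertion_code,
                "residue_name": res.name,
                "wcn": float(w),
                "asa": float(a),
                "rsa": rsa(a, res.name) if res.name in MAX_ASA_GLY_X_GLY
                else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index(["chain", "number", "icode"])


FEATURE_COLUMNS = ["mutant_id", "rsa", "wcn", "ss", "mean_score", "functional"]


def build_feature_table(
    structure: Structure,
    mutants: Sequence[MutantRecord],
    scores: Optional[Mapping[str, float]] = None,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> pd.DataFrame:
    """Join per-residue structural features onto the deletion mutants.

    Returns one row per mutant with columns
    ``mutant_id, rsa, wcn, ss, mean_score, functional`` (``mean_score`` is
    NaN when no score mapping is supplied).

    Raises
    ------
    JoinError
        If a mutant position does not resolve to exactly one residue, or
        mutant ids are duplicated.
    """
    ids = [m.mutant_id for m in mutants]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise JoinError(f"duplicate mutant_id values: {sorted(dupes)}")
    if not mutants:
        return pd.DataFrame(columns=FEATURE_COLUMNS)

    per_residue = compute_residue_features(
        structure, probe_radius=probe_radius, n_sphere_points=n_sphere_points
    )
    unmapped, ambiguous, rows = [], [], []
    for m in mutants:
        matches = structure.find_residues(m.position, chain=m.chain)
        if not matches:
            unmapped.append(m.mutant_id)
            continue
        if len(matches) > 1:
            ambiguous.append(m.mutant_id)
            continue
        res = matches[0]
        feats = per_residue.loc[(res.chain_id, res.number, res.insertion_code)]
        rows.append(
            {
                "mutant_id": m.mutant_id,
                "rsa": float(feats["rsa"]),
                "wcn": float(feats["wcn"]),
                "ss": m.ss,
                "mean_score": (
                    float(scores[m.mutant_id])
                    if scores is not None and m.mutant_id in scores
                    else np.nan
                ),
                "functional": bool(m.functional),
            }
        )
    if unmapped or ambiguous:
        parts = []
        if unmapped:
            parts.append(f"positions not found in structure: {unmapped}")
        if ambiguous:
            parts.append(f"ambiguous positions (specify chain): {ambiguous}")
        raise JoinError("; ".join(parts))
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


_TRUTHY = {"true", "1", "yes", "t", "functional", "tolerated"}
_FALSY = {"false", "0", "no", "f", "non-functional", "non-tolerated"}


def read_mutant_table(text: str) -> list[MutantRecord]:
    """Parse a CSV/TSV mutant table into records.

    Required columns: ``mutant_id, position, ss, functional``; optional
    ``chain``.  The functional column accepts true/false, 1/0 and
    tolerated/non-tolerated spellings.
    """
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, comment="#")
    required = {"mutant_id", "position", "ss", "functional"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"mutant table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        raw = str(row["functional"]).strip().lower()
        if raw in _TRUTHY:
            functional = True
        elif raw in _FALSY:
            functional = False
        else:
            raise SchemaError(
                f"unrecognized functional value {row['functional']!r} "
                f"for mutant {row['mutant_id']!r}"
            )
        chain = None
        if "chain" in df.columns and pd.notna(row["chain"]):
            chain = str(row["chain"])
        records.append(
            MutantRecord(
                mutant_id=str(row["mutant_id"]),
                position=int(row["position"]),
                ss=str(row["ss"]).strip().lower(),
                functional=functional,
                chain=chain,
            )
        )
    return records
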