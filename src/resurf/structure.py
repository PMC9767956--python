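"""Lightweight multimeric protein structure model.

Parsing of PDB/mmCIF files is delegated to :mod:`gemmi`; the in-memory
representation kept here is deliberately minimal — chains, residues and
heavy atoms with coordinates and van der Waals radii — because that is all
the surface-accessibility and interface geometry downstream requires.

Contract notes
--------------
* Hydrogens are ignored everywhere: crystal structures of the target class
  (e.g. bacterial asparaginases solved by X-ray) carry none, and all SASA
  and distance computations are defined over heavy atoms.
* Alternate locations are resolved to the highest-occupancy conformer
  (ties broken by altloc identifier order).
* Waters and hetero ligands are excluded from the polymer residue list but
  retained separately so callers can opt back in.
* Residue numbering follows the author (PDB) numbering, 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "StructureError",
    "VDW_RADII",
    "VDW_RADII_NAME",
    "read_structure",
    "write_structure",
    "chain_sequence",
    "min_interchain_distance",
]


class StructureError(ValueError):
    """Raised for unparseable, empty, or inconsistent structures."""


#: Single published per-element van der Waals radii (Bondi, J. Phys. Chem.
#: 1964), Å.  The set name is recorded in every SASA result's params.
VDW_RADII_NAME = "bondi64"
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "SE": 1.90,
    "BR": 1.85,
    "I": 1.98,
}
_DEFAULT_RADIUS = 1.70

# Three-letter -> one-letter, 20 canonical plus common modified parents.
THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # standard parent mappings for frequent modified residues
    "MSE": "M", "SEC": "C", "PYL": "K", "HYP": "P", "SEP": "S",
    "TPO": "T", "PTR": "Y", "CSO": "C", "MLY": "K",
}


@dataclass
class Atom:
    element: str
    name: str
    coords: np.ndarray  # shape (3,), Å
    vdw_radius: float
    is_heavy: bool = True

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: coords must be a finite 3-vector")
        if self.vdw_radius <= 0:
            raise StructureError(f"atom {self.name}: vdw_radius must be > 0")


@dataclass
class Residue:
    chain_id: str
    seq_index: int  # author numbering, 1-based
    aa: str  # one-letter code, X for unknown
    atoms: list[Atom] = field(default_factory=list)
    name: str = ""  # three-letter residue name, informational

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if a.is_heavy], dtype=float)


@dataclass
class StructureModel:
    chains: list[str]
    residues: list[Residue]
    ligands: list[Residue] = field(default_factory=list)
    assembly_note: str = ""

    def __post_init__(self) -> None:
        if not self.chains:
            raise StructureError("structure must have at least one chain")

    def chain_residues(self, chain_id: str) -> list[Residue]:
        if chain_id not in self.chains:
            raise KeyError(f"unknown chain {chain_id!r}")
        res = [r for r in self.residues if r.chain_id == chain_id]
        return sorted(res, key=lambda r: r.seq_index)

    def atoms_with_residues(self) -> list[tuple[Residue, Atom]]:
        return [(r, a) for r in self.residues for a in r.atoms]

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def monomer_positions(self) -> list[int]:
        """Sorted union of residue seq indices across chains (monomer grid)."""
        return sorted({r.seq_index for r in self.residues})


def _element_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), _DEFAULT_RADIUS)


def _pick_altloc(atoms: Iterable) -> list:
    """Resolve alternate conformers: keep the highest-occupancy copy per
    atom name; ties go to the alphabetically first altloc id."""
    best: dict[str, object] = {}
    for a in atoms:
        key = a.name
        if key not in best:
            best[key] = a
            continue
        b = best[key]
        if (a.occ, _neg_altloc(a.altloc)) > (b.occ, _neg_altloc(b.altloc)):
            best[key] = a
    return list(best.values())


class _neg_altloc:
    """Ordering helper so that among equal occupancies altloc 'A' wins."""

    def __init__(self, altloc: str) -> None:
        self.altloc = altloc or "~"

    def __gt__(self, other: "_neg_altloc") -> bool:
        return self.altloc < other.altloc

    def __lt__(self, other: "_neg_altloc") -> bool:
        return self.altloc > other.altloc

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _neg_altloc) and self.altloc == other.altloc


def read_structure(path: str | Path, format: str | None = None) -> StructureModel:
    """Read a protein structure from PDB or mmCIF.

    Parameters
    ----------
    path
        File path; format is inferred from the extension unless ``format``
        ("pdb" or "mmcif") is given.

    Returns
    -------
    StructureModel with heavy atoms of all polymer chains; waters and
    hetero ligands are kept on ``model.ligands``.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format in ("mmcif", "cif"):
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi raises RuntimeError on parse failure
        raise StructureError(f"could not parse {path}: {exc}") from None

    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    model = st[0]

    residues: list[Residue] = []
    ligands: list[Residue] = []
    chains: list[str] = []
    for chain in model:
        chain_has_polymer = False
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            is_water = info is not None and info.is_water()
            is_aa = res.name in THREE_TO_ONE or (info is not None and info.is_amino_acid())
            atoms: list[Atom] = []
            for ga in _pick_altloc(res):
                el = ga.element.name.upper()
                if el in ("H", "D"):
                    continue
                atoms.append(
                    Atom(
                        element=el,
                        name=ga.name,
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        vdw_radius=_element_radius(el),
                    )
                )
            rec = Residue(
                chain_id=chain.name,
                seq_index=res.seqid.num,
                aa=THREE_TO_ONE.get(res.name, "X"),
                atoms=atoms,
                name=res.name,
            )
            if is_aa and atoms:
                residues.append(rec)
                chain_has_polymer = True
            elif not is_water:
                ligands.append(rec)
        if chain_has_polymer:
            chains.append(chain.name)

    if not residues:
        raise StructureError(f"{path}: no polymer residues")
    residues = [r for r in residues if r.chain_id in chains]
    return StructureModel(chains=chains, residues=residues, ligands=ligands)


_ONE_TO_THREE = {v: k for k, v in reversed(list(THREE_TO_ONE.items()))}


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write the model as a minimal PDB file (heavy atoms only).

    Deterministic: identical models produce byte-identical files, which the
    synthetic generators rely on.
    """
    lines: list[str] = []
    serial = 1
    for chain_id in model.chains:
        for res in model.chain_residues(chain_id):
            resname = res.name or _ONE_TO_THREE.get(res.aa, "UNK")
            for atom in res.atoms:
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                x, y, z = atom.coords
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s} {resname:<3s} {chain_id[:1]}"
                    f"{res.seq_index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def chain_sequence(model: StructureModel, chain_id: str) -> str:
    """One-letter sequence of a chain in seq_index order.

    Gaps in author numbering do not insert placeholders.
    """
    residues = model.chain_residues(chain_id)
    if not residues:
        raise KeyError(f"chain {chain_id!r} has no residues")
    return "".join(r.aa for r in residues)


def min_interchain_distance(model: StructureModel, residue: Residue) -> float:
    """Minimum heavy-atom distance from ``residue`` to any other chain."""
    if len(model.chains) < 2:
        raise StructureError("min_interchain_distance requires >= 2 chains")
    own = residue.heavy_coords()
    if own.size == 0:
        raise StructureError("residue has no heavy atoms")
    other = np.array(
        [
            a.coords
            for r in model.residues
            if r.chain_id != residue.chain_id
            for a in r.atoms
            if a.is_heavy
        ]
    )
    if other.size == 0:
        raise StructureError("no heavy atoms on other chains")
    d = np.linalg.norm(own[:, None, :] - other[None, :, :], axis=-1)
    return float(d.min())


def min_interchain_distances(model: StructureModel) -> dict[tuple[str, int], float]:
    """Per-residue minimum distance to any other chain, for all residues.

    Uses a KD-tree per chain complement; equivalent to calling
    :func:`min_interchain_distance` on every residue but far cheaper.
    """
    from scipy.spatial import cKDTree

    if len(model.chains) < 2:
        raise StructureError("min_interchain_distances requires >= 2 chains")
    coords_by_chain: dict[str, np.ndarray] = {}
    for cid in model.chains:
        pts = np.array(
            [a.coords for r in model.chain_residues(cid) for a in r.atoms if a.is_heavy]
        )
        coords_by_chain[cid] = pts
    out: dict[tuple[str, int], float] = {}
    for cid in model.chains:
        other = np.vstack([c for k, c in coords_by_chain.items() if k != cid])
        tree = cKDTree(other)
        for res in model.chain_residues(cid):
            own = res.heavy_coords()
            d, _ = tree.query(own, k=1)
            out[(cid, res.seq_index)] = float(np.min(d))
    return out
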