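"""Reading protein structures, extracting binding pockets, and apo/holo
superposition.

Conventions:

* Proteins are read from PDB files; hydrogens are dropped and hetero records
  (waters, ions, cofactors) are kept and flagged.
* A pocket is the set of heavy atoms inside an axis-aligned cubic box
  (default edge 20 Angstrom) centered on the binding site; membership uses a
  closed boundary (``<=``) so filtering is deterministic and
  order-independent.
* Binding-site residues are those with any heavy atom within 8 Angstrom of
  any ligand heavy atom.
* Apo structures are superimposed onto their holo counterparts by a
  least-squares (Kabsch) fit of the binding-site C-alpha atoms; the post-fit
  C-alpha RMSD quantifies the holo-apo pocket deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile
from scipy.spatial import cKDTree

from .errors import (
    EmptyPocketError,
    EmptyStructureError,
    FormatError,
    UnderdeterminedError,
)
from .geometry import RigidTransform, kabsch

logger = logging.getLogger(__name__)

ResidueKey = tuple[str, int, str]  # (chain id, residue index, residue name)


@dataclass
class ProteinStructure:
    """A heavy-atom protein structure as parallel per-atom arrays."""

    element: np.ndarray  # (n,) str
    atom_name: np.ndarray  # (n,) str
    res_name: np.ndarray  # (n,) str
    res_id: np.ndarray  # (n,) int
    chain_id: np.ndarray  # (n,) str
    coords: np.ndarray  # (n, 3) float, Angstrom
    is_hetero: np.ndarray  # (n,) bool

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        self.res_id = np.asarray(self.res_id, dtype=np.int64)
        self.is_hetero = np.asarray(self.is_hetero, dtype=bool)
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("non-finite coordinates in structure")

    def __len__(self) -> int:
        return len(self.coords)

    def subset(self, mask: np.ndarray) -> "ProteinStructure":
        return ProteinStructure(
            element=self.element[mask],
            atom_name=self.atom_name[mask],
            res_name=self.res_name[mask],
            res_id=self.res_id[mask],
            chain_id=self.chain_id[mask],
            coords=self.coords[mask],
            is_hetero=self.is_hetero[mask],
        )

    def residue_keys(self) -> list[ResidueKey]:
        """Unique (chain, res_id, res_name) keys in order of appearance."""
        seen: dict[ResidueKey, None] = {}
        for c, i, r in zip(self.chain_id, self.res_id, self.res_name):
            seen.setdefault((str(c), int(i), str(r)), None)
        return list(seen)

    def with_coords(self, coords: np.ndarray) -> "ProteinStructure":
        out = self.subset(np.ones(len(self), dtype=bool))
        out.coords = np.asarray(coords, dtype=np.float64).reshape(-1, 3)
        return out


@dataclass(frozen=True)
class PocketSpec:
    """A cubic binding-site box: center (Angstrom) and edge length."""

    center: np.ndarray
    box_edge: float = 20.0
    include_hetero: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "center",
                           np.asarray(self.center, dtype=np.float64).reshape(3))
        if not self.box_edge > 0:
            raise ValueError("box_edge must be positive")


@dataclass
class Pocket:
    """Heavy atoms of the receptor inside the binding-site box."""

    atoms: ProteinStructure
    centroid: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise EmptyPocketError("pocket contains no atoms")
        self.centroid = self.atoms.coords.mean(axis=0)

    @property
    def coords(self) -> np.ndarray:
        return self.atoms.coords

    def __len__(self) -> int:
        return len(self.atoms)


def _from_atom_array(arr: bst.AtomArray) -> ProteinStructure:
    heavy = ~np.isin(np.char.upper(arr.element.astype("U4")), ("H", "D"))
    arr = arr[heavy]
    if arr.array_length() == 0:
        raise EmptyStructureError("structure has no heavy atoms")
    return ProteinStructure(
        element=np.char.capitalize(arr.element.astype("U4")),
        atom_name=arr.atom_name.astype("U6"),
        res_name=arr.res_name.astype("U5"),
        res_id=arr.res_id.astype(np.int64),
        chain_id=arr.chain_id.astype("U4"),
        coords=np.asarray(arr.coord, dtype=np.float64),
        is_hetero=np.asarray(arr.hetero, dtype=bool),
    )


def read_protein(path) -> ProteinStructure:
    """Read a PDB file; drop hydrogens, keep hetero atoms flagged.

    Alternate locations are resolved to the highest-occupancy conformer.
    """
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1, altloc="occupancy")
    except Exception as exc:  # biotite raises a mix of error types
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise EmptyStructureError(f"no atoms in {path}")
    return _from_atom_array(arr)


def write_protein(structure: ProteinStructure, path) -> None:
    """Write a ProteinStructure to a PDB file (ATOM + HETATM records)."""
    n = len(structure)
    arr = bst.AtomArray(n)
    arr.coord = structure.coords.astype(np.float32)
    arr.element = structure.element.astype("U2")
    arr.atom_name = structure.atom_name.astype("U6")
    arr.res_name = structure.res_name.astype("U5")
    arr.res_id = structure.res_id.astype(int)
    arr.chain_id = structure.chain_id.astype("U4")
    arr.hetero = structure.is_hetero
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def extract_pocket(protein: ProteinStructure, spec: PocketSpec) -> Pocket:
    """Heavy atoms inside the cubic box; closed boundary on every axis.

    Hetero atoms (waters, ions, other ligands) are included when
    ``spec.include_hetero`` is set, mirroring pockets in which all
    non-protein entities are retained.
    """
    if len(protein) == 0:
        raise EmptyStructureError("empty protein")
    inside = np.all(
        np.abs(protein.coords - spec.center) <= spec.box_edge / 2.0, axis=1
    )
    if not spec.include_hetero:
        inside &= ~protein.is_hetero
    if not inside.any():
        raise EmptyPocketError("no atoms inside the pocket box")
    return Pocket(atoms=protein.subset(inside))


def binding_site_residues(protein: ProteinStructure, ligand_coords: np.ndarray,
                          radius: float = 8.0) -> set[ResidueKey]:
    """Residues with any heavy atom within ``radius`` of any ligand heavy atom."""
    ligand_coords = np.asarray(ligand_coords, dtype=np.float64).reshape(-1, 3)
    if len(ligand_coords) == 0:
        raise ValueError("ligand has no heavy atoms")
    tree = cKDTree(ligand_coords)
    dmin, _ = tree.query(protein.coords, k=1)
    near = dmin <= radius
    out: set[ResidueKey] = set()
    for c, i, r in zip(protein.chain_id[near], protein.res_id[near],
                       protein.res_name[near]):
        out.add((str(c), int(i), str(r)))
    return out


def _ca_coords_for_site(structure: ProteinStructure,
                        site: set[ResidueKey]) -> dict[ResidueKey, np.ndarray]:
    is_ca = structure.atom_name == "CA"
    out: dict[ResidueKey, np.ndarray] = {}
    for idx in np.nonzero(is_ca)[0]:
        key = (str(structure.chain_id[idx]), int(structure.res_id[idx]),
               str(structure.res_name[idx]))
        if key in site and key not in out:
            out[key] = structure.coords[idx]
    return out


def superimpose_pockets(mobile: ProteinStructure, reference: ProteinStructure,
                        site: set[ResidueKey]) -> tuple[RigidTransform, float]:
    """Kabsch fit of matched binding-site C-alpha atoms.

    Residues are matched on (chain, residue index, residue name); unmatched
    residues are dropped with a warning.  Returns the rigid transform taking
    ``mobile`` onto ``reference`` and the post-fit C-alpha RMSD (the
    holo-apo pocket deviation when comparing bound and unbound structures).
    """
    ca_m = _ca_coords_for_site(mobile, site)
    ca_r = _ca_coords_for_site(reference, site)
    common = sorted(set(ca_m) & set(ca_r))
    dropped = (set(ca_m) | set(ca_r)) - set(common)
    if dropped:
        logger.warning("superimpose_pockets: dropping %d unmatched residues",
                       len(dropped))
    if len(common) < 3:
        raise UnderdeterminedError(
            f"only {len(common)} matched C-alpha atoms; need at least 3")
    p = np.array([ca_m[k] for k in common])
    q = np.array([ca_r[k] for k in common])
    return kabsch(p, q)
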