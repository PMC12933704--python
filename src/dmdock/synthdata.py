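"""Synthetic protein-ligand complexes with exact ground truth.

A complex is built by embedding a ligand conformer as the "bound pose" at
the origin and surrounding it with a shell of pseudo-protein heavy atoms:
each pocket atom sits at a uniform random distance (default 6-12 Angstrom)
from its nearest ligand atom, never closer than 2.8 Angstrom (a van der
Waals contact floor), and inside the standard 20 Angstrom binding-site box.
Pocket atoms carry simplified element/residue labels — including a
configurable fraction of water/ion hetero atoms — sufficient to exercise
every featurization vocabulary.  The exact pocket-ligand distance matrix is
stored alongside, so distance-matrix-to-pose algorithms can be tested
against a known answer.

Apo-like variants Gaussian-perturb the pocket and record the post-fit
deviation, emulating unbound-receptor (cross-docking) conditions.

These complexes have no physical energetics or realistic protein sequences;
they probe geometry, featurization, and learnability, not chemistry.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from rdkit import Chem
from scipy.spatial.distance import cdist

from .errors import InputError
from .featurize import embed_conformer
from .geometry import kabsch
from .mol_io import Pocket, PocketSpec, ProteinStructure
from .trainkit import TrainingExample, save_example

_PROTEIN_RESIDUES = ["ALA", "SER", "LEU", "VAL", "THR", "GLY"]
_ATOM_NAMES = ["N", "CA", "C", "O", "CB"]
_ATOMS_PER_RESIDUE = 5
MIN_CONTACT = 2.8       # Angstrom, ligand-pocket van-der-Waals contact floor
MIN_POCKET_SPACING = 2.5  # Angstrom, between pocket pseudo-atoms


def packaged_smiles() -> dict[str, str]:
    """The shipped ligand library: code -> SMILES."""
    text = resources.files("dmdock.data").joinpath(
        "ligand_smiles.txt").read_text()
    out: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        code, smi = line.split("\t")
        out[code] = smi
    return out


def _ligand_code(smiles: str) -> str:
    for code, smi in packaged_smiles().items():
        if smi == smiles:
            return code
    return "X" + hashlib.sha1(smiles.encode()).hexdigest()[:6].upper()


@dataclass
class SyntheticComplex:
    """A pseudo protein-ligand pair with exact distance-matrix truth."""

    example: TrainingExample
    pocket: Pocket                 # full pseudo-protein shell (all atoms)
    true_pose: np.ndarray          # (c, 3)
    true_dm: np.ndarray            # (p, c), exact Angstrom distances
    apo_deviation: float | None = None  # post-fit RMSD vs the holo pocket


def make_complex(smiles: str, shell_radius: tuple[float, float] = (6.0, 12.0),
                 n_pocket: tuple[int, int] = (60, 150),
                 hetero_frac: float = 0.1, seed: int = 0,
                 box_edge: float = 20.0,
                 cluster_id: str | None = None) -> SyntheticComplex:
    """Build one synthetic complex, deterministically from ``seed``."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"invalid SMILES {smiles!r}")
    rng = np.random.default_rng(seed)
    mol = embed_conformer(mol, seed=int(rng.integers(1, 2**31 - 1)))
    pose = np.asarray(mol.GetConformer().GetPositions(), dtype=np.float64)
    pose = pose - pose.mean(axis=0)
    for a in range(mol.GetNumAtoms()):
        mol.GetConformer().SetAtomPosition(a, pose[a].tolist())

    lig_elements = [a.GetSymbol() for a in mol.GetAtoms()]
    lig_polar = np.array([e in ("N", "O", "S") for e in lig_elements])

    lo, hi = shell_radius
    n_p = int(rng.integers(n_pocket[0], n_pocket[1] + 1))
    half = box_edge / 2.0
    coords = np.zeros((n_p, 3))
    element = np.empty(n_p, dtype="U4")
    placed = 0
    while placed < n_p:
        a_idx = int(rng.integers(len(pose)))
        anchor = pose[a_idx]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        # chemical complementarity: polar ligand atoms attract polar pocket
        # atoms at tight shell distances, apolar atoms get carbon/sulfur at
        # any shell distance -- so pocket composition and geometry carry
        # information about the pose, as in real binding sites
        complementary = lig_polar[a_idx] and rng.random() < 0.8
        if complementary:
            r = rng.uniform(lo, min(lo + 2.0, hi))
            el = "N" if rng.random() < 0.5 else "O"
        else:
            r = rng.uniform(lo, hi)
            el = "C" if rng.random() < 0.85 else "S"
        x = anchor + direction * r
        dmin = np.min(np.linalg.norm(pose - x, axis=1))
        if not (lo <= dmin <= hi and dmin >= MIN_CONTACT
                and np.all(np.abs(x) <= half)):
            continue
        if placed and np.min(np.linalg.norm(
                coords[:placed] - x, axis=1)) < MIN_POCKET_SPACING:
            continue
        coords[placed] = x
        element[placed] = el
        placed += 1

    is_het = rng.random(n_p) < hetero_frac
    res_name = np.empty(n_p, dtype="U4")
    atom_name = np.empty(n_p, dtype="U4")
    res_id = np.empty(n_p, dtype=np.int64)
    next_res = 1
    for i in range(n_p):
        if is_het[i]:
            if rng.random() < 0.8:
                res_name[i], atom_name[i], element[i] = "HOH", "O", "O"
            else:
                res_name[i], atom_name[i], element[i] = "ZN", "ZN", "Zn"
            res_id[i] = 900 + i
        else:
            res_id[i] = 1 + i // _ATOMS_PER_RESIDUE
            res_name[i] = _PROTEIN_RESIDUES[
                (i // _ATOMS_PER_RESIDUE) % len(_PROTEIN_RESIDUES)]
            atom_name[i] = _ATOM_NAMES[i % _ATOMS_PER_RESIDUE]
    protein = ProteinStructure(
        element=element.astype("U4"), atom_name=atom_name,
        res_name=res_name, res_id=res_id,
        chain_id=np.array(["A"] * n_p), coords=coords,
        is_hetero=is_het)
    pocket = Pocket(atoms=protein)
    true_dm = cdist(coords, pose)
    code = _ligand_code(smiles)
    example = TrainingExample(
        mol=mol, true_coords=pose, protein=protein,
        pocket_spec=PocketSpec(center=np.zeros(3), box_edge=box_edge),
        cluster_id=cluster_id or code,
        ligand_code=code,
        conformer_seed=int(rng.integers(1, 2**31 - 1)))
    return SyntheticComplex(example=example, pocket=pocket, true_pose=pose,
                            true_dm=true_dm)


def make_apo_variant(cx: SyntheticComplex, sigma: float,
                     seed: int = 0) -> SyntheticComplex:
    """Gaussian-perturb the pocket, superimpose it back onto the original,
    and record the achieved post-fit deviation.  The distance-matrix truth
    is recomputed against the perturbed pocket."""
    if sigma < 0:
        raise InputError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    coords = cx.pocket.coords
    perturbed = coords + rng.normal(0.0, sigma, size=coords.shape) \
        if sigma > 0 else coords.copy()
    tf, deviation = kabsch(perturbed, coords)
    fitted = tf.apply(perturbed)
    protein = cx.example.protein.with_coords(fitted)
    pocket = Pocket(atoms=protein)
    example = TrainingExample(
        mol=cx.example.mol, true_coords=cx.true_pose, protein=protein,
        pocket_spec=cx.example.pocket_spec,
        cluster_id=cx.example.cluster_id,
        ligand_code=cx.example.ligand_code,
        conformer_seed=cx.example.conformer_seed)
    return SyntheticComplex(example=example, pocket=pocket,
                            true_pose=cx.true_pose,
                            true_dm=cdist(fitted, cx.true_pose),
                            apo_deviation=float(deviation))


def make_dataset(n: int, cluster_structure: list[int] | None = None,
                 seed: int = 0, out_dir=None,
                 n_pocket: tuple[int, int] = (60, 150),
                 hetero_frac: float = 0.1,
                 smiles_subset: list[str] | None = None,
                 ) -> list[SyntheticComplex]:
    """Generate ``n`` complexes; optionally write the training layout.

    ``cluster_structure`` lists the sizes of shared-ligand groups (group
    members reuse the same complex with small pocket jitter, so joint
    ligand/pocket/interaction clustering recovers them); remaining examples
    are singletons with distinct ligands.  With ``out_dir`` set, one
    subdirectory per example is written in the training-data layout.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    groups = list(cluster_structure or [])
    if sum(groups) > n:
        raise InputError("cluster_structure exceeds n")
    rng = np.random.default_rng(seed)
    codes = list(packaged_smiles().items())
    if smiles_subset is not None:
        codes = [(c, s) for c, s in codes if s in smiles_subset or c in smiles_subset]
    order = rng.permutation(len(codes))

    complexes: list[SyntheticComplex] = []
    gi = 0
    for size in groups:
        code, smi = codes[order[gi % len(codes)]]
        gi += 1
        base = make_complex(smi, seed=int(rng.integers(2**31)),
                            n_pocket=n_pocket, hetero_frac=hetero_frac,
                            cluster_id=f"G{gi:03d}")
        complexes.append(base)
        for _ in range(size - 1):
            jit = make_apo_variant(base, sigma=0.2,
                                   seed=int(rng.integers(2**31)))
            complexes.append(jit)
    while len(complexes) < n:
        code, smi = codes[order[gi % len(codes)]]
        gi += 1
        complexes.append(make_complex(
            smi, seed=int(rng.integers(2**31)), n_pocket=n_pocket,
            hetero_frac=hetero_frac, cluster_id=f"S{gi:03d}"))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, cx in enumerate(complexes):
            save_example(cx.example, out_dir / f"example_{i:04d}")
        manifest = {
            "n": n, "seed": seed,
            "cluster_structure": groups,
            "ligand_codes": [cx.example.ligand_code for cx in complexes],
        }
        (out_dir / "dataset.json").write_text(
            json.dumps(manifest, sort_keys=True, indent=1) + "\n")
    return complexes
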