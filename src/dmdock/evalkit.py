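"""Docking evaluation metrics and benchmark aggregation.

* ``symmetry_corrected_rmsd`` — minimum heavy-atom RMSD over the ligand's
  graph automorphisms (element- and bond-type-preserving self-mappings),
  with no re-superposition: predicted and reference poses live in the
  receptor frame.
* ``lddt_pli`` — local distance difference test restricted to
  protein-ligand contacts: the fraction of reference pocket-ligand contact
  distances reproduced within {0.5, 1, 2, 4} Angstrom, averaged over the
  four thresholds.
* ``validity_checks`` — a documented subset of the PoseBusters battery
  (bond lengths/angles vs a relaxed reference conformer, intra-ligand and
  ligand-pocket clash floors, a UFF internal-energy ratio); the overall
  flag is named ``pb_valid_subset`` to make the reduced scope explicit.
* ``summarize`` — medians and strict-threshold fractions over scored cases
  only; failed predictions are tallied separately and never penalize the
  aggregate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.spatial.distance import cdist

from .errors import InputError
from .featurize import embed_conformer
from .mol_io import Pocket

logger = logging.getLogger(__name__)

MAX_AUTOMORPHISMS = 10_000


# ---------------------------------------------------------------------------
# symmetry-corrected RMSD

def ligand_automorphisms(mol: Chem.Mol,
                         max_matches: int = MAX_AUTOMORPHISMS) -> np.ndarray:
    """Element- and bond-type-preserving self-mappings of the heavy-atom
    graph, as an (m, c) index array.  Falls back to the identity with a
    warning if the cap is exceeded."""
    mol = Chem.RemoveHs(Chem.Mol(mol))
    matches = mol.GetSubstructMatches(mol, uniquify=False,
                                      maxMatches=max_matches + 1,
                                      useChirality=False)
    if len(matches) == 0 or len(matches) > max_matches:
        if len(matches) > max_matches:
            logger.warning("automorphism cap exceeded; using identity only")
        return np.arange(mol.GetNumAtoms())[None, :]
    return np.asarray(matches, dtype=np.int64)


def symmetry_corrected_rmsd(pred_coords: np.ndarray, ref_coords: np.ndarray,
                            mol: Chem.Mol) -> float:
    """Minimum RMSD over graph automorphisms, no re-superposition."""
    pred = np.asarray(pred_coords, dtype=np.float64).reshape(-1, 3)
    ref = np.asarray(ref_coords, dtype=np.float64).reshape(-1, 3)
    if pred.shape != ref.shape or len(pred) != mol.GetNumHeavyAtoms():
        raise InputError("atom count mismatch between poses and topology")
    perms = ligand_automorphisms(mol)
    diffs = pred[perms] - ref[None, :, :]          # (m, c, 3)
    rmsds = np.sqrt(np.mean(np.sum(diffs**2, axis=-1), axis=-1))
    return float(rmsds.min())


# ---------------------------------------------------------------------------
# lDDT-PLI

def lddt_pli(pred_coords: np.ndarray, ref_coords: np.ndarray, pocket: Pocket,
             inclusion_radius: float = 6.0,
             thresholds: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)) -> float:
    """Fraction of reference pocket-ligand contacts preserved in the
    prediction, averaged over the distance-difference thresholds.

    Returns NaN when the reference defines no contacts inside the
    inclusion radius.
    """
    pred = np.asarray(pred_coords, dtype=np.float64).reshape(-1, 3)
    ref = np.asarray(ref_coords, dtype=np.float64).reshape(-1, 3)
    d_ref = cdist(pocket.coords, ref)
    mask = d_ref < inclusion_radius
    if not mask.any():
        return float("nan")
    d_pred = cdist(pocket.coords, pred)
    delta = np.abs(d_pred[mask] - d_ref[mask])
    fracs = [(delta < t).mean() for t in thresholds]
    return float(np.mean(fracs))


# ---------------------------------------------------------------------------
# validity checks (PoseBusters-style subset)

BOND_LENGTH_TOL = 0.25       # relative deviation vs the reference conformer
BOND_ANGLE_TOL = 25.0        # degrees
CLASH_FLOOR = 2.0            # Angstrom, heavy-atom pairs
ENERGY_RATIO_CAP = 100.0     # pose energy vs mean relaxed-ensemble energy


def _angles(mol: Chem.Mol) -> list[tuple[int, int, int]]:
    out = []
    for atom in mol.GetAtoms():
        nbrs = [n.GetIdx() for n in atom.GetNeighbors()]
        j = atom.GetIdx()
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                out.append((nbrs[a], j, nbrs[b]))
    return out


def _angle_deg(coords: np.ndarray, i: int, j: int, k: int) -> float:
    v1, v2 = coords[i] - coords[j], coords[k] - coords[j]
    cosang = v1 @ v2 / max(np.linalg.norm(v1) * np.linalg.norm(v2), 1e-12)
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _uff_energy(mol: Chem.Mol, coords: np.ndarray | None = None) -> float:
    m = Chem.Mol(mol)
    if coords is not None:
        conf = Chem.Conformer(m.GetNumAtoms())
        for a in range(m.GetNumAtoms()):
            conf.SetAtomPosition(a, coords[a].tolist())
        m.RemoveAllConformers()
        m.AddConformer(conf)
    ff = AllChem.UFFGetMoleculeForceField(m)
    return float(ff.CalcEnergy())


def validity_checks(pred_coords: np.ndarray, mol: Chem.Mol,
                    pocket: Pocket | None = None,
                    n_ensemble: int = 10,
                    ensemble_seed: int = 20_000) -> dict:
    """Physical/chemical plausibility checks for a predicted pose.

    Implemented subset: bond lengths within 25% of a relaxed reference
    conformer, bond angles within 25 degrees, no intra-ligand non-bonded
    heavy-atom pair below 2 Angstrom, no ligand-pocket heavy-atom pair
    below 2 Angstrom (hetero pocket atoms included), and a UFF
    internal-energy ratio against a small relaxed-conformer ensemble.
    Checks that cannot be evaluated are reported as None and excluded from
    the overall ``pb_valid_subset`` flag.
    """
    mol = Chem.RemoveHs(Chem.Mol(mol))
    pred = np.asarray(pred_coords, dtype=np.float64).reshape(-1, 3)
    if len(pred) != mol.GetNumAtoms():
        raise InputError("pose does not match ligand topology")
    results: dict[str, bool | None] = {}

    try:
        ref_mol = embed_conformer(mol, seed=ensemble_seed)
        ref = np.asarray(ref_mol.GetConformer().GetPositions())
    except Exception:
        ref = None

    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    if ref is not None and bonds:
        ok = True
        for i, j in bonds:
            r = np.linalg.norm(ref[i] - ref[j])
            p = np.linalg.norm(pred[i] - pred[j])
            if abs(p - r) > BOND_LENGTH_TOL * r:
                ok = False
                break
        results["bond_lengths"] = ok
        ok = True
        for i, j, k in _angles(mol):
            if abs(_angle_deg(pred, i, j, k)
                   - _angle_deg(ref, i, j, k)) > BOND_ANGLE_TOL:
                ok = False
                break
        results["bond_angles"] = ok
    else:
        results["bond_lengths"] = None
        results["bond_angles"] = None

    bonded = set()
    for i, j in bonds:
        bonded.add((min(i, j), max(i, j)))
    d_intra = cdist(pred, pred)
    clash = False
    for i in range(len(pred)):
        for j in range(i + 1, len(pred)):
            if (i, j) not in bonded and d_intra[i, j] < CLASH_FLOOR:
                clash = True
    results["internal_clash"] = not clash

    if pocket is not None:
        dmin = cdist(pocket.coords, pred).min()
        results["pocket_clash"] = bool(dmin >= CLASH_FLOOR)
    else:
        results["pocket_clash"] = None

    try:
        e_pose = _uff_energy(mol, pred)
        rng = np.random.default_rng(ensemble_seed)
        energies = []
        for _ in range(n_ensemble):
            m = embed_conformer(mol, seed=int(rng.integers(1, 2**31)))
            AllChem.UFFOptimizeMolecule(m, maxIters=200)
            energies.append(_uff_energy(m))
        e_ref = float(np.mean(energies))
        # UFF relaxed energies of drug-like molecules are positive in
        # practice; |.| guards the ratio against near-zero references
        results["internal_energy"] = bool(
            e_pose <= ENERGY_RATIO_CAP * max(abs(e_ref), 1.0))
    except Exception:
        results["internal_energy"] = None

    evaluable = [v for v in results.values() if v is not None]
    results["pb_valid_subset"] = bool(all(evaluable)) if evaluable else None
    return results


# ---------------------------------------------------------------------------
# aggregation

@dataclass
class EvalScores:
    srmsd: float
    lddt_pli: float
    validity: dict = field(default_factory=dict)
    rmsd_ca_holo_apo: float | None = None


@dataclass
class BenchmarkSummary:
    median_srmsd: float
    frac_srmsd_lt2: float
    median_lddt_pli: float
    frac_lddt_gt_0_5: float
    frac_valid: float
    n_scored: int
    n_failed: int


def summarize(scores: list[EvalScores], n_failed: int = 0) -> BenchmarkSummary:
    """Medians and strict-threshold fractions over scored cases only."""
    if not scores:
        raise InputError("no scored cases to summarize")
    srmsd = np.array([s.srmsd for s in scores], dtype=float)
    lddt = np.array([s.lddt_pli for s in scores], dtype=float)
    valid_flags = [s.validity.get("pb_valid_subset") for s in scores
                   if s.validity.get("pb_valid_subset") is not None]
    lddt_ok = lddt[~np.isnan(lddt)]
    return BenchmarkSummary(
        median_srmsd=float(np.median(srmsd)),
        frac_srmsd_lt2=float(np.mean(srmsd < 2.0)),
        median_lddt_pli=float(np.median(lddt_ok)) if len(lddt_ok) else float("nan"),
        frac_lddt_gt_0_5=float(np.mean(lddt_ok > 0.5)) if len(lddt_ok) else float("nan"),
        frac_valid=float(np.mean(valid_flags)) if valid_flags else float("nan"),
        n_scored=len(scores),
        n_failed=int(n_failed),
    )


def evaluate_manifest(manifest_path, out_dir=None,
                      run_validity: bool = False) -> tuple[pd.DataFrame,
                                                           BenchmarkSummary]:
    """Batch evaluation from a manifest CSV.

    Columns: ``pred_sdf``, ``ref_sdf``, ``pocket_pdb``.  Unreadable rows
    are counted as failures and never abort the batch.
    """
    from .mol_io import read_protein  # late import to keep module load light

    manifest = pd.read_csv(manifest_path)
    rows, scores = [], []
    n_failed = 0
    for _, row in manifest.iterrows():
        try:
            pred_mol = next(iter(Chem.SDMolSupplier(str(row["pred_sdf"]),
                                                    removeHs=True)))
            ref_mol = next(iter(Chem.SDMolSupplier(str(row["ref_sdf"]),
                                                   removeHs=True)))
            if pred_mol is None or ref_mol is None:
                raise InputError("unreadable SDF")
            protein = read_protein(row["pocket_pdb"])
            pocket = Pocket(atoms=protein)
            pred = np.asarray(pred_mol.GetConformer().GetPositions())
            ref = np.asarray(ref_mol.GetConformer().GetPositions())
            s = symmetry_corrected_rmsd(pred, ref, ref_mol)
            l = lddt_pli(pred, ref, pocket)
            validity = (validity_checks(pred, ref_mol, pocket)
                        if run_validity else {})
            scores.append(EvalScores(srmsd=s, lddt_pli=l, validity=validity))
            rows.append({"pred_sdf": row["pred_sdf"], "srmsd": s,
                         "lddt_pli": l, "failed": False})
        except Exception as exc:
            logger.warning("evaluation failed for row %s: %s",
                           row.to_dict(), exc)
            n_failed += 1
            rows.append({"pred_sdf": row.get("pred_sdf"), "srmsd": np.nan,
                         "lddt_pli": np.nan, "failed": True})
    per_case = pd.DataFrame(rows)
    summary = summarize(scores, n_failed=n_failed) if scores else None
    if out_dir is not None:
        from pathlib import Path
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        per_case.to_csv(out_dir / "per_case.csv", index=False)
        if summary is not None:
            pd.DataFrame([vars(summary)]).to_csv(out_dir / "summary.csv",
                                                 index=False)
    return per_case, summary
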