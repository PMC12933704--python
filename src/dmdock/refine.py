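"""Physics-based local refinement of raw poses.

The ligand is minimized with the Universal Force Field inside the frozen
pocket: ligand and pocket atoms form one nonbonded-interacting system,
every pocket atom is position-locked, and only the ligand moves (up to 500
iterations by default).  Pocket atoms whose elements cannot be
force-field-typed are dropped from the refinement system with a warning.

An optional hook shells out to an external BFGS local optimizer (e.g. a
Vina binary, up to 500 steps); it is disabled unless an executable is
configured and passes poses through unchanged otherwise.
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .errors import FeatureUnavailableError, RefinementError, TypedSystemError
from .mol_io import Pocket
from .posegen import Pose

logger = logging.getLogger(__name__)


@dataclass
class RefineReport:
    initial_energy: float   # kcal/mol (UFF)
    final_energy: float
    n_iters: int            # upper bound actually spent
    converged: bool
    n_pocket_dropped: int = 0


def _pocket_mol(pocket: Pocket) -> tuple[Chem.Mol, list[int], int]:
    """Pocket atoms as a bond-less RDKit fragment; untypeable atoms dropped."""
    em = Chem.RWMol()
    kept: list[int] = []
    dropped = 0
    charges = {"Zn": 2, "Mg": 2, "Ca": 2, "Na": 1, "K": 1, "Fe": 2,
               "Mn": 2, "Cu": 2, "Ni": 2, "Co": 2, "Cd": 2}
    for i in range(len(pocket)):
        sym = str(pocket.atoms.element[i])
        try:
            atom = Chem.Atom(sym)
        except Exception:
            dropped += 1
            logger.warning("pocket atom %d (%s) not typeable; dropped", i, sym)
            continue
        atom.SetNoImplicit(True)
        # isolated pseudo-atoms need an explicit hybridization for UFF typing
        atom.SetHybridization(Chem.HybridizationType.SP3)
        if sym in charges:
            atom.SetFormalCharge(charges[sym])
        em.AddAtom(atom)
        kept.append(i)
    mol = em.GetMol()
    conf = Chem.Conformer(mol.GetNumAtoms())
    for j, i in enumerate(kept):
        conf.SetAtomPosition(j, pocket.coords[i].tolist())
    mol.AddConformer(conf)
    return mol, kept, dropped


def uff_minimize(pose: Pose, mol: Chem.Mol, pocket: Pocket,
                 max_iters: int = 500,
                 force_tol: float = 1e-4) -> tuple[Pose, RefineReport]:
    """UFF minimization of the ligand with every pocket atom frozen.

    ``mol`` supplies the ligand topology; ``pose.coords`` its heavy-atom
    coordinates.  Returns the refined pose (stage = "refined") and an
    energy report.  Pocket coordinates are bit-identical before and after.
    """
    lig = Chem.RemoveHs(Chem.Mol(mol))
    if lig.GetNumAtoms() != len(pose.coords):
        raise TypedSystemError("pose does not match ligand topology")
    conf = Chem.Conformer(lig.GetNumAtoms())
    for a in range(lig.GetNumAtoms()):
        conf.SetAtomPosition(a, pose.coords[a].tolist())
    lig.RemoveAllConformers()
    lig.AddConformer(conf)

    pmol, kept, dropped = _pocket_mol(pocket)
    combo = Chem.CombineMols(lig, pmol)
    Chem.SanitizeMol(combo, Chem.SanitizeFlags.SANITIZE_FINDRADICALS
                     | Chem.SanitizeFlags.SANITIZE_SETAROMATICITY
                     | Chem.SanitizeFlags.SANITIZE_SYMMRINGS,
                     catchErrors=True)
    n_lig = lig.GetNumAtoms()
    try:
        if not AllChem.UFFHasAllMoleculeParams(combo):
            raise TypedSystemError("UFF typing failed for the combined system")
        ff = AllChem.UFFGetMoleculeForceField(
            combo, ignoreInterfragInteractions=False)
    except TypedSystemError:
        raise
    except Exception as exc:
        raise TypedSystemError(f"UFF setup failed: {exc}") from exc
    for j in range(len(kept)):
        ff.AddFixedPoint(n_lig + j)
    ff.Initialize()
    e0 = float(ff.CalcEnergy())
    if not np.isfinite(e0):
        raise RefinementError("non-finite initial energy")
    status = ff.Minimize(maxIts=max_iters, forceTol=force_tol)
    e1 = float(ff.CalcEnergy())
    if not np.isfinite(e1) or e1 > e0 + 1e-6:
        logger.warning("refinement did not lower the energy; keeping raw pose")
        return (Pose(coords=pose.coords.copy(), stage="raw",
                     fit_rmsd=pose.fit_rmsd),
                RefineReport(e0, e0, 0, False, dropped))
    new_coords = np.asarray(
        combo.GetConformer().GetPositions()[:n_lig], dtype=np.float64)
    report = RefineReport(initial_energy=e0, final_energy=e1,
                          n_iters=max_iters, converged=(status == 0),
                          n_pocket_dropped=dropped)
    return Pose(coords=new_coords, stage="refined",
                fit_rmsd=pose.fit_rmsd), report


def vina_local_opt_hook(pose: Pose, mol: Chem.Mol, receptor_file,
                        max_steps: int = 500,
                        executable: str | None = None) -> Pose:
    """Pass a pose through an external BFGS local optimizer.

    Disabled by default; the configured executable is called as
    ``exe --in POSE.sdf --out OUT.sdf --receptor FILE --steps N`` and its
    output pose is returned verbatim.
    """
    if executable is None:
        raise FeatureUnavailableError(
            "no local-optimization executable configured")
    from .posegen import write_poses  # local import avoids cycle at import time

    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "pose.sdf"
        out = Path(tmp) / "opt.sdf"
        write_poses([pose], mol, inp)
        subprocess.run(
            [executable, "--in", str(inp), "--out", str(out),
             "--receptor", str(receptor_file), "--steps", str(max_steps)],
            check=True)
        supplier = Chem.SDMolSupplier(str(out), removeHs=True)
        opt = next(iter(supplier))
        if opt is None:
            raise RefinementError("external optimizer produced no pose")
        coords = np.asarray(opt.GetConformer().GetPositions(),
                            dtype=np.float64)
    return Pose(coords=coords, stage="refined", fit_rmsd=pose.fit_rmsd)
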