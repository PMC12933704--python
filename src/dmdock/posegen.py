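"""Distance-matrix-to-pose conversion.

Stage 1 (``infer_point_cloud``): each ligand atom is located independently
by multilateration — robust iterative least squares on the residuals
``||P_i - x|| - dm_ik`` over the pocket anchors ``P_i``, initialized from
the linearized closed-form solution and damped so the objective is
monotonically non-increasing.  Large predicted distances are down-weighted
(w_i = 1 / (1 + dm_ik)) because short contacts are both better determined
and better predicted.

Stage 2 (``align_conformer``): a chemically valid conformer is mapped onto
the point cloud by a proper-rotation Kabsch fit (reflections are rejected,
preserving chirality), optionally followed by a few sweeps of coordinate
descent over rotatable-bond torsions.  The conformer supplies all internal
geometry, so raw poses always have sane bond lengths.

``dock`` chains featurization, distance-matrix prediction, cloud inference
and conformer alignment over several conformer seeds, ranking poses by
their cloud-fit RMSD (a proxy rank: the distance-matrix model itself has no
scoring function).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from .errors import InputError, UnderdeterminedError
from .featurize import build_ligand_graph, build_pocket_graph
from .geometry import kabsch, rmsd, rotation_about_axis
from .mol_io import PocketSpec, ProteinStructure, extract_pocket

logger = logging.getLogger(__name__)


@dataclass
class PointCloud:
    points: np.ndarray          # (c, 3) Angstrom
    residual: float             # weighted RMS distance-fit error, Angstrom
    converged: bool = True


@dataclass
class Pose:
    coords: np.ndarray          # (c, 3) Angstrom
    stage: str = "raw"          # raw | refined
    fit_rmsd: float = 0.0       # conformer-to-cloud RMSD, Angstrom


def _check_anchors(pocket_coords: np.ndarray) -> None:
    p = len(pocket_coords)
    if p < 4:
        raise UnderdeterminedError(f"{p} pocket anchors; need >= 4")
    centered = pocket_coords - pocket_coords.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[2] < 1e-6 * max(sv[0], 1.0):
        raise UnderdeterminedError("pocket anchors are (nearly) coplanar")


def _linear_init(anchors: np.ndarray, d: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Closed-form linearized multilateration (difference-of-spheres)."""
    b = np.sum(anchors * anchors, axis=1) - d * d
    wm = w / w.sum()
    a_mat = 2.0 * (anchors - wm @ anchors)
    b_vec = b - wm @ b
    sw = np.sqrt(w)
    x, *_ = np.linalg.lstsq(a_mat * sw[:, None], b_vec * sw, rcond=None)
    return x


def _gauss_newton(anchors: np.ndarray, d: np.ndarray, w: np.ndarray,
                  x0: np.ndarray, max_iters: int = 60,
                  tol: float = 1e-10) -> tuple[np.ndarray, float, bool]:
    """Damped Gauss-Newton on sum_i w_i (||P_i - x|| - d_i)^2; monotone."""
    x = x0.copy()
    sw = np.sqrt(w)

    def resid(pt):
        dist = np.linalg.norm(anchors - pt, axis=1)
        return sw * (dist - d), dist

    r, dist = resid(x)
    obj = float(r @ r)
    converged = False
    for _ in range(max_iters):
        safe = np.maximum(dist, 1e-9)
        jac = sw[:, None] * (x - anchors) / safe[:, None]
        g = jac.T @ r
        h = jac.T @ jac + 1e-12 * np.eye(3)
        step = -np.linalg.solve(h, g)
        # backtracking line search keeps the objective non-increasing
        alpha, accepted = 1.0, False
        for _ in range(30):
            x_new = x + alpha * step
            r_new, dist_new = resid(x_new)
            obj_new = float(r_new @ r_new)
            if obj_new <= obj:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
        moved = np.linalg.norm(alpha * step)
        x, r, dist, prev_obj, obj = x_new, r_new, dist_new, obj, obj_new
        if prev_obj - obj <= tol * max(obj, 1.0) and moved < 1e-8:
            converged = True
            break
    else:
        converged = obj <= tol
    return x, obj, converged or obj <= 1e-12


def infer_point_cloud(dm: np.ndarray, pocket_coords: np.ndarray) -> PointCloud:
    """Infer ligand atom positions from a pocket-ligand distance matrix.

    Each column of ``dm`` (one ligand atom) is multilaterated independently
    against the pocket anchor coordinates.
    """
    dm = np.asarray(dm, dtype=np.float64)
    pocket_coords = np.asarray(pocket_coords, dtype=np.float64).reshape(-1, 3)
    if dm.ndim != 2 or dm.shape[0] != len(pocket_coords):
        raise InputError("dm shape does not match pocket anchor count")
    _check_anchors(pocket_coords)
    c = dm.shape[1]
    points = np.zeros((c, 3))
    sq_sum, w_sum = 0.0, 0.0
    all_ok = True
    for k in range(c):
        d = dm[:, k]
        w = 1.0 / (1.0 + d)
        x0 = _linear_init(pocket_coords, d, w)
        x, obj, ok = _gauss_newton(pocket_coords, d, w, x0)
        if not ok:
            logger.warning("multilateration: atom %d not fully converged", k)
            all_ok = False
        points[k] = x
        sq_sum += obj
        w_sum += w.sum()
    residual = float(np.sqrt(sq_sum / max(w_sum, 1e-12)))
    return PointCloud(points=points, residual=residual, converged=all_ok)


# ---------------------------------------------------------------------------
# conformer alignment

def get_rotatable_bonds(mol: Chem.Mol
                        ) -> list[tuple[int, int, np.ndarray, int, int]]:
    """Rotatable bonds: single, non-ring, non-terminal heavy-atom bonds.

    Returns (i, j, moving_atoms, a, b) where ``moving_atoms`` is the index
    array of the smaller fragment on the j side and a-i-j-b defines a
    reference dihedral (a a neighbor of i, b a neighbor of j).
    """
    out = []
    n = mol.GetNumAtoms()
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if bond.GetBeginAtom().GetDegree() < 2 or bond.GetEndAtom().GetDegree() < 2:
            continue
        em = Chem.RWMol(mol)
        em.RemoveBond(i, j)
        frags = Chem.GetMolFrags(em.GetMol())
        if len(frags) != 2:
            continue
        side_j = next(f for f in frags if j in f)
        moving = np.array(sorted(side_j))
        if len(moving) > n - len(moving):
            i, j = j, i
            moving = np.array(sorted(next(f for f in frags if j in f)))
        a = next(nb.GetIdx() for nb in mol.GetAtomWithIdx(i).GetNeighbors()
                 if nb.GetIdx() != j)
        b = next(nb.GetIdx() for nb in mol.GetAtomWithIdx(j).GetNeighbors()
                 if nb.GetIdx() != i)
        out.append((i, j, moving, a, b))
    return out


def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
              p3: np.ndarray) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m = np.cross(n1, b1 / max(np.linalg.norm(b1), 1e-12))
    return float(np.arctan2(m @ n2, n1 @ n2))


def _rotate_about_bond(coords: np.ndarray, i: int, j: int,
                       moving: np.ndarray, angle: float) -> np.ndarray:
    rot = rotation_about_axis(coords[j] - coords[i], angle)
    out = coords.copy()
    out[moving] = (coords[moving] - coords[j]) @ rot.T + coords[j]
    return out


def mol_is_achiral(mol: Chem.Mol) -> bool:
    """No chiral centers (assigned or potential) anywhere in the molecule."""
    from rdkit.Chem import FindMolChiralCenters
    return len(FindMolChiralCenters(mol, includeUnassigned=True,
                                    useLegacyImplementation=False)) == 0


def align_conformer(conformer_coords: np.ndarray, cloud: PointCloud,
                    rotatable_bonds: list | None = None,
                    max_sweeps: int = 3, n_angles: int = 72,
                    try_reflection: bool = False) -> Pose:
    """Fit a conformer onto the point cloud.

    A proper-rotation Kabsch fit first (reflections rejected, preserving
    chirality); when rotatable bonds are supplied, up to ``max_sweeps``
    rounds of per-torsion coordinate descent.  For each bond the candidate
    set is a uniform angle grid plus the rotation that matches the
    dihedral observed in the cloud itself (so clean clouds are matched in
    a single sweep); the conformer is re-fit rigidly after every accepted
    change.

    ``try_reflection`` additionally fits the mirrored conformer and keeps
    the better result.  Use it only for achiral molecules (see
    :func:`mol_is_achiral`): there a mirrored conformer is the same
    compound in the enantiomeric conformation — e.g. the flipped pucker of
    a non-planar ring — which torsion descent alone cannot reach.
    """
    if try_reflection:
        straight = align_conformer(conformer_coords, cloud, rotatable_bonds,
                                   max_sweeps, n_angles, False)
        mirrored = align_conformer(
            np.asarray(conformer_coords, dtype=np.float64)
            * np.array([1.0, 1.0, -1.0]),
            cloud, rotatable_bonds, max_sweeps, n_angles, False)
        return mirrored if mirrored.fit_rmsd < straight.fit_rmsd else straight
    conf = np.asarray(conformer_coords, dtype=np.float64).reshape(-1, 3)
    if conf.shape != cloud.points.shape:
        raise InputError("conformer and cloud atom counts differ")
    tf, fit = kabsch(conf, cloud.points)
    coords = tf.apply(conf)
    if rotatable_bonds:
        grid = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)[1:]
        for _ in range(max_sweeps):
            improved = False
            for (i, j, moving, a, b) in rotatable_bonds:
                target = _dihedral(cloud.points[a], cloud.points[i],
                                   cloud.points[j], cloud.points[b])
                current = _dihedral(coords[a], coords[i], coords[j],
                                    coords[b])
                delta = target - current
                best_coords, best_fit = coords, fit
                for ang in np.concatenate(([delta, -delta], grid)):
                    cand = _rotate_about_bond(coords, i, j, moving, ang)
                    tf2, f2 = kabsch(cand, cloud.points)
                    if f2 < best_fit - 1e-9:
                        best_coords, best_fit = tf2.apply(cand), f2
                if best_fit < fit - 1e-9:
                    coords, fit = best_coords, best_fit
                    improved = True
            if not improved:
                break
    return Pose(coords=coords, stage="raw", fit_rmsd=float(fit))


# ---------------------------------------------------------------------------
# end-to-end docking

def dock(mol: Chem.Mol, protein: ProteinStructure, spec: PocketSpec,
         model=None, n_conformers: int = 3, seed: int = 0,
         dm_fn=None, torsion_refine: bool = True) -> list[Pose]:
    """Featurize -> predict distance matrix -> point cloud -> pose.

    One pose per conformer seed, sorted ascending by cloud-fit RMSD.
    ``dm_fn(lig_graph, pocket_graph) -> (p, c) array`` may replace the
    model's prediction (used for oracle-distance experiments).
    """
    if model is None and dm_fn is None:
        raise InputError("either a model or a dm_fn must be supplied")
    pocket = extract_pocket(protein, spec)
    pocket_graph = build_pocket_graph(pocket)
    achiral = mol_is_achiral(mol)
    poses = []
    for t in range(n_conformers):
        lig = build_ligand_graph(mol, conformer_seed=seed + 7919 * t)
        dm = dm_fn(lig, pocket_graph) if dm_fn is not None \
            else model.predict_dm(lig, pocket_graph)
        cloud = infer_point_cloud(dm, pocket_graph.coords)
        rot = get_rotatable_bonds(lig.mol) if (torsion_refine and lig.mol) else None
        poses.append(align_conformer(lig.conformer_coords, cloud, rot,
                                     try_reflection=achiral))
    poses.sort(key=lambda p: p.fit_rmsd)
    return poses


def write_poses(poses: list[Pose], mol: Chem.Mol, path) -> None:
    """Write poses as a multi-record SDF with stage/fit_rmsd/rank fields."""
    mol = Chem.RemoveHs(Chem.Mol(mol))
    writer = Chem.SDWriter(str(path))
    try:
        for rank, pose in enumerate(poses, start=1):
            m = Chem.Mol(mol)
            conf = Chem.Conformer(m.GetNumAtoms())
            for a in range(m.GetNumAtoms()):
                conf.SetAtomPosition(a, pose.coords[a].tolist())
            m.RemoveAllConformers()
            m.AddConformer(conf, assignId=True)
            m.SetProp("stage", pose.stage)
            m.SetProp("fit_rmsd", f"{pose.fit_rmsd:.6f}")
            m.SetProp("rank", str(rank))
            writer.write(m)
    finally:
        writer.close()
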