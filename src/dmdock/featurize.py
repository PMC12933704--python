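"""Graph featurization of ligands and pockets.

Ligands become heavy-atom molecular graphs whose nodes carry one-hot IUPAC
group (1-18) and period (1-7) encodings and whose edges are covalent bonds
with a one-hot bond type (single / double / triple / aromatic).  A 3D
conformer is embedded deterministically from a seed; the conformer supplies
the ligand's internal geometry and is *not* the bound pose.

Pockets become directed k-nearest-neighbor graphs (k = 30) over heavy atoms.
Node scalars add residue-name and atom-name encodings to group/period; the
node vector feature is the atom position relative to the pocket centroid.
Edge scalars are a radial-basis embedding of the edge length; edge vectors
are the displacement between the connected atoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .errors import ConformerError, DegeneratePocketError, InputError
from .mol_io import Pocket

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# periodic table: symbol -> (IUPAC group 1-18, period 1-7)
# lanthanides and actinides are folded into group 3

N_GROUPS = 18
N_PERIODS = 7

_PERIOD_RANGES = [(1, 2, 1), (3, 10, 2), (11, 18, 3), (19, 36, 4),
                  (37, 54, 5), (55, 86, 6), (87, 118, 7)]


def group_period(symbol: str) -> tuple[int, int]:
    """IUPAC group (1-18) and period (1-7) for an element symbol."""
    z = Chem.GetPeriodicTable().GetAtomicNumber(symbol.capitalize())
    for lo, hi, period in _PERIOD_RANGES:
        if lo <= z <= hi:
            break
    else:
        raise InputError(f"unsupported element {symbol!r}")
    pos = z - lo + 1  # 1-based position within the period
    if period == 1:
        group = 1 if pos == 1 else 18
    elif period in (2, 3):
        group = pos if pos <= 2 else pos + 10
    elif period in (4, 5):
        group = pos
    else:  # periods 6, 7 contain the f-block after position 3
        if pos <= 2:
            group = pos
        elif pos <= 17:  # La/Ac + lanthanides/actinides -> group 3
            group = 3
        else:
            group = pos - 14
    return group, period


def _one_hot(index: int, size: int) -> np.ndarray:
    v = np.zeros(size)
    v[index] = 1.0
    return v


def group_period_onehot(symbol: str) -> tuple[np.ndarray, np.ndarray]:
    g, p = group_period(symbol)
    return _one_hot(g - 1, N_GROUPS), _one_hot(p - 1, N_PERIODS)


# ---------------------------------------------------------------------------
# residue and atom-name vocabularies (pocket scalars)

STANDARD_RESIDUES = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]
_ION_RESIDUES = {"ZN", "MG", "CA", "NA", "K", "MN", "FE", "CU", "NI", "CO",
                 "CD", "CL", "BR", "IOD"}
RESIDUE_VOCAB = STANDARD_RESIDUES + ["HET", "HOH", "ION"]
N_ATOM_NAME_BUCKETS = 32


def residue_onehot(res_name: str, is_hetero: bool) -> np.ndarray:
    name = res_name.strip().upper()
    if name in ("HOH", "WAT", "DOD"):
        idx = RESIDUE_VOCAB.index("HOH")
    elif name in _ION_RESIDUES:
        idx = RESIDUE_VOCAB.index("ION")
    elif name in STANDARD_RESIDUES and not is_hetero:
        idx = STANDARD_RESIDUES.index(name)
    else:
        idx = RESIDUE_VOCAB.index("HET")
    return _one_hot(idx, len(RESIDUE_VOCAB))


def atom_name_onehot(atom_name: str) -> np.ndarray:
    """Hashed one-hot over PDB atom names with an out-of-vocabulary bucket.

    A stable (non-salted) polynomial hash keeps featurization deterministic
    across processes.
    """
    h = 0
    for ch in atom_name.strip().upper():
        h = (h * 131 + ord(ch)) % (N_ATOM_NAME_BUCKETS - 1)
    return _one_hot(h, N_ATOM_NAME_BUCKETS)


# ---------------------------------------------------------------------------
# radial basis embedding

DEFAULT_RBF_CENTERS = np.linspace(0.0, 15.0, 16)
DEFAULT_RBF_GAMMA = 4.0  # 1 / Angstrom^2


def rbf_embed(d, centers: np.ndarray | None = None,
              gamma: float = DEFAULT_RBF_GAMMA) -> np.ndarray:
    """Gaussian radial-basis embedding exp(-gamma * (d - center)^2).

    ``d`` may be a scalar or an array; the center axis is appended last.
    """
    centers = DEFAULT_RBF_CENTERS if centers is None else np.asarray(centers)
    d = np.asarray(d, dtype=np.float64)
    if np.any(d < 0):
        raise InputError("distances must be non-negative")
    return np.exp(-gamma * (d[..., None] - centers) ** 2)


# ---------------------------------------------------------------------------
# ligand graph

BOND_TYPES = ["single", "double", "triple", "aromatic"]
_RDKIT_BOND_MAP = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}

def usr_anchors(coords: np.ndarray) -> np.ndarray:
    """Reference points for an invariant per-atom positional code.

    In the spirit of ultrafast shape recognition, four reference points
    are derived from the atom cloud itself: the centroid plus three points
    one mean-radius away along a moment-based orthogonal frame (the
    third-moment "skewness" direction, an orthogonalized near-field mean,
    and their cross product).  Moments are smooth functions of the
    coordinates, so the anchors move continuously under small perturbations
    or membership changes (unlike picking extreme atoms) and transform
    exactly with proper rigid motions.  Distances to four non-coplanar
    anchors determine an atom's position completely.  Returns (4, 3).
    """
    coords = np.asarray(coords, dtype=np.float64)
    ctd = coords.mean(axis=0)
    rel = coords - ctd
    d = np.linalg.norm(rel, axis=1)
    rbar = max(float(d.mean()), 1e-9)
    skew = (rel * (d ** 2)[:, None]).mean(axis=0)
    if np.linalg.norm(skew) > 1e-8 * rbar ** 3:
        v1 = skew / np.linalg.norm(skew)
    else:  # near-symmetric cloud: fall back to the farthest atom direction
        v1 = rel[int(np.argmax(d))]
        n1 = np.linalg.norm(v1)
        v1 = v1 / n1 if n1 > 0 else np.array([1.0, 0.0, 0.0])
    near = (rel * np.exp(-d / rbar)[:, None]).mean(axis=0)
    t = near - (near @ v1) * v1
    if np.linalg.norm(t) < 1e-10 * rbar:
        # fall back to the atom most orthogonal to v1
        residual = rel - np.outer(rel @ v1, v1)
        t = residual[int(np.argmax(np.linalg.norm(residual, axis=1)))]
        if np.linalg.norm(t) < 1e-12:
            t = np.array([0.0, 1.0, 0.0]) - v1[1] * v1
    v2 = t / np.linalg.norm(t)
    v3 = np.cross(v1, v2)
    return np.stack([ctd, ctd + rbar * v1, ctd + rbar * v2, ctd + rbar * v3])


def anchor_distance_feats(coords: np.ndarray,
                          anchors: np.ndarray | None = None) -> np.ndarray:
    """Per-atom RBF embeddings of the distances to the USR anchors — an
    invariant positional code, shape (n, 4 * 16)."""
    coords = np.asarray(coords, dtype=np.float64)
    if anchors is None:
        anchors = usr_anchors(coords)
    d = np.linalg.norm(coords[:, None, :] - anchors[None, :, :], axis=-1)
    return rbf_embed(d).reshape(len(coords), -1)


# group/period one-hots plus the USR anchor-distance positional code
N_ANCHOR_FEATS = 4 * 16
LIGAND_NODE_DIM = N_GROUPS + N_PERIODS + N_ANCHOR_FEATS


@dataclass
class LigandGraph:
    """Heavy-atom molecular graph with a generated 3D conformer."""

    node_feats: np.ndarray        # (c, 25) group ++ period one-hots
    edges: np.ndarray             # (e, 2) directed, both directions present
    edge_feats: np.ndarray        # (e, 4) bond-type one-hot
    conformer_coords: np.ndarray  # (c, 3) Angstrom
    elements: list[str]
    mol: Chem.Mol | None = None   # heavy-atom topology (optional plumbing)

    @property
    def c(self) -> int:
        return len(self.node_feats)

    def permute(self, perm: np.ndarray) -> "LigandGraph":
        """Relabel nodes: new index ``i`` holds old node ``perm[i]``."""
        perm = np.asarray(perm)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        edges = inv[self.edges]
        order = np.lexsort((edges[:, 1], edges[:, 0]))
        return LigandGraph(
            node_feats=self.node_feats[perm],
            edges=edges[order],
            edge_feats=self.edge_feats[order],
            conformer_coords=self.conformer_coords[perm],
            elements=[self.elements[j] for j in perm],
            mol=None,
        )


def embed_conformer(mol: Chem.Mol, seed: int = 0) -> Chem.Mol:
    """Embed and force-field-relax a 3D conformer, deterministically."""
    mol = Chem.AddHs(Chem.Mol(mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1) or 1
    ok = AllChem.EmbedMolecule(mol, params)
    if ok != 0:
        params.useRandomCoords = True
        ok = AllChem.EmbedMolecule(mol, params)
    if ok != 0:
        raise ConformerError("3D embedding failed")
    try:
        AllChem.MMFFOptimizeMolecule(mol, maxIters=500)
    except Exception:  # pragma: no cover - MMFF typing gaps
        AllChem.UFFOptimizeMolecule(mol, maxIters=500)
    return Chem.RemoveHs(mol)


def build_ligand_graph(mol: Chem.Mol, conformer_seed: int = 0) -> LigandGraph:
    """Build the ligand graph; embeds a conformer when the mol has none."""
    if mol is None or mol.GetNumAtoms() == 0:
        raise InputError("empty molecule")
    mol = Chem.RemoveHs(Chem.Mol(mol))
    if len(Chem.GetMolFrags(mol)) > 1:
        raise InputError("disconnected molecule")
    if mol.GetNumConformers() == 0:
        mol = embed_conformer(mol, seed=conformer_seed)
    coords = np.asarray(mol.GetConformer().GetPositions(), dtype=np.float64)

    feats = np.zeros((mol.GetNumAtoms(), LIGAND_NODE_DIM))
    elements = []
    pos_code = anchor_distance_feats(coords)
    for atom in mol.GetAtoms():
        g, p = group_period_onehot(atom.GetSymbol())
        idx = atom.GetIdx()
        feats[idx] = np.concatenate([g, p, pos_code[idx]])
        elements.append(atom.GetSymbol())

    edges, efeats = [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bt = _RDKIT_BOND_MAP.get(bond.GetBondType())
        if bt is None:
            logger.warning("bond type %s mapped to single", bond.GetBondType())
            bt = 0
        for a, b in ((i, j), (j, i)):
            edges.append((a, b))
            efeats.append(_one_hot(bt, len(BOND_TYPES)))
    if edges:
        edges = np.asarray(edges, dtype=np.int64)
        efeats = np.asarray(efeats)
        order = np.lexsort((edges[:, 1], edges[:, 0]))
        edges, efeats = edges[order], efeats[order]
    else:
        edges = np.zeros((0, 2), dtype=np.int64)
        efeats = np.zeros((0, len(BOND_TYPES)))
    return LigandGraph(node_feats=feats, edges=edges, edge_feats=efeats,
                       conformer_coords=coords, elements=elements, mol=mol)


# ---------------------------------------------------------------------------
# pocket graph

# categorical blocks plus two invariant geometric codes: RBFs of the
# distances to the N_SIGNATURE nearest neighbors (local identity) and to
# the USR anchors (global position)
N_SIGNATURE = 4
POCKET_SCALAR_DIM = (N_GROUPS + N_PERIODS + len(RESIDUE_VOCAB)
                     + N_ATOM_NAME_BUCKETS + N_SIGNATURE * 16
                     + N_ANCHOR_FEATS)


@dataclass
class PocketGraph:
    """Directed k-NN graph over pocket heavy atoms."""

    node_scalars: np.ndarray   # (p, POCKET_SCALAR_DIM)
    node_vectors: np.ndarray   # (p, 3)  x_i - centroid
    coords: np.ndarray         # (p, 3)
    nbr_idx: np.ndarray        # (p, k) neighbor indices, sorted by distance
    edge_rbf: np.ndarray       # (p, k, n_rbf)
    edge_vec: np.ndarray       # (p, k, 3)  x_j - x_i
    centroid: np.ndarray = field(default=None)

    @property
    def p(self) -> int:
        return len(self.coords)

    @property
    def k(self) -> int:
        return self.nbr_idx.shape[1]

    def permute(self, perm: np.ndarray) -> "PocketGraph":
        """Relabel nodes; neighbor lists keep their distance-sorted order."""
        perm = np.asarray(perm)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        return PocketGraph(
            node_scalars=self.node_scalars[perm],
            node_vectors=self.node_vectors[perm],
            coords=self.coords[perm],
            nbr_idx=inv[self.nbr_idx[perm]],
            edge_rbf=self.edge_rbf[perm],
            edge_vec=self.edge_vec[perm],
            centroid=self.centroid,
        )


def build_pocket_graph(pocket: Pocket, k: int = 30,
                       rbf_centers: np.ndarray | None = None,
                       rbf_gamma: float = DEFAULT_RBF_GAMMA) -> PocketGraph:
    """k-nearest-neighbor pocket graph (k = 30 by default).

    Neighbors are ranked by Euclidean distance with ties broken by atom
    index; each node gets min(k, p - 1) out-edges.
    """
    p = len(pocket)
    if p < 2:
        raise DegeneratePocketError(f"pocket has {p} atom(s); need >= 2")
    coords = pocket.coords
    centroid = pocket.centroid
    k_eff = min(k, p - 1)

    diff = coords[None, :, :] - coords[:, None, :]
    dist = np.sqrt(np.sum(diff * diff, axis=-1))
    np.fill_diagonal(dist, np.inf)
    # stable argsort on distance => ties broken by atom index
    nbr = np.argsort(dist, axis=1, kind="stable")[:, :k_eff]
    rows = np.arange(p)[:, None]
    edge_vec = coords[nbr] - coords[:, None, :]
    edge_rbf = rbf_embed(dist[rows, nbr], centers=rbf_centers, gamma=rbf_gamma)

    n_sig = min(N_SIGNATURE, k_eff)
    signature = np.zeros((p, N_SIGNATURE * 16))
    sig_d = dist[rows, nbr[:, :n_sig]]
    signature[:, :n_sig * 16] = rbf_embed(sig_d).reshape(p, -1)
    pos_code = anchor_distance_feats(coords)

    scalars = np.zeros((p, POCKET_SCALAR_DIM))
    at = pocket.atoms
    for i in range(p):
        g, per = group_period_onehot(str(at.element[i]))
        scalars[i] = np.concatenate([
            g, per,
            residue_onehot(str(at.res_name[i]), bool(at.is_hetero[i])),
            atom_name_onehot(str(at.atom_name[i])),
            signature[i],
            pos_code[i],
        ])
    return PocketGraph(
        node_scalars=scalars,
        node_vectors=coords - centroid,
        coords=coords,
        nbr_idx=nbr,
        edge_rbf=edge_rbf,
        edge_vec=edge_vec,
        centroid=centroid,
    )


# ---------------------------------------------------------------------------
# intramolecular distance embeddings

def pairwise_distance_rbf(coords: np.ndarray,
                          centers: np.ndarray | None = None,
                          gamma: float = DEFAULT_RBF_GAMMA) -> np.ndarray:
    """All-pairs distance RBF tensor, shape (n, n, n_centers); symmetric."""
    coords = np.asarray(coords, dtype=np.float64)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=-1))
    return rbf_embed(dist, centers=centers, gamma=gamma)


def intramolecular_distance_embeddings(graph, weight: np.ndarray | None = None,
                                       centers: np.ndarray | None = None,
                                       gamma: float = DEFAULT_RBF_GAMMA
                                       ) -> np.ndarray:
    """Pairwise-distance embedding z_intra (n, n, d).

    Entry (i, j) is a linear map of the RBF embedding of ||x_i - x_j||;
    with ``weight=None`` the raw (symmetric) RBF tensor is returned.  Pocket
    graphs contribute their true coordinates, ligand graphs their generated
    conformer.
    """
    if isinstance(graph, PocketGraph):
        coords = graph.coords
    elif isinstance(graph, LigandGraph):
        coords = graph.conformer_coords
    else:
        coords = np.asarray(graph, dtype=np.float64)
    rbf = pairwise_distance_rbf(coords, centers=centers, gamma=gamma)
    if weight is None:
        return rbf
    return rbf @ weight
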