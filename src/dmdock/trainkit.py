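"""Training utilities: distance-matrix loss, redundancy-removing cluster
sampling, ligand downsampling, pocket augmentation, and a desk-scale
training loop.

Protein-ligand corpora are heavily redundant (popular targets, ubiquitous
cofactors), so examples are grouped by joint ligand / pocket-composition /
interaction similarity and each epoch draws exactly one example per
cluster; ligand species that still dominate are thinned to at most 0.1% of
the epoch.  Pockets are augmented per epoch by jittering the binding-site
box center and adding small coordinate noise, emulating box-placement
uncertainty at inference time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from math import ceil
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, DataStructs
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .errors import DmdockError, InputError
from .featurize import build_ligand_graph, build_pocket_graph
from .mol_io import (
    Pocket,
    PocketSpec,
    ProteinStructure,
    extract_pocket,
    read_protein,
    write_protein,
)
from .net import DockingModel, ModelConfig
from .nn import Adam, Tensor, smooth_l1

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# training example + dataset directory layout

@dataclass
class TrainingExample:
    """One protein-ligand pair with its ground-truth bound pose."""

    mol: Chem.Mol                 # heavy-atom topology, conformer = true pose
    true_coords: np.ndarray       # (c, 3) bound-pose heavy-atom coordinates
    protein: ProteinStructure
    pocket_spec: PocketSpec
    cluster_id: str
    ligand_code: str              # CCD-like ligand species identifier
    conformer_seed: int = 0
    pocket_override: Pocket | None = None

    def pocket(self) -> Pocket:
        if self.pocket_override is not None:
            return self.pocket_override
        return extract_pocket(self.protein, self.pocket_spec)

    def ligand_graph(self):
        mol_noconf = Chem.Mol(self.mol)
        mol_noconf.RemoveAllConformers()
        return build_ligand_graph(mol_noconf, conformer_seed=self.conformer_seed)


def save_example(example: TrainingExample, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    writer = Chem.SDWriter(str(directory / "ligand.sdf"))
    try:
        m = Chem.Mol(example.mol)
        m.SetProp("ligand_code", example.ligand_code)
        writer.write(m)
    finally:
        writer.close()
    write_protein(example.protein, directory / "protein.pdb")
    meta = {
        "cluster_id": example.cluster_id,
        "ligand_code": example.ligand_code,
        "center": [round(float(x), 6) for x in example.pocket_spec.center],
        "box_edge": float(example.pocket_spec.box_edge),
        "include_hetero": bool(example.pocket_spec.include_hetero),
        "conformer_seed": int(example.conformer_seed),
    }
    (directory / "meta.json").write_text(json.dumps(meta, sort_keys=True,
                                                    indent=1) + "\n")


def load_example(directory) -> TrainingExample:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    supplier = Chem.SDMolSupplier(str(directory / "ligand.sdf"), removeHs=True)
    mol = next(iter(supplier))
    if mol is None:
        raise InputError(f"unreadable ligand in {directory}")
    protein = read_protein(directory / "protein.pdb")
    spec = PocketSpec(center=np.array(meta["center"]),
                      box_edge=meta["box_edge"],
                      include_hetero=meta.get("include_hetero", True))
    return TrainingExample(
        mol=mol,
        true_coords=np.asarray(mol.GetConformer().GetPositions()),
        protein=protein,
        pocket_spec=spec,
        cluster_id=str(meta["cluster_id"]),
        ligand_code=str(meta["ligand_code"]),
        conformer_seed=int(meta.get("conformer_seed", 0)),
    )


def load_dataset(directory) -> list[TrainingExample]:
    directory = Path(directory)
    dirs = sorted(d for d in directory.iterdir() if d.is_dir())
    if not dirs:
        raise InputError(f"no example subdirectories in {directory}")
    out = []
    for d in dirs:
        try:
            out.append(load_example(d))
        except Exception as exc:
            raise InputError(f"malformed example {d.name}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# loss

def dm_loss(pred, true_pose: np.ndarray, pocket_coords: np.ndarray,
            cutoff: float = 10.0, far_weight: float = 0.1):
    """Smooth-L1 distance-matrix loss, mean over pocket-ligand pairs.

    Pairs whose true distance is below ``cutoff`` get weight 1; far pairs
    get ``far_weight`` — contacts matter most, but remote geometry is not
    ignored entirely.  Accepts a plain array (returns float) or an autodiff
    tensor (returns a differentiable scalar).
    """
    true_d = cdist(np.asarray(pocket_coords, dtype=np.float64),
                   np.asarray(true_pose, dtype=np.float64))
    w = np.where(true_d < cutoff, 1.0, far_weight)
    if isinstance(pred, Tensor):
        per_pair = smooth_l1(pred, true_d) * Tensor(w)
        return per_pair.sum() * (1.0 / true_d.size)
    pred = np.asarray(pred, dtype=np.float64)
    e = pred - true_d
    ae = np.abs(e)
    h = np.where(ae < 1.0, 0.5 * e * e, ae - 0.5)
    return float((w * h).sum() / true_d.size)


# ---------------------------------------------------------------------------
# clustering

@dataclass
class ClusterAssignment:
    examples: list
    labels: np.ndarray  # (n,) int cluster index per example

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def members(self) -> list[np.ndarray]:
        return [np.nonzero(self.labels == c)[0]
                for c in range(self.n_clusters)]


DEFAULT_THRESHOLDS = {"t_lig": 0.6, "t_poc": 0.8, "t_int": 0.5}


def _fingerprint(mol: Chem.Mol):
    return AllChem.GetMorganFingerprintAsBitVect(mol, 2, nBits=2048)


def _residue_composition(example: TrainingExample) -> np.ndarray:
    pocket = example.pocket()
    names, counts = np.unique(pocket.atoms.res_name, return_counts=True)
    vec = np.zeros(64)
    for name, cnt in zip(names, counts):
        vec[hash_name(name)] += cnt
    return vec


def hash_name(name: str, buckets: int = 64) -> int:
    h = 0
    for ch in str(name).strip().upper():
        h = (h * 131 + ord(ch)) % buckets
    return h


def _contact_set(example: TrainingExample, cutoff: float = 4.0) -> frozenset:
    pocket = example.pocket()
    d = cdist(pocket.coords, example.true_coords)
    near_p, near_l = np.nonzero(d < cutoff)
    elements = [a.GetSymbol() for a in example.mol.GetAtoms()]
    return frozenset((str(pocket.atoms.res_name[i]), elements[k])
                     for i, k in zip(near_p, near_l))


def cluster_examples(examples: list[TrainingExample],
                     thresholds: dict | None = None) -> ClusterAssignment:
    """Single-linkage clusters under joint ligand / pocket / interaction
    similarity.

    Two examples link when Tanimoto(ligand fingerprints) >= t_lig AND
    cosine(pocket residue compositions) >= t_poc AND Jaccard(contact
    fingerprints) >= t_int; clusters are the connected components.
    """
    if not examples:
        raise InputError("no examples to cluster")
    th = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    n = len(examples)
    fps = [_fingerprint(ex.mol) for ex in examples]
    comps = np.stack([_residue_composition(ex) for ex in examples])
    norms = np.linalg.norm(comps, axis=1)
    contacts = [_contact_set(ex) for ex in examples]

    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if DataStructs.TanimotoSimilarity(fps[i], fps[j]) < th["t_lig"]:
                continue
            cos = comps[i] @ comps[j] / max(norms[i] * norms[j], 1e-12)
            if cos < th["t_poc"]:
                continue
            union = contacts[i] | contacts[j]
            jac = (len(contacts[i] & contacts[j]) / len(union)) if union else 1.0
            if jac < th["t_int"]:
                continue
            rows.append(i)
            cols.append(j)
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    return ClusterAssignment(examples=list(examples), labels=labels)


# ---------------------------------------------------------------------------
# epoch sampling with the ligand-species cap

def sample_epoch(assignment: ClusterAssignment, rng_seed: int,
                 ligand_cap: float = 0.001) -> list[TrainingExample]:
    """One uniformly sampled example per cluster, then ligand thinning.

    After the per-cluster draw (epoch size = number of clusters), any
    ligand code exceeding ``ceil(ligand_cap * epoch_size)`` occurrences
    (minimum cap 1) is randomly thinned down to the cap.
    """
    if assignment.n_clusters == 0:
        raise InputError("empty cluster assignment")
    rng = np.random.default_rng(rng_seed)
    picked: list[int] = []
    for members in assignment.members():
        picked.append(int(rng.choice(members)))
    epoch_size = len(picked)
    cap = max(1, ceil(ligand_cap * epoch_size))
    by_code: dict[str, list[int]] = {}
    for idx in picked:
        by_code.setdefault(assignment.examples[idx].ligand_code, []).append(idx)
    kept: list[int] = []
    for code, idxs in by_code.items():
        if len(idxs) > cap:
            idxs = list(rng.choice(idxs, size=cap, replace=False))
        kept.extend(idxs)
    kept.sort()
    return [assignment.examples[i] for i in kept]


# ---------------------------------------------------------------------------
# pocket augmentation

def augment_pocket(example: TrainingExample, rng: np.random.Generator,
                   jitter: float = 2.0, sigma: float = 0.1) -> TrainingExample:
    """Jitter the box center by U(-jitter, jitter) per axis, re-extract the
    pocket, and add N(0, sigma^2) noise to the pocket coordinates.  The true
    pose is untouched.  If the shifted box is empty the original example is
    returned unchanged."""
    shift = rng.uniform(-jitter, jitter, size=3)
    spec = PocketSpec(center=example.pocket_spec.center + shift,
                      box_edge=example.pocket_spec.box_edge,
                      include_hetero=example.pocket_spec.include_hetero)
    try:
        pocket = extract_pocket(example.protein, spec)
    except DmdockError:
        return example
    noisy = pocket.atoms.with_coords(
        pocket.coords + rng.normal(0.0, sigma, size=pocket.coords.shape)
        if sigma > 0 else pocket.coords)
    return replace(example, pocket_override=Pocket(atoms=noisy))


# ---------------------------------------------------------------------------
# training loop

def train(dataset: list[TrainingExample], config: ModelConfig | None = None,
          epochs: int = 200, seed: int = 0, lr: float = 6e-3,
          batch_size: int = 4, augment: bool = True,
          ligand_cap: float = 0.001, thresholds: dict | None = None,
          model: DockingModel | None = None, lr_schedule: str = "cosine",
          grad_clip: float = 100.0,
          ) -> tuple[DockingModel, list[float]]:
    """Cluster-balanced minibatch training of the distance-matrix model.

    Per epoch: sample one example per cluster, augment pockets, shuffle,
    and take adaptive-moment gradient steps on the distance-matrix loss
    accumulated over minibatches.  The learning rate follows a cosine
    decay from ``lr`` to lr/20 over the run (``lr_schedule="constant"``
    disables it).  Deterministic given ``seed``.  Returns the trained
    model and the per-epoch mean loss trace.
    """
    if not dataset:
        raise InputError("empty dataset")
    if model is None:
        model = DockingModel(config or ModelConfig(), seed=seed)
    assignment = cluster_examples(dataset, thresholds=thresholds)
    # the graph encoders refine a pair pathway that already sees the raw
    # node features; training them at a slower timescale keeps their drift
    # from destabilizing the pair projection
    opt = Adam(model.parameters(), lr=lr,
               lr_scales={"poc_enc": 0.1, "lig_enc": 0.1,
                          "proj_s": 0.1, "proj_l": 0.1})
    trace: list[float] = []
    lig_cache: dict[int, object] = {}

    for epoch in range(epochs):
        if lr_schedule == "cosine" and epochs > 1:
            frac = epoch / (epochs - 1)
            opt.lr = lr * (0.05 + 0.95 * 0.5 * (1 + np.cos(np.pi * frac)))
        rng = np.random.default_rng([seed, epoch, 0x5eed])
        epoch_examples = sample_epoch(
            assignment, rng_seed=int(rng.integers(2**31)),
            ligand_cap=ligand_cap)
        if augment:
            epoch_examples = [augment_pocket(ex, rng) for ex in epoch_examples]
        order = rng.permutation(len(epoch_examples))
        losses = []
        for start in range(0, len(order), batch_size):
            batch = order[start:start + batch_size]
            opt.zero_grad()
            batch_loss = 0.0
            for idx in batch:
                ex = epoch_examples[idx]
                lig = lig_cache.get(id(ex.mol))
                if lig is None:
                    lig = ex.ligand_graph()
                    lig_cache[id(ex.mol)] = lig
                pocket = ex.pocket()
                pgraph = build_pocket_graph(
                    pocket, rbf_centers=model.config.rbf_centers,
                    rbf_gamma=model.config.rbf_gamma)
                pred = model.forward(lig, pgraph)
                loss = dm_loss(pred, ex.true_coords, pgraph.coords)
                if not np.isfinite(loss.data):
                    raise DmdockError(
                        f"non-finite loss at epoch {epoch}; aborting")
                loss.backward(np.array(1.0 / len(batch)))
                batch_loss += float(loss.data) / len(batch)
            if grad_clip:
                sq = sum(float(np.sum(p.grad * p.grad))
                         for p in opt.params.values() if p.grad is not None)
                norm = np.sqrt(sq)
                if norm > grad_clip:
                    scale = grad_clip / norm
                    for p in opt.params.values():
                        if p.grad is not None:
                            p.grad *= scale
            opt.step()
            losses.append(batch_loss)
        trace.append(float(np.mean(losses)))
    return model, trace
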