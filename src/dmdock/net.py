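"""The pocket–ligand distance-matrix prediction network.

The model consumes a ligand molecular graph and a pocket k-NN graph and
predicts the p x c matrix of pocket-atom-to-ligand-atom distances (Angstrom)
for the bound pose.  Its parts:

* **Ligand encoder** — graph-isomorphism-style message passing with covalent
  bond-type edge features; permutation-equivariant over atoms.
* **Pocket encoder** — a geometric vector perceptron GNN carrying scalar
  (rotation-invariant) and vector (rotation-equivariant) channels; vectors
  enter the pair representation only through their norms, so the predicted
  matrix is exactly invariant under rigid motions of the pocket.
* **Interaction stack** — each block updates the intermolecular pair tensor
  z (p x c x d) by a trigonometry-aware multiplicative mix with the
  intramolecular distance embeddings z_p (p x p x d) and z_c (c x c x d),
  then multihead self-attention over ligand positions within each pocket
  row, then a pointwise MLP transition; all three are residual branches
  that start at the identity (zero-initialized output layers).
* **Head** — a linear map followed by a scaled sigmoid bounding the output
  to [0, dm_max].

Exact permutation equivariance (bitwise, not just numerical) is obtained by
canonicalizing the atom order internally — atoms are sorted
lexicographically by coordinates before the forward pass and the output
matrix is mapped back — so floating-point summation order never depends on
the caller's atom labelling.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .featurize import (
    LIGAND_NODE_DIM,
    POCKET_SCALAR_DIM,
    BOND_TYPES,
    LigandGraph,
    PocketGraph,
    pairwise_distance_rbf,
)
from .nn import MLP, LayerNorm, Linear, Module, RowAttention, Tensor, concat, matmul


@dataclass
class ModelConfig:
    """Hyperparameters of the distance-matrix network."""

    d: int = 64               # embedding size of the pair tensor
    n_blocks: int = 4         # interaction blocks
    n_heads: int = 4          # attention heads
    ligand_depth: int = 3     # ligand GNN layers
    pocket_depth: int = 3     # pocket GVP-GNN layers
    n_vector: int = 16        # pocket vector channels
    n_rbf: int = 16           # radial basis size
    rbf_max: float = 15.0     # Angstrom span of the RBF centers
    rbf_gamma: float = 4.0    # 1 / Angstrom^2
    dropout: float = 0.0      # reserved; training here is full-batch small
    dm_max: float = 24.0      # Angstrom cap of the predicted distance

    def __post_init__(self) -> None:
        if self.d % self.n_heads:
            raise ValueError("d must be divisible by n_heads")
        if self.dm_max <= 0:
            raise ValueError("dm_max must be positive")

    @property
    def rbf_centers(self) -> np.ndarray:
        return np.linspace(0.0, self.rbf_max, self.n_rbf)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


TINY = dict(d=32, n_blocks=2, n_heads=4, ligand_depth=2, pocket_depth=2,
            n_vector=8)


def _norms(v: Tensor, eps: float = 1e-8) -> Tensor:
    """Channel-wise vector norms: (..., nv, 3) -> (..., nv); invariant."""
    return ((v * v).sum(axis=-1) + eps).sqrt()


class VectorLinear(Module):
    """Channel mixing of vector features, (..., c_in, 3) -> (..., c_out, 3).

    Linear in the vectors with no bias, hence exactly rotation-equivariant.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.weight = Tensor(rng.normal(0, np.sqrt(1.0 / c_in),
                                        size=(c_in, c_out)),
                             requires_grad=True)

    def __call__(self, v: Tensor) -> Tensor:
        return self._apply(v)

    def _apply(self, v: Tensor) -> Tensor:
        # (..., c_in, 3) x (c_in, c_out) -> (..., c_out, 3)
        if v.ndim == 3:
            return matmul(v.transpose(0, 2, 1), self.weight).transpose(0, 2, 1)
        if v.ndim == 4:
            return matmul(v.transpose(0, 1, 3, 2),
                          self.weight).transpose(0, 1, 3, 2)
        raise ValueError("unsupported vector rank")


class LigandEncoder(Module):
    """GIN-style message passing with bond-type edge features."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        d = cfg.d
        self.embed = Linear(LIGAND_NODE_DIM, d, rng)
        self.edge_embed = Linear(len(BOND_TYPES), d, rng)
        self.layers = [MLP(d, 2 * d, d, rng) for _ in range(cfg.ligand_depth)]
        self.norms = [LayerNorm(d) for _ in range(cfg.ligand_depth)]
        self.eps = Tensor(np.zeros(cfg.ligand_depth), requires_grad=True)

    def __call__(self, g: LigandGraph) -> Tensor:
        h = self.embed(Tensor(g.node_feats))
        if len(g.edges):
            src, dst = g.edges[:, 0], g.edges[:, 1]
            # dense incidence: agg_i = sum over edges into i, in the
            # canonical (sorted) edge order
            inc = np.zeros((g.c, len(src)))
            inc[dst, np.arange(len(src))] = 1.0
            inc_t = Tensor(inc)
            e_emb = self.edge_embed(Tensor(g.edge_feats))
        for layer_idx, (mlp, ln) in enumerate(zip(self.layers, self.norms)):
            if len(g.edges):
                msg = h.take0(src) + e_emb
                agg = inc_t @ msg
            else:
                agg = h * 0.0
            eps_l = self.eps.take0(np.array([layer_idx]))
            h = ln(h + mlp(h * (1.0 + eps_l) + agg))
        return h  # (c, d)


class PocketEncoder(Module):
    """GVP-GNN over the pocket k-NN graph.

    Scalars are rotation-invariant; vector channels transform with the
    rotation because every vector operation is a linear channel mix or a
    scalar gating.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        d, nv = cfg.d, cfg.n_vector
        self.embed = Linear(POCKET_SCALAR_DIM + 1, d, rng)
        self.lift = VectorLinear(1, nv, rng)
        msg_in = 2 * d + cfg.n_rbf + 2 * nv
        self.msg_mlps = [MLP(msg_in, d, d, rng) for _ in range(cfg.pocket_depth)]
        self.upd_norms = [LayerNorm(d) for _ in range(cfg.pocket_depth)]
        self.vec_mix = [VectorLinear(nv + 1, nv, rng)
                        for _ in range(cfg.pocket_depth)]
        self.vec_gates = [Linear(d, nv, rng) for _ in range(cfg.pocket_depth)]
        self.nv = nv

    def __call__(self, g: PocketGraph) -> tuple[Tensor, Tensor]:
        p, k = g.p, g.k
        rel = Tensor(g.node_vectors)  # (p, 3), x_i - centroid
        rel_norm = np.linalg.norm(g.node_vectors, axis=-1, keepdims=True)
        s = self.embed(Tensor(np.concatenate([g.node_scalars, rel_norm], axis=1)))
        v = self.lift._apply(rel.reshape(p, 1, 3))  # (p, nv, 3)
        rbf = Tensor(g.edge_rbf)  # (p, k, nrbf) constant
        evec = Tensor(g.edge_vec.reshape(p, k, 1, 3))

        for mlp, ln, vmix, vgate in zip(self.msg_mlps, self.upd_norms,
                                        self.vec_mix, self.vec_gates):
            s_j = s.take0(g.nbr_idx)          # (p, k, d)
            v_j = v.take0(g.nbr_idx)          # (p, k, nv, 3)
            vnorm_j = _norms(v_j)             # (p, k, nv) invariant
            # <v_j, edge_vec> per channel: invariant under joint rotation
            dots = (v_j * evec).sum(axis=-1)  # (p, k, nv)
            s_i = s.reshape(p, 1, -1) + Tensor(np.zeros((p, k, 1)))
            msg = mlp(concat([s_i, s_j, rbf, vnorm_j, dots], axis=-1))
            msg_mean = msg.mean(axis=1)       # (p, d), canonical k order
            s = ln(s + msg_mean)
            stacked = concat([v_j, evec], axis=2)       # (p, k, nv+1, 3)
            mixed = vmix._apply(stacked)                # (p, k, nv, 3)
            gate = vgate(msg).sigmoid().reshape(p, k, self.nv, 1)
            v = v + (mixed * gate).mean(axis=1)
        return s, v  # (p, d), (p, nv, 3)


class InteractionBlock(Module):
    """Trigonometry-aware pair update + row attention + MLP transition.

    Each residual branch ends in a down-scaled output layer so the block
    starts close to (but not gradient-dead at) the identity;
    ``out_scale=0`` makes the branches exactly zero at initialization.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 out_scale: float = 1.0):
        d = cfg.d
        zero = out_scale == 0.0
        self.ln_in = LayerNorm(d)
        self.gate = Linear(d, d, rng)
        self.proj_p = Linear(d, d, rng)   # h() on z for the pocket-axis mix
        self.proj_c = Linear(d, d, rng)   # h() on z for the ligand-axis mix
        self.fp = Linear(d, d, rng)       # f_p() on z_p
        self.fc = Linear(d, d, rng)       # f_c() on z_c
        self.ln_mix = LayerNorm(d)
        self.out = Linear(d, d, rng, zero_init=zero, init_scale=out_scale)
        self.ln_attn = LayerNorm(d)
        self.attn = RowAttention(d, cfg.n_heads, rng, out_scale=out_scale)
        self.ln_mlp = LayerNorm(d)
        self.mlp = MLP(d, 4 * d, d, rng, zero_init_out=zero,
                       out_scale=out_scale)

    def __call__(self, z: Tensor, zp: Tensor, zc: Tensor) -> Tensor:
        zn = self.ln_in(z)

        def mix3(a: Tensor, b: Tensor) -> Tensor:
            # 'ijd,jkd->ikd' as a d-batched matmul (BLAS path)
            return matmul(a.transpose(2, 0, 1),
                          b.transpose(2, 0, 1)).transpose(1, 2, 0)

        # pocket axis: z'_{ik} <- sum_j f_p(z_p[i,j]) * h(z[j,k])
        mix_p = mix3(self.fp(zp).sigmoid(), self.proj_p(zn))
        # ligand axis: z'_{ik} <- sum_m h(z[i,m]) * f_c(z_c[m,k])
        mix_c = mix3(self.proj_c(zn), self.fc(zc).sigmoid())
        p = zp.shape[0]
        c = zc.shape[0]
        mix = mix_p * (1.0 / p) + mix_c * (1.0 / c)
        z = z + self.out(self.gate(zn).sigmoid() * self.ln_mix(mix))
        z = z + self.attn(self.ln_attn(z))
        z = z + self.mlp(self.ln_mlp(z))
        return z


class DockingModel(Module):
    """End-to-end pocket-conditioned distance-matrix predictor."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        rng = np.random.default_rng(seed)
        cfg = self.config
        self.lig_enc = LigandEncoder(cfg, rng)
        self.poc_enc = PocketEncoder(cfg, rng)
        self.proj_s = Linear(cfg.d + cfg.n_vector, cfg.d, rng)
        self.proj_l = Linear(cfg.d, cfg.d, rng)
        self.proj_pair = Linear(POCKET_SCALAR_DIM + LIGAND_NODE_DIM,
                                cfg.d, rng)
        self.zp_embed = Linear(cfg.n_rbf, cfg.d, rng)
        self.zc_embed = Linear(cfg.n_rbf, cfg.d, rng)
        self.blocks = [InteractionBlock(cfg, rng) for _ in range(cfg.n_blocks)]
        self.ln_head = LayerNorm(cfg.d)
        # small head init keeps early predictions near the geometric prior
        self.head = Linear(cfg.d, 1, rng, init_scale=0.1)

    # -- forward -----------------------------------------------------------
    def forward(self, lig: LigandGraph, pocket: PocketGraph) -> Tensor:
        """Predicted distance matrix as a differentiable (p, c) tensor.

        Uses the graphs in the caller's atom order; see :meth:`predict_dm`
        for the canonicalized inference entry point.
        """
        cfg = self.config
        l_emb = self.lig_enc(lig)                     # (c, d)
        s, v = self.poc_enc(pocket)                   # (p, d), (p, nv, 3)
        s_inv = concat([s, _norms(v)], axis=-1)       # invariant readout
        zs = self.proj_s(s_inv)                       # (p, d)
        zl = self.proj_l(l_emb)                       # (c, d)
        p, c = pocket.p, lig.c
        # stable pair seed: the raw invariant node features of both sides
        # (categorical chemistry plus the USR positional codes) enter the
        # pair tensor directly, so each (i, k) channel sees everything the
        # intermolecular distance depends on without passing through the
        # (slower-trained) encoders
        pair_feats = np.concatenate([
            np.broadcast_to(pocket.node_scalars[:, None, :],
                            (p, c, pocket.node_scalars.shape[1])),
            np.broadcast_to(lig.node_feats[None, :, :],
                            (p, c, lig.node_feats.shape[1])),
        ], axis=-1)
        z = (zs.reshape(p, 1, cfg.d) + zl.reshape(1, c, cfg.d)
             + self.proj_pair(Tensor(pair_feats)))
        radial = np.linalg.norm(pocket.coords - pocket.centroid, axis=1)
        rho = np.linalg.norm(
            lig.conformer_coords - lig.conformer_coords.mean(axis=0), axis=1)

        zp = self.zp_embed(Tensor(pairwise_distance_rbf(
            pocket.coords, centers=cfg.rbf_centers, gamma=cfg.rbf_gamma)))
        zc = self.zc_embed(Tensor(pairwise_distance_rbf(
            lig.conformer_coords, centers=cfg.rbf_centers, gamma=cfg.rbf_gamma)))
        for block in self.blocks:
            z = block(z, zp, zc)
        logits = self.head(self.ln_head(z)).reshape(p, c)
        # geometric prior: for a ligand centered at the pocket centroid with
        # isotropic orientation, E[d_ik^2] = r_i^2 + rho_k^2; the network
        # learns the (bounded) correction around this baseline.
        expected = np.sqrt(radial[:, None] ** 2 + rho[None, :] ** 2)
        base = np.clip(expected / cfg.dm_max, 1e-3, 1 - 1e-3)
        prior = Tensor(np.log(base / (1.0 - base)))  # (p, c) logit
        return (logits + prior).sigmoid() * cfg.dm_max

    def predict_dm(self, lig: LigandGraph, pocket: PocketGraph) -> np.ndarray:
        """Predict the pocket-ligand distance matrix, shape (p, c), Angstrom.

        Atom order is canonicalized internally (lexicographic sort on
        coordinates) and restored on output, so permuting input atoms
        permutes the result rows/columns exactly.
        """
        cs = pocket.coords
        perm_p = np.lexsort((cs[:, 2], cs[:, 1], cs[:, 0]))
        cl = lig.conformer_coords
        perm_c = np.lexsort((cl[:, 2], cl[:, 1], cl[:, 0]))
        dm_canon = self.forward(lig.permute(perm_c),
                                pocket.permute(perm_p)).data
        dm = np.empty_like(dm_canon)
        dm[np.ix_(perm_p, perm_c)] = dm_canon
        return dm


# ---------------------------------------------------------------------------
# checkpoints: single .npz file with the config embedded as JSON

def save_checkpoint(model: DockingModel, path) -> None:
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path) -> DockingModel:
    with np.load(path) as data:
        cfg = ModelConfig.from_dict(
            json.loads(bytes(data["__config__"].tobytes()).decode()))
        state = {k: data[k] for k in data.files if k != "__config__"}
    model = DockingModel(cfg, seed=0)
    model.load_state_dict(state)
    return model
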