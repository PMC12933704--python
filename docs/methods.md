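# Methods

`dmdock` implements pocket-conditioned ligand pose prediction by
interatomic distance-matrix regression: a neural network predicts the
p × c matrix `DM` of distances (Å) between the p heavy atoms of a binding
pocket and the c heavy atoms of a ligand in its bound pose, and a
geometric decoder converts that matrix into ligand coordinates.  This note
records the model, the numerical choices, what the synthetic data do and
do not emulate, and the known limitations.

## Pocket and ligand representations

**Pocket.**  The receptor side is the set of heavy atoms inside an
axis-aligned cubic box (default edge 20 Å) centered on the binding site,
with hetero entities (waters, ions, cofactors) retained by default.  Box
membership uses a closed boundary (`|x_i − center_i| ≤ edge/2`), which
makes extraction deterministic and independent of atom order.  Binding-site
residues are defined as those with any heavy atom within 8 Å of any ligand
heavy atom.  Apo (unbound) structures are superimposed onto their holo
counterparts by a Kabsch fit of binding-site Cα atoms; the post-fit Cα RMSD
is the holo–apo deviation used to stratify cross-docking difficulty.

The pocket becomes a directed k-nearest-neighbor graph (k = 30, ties broken
by atom index).  Node scalars: one-hot IUPAC group (18) and period (7),
residue name over the 20 standard residues plus HET/HOH/ION classes, a
32-bucket hashed atom-name code, an invariant local-geometry signature
(Gaussian radial-basis embeddings of the distances to the four nearest
neighbors), and an invariant **positional code** — RBF embeddings of the
distances to four reference points derived from the atom cloud in the
spirit of ultrafast shape recognition: the centroid plus three points one
mean-radius away along a moment-based orthogonal frame (third-moment
skewness direction, orthogonalized near-field mean, and their cross
product).  Because the anchors are smooth functions of the coordinates,
the code varies continuously under perturbation and membership changes and
is exactly invariant under proper rigid motions; four non-coplanar anchors
determine an atom's position completely, so the code is a full invariant
coordinate.  The node vector feature is the atom position relative to the
pocket centroid.  Edge scalars are RBF embeddings of the edge length
(16 centers evenly spaced on [0, 15] Å, γ = 4 Å⁻²; chosen to cover
pocket-scale distances at ~0.5 Å resolution); edge vectors are the
interatomic displacements.

**Ligand.**  The ligand is a heavy-atom molecular graph with covalent
bonds typed single/double/triple/aromatic (anything else maps to single
with a warning).  Node features are the group/period one-hots plus the
same anchor-distance positional code computed on the conformer.  A 3D
conformer is embedded deterministically (ETKDG with a fixed seed, then
MMFF cleanup); it supplies the ligand's *internal* geometry only — the
bound pose never enters the model input.  Distances that depend on
rotatable torsions therefore carry conformer noise by design.  A side
effect of the positional code is that graph-automorphic atoms (e.g. the
carbons of a phenyl ring) receive *distinct* features from the conformer
frame, which partially mitigates the symmetry degeneracy discussed under
limitations; the message-passing encoder itself remains symmetric and
treats automorphic atoms identically when the positional block is
removed.

## Network

* **Ligand encoder** — GIN-style message passing (depth 2–3) in which each
  message adds a learned bond-type embedding; aggregation is a dense
  incidence-matrix product over a canonically sorted edge list.
* **Pocket encoder** — a geometric-vector-perceptron GNN with separate
  scalar and vector channels.  Scalar messages mix neighbor scalars, edge
  RBFs, neighbor vector norms, and vector/edge-vector inner products (all
  rotation-invariant); vector updates are linear channel mixes of neighbor
  vectors and edge vectors gated by scalars (exactly equivariant).
  Translations drop out exactly because all vectors are centroid-relative.
* **Pair tensor** — `z ∈ R^{p×c×d}` is initialized from (a) projected
  pocket and ligand node embeddings and (b) a direct projection of the
  *raw* invariant node features of both atoms (categorical chemistry plus
  the positional codes).  Path (b) matters: it gives every pair channel a
  stable view of exactly the quantities the intermolecular distance
  depends on, without routing them through the still-training encoders.
  For a pocket-centered ligand with isotropic orientation
  E[d_ik²] = r_i² + ρ_k² (r_i, ρ_k the centroid radii), so the head adds
  √(r_i² + ρ_k²) as a logit-space prior and the network learns the
  bounded correction.
* **Interaction blocks** — each block applies (1) a trigonometry-style
  multiplicative update mixing `z` along the pocket axis with the
  intramolecular pocket embedding `z_p` (and symmetrically along the
  ligand axis with `z_c`):
  `z'_{ik} ← z_{ik} + W_out( g(z_{ik}) ⊙ LN( Σ_j σ(f_p(z_p[i,j])) ⊙ h(z[j,k])/p
  + Σ_m h'(z[i,m]) ⊙ σ(f_c(z_c[m,k]))/c ) )`,
  (2) multihead self-attention over ligand positions within each pocket
  row (cost O(p·c²·d)), and (3) a pointwise two-layer MLP (hidden width
  4d).  All three are pre-norm residual branches; an ``out_scale=0``
  option makes every branch exactly zero at initialization (identity
  block).
* **Head** — LayerNorm, a linear map to one channel (weight initialized
  at 0.1× Xavier so early predictions sit near the prior instead of in
  the sigmoid tails), the radial prior added in logit space, and a scaled
  sigmoid bounding the output to [0, dm_max] (default 24 Å ≈ pocket
  diameter plus margin).

Defaults: d = 64, 4 blocks, 4 heads; the "tiny" CPU configuration used
throughout the tests is d = 32, 2 blocks.

**Symmetry contract.**  Pocket vectors reach `z` only through invariant
readouts (channel norms), so the predicted matrix is invariant to rigid
motions of the pocket to ~1e-12 Å in double precision.  Exact (bitwise)
permutation equivariance is obtained by canonicalizing atom order
internally — atoms are lexicographically sorted by coordinates before the
forward pass and the output is mapped back — so floating-point summation
order never depends on the caller's labeling.

The network is implemented on a compact in-package reverse-mode autodiff
engine over numpy (`dmdock.nn`): a tape of closures over a ~20-operation
vocabulary (broadcasted arithmetic, matmul/einsum, reductions, gather,
softmax, layer norm, pointwise nonlinearities), with the hot contractions
expressed as batched BLAS matmuls.  Every operation is verified against
central finite differences in the test suite.

## Pose generation

`infer_point_cloud` multilaterates each ligand atom independently:
minimize `Σ_i w_i (‖P_i − x‖ − DM_{ik})²` over anchors `P_i` with weights
`w_i = 1/(1 + DM_{ik})` (short, better-determined distances count more).
The solver initializes from the linearized difference-of-spheres least
squares and polishes with damped Gauss–Newton under a backtracking line
search, so the objective is monotonically non-increasing; it requires at
least four non-coplanar anchors and flags non-convergence instead of
failing.  Ligand–ligand coupling is deliberately omitted: the conformer
restores internal geometry in the next stage.

`align_conformer` fits the conformer to the cloud with a proper-rotation
Kabsch superposition (reflections rejected, preserving chirality),
optionally followed by ≤3 sweeps of per-torsion coordinate descent over
rotatable bonds (single, non-ring, non-terminal).  Each bond's candidate
angles are a 5° grid plus the dihedral read directly off the cloud, so a
clean cloud is matched in one sweep.  For *achiral* molecules the
mirrored conformer may also be fit and the better result kept: a
mirrored conformer of an achiral compound is the same molecule in the
enantiomeric conformation (e.g. the flipped pucker of a non-planar
ring), a degree of freedom torsion descent cannot reach; the option is
gated on the absence of assigned or potential stereocenters, so
chirality is never violated.  Raw poses always inherit chemically valid
bond lengths and angles from the conformer.

`dock` runs featurize → predict → cloud → align over several conformer
seeds and ranks poses by cloud-fit RMSD.  This rank is a documented proxy:
distance-matrix regression has no scoring function of its own.

## Refinement

`uff_minimize` builds one RDKit system from the ligand plus bond-less
pocket pseudo-atoms (explicit SP3 hybridization; common ions typed with
their formal charges), position-locks every pocket atom, and runs UFF
minimization for up to 500 iterations (force tolerance 1e-4).  Pocket
coordinates are bit-identical before and after; if the energy fails to
decrease the raw pose is returned unchanged.  Pocket atoms that cannot be
force-field-typed are dropped from the refinement system with a warning.
An optional hook shells out to an external BFGS local optimizer (up to 500
steps) and is disabled unless an executable is configured.

## Training

The loss is a smooth-L1 (Huber) on the predicted vs true distance matrix,
weight 1 where the true distance is below 10 Å and 0.1 elsewhere, averaged
over all pairs: contacts dominate but remote geometry still anchors the
scale.

Redundancy control follows the cluster-then-sample pattern: examples are
single-linkage-clustered by joint similarity — ligand Morgan-fingerprint
Tanimoto ≥ 0.6 AND pocket residue-composition cosine ≥ 0.8 AND
contact-fingerprint (residue-name × ligand-element pairs within 4 Å)
Jaccard ≥ 0.5 — and each epoch draws exactly one uniformly sampled example
per cluster.  Any ligand species still exceeding ceil(0.001 × epoch size)
slots (minimum 1) is randomly thinned to that cap.  These similarity
functions are simplified stand-ins for full sequence/interaction
pipelines, declared as such.

Pocket augmentation jitters the box center by U(−2, 2) Å per axis,
re-extracts the pocket, and adds N(0, 0.1² Å²) coordinate noise —
sub-pocket-scale perturbations emulating box-placement uncertainty; the
true pose is untouched and the loss target is recomputed against the
augmented pocket.

Optimization is adaptive-moment gradient descent (Adam), minibatch 4 by
default, peak learning rate 6e-3 with cosine decay to 5%, global gradient
norm clipped at 100 (a safety net, roughly 5× the typical initial norm).
The elevated peak rate plus decay replaces a flat conservative setting
because the desk-scale experiments take only a few hundred to a few
thousand optimizer steps.  Encoder parameters (and their projections into
the pair tensor) train at 0.1× the base rate: the pair pathway already
sees the raw node features, and two-timescale training prevents the
encoders' per-atom drift — whose gradients are amplified by the pair
fan-out — from destabilizing it.  Training is bit-deterministic given the
seed.

One protocol note: the tiny-overfit sanity experiment (can the model
memorize 20 complexes?) is run with pocket augmentation disabled, as is
standard when measuring memorization capacity — augmentation is a
regularizer whose explicit purpose is to prevent memorization.  All other
training runs keep augmentation on by default.

## Synthetic complexes

The generator emulates a protein–ligand pair with exact ground truth: a
drug-like ligand conformer (packaged 25-molecule library, 9–24 heavy
atoms, rigid subset = asymmetric fused aromatics) is placed at the origin
as the bound pose and surrounded by a shell of pseudo-protein heavy atoms.
Each shell atom lies at U(6, 12) Å from its nearest ligand atom, at least
2.8 Å from the ligand (a van-der-Waals contact floor), at least 2.5 Å from
other shell atoms, and inside the 20 Å box.  Atoms carry plausible
element/residue/atom-name labels with a configurable water/ion fraction.
The exact distance matrix is stored with the complex.  Apo-like variants
add Gaussian noise to the pocket, superimpose it back, and record the
post-fit deviation; cross-docking degradation is emulated by decoding the
*holo* distance matrix against the *apo* anchors.

What the generator does **not** emulate: binding energetics or shape
complementarity (pocket placement is isotropic around the ligand, so pose
orientation is statistically independent of pocket arrangement — learning
on these complexes is memorization, which is exactly what the tiny-overfit
sanity experiments measure), realistic protein sequences or secondary
structure, and conformational strain of bound ligands.  Passing tests on
synthetic complexes validate geometry, featurization, invariances, and
trainability — not chemical accuracy on real receptors.

## Evaluation metrics

* **Symmetry-corrected RMSD** — minimum coordinate RMSD over the ligand's
  element- and bond-type-preserving graph automorphisms, with no
  re-superposition (poses share the receptor frame).  Automorphisms are
  enumerated with colored substructure matching, capped at 10,000 with an
  identity fallback.  An independent VF2 brute-force enumeration serves as
  the oracle in tests.
* **lDDT-PLI** — reference contacts are pocket–ligand atom pairs within
  6 Å; the score is the mean over thresholds {0.5, 1, 2, 4} Å of the
  fraction of contacts whose predicted distance deviates by less than the
  threshold.  An empty contact set yields NaN, reported as not-evaluable.
* **Validity** — a documented subset of the PoseBusters-style battery:
  bond lengths within 25% of a relaxed reference conformer, bond angles
  within 25°, no non-bonded intra-ligand pair below 2 Å, no ligand–pocket
  heavy-atom pair below 2 Å (hetero atoms included), and a UFF
  internal-energy ratio ≤ 100× the mean of ten relaxed conformer energies
  (the reference magnitude is floored at 1 kcal/mol to keep the ratio
  meaningful).  The overall flag is deliberately named `pb_valid_subset`.
* **Aggregation** — medians and strict-threshold fractions (RMSD < 2 Å,
  lDDT-PLI > 0.5) over scored cases only; failed predictions are counted
  separately and never penalize the aggregate.

## Known limitations

* **Ligand symmetry degeneracy.**  Every component of the model is
  equivariant under ligand graph automorphisms, so automorphic atoms
  necessarily receive identical distance-matrix columns.  For a fully
  symmetric ligand (benzene: 12 automorphisms) the best reachable
  prediction is the orbit average — the decoded cloud collapses toward
  the ring center and orientation is undetermined.  This is intrinsic to
  the method class (and is why pose accuracy is measured with
  symmetry-corrected RMSD); the packaged library therefore consists of
  predominantly asymmetric drug-like molecules, where the effect is
  limited to locally symmetric groups (e.g. para-phenyl flips).
* The cloud decoder treats ligand atoms independently; internal
  consistency is restored only by the conformer fit, so a heavily biased
  distance matrix can produce clouds no conformer can match (reported via
  `fit_rmsd`).
* Pose ranking is a proxy (cloud-fit RMSD); there is no learned or
  physical scoring function.
* The training experiments here are desk-scale sanity checks (tens of
  complexes, pockets of 40–60 atoms, small model) that establish
  trainability, determinism, and protocol correctness — not accuracy
  claims transferable to real structures.
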