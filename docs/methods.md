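# Methods

This note documents the models, the synthetic data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Data model and curation

A `LabeledPair` couples a chromophore graph (from SMILES, heavy atoms with
attached-H counts), a solvent graph, a three-slot target vector
(λ_abs nm, λ_ems nm, log₁₀ PLQY) with an observation mask, and a ladder of
3D conformers keyed by fidelity tag.  The registry of fidelity levels
(`RDKIT`, `XTB`, `DFT_VAC`, `DFT_IMP`, plus `REFINED` for model output) is
extensible and the number of levels is data-driven.  PLQY is stored on a
log₁₀ scale (the spectroscopy convention when a log transform is reported
without a base); raw PLQY outside (0, 1] is rejected at load time with a
report entry.

Curation is restricted to automatable checks: records whose perceived 3D
connectivity disagrees with the SMILES graph are removed; byte-identical
(pair, targets) duplicates are collapsed; same-pair records with conflicting
labels, and protonation variants sharing an uncharged parent skeleton, are
flagged for manual review rather than silently altered — averaging
conflicting measurements would hide exactly the label noise that manual
verification is meant to resolve.  Topology is validated against the
highest-fidelity conformer present: graph consistency is a property of the
optimized structure, while coarser levels are expected to be geometrically
noisy.  Connectivity perception bonds atoms i, j when
d(i,j) ≤ r_cov(i) + r_cov(j) + 0.4 Å (Cordero radii; tolerance
configurable).  Bond orders are never perceived from geometry — the
consistency check compares element-labelled connectivity only, since
geometric bond-order assignment is unreliable.

## Scaffold splitting

Grouping uses the generic Bemis–Murcko framework (ring systems plus
linkers, element and bond identity retained) at the chromophore level;
solvent variation never splits a chromophore across subsets, and solvents
themselves are not scaffold-constrained.  Assignment shuffles scaffolds with
the seed and greedily fills TRAIN, then VAL, then TEST against
largest-remainder record quotas; a scaffold that would overflow a quota
falls through to the next subset, and three nonempty subsets are guaranteed
by demoting the smallest group when necessary.  k-fold assignment gives each
shuffled scaffold to the currently smallest fold; per-fold validation
scaffolds are re-drawn with the fold index mixed into the seed.  Acyclic
molecules share the designated EMPTY scaffold and therefore travel together.

## Neural components

All learnable parts run on `solvaprop.autodiff`, a reverse-mode automatic
differentiation engine over NumPy arrays written for this package
(broadcast arithmetic, batched matmul, gather/segment-sum for graph
batching, softmax; float64 throughout).  Gradients are verified against
central finite differences in the test suite.  The optimizer is Adam with
global-norm gradient clipping (default 5.0) and per-epoch multiplicative
learning-rate decay; clipping matters because the L1 property loss produces
occasional large gradient spikes that otherwise knock small models off
their descent path.

**Solvent encoder.**  Classic directed-MPNN: directed edge states from
source-atom + bond features, T = 3 update rounds by default (width 128 by
default; the desk-scale experiments use width 32, T = 2), rectifier
nonlinearity, mean readout.  Featurization: element one-hot over
{H, C, N, O, F, Si, P, S, Cl, Br, I} + OTHER, formal charge one-hot
(−2…+2), aromaticity flag, attached-H count one-hot (0…4+).  Pretraining
runs the dual chromophore/solvent 2D baseline on TRAIN absorption labels
(multitarget pretraining is a config switch), then freezes the solvent
branch; frozen encoders cache embeddings by canonical key, which is sound
because they are deterministic.

**Invariant backbone.**  N atom tokens plus a virtual node (row 0).  Scalar
channels see geometry only through a Gaussian radial basis over pairwise
distances (default K = 64 over 0–12 Å; desk-scale runs use K = 16 over
0–10 Å) projected into per-head additive attention biases, together with
shortest-path-bucket biases (capped at 6, bucket 7 for disconnected pairs)
from the bond graph.  The virtual node has no coordinates; its pair bias to
real atoms is a learned per-layer, per-head scalar.  Because softmax
attention is scale-normalized, molecule-level size and shape cannot be
recovered from pooling alone; the virtual token therefore also receives a
learned projection of global invariant descriptors — atom count, log atom
count, radius of gyration, mean pairwise distance, and the two smaller
gyration-tensor eigenvalues (the smallest is a planarity measure).  These
descriptors are exactly invariant under rigid motions and are the route by
which conjugation length and backbone twist become learnable at desk scale.

The coordinate head emits Δr_i = Σ_j w_ij (r_i − r_j)/d_ij with
w_ij = (h_i W₁)·(h_j W₂)/N + g_ij·w₃, where g_ij is the Gaussian distance
expansion; both W₂ and w₃ are zero-initialized so an untrained model moves
nothing.  The unit-vector pair-sum form guarantees rotation equivariance
and translation invariance by construction rather than by training.
Refinement applies the forward pass R times (default R = 1), re-featurizing
after each step; a per-atom displacement norm above the explosion threshold
(50 Å default) raises immediately, as runaway displacements only occur when
training has destabilized.

**Fusion and objective.**  Virtual-node injection adds W_p·(solvent
embedding) to the virtual token once, before the first attention block.
Head concatenation keeps the backbone solvent-blind and concatenates at the
regression head.  The joint loss is
w_prop·masked-L1 + w_coord·(Kabsch-aligned mean per-atom distance), with
w_prop = w_coord = 1 by default.  The optimal alignment rotation is computed
outside the autodiff graph; for the RMSD-minimizing rotation this yields
the exact gradient of the aligned objective in the refined coordinates
(envelope argument), and it removes the rigid-body ambiguity that raw
coordinate regression would suffer.  Property targets are normalized by
TRAIN-set mean/std per target and de-normalized before metrics, keeping
nm-scale MAE exact.  Coordinate supervision is enabled for the virtual-node
models only; head-concatenation and solvent-blind ablations train
property-only, matching their role as fixed-conformer baselines.

## Training schedule

Phase 1 freezes both encoders (3D backbone and solvent encoder) bit-exactly
— they are excluded from the optimizer and flagged so their moment buffers
never advance — while the head (plus the solvent projection) is fitted;
phase 2 unfreezes everything for a joint finetune.  "Convergence" is
operationalized as early stopping on the validation metric (λ_abs MAE for
single-target runs, masked multitarget validation L1 otherwise) with
configurable patience; the best checkpoint by validation metric is restored
before evaluation.  Per-fold CV seeds are `seed + fold`; benchmark-grid
cell seeds mix a CRC32 hash of the cell key into the base seed.  Runs are
deterministic given (data, config, seed): batching is the only stochastic
element and is driven by one seeded generator.

## Synthetic data generator

The generator emulates the statistical structure of a curated
solvatochromism benchmark, not its physics.  Chromophores are two terminal
aromatic rings (benzene, thiophene, furan, pyrrole, pyridine) bridged by a
polyene linker of L vinylene units, with optional inert single-atom ring
substituents providing scaffold-neutral diversity; geometries are idealized
(aromatic C–C 1.40 Å, conjugated single/double 1.45/1.35 Å, 120° zig-zag;
five-membered rings use a 1.55 Å side so heteroatom ring diagonals stay
clear of the perception cutoff under ladder noise).  The terminal ring is
twisted about the linker bond by θ₀ ~ U(0°, 60°) per chromophore.

Targets follow a closed-form surrogate chosen so that the solvent
contribution is controllable and geometry fidelity matters through the
twist:

    λ_abs = 250 + 25·L + 60·P − 40·(1 − cos θ)   [nm]
    λ_ems = λ_abs + 20 + 30·P                    [nm]
    PLQY  = logistic(2 − 6·(1 − cos θ))

with P the solvent polarity (eight common solvents, polarities evenly
spaced on [0, 1]) and θ the twist of the reference geometry,
θ = θ₀(1 − 0.2·P): the implicit-solvent level relaxes the twist toward
planarity by 20% of the gap scaled by polarity, emulating solvent-dependent
geometry relaxation.  Labels get Gaussian noise (σ_y = 5 nm on wavelengths,
σ = 0.05 on log₁₀ PLQY) and per-target Bernoulli missingness (5% absorption,
35% emission, 50% PLQY — absorption data is the abundant one).  The
geometry ladder adds i.i.d. coordinate noise σ_geo = 0.30/0.15/0.05/0.02 Å
for RDKIT/XTB/DFT_VAC/DFT_IMP, validated as strictly decreasing at spec
load.  With the default ranges (L ∈ {2…5}), the solvent term contributes
roughly one third of the λ_abs label variance, the conjugation term about
half, and twist plus noise the remainder.

What passing tests on this generator do **not** show: chemical realism of
the surrogate (it is linear where real solvatochromism is not), transfer to
real spectra, or the behaviour of GPU-scale pretrained backbones.  They do
show that the architecture is exactly invariant/equivariant, that the
solvent-embedding route carries solvent information the solvent-blind model
cannot recover, that coordinate supervision lets the model denoise coarse
geometries, and that the split/CV/masking machinery is leak-free.

## Problem sizes and numerical choices

Desk-scale experiment sizes were chosen once as the package's standard
verification conditions: the solvent-ablation benchmark uses 250
chromophores × 8 solvents (2000 pairs) with a width-64, 2-layer backbone;
the refinement and fidelity-grid experiments use 80 chromophores (640
pairs).  Kabsch alignment uses the SVD closed form with a determinant
correction restricting to proper rotations; coordinate distances add 1e-12
inside the square root to keep the gradient finite at coincident points;
masked metrics report a target as absent (with a warning) when it has no
observations rather than emitting NaN.  Degenerate inputs: single-atom
molecules have zero displacement by definition; empty TRAIN or VAL subsets
raise before training starts.

## Known limitations

- The backbone reads conformers with explicit hydrogens only through
  geometry-perceived graph biases; the synthetic generator emits heavy-atom
  conformers, and mixed explicit/implicit-H datasets get a degraded
  (distance-only) graph bias when atom counts disagree with the SMILES
  graph.
- Refinement supervises only the final geometry (single-step by default);
  intermediate-step supervision schemes are not implemented.
- No uncertainty estimation, no conformer ensembles (one conformer per
  fidelity level per record; duplicates at one level are an error), no
  tautomer/protonation enumeration, and no quantum-chemistry execution —
  the package only reads the outputs of such pipelines.
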