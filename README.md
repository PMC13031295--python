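# solvaprop

Solvent-aware 3D neural prediction of chromophore optical properties —
absorption maximum λ_abs, emission maximum λ_ems (both in nm) and the
photoluminescence quantum yield (PLQY, modelled as log₁₀ PLQY) — for
chromophore–solvent pairs with multi-fidelity 3D conformers.

The package is aimed at researchers benchmarking geometry-aware models for
UV/Vis property prediction: it provides the data model and curation checks
for chromophore–solvent records, Bemis–Murcko scaffold splitting, a 2D
directed-message-passing solvent encoder, an SE(3)-invariant attention
backbone with a virtual node and an equivariant coordinate-refinement head,
the fused solvent-aware property model, the two-phase training schedule with
masked multitarget losses, scaffold cross-validation, and a seeded synthetic
data generator with a closed-form solvatochromic ground truth.

## The model

A record is a chromophore–solvent pair with targets
**y** = (λ_abs, λ_ems, log₁₀ PLQY) and an observation mask **m**.

**Solvent encoder (2D).** A directed edge-message-passing network (D-MPNN)
over the solvent graph: edge states `h⁰_vw = ReLU(W_i [x_v ; e_vw])` are
updated for T rounds with `h^{t+1}_vw = ReLU(h⁰_vw + W_m Σ_{k∈N(v)\{w}}
h^t_kv)`; atom states are read out through `W_a` and mean-pooled.  It is
pretrained inside a dual chromophore/solvent 2D baseline and then frozen as
a fixed source of solvent embeddings.

**Invariant backbone (3D).** Atoms plus one virtual node attend globally.
Geometry enters only through a Gaussian radial-basis expansion of pairwise
distances, projected into per-head attention biases (plus shortest-path
bucket biases from the bond graph), so every scalar channel is invariant to
rigid motions by construction.  The coordinate head emits displacements
`Δr_i = Σ_j w_ij (r_i − r_j)/d_ij` with scalar pair weights `w_ij`, which
are therefore rotation-equivariant and translation-invariant.

**Fusion.** Either the solvent embedding is concatenated with the final
virtual-node embedding at the regression head (head concatenation), or it is
projected onto the atom feature width and summed into the virtual node
before the first attention block (virtual-node injection); a solvent-blind
ablation (`NONE`) is also available.

**Joint objective.** Training pairs a coarse input conformer (e.g. a
force-field geometry) with a high-fidelity reference (e.g. DFT in implicit
solvent):

    L = w_prop · masked-L1(ŷ, y) + w_coord · mean_i ‖r̂_i − r^ref_i‖

where the reference is Kabsch-aligned onto the refined coordinates before
the per-atom distances are averaged, and the masked L1 runs over observed
target slots only.  At inference the model needs only the coarse conformer.

**Evaluation.** Bemis–Murcko scaffold groups (at the chromophore level) are
assigned wholly to train/validation/test (80/10/10) or to k CV folds, so no
framework ever leaks across subsets.  Metrics are per-target MAE, RMSE and
R² over observed slots.

## Worked example

```python
import numpy as np
from solvaprop import (FixtureSpec, make_fixture_dataset, scaffold_split,
                       SolventAwareModel, PairTrainingConfig,
                       TrainSchedule, two_phase_train)
from solvaprop.backbone import PairFeatureSpec
from solvaprop.training import evaluate

dataset, truth = make_fixture_dataset(FixtureSpec(n_chromophores=250, seed=11))
split = scaffold_split(dataset, (0.8, 0.1, 0.1), seed=11)

model = SolventAwareModel.create(
    strategy="VIRTUAL_NODE", width=64, n_layers=2, n_heads=4,
    solvent_width=32, solvent_depth=2, head_hidden=64,
    pair_spec=PairFeatureSpec(16, 10.0),
    pair_config=PairTrainingConfig(input_fidelity="DFT_IMP", w_coord=0.0),
    seed=5, ffn_mult=1)
schedule = TrainSchedule(phase1_epochs=3, phase2_epochs=40, patience=12,
                         lr_phase1=1e-2, lr_phase2=3e-3, batch_size=128, seed=5)
two_phase_train(model, dataset, split, schedule)
report = evaluate(model, dataset, split)
print(f"test λ_abs MAE: {report.mae():.2f} nm")
```

On this 2000-pair synthetic benchmark (label noise σ_y = 5 nm, solvent term
contributing ≈1/3 of the λ_abs variance) the run above prints

```
test λ_abs MAE: 5.03 nm
```

while the identically trained solvent-blind ablation (`strategy="NONE"`)
reaches 17.73 nm — the solvent embedding removes most of the error, because
the solvent polarity term of the generator is invisible to a solvent-blind
model, which is pinned near the ~15 nm floor that term implies.  Exact
numbers vary slightly with the seeds used.

A CLI mirrors the library (`solvaprop curate | split | make-fixtures |
pretrain-solvent | train | crossval | benchmark-grid`).

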