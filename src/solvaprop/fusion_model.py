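"""Solvent-aware 3D property models: fusion strategies, joint objective,
coarse-conformer inference.

Two fusion routes combine the frozen (or finetuned) 2D solvent embedding
with the invariant 3D backbone over the chromophore conformer:

* ``HEAD_CONCAT`` — the backbone runs solvent-blind and the regression
  head reads concat(virtual-node embedding, solvent embedding);
* ``VIRTUAL_NODE`` — the solvent embedding is projected onto the atom
  feature width and summed into the virtual node once, before the first
  attention block, so solvent context shapes the intermediate molecular
  representation;
* ``NONE`` — solvent-blind ablation.

Training couples a masked-L1 property term with a coordinate-refinement
term: the model sees a coarse conformer and is supervised to displace it
toward the high-fidelity reference geometry (Kabsch-aligned mean
per-atom distance), so that at inference time cheap geometries suffice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Parameter, Tensor, concat
from .backbone import (BackboneInput, BackboneParams, backbone_forward_batch,
                       featurize_3d, kabsch_rmsd)
from .molecular_data import Conformer, Dataset, LabeledPair, N_TARGETS
from .solvent_encoder import EncoderParams, HeadParams, solvent_embeddings

__all__ = [
    "FusionConfig", "PairTrainingConfig", "SolventAwareModel",
    "inject_solvent", "joint_loss", "forward_record", "infer_coarse",
]

STRATEGIES = ("HEAD_CONCAT", "VIRTUAL_NODE", "NONE")


def inject_solvent(virtual_embedding: Tensor, solvent_embedding: Tensor,
                   projection: Tensor) -> Tensor:
    """virtual + W_p · solvent, applied once before the first attention block."""
    if projection.shape[0] != solvent_embedding.shape[-1]:
        raise ValueError(
            f"projection expects solvent width {projection.shape[0]}, "
            f"got {solvent_embedding.shape[-1]}")
    if projection.shape[1] != virtual_embedding.shape[-1]:
        raise ValueError(
            f"projection output width {projection.shape[1]} does not match "
            f"virtual-node width {virtual_embedding.shape[-1]}")
    return virtual_embedding + solvent_embedding @ projection


@dataclass
class FusionConfig:
    strategy: str = "VIRTUAL_NODE"
    W_p: Tensor | None = None      # solvent width -> backbone width

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown fusion strategy {self.strategy!r}")


@dataclass
class PairTrainingConfig:
    """Conformation-pair regime: coarse input, high-fidelity reference."""

    input_fidelity: str = "XTB"
    reference_fidelity: str = "DFT_IMP"
    w_prop: float = 1.0
    w_coord: float = 1.0

    def __post_init__(self):
        if self.w_prop < 0 or self.w_coord < 0 or (
                self.w_prop == 0 and self.w_coord == 0):
            raise ValueError("loss weights must be >= 0 and not both zero")


class SolventAwareModel:
    """Backbone + solvent encoder + fusion + property head bundle."""

    def __init__(self, backbone: BackboneParams,
                 solvent_encoder: EncoderParams | None,
                 fusion: FusionConfig,
                 head: HeadParams,
                 pair_config: PairTrainingConfig | None = None,
                 seed: int = 0):
        self.backbone = backbone
        self.solvent_encoder = solvent_encoder
        self.fusion = fusion
        self.head = head
        self.pair_config = pair_config or PairTrainingConfig()
        self.norm_mu = np.zeros(N_TARGETS)
        self.norm_sd = np.ones(N_TARGETS)
        self.seed = seed
        self._feat_cache: dict = {}
        self._cache_owners: dict = {}
        if fusion.strategy == "VIRTUAL_NODE":
            if fusion.W_p is None:
                rng = np.random.default_rng(seed + 17)
                fusion.W_p = Parameter(
                    rng.uniform(-1, 1, (solvent_encoder.width, backbone.width))
                    / np.sqrt(solvent_encoder.width))
            if fusion.W_p.shape[1] != backbone.width:
                raise ValueError("projection output width must equal "
                                 "backbone atom feature width")

    # -- assembly ----------------------------------------------------------
    @classmethod
    def create(cls, strategy: str = "VIRTUAL_NODE", width: int = 128,
               n_layers: int = 4, n_heads: int = 8,
               solvent_encoder: EncoderParams | None = None,
               solvent_width: int = 128, solvent_depth: int = 3,
               head_hidden: int = 128, pair_spec=None,
               pair_config: PairTrainingConfig | None = None, seed: int = 0,
               ffn_mult: int = 2):
        backbone = BackboneParams.create(width, n_layers, n_heads,
                                         pair_spec=pair_spec, seed=seed,
                                         ffn_mult=ffn_mult)
        if solvent_encoder is None and strategy != "NONE":
            solvent_encoder = EncoderParams.create(solvent_width,
                                                   solvent_depth, seed + 1)
        head_in = width
        if strategy == "HEAD_CONCAT":
            head_in = width + solvent_encoder.width
        head = HeadParams.create(head_in, head_hidden, N_TARGETS, seed + 2)
        return cls(backbone, solvent_encoder, FusionConfig(strategy), head,
                   pair_config=pair_config, seed=seed)

    def set_normalization(self, mu: np.ndarray, sd: np.ndarray) -> None:
        self.norm_mu = np.asarray(mu, dtype=float)
        self.norm_sd = np.where(np.asarray(sd, dtype=float) > 1e-9, sd, 1.0)

    def parameter_groups(self) -> dict:
        groups = {
            "backbone": self.backbone.parameters(),
            "head": list(self.head.parameters()),
        }
        if self.fusion.strategy == "VIRTUAL_NODE":
            groups["head"] = groups["head"] + [self.fusion.W_p]
        if self.solvent_encoder is not None and self.fusion.strategy != "NONE":
            groups["solvent_encoder"] = self.solvent_encoder.parameters()
        return groups

    def parameters(self):
        return [p for ps in self.parameter_groups().values() for p in ps]

    # -- forward -----------------------------------------------------------
    def _featurize(self, dataset: Dataset, idx: int, fidelity: str,
                   log: bool = True) -> BackboneInput:
        # hold a reference to each dataset seen so id() keys are never
        # recycled by the allocator after garbage collection
        self._cache_owners[id(dataset)] = dataset
        key = (id(dataset), idx, fidelity)
        if key not in self._feat_cache:
            rec = dataset.records[idx]
            conf = (dataset.get_conformer(idx, fidelity) if log
                    else rec.conformers[fidelity])
            self._feat_cache[key] = featurize_3d(rec.chromophore, conf,
                                                 self.backbone.pair_spec)
        return self._feat_cache[key]

    def forward_batch(self, dataset: Dataset, indices, fidelity: str,
                      need_displacement: bool = True):
        """Predictions and displacements for records sharing an atom count.

        Returns (normalized predictions (B, 3), displacements (B, N, 3),
        input coordinates (B, N, 3)).
        """
        inputs = [self._featurize(dataset, i, fidelity) for i in indices]
        sizes = {len(x.elem_idx) for x in inputs}
        if len(sizes) != 1:
            raise ValueError("forward_batch requires equal-size records; "
                             "group by atom count first")
        inject = None
        solv_emb = None
        if self.fusion.strategy != "NONE" and self.solvent_encoder is not None:
            solvents = [dataset.records[i].solvent for i in indices]
            solv_emb = solvent_embeddings(solvents, self.solvent_encoder)
        if self.fusion.strategy == "VIRTUAL_NODE":
            inject = solv_emb @ self.fusion.W_p
        vn, _, disp = backbone_forward_batch(
            inputs, self.backbone, inject=inject,
            compute_displacement=need_displacement)
        if self.fusion.strategy == "HEAD_CONCAT":
            rep = concat([vn, solv_emb], axis=-1)
        else:
            rep = vn
        pred_norm = self.head.forward(rep)
        coords = np.stack([x.coords for x in inputs])
        return pred_norm, disp, coords

    def predict(self, dataset: Dataset, indices, fidelity: str) -> np.ndarray:
        """De-normalized predictions (physical units), any record sizes."""
        indices = list(indices)
        by_size: dict = {}
        for pos, i in enumerate(indices):
            n = self._featurize(dataset, i, fidelity).elem_idx.shape[0]
            by_size.setdefault(n, []).append((pos, i))
        out = np.zeros((len(indices), N_TARGETS))
        for _, group in sorted(by_size.items()):
            pos, idxs = zip(*group)
            pred_norm, _, _ = self.forward_batch(dataset, list(idxs), fidelity,
                                                 need_displacement=False)
            out[list(pos)] = pred_norm.data * self.norm_sd + self.norm_mu
        return out


# --------------------------------------------------------------------------
# objectives
# --------------------------------------------------------------------------

def masked_l1(pred_norm: Tensor, targets_norm: np.ndarray,
              mask: np.ndarray) -> Tensor:
    """Mean absolute error over observed target slots only.

    Gradients at masked slots are exactly zero (the residual is
    multiplied by the 0/1 mask before reduction).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return Tensor(0.0)
    safe = np.where(mask, targets_norm, 0.0)
    diff = (pred_norm - Tensor(safe)).abs() * Tensor(mask.astype(float))
    return diff.sum() * (1.0 / mask.sum())


def coordinate_loss(refined: Tensor, reference: np.ndarray,
                    eps: float = 1e-12) -> Tensor:
    """Mean per-atom distance after Kabsch alignment of the reference.

    The optimal rotation is computed outside the autodiff graph; the
    loss is differentiable in the refined coordinates (alignment of the
    reference absorbs rigid-body ambiguity).
    """
    ref = np.asarray(reference, dtype=float)
    if refined.shape != ref.shape:
        raise ValueError(
            f"coordinate shapes differ: {refined.shape} vs {ref.shape}")
    batched = refined.ndim == 3
    refined_b = refined if batched else refined.reshape(1, *refined.shape)
    ref_b = ref if batched else ref[None]
    aligned = np.empty_like(ref_b)
    for b in range(ref_b.shape[0]):
        _, R, t = kabsch_rmsd(refined_b.data[b], ref_b[b])
        aligned[b] = ref_b[b] @ R + t
    sq = ((refined_b - Tensor(aligned)) ** 2.0).sum(axis=-1)
    dist = (sq + eps).sqrt()
    return dist.mean()


def joint_loss(predictions: Tensor, refined_coords: Tensor,
               record: LabeledPair, reference: Conformer,
               config: PairTrainingConfig,
               norm_mu: np.ndarray | None = None,
               norm_sd: np.ndarray | None = None) -> Tensor:
    """w_prop · masked-L1(normalized property) + w_coord · aligned coord loss.

    A record with no observed targets contributes only the coordinate
    term.  ``predictions`` must be on the normalized scale; targets are
    normalized with the supplied constants (identity by default).
    """
    if reference.fidelity_tag != config.reference_fidelity:
        raise ValueError(
            f"reference fidelity {reference.fidelity_tag!r} does not match "
            f"configured {config.reference_fidelity!r}")
    if refined_coords.shape[-2] != reference.n_atoms:
        raise ValueError("reference atom count mismatch")
    mu = np.zeros(N_TARGETS) if norm_mu is None else np.asarray(norm_mu)
    sd = np.ones(N_TARGETS) if norm_sd is None else np.asarray(norm_sd)
    with np.errstate(invalid="ignore"):
        t_norm = (record.targets - mu) / sd
    loss = Tensor(0.0)
    if config.w_prop > 0:
        loss = loss + config.w_prop * masked_l1(predictions, t_norm, record.mask)
    if config.w_coord > 0:
        loss = loss + config.w_coord * coordinate_loss(
            refined_coords, reference.coordinates)
    return loss


# --------------------------------------------------------------------------
# record-level forward / inference
# --------------------------------------------------------------------------

def forward_record(dataset: Dataset, idx: int, fidelity: str,
                    model: SolventAwareModel):
    """Predictions (physical units) and refined coordinates for one record."""
    rec = dataset.records[idx]
    if fidelity not in rec.conformers:
        raise KeyError(
            f"record {idx} has no conformer at {fidelity!r}; "
            f"available: {sorted(rec.conformers)}")
    pred_norm, disp, coords = model.forward_batch(dataset, [idx], fidelity)
    preds = pred_norm.data[0] * model.norm_sd + model.norm_mu
    refined = Conformer(coords[0] + disp.data[0],
                        rec.conformers[fidelity].elements, "REFINED",
                        source_id=rec.chromophore.canonical_key)
    return preds, refined


def infer_coarse(dataset: Dataset, idx: int, model: SolventAwareModel,
                 inference_fidelity: str) -> np.ndarray:
    """Coarse-conformer inference: never touches reference-fidelity geometry."""
    preds, _ = forward_record(dataset, idx, inference_fidelity, model)
    return preds
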