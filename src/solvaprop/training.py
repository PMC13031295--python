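"""Two-phase training, masked multitarget metrics, scaffold CV, and the
conformer-fidelity × solvent-regime benchmark grid.

Training follows the transfer-learning schedule used for solvent-aware
3D models: phase 1 freezes the (pretrained) encoders and fits the
regression head to convergence; phase 2 unfreezes the whole network for
a joint finetune.  All metrics are computed only over observed target
slots; training paths never read TEST labels before final evaluation
(auditable from the dataset access log).
"""

from __future__ import annotations

import copy
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor
from .fusion_model import (PairTrainingConfig, SolventAwareModel,
                           coordinate_loss, masked_l1)
from .molecular_data import Dataset, N_TARGETS, TARGET_NAMES
from .scaffold_split import SplitAssignment, scaffold_kfold

__all__ = [
    "TrainSchedule", "TrainState", "MetricsReport", "GridResult",
    "masked_metrics", "two_phase_train", "train_multitarget",
    "evaluate", "crossvalidate", "run_benchmark_grid",
]


@dataclass
class TrainSchedule:
    """Optimization schedule for the two training phases."""

    phase1_epochs: int = 20
    phase2_epochs: int = 30
    patience: int = 10               # evaluations without improvement
    lr_phase1: float = 1e-3
    lr_phase2: float = 1e-3
    lr_decay: float = 0.97           # per-epoch multiplicative decay
    batch_size: int = 128
    seed: int = 0
    targets: tuple = ("lambda_abs_nm",)
    eval_metric: str = "lambda_abs_nm"   # per-target MAE or "multitarget"
    input_fidelity: str | None = None    # default: model pair config


@dataclass
class TrainState:
    history: list = field(default_factory=list)
    best_epoch: int = -1
    best_val: float = np.inf
    seed: int = 0
    update_counts: dict = field(default_factory=dict)

    def record(self, **kw):
        self.history.append(dict(kw))


@dataclass
class MetricsReport:
    """Per-target MAE/RMSE/R² over observed slots of one subset."""

    per_target: dict
    n_records: int
    subset: str = ""

    def mae(self, target: str = "lambda_abs_nm") -> float:
        return self.per_target[target]["mae"]


@dataclass
class GridResult:
    cells: dict            # (source, regime) -> MetricsReport
    test_indices: list


def masked_metrics(predictions, labels, masks, subset: str = "") -> MetricsReport:
    """MAE / RMSE / R² per target over observed (mask=1) slots only.

    Targets with zero observations are reported as absent (with a
    warning), never as zero or NaN.  R² uses the evaluation subset's own
    observed-label mean.
    """
    P = np.asarray(predictions, dtype=float)
    Y = np.asarray(labels, dtype=float)
    M = np.asarray(masks, dtype=bool)
    if not (P.shape == Y.shape == M.shape):
        raise ValueError("predictions, labels and masks must share a shape")
    out = {}
    for k, name in enumerate(TARGET_NAMES):
        m = M[:, k]
        if not m.any():
            warnings.warn(f"no observed values for {name}; omitted from report")
            continue
        err = P[m, k] - Y[m, k]
        sse = float(np.sum(err ** 2))
        sst = float(np.sum((Y[m, k] - Y[m, k].mean()) ** 2))
        out[name] = {
            "mae": float(np.mean(np.abs(err))),
            "rmse": float(np.sqrt(np.mean(err ** 2))),
            "r2": 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -np.inf),
            "n": int(m.sum()),
        }
    return MetricsReport(out, n_records=len(P), subset=subset)


# --------------------------------------------------------------------------
# training internals
# --------------------------------------------------------------------------

def _group_by_size(model, dataset, indices, fidelity):
    groups: dict = {}
    for i in indices:
        n = model._featurize(dataset, i, fidelity).elem_idx.shape[0]
        groups.setdefault(n, []).append(i)
    return groups


def _target_selector(targets) -> np.ndarray:
    sel = np.zeros(N_TARGETS, dtype=bool)
    for t in targets:
        sel[TARGET_NAMES.index(t)] = True
    return sel


def _val_metric(model, dataset, split, schedule, fidelity, Y, M, sel):
    val_idx = split.indices("VAL")
    preds = model.predict(dataset, val_idx, fidelity)
    y = Y[val_idx]
    m = M[val_idx] & sel[None, :]
    if schedule.eval_metric == "multitarget":
        pn = (preds - model.norm_mu) / model.norm_sd
        yn = (y - model.norm_mu) / model.norm_sd
        return float(np.abs((pn - yn))[m].mean()) if m.any() else np.inf
    k = TARGET_NAMES.index(schedule.eval_metric)
    mk = M[val_idx, k]
    if not mk.any():
        return np.inf
    return float(np.mean(np.abs(preds[mk, k] - y[mk, k])))


def _epoch(model, dataset, groups, Y, M, sel, schedule, opt, rng,
           fidelity, pair: PairTrainingConfig, use_coord: bool):
    order_groups = sorted(groups)
    batches = []
    for n in order_groups:
        idxs = np.array(groups[n])
        perm = rng.permutation(len(idxs))
        for s in range(0, len(idxs), schedule.batch_size):
            batches.append(idxs[perm[s:s + schedule.batch_size]])
    rng.shuffle(batches)
    total, nb = 0.0, 0
    for batch in batches:
        yb = (Y[batch] - model.norm_mu) / model.norm_sd
        mb = M[batch] & sel[None, :]
        pred, disp, coords = model.forward_batch(
            dataset, list(batch), fidelity, need_displacement=use_coord)
        loss = Tensor(0.0)
        if pair.w_prop > 0 and mb.any():
            loss = loss + pair.w_prop * masked_l1(pred, np.where(mb, yb, 0.0), mb)
        if use_coord:
            refs = np.stack([
                dataset.get_conformer(i, pair.reference_fidelity).coordinates
                for i in batch])
            loss = loss + pair.w_coord * coordinate_loss(
                Tensor(coords) + disp, refs)
        if loss._prev:
            opt.zero_grad()
            loss.backward()
            opt.step()
        total += float(loss.data)
        nb += 1
    return total / max(nb, 1)


def two_phase_train(model: SolventAwareModel, dataset: Dataset,
                    split: SplitAssignment,
                    schedule: TrainSchedule) -> TrainState:
    """Phase 1: frozen encoders, head-only fit; phase 2: joint finetune.

    The best checkpoint (by validation metric) is restored into the
    model before returning.  Per-epoch losses, validation metrics and
    parameter-group update counts are recorded in the TrainState.
    """
    train_idx = split.indices("TRAIN")
    val_idx = split.indices("VAL")
    if not val_idx:
        raise ValueError("validation subset is empty")
    if not train_idx:
        raise ValueError("training subset is empty")

    pair = model.pair_config
    fidelity = schedule.input_fidelity or pair.input_fidelity
    # coordinate supervision is part of the virtual-node training recipe;
    # head-fusion / solvent-blind ablations train property-only
    use_coord = (pair.w_coord > 0
                 and model.fusion.strategy == "VIRTUAL_NODE")

    Y = np.zeros((len(dataset), N_TARGETS))
    M = np.zeros((len(dataset), N_TARGETS), dtype=bool)
    for i in train_idx + val_idx:
        t, m = dataset.get_targets(i)
        Y[i], M[i] = np.where(m, t, 0.0), m
    sel = _target_selector(schedule.targets)

    obs = M[train_idx] & sel[None, :]
    Yt = Y[train_idx]
    mu = np.zeros(N_TARGETS)
    sd = np.ones(N_TARGETS)
    for k in range(N_TARGETS):
        if obs[:, k].any():
            mu[k] = Yt[obs[:, k], k].mean()
            sd[k] = max(Yt[obs[:, k], k].std(), 1e-9)
    model.set_normalization(mu, sd)

    groups = _group_by_size(model, dataset, train_idx, fidelity)
    state = TrainState(seed=schedule.seed)
    rng = np.random.default_rng(schedule.seed)
    best_params = None

    def snapshot():
        return [p.data.copy() for p in model.parameters()]

    def restore(snap):
        for p, d in zip(model.parameters(), snap):
            p.data = d.copy()

    epoch_counter = 0
    bad = 0
    for phase in (1, 2):
        gps = model.parameter_groups()
        if phase == 1:
            for name, ps in gps.items():
                frozen = name in ("backbone", "solvent_encoder")
                for p in ps:
                    p.frozen = frozen
            params = gps["head"]
            lr = schedule.lr_phase1
            n_epochs = schedule.phase1_epochs
        else:
            for ps in gps.values():
                for p in ps:
                    p.frozen = False
            if model.solvent_encoder is not None:
                model.solvent_encoder.set_frozen(False)  # clears frozen cache
            params = model.parameters()
            lr = schedule.lr_phase2
            n_epochs = schedule.phase2_epochs
        opt = Adam(params, lr=lr)
        bad = 0
        for ep in range(n_epochs):
            opt.lr = lr * schedule.lr_decay ** ep
            train_loss = _epoch(model, dataset, groups, Y, M, sel, schedule,
                                opt, rng, fidelity, pair, use_coord)
            val = _val_metric(model, dataset, split, schedule, fidelity,
                              Y, M, sel)
            state.record(epoch=epoch_counter, phase=phase,
                         train_loss=train_loss, val_metric=val)
            if val < state.best_val - 1e-12:
                state.best_val = val
                state.best_epoch = epoch_counter
                best_params = snapshot()
                bad = 0
            else:
                bad += 1
            epoch_counter += 1
            if bad >= schedule.patience:
                break
        state.update_counts[f"phase{phase}_steps"] = opt.t

    if best_params is not None:
        restore(best_params)
    if model.solvent_encoder is not None:
        model.solvent_encoder.cache.clear()
    return state


def train_multitarget(model: SolventAwareModel, dataset: Dataset,
                      split: SplitAssignment,
                      schedule: TrainSchedule | None = None) -> TrainState:
    """Two-phase training with the masked loss over all three targets."""
    import dataclasses
    schedule = schedule or TrainSchedule()
    sched = dataclasses.replace(schedule, targets=TARGET_NAMES,
                                eval_metric="multitarget")
    return two_phase_train(model, dataset, split, sched)


def evaluate(model: SolventAwareModel, dataset: Dataset,
             split: SplitAssignment, subset: str = "TEST",
             fidelity: str | None = None,
             exclude_indices=()) -> MetricsReport:
    idx = [i for i in split.indices(subset) if i not in set(exclude_indices)]
    fid = fidelity or model.pair_config.input_fidelity
    preds = model.predict(dataset, idx, fid)
    ys, ms = [], []
    for i in idx:
        t, m = dataset.get_targets(i)
        ys.append(np.where(m, t, 0.0))
        ms.append(m)
    return masked_metrics(preds, np.array(ys), np.array(ms), subset=subset)


# --------------------------------------------------------------------------
# cross-validation and benchmark grid
# --------------------------------------------------------------------------

def crossvalidate(model_factory, dataset: Dataset, k: int, seed: int,
                  schedule: TrainSchedule, exclusions=()):
    """Scaffold k-fold CV; fresh model per fold, per-fold seeds seed+fold.

    ``exclusions`` is a collection of record keys
    ("chromophore_key|solvent_key") dropped from TEST metrics only.
    Returns (list of per-fold MetricsReport, summary dict
    target -> metric -> (mean, sample std)).
    """
    folds = scaffold_kfold(dataset, k, seed=seed, val_fraction=0.1)
    excl = set(exclusions)
    reports = []
    for f, split in enumerate(folds):
        model = model_factory(seed + f)
        sched = copy.copy(schedule)
        sched.seed = seed + f
        two_phase_train(model, dataset, split, sched)
        drop = [i for i in split.indices("TEST")
                if "|".join(dataset.records[i].pair_key) in excl]
        reports.append(evaluate(model, dataset, split,
                                exclude_indices=drop))
    summary = {}
    for name in TARGET_NAMES:
        vals = {met: [r.per_target[name][met] for r in reports
                      if name in r.per_target]
                for met in ("mae", "rmse", "r2")}
        if vals["mae"]:
            summary[name] = {
                met: (float(np.mean(v)), float(np.std(v, ddof=1)) if len(v) > 1
                      else 0.0)
                for met, v in vals.items()}
    return reports, summary


def _cell_seed(base: int, cell) -> int:
    return (base + zlib.crc32("|".join(map(str, cell)).encode())) % (2 ** 31)


def run_benchmark_grid(dataset: Dataset, split: SplitAssignment,
                       sources, regimes, schedule: TrainSchedule,
                       model_factory=None) -> GridResult:
    """Train one model per (conformer source, solvent regime) cell.

    regimes: "NONE" (solvent-blind) or "EMBEDDING" (virtual-node
    fusion).  Every cell shares the TEST assignment and all non-varied
    hyperparameters; cell seeds are derived from the schedule seed and a
    stable hash of the cell key.
    """
    for src in sources:
        missing = [i for i in split.subsets
                   if src not in dataset.records[i].conformers]
        if missing:
            raise ValueError(
                f"fidelity {src!r} missing for records {missing[:5]}...")
    if model_factory is None:
        def model_factory(strategy, source, seed):
            return SolventAwareModel.create(
                strategy=strategy, width=64, n_layers=2, n_heads=4,
                solvent_width=32, solvent_depth=2, head_hidden=64,
                pair_config=PairTrainingConfig(
                    input_fidelity=source, w_coord=0.0), seed=seed)
    cells = {}
    test_idx = split.indices("TEST")
    for src in sources:
        for regime in regimes:
            strategy = "NONE" if regime == "NONE" else "VIRTUAL_NODE"
            seed = _cell_seed(schedule.seed, (src, regime))
            model = model_factory(strategy, src, seed)
            sched = copy.copy(schedule)
            sched.seed = seed
            sched.input_fidelity = src
            two_phase_train(model, dataset, split, sched)
            rep = evaluate(model, dataset, split, fidelity=src)
            cells[(src, regime)] = rep
            if rep.n_records != len(test_idx):
                raise AssertionError("grid cells must share the TEST set")
    return GridResult(cells=cells, test_indices=test_idx)
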