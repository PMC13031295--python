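"""Metric computation, two-phase freeze contract, determinism, CV harness."""

import numpy as np
import pytest

from solvaprop.backbone import PairFeatureSpec
from solvaprop.fusion_model import PairTrainingConfig, SolventAwareModel
from solvaprop.molecular_data import TARGET_NAMES
from solvaprop.scaffold_split import scaffold_split
from solvaprop.training import (TrainSchedule, crossvalidate, evaluate,
                                masked_metrics, two_phase_train)


# -- masked metrics ----------------------------------------------------------

def test_metrics_perfect_prediction():
    y = np.array([[400.0, 450, -0.3], [500, 550, -1.0]])
    m = np.ones_like(y, dtype=bool)
    rep = masked_metrics(y, y, m)
    for t in TARGET_NAMES:
        assert rep.per_target[t]["mae"] == 0.0
        assert rep.per_target[t]["rmse"] == 0.0
        assert rep.per_target[t]["r2"] == 1.0


def test_metrics_constant_mean_prediction_r2_zero():
    y = np.array([[1.0], [2], [3]]) * np.ones((3, 3))
    pred = np.full((3, 3), 2.0)
    rep = masked_metrics(pred, y, np.ones((3, 3), dtype=bool))
    assert np.isclose(rep.per_target["lambda_abs_nm"]["r2"], 0.0)


def test_metrics_worked_example():
    y = np.array([[1.0], [2], [3]]) * np.ones((3, 3))
    pred = np.full((3, 3), 2.0)
    rep = masked_metrics(pred, y, np.ones((3, 3), dtype=bool))
    cell = rep.per_target["lambda_ems_nm"]
    assert np.isclose(cell["mae"], 2 / 3)
    assert np.isclose(cell["rmse"], np.sqrt(2 / 3))


def test_metrics_all_masked_target_absent():
    y = np.array([[400.0, 0, 0]])
    m = np.array([[True, False, False]])
    with pytest.warns(UserWarning):
        rep = masked_metrics(y, y, m)
    assert "lambda_ems_nm" not in rep.per_target
    assert "lambda_abs_nm" in rep.per_target


def _loop_metrics(P, Y, M):
    out = {}
    for k, name in enumerate(TARGET_NAMES):
        errs = [P[i, k] - Y[i, k] for i in range(len(P)) if M[i, k]]
        if not errs:
            continue
        obs = [Y[i, k] for i in range(len(P)) if M[i, k]]
        mean = sum(obs) / len(obs)
        sse = sum(e ** 2 for e in errs)
        sst = sum((o - mean) ** 2 for o in obs)
        out[name] = {"mae": sum(abs(e) for e in errs) / len(errs),
                     "rmse": (sse / len(errs)) ** 0.5,
                     "r2": 1 - sse / sst}
    return out


def test_metrics_match_bruteforce_loop(rng):
    for _ in range(10):
        n = int(rng.integers(3, 30))
        Y = rng.normal(size=(n, 3)) * 50 + 400
        P = Y + rng.normal(size=(n, 3)) * 10
        M = rng.random((n, 3)) > 0.3
        M[0] = True                      # at least one observation
        rep = masked_metrics(P, Y, M)
        want = _loop_metrics(P, Y, M)
        for t, vals in want.items():
            for met in ("mae", "rmse", "r2"):
                assert abs(rep.per_target[t][met] - vals[met]) < 1e-10


# -- two-phase training ------------------------------------------------------

@pytest.fixture(scope="module")
def trained(small_fixture):
    _, dataset, _ = small_fixture
    split = scaffold_split(dataset, seed=4)
    model = SolventAwareModel.create(
        strategy="VIRTUAL_NODE", width=32, n_layers=1, n_heads=4,
        solvent_width=16, solvent_depth=1, head_hidden=16,
        pair_spec=PairFeatureSpec(8, 8.0),
        pair_config=PairTrainingConfig(input_fidelity="XTB", w_coord=0.0),
        seed=0, ffn_mult=1)
    backbone_before = model.backbone.snapshot()
    solvent_before = model.solvent_encoder.snapshot()
    sched = TrainSchedule(phase1_epochs=2, phase2_epochs=0, patience=5,
                          lr_phase1=3e-3, batch_size=64, seed=0)
    state1 = two_phase_train(model, dataset, split, sched)
    after_phase1_backbone = model.backbone.snapshot()
    after_phase1_solvent = model.solvent_encoder.snapshot()
    return (dataset, split, model, backbone_before, solvent_before,
            after_phase1_backbone, after_phase1_solvent, state1)


def test_phase1_freezes_encoders_bit_exactly(trained):
    (_, _, _, bb_before, sv_before, bb_after, sv_after, _) = trained
    for a, b in zip(bb_before, bb_after):
        assert np.array_equal(a, b)
    for a, b in zip(sv_before, sv_after):
        assert np.array_equal(a, b)


def test_phase2_updates_encoders(small_fixture):
    _, dataset, _ = small_fixture
    split = scaffold_split(dataset, seed=4)
    model = SolventAwareModel.create(
        strategy="VIRTUAL_NODE", width=32, n_layers=1, n_heads=4,
        solvent_width=16, solvent_depth=1, head_hidden=16,
        pair_spec=PairFeatureSpec(8, 8.0),
        pair_config=PairTrainingConfig(input_fidelity="XTB", w_coord=0.0),
        seed=0, ffn_mult=1)
    before = model.backbone.snapshot()
    sched = TrainSchedule(phase1_epochs=1, phase2_epochs=2, patience=5,
                          lr_phase1=3e-3, lr_phase2=1e-3, batch_size=64,
                          seed=0)
    two_phase_train(model, dataset, split, sched)
    assert any(not np.array_equal(a, b)
               for a, b in zip(before, model.backbone.snapshot()))


def test_training_deterministic_given_seed(small_fixture):
    _, dataset, _ = small_fixture
    split = scaffold_split(dataset, seed=4)

    def run():
        model = SolventAwareModel.create(
            strategy="VIRTUAL_NODE", width=32, n_layers=1, n_heads=4,
            solvent_width=16, solvent_depth=1, head_hidden=16,
            pair_spec=PairFeatureSpec(8, 8.0),
            pair_config=PairTrainingConfig(input_fidelity="XTB",
                                           w_coord=0.0),
            seed=0, ffn_mult=1)
        sched = TrainSchedule(phase1_epochs=1, phase2_epochs=2, patience=5,
                              batch_size=64, seed=11)
        state = two_phase_train(model, dataset, split, sched)
        return state.best_val, model.predict(dataset, [0, 5], "XTB")

    (v1, p1), (v2, p2) = run(), run()
    assert v1 == v2
    assert np.array_equal(p1, p2)


def test_no_test_labels_read_during_training(small_fixture):
    _, dataset, _ = small_fixture
    split = scaffold_split(dataset, seed=4)
    model = SolventAwareModel.create(
        strategy="NONE", width=32, n_layers=1, n_heads=4,
        head_hidden=16, pair_spec=PairFeatureSpec(8, 8.0),
        pair_config=PairTrainingConfig(input_fidelity="XTB", w_coord=0.0),
        seed=0, ffn_mult=1)
    dataset.clear_log()
    sched = TrainSchedule(phase1_epochs=1, phase2_epochs=1, patience=5,
                          batch_size=64, seed=0)
    two_phase_train(model, dataset, split, sched)
    test_set = set(split.indices("TEST"))
    touched = {i for kind, i, *_ in dataset.access_log if kind == "targets"}
    assert not (touched & test_set)


def test_early_stopping_restores_best_checkpoint(trained):
    dataset, split, model, *_, state = trained
    # recorded best equals the re-evaluated validation MAE of the model
    rep = evaluate(model, dataset, split, subset="VAL", fidelity="XTB")
    assert np.isclose(rep.mae(), state.best_val, atol=1e-9)
    assert state.best_val == min(h["val_metric"] for h in state.history)


def test_multitarget_training_uses_all_observed_targets(small_fixture):
    """Masked multitarget training runs and improves the validation loss;
    records observing only some targets still contribute."""
    from solvaprop.training import train_multitarget
    _, dataset, _ = small_fixture
    split = scaffold_split(dataset, seed=4)
    model = SolventAwareModel.create(
        strategy="VIRTUAL_NODE", width=32, n_layers=1, n_heads=4,
        solvent_width=16, solvent_depth=1, head_hidden=16,
        pair_spec=PairFeatureSpec(8, 8.0),
        pair_config=PairTrainingConfig(input_fidelity="DFT_IMP",
                                       w_coord=0.0),
        seed=1, ffn_mult=1)
    sched = TrainSchedule(phase1_epochs=2, phase2_epochs=6, patience=8,
                          lr_phase1=1e-2, lr_phase2=3e-3, batch_size=64,
                          seed=1)
    state = train_multitarget(model, dataset, split, sched)
    vals = [h["val_metric"] for h in state.history]
    assert state.best_val < vals[0]          # improved from initialization
    rep = evaluate(model, dataset, split)
    # all three targets have observations and are reported
    assert set(rep.per_target) == set(TARGET_NAMES)


# -- cross-validation --------------------------------------------------------

def _tiny_factory(seed):
    return SolventAwareModel.create(
        strategy="NONE", width=32, n_layers=1, n_heads=4, head_hidden=16,
        pair_spec=PairFeatureSpec(8, 8.0),
        pair_config=PairTrainingConfig(input_fidelity="DFT_IMP",
                                       w_coord=0.0),
        seed=seed, ffn_mult=1)


@pytest.fixture(scope="module")
def cv_results(small_fixture):
    _, dataset, _ = small_fixture
    sched = TrainSchedule(phase1_epochs=1, phase2_epochs=2, patience=3,
                          batch_size=64, seed=0,
                          input_fidelity="DFT_IMP")
    return dataset, crossvalidate(_tiny_factory, dataset, 3, 0, sched)


def test_cv_summary_matches_recomputation(cv_results):
    _, (reports, summary) = cv_results
    maes = [r.per_target["lambda_abs_nm"]["mae"] for r in reports]
    mean, std = summary["lambda_abs_nm"]["mae"]
    assert np.isclose(mean, np.mean(maes))
    assert np.isclose(std, np.std(maes, ddof=1))


def test_cv_covers_every_record_once(cv_results, small_fixture):
    _, dataset, _ = small_fixture
    _, (reports, _) = cv_results
    assert sum(r.n_records for r in reports) == len(dataset)


def test_cv_exclusions_shrink_only_target_fold(small_fixture):
    _, dataset, _ = small_fixture
    sched = TrainSchedule(phase1_epochs=1, phase2_epochs=1, patience=3,
                          batch_size=64, seed=0, input_fidelity="DFT_IMP")
    base, _ = crossvalidate(_tiny_factory, dataset, 3, 0, sched)
    key = "|".join(dataset.records[0].pair_key)
    drop, _ = crossvalidate(_tiny_factory, dataset, 3, 0, sched,
                            exclusions=[key])
    diffs = [b.n_records - d.n_records for b, d in zip(base, drop)]
    assert sorted(diffs) == [0, 0, 1]
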