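"""The gene-weighted loss, its exclusion rules, the accumulation training
loop, the plateau scheduler, and checkpointing."""

import numpy as np
import pytest

import zipaer as z
from zipaer.training import _validation_loss


def _stack_with_totals(totals, side=2):
    """A (1, G, side, side) count stack whose per-gene totals are as given."""
    G = len(totals)
    stack = np.zeros((1, G, side, side), dtype=np.int64)
    for g, t in enumerate(totals):
        flat = np.zeros(side * side, dtype=np.int64)
        remaining = t
        i = 0
        while remaining:
            take = min(remaining, 1)
            flat[i % (side * side)] += take
            remaining -= take
            i += 1
        stack[0, g] = flat.reshape(side, side)
    return stack


@pytest.mark.parametrize(
    "totals,expected",
    [
        ((1, 2, 3), (2.0, 1.0, 2.0 / 3.0)),
        ((5, 5, 5), (1.0, 1.0, 1.0)),
        ((0, 4, 4), (0.0, 1.0, 1.0)),
    ],
)
def test_gene_weights(totals, expected):
    table = z.compute_gene_weights(_stack_with_totals(totals))
    np.testing.assert_allclose(table.s, totals)
    np.testing.assert_allclose(table.weight, expected)


def test_median_total_gene_has_weight_one():
    table = z.compute_gene_weights(_stack_with_totals((1, 2, 9)))
    assert table.weight[1] == 1.0


def test_all_zero_totals_rejected():
    with pytest.raises(z.DataError):
        z.compute_gene_weights(np.zeros((2, 3, 4, 4)))


def test_perfect_reconstruction_has_zero_loss(rng):
    x = rng.standard_normal((2, 4, 5, 5))
    report = z.weighted_mse_loss(x, x, np.ones(4))
    assert report.total == 0.0


def test_uniform_weights_degenerate_to_mean_mse(rng):
    recon = rng.standard_normal((2, 4, 5, 5))
    target = rng.standard_normal((2, 4, 5, 5))
    report = z.weighted_mse_loss(recon, target, np.ones(4))
    expected = 1e6 * np.square(recon - target).mean(axis=(0, 2, 3)).mean()
    np.testing.assert_allclose(report.total, expected)


def test_two_gene_hand_computed_case():
    """Totals (1, 3): median 2, weights (2, 2/3); MSEs (0.5, 0.1) give
    1e6 * (2*0.5 + (2/3)*0.1)/2 = 533,333.3."""
    weights = z.compute_gene_weights(_stack_with_totals((1, 3))).weight
    np.testing.assert_allclose(weights, [2.0, 2.0 / 3.0])
    target = np.zeros((1, 2, 1, 1))
    recon = np.array([np.sqrt(0.5), np.sqrt(0.1)]).reshape(1, 2, 1, 1)
    report = z.weighted_mse_loss(recon, target, weights)
    np.testing.assert_allclose(report.total, 533_333.3333, rtol=1e-9)
    np.testing.assert_allclose(report.per_gene_mse, [0.5, 0.1])


def test_loss_scale_equivariance(rng):
    """Multiplying all per-gene MSEs by c multiplies the total by c."""
    target = np.zeros((2, 3, 4, 4))
    diff = rng.standard_normal((2, 3, 4, 4))
    w = np.array([0.5, 1.0, 2.0])
    base = z.weighted_mse_loss(diff, target, w).total
    c = 7.0
    scaled = z.weighted_mse_loss(np.sqrt(c) * diff, target, w).total
    np.testing.assert_allclose(scaled, c * base)


def test_zero_weight_genes_excluded_from_mean(rng):
    recon = rng.standard_normal((1, 3, 2, 2))
    target = np.zeros((1, 3, 2, 2))
    w = np.array([1.0, 0.0, 1.0])
    report = z.weighted_mse_loss(recon, target, w)
    mse = np.square(recon).mean(axis=(0, 2, 3))
    np.testing.assert_allclose(report.total, 1e6 * (mse[0] + mse[2]) / 2)


@pytest.mark.parametrize(
    "devices,batch,accum,expected", [(9, 2, 4, 72), (1, 1, 1, 1), (3, 2, 4, 24)]
)
def test_effective_batch_size(devices, batch, accum, expected):
    assert z.effective_batch_size(devices, batch, accum) == expected


@pytest.mark.parametrize(
    "n,batch,expected", [(190_000, 72, 2_639), (72, 72, 1), (100, 72, 2)]
)
def test_steps_per_epoch(n, batch, expected):
    assert z.steps_per_epoch(n, batch) == expected


class TestPlateauScheduler:
    cfg = z.TrainConfig()

    def test_improving_history_keeps_lr(self):
        history = [100.0 * 0.97 ** i for i in range(20)]  # 3% better each epoch
        assert z.plateau_scheduler_step(history, 1e-3, self.cfg) == 1e-3

    def test_constant_history_reduces_once_after_patience(self):
        history = [100.0] + [100.0] * 9
        lr = z.plateau_scheduler_step(history, 1e-3, self.cfg)
        np.testing.assert_allclose(lr, 1e-3 * 0.3)

    def test_eight_bad_epochs_not_yet_reduced(self):
        history = [100.0] + [100.0] * 8
        assert z.plateau_scheduler_step(history, 1e-3, self.cfg) == 1e-3

    def test_sub_threshold_improvement_counts_as_plateau(self):
        history = [100.0 * 0.995 ** i for i in range(10)]  # 0.5% < 1% threshold
        lr = z.plateau_scheduler_step(history, 1e-3, self.cfg)
        np.testing.assert_allclose(lr, 1e-3 * 0.3)

    def test_every_reduction_is_exactly_the_factor(self):
        history = [100.0] * 30
        lr = z.plateau_scheduler_step(history, 1e-3, self.cfg)
        np.testing.assert_allclose(lr, 1e-3 * 0.3 ** 3)  # epochs 10, 19, 28


class TestTrainValSplit:
    def test_counts(self):
        tr, va = z.train_val_split(np.arange(10), 0.3, seed=0)
        assert len(tr) == 7 and len(va) == 3

    def test_deterministic_disjoint_exhaustive(self):
        ids = np.arange(20)
        tr1, va1 = z.train_val_split(ids, 0.25, seed=5)
        tr2, va2 = z.train_val_split(ids, 0.25, seed=5)
        np.testing.assert_array_equal(tr1, tr2)
        np.testing.assert_array_equal(va1, va2)
        assert set(tr1) | set(va1) == set(ids)
        assert set(tr1) & set(va1) == set()

    def test_too_few_patches(self):
        with pytest.raises(z.DataError):
            z.train_val_split([1], 0.3, seed=0)


def _tiny_setup(rng, n=8, bn=True):
    stack = rng.poisson(1.0, size=(n, 5, 8, 8)).astype(np.int64)
    weights = z.compute_gene_weights(stack)
    spec = z.ModelSpec(5, 8, (4,), name="tiny")
    model = z.build_autoencoder(spec, seed=3, batch_norm=bn)
    return stack, weights, spec, model


def test_fit_smoke_logs_one_epoch(rng, tmp_path):
    stack, weights, _, model = _tiny_setup(rng)
    cfg = z.TrainConfig(max_epochs=1, per_device_batch=2, accumulation_steps=1,
                        seed=0)
    model, log = z.fit(model, stack[:4], stack[4:], weights, cfg,
                       checkpoint_dir=tmp_path)
    df = log.to_frame()
    assert len(df) == 1
    assert np.isfinite(df.loc[0, "train_loss"]) and np.isfinite(df.loc[0, "val_loss"])
    assert len(log.checkpoint_paths) == 1


def test_gradient_accumulation_matches_full_batch(rng):
    """On a batch-norm-free model, 4 accumulated micro-batches of 2 produce
    the same first update as one batch of 8 (loss scaled by 1/steps)."""
    stack, weights, spec, _ = _tiny_setup(rng, n=10, bn=False)
    ref = z.build_autoencoder(spec, seed=3, batch_norm=False)
    acc = z.build_autoencoder(spec, seed=3, batch_norm=False)
    common = dict(max_epochs=1, seed=11)
    z.fit(ref, stack[:8], stack[8:], weights,
          z.TrainConfig(per_device_batch=8, accumulation_steps=1, **common))
    z.fit(acc, stack[:8], stack[8:], weights,
          z.TrainConfig(per_device_batch=2, accumulation_steps=4, **common))
    for p_ref, p_acc in zip(ref.parameters(), acc.parameters()):
        np.testing.assert_allclose(p_acc.value, p_ref.value, rtol=1e-5)


def test_gradient_accumulation_with_batchnorm_deviates(rng):
    """With batch norm the micro-batch statistics differ from the full-batch
    statistics, so exact equivalence is not expected — documented behavior."""
    stack, weights, spec, _ = _tiny_setup(rng, n=10, bn=True)
    ref = z.build_autoencoder(spec, seed=3)
    acc = z.build_autoencoder(spec, seed=3)
    common = dict(max_epochs=1, seed=11)
    z.fit(ref, stack[:8], stack[8:], weights,
          z.TrainConfig(per_device_batch=8, accumulation_steps=1, **common))
    z.fit(acc, stack[:8], stack[8:], weights,
          z.TrainConfig(per_device_batch=2, accumulation_steps=4, **common))
    diffs = [
        np.max(np.abs(p_acc.value - p_ref.value))
        for p_ref, p_acc in zip(ref.parameters(), acc.parameters())
    ]
    assert max(diffs) > 1e-8


def test_checkpoint_restores_logged_validation_loss(rng, tmp_path):
    stack, weights, spec, model = _tiny_setup(rng, n=12)
    cfg = z.TrainConfig(max_epochs=5, per_device_batch=2, accumulation_steps=2,
                        seed=2)
    model, log = z.fit(model, stack[:8], stack[8:], weights, cfg,
                       checkpoint_dir=tmp_path)
    assert log.checkpoint_paths, "no improvement checkpoint written"
    fresh = z.build_autoencoder(spec, seed=99)
    meta = z.load_checkpoint(fresh, log.checkpoint_paths[-1])
    val = _validation_loss(fresh, stack[8:], weights.weight, batch=2)
    assert val == meta["val_loss"]
    logged = log.to_frame().set_index("epoch").loc[meta["epoch"], "val_loss"]
    assert val == logged


def test_lr_trace_non_increasing_and_reductions_exact(rng):
    stack, weights, _, model = _tiny_setup(rng, n=8)
    cfg = z.TrainConfig(max_epochs=14, per_device_batch=4, accumulation_steps=1,
                        scheduler_patience=2, seed=0, learning_rate=1e-12)
    # learning rate tiny on purpose: the loss plateaus, forcing reductions
    model, log = z.fit(model, stack[:6], stack[6:], weights, cfg)
    lrs = log.to_frame()["lr"].to_numpy()
    assert (np.diff(lrs) <= 0).all()
    distinct = np.unique(lrs)[::-1]
    for a, b in zip(distinct, distinct[1:]):
        np.testing.assert_allclose(b / a, cfg.scheduler_factor)
    assert len(distinct) >= 2  # at least one reduction happened


def test_non_finite_loss_raises(rng):
    stack, weights, _, model = _tiny_setup(rng)
    model.parameters()[0].value[...] = np.inf
    with pytest.raises(z.TrainingError):
        z.fit(model, stack[:4], stack[4:], weights,
              z.TrainConfig(max_epochs=1, seed=0))


def test_empty_split_rejected(rng):
    stack, weights, _, model = _tiny_setup(rng)
    with pytest.raises(z.DataError):
        z.fit(model, stack[:0], stack, weights, z.TrainConfig(max_epochs=1))
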