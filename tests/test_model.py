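"""Training scheme: normalization, losses, augmentation, splits,
training mechanics and inference."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctmar.core import CTSlice, PairedSample
from ctmar.metrics import rmse
from ctmar.model import (AugmentToggles, CycleMarModel, TrainConfig,
                         apply_mar, augment_pair, cyclemar_losses,
                         denormalize, holdout_split, kfold_split, load_model,
                         normalize, save_model, train_cyclemar)
from ctmar.model.nn import Sequential


def _pairs(n, size=32, seed=0, pid_prefix="p"):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        ref = rng.normal(0, 300, (size, size))
        art = ref + rng.normal(0, 150, (size, size))
        out.append(PairedSample(ref=CTSlice(ref), art=CTSlice(art),
                                patient_id=f"{pid_prefix}{i}",
                                slice_id=f"{pid_prefix}{i}s0"))
    return out


class TestNormalize:
    def test_anchor_points(self):
        ct = CTSlice(np.array([[0.0, 1000.0], [-1000.0, 2500.0]]))
        x = normalize(ct)
        assert x[0, 0] == 0.0 and x[0, 1] == 1.0
        assert x[1, 0] == -1.0 and x[1, 1] == 1.0  # 2500 clipped

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_roundtrip_equals_clip(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(-3000, 4000, (8, 8))
        ct = CTSlice(v)
        back = denormalize(normalize(ct), like=ct)
        assert np.allclose(back.values, np.clip(v, -1000, 1000), atol=1e-3)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            normalize(np.array([[np.nan, 0.0]]))


class TestLosses:
    def test_identity_generators_zero_cycle_and_identity(self):
        cfg = TrainConfig.desk(image_size=32, epochs=1, ngf=4, n_blocks=1)
        model = CycleMarModel.build(cfg)
        model.G_corr = Sequential([])  # identity mapping
        model.G_art = Sequential([])
        rng = np.random.default_rng(0)
        x = rng.uniform(-1, 1, (32, 32)).astype(np.float32)
        y = rng.uniform(-1, 1, (32, 32)).astype(np.float32)
        comp = cyclemar_losses(model, x, y, cfg)
        assert comp["cycle"] == 0.0
        assert comp["identity"] == 0.0

    def test_perfect_correction_zeroes_paired_term(self):
        cfg = TrainConfig.desk(image_size=32, epochs=1, ngf=4, n_blocks=1)
        model = CycleMarModel.build(cfg)
        model.G_corr = Sequential([])
        x = np.random.default_rng(0).uniform(-1, 1, (32, 32)
                                             ).astype(np.float32)
        comp = cyclemar_losses(model, x, x, cfg)  # G_corr(x) == y == x
        assert comp["paired"] == 0.0

    def test_default_regularization_weights(self):
        cfg = TrainConfig()
        assert cfg.lambda_cycle == 10.0
        assert cfg.lambda_identity == 15.0

    def test_total_equals_sum_of_components(self):
        cfg = TrainConfig.desk(image_size=32, epochs=1, ngf=4, n_blocks=1)
        model = CycleMarModel.build(cfg)
        rng = np.random.default_rng(3)
        x = rng.uniform(-1, 1, (32, 32)).astype(np.float32)
        y = rng.uniform(-1, 1, (32, 32)).astype(np.float32)
        comp = cyclemar_losses(model, x, y, cfg)
        assert comp["total_G"] == (comp["adv_G"] + comp["cycle"]
                                   + comp["identity"] + comp["paired"])

    def test_shape_mismatch_rejected(self):
        cfg = TrainConfig.desk(image_size=32, epochs=1, ngf=4, n_blocks=1)
        model = CycleMarModel.build(cfg)
        with pytest.raises(ValueError, match="congruent"):
            cyclemar_losses(model, np.zeros((32, 32), np.float32),
                            np.zeros((16, 16), np.float32), cfg)


class TestAugment:
    def test_all_toggles_off_is_identity(self):
        rng = np.random.default_rng(0)
        ref = rng.uniform(-1, 1, (32, 32)).astype(np.float32)
        art = rng.uniform(-1, 1, (32, 32)).astype(np.float32)
        off = AugmentToggles(False, False, False, False)
        r2, a2 = augment_pair(ref, art, off, rng)
        assert np.array_equal(r2, ref) and np.array_equal(a2, art)

    def test_double_flip_with_same_seed_is_involution(self):
        rng = np.random.default_rng(0)
        ref = rng.uniform(-1, 1, (32, 32)).astype(np.float32)
        art = rng.uniform(-1, 1, (32, 32)).astype(np.float32)
        flip_only = AugmentToggles(rotation=False, horizontal_flip=True,
                                   resized_crop=False, perspective=False)
        r1, a1 = augment_pair(ref, art, flip_only, np.random.default_rng(42))
        r2, a2 = augment_pair(r1, a1, flip_only, np.random.default_rng(42))
        assert np.array_equal(r2, ref) and np.array_equal(a2, art)

    def test_pairing_survives_joint_transform(self, dataset64):
        # the sampled transform hits ref and art identically, so their
        # mutual RMSE is nearly unchanged for content-preserving transforms;
        # the resized crop re-weights image content (the probe streaks are
        # localized) and gets a looser bound
        s = dataset64[0]
        ref, art = normalize(s.ref), normalize(s.art)
        before = float(np.sqrt(np.mean((ref - art) ** 2)))
        keep_field = AugmentToggles(rotation=True, horizontal_flip=True,
                                    resized_crop=False, perspective=True)
        for seed in range(5):
            r2, a2 = augment_pair(ref, art, keep_field,
                                  np.random.default_rng(seed))
            after = float(np.sqrt(np.mean((r2 - a2) ** 2)))
            assert abs(after - before) < 0.2 * before
        for seed in range(5):
            r2, a2 = augment_pair(ref, art, AugmentToggles(),
                                  np.random.default_rng(seed))
            after = float(np.sqrt(np.mean((r2 - a2) ** 2)))
            assert abs(after - before) < 0.35 * before


class TestSplits:
    def test_70_patients_5_folds_balanced(self):
        samples = _pairs(70)
        fold_of = kfold_split(samples, folds=5, seed=1)
        counts = np.bincount(list(fold_of.values()), minlength=5)
        assert np.all(counts == 14)

    def test_holdout_15_percent_disjoint(self):
        samples = _pairs(84)
        train, test = holdout_split(samples, test_fraction=0.15, seed=2)
        test_pids = {s.patient_id for s in test}
        train_pids = {s.patient_id for s in train}
        assert len(test_pids) == 13  # round(0.15 * 84)
        assert not (test_pids & train_pids)
        assert len(train) + len(test) == 84

    def test_same_seed_identical_assignment(self):
        samples = _pairs(30)
        assert kfold_split(samples, 5, 7) == kfold_split(samples, 5, 7)
        t1 = holdout_split(samples, 0.15, 7)
        t2 = holdout_split(samples, 0.15, 7)
        assert [s.patient_id for s in t1[1]] == [s.patient_id for s in t2[1]]

    def test_multislice_patients_stay_together(self):
        samples = []
        for i in range(10):
            for k in range(3):
                s = _pairs(1, seed=i * 3 + k, pid_prefix=f"q{i}_")[0]
                s.patient_id = f"q{i}"
                samples.append(s)
        train, test = holdout_split(samples, 0.2, seed=0)
        assert {s.patient_id for s in train}.isdisjoint(
            {s.patient_id for s in test})

    def test_fewer_patients_than_folds_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            kfold_split(_pairs(3), folds=5, seed=0)


class TestTraining:
    def test_invalid_epochs_rejected(self):
        with pytest.raises(ValueError, match="epochs"):
            TrainConfig(epochs=0)

    def test_too_few_pairs_rejected(self):
        cfg = TrainConfig.desk(image_size=32, epochs=1)
        with pytest.raises(ValueError, match="2 training pairs"):
            train_cyclemar(_pairs(1), cfg)

    def test_two_runs_same_seed_identical(self):
        pairs = _pairs(3)
        cfg = TrainConfig.desk(image_size=32, epochs=2, seed=5, ngf=4,
                               n_blocks=1)
        m1 = train_cyclemar(pairs, cfg)
        m2 = train_cyclemar(pairs, cfg)
        assert m1.history == m2.history
        for (mod1, n1), (mod2, n2) in zip(
                *(map(lambda m: __import__("ctmar.model.nn", fromlist=["x"])
                      .collect_params(m.G_corr), (m1, m2)))):
            assert np.array_equal(mod1.params[n1], mod2.params[n2])

    def test_history_logs_all_components_per_epoch(self):
        m = train_cyclemar(_pairs(3), TrainConfig.desk(image_size=32,
                                                       epochs=2, ngf=4,
                                                       n_blocks=1))
        assert len(m.history) == 2
        for rec in m.history:
            for key in ("adv_G", "adv_D", "cycle", "identity", "paired",
                        "total_G"):
                assert np.isfinite(rec[key])


@pytest.fixture(scope="module")
def tiny_model():
    return train_cyclemar(_pairs(3), TrainConfig.desk(
        image_size=32, epochs=2, seed=1, ngf=4, n_blocks=1))


class TestApply:
    def test_untrained_model_rejected(self):
        model = CycleMarModel.build(TrainConfig.desk(image_size=32, epochs=1,
                                                     ngf=4, n_blocks=1))
        with pytest.raises(ValueError, match="trained"):
            apply_mar(model, CTSlice(np.zeros((32, 32))))

    def test_output_bounded_by_clip_range(self, tiny_model):
        ct = CTSlice(np.random.default_rng(0).uniform(-2000, 4000, (32, 32)))
        cor = apply_mar(tiny_model, ct)
        assert np.all(np.abs(cor.values) <= 1000.0)
        assert cor.meta["clipped_pixels"] > 0

    def test_inference_deterministic(self, tiny_model):
        ct = CTSlice(np.random.default_rng(1).uniform(-500, 500, (32, 32)))
        a = apply_mar(tiny_model, ct)
        b = apply_mar(tiny_model, ct)
        assert np.array_equal(a.values, b.values)

    def test_off_size_input_resized_and_recorded(self, tiny_model):
        ct = CTSlice(np.zeros((48, 48)))
        cor = apply_mar(tiny_model, ct)
        assert cor.shape == (48, 48)
        assert cor.meta["inference_resized"] is True

    def test_checkpoint_roundtrip_bit_exact(self, tiny_model, tmp_path):
        from ctmar.model.nn import collect_params
        path = tmp_path / "model.ckpt"
        save_model(tiny_model, path)
        loaded = load_model(path)
        for (m1, n1), (m2, n2) in zip(collect_params(tiny_model.G_corr),
                                      collect_params(loaded.G_corr)):
            assert np.array_equal(m1.params[n1], m2.params[n2])
        ct = CTSlice(np.random.default_rng(2).uniform(-500, 500, (32, 32)))
        assert np.array_equal(apply_mar(tiny_model, ct).values,
                              apply_mar(loaded, ct).values)
        assert loaded.history == tiny_model.history
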