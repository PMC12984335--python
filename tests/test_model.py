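import numpy as np
import pytest
from sklearn.base import clone

from mffae._nn import Linear
from mffae.model import (
    MffaeDetector,
    ModelConfig,
    build_model,
    cls_loss,
    load_checkpoint,
    partition_groups,
    reconstruction_loss,
    save_checkpoint,
    score,
    total_loss,
    train,
)

TINY = dict(feat_n=30, f1_dim=16, f2_dim=8, groups_g=4, seed=7)


def _flat_params(model):
    return np.concatenate([p.ravel() for mod in model.modules() for p in mod.params.values()])


class TestConfig:
    def test_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(feat_n=200, f1_dim=100, f2_dim=10, groups_g=8)

    def test_width_ordering_enforced(self):
        with pytest.raises(ValueError, match="f2_dim < f1_dim < feat_n"):
            ModelConfig(feat_n=50, f1_dim=64, f2_dim=16)

    @pytest.mark.parametrize("variant,has_cls,has_fusion", [
        ("SAE", False, False),
        ("AE_CLS", True, False),
        ("AE_MSF", False, True),
        ("MFF_AE", True, True),
    ])
    def test_variant_controls_submodules(self, variant, has_cls, has_fusion):
        model = build_model(ModelConfig(variant=variant, **TINY), [f"s{i}" for i in range(5)])
        assert (model.classifier is not None) == has_cls
        assert (model.fusion_linear is not None) == has_fusion

    def test_same_seed_same_parameters(self):
        cfg = ModelConfig(**TINY)
        ids = [f"s{i}" for i in range(5)]
        a, b = build_model(cfg, ids), build_model(cfg, ids)
        assert np.array_equal(_flat_params(a), _flat_params(b))


class TestPartition:
    def test_concat_reconstructs_input(self, rng):
        f1 = rng.normal(size=(3, 16))
        blocks = partition_groups(f1, 8)
        assert len(blocks) == 8 and all(b.shape == (3, 2) for b in blocks)
        assert np.array_equal(np.concatenate(blocks, axis=1), f1)

    def test_single_group_degenerate(self, rng):
        f1 = rng.normal(size=(2, 6))
        assert np.array_equal(partition_groups(f1, 1)[0], f1)

    def test_block_indexing(self, rng):
        f1 = rng.normal(size=(3, 12))
        blocks = partition_groups(f1, 4)
        assert np.array_equal(blocks[2], f1[:, 6:9])

    def test_non_divisible_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            partition_groups(rng.normal(size=(2, 10)), 4)


class TestLosses:
    def test_reconstruction_hand_values(self):
        assert reconstruction_loss(np.array([[0.0, 0.0]]), np.array([[1.0, 1.0]])) == 2.0
        assert reconstruction_loss(np.array([[0.0], [0.0]]), np.array([[1.0], [3.0]])) == 5.0
        x = np.ones((3, 4))
        assert reconstruction_loss(x, x) == 0.0

    def test_cls_uniform_logits_is_log_c(self):
        logits = np.zeros((6, 4))
        assert cls_loss(logits, np.arange(6) % 4) == pytest.approx(np.log(4), abs=1e-12)

    def test_cls_closed_form_two_classes(self):
        val = cls_loss(np.array([[2.0, 0.0]]), np.array([0]))
        assert val == pytest.approx(-np.log(np.exp(2) / (np.exp(2) + 1)), abs=1e-9)

    def test_cls_label_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            cls_loss(np.zeros((2, 3)), np.array([0, 3]))

    def test_total_is_plain_sum(self):
        assert total_loss(0.5, 0.25) == 0.75
        assert total_loss(0.0, 0.0) == 0.0


class TestForward:
    def test_eval_mode_deterministic(self, rng):
        model = build_model(ModelConfig(**TINY), [f"s{i}" for i in range(4)])
        x = rng.normal(size=(4, 30))
        a, b = model.forward(x, "eval"), model.forward(x, "eval")
        assert np.array_equal(a.recon, b.recon)
        assert np.array_equal(a.cls_logits, b.cls_logits)

    def test_fusion_is_nonnegative(self, rng):
        model = build_model(ModelConfig(**TINY))
        state = model.forward(rng.normal(size=(5, 30)), "train")
        assert state.f_fusion.min() >= 0.0

    def test_sae_state_has_no_local_or_cls(self, rng):
        model = build_model(ModelConfig(variant="SAE", **TINY))
        state = model.forward(rng.normal(size=(4, 30)), "eval")
        assert state.f_local is None and state.cls_logits is None
        assert state.recon.shape == (4, 30)

    def test_variant_nesting_sae_equals_mffae_disabled(self, rng):
        """SAE forward == MFF_AE forward when fusion/CLS pathways are removed:
        shared encoder/decoder init is identical across variants."""
        sae = build_model(ModelConfig(variant="SAE", **TINY))
        full = build_model(ModelConfig(variant="MFF_AE", **TINY), ["a", "b", "c"])
        x = rng.normal(size=(3, 30))
        f1_sae = sae.enc1.forward(x, False)
        f1_full = full.enc1.forward(x, False)
        assert np.array_equal(f1_sae, f1_full)
        latent = sae.enc2.forward(f1_sae, False)
        recon_sae = sae.dec_out.forward(sae.dec1.forward(latent, False), False)
        recon_full = full.dec_out.forward(full.dec1.forward(latent, False), False)
        assert np.array_equal(recon_sae, recon_full)

    def test_shape_mismatch_rejected(self, rng):
        model = build_model(ModelConfig(**TINY))
        with pytest.raises(ValueError, match="input must be"):
            model.forward(rng.normal(size=(4, 31)), "eval")


class TestGradients:
    def test_full_model_matches_finite_differences(self, rng):
        """Analytic backprop vs central differences on every submodule."""
        cfg = ModelConfig(feat_n=12, f1_dim=8, f2_dim=4, groups_g=4,
                          dropout=0.0, seed=3, variant="MFF_AE")
        model = build_model(cfg, [f"s{i}" for i in range(5)])
        x = rng.normal(size=(5, 12))
        labels = np.arange(5)

        state = model.forward(x, "train")
        model.backward(x, state, labels)
        eps = 1e-6
        for mod in model.modules():
            for key, p in mod.params.items():
                idx = tuple(rng.integers(0, s) for s in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp = model.losses(x, model.forward(x, "train"), labels).l_total
                p[idx] = orig - eps
                lm = model.losses(x, model.forward(x, "train"), labels).l_total
                p[idx] = orig
                assert mod.grads[key][idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-4)


class TestTraining:
    def test_fixed_seed_reproducible_history(self, small_training_matrix):
        cfg = ModelConfig(epochs=3, **TINY)
        h1 = train(build_model(cfg), small_training_matrix.values[:, :30])[1]
        h2 = train(build_model(cfg), small_training_matrix.values[:, :30])[1]
        assert [b.l_total for b in h1] == [b.l_total for b in h2]

    def test_loss_additivity_every_epoch(self, small_training_matrix):
        cfg = ModelConfig(epochs=4, **TINY)
        _, hist = train(build_model(cfg), small_training_matrix.values[:, :30])
        for b in hist:
            assert b.l_total == b.l_rec + b.l_cls

    @pytest.mark.parametrize("seed", range(10))
    def test_descent_on_structured_data(self, small_training_matrix, seed):
        cfg = ModelConfig(feat_n=60, f1_dim=16, f2_dim=8, groups_g=4,
                          epochs=100, seed=seed)
        _, hist = train(build_model(cfg), small_training_matrix)
        assert hist[-1].l_rec < hist[0].l_rec

    def test_oversized_batch_trains_single_batch(self, small_training_matrix):
        cfg = ModelConfig(batch_size=1000, epochs=2, **TINY)
        _, hist = train(build_model(cfg), small_training_matrix.values[:, :30])
        assert len(hist) == 2

    def test_missing_cells_rejected(self):
        cfg = ModelConfig(epochs=1, **TINY)
        x = np.ones((6, 30))
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            train(build_model(cfg), x)


class TestScoring:
    def test_row_permutation_equivariance(self, small_training_matrix):
        cfg = ModelConfig(epochs=2, **TINY)
        model, _ = train(build_model(cfg), small_training_matrix.values[:, :30])
        x = small_training_matrix.values[:, :30]
        perm = np.random.default_rng(0).permutation(x.shape[0])
        assert np.array_equal(score(model, x)[perm], score(model, x[perm]))

    def test_two_passes_bit_identical(self, small_training_matrix):
        cfg = ModelConfig(epochs=2, **TINY)
        model, _ = train(build_model(cfg), small_training_matrix.values[:, :30])
        x = small_training_matrix.values[:, :30]
        assert np.array_equal(score(model, x), score(model, x))

    def test_feature_count_mismatch(self, small_training_matrix):
        cfg = ModelConfig(epochs=1, **TINY)
        model, _ = train(build_model(cfg), small_training_matrix.values[:, :30])
        with pytest.raises(ValueError, match="proteins"):
            score(model, small_training_matrix.values)


class TestCheckpoint:
    @pytest.mark.parametrize("dtype", ["float64", "float32"])
    def test_roundtrip_reproduces_scores(self, tmp_path, small_training_matrix, dtype):
        cfg = ModelConfig(epochs=2, dtype=dtype, **TINY)
        x = small_training_matrix.values[:, :30]
        model, _ = train(build_model(cfg), x)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        assert back.config == model.config
        assert back.train_sample_ids == model.train_sample_ids
        assert np.array_equal(score(back, x), score(model, x))


class TestDetectorEstimator:
    def test_sklearn_clone_and_params(self):
        det = MffaeDetector(variant="SAE", epochs=5)
        c = clone(det)
        assert c.get_params()["variant"] == "SAE"
        assert c.get_params()["epochs"] == 5

    def test_fit_score_shapes_and_sign(self, small_training_matrix):
        det = MffaeDetector(f1_dim=16, f2_dim=8, groups_g=4, epochs=3, seed=0)
        scores = det.fit_score(small_training_matrix)
        assert scores.shape == (40,)
        assert (scores >= 0).all()
        assert det.n_features_in_ == 60

    def test_unfitted_scoring_refused(self, small_training_matrix):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            MffaeDetector().score_samples(small_training_matrix)
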