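"""Conditional GAN: bookkeeping, objective arithmetic, training mechanics."""

import numpy as np
import pytest

from dlept.cgan import (DatasetSplit, NetworkConfig, TrainedModel, UNet,
                        cgan_objective, count_dataset_slices, predict,
                        select_model, train, scale_target, unscale_target,
                        TrainingExample)
from dlept.em_forward import Acquisition


@pytest.mark.parametrize("args,expected", [
    ((42, 25, 20, 56), 2170),   # full database
    ((38, 25, 19, 56), 2014),   # mask-variant training set
    ((0, 25, 19, 56), 1064),    # tissue-variant training set (heads only)
])
def test_database_slice_bookkeeping(args, expected):
    assert count_dataset_slices(*args) == expected


def test_split_disjointness_enforced():
    with pytest.raises(ValueError):
        DatasetSplit(train=[0, 1, 2], validation=[2], test=[3])
    s = DatasetSplit(train=[0, 1], validation=[2], test=[3])
    assert set(s.train) & set(s.test) == set()


class TestObjective:
    def setup_method(self):
        self.cfg = NetworkConfig(lambda_gan=0.0, lambda_l1=100.0,
                                 lambda_l2=200.0)

    def test_perfect_output_has_zero_supervised_loss(self):
        t = np.random.default_rng(0).uniform(0, 1, (2, 1, 8, 8))
        g, d = cgan_objective(t, t, {}, self.cfg)
        assert g == 0.0

    def test_toy_arithmetic(self):
        """2x2 maps, hand-computed: L1 = 0.25, L2 = 0.125."""
        out = np.array([[[[0.5, 0.0], [1.0, 1.0]]]])
        tgt = np.array([[[[0.0, 0.5], [1.0, 1.0]]]])
        g, _ = cgan_objective(out, tgt, {}, self.cfg)
        assert g == pytest.approx(100.0 * 0.25 + 200.0 * 0.125)

    def test_gan_weight_zero_reduces_to_supervised(self):
        out = np.zeros((1, 1, 4, 4))
        tgt = np.ones((1, 1, 4, 4))
        scores = {"fake": np.full((1, 1, 2, 2), -3.0),
                  "real": np.full((1, 1, 2, 2), 3.0)}
        g0, _ = cgan_objective(out, tgt, scores, self.cfg)
        cfg_gan = NetworkConfig(lambda_gan=2.0, lambda_l1=100.0,
                                lambda_l2=200.0)
        g1, d1 = cgan_objective(out, tgt, scores, cfg_gan)
        assert g1 > g0          # adversarial term adds for a fooled D
        assert d1 > 0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NetworkConfig(target="both")
        with pytest.raises(ValueError):
            NetworkConfig(lambda_l1=-1)


def test_target_scaling_roundtrip():
    cfg = NetworkConfig(target="epsr")
    t = np.random.default_rng(1).uniform(1, 100, (16, 16))
    assert np.allclose(unscale_target(scale_target(t, cfg), cfg), t,
                       atol=1e-4)


def _toy_examples(n=10, size=16, seed=0):
    """Tiny synthetic regression set: target = smoothed input channel."""
    rng = np.random.default_rng(seed)
    examples = []
    for _ in range(n):
        level = rng.uniform(0.3, 1.8)
        x = np.zeros((3, size, size), dtype=np.float32)
        yy, xx = np.mgrid[:size, :size]
        mask = (yy - size / 2) ** 2 + (xx - size / 2) ** 2 < (size * 0.4) ** 2
        x[0] = np.where(mask, level, 0.0)
        x[1] = rng.normal(0, 0.02, (size, size))
        x[2] = mask
        target = np.where(mask, level, 0.0)
        examples.append(TrainingExample(inputs=x, target=target,
                                        mask=mask, provenance="toy"))
    return examples


class TestTraining:
    def test_overfit_smoke(self):
        """Capacity check: 10 examples, enough epochs, training L1 below
        5% of the target dynamic range."""
        examples = _toy_examples()
        cfg = NetworkConfig(target="sigma", epochs=250, base_channels=8,
                            batch_size=5, seed=0, lambda_gan=0.0,
                            learning_rate=2e-3)
        tm = train(examples, cfg)
        # targets span ~[0.3, 1.8] scaled by 2.5 -> range 0.6 in [0,1] units
        assert tm.history["l1"][-1] < 0.05 * 0.6

    def test_determinism_under_seed(self):
        examples = _toy_examples(6)
        cfg = NetworkConfig(epochs=2, base_channels=8, batch_size=3, seed=5)
        a = train(examples, cfg)
        b = train(examples, cfg)
        for (pa, _), (pb, _) in zip(a.generator.params, b.generator.params):
            assert np.array_equal(pa, pb)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], NetworkConfig())

    def test_unet_output_shape_matches_input(self):
        net = UNet(cin=3, base=8, rng=np.random.default_rng(0))
        x = np.random.default_rng(1).standard_normal((2, 3, 32, 32))
        assert net.forward(x.astype(np.float32), train=False).shape \
            == (2, 1, 32, 32)


class TestSelection:
    def _cand(self, bias, seed=0):
        examples = _toy_examples(4, seed=seed)
        cfg = NetworkConfig(epochs=1, base_channels=8, batch_size=2,
                            seed=seed, lambda_gan=0.0)
        tm = train(examples, cfg)
        return tm

    def test_single_candidate_returns_itself(self):
        tm = self._cand(0)
        val = _toy_examples(3, seed=9)
        best, scores = select_model([tm], val)
        assert best is tm and len(scores) == 1

    def test_lowest_average_nrmse_wins(self):
        """Mean-of-two selection: (0.1, 0.1) beats (0.05, 0.3)."""

        class Fake:
            def __init__(self, scores):
                self._s = scores

        # exercise the averaging rule directly via pairs of models whose
        # NRMSEs we control through monkeypatched scoring
        import dlept.cgan as cg
        cands = [("a1", "a2"), ("b1", "b2")]
        table = {"a1": 0.1, "a2": 0.1, "b1": 0.05, "b2": 0.3}
        orig = cg._validation_nrmse
        try:
            cg._validation_nrmse = lambda G, val, cfg: table[G]
            fake = [tuple(type("M", (), {"generator": g,
                                         "config": None})() for g in pair)
                    for pair in cands]
            best, scores = cg.select_model(fake, ["v"])
            assert scores == [pytest.approx(0.1), pytest.approx(0.175)]
            assert best is fake[0]
        finally:
            cg._validation_nrmse = orig

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_model([], [])


class TestPredict:
    def _trained(self):
        examples = _toy_examples(6)
        cfg = NetworkConfig(epochs=1, base_channels=8, batch_size=3, seed=1)
        return train(examples, cfg)

    def _acq(self, aux_kind="mask", size=16):
        mask = np.zeros((size, size), bool)
        mask[4:-4, 4:-4] = True
        return Acquisition(magnitude=np.where(mask, 1.0, 0.1),
                           phase=np.zeros((size, size)),
                           aux=mask.astype(float), mask=mask, spacing=0.004,
                           aux_kind=aux_kind)

    def test_air_forced_to_vacuum_values(self):
        maps = predict(self._trained(), self._acq())
        assert np.all(maps.sigma_map[~maps.valid_mask] == 0.0)
        assert np.all(maps.epsr_map[~maps.valid_mask] == 1.0)

    def test_inference_is_deterministic(self):
        tm = self._trained()
        a = predict(tm, self._acq())
        b = predict(tm, self._acq())
        assert np.array_equal(a.sigma_map, b.sigma_map)

    def test_channel_kind_mismatch_rejected(self):
        tm = self._trained()  # trained with aux="mask"
        with pytest.raises(ValueError):
            predict(tm, self._acq(aux_kind="tissue_contrast"))


class TestAssembleDataset:
    def test_bookkeeping_targets_and_determinism(self):
        from dlept.cgan import assemble_dataset
        from dlept.models import build_phantom_model
        from dlept.noise import NoiseSpec

        models = [build_phantom_model(0.12, 0.4 + 0.3 * i, 60.0, (32, 32),
                                      0.008) for i in range(3)]
        split = DatasetSplit(train=[0, 1], test=[2])
        ds1 = assemble_dataset(models, split, NoiseSpec(seed=4),
                               target="epsr", slices_per_model=2)
        assert len(ds1["train"]) == 4      # 2 models x 2 slices
        assert len(ds1["test"]) == 1
        # targets are exactly the generating model's property maps
        assert np.array_equal(ds1["train"][0].target, models[0].epsr_map)
        assert ds1["train"][0].provenance == "model0/slice0"
        ds2 = assemble_dataset(models, split, NoiseSpec(seed=4),
                               target="epsr", slices_per_model=2)
        for a, b in zip(ds1["train"], ds2["train"]):
            assert np.array_equal(a.inputs, b.inputs)

    def test_unknown_model_id_rejected(self):
        from dlept.cgan import assemble_dataset
        from dlept.models import build_phantom_model
        from dlept.noise import NoiseSpec

        models = [build_phantom_model(0.12, 0.5, 60.0, (32, 32), 0.008)]
        with pytest.raises(ValueError):
            assemble_dataset(models, DatasetSplit(train=[0, 5]),
                             NoiseSpec(seed=0))
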