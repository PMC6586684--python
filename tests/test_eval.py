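"""Evaluation metrics: ROI statistics, NRMSE, relative errors, CNR."""

import numpy as np
import pytest

from dlept.evaluate import (contrast_to_noise, nrmse, relative_error,
                            roi_statistics)
from dlept.hept import EpsMaps
from dlept.models import LABELS, build_head_model


def _maps_from(sigma, epsr, valid=None):
    valid = np.ones_like(sigma, dtype=bool) if valid is None else valid
    return EpsMaps(sigma_map=sigma, epsr_map=epsr, method="test",
                   valid_mask=valid)


class TestRoiStatistics:
    def test_ground_truth_maps_have_zero_sd(self):
        head = build_head_model(seed=5, grid_shape=(128, 128), spacing=0.002)
        maps = _maps_from(head.sigma_map, head.epsr_map)
        stats = roi_statistics(maps, head.label_grid, erosion=3)
        for tissue in ("WM", "GM"):
            s, e = head.region_properties[LABELS[tissue]]
            assert stats[tissue]["sigma_mean"] == pytest.approx(s)
            assert stats[tissue]["sigma_sd"] < 1e-12
            assert stats[tissue]["epsr_mean"] == pytest.approx(e)
            assert stats[tissue]["epsr_sd"] < 1e-12

    def test_population_sd_convention(self):
        """4-voxel region {1,1,2,2}: mean 1.5, population SD 0.5."""
        labels = np.zeros((4, 4), dtype=int)
        labels[0, :4] = 1
        sigma = np.zeros((4, 4))
        sigma[0] = [1.0, 1.0, 2.0, 2.0]
        stats = roi_statistics(_maps_from(sigma, sigma + 1), labels,
                               erosion=0)
        assert stats["WM"]["sigma_mean"] == pytest.approx(1.5)
        assert stats["WM"]["sigma_sd"] == pytest.approx(0.5)

    def test_erosion_shrinks_voxel_count(self):
        head = build_head_model(seed=5, grid_shape=(128, 128), spacing=0.002)
        maps = _maps_from(head.sigma_map, head.epsr_map)
        n0 = roi_statistics(maps, head.label_grid, 0)["WM"]["n_voxels"]
        n3 = roi_statistics(maps, head.label_grid, 3)["WM"]["n_voxels"]
        assert n3 < n0

    def test_empty_region_warns_and_is_omitted(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[9:11, 9:11] = 1   # vanishes under 3-voxel erosion
        maps = _maps_from(np.ones((20, 20)), np.ones((20, 20)))
        with pytest.warns(UserWarning):
            stats = roi_statistics(maps, labels, erosion=3)
        assert stats == {}


class TestNrmse:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.truth = 1.0 + rng.uniform(0, 1, (32, 32))
        self.mask = np.ones((32, 32), dtype=bool)

    def test_exact_reconstruction_is_zero(self):
        assert nrmse(self.truth, self.truth, self.mask) == 0.0

    def test_constant_offset_closed_form(self):
        c = 0.25
        expected = c / self.truth[self.mask].mean()
        assert nrmse(self.truth + c, self.truth, self.mask) == \
            pytest.approx(expected)

    def test_uniform_scaling_closed_form(self):
        """recon = 1.05 * truth gives RMSE/mean = 0.05 * rms/mean."""
        val = nrmse(1.05 * self.truth, self.truth, self.mask)
        rms = np.sqrt((self.truth ** 2).mean())
        assert val == pytest.approx(0.05 * rms / self.truth.mean())

    def test_zero_mean_truth_rejected(self):
        with pytest.raises(ValueError):
            nrmse(self.truth, np.zeros_like(self.truth), self.mask)


@pytest.mark.parametrize("recon,truth,expected", [
    (0.34, 0.34, 0.0),
    (0.56, 0.59, 5.1),     # the GM conductivity discrepancy scale
    (1.83, 2.14, 14.5),    # the CSF conductivity discrepancy scale
])
def test_relative_error_percentages(recon, truth, expected):
    assert relative_error(recon, truth) == pytest.approx(expected, abs=0.05)


def test_relative_error_rejects_zero_truth():
    with pytest.raises(ValueError):
        relative_error(1.0, 0.0)


class TestCnr:
    def test_removed_contrast_gives_zero(self):
        rng = np.random.default_rng(1)
        m = rng.normal(1.0, 0.1, (32, 32))
        maps = _maps_from(m, m)
        a = np.zeros((32, 32), bool)
        b = np.zeros((32, 32), bool)
        a[:16] = True
        b[16:] = True
        assert contrast_to_noise(maps, a, b) < 0.5

    def test_strong_contrast_with_low_noise(self):
        m = np.ones((32, 32))
        m[:16] = 2.0
        m += np.random.default_rng(2).normal(0, 0.01, m.shape)
        maps = _maps_from(m, m)
        a = np.zeros((32, 32), bool)
        b = np.zeros((32, 32), bool)
        a[:16] = True
        b[16:] = True
        assert contrast_to_noise(maps, a, b) > 10


class TestSnrSweep:
    def test_hept_rows_and_noise_monotonicity(self):
        from dlept.evaluate import snr_sweep
        from dlept.em_forward import analytic_cylinder_field, make_acquisition
        from dlept.hept import hept_reconstruct
        from dlept.models import build_phantom_model

        model = build_phantom_model(0.12, 0.88, 80.0, (64, 64), 0.004)
        sol = analytic_cylinder_field(0.06, 0.88, 80.0, (64, 64), 0.004)
        clean = make_acquisition(sol, model, aux="mask")
        rows = snr_sweep(hept_reconstruct, model, clean,
                         snr_levels=[30.0, np.inf], erosion=2, n_seeds=2,
                         seed=3)
        assert len(rows) == 4
        noisy_sd = np.mean([r["per_tissue"]["phantom"]["sigma_sd"]
                            for r in rows if r["snr"] == 30.0])
        clean_sd = np.mean([r["per_tissue"]["phantom"]["sigma_sd"]
                            for r in rows if np.isinf(r["snr"])])
        assert noisy_sd > clean_sd  # the noiseless entry is the baseline


class TestTumorExperiment:
    def test_ground_truth_reconstructor_recovers_inclusion_exactly(self):
        from dlept.evaluate import tumor_experiment
        from dlept.models import add_tumor, build_head_model

        head = add_tumor(build_head_model(seed=0, eps_variation=0.0,
                                          grid_shape=(128, 128),
                                          spacing=0.002))

        def oracle(acq):
            return _maps_from(head.sigma_map, head.epsr_map)

        res = tumor_experiment(head, acq_noisy=None,
                               predictors={"truth": oracle})
        assert res["truth"]["sigma_mean"] == pytest.approx(1.4)
        assert res["truth"]["epsr_mean"] == pytest.approx(73.0)
        assert res["truth"]["sigma_rel_error"] == 0.0
        assert res["truth"]["sigma_cnr"] > 100  # piecewise-constant truth

    def test_missing_tumor_label_rejected(self):
        from dlept.evaluate import tumor_experiment
        from dlept.models import build_head_model

        head = build_head_model(seed=0, grid_shape=(64, 64), spacing=0.004)
        with pytest.raises(ValueError):
            tumor_experiment(head, None, {})
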