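"""Field solver: oracle agreement, linearity, transceive phase, acquisitions."""

import numpy as np
import pytest

from dlept.em_forward import (CoilConfig, analytic_cylinder_field,
                              make_acquisition, solve_fields,
                              transceive_phase)
from dlept.hept import erode_rois, hept_reconstruct
from dlept.models import build_phantom_model


@pytest.fixture(scope="module")
def phantom64():
    model = build_phantom_model(0.12, 0.88, 80.0, (64, 64), 0.004)
    return model, solve_fields(model)


class TestSolver:
    def test_interior_matches_bessel_oracle(self, phantom64):
        """Normalized interior |B1+| agrees with the J0 mode to < 2%."""
        model, sol = phantom64
        ana = analytic_cylinder_field(0.06, 0.88, 80.0, (64, 64), 0.004)
        roi = erode_rois(model.label_grid, 2) != 0
        c = np.mean(sol.B1p[roi] / ana.B1p[roi])
        rel = np.abs(np.abs(sol.B1p[roi] / c) - np.abs(ana.B1p[roi])) \
            / np.abs(ana.B1p[roi])
        assert rel.max() < 0.02

    def test_linearity_in_drive_amplitude(self, phantom64):
        model, sol = phantom64
        coil = CoilConfig(amplitude=2.0)
        sol2 = solve_fields(model, coil, normalize=False)
        sol1 = solve_fields(model, CoilConfig(), normalize=False)
        assert np.allclose(sol2.Ez, 2.0 * sol1.Ez, rtol=1e-10)
        assert np.allclose(sol2.B1p, 2.0 * sol1.B1p, rtol=1e-10)

    def test_fields_finite_and_normalized(self, phantom64):
        model, sol = phantom64
        for f in (sol.Ez, sol.B1p, sol.B1m):
            assert np.all(np.isfinite(f))
        assert np.abs(sol.B1p[model.mask]).mean() == pytest.approx(1.0)

    def test_vacuum_interior_is_uniform(self):
        """Air-filled object: |B1+| flat to ~1%, and the Helmholtz route
        returns epsr ~ 1, sigma ~ 0."""
        model = build_phantom_model(0.12, 0.0, 1.0, (64, 64), 0.004)
        sol = solve_fields(model)
        a = np.abs(sol.B1p[model.mask])
        assert (a.max() - a.min()) / a.mean() < 0.02
        maps = hept_reconstruct(make_acquisition(sol, model))
        roi = (erode_rois(model.label_grid, 2) != 0) & maps.valid_mask
        assert abs(maps.sigma_map[roi].mean()) < 0.05
        assert abs(maps.epsr_map[roi].mean() - 1.0) < 6.0

    def test_coil_validation(self):
        with pytest.raises(ValueError):
            CoilConfig(n_sources=4)
        with pytest.raises(ValueError):
            CoilConfig(phase_scheme=2)


class TestAnalyticCylinder:
    def test_vacuum_limit(self):
        sol = analytic_cylinder_field(0.06, 0.0, 1.0, (64, 64), 0.004)
        mag = np.abs(sol.B1p)
        assert mag.min() > 0.99 and mag.max() < 1.01

    def test_dielectric_brightening(self):
        """High permittivity: |B1+| larger at the center than the rim."""
        sol = analytic_cylinder_field(0.06, 0.88, 80.0, (128, 128), 0.002)
        center = np.abs(sol.B1p[64, 64])
        assert center > 1.2  # boundary value is 1 by normalization

    def test_hept_consistency(self):
        """The Helmholtz route inverts the analytic forward exactly
        (up to kernel discretization)."""
        model = build_phantom_model(0.12, 0.5, 60.0, (128, 128), 0.002)
        sol = analytic_cylinder_field(0.06, 0.5, 60.0, (128, 128), 0.002)
        maps = hept_reconstruct(make_acquisition(sol, model))
        roi = (erode_rois(model.label_grid, 5) != 0) & maps.valid_mask
        assert maps.sigma_map[roi].mean() == pytest.approx(0.5, rel=0.03)
        assert maps.epsr_map[roi].mean() == pytest.approx(60.0, rel=0.03)


class TestTransceivePhase:
    def test_half_relation_exact(self, phantom64):
        model, sol = phantom64
        phi_pm, phi_p = transceive_phase(sol, model.mask)
        assert np.array_equal(phi_p, phi_pm / 2.0)

    def test_symmetric_phantom_phase_matches_transmit(self, phantom64):
        """In a centered cylinder the transceive assumption is near-exact:
        phi±/2 tracks arg B1+ up to a constant."""
        model, sol = phantom64
        _, phi_p = transceive_phase(sol, model.mask)
        delta = phi_p - np.angle(sol.B1p)
        d = delta[model.mask]
        assert (d - d.mean()).std() < 0.01

    def test_conductive_phantom_phase_curvature(self, phantom64):
        """Conductivity delays the field toward the center: the transmit
        phase has a consistent sign of curvature (recovered as sigma>0)."""
        model, sol = phantom64
        maps = hept_reconstruct(make_acquisition(sol, model))
        roi = (erode_rois(model.label_grid, 2) != 0) & maps.valid_mask
        assert maps.sigma_map[roi].mean() > 0.5


class TestAcquisition:
    def test_mask_channel_binary(self, phantom64):
        model, sol = phantom64
        acq = make_acquisition(sol, model, aux="mask")
        assert set(np.unique(acq.aux)) <= {0.0, 1.0}
        assert acq.aux_kind == "mask"

    def test_tissue_contrast_channel(self, phantom64):
        model, sol = phantom64
        acq = make_acquisition(sol, model, aux="tissue_contrast")
        assert acq.aux[model.mask].std() == 0.0
        assert acq.aux.max() == 1.0

    def test_magnitude_normalized(self, phantom64):
        model, sol = phantom64
        acq = make_acquisition(sol, model)
        assert acq.magnitude[model.mask].mean() == pytest.approx(1.0)


def test_mirror_reciprocity_swaps_transmit_and_receive():
    """Mirroring the tissue model left-right exchanges the transmit and
    receive field magnitudes (the polarity conjugation is built into the
    receive-drive solve), up to solver tolerance."""
    from dlept.models import TissueModel, build_head_model

    head = build_head_model(seed=5, grid_shape=(64, 64), spacing=0.004)
    sol = solve_fields(head, normalize=False)
    mirrored = TissueModel(head.label_grid[:, ::-1].copy(),
                           head.sigma_map[:, ::-1].copy(),
                           head.epsr_map[:, ::-1].copy(),
                           head.spacing, head.region_properties)
    sol_m = solve_fields(mirrored, normalize=False)
    mask = head.mask
    for a, b in ((sol.B1p, sol_m.B1m[:, ::-1]), (sol.B1m, sol_m.B1p[:, ::-1])):
        rel = np.abs(np.abs(a[mask]) - np.abs(b[mask])) \
            / np.abs(a[mask]).max()
        assert rel.max() < 0.01


def test_oracle_agreement_at_default_grid():
    """Solver vs Bessel mode at the 128x128 / 2 mm default: interior
    |B1+| agrees to well under 2%."""
    model = build_phantom_model(0.12, 0.88, 80.0, (128, 128), 0.002)
    sol = solve_fields(model)
    ana = analytic_cylinder_field(0.06, 0.88, 80.0, (128, 128), 0.002)
    roi = erode_rois(model.label_grid, 4) != 0
    c = np.mean(sol.B1p[roi] / ana.B1p[roi])
    rel = np.abs(np.abs(sol.B1p[roi] / c) - np.abs(ana.B1p[roi])) \
        / np.abs(ana.B1p[roi])
    assert rel.max() < 0.02
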