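import numpy as np
import pytest
from scipy import ndimage

from hkls import drlse as D
from hkls.hk_cluster import InitialRegion
from hkls.io_formats import ValidationError
from hkls.preprocess import FusionImage


def _fusion(gray):
    gray = np.asarray(gray, float)
    return FusionImage(np.stack([gray, gray, gray], axis=-1))


def _disk(shape, center, radius):
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    return np.hypot(rows - center[0], cols - center[1]) <= radius


def _signed_distance_disk(shape, center, radius):
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    return np.hypot(rows - center[0], cols - center[1]) - radius


class TestEdgeIndicator:
    def test_constant_image_gives_ones(self):
        g = D.edge_indicator(_fusion(np.full((32, 32), 0.4)), 1.5)
        np.testing.assert_allclose(g.g, 1.0)

    def test_step_edge_minimum_matches_smoothed_gradient(self):
        gray = np.zeros((16, 64))
        gray[:, 32:] = 0.6
        g = D.edge_indicator(_fusion(gray), 1.5)
        # independent 1-D oracle: smooth one row, central differences
        row = gray[0] * 255.0
        smoothed = ndimage.gaussian_filter1d(row, 1.5, truncate=4.0, mode="reflect")
        grad = np.gradient(smoothed)
        ghat = np.abs(grad).max()
        assert g.g.min() == pytest.approx(1.0 / (1.0 + ghat ** 2), rel=1e-9)

    def test_contrast_scaling_deepens_minimum(self):
        gray = np.zeros((16, 64))
        gray[:, 32:] = 0.3
        g1 = D.edge_indicator(_fusion(gray), 1.5)
        g2 = D.edge_indicator(_fusion(2 * gray), 1.5)
        assert g2.g.min() < g1.g.min()

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValidationError):
            D.edge_indicator(_fusion(np.zeros((16, 16))), 0.0)


class TestInitLsf:
    def _region(self, mask):
        rows, cols = np.nonzero(mask)
        return InitialRegion(mask=mask,
                             bbox=(rows.min(), cols.min(), rows.max() + 1, cols.max() + 1),
                             area_fraction=mask.mean())

    def test_centered_box_with_margin(self):
        mask = np.zeros((50, 50), bool)
        mask[20:30, 20:30] = True
        phi = D.init_lsf(self._region(mask), (50, 50), c0=3.0, margin_px=5)
        assert (phi.phi[15:35, 15:35] == -3.0).all()
        outside = np.ones((50, 50), bool)
        outside[15:35, 15:35] = False
        assert (phi.phi[outside] == 3.0).all()

    def test_zero_crossing_on_rectangle_boundary(self):
        mask = np.zeros((40, 40), bool)
        mask[10:20, 12:25] = True
        phi = D.init_lsf(self._region(mask), (40, 40), margin_px=3).phi
        # brute-force sign-change scan
        sign_change = np.zeros((40, 40), bool)
        for r in range(40):
            for c in range(40):
                for dr, dc in ((0, 1), (1, 0)):
                    rr, cc = r + dr, c + dc
                    if rr < 40 and cc < 40 and phi[r, c] * phi[rr, cc] < 0:
                        sign_change[r, c] = True
        rows, cols = np.nonzero(sign_change)
        assert rows.min() == 6 and rows.max() == 22
        assert cols.min() == 8 and cols.max() == 27

    def test_full_image_region_rejected(self):
        mask = np.ones((30, 30), bool)
        with pytest.raises(ValidationError):
            D.init_lsf(self._region(mask), (30, 30), margin_px=5)

    def test_empty_region_rejected(self):
        region = InitialRegion(mask=np.zeros((20, 20), bool), bbox=(0, 0, 0, 0),
                               area_fraction=0.0)
        with pytest.raises(ValidationError):
            D.init_lsf(region, (20, 20))


class TestChooseAlpha:
    @pytest.mark.parametrize("frac,expect", [(0.30, 5.0), (0.05, 3.0), (0.15, 3.0)])
    def test_area_rule(self, frac, expect):
        region = InitialRegion(mask=np.ones((4, 4), bool), bbox=(0, 0, 4, 4),
                               area_fraction=frac)
        assert D.choose_alpha(region) == expect


class TestEvolve:
    def test_pure_regularization_preserves_contour(self):
        phi0 = _signed_distance_disk((96, 96), (48, 48), 30.0)
        p = D.DRLSEParams(lam=0.0, alpha=0.0, early_stop=False)
        g = D.EdgeIndicator(np.ones((96, 96)), 1.5)
        phi = D.evolve(D.LevelSetField(phi0.copy()), g, p, alpha=0.0, n_iter=200)
        r0 = np.sqrt((phi0 < 0).sum() / np.pi)
        r1 = np.sqrt((phi.phi < 0).sum() / np.pi)
        assert abs(r1 - r0) <= 0.5

    def test_signed_distance_property_maintained(self):
        phi0 = _signed_distance_disk((96, 96), (48, 48), 30.0)
        p = D.DRLSEParams(lam=0.0, alpha=0.0, early_stop=False)
        g = D.EdgeIndicator(np.ones((96, 96)), 1.5)
        phi = D.evolve(D.LevelSetField(phi0.copy()), g, p, alpha=0.0, n_iter=200).phi
        py, px = np.gradient(phi)
        s = np.hypot(py, px)
        band = np.abs(phi) < 2
        assert ((s[band] >= 0.7) & (s[band] <= 1.3)).mean() >= 0.95

    @pytest.mark.parametrize("alpha,increasing", [(3.0, False), (-3.0, True)])
    def test_area_term_sign_drives_shrink_or_grow(self, alpha, increasing):
        phi = D.LevelSetField(_signed_distance_disk((96, 96), (48, 48), 25.0))
        p = D.DRLSEParams(lam=0.0, alpha=alpha, early_stop=False)
        g = D.EdgeIndicator(np.ones((96, 96)), 1.5)
        areas = [(phi.phi < 0).sum()]
        for _ in range(6):
            phi = D.evolve(phi, g, p, alpha=alpha, n_iter=10)
            areas.append((phi.phi < 0).sum())
        diffs = np.diff(areas)
        assert (diffs > 0).all() if increasing else (diffs < 0).all()

    def test_sign_symmetry_of_evolution(self):
        phi0 = _signed_distance_disk((64, 64), (32, 32), 18.0)
        g = D.EdgeIndicator(np.ones((64, 64)), 1.5)
        p = D.DRLSEParams(lam=0.0, early_stop=False)
        fwd = D.evolve(D.LevelSetField(phi0.copy()), g, p, alpha=3.0, n_iter=50).phi
        mirrored = D.evolve(D.LevelSetField(-phi0.copy()), g, p, alpha=-3.0, n_iter=50).phi
        np.testing.assert_allclose(fwd, -mirrored, atol=1e-8)

    def test_energy_nonincreasing_on_disk_fixture(self):
        gray = np.where(_disk((96, 96), (48, 48), 25), 0.3, 0.9)
        g = D.edge_indicator(_fusion(gray), 1.5)
        p = D.DRLSEParams(early_stop=False)
        phi = D.LevelSetField(np.where(_disk((96, 96), (48, 48), 35), -3.0, 3.0))
        energies = [D.energy(phi.phi, g.g, p, alpha=3.0)]
        for _ in range(20):
            phi = D.evolve(phi, g, p, alpha=3.0, n_iter=10)
            energies.append(D.energy(phi.phi, g.g, p, alpha=3.0))
        assert (np.diff(energies) <= 1e-6).all()

    def test_edge_convergence_on_sharp_disk(self):
        shape, center, radius = (128, 128), (64, 64), 35.0
        disk = _disk(shape, center, radius)
        g = D.edge_indicator(_fusion(np.where(disk, 0.3, 0.9)), 1.5)
        rows, cols = np.nonzero(disk)
        region = InitialRegion(mask=disk,
                               bbox=(rows.min(), cols.min(), rows.max() + 1, cols.max() + 1),
                               area_fraction=disk.mean())
        p = D.DRLSEParams()
        phi0 = D.init_lsf(region, shape, margin_px=10)
        phi = D.evolve(phi0, g, p, alpha=D.choose_alpha(region, p))
        mask = D.extract_mask(phi)
        from hkls.evaluate import boundary_points
        bp = boundary_points(mask).astype(float)
        err = np.abs(np.hypot(bp[:, 0] - center[0], bp[:, 1] - center[1]) - radius)
        assert err.mean() <= 1.5
        inter = (mask & disk).sum()
        assert 2 * inter / (mask.sum() + disk.sum()) >= 0.95

    def test_unstable_parameter_combination_rejected(self):
        with pytest.raises(ValidationError):
            D.DRLSEParams(mu=0.05, dt=8.0)  # mu*dt = 0.4 >= 0.25


class TestExtractMask:
    def test_constant_fields(self):
        assert not D.extract_mask(np.full((8, 8), 3.0)).any()
        assert D.extract_mask(np.full((8, 8), -3.0)).all()

    def test_linear_ramp_boundary_column(self):
        w = 101
        phi = np.tile(np.linspace(-3.0, 3.0, w), (5, 1))
        mask = D.extract_mask(phi, threshold_8bit=80, c0=3.0)
        # hand-solved affine map: keep phi < 3*(1 - 2*80/255)
        threshold_phi = 3.0 * (1 - 2 * 80 / 255)
        expect_cols = np.nonzero(phi[0] < threshold_phi)[0]
        np.testing.assert_array_equal(np.nonzero(mask[0])[0], expect_cols)
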