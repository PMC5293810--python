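"""Frame discard, Gaussian smoothing, nuisance regression, band-pass."""

import numpy as np
import pytest

from midfc.denoise import (
    bandpass,
    build_nuisance,
    drop_initial_frames,
    gaussian_smooth,
    regress_nuisance,
)

from conftest import make_bold


def motion_for(series):
    return np.zeros((series.n_timepoints, 6))


class TestDropInitialFrames:
    def test_shortens_by_five(self, rng):
        bold = make_bold(rng.standard_normal((4, 4, 4, 225)))
        out, mot = drop_initial_frames(bold, motion_for(bold), n=5)
        assert out.n_timepoints == 220
        assert mot.shape[0] == 220

    def test_series_and_motion_stay_in_sync(self, rng):
        bold = make_bold(rng.standard_normal((4, 4, 4, 30)))
        motion = rng.standard_normal((30, 6))
        out, mot = drop_initial_frames(bold, motion, n=7)
        assert out.n_timepoints == mot.shape[0]
        np.testing.assert_array_equal(mot, motion[7:])
        np.testing.assert_array_equal(out.data, bold.data[..., 7:])

    def test_zero_is_identity(self, small_series):
        out, _ = drop_initial_frames(small_series, motion_for(small_series), n=0)
        np.testing.assert_array_equal(out.data, small_series.data)

    def test_too_short_series_rejected(self, rng):
        bold = make_bold(rng.standard_normal((4, 4, 4, 5)))
        with pytest.raises(ValueError, match="drop"):
            drop_initial_frames(bold, motion_for(bold), n=5)


class TestGaussianSmooth:
    def test_constant_frame_unchanged(self):
        bold = make_bold(np.full((8, 8, 8, 3), 7.0))
        out = gaussian_smooth(bold, fwhm=4.0)
        np.testing.assert_allclose(out.data, 7.0, rtol=1e-12)

    def test_impulse_profile_matches_gaussian(self):
        # sigma = 4 mm / 2.3548 = 1.699 mm = 0.566 voxels at 3 mm; the
        # sampled-kernel ratio at +-1 voxel is exp(-1 / (2 sigma_vox^2))
        data = np.zeros((11, 11, 11, 1))
        data[5, 5, 5, 0] = 1.0
        out = gaussian_smooth(make_bold(data), fwhm=4.0).data[..., 0]
        sigma_vox = 4.0 / (2 * np.sqrt(2 * np.log(2))) / 3.0
        expect = np.exp(-1.0 / (2 * sigma_vox ** 2))
        assert out[6, 5, 5] / out[5, 5, 5] == pytest.approx(expect, rel=1e-6)
        assert out[5, 4, 5] / out[5, 5, 5] == pytest.approx(expect, rel=1e-6)

    def test_interior_impulse_mass_preserved(self):
        data = np.zeros((15, 15, 15, 1))
        data[7, 7, 7, 0] = 3.0
        out = gaussian_smooth(make_bold(data), fwhm=4.0)
        assert out.data.sum() == pytest.approx(3.0, rel=1e-9)

    def test_negative_fwhm_rejected(self, small_series):
        with pytest.raises(ValueError):
            gaussian_smooth(small_series, fwhm=-1.0)


def tissue_masks(shape):
    wb = np.ones(shape, bool)
    wm = np.zeros(shape, bool)
    wm[0] = True
    vent = np.zeros(shape, bool)
    vent[-1] = True
    return {"whole_brain": wb, "white_matter": wm, "ventricle": vent}


class TestBuildNuisance:
    def test_twelve_named_columns(self, small_series, rng):
        nuis = build_nuisance(small_series, tissue_masks(small_series.shape3),
                              rng.standard_normal((40, 6)))
        assert len(nuis.names) == 12
        assert nuis.names[:3] == ["whole_brain", "white_matter", "ventricle"]

    def test_constant_series_gives_zero_derivative(self):
        bold = make_bold(np.full((4, 4, 4, 20), 7.0))
        nuis = build_nuisance(bold, tissue_masks((4, 4, 4)), np.zeros((20, 6)))
        np.testing.assert_array_equal(nuis.frame["whole_brain_deriv"], 0.0)
        np.testing.assert_array_equal(nuis.frame["whole_brain"], 7.0)

    def test_derivative_of_linear_signal_is_constant(self):
        t = np.arange(20, dtype=float)
        data = np.broadcast_to(3.0 * t, (4, 4, 4, 20)).copy()
        nuis = build_nuisance(make_bold(data), tissue_masks((4, 4, 4)),
                              np.zeros((20, 6)))
        deriv = nuis.frame["whole_brain_deriv"].to_numpy()
        assert deriv[0] == 0.0
        np.testing.assert_allclose(deriv[1:], 3.0, rtol=1e-12)

    def test_empty_mask_named_in_error(self, small_series):
        masks = tissue_masks(small_series.shape3)
        masks["ventricle"] = np.zeros(small_series.shape3, bool)
        with pytest.raises(ValueError, match="ventricle"):
            build_nuisance(small_series, masks, np.zeros((40, 6)))

    def test_motion_derivative_switch(self, small_series, rng):
        nuis = build_nuisance(small_series, tissue_masks(small_series.shape3),
                              rng.standard_normal((40, 6)),
                              motion_derivatives=True)
        assert len(nuis.names) == 18


class TestRegressNuisance:
    def test_voxel_equal_to_regressor_has_zero_residual(self, rng):
        T = 40
        motion = rng.standard_normal((T, 6))
        data = 50.0 + rng.standard_normal((4, 4, 4, T))
        masks = tissue_masks((4, 4, 4))
        bold = make_bold(data)
        vent = bold.data[masks["ventricle"]].mean(axis=0)
        # voxel outside the ventricle mask set to an affine function of the
        # ventricle regressor: OLS must fit it exactly
        bold.data[2, 2, 2] = 3.0 * vent - 1.0
        nuis = build_nuisance(bold, masks, motion)
        out = regress_nuisance(bold, nuis)
        np.testing.assert_allclose(out.data[2, 2, 2], 0.0, atol=1e-8)

    def test_residuals_orthogonal_to_design(self, rng):
        T = 40
        motion = rng.standard_normal((T, 6))
        bold = make_bold(100 + rng.standard_normal((3, 3, 3, T)))
        nuis = build_nuisance(bold, tissue_masks((3, 3, 3)), motion)
        out = regress_nuisance(bold, nuis)
        resid = out.data.reshape(-1, T)
        X = np.column_stack([np.ones(T), nuis.matrix])
        assert np.max(np.abs(resid @ X)) < 1e-6

    def test_matches_normal_equations_oracle(self, rng):
        T, V = 20, 5
        flat = rng.standard_normal((V, T))
        X = rng.standard_normal((T, 3))
        bold = make_bold(flat.reshape(5, 1, 1, T))
        import pandas as pd

        from midfc.denoise import NuisanceSet
        nuis = NuisanceSet(pd.DataFrame(X, columns=list("abc")))
        out = regress_nuisance(bold, nuis).data.reshape(V, T)
        D = np.column_stack([np.ones(T), X])
        beta = np.linalg.solve(D.T @ D, D.T @ flat.T)
        oracle = flat - (D @ beta).T
        np.testing.assert_allclose(out, oracle, atol=1e-8)

    def test_idempotent(self, rng):
        T = 40
        motion = rng.standard_normal((T, 6))
        bold = make_bold(100 + rng.standard_normal((3, 3, 3, T)))
        nuis = build_nuisance(bold, tissue_masks((3, 3, 3)), motion)
        once = regress_nuisance(bold, nuis)
        nuis2 = build_nuisance(once, tissue_masks((3, 3, 3)), motion)
        # re-using the original design on residuals changes nothing
        twice = regress_nuisance(once, nuis)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-8)

    def test_rank_deficient_design_names_columns(self, rng):
        import pandas as pd

        from midfc.denoise import NuisanceSet
        T = 30
        x = rng.standard_normal(T)
        X = pd.DataFrame({"a": x, "b": 2.0 * x, "c": rng.standard_normal(T)})
        bold = make_bold(rng.standard_normal((2, 2, 2, T)))
        with pytest.raises(ValueError, match="b"):
            regress_nuisance(bold, NuisanceSet(X))


class TestBandpass:
    def make_sinusoid(self, freq, tr=2.0, n=300):
        t = np.arange(n) * tr
        x = np.sin(2 * np.pi * freq * t)
        return make_bold(np.broadcast_to(x, (2, 2, 2, n)).copy(), tr=tr)

    def test_passband_sinusoid_preserved(self):
        bold = self.make_sinusoid(0.04)
        out = bandpass(bold)
        mid = slice(50, 250)   # avoid edge transients
        ratio = (np.abs(out.data[0, 0, 0, mid]).max()
                 / np.abs(bold.data[0, 0, 0, mid]).max())
        assert ratio >= 0.95

    def test_stopband_sinusoid_suppressed(self):
        bold = self.make_sinusoid(0.2)
        out = bandpass(bold)
        mid = slice(50, 250)   # steady-state response, away from edges
        ratio = (np.abs(out.data[0, 0, 0, mid]).max()
                 / np.abs(bold.data[0, 0, 0, mid]).max())
        assert ratio <= 0.10

    def test_constant_series_removed(self):
        bold = make_bold(np.full((2, 2, 2, 200), 42.0))
        out = bandpass(bold)
        assert np.max(np.abs(out.data)) < 1e-8

    def test_linearity(self, rng):
        n = 200
        x = rng.standard_normal((2, 2, 2, n))
        y = rng.standard_normal((2, 2, 2, n))
        fx = bandpass(make_bold(x)).data
        fy = bandpass(make_bold(y)).data
        fxy = bandpass(make_bold(2.0 * x + 3.0 * y)).data
        np.testing.assert_allclose(fxy, 2.0 * fx + 3.0 * fy, atol=1e-10)

    def test_infeasible_band_mentions_nyquist(self):
        bold = make_bold(np.zeros((2, 2, 2, 50)), tr=10.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(bold, 0.009, 0.08)
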