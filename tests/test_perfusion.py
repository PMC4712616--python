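"""DSC perfusion chain: arrival, concentration, AIF, SVD deconvolution, maps."""

import numpy as np
import pytest
from scipy.linalg import toeplitz

from msquant.image import TimeSeriesImage, VolumeImage
from msquant.perfusion import (AifSelection, ArrivalNotFound, DscSeries,
                               aif_from_roi, detect_arrival, perfusion_maps,
                               select_aif, signal_to_concentration,
                               svd_deconvolve, volume_mean_series)
from msquant.phantom import AifParams, gamma_variate_aif


def _series(data, tr=1.0, te=0.03, mask=None):
    data = np.asarray(data, dtype=float)
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=np.uint8)
    return DscSeries(TimeSeriesImage(data, np.eye(4), tr_s=tr, te_s=te),
                     VolumeImage(mask, np.eye(4)))


class TestVolumeMeanSeries:
    def test_constant_data(self):
        dsc = _series(np.full((3, 3, 3, 10), 100.0))
        np.testing.assert_array_equal(volume_mean_series(dsc), 100.0)

    def test_single_voxel_mask_returns_that_voxel(self):
        data = np.zeros((3, 3, 3, 10))
        data[1, 2, 0] = np.arange(10)
        mask = np.zeros((3, 3, 3), dtype=np.uint8)
        mask[1, 2, 0] = 1
        dsc = _series(data, mask=mask)
        np.testing.assert_array_equal(volume_mean_series(dsc), np.arange(10))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            volume_mean_series(_series(np.zeros((2, 2, 2, 8)),
                                       mask=np.zeros((2, 2, 2), dtype=np.uint8)))

    def test_phantom_curve_drops_after_arrival(self, noiseless_bundle):
        b = noiseless_bundle
        curve = volume_mean_series(DscSeries(b.dsc, b.brain_mask))
        assert curve[b.truth_arrival + 3] < curve[0]
        np.testing.assert_allclose(curve[:b.truth_arrival], curve[0])


class TestDetectArrival:
    def test_step_series(self):
        series = [100.0] * 10 + [60.0, 60.0]
        assert detect_arrival(np.array(series), fraction=0.5) == 10

    def test_flat_series_signals_failure(self):
        with pytest.raises(ArrivalNotFound):
            detect_arrival(np.full(12, 7.0), fraction=0.1)

    def test_subthreshold_wiggle_signals_failure(self):
        series = np.array([100.0, 100.2, 99.8, 100.1, 100.0, 99.9, 100.15, 100.0])
        with pytest.raises(ArrivalNotFound):
            detect_arrival(series, fraction=0.9)

    def test_phantom_mean_curve_recovers_truth(self, noiseless_bundle):
        b = noiseless_bundle
        curve = volume_mean_series(DscSeries(b.dsc, b.brain_mask))
        assert detect_arrival(curve, fraction=0.1) == b.truth_arrival

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            detect_arrival(np.arange(10.0), fraction=1.5)


class TestSignalToConcentration:
    def test_steady_signal_gives_zero(self):
        dsc = _series(np.full((2, 2, 2, 12), 80.0))
        np.testing.assert_array_equal(signal_to_concentration(dsc, 6), 0.0)

    def test_closed_form_single_drop(self):
        data = np.full((2, 2, 2, 12), 100.0)
        data[..., 8] = 100.0 * np.exp(-1)
        conc = signal_to_concentration(_series(data, te=0.05), arrival_index=6)
        np.testing.assert_allclose(conc[..., 8], 20.0, rtol=1e-12)
        np.testing.assert_allclose(conc[..., :8], 0.0, atol=1e-12)

    def test_baseline_skip_discards_initial_volumes(self):
        data = np.full((2, 2, 2, 12), 100.0)
        data[..., 0] = 500.0  # non-steady-state first volume
        conc = signal_to_concentration(_series(data), arrival_index=6, skip=1)
        np.testing.assert_allclose(conc[..., 1:6], 0.0, atol=1e-12)

    def test_arrival_too_early_rejected(self):
        with pytest.raises(ValueError):
            signal_to_concentration(_series(np.ones((2, 2, 2, 12))), arrival_index=1)

    def test_phantom_concentration_matches_forward_model(self, noiseless_bundle):
        b = noiseless_bundle
        dsc = DscSeries(b.dsc, b.brain_mask)
        conc = signal_to_concentration(dsc, b.truth_arrival, skip=1)
        art = np.argwhere(b.truth_artery.data)[0]
        truth = gamma_variate_aif(b.spec.aif_params, dsc.series.times_s)
        np.testing.assert_allclose(conc[tuple(art)], truth, atol=1e-9)


class TestSelectAif:
    def test_phantom_arterial_region_found(self, noiseless_bundle):
        b = noiseless_bundle
        dsc = DscSeries(b.dsc, b.brain_mask)
        conc = signal_to_concentration(dsc, b.truth_arrival)
        sel = select_aif(conc, b.brain_mask, n_voxels=10)
        in_artery = sum(b.truth_artery.data[v] == 1 for v in sel.voxels)
        assert in_artery / len(sel.voxels) >= 0.9

    def test_single_candidate_equals_best_voxel_curve(self, noiseless_bundle):
        b = noiseless_bundle
        dsc = DscSeries(b.dsc, b.brain_mask)
        conc = signal_to_concentration(dsc, b.truth_arrival)
        sel = select_aif(conc, b.brain_mask, n_voxels=1)
        np.testing.assert_array_equal(sel.curve, conc[sel.voxels[0]])

    def test_manual_override_roi(self):
        conc = np.zeros((3, 3, 3, 10))
        conc[0, 0, 0] = np.arange(10)
        conc[1, 1, 1] = 2 * np.arange(10)
        sel = aif_from_roi(conc, [(0, 0, 0), (1, 1, 1)])
        assert not sel.automatic
        np.testing.assert_allclose(sel.curve, 1.5 * np.arange(10))

    def test_no_positive_peak_fails(self):
        conc = np.zeros((2, 2, 2, 10))
        with pytest.raises(ValueError):
            select_aif(conc, VolumeImage(np.ones((2, 2, 2), np.uint8), np.eye(4)))


def _toeplitz_forward(aif, k, tr):
    a = tr * toeplitz(aif, np.zeros(len(aif)))
    return a @ k


class TestSvdDeconvolve:
    def setup_method(self):
        self.times = np.arange(40.0)
        self.aif = gamma_variate_aif(AifParams(t0_s=5.0, alpha=1.0, beta_s=1.5,
                                               amplitude=4.0), self.times)

    def test_identity_deconvolution_of_impulse(self):
        delta = np.zeros(40)
        delta[0] = 1.0
        c = _toeplitz_forward(self.aif, delta, 1.0)
        k = svd_deconvolve(c, self.aif, tr_s=1.0, svd_threshold=0.0)
        assert np.argmax(k) == 0
        np.testing.assert_allclose(k, delta, atol=1e-6)

    def test_zero_tissue_curve_gives_zero_residue(self):
        k = svd_deconvolve(np.zeros(40), self.aif, tr_s=1.0, svd_threshold=0.0)
        np.testing.assert_allclose(k, 0.0, atol=1e-12)

    def test_exponential_residue_peak_recovers_cbf(self):
        cbf, mtt = 0.01, 4.0
        k_true = cbf * np.exp(-self.times / mtt)
        c = _toeplitz_forward(self.aif, k_true, 1.0)
        k = svd_deconvolve(c, self.aif, tr_s=1.0, svd_threshold=0.01)
        assert abs(k.max() - cbf) / cbf < 0.05

    def test_all_zero_aif_rejected(self):
        with pytest.raises(ValueError):
            svd_deconvolve(np.ones(40), np.zeros(40), tr_s=1.0)

    def test_full_truncation_rejected(self):
        with pytest.raises(ValueError):
            svd_deconvolve(np.ones(40), self.aif, tr_s=1.0, svd_threshold=2.0)


class TestPerfusionMaps:
    def _aif(self, n=40):
        times = np.arange(float(n))
        curve = gamma_variate_aif(AifParams(t0_s=5.0, alpha=1.0, beta_s=1.5,
                                            amplitude=4.0), times)
        return AifSelection(curve=curve, voxels=[(0, 0, 0)])

    def _maps(self, conc_scale=1.0, aif_scale=1.0):
        aif = self._aif()
        conc = np.zeros((2, 2, 2, 40))
        conc[..., :] = 0.04 * aif.curve * conc_scale          # scaled-AIF voxels
        mask = VolumeImage(np.ones((2, 2, 2), np.uint8), np.eye(4))
        scaled = AifSelection(curve=aif.curve * aif_scale, voxels=aif.voxels)
        return perfusion_maps(conc, scaled, tr_s=1.0, brain_mask=mask,
                              svd_threshold=0.05)

    def test_scaled_aif_voxel_cbv_exact(self):
        res = self._maps()
        np.testing.assert_allclose(res.cbv.data, 0.04, rtol=1e-12)

    def test_central_volume_identity(self):
        res = self._maps()
        cbf, cbv, mtt = (np.asarray(m.data, dtype=float)
                         for m in (res.cbf, res.cbv, res.mtt))
        sel = cbf > 0
        np.testing.assert_allclose(mtt[sel], cbv[sel] / cbf[sel], rtol=1e-6)

    def test_tissue_scaling_moves_cbf_cbv_not_mtt(self):
        base, scaled = self._maps(), self._maps(conc_scale=3.0)
        np.testing.assert_allclose(scaled.cbf.data, 3 * base.cbf.data, rtol=1e-6)
        np.testing.assert_allclose(scaled.cbv.data, 3 * base.cbv.data, rtol=1e-6)
        np.testing.assert_allclose(scaled.mtt.data, base.mtt.data, rtol=1e-6)

    def test_aif_scaling_inverts_cbf_cbv(self):
        base, scaled = self._maps(), self._maps(aif_scale=2.0)
        np.testing.assert_allclose(scaled.cbf.data, base.cbf.data / 2, rtol=1e-6)
        np.testing.assert_allclose(scaled.cbv.data, base.cbv.data / 2, rtol=1e-6)

    def test_nonpositive_aif_integral_rejected(self):
        aif = AifSelection(curve=np.zeros(40), voxels=[(0, 0, 0)])
        with pytest.raises(ValueError):
            perfusion_maps(np.zeros((2, 2, 2, 40)), aif, 1.0,
                           VolumeImage(np.ones((2, 2, 2), np.uint8), np.eye(4)))


def test_recovery_bias_decreases_with_noise(noiseless_bundle):
    """Monte-Carlo: CBF error shrinks monotonically as curve noise -> 0."""
    b = noiseless_bundle
    times = np.arange(60.0)
    aif_curve = gamma_variate_aif(b.spec.aif_params, times)
    cbf, mtt = 0.01, 4.0
    from msquant.phantom import continuous_tissue_curve
    c_true = continuous_tissue_curve(b.spec.aif_params, cbf, mtt, times, 1.0)
    errors = []
    for sd in (0.0, 0.005, 0.02):
        errs = []
        for seed in range(25):
            rng = np.random.default_rng(seed)
            c = c_true + rng.normal(0, sd, c_true.shape)
            k = svd_deconvolve(c, aif_curve, tr_s=1.0, svd_threshold=0.05)
            errs.append(abs(k.max() - cbf) / cbf)
        errors.append(np.mean(errs))
    assert errors[0] <= errors[1] <= errors[2]
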