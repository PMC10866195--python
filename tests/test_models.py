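"""Forward models: Gaussian RF, temporal kernels, CST / DN-ST / Spatial."""

import numpy as np
import pytest
from scipy.signal import fftconvolve

import stprf
from stprf import models
from stprf.exceptions import ParameterError, ShapeError
from stprf.models import (
    CSTParams,
    DNSTParams,
    SpatialParams,
    _gamma_kernel,
    gaussian_rf,
    predict_cst,
    predict_dnst,
    predict_spatial,
    spatial_drive,
    sustained_irf,
    transient_irfs,
)

GEOM = stprf.BarGeometry.spatiotemporal()


def pulse_frames(n_frames, on, full=True, rng=None):
    """Full-field (or random) binary frame stack with a given on-mask."""
    fr = np.zeros((n_frames, 61, 61), dtype=np.uint8)
    if full:
        fr[on] = 1
    else:
        fr[on] = (rng.random((61, 61)) < 0.5)
    return fr


class TestGaussianRF:
    def test_closed_form_values(self):
        grid = (np.array([[0.0, 1.0]]), np.array([[0.0, 0.0]]))
        rf = gaussian_rf(SpatialParams(0.0, 0.0, 1.0), grid)
        assert rf[0, 0] == pytest.approx(1.0)          # center value
        assert rf[0, 1] == pytest.approx(np.exp(-0.5))  # one sigma away

    def test_grid_sum_matches_gaussian_integral(self):
        p = SpatialParams(0.5, -0.5, 1.3)
        rf = gaussian_rf(p, GEOM)
        expected = 2 * np.pi * p.sigma**2 / GEOM.pixel_size_deg**2
        assert rf.sum() == pytest.approx(expected, rel=1e-3)

    def test_sigma_must_be_positive(self):
        with pytest.raises(ParameterError):
            SpatialParams(0.0, 0.0, -1.0)


class TestSpatialDrive:
    def test_off_and_full_field(self):
        rf = gaussian_rf(SpatialParams(0, 0, 2.0), GEOM)
        frames = pulse_frames(4, slice(2, 4))
        d = spatial_drive(frames, rf)
        assert d[0] == d[1] == 0.0
        assert d[2] == pytest.approx(rf.sum())

    def test_grid_mismatch_raises(self):
        rf = np.ones((31, 31))
        with pytest.raises(ShapeError):
            spatial_drive(np.zeros((2, 61, 61)), rf)

    def test_full_vs_half_coverage_ratio(self):
        """A bar covering a tiny pRF drives ~2x the response of one
        covering half of it (brute-force pixel sums)."""
        X, _ = GEOM.pixel_grid()
        # pRF centered midway between two pixel columns so a half-plane
        # edge through that point splits its mass evenly
        p = SpatialParams(GEOM.pixel_size_deg / 2, 0.0, 0.15)
        rf = gaussian_rf(p, GEOM)
        full = np.ones((1, 61, 61), dtype=np.uint8)
        half = (X > 0.1).astype(np.uint8)[None]
        ratio = spatial_drive(full, rf)[0] / spatial_drive(half, rf)[0]
        assert ratio == pytest.approx(2.0, rel=0.05)


class TestTemporalKernels:
    @pytest.mark.parametrize("tau", [5.0, 20.0, 50.0])
    def test_sustained_gamma_peaks_at_8tau(self, tau):
        h = sustained_irf(tau)
        assert np.argmax(h) + 0.5 == pytest.approx(8 * tau, abs=1.0)
        assert (h >= 0).all()
        assert h.sum() == pytest.approx(1.0, abs=1e-6)
        assert h[0] < h.max() * 1e-3

    @pytest.mark.parametrize("tau", [5.0, 30.0, 100.0])
    def test_transient_is_balanced_biphasic(self, tau):
        h_on, h_off = transient_irfs(tau)
        assert abs(h_on.sum()) < 1e-6          # unit-area lobes cancel
        assert np.array_equal(h_off, -h_on)
        assert h_on.max() > 0 and h_on.min() < 0

    def test_transient_peaks_before_sustained(self):
        for tau in (5.0, 40.0):
            h1 = sustained_irf(tau)
            h_on, _ = transient_irfs(tau)
            assert np.argmax(h_on) < np.argmax(h1)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ParameterError):
            sustained_irf(-3.0)


class TestPredictCST:
    def test_zero_stimulus_zero_channels(self):
        ntc = predict_cst(np.zeros((50, 61, 61), dtype=np.uint8),
                          CSTParams(SpatialParams(0, 0, 1), 10.0, 0.5))
        assert not ntc.channels.any()
        assert ntc.channels.shape == (3, 50)

    def test_matches_direct_convolution_oracle(self):
        """Channels equal ReLU(kernel * drive)^n computed independently."""
        rng = np.random.default_rng(3)
        frames = pulse_frames(300, rng.random(300) < 0.3, full=False, rng=rng)
        params = CSTParams(SpatialParams(1.0, -2.0, 1.5), 12.0, 0.62)
        ntc = predict_cst(frames, params)
        rf = gaussian_rf(params.spatial, GEOM)
        d = np.tensordot(frames, rf, axes=([1, 2], [0, 1]))
        h1 = _gamma_kernel(12.0, 1.0, 9.0)
        h2 = (np.pad(_gamma_kernel(12.0, 1.0, 9.0),
                     (0, len(_gamma_kernel(12.0, 1.33, 10.0))
                      - len(_gamma_kernel(12.0, 1.0, 9.0))))
              - _gamma_kernel(12.0, 1.33, 10.0))
        r1 = fftconvolve(d, h1)[:300]
        r2 = fftconvolve(d, h2)[:300]
        assert np.allclose(ntc.channels[0], np.maximum(r1, 0) ** 0.62,
                           atol=1e-8)
        assert np.allclose(ntc.channels[1], np.maximum(r2, 0) ** 0.62,
                           atol=1e-8)
        assert np.allclose(ntc.channels[2], np.maximum(-r2, 0) ** 0.62,
                           atol=1e-8)

    def test_power_law_compression_is_exact(self):
        """Scaling the drive by c scales every channel by c^n exactly."""
        h1 = _gamma_kernel(15.0, 1.0, 9.0)
        rng = np.random.default_rng(0)
        d = rng.random(400)
        n, c = 0.37, 3.7
        # direct convolution of nonnegative terms: no FFT rounding noise
        p1 = np.maximum(np.convolve(d, h1)[:400], 0) ** n
        p2 = np.maximum(np.convolve(c * d, h1)[:400], 0) ** n
        assert np.allclose(p2, c**n * p1, rtol=1e-12, atol=0)

    def test_pulse_drives_onset_and_offset_channels(self):
        frames = pulse_frames(400, slice(50, 60))     # 100 ms pulse
        params = CSTParams(SpatialParams(0, 0, 2.0), 8.0, 1.0)
        ntc = predict_cst(frames, params)
        on_peak = np.argmax(ntc.channels[1])
        off_peak = np.argmax(ntc.channels[2])
        assert ntc.channels[1].max() > 0 and ntc.channels[2].max() > 0
        # onset response follows the onset; offset response trails it
        assert 50 < on_peak < off_peak
        # before the pulse ends plus the kernel's rise, no offset response
        assert ntc.channels[2][:on_peak].max() < 1e-3 * ntc.channels[2].max()

    def test_n_identity_when_one(self):
        frames = pulse_frames(200, slice(20, 120))
        params = CSTParams(SpatialParams(0, 0, 2.0), 8.0, 1.0)
        ntc = predict_cst(frames, params)
        rf = gaussian_rf(params.spatial, GEOM)
        d = np.tensordot(frames, rf, axes=([1, 2], [0, 1]))
        r1 = fftconvolve(d, _gamma_kernel(8.0, 1.0, 9.0))[:200]
        assert np.allclose(ntc.channels[0], r1, atol=1e-9)

    def test_exponent_bounds_enforced(self):
        with pytest.raises(ParameterError):
            CSTParams(SpatialParams(0, 0, 1), 10.0, 1.5)
        with pytest.raises(ParameterError):
            CSTParams(SpatialParams(0, 0, 1), -1.0, 0.5)


class TestPredictDNST:
    PARAMS = DNSTParams(SpatialParams(0, 0, 2.0), tau1=0.05, tau2=0.1,
                        sigma_dn=0.1, n_dn=2.0)

    def test_zero_stimulus(self):
        ntc = predict_dnst(np.zeros((50, 61, 61), dtype=np.uint8), self.PARAMS)
        assert not ntc.channels.any()

    def test_temporal_subadditivity(self):
        """One long pulse yields less total response than the same on-time
        split into brief pulses."""
        total_on = 80
        long_fr = pulse_frames(600, slice(0, total_on))
        split_on = np.zeros(600, bool)
        for k in range(8):
            split_on[k * 60:k * 60 + 10] = True     # 8 x 100 ms
        split_fr = pulse_frames(600, split_on)
        long_sum = predict_dnst(long_fr, self.PARAMS).channels.sum()
        split_sum = predict_dnst(split_fr, self.PARAMS).channels.sum()
        assert long_sum < split_sum

    def test_large_semisaturation_linearizes(self):
        """sigma_dn >> pool with n=1 reduces to |r| / sigma_dn."""
        params = DNSTParams(SpatialParams(0, 0, 2.0), 0.05, 0.1,
                            sigma_dn=1e4, n_dn=1.0)
        rng = np.random.default_rng(1)
        frames = pulse_frames(300, rng.random(300) < 0.4)
        p = predict_dnst(frames, params).channels[0]
        rf = gaussian_rf(params.spatial, GEOM)
        d = np.tensordot(frames, rf, axes=([1, 2], [0, 1])) / rf.sum()
        r = fftconvolve(d, models.dnst_irf(0.05))[:300]
        assert np.allclose(p, np.abs(r) / 1e4, rtol=1e-3)

    def test_output_nonnegative(self):
        rng = np.random.default_rng(2)
        frames = pulse_frames(200, rng.random(200) < 0.5)
        assert (predict_dnst(frames, self.PARAMS).channels >= 0).all()

    def test_parameter_domain(self):
        with pytest.raises(ParameterError):
            DNSTParams(SpatialParams(0, 0, 1), -0.1, 0.1, 0.1, 2.0)


class TestPredictSpatial:
    def test_equals_drive_and_linear(self):
        frames = pulse_frames(100, slice(10, 30))
        p = SpatialParams(1.0, 1.0, 1.5)
        ntc = predict_spatial(frames, p)
        rf = gaussian_rf(p, GEOM)
        assert np.allclose(ntc.channels[0],
                           np.tensordot(frames, rf, axes=([1, 2], [0, 1])))
        # the drive is additive over on-pixels
        one = np.zeros((1, 61, 61), np.uint8)
        one[0, 30, 28] = 1
        other = np.zeros_like(one)
        other[0, 30, 32] = 1
        both = one | other
        rf0 = gaussian_rf(SpatialParams(-0.2, 0.0, 2.0), GEOM)
        assert spatial_drive(both, rf0)[0] == pytest.approx(
            spatial_drive(one, rf0)[0] + spatial_drive(other, rf0)[0]
        )


class TestSharedInvariants:
    def test_time_shift_equivariance(self):
        rng = np.random.default_rng(4)
        on = rng.random(200) < 0.3
        base = pulse_frames(260, np.concatenate([on, np.zeros(60, bool)]))
        shifted = pulse_frames(260, np.concatenate([np.zeros(30, bool), on,
                                                    np.zeros(30, bool)]))
        cst = CSTParams(SpatialParams(0, 0, 2.0), 6.0, 0.5)
        a = predict_cst(base, cst).channels
        b = predict_cst(shifted, cst).channels
        # compression amplifies FFT rounding noise near zero crossings,
        # hence the absolute tolerance
        assert np.allclose(a[:, :200], b[:, 30:230], atol=1e-5)
        dn = DNSTParams(SpatialParams(0, 0, 2.0), 0.05, 0.1, 0.1, 2.0)
        a = predict_dnst(base, dn).channels
        b = predict_dnst(shifted, dn).channels
        assert np.allclose(a[:, :200], b[:, 30:230], atol=1e-5)

    def test_models_localize_same_sweep_positions(self, default_hrf_kernel):
        """With shared spatial parameters, all models peak when the bar
        crosses the pRF, i.e., in the same slot of each sweep."""
        from stprf._engine import ModelEngine

        seq = stprf.spatiotemporal_sequence(n_runs=1, seed=2)
        sp = SpatialParams(6.0, 0.0, 1.5)
        peaks = {}
        for kind, theta in [
            ("spatial", [6.0, 0.0, 1.5]),
            ("cst", [6.0, 0.0, 1.5, 20.0, 0.5]),
            ("dnst", [6.0, 0.0, 1.5, 0.05, 0.1, 0.1, 2.0]),
        ]:
            eng = ModelEngine(seq, kind, default_hrf_kernel)
            reg = eng.regressors(np.array(theta))
            bold = reg.sum(axis=0)
            # first sweep (angle 0): 45 s of data
            peaks[kind] = np.argmax(bold[:45])
        spread = max(peaks.values()) - min(peaks.values())
        assert spread <= 6          # within ~one 5 s bar slot

    def test_engine_matches_reference_pipeline(self, spatio_seq2,
                                               default_hrf_kernel):
        """The factored solver engine reproduces the naive
        predict -> HRF-convolve -> downsample pipeline."""
        from stprf._engine import ModelEngine
        from stprf.hrf import bold_predictors

        cases = [
            ("spatial", SpatialParams(2.0, -1.5, 1.2)),
            ("cst", CSTParams(SpatialParams(2.0, -1.5, 1.2), 33.0, 0.41)),
            ("dnst", DNSTParams(SpatialParams(2.0, -1.5, 1.2), 0.21, 0.44,
                                0.07, 2.9)),
        ]
        for kind, params in cases:
            ntc = models.predict_neural(spatio_seq2, params)
            ref = bold_predictors(ntc, default_hrf_kernel,
                                  spatio_seq2.run_breaks)
            eng = ModelEngine(spatio_seq2, kind, default_hrf_kernel)
            d = models.params_to_dict(params)
            theta = np.array(
                [d[k] for k in models.free_param_names(kind)]
            )
            got = eng.regressors(theta)
            scale = np.max(np.abs(ref))
            assert np.max(np.abs(ref - got)) < 1e-5 * scale
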