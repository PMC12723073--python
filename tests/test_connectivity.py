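import numpy as np
import pytest

from tmsnet.connectivity import (
    BANDS,
    DELTA,
    POSTSTIMULUS,
    PRESTIMULUS,
    AnalysisWindow,
    BandInvalidError,
    BandSpec,
    ConnectivityMatrix,
    band_window_average,
    build_connectivity,
    ciplv,
    connectivity_suite,
    matrices_from_spectrum,
    pairwise_mean_phasor,
    plv,
)
from tmsnet.synthetic import generate_cohort, null_config
from tmsnet.wavelet import WaveletParams, coi_for, cwt, default_freq_grid

CHANCE_60 = np.sqrt(np.pi / (4 * 60))


def _phasor_stack(phases):
    """(trials, scales, times) coefficients from a (trials,) phase list."""
    return np.exp(1j * np.asarray(phases))[:, None, None] * np.ones((1, 2, 3))


class TestPlv:
    def test_identical_locking_gives_one(self):
        x = _phasor_stack([0.3, 1.1, -2.0, 0.9])
        y = x * np.exp(-1j * 0.7)  # constant lag
        np.testing.assert_allclose(plv(x, y), 1.0, atol=1e-12)

    def test_opposite_phasors_cancel(self):
        x = _phasor_stack([0.0, 0.0])
        y = _phasor_stack([0.0, np.pi])
        np.testing.assert_allclose(plv(x, y), 0.0, atol=1e-12)

    def test_known_three_trial_value(self):
        # dphi = 0, pi/2, -pi/2 -> mean phasor (1 + i - i)/3 = 1/3
        x = _phasor_stack([0.0, np.pi / 2, -np.pi / 2])
        y = _phasor_stack([0.0, 0.0, 0.0])
        np.testing.assert_allclose(plv(x, y), 1.0 / 3.0, atol=1e-12)

    def test_amplitude_invariance(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 8)
        x = _phasor_stack(ph)
        y = _phasor_stack(rng.uniform(-np.pi, np.pi, 8))
        amps = rng.uniform(0.1, 10.0, x.shape)
        np.testing.assert_allclose(plv(x * amps, y), plv(x, y), atol=1e-12)

    def test_zero_coefficient_contributes_zero_phasor(self):
        x = _phasor_stack([0.0, 0.0])
        x[1] = 0.0  # dead cell in one trial
        y = _phasor_stack([0.0, 0.0])
        np.testing.assert_allclose(plv(x, y), 0.5, atol=1e-12)

    def test_chance_level_60_trials_monte_carlo(self, rng):
        # E|mean of Nt uniform unit phasors| -> sqrt(pi / (4 Nt))
        reps = 2000
        ph = rng.uniform(-np.pi, np.pi, (reps, 60))
        r = np.abs(np.exp(1j * ph).mean(axis=1))
        assert abs(r.mean() - CHANCE_60) < 0.01

    def test_fewer_than_two_trials_rejected(self):
        x = _phasor_stack([0.0])
        with pytest.raises(ValueError, match="2 trials"):
            plv(x, x)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="share"):
            plv(_phasor_stack([0.0, 1.0]), _phasor_stack([0.0, 1.0, 2.0]))


class TestCiplv:
    def test_zero_lag_locking_gives_zero(self):
        x = _phasor_stack([0.2, 0.2, 0.2])
        np.testing.assert_allclose(ciplv(x, x), 0.0, atol=1e-12)

    def test_quarter_cycle_lag_gives_plus_minus_one(self):
        x = _phasor_stack([0.0, 0.0])
        y = x * np.exp(-1j * np.pi / 2)  # x leads y by pi/2
        np.testing.assert_allclose(ciplv(x, y), 1.0, atol=1e-9)
        np.testing.assert_allclose(ciplv(y, x), -1.0, atol=1e-9)

    def test_real_mean_phasor_of_magnitude_one_guarded(self):
        # dphi identically 0: Re(P) = 1, denominator 0 -> defined as 0
        x = _phasor_stack([0.0, 0.0, 0.0])
        y = _phasor_stack([0.0, 0.0, 0.0])
        assert np.all(np.isfinite(ciplv(x, y)))
        np.testing.assert_allclose(ciplv(x, y), 0.0)

    def test_bounded(self, rng):
        x = _phasor_stack(rng.uniform(-np.pi, np.pi, 20))
        y = _phasor_stack(rng.uniform(-np.pi, np.pi, 20))
        v = ciplv(x, y)
        assert np.all(v >= -1.0) and np.all(v <= 1.0)

    def test_time_mode_shape(self, rng):
        x = np.exp(1j * rng.uniform(-np.pi, np.pi, (5, 2, 30)))
        y = np.exp(1j * rng.uniform(-np.pi, np.pi, (5, 2, 30)))
        assert ciplv(x, y, mode="time").shape == (5, 2)

    def test_bad_mode_rejected(self):
        x = _phasor_stack([0.0, 1.0])
        with pytest.raises(ValueError, match="mode"):
            ciplv(x, x, mode="bands")

    def test_known_formula_value(self):
        # dphi = 0, pi/2 -> P = (1 + i)/2; ciPLV = 0.5 / sqrt(1 - 0.25)
        x = _phasor_stack([0.0, np.pi / 2])
        y = _phasor_stack([0.0, 0.0])
        np.testing.assert_allclose(
            ciplv(x, y), 0.5 / np.sqrt(0.75), atol=1e-9
        )


class TestBandWindowAverage:
    def test_loop_oracle(self, rng):
        freqs = default_freq_grid(4.0, 70.0, 6)
        vals = rng.uniform(0, 1, (len(freqs), 40))
        coi = rng.uniform(0, 1, vals.shape) > 0.3
        for band in BANDS.values():
            sel = band.member(freqs)
            cells = [
                vals[s, k]
                for s in range(len(freqs))
                for k in range(40)
                if sel[s] and coi[s, k]
            ]
            got = band_window_average(vals, band, coi, freqs, 1.0)
            assert got == pytest.approx(np.mean(cells), abs=1e-12)

    def test_masked_cells_do_not_contribute(self, rng):
        freqs = default_freq_grid(4.0, 70.0, 6)
        vals = rng.uniform(0, 1, (len(freqs), 40))
        coi = np.zeros(vals.shape, bool)
        coi[:, 10:20] = True
        poisoned = vals.copy()
        poisoned[:, :10] = 1e6
        a = band_window_average(vals, BANDS["alpha"], coi, freqs, 1.0)
        b = band_window_average(poisoned, BANDS["alpha"], coi, freqs, 1.0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_empty_valid_set_raises(self):
        freqs = default_freq_grid(4.0, 70.0, 6)
        vals = np.zeros((len(freqs), 10))
        coi = np.zeros(vals.shape, bool)
        with pytest.raises(BandInvalidError, match="alpha"):
            band_window_average(vals, BANDS["alpha"], coi, freqs, 0.3)

    def test_band_membership_edges(self):
        f = np.array([70.0, 30.0, 13.0, 8.0, 4.0])
        assert list(BANDS["alpha"].member(f)) == [False, False, False, True,
                                                  False]
        # topmost band is closed at 70
        assert list(BANDS["gamma"].member(f)) == [True, True, False, False,
                                                  False]
        assert list(BANDS["global"].member(f)) == [True] * 5


class TestPairwiseMeanPhasor:
    def test_matches_per_pair_estimators(self):
        rec = generate_cohort(
            null_config(seed=7, n_subjects=1, n_channels=4, n_trials=12)
        )[0]
        spec = cwt(rec, PRESTIMULUS, default_freq_grid(4.0, 70.0, 4),
                   WaveletParams(hop_s=0.02))
        p = pairwise_mean_phasor(spec)
        for x in range(4):
            for y in range(4):
                ref = plv(spec.coeffs[x], spec.coeffs[y])
                np.testing.assert_allclose(np.abs(p[x, y]), ref, atol=2e-4)
                if x == y:
                    continue  # Re(P)=1 guard behaviour covered in TestCiplv
                ref_ci = ciplv(spec.coeffs[x], spec.coeffs[y])
                got_ci = np.clip(
                    p[x, y].imag / np.sqrt(np.maximum(1 - p[x, y].real**2,
                                                      1e-12)),
                    -1, 1,
                )
                np.testing.assert_allclose(got_ci, ref_ci, atol=2e-3)

    def test_tiny_coefficients_stay_finite(self, rng):
        # magnitudes ~1e-20 underflow a naive float32 |.|^2 normalization;
        # regression for inf/NaN escaping the unit-phasor kernel
        rec = generate_cohort(
            null_config(seed=2, n_subjects=1, n_channels=3, n_trials=6)
        )[0]
        rec.data *= 1e-20
        spec = cwt(rec, PRESTIMULUS, default_freq_grid(8.0, 30.0, 3),
                   WaveletParams(hop_s=0.05))
        p = pairwise_mean_phasor(spec)
        assert np.isfinite(p).all()
        assert np.abs(p).max() <= 1.0 + 1e-5

    def test_hermitian(self):
        rec = generate_cohort(
            null_config(seed=8, n_subjects=1, n_channels=3, n_trials=6)
        )[0]
        spec = cwt(rec, PRESTIMULUS, default_freq_grid(8.0, 30.0, 3),
                   WaveletParams(hop_s=0.05))
        p = pairwise_mean_phasor(spec)
        np.testing.assert_allclose(p, np.conj(p.transpose(1, 0, 2, 3)),
                                   atol=1e-6)


class TestMatrices:
    def test_duplicated_channel_gives_plv_one(self):
        rec = generate_cohort(
            null_config(seed=9, n_subjects=1, n_channels=2, n_trials=10)
        )[0]
        rec.data[1] = rec.data[0]
        mat = build_connectivity(rec, PRESTIMULUS, "global", "plv",
                                 params=WaveletParams(hop_s=0.01))
        assert mat.weights[0, 1] == pytest.approx(1.0, abs=1e-5)

    def test_symmetry_diag_bounds(self, vc_suite):
        for mat in vc_suite.values():
            w = mat.weights
            np.testing.assert_allclose(w, w.T, atol=1e-12)
            np.testing.assert_array_equal(np.diag(w), 0.0)
            assert w.min() >= 0.0 and w.max() <= 1.0

    def test_volume_conduction_separation(self, vc_suite):
        # channels 0/1 are instantaneously mixed copies (zero lag); channels
        # 2/3 share a quarter-cycle-lagged alpha interaction
        plv_m = vc_suite[("prestimulus", "plv", "alpha")].weights
        ci_m = vc_suite[("prestimulus", "ciplv", "alpha")].weights
        assert plv_m[0, 1] > 0.9
        assert ci_m[0, 1] < 0.05
        assert plv_m[2, 3] > 0.9
        assert ci_m[2, 3] > 0.9

    def test_ciplv_not_above_plv(self, vc_suite):
        # |mean signed ciPLV| can exceed per-cell PLV only through the
        # denominator; in practice it stays at or below PLV + tolerance
        for band in BANDS:
            p = vc_suite[("prestimulus", "plv", band)].weights
            c = vc_suite[("prestimulus", "ciplv", band)].weights
            assert np.all(c <= p + 0.05)

    def test_suite_keys_and_reuse(self):
        rec = generate_cohort(
            null_config(seed=10, n_subjects=1, n_channels=3, n_trials=8)
        )[0]
        suite = connectivity_suite(
            rec,
            bands=("alpha", "global"),
            estimators=("plv", "ciplv"),
            freqs_hz=default_freq_grid(4.0, 70.0, 4),
            params=WaveletParams(hop_s=0.02),
        )
        assert set(suite) == {
            (w, e, b)
            for w in ("prestimulus", "poststimulus")
            for e in ("plv", "ciplv")
            for b in ("alpha", "global")
        }
        single = build_connectivity(
            rec, PRESTIMULUS, "alpha", "plv",
            freqs_hz=default_freq_grid(4.0, 70.0, 4),
            params=WaveletParams(hop_s=0.02),
        )
        np.testing.assert_allclose(
            suite[("prestimulus", "plv", "alpha")].weights, single.weights,
            atol=1e-12,
        )

    def test_asymmetric_weights_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            ConnectivityMatrix(
                weights=np.array([[0.0, 0.5], [0.4, 0.0]]),
                estimator="plv",
                band=BANDS["alpha"],
                window=PRESTIMULUS,
            )


class TestDeltaExclusion:
    def test_delta_invalid_in_poststimulus_window(self):
        rec = generate_cohort(
            null_config(seed=4, n_subjects=1, n_channels=2, n_trials=4)
        )[0]
        with pytest.raises(BandInvalidError, match="delta"):
            build_connectivity(
                rec, POSTSTIMULUS, DELTA, "plv",
                freqs_hz=default_freq_grid(2.0, 70.0, 6),
                params=WaveletParams(hop_s=0.01),
            )

    def test_delta_valid_in_prestimulus_window(self):
        rec = generate_cohort(
            null_config(seed=4, n_subjects=1, n_channels=2, n_trials=4)
        )[0]
        mat = build_connectivity(
            rec, PRESTIMULUS, DELTA, "plv",
            freqs_hz=default_freq_grid(2.0, 70.0, 6),
            params=WaveletParams(hop_s=0.01),
        )
        assert np.isfinite(mat.weights).all()

    def test_theta_valid_in_poststimulus_window(self):
        rec = generate_cohort(
            null_config(seed=4, n_subjects=1, n_channels=2, n_trials=4)
        )[0]
        mat = build_connectivity(rec, POSTSTIMULUS, "theta", "plv",
                                 params=WaveletParams(hop_s=0.01))
        assert np.isfinite(mat.weights).all()

    def test_window_lengths(self):
        assert PRESTIMULUS.length_s == pytest.approx(1.0)
        assert POSTSTIMULUS.length_s == pytest.approx(0.3)
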