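"""Phase assignment, response functions, and nuisance-design assembly."""

import numpy as np
import pytest
from scipy import stats

from physnoise import (
    EventTimes,
    PhysioRecording,
    RegressorSet,
    assemble_model,
    build_crp,
    cardiac_phase,
    default_crf,
    default_rrf,
    drift_regressors,
    fourier_expand,
    heart_rate_series,
    highpass_basis,
    hr_regressor,
    motion_regressors,
    respiratory_phase,
    rv_regressor,
    sliding_window_std,
)
from physnoise.regressors import PhaseSeries, _convolve_response

from conftest import timing_at


class TestCardiacPhase:
    @pytest.mark.parametrize(
        "beats, t, expected",
        [
            ([10.0, 11.0], 10.5, np.pi),  # interval midpoint
            ([10.0, 11.0], 10.0, 0.0),  # interval start
            ([0.0, 0.8, 2.0], 1.4, 2 * np.pi * (1.4 - 0.8) / (2.0 - 0.8)),
        ],
    )
    def test_linear_phase_within_interval(self, beats, t, expected):
        phase = cardiac_phase(EventTimes(np.array(beats), "beat"), timing_at([t]))
        assert phase.values[0] == pytest.approx(expected, abs=1e-12)

    def test_extrapolation_clamps_to_nearest_interval(self):
        beats = EventTimes(np.array([10.0, 11.0, 12.5]), "beat")
        phase = cardiac_phase(beats, timing_at([9.5, 13.0]))
        # before first beat: first interval extrapolated backwards, wrapped
        assert phase.values[0] == pytest.approx(np.pi, abs=1e-12)
        # after last beat: last interval (1.5 s) extrapolated forwards
        assert phase.values[1] == pytest.approx(2 * np.pi * 0.5 / 1.5, abs=1e-12)

    def test_phase_range_enforced(self):
        with pytest.raises(ValueError, match=r"\[0, 2\*pi\)"):
            PhaseSeries(np.array([7.0]), source="cardiac")


class TestRespiratoryPhase:
    @staticmethod
    def _sine_recording(duration=120.0, period=3.0, fs=100.0):
        t = np.arange(0, duration, 1 / fs)
        return PhysioRecording(
            sampling_rate=fs, respiratory=np.sin(2 * np.pi * t / period)
        ), t

    def test_monotone_advance_through_cycle(self):
        rec, _ = self._sine_recording()
        # sample one breath cycle densely, away from run edges
        ref = 30.0 + np.arange(0, 3.0, 0.1)
        phase = respiratory_phase(rec, timing_at(ref)).values
        unwrapped = np.unwrap(phase)
        assert np.all(np.diff(unwrapped) > -0.15)  # monotone modulo small binning steps
        assert unwrapped[-1] - unwrapped[0] == pytest.approx(2 * np.pi, rel=0.12)

    def test_constant_belt_rejected(self):
        rec = PhysioRecording(sampling_rate=100.0, respiratory=np.full(6000, 2.0))
        with pytest.raises(ValueError, match="respiratory phase undefined"):
            respiratory_phase(rec, timing_at([10.0, 20.0]))

    def test_triangular_belt_gives_uniform_phase_histogram(self):
        fs = 100.0
        t = np.arange(0, 1200, 1 / fs)
        belt = 2 * np.abs((t / 3.1) % 1 - 0.5)  # symmetric triangle, 3.1 s period
        rec = PhysioRecording(sampling_rate=fs, respiratory=belt)
        ref = np.arange(5.0, 1190.0, 2.0)
        phase = respiratory_phase(rec, timing_at(ref)).values
        counts, _ = np.histogram(phase, bins=10, range=(0, 2 * np.pi))
        assert stats.chisquare(counts).pvalue > 0.01


class TestFourierExpansion:
    def test_third_harmonic_gives_six_terms(self):
        phase = PhaseSeries(np.linspace(0, 6.0, 50), "cardiac")
        rs = fourier_expand(phase, n_harmonics=3)
        assert rs.n_regressors == 6
        assert np.all(np.abs(rs.matrix) <= 1.0)

    def test_zero_phase_columns(self):
        rs = fourier_expand(PhaseSeries(np.zeros(10), "respiratory"), 2)
        assert np.allclose(rs.matrix[:, 0::2], 0.0)  # sines
        assert np.allclose(rs.matrix[:, 1::2], 1.0)  # cosines

    def test_crp_has_12_columns_and_low_phase_crosstalk(self, physio_run):
        cfg, rec, truth = physio_run
        from physnoise import detect_cardiac_beats, uniform_slice_timing

        timing = uniform_slice_timing(cfg.volume_tr, cfg.n_slices, cfg.n_volumes, 0)
        crp = build_crp(detect_cardiac_beats(rec), rec, timing)
        assert crp.n_regressors == 12
        assert len(set(crp.labels)) == 12
        crp1 = build_crp(detect_cardiac_beats(rec), rec, timing, n_harmonics=1)
        assert crp1.n_regressors == 4

    def test_independent_phase_columns_nearly_orthogonal(self):
        rng = np.random.default_rng(5)
        n = 10_000
        cp = fourier_expand(PhaseSeries(rng.uniform(0, 2 * np.pi, n), "cardiac"), 3)
        rp = fourier_expand(PhaseSeries(rng.uniform(0, 2 * np.pi, n), "respiratory"), 3)
        m = np.hstack([cp.matrix, rp.matrix])
        corr = np.corrcoef(m.T)
        off = corr[~np.eye(12, dtype=bool)]
        assert np.max(np.abs(off)) < 0.05

    def test_periodic_physiology_gives_periodic_crp_columns(self):
        fs = 100.0
        t = np.arange(0, 120, 1 / fs)
        rec = PhysioRecording(sampling_rate=fs, respiratory=np.sin(2 * np.pi * t / 3.0))
        beats = EventTimes(np.arange(0.5, 119.0, 1.0), "beat")
        ref = np.arange(10.0, 110.0, 0.05)
        timing = timing_at(ref)
        card = fourier_expand(cardiac_phase(beats, timing), 3).matrix[:, 0]
        resp = fourier_expand(respiratory_phase(rec, timing), 3).matrix[:, 0]
        lag_card, lag_resp = int(1.0 / 0.05), int(3.0 / 0.05)
        assert np.corrcoef(card[:-lag_card], card[lag_card:])[0, 1] > 0.99
        assert np.corrcoef(resp[:-lag_resp], resp[lag_resp:])[0, 1] > 0.99


def brute_force_window_std(x, n_w):
    half = n_w // 2
    out = np.empty(x.size)
    for i in range(x.size):
        seg = x[max(i - half, 0): min(i - half + n_w, x.size)]
        out[i] = np.std(seg, ddof=1) if seg.size > 1 else 0.0
    return out


class TestSlidingWindowStd:
    def test_constant_series_is_zero(self):
        assert np.allclose(sliding_window_std(np.full(100, 7.0), fs=10.0), 0.0)

    def test_sinusoid_rms(self):
        fs, a = 50.0, 2.5
        t = np.arange(0, 60, 1 / fs)
        x = a * np.sin(2 * np.pi * t / 2.0)  # window of 6 s = 3 periods
        out = sliding_window_std(x, fs=fs, window=6.0)
        interior = out[int(5 * fs): -int(5 * fs)]
        assert np.allclose(interior, a / np.sqrt(2), rtol=0.01)

    def test_matches_brute_force_exactly(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(10, 200)
            fs = rng.choice([5.0, 10.0, 20.0])
            window = rng.uniform(0.5, 4.0)
            x = rng.normal(size=n)
            n_w = int(round(window * fs))
            if n_w < 2:
                continue
            expected = brute_force_window_std(x, n_w)
            np.testing.assert_array_equal(sliding_window_std(x, fs, window), expected)


class TestResponseFunctions:
    def test_rrf_peak_and_negative_lobe(self):
        rrf = default_rrf()
        t = np.arange(rrf.samples.size) * rrf.dt
        assert 2.5 < t[np.argmax(rrf.samples)] < 4.0
        assert rrf.samples.min() < 0 and t[np.argmin(rrf.samples)] > 8.0

    def test_crf_peak_and_undershoot_near_12s(self):
        crf = default_crf()
        t = np.arange(crf.samples.size) * crf.dt
        assert 2.0 < t[np.argmax(crf.samples)] < 6.0 and crf.samples.max() > 0
        assert crf.samples.min() < 0
        assert t[np.argmin(crf.samples)] == pytest.approx(12.0, abs=1.0)

    def test_duration_invariant(self):
        with pytest.raises(ValueError, match="30 s"):
            default_rrf(duration=10.0)


class TestRvHrRegressors:
    def test_constant_belt_gives_zero_rv(self):
        rec = PhysioRecording(sampling_rate=100.0, respiratory=np.full(30_000, 4.0))
        rv = rv_regressor(rec, timing_at(np.arange(10.0, 290.0, 2.0)))
        assert np.allclose(rv.matrix, 0.0)

    def test_convolution_impulse_reproduces_kernel(self):
        rrf = default_rrf()
        x = np.zeros(2000)
        dt = 0.05
        x[0] = 1.0 / dt  # unit-area impulse
        out = _convolve_response(x, dt, rrf)
        np.testing.assert_allclose(out[: rrf.samples.size], rrf.samples, rtol=1e-12)

    def test_constant_heart_rate_gives_constant_hr_column(self):
        beats = EventTimes(np.arange(0, 300, 1.0), "beat")
        hr = hr_regressor(beats, timing_at(np.arange(80.0, 280.0, 2.0)))
        # fully developed convolution of a constant: constant column
        assert np.ptp(hr.matrix) / np.abs(hr.matrix).max() < 1e-6

    @pytest.mark.parametrize("interval, expected", [(1.0, 1.0), (0.5, 2.0)])
    def test_heart_rate_periodic_beats(self, interval, expected):
        beats = EventTimes(np.arange(0, 60, interval), "beat")
        _, hr = heart_rate_series(beats)
        assert np.allclose(hr, expected)

    def test_heart_rate_matches_brute_force_on_ramp(self):
        intervals = np.linspace(1.0, 0.8, 60)
        beats = EventTimes(np.concatenate([[0.0], np.cumsum(intervals)]), "beat")
        t, hr = heart_rate_series(beats, window=6.0, fs=20.0)
        starts, ends = beats.times[:-1], beats.times[1:]
        for ti, hri in zip(t[::7], hr[::7]):
            sel = (ends > ti - 3.0) & (starts < ti + 3.0)
            assert sel.any()
            assert hri == pytest.approx(1.0 / np.mean(intervals[sel]), abs=1e-12)


class TestMotionDriftHighpass:
    def test_motion_file_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        path = tmp_path / "rp.txt"
        np.savetxt(path, rng.normal(size=(150, 6)))
        mp = motion_regressors(path, 150)
        assert mp.matrix.shape == (150, 6)
        np.savetxt(path, rng.normal(size=(150, 7)))
        with pytest.raises(ValueError, match="6 columns"):
            motion_regressors(path, 150)

    def test_drift_shapes_and_orthogonality(self):
        d3 = drift_regressors(3)
        assert np.allclose(d3.matrix[:, 0], [-1.0, 0.0, 1.0])
        d150 = drift_regressors(150).mean_center()
        assert d150.n_regressors == 2
        assert abs(d150.matrix[:, 0] @ d150.matrix[:, 1]) < 1e-10

    def test_highpass_column_count(self):
        assert highpass_basis(200, 2.0, 128.0).n_regressors == 6
        assert highpass_basis(100, 2.0, cutoff=500.0).n_regressors == 0

    def test_highpass_orthogonality(self):
        hp = highpass_basis(200, 2.0, 128.0)
        gram = hp.matrix.T @ hp.matrix
        off = gram[~np.eye(hp.n_regressors, dtype=bool)]
        assert np.max(np.abs(off)) < 1e-8


class TestAssembleModel:
    @staticmethod
    def _parts(n=150, seed=3):
        rng = np.random.default_rng(seed)
        mk = lambda p, pre: RegressorSet(rng.normal(size=(n, p)),
                                         [f"{pre}{i}" for i in range(p)])
        return {
            "HW": drift_regressors(n),
            "CP": mk(6, "c"), "RP": mk(6, "r"),
            "RV": mk(1, "rv"), "HR": mk(1, "hr"), "MP": mk(6, "m"),
        }

    def test_standard_combination_sizes(self):
        parts = self._parts()
        assert assemble_model(1, parts).n_regressors == 2  # HW only
        assert assemble_model(6, parts).n_regressors == 22
        assert assemble_model(6, parts, include_baseline=False).n_regressors == 20
        assert assemble_model(7, parts).n_regressors == 8  # HW + cardiac Fourier

    def test_missing_part_named(self):
        parts = self._parts()
        del parts["MP"]
        with pytest.raises(ValueError, match="'MP'"):
            assemble_model(6, parts)

    def test_mean_centering_idempotent(self):
        parts = self._parts()
        once = assemble_model(6, parts)
        twice = once.mean_center()
        assert np.max(np.abs(once.matrix.mean(axis=0))) < 1e-10
        assert np.max(np.abs(twice.matrix - once.matrix)) < 1e-12

    def test_unknown_model_id(self):
        with pytest.raises(ValueError, match="1..12"):
            assemble_model(13, self._parts())
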