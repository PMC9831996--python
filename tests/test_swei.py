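"""k-space phase-velocity estimator: unit behaviour and wave round trips."""

import numpy as np
import pytest

from octforce import simkit as sk
from octforce import swei as sw


def make_sequence(c=2.0, snr=None, seed=0, duration=0.1, f=1000.0,
                  attenuation=3.0, geometry=None):
    geometry = geometry or sk.ScanGeometry.default_swei(depth_px=48,
                                                        depth_extent_mm=0.353)
    mat = sk.make_material("gelatin", youngs_modulus=3 * 1000 * c**2)
    exc = sk.ExcitationSpec(frequency_hz=f, duration_s=duration,
                            attenuation_length_mm=attenuation)
    return sk.simulate_swei_sequence(mat, geometry, exc, noise_snr_db=snr,
                                     seed=seed)


class TestCrop:
    def test_flat_surface_crop_window(self):
        seq = make_sequence()
        surf0 = int(seq.surface_depth_px[0])
        cropped = sw.crop_beneath_surface(seq, crop_px=32)
        assert cropped.data.shape[0] == 32
        assert np.array_equal(cropped.data[0, 0], seq.data[surf0, 0])
        assert np.array_equal(cropped.data[31, 0], seq.data[surf0 + 31, 0])

    def test_tilted_surface_follows_per_column_offsets(self):
        geometry = sk.ScanGeometry.default_swei(depth_px=64, depth_extent_mm=0.47)
        mat = sk.make_material("gelatin", 0.10)
        seq = sk.simulate_swei_sequence(mat, geometry,
                                        sk.ExcitationSpec(duration_s=0.1),
                                        noise_snr_db=None, seed=0,
                                        surface_depth_px=8, surface_tilt_px=0.5)
        cropped = sw.crop_beneath_surface(seq, crop_px=32)
        for col in (0, 15, 31):
            surf = int(seq.surface_depth_px[col])
            assert np.array_equal(cropped.data[0, col], seq.data[surf, col])

    def test_surface_detection_on_speckled_sequence(self):
        seq = make_sequence(snr=20, seed=4)
        detected = sw.detect_surface(seq)
        hits = np.mean(np.abs(detected - seq.surface_depth_px) <= 1)
        assert hits >= 0.95

    def test_crop_too_deep_rejected(self):
        seq = make_sequence()
        with pytest.raises(sw.SweiError, match="too deep"):
            sw.crop_beneath_surface(seq, crop_px=48)


class TestUnwrap:
    def test_constant_field_constant_map(self):
        geom = sk.ScanGeometry.default_swei(depth_px=8, depth_extent_mm=0.06)
        seq = sk.ComplexBScanSequence(
            data=np.full((8, 32, 900), 0.3 + 0.4j, dtype=np.complex64),
            geometry=geom, excitation=sk.ExcitationSpec(),
            surface_depth_px=np.zeros(32, dtype=int))
        pm = sw.unwrap_and_average(seq)
        assert np.ptp(pm.phase) < 1e-6

    @pytest.mark.parametrize("amplitude", [0.5, 4.0])
    def test_recovers_analytic_phase(self, amplitude):
        """Unwrapped depth-averaged phase equals the generator's travelling
        sinusoid, including when the phase wraps (amplitude 4 rad)."""
        geometry = sk.ScanGeometry.default_swei(depth_px=40, depth_extent_mm=0.294)
        mat = sk.make_material("gelatin", youngs_modulus=3 * 1000 * 4.0)
        exc = sk.ExcitationSpec(duration_s=0.1, amplitude_rad=amplitude)
        seq = sk.simulate_swei_sequence(mat, geometry, exc, noise_snr_db=None,
                                        seed=0, surface_depth_px=4)
        cropped = sw.crop_beneath_surface(seq, crop_px=32)
        pm = sw.unwrap_and_average(cropped)
        expected = sk.swei_phase_field(mat, geometry, exc, pm.n_time)
        # global 2-pi-free comparison after removing each column's t=0 value
        got = pm.phase - pm.phase[:, :1]
        exp = expected - expected[:, :1]
        # complex64 storage limits the recoverable angle precision
        assert np.allclose(got, exp, atol=1e-3)

    def test_zero_magnitude_samples_interpolated(self):
        seq = make_sequence()
        cropped = sw.crop_beneath_surface(seq)
        cropped.data[5, 7, 100:103] = 0
        pm = sw.unwrap_and_average(cropped)
        assert np.all(np.isfinite(pm.phase))


class TestSubsets:
    def make_map(self, n_t):
        return sw.SpaceTimePhaseMap(phase=np.zeros((32, n_t)),
                                    lateral_pitch_m=9.375e-5, dt_s=1 / 14200)

    def test_exact_length_all_start_at_zero(self):
        subs = sw.sample_subsets(self.make_map(800), n_subsets=5, seed=1)
        assert len(subs) == 5
        assert all(s.n_time == 800 for s in subs)

    def test_seeded_reproducible_starts(self):
        pm = self.make_map(11360)
        rng_starts = lambda seed: np.random.default_rng(seed).integers(
            0, 11360 - 800 + 1, size=30)
        a = sw.sample_subsets(pm, seed=7)
        b = sw.sample_subsets(pm, seed=7)
        for s1, s2 in zip(a, b):
            assert np.array_equal(s1.phase, s2.phase)
        assert np.array_equal(rng_starts(7), rng_starts(7))

    def test_start_bounds(self):
        pm = self.make_map(11360)
        pm.phase[:, :] = np.arange(11360)  # label columns by time index
        subs = sw.sample_subsets(pm, n_subsets=50, seed=0)
        starts = [int(s.phase[0, 0]) for s in subs]
        assert min(starts) >= 0 and max(starts) <= 10560

    def test_too_short_rejected(self):
        with pytest.raises(sw.SweiError, match="subset"):
            sw.sample_subsets(self.make_map(500))


def plane_wave_map(f0, k0, n_t=800, n_x=32, dt=1 / 14200, pitch=9.375e-5):
    t = np.arange(n_t) * dt
    x = np.arange(n_x) * pitch
    return sw.SpaceTimePhaseMap(
        phase=np.sin(2 * np.pi * (f0 * t[None, :] - k0 * x[:, None])),
        lateral_pitch_m=pitch, dt_s=dt)


class TestKSpace:
    def test_grid_aligned_wave_single_bin(self):
        # f0 on bin 50 of 800, k0 on bin 2 of 32 -> single nonzero bin
        f0 = 50 * 14200 / 800
        k0 = 2 / (32 * 9.375e-5)
        pm = plane_wave_map(f0, k0)
        ks = sw.compute_kspace(pm, pad_time=800, pad_lateral=32)
        peak = ks.amplitude.max()
        i, j = np.unravel_index(np.argmax(ks.amplitude), ks.amplitude.shape)
        assert ks.f_axis[i] == pytest.approx(f0)
        assert ks.k_axis[j] == pytest.approx(k0)
        rest = ks.amplitude.copy()
        rest[i, j] = 0
        assert rest.max() <= 1e-9 * peak

    def test_zero_map_zero_spectrum(self):
        pm = sw.SpaceTimePhaseMap(phase=np.zeros((32, 800)),
                                  lateral_pitch_m=9.375e-5, dt_s=1 / 14200)
        ks = sw.compute_kspace(pm)
        assert ks.amplitude.max() == 0

    def test_two_waves_peak_at_stronger(self):
        f1 = 50 * 14200 / 800
        k1 = 2 / (32 * 9.375e-5)
        f2 = 80 * 14200 / 800
        k2 = 5 / (32 * 9.375e-5)
        strong = plane_wave_map(f1, k1)
        weak = plane_wave_map(f2, k2)
        pm = sw.SpaceTimePhaseMap(phase=strong.phase + 0.05 * weak.phase,
                                  lateral_pitch_m=strong.lateral_pitch_m,
                                  dt_s=strong.dt_s)
        ks = sw.compute_kspace(pm, pad_time=800, pad_lateral=32)
        # brute-force argmax over every bin is the oracle
        i, j = np.unravel_index(int(np.argmax(ks.amplitude)), ks.amplitude.shape)
        assert ks.f_axis[i] == pytest.approx(f1)
        assert ks.k_axis[j] == pytest.approx(k1)


class TestFilters:
    def make_kspace(self, amp, f=None, k=None):
        nf, nk = amp.shape
        return sw.KSpace(amplitude=amp.astype(float),
                         f_axis=f if f is not None else np.linspace(10, 5000, nf),
                         k_axis=k if k is not None else np.linspace(50, 3000, nk))

    def test_dc_only_spectrum_filtered_to_empty(self):
        amp = np.zeros((10, 8))
        amp[0, 0] = 5.0
        ks = self.make_kspace(amp, f=np.linspace(5, 95, 10))
        out = sw.filter_kspace(ks, highpass_hz=100.0)
        assert out.amplitude.max() == 0
        with pytest.raises(sw.SweiError, match="no peak"):
            sw.peak_velocity(out)

    def test_peak_inside_velocity_sector_retained(self):
        amp = np.zeros((6, 6))
        f = np.array([100, 500, 1000, 2000, 3000, 4000.0])
        k = np.array([100, 200, 500, 1000, 2000, 3000.0])
        amp[2, 2] = 1.0  # 1000 Hz / 500 m^-1 = 2 m/s
        out = sw.filter_kspace(self.make_kspace(amp, f, k),
                               velocity_range_m_s=(0.5, 15.0))
        assert out.amplitude[2, 2] == 1.0

    def test_threshold_rule(self):
        amp = np.zeros((4, 4))
        f = np.array([1000.0, 1100, 1200, 1300])
        k = np.array([500.0, 550, 600, 650])
        amp[0, 0] = 1.0
        amp[1, 1] = 0.05
        amp[2, 2] = 0.11
        amp[3, 3] = 0.5
        out = sw.filter_kspace(self.make_kspace(amp, f, k))
        survivors = sorted(out.amplitude[out.amplitude > 0].tolist())
        assert survivors == [0.11, 0.5, 1.0]

    def test_filters_recorded_and_not_reapplicable(self):
        amp = np.ones((4, 4))
        out = sw.filter_kspace(self.make_kspace(amp))
        assert out.filters_applied == ["highpass", "velocity_sector", "threshold"]
        with pytest.raises(sw.SweiError, match="already"):
            sw.filter_kspace(out)

    def test_empty_sector_rejected(self):
        with pytest.raises(sw.SweiError, match="sector"):
            sw.filter_kspace(self.make_kspace(np.ones((3, 3))),
                             velocity_range_m_s=(5.0, 5.0))

    def test_threshold_preserves_max(self):
        rng = np.random.default_rng(0)
        amp = rng.random((20, 20))
        out = sw.filter_kspace(self.make_kspace(amp), highpass_hz=0.0,
                               velocity_range_m_s=(0.0, np.inf))
        assert out.amplitude.max() == amp.max()
        nz = out.amplitude[out.amplitude > 0]
        assert np.all(nz >= 0.10 * amp.max())


class TestPeakVelocity:
    def test_direct_division(self):
        amp = np.zeros((3, 3))
        amp[1, 2] = 1.0
        ks = sw.KSpace(amplitude=amp, f_axis=np.array([500.0, 1000, 1500]),
                       k_axis=np.array([100.0, 250, 500]))
        v, f, k = sw.peak_velocity(ks)
        assert (v, f, k) == (2.0, 1000.0, 500.0)

    def test_fractional_bins(self):
        amp = np.zeros((2, 2))
        amp[0, 1] = 3.0
        ks = sw.KSpace(amplitude=amp, f_axis=np.array([887.5, 900.0]),
                       k_axis=np.array([300.0, 666.67]))
        v, _, _ = sw.peak_velocity(ks)
        assert v == pytest.approx(887.5 / 666.67)

    def test_matches_exhaustive_argmax_on_random_spectra(self):
        """Oracle equivalence on 1000 random filtered spectra."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            nf, nk = rng.integers(2, 12, size=2)
            amp = rng.random((nf, nk)) * (rng.random((nf, nk)) > 0.3)
            if amp.max() == 0:
                continue
            f_axis = np.sort(rng.uniform(10, 5000, nf))
            k_axis = np.sort(rng.uniform(10, 3000, nk))
            ks = sw.KSpace(amplitude=amp, f_axis=f_axis, k_axis=k_axis)
            v, f, k = sw.peak_velocity(ks)
            best = None
            for i in range(nf):
                for j in range(nk):
                    if best is None or amp[i, j] > amp[best]:
                        best = (i, j)
            assert amp[best] == amp.max()
            i, j = best
            assert v == f_axis[i] / k_axis[j] or amp[i, j] == amp[
                np.unravel_index(np.argmax(amp), amp.shape)]

    def test_tie_breaks_lowest_f_then_k(self):
        amp = np.zeros((3, 3))
        amp[2, 0] = amp[1, 1] = amp[1, 0] = 0.7
        ks = sw.KSpace(amplitude=amp, f_axis=np.array([100.0, 200, 300]),
                       k_axis=np.array([10.0, 20, 30]))
        v, f, k = sw.peak_velocity(ks)
        assert (f, k) == (200.0, 10.0)


class TestEstimator:
    def test_noiseless_grid_aligned_exact(self):
        """Bin-aligned plane wave: velocity recovered exactly, spread zero."""
        f0 = 50 * 14200 / 800  # 887.5 Hz
        k0 = 2 / (32 * 9.375e-5)  # 666.67 1/m
        c = f0 / k0
        seq = make_sequence(c=c, snr=None, f=f0, attenuation=float("inf"))
        est = sw.estimate_phase_velocity(seq, seed=0)
        assert est.velocity == pytest.approx(c, rel=1e-9)
        assert np.ptp(est.subset_velocities) == 0
        assert est.velocity == pytest.approx(np.mean(est.subset_velocities))

    def test_noisy_recovery_within_bin_tolerance(self):
        c = sk.make_material("gelatin", 0.05).shear_wave_speed  # ~2.41 m/s
        seq = make_sequence(c=c, snr=20, seed=5)
        est = sw.estimate_phase_velocity(seq, seed=6)
        tol = sw.velocity_bin_tolerance(c, 1000.0)
        assert abs(est.velocity - c) <= tol

    def test_subset_seed_irrelevant_for_noiseless_input(self):
        seq = make_sequence(c=2.0, snr=None)
        a = sw.estimate_phase_velocity(seq, seed=1)
        b = sw.estimate_phase_velocity(seq, seed=99)
        assert a.velocity == pytest.approx(b.velocity, rel=1e-12)

    def test_invariant_to_global_phase_and_amplitude(self):
        seq = make_sequence(c=3.0, snr=20, seed=2)
        est0 = sw.estimate_phase_velocity(seq, seed=3)
        mod = sk.ComplexBScanSequence(
            data=(2.5 * np.exp(1j * 0.7) * seq.data).astype(np.complex64),
            geometry=seq.geometry, excitation=seq.excitation,
            surface_depth_px=seq.surface_depth_px)
        est1 = sw.estimate_phase_velocity(mod, seed=3)
        assert est1.velocity == pytest.approx(est0.velocity, rel=1e-6)

    def test_velocity_monotone_across_gelatin_series(self):
        """Estimated speeds strictly increase from 5 % to 20 % gels (finer
        lateral padding resolves all seven wavenumbers)."""
        params = sw.SweiParams(pad_lateral=1024)
        vs = []
        for i, conc in enumerate(sk.GELATIN_CONCENTRATIONS):
            mat = sk.make_material("gelatin", concentration=conc)
            seq = make_sequence(c=mat.shear_wave_speed, snr=20, seed=10 + i)
            vs.append(sw.estimate_phase_velocity(seq, params, seed=i).velocity)
        assert np.all(np.diff(vs) > 0)

    def test_sequence_too_short_rejected(self):
        geom = sk.ScanGeometry.default_swei(depth_px=48, depth_extent_mm=0.353,
                                            bscan_rate_hz=1000.0)
        mat = sk.make_material("gelatin", 0.10)
        with pytest.raises((sw.SweiError, ValueError)):
            seq = sk.simulate_swei_sequence(
                mat, geom, sk.ExcitationSpec(duration_s=0.5), seed=0)
            sw.estimate_phase_velocity(seq)
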