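"""HSVD decomposition, component assignment, baseline removal and regression."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from downfield_mrs.fid import FidSeries
from downfield_mrs.hsvd import (
    DEFAULT_WINDOWS,
    HsvdComponent,
    PeakBasis,
    assign_components,
    build_basis,
    extract_series,
    hsvd_decompose,
    reconstruct,
    regress_amplitudes,
    subtract_baseline,
)
from downfield_mrs.processing import process_scan, to_spectrum
from downfield_mrs.relaxation import two_spin_solve
from downfield_mrs.synthetic import AcquisitionProtocol, generate_saturation_series

DWELL = 5e-4
N = 512


def _fid_from_lines(lines, n=N, dwell=DWELL):
    """lines: iterable of (freq_hz, damping_1_per_s, complex amplitude)."""
    t = np.arange(n) * dwell
    x = np.zeros(n, dtype=complex)
    for f, d, a in lines:
        x += a * np.exp((1j * 2 * np.pi * f - d) * t)
    return FidSeries(x[None, :], dwell, 297.2, 9.7)


def _nls_oracle(fid, lines_guess):
    """Brute-force nonlinear least squares fit of damped complex exponentials."""
    t = fid.times
    x = fid.samples[0]
    target = np.concatenate([x.real, x.imag])

    def unpack(theta):
        k = len(theta) // 4
        return theta.reshape(k, 4)

    def residual(theta):
        model = np.zeros_like(x)
        for f, d, re, im in unpack(theta):
            model += (re + 1j * im) * np.exp((1j * 2 * np.pi * f - d) * t)
        return np.concatenate([model.real, model.imag]) - target

    theta0 = np.concatenate(
        [[f, d, a.real, a.imag] for f, d, a in lines_guess])
    sol = least_squares(residual, theta0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    return unpack(sol.x)


class TestHsvdDecompose:
    def test_single_lorentzian_recovered(self):
        fid = _fid_from_lines([(150.0, np.pi * 30, 1.0 + 0j)])
        comps = hsvd_decompose(fid, n_components=10)
        big = max(comps, key=lambda c: abs(c.amplitude))
        assert big.frequency == pytest.approx(150.0, abs=0.01)
        assert big.damping == pytest.approx(np.pi * 30, rel=1e-3)

    def test_two_tones_amplitudes_exact(self):
        lines = [(50.0, np.pi * 25, 2.0 + 0j), (150.0, np.pi * 40, 0.7 - 0.3j)]
        comps = hsvd_decompose(_fid_from_lines(lines), n_components=8)
        comps = sorted(comps, key=lambda c: -abs(c.amplitude))[:2]
        comps.sort(key=lambda c: c.frequency)
        for (f, d, a), c in zip(lines, comps):
            assert c.frequency == pytest.approx(f, abs=1e-4)
            assert c.damping == pytest.approx(d, rel=1e-6)
            assert abs(c.amplitude - a) < 1e-6

    def test_zero_signal_gives_empty(self):
        fid = FidSeries(np.zeros((1, N), complex), DWELL, 297.2, 9.7)
        assert hsvd_decompose(fid) == []

    def test_reconstruction_accuracy(self):
        """Sum of all components reproduces a noiseless multi-line FID."""
        lines = [(-200.0, np.pi * 80, 1.5), (30.0, np.pi * 28, 1.0),
                 (119.0, np.pi * 54, 0.8 * np.exp(1j * 0.4))]
        fid = _fid_from_lines(lines)
        comps = hsvd_decompose(fid, n_components=10)
        resid = fid.samples[0] - reconstruct(comps, fid.times)
        rel = np.linalg.norm(resid) / np.linalg.norm(fid.samples[0])
        assert rel < 1e-6

    def test_matches_nonlinear_least_squares_oracle(self):
        """On a 3-line fixture the subspace estimates equal a brute-force fit."""
        lines = [(-150.0, np.pi * 35, 1.2 + 0j), (40.0, np.pi * 28, 1.0 + 0j),
                 (119.0, np.pi * 54, 0.5 + 0.2j)]
        fid = _fid_from_lines(lines)
        comps = sorted(hsvd_decompose(fid, n_components=6),
                       key=lambda c: -abs(c.amplitude))[:3]
        comps.sort(key=lambda c: c.frequency)
        oracle = _nls_oracle(fid, lines)
        oracle = oracle[np.argsort(oracle[:, 0])]
        for c, (f, d, re, im) in zip(comps, oracle):
            assert c.frequency == pytest.approx(f, rel=1e-3, abs=1e-3)
            assert c.damping == pytest.approx(d, rel=1e-3)

    def test_requires_enough_points(self):
        fid = _fid_from_lines([(0.0, 50.0, 1.0)], n=64)
        with pytest.raises(ValueError):
            hsvd_decompose(fid, n_components=60)


class TestAssignComponents:
    W = {"TRP": (10.02, 10.18), "NAD_H4": (8.82, 8.98)}

    def _comp(self, ppm, amp=1.0):
        return HsvdComponent((ppm - 9.7) * 297.2, 100.0, amp)

    def test_component_in_window_assigned(self):
        basis = assign_components([self._comp(10.10)], self.W, 9.7, 297.2)
        assert basis.labels == ["TRP"]
        assert basis.baseline == []

    def test_largest_magnitude_wins(self):
        small, big = self._comp(10.05, 0.5), self._comp(10.12, 2.0)
        basis = assign_components([small, big], self.W, 9.7, 297.2)
        assert basis.components["TRP"] == [big]
        assert basis.baseline == [small]

    def test_empty_window_marks_resonance_missing(self):
        basis = assign_components([self._comp(10.10)], self.W, 9.7, 297.2)
        assert "NAD_H4" not in basis.components  # missing, not an error

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError):
            assign_components([], {"A": (9.0, 9.2), "B": (9.1, 9.3)}, 9.7, 297.2)


class TestSubtractBaseline:
    def test_no_baseline_is_identity(self):
        fid = _fid_from_lines([(119.0, 100.0, 1.0)])
        out = subtract_baseline(fid, [])
        np.testing.assert_array_equal(out.samples, fid.samples)

    def test_known_baseline_removed(self):
        """Peak + baseline fixture: upfield residual drops >= 10x in RMS."""
        peak = (119.0, np.pi * 54, 1.0 + 0j)
        base_lines = [((8.45 - 9.7) * 297.2, np.pi * 100, 2.0 + 0j),
                      ((8.65 - 9.7) * 297.2, np.pi * 90, 1.5 + 0j)]
        fid = _fid_from_lines([peak] + base_lines)
        base_comps = [HsvdComponent(f, d, a) for f, d, a in base_lines]
        clean = subtract_baseline(fid, base_comps)

        def band_rms(f):
            spec = to_spectrum(f)
            mask = spec.window(8.2, 8.7)
            return np.sqrt(np.mean(np.abs(spec.values[mask]) ** 2))

        assert band_rms(fid) / band_rms(clean) >= 10.0

    def test_redecomposition_finds_no_large_baseline(self):
        base_lines = [((8.5 - 9.7) * 297.2, np.pi * 100, 2.0 + 0j)]
        fid = _fid_from_lines([(119.0, np.pi * 30, 1.0)] + base_lines)
        clean = subtract_baseline(
            fid, [HsvdComponent(f, d, a) for f, d, a in base_lines])
        comps = hsvd_decompose(clean, n_components=6)
        upfield = [c for c in comps
                   if 8.2 <= 9.7 + c.frequency / 297.2 <= 8.7
                   and abs(c.amplitude) > 1e-6]
        assert upfield == []


class TestRegression:
    def _basis(self):
        comps = {
            "A": [HsvdComponent(119.0, np.pi * 54, 1.0)],
            "B": [HsvdComponent(-119.0, np.pi * 28, 1.0)],
            "C": [HsvdComponent(-178.0, np.pi * 32, 1.0)],
            "D": [HsvdComponent(-238.0, np.pi * 38, 1.0)],
        }
        return PeakBasis(comps)

    def test_exact_linear_model_recovered(self):
        basis = self._basis()
        amps = {"A": 2.0, "B": 1.0, "C": 1.0, "D": 0.5}
        lines = [(c.frequency, c.damping, amps[k])
                 for k, cs in basis.components.items() for c in cs]
        fid = _fid_from_lines(lines)
        got, rsq = regress_amplitudes(fid, basis)
        for k, v in amps.items():
            assert abs(got[k] - v) < 1e-10
        assert rsq == pytest.approx(1.0, abs=1e-12)

    def test_scaling_equivariance(self):
        basis = self._basis()
        lines = [(c.frequency, c.damping, 1.0)
                 for cs in basis.components.values() for c in cs]
        fid = _fid_from_lines(lines)
        tripled = fid.with_samples(3 * fid.samples)
        a1, _ = regress_amplitudes(fid, basis)
        a3, _ = regress_amplitudes(tripled, basis)
        for k in a1:
            assert a3[k] == pytest.approx(3 * a1[k], rel=1e-12)

    def test_rank_deficient_basis_rejected(self):
        dup = HsvdComponent(119.0, np.pi * 54, 1.0)
        basis = PeakBasis({"A": [dup], "B": [dup]})
        fid = _fid_from_lines([(119.0, np.pi * 54, 1.0)])
        with pytest.raises(ValueError):
            regress_amplitudes(fid, basis)

    def test_amplitude_cv_under_noise(self, truth, fixed_channel_weights):
        """NAD_H2 amplitude CV at the calibrated SNR stays below 10%."""
        prot = AcquisitionProtocol()
        amps = []
        basis = None
        for seed in range(40):
            ds = generate_saturation_series(
                truth, prot, channel_weights=fixed_channel_weights, seed=seed)
            m0c = process_scan(ds.m0, ds.water_ref)
            if basis is None:
                basis = build_basis(m0c)
            a, _ = regress_amplitudes(m0c, basis)
            amps.append(abs(a["NAD_H2"]))
        cv = np.std(amps) / np.mean(amps)
        assert cv < 0.10


class TestExtractSeries:
    def test_noiseless_round_trip(self, truth, noiseless_subject):
        """End to end on noiseless data the series equal the ground truth."""
        ds = noiseless_subject
        m0c = process_scan(ds.m0, ds.water_ref)
        basis = build_basis(m0c)
        scans = {
            "selective": {ts: process_scan(f, ds.water_ref)
                          for ts, f in ds.selective.items()},
            "broadband": {ts: process_scan(f, ds.water_ref)
                          for ts, f in ds.broadband.items()},
        }
        series = extract_series(scans, m0c, basis)
        assert set(basis.labels) == set(DEFAULT_WINDOWS)
        for (label, exp_), s in series.items():
            assert s.ts_ms.size == 5  # 4 acquired TS + equilibrium point
            assert s.ts_ms[-1] == 10000.0
            p = truth.two_spin_params(label)
            expect = two_spin_solve(p, exp_, s.ts_ms[:-1])
            rel = s.amplitudes[:-1] / s.amplitudes[-1]
            np.testing.assert_allclose(rel, expect, atol=1e-8)

    def test_full_saturation_start_nonnegative(self):
        """With k=1 the TS->0 amplitude is ~0 and never substantially negative."""
        from downfield_mrs.synthetic import SubjectTruth
        truth = SubjectTruth(
            t1_a_ms={"TRP": 600.0}, sigma_ab_hz={"TRP": 0.0},
            k_sel={"TRP": 1.0}, k_broad={"TRP": 1.0},
        )
        ts = np.array([1e-6])
        val = two_spin_solve(truth.two_spin_params("TRP"), "selective", ts)[0]
        assert val == pytest.approx(0.0, abs=1e-6)

    def test_missing_equilibrium_scan_raises(self, noiseless_subject):
        ds = noiseless_subject
        m0c = process_scan(ds.m0, ds.water_ref)
        basis = build_basis(m0c)
        with pytest.raises(ValueError):
            extract_series({}, None, basis)
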