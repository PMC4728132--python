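import numpy as np
import pytest

import polarcomp as pc
from polarcomp.competition import PeakSummary, radial_profile


def gaussian_field(L, N, centers, amplitudes, sigma, offset=0.0):
    h = L / N
    xs = (np.arange(N) + 0.5) * h
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    f = np.full((N, N), float(offset))
    for (cx, cy), A in zip(centers, amplitudes):
        dx = np.minimum(np.abs(X - cx), L - np.abs(X - cx))
        dy = np.minimum(np.abs(Y - cy), L - np.abs(Y - cy))
        f += A * np.exp(-(dx ** 2 + dy ** 2) / (2 * sigma ** 2))
    return f


class TestDetectPeaks:
    L = 8.0

    def test_homogeneous_empty(self):
        f = np.full((48, 48), 5.0)
        assert pc.detect_peaks(f, self.L, min_height=1.0) == []

    def test_two_seeded_gaussians(self):
        centers = [(2.0, 2.0), (6.0, 6.0)]
        f = gaussian_field(self.L, 64, centers, [100, 80], 0.5)
        peaks = pc.detect_peaks(f, self.L, min_height=10.0,
                                min_separation=1.0)
        assert len(peaks) == 2
        h = self.L / 64
        for pk, c in zip(peaks, centers):
            from polarcomp.competition import periodic_distance
            assert periodic_distance(pk.centroid, c, self.L) <= h

    def test_single_gaussian_centroid(self):
        f = gaussian_field(self.L, 64, [(3.3, 5.1)], [50], 0.6)
        peaks = pc.detect_peaks(f, self.L, min_height=5.0)
        assert len(peaks) == 1
        from polarcomp.competition import periodic_distance
        assert periodic_distance(peaks[0].centroid, (3.3, 5.1),
                                 self.L) <= self.L / 64


class TestWaistline:
    L = 10.0

    def make_peak(self, sigma, amplitude=100.0):
        f = gaussian_field(self.L, 128, [(5.0, 5.0)], [amplitude], sigma)
        pk = pc.detect_peaks(f, self.L, min_height=1.0)[0]
        return f, pk

    def test_gaussian_half_width(self):
        sigma = 0.8
        f, pk = self.make_peak(sigma)
        w = pc.waistline(f, pk, self.L)
        assert w == pytest.approx(sigma * np.sqrt(2 * np.log(2)), rel=0.02)

    def test_scale_free(self):
        f, pk = self.make_peak(0.8, amplitude=100.0)
        f2, pk2 = self.make_peak(0.8, amplitude=200.0)
        assert pc.waistline(f2, pk2, self.L) == pytest.approx(
            pc.waistline(f, pk, self.L), rel=1e-6)

    def test_monotone_in_width(self):
        widths = [pc.waistline(*self.make_peak(s), self.L)
                  for s in (0.5, 0.8, 1.2)]
        assert widths[0] < widths[1] < widths[2]

    def test_never_half_maximal_raises(self):
        f = np.full((64, 64), 10.0)
        f[32, 32] = 10.5
        pk = PeakSummary(centroid=(5.0, 5.0), height=10.5)
        with pytest.raises(ValueError):
            pc.waistline(f, pk, self.L)


class TestDiffusiveFlux:
    L = 10.0

    def test_uniform_field_zero(self):
        f = np.full((64, 64), 7.0)
        pk = PeakSummary(centroid=(5.0, 5.0), height=7.0, radius=1.0)
        flux, _ = pc.diffusive_flux_across_waistline(f, pk, 0.0025, self.L)
        assert abs(flux) < 1e-12

    def test_gaussian_closed_form(self):
        sigma, A, Dm = 1.0, 100.0, 0.0025
        f = gaussian_field(self.L, 128, [(5.0, 5.0)], [A], sigma)
        pk = pc.detect_peaks(f, self.L, min_height=1.0)[0]
        pk.radius = pc.waistline(f, pk, self.L)
        flux, pct = pc.diffusive_flux_across_waistline(f, pk, Dm, self.L)
        w = pk.radius
        analytic = Dm * 2 * np.pi * w * (A * w / sigma ** 2) \
            * np.exp(-w ** 2 / (2 * sigma ** 2))
        assert flux == pytest.approx(analytic, rel=0.02)
        assert pct > 0


class TestCytoplasmicFlux:
    def test_zero_when_empty(self, params):
        state = pc.FullState.uniform(48, {})
        pk = PeakSummary(centroid=(2.0, 2.0), height=0.0, radius=1.0)
        assert pc.cytoplasmic_flux_within_waistline(state, pk, params) == 0.0

    def test_detailed_balance(self, params):
        dm = 1.3
        dc = params.k5b * dm / params.k5a
        state = pc.FullState.uniform(48, {"Cdc42Dm": dm, "Cdc42Dc": dc})
        pk = PeakSummary(centroid=(2.0, 2.0), height=dm, radius=1.5)
        flux = pc.cytoplasmic_flux_within_waistline(state, pk, params)
        assert abs(flux) < 1e-10


class TestTwoPeakFluxBalance:
    def test_recruitment_balances_diffusion(self, params, two_peak_48):
        """At the symmetric stationary state each peak's cytoplasmic
        recruitment equals its diffusive waistline loss."""
        f = two_peak_48.membrane.total_membrane_cdc42()
        peaks = pc.detect_peaks(f, params.L, min_height=100.0,
                                min_separation=1.0)
        assert len(peaks) == 2
        for pk in peaks:
            pk = pc.summarize_peak(two_peak_48, pk, params)
            assert pk.cytoplasmic_influx == pytest.approx(
                pk.diffusive_outflux, rel=0.05)
            assert pk.loss_percent_per_s == pytest.approx(
                100 * pk.diffusive_outflux / pk.content)

    def test_single_peak_balance(self, params, single_peak_48):
        f = single_peak_48.membrane.total_membrane_cdc42()
        pk = pc.detect_peaks(f, params.L, min_height=100.0)[0]
        pk = pc.summarize_peak(single_peak_48, pk, params)
        assert pk.cytoplasmic_influx == pytest.approx(pk.diffusive_outflux,
                                                      rel=0.05)


class TestRateBalanceCurve:
    def test_empty_without_peaks(self, params, hss):
        cfg = pc.SimulationConfig(N=48, dt=0.01, T=1.0, noise=False,
                                  cadence=1.0)
        traj = pc.simulate(hss, params, cfg)
        curve = pc.rate_balance_curve(traj, params)
        assert len(curve) == 0

    def test_balance_at_stationary_states(self, params, two_peak_48,
                                          single_peak_48):
        traj = pc.Trajectory()
        traj.append(two_peak_48, params)
        one = single_peak_48.copy()
        one.t = two_peak_48.t + 1.0
        traj.append(one, params)
        curve = pc.rate_balance_curve(traj, params)
        # winner normalization: final snapshot's peak has norm_content 1
        assert curve["norm_content"].max() == pytest.approx(1.0)
        net = curve["recruitment"] - curve["diffusive_outflux"]
        assert np.all(np.abs(net) < 0.05 * curve["diffusive_outflux"])

    def test_intersections_from_sign_changes(self):
        import pandas as pd
        df = pd.DataFrame({
            "norm_content": [0.2, 0.4, 0.6, 0.8, 1.0],
            "recruitment": [1.0, 1.1, 1.3, 1.2, 1.0],
            "diffusive_outflux": [1.2, 1.0, 1.1, 1.3, 1.0],
        })
        crossings = pc.balance_intersections(df)
        assert len(crossings) >= 2
        assert np.all((crossings >= 0.2) & (crossings <= 1.0))


class TestRadialProfile:
    def test_recovers_gaussian(self):
        L, N, sigma = 10.0, 128, 1.0
        f = gaussian_field(L, N, [(5.0, 5.0)], [100.0], sigma)
        r, prof = radial_profile(f, (5.0, 5.0), L)
        sel = r < 3 * sigma
        expected = 100.0 * np.exp(-r[sel] ** 2 / (2 * sigma ** 2))
        assert np.max(np.abs(prof[sel] - expected)) < 2.0
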