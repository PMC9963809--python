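"""Fixture spectra, emission sampling, and scintillator/photosensitizer coupling."""

import numpy as np
import pytest
from scipy import stats
from scipy.signal import argrelmax

from crpdt.physics import Photon
from crpdt.spectra import (
    Spectrum,
    gd_emission_spectrum,
    gd_scintillator,
    lanthanide_uv_fluorescence,
    overlap_integral,
    p1_absorption_spectrum,
    p1_emission_spectrum,
    p1_fluorophore,
    ps_absorb,
    ps_emit,
    sample_emission,
    scintillate,
    tb_emission_spectrum,
    tb_scintillator,
)


def _photon(wavelength, weight=1.0):
    return Photon(
        position_um=np.zeros(3),
        direction=np.array([0.0, 0.0, 1.0]),
        weight=weight,
        wavelength_nm=wavelength,
    )


class TestFixtures:
    def test_tb_has_four_peaks_with_global_at_545(self):
        spec = tb_emission_spectrum()
        peaks = argrelmax(spec.values, order=3)[0]
        peaks = peaks[spec.values[peaks] > 1e-3 * spec.values.max()]
        assert len(peaks) == 4
        assert abs(spec.mode_nm() - 545.0) <= 2.0

    def test_gd_unimodal_below_350(self):
        spec = gd_emission_spectrum()
        peaks = argrelmax(spec.values, order=3)[0]
        peaks = peaks[spec.values[peaks] > 1e-3 * spec.values.max()]
        assert len(peaks) == 1
        support = spec.wavelengths_nm[spec.values > 1e-6 * spec.values.max()]
        assert support.max() < 350.0

    def test_p1_absorption_peaks_in_soret_region(self):
        spec = p1_absorption_spectrum()
        assert 405.0 <= spec.mode_nm() <= 420.0

    def test_p1_emission_mode_at_652(self):
        assert abs(p1_emission_spectrum().mode_nm() - 652.0) <= 2.0

    def test_p1_red_shift(self):
        ps = p1_fluorophore()
        assert ps.emission.mode_nm() >= ps.absorption.mode_nm()

    def test_absorption_values_are_probabilities(self):
        for spec in (p1_absorption_spectrum(), tb_scintillator().uv_absorption):
            assert spec.values.min() >= 0.0 and spec.values.max() <= 1.0


class TestSampleEmission:
    def test_delta_like_spectrum(self, rng):
        values = np.zeros(551)
        values[300] = 1.0
        spec = Spectrum(np.arange(250.0, 801.0), values)
        lam = sample_emission(spec, 1000, rng)
        assert np.all(np.abs(lam - spec.wavelengths_nm[300]) <= 1.0)

    def test_tb_histogram_mode_at_545(self, rng):
        lam = sample_emission(tb_emission_spectrum(), 100_000, rng)
        counts, edges = np.histogram(lam, bins=np.arange(250.0, 801.0))
        mode = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
        assert abs(mode - 545.0) <= 2.0

    def test_two_equal_peaks_split_evenly(self, rng):
        grid = np.arange(250.0, 801.0)
        values = np.exp(-0.5 * ((grid - 400) / 5) ** 2) + np.exp(
            -0.5 * ((grid - 600) / 5) ** 2
        )
        lam = sample_emission(Spectrum(grid, values), 40_000, rng)
        frac = (lam < 500).mean()
        assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(40_000)

    def test_empirical_cdf_matches_spectrum_cdf(self, rng):
        """Kolmogorov-Smirnov agreement of the sampler with the target CDF."""
        spec = tb_emission_spectrum()
        lam = sample_emission(spec, 100_000, rng)
        w, v = spec.wavelengths_nm, spec.values
        mass = np.concatenate(([0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * np.diff(w))))
        cdf = lambda x: np.interp(x, w, mass / mass[-1])
        stat = stats.ks_1samp(lam, cdf)
        assert stat.pvalue > 0.01

    def test_all_zero_spectrum_rejected(self, rng):
        spec = Spectrum(np.arange(250.0, 801.0), np.zeros(551))
        with pytest.raises(ValueError, match="degenerate"):
            sample_emission(spec, 10, rng)


class TestScintillate:
    def test_zero_energy_yields_nothing(self, rng):
        assert scintillate(0.0, tb_scintillator(), rng) == []

    def test_poisson_mean_for_511_kev(self, rng):
        counts = [len(scintillate(511.0, tb_scintillator(), rng)) for _ in range(40)]
        mean = 1e4 * 0.511
        assert abs(np.mean(counts) - mean) < 3 * np.sqrt(mean / len(counts))

    def test_gd_photons_all_below_350(self, rng):
        photons = scintillate(511.0, gd_scintillator(), rng)
        assert all(ph.wavelength_nm < 350.0 for ph in photons)
        assert all(ph.origin == "scintillation" for ph in photons)


class TestUvFluorescence:
    def test_red_photon_never_absorbed(self, rng):
        for _ in range(200):
            absorbed, out = lanthanide_uv_fluorescence(
                _photon(650.0), tb_scintillator(), rng
            )
            assert not absorbed and out.wavelength_nm == 650.0

    def test_300nm_absorption_probability_matches_fixture(self, rng):
        spec = tb_scintillator()
        p_expected = float(spec.uv_absorption(300.0))
        hits = sum(
            lanthanide_uv_fluorescence(_photon(300.0), spec, rng)[0]
            for _ in range(4000)
        )
        se = np.sqrt(p_expected * (1 - p_expected) / 4000)
        assert abs(hits / 4000 - p_expected) < 4 * se

    def test_reemission_distribution_matches_scintillation(self, rng):
        """Shared sampler: re-emitted and scintillation wavelengths agree (KS)."""
        spec = tb_scintillator()
        re_emitted = []
        while len(re_emitted) < 3000:
            absorbed, out = lanthanide_uv_fluorescence(_photon(300.0), spec, rng)
            if absorbed:
                re_emitted.append(out.wavelength_nm)
        scint = sample_emission(spec.emission, 3000, rng)
        assert stats.ks_2samp(re_emitted, scint).pvalue > 0.01


class TestPsCoupling:
    def test_photon_outside_support_not_absorbed(self, rng):
        assert not any(
            ps_absorb(_photon(300.0), p1_fluorophore(), 1.0, rng) for _ in range(500)
        )

    def test_545_stronger_than_350(self, rng):
        ps = p1_fluorophore()
        n = 5000
        a545 = sum(ps_absorb(_photon(545.0), ps, 1.0, rng) for _ in range(n))
        a350 = sum(ps_absorb(_photon(350.0), ps, 1.0, rng) for _ in range(n))
        assert a545 > a350

    def test_zero_transfer_efficiency_blocks_absorption(self, rng):
        ps = p1_fluorophore()
        assert not any(
            ps_absorb(_photon(412.0), ps, 0.0, rng) for _ in range(500)
        )

    def test_monotone_in_transfer_efficiency(self, rng):
        ps = p1_fluorophore()
        n = 8000
        rates = []
        for eta in (0.1, 0.5, 1.0):
            r = np.random.default_rng(0)  # common random numbers
            rates.append(sum(ps_absorb(_photon(412.0), ps, eta, r) for _ in range(n)))
        assert rates[0] <= rates[1] <= rates[2]

    @pytest.mark.parametrize("phi, expected", [(0.0, 0), (1.0, 300)])
    def test_singlet_oxygen_quantum_yield_extremes(self, rng, phi, expected):
        ps = p1_fluorophore(singlet_oxygen_yield=phi)
        events = sum(ps_emit(ps, rng)[1] for _ in range(300))
        assert events == expected

    def test_ps_emission_mode(self, rng):
        ps = p1_fluorophore()
        lam = np.array([ps_emit(ps, rng)[0].wavelength_nm for _ in range(20_000)])
        counts, edges = np.histogram(lam, bins=np.arange(250.0, 801.0))
        mode = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
        assert abs(mode - 652.0) <= 2.0


class TestOverlapIntegral:
    def test_identical_delta_peaks(self):
        grid = np.arange(250.0, 801.0)
        em = np.exp(-0.5 * ((grid - 545) / 2.0) ** 2)
        ab = np.full_like(grid, 0.0)
        ab[(grid > 530) & (grid < 560)] = 0.7
        val = overlap_integral(Spectrum(grid, em), Spectrum(grid, ab, "absorption"))
        assert val == pytest.approx(0.7, rel=1e-3)

    def test_tb_p1_overlap_exceeds_gd_p1(self):
        p1 = p1_absorption_spectrum()
        tb = overlap_integral(tb_emission_spectrum(), p1)
        gd = overlap_integral(gd_emission_spectrum(), p1)
        assert tb > gd
        assert gd == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_supports_give_zero(self):
        a = Spectrum(np.arange(250.0, 300.0), np.ones(50))
        b = Spectrum(np.arange(600.0, 650.0), np.full(50, 0.5), "absorption")
        assert overlap_integral(a, b) == 0.0

    def test_grid_refinement_convergence(self):
        coarse = np.arange(250.0, 801.0, 2.0)
        fine = np.arange(250.0, 800.0 + 0.5, 1.0)
        p1_c, p1_f = p1_absorption_spectrum(coarse), p1_absorption_spectrum(fine)
        tb_c, tb_f = tb_emission_spectrum(coarse), tb_emission_spectrum(fine)
        v_c = overlap_integral(tb_c, p1_c)
        v_f = overlap_integral(tb_f, p1_f)
        assert abs(v_f - v_c) / v_f < 0.01
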