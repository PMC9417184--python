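"""Debye profiles, Guinier fits, chi fitting, classification, merging."""

import numpy as np
import pytest

from oligoshift.saxs import (SAXSProfile, chi_fit, classify_oligomer,
                             debye_profile, guinier_fit, merge_frames,
                             rg_from_coordinates, subunit_count_from_mass)
from oligoshift.structure import AssemblyModel, Atom, Chain, Residue
from oligoshift.synthetic import (SyntheticSpec, make_assembly,
                                  make_noisy_profile)


def point_model(positions, element="C"):
    residues = [Residue(i + 1, "GLY", "", [Atom("CA", element, np.array(p, float))])
                for i, p in enumerate(positions)]
    return AssemblyModel([Chain("A", residues)])


class TestDebyeClosedForms:
    def test_single_scatterer_is_flat(self):
        q = np.linspace(0.0, 0.5, 20)
        profile = debye_profile(point_model([[1.0, 2.0, 3.0]]), q, "atom")
        np.testing.assert_allclose(profile.intensity, 36.0)  # f = 6 electrons

    def test_two_point_interference(self):
        d = 10.0
        q = np.linspace(0.01, 0.5, 10)
        profile = debye_profile(point_model([[0, 0, 0], [d, 0, 0]]), q, "atom")
        f = 6.0
        expected = 2 * f ** 2 * (1 + np.sin(q * d) / (q * d))
        np.testing.assert_allclose(profile.intensity, expected, rtol=1e-12)

    def test_zero_angle_intensity(self):
        model = point_model(np.random.default_rng(0).normal(scale=5, size=(30, 3)))
        profile = debye_profile(model, np.array([0.0, 0.01]), "atom")
        assert profile.intensity[0] == pytest.approx((30 * 6.0) ** 2)

    def test_rotation_translation_invariance(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(scale=8, size=(40, 3))
        q = np.linspace(0.01, 0.4, 30)
        base = debye_profile(point_model(pts), q, "atom").intensity
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        moved = debye_profile(point_model(pts @ rot.T + [5, -3, 2]), q,
                              "atom").intensity
        np.testing.assert_allclose(moved, base, rtol=1e-9)

    def test_nonnegative_for_positive_form_factors(self):
        rng = np.random.default_rng(4)
        model = point_model(rng.normal(scale=10, size=(25, 3)))
        q = np.linspace(0.0, 1.0, 50)
        assert np.all(debye_profile(model, q, "atom").intensity >= 0)


class TestGuinier:
    def test_exact_gaussian_recovers_rg(self):
        rg = 30.0
        q = np.linspace(0.002, 0.05, 60)
        profile = SAXSProfile(q, 100.0 * np.exp(-q ** 2 * rg ** 2 / 3.0))
        fit = guinier_fit(profile)
        assert fit.Rg == pytest.approx(rg, rel=1e-3)
        assert fit.I0 == pytest.approx(100.0, rel=1e-3)
        assert fit.q_max_used * fit.Rg <= 1.5

    def test_sphere_bead_model(self, sphere_model, sphere_guinier):
        model, radius = sphere_model
        analytic = np.sqrt(3.0 / 5.0) * radius
        assert sphere_guinier.Rg == pytest.approx(analytic, rel=0.02)
        # coordinate second moment is the tighter oracle
        assert sphere_guinier.Rg == pytest.approx(rg_from_coordinates(model),
                                                  rel=0.03)

    def test_window_respects_qrg_limit(self, c2_assembly):
        assembly, _ = c2_assembly
        profile = make_noisy_profile(assembly, noise_rel=0.0)
        fit = guinier_fit(profile)
        assert fit.q_max_used * fit.Rg <= 1.5
        assert fit.n_points >= 5

    def test_compact_body_matches_coordinates(self, c2_assembly):
        assembly, _ = c2_assembly
        fit = guinier_fit(make_noisy_profile(assembly, noise_rel=0.0))
        assert fit.Rg == pytest.approx(rg_from_coordinates(assembly), rel=0.05)

    def test_negative_low_q_errors(self):
        q = np.linspace(0.002, 0.05, 30)
        intensity = np.full_like(q, 10.0)
        intensity[2] = -1.0
        with pytest.raises(ValueError, match="non-positive"):
            guinier_fit(SAXSProfile(q, intensity))

    def test_too_few_points_errors(self):
        q = np.linspace(0.01, 0.02, 4)
        with pytest.raises(ValueError):
            guinier_fit(SAXSProfile(q, np.exp(-q ** 2)))


class TestRgFromCoordinates:
    def test_single_point(self):
        assert rg_from_coordinates(point_model([[3.0, 2.0, 1.0]])) == 0.0

    def test_two_equal_points(self):
        assert rg_from_coordinates(point_model([[0, 0, 0], [6.0, 0, 0]])) == \
            pytest.approx(3.0)


class TestChiFit:
    def test_proportional_profiles(self):
        q = np.linspace(0.01, 0.4, 50)
        base = np.exp(-q ** 2 * 100)
        fit = chi_fit(SAXSProfile(q, base), SAXSProfile(q, 5 * base, label="m"))
        assert fit.scale == pytest.approx(0.2)
        assert fit.chi == pytest.approx(0.0, abs=1e-12)

    def test_reduced_chi_calibrated_under_true_noise(self):
        # a single draw of chi has std ~ 1/sqrt(2N); test the replicate mean
        q = np.linspace(0.01, 0.4, 200)
        truth = 1000 * np.exp(-q ** 2 * 400)
        sigma = 0.02 * truth
        chis = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            noisy = truth + rng.normal(size=q.size) * sigma
            fit = chi_fit(SAXSProfile(q, noisy, sigma), SAXSProfile(q, truth))
            chis.append(fit.chi)
        assert np.mean(chis) == pytest.approx(1.0, rel=0.10)
        assert all(abs(c - 1.0) < 0.3 for c in chis)

    def test_scale_matches_grid_search_oracle(self):
        rng = np.random.default_rng(8)
        q = np.linspace(0.01, 0.3, 80)
        i_exp = np.exp(-q ** 2 * 250) + rng.normal(scale=0.01, size=q.size)
        sigma = np.full_like(q, 0.01)
        i_mod = 3.0 * np.exp(-q ** 2 * 250)
        fit = chi_fit(SAXSProfile(q, i_exp, sigma), SAXSProfile(q, i_mod))
        grid = np.linspace(0.01, 1.0, 20001)
        cost = [np.sum(((i_exp - c * i_mod) / sigma) ** 2) for c in grid]
        assert fit.scale == pytest.approx(grid[int(np.argmin(cost))], abs=1e-4)

    def test_disjoint_ranges_error(self):
        a = SAXSProfile(np.linspace(0.01, 0.1, 10), np.ones(10))
        b = SAXSProfile(np.linspace(0.2, 0.3, 10), np.ones(10))
        with pytest.raises(ValueError, match="overlap"):
            chi_fit(a, b)


@pytest.fixture(scope="module")
def candidates():
    return {pg: make_assembly(SyntheticSpec(point_group=pg, seed=21))[0]
            for pg in ("C2", "D2", "D3")}


class TestClassification:

    def test_hexamer_data_prefers_hexamer_model(self, candidates):
        data = make_noisy_profile(candidates["D3"], noise_rel=0.02, seed=22)
        call = classify_oligomer(data, candidates)
        assert call.best_model == "D3"
        assert call.chis["D3"] < call.chis["C2"]

    def test_exact_profile_gives_zero_chi(self, candidates):
        data = make_noisy_profile(candidates["D2"], noise_rel=0.0)
        call = classify_oligomer(data, candidates)
        assert call.best_model == "D2"
        assert call.chis["D2"] == pytest.approx(0.0, abs=1e-9)

    def test_mass_consistency_tetramer(self, candidates):
        data = make_noisy_profile(candidates["D2"], noise_rel=0.0)
        call = classify_oligomer(data, candidates, measured_mass=218.3,
                                 subunit_mass=50.0)
        assert call.subunit_count == 4
        assert call.mass_consistent is True  # D2 fixture has four chains

    def test_mass_helper(self):
        assert subunit_count_from_mass(218.3, 50.0) == 4

    def test_needs_two_candidates(self, candidates):
        data = make_noisy_profile(candidates["C2"], noise_rel=0.0)
        with pytest.raises(ValueError):
            classify_oligomer(data, {"C2": candidates["C2"]})


class TestMergeFrames:
    def _frame(self, rg, seed=None, n=60):
        q = np.linspace(0.002, 0.06, n)
        intensity = 100 * np.exp(-q ** 2 * rg ** 2 / 3)
        sigma = np.full_like(q, 0.5)
        if seed is not None:
            intensity = intensity + np.random.default_rng(seed).normal(
                scale=0.25, size=n)
        return SAXSProfile(q, intensity, sigma)

    def test_identical_frames_reduce_sigma(self):
        frames = [self._frame(25.0) for _ in range(10)]
        merged = merge_frames(frames)
        np.testing.assert_allclose(merged.intensity, frames[0].intensity)
        np.testing.assert_allclose(merged.sigma, 0.5 / np.sqrt(10))

    def test_outlier_frames_excluded(self):
        frames = [self._frame(30.0, seed=i) for i in range(8)]
        frames += [self._frame(40.0, seed=100 + i) for i in range(2)]
        merged = merge_frames(frames, rg_tolerance=0.05)
        fit = guinier_fit(merged)
        assert fit.Rg == pytest.approx(30.0, rel=0.02)

    def test_mismatched_grids_error(self):
        a = self._frame(25.0)
        q = np.linspace(0.003, 0.07, 60)
        b = SAXSProfile(q, 100 * np.exp(-q ** 2 * 25 ** 2 / 3))
        with pytest.raises(ValueError, match="common q grid"):
            merge_frames([a, b])

    def test_no_uniform_run_errors(self):
        frames = [self._frame(20.0 + 8 * i) for i in range(4)]
        with pytest.raises(ValueError, match="uniform"):
            merge_frames(frames, rg_tolerance=0.01)


class TestProfileIO:
    def test_dat_round_trip(self, tmp_path):
        q = np.linspace(0.01, 0.3, 25)
        profile = SAXSProfile(q, np.exp(-q ** 2 * 90), np.full(25, 0.01), "x")
        path = tmp_path / "profile.dat"
        profile.write_dat(path, header="demo")
        again = SAXSProfile.read_dat(path)
        np.testing.assert_allclose(again.q, profile.q, rtol=1e-5)
        np.testing.assert_allclose(again.intensity, profile.intensity, rtol=1e-5)
        np.testing.assert_allclose(again.sigma, profile.sigma, rtol=1e-5)

    def test_decreasing_grid_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            SAXSProfile(np.array([0.2, 0.1]), np.array([1.0, 1.0]))
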