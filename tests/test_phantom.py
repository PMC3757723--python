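"""Phantom template and cohort simulator."""

import numpy as np
import pytest
from scipy import stats
from scipy.ndimage import map_coordinates

from tbmtools import (
    DemographicSpec,
    EffectSpec,
    PhantomGeometry,
    SubjectRecord,
    make_template_phantom,
    simulate_covariates,
    simulate_genotypes,
    synthesize_followup_pair,
    synthesize_subject_volume,
)
from tbmtools.phantom import (
    INTERVAL_COUNTS,
    INTERVAL_MONTHS,
    implanted_percent,
    sample_intervals,
)


class TestTemplate:
    def test_labels_partition_grid(self, template48):
        counts = template48.label_counts()
        assert sum(counts.values()) == 48**3
        assert set(counts) == {0, 1, 2, 3, 4}

    def test_deterministic(self, template48):
        again = make_template_phantom((48, 48, 48))
        np.testing.assert_array_equal(again.labels, template48.labels)
        np.testing.assert_array_equal(again.intensity, template48.intensity)

    def test_wm_count_matches_bruteforce_ellipsoid_scan(self, template48):
        # independent voxel-by-voxel evaluation of the shell inequalities
        t = template48
        gm_t, wm_t = t.geometry.resolved_thicknesses(t.radii)
        amax = t.radii.max()
        rho_wm, rho_vent = 1 - gm_t / amax, 1 - (gm_t + wm_t) / amax
        n = 0
        for i in range(48):
            for j in range(48):
                d0 = (i - t.center[0]) / t.radii[0]
                d1 = (j - t.center[1]) / t.radii[1]
                k = np.arange(48)
                d2 = (k - t.center[2]) / t.radii[2]
                rho = np.sqrt(d0**2 + d1**2 + d2**2)
                n += int(((rho <= rho_wm) & (rho > rho_vent)).sum())
        assert n == t.label_counts()[2]

    def test_wm_region_is_interior(self, template48):
        # no face-adjacent contact between the target region and background
        lab = template48.labels
        wm = lab == 2
        for ax in range(3):
            for off in (-1, 1):
                neigh = np.roll(lab, off, axis=ax)
                assert not np.any(wm & (neigh == 0))

    def test_oversized_geometry_names_axis(self):
        with pytest.raises(ValueError, match="axis"):
            make_template_phantom((48, 48, 48), PhantomGeometry(radii=(30, 10, 10)))

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_template_phantom((16, 16, 16))


class TestGenotypes:
    def test_monomorphic(self):
        assert np.all(simulate_genotypes(100, 0.0, seed=1) == 0)

    def test_hardy_weinberg_dose2_fraction(self):
        doses = simulate_genotypes(100_000, 0.31, seed=3)
        frac2 = (doses == 2).mean()
        p = 0.31**2
        se = np.sqrt(p * (1 - p) / 100_000)
        assert abs(frac2 - p) < 3 * se

    def test_matches_multinomial_oracle(self):
        n, q = 100_000, 0.31
        doses = simulate_genotypes(n, q, seed=7)
        probs = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
        oracle = np.random.default_rng(7).multinomial(n, probs)
        obs = np.bincount(doses, minlength=3)
        # two draws of the same multinomial: 4 SD tolerance per cell
        sd = np.sqrt(2 * n * probs * (1 - probs))
        assert np.all(np.abs(obs - oracle) < 4 * sd)

    def test_goodness_of_fit_over_seeds(self):
        ok = 0
        q = 0.31
        expected = 100_000 * np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
        for seed in range(20):
            obs = np.bincount(simulate_genotypes(100_000, q, seed), minlength=3)
            _, p = stats.chisquare(obs, expected)
            ok += p > 0.01
        assert ok >= 19

    def test_reproducible(self):
        np.testing.assert_array_equal(
            simulate_genotypes(500, 0.31, seed=11), simulate_genotypes(500, 0.31, seed=11)
        )

    def test_invalid_maf(self):
        with pytest.raises(ValueError):
            simulate_genotypes(10, 0.7, seed=0)


class TestCovariates:
    def test_tt_homocysteine_mean(self):
        doses = np.full(10_000, 2)
        eff = EffectSpec(hcy_per_allele=0.75, hcy_baseline=10.2, sigma_hcy=2.4)
        recs = simulate_covariates(doses, eff, seed=5)
        hcy = np.array([r.homocysteine for r in recs])
        se = 2.4 / np.sqrt(len(hcy))
        assert abs(hcy.mean() - 11.7) < 3 * se

    def test_noiseless_homocysteine_exact(self):
        doses = np.array([0, 1, 2, 2])
        eff = EffectSpec(sigma_hcy=0.0)
        recs = simulate_covariates(doses, eff, seed=5)
        np.testing.assert_allclose(
            [r.homocysteine for r in recs], 10.2 + 0.75 * doses
        )

    def test_seeded_determinism(self):
        doses = simulate_genotypes(50, 0.31, seed=2)
        a = simulate_covariates(doses, seed=9)
        b = simulate_covariates(doses, seed=9)
        assert [vars(r) for r in a] == [vars(r) for r in b]

    def test_age_range_and_alignment(self):
        doses = simulate_genotypes(200, 0.31, seed=2)
        recs = simulate_covariates(doses, seed=9)
        assert [r.dose for r in recs] == list(doses)
        ages = np.array([r.age for r in recs])
        assert ages.min() >= 55 and ages.max() <= 95

    def test_interval_distribution(self):
        rng = np.random.default_rng(0)
        iv = sample_intervals(50_000, rng)
        freqs = np.array([(iv == m).mean() for m in INTERVAL_MONTHS])
        expect = INTERVAL_COUNTS / INTERVAL_COUNTS.sum()
        assert np.all(np.abs(freqs - expect) < 0.01)


class TestSubjectVolume:
    def test_null_subject_equals_template(self, template48, clean_effect):
        rec = SubjectRecord("N0", 0, 75.0, 0, homocysteine=10.2)
        sv = synthesize_subject_volume(template48, rec, clean_effect, seed=1)
        np.testing.assert_array_equal(sv.image, template48.intensity)
        assert sv.percent_implanted == 0.0

    def test_dose2_ground_truth_jacobian(self, template48, dose2_subject48):
        wm = template48.labels == 2
        np.testing.assert_allclose(dose2_subject48.gt_jacobian[wm], 0.88, atol=5e-3)

    def test_ground_truth_jacobian_positive(self, template48, dose2_subject48):
        assert np.all(dose2_subject48.gt_jacobian > 0)

    @pytest.mark.parametrize("dose", [1, 2])
    def test_mass_conservation_oracle(self, template48, clean_effect, dose):
        # integral of the ground-truth Jacobian over template tissue must
        # equal the warped tissue volume, counted brute-force on a 2x
        # supersampled grid (linear interpolation of the tissue mask
        # localizes the warped surface to sub-voxel precision)
        rec = SubjectRecord("M1", dose, 75.0, 1, homocysteine=10.95)
        sv = synthesize_subject_volume(template48, rec, clean_effect, seed=1)
        tissue = (template48.labels > 0).astype(float)
        predicted = sv.gt_jacobian[template48.labels > 0].sum()
        from tbmtools.phantom import _radial_warp_arrays

        _, coords = _radial_warp_arrays(template48, sv.percent_implanted)
        fine = (np.indices((96, 96, 96), dtype=float) + 0.5) / 2.0 - 0.5
        cs = np.stack(
            [map_coordinates(coords[a], fine, order=1, mode="nearest") for a in range(3)]
        )
        measured = (map_coordinates(tissue, cs, order=1, cval=0.0) > 0.5).sum() / 8.0
        assert abs(predicted - measured) / measured < 0.02

    def test_non_invertible_contraction_rejected(self, template48, clean_effect):
        rec = SubjectRecord("X", 2, 75.0, 1, homocysteine=10.2)
        with pytest.raises(ValueError):
            synthesize_subject_volume(
                template48, rec, clean_effect, seed=0, percent_override=-120.0
            )

    def test_mediation_full_conditional_independence(self, template48):
        # with full mediation, ground-truth volume change given homocysteine
        # carries no extra dose information
        eff = EffectSpec(mediation_fraction=1.0)
        doses = simulate_genotypes(400, 0.31, seed=21)
        recs = simulate_covariates(doses, eff, seed=22)
        pct = np.array([implanted_percent(r, eff) for r in recs])
        hcy = np.array([r.homocysteine for r in recs])
        X = np.column_stack([np.ones(len(recs)), doses, hcy])
        beta, *_ = np.linalg.lstsq(X, pct, rcond=None)
        resid = pct - X @ beta
        dof = len(recs) - 3
        cov = np.linalg.inv(X.T @ X) * (resid @ resid / max(dof, 1))
        se = np.sqrt(cov[1, 1])
        assert abs(beta[1]) < 3 * max(se, 1e-12)

    def test_mediation_zero_ignores_homocysteine(self):
        eff = EffectSpec(mediation_fraction=0.0)
        r1 = SubjectRecord("a", 2, 75, 1, homocysteine=8.0)
        r2 = SubjectRecord("b", 2, 75, 1, homocysteine=14.0)
        assert implanted_percent(r1, eff) == implanted_percent(r2, eff) == -12.0


class TestFollowupPair:
    def test_dose0_differs_only_by_noise(self, template48):
        eff = EffectSpec(noise_sd=0.02)
        rec = SubjectRecord("L0", 0, 75.0, 1, homocysteine=10.2, interval_months=12)
        base, fol = synthesize_followup_pair(template48, rec, eff, seed=3)
        diff = fol.image - base.image
        # difference is pure iid Gaussian noise: zero mean, sd ~ sqrt(2)*0.02
        assert abs(diff.mean()) < 1e-3
        assert abs(diff.std() - np.sqrt(2) * 0.02) < 2e-3
        np.testing.assert_array_equal(base.gt_jacobian, fol.gt_jacobian)

    def test_followup_jacobian_ratio(self, template48, clean_effect):
        rec = SubjectRecord("L2", 2, 75.0, 1, homocysteine=11.7, interval_months=12)
        base, fol = synthesize_followup_pair(template48, rec, clean_effect, seed=3)
        wm = template48.labels == 2
        ratio = fol.gt_jacobian[wm] / base.gt_jacobian[wm]
        np.testing.assert_allclose(ratio, 0.97, atol=5e-3)

    def test_interval_scales_linearly(self, template48, clean_effect):
        rec = SubjectRecord(
            "L1", 1, 75.0, 1, homocysteine=10.95, interval_months=18
        )
        eff = EffectSpec(
            percent_per_allele=0.0, annual_percent_per_allele=-1.5,
            nuisance_warp_mm=0.0, noise_sd=0.0,
        )
        base, fol = synthesize_followup_pair(template48, rec, eff, seed=3)
        wm = template48.labels == 2
        extra = (fol.gt_jacobian[wm] / base.gt_jacobian[wm] - 1) * 100
        np.testing.assert_allclose(extra, -2.25, atol=0.05)

    def test_requires_interval(self, template48, clean_effect):
        rec = SubjectRecord("L3", 1, 75.0, 1, homocysteine=10.95)
        with pytest.raises(ValueError):
            synthesize_followup_pair(template48, rec, clean_effect, seed=0)


def test_record_validation():
    with pytest.raises(ValueError):
        SubjectRecord("x", 3, 75.0, 1)
    with pytest.raises(ValueError):
        SubjectRecord("x", 1, 75.0, 1, interval_months=30)
    with pytest.raises(ValueError):
        EffectSpec(mediation_fraction=1.5)
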