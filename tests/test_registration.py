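"""Nonlinear registration, field algebra, and template construction."""

import numpy as np
import pytest
from scipy.ndimage import affine_transform, gaussian_filter, shift

from tbmtools import (
    DisplacementField,
    EffectSpec,
    RegistrationConfig,
    SubjectRecord,
    build_mdt,
    inverse_consistency_error,
    invert_field,
    register_affine,
    register_nonlinear,
    synthesize_subject_volume,
    warp_volume,
)
from tbmtools.jacobian import jacobian_determinant, jacobian_determinant_array
from tbmtools.registration import RegistrationError


def smooth_random_field(shape, amplitude, seed, sigma=3.0):
    rng = np.random.default_rng(seed)
    u = np.stack([gaussian_filter(rng.standard_normal(shape), sigma) for _ in range(3)])
    u *= amplitude / np.sqrt((u**2).sum(axis=0)).max()
    return DisplacementField(u)


class TestWarpVolume:
    def test_zero_field_is_identity(self, template32):
        f = DisplacementField(np.zeros((3, 32, 32, 32)))
        np.testing.assert_array_equal(
            warp_volume(template32.intensity, f), template32.intensity
        )

    def test_constant_field_translates(self, template32):
        u = np.zeros((3, 32, 32, 32))
        u[0] = 1.0
        out = warp_volume(template32.intensity, DisplacementField(u))
        np.testing.assert_allclose(
            out[:-1], template32.intensity[1:], atol=1e-12
        )

    def test_warp_then_inverse_recovers(self, template32):
        fld = smooth_random_field((32, 32, 32), 1.5, seed=4)
        warped = warp_volume(template32.intensity, fld)
        back = warp_volume(warped, invert_field(fld))
        rng_span = template32.intensity.max() - template32.intensity.min()
        core = (slice(4, -4),) * 3
        err = np.abs(back[core] - template32.intensity[core]).mean()
        assert err < 0.02 * rng_span

    def test_shape_mismatch_rejected(self, template32):
        f = DisplacementField(np.zeros((3, 16, 16, 16)))
        with pytest.raises(ValueError):
            warp_volume(template32.intensity, f)


class TestInverseConsistencyError:
    def test_zero_fields(self):
        z = DisplacementField(np.zeros((3, 16, 16, 16)))
        assert inverse_consistency_error(z, z) == 0.0

    def test_constant_opposites(self):
        u = np.zeros((3, 16, 16, 16))
        u[1] = 0.75
        fwd = DisplacementField(u)
        bwd = DisplacementField(-u)
        assert inverse_consistency_error(fwd, bwd) < 1e-12

    def test_numerical_inverse_is_consistent(self):
        fwd = smooth_random_field((32, 32, 32), 1.5, seed=8, sigma=3.0)
        bwd = invert_field(fwd)
        assert inverse_consistency_error(fwd, bwd) < 0.1


class TestAffine:
    def test_self_registration_is_identity(self, template32):
        tr = register_affine(template32.intensity, template32.intensity)
        assert np.abs(tr.translation).max() < 0.1
        assert np.abs(tr.matrix - np.eye(3)).max() < 0.01

    def test_recovers_known_translation(self, template32):
        mov = shift(template32.intensity, (3, -2, 1), order=1)
        tr = register_affine(mov, template32.intensity, dof=12)
        np.testing.assert_allclose(tr.translation, [3, -2, 1], atol=0.5)

    def test_recovers_known_scaling(self, template32):
        fix = template32.intensity
        c = (np.array(fix.shape) - 1) / 2
        A = np.eye(3) / 1.05
        mov = affine_transform(fix, A, offset=c - A @ c, order=1)
        tr = register_affine(mov, fix, dof=9)
        np.testing.assert_allclose(np.diag(tr.matrix), 1.05, atol=0.01)

    def test_zero_variance_rejected(self):
        flat = np.zeros((32, 32, 32))
        with pytest.raises(RegistrationError):
            register_affine(flat, flat)


class TestNonlinear:
    def test_self_registration_near_zero(self, template32):
        fld = register_nonlinear(template32.intensity, template32.intensity)
        assert fld.magnitude().max() < 0.2

    def test_recovers_implanted_contraction(self, template48):
        # -10% uniform white-matter contraction; mean recovered Jacobian in
        # the region must sit within +/-0.03 of the implanted 0.90
        eff = EffectSpec(percent_per_allele=-5.0, nuisance_warp_mm=0, noise_sd=0)
        rec = SubjectRecord("R2", 2, 75.0, 1, homocysteine=11.7)
        sv = synthesize_subject_volume(template48, rec, eff, seed=2)
        fld = register_nonlinear(sv.image, template48.intensity)
        j = jacobian_determinant(fld).j
        wm = template48.labels == 2
        assert abs(j[wm].mean() - 0.90) < 0.03

    def test_symmetric_improves_inverse_consistency(self, template48):
        eff = EffectSpec(percent_per_allele=-6.0)
        rec = SubjectRecord("R1", 1, 75.0, 1, homocysteine=10.95)
        sv = synthesize_subject_volume(template48, rec, eff, seed=3)
        cfg_sym = RegistrationConfig(
            symmetric=True, n_levels=1, iters_per_level=(40,)
        )
        fld_sym = register_nonlinear(sv.image, template48.intensity, cfg_sym)
        ice_sym = inverse_consistency_error(fld_sym, fld_sym.backward)
        fwd = register_nonlinear(sv.image, template48.intensity)
        bwd = register_nonlinear(template48.intensity, sv.image)
        ice_asym = inverse_consistency_error(fwd, bwd)
        assert ice_sym < ice_asym / 2

    def test_jacobian_positive_on_interior(self, template48):
        eff = EffectSpec()
        rec = SubjectRecord("R3", 2, 75.0, 0, homocysteine=11.7)
        sv = synthesize_subject_volume(template48, rec, eff, seed=5)
        fld = register_nonlinear(sv.image, template48.intensity)
        j = jacobian_determinant_array(fld.u)
        assert np.all(j[2:-2, 2:-2, 2:-2] > 0)

    def test_translation_equivariance(self, template32):
        # translating both images by the same integer offset leaves the
        # recovered field unchanged on the shared interior
        eff = EffectSpec(percent_per_allele=-6.0, nuisance_warp_mm=0, noise_sd=0)
        rec = SubjectRecord("R4", 2, 75.0, 1, homocysteine=11.7)
        sv = synthesize_subject_volume(template32, rec, eff, seed=6)
        fld = register_nonlinear(sv.image, template32.intensity)
        mov_t = np.roll(sv.image, 2, axis=0)
        fix_t = np.roll(template32.intensity, 2, axis=0)
        fld_t = register_nonlinear(mov_t, fix_t)
        a = fld.u[:, 6:-6, 6:-6, 6:-6]
        b = fld_t.u[:, 8:-4, 6:-6, 6:-6]
        assert np.abs(a - b).max() < 0.2

    def test_shape_mismatch_rejected(self, template32):
        with pytest.raises(ValueError):
            register_nonlinear(template32.intensity, template32.intensity[:16])


class TestMDT:
    def test_identical_inputs_give_common_volume(self, template32):
        vols = [template32.intensity.copy() for _ in range(3)]
        mdt, fields = build_mdt(vols, n_iter=1)
        np.testing.assert_allclose(mdt, template32.intensity, atol=0.02)
        for f in fields:
            assert f.magnitude().max() < 0.2

    def test_centering_on_random_scalings(self, template32):
        # global +/-5% volume scalings: the MDT sits at the geometric
        # center, so recovered log-Jacobian integrals average to ~0
        rng = np.random.default_rng(12)
        fix = template32.intensity
        c = (np.array(fix.shape) - 1) / 2
        vols = []
        scales = 1.0 + 0.05 * rng.uniform(-1, 1, size=6)
        for s in scales:
            A = np.eye(3) / s ** (1 / 3)
            vols.append(affine_transform(fix, A, offset=c - A @ c, order=1))
        mdt, fields = build_mdt(vols, n_iter=2)
        brain = template32.labels > 0
        logj = [
            np.log(np.clip(jacobian_determinant(f).j, 1e-3, None))[brain].mean()
            for f in fields
        ]
        assert abs(np.mean(logj)) < 0.01

    def test_too_few_volumes(self, template32):
        with pytest.raises(ValueError):
            build_mdt([template32.intensity] * 2)


def test_similarity_monotone_within_levels(template32):
    eff = EffectSpec(percent_per_allele=-6.0, nuisance_warp_mm=0, noise_sd=0)
    rec = SubjectRecord("R5", 2, 75.0, 1, homocysteine=11.7)
    sv = synthesize_subject_volume(template32, rec, eff, seed=7)
    cfg = RegistrationConfig()
    fld = register_nonlinear(sv.image, template32.intensity, cfg)
    for level in fld.ssd_history:
        # every step improves by at least tol, except the final recorded
        # iteration, which is the one that triggers the stopping rule
        for a, b in zip(level[:-2], level[1:-1]):
            assert a - b >= cfg.tol * a
        if len(level) >= 2:
            assert level[-1] <= level[-2] * 1.01
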