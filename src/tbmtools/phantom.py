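"""Synthetic brain-phantom cohorts with implanted allele-dose volume effects.

The phantom is a nested-ellipsoid "brain": a gray-matter shell (label 1)
around a periventricular white-matter shell (label 2) around a central
ventricle (label 3), with a small brainstem appendage (label 4) and
background 0.  Subject volumes are produced by warping the template with an
analytic radial contraction whose Jacobian determinant inside the target
tissue is known exactly, so the downstream morphometry pipeline can be
scored against exact ground truth.

The covariate generator reproduces the statistical structure of an elderly
mild-cognitive-impairment cohort: Hardy-Weinberg genotypes at a configurable
minor-allele frequency, ages around 75 +/- 7 years, and a homocysteine level
that rises with the risk-allele dose.  A ``mediation_fraction`` routes part
(or all) of the allele's volume effect through homocysteine, so adjusting
for homocysteine in the regression attenuates the dose coefficient.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

__all__ = [
    "PhantomTemplate",
    "PhantomGeometry",
    "SubjectRecord",
    "EffectSpec",
    "DemographicSpec",
    "SubjectVolume",
    "INTERVAL_MONTHS",
    "INTERVAL_COUNTS",
    "make_template_phantom",
    "simulate_genotypes",
    "simulate_covariates",
    "sample_intervals",
    "synthesize_subject_volume",
    "synthesize_followup_pair",
    "subject_rng",
]

# Follow-up interval distribution (months: number of subjects) of a cohort
# re-scanned "around one year" after baseline.
INTERVAL_MONTHS = np.array([10, 12, 13, 14, 15, 16])
INTERVAL_COUNTS = np.array([1, 59, 176, 52, 12, 7])

LABEL_BACKGROUND = 0
LABEL_GM = 1
LABEL_WM = 2
LABEL_VENTRICLE = 3
LABEL_BRAINSTEM = 4

# base intensity per label; texture is added on top inside the head
_LABEL_INTENSITY = {0: 0.0, 1: 0.5, 2: 0.8, 3: 0.15, 4: 0.6}
_TEXTURE_SEED = 745318  # fixed: the template is deterministic by contract
_TEXTURE_AMPLITUDE = 0.10
_TEXTURE_SIGMA = 2.0


@dataclass(frozen=True)
class PhantomGeometry:
    """Ellipsoid radii and shell thicknesses, all in voxels."""

    radii: tuple[float, float, float] | None = None  # outer (GM) semi-axes
    gm_thickness: float | None = None  # voxels; default scales with radii
    wm_thickness: float | None = None
    brainstem_radii: tuple[float, float, float] | None = None

    def resolved_radii(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        if self.radii is not None:
            return np.asarray(self.radii, dtype=float)
        # oblate: slightly shorter along the inferior-superior axis, which
        # also leaves room for the brainstem appendage
        return np.array([0.42, 0.42, 0.365]) * np.asarray(grid_shape, dtype=float)

    def resolved_brainstem(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        if self.brainstem_radii is not None:
            return np.asarray(self.brainstem_radii, dtype=float)
        return np.array([0.073, 0.073, 0.083]) * float(min(grid_shape))

    def resolved_thicknesses(self, radii: np.ndarray) -> tuple[float, float]:
        amax = float(np.max(radii))
        gm = self.gm_thickness if self.gm_thickness is not None else 0.174 * amax
        wm = self.wm_thickness if self.wm_thickness is not None else 0.397 * amax
        return gm, wm


@dataclass
class PhantomTemplate:
    intensity: np.ndarray
    labels: np.ndarray
    voxel_size_mm: float
    geometry: PhantomGeometry
    center: np.ndarray  # ellipsoid center, voxel coords
    radii: np.ndarray  # outer semi-axes, voxels

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.intensity.shape)

    def label_counts(self) -> dict[int, int]:
        codes, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(codes.tolist(), counts.tolist()))

    def elliptical_radius(self, coords: np.ndarray) -> np.ndarray:
        """Normalized elliptical radius (1.0 = outer brain surface).

        ``coords`` has shape (3, ...) in voxel units.
        """
        d = (coords - self.center.reshape((3,) + (1,) * (coords.ndim - 1)))
        d = d / self.radii.reshape((3,) + (1,) * (coords.ndim - 1))
        return np.sqrt((d**2).sum(axis=0))


@dataclass
class SubjectRecord:
    """One subject's genotype dose and covariates.

    Sex coding: 0 = female, 1 = male.  ``dose`` counts risk alleles (0/1/2).
    """

    subject_id: str
    dose: int
    age: float
    sex: int
    homocysteine: float | None = None
    folate: float | None = None
    apoe4: int | None = None
    interval_months: float | None = None

    def __post_init__(self):
        if self.dose not in (0, 1, 2):
            raise ValueError(f"dose must be 0, 1 or 2, got {self.dose}")
        if self.homocysteine is not None and self.homocysteine <= 0:
            raise ValueError("homocysteine must be positive")
        if self.interval_months is not None and not (6 <= self.interval_months <= 24):
            raise ValueError("interval_months must lie in [6, 24]")


@dataclass(frozen=True)
class EffectSpec:
    """Implanted ground-truth effect of the risk allele.

    percent_per_allele : cross-sectional percent volume change per allele in
        the target label (negative = deficit).
    annual_percent_per_allele : longitudinal percent per year per allele.
    mediation_fraction : share of the dose effect routed through
        homocysteine; 1.0 means the volume effect depends on dose only
        through the subject's homocysteine level.
    hcy_per_allele / hcy_baseline : linear homocysteine model (umol/L).
    nuisance_warp_mm : RMS amplitude of the random smooth anatomical warp.
    noise_sd : additive Gaussian intensity noise (intensity units in [0,1]).
    """

    percent_per_allele: float = -6.0
    target_label: int = LABEL_WM
    annual_percent_per_allele: float = -1.5
    mediation_fraction: float = 0.0
    hcy_per_allele: float = 0.75
    hcy_baseline: float = 10.2
    sigma_hcy: float = 2.4
    nuisance_warp_mm: float = 0.5
    noise_sd: float = 0.02

    def __post_init__(self):
        if not 0.0 <= self.mediation_fraction <= 1.0:
            raise ValueError("mediation_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class DemographicSpec:
    """Cohort demographics: elderly MCI-like defaults."""

    age_mean: float = 75.0
    age_sd: float = 7.0
    age_range: tuple[float, float] = (55.0, 95.0)
    male_fraction: float = 0.643  # 231/359 males
    folate_mean: float = 500.0
    folate_sd: float = 120.0
    # marginal ApoE4 allele-count distribution of an elderly MCI cohort
    apoe4_probs: tuple[float, float, float] = (173 / 359, 143 / 359, 43 / 359)


@dataclass
class SubjectVolume:
    """A synthesized scan plus its exact implanted ground truth."""

    image: np.ndarray
    gt_jacobian: np.ndarray  # template-grid Jacobian of the implanted warp
    labels: np.ndarray  # template labels carried into subject space
    percent_implanted: float  # scalar percent volume change in target label


def subject_rng(seed: int, subject_id: str, salt: int = 0) -> np.random.Generator:
    """Per-subject random stream derived by stable hashing of the id."""
    key = zlib.crc32(subject_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key, salt]))


def make_template_phantom(
    grid_shape: tuple[int, int, int] = (48, 48, 48),
    geometry: PhantomGeometry | None = None,
    voxel_size_mm: float = 1.0,
) -> PhantomTemplate:
    """Build the deterministic nested-ellipsoid template.

    Raises ``ValueError`` naming the offending axis when the requested
    geometry does not fit inside the grid with a 2-voxel background margin.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if len(grid_shape) != 3 or any(s < 32 for s in grid_shape):
        raise ValueError("grid_shape must be three integers, each >= 32")
    geometry = geometry or PhantomGeometry()
    radii = geometry.resolved_radii(grid_shape)
    # keep the brain slightly above center so the brainstem appendage fits
    center = (np.asarray(grid_shape, float) - 1) / 2.0
    center[2] += 0.04 * grid_shape[2]
    stem_radii = geometry.resolved_brainstem(grid_shape)
    for ax in range(3):
        lo = center[ax] - radii[ax]
        hi = center[ax] + radii[ax]
        if ax == 2:
            lo -= stem_radii[2]  # stem extends downward
        if lo < 2 or hi > grid_shape[ax] - 3:
            raise ValueError(
                f"geometry exceeds grid along axis {ax}: "
                f"extent [{lo:.1f}, {hi:.1f}] vs grid {grid_shape[ax]}"
            )
    # shell boundaries are level sets of the normalized elliptical radius,
    # so the implanted radial warp aligns exactly with the tissue labels;
    # thickness is nominal along the major axis, proportionally thinner
    # along the others
    amax = float(radii.max())
    gm_t, wm_t = geometry.resolved_thicknesses(radii)
    rho_wm = 1.0 - gm_t / amax
    rho_vent = 1.0 - (gm_t + wm_t) / amax
    if rho_vent * radii.min() < 2:
        raise ValueError("shell thicknesses leave no room for the ventricle")

    idx = np.indices(grid_shape, dtype=float)
    d = idx - center.reshape(3, 1, 1, 1)
    rho_grid = np.sqrt(((d / radii.reshape(3, 1, 1, 1)) ** 2).sum(axis=0))

    labels = np.zeros(grid_shape, dtype=np.int16)
    labels[rho_grid <= 1.0] = LABEL_GM
    labels[rho_grid <= rho_wm] = LABEL_WM
    labels[rho_grid <= rho_vent] = LABEL_VENTRICLE
    stem_center = center.copy()
    stem_center[2] -= radii[2]
    ds = idx - stem_center.reshape(3, 1, 1, 1)
    in_stem = np.sqrt(((ds / stem_radii.reshape(3, 1, 1, 1)) ** 2).sum(axis=0)) <= 1.0
    labels[in_stem & (labels == LABEL_BACKGROUND)] = LABEL_BRAINSTEM

    intensity = np.zeros(grid_shape, dtype=np.float64)
    for code, value in _LABEL_INTENSITY.items():
        intensity[labels == code] = value
    # deterministic smooth texture: gives the intensity-driven registration
    # signal inside otherwise uniform compartments (cf. real MR tissue
    # heterogeneity); without it dense Jacobian recovery is ill-posed
    rng = np.random.default_rng(_TEXTURE_SEED)
    texture = gaussian_filter(rng.standard_normal(grid_shape), _TEXTURE_SIGMA)
    texture *= _TEXTURE_AMPLITUDE / max(texture.std(), 1e-12)
    intensity += texture * (labels != LABEL_BACKGROUND)
    intensity = gaussian_filter(intensity, 0.6)  # soften compartment edges
    intensity[labels == LABEL_BACKGROUND] *= 0.0
    np.clip(intensity, 0.0, 1.2, out=intensity)

    return PhantomTemplate(
        intensity=intensity,
        labels=labels,
        voxel_size_mm=float(voxel_size_mm),
        geometry=geometry,
        center=center,
        radii=radii,
    )


def simulate_genotypes(n: int, maf: float, seed: int) -> np.ndarray:
    """Draw risk-allele doses under Hardy-Weinberg proportions.

    With minor-allele frequency ``q`` the genotype probabilities are
    ((1-q)^2, 2q(1-q), q^2) for doses (0, 1, 2).
    """
    if not 0.0 <= maf <= 0.5:
        raise ValueError(f"maf must lie in [0, 0.5], got {maf}")
    if n < 1:
        raise ValueError("n must be >= 1")
    q = float(maf)
    probs = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    rng = np.random.default_rng(seed)
    return rng.choice(3, size=int(n), p=probs).astype(np.int64)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def sample_intervals(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw follow-up intervals from the observed frequency table."""
    p = INTERVAL_COUNTS / INTERVAL_COUNTS.sum()
    return INTERVAL_MONTHS[rng.choice(len(p), size=n, p=p)].astype(float)


def simulate_covariates(
    doses,
    effect: EffectSpec | None = None,
    demo: DemographicSpec | None = None,
    seed: int = 0,
    longitudinal: bool = False,
) -> list[SubjectRecord]:
    """Generate subject records aligned index-wise with ``doses``.

    Homocysteine follows ``baseline + hcy_per_allele * dose + N(0, sigma)``;
    age is truncated normal; folate is independent of dose.
    """
    doses = np.asarray(doses, dtype=int)
    if doses.size == 0:
        raise ValueError("doses must be nonempty")
    effect = effect or EffectSpec()
    demo = demo or DemographicSpec()
    rng = np.random.default_rng(seed)
    n = doses.size
    ages = _truncated_normal(rng, demo.age_mean, demo.age_sd, *demo.age_range, n)
    sexes = (rng.random(n) < demo.male_fraction).astype(int)
    hcy = effect.hcy_baseline + effect.hcy_per_allele * doses + rng.normal(
        0.0, effect.sigma_hcy, n
    )
    hcy = np.maximum(hcy, 1.0)
    folate = np.maximum(rng.normal(demo.folate_mean, demo.folate_sd, n), 10.0)
    apoe4 = rng.choice(3, size=n, p=np.asarray(demo.apoe4_probs))
    intervals = sample_intervals(n, rng) if longitudinal else [None] * n
    width = max(4, len(str(n)))
    return [
        SubjectRecord(
            subject_id=f"S{i:0{width}d}",
            dose=int(doses[i]),
            age=float(ages[i]),
            sex=int(sexes[i]),
            homocysteine=float(hcy[i]),
            folate=float(folate[i]),
            apoe4=int(apoe4[i]),
            interval_months=None if intervals[i] is None else float(intervals[i]),
        )
        for i in range(n)
    ]


def implanted_percent(record: SubjectRecord, effect: EffectSpec) -> float:
    """Scalar percent volume change implanted for one subject.

    The direct path scales with dose; the mediated path scales with the
    subject's homocysteine excess over baseline, calibrated so the expected
    total effect per allele equals ``percent_per_allele`` at any
    mediation_fraction.
    """
    direct = effect.percent_per_allele * (1.0 - effect.mediation_fraction) * record.dose
    mediated = 0.0
    if effect.mediation_fraction > 0:
        if record.homocysteine is None:
            raise ValueError("mediated effect requires a homocysteine value")
        slope = effect.percent_per_allele * effect.mediation_fraction / effect.hcy_per_allele
        mediated = slope * (record.homocysteine - effect.hcy_baseline)
    return direct + mediated


def _smoothstep(t):
    t = np.clip(t, 0.0, 1.0)
    return 3 * t**2 - 2 * t**3


def _jacobian_profile(template: PhantomTemplate, percent: float, rg: np.ndarray):
    """Radial Jacobian-determinant profile J(rho) of the implanted warp.

    The white-matter shell carries a uniform factor 1 + percent/100.  The
    displaced volume is released into the extra-cerebral CSF space just
    beyond the brain surface (the brain shrinks within a fixed skull, the
    usual picture of age-related atrophy), so inside the brain the warp is
    the implanted deficit plus narrow transitions, it is identity far from
    the head, and it conserves total volume.
    """
    a = template.radii
    amax = float(a.max())
    amin = float(a.min())
    gm_t, wm_t = template.geometry.resolved_thicknesses(a)
    rho_wm_out = 1.0 - gm_t / amax
    rho_wm_in = 1.0 - (gm_t + wm_t) / amax
    trans = 1.2 / amin  # transition width ~1.2 voxels
    rho_csf_lo = 1.0 - 0.3 / amin  # expansion starts at the brain surface
    rho_csf_hi = 1.0 + 3.0 / amin

    mu = percent / 100.0  # target J - 1 in white matter
    wm_band = _smoothstep((rg - (rho_wm_in - trans)) / trans) * (
        1.0 - _smoothstep((rg - rho_wm_out) / trans)
    )
    csf_bump = _smoothstep((rg - rho_csf_lo) / trans) * (
        1.0 - _smoothstep((rg - (rho_csf_hi - trans)) / trans)
    )
    w = rg**2
    deficit = -mu * np.trapezoid(w * wm_band, rg)  # volume to re-absorb
    vol_csf = np.trapezoid(w * csf_bump, rg)
    J = 1.0 + mu * wm_band + (deficit / max(vol_csf, 1e-12)) * csf_bump
    return J


def _radial_warp_arrays(template: PhantomTemplate, percent: float):
    """Analytic local contraction of the white-matter shell.

    The warp is radial in the normalized elliptical coordinate rho: a point
    at elliptical radius rho maps to f(rho), with f obtained by integrating
    the prescribed Jacobian profile, f(rho)^3 = 3 * int_0^rho t^2 J(t) dt.
    For a radial map x -> x0 + (x - x0) f(rho)/rho the determinant is
    exactly (f/rho)^2 f'(rho) = J(rho), so the per-voxel ground truth is the
    profile itself, evaluated at each voxel's rho.

    Returns (gt_jacobian on the template grid, sampling coordinates that
    pull the template into subject space).
    """
    if percent <= -100.0:
        raise ValueError("requested contraction <= -100% is non-invertible")
    shape = template.grid_shape
    idx = np.indices(shape, dtype=float)
    if percent == 0.0:
        return np.ones(shape), idx  # exact identity
    rho = template.elliptical_radius(idx)

    rho_max = float(rho.max()) + 1.0
    rg = np.linspace(1e-6, rho_max, 8192)
    J = _jacobian_profile(template, percent, rg)
    if np.any(J <= 0):
        raise ValueError("requested contraction yields a non-invertible warp")
    f3 = 3.0 * np.concatenate(
        [[0.0], np.cumsum(0.5 * (rg[1:] ** 2 * J[1:] + rg[:-1] ** 2 * J[:-1]) * np.diff(rg))]
    )
    f = np.cbrt(f3)

    gt_jac = np.interp(rho.ravel(), rg, J).reshape(shape)
    # subject voxel at radius rho_s came from template radius f^{-1}(rho_s)
    rho_t = np.interp(rho.ravel(), f, rg).reshape(shape)
    scale = np.divide(rho_t, rho, out=np.ones_like(rho), where=rho > 1e-9)
    coords = template.center.reshape(3, 1, 1, 1) + (
        idx - template.center.reshape(3, 1, 1, 1)
    ) * scale
    return gt_jac, coords


def _nuisance_field(shape, amplitude_vox, rng, sigma=4.0):
    """Random smooth displacement with the requested RMS amplitude."""
    u = np.stack([gaussian_filter(rng.standard_normal(shape), sigma) for _ in range(3)])
    rms = np.sqrt((u**2).sum(axis=0).mean())
    u *= amplitude_vox / max(rms, 1e-12)
    # clamp the outer shell so the head never leaves the grid
    for ax in range(3):
        sl = [slice(None)] * 4
        for edge in (0, -1):
            sl[ax + 1] = edge
            u[tuple(sl)] = 0.0
    return u


def _sample(volume, coords, order=1, cval=0.0):
    return map_coordinates(volume, coords, order=order, mode="constant", cval=cval)


def synthesize_subject_volume(
    template: PhantomTemplate,
    record: SubjectRecord,
    effect: EffectSpec | None = None,
    seed: int = 0,
    percent_override: float | None = None,
    _shared_rng_salt: int = 0,
    _noise_salt: int = 1,
) -> SubjectVolume:
    """Warp the template by the subject's implanted contraction, add a random
    smooth nuisance warp and intensity noise.

    The returned ``gt_jacobian`` is the exact analytic Jacobian determinant of
    the implanted (effect) warp on the template grid; the nuisance warp and
    noise are treated as measurement confounds, not signal.
    """
    effect = effect or EffectSpec()
    if not np.any(template.labels == effect.target_label):
        raise ValueError(f"target label {effect.target_label} absent from template")
    percent = (
        implanted_percent(record, effect) if percent_override is None else percent_override
    )
    gt_jac, coords = _radial_warp_arrays(template, percent)

    rng = subject_rng(seed, record.subject_id, salt=_shared_rng_salt)
    amp_vox = effect.nuisance_warp_mm / template.voxel_size_mm
    if amp_vox > 0:
        nu = _nuisance_field(template.grid_shape, amp_vox, rng)
        idx = np.indices(template.grid_shape, dtype=float)
        pts = idx + nu
        # compose: subject voxel -> nuisance-perturbed point -> template coord
        coords = np.stack([_sample(coords[a], pts, order=1) for a in range(3)])
    else:
        rng.standard_normal(1)  # keep the noise stream aligned across settings

    image = _sample(template.intensity, coords, order=1)
    labels = _sample(template.labels.astype(float), coords, order=0).astype(np.int16)

    noise_rng = subject_rng(seed, record.subject_id, salt=_noise_salt)
    if effect.noise_sd > 0:
        image = image + noise_rng.normal(0.0, effect.noise_sd, template.grid_shape)
    return SubjectVolume(
        image=image, gt_jacobian=gt_jac, labels=labels, percent_implanted=percent
    )


def synthesize_followup_pair(
    template: PhantomTemplate,
    record: SubjectRecord,
    effect: EffectSpec | None = None,
    seed: int = 0,
) -> tuple[SubjectVolume, SubjectVolume]:
    """Baseline and follow-up scans of one subject.

    The follow-up applies an extra contraction of
    ``annual_percent_per_allele * dose * interval/12`` percent on top of the
    baseline warp, multiplicatively, so the follow-up/baseline Jacobian in the
    target region equals ``1 + extra/100`` exactly.  The anatomical nuisance
    warp is shared between the two scans (same subject); intensity noise is
    drawn independently per scan.
    """
    effect = effect or EffectSpec()
    if record.interval_months is None:
        raise ValueError("longitudinal synthesis requires interval_months")
    p_base = implanted_percent(record, effect)
    extra = effect.annual_percent_per_allele * record.dose * record.interval_months / 12.0
    p_follow = ((1.0 + p_base / 100.0) * (1.0 + extra / 100.0) - 1.0) * 100.0
    baseline = synthesize_subject_volume(
        template, record, effect, seed, percent_override=p_base
    )
    # identical nuisance stream (same shared salt), fresh intensity noise
    follow = synthesize_subject_volume(
        template,
        record,
        replace(effect),
        seed,
        percent_override=p_follow,
        _noise_salt=17,
    )
    return baseline, follow
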