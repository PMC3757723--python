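"""Formats, configuration and end-to-end orchestration.

Volumes travel as NIfTI-1 with an identity affine scaled by the voxel size;
covariates as a tab-separated table; the run configuration as plain-text
``key = value`` lines.  ``run_pipeline`` chains simulate -> template ->
register -> jacobian -> smooth -> voxel-wise GLM -> FDR -> report and
records every stage in a manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import binary_dilation

from . import fdr as fdr_mod
from . import glm as glm_mod
from .cohort import wm_volume_regression
from .jacobian import (
    annualize,
    jacobian_determinant,
    log_volume_map,
    percent_volume_map,
    smooth_change_map,
)
from .phantom import (
    LABEL_BRAINSTEM,
    LABEL_GM,
    LABEL_VENTRICLE,
    LABEL_WM,
    DemographicSpec,
    EffectSpec,
    PhantomTemplate,
    SubjectRecord,
    make_template_phantom,
    simulate_covariates,
    simulate_genotypes,
    synthesize_followup_pair,
    synthesize_subject_volume,
)
from .registration import (
    RegistrationConfig,
    build_mdt,
    register_nonlinear,
    warp_volume,
)

__all__ = [
    "read_volume",
    "write_volume",
    "write_change_map",
    "read_covariates",
    "write_covariates",
    "RunConfig",
    "RunManifest",
    "analysis_mask",
    "implant_region",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = [
    "subject_id",
    "dose",
    "age",
    "sex",
    "hcy",
    "folate",
    "apoe4",
    "interval_months",
]


# ---------------------------------------------------------------------------
# volumes


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Load a NIfTI-1 volume, reorienting to canonical axes if needed."""
    img = nib.load(str(path))
    canon = nib.as_closest_canonical(img)
    if canon.affine is not img.affine and not np.allclose(canon.affine, img.affine):
        logger.info("reoriented %s to canonical axis order", path)
    data = np.asarray(canon.dataobj, dtype=np.float64)
    zooms = tuple(float(z) for z in canon.header.get_zooms()[:3])
    return data, zooms


def write_volume(data: np.ndarray, path, voxel_size_mm=1.0) -> Path:
    """Write a volume as NIfTI-1 with an identity affine scaled by voxel size."""
    path = Path(path)
    zooms = (
        (voxel_size_mm,) * 3 if np.isscalar(voxel_size_mm) else tuple(voxel_size_mm)
    )
    affine = np.diag(list(zooms) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, np.float32), affine)
    img.header.set_zooms(zooms)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def write_change_map(change, path, voxel_size_mm=1.0, smoothing_sigma=None,
                     provenance=None) -> Path:
    """Write a change map with a sidecar text file recording its mode,
    smoothing, and provenance (source field / config hash)."""
    path = Path(path)
    write_volume(change.c, path, voxel_size_mm)
    lines = [f"mode = {change.mode}"]
    if smoothing_sigma is not None:
        lines.append(f"smoothing_sigma_voxels = {smoothing_sigma}")
    for key, val in (provenance or {}).items():
        lines.append(f"{key} = {val}")
    sidecar = path.with_name(path.name.split(".")[0] + ".provenance.txt")
    sidecar.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# covariates


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_covariates(records: list[SubjectRecord], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["\t".join(COVARIATE_COLUMNS)]
    for r in records:
        lines.append(
            "\t".join(
                _fmt(v)
                for v in (
                    r.subject_id,
                    r.dose,
                    r.age,
                    r.sex,
                    r.homocysteine,
                    r.folate,
                    r.apoe4,
                    r.interval_months,
                )
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_covariates(path) -> list[SubjectRecord]:
    """Parse the tab-separated covariate table; empty fields mean missing."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError("empty covariate file")
    header = lines[0].rstrip("\n").split("\t")
    if header != COVARIATE_COLUMNS:
        raise ValueError(
            f"unexpected header {header}; expected {COVARIATE_COLUMNS}"
        )
    records = []
    seen = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(COVARIATE_COLUMNS):
            raise ValueError(f"line {lineno}: expected {len(COVARIATE_COLUMNS)} fields")
        vals = dict(zip(COVARIATE_COLUMNS, parts))
        sid = vals["subject_id"]
        if sid in seen:
            raise ValueError(f"line {lineno}: duplicate subject id {sid!r}")
        seen.add(sid)
        try:
            dose = int(vals["dose"])
        except ValueError:
            raise ValueError(f"line {lineno}: dose {vals['dose']!r} is not an integer")
        if dose not in (0, 1, 2):
            raise ValueError(f"line {lineno}: dose must be 0, 1 or 2, got {dose}")

        def opt_float(key):
            return float(vals[key]) if vals[key] != "" else None

        records.append(
            SubjectRecord(
                subject_id=sid,
                dose=dose,
                age=float(vals["age"]),
                sex=int(vals["sex"]),
                homocysteine=opt_float("hcy"),
                folate=opt_float("folate"),
                apoe4=int(vals["apoe4"]) if vals["apoe4"] != "" else None,
                interval_months=opt_float("interval_months"),
            )
        )
    return records


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    seed: int = 0
    n: int = 120
    maf: float = 0.31
    mode: str = "cross_sectional"  # or "longitudinal"
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: float = 1.0
    effect: EffectSpec = field(default_factory=EffectSpec)
    demo: DemographicSpec = field(default_factory=DemographicSpec)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    # baseline/follow-up pairs differ by a sub-voxel warp: a single-level
    # inverse-consistent registration resolves it
    pair_registration: RegistrationConfig = field(
        default_factory=lambda: RegistrationConfig(
            symmetric=True, n_levels=1, iters_per_level=(30,)
        )
    )
    smoothing_sigma: float = 1.5
    use_log_jacobian: bool = False
    models: tuple[str, ...] = ("base",)
    q: float = 0.05
    mdt_subjects: int = 0  # 0: register to the phantom template directly
    mdt_iters: int = 2
    annualize_by_actual_interval: bool = True
    write_volumes: bool = False
    out_dir: str = "tbm_run"

    def __post_init__(self):
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")
        if self.mode not in ("cross_sectional", "longitudinal"):
            raise ValueError(f"invalid mode {self.mode!r}")

    # -- plain-text round trip ------------------------------------------------
    _NESTED = {"effect": EffectSpec, "demo": DemographicSpec,
               "registration": RegistrationConfig,
               "pair_registration": RegistrationConfig}

    def to_file(self, path) -> Path:
        path = Path(path)
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name in self._NESTED:
                for sub in dataclasses.fields(v):
                    lines.append(f"{f.name}.{sub.name} = {_cfg_fmt(getattr(v, sub.name))}")
            else:
                lines.append(f"{f.name} = {_cfg_fmt(v)}")
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text("\n".join(lines) + "\n")
        return path

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            raw[key] = val
        kwargs: dict = {}
        nested: dict[str, dict] = {k: {} for k in cls._NESTED}
        for key, val in raw.items():
            if "." in key:
                head, sub = key.split(".", 1)
                if head not in nested:
                    raise ValueError(f"unknown config section {head!r}")
                nested[head][sub] = val
            else:
                kwargs[key] = val
        cfg_fields = {f.name: f for f in dataclasses.fields(cls)}
        for key in list(kwargs):
            if key not in cfg_fields:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = _cfg_parse(kwargs[key], cfg_fields[key].type)
        for head, sub_cls in cls._NESTED.items():
            if nested[head]:
                sub_fields = {f.name: f for f in dataclasses.fields(sub_cls)}
                sub_kwargs = {}
                for sub, val in nested[head].items():
                    if sub not in sub_fields:
                        raise ValueError(f"unknown config key {head}.{sub!r}")
                    sub_kwargs[sub] = _cfg_parse(val, sub_fields[sub].type)
                kwargs[head] = sub_cls(**sub_kwargs)
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _cfg_fmt(v) -> str:
    if isinstance(v, (tuple, list)):
        return ",".join(_cfg_fmt(x) for x in v)
    if isinstance(v, bool):
        return "true" if v else "false"
    return str(v)


def _cfg_parse(text: str, annot: str):
    annot = str(annot)
    text = text.strip()
    if "bool" in annot:
        return text.lower() in ("1", "true", "yes")
    if "tuple" in annot:
        parts = [p for p in text.split(",") if p.strip() != ""]
        if "str" in annot:
            return tuple(p.strip() for p in parts)
        if "int" in annot and "float" not in annot:
            return tuple(int(float(p)) for p in parts)
        return tuple(float(p) for p in parts)
    if "int" in annot:
        return int(text)
    if "float" in annot:
        return float(text)
    return text


# ---------------------------------------------------------------------------
# masks


def analysis_mask(template: PhantomTemplate) -> np.ndarray:
    """Brain tissue excluding the brainstem: gray + white matter plus the
    ventricle shell adjacent to white matter (partial-volume zone)."""
    labels = template.labels
    mask = (labels == LABEL_GM) | (labels == LABEL_WM)
    vent_shell = (labels == LABEL_VENTRICLE) & binary_dilation(labels == LABEL_WM)
    mask |= vent_shell
    mask &= labels != LABEL_BRAINSTEM
    return mask


def implant_region(template: PhantomTemplate, effect: EffectSpec) -> np.ndarray:
    return template.labels == effect.target_label


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunManifest:
    config_hash: str
    stages: dict = field(default_factory=dict)
    files: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    report: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)

    def add_stage(self, name: str, seconds: float, **info):
        self.stages[name] = {"seconds": round(seconds, 3), **info}

    def add_file(self, path):
        self.files.append(str(path))

    def write(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))
        return path


class _Timer:
    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.seconds = time.perf_counter() - self.t0


def _hemisphere_wm_volumes(labels_stack, template: PhantomTemplate):
    """Left/right white-matter volumes (cc) from warped subject labels."""
    half = template.grid_shape[0] // 2
    vox_cc = (template.voxel_size_mm / 10.0) ** 3
    left = np.array(
        [(lab[:half] == LABEL_WM).sum() * vox_cc for lab in labels_stack]
    )
    right = np.array(
        [(lab[half:] == LABEL_WM).sum() * vox_cc for lab in labels_stack]
    )
    return {"left": left, "right": right}


def simulate_cohort(config: RunConfig):
    """Genotypes, covariates and synthetic scans for one cohort."""
    doses = simulate_genotypes(config.n, config.maf, config.seed)
    records = simulate_covariates(
        doses,
        config.effect,
        config.demo,
        seed=config.seed + 1,
        longitudinal=config.mode == "longitudinal",
    )
    return records


def _registration_target(template, records, config, manifest):
    """The phantom template, or an MDT built from extra dose-0 subjects."""
    if config.mdt_subjects <= 0:
        return template.intensity, "template"
    mdt_records = [
        SubjectRecord(subject_id=f"MDT{i:03d}", dose=0, age=75.0, sex=i % 2,
                      homocysteine=config.effect.hcy_baseline)
        for i in range(config.mdt_subjects)
    ]
    vols = [
        synthesize_subject_volume(
            template, r, config.effect, seed=config.seed + 7
        ).image
        for r in mdt_records
    ]
    with _Timer() as t:
        mdt, _ = build_mdt(vols, n_iter=config.mdt_iters, config=config.registration)
    manifest.add_stage("mdt", t.seconds, n_subjects=config.mdt_subjects)
    return mdt, "mdt"


def subject_change_map(template, target, record, config, longitudinal=False):
    """Synthesize one subject and measure the percent change map.

    Cross-sectional: register the subject scan to the target and take the
    percent Jacobian map on the template grid.  Longitudinal: register
    follow-up to baseline (inverse-consistent), annualize, and carry the
    map into template space through the baseline-to-template registration.
    """
    to_percent = log_volume_map if config.use_log_jacobian else percent_volume_map
    if not longitudinal:
        sv = synthesize_subject_volume(template, record, config.effect, config.seed)
        fld = register_nonlinear(sv.image, target, config.registration)
        change = to_percent(jacobian_determinant(fld))
        return smooth_change_map(change, config.smoothing_sigma), sv
    base, follow = synthesize_followup_pair(
        template, record, config.effect, config.seed
    )
    fld_pair = register_nonlinear(follow.image, base.image, config.pair_registration)
    change = to_percent(jacobian_determinant(fld_pair))
    months = (
        record.interval_months if config.annualize_by_actual_interval else 12.0
    )
    change = annualize(change, months)
    # map into template space: sample the baseline-space rate map at the
    # template->baseline correspondence
    fld_tb = register_nonlinear(base.image, target, config.registration)
    c_t = warp_volume(change.c, fld_tb)
    change = dataclasses.replace(change, c=c_t)
    return smooth_change_map(change, config.smoothing_sigma), base


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full chain and write the summary report.

    Returns the manifest; numeric results live in ``manifest.report``.
    """
    import nibabel
    import scipy

    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.config_hash(),
        versions={
            "tbmtools": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "nibabel": nibabel.__version__,
        },
    )
    longitudinal = config.mode == "longitudinal"

    with _Timer() as t:
        template = make_template_phantom(
            config.grid_shape, voxel_size_mm=config.voxel_size_mm
        )
        records = simulate_cohort(config)
    manifest.add_stage("simulate", t.seconds, n=len(records))
    cov_path = write_covariates(records, out / "covariates.tsv")
    manifest.add_file(cov_path)
    manifest.add_file(
        write_volume(template.intensity, out / "template.nii.gz", config.voxel_size_mm)
    )
    manifest.add_file(
        write_volume(template.labels, out / "template_labels.nii.gz", config.voxel_size_mm)
    )

    target, target_kind = _registration_target(template, records, config, manifest)
    if target_kind == "mdt":
        manifest.add_file(
            write_volume(target, out / "mdt.nii.gz", config.voxel_size_mm)
        )

    with _Timer() as t:
        stack, labels_stack = [], []
        for rec in records:
            change, sv = subject_change_map(
                template, target, rec, config, longitudinal=longitudinal
            )
            stack.append(change)
            labels_stack.append(sv.labels)
            if config.write_volumes:
                p = write_volume(
                    sv.image, out / "subjects" / f"{rec.subject_id}.nii.gz",
                    config.voxel_size_mm,
                )
                manifest.add_file(p)
    manifest.add_stage("register_jacobian", t.seconds, n=len(records))

    mask = analysis_mask(template)
    region = implant_region(template, config.effect)
    report: dict = {
        "mode": config.mode,
        "registration_target": target_kind,
        "n_subjects": len(records),
    }

    with _Timer() as t:
        fits = {}
        for model in config.models:
            design = glm_mod.assemble_design(records, model)
            maps = [stack[i] for i, r in enumerate(records)
                    if r.subject_id in set(design.subject_ids)]
            fits[model] = glm_mod.VoxelwiseOLS(maps, design, mask).fit()
            res = fits[model]
            fdr_res = res.fdr("dose", config.q)
            thr = fdr_mod.threshold_maps(res, "dose", fdr_res)
            in_region = thr["survivor_mask"] & binary_dilation(region, iterations=2)
            frac_in = (
                float(in_region.sum() / thr["survivor_mask"].sum())
                if thr["survivor_mask"].any()
                else np.nan
            )
            report[model] = {
                "dose_beta_region_mean": res.region_mean_beta("dose", region),
                "critical_p": thr["critical_p"],
                "n_surviving": thr["n_surviving"],
                "peak_abs_beta": thr["peak_abs_beta"],
                "survivor_fraction_in_region": frac_in,
                "n_complete_cases": design.n,
            }
            beta_path = write_volume(
                np.nan_to_num(res.beta_map("dose")),
                out / f"beta_dose_{model.replace('+', 'adj_')}.nii.gz",
                config.voxel_size_mm,
            )
            manifest.add_file(beta_path)
        if "base" in fits:
            for model in config.models:
                if model == "base":
                    continue
                att = glm_mod.attenuation_report(fits["base"], fits[model], region)
                report[model]["attenuation_ratio_vs_base"] = att["ratio"]
    manifest.add_stage("glm_fdr", t.seconds, models=list(config.models))

    if not longitudinal:
        wm = _hemisphere_wm_volumes(labels_stack, template)
        wm_fit = wm_volume_regression(records, wm)
        report["wm_volume_regression"] = {
            hemi: {k: float(v) for k, v in row.items()}
            for hemi, row in wm_fit.iterrows()
        }

    manifest.report = report
    report_path = out / "report.tsv"
    _write_report_tsv(report, report_path)
    manifest.add_file(report_path)
    manifest_path = manifest.write(out / "manifest.json")
    missing = [f for f in manifest.files if not Path(f).exists()]
    if missing:
        raise RuntimeError(f"manifest lists missing files: {missing}")
    logger.info("pipeline complete: %s", manifest_path)
    return manifest


def _flatten(d, prefix=""):
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            yield from _flatten(v, key + ".")
        else:
            yield key, v


def _write_report_tsv(report: dict, path) -> Path:
    path = Path(path)
    lines = ["key\tvalue"]
    for k, v in _flatten(report):
        if isinstance(v, float):
            v = f"{v:.6g}"
        lines.append(f"{k}\t{v}")
    path.write_text("\n".join(lines) + "\n")
    return path
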