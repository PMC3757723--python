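"""Voxel-wise additive allele-dose regression.

At every voxel inside the analysis mask an ordinary least squares model

    y = b0 + b_dose * dose + b_age * age + b_sex * sex (+ adjustments) + e

is fitted across subjects, where y is the percent volume change at that
voxel.  The dose predictor is the risk-allele count coded 0/1/2, so
``b_dose`` is the average percent brain tissue change per risk allele.
Optional adjustment sets add ApoE4 allele count, homocysteine, folate, or a
dose-by-ApoE4 interaction.

The interface follows the Model / Results pattern: ``VoxelwiseOLS`` holds
the data and design, ``fit()`` returns a ``VoxelwiseOLSResults`` carrying
beta / SE / t / p maps per predictor, with ``summary()`` and ``fdr()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .jacobian import ChangeMap
from .phantom import SubjectRecord

__all__ = [
    "DesignMatrix",
    "assemble_design",
    "VoxelwiseOLS",
    "VoxelwiseOLSResults",
    "attenuation_report",
    "MODELS",
]

logger = logging.getLogger(__name__)

MODELS = ("base", "+apoe4", "+hcy", "+folate", "+apoe4_interaction")

_EXTRA_COLUMNS = {
    "base": [],
    "+apoe4": ["apoe4"],
    "+hcy": ["hcy"],
    "+folate": ["folate"],
    "+apoe4_interaction": ["apoe4", "dose_x_apoe4"],
}


@dataclass
class DesignMatrix:
    X: np.ndarray  # n x k
    columns: list[str]
    subject_ids: list[str]
    dropped_ids: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.columns, index=self.subject_ids)


def _record_value(rec: SubjectRecord, col: str):
    if col == "hcy":
        return rec.homocysteine
    return getattr(rec, col)


def assemble_design(
    records: list[SubjectRecord],
    model: str = "base",
    apoe4_carrier: bool = False,
) -> DesignMatrix:
    """Build the design matrix for one adjustment set.

    Subjects missing any required covariate are dropped (complete-case) and
    logged.  Age is centered at the sample mean; dose stays raw 0/1/2.
    ``apoe4_carrier`` recodes ApoE4 as a carrier indicator instead of allele
    count.
    """
    if not records:
        raise ValueError("records must be nonempty")
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    extras = _EXTRA_COLUMNS[model]
    needed = ["dose", "age", "sex"] + [c for c in extras if c != "dose_x_apoe4"]

    kept, dropped = [], []
    for rec in records:
        if any(_record_value(rec, c) is None for c in needed):
            dropped.append(rec.subject_id)
        else:
            kept.append(rec)
    if dropped:
        logger.info("complete-case: dropped %d subjects: %s", len(dropped), dropped)
    if not kept:
        raise ValueError("no complete cases for model " + model)

    cols = {"intercept": np.ones(len(kept))}
    cols["dose"] = np.array([r.dose for r in kept], float)
    age = np.array([r.age for r in kept], float)
    cols["age"] = age - age.mean()
    cols["sex"] = np.array([r.sex for r in kept], float)
    for c in extras:
        if c == "dose_x_apoe4":
            continue
        v = np.array([_record_value(r, c) for r in kept], float)
        if c == "apoe4" and apoe4_carrier:
            v = (v > 0).astype(float)
        cols[c] = v
    if "dose_x_apoe4" in extras:
        cols["dose_x_apoe4"] = cols["dose"] * cols["apoe4"]

    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    if cols["dose"].std() == 0:
        raise ValueError("design invalid: column 'dose' has zero variance")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the offending column: first column collinear with the rest
        for j in range(1, X.shape[1]):
            sub = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(X):
                raise ValueError(f"design rank-deficient: column {names[j]!r}")
        raise ValueError("design rank-deficient")
    return DesignMatrix(
        X=X,
        columns=names,
        subject_ids=[r.subject_id for r in kept],
        dropped_ids=dropped,
    )


class VoxelwiseOLS:
    """Mass-univariate OLS over a stack of aligned change maps.

    Parameters
    ----------
    stack : list of ChangeMap or ndarray (n_subjects, *grid)
        Per-subject response maps, row order matching the design.
    design : DesignMatrix
    mask : boolean ndarray on the map grid
        Analysis mask; voxels outside are never fitted.
    subject_ids : optional list checked against the design rows.
    """

    def __init__(self, stack, design: DesignMatrix, mask: np.ndarray, subject_ids=None):
        if isinstance(stack, (list, tuple)):
            modes = {m.mode for m in stack if isinstance(m, ChangeMap)}
            if len(modes) > 1:
                raise ValueError("mixed change-map modes in stack")
            arrs = [m.c if isinstance(m, ChangeMap) else np.asarray(m) for m in stack]
            stack = np.stack(arrs)
        self.stack = np.asarray(stack, float)
        self.design = design
        self.mask = np.asarray(mask, bool)
        if self.stack.shape[0] != design.n:
            raise ValueError(
                f"stack has {self.stack.shape[0]} rows, design has {design.n}"
            )
        if self.stack.shape[1:] != self.mask.shape:
            raise ValueError("mask grid does not match map grid")
        if subject_ids is not None and list(subject_ids) != design.subject_ids:
            raise ValueError("subject id order mismatch between stack and design")
        if design.n <= design.k + 5:
            raise ValueError("too few subjects for the requested design")

    def fit(self) -> "VoxelwiseOLSResults":
        X = self.design.X
        n, k = X.shape
        Y = self.stack[:, self.mask]  # n x V
        pinv = np.linalg.pinv(X)
        B = pinv @ Y  # k x V
        resid = Y - X @ B
        df = n - k
        rss = (resid**2).sum(axis=0)
        sigma2 = rss / df
        XtX_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
        # voxels where the response is constant across subjects carry no
        # information: flag them out of the valid-test set
        valid = Y.std(axis=0) > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            T = np.where(se > 0, B / se, np.nan)
        P = 2.0 * stats.t.sf(np.abs(T), df)
        return VoxelwiseOLSResults(
            model=self, beta_flat=B, se_flat=se, t_flat=T, p_flat=P,
            sigma2_flat=sigma2, valid_flat=valid, df=df,
        )


@dataclass
class VoxelwiseOLSResults:
    """Per-predictor beta/SE/t/p maps from a voxel-wise OLS fit."""

    model: VoxelwiseOLS
    beta_flat: np.ndarray  # k x V over masked voxels
    se_flat: np.ndarray
    t_flat: np.ndarray
    p_flat: np.ndarray
    sigma2_flat: np.ndarray
    valid_flat: np.ndarray
    df: int

    @property
    def predictors(self) -> list[str]:
        return self.model.design.columns

    def _idx(self, predictor: str) -> int:
        try:
            return self.predictors.index(predictor)
        except ValueError:
            raise KeyError(f"predictor {predictor!r} not in {self.predictors}")

    def _to_map(self, flat: np.ndarray) -> np.ndarray:
        out = np.full(self.model.mask.shape, np.nan)
        out[self.model.mask] = flat
        return out

    def beta_map(self, predictor: str) -> np.ndarray:
        return self._to_map(self.beta_flat[self._idx(predictor)])

    def se_map(self, predictor: str) -> np.ndarray:
        return self._to_map(self.se_flat[self._idx(predictor)])

    def t_map(self, predictor: str) -> np.ndarray:
        return self._to_map(self.t_flat[self._idx(predictor)])

    def p_map(self, predictor: str) -> np.ndarray:
        return self._to_map(self.p_flat[self._idx(predictor)])

    def residual_variance_map(self) -> np.ndarray:
        return self._to_map(self.sigma2_flat)

    def valid_pvalues(self, predictor: str) -> np.ndarray:
        """p-values of non-degenerate voxel tests (the FDR input)."""
        return self.p_flat[self._idx(predictor)][self.valid_flat]

    @property
    def n_valid(self) -> int:
        return int(self.valid_flat.sum())

    def fdr(self, predictor: str = "dose", q: float = 0.05):
        from .fdr import bh_critical_p

        return bh_critical_p(self.valid_pvalues(predictor), q)

    def region_mean_beta(self, predictor: str, region: np.ndarray) -> float:
        b = self.beta_map(predictor)
        return float(np.nanmean(b[region & self.model.mask]))

    def summary(self) -> str:
        lines = [
            "Voxel-wise OLS",
            f"  subjects: {self.model.design.n}   predictors: {self.predictors}",
            f"  masked voxels: {int(self.model.mask.sum())} "
            f"(valid tests: {self.n_valid})   residual df: {self.df}",
            f"{'predictor':<14}{'mean beta':>12}{'mean |t|':>12}{'min p':>12}",
        ]
        for name in self.predictors:
            i = self._idx(name)
            lines.append(
                f"{name:<14}{np.nanmean(self.beta_flat[i]):>12.4f}"
                f"{np.nanmean(np.abs(self.t_flat[i])):>12.3f}"
                f"{np.nanmin(self.p_flat[i][self.valid_flat]):>12.3g}"
            )
        return "\n".join(lines)


def attenuation_report(
    fit_base: VoxelwiseOLSResults,
    fit_adjusted: VoxelwiseOLSResults,
    region: np.ndarray,
    predictor: str = "dose",
) -> dict:
    """Mean |dose beta| in a region before/after covariate adjustment.

    A ratio well below 1 means the adjustment absorbed the allele effect,
    the signature of mediation through the adjusted covariate.
    """
    region = np.asarray(region, bool)
    if fit_base.model.mask.shape != fit_adjusted.model.mask.shape:
        raise ValueError("fits live on different grids")
    if not region.any():
        raise ValueError("empty region")
    mean_abs = []
    for res in (fit_base, fit_adjusted):
        b = res.beta_map(predictor)
        vals = np.abs(b[region & res.model.mask])
        mean_abs.append(float(np.nanmean(vals)))
    base, adj = mean_abs
    return {
        "mean_abs_beta_base": base,
        "mean_abs_beta_adjusted": adj,
        "ratio": adj / base if base > 0 else np.nan,
    }
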