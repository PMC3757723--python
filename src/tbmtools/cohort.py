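"""Scalar genotype-group statistics: demographic tables, chi-square and
ANOVA comparisons, and the post-hoc hemispheric white-matter volume
regressions against risk-allele dose."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .phantom import SubjectRecord

__all__ = [
    "GenotypeCounts",
    "genotype_percentages",
    "contingency_chi2",
    "group_anova",
    "wm_volume_regression",
    "demographics_table",
]

logger = logging.getLogger(__name__)

GENOTYPE_NAMES = {0: "CC", 1: "CT", 2: "TT"}


@dataclass(frozen=True)
class GenotypeCounts:
    n_cc: int
    n_ct: int
    n_tt: int

    @property
    def total(self) -> int:
        return self.n_cc + self.n_ct + self.n_tt


def _round_half_away(x: float, decimals: int = 1) -> float:
    factor = 10**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def genotype_percentages(counts: GenotypeCounts) -> tuple[float, float]:
    """(percent homozygous TT, percent heterozygous CT), one decimal,
    round-half-away-from-zero."""
    if counts.total <= 0:
        raise ValueError("total count must be positive")
    pct_tt = _round_half_away(100.0 * counts.n_tt / counts.total)
    pct_ct = _round_half_away(100.0 * counts.n_ct / counts.total)
    return pct_tt, pct_ct


def contingency_chi2(table) -> tuple[float, int, float]:
    """Pearson chi-square of independence, no continuity correction."""
    obs = np.asarray(table, float)
    if obs.ndim != 2 or np.any(obs < 0):
        raise ValueError("table must be a non-negative 2-D matrix")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), int(df), float(p)


def group_anova(values, groups) -> tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA: (F, df_between, df_within, p)."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in np.unique(groups)]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least 2 observations")
    F, p = stats.f_oneway(*samples)
    g = len(samples)
    n = values.size
    return float(F), g - 1, n - g, float(p)


def wm_volume_regression(
    records: list[SubjectRecord],
    wm_volumes: dict[str, np.ndarray] | pd.DataFrame,
) -> pd.DataFrame:
    """Per-hemisphere OLS of white-matter volume (cc) on dose, age, sex.

    ``wm_volumes`` holds one volume per subject per hemisphere, aligned with
    ``records``.  Returns a frame with the dose coefficient and two-sided p
    for each hemisphere.
    """
    if len(records) <= 10:
        raise ValueError("need more than 10 subjects")
    vols = pd.DataFrame(wm_volumes)
    if len(vols) != len(records):
        raise ValueError("wm_volumes not aligned with records")
    age = np.array([r.age for r in records], float)
    X = pd.DataFrame(
        {
            "dose": [r.dose for r in records],
            "age": age - age.mean(),
            "sex": [r.sex for r in records],
        },
        index=vols.index,
    )
    X = sm.add_constant(X)
    rows = {}
    for hemi in vols.columns:
        fit = sm.OLS(vols[hemi].to_numpy(float), X).fit()
        rows[hemi] = {
            "dose_beta": float(fit.params["dose"]),
            "dose_se": float(fit.bse["dose"]),
            "p": float(fit.pvalues["dose"]),
            "n": int(fit.nobs),
        }
    return pd.DataFrame(rows).T


def demographics_table(
    records: list[SubjectRecord],
    extra_measures: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-genotype n / mean (SE) table with ANOVA and chi-square tests.

    Continuous rows (age, homocysteine, folate, any ``extra_measures``) get
    a one-way ANOVA across genotype groups; the sex breakdown gets a
    Pearson chi-square.  SE = SD / sqrt(n) per cell.
    """
    if not records:
        raise ValueError("records must be nonempty")
    doses = np.array([r.dose for r in records])
    present = [g for g in (0, 1, 2) if (doses == g).any()]
    if len(present) < 2:
        logger.warning("single genotype group present; no tests emitted")

    measures: dict[str, np.ndarray] = {
        "age": np.array([r.age for r in records], float),
        "hcy": np.array(
            [np.nan if r.homocysteine is None else r.homocysteine for r in records]
        ),
        "folate": np.array(
            [np.nan if r.folate is None else r.folate for r in records], float
        ),
    }
    measures.update(extra_measures or {})
    sex = np.array([r.sex for r in records])

    rows = []
    # sample-size / sex row
    row = {"measure": "n (M/F)"}
    for g in (0, 1, 2):
        sel = doses == g
        row[GENOTYPE_NAMES[g]] = (
            f"{sel.sum()} ({(sex[sel] == 1).sum()}M/{(sex[sel] == 0).sum()}F)"
            if sel.any()
            else ""
        )
    if len(present) >= 2:
        table = [
            [(sex[doses == g] == 1).sum(), (sex[doses == g] == 0).sum()]
            for g in present
        ]
        try:
            chi2, df, p = contingency_chi2(np.array(table).T)
            row["test"] = f"chi2_{df} = {chi2:.2f}, p = {p:.3g}"
        except ValueError:
            row["test"] = ""
    else:
        row["test"] = ""
    rows.append(row)

    for name, vals in measures.items():
        row = {"measure": name}
        for g in (0, 1, 2):
            v = vals[(doses == g) & np.isfinite(vals)]
            if v.size:
                se = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else np.nan
                row[GENOTYPE_NAMES[g]] = f"{v.mean():.1f} ({se:.2f})"
            else:
                row[GENOTYPE_NAMES[g]] = ""
        groups_ok = [
            vals[(doses == g) & np.isfinite(vals)]
            for g in present
            if ((doses == g) & np.isfinite(vals)).sum() >= 2
        ]
        if len(groups_ok) >= 2:
            F, p = stats.f_oneway(*groups_ok)
            n_used = sum(len(v) for v in groups_ok)
            row["test"] = f"F_{len(groups_ok)-1},{n_used-len(groups_ok)} = {F:.2f}, p = {p:.3g}"
        else:
            row["test"] = ""
        rows.append(row)
    return pd.DataFrame(rows).set_index("measure")
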