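"""Benjamini-Hochberg false-discovery-rate control across voxels.

The step-up rule sorts the m valid voxel p-values and finds the largest
p(i) with p(i) <= i*q/m.  That value is the *critical p-value*: the highest
threshold at which only a fraction q of surviving voxels is expected to be
false positives.  Plain BH, no positive-dependence correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FDRResult", "bh_critical_p", "threshold_maps"]


@dataclass
class FDRResult:
    q: float
    m: int
    critical_p: float
    n_surviving: int
    survivor_flat: np.ndarray  # boolean over the input p-vector


def bh_critical_p(pvals, q: float = 0.05) -> FDRResult:
    """Benjamini-Hochberg critical p-value over a vector of valid tests."""
    p = np.asarray(pvals, float).ravel()
    if p.size == 0:
        raise ValueError("pvals must be nonempty")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    order = np.sort(p)
    thresh = np.arange(1, m + 1) * (q / m)
    passing = np.nonzero(order <= thresh)[0]
    if passing.size == 0:
        critical = 0.0
    else:
        critical = float(order[passing[-1]])
    survivors = p <= critical if critical > 0 else np.zeros(m, bool)
    return FDRResult(
        q=float(q),
        m=m,
        critical_p=critical,
        n_surviving=int(survivors.sum()),
        survivor_flat=survivors,
    )


def threshold_maps(stats, predictor: str, fdr: FDRResult) -> dict:
    """Apply an FDR result to a results object's beta map.

    Returns the thresholded beta map (NaN where not surviving) together
    with the critical p, survivor count, survivor mask and peak |beta|.
    """
    if fdr.m != stats.n_valid:
        raise ValueError(
            f"stale FDR result: m={fdr.m} but fit has {stats.n_valid} valid tests"
        )
    beta = stats.beta_map(predictor)
    grid_mask = np.zeros(stats.model.mask.shape, bool)
    flat = np.zeros(stats.valid_flat.shape, bool)
    flat[stats.valid_flat] = fdr.survivor_flat
    grid_mask[stats.model.mask] = flat
    out = np.where(grid_mask, beta, np.nan)
    surviving = beta[grid_mask]
    return {
        "beta_thresholded": out,
        "survivor_mask": grid_mask,
        "critical_p": fdr.critical_p,
        "n_surviving": fdr.n_surviving,
        "peak_abs_beta": float(np.nanmax(np.abs(surviving))) if surviving.size else 0.0,
    }
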