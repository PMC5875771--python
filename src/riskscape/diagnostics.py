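"""Residual spatial-autocorrelation diagnostics.

Model residuals (Pearson by default, using fitted probabilities that include
the random-effect modes) are checked for spatial autocorrelation with
Moran's I under binary distance-band weights: w_ij = 1 iff the pair of
units lies within the chosen neighbourhood radius (self-pairs excluded,
weights not row-standardised).  Inference uses the normal approximation
(E[I] = -1/(n-1) and the closed-form variance under normality); a seeded
permutation test is available for small samples.  Residuals of boxes sharing
a coordinate are averaged before the statistic is computed, and by default
each box contributes its mean residual across years.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import ndtr

from .glmm import FitResult

logger = logging.getLogger(__name__)

__all__ = ["MoranResult", "model_residuals", "morans_i", "residual_moran"]

_PCLIP = 1e-12


@dataclass
class MoranResult:
    radius_m: float
    n: int
    I: float
    expected_I: float
    variance_I: float
    z: float
    p: float
    w_sum: float

    def as_row(self) -> dict:
        return {
            "radius_m": self.radius_m,
            "n": self.n,
            "I": self.I,
            "expected": self.expected_I,
            "variance": self.variance_I,
            "z": self.z,
            "p": self.p,
        }


def model_residuals(fit: FitResult, y=None, kind: str = "pearson") -> np.ndarray:
    """Per-observation residuals from a converged fit.

    ``kind`` is "pearson" ((y - p)/sqrt(p(1-p))), "deviance", or "response".
    Fitted probabilities include the random-effect modes; probabilities of
    exactly 0 or 1 are clipped with a warning.
    """
    if not fit.converged:
        raise ValueError("refusing residuals from a non-converged fit")
    p = np.asarray(fit.fitted, dtype=float)
    if y is None:
        raise ValueError("observed response y is required")
    y = np.asarray(y, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        warnings.warn("fitted probabilities clipped away from 0/1", RuntimeWarning,
                      stacklevel=2)
        p = np.clip(p, _PCLIP, 1.0 - _PCLIP)
    if kind == "response":
        return y - p
    if kind == "pearson":
        return (y - p) / np.sqrt(p * (1.0 - p))
    if kind == "deviance":
        dev = -2.0 * (y * np.log(p) + (1.0 - y) * np.log1p(-p))
        return np.sign(y - p) * np.sqrt(dev)
    raise ValueError("kind must be 'pearson', 'deviance' or 'response'")


def morans_i(
    values,
    coords,
    radius_m: float,
    permutations: int = 0,
    seed: int | None = None,
) -> MoranResult:
    """Moran's I with binary distance-band weights of the given radius.

    I = (n/W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2
    with w_ij = 1 iff 0 < d(i,j) <= radius_m.  Normal-approximation z and
    two-sided p; with ``permutations`` > 0 the p-value comes from a seeded
    permutation test instead.
    """
    x = np.asarray(values, dtype=float)
    xy = np.asarray(coords, dtype=float).reshape(-1, 2)
    n = x.size
    if n < 3:
        raise ValueError("Moran's I needs at least 3 units")
    if np.ptp(x) == 0:
        raise ValueError("Moran's I undefined for constant values")
    d = squareform(pdist(xy))
    w = ((d > 0) & (d <= radius_m)).astype(float)
    W = w.sum()
    if W == 0:
        raise ValueError(f"empty weight matrix at radius {radius_m} m")
    z = x - x.mean()
    num = float(z @ w @ z)
    den = float(z @ z)
    I = (n / W) * num / den

    expected = -1.0 / (n - 1.0)
    s1 = 0.5 * float(((w + w.T) ** 2).sum())
    s2 = float(((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum())
    var = (n**2 * s1 - n * s2 + 3.0 * W**2) / (W**2 * (n**2 - 1.0)) - expected**2
    # degenerate weight layouts (e.g. a fully saturated tiny lattice) can
    # drive the normality variance to zero
    zscore = (I - expected) / np.sqrt(var) if var > 0 else np.nan
    if permutations > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(permutations):
            xp = rng.permutation(z)
            Ip = (n / W) * float(xp @ w @ xp) / den
            if abs(Ip - expected) >= abs(I - expected):
                count += 1
        pval = (count + 1.0) / (permutations + 1.0)
    else:
        pval = 2.0 * ndtr(-abs(zscore))
    return MoranResult(
        radius_m=float(radius_m), n=int(n), I=float(I), expected_I=float(expected),
        variance_I=float(var), z=float(zscore), p=float(pval), w_sum=float(W),
    )


def residual_moran(
    residuals: np.ndarray,
    table: pd.DataFrame,
    boxes: pd.DataFrame,
    radii: tuple[float, ...] = (50.0, 500.0, 5000.0),
    per_year: bool = False,
    permutations: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Moran's I of model residuals at each neighbourhood radius.

    ``table`` provides box_id (and year) per residual row; ``boxes`` provides
    box coordinates.  By default each box enters with its mean residual over
    years; with ``per_year`` a separate test is run for every year.
    """
    df = table[["box_id"] + (["year"] if per_year else [])].copy()
    df["residual"] = np.asarray(residuals, dtype=float)
    coords = boxes.set_index("box_id")[["x", "y"]]
    rows = []
    groups = df.groupby("year") if per_year else [(None, df)]
    for year, grp in groups:
        agg = grp.groupby("box_id", sort=True)["residual"].mean()
        xy = coords.loc[agg.index].to_numpy(dtype=float)
        # average boxes sharing an exact coordinate
        key = pd.MultiIndex.from_arrays([xy[:, 0], xy[:, 1]])
        per_coord = agg.groupby(key).mean()
        uxy = np.array([[a, b] for a, b in per_coord.index])
        for radius in radii:
            res = morans_i(per_coord.to_numpy(), uxy, radius,
                           permutations=permutations, seed=seed)
            row = res.as_row()
            if per_year:
                row["year"] = year
            rows.append(row)
    return pd.DataFrame(rows)
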