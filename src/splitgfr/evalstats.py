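"""Agreement statistics: Dice, Lin's CCC, regression slope, Bland-Altman,
and threshold-based agreement fractions.

Conventions: differences are ground-truth minus comparison (``gt - dl``);
relative differences use the ground-truth value as denominator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "PairedSeries",
    "AgreementReport",
    "dice",
    "lin_ccc",
    "ols_slope",
    "bland_altman",
    "agreement_fractions",
    "compute_agreement",
]


@dataclass(frozen=True)
class PairedSeries:
    """Equal-length paired measurements (ground truth vs comparison)."""

    gt: np.ndarray
    dl: np.ndarray

    def __post_init__(self) -> None:
        gt = np.asarray(self.gt, dtype=float)
        dl = np.asarray(self.dl, dtype=float)
        if gt.ndim != 1 or dl.ndim != 1 or len(gt) != len(dl):
            raise ValueError("gt and dl must be equal-length 1-D sequences")
        if len(gt) == 0:
            raise ValueError("empty series")
        if not (np.all(np.isfinite(gt)) and np.all(np.isfinite(dl))):
            raise ValueError("non-finite values in paired series")
        object.__setattr__(self, "gt", gt)
        object.__setattr__(self, "dl", dl)

    def __len__(self) -> int:
        return len(self.gt)


@dataclass
class AgreementReport:
    n: int
    ccc: float
    ccc_ci: tuple[float, float]
    slope: float
    slope_ci: tuple[float, float]
    bias: float
    loa_low: float
    loa_high: float
    frac_abs_lt: float
    frac_rel_lt: dict[float, float]
    abs_threshold: float
    rel_thresholds: tuple[float, ...]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity 2|A∩B|/(|A|+|B|); both-empty is defined as 1."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def lin_ccc(pairs: PairedSeries, ci_level: float = 0.95) -> tuple[float, float, float]:
    """Lin's concordance correlation coefficient with a Fisher-z CI.

    Uses population (1/n) moments for the point estimate; the CI follows
    Lin's asymptotic variance of the z-transformed coefficient.
    """
    x, y = pairs.gt, pairs.dl
    n = len(pairs)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population variances
    if vx == 0 and vy == 0:
        raise ValueError("both series constant: CCC undefined")
    sxy = ((x - mx) * (y - my)).mean()
    ccc = 2.0 * sxy / (vx + vy + (mx - my) ** 2)

    # Fisher z CI (Lin 1989, with the 2000 erratum variance terms)
    if vx == 0 or vy == 0:
        return ccc, float("nan"), float("nan")
    r = sxy / math.sqrt(vx * vy)
    if abs(ccc) >= 1.0 - 1e-12 or abs(r) < 1e-12:
        return ccc, ccc, ccc
    u = (mx - my) / (vx * vy) ** 0.25
    c2 = ccc * ccc
    var_z = (
        (1 - r * r) * c2 / ((1 - c2) * r * r)
        + 2 * ccc**3 * (1 - ccc) * u * u / (r * (1 - c2) ** 2)
        - ccc**4 * u**4 / (2 * r * r * (1 - c2) ** 2)
    ) / (n - 2)
    if var_z <= 0:
        return ccc, ccc, ccc
    z = math.atanh(ccc)
    zcrit = stats.norm.ppf(0.5 + ci_level / 2.0)
    half = zcrit * math.sqrt(var_z)
    return ccc, math.tanh(z - half), math.tanh(z + half)


def ols_slope(pairs: PairedSeries, ci_level: float = 0.95) -> tuple[float, float, float]:
    """OLS slope of the comparison values on ground truth, with a t CI."""
    x, y = pairs.gt, pairs.dl
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    if x.var() == 0:
        raise ValueError("zero predictor variance")
    model = sm.OLS(y, sm.add_constant(x))
    with warnings.catch_warnings():
        # perfectly collinear inputs trigger harmless numerical warnings
        warnings.simplefilter("ignore")
        fit = model.fit()
        ci = fit.conf_int(alpha=1.0 - ci_level)
    return float(fit.params[1]), float(ci[1][0]), float(ci[1][1])


def bland_altman(pairs: PairedSeries) -> tuple[float, float, float]:
    """Mean difference (gt - dl) and 95% limits of agreement (bias ± 1.96 sd)."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    d = pairs.gt - pairs.dl
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def agreement_fractions(
    pairs: PairedSeries,
    abs_threshold: float = 5.0,
    rel_thresholds: Sequence[float] = (10.0, 20.0),
) -> dict:
    """Fractions of pairs within an absolute and relative difference bound.

    Strict inequalities.  Pairs with gt == 0 are excluded from (and counted
    alongside) the relative fractions.
    """
    d = np.abs(pairs.gt - pairs.dl)
    out = {"abs": float(np.mean(d < abs_threshold)), "rel": {}, "n_zero_gt": int(np.sum(pairs.gt == 0))}
    nz = pairs.gt != 0
    for thr in rel_thresholds:
        if nz.any():
            rel = d[nz] / np.abs(pairs.gt[nz]) * 100.0
            out["rel"][float(thr)] = float(np.mean(rel < thr))
        else:
            out["rel"][float(thr)] = float("nan")
    return out


def compute_agreement(
    gt: Sequence[float],
    dl: Sequence[float],
    abs_threshold: float = 5.0,
    rel_thresholds: Sequence[float] = (10.0, 20.0),
    ci_level: float = 0.95,
) -> AgreementReport:
    """One-stop agreement summary for a pair of GFR series."""
    pairs = PairedSeries(np.asarray(gt), np.asarray(dl))
    ccc, clo, chi = lin_ccc(pairs, ci_level)
    slope, slo, shi = ols_slope(pairs, ci_level)
    bias, lo, hi = bland_altman(pairs)
    fr = agreement_fractions(pairs, abs_threshold, rel_thresholds)
    return AgreementReport(
        n=len(pairs),
        ccc=ccc,
        ccc_ci=(clo, chi),
        slope=slope,
        slope_ci=(slo, shi),
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        frac_abs_lt=fr["abs"],
        frac_rel_lt=fr["rel"],
        abs_threshold=abs_threshold,
        rel_thresholds=tuple(rel_thresholds),
    )
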