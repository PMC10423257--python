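"""Agreement statistics for paired predicted/delivered dose sets.

Lin's concordance correlation coefficient factorizes the agreement between
two measurements into precision (Pearson's rho) and accuracy (the bias
correction factor C_b = rho_c / rho).  Bland-Altman analysis reports the
mean difference (delivered minus predicted, so a negative mean means the
prediction overestimates) with 95% limits of agreement.  Moments for the
CCC use the population (divisor-n) convention of Lin's original estimator;
the Bland-Altman SD uses the sample (divisor n-1) convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class AgreementResult:
    n: int
    pearson_rho: float
    ccc: float
    bias_correction: float
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    loa_multiplier: float = 1.96

    def to_dict(self) -> dict:
        return {
            "n": self.n, "pearson_rho": self.pearson_rho, "ccc": self.ccc,
            "bias_correction": self.bias_correction, "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff, "loa_low": self.loa_low,
            "loa_high": self.loa_high, "loa_multiplier": self.loa_multiplier,
        }


@dataclass
class RatioSummary:
    """Element-wise predicted/actual ratios with summary statistics."""

    ratios: np.ndarray
    mean: float
    median: float
    min: float
    max: float


def _paired(x, y, min_n: int):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("paired vectors must have equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {x.size}")
    return x, y


def lin_ccc(x, y) -> tuple[float, float, float]:
    """Lin's concordance correlation: returns (rho, rho_c, C_b).

    rho_c = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2) with
    population (divisor-n) moments; C_b = rho_c / rho.
    """
    x, y = _paired(x, y, 3)
    mx, my = x.mean(), y.mean()
    sx2 = float(np.mean((x - mx) ** 2))
    sy2 = float(np.mean((y - my) ** 2))
    if sx2 == 0 or sy2 == 0:
        raise ValueError("zero variance in one of the inputs")
    sxy = float(np.mean((x - mx) * (y - my)))
    rho_c = 2.0 * sxy / (sx2 + sy2 + (mx - my) ** 2)
    rho = sxy / np.sqrt(sx2 * sy2)
    return float(rho), float(rho_c), float(rho_c / rho)


def bland_altman(pred, actual, k: float = 1.96
                 ) -> tuple[float, float, float, float]:
    """Bland-Altman agreement: (mean_diff, sd_diff, loa_low, loa_high).

    Differences are actual - predicted; limits of agreement are
    mean +/- k * SD with the sample (n-1) SD.
    """
    pred, actual = _paired(pred, actual, 2)
    diffs = actual - pred
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return mean, sd, mean - k * sd, mean + k * sd


def agreement(pred, actual, k: float = 1.96) -> AgreementResult:
    """Full agreement summary (CCC decomposition + Bland-Altman)."""
    pred_arr, actual_arr = _paired(pred, actual, 3)
    rho, rho_c, c_b = lin_ccc(pred_arr, actual_arr)
    mean, sd, low, high = bland_altman(pred_arr, actual_arr, k=k)
    return AgreementResult(n=pred_arr.size, pearson_rho=rho, ccc=rho_c,
                           bias_correction=c_b, mean_diff=mean, sd_diff=sd,
                           loa_low=low, loa_high=high, loa_multiplier=k)


def ratio_stats(pred, actual) -> RatioSummary:
    """Predicted-to-actual ratio per pair, with mean/median/min/max."""
    pred, actual = _paired(pred, actual, 1)
    if np.any(actual <= 0):
        raise ValueError("actual values must be strictly positive")
    ratios = pred / actual
    return RatioSummary(ratios=ratios, mean=float(ratios.mean()),
                        median=float(np.median(ratios)),
                        min=float(ratios.min()), max=float(ratios.max()))


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks."""
    x, y = _paired(x, y, 3)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector has no rank correlation")
    return float(stats.spearmanr(x, y).statistic)
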