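"""Tumor response classification and dose-response tabulation.

Six criteria are supported: size-based (RECIST 1.1 on longest diameter,
WHO on cross-sectional area, vRECIST on volume), enhancement-based
(mRECIST on enhancing diameter, EASL on enhancing area) and metabolic
(EORTC on SUV change).  Each maps a percent change between baseline and
follow-up onto CR/PR/SD/PD; responders are CR or PR.

Default thresholds follow the criteria's published conventions (RECIST:
-30% / +20% with a 0.5 cm absolute minimum for progression; WHO/EASL:
-50% / +25%; vRECIST: the spherical equivalents -65% / +73%; EORTC:
+/-25% SUV) and are configurable.  Boundary values classify into the
category whose threshold they meet exactly (PR at exactly -30%, PD at
exactly +20%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .uptake import SUVStats

CRITERIA = ("RECIST", "mRECIST", "WHO", "EASL", "vRECIST", "EORTC")
CATEGORIES = ("CR", "PR", "SD", "PD")

#: ordinal coding used for dose-response association (worse -> lower)
CATEGORY_ORDINAL = {"PD": 0, "SD": 1, "PR": 2, "CR": 3}

#: measure used by each size/enhancement criterion
CRITERION_MEASURE = {
    "RECIST": "diameter_cm",
    "mRECIST": "enhancing_diameter_cm",
    "WHO": "area_cm2",
    "EASL": "enhancing_area_cm2",
    "vRECIST": "volume_cm3",
}

#: (PR threshold %, PD threshold %) per criterion
DEFAULT_THRESHOLDS = {
    "RECIST": (-30.0, 20.0),
    "mRECIST": (-30.0, 20.0),
    "WHO": (-50.0, 25.0),
    "EASL": (-50.0, 25.0),
    "vRECIST": (-65.0, 73.0),
    "EORTC": (-25.0, 25.0),
}

#: minimum absolute increase (in the measure's unit) required for PD
PD_ABSOLUTE_MINIMUM = {"RECIST": 0.5, "mRECIST": 0.5}


@dataclass
class LesionTimepoint:
    """Per-lesion measurements at one imaging timepoint."""

    diameter_cm: float = 0.0
    enhancing_diameter_cm: float = 0.0
    area_cm2: float = 0.0
    enhancing_area_cm2: float = 0.0
    volume_cm3: float = 0.0
    suv: SUVStats | None = None

    def __post_init__(self) -> None:
        for name in CRITERION_MEASURE.values():
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.enhancing_diameter_cm > self.diameter_cm:
            raise ValueError("enhancing diameter exceeds overall diameter")
        if self.enhancing_area_cm2 > self.area_cm2:
            raise ValueError("enhancing area exceeds overall area")


@dataclass
class ResponseResult:
    criterion: str
    category: str
    percent_change: float

    @property
    def responder(self) -> bool:
        return self.category in ("CR", "PR")


def _categorize(percent_change: float, followup_value: float,
                pr_threshold: float, pd_threshold: float,
                absolute_increase: float = 0.0,
                pd_minimum: float = 0.0) -> str:
    if followup_value == 0:
        return "CR"
    if percent_change <= pr_threshold:
        return "PR"
    if percent_change >= pd_threshold and absolute_increase >= pd_minimum:
        return "PD"
    return "SD"


def classify_size(baseline: LesionTimepoint, followup: LesionTimepoint,
                  criterion: str,
                  thresholds: dict[str, tuple[float, float]] | None = None
                  ) -> ResponseResult:
    """Classify one lesion under a size/enhancement/volume criterion."""
    if criterion not in CRITERION_MEASURE:
        raise ValueError(f"unknown size criterion {criterion!r}")
    measure = CRITERION_MEASURE[criterion]
    b = getattr(baseline, measure)
    f = getattr(followup, measure)
    if b <= 0:
        raise ValueError(f"baseline {measure} must be positive for {criterion}")
    pr_thr, pd_thr = (thresholds or DEFAULT_THRESHOLDS)[criterion]
    pct = 100.0 * (f - b) / b
    category = _categorize(pct, f, pr_thr, pd_thr, absolute_increase=f - b,
                           pd_minimum=PD_ABSOLUTE_MINIMUM.get(criterion, 0.0))
    return ResponseResult(criterion, category, pct)


def classify_eortc(baseline_suv: SUVStats, followup_suv: SUVStats,
                   on: str = "suv_mean",
                   thresholds: tuple[float, float] | None = None
                   ) -> ResponseResult:
    """Metabolic response: CR if uptake resolves, PR/PD at +/-25% SUV change."""
    if baseline_suv is None or followup_suv is None:
        raise ValueError("both timepoints need SUV statistics")
    b = getattr(baseline_suv, on)
    f = getattr(followup_suv, on)
    if b <= 0:
        raise ValueError(f"baseline {on} must be positive")
    pr_thr, pd_thr = thresholds or DEFAULT_THRESHOLDS["EORTC"]
    pct = 100.0 * (f - b) / b
    return ResponseResult("EORTC", _categorize(pct, f, pr_thr, pd_thr), pct)


def sum_timepoints(timepoints: list[LesionTimepoint]) -> LesionTimepoint:
    """Patient-level measurements: sum of target-lesion measures."""
    if not timepoints:
        raise ValueError("no lesions to sum")
    return LesionTimepoint(
        diameter_cm=sum(t.diameter_cm for t in timepoints),
        enhancing_diameter_cm=sum(t.enhancing_diameter_cm for t in timepoints),
        area_cm2=sum(t.area_cm2 for t in timepoints),
        enhancing_area_cm2=sum(t.enhancing_area_cm2 for t in timepoints),
        volume_cm3=sum(t.volume_cm3 for t in timepoints),
    )


def dose_response_table(doses: pd.DataFrame, responses: pd.DataFrame
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-tabulate response category against absorbed dose per criterion.

    ``doses`` needs columns ``lesion_id, mean_dose_Gy``; ``responses`` needs
    ``lesion_id, criterion, category``.  Returns ``(counts, assoc)`` where
    ``counts`` has one row per criterion with CR/PR/SD/PD counts and
    ``assoc`` holds the Spearman rho of dose vs ordinal category and a
    Kruskal-Wallis p-value across categories.  Degenerate strata (a single
    category, or constant doses) are flagged with ``degenerate=True`` and
    NaN statistics.
    """
    merged = responses.merge(doses[["lesion_id", "mean_dose_Gy"]], on="lesion_id")
    if merged.empty:
        raise ValueError("no overlapping lesion ids between doses and responses")
    count_rows, assoc_rows = [], []
    for criterion, group in merged.groupby("criterion", sort=False):
        counts = {cat: int((group["category"] == cat).sum()) for cat in CATEGORIES}
        dose = group["mean_dose_Gy"].to_numpy(dtype=float)
        ordinal = group["category"].map(CATEGORY_ORDINAL).to_numpy(dtype=float)
        present = [cat for cat in CATEGORIES if counts[cat] > 0]
        degenerate = len(present) < 2 or np.all(dose == dose[0])
        if degenerate:
            rho, p = np.nan, np.nan
        else:
            rho = float(stats.spearmanr(dose, ordinal).statistic)
            groups = [dose[group["category"].to_numpy() == cat] for cat in present]
            p = float(stats.kruskal(*groups).pvalue)
        count_rows.append({"criterion": criterion, **counts})
        assoc_rows.append({"criterion": criterion, "n": len(group),
                           "spearman_rho": rho, "kruskal_p": p,
                           "degenerate": degenerate})
    return pd.DataFrame(count_rows), pd.DataFrame(assoc_rows)
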