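"""Matched-pair radionuclide comparison and cohort dose-toxicity reporting.

Matched-pair dosimetry predicts the dose distribution of a therapeutic
nuclide (90Y) from serial imaging of a chemically identical surrogate
(177Lu): the measured activity maps are rescaled to undo the surrogate's
physical decay and apply the therapeutic nuclide's, keeping the biological
kinetics fixed, and the transport is re-run with the other emission data.
The figure of merit is the tumor-to-marrow absorbed dose ratio.

The reporting half summarises a patient cohort: per-column dose means,
per-patient ratio tables with percentage changes, and the separation of
toxicity and no-toxicity groups along a chosen dose axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel_io import (CohortRecord, Nuclide, ScalarVolume,
                           TimeSeriesVolumes, ValidationError)


# ---------------------------------------------------------------------------
# matched-pair rescaling and ratios
# ---------------------------------------------------------------------------

def rescale_activity_for_nuclide(activity_series: TimeSeriesVolumes,
                                 from_nuclide: Nuclide,
                                 to_nuclide: Nuclide) -> TimeSeriesVolumes:
    """Swap the physical decay of an activity series between nuclides.

    Each volume at time t is multiplied by exp(-(lambda_to - lambda_from) t),
    which preserves the administered activity and the biological retention
    while substituting the other nuclide's physical half-life.
    """
    lam_from = from_nuclide.decay_const_per_h
    lam_to = to_nuclide.decay_const_per_h
    vols = []
    for t, v in zip(activity_series.times_h, activity_series.volumes):
        factor = math.exp(-(lam_to - lam_from) * t)
        vols.append(ScalarVolume(v.grid, v.values * factor, v.quantity))
    return TimeSeriesVolumes(times_h=activity_series.times_h, volumes=vols)


def tumor_rbm_ratio(ad_tumor_Gy: float, ad_rbm_Gy: float) -> float:
    """Tumor-to-red-bone-marrow absorbed dose ratio."""
    if not (ad_rbm_Gy > 0):
        raise ValidationError("RBM dose must be positive to form a ratio")
    return ad_tumor_Gy / ad_rbm_Gy


@dataclass(frozen=True)
class MatchedPairResult:
    """Per-patient tumor-to-RBM ratios for the surrogate and therapy nuclide.

    ``percent_difference`` is taken relative to the surrogate (177Lu) ratio.
    """

    patient_id: int
    ratio_lu: float
    ratio_y: float

    def __post_init__(self):
        if self.ratio_lu <= 0 or self.ratio_y <= 0:
            raise ValidationError("ratios must be positive")

    @property
    def percent_difference(self) -> float:
        return 100.0 * (self.ratio_y - self.ratio_lu) / self.ratio_lu


def matched_pair_summary(results: Sequence[MatchedPairResult],
                         printed_percent: Optional[Sequence[float]] = None
                         ) -> tuple[float, float, float]:
    """Arithmetic means of (surrogate ratio, therapy ratio, percentage change).

    ``printed_percent`` optionally substitutes externally tabulated
    percentage differences (already rounded) for the recomputed ones, for
    reproducing published summary rows exactly.
    """
    if not results:
        raise ValidationError("matched-pair summary of an empty list")
    mean_lu = float(np.mean([r.ratio_lu for r in results]))
    mean_y = float(np.mean([r.ratio_y for r in results]))
    if printed_percent is not None:
        mean_pct = float(np.mean(list(printed_percent)))
    else:
        mean_pct = float(np.mean([r.percent_difference for r in results]))
    return mean_lu, mean_y, mean_pct


def matched_pair_from_table(df: pd.DataFrame) -> list[MatchedPairResult]:
    """Build results from a table with patient_id / ratio_lu / ratio_y columns."""
    return [MatchedPairResult(int(r.patient_id), float(r.ratio_lu), float(r.ratio_y))
            for r in df.itertuples()]


# ---------------------------------------------------------------------------
# dose-toxicity separation
# ---------------------------------------------------------------------------

@dataclass
class SeparationReport:
    """Extremes of the no-toxicity and toxicity groups along one dose axis."""

    method: str
    max_dose_no_toxicity_Gy: Optional[float]
    min_dose_toxicity_Gy: Optional[float]
    max_dose_toxicity_Gy: Optional[float]
    min_dose_no_toxicity_Gy: Optional[float]
    fully_separated: bool
    separating_threshold_Gy: Optional[float]

    def __post_init__(self):
        both = self.max_dose_no_toxicity_Gy is not None and self.min_dose_toxicity_Gy is not None
        expected = bool(both and self.max_dose_no_toxicity_Gy < self.min_dose_toxicity_Gy)
        if self.fully_separated != expected:
            raise ValidationError("fully_separated flag inconsistent with group extremes")


_TOXICITY_RULES = {
    "any_toxicity": lambda r: r.grade_thrombocytopenia >= 1 or r.grade_leucopenia >= 1,
    "thrombocytopenia_only": lambda r: r.grade_thrombocytopenia >= 1,
}


def toxicity_separation(cohort: Sequence[CohortRecord], dose_field: str,
                        toxicity_rule: str = "any_toxicity") -> SeparationReport:
    """Partition the cohort by toxicity and report the group dose extremes.

    ``fully_separated`` is true when every toxicity patient's dose exceeds
    every no-toxicity patient's; the midpoint between the two extremes is
    then a descriptive separating threshold (not a clinical limit).
    """
    if not cohort:
        raise ValidationError("empty cohort")
    if toxicity_rule not in _TOXICITY_RULES:
        raise ValidationError(f"unknown toxicity rule {toxicity_rule!r}")
    rule = _TOXICITY_RULES[toxicity_rule]
    doses_tox, doses_ok = [], []
    for r in cohort:
        d = getattr(r, dose_field)
        if d is None:
            raise ValidationError(f"patient {r.patient_id} lacks {dose_field}")
        (doses_tox if rule(r) else doses_ok).append(float(d))
    max_ok = max(doses_ok) if doses_ok else None
    min_ok = min(doses_ok) if doses_ok else None
    max_tox = max(doses_tox) if doses_tox else None
    min_tox = min(doses_tox) if doses_tox else None
    separated = max_ok is not None and min_tox is not None and max_ok < min_tox
    threshold = 0.5 * (max_ok + min_tox) if separated else None
    return SeparationReport(method=f"{dose_field}/{toxicity_rule}",
                            max_dose_no_toxicity_Gy=max_ok,
                            min_dose_no_toxicity_Gy=min_ok,
                            min_dose_toxicity_Gy=min_tox,
                            max_dose_toxicity_Gy=max_tox,
                            fully_separated=separated,
                            separating_threshold_Gy=threshold)


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

_SUMMARY_FIELDS = ("administered_activity_GBq", "tumor_volume_mL",
                   "ad_tumor_3d_Gy", "ad_rbm_3d_Gy", "ad_tumor_sphere_Gy")


def cohort_summary(cohort: Sequence[CohortRecord], ndigits: Optional[int] = None
                   ) -> dict[str, float]:
    """Arithmetic means of the dose and volume columns.

    ``ndigits`` rounds for table-style reporting; internals stay full
    precision when it is None.
    """
    if not cohort:
        raise ValidationError("empty cohort")
    out = {}
    for f in _SUMMARY_FIELDS:
        m = float(np.mean([getattr(r, f) for r in cohort]))
        out[f] = round(m, ndigits) if ndigits is not None else m
    return out


def plot_dose_vs_grade(cohort: Sequence[CohortRecord], dose_field: str, path,
                       grade_field: str = "grade_thrombocytopenia") -> None:
    """Scatter of per-patient dose against toxicity grade, saved to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grades = [getattr(r, grade_field) for r in cohort]
    doses = [getattr(r, dose_field) for r in cohort]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(grades, doses, c="k", s=25)
    ax.set_xlabel(grade_field.replace("_", " "))
    ax.set_ylabel(f"{dose_field.replace('_', ' ')} (Gy)")
    ax.set_xticks(range(5))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
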