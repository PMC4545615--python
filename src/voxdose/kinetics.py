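"""Time integration of dose rates and activities.

Serial quantitative imaging yields a handful of samples of a decaying
quantity (voxel dose rate, VOI dose rate, VOI activity).  The cumulative
quantity is obtained with a hybrid trapezoidal-exponential rule: straight
lines connect the early samples, and a single exponential tail—anchored at
the penultimate sample and passing through the final one—covers the last
interval and the extrapolation to infinity.  With the standard four-point
protocol (≈0, 3, 24, 72 h) this means trapezoids over the first three
samples and a two-point exponential tail.

Degenerate tails (final sample not below the penultimate one) fall back to a
caller-supplied rate, conventionally the nuclide's physical decay constant —
the fastest physically guaranteed clearance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .datamodel_io import ScalarVolume, TimeSeriesVolumes, ValidationError, VoiMask

logger = logging.getLogger("voxdose")


@dataclass(frozen=True)
class HybridFit:
    """Piecewise linear curve with an exponential tail, and its 0..inf integral.

    ``times_h``/``values`` hold the linear-part anchor samples up to and
    including the tail start.  The tail is ``tail_value * exp(-tail_rate *
    (t - tail_start))`` for ``t >= tail_start``.  ``leading_rule`` states how
    the stretch from t=0 to the first sample is handled: ``"rectangle"``
    holds the first value constant back to zero, ``"zero"`` ignores it.
    """

    times_h: tuple[float, ...]
    values: tuple[float, ...]
    tail_rate_per_h: float
    tail_start_h: float
    tail_value: float
    integral: float
    leading_rule: str = "rectangle"
    fallback_used: bool = False

    @classmethod
    def exponential(cls, value0: float, rate_per_h: float) -> "HybridFit":
        """A pure mono-exponential curve from t=0 (no linear segments)."""
        if rate_per_h <= 0:
            raise ValidationError("exponential rate must be positive")
        return cls(times_h=(0.0,), values=(float(value0),), tail_rate_per_h=float(rate_per_h),
                   tail_start_h=0.0, tail_value=float(value0),
                   integral=float(value0) / float(rate_per_h), leading_rule="zero")

    def __call__(self, t: float | np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        tail = t >= self.tail_start_h
        out[tail] = self.tail_value * np.exp(-self.tail_rate_per_h * (t[tail] - self.tail_start_h))
        if len(self.times_h) > 1:
            lin = (~tail) & (t >= self.times_h[0])
            out[lin] = np.interp(t[lin], self.times_h, self.values)
        if self.leading_rule == "rectangle":
            lead = t < self.times_h[0]
            out[lead] = self.values[0]
        return out


def fit_hybrid(times_h: Sequence[float], values: Sequence[float],
               fallback_rate_per_h: float, leading_rule: str = "rectangle") -> HybridFit:
    """Fit the hybrid trapezoidal-exponential rule to sampled values.

    Trapezoids span the first ``n-1`` samples; the exponential tail is
    anchored exactly at the penultimate sample and its rate comes from the
    final two samples, ``k = ln(y_{n-1}/y_n) / (t_n - t_{n-1})``, provided
    the curve is falling there.  Otherwise (flat or rising end, including a
    zero final sample following a zero anchor) the fallback rate is used.

    Returns the fit object; ``fit.integral`` is the 0..infinity integral in
    (value x hours).
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != y.shape or len(t) < 2:
        raise ValidationError("need equal-length 1D times and values with >= 2 samples")
    if np.any(np.diff(t) <= 0) or t[0] < 0:
        raise ValidationError(f"times must be non-negative and strictly increasing, got {t}")
    if not np.all(np.isfinite(y)) or np.any(y < 0):
        raise ValidationError("values must be finite and non-negative")
    if leading_rule not in ("rectangle", "zero"):
        raise ValidationError(f"unknown leading_rule {leading_rule!r}")
    if not (fallback_rate_per_h > 0):
        raise ValidationError("fallback_rate_per_h must be positive")

    y_anchor, y_last = y[-2], y[-1]
    if y_anchor == 0.0 and y_last > 0.0:
        raise ValidationError("non-physical growth from zero at the tail anchor")
    fallback_used = False
    if y_anchor > 0.0 and y_last < y_anchor and y_last > 0.0:
        k = math.log(y_anchor / y_last) / (t[-1] - t[-2])
    else:
        k = fallback_rate_per_h
        fallback_used = True
        if y_anchor > 0.0:
            logger.debug("tail not falling (y=%g -> %g); using fallback rate %g /h",
                         y_anchor, y_last, k)

    leading = y[0] * t[0] if leading_rule == "rectangle" else 0.0
    trapezoid = float(np.trapezoid(y[:-1], t[:-1])) if len(t) > 2 else 0.0
    tail = y_anchor / k
    return HybridFit(times_h=tuple(t[:-1]), values=tuple(y[:-1]),
                     tail_rate_per_h=k, tail_start_h=float(t[-2]), tail_value=float(y_anchor),
                     integral=float(leading + trapezoid + tail),
                     leading_rule=leading_rule, fallback_used=fallback_used)


def integrate_dose_map(doserate_series: TimeSeriesVolumes, fallback_rate_per_h: float,
                       leading_rule: str = "rectangle", strict: bool = False) -> ScalarVolume:
    """Voxel-wise hybrid time integration of serial dose-rate maps -> dose (Gy).

    Vectorised application of :func:`fit_hybrid` over every voxel; the fit
    structure (which rule covers which interval) is identical for all voxels,
    only the tail rate varies per voxel.

    With ``strict=True`` a voxel whose tail anchor is zero but whose final
    sample is positive raises (non-physical growth from zero).  The default
    tolerates such voxels — on Monte Carlo dose-rate maps they are ordinary
    tally noise — by taking a zero tail there (the anchor value is zero, so
    the tail integral vanishes regardless of the rate).
    """
    if doserate_series.volumes[0].quantity != "doserate_Gy_h":
        raise ValidationError("integrate_dose_map expects a doserate_Gy_h series")
    t = np.asarray(doserate_series.times_h)
    stack = np.stack([v.values for v in doserate_series.volumes], axis=0)
    y_anchor, y_last = stack[-2], stack[-1]

    bad = (y_anchor == 0) & (y_last > 0)
    if strict and np.any(bad):
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise ValidationError(f"non-physical growth from zero at voxel {idx}")
    if np.any(bad):
        logger.debug("%d voxels grow from a zero tail anchor; zero tail used", int(bad.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.log(y_anchor / y_last) / (t[-1] - t[-2])
    falling = (y_anchor > 0) & (y_last > 0) & (y_last < y_anchor)
    k = np.where(falling, k, fallback_rate_per_h)

    leading = stack[0] * t[0] if leading_rule == "rectangle" else 0.0
    trapezoid = np.trapezoid(stack[:-1], t[:-1], axis=0) if len(t) > 2 else 0.0
    dose = leading + trapezoid + y_anchor / k
    return ScalarVolume(doserate_series.grid, dose, "dose_Gy")


def _voi_mean_rates(doserate_series: TimeSeriesVolumes, mask: VoiMask,
                    density: Optional[ScalarVolume] = None) -> np.ndarray:
    """Mass-weighted (energy-preserving) VOI mean dose rate per time point."""
    m = mask.mask
    if density is not None:
        w = density.values[m]
        if w.sum() <= 0:
            raise ValidationError("VOI has zero mass under the density map")
    else:
        w = np.ones(int(m.sum()))
    return np.array([float(np.average(v.values[m], weights=w)) for v in doserate_series.volumes])


def integrate_voi(doserate_series: TimeSeriesVolumes, mask: VoiMask,
                  fallback_rate_per_h: float, density: Optional[ScalarVolume] = None,
                  leading_rule: str = "rectangle") -> float:
    """VOI mean absorbed dose (Gy): mean dose rate per time point, then one
    hybrid fit on the resulting scalars.

    When a density map is given the per-time-point mean is mass weighted,
    i.e. total deposited energy in the VOI divided by VOI mass; otherwise
    voxels weigh equally.
    """
    mask.require_nonempty()
    rates = _voi_mean_rates(doserate_series, mask, density)
    return fit_hybrid(doserate_series.times_h, rates, fallback_rate_per_h, leading_rule).integral


def tiac(activity_series: TimeSeriesVolumes | tuple[Sequence[float], Sequence[float]],
         mask: Optional[VoiMask], administered_MBq: float,
         fallback_rate_per_h: float, leading_rule: str = "rectangle") -> float:
    """Time-integrated activity coefficient (hours).

    The total VOI activity at each time point (or a caller-supplied scalar
    series as a ``(times, activities)`` pair with ``mask=None``) is
    integrated with the hybrid rule and normalised by the administered
    activity.
    """
    if not (administered_MBq > 0):
        raise ValidationError("administered activity must be positive")
    if isinstance(activity_series, TimeSeriesVolumes):
        if activity_series.volumes[0].quantity != "activity_MBq":
            raise ValidationError("tiac expects an activity_MBq series")
        times = activity_series.times_h
        if mask is not None:
            mask.require_nonempty()
            values = [float(v.values[mask.mask].sum()) for v in activity_series.volumes]
        else:
            values = [v.total() for v in activity_series.volumes]
    else:
        times, values = activity_series
    fit = fit_hybrid(times, values, fallback_rate_per_h, leading_rule)
    return fit.integral / administered_MBq
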