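"""Tumor VOI dosimetry: mean absorbed dose, dose-volume histogram, and the
unit-density sphere-model comparison.

The 3D route averages the Monte Carlo voxel dose map over the tumor mask
(mass-weighted).  The sphere route mimics model-based dosimetry software:
the VOI's time-integrated activity times a self-irradiation S-value
interpolated from a sphere table at the VOI mass.  Both S-values and the 3D
map come from the same transport engine here, so their difference isolates
geometry (surrounding activity, non-spherical shape), not physics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .datamodel_io import (DosimetryConfig, Nuclide, ScalarVolume,
                           TimeSeriesVolumes, ValidationError, VoiMask)
from .kinetics import fit_hybrid
from .mc_dose import SphereSValue, interp_sphere_s, sphere_self_dose_table

__all__ = ["Dvh", "TumorDoseReport", "tumor_dose_3d", "dvh", "tumor_dose_sphere"]


@dataclass(frozen=True)
class Dvh:
    """Cumulative dose-volume histogram: volume fraction receiving >= each edge."""

    dose_bin_edges_Gy: np.ndarray
    volume_fraction_at_least: np.ndarray

    def __post_init__(self):
        f = self.volume_fraction_at_least
        if np.any(np.diff(self.dose_bin_edges_Gy) <= 0):
            raise ValidationError("DVH bin edges must be strictly increasing")
        if np.any(np.diff(f) > 1e-12) or f[0] > 1.0 + 1e-12 or np.any(f < -1e-12):
            raise ValidationError("DVH must be non-increasing within [0, 1]")

    def mean_dose_Gy(self) -> float:
        """Volume-weighted mean dose as the area under the cumulative curve.

        The curve is a step function that drops at each edge, so the area is
        the right-rectangle sum sum_j F(e_{j+1}) (e_{j+1} - e_j) (plus the
        stretch below the first edge where F = F(e_0)).  This is *exact*
        whenever the edges contain every distinct dose value (see
        ``dvh(..., edges="unique")``) and accurate to one bin width for
        uniform binning.
        """
        e = self.dose_bin_edges_Gy
        f = self.volume_fraction_at_least
        return float(f[0] * e[0] + np.sum(f[1:] * np.diff(e)))


@dataclass
class TumorDoseReport:
    ad_3d_Gy: float
    ad_sphere_Gy: float
    mass_g: float
    dvh: Optional[Dvh] = None

    def __post_init__(self):
        if not (self.mass_g > 0):
            raise ValidationError("tumor mass must be positive")

    @property
    def fractional_difference(self) -> float:
        return (self.ad_3d_Gy - self.ad_sphere_Gy) / self.ad_sphere_Gy


def tumor_dose_3d(dose_map: ScalarVolume, mask: VoiMask,
                  density: Optional[ScalarVolume] = None) -> float:
    """Mass-weighted mean voxel dose (Gy) over the tumor mask."""
    mask.require_nonempty()
    doses = dose_map.values[mask.mask]
    if density is None:
        return float(doses.mean())
    w = density.values[mask.mask]
    if w.sum() <= 0:
        raise ValidationError("tumor mask has zero mass under the density map")
    return float(np.average(doses, weights=w))


def dvh(dose_map: ScalarVolume, mask: VoiMask, n_bins: int = 100,
        edges: Optional[np.ndarray | str] = None) -> Dvh:
    """Cumulative DVH over the mask voxels (equal voxel volumes).

    By default ``n_bins`` uniform edges run from 0 to the maximum masked
    dose (plus one closing edge past the maximum where the curve is 0).
    ``edges="unique"`` places an edge at every distinct dose value, making
    :meth:`Dvh.mean_dose_Gy` exact.
    """
    mask.require_nonempty()
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    doses = dose_map.values[mask.mask]
    top = float(doses.max())
    if top == 0.0:
        return Dvh(np.array([0.0, 1.0]), np.array([1.0, 0.0]))
    if isinstance(edges, str) and edges == "unique":
        e = np.unique(np.concatenate([[0.0], doses.ravel()]))
        e = np.append(e, top * (1.0 + 1e-9) + 1e-300)
    elif edges is None:
        e = np.linspace(0.0, top, n_bins + 1)
        e = np.append(e, top + e[1])        # closing edge past the maximum
    else:
        e = np.asarray(edges, dtype=float)
    sorted_doses = np.sort(doses.ravel())
    frac = 1.0 - np.searchsorted(sorted_doses, e - 1e-12 * top, side="left") / sorted_doses.size
    frac[e > top] = 0.0
    return Dvh(e, frac)


def tumor_dose_sphere(activity_series: TimeSeriesVolumes, mask: VoiMask,
                      density: ScalarVolume, nuclide: Nuclide,
                      config: DosimetryConfig, administered_MBq: float,
                      s_table: Optional[Sequence[SphereSValue]] = None,
                      n_histories: int = 40_000, seed: int = 0
                      ) -> tuple[float, float]:
    """Sphere-model tumor dose: (dose_Gy, voxelised VOI mass in g).

    The VOI mass comes from the density map; the VOI time-integrated
    activity uses the hybrid trapezoidal-exponential rule on total VOI
    activity per time point; the S-value is log-log interpolated from a
    unit-density sphere self-dose table (computed with the same transport
    engine if not supplied).
    """
    mask.require_nonempty()
    vox_mL = mask.grid.voxel_volume_mL
    mass_g = float(density.values[mask.mask].sum()) * vox_mL
    if mass_g <= 0:
        raise ValidationError("VOI mass is zero under the density map")
    totals = [float(v.values[mask.mask].sum()) for v in activity_series.volumes]
    a_tumor = fit_hybrid(activity_series.times_h, totals,
                         nuclide.decay_const_per_h).integral           # MBq.h
    if a_tumor == 0.0:
        return 0.0, mass_g
    if s_table is None:
        s_table = sphere_self_dose_table(nuclide, [mass_g], config,
                                         n_histories=n_histories, seed=seed)
    masses = [t.mass_g for t in s_table]
    if not (min(masses) * 0.5 <= mass_g <= max(masses) * 2.0) and len(s_table) > 1:
        import logging
        logging.getLogger("voxdose").warning(
            "VOI mass %.3g g outside sphere table range [%.3g, %.3g] g; extrapolating",
            mass_g, min(masses), max(masses))
    s = interp_sphere_s(s_table, mass_g)
    return a_tumor * s, mass_g
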