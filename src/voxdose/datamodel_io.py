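"""Shared domain types and file I/O for the voxel dosimetry pipeline.

The pipeline operates on co-registered 3D scalar fields (activity, density,
dose rate, dose, counts) defined on a common isotropic voxel grid, together
with VOI masks, nuclide decay data, blood time-activity series, and a cohort
table of per-patient dose/toxicity results.

Volumes are stored as NIfTI-1 (values in the quantity's stated unit, world
units mm) with a JSON sidecar carrying the physical quantity, since the
NIfTI header has no slot for it.  Arrays are indexed (x, y, z) matching the
NIfTI i, j, k axes; masks are assumed co-registered by construction.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, fields, asdict, replace
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("voxdose")

#: physical quantities a ScalarVolume may carry; all are non-negative fields
QUANTITIES = ("activity_MBq", "density_g_cm3", "doserate_Gy_h", "dose_Gy", "counts")

#: voxel composition categories, in label-code order
MATERIALS = ("soft_tissue", "lung", "bone")

MEV_TO_J = 1.602176634e-13


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


# ---------------------------------------------------------------------------
# grid and volumes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VoxelGrid:
    """Isotropic 3D voxel lattice shared by all volumes of one study.

    The default 4.795 mm spacing matches the 128 x 128 x 78 SPECT matrices
    this pipeline was designed around; tests use smaller grids.
    """

    shape: tuple[int, int, int]
    voxel_size_mm: float = 4.795
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "origin_mm", tuple(float(v) for v in self.origin_mm))
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValidationError(f"grid shape must be a positive integer triple, got {self.shape}")
        if not (self.voxel_size_mm > 0):
            raise ValidationError(f"voxel_size_mm must be > 0, got {self.voxel_size_mm}")

    @property
    def voxel_volume_mL(self) -> float:
        """Volume of one voxel in mL ( = cm^3 )."""
        return (self.voxel_size_mm / 10.0) ** 3

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def affine(self) -> np.ndarray:
        a = np.diag([self.voxel_size_mm] * 3 + [1.0])
        a[:3, 3] = self.origin_mm
        return a


def _check_array(grid: VoxelGrid, arr: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.shape != grid.shape:
        raise ValidationError(f"{what} shape {arr.shape} does not match grid shape {grid.shape}")
    return arr


@dataclass
class ScalarVolume:
    """A 3D scalar field on a voxel grid with an explicit physical quantity."""

    grid: VoxelGrid
    values: np.ndarray
    quantity: str

    def __post_init__(self):
        if self.quantity not in QUANTITIES:
            raise ValidationError(f"unknown quantity {self.quantity!r}; expected one of {QUANTITIES}")
        self.values = _check_array(self.grid, self.values, "values").astype(np.float64, copy=False)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"{self.quantity} volume contains non-finite values")
        if self.values.min() < 0:
            raise ValidationError(f"{self.quantity} volume contains negative values")

    def total(self) -> float:
        """Sum of all voxel values (e.g. total activity in MBq)."""
        return float(self.values.sum())

    def with_values(self, values: np.ndarray, quantity: Optional[str] = None) -> "ScalarVolume":
        return ScalarVolume(self.grid, values, quantity or self.quantity)


@dataclass
class CompositionVolume:
    """Per-voxel material category (soft tissue / lung / bone) as int codes."""

    grid: VoxelGrid
    labels: np.ndarray  # int codes indexing MATERIALS

    def __post_init__(self):
        self.labels = _check_array(self.grid, self.labels, "labels").astype(np.int8, copy=False)
        if self.labels.min() < 0 or self.labels.max() >= len(MATERIALS):
            raise ValidationError("composition labels outside the material code range")


@dataclass
class VoiMask:
    """Boolean volume-of-interest mask on the shared grid."""

    grid: VoxelGrid
    mask: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.mask = _check_array(self.grid, self.mask, "mask").astype(bool, copy=False)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_mL(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_mL

    def require_nonempty(self):
        if self.n_voxels == 0:
            raise ValidationError(f"VOI mask {self.label!r} is empty")


@dataclass
class TimeSeriesVolumes:
    """Serial acquisitions: strictly increasing times (h), one volume each."""

    times_h: tuple[float, ...]
    volumes: list[ScalarVolume]

    def __post_init__(self):
        self.times_h = tuple(float(t) for t in self.times_h)
        if len(self.times_h) != len(self.volumes):
            raise ValidationError("times and volumes differ in length")
        if len(self.times_h) < 2:
            raise ValidationError("a time series needs at least 2 acquisitions")
        if self.times_h[0] < 0 or any(b <= a for a, b in zip(self.times_h, self.times_h[1:])):
            raise ValidationError(f"times must be non-negative and strictly increasing, got {self.times_h}")
        g0, q0 = self.volumes[0].grid, self.volumes[0].quantity
        for v in self.volumes[1:]:
            if v.grid != g0:
                raise ValidationError("all volumes in a series must share one grid")
            if v.quantity != q0:
                raise ValidationError("all volumes in a series must share one quantity")

    @property
    def grid(self) -> VoxelGrid:
        return self.volumes[0].grid

    def __len__(self) -> int:
        return len(self.times_h)


# ---------------------------------------------------------------------------
# nuclide decay data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Nuclide:
    """Radionuclide decay data driving the Monte Carlo engine.

    ``photon_lines`` are (energy_MeV, yield_per_decay) pairs.  Beta emission
    is summarised by a mean energy per decay for transport bookkeeping; when
    ``beta_transport`` is ``"kernel"`` a tabulated (energy_MeV, probability)
    spectrum must be present so a radial deposition kernel can be derived.
    """

    name: str
    half_life_h: float
    photon_lines: tuple[tuple[float, float], ...] = ()
    beta_mean_energy_MeV: float = 0.0
    beta_yield: float = 1.0
    beta_spectrum: Optional[tuple[tuple[float, float], ...]] = None
    beta_max_energy_MeV: Optional[float] = None
    beta_transport: str = "local"

    def __post_init__(self):
        if not (self.half_life_h > 0):
            raise ValidationError(f"half_life_h must be positive, got {self.half_life_h}")
        if self.beta_transport not in ("local", "kernel"):
            raise ValidationError("beta_transport must be 'local' or 'kernel'")
        for e, y in self.photon_lines:
            if e <= 0 or y < 0:
                raise ValidationError(f"bad photon line ({e} MeV, yield {y})")
        if self.beta_yield < 0 or self.beta_mean_energy_MeV < 0:
            raise ValidationError("beta energy and yield must be non-negative")
        if self.beta_transport == "kernel" and self.beta_spectrum is None and self.beta_max_energy_MeV is None:
            raise ValidationError("kernel beta transport needs a spectrum or an endpoint energy")

    @property
    def decay_const_per_h(self) -> float:
        return math.log(2.0) / self.half_life_h

    @property
    def photon_energy_per_decay_MeV(self) -> float:
        return sum(e * y for e, y in self.photon_lines)

    @property
    def beta_energy_per_decay_MeV(self) -> float:
        return self.beta_mean_energy_MeV * self.beta_yield

    @property
    def energy_per_decay_MeV(self) -> float:
        return self.photon_energy_per_decay_MeV + self.beta_energy_per_decay_MeV


def load_nuclide(name: str) -> Nuclide:
    """Load bundled decay data (``lu177``, ``y90``) by case-insensitive name.

    The packaged table is compiled from the standard MIRD/ICRP-107 decay
    compendia; see the data file header for the provenance of each entry.
    """
    with resources.files("voxdose.data").joinpath("nuclides.yaml").open() as fh:
        table = yaml.safe_load(fh)
    key = name.lower().replace("-", "")
    if key not in table:
        raise KeyError(f"no bundled decay data for {name!r}; have {sorted(table)}")
    d = table[key]
    spectrum = d.get("beta_spectrum")
    return Nuclide(
        name=d["name"],
        half_life_h=float(d["half_life_h"]),
        photon_lines=tuple((float(e), float(y)) for e, y in d.get("photon_lines", [])),
        beta_mean_energy_MeV=float(d.get("beta_mean_energy_MeV", 0.0)),
        beta_yield=float(d.get("beta_yield", 1.0)),
        beta_spectrum=tuple((float(e), float(p)) for e, p in spectrum) if spectrum else None,
        beta_max_energy_MeV=float(d["beta_max_energy_MeV"]) if "beta_max_energy_MeV" in d else None,
        beta_transport=d.get("beta_transport", "local"),
    )


# ---------------------------------------------------------------------------
# blood and cohort tables
# ---------------------------------------------------------------------------

@dataclass
class BloodSeries:
    """Blood-sample activity concentrations with optional whole-body totals."""

    times_h: tuple[float, ...]
    concentration_MBq_per_mL: tuple[float, ...]
    whole_body_MBq: Optional[tuple[float, ...]] = None

    def __post_init__(self):
        self.times_h = tuple(float(t) for t in self.times_h)
        self.concentration_MBq_per_mL = tuple(float(c) for c in self.concentration_MBq_per_mL)
        if len(self.times_h) != len(self.concentration_MBq_per_mL):
            raise ValidationError("blood series lengths differ")
        if any(b <= a for a, b in zip(self.times_h, self.times_h[1:])):
            raise ValidationError("blood sample times must be strictly increasing")
        if not all(math.isfinite(c) and c >= 0 for c in self.concentration_MBq_per_mL):
            raise ValidationError("blood concentrations must be finite and non-negative")
        if self.whole_body_MBq is not None:
            self.whole_body_MBq = tuple(float(a) for a in self.whole_body_MBq)
            if len(self.whole_body_MBq) != len(self.times_h):
                raise ValidationError("whole-body series length differs from blood series")


_COHORT_COLUMNS = [
    "patient_id", "administered_activity_GBq", "tumor_volume_mL",
    "ad_tumor_3d_Gy", "ad_rbm_3d_Gy", "ad_tumor_sphere_Gy",
    "ad_rbm_blood_Gy", "ad_rbm_cranium_Gy",
    "grade_thrombocytopenia", "grade_leucopenia",
]


@dataclass
class CohortRecord:
    """One patient's administered activity, doses and hematologic toxicity.

    Toxicity grades follow NCI-CTC (0 = none .. 4); the dose fields carry the
    method-wise red-bone-marrow and tumor absorbed doses in Gy.
    """

    patient_id: int
    administered_activity_GBq: float
    tumor_volume_mL: float
    ad_tumor_3d_Gy: float
    ad_rbm_3d_Gy: float
    ad_tumor_sphere_Gy: float
    ad_rbm_blood_Gy: Optional[float] = None
    ad_rbm_cranium_Gy: Optional[float] = None
    grade_thrombocytopenia: int = 0
    grade_leucopenia: int = 0

    def __post_init__(self):
        for g in (self.grade_thrombocytopenia, self.grade_leucopenia):
            if not (isinstance(g, (int, np.integer)) and 0 <= g <= 4):
                raise ValidationError(f"toxicity grade must be an integer in 0..4, got {g!r}")
        for name in ("administered_activity_GBq", "tumor_volume_mL", "ad_tumor_3d_Gy",
                     "ad_rbm_3d_Gy", "ad_tumor_sphere_Gy", "ad_rbm_blood_Gy", "ad_rbm_cranium_Gy"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be non-negative, got {v}")

    @property
    def any_toxicity(self) -> bool:
        return self.grade_thrombocytopenia >= 1 or self.grade_leucopenia >= 1


def load_cohort(path: str | Path) -> list[CohortRecord]:
    """Read a cohort CSV into validated records (one per patient row)."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValidationError(f"cohort file {path} contains no records")
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns and not c.startswith("ad_rbm_blood")
               and not c.startswith("ad_rbm_cranium")]
    if missing:
        raise ValidationError(f"cohort file {path} lacks columns {missing}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(CohortRecord(
                patient_id=int(row["patient_id"]),
                administered_activity_GBq=float(row["administered_activity_GBq"]),
                tumor_volume_mL=float(row["tumor_volume_mL"]),
                ad_tumor_3d_Gy=float(row["ad_tumor_3d_Gy"]),
                ad_rbm_3d_Gy=float(row["ad_rbm_3d_Gy"]),
                ad_tumor_sphere_Gy=float(row["ad_tumor_sphere_Gy"]),
                ad_rbm_blood_Gy=_opt(row.get("ad_rbm_blood_Gy")),
                ad_rbm_cranium_Gy=_opt(row.get("ad_rbm_cranium_Gy")),
                grade_thrombocytopenia=_grade(row["grade_thrombocytopenia"]),
                grade_leucopenia=_grade(row["grade_leucopenia"]),
            ))
        except (ValidationError, ValueError, TypeError) as exc:
            raise ValidationError(f"cohort row {idx} (patient_id={row.get('patient_id')}): {exc}") from exc
    return records


def _opt(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or pd.isna(v):
        return None
    return float(v)


def _grade(v) -> int:
    f = float(v)
    if not f.is_integer():
        raise ValidationError(f"grade {v!r} is not an integer")
    return int(f)


def save_cohort(records: Sequence[CohortRecord], path: str | Path) -> None:
    pd.DataFrame([asdict(r) for r in records])[_COHORT_COLUMNS].to_csv(path, index=False)


def packaged_cohort() -> list[CohortRecord]:
    """The bundled 13-patient 177Lu pretargeted-RIT cohort fixture."""
    with resources.as_file(resources.files("voxdose.data").joinpath("cohort_lu177_prit.csv")) as p:
        return load_cohort(p)


def packaged_matched_pair() -> pd.DataFrame:
    """Bundled per-patient tumor-to-RBM dose ratios for 177Lu and simulated 90Y."""
    with resources.as_file(resources.files("voxdose.data").joinpath("tumor_rbm_ratios_lu177_y90.csv")) as p:
        return pd.read_csv(p)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class DosimetryConfig:
    """Every fixed constant of the pipeline, with its study default.

    The SPECT calibration factor, attenuation coefficient, cranium RBM mass
    fraction, RBM-to-blood activity concentration ratio, linear-quadratic
    alpha/beta, repair rate and history count are protocol constants.  The
    marrow S-values and RBM mass are reference-phantom placeholders (the
    quantities a model-based dosimetry code would supply) and are expected
    to be overridden per anatomical model; every report embeds the values
    actually used.
    """

    calibration_MBq_per_count: float = 6.23e-6
    attenuation_cm_inv: float = 0.13
    cranium_rbm_fraction: float = 0.119
    rbm_to_blood_ratio: float = 1.0
    alpha_over_beta_Gy: float = 10.0
    repair_rate_mu_per_h: float = 0.46
    n_histories: int = 1_000_000
    rng_seed: int = 0
    rbm_mass_g: float = 1170.0
    # beta-only self-irradiation S-value for a 1170 g reference marrow and the
    # bundled 177Lu mean beta energy; photon remainder-of-body cross-dose is a
    # small placeholder of the same order as reference-phantom photon terms.
    s_rbm_self_mGy_per_MBq_h: float = 6.58e-2
    s_rbm_from_remainder_mGy_per_MBq_h: float = 1.5e-4
    photon_cutoff_MeV: float = 0.02
    lung_max_g_cm3: float = 0.5
    bone_min_g_cm3: float = 1.2

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "rng_seed":
                if v < 0:
                    raise ValidationError("rng_seed must be non-negative")
                continue
            if not (v > 0):
                raise ValidationError(f"config key {f.name} must be positive, got {v}")
        for f in ("cranium_rbm_fraction", "rbm_to_blood_ratio"):
            v = getattr(self, f)
            if not (0 < v <= 1):
                raise ValidationError(f"config key {f} must lie in (0, 1], got {v}")
        if self.lung_max_g_cm3 >= self.bone_min_g_cm3:
            raise ValidationError("lung_max_g_cm3 must be below bone_min_g_cm3")
        self.n_histories = int(self.n_histories)
        if self.n_histories < 1:
            raise ValidationError("n_histories must be >= 1")

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]

    def replace(self, **kw) -> "DosimetryConfig":
        return replace(self, **kw)


def load_config(path: Optional[str | Path] = None, **overrides) -> DosimetryConfig:
    """Load a YAML config; absent keys take defaults, unknown keys are rejected."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} must contain a mapping")
    data.update(overrides)
    known = {f.name for f in fields(DosimetryConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    cfg = DosimetryConfig(**data)
    logger.info("config loaded (digest %s)", cfg.digest())
    return cfg


# ---------------------------------------------------------------------------
# volume I/O
# ---------------------------------------------------------------------------

def write_volume(vol: ScalarVolume, path: str | Path) -> None:
    """Write a ScalarVolume as NIfTI-1 plus a JSON sidecar with the quantity."""
    path = Path(path)
    img = nib.Nifti1Image(vol.values.astype(np.float64), vol.grid.affine())
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix("")
    sidecar = sidecar.parent / (sidecar.name + ".json")
    sidecar.write_text(json.dumps({"quantity": vol.quantity}))


def read_volume(path: str | Path, quantity: Optional[str] = None,
                spacing_tol_mm: float = 1e-3) -> ScalarVolume:
    """Read a NIfTI volume; spacing from the header must be isotropic.

    The physical quantity is taken from the JSON sidecar written by
    :func:`write_volume`, or from the ``quantity`` argument which overrides it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if max(zooms) - min(zooms) > spacing_tol_mm:
        raise ValidationError(f"anisotropic voxel spacing {zooms} mm exceeds tolerance {spacing_tol_mm} mm")
    if quantity is None:
        sidecar = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix("")
        sidecar = sidecar.parent / (sidecar.name + ".json")
        if not sidecar.exists():
            raise ValidationError(f"no quantity sidecar at {sidecar}; pass quantity= explicitly")
        quantity = json.loads(sidecar.read_text())["quantity"]
    values = np.asarray(img.dataobj, dtype=np.float64)
    origin = tuple(float(v) for v in img.affine[:3, 3])
    grid = VoxelGrid(shape=values.shape, voxel_size_mm=zooms[0], origin_mm=origin)
    return ScalarVolume(grid=grid, values=values, quantity=quantity)


def write_mask(mask: VoiMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), mask.grid.affine())
    nib.save(img, str(path))


def read_mask(path: str | Path, label: str = "") -> VoiMask:
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    values = np.asarray(img.dataobj)
    grid = VoxelGrid(shape=values.shape, voxel_size_mm=zooms[0],
                     origin_mm=tuple(float(v) for v in img.affine[:3, 3]))
    return VoiMask(grid=grid, mask=values > 0, label=label)
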