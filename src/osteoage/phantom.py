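"""Synthetic CT phantom cohorts with a known, parameterized age signal.

Real post-mortem CT collections are not redistributable, so the package
ships a generator that emulates the two age indicators the pipeline
consumes. Each subject gets two small CT volumes:

* a **femur** region: a cortical-shell cylinder (shaft) plus a spherical
  head, embedded in soft tissue;
* a **mandible** region: per-slice U-shaped cortical arch, plus a small,
  disconnected "neck bone" cylinder that the component-retention rule is
  expected to remove.

The age signal is linear in both cortical density and cortical thickness:

    density(age, sex) = h0 - beta * age + delta * sex   [HU]
    thickness(age)    = t0 - gamma * age                [mm]

with i.i.d. Gaussian voxel noise on top. An optional per-subject,
per-modality density jitter makes the two bones carry *independent* noisy
copies of the age signal, which is what gives multimodal fusion something
to average away.

Volumes are emitted at 2 mm spacing on small grids so the 1 mm isotropic
resampler exercises its real code path on every phantom.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import stats

from .dicom_io import CTVolume, write_series
from .preprocessing import HU_WINDOW

__all__ = [
    "PhantomParams",
    "TruthRecord",
    "InvalidPhantomParams",
    "generate_subject",
    "iter_cohort",
    "generate_cohort",
]

AIR_HU = -1000.0
SOFT_TISSUE_HU = 50.0
MEDULLARY_HU = 150.0


class InvalidPhantomParams(ValueError):
    """Phantom parameters violate their stated invariants."""


@dataclass(frozen=True)
class PhantomParams:
    """Cohort-level generator settings.

    Defaults mirror the study population the pipeline targets: ages 20-70
    drawn from a truncated normal with mean 49.59 and sd 11.80 years, and a
    76% male cohort. The density model keeps cortical bone inside the
    400-1000 HU segmentation window across the whole age range.
    """

    n_subjects: int = 100
    age_range: tuple[float, float] = (20.0, 70.0)
    age_mean: float = 49.59
    age_sd: float = 11.80
    sex_ratio_male: float = 0.76
    #: cortical density extrapolated to age 0, HU
    h0: float = 900.0
    #: density decline, HU per year (> 0 means older = less dense)
    beta: float = 4.0
    #: sex offset on density, HU (added for sex=1, female)
    delta: float = -25.0
    #: cortical thickness extrapolated to age 0, mm
    t0: float = 7.0
    #: cortical thinning, mm per year
    gamma: float = 0.04
    #: i.i.d. voxel noise, HU
    noise_sd: float = 30.0
    #: per-subject, per-modality density offset sd, HU (complementary signal)
    modality_jitter_sd: float = 0.0
    #: isotropic voxel spacing of the emitted grids, mm
    spacing: float = 2.0
    femur_grid: tuple[int, int, int] = (40, 64, 64)
    mandible_grid: tuple[int, int, int] = (24, 80, 80)
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.age_range
        if not (lo < hi):
            raise InvalidPhantomParams("invalid phantom params: empty age range")
        if self.noise_sd < 0 or self.modality_jitter_sd < 0:
            raise InvalidPhantomParams("invalid phantom params: negative noise sd")
        if not (0.0 <= self.sex_ratio_male <= 1.0):
            raise InvalidPhantomParams("invalid phantom params: sex ratio outside [0, 1]")
        floor = self.h0 - self.beta * hi + min(0.0, self.delta)
        if floor < 450.0:
            raise InvalidPhantomParams(
                f"invalid phantom params: cortical density can fall to {floor:g} HU, "
                "leaving the 400-1000 HU bone window"
            )
        if self.t0 - self.gamma * hi <= 0:
            raise InvalidPhantomParams("invalid phantom params: cortical shell vanishes")


@dataclass
class TruthRecord:
    """Ground truth for one generated subject."""

    subject_id: str
    age_years: float
    sex: int  # 0 = male, 1 = female
    femur_density_hu: float
    mandible_density_hu: float
    cortical_thickness_mm: float


def _coordinate_grids(shape: tuple[int, int, int], spacing: float):
    """Physical (z, y, x) coordinates of voxel centers, centered at 0 in-plane."""
    z = np.arange(shape[0])[:, None, None] * spacing
    y = (np.arange(shape[1]) - shape[1] / 2 + 0.5)[None, :, None] * spacing
    x = (np.arange(shape[2]) - shape[2] / 2 + 0.5)[None, None, :] * spacing
    return z, y, x


def _femur_volume(
    density: float, thickness: float, params: PhantomParams, rng: np.random.Generator
) -> np.ndarray:
    shape = params.femur_grid
    z, y, x = _coordinate_grids(shape, params.spacing)
    height = shape[0] * params.spacing
    vol = np.full(shape, AIR_HU, dtype=np.float32)

    body_r = min(shape[1], shape[2]) * params.spacing / 2 - 2.0
    r2 = y**2 + x**2
    vol[np.broadcast_to(r2 < body_r**2, shape)] = SOFT_TISSUE_HU

    # shaft: cortical annulus around a medullary core, along the full height
    shaft_r = 13.0
    shaft = np.broadcast_to(r2 < shaft_r**2, shape)
    core = np.broadcast_to(r2 < (shaft_r - thickness) ** 2, shape)
    vol[shaft] = density
    vol[core] = MEDULLARY_HU

    # femoral head: cortical spherical shell near the top of the region
    head_r = 17.0
    head_center = (height - head_r - 2.0, 0.0, shaft_r + 8.0)
    d2 = (z - head_center[0]) ** 2 + (y - head_center[1]) ** 2 + (x - head_center[2]) ** 2
    vol[d2 < head_r**2] = density
    vol[d2 < (head_r - thickness) ** 2] = MEDULLARY_HU

    if params.noise_sd > 0:
        vol = vol + rng.normal(0.0, params.noise_sd, shape).astype(np.float32)
    return vol.astype(np.float32)


def _mandible_volume(
    density: float, thickness: float, params: PhantomParams, rng: np.random.Generator
) -> np.ndarray:
    shape = params.mandible_grid
    _, y, x = _coordinate_grids(shape, params.spacing)
    vol = np.full(shape, AIR_HU, dtype=np.float32)

    body_r = min(shape[1], shape[2]) * params.spacing / 2 - 2.0
    vol[np.broadcast_to(y**2 + x**2 < body_r**2, shape)] = SOFT_TISSUE_HU

    # U-shaped arch: anterior (y < 0) half of a cortical annulus
    arch_r = 45.0
    arch_c = (12.0, 0.0)  # (y, x) center, pushed posterior so the arch fits
    rr2 = (y - arch_c[0]) ** 2 + (x - arch_c[1]) ** 2
    arch2d = (rr2 < arch_r**2) & (rr2 >= (arch_r - thickness) ** 2) & (y < arch_c[0])

    # small disconnected "neck bone" fragment, posterior to the arch
    neck2d = (y - (arch_c[0] + arch_r + 8.0)) ** 2 + x**2 < 3.0**2

    band = slice(4, shape[0] - 4)
    arch3d = np.zeros(shape, dtype=bool)
    arch3d[band] = np.broadcast_to(arch2d, (band.stop - band.start,) + arch2d.shape[1:])
    neck3d = np.zeros(shape, dtype=bool)
    neck3d[band] = np.broadcast_to(neck2d, (band.stop - band.start,) + neck2d.shape[1:])
    vol[arch3d] = density
    vol[neck3d] = density

    if params.noise_sd > 0:
        vol = vol + rng.normal(0.0, params.noise_sd, shape).astype(np.float32)
    return vol.astype(np.float32)


def generate_subject(
    age: float,
    sex: int,
    params: PhantomParams,
    rng: np.random.Generator,
    subject_id: str = "phantom",
) -> tuple[CTVolume, CTVolume, TruthRecord]:
    """Generate (femur volume, mandible volume, truth record) for one subject."""
    params.validate()
    if sex not in (0, 1):
        raise ValueError("invalid sex code: expected 0 (male) or 1 (female)")
    base = params.h0 - params.beta * age + params.delta * sex
    jitter_f = jitter_m = 0.0
    if params.modality_jitter_sd > 0:
        jitter_f, jitter_m = rng.normal(0.0, params.modality_jitter_sd, 2)
    thickness = params.t0 - params.gamma * age

    spacing = (params.spacing,) * 3
    femur = CTVolume(
        values=_femur_volume(base + jitter_f, thickness, params, rng),
        spacing=spacing,
        subject_id=subject_id,
    )
    mandible = CTVolume(
        values=_mandible_volume(base + jitter_m, thickness, params, rng),
        spacing=spacing,
        subject_id=subject_id,
    )
    record = TruthRecord(
        subject_id=subject_id,
        age_years=float(age),
        sex=int(sex),
        femur_density_hu=float(base + jitter_f),
        mandible_density_hu=float(base + jitter_m),
        cortical_thickness_mm=float(thickness),
    )
    return femur, mandible, record


def _draw_demographics(params: PhantomParams, rng: np.random.Generator):
    lo, hi = params.age_range
    a = (lo - params.age_mean) / params.age_sd
    b = (hi - params.age_mean) / params.age_sd
    ages = stats.truncnorm.rvs(
        a, b, loc=params.age_mean, scale=params.age_sd, size=params.n_subjects, random_state=rng
    )
    sexes = (rng.random(params.n_subjects) >= params.sex_ratio_male).astype(int)
    return ages, sexes


def iter_cohort(params: PhantomParams):
    """Yield ``(femur, mandible, TruthRecord)`` per subject, deterministically.

    Demographics come from the master seed; each subject owns a spawned
    child stream so per-subject noise is independent of cohort size.
    """
    params.validate()
    master = np.random.default_rng(params.seed)
    ages, sexes = _draw_demographics(params, master)
    children = np.random.SeedSequence(params.seed).spawn(params.n_subjects)
    for i in range(params.n_subjects):
        rng = np.random.default_rng(children[i])
        yield generate_subject(
            float(ages[i]), int(sexes[i]), params, rng, subject_id=f"P{i:04d}"
        )


def generate_cohort(params: PhantomParams, out_dir: str | Path):
    """Write a DICOM cohort tree plus manifest and truth CSVs.

    Layout: ``out/dicom/<id>/<modality>/slice_*.dcm``; ``out/manifest.csv``
    with columns (subject_id, age_years, sex, femur_dir, mandible_dir);
    ``out/truth.csv`` with the realized per-subject signal. Deterministic
    given ``params.seed`` (the truth CSV is byte-identical across runs).
    """
    import pandas as pd

    out_dir = Path(out_dir)
    (out_dir / "dicom").mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    truth_rows = []
    for femur, mandible, rec in iter_cohort(params):
        subj_dir = out_dir / "dicom" / rec.subject_id
        write_series(femur, subj_dir / "femur", subject_id=rec.subject_id)
        write_series(mandible, subj_dir / "mandible", subject_id=rec.subject_id)
        manifest_rows.append(
            {
                "subject_id": rec.subject_id,
                "age_years": rec.age_years,
                "sex": rec.sex,
                "femur_dir": str(subj_dir / "femur"),
                "mandible_dir": str(subj_dir / "mandible"),
            }
        )
        truth_rows.append(vars(rec))
    manifest = pd.DataFrame(manifest_rows)
    truth = pd.DataFrame(truth_rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False, float_format="%.6f")
    truth.to_csv(out_dir / "truth.csv", index=False, float_format="%.6f")
    return manifest, truth
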