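"""End-to-end plumbing: cohorts -> preprocessed bone voxels -> model samples.

Ties the stages together for scripts, tests and the CLI: generate or load a
cohort, run the real preprocessing chain (1 mm isotropic resampling, femur
windowing, mandible extraction), and package the results as training
samples, optionally block-averaged down to a desk-scale network grid and
augmented with the stacked two-channel early-fusion input.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dicom_io import CTVolume, read_series, to_hounsfield
from .networks import resize_volume
from .phantom import PhantomParams, iter_cohort
from .preprocessing import (
    downsample_block_mean,
    extract_mandible,
    resample_isotropic,
    segment_femur,
)
from .training import Sample

__all__ = [
    "preprocess_subject",
    "phantom_dataset",
    "load_dicom_subject",
    "prep_manifest",
    "load_voxel_dataset",
    "add_early_channel",
    "DESK_DOWNSAMPLE",
    "DESK_INPUT_SHAPES",
    "desk_network_config",
    "desk_train_config",
]

#: block-mean factors taking full-size bone voxels to desk-scale grids
#: (femur 112x128x128 -> 14x16x16, mandible 20x256x256 -> 10x16x16)
DESK_DOWNSAMPLE = {"femur": (8, 8, 8), "mandible": (2, 16, 16)}
#: network crop shapes on the desk-scale grids (2-voxel jitter per axis)
DESK_INPUT_SHAPES = {"femur": (12, 14, 14), "mandible": (10, 14, 14), "early": (10, 14, 14)}
#: shared grid for the stacked two-channel early-fusion input
DESK_EARLY_GRID = (10, 16, 16)


def desk_network_config(fusion: str = "none", modality: str = "femur", seed: int = 0):
    """Scale-reduced model configuration for CPU-sized experiments.

    Same architectures and fusion wiring as the full-size models, with
    channel widths at 1/8 scale and inputs on the block-averaged grids.
    """
    from .networks import NetworkConfig

    return NetworkConfig(
        fusion=fusion,
        modality=modality,
        input_shapes=dict(DESK_INPUT_SHAPES),
        scale=0.125,
        seed=seed,
    )


def desk_train_config(seed: int = 0, epochs: int = 35):
    """Desk-scale optimization recipe (see the package methods note).

    Keeps the full-size recipe's structure (Adam, MSE, plateau schedule,
    crop augmentation, minibatch 16) with a learning rate sized for the
    much smaller parameter count and shorter schedule.
    """
    from .training import TrainConfig

    return TrainConfig(
        epochs=epochs,
        lr=0.02,
        min_lr=2e-3,
        plateau_patience=6,
        crop_shapes=dict(DESK_INPUT_SHAPES),
        seed=seed,
    )


def preprocess_subject(
    femur_vol: CTVolume | None,
    mandible_vol: CTVolume | None,
    downsample: dict | None = None,
) -> dict[str, np.ndarray]:
    """Resample to 1 mm and segment; return modality -> voxel array.

    ``downsample`` maps modality to integer block-mean factors, applied
    after segmentation to produce desk-scale inputs.
    """
    voxels: dict[str, np.ndarray] = {}
    if femur_vol is not None:
        iso = resample_isotropic(femur_vol)
        voxels["femur"] = segment_femur(iso).values
    if mandible_vol is not None:
        iso = resample_isotropic(mandible_vol)
        voxels["mandible"] = extract_mandible(iso).values
    if downsample:
        for m, factors in downsample.items():
            if m in voxels:
                voxels[m] = downsample_block_mean(voxels[m], factors)
    return voxels


def add_early_channel(voxels: dict[str, np.ndarray], grid: tuple[int, int, int]) -> None:
    """Attach the 2-channel early-fusion input (mandible, femur) on ``grid``."""
    voxels["early"] = np.stack(
        [resize_volume(voxels["mandible"], grid), resize_volume(voxels["femur"], grid)]
    )


def phantom_dataset(
    params: PhantomParams,
    downsample: dict | None = None,
    early_grid: tuple[int, int, int] | None = None,
    modalities: tuple[str, ...] = ("femur", "mandible"),
) -> tuple[list[Sample], pd.DataFrame]:
    """Generate a phantom cohort and preprocess it in memory.

    Returns (samples, truth table). The full preprocessing chain runs per
    subject; DICOM round-tripping is exercised separately because it only
    re-quantizes intensities by <= 1 HU.
    """
    samples: list[Sample] = []
    truth_rows = []
    for femur, mandible, rec in iter_cohort(params):
        voxels = preprocess_subject(
            femur if "femur" in modalities else None,
            mandible if "mandible" in modalities else None,
            downsample,
        )
        if early_grid is not None:
            add_early_channel(voxels, early_grid)
        samples.append(Sample(sid=rec.subject_id, age=rec.age_years, sex=rec.sex, voxels=voxels))
        truth_rows.append(vars(rec))
    return samples, pd.DataFrame(truth_rows)


def load_dicom_subject(
    femur_dir: str | Path | None, mandible_dir: str | Path | None
) -> tuple[CTVolume | None, CTVolume | None]:
    """Read the per-modality DICOM series of one subject into HU volumes."""
    femur = to_hounsfield(read_series(femur_dir)) if femur_dir else None
    mandible = to_hounsfield(read_series(mandible_dir)) if mandible_dir else None
    return femur, mandible


def prep_manifest(
    manifest: pd.DataFrame, out_dir: str | Path, modality: str = "both"
) -> pd.DataFrame:
    """Preprocess every manifest subject to NPZ voxels with JSON sidecars.

    The manifest needs columns subject_id, age_years, sex and the
    per-modality series directories (femur_dir / mandible_dir).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    want_femur = modality in ("femur", "both")
    want_mandible = modality in ("mandible", "both")
    rows = []
    for _, row in manifest.iterrows():
        femur, mandible = load_dicom_subject(
            row.get("femur_dir") if want_femur else None,
            row.get("mandible_dir") if want_mandible else None,
        )
        voxels = preprocess_subject(femur, mandible)
        entry = {"subject_id": row["subject_id"], "age_years": row["age_years"], "sex": row["sex"]}
        for m, arr in voxels.items():
            path = out_dir / f"{row['subject_id']}_{m}.npz"
            np.savez_compressed(path, values=arr)
            path.with_suffix(".json").write_text(
                json.dumps(
                    {
                        "subject_id": str(row["subject_id"]),
                        "modality": m,
                        "shape": list(arr.shape),
                        "window_hu": [400, 1000],
                    },
                    indent=2,
                )
            )
            entry[f"{m}_voxels"] = str(path)
        rows.append(entry)
    index = pd.DataFrame(rows)
    index.to_csv(out_dir / "voxels.csv", index=False)
    return index


def load_voxel_dataset(index: pd.DataFrame, downsample: dict | None = None) -> list[Sample]:
    """Load NPZ voxels listed in a prep index into training samples."""
    samples = []
    for _, row in index.iterrows():
        voxels = {}
        for m in ("femur", "mandible"):
            col = f"{m}_voxels"
            if col in row and isinstance(row[col], str):
                with np.load(row[col]) as data:
                    voxels[m] = data["values"]
                if downsample and m in downsample:
                    voxels[m] = downsample_block_mean(voxels[m], downsample[m])
        samples.append(
            Sample(
                sid=str(row["subject_id"]),
                age=float(row["age_years"]),
                sex=int(row["sex"]),
                voxels=voxels,
            )
        )
    return samples
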