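"""File formats: NIfTI rasters, lesion/training CSV tables, model JSON,
and YAML configuration echoes.

Each slide directory holds one NIfTI per feature map plus the prostate
mask, the truth density, and one int16 label volume per observer; grids are
row-major with 0-based voxel indices, and the in-plane voxel area is stored
in the NIfTI zooms.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .phantom import FEATURE_NAMES, AnnotationSet, DensityMap, FeatureVolume, Slide
from .plsmap import Pls1Model

TRAINING_COLUMNS = ["lesion_id", "slide_id", "observer", "class", "area_vox",
                    "group"] + [f"x_{n}" for n in FEATURE_NAMES] + ["y"]


def write_nifti(path: Path, data: np.ndarray, voxel_mm: float = 1.0,
                dtype=np.float32) -> None:
    affine = np.diag([voxel_mm, voxel_mm, 1.0, 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine)
    nib.save(img, str(path))


def read_nifti(path: Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return np.asarray(nib.load(str(path)).get_fdata())
    except Exception as exc:  # malformed file
        raise ValueError(f"could not parse NIfTI file {path}: {exc}") from exc


def write_slide(slide: Slide, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vox_mm = float(np.sqrt(slide.features.voxel_area_mm2))
    for j, name in enumerate(slide.features.feature_names):
        write_nifti(outdir / f"feature_{name}.nii.gz",
                    slide.features.data[:, :, j], vox_mm)
    write_nifti(outdir / "prostate_mask.nii.gz",
                slide.prostate_mask.astype(np.int16), vox_mm, dtype=np.int16)
    write_nifti(outdir / "truth_density.nii.gz", slide.truth_density.data, vox_mm)
    if slide.annotations is not None:
        for obs, arr in slide.annotations.labels.items():
            write_nifti(outdir / f"labels_{obs}.nii.gz", arr, vox_mm,
                        dtype=np.int16)
    meta = {"slide_id": slide.slide_id, "patient_id": slide.patient_id,
            "voxel_area_mm2": slide.features.voxel_area_mm2}
    (outdir / "slide.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_slide(indir: Path) -> Slide:
    indir = Path(indir)
    meta = json.loads((indir / "slide.json").read_text())
    mask = read_nifti(indir / "prostate_mask.nii.gz").astype(bool)
    data = np.stack(
        [read_nifti(indir / f"feature_{n}.nii.gz") for n in FEATURE_NAMES], axis=-1
    )
    if data.shape[:2] != mask.shape:
        raise ValueError(
            f"{indir}: feature grid {data.shape[:2]} does not match "
            f"mask grid {mask.shape}"
        )
    features = FeatureVolume(data=data, prostate_mask=mask,
                             voxel_area_mm2=float(meta["voxel_area_mm2"]))
    density = DensityMap(read_nifti(indir / "truth_density.nii.gz"), role="truth")
    labels = {}
    for f in sorted(indir.glob("labels_*.nii.gz")):
        obs = f.name[len("labels_"):-len(".nii.gz")]
        arr = read_nifti(f).astype(np.int16)
        if arr.shape != mask.shape:
            raise ValueError(f"{f}: label grid does not match mask grid")
        labels[obs] = arr
    annotations = AnnotationSet(labels) if labels else None
    return Slide(slide_id=meta["slide_id"], patient_id=meta["patient_id"],
                 features=features, truth_density=density,
                 truth_labels=np.zeros(mask.shape, dtype=np.int16),
                 lesions=[], annotations=annotations)


def write_table(table: pd.DataFrame, path: Path, sep: str = ",") -> None:
    table.to_csv(path, sep=sep, index=False)


def read_table(path: Path, required: list[str] | None = None,
               sep: str = ",") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep=sep)
    if required:
        missing = [c for c in required if c not in table.columns]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
    return table


def write_model(model: Pls1Model, path: Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2, sort_keys=True))


def read_model(path: Path) -> Pls1Model:
    path = Path(path)
    try:
        return Pls1Model.from_dict(json.loads(path.read_text()))
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ValueError(f"could not parse model file {path}: {exc}") from exc


def write_yaml(obj: dict, path: Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_yaml(path: Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"could not parse YAML file {path}: {exc}") from exc
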