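"""File formats: NIfTI volumes/masks, CSV/TSV tables, GMT gene sets."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from radgen.cohort import TumorVolume


def save_volume(vol: TumorVolume, out_dir: Path) -> tuple[Path, Path]:
    """Write one patient's intensities and mask as ``<id>_{image,mask}.nii.gz``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(vol.spacing) + [1.0])
    img_path = out_dir / f"{vol.patient_id}_image.nii.gz"
    mask_path = out_dir / f"{vol.patient_id}_mask.nii.gz"
    nib.save(nib.Nifti1Image(vol.intensities.astype(np.float32), affine), img_path)
    nib.save(nib.Nifti1Image(vol.mask.astype(np.uint8), affine), mask_path)
    return img_path, mask_path


def load_volume(image_path: Path, mask_path: Path, patient_id: str | None = None) -> TumorVolume:
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    pid = patient_id or Path(image_path).name.split("_image")[0].split(".nii")[0]
    return TumorVolume(
        intensities=np.asarray(img.dataobj, dtype=float),
        mask=np.asarray(msk.dataobj) > 0,
        spacing=spacing,
        patient_id=pid,
    )


def save_outcomes(outcomes: pd.DataFrame, path: Path) -> None:
    outcomes.to_csv(path, index=False)


def load_outcomes(path: Path) -> pd.DataFrame:
    out = pd.read_csv(path)
    required = {"patient_id", "metastasis", "time", "event"}
    if not required <= set(out.columns):
        raise ValueError(f"outcome CSV needs columns {sorted(required)}")
    return out


def save_expression(values: pd.DataFrame, path: Path) -> None:
    """Genes x samples TSV with gene ids in the first column."""
    values.to_csv(path, sep="\t")


def load_expression(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def save_gmt(gene_sets: dict[str, set[str]], path: Path, description: str = "radgen") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def load_gmt(path: Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(parts[2:])
    return sets
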