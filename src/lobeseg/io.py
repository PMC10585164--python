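"""Readers and writers for slice/mask data.

Supports per-subject NIfTI volumes (image + mask, float32/uint8, lossless
round-trip), per-slice 16-bit PNG pairs (images quantized to 1/65535
steps; masks exact), an optional DICOM series reader that picks up the
rescale slope/intercept and pixel spacing from the headers, and the cohort
export with its manifest CSV.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from lobeseg.phantom import Cohort
from lobeseg.preprocess import CTSlice

__all__ = [
    "write_nifti_subject",
    "read_nifti_subject",
    "write_png_pair",
    "read_png_pair",
    "read_dicom_slice",
    "export_cohort",
    "load_cohort_arrays",
]


def write_nifti_subject(directory, subject: int, images: np.ndarray, masks: np.ndarray,
                        spacing=(1.0, 1.0)) -> tuple[Path, Path]:
    """Write one subject's (n, H, W) stacks as image/mask NIfTI volumes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = np.diag([spacing[0], spacing[1], 1.0, 1.0])
    img_path = directory / f"subject{subject:03d}_image.nii"
    msk_path = directory / f"subject{subject:03d}_mask.nii"
    nib.save(nib.Nifti1Image(np.asarray(images, dtype=np.float32).transpose(1, 2, 0), affine), img_path)
    nib.save(nib.Nifti1Image(np.asarray(masks, dtype=np.uint8).transpose(1, 2, 0), affine), msk_path)
    return img_path, msk_path


def read_nifti_subject(directory, subject: int) -> tuple[np.ndarray, np.ndarray]:
    directory = Path(directory)
    img = nib.load(directory / f"subject{subject:03d}_image.nii")
    msk = nib.load(directory / f"subject{subject:03d}_mask.nii")
    images = np.asarray(img.dataobj, dtype=np.float32).transpose(2, 0, 1)
    masks = np.asarray(msk.dataobj, dtype=np.uint8).transpose(2, 0, 1)
    return images, masks


def write_png_pair(directory, stem: str, image: np.ndarray, mask: np.ndarray) -> tuple[Path, Path]:
    """16-bit PNGs: image scaled from [0,1] to [0, 65535], mask {0, 255}."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if image.min() < 0 or image.max() > 1:
        raise ValueError("PNG export expects image pixels in [0, 1]")
    img_path = directory / f"{stem}_image.png"
    msk_path = directory / f"{stem}_mask.png"
    iio.imwrite(img_path, np.round(image * 65535).astype(np.uint16))
    iio.imwrite(msk_path, (np.asarray(mask, dtype=np.uint16) * 65535))
    return img_path, msk_path


def read_png_pair(directory, stem: str) -> tuple[np.ndarray, np.ndarray]:
    directory = Path(directory)
    image = iio.imread(directory / f"{stem}_image.png").astype(np.float64) / 65535.0
    mask = (iio.imread(directory / f"{stem}_mask.png") > 0).astype(np.uint8)
    return image, mask


def read_dicom_slice(path) -> CTSlice:
    """One raw CT slice from a DICOM file, with rescale and spacing from
    the header (requires pydicom)."""
    import pydicom

    ds = pydicom.dcmread(path)
    spacing = tuple(float(v) for v in getattr(ds, "PixelSpacing", (1.0, 1.0)))
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return CTSlice(ds.pixel_array.astype(np.float64), "raw", spacing, (slope, intercept))


def export_cohort(cohort: Cohort, directory, fmt: str = "nifti") -> Path:
    """Write a generated cohort to ``directory`` in ``fmt`` ("nifti" or
    "png") plus a ``manifest.csv`` (subject, slice, partition, is_pole,
    stem). Returns the manifest path."""
    if fmt not in ("nifti", "png"):
        raise ValueError("format must be 'nifti' or 'png'")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = cohort.manifest.copy()
    manifest["stem"] = [
        f"s{r.subject:03d}_z{r.slice:03d}" for r in manifest.itertuples()
    ]
    if fmt == "nifti":
        for s in range(cohort.spec.n_subjects):
            idx = manifest.index[manifest["subject"] == s].to_numpy()
            write_nifti_subject(directory, s, cohort.images[idx], cohort.masks[idx])
    else:
        for i, r in manifest.iterrows():
            write_png_pair(directory, r["stem"], cohort.images[i], cohort.masks[i])
    path = directory / "manifest.csv"
    manifest.to_csv(path, index=False, lineterminator="\n")
    return path


def load_cohort_arrays(directory) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Read an exported cohort back into (images, masks, manifest)."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    images, masks = [], []
    if (directory / "subject000_image.nii").exists():
        per_subject = {}
        for s in sorted(manifest["subject"].unique()):
            per_subject[s] = read_nifti_subject(directory, s)
        counters = {s: 0 for s in per_subject}
        for r in manifest.itertuples():
            i = counters[r.subject]
            images.append(per_subject[r.subject][0][i])
            masks.append(per_subject[r.subject][1][i])
            counters[r.subject] += 1
    else:
        for r in manifest.itertuples():
            img, msk = read_png_pair(directory, r.stem)
            images.append(img)
            masks.append(msk)
    return np.stack(images).astype(np.float64), np.stack(masks), manifest
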