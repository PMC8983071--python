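"""Volume and patch I/O.

Readers: NIfTI (.nii/.nii.gz, via nibabel), MetaImage (.mha/.mhd, via
SimpleITK), and read-only DICOM series (pydicom, sorted along
ImagePositionPatient).  Writers: NIfTI volumes and 16-bit TIFF patches
(normalized [−1, 1] values mapped linearly to [0, 65535]) with a CSV
manifest recording provenance.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import CLINICAL, MICRO, CTVolume, ImagePatch, IntensityDomain

__all__ = [
    "read_volume",
    "write_nifti",
    "write_patch_tiffs",
    "read_patch_tiffs",
]


def read_volume(path, domain: IntensityDomain = CLINICAL) -> CTVolume:
    """Read a 3-D volume in native intensities; dispatch on extension.

    A directory is treated as a DICOM series.  Arrays are returned (z, y, x).
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path, domain)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float64)
        # nibabel axes are (x, y, z); reorder to (z, y, x)
        data = np.transpose(data, (2, 1, 0))
        zooms = img.header.get_zooms()[:3]
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
        return CTVolume(data, spacing, domain)
    if name.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img).astype(np.float64)  # (z, y, x)
        sp = img.GetSpacing()  # (x, y, z)
        return CTVolume(data, (float(sp[2]), float(sp[1]), float(sp[0])), domain)
    raise ValueError(f"unsupported volume format: {path.name}")


def _read_dicom_series(directory: Path, domain: IntensityDomain) -> CTVolume:
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        files = sorted(p for p in directory.iterdir() if p.is_file())
    slices = [pydicom.dcmread(str(f)) for f in files]
    slices.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    arrays = []
    for d in slices:
        arr = d.pixel_array.astype(np.float64)
        slope = float(getattr(d, "RescaleSlope", 1.0))
        intercept = float(getattr(d, "RescaleIntercept", 0.0))
        arrays.append(arr * slope + intercept)
    data = np.stack(arrays)
    first = slices[0]
    dy, dx = (float(v) for v in first.PixelSpacing)
    if len(slices) > 1:
        dz = abs(
            float(slices[1].ImagePositionPatient[2])
            - float(first.ImagePositionPatient[2])
        )
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    return CTVolume(data, (dz, dy, dx), domain)


def write_nifti(path, volume: CTVolume) -> None:
    import nibabel as nib

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.transpose(volume.data, (2, 1, 0))  # back to (x, y, z)
    affine = np.diag([volume.spacing[2], volume.spacing[1], volume.spacing[0], 1.0])
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))


def write_patch_tiffs(directory, patches: list[ImagePatch], seed: int | None = None,
                      source: str = "") -> Path:
    """Write normalized patches as 16-bit TIFFs plus a CSV manifest.

    [−1, 1] maps linearly to [0, 65535].  Returns the manifest path.
    """
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, p in enumerate(patches):
        if not p.normalized:
            raise ValueError("patches must be normalized before TIFF export")
        u16 = np.round((p.data + 1.0) / 2.0 * 65535.0).astype(np.uint16)
        fname = f"patch_{i:06d}.tif"
        tifffile.imwrite(directory / fname, u16)
        rows.append(
            {
                "filename": fname,
                "source": source,
                "domain": p.domain.name.value,
                "z": p.meta.get("z", -1),
                "y": p.meta.get("y", -1),
                "x": p.meta.get("x", -1),
                "seed": seed if seed is not None else p.meta.get("seed", -1),
            }
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_patch_tiffs(directory) -> list[ImagePatch]:
    """Read a patch directory written by :func:`write_patch_tiffs`."""
    import tifffile

    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    patches = []
    for _, row in manifest.iterrows():
        u16 = tifffile.imread(directory / row["filename"]).astype(np.float64)
        data = u16 / 65535.0 * 2.0 - 1.0
        domain = CLINICAL if row["domain"] == "clinical" else MICRO
        patches.append(
            ImagePatch(data, domain=domain, normalized=True,
                       meta={"z": row["z"], "y": row["y"], "x": row["x"],
                             "seed": row["seed"]})
        )
    return patches
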