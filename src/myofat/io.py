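"""Volume, label-map and contour readers/writers.

NIfTI is the primary volume format (via nibabel); single axial slices may
also be supplied as PNG or TIFF.  Volumes are handled as (n_slices, H, W)
arrays ordered proximal → distal.  Contours serialize to CSV rows of
(slice_index, point_index, x, y).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .active_contour import Contour
from .errors import FormatError

DEFAULT_SPACING_MM = 2.5


@dataclass
class ImageVolume:
    """Stack of axial slices, proximal first, with in-plane pixel spacing."""

    data: np.ndarray          # (n_slices, H, W) float
    spacing_mm: float = DEFAULT_SPACING_MM

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    def slice(self, i: int) -> np.ndarray:
        return self.data[i]


def read_volume(path: str | Path) -> ImageVolume:
    """Read a NIfTI volume or a PNG/TIFF single slice.

    NIfTI data are stored (x, y, z); they are transposed to (slice, row,
    col).  Pixel spacing comes from the header zooms; when absent (or for
    PNG/TIFF) the default of 2.5 mm/px is assumed with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    suffixes = "".join(path.suffixes).lower()
    try:
        if suffixes.endswith((".nii", ".nii.gz")):
            img = nib.load(str(path))
            arr = np.asanyarray(img.dataobj, dtype=float)
            if arr.ndim == 2:
                arr = arr[:, :, None]
            if arr.ndim != 3:
                raise FormatError(
                    f"expected a 3-D volume, got shape {arr.shape}; "
                    f"header: {img.header}"
                )
            data = np.transpose(arr, (2, 1, 0))  # (z, y, x) -> (slice, row, col)
            zooms = img.header.get_zooms()
            spacing = float(zooms[0]) if len(zooms) >= 1 and zooms[0] > 0 else 0.0
            if spacing <= 0:
                warnings.warn(
                    f"no pixel spacing in header; assuming {DEFAULT_SPACING_MM} mm/px",
                    stacklevel=2,
                )
                spacing = DEFAULT_SPACING_MM
            return ImageVolume(data, spacing)
        if suffixes.endswith((".png", ".tif", ".tiff")):
            arr = np.asarray(iio.imread(path), dtype=float)
            if arr.ndim == 3:  # collapse RGB(A)
                arr = arr[..., :3].mean(axis=-1)
            warnings.warn(
                f"single-slice image without spacing; assuming "
                f"{DEFAULT_SPACING_MM} mm/px",
                stacklevel=2,
            )
            return ImageVolume(arr[None, :, :], DEFAULT_SPACING_MM)
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"could not read {path}: {exc}") from exc
    raise FormatError(f"unsupported volume format: {path.name}")


def write_volume(
    volume: np.ndarray, path: str | Path, spacing_mm: float = DEFAULT_SPACING_MM
) -> None:
    """Write a (n_slices, H, W) array as NIfTI with isotropic in-plane spacing."""
    arr = np.transpose(np.asarray(volume), (2, 1, 0))
    affine = np.diag([spacing_mm, spacing_mm, spacing_mm, 1.0])
    nib.save(nib.Nifti1Image(arr.astype(np.float32), affine), str(path))


def write_labels(
    labels: np.ndarray, path: str | Path, spacing_mm: float = DEFAULT_SPACING_MM
) -> None:
    arr = np.transpose(np.asarray(labels), (2, 1, 0))
    affine = np.diag([spacing_mm, spacing_mm, spacing_mm, 1.0])
    nib.save(nib.Nifti1Image(arr.astype(np.int16), affine), str(path))


def write_slice_png(image: np.ndarray, path: str | Path) -> None:
    """Export one slice as 16-bit PNG (intensities rescaled to the full range)."""
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    scaled = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    iio.imwrite(Path(path), (scaled * 65535).astype(np.uint16))


def contours_to_frame(contours: dict[int, dict[str, Contour]]) -> pd.DataFrame:
    """Flatten {slice_index: {name: Contour}} into long-format rows."""
    rows = []
    for s, named in sorted(contours.items()):
        for name, c in named.items():
            for j, (x, y) in enumerate(c.points):
                rows.append(
                    {"slice_index": s, "contour": name, "point_index": j,
                     "x": x, "y": y}
                )
    return pd.DataFrame(rows)


def read_contour_csv(path: str | Path, slice_index: int | None = None,
                     name: str | None = None) -> Contour:
    """Read one polygon from a contour CSV (columns x, y; optional
    slice_index / contour filters)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"could not parse contour file {path}: {exc}") from exc
    if not {"x", "y"}.issubset(df.columns):
        raise FormatError(f"contour file {path} lacks x/y columns")
    if slice_index is not None and "slice_index" in df:
        df = df[df["slice_index"] == slice_index]
    if name is not None and "contour" in df:
        df = df[df["contour"] == name]
    if "point_index" in df:
        df = df.sort_values("point_index")
    if len(df) < 3:
        raise FormatError(f"contour in {path} has fewer than 3 points")
    return Contour(df[["x", "y"]].to_numpy(dtype=float))
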