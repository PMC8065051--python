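"""Readers and writers for the formats the pipeline consumes and emits.

Acquisition tables use the FSL dialect (a ``.bval`` file with one row of
b-values and a ``.bvec`` file with three rows of direction components) or a
JSON list of (b, direction) pairs.  Volumes are NIfTI via nibabel (affine
carried through unchanged); histology images are TIFF/PNG with an optional
JSON sidecar holding the pixel size and ROI labels.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .dki import GradientScheme, SchemeError
from .hog import HistologyImage

__all__ = [
    "read_scheme",
    "write_scheme",
    "scheme_from_json",
    "scheme_to_json",
    "load_nifti",
    "save_nifti",
    "read_histology_image",
    "write_histology_image",
]


def _read_rows(path: Path) -> np.ndarray:
    try:
        return np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise SchemeError(f"cannot parse {path}: {exc}") from exc


def read_scheme(bval_path: str | Path, bvec_path: str | Path) -> GradientScheme:
    """Read an FSL-style b-value/b-vector pair into a validated scheme.

    Validation failures name the offending measurement column.
    """
    bvals = _read_rows(Path(bval_path)).ravel()
    bvecs = _read_rows(Path(bvec_path))
    if bvecs.shape[0] != 3:
        raise SchemeError(f"{bvec_path}: expected 3 rows of direction components, "
                          f"got {bvecs.shape[0]}")
    if bvecs.shape[1] != bvals.size:
        raise SchemeError(
            f"{bvec_path}: {bvecs.shape[1]} directions but {bvals.size} b-values"
        )
    return GradientScheme(bvals, bvecs.T)


def write_scheme(scheme: GradientScheme, bval_path: str | Path, bvec_path: str | Path) -> None:
    """Write the FSL-style b-value / b-vector text pair."""
    np.savetxt(bval_path, scheme.bvalues[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.directions.T, fmt="%.10g")


def scheme_to_json(scheme: GradientScheme, path: str | Path) -> None:
    """JSON alternative: a list of {"b": ..., "direction": [...]} entries."""
    payload = {
        "measurements": [
            {"b": float(b), "direction": [float(c) for c in d]}
            for b, d in zip(scheme.bvalues, scheme.directions)
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def scheme_from_json(path: str | Path) -> GradientScheme:
    try:
        payload = json.loads(Path(path).read_text())
        meas = payload["measurements"]
        bvals = np.array([m["b"] for m in meas], dtype=float)
        dirs = np.array([m["direction"] for m in meas], dtype=float)
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise SchemeError(f"malformed scheme JSON {path}: {exc}") from exc
    return GradientScheme(bvals, dirs)


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray, tuple[float, ...]]:
    """Return (data, affine, voxel_size_mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, img.affine, voxel_size


def save_nifti(
    data: np.ndarray,
    path: str | Path,
    affine: np.ndarray | None = None,
    voxel_size: tuple[float, float, float] | None = None,
) -> None:
    """Write a NIfTI volume; the affine (or a diagonal one from the voxel
    size) is carried through unchanged."""
    if affine is None:
        vz = voxel_size or (1.0, 1.0, 1.0)
        affine = np.diag([vz[0], vz[1], vz[2], 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def read_histology_image(
    path: str | Path,
    pixel_size_um: float | None = None,
    sidecar: str | Path | None = None,
) -> HistologyImage:
    """Read a TIFF/PNG histology ROI as a [0, 1] grayscale image.

    The pixel size comes from the JSON sidecar (``<image>.json`` by
    default) when present, else from the argument; one of the two is
    required since slide scans rarely embed a trustworthy resolution.
    """
    path = Path(path)
    meta: dict = {}
    sidecar = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    px = meta.get("pixel_size_um", pixel_size_um)
    if px is None:
        raise ValueError(f"{path}: pixel size not in sidecar and not provided")

    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        arr = iio.imread(str(path))
    arr = np.asarray(arr, dtype=float)
    if np.issubdtype(np.asarray(arr).dtype, np.floating) and arr.max(initial=0.0) > 1.5:
        arr = arr / 255.0
    arr = np.clip(arr, 0.0, 1.0)
    return HistologyImage(
        pixels=arr,
        pixel_size_um=float(px),
        roi_label=meta.get("roi_label", path.stem),
        tissue_class=meta.get("tissue_class", "WM"),
    )


def write_histology_image(
    img: HistologyImage, path: str | Path, sidecar: bool = True
) -> None:
    """Write a grayscale image as 8-bit TIFF/PNG plus a JSON sidecar with
    pixel size and labels."""
    path = Path(path)
    arr = np.clip(np.round(img.pixels * 255.0), 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(str(path), arr)
    if sidecar:
        meta = {
            "pixel_size_um": img.pixel_size_um,
            "roi_label": img.roi_label,
            "tissue_class": img.tissue_class,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
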