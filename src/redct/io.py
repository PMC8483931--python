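"""Readers and writers for CT slices.

Three interchange formats are supported:

* DICOM (single-frame CT): rescale slope/intercept are applied on read and
  written back so stored pixel data round-trips through Hounsfield units.
* 16-bit PNG/TIFF: HU are mapped through an explicit window into the
  16-bit range; the window and pixel spacing go to a ``<name>.json``
  sidecar so the mapping is invertible.
* Raw ``.npy`` arrays: numpy's own container already records shape and
  dtype; HU are stored verbatim with an optional sidecar for spacing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .red_model import HU_WINDOW
from .synthetic_ct import CTImage

__all__ = ["read_image", "write_image"]

_UINT16_MAX = 65535


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(image: CTImage, path, window=HU_WINDOW) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npy":
        np.save(path, image.values)
        _sidecar(path).write_text(json.dumps(
            {"pixel_spacing_mm": image.pixel_spacing, "units": "HU"}))
    elif suffix in (".png", ".tif", ".tiff"):
        lo, hi = window
        scaled = np.clip((image.values - lo) / (hi - lo), 0, 1)
        data = np.round(scaled * _UINT16_MAX).astype(np.uint16)
        if suffix == ".png":
            from PIL import Image
            Image.fromarray(data).save(path)
        else:
            import tifffile
            tifffile.imwrite(path, data)
        _sidecar(path).write_text(json.dumps(
            {"hu_window": [lo, hi], "pixel_spacing_mm": image.pixel_spacing,
             "units": "HU"}))
    elif suffix == ".dcm":
        _write_dicom(image, path)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")


def read_image(path) -> CTImage:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npy":
        values = np.load(path)
        spacing = 1.0
        side = _sidecar(path)
        if side.exists():
            spacing = json.loads(side.read_text()).get("pixel_spacing_mm", 1.0)
        return CTImage(values, pixel_spacing=spacing)
    if suffix in (".png", ".tif", ".tiff"):
        side = _sidecar(path)
        if not side.exists():
            raise FileNotFoundError(
                f"sidecar {side} with the HU window is required to read {path}")
        meta = json.loads(side.read_text())
        lo, hi = meta["hu_window"]
        if suffix == ".png":
            from PIL import Image
            data = np.asarray(Image.open(path), dtype=np.float64)
        else:
            import tifffile
            data = tifffile.imread(path).astype(np.float64)
        values = data / _UINT16_MAX * (hi - lo) + lo
        return CTImage(values, pixel_spacing=meta.get("pixel_spacing_mm", 1.0))
    if suffix == ".dcm":
        return _read_dicom(path)
    raise ValueError(f"unsupported image format: {path.suffix}")


def _write_dicom(image: CTImage, path: Path) -> None:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.Rows, ds.Columns = image.shape
    ds.PixelSpacing = [image.pixel_spacing, image.pixel_spacing]
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    # stored = (HU - intercept) / slope with the CT convention slope=1,
    # intercept=-1024 so air stays non-negative in uint16
    ds.RescaleSlope = 1.0
    ds.RescaleIntercept = -1024.0
    stored = np.round(image.values - ds.RescaleIntercept)
    stored = np.clip(stored, 0, _UINT16_MAX).astype(np.uint16)
    ds.PixelData = stored.tobytes()
    ds.save_as(path, enforce_file_format=True)


def _read_dicom(path: Path) -> CTImage:
    import pydicom

    ds = pydicom.dcmread(path)
    values = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    spacing = 1.0
    if getattr(ds, "PixelSpacing", None):
        spacing = float(ds.PixelSpacing[0])
    return CTImage(values * slope + intercept, pixel_spacing=spacing)
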