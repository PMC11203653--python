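"""Reading and writing the pipeline's on-disk formats.

Inversion-recovery series travel as 4-D NIfTI volumes (x, y, 1, TI) with a
JSON sidecar holding the inversion times, magnitude flag and pixel spacing,
or as directories of single-frame DICOM files carrying the InversionTime
tag.  Region masks are NIfTI label volumes with a JSON label dictionary.
T1 maps are float32 NIfTI in ms.  All tabular outputs are CSV with frozen
headers so reruns are byte-comparable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

import nibabel as nib

from .roi import RegionSet
from .t1fit import InversionSeries, T1Map

__all__ = [
    "write_series", "read_series", "write_regions", "read_regions",
    "write_t1_map", "read_t1_map", "write_dicom_series",
    "METRICS_COLUMNS", "ECV_COLUMNS",
]

METRICS_COLUMNS = [
    "subject", "group", "compartment", "side",
    "peak_t1_pre_ms", "mean_t1_pre_ms", "min_t1_pre_ms",
    "peak_t1_post_ms", "mean_t1_post_ms", "min_t1_post_ms",
    "csa_mm2", "n_voxels",
]
ECV_COLUMNS = ["subject", "group", "compartment", "ecv_percent", "plausible"]


class FormatError(ValueError):
    pass


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def write_series(path, series: InversionSeries) -> Path:
    """Write a series as 4-D NIfTI plus a JSON sidecar; returns the NIfTI path."""
    path = Path(path)
    data = np.transpose(series.frames, (2, 1, 0))[:, :, None, :]  # x, y, z=1, t
    affine = np.diag([series.pixel_spacing_mm[1], series.pixel_spacing_mm[0], 1.0, 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    img.header.set_xyzt_units("mm", "msec")
    nib.save(img, path)
    sidecar = {
        "ti_ms": [float(t) for t in series.ti_ms],
        "magnitude": bool(series.magnitude),
        "pixel_spacing_mm": [float(s) for s in series.pixel_spacing_mm],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def _read_nifti_series(path: Path) -> InversionSeries:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing TI sidecar {sidecar} for {path}")
    meta = json.loads(sidecar.read_text())
    data = np.asarray(nib.load(path).dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"{path}: expected a 4-D volume, got shape {data.shape}")
    frames = np.transpose(data[:, :, 0, :], (2, 1, 0))
    ti = np.asarray(meta["ti_ms"], dtype=float)
    order = np.argsort(ti)
    return InversionSeries(
        frames=frames[order],
        ti_ms=ti[order],
        magnitude=bool(meta.get("magnitude", True)),
        pixel_spacing_mm=tuple(meta.get("pixel_spacing_mm", (1.48, 1.48))),
    )


def _read_dicom_series(path: Path) -> InversionSeries:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".dcm", ".ima", ""})
    if not files:
        raise FormatError(f"no DICOM files in {path}")
    frames, tis, spacing = [], [], (1.48, 1.48)
    for f in files:
        ds = pydicom.dcmread(f)
        if "InversionTime" not in ds:
            raise FormatError(f"{f}: missing InversionTime tag")
        tis.append(float(ds.InversionTime))
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        inter = float(getattr(ds, "RescaleIntercept", 0.0))
        frames.append(arr * slope + inter)
        if "PixelSpacing" in ds:
            spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    tis = np.asarray(tis)
    uniq, counts = np.unique(tis, return_counts=True)
    if (counts > 1).any():
        dups = ", ".join(f"{t:g} ms" for t in uniq[counts > 1])
        raise FormatError(f"duplicate inversion times in {path}: {dups}")
    order = np.argsort(tis)
    return InversionSeries(
        frames=np.asarray(frames)[order], ti_ms=tis[order],
        magnitude=True, pixel_spacing_mm=spacing,
    )


def read_series(path) -> InversionSeries:
    """Read a series from a DICOM directory or a NIfTI file with TI sidecar.

    Frames are returned sorted by ascending inversion time regardless of
    file order; magnitude is assumed unless the sidecar says otherwise.
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    return _read_nifti_series(path)


def write_dicom_series(directory, series: InversionSeries, scale: float = 1.0) -> list[Path]:
    """Export a series as one uint16 DICOM per inversion time.

    Pixel values are rounded to integers (after ``scale``); the
    InversionTime and PixelSpacing tags are populated.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    series_uid = generate_uid(entropy_srcs=["calfmolli-series"])
    for i, (frame, ti) in enumerate(zip(series.frames, series.ti_ms)):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=[f"calfmolli-{i}"])
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "MR"
        ds.InversionTime = float(ti)
        ds.PixelSpacing = [series.pixel_spacing_mm[0], series.pixel_spacing_mm[1]]
        ds.Rows, ds.Columns = frame.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = 1.0 / scale
        ds.RescaleIntercept = 0.0
        pix = np.clip(np.round(frame * scale), 0, 65535).astype(np.uint16)
        ds.PixelData = pix.tobytes()
        out = directory / f"ti_{int(round(ti)):05d}.dcm"
        ds.save_as(out, enforce_file_format=True)
        paths.append(out)
    return paths


def write_regions(path, regions: RegionSet) -> Path:
    """Write masks as one NIfTI label volume plus a JSON label dictionary."""
    path = Path(path)
    names = sorted(regions.labels)
    shape = next(iter(regions.labels.values())).shape
    lab = np.zeros(shape, dtype=np.int16)
    mapping = {}
    for i, name in enumerate(names, start=1):
        lab[regions.labels[name]] = i
        mapping[str(i)] = name
    data = np.transpose(lab, (1, 0))[:, :, None]
    affine = np.diag([regions.pixel_spacing_mm[1], regions.pixel_spacing_mm[0], 1.0, 1.0])
    nib.save(nib.Nifti1Image(data, affine), path)
    meta = {"labels": mapping,
            "pixel_spacing_mm": list(regions.pixel_spacing_mm),
            "side": regions.side}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_regions(path) -> RegionSet:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    data = np.asarray(nib.load(path).dataobj)
    lab = np.transpose(data[:, :, 0], (1, 0))
    labels = {name: lab == int(i) for i, name in meta["labels"].items()}
    return RegionSet(labels=labels,
                     pixel_spacing_mm=tuple(meta["pixel_spacing_mm"]),
                     side=meta.get("side", "bilateral"))


def write_t1_map(path, t1map: T1Map) -> Path:
    """T1 map as float32 NIfTI (ms; NaN marks invalid voxels) + sidecar."""
    path = Path(path)
    sp = t1map.provenance.get("pixel_spacing_mm", [1.48, 1.48])
    data = np.transpose(t1map.t1_ms, (1, 0))[:, :, None].astype(np.float32)
    affine = np.diag([sp[1], sp[0], 1.0, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header["descrip"] = b"T1 map [ms]"
    nib.save(img, path)
    _sidecar_path(path).write_text(
        json.dumps(t1map.provenance, indent=1, sort_keys=True))
    return path


def read_t1_map(path) -> np.ndarray:
    """Read a T1 map written by :func:`write_t1_map` (values only, ms)."""
    data = np.asarray(nib.load(Path(path)).dataobj, dtype=float)
    return np.transpose(data[:, :, 0], (1, 0))


def write_table(path, df: pd.DataFrame, columns: list[str] | None = None) -> Path:
    """CSV with frozen header and stable float formatting."""
    path = Path(path)
    if columns is not None:
        df = df[columns]
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
    return path
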