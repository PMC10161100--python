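"""Readers and writers for the standard interchange formats.

3D grids travel as MetaImage (single ``.mha`` file, via SimpleITK) or as a
DICOM CT series (one file per slice); films as 16-bit TIFF with a JSON
sidecar carrying pitch, origin and the reporting-medium flag; phantom and
material specifications as YAML; calibration curves as CSV (handled on
:class:`~gkdosim.ct_density.CalibrationCurve` itself).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pydicom
import SimpleITK as sitk
import tifffile
import yaml
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .grids import VoxelGrid
from .phantom import Box, FilmImage, FilmPlane, MaterialTable, Material, PhantomSpec

# ---------------------------------------------------------------------------
# MetaImage (x-fastest on disk; SimpleITK arrays are indexed [z, y, x])
# ---------------------------------------------------------------------------

def write_metaimage(grid: VoxelGrid, path: str | Path) -> None:
    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.data.T))
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    sitk.WriteImage(img, str(path))


def read_metaimage(path: str | Path) -> VoxelGrid:
    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img).T
    return VoxelGrid(data, tuple(img.GetOrigin()), tuple(img.GetSpacing()))


# ---------------------------------------------------------------------------
# DICOM CT series
# ---------------------------------------------------------------------------

def write_ct_series(grid: VoxelGrid, out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Write a HU grid as one CT DICOM file per axial slice.

    UIDs are generated deterministically from ``seed`` so repeated exports
    of the same grid are stable.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    entropy = "".join(str(d) for d in rng.integers(0, 10, 8))
    series_uid = generate_uid(entropy_srcs=[f"series{entropy}"])
    study_uid = generate_uid(entropy_srcs=[f"study{entropy}"])
    paths = []
    data = np.round(grid.data).astype(np.int16)
    for k in range(grid.shape[2]):
        ds = Dataset()
        ds.SOPClassUID = pydicom.uid.CTImageStorage
        ds.SOPInstanceUID = generate_uid(entropy_srcs=[f"slice{entropy}{k}"])
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.PatientName = "PHANTOM^SYNTHETIC"
        ds.PatientID = "GKDOSIM"
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [
            grid.origin[0],
            grid.origin[1],
            grid.origin[2] + k * grid.spacing[2],
        ]
        ds.PixelSpacing = [grid.spacing[1], grid.spacing[0]]
        ds.SliceThickness = grid.spacing[2]
        ds.InstanceNumber = k + 1
        ds.Rows, ds.Columns = data.shape[1], data.shape[0]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleIntercept = 0.0
        ds.RescaleSlope = 1.0
        # rows ↔ y, columns ↔ x
        ds.PixelData = np.ascontiguousarray(data[:, :, k].T).tobytes()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        p = out / f"ct_{k:04d}.dcm"
        ds.save_as(p, enforce_file_format=True)
        paths.append(p)
    return paths


def read_ct_series(in_dir: str | Path) -> VoxelGrid:
    files = sorted(Path(in_dir).glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no DICOM files in {in_dir}")
    slices = [pydicom.dcmread(f) for f in files]
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    first = slices[0]
    data = np.stack(
        [
            s.pixel_array.T * float(s.RescaleSlope) + float(s.RescaleIntercept)
            for s in slices
        ],
        axis=2,
    )
    dz = (
        float(slices[1].ImagePositionPatient[2]) - float(first.ImagePositionPatient[2])
        if len(slices) > 1
        else float(first.SliceThickness)
    )
    spacing = (float(first.PixelSpacing[1]), float(first.PixelSpacing[0]), dz)
    origin = tuple(float(v) for v in first.ImagePositionPatient)
    return VoxelGrid(data, origin, spacing)


# ---------------------------------------------------------------------------
# DICOM RT-Dose-like grid
# ---------------------------------------------------------------------------

def write_rt_dose(dose, path: str | Path, seed: int = 0) -> None:
    """Write an absolute dose grid as a single multi-frame RT-Dose file.

    Dose values are stored as 32-bit integers with the DoseGridScaling
    attribute chosen so the full dynamic range is used; frames run along z
    with the per-frame offsets in GridFrameOffsetVector.  A JSON sidecar
    records the reporting medium, beam-on time and seed.
    """
    grid = dose.grid if hasattr(dose, "grid") else dose
    path = Path(path)
    rng = np.random.default_rng(seed)
    entropy = "".join(str(d) for d in rng.integers(0, 10, 8))
    scaling = max(float(grid.data.max()), 1e-12) / (2**31 - 1)
    ds = Dataset()
    ds.SOPClassUID = pydicom.uid.RTDoseStorage
    ds.SOPInstanceUID = generate_uid(entropy_srcs=[f"rtdose{entropy}"])
    ds.SeriesInstanceUID = generate_uid(entropy_srcs=[f"rtdoseseries{entropy}"])
    ds.StudyInstanceUID = generate_uid(entropy_srcs=[f"rtdosestudy{entropy}"])
    ds.Modality = "RTDOSE"
    ds.PatientName = "PHANTOM^SYNTHETIC"
    ds.PatientID = "GKDOSIM"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.ImagePositionPatient = list(grid.origin)
    ds.PixelSpacing = [grid.spacing[1], grid.spacing[0]]
    ds.GridFrameOffsetVector = [
        float(k * grid.spacing[2]) for k in range(grid.shape[2])
    ]
    ds.NumberOfFrames = grid.shape[2]
    ds.Rows, ds.Columns = grid.shape[1], grid.shape[0]
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    counts = np.round(grid.data / scaling).astype(np.uint32)
    # frame-major: (z, rows=y, cols=x)
    ds.PixelData = np.ascontiguousarray(counts.transpose(2, 1, 0)).tobytes()
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = ds.SOPClassUID
    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta = meta
    ds.save_as(path, enforce_file_format=True)
    sidecar = {
        "medium": getattr(dose, "medium", None),
        "bot_min": getattr(dose, "bot", None),
        "seed": seed,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_rt_dose(path: str | Path) -> VoxelGrid:
    ds = pydicom.dcmread(path)
    counts = ds.pixel_array  # (frames, rows, cols)
    data = counts.transpose(2, 1, 0).astype(float) * float(ds.DoseGridScaling)
    offsets = [float(v) for v in ds.GridFrameOffsetVector]
    dz = offsets[1] - offsets[0] if len(offsets) > 1 else 1.0
    spacing = (float(ds.PixelSpacing[1]), float(ds.PixelSpacing[0]), dz)
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    return VoxelGrid(data, origin, spacing)


# ---------------------------------------------------------------------------
# Film TIFF + JSON sidecar
# ---------------------------------------------------------------------------

def write_film(film: FilmImage, path: str | Path, max_gy: float | None = None) -> None:
    path = Path(path)
    max_gy = max_gy or max(float(film.data.max()), 1e-12)
    scale = 65535.0 / max_gy
    tifffile.imwrite(path, np.round(film.data * scale).astype(np.uint16))
    sidecar = {
        "pitch_mm": film.pitch,
        "medium": film.medium,
        "max_gy": max_gy,
        "plane": {
            "origin": list(film.plane.origin),
            "axis_u": list(film.plane.axis_u),
            "axis_v": list(film.plane.axis_v),
        },
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_film(path: str | Path) -> FilmImage:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    raw = tifffile.imread(path).astype(float)
    data = raw * sidecar["max_gy"] / 65535.0
    plane = FilmPlane(
        origin=tuple(sidecar["plane"]["origin"]),
        axis_u=tuple(sidecar["plane"]["axis_u"]),
        axis_v=tuple(sidecar["plane"]["axis_v"]),
        pitch=sidecar["pitch_mm"],
        shape=data.shape,
    )
    return FilmImage(
        data=data, pitch=sidecar["pitch_mm"], plane=plane, medium=sidecar["medium"]
    )


# ---------------------------------------------------------------------------
# YAML specs
# ---------------------------------------------------------------------------

def _plain(obj):
    """Recursively convert numpy scalars/arrays to plain Python types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_phantom_spec(spec: PhantomSpec, path: str | Path) -> None:
    payload = _plain(dataclasses.asdict(spec))
    Path(path).write_text(yaml.safe_dump(payload))


def read_phantom_spec(path: str | Path) -> PhantomSpec:
    raw = yaml.safe_load(Path(path).read_text())
    for key in ("bone_boxes",):
        if key in raw:
            raw[key] = tuple(Box(tuple(b["low"]), tuple(b["high"])) for b in raw[key])
    for key in ("core_box", "air_box"):
        if key in raw:
            raw[key] = Box(tuple(raw[key]["low"]), tuple(raw[key]["high"]))
    for key in ("sphere_center", "voxel_spacing"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if "pin_positions" in raw:
        raw["pin_positions"] = tuple(tuple(p) for p in raw["pin_positions"])
    return PhantomSpec(**raw)


def write_material_table(table: MaterialTable, path: str | Path) -> None:
    payload = {
        name: dataclasses.asdict(m) for name, m in table.materials.items()
    }
    Path(path).write_text(yaml.safe_dump(payload))


def read_material_table(path: str | Path) -> MaterialTable:
    raw = yaml.safe_load(Path(path).read_text())
    mats = {}
    for name, m in raw.items():
        m.pop("name", None)
        mats[name] = Material(name=name, **m)
    return MaterialTable(mats)
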