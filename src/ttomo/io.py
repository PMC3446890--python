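"""Readers and writers for volumes, tables and design descriptors.

Internally everything is micrometres; NIfTI and NRRD use millimetres at
the file boundary.  NIfTI goes through nibabel.  NRRD support is a
minimal self-contained NRRD0004 implementation (raw little-endian
encoding, 3D, isotropic spacing) — enough to round-trip masks, label
volumes and maps.

The grid contract is isotropic: anisotropic or sheared voxel spacings are
rejected on read.  Grid origin is the *corner* of voxel (0,0,0); both
formats store the center of the first voxel, and the half-voxel shift is
applied on both paths so volumes round-trip exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fraction_stats import FractionDataMatrix
from .geometry import SectioningSeries, VoxelGrid

logger = logging.getLogger("ttomo")

_SPACING_TOL_MM = 1e-6

_NRRD_TYPES = {
    "float": np.float32, "float32": np.float32,
    "double": np.float64, "float64": np.float64,
    "int": np.int32, "int32": np.int32,
    "short": np.int16, "int16": np.int16,
    "uchar": np.uint8, "uint8": np.uint8,
    "uint16": np.uint16, "int64": np.int64,
}
_NRRD_NAMES = {
    np.dtype(np.float32): "float", np.dtype(np.float64): "double",
    np.dtype(np.int32): "int", np.dtype(np.int16): "short",
    np.dtype(np.uint8): "uchar", np.dtype(np.uint16): "uint16",
    np.dtype(np.int64): "int64",
}


def _check_isotropic(spacings_mm) -> float:
    s = np.asarray(spacings_mm, dtype=float)
    if np.ptp(s) > _SPACING_TOL_MM:
        raise ValueError(f"anisotropic voxel spacing {s.tolist()} mm; the grid contract is isotropic")
    return float(s.mean())


def write_volume(path, array: np.ndarray, grid: VoxelGrid) -> None:
    """Write a 3D volume as NIfTI-1 (.nii/.nii.gz) or NRRD (.nrrd)."""
    path = Path(path)
    array = np.asarray(array)
    if array.shape != grid.shape:
        raise ValueError("array shape does not match grid")
    vox_mm = grid.voxel_size / 1000.0
    first_center_mm = (np.asarray(grid.origin) + 0.5 * grid.voxel_size) / 1000.0
    if path.suffix == ".nrrd":
        _write_nrrd(path, array, vox_mm, first_center_mm)
        return
    if array.dtype == np.bool_:
        array = array.astype(np.uint8)
    affine = np.diag([vox_mm, vox_mm, vox_mm, 1.0])
    affine[:3, 3] = first_center_mm
    img = nib.Nifti1Image(array, affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_volume(path) -> tuple[np.ndarray, VoxelGrid]:
    """Read a NIfTI or NRRD volume; returns the array and its grid (µm)."""
    path = Path(path)
    if path.suffix == ".nrrd":
        return _read_nrrd(path)
    img = nib.load(str(path))
    affine = img.affine
    lin = affine[:3, :3]
    if np.abs(lin - np.diag(np.diag(lin))).max() > _SPACING_TOL_MM:
        raise ValueError("volume has a sheared/rotated affine; expected axis-aligned")
    vox_mm = _check_isotropic(np.diag(lin))
    first_center_mm = affine[:3, 3]
    origin_um = first_center_mm * 1000.0 - 0.5 * vox_mm * 1000.0
    array = np.asarray(img.dataobj)
    grid = VoxelGrid(
        shape=array.shape, voxel_size=vox_mm * 1000.0, origin=tuple(origin_um)
    )
    return array, grid


def _write_nrrd(path: Path, array: np.ndarray, vox_mm: float, first_center_mm) -> None:
    if array.dtype == np.bool_:
        array = array.astype(np.uint8)
    dtype = np.dtype(array.dtype)
    if dtype not in _NRRD_NAMES:
        raise ValueError(f"unsupported NRRD dtype {dtype}")
    header = [
        "NRRD0004",
        f"type: {_NRRD_NAMES[dtype]}",
        "dimension: 3",
        "space: right-anterior-superior",
        f"sizes: {array.shape[0]} {array.shape[1]} {array.shape[2]}",
        f"space directions: ({vox_mm},0,0) (0,{vox_mm},0) (0,0,{vox_mm})",
        "kinds: domain domain domain",
        "endian: little",
        "encoding: raw",
        f"space origin: ({first_center_mm[0]},{first_center_mm[1]},{first_center_mm[2]})",
    ]
    data = np.asfortranarray(array)
    if dtype.itemsize > 1 and dtype.byteorder == ">":
        data = data.astype(dtype.newbyteorder("<"))
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n\n").encode())
        fh.write(data.tobytes(order="F"))


def _read_nrrd(path: Path) -> tuple[np.ndarray, VoxelGrid]:
    with open(path, "rb") as fh:
        magic = fh.readline().decode().strip()
        if not magic.startswith("NRRD"):
            raise ValueError(f"{path} is not an NRRD file")
        fields = {}
        while True:
            line = fh.readline().decode()
            if line in ("\n", "\r\n", ""):
                break
            if line.startswith("#") or ":" not in line:
                continue
            key, val = line.split(":", 1)
            fields[key.strip()] = val.strip()
        data = fh.read()
    if fields.get("encoding") != "raw":
        raise ValueError("only raw NRRD encoding is supported")
    if int(fields["dimension"]) != 3:
        raise ValueError("only 3D NRRD volumes are supported")
    dtype = np.dtype(_NRRD_TYPES[fields["type"]])
    if fields.get("endian", "little") == "big" and dtype.itemsize > 1:
        dtype = dtype.newbyteorder(">")
    sizes = tuple(int(s) for s in fields["sizes"].split())
    if "space directions" in fields:
        vecs = [
            [float(x) for x in v.strip("()").split(",")]
            for v in fields["space directions"].split()
        ]
        vecs = np.asarray(vecs)
        if np.abs(vecs - np.diag(np.diag(vecs))).max() > _SPACING_TOL_MM:
            raise ValueError("NRRD space directions are not axis-aligned")
        vox_mm = _check_isotropic(np.diag(vecs))
    elif "spacings" in fields:
        vox_mm = _check_isotropic([float(x) for x in fields["spacings"].split()])
    else:
        raise ValueError("NRRD header lacks spacing information")
    if "space origin" in fields:
        first_center_mm = np.asarray(
            [float(x) for x in fields["space origin"].strip("()").split(",")]
        )
    else:
        first_center_mm = np.full(3, 0.5 * vox_mm)
    array = np.frombuffer(data, dtype=dtype, count=int(np.prod(sizes)))
    array = array.reshape(sizes, order="F").astype(dtype.newbyteorder("="), copy=False)
    origin_um = first_center_mm * 1000.0 - 0.5 * vox_mm * 1000.0
    grid = VoxelGrid(shape=sizes, voxel_size=vox_mm * 1000.0, origin=tuple(origin_um))
    return array, grid


def write_design(path, design: list[SectioningSeries]) -> None:
    with open(path, "w") as fh:
        json.dump([s.to_dict() for s in design], fh, indent=2)


def read_design(path) -> list[SectioningSeries]:
    with open(path) as fh:
        return [SectioningSeries.from_dict(d) for d in json.load(fh)]


def read_fraction_matrix(path, flags_path=None) -> FractionDataMatrix:
    """Read a probe x fraction CSV/TSV (first column = probe id).

    ``flags_path`` is an aligned boolean/0-1 companion table of present
    flags; when absent every measurement is treated as present and a
    warning is logged.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    intensity = pd.read_csv(path, sep=sep, index_col=0)
    if intensity.index.duplicated().any():
        dup = intensity.index[intensity.index.duplicated()].tolist()
        raise ValueError(f"duplicate probe ids in {path}: {dup[:5]}")
    if (intensity.to_numpy() < 0).any():
        raise ValueError(f"negative intensities in {path}")
    present = None
    if flags_path is not None:
        flags = pd.read_csv(flags_path, sep=sep, index_col=0)
        if flags.shape != intensity.shape or not (
            flags.index.equals(intensity.index) and flags.columns.equals(intensity.columns)
        ):
            raise ValueError("flags file does not align with the intensity matrix")
        present = flags.astype(bool)
    else:
        logger.warning("no flags file given; treating every measurement as present")
    return FractionDataMatrix.from_intensity(intensity, present)


def write_fraction_matrix(matrix: FractionDataMatrix, path, flags_path=None) -> None:
    matrix.intensity.to_csv(path)
    if flags_path is not None:
        matrix.present.astype(int).to_csv(flags_path)


def read_centroids(path) -> list[dict]:
    """Area definitions: [{area_id, x_um, y_um, z_um, diameter_um}, ...]."""
    with open(path) as fh:
        entries = json.load(fh)
    for e in entries:
        for key in ("area_id", "x_um", "y_um", "z_um", "diameter_um"):
            if key not in e:
                raise ValueError(f"centroid entry missing {key!r}: {e}")
    return entries


def write_map_sidecar(path, emap, series_ids: list[str]) -> None:
    """JSON sidecar carrying the map's provenance-critical scalars."""
    with open(path, "w") as fh:
        json.dump(
            {
                "probe_id": emap.probe_id,
                "threshold": emap.cutoff_threshold,
                "keep_fraction": emap.keep_fraction,
                "series_ids": series_ids,
            },
            fh,
            indent=2,
        )
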