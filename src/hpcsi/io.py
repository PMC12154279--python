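"""File formats: HDF5 for raw/spectral data, NIfTI for maps, CSV/JSON tables.

Complex arrays are stored as paired real/imaginary datasets.  Every HDF5
file carries a ``schema_version`` attribute that is checked on read.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .acquisition import AcquisitionParams
from .recon import SpectralImage
from .simulate import KSpaceData

__all__ = [
    "SCHEMA_VERSION",
    "HpcsiIOError",
    "save_kspace",
    "load_kspace",
    "save_spectral_image",
    "load_spectral_image",
    "save_maps_nifti",
    "save_json",
]

SCHEMA_VERSION = 1


class HpcsiIOError(RuntimeError):
    """Raised for unreadable or schema-incompatible files."""


def _check_schema(handle: h5py.File, kind: str) -> None:
    version = handle.attrs.get("schema_version")
    if version != SCHEMA_VERSION:
        raise HpcsiIOError(
            f"{kind} schema version mismatch: file has {version!r}, "
            f"expected {SCHEMA_VERSION}"
        )


def _acq_to_attrs(acq: AcquisitionParams, grp: h5py.Group) -> None:
    for f in dataclasses.fields(acq):
        value = getattr(acq, f.name)
        if value is None:
            continue
        if f.name == "flip_schedule":
            grp.attrs[f.name] = np.asarray(value, dtype=float)
        else:
            grp.attrs[f.name] = value


def _acq_from_attrs(grp: h5py.Group) -> AcquisitionParams:
    kwargs = {}
    for f in dataclasses.fields(AcquisitionParams):
        if f.name in grp.attrs:
            value = grp.attrs[f.name]
            if f.name == "flip_schedule":
                value = tuple(float(v) for v in np.asarray(value))
            elif isinstance(value, np.generic):
                value = value.item()
            kwargs[f.name] = value
    return AcquisitionParams(**kwargs)


def save_kspace(k: KSpaceData, path: str | Path) -> None:
    with h5py.File(path, "w") as h:
        h.attrs["schema_version"] = SCHEMA_VERSION
        h.attrs["kind"] = "kspace"
        h.create_dataset("data_re", data=k.data.real, compression=None)
        h.create_dataset("data_im", data=k.data.imag, compression=None)
        h.create_dataset("mask", data=k.mask.astype(np.uint8))
        h.create_dataset("encode_order", data=np.asarray(k.encode_order, dtype=np.int64))
        _acq_to_attrs(k.acq, h.create_group("acq"))


def load_kspace(path: str | Path) -> KSpaceData:
    try:
        with h5py.File(path, "r") as h:
            _check_schema(h, "kspace")
            data = h["data_re"][()] + 1j * h["data_im"][()]
            mask = h["mask"][()].astype(bool)
            order = h["encode_order"][()]
            acq = _acq_from_attrs(h["acq"])
    except (OSError, KeyError) as err:
        raise HpcsiIOError(f"cannot read k-space file {path}: {err}") from err
    return KSpaceData(data, mask, order, acq)


def save_spectral_image(img: SpectralImage, path: str | Path) -> None:
    with h5py.File(path, "w") as h:
        h.attrs["schema_version"] = SCHEMA_VERSION
        h.attrs["kind"] = "spectral_image"
        h.attrs["phased"] = img.phased
        h.create_dataset("spectra_re", data=img.spectra.real)
        h.create_dataset("spectra_im", data=img.spectra.imag)
        h.create_dataset("freq_hz", data=img.freq_hz)
        h.create_dataset("ppm", data=img.ppm)
        if "acq" in img.provenance:
            _acq_to_attrs(img.provenance["acq"], h.create_group("acq"))


def load_spectral_image(path: str | Path) -> SpectralImage:
    try:
        with h5py.File(path, "r") as h:
            _check_schema(h, "spectral image")
            spectra = h["spectra_re"][()] + 1j * h["spectra_im"][()]
            freq = h["freq_hz"][()]
            ppm = h["ppm"][()]
            phased = bool(h.attrs.get("phased", False))
            provenance = {}
            if "acq" in h:
                provenance["acq"] = _acq_from_attrs(h["acq"])
    except (OSError, KeyError) as err:
        raise HpcsiIOError(f"cannot read spectral image {path}: {err}") from err
    return SpectralImage(spectra, freq, ppm, phased=phased, provenance=provenance)


def save_maps_nifti(
    maps: dict[str, np.ndarray], fov_mm: float, path_prefix: str | Path
) -> list[Path]:
    """Write each 2-D map as a NIfTI volume; voxel size encodes the FOV
    (1.875 mm for a 60 mm FOV on a 32x32 grid)."""
    paths = []
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    for name, arr in maps.items():
        n = arr.shape[0]
        voxel = fov_mm / n
        affine = np.diag([voxel, voxel, 1.0, 1.0])
        img = nib.Nifti1Image(
            np.asarray(arr, dtype=np.float64)[:, :, None], affine
        )
        p = prefix.with_name(f"{prefix.name}_{name}.nii")
        nib.save(img, p)
        paths.append(p)
    return paths


def save_json(payload: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
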