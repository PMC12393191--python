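"""Readers/writers (NIfTI, HDF5, JSON, CSV) and run manifests."""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from . import __version__
from .protocol import ProtocolConfig
from .sequence import EchoTrainTiming

__all__ = [
    "write_nifti",
    "read_nifti",
    "write_kspace_h5",
    "read_kspace_h5",
    "RunManifest",
]


def write_nifti(
    path: str | Path,
    data: np.ndarray,
    units: str = "",
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> None:
    """Write a 2D/3D/echo-stack array as NIfTI with units in the header.

    Echo stacks arrive as (n_echoes, nx, ny) and are stored with the echo
    dimension as the 4th NIfTI axis.
    """
    arr = np.asarray(data)
    if arr.ndim == 2:
        vol = arr[:, :, None]
    elif arr.ndim == 3:  # (echo, x, y) -> (x, y, 1, echo)
        vol = arr.transpose(1, 2, 0)[:, :, None, :]
    else:
        vol = arr
    affine = np.diag([*voxel_size_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(vol, np.float64), affine)
    if units:
        img.header["descrip"] = units.encode()[:79]
    nib.save(img, str(path))


def read_nifti(path: str | Path) -> np.ndarray:
    """Read a NIfTI file; 4D echo stacks return as (n_echoes, nx, ny)."""
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    if arr.ndim == 4 and arr.shape[2] == 1:
        return arr[:, :, 0, :].transpose(2, 0, 1)
    if arr.ndim == 3 and arr.shape[2] == 1:
        return arr[:, :, 0]
    return arr


def write_kspace_h5(path: str | Path, kspace) -> None:
    """Store a :class:`~esmgre.kspace.MultiEchoKSpace` in HDF5."""
    with h5py.File(str(path), "w") as f:
        # track_times=False keeps reruns with identical inputs byte-identical
        f.create_dataset("data", data=kspace.data, track_times=False)
        f.create_dataset("navs", data=kspace.navs, track_times=False)
        if kspace.df0_applied is not None:
            f.create_dataset("df0_applied_hz", data=kspace.df0_applied,
                             track_times=False)
        if kspace.df0_shifted_extra is not None:
            f.create_dataset("df0_shifted_extra_hz",
                             data=kspace.df0_shifted_extra, track_times=False)
        f.attrs["step1_done"] = kspace.step1_done
        f.attrs["step2_done"] = kspace.step2_done
        f.attrs["train_json"] = json.dumps(kspace.train.to_dict())
        f.attrs["config_json"] = json.dumps(kspace.config.to_dict())


def read_kspace_h5(path: str | Path):
    from .kspace import MultiEchoKSpace  # local import avoids a cycle

    with h5py.File(str(path), "r") as f:
        train = EchoTrainTiming.from_dict(json.loads(f.attrs["train_json"]))
        config = ProtocolConfig.from_dict(json.loads(f.attrs["config_json"]))
        ks = MultiEchoKSpace(
            data=f["data"][()],
            navs=f["navs"][()],
            train=train,
            config=config,
            df0_applied=(
                f["df0_applied_hz"][()] if "df0_applied_hz" in f else None
            ),
            df0_shifted_extra=(
                f["df0_shifted_extra_hz"][()]
                if "df0_shifted_extra_hz" in f else None
            ),
            step1_done=bool(f.attrs["step1_done"]),
            step2_done=bool(f.attrs["step2_done"]),
        )
    return ks


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written once per CLI run."""

    stage: str
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(
            datetime.timezone.utc
        ).isoformat()
    )

    def add_input(self, name: str, path: str | Path) -> None:
        self.inputs[name] = {"path": str(path), "sha256": _sha256(Path(path))}

    def add_output(self, name: str, path: str | Path) -> None:
        self.outputs[name] = {"path": str(path), "sha256": _sha256(Path(path))}

    def write(self, path: str | Path) -> None:
        d = {
            "stage": self.stage,
            "version": self.version,
            "timestamp": self.timestamp,
            "config": self.config,
            "seeds": self.seeds,
            "inputs": self.inputs,
            "outputs": self.outputs,
        }
        Path(path).write_text(json.dumps(d, indent=1))
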