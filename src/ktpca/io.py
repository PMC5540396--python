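"""HDF5 containers for complex k-t data and phantom series; NIfTI magnitude export.

Layout of a k-t data file::

    /kspace   complex128, (coil, readout, pe, frame)
    /mask     bool, (pe, frame)
    attrs: axes = "coil,readout,pe,frame"

A phantom file additionally stores /truth, /sensitivities, /roi_labels
and the generator configuration as root attributes.  Complex data lives
only in HDF5; NIfTI files carry magnitude images for viewing.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .datatypes import DynamicSeries, KTData
from .phantom import PhantomConfig
from .sampling import SamplingPattern

__all__ = [
    "read_ktdata",
    "write_ktdata",
    "write_phantom",
    "read_phantom",
    "write_pattern",
    "read_pattern",
    "export_magnitude_nifti",
]

KT_AXES = "coil,readout,pe,frame"


def write_ktdata(kt: KTData, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=np.asarray(kt.data, dtype=np.complex128))
        f.create_dataset("mask", data=kt.mask)
        f.attrs["axes"] = KT_AXES


def read_ktdata(path: str | Path) -> KTData:
    with h5py.File(path, "r") as f:
        for name in ("kspace", "mask"):
            if name not in f:
                raise KeyError(f"{path}: missing required dataset /{name}")
        if "axes" not in f.attrs:
            raise KeyError(f"{path}: missing required attribute 'axes'")
        axes = f.attrs["axes"]
        if isinstance(axes, bytes):
            axes = axes.decode()
        if axes != KT_AXES:
            raise ValueError(
                f"{path}: axis order {axes!r} does not match expected {KT_AXES!r}; "
                "refusing to transpose silently"
            )
        return KTData(f["kspace"][()], f["mask"][()])


def write_phantom(
    series: DynamicSeries, kt: KTData, config: PhantomConfig, path: str | Path
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("truth", data=series.truth)
        f.create_dataset("sensitivities", data=series.sensitivities)
        f.create_dataset("kspace", data=np.asarray(kt.data, dtype=np.complex128))
        f.create_dataset("mask", data=kt.mask)
        f.create_dataset("object_mask", data=series.object_mask)
        f.create_dataset("roi_labels", data=series.roi_labels)
        if series.roi_curves is not None:
            f.create_dataset("roi_curves", data=series.roi_curves)
        f.attrs["axes"] = KT_AXES
        for k, v in dataclasses.asdict(config).items():
            f.attrs[k] = v


def read_phantom(path: str | Path) -> tuple[DynamicSeries, KTData, PhantomConfig]:
    with h5py.File(path, "r") as f:
        required = ["truth", "sensitivities", "kspace", "mask", "object_mask", "roi_labels"]
        missing = [n for n in required if n not in f]
        if missing:
            raise KeyError(f"{path}: missing required datasets {missing}")
        series = DynamicSeries(
            truth=f["truth"][()],
            sensitivities=f["sensitivities"][()],
            object_mask=f["object_mask"][()].astype(bool),
            roi_labels=f["roi_labels"][()],
            roi_curves=f["roi_curves"][()] if "roi_curves" in f else None,
        )
        kt = KTData(f["kspace"][()], f["mask"][()])
        cfg_fields = {fld.name for fld in dataclasses.fields(PhantomConfig)}
        cfg = PhantomConfig(
            **{k: f.attrs[k] for k in cfg_fields if k in f.attrs}
        )
    return series, kt, cfg


def write_pattern(pattern: SamplingPattern, path: str | Path) -> None:
    """Mask as HDF5 plus a JSON sidecar with the lattice parameters."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("mask", data=pattern.acquired)
    sidecar = {
        "R": pattern.R,
        "n_pe": pattern.n_pe,
        "n_frames": pattern.n_frames,
        "shift_per_frame": pattern.shift_per_frame,
        "training_profiles": [int(i) for i in pattern.training_profiles],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_pattern(path: str | Path) -> SamplingPattern:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    with h5py.File(path, "r") as f:
        if "mask" not in f:
            raise KeyError(f"{path}: missing required dataset /mask")
        acquired = f["mask"][()]
    return SamplingPattern(
        R=int(sidecar["R"]),
        n_pe=int(sidecar["n_pe"]),
        n_frames=int(sidecar["n_frames"]),
        acquired=acquired,
        shift_per_frame=int(sidecar["shift_per_frame"]),
        training_profiles=list(sidecar.get("training_profiles", [])),
    )


def export_magnitude_nifti(images: np.ndarray, path: str | Path) -> None:
    """Write |images| as a NIfTI volume (frames on the last axis)."""
    mag = np.abs(np.asarray(images)).astype(np.float32)
    nib.save(nib.Nifti1Image(mag, affine=np.eye(4)), str(path))
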