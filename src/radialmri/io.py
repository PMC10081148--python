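"""File formats: HDF5 for complex series and k-space, NIfTI for magnitude
series, YAML for phantom/experiment configuration, CSV for metric tables."""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .phantom import DynamicImageSeries, PhantomSpec
from .radial import RadialKSpaceFrame, make_sampling

__all__ = [
    "save_series_hdf5",
    "load_series_hdf5",
    "save_kspace_hdf5",
    "load_kspace_hdf5",
    "save_magnitude_nifti",
    "save_spec_yaml",
    "load_spec_yaml",
]


def save_series_hdf5(path, series: DynamicImageSeries) -> None:
    """Complex frames stored as paired real/imag float datasets."""
    with h5py.File(path, "w") as f:
        f.create_dataset("frames_real", data=series.frames.real)
        f.create_dataset("frames_imag", data=series.frames.imag)
        f.create_dataset("frame_times", data=series.frame_times)
        f.attrs["pixel_size"] = series.pixel_size


def load_series_hdf5(path) -> DynamicImageSeries:
    with h5py.File(path, "r") as f:
        frames = f["frames_real"][()] + 1j * f["frames_imag"][()]
        times = f["frame_times"][()]
        pixel_size = float(f.attrs.get("pixel_size", 1.0))
    return DynamicImageSeries(frames=frames, frame_times=times, pixel_size=pixel_size)


def save_kspace_hdf5(path, frames: list[RadialKSpaceFrame]) -> None:
    lines = np.stack([f.lines for f in frames])
    with h5py.File(path, "w") as f:
        f.create_dataset("lines_real", data=lines.real)
        f.create_dataset("lines_imag", data=lines.imag)
        f.attrs["n_views"] = frames[0].sampling.n_views
        f.attrs["n_samples"] = frames[0].sampling.n_samples


def load_kspace_hdf5(path) -> list[RadialKSpaceFrame]:
    with h5py.File(path, "r") as f:
        lines = f["lines_real"][()] + 1j * f["lines_imag"][()]
        sampling = make_sampling(int(f.attrs["n_views"]), int(f.attrs["n_samples"]))
    return [
        RadialKSpaceFrame(sampling=sampling, lines=lines[t], frame_index=t)
        for t in range(len(lines))
    ]


def save_magnitude_nifti(path, series) -> None:
    """Magnitude series as a (N, N, 1, T) NIfTI volume."""
    if isinstance(series, DynamicImageSeries):
        mag = series.magnitude()
        px = series.pixel_size
    else:
        mag = np.abs(np.asarray(series))
        px = 1.0
    vol = np.transpose(mag, (1, 2, 0))[:, :, None, :]
    affine = np.diag([px, px, 1.0, 1.0])
    nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), str(path))


def save_spec_yaml(path, spec: PhantomSpec) -> None:
    Path(path).write_text(yaml.safe_dump(spec.to_dict(), sort_keys=True))


def load_spec_yaml(path) -> PhantomSpec:
    return PhantomSpec.from_dict(yaml.safe_load(Path(path).read_text()))
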