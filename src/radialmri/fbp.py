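"""Non-iterative filtered backprojection with a regularized ramp filter.

Reconstruction proceeds spoke by spoke: each radial k-space line is
multiplied by the 1D transfer function

    H(ω) = |ω| / (1 + β |ω|)

(the plain ramp |ω| when β = 0), inverse-Fourier-transformed into a filtered
projection, and backprojected.  ω is the radial frequency in cycles/sample,
so |ω| ≤ 1/2 and β = 1, 2 act as mild lowpasses that trade resolution for
noise.  The real and imaginary parts of the filtered projections are
backprojected separately and the two channel images are combined into the
norm image sqrt(re² + im²) as the final step.

Four pipeline versions are exposed:

* V1 — 24-view raw data extended to 72 views by deformation, regularized filter;
* V2 — 24-view raw data, regularized filter;
* V3 — 24-view raw data, plain ramp;
* V4 — 72-view raw data, plain ramp: the gold standard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fourier import centered_ifft1, freq_axis
from .radial import RadialKSpaceFrame
from .view_extension import extend_views

__all__ = [
    "FbpConfig",
    "filter_transfer",
    "filter_lines",
    "backproject",
    "project_image",
    "fbp_reconstruct",
    "run_version",
]

VERSIONS = ("V1", "V2", "V3", "V4")


@dataclass(frozen=True)
class FbpConfig:
    beta: float = 0.0
    use_ramp: bool = False  # force β = 0 regardless of `beta`
    version: str = "V3"
    output_size: int | None = None  # default: n_samples of the input frame
    extension_factor: int = 3

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.version not in VERSIONS:
            raise ValueError(f"version must be one of {VERSIONS}, got {self.version!r}")

    @property
    def effective_beta(self) -> float:
        return 0.0 if self.use_ramp else self.beta


def filter_transfer(omega, beta: float):
    """Regularized ramp gain |ω| / (1 + β |ω|); the exact ramp when β = 0."""
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    a = np.abs(omega)
    return a / (1.0 + beta * a)


def filter_lines(frame: RadialKSpaceFrame, config: FbpConfig) -> RadialKSpaceFrame:
    """Multiply every spoke elementwise by H(|ω_k|); linear in the input."""
    gain = filter_transfer(freq_axis(frame.sampling.n_samples), config.effective_beta)
    return RadialKSpaceFrame(
        sampling=frame.sampling,
        lines=frame.lines * gain[None, :],
        frame_index=frame.frame_index,
    )


def backproject(projections: np.ndarray, angles_deg: np.ndarray, N: int) -> np.ndarray:
    """Pixel-driven backprojection over 180°, scaled by π / n_views.

    For each pixel with centered coordinates (u', v') and each view θ the
    projection is sampled at t = u'·cosθ + v'·sinθ by linear interpolation;
    out-of-range t contributes zero.
    """
    projections = np.asarray(projections, dtype=float)
    angles_deg = np.asarray(angles_deg, dtype=float)
    if projections.ndim != 2 or projections.shape[0] != len(angles_deg):
        raise ValueError(
            f"projections shape {projections.shape} does not match "
            f"{len(angles_deg)} angles"
        )
    n_views, n_samples = projections.shape
    cs = n_samples // 2
    cg = N // 2
    u = (np.arange(N) - cg).astype(float)
    uu = u[:, None]
    vv = u[None, :]
    img = np.zeros((N, N))
    for p, th in zip(projections, np.deg2rad(angles_deg)):
        t = uu * np.cos(th) + vv * np.sin(th) + cs
        i0 = np.floor(t).astype(int)
        frac = t - i0
        ok0 = (i0 >= 0) & (i0 <= n_samples - 1)
        ok1 = (i0 + 1 >= 0) & (i0 + 1 <= n_samples - 1)
        acc = np.zeros((N, N))
        acc[ok0] += (1.0 - frac[ok0]) * p[np.clip(i0, 0, n_samples - 1)[ok0]]
        acc[ok1] += frac[ok1] * p[np.clip(i0 + 1, 0, n_samples - 1)[ok1]]
        img += acc
    return img * (np.pi / n_views)


def project_image(image: np.ndarray, angles_deg: np.ndarray, n_samples: int) -> np.ndarray:
    """Forward projector matched to :func:`backproject` (its exact adjoint
    up to the π / n_views scale): pixel values are scattered into projection
    bins with the same linear-interpolation weights."""
    image = np.asarray(image, dtype=float)
    N = image.shape[0]
    cs = n_samples // 2
    cg = N // 2
    u = (np.arange(N) - cg).astype(float)
    uu = u[:, None]
    vv = u[None, :]
    out = np.zeros((len(angles_deg), n_samples))
    for k, th in enumerate(np.deg2rad(np.asarray(angles_deg, dtype=float))):
        t = (uu * np.cos(th) + vv * np.sin(th) + cs).ravel()
        i0 = np.floor(t).astype(int)
        frac = t - i0
        vals = image.ravel()
        ok0 = (i0 >= 0) & (i0 <= n_samples - 1)
        ok1 = (i0 + 1 >= 0) & (i0 + 1 <= n_samples - 1)
        np.add.at(out[k], i0[ok0], (1.0 - frac[ok0]) * vals[ok0])
        np.add.at(out[k], i0[ok1] + 1, frac[ok1] * vals[ok1])
    return out


def fbp_reconstruct(frame: RadialKSpaceFrame, config: FbpConfig) -> np.ndarray:
    """Filter → per-spoke inverse FFT → per-channel backprojection → norm image.

    Under version V1 the frame is first extended threefold by the deformation
    method.  The real and imaginary parts of the filtered projections are
    backprojected separately and combined elementwise as sqrt(re² + im²); the
    output is therefore nonnegative.
    """
    if config.version == "V1":
        frame = extend_views(frame, factor=config.extension_factor)
    N = config.output_size or frame.sampling.n_samples
    filtered = filter_lines(frame, config)
    proj = centered_ifft1(filtered.lines, axis=-1)
    angles = frame.sampling.angles_deg
    img_re = backproject(proj.real, angles, N)
    img_im = backproject(proj.imag, angles, N)
    return np.hypot(img_re, img_im)


def run_version(
    frame24: RadialKSpaceFrame | None,
    frame72: RadialKSpaceFrame | None,
    version: str,
    beta: float = 1.0,
    output_size: int | None = None,
) -> np.ndarray:
    """Dispatch one of the four non-iterative pipeline versions."""
    if version not in VERSIONS:
        raise ValueError(f"version must be one of {VERSIONS}, got {version!r}")
    if version == "V4":
        if frame72 is None:
            raise ValueError("V4 requires the fully sampled 72-view frame")
        cfg = FbpConfig(version="V4", use_ramp=True, output_size=output_size)
        return fbp_reconstruct(frame72, cfg)
    if frame24 is None:
        raise ValueError(f"{version} requires the undersampled 24-view frame")
    if version == "V1":
        cfg = FbpConfig(version="V1", beta=beta, output_size=output_size)
    elif version == "V2":
        cfg = FbpConfig(version="V2", beta=beta, output_size=output_size)
    else:  # V3: plain ramp on the raw sparse data
        cfg = FbpConfig(version="V3", use_ramp=True, output_size=output_size)
    return fbp_reconstruct(frame24, cfg)
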