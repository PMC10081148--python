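"""Radial k-space sampling geometry, acquisition simulation, undersampling.

A radial acquisition measures the object's 2D Fourier transform along
diameters ("spokes") through the k-space center at ``n_views`` angles
uniformly covering [0°, 180°).  By the central-slice theorem each spoke is
also the 1D Fourier transform of the object's parallel projection at the same
angle, which is what links this module to the filtered-backprojection path.

Two evaluation paths are provided for the simulated acquisition and must
agree: a direct nonuniform-DFT summation over all pixels (the slow oracle)
and a semi-separable factorization of the same sum evaluated with matrix
products (the fast path, exact to rounding).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .fourier import radial_offsets

__all__ = [
    "RadialSampling",
    "RadialKSpaceFrame",
    "make_sampling",
    "simulate_acquisition",
    "simulate_series",
    "undersample",
]


@dataclass(frozen=True)
class RadialSampling:
    """Uniform radial view set: angle[j] = offset + j * (180 / n_views) deg.

    ``angle_offset_deg`` is zero for a canonical acquisition; an interleaved
    undersampled frame carries the rigid rotation of its retained subset.
    """

    n_views: int
    n_samples: int
    sample_spacing: float = 1.0  # Δk in 1/FOV units
    angle_offset_deg: float = 0.0

    @property
    def angles_deg(self) -> np.ndarray:
        return self.angle_offset_deg + np.arange(self.n_views) * (180.0 / self.n_views)

    @property
    def angles_rad(self) -> np.ndarray:
        return np.deg2rad(self.angles_deg)


@dataclass
class RadialKSpaceFrame:
    """Complex samples on radial lines for one time frame.

    ``lines[v, k]`` is the sample at signed radius ``(k - n_samples//2) * Δk``
    along view ``v``; the DC sample of every line sits at index
    ``n_samples // 2``.
    """

    sampling: RadialSampling
    lines: np.ndarray  # (n_views, n_samples) complex
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.lines = np.asarray(self.lines, dtype=complex)
        if self.lines.shape != (self.sampling.n_views, self.sampling.n_samples):
            raise ValueError(
                f"lines shape {self.lines.shape} does not match sampling "
                f"({self.sampling.n_views}, {self.sampling.n_samples})"
            )


def make_sampling(n_views: int, n_samples: int) -> RadialSampling:
    if n_views < 1:
        raise ValueError(f"n_views must be >= 1, got {n_views}")
    if n_samples < 2:
        raise ValueError(f"n_samples must be >= 2, got {n_samples}")
    return RadialSampling(n_views=n_views, n_samples=n_samples)


def _check_square(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError(f"image must be square 2D, got shape {image.shape}")
    return image


def _kspace_points(sampling: RadialSampling) -> tuple[np.ndarray, np.ndarray]:
    """Frequency-plane coordinates (ku, kv) of every sample, in grid units."""
    r = radial_offsets(sampling.n_samples) * sampling.sample_spacing
    th = sampling.angles_rad
    ku = np.cos(th)[:, None] * r[None, :]
    kv = np.sin(th)[:, None] * r[None, :]
    return ku, kv


def _nudft_direct(image: np.ndarray, sampling: RadialSampling) -> np.ndarray:
    """Brute-force nonuniform DFT: explicit sum over all pixels per sample."""
    n = image.shape[0]
    c = n // 2
    u = np.arange(n) - c
    ku, kv = _kspace_points(sampling)
    lines = np.empty((sampling.n_views, sampling.n_samples), dtype=complex)
    for v in range(sampling.n_views):
        phase = np.exp(
            -2j * np.pi
            * (ku[v][:, None, None] * u[None, :, None] + kv[v][:, None, None] * u[None, None, :])
            / n
        )
        lines[v] = np.tensordot(phase, image, axes=([1, 2], [0, 1]))
    return lines


def _nudft_fast(image: np.ndarray, sampling: RadialSampling) -> np.ndarray:
    """Semi-separable NUDFT: per view, line = diag(A @ image @ B).

    A[k, u] = exp(-2πi ku_k (u-c)/n), B[w, k] = exp(-2πi kv_k (w-c)/n); the
    sum over pixels factorizes into two matrix products, identical to the
    direct summation up to floating-point rounding.
    """
    n = image.shape[0]
    c = n // 2
    u = np.arange(n) - c
    ku, kv = _kspace_points(sampling)
    a = np.exp(-2j * np.pi * ku[:, :, None] * u[None, None, :] / n)  # (V, S, n)
    b = np.exp(-2j * np.pi * kv[:, :, None] * u[None, None, :] / n)  # (V, S, n)
    t = a @ image  # (V, S, n)
    return np.einsum("vkn,vkn->vk", t, b)


def simulate_acquisition(
    image: np.ndarray,
    sampling: RadialSampling,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | int | None = None,
    method: str = "fast",
    frame_index: int = 0,
) -> RadialKSpaceFrame:
    """Sample the image's continuous 2D Fourier transform on radial spokes.

    Additive i.i.d. complex Gaussian noise of standard deviation
    ``noise_sigma`` per real/imaginary component is applied in k-space.
    """
    image = _check_square(image)
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if method == "fast":
        lines = _nudft_fast(image, sampling)
    elif method == "direct":
        lines = _nudft_direct(image, sampling)
    else:
        raise ValueError(f"unknown method {method!r}")
    if noise_sigma > 0:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        lines = lines + noise_sigma * (
            rng.standard_normal(lines.shape) + 1j * rng.standard_normal(lines.shape)
        )
    return RadialKSpaceFrame(sampling=sampling, lines=lines, frame_index=frame_index)


def simulate_series(
    frames: np.ndarray,
    sampling: RadialSampling,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> list[RadialKSpaceFrame]:
    """Acquire every frame of a (T, N, N) series with one noise stream."""
    rng = np.random.default_rng(seed)
    return [
        simulate_acquisition(
            frames[t], sampling, noise_sigma=noise_sigma, rng=rng, frame_index=t
        )
        for t in range(len(frames))
    ]


def undersample(
    frame: RadialKSpaceFrame, keep_every: int, offset: int = 0
) -> RadialKSpaceFrame:
    """Keep views with index ≡ offset (mod keep_every); values are untouched.

    72 views at 2.5° spacing with ``keep_every=3`` gives the 24-view raw data
    at 7.5° spacing.  In a dynamic series the ``offset`` is typically rotated
    frame by frame (``offset = t mod keep_every``, interleaved undersampling)
    so that consecutive frames measure complementary view subsets — the
    pattern under which a temporal constraint can recruit "assisting" views
    from adjacent frames.

    Note the retained angles with ``offset > 0`` are a rigid rotation of the
    ``offset == 0`` set; the returned sampling records the canonical uniform
    grid and the rotation is carried by ``angle_offset_deg``.
    """
    n_views = frame.sampling.n_views
    if keep_every < 1 or n_views % keep_every != 0:
        raise ValueError(
            f"n_views={n_views} is not divisible by keep_every={keep_every}"
        )
    if not 0 <= offset < keep_every:
        raise ValueError(f"offset must be in [0, {keep_every}), got {offset}")
    sub = replace(
        frame.sampling,
        n_views=n_views // keep_every,
        angle_offset_deg=frame.sampling.angle_offset_deg + offset * (180.0 / n_views),
    )
    return RadialKSpaceFrame(
        sampling=sub,
        lines=frame.lines[offset::keep_every].copy(),
        frame_index=frame.frame_index,
    )
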