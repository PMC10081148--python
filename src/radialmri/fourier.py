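"""Centered discrete Fourier conventions shared by every reconstruction path.

All k-space arrays in this package use a *centered* layout: the DC sample sits
at index ``n // 2`` along each frequency axis, and image pixel ``(n//2, n//2)``
is the rotation center of the field of view.  The helpers here own the
fftshift bookkeeping so that the radial simulator, the gridding step, the FBP
filter and the iterative reconstruction all agree on phase conventions.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "radial_offsets",
    "freq_axis",
    "kspace_of_image",
    "image_of_kspace",
    "centered_ifft1",
    "half_turn_reverse",
]


def radial_offsets(n: int) -> np.ndarray:
    """Signed sample offsets from the DC index, in units of Δk = 1/FOV.

    For even ``n`` the most-negative offset ``-n//2`` has no positive partner
    (standard FFT layout).
    """
    return np.arange(n) - n // 2


def freq_axis(n: int) -> np.ndarray:
    """Signed frequency of each sample in cycles/sample, DC at index ``n//2``."""
    return radial_offsets(n) / n


def kspace_of_image(img: np.ndarray, norm: str = "ortho") -> np.ndarray:
    """Centered 2D DFT over the last two axes.

    With ``norm="backward"`` this matches the nonuniform-DFT convention of the
    radial simulator (a plain sum over pixels with centered coordinates); with
    ``norm="ortho"`` the transform is unitary, which is what the iterative
    reconstruction uses so that the adjoint equals the inverse.
    """
    axes = (-2, -1)
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(img, axes=axes), axes=axes, norm=norm), axes=axes
    )


def image_of_kspace(k: np.ndarray, norm: str = "ortho") -> np.ndarray:
    """Inverse of :func:`kspace_of_image` with the same layout and norm."""
    axes = (-2, -1)
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(k, axes=axes), axes=axes, norm=norm), axes=axes
    )


def centered_ifft1(lines: np.ndarray, axis: int = -1) -> np.ndarray:
    """1D inverse DFT along ``axis`` with DC-centered input and centered output.

    Uses the "backward" norm (1/n), which supplies the dν frequency-bin width
    in the filtered-backprojection quadrature.
    """
    return np.fft.fftshift(
        np.fft.ifft(np.fft.ifftshift(lines, axes=axis), axis=axis), axes=axis
    )


def half_turn_reverse(line: np.ndarray) -> np.ndarray:
    """Resample a radial k-space line as seen from the antipodal view angle.

    ``K(r, θ+180°) = K(-r, θ)``: the sample at signed radius ``r`` on the
    rotated line is the sample at ``-r`` on the original.  No conjugation is
    involved; that shortcut only holds for real-valued images.  For even ``n``
    the unpaired most-negative sample keeps its own value.
    """
    line = np.asarray(line)
    out = np.roll(line[..., ::-1], 1, axis=-1)
    return out
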