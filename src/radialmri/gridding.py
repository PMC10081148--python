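"""Scatter radial k-space samples onto a Cartesian grid with a binary mask.

The iterative reconstruction works on a Cartesian k-space matrix ``d`` and a
binary mask ``W`` marking which cells are considered measured.  Each radial
sample is distributed to its four surrounding grid cells with bilinear
weights; a cell's value is the weight-normalized average of its contributions
and it is flagged measured when the accumulated weight exceeds a small
threshold.  No density compensation is applied: the fidelity term of the
iterative method compares measured cells directly.

Unit convention: ``d`` is stored in *unitary* (orthonormal) DFT units — the
raw nonuniform-DFT sample values divided by N — so that the iterative module
can use the unitary centered FFT whose adjoint equals its inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .radial import RadialKSpaceFrame, _kspace_points

__all__ = ["CartesianKSpace", "grid_radial", "mask_coverage", "WEIGHT_THRESHOLD"]

WEIGHT_THRESHOLD = 1e-8  # accumulated bilinear weight defining "measured"


@dataclass
class CartesianKSpace:
    """Gridded measurements ``d`` (zero where unmeasured) and mask ``W``."""

    d: np.ndarray  # (N, N) complex, unitary-DFT units
    W: np.ndarray  # (N, N) float in {0, 1}
    N: int

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=complex)
        self.W = np.asarray(self.W, dtype=float)
        if self.d.shape != (self.N, self.N) or self.W.shape != (self.N, self.N):
            raise ValueError("d and W must both be (N, N)")


def grid_radial(frame: RadialKSpaceFrame, N: int | None = None) -> CartesianKSpace:
    """Bilinear scatter of one radial frame onto an N×N Cartesian k-space."""
    if frame.lines.size == 0:
        raise ValueError("cannot grid an empty frame")
    if N is None:
        N = frame.sampling.n_samples
    c = N // 2
    ku, kv = _kspace_points(frame.sampling)
    pu = (ku + c).ravel()
    pv = (kv + c).ravel()
    vals = frame.lines.ravel()

    u0 = np.floor(pu).astype(int)
    v0 = np.floor(pv).astype(int)
    fu = pu - u0
    fv = pv - v0

    wsum = np.zeros((N, N))
    acc = np.zeros((N, N), dtype=complex)
    for du, dv, w in (
        (0, 0, (1 - fu) * (1 - fv)),
        (1, 0, fu * (1 - fv)),
        (0, 1, (1 - fu) * fv),
        (1, 1, fu * fv),
    ):
        uu, vv = u0 + du, v0 + dv
        ok = (w > 0) & (uu >= 0) & (uu < N) & (vv >= 0) & (vv < N)
        np.add.at(wsum, (uu[ok], vv[ok]), w[ok])
        np.add.at(acc, (uu[ok], vv[ok]), w[ok] * vals[ok])

    W = (wsum > WEIGHT_THRESHOLD).astype(float)
    d = np.zeros((N, N), dtype=complex)
    hit = W > 0
    d[hit] = acc[hit] / wsum[hit]
    d /= N  # raw NUDFT values -> unitary-DFT units
    return CartesianKSpace(d=d, W=W, N=N)


def mask_coverage(W: np.ndarray) -> float:
    """Fraction of Cartesian cells marked measured."""
    W = np.asarray(W)
    return float(np.mean(W))
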