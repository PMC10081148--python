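"""Deformation-based synthesis of unmeasured radial k-space lines.

Between two adjacent measured spokes L1 (angle θ1) and L4 (angle θ4), every
sample on L1 is matched to a close-valued sample on L4; the matches form a
deformation field.  A missing intermediate spoke at θ is filled by moving
along each deformation path from L1 towards L4: the path is interpolated
linearly in polar coordinates (signed radius and complex value both linear in
the angular fraction), and the scattered (radius, value) pairs are resampled
onto the uniform radial grid.  This turns a 24-view frame into a 72-view
frame without touching any measured sample.

The correspondence is estimated by dynamic programming on the magnitude
profiles: among monotone non-decreasing index maps with pinned endpoints and
a pinned DC sample, the map minimizing the sum of squared magnitude
mismatches is selected, with ties broken towards the identity map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fourier import half_turn_reverse, radial_offsets
from .radial import RadialKSpaceFrame, RadialSampling

__all__ = [
    "DeformationField",
    "estimate_deformation",
    "synthesize_intermediate",
    "extend_views",
]

_INF = np.inf


@dataclass
class DeformationField:
    """Monotone sample correspondence i -> mapping[i] between two spokes."""

    mapping: np.ndarray  # (n,) int indices into the target line
    cost: float  # sum of squared magnitude mismatches along the map

    def __post_init__(self) -> None:
        self.mapping = np.asarray(self.mapping)
        n = len(self.mapping)
        if np.any(np.diff(self.mapping) < 0):
            raise ValueError("deformation mapping must be monotone non-decreasing")
        if self.mapping[0] != 0 or self.mapping[-1] != n - 1:
            raise ValueError("deformation endpoints must be pinned")


def estimate_deformation(line1: np.ndarray, line4: np.ndarray) -> DeformationField:
    """Optimal monotone magnitude matching between two equal-length spokes.

    Minimizes sum_i (|line1[i]| - |line4[j(i)]|)^2 over monotone maps j with
    j(0)=0, j(n-1)=n-1 and j(center)=center; among equal-cost maps the one
    with minimal sum |j(i)-i| is returned (so identical lines map to the
    identity).  Deterministic; O(n^2).
    """
    line1 = np.asarray(line1)
    line4 = np.asarray(line4)
    if line1.shape != line4.shape or line1.ndim != 1:
        raise ValueError("lines must be 1D and of equal length")
    n = line1.size
    if n < 4:
        raise ValueError("lines must have length >= 4")
    c = n // 2
    m1 = np.abs(line1)
    m4 = np.abs(line4)
    cost = (m1[:, None] - m4[None, :]) ** 2  # (i, j)

    j_idx = np.arange(n)
    off = 4 * n * n + 1  # strictly larger than any achievable secondary cost
    big_s = 8 * n * n

    P = np.full((n, n), _INF)
    S = np.full((n, n), big_s, dtype=np.int64)
    P[0, 0] = cost[0, 0]
    S[0, 0] = 0
    for i in range(1, n):
        prev_p, prev_s = P[i - 1], S[i - 1]
        pm = np.minimum.accumulate(prev_p)
        achieves = prev_p <= pm
        # group id increments at each strict improvement of the running min
        gid = np.cumsum(np.concatenate(([0], (pm[1:] < pm[:-1]).astype(np.int64))))
        s2 = np.where(achieves, prev_s, big_s)
        sm = np.minimum.accumulate(s2 - gid * off) + gid * off
        P[i] = cost[i] + pm
        S[i] = np.abs(j_idx - i) + sm
        if i == c:  # DC-to-DC pin
            keep = P[i, c], S[i, c]
            P[i] = _INF
            S[i] = big_s
            P[i, c], S[i, c] = keep

    # backtrack (lexicographic: primary cost, then distance-to-identity)
    mapping = np.empty(n, dtype=int)
    mapping[-1] = n - 1
    j = n - 1
    for i in range(n - 1, 0, -1):
        pp = P[i - 1, : j + 1]
        ss = S[i - 1, : j + 1]
        best_p = pp.min()
        cand = np.flatnonzero(pp == best_p)
        cand = cand[ss[cand] == ss[cand].min()]
        # residual tie: prefer the index closest to the identity
        j = int(cand[np.argmin(np.abs(cand - (i - 1)))])
        mapping[i - 1] = j
    return DeformationField(mapping=mapping, cost=float(P[n - 1, n - 1]))


def synthesize_intermediate(
    line1: np.ndarray,
    line4: np.ndarray,
    field: DeformationField,
    theta1_deg: float,
    theta4_deg: float,
    theta_target_deg: float,
) -> np.ndarray:
    """Estimate the spoke at an intermediate angle from a matched pair.

    Each deformation path runs from (r_i, θ1) to (r_{j(i)}, θ4); at the
    target angle the path's signed radius and complex value are both linear
    in the angular fraction s = (θ - θ1)/(θ4 - θ1).  The resulting scattered
    samples are resampled to the uniform radial grid by linear interpolation
    (real and imaginary parts independently); radii outside the scattered
    support are zero.
    """
    if not (theta1_deg < theta_target_deg < theta4_deg):
        raise ValueError(
            f"target angle {theta_target_deg} not strictly inside "
            f"({theta1_deg}, {theta4_deg})"
        )
    line1 = np.asarray(line1, dtype=complex)
    line4 = np.asarray(line4, dtype=complex)
    n = line1.size
    r = radial_offsets(n).astype(float)
    j = field.mapping
    s = (theta_target_deg - theta1_deg) / (theta4_deg - theta1_deg)
    rho = (1.0 - s) * r + s * r[j]
    val = (1.0 - s) * line1 + s * line4[j]
    out_re = np.interp(r, rho, val.real, left=0.0, right=0.0)
    out_im = np.interp(r, rho, val.imag, left=0.0, right=0.0)
    return out_re + 1j * out_im


def extend_views(frame: RadialKSpaceFrame, factor: int = 3) -> RadialKSpaceFrame:
    """Insert ``factor - 1`` synthesized spokes between each measured pair.

    Measured spokes are copied bit-exactly to their original angles.  The gap
    between the last spoke and the first one rotated by 180° is bridged using
    the half-turn identity K(r, θ+180°) = K(-r, θ) (sample reversal).
    """
    V = frame.sampling.n_views
    if V < 2:
        raise ValueError("view extension needs at least 2 measured views")
    if factor < 2:
        raise ValueError("factor must be >= 2")
    n = frame.sampling.n_samples
    angles = frame.sampling.angles_deg
    out = np.empty((V * factor, n), dtype=complex)
    for v in range(V):
        l1 = frame.lines[v]
        th1 = angles[v]
        if v < V - 1:
            l4 = frame.lines[v + 1]
            th4 = angles[v + 1]
        else:
            l4 = half_turn_reverse(frame.lines[0])
            th4 = angles[0] + 180.0
        field = estimate_deformation(l1, l4)
        out[v * factor] = l1
        for f in range(1, factor):
            tht = th1 + f * (th4 - th1) / factor
            out[v * factor + f] = synthesize_intermediate(l1, l4, field, th1, th4, tht)
    sampling = RadialSampling(
        n_views=V * factor,
        n_samples=n,
        sample_spacing=frame.sampling.sample_spacing,
        angle_offset_deg=frame.sampling.angle_offset_deg,
    )
    return RadialKSpaceFrame(
        sampling=sampling, lines=out, frame_index=frame.frame_index
    )
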