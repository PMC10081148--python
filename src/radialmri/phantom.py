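"""Synthetic dynamic cardiac-perfusion-like phantom with known ground truth.

The phantom is a sum of ellipse indicator functions on the unit field of view.
Each ellipse carries a static baseline intensity and, optionally, a
gamma-variate contrast-enhancement curve

    g(t) = A * ((t - t0)/beta)**alpha * exp(alpha * (1 - (t - t0)/beta))

for t > t0 and 0 otherwise.  This is the Madsen-normalized gamma-variate: it
peaks at ``t = t0 + beta`` with value exactly ``A``, which is the standard
parametric model for a first-pass contrast bolus.  A fixed low-order
polynomial phase (scaled by ``phase_amplitude``) makes the series complex so
that the separate real/imaginary reconstruction paths are exercised
nontrivially.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

__all__ = [
    "BolusCurve",
    "Ellipse",
    "PhantomSpec",
    "DynamicImageSeries",
    "enhancement_curve",
    "generate_phantom",
    "default_spec",
]


class PhantomValidationError(ValueError):
    """Raised when a phantom specification violates an invariant."""


@dataclass(frozen=True)
class BolusCurve:
    """Gamma-variate enhancement parameters.

    amplitude
        Peak enhancement A, added on top of the baseline intensity.
    arrival
        Bolus arrival frame t0; the curve is zero for t <= t0.
    shape
        Dimensionless shape alpha (> 0); larger values sharpen the wash-in.
    scale
        Time-to-peak beta in frames (> 0); the curve peaks at t0 + beta.
    """

    amplitude: float
    arrival: float
    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.shape <= 0:
            raise PhantomValidationError(f"shape must be > 0, got {self.shape}")
        if self.scale <= 0:
            raise PhantomValidationError(f"scale must be > 0, got {self.scale}")


@dataclass(frozen=True)
class Ellipse:
    """One tissue region: an ellipse in normalized [-1, 1] coordinates."""

    cx: float
    cy: float
    a: float  # semi-axis along x before rotation
    b: float  # semi-axis along y before rotation
    angle_deg: float = 0.0
    baseline: float = 0.0
    curve: Optional[str] = None  # key into PhantomSpec.bolus_params

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise PhantomValidationError(f"semi-axes must be positive, got {self.a}, {self.b}")
        reach = max(abs(self.cx), abs(self.cy)) + max(self.a, self.b)
        if reach > 1.0:
            raise PhantomValidationError(
                f"ellipse extends outside the unit field of view (reach {reach:.3f})"
            )


@dataclass(frozen=True)
class PhantomSpec:
    grid_size: int = 128
    n_frames: int = 20
    ellipses: tuple = ()
    bolus_params: dict = field(default_factory=dict)
    noise_sigma: float = 0.5
    phase_amplitude: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size < 16:
            raise PhantomValidationError(f"grid_size must be >= 16, got {self.grid_size}")
        if self.n_frames < 2:
            raise PhantomValidationError(f"n_frames must be >= 2, got {self.n_frames}")
        if self.noise_sigma < 0:
            raise PhantomValidationError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        for ell in self.ellipses:
            if ell.curve is not None and ell.curve not in self.bolus_params:
                raise PhantomValidationError(f"ellipses reference unknown curve {ell.curve!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ellipses"] = [asdict(e) for e in self.ellipses]
        d["bolus_params"] = {k: asdict(v) for k, v in self.bolus_params.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["ellipses"] = tuple(Ellipse(**e) for e in d.get("ellipses", ()))
        d["bolus_params"] = {k: BolusCurve(**v) for k, v in d.get("bolus_params", {}).items()}
        return cls(**d)


@dataclass
class DynamicImageSeries:
    """A time series of complex 2D images, all the same square shape."""

    frames: np.ndarray  # (n_frames, N, N) complex
    frame_times: np.ndarray  # (n_frames,)
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.frame_times = np.asarray(self.frame_times)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.frames.shape[2]:
            raise PhantomValidationError(
                f"frames must be (T, N, N), got shape {self.frames.shape}"
            )
        if len(self.frame_times) != len(self.frames):
            raise PhantomValidationError("frame_times length must match frame count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_size(self) -> int:
        return self.frames.shape[1]

    def magnitude(self) -> np.ndarray:
        return np.abs(self.frames)


def enhancement_curve(curve: BolusCurve, t) -> np.ndarray:
    """Evaluate the gamma-variate enhancement g(t); zero for t <= arrival.

    Continuous in t; g(arrival) = 0 and g(arrival + scale) = amplitude.
    """
    if curve.shape <= 0 or curve.scale <= 0:
        raise PhantomValidationError("shape and scale must be positive")
    t = np.asarray(t, dtype=float)
    tau = (t - curve.arrival) / curve.scale
    with np.errstate(invalid="ignore"):
        g = np.where(
            tau > 0,
            curve.amplitude * np.power(np.clip(tau, 0, None), curve.shape)
            * np.exp(curve.shape * (1.0 - np.clip(tau, 0, None))),
            0.0,
        )
    return g if g.ndim else float(g)


def _unit_coords(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalized pixel-center coordinates; the grid center maps to 0."""
    ax = (np.arange(n) - n // 2) / (n / 2)
    y, x = np.meshgrid(ax, ax, indexing="ij")
    return x, y


def _ellipse_mask(ell: Ellipse, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    th = np.deg2rad(ell.angle_deg)
    dx, dy = x - ell.cx, y - ell.cy
    xr = dx * np.cos(th) + dy * np.sin(th)
    yr = -dx * np.sin(th) + dy * np.cos(th)
    return (xr / ell.a) ** 2 + (yr / ell.b) ** 2 <= 1.0


# Fixed low-order polynomial used for the spatial phase map; the coefficients
# are arbitrary but frozen so a spec is fully reproducible.
_PHASE_COEFFS = (0.4, 0.9, -0.7, 0.6, 0.8, -0.5)  # 1, x, y, xy, x^2, y^2


def _phase_map(amplitude: float, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    c0, cx, cy, cxy, cxx, cyy = _PHASE_COEFFS
    return amplitude * (c0 + cx * x + cy * y + cxy * x * y + cxx * x * x + cyy * y * y)


def generate_phantom(spec: PhantomSpec) -> DynamicImageSeries:
    """Render the noiseless complex ground-truth series for ``spec``.

    Deterministic: measurement noise belongs to the acquisition step
    (:func:`radialmri.radial.simulate_acquisition`), not to the object.
    """
    n = spec.grid_size
    x, y = _unit_coords(n)
    masks = [_ellipse_mask(e, x, y) for e in spec.ellipses]
    phase = np.exp(1j * _phase_map(spec.phase_amplitude, x, y))
    t = np.arange(spec.n_frames, dtype=float)
    frames = np.zeros((spec.n_frames, n, n), dtype=complex)
    for ell, mask in zip(spec.ellipses, masks):
        levels = np.full(spec.n_frames, ell.baseline)
        if ell.curve is not None:
            levels = levels + enhancement_curve(spec.bolus_params[ell.curve], t)
        frames += levels[:, None, None] * mask[None, :, :]
    frames *= phase[None, :, :]
    return DynamicImageSeries(frames=frames, frame_times=t)


def default_spec(grid_size: int = 128, n_frames: int = 20, **overrides) -> PhantomSpec:
    """Desk-scale default phantom emulating a cardiac perfusion field of view.

    Most of the FOV is dark (air), with a dim torso, a myocardial region,
    right- and left-ventricular blood pools carrying strong, fast
    gamma-variate boluses (RV enhancing first), and one small bright static
    chest-wall marker.  The LV bolus peaks at frame ``arrival + scale`` with
    enhancement 2.0, giving the strong dynamics that make the temporal
    constraint of the iterative method consequential.
    """
    ellipses = (
        Ellipse(cx=0.0, cy=0.03, a=0.72, b=0.52, angle_deg=0.0, baseline=0.12),
        Ellipse(cx=0.06, cy=-0.05, a=0.34, b=0.29, angle_deg=25.0, baseline=0.22, curve="myo"),
        Ellipse(cx=0.12, cy=-0.02, a=0.16, b=0.12, angle_deg=25.0, baseline=0.18, curve="lv"),
        Ellipse(cx=-0.16, cy=-0.14, a=0.11, b=0.08, angle_deg=-20.0, baseline=0.18, curve="rv"),
        # descending aorta: small, bright, enhances early and strongly
        Ellipse(cx=-0.02, cy=0.34, a=0.07, b=0.07, baseline=0.25, curve="aorta"),
        # static high-contrast chest-wall fat / marker structures
        Ellipse(cx=-0.40, cy=0.32, a=0.10, b=0.06, angle_deg=-30.0, baseline=0.80),
        Ellipse(cx=0.44, cy=0.28, a=0.08, b=0.05, angle_deg=35.0, baseline=0.75),
        Ellipse(cx=0.02, cy=-0.44, a=0.12, b=0.045, angle_deg=3.0, baseline=0.70),
    )
    bolus = {
        "rv": BolusCurve(amplitude=2.0, arrival=1.0, shape=3.0, scale=2.0),
        "aorta": BolusCurve(amplitude=2.5, arrival=2.0, shape=4.0, scale=2.0),
        "lv": BolusCurve(amplitude=2.5, arrival=3.0, shape=3.0, scale=3.0),
        "myo": BolusCurve(amplitude=0.8, arrival=6.0, shape=3.0, scale=6.0),
    }
    params = dict(
        grid_size=grid_size,
        n_frames=n_frames,
        ellipses=ellipses,
        bolus_params=bolus,
    )
    params.update(overrides)
    return PhantomSpec(**params)
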