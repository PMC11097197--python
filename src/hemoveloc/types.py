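"""Core data containers shared across the pipeline.

Units policy (enforced at every module boundary): lengths in mm,
velocities in cm/s, time in s, volumetric flow in mL/s, shear stress
in Pa.  Conversions happen only inside operations.

Coordinate convention: physical frame with x rightward and y upward,
origin at the image lower-left corner.  Image arrays put row 0 at the
top; the readers/writers and the particle renderer perform the flip so
the convention never leaks through an interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "FluidProps",
    "VesselSpec",
    "FlowWaveform",
    "FlowProfile",
    "VelocityField2D",
    "ParticleImageSequence",
    "BLOOD_MIMICKING_FLUID",
]


@dataclass(frozen=True)
class FluidProps:
    """Newtonian fluid properties.

    Parameters
    ----------
    density : float
        Mass density in kg/m^3.
    dynamic_viscosity : float
        Dynamic viscosity in Pa*s.
    """

    density: float
    dynamic_viscosity: float

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be > 0, got {self.density}")
        if self.dynamic_viscosity <= 0:
            raise ValueError(
                f"dynamic_viscosity must be > 0, got {self.dynamic_viscosity}"
            )

    @property
    def kinematic_viscosity(self) -> float:
        """Kinematic viscosity nu = mu / rho in m^2/s."""
        return self.dynamic_viscosity / self.density


#: Water/glycerol/urea blood-mimicking fluid: rho = 1144 kg/m^3,
#: mu = 4.17 mPa*s (within the physiological range of blood).
BLOOD_MIMICKING_FLUID = FluidProps(density=1144.0, dynamic_viscosity=4.17e-3)


@dataclass(frozen=True)
class VesselSpec:
    """Femoral bifurcation geometry parameters.

    Defaults are population means for the common (CFA), superficial
    (SFA) and deep (DFA) femoral arteries, a planar bifurcation, and a
    75%-area concentric CFA stenosis.
    """

    cfa_diameter: float = 8.9  # mm
    sfa_diameter: float = 6.2  # mm
    dfa_diameter: float = 6.1  # mm
    bifurcation_angle: float = 37.5  # degrees
    stenosis_area_reduction: float = 0.75  # fraction of lumen area removed

    def __post_init__(self) -> None:
        for name in ("cfa_diameter", "sfa_diameter", "dfa_diameter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.stenosis_area_reduction < 1.0):
            raise ValueError(
                "stenosis_area_reduction must lie in [0, 1), got "
                f"{self.stenosis_area_reduction}"
            )


@dataclass
class FlowWaveform:
    """Periodic volumetric flow rate for one vessel.

    ``time`` spans one period inclusive of both endpoints
    (``time[0] == 0`` and ``time[-1] == period``) on a uniform grid,
    and ``flow_rate[0] == flow_rate[-1]`` so the waveform is strictly
    periodic.
    """

    time: np.ndarray  # s
    flow_rate: np.ndarray  # mL/s
    period: float  # s

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.flow_rate = np.asarray(self.flow_rate, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.flow_rate.shape:
            raise ValueError("time and flow_rate must be 1-D arrays of equal length")
        if self.period <= 0:
            raise ValueError("period must be > 0")
        dt = np.diff(self.time)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise ValueError("time must be uniformly sampled")
        if not np.isclose(self.flow_rate[0], self.flow_rate[-1], atol=1e-9):
            raise ValueError("waveform must be periodic: first/last samples differ")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def mean_flow(self) -> float:
        """Cycle-mean flow rate in mL/s (trapezoidal)."""
        return float(np.trapezoid(self.flow_rate, self.time) / self.period)

    @property
    def forward_volume(self) -> float:
        """Volume carried by the positive part of the cycle, mL."""
        return float(np.trapezoid(np.clip(self.flow_rate, 0.0, None), self.time))

    @property
    def backflow_volume(self) -> float:
        """Magnitude of the volume carried by the negative part, mL."""
        return float(-np.trapezoid(np.clip(self.flow_rate, None, 0.0), self.time))

    @property
    def net_volume(self) -> float:
        return self.forward_volume - self.backflow_volume


@dataclass
class FlowProfile:
    """Time-resolved axial velocity across a full vessel diameter.

    ``u`` has shape ``(n_time, n_radial)`` in cm/s on the radial grid
    ``r`` (mm), symmetric about 0 and spanning [-R, R].  No-slip
    analytic profiles are exactly zero at r = +/-R.
    """

    r: np.ndarray  # mm
    time: np.ndarray  # s
    u: np.ndarray  # cm/s, shape (nt, nr)
    radius: float  # mm

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if self.u.shape != (self.time.size, self.r.size):
            raise ValueError("u must have shape (n_time, n_radial)")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if not np.allclose(self.r, -self.r[::-1], atol=1e-9):
            raise ValueError("r grid must be symmetric about 0")

    def centerline(self) -> np.ndarray:
        """Velocity time series at r = 0, cm/s."""
        idx = int(np.argmin(np.abs(self.r)))
        return self.u[:, idx].copy()


@dataclass
class VelocityField2D:
    """Time-resolved in-plane velocity field on a uniform isotropic grid.

    ``vx``/``vy`` have shape ``(nt, ny, nx)`` in cm/s; ``x`` and ``y``
    are node coordinates in mm (both ascending, y upward); ``mask``
    marks lumen nodes.
    """

    x: np.ndarray  # mm, (nx,)
    y: np.ndarray  # mm, (ny,)
    t: np.ndarray  # s, (nt,)
    vx: np.ndarray  # cm/s, (nt, ny, nx)
    vy: np.ndarray  # cm/s, (nt, ny, nx)
    mask: np.ndarray  # bool, (ny, nx)
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        self.vx = np.asarray(self.vx, dtype=float)
        self.vy = np.asarray(self.vy, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        shape = (self.t.size, self.y.size, self.x.size)
        if self.vx.shape != shape or self.vy.shape != shape:
            raise ValueError(f"vx/vy must have shape {shape}")
        if self.mask.shape != (self.y.size, self.x.size):
            raise ValueError("mask shape must match (ny, nx)")
        dx = np.diff(self.x)
        dy = np.diff(self.y)
        if dx.size and dy.size:
            if not (np.allclose(dx, dx[0], rtol=1e-6) and np.allclose(dy, dy[0], rtol=1e-6)):
                raise ValueError("grid must be uniform")
            if not np.isclose(dx[0], dy[0], rtol=1e-6):
                raise ValueError("grid spacing must be isotropic")
            if dx[0] <= 0 or dy[0] <= 0:
                raise ValueError("grid spacing must be > 0")
        if self.mask.any():
            inside_x = self.vx[:, self.mask]
            inside_y = self.vy[:, self.mask]
            if not (np.all(np.isfinite(inside_x)) and np.all(np.isfinite(inside_y))):
                raise ValueError("velocity components must be finite inside the mask")

    @property
    def spacing(self) -> float:
        """Grid spacing in mm."""
        return float(self.x[1] - self.x[0]) if self.x.size > 1 else float("nan")

    @property
    def frame_rate(self) -> float:
        """Field rate in 1/s (nan for a single time sample)."""
        if self.t.size < 2:
            return float("nan")
        return float(1.0 / (self.t[1] - self.t[0]))

    def speed(self) -> np.ndarray:
        """Velocity magnitude, cm/s, shape (nt, ny, nx)."""
        return np.hypot(self.vx, self.vy)

    def mean_speed_series(self) -> np.ndarray:
        """Spatial-mean speed inside the mask per time sample."""
        sp = self.speed()[:, self.mask]
        return sp.mean(axis=1) if sp.size else np.zeros(self.t.size)


@dataclass
class ParticleImageSequence:
    """Rendered tracer-particle image frames.

    Frames are stored as float64 in ``[0, 2**bit_depth - 1]``; they are
    quantized only when written to TIFF.  ``clutter`` optionally holds a
    known additive clutter component (same shape as ``frames``) so that
    synthetic benchmarks can recover the clean sequence exactly.
    """

    frames: np.ndarray  # (n_frames, ny, nx)
    pixel_size: float  # mm
    frame_rate: float  # fps
    bit_depth: int = 8
    ground_truth: Optional[VelocityField2D] = None
    clutter: Optional[np.ndarray] = None
    #: physical (x, y) of the image's lower-left corner, mm — the
    #: calibration that anchors PIV output grids in the lab frame
    origin: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be (n_frames>=2, ny, nx)")
        if self.pixel_size <= 0 or self.frame_rate <= 0:
            raise ValueError("pixel_size and frame_rate must be > 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def max_intensity(self) -> float:
        return float(2**self.bit_depth - 1)
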