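"""Pulsed CBCT acquisition model and polyenergetic forward projector.

Protocols are pulsed-fluoroscopy style: ``framerate`` pulses/s of ``pulse_ms``
at ``ma`` over a 60 s, 360 deg rotation, so cumulative mAs equals
``ma * pulse_ms/1000 * pulse_count``.  The projector traces analytic
source-to-element rays through the circular phantom (exact chord lengths per
material), integrates Beer-Lambert attenuation over the spectrum with an
energy-integrating detector weighting, and applies Poisson counting noise
scaled by mAs and a configurable expected-photon fluence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import PairingError, ValidationError
from .materials import Spectrum, detector_weights, generate_spectrum, linear_attenuation
from .phantom import SENSITOMETRY, PhantomSpec

#: expected photons per detector element per mAs in the unattenuated beam
DEFAULT_FLUENCE_SCALE = 1.0e5


@dataclass(frozen=True)
class ProtocolSpec:
    """One CBCT acquisition protocol (tube setting and pulse structure)."""

    kvp: float
    ma: float
    pulse_ms: float
    framerate: float  # pulses per second
    rotation_s: float = 60.0
    arc_deg: float = 360.0

    def __post_init__(self) -> None:
        for name in ("kvp", "ma", "pulse_ms", "framerate", "rotation_s", "arc_deg"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"protocol field {name} must be positive")
        if self.arc_deg > 360.0:
            raise ValidationError("arc must be at most 360 deg")

    @property
    def mAs_per_pulse(self) -> float:
        return self.ma * self.pulse_ms / 1000.0

    @property
    def cumulative_mAs(self) -> float:
        return self.mAs_per_pulse * pulse_count(self)


def pulse_count(protocol: ProtocolSpec) -> int:
    """Number of x-ray pulses in the scan (framerate x time x arc fraction)."""
    return int(
        round(protocol.framerate * protocol.rotation_s * protocol.arc_deg / 360.0)
    )


def protocol_from_cumulative(
    kvp: float,
    cumulative_mAs: float,
    framerate: float,
    pulse_ms: float = 25.0,
    rotation_s: float = 60.0,
) -> ProtocolSpec:
    """Protocol with the tube current chosen to hit a target cumulative mAs."""
    n = int(round(framerate * rotation_s))
    ma = cumulative_mAs / (pulse_ms / 1000.0) / n
    return ProtocolSpec(
        kvp=kvp, ma=ma, pulse_ms=pulse_ms, framerate=framerate, rotation_s=rotation_s
    )


@dataclass(frozen=True)
class Geometry:
    """Source/detector geometry; distances in mm."""

    source_axis_mm: float = 1000.0
    source_detector_mm: float = 1500.0
    detector_pixel_mm: float = 1.6
    detector_columns: int = 256
    detector_rows: int = 1
    detector_row_mm: float = 1.6
    lateral_offset_mm: float = 0.0
    mode: str = "fan2d"

    def __post_init__(self) -> None:
        if not (self.source_detector_mm > self.source_axis_mm > 0):
            raise ValidationError("need source_detector > source_axis > 0")
        if self.detector_columns <= 0 or self.detector_rows <= 0:
            raise ValidationError("detector dimensions must be positive")
        if self.mode not in ("fan2d", "cone3d"):
            raise ValidationError(f"unknown geometry mode {self.mode!r}")

    def element_positions(self):
        """Detector element centres (x_det lateral, z_det axial) in mm."""
        u = (
            np.arange(self.detector_columns) - (self.detector_columns - 1) / 2.0
        ) * self.detector_pixel_mm + self.lateral_offset_mm
        w = (
            np.arange(self.detector_rows) - (self.detector_rows - 1) / 2.0
        ) * self.detector_row_mm
        return u, w


@dataclass(frozen=True)
class ProjectionSet:
    """Log sinogram ln(I0/I) per angle and detector element, plus metadata."""

    angles: np.ndarray  # degrees
    line_integrals: np.ndarray  # (n_angles, [n_rows,] n_columns)
    kvp: float
    mAs_per_pulse: float
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, float)
        li = np.asarray(self.line_integrals, float)
        if li.shape[0] != a.size:
            raise ValidationError("angle count must match sinogram")
        if not np.all(np.isfinite(li)):
            raise ValidationError("line integrals must be finite")
        object.__setattr__(self, "angles", a)
        object.__setattr__(self, "line_integrals", li)


# ---------------------------------------------------------------------------
# ray tracing (analytic chords through circles)
# ---------------------------------------------------------------------------


def _chords(spec: PhantomSpec, src, dirs, module: str) -> dict[str, np.ndarray]:
    """Intersection length (cm) of each ray with each material region.

    ``src`` is (2,) or (3,), ``dirs`` is (n, 2) or (n, 3) unit vectors.
    Circle chords are exact: 2 sqrt(r^2 - d^2); insert chords are subtracted
    from the background cylinder.  3D rays scale the in-plane chord by the
    path obliquity (cylinders treated as axially long).
    """
    dirs = np.atleast_2d(dirs)
    three_d = dirs.shape[1] == 3
    dxy = dirs[:, :2]
    norm_xy = np.linalg.norm(dxy, axis=1)
    obliquity = np.linalg.norm(dirs, axis=1) / norm_xy if three_d else 1.0
    sx, sy = src[0], src[1]

    def disk_chord(cx, cy, r):
        rel = np.array([cx - sx, cy - sy])
        # perpendicular distance from circle centre to the ray line
        t_closest = (dxy @ rel) / norm_xy**2
        px = sx + t_closest * dxy[:, 0] - cx
        py = sy + t_closest * dxy[:, 1] - cy
        d2 = px**2 + py**2
        chord = 2.0 * np.sqrt(np.clip(r**2 - d2, 0.0, None))
        return np.where(t_closest > 0, chord, 0.0) * obliquity

    out: dict[str, np.ndarray] = {}
    bg = disk_chord(0.0, 0.0, spec.outer_radius)
    for ins in spec.module_inserts(module):
        c = disk_chord(ins.center[0], ins.center[1], ins.radius)
        bg = bg - c
        out[ins.material] = out.get(ins.material, 0.0) + c
    out[spec.background_material] = out.get(spec.background_material, 0.0) + bg
    return {m: np.asarray(v) / 10.0 for m, v in out.items()}  # mm -> cm


def raytrace(
    spec: PhantomSpec, geometry: Geometry, angle_deg: float, module: str = SENSITOMETRY
) -> dict[str, np.ndarray]:
    """Per-element material path lengths (cm) for one gantry angle."""
    beta = np.radians(angle_deg)
    D = geometry.source_axis_mm
    src_xy = np.array([D * np.cos(beta), D * np.sin(beta)])
    u, w = geometry.element_positions()
    # detector plane passes through the line from source through isocenter
    e_t = np.array([-np.sin(beta), np.cos(beta)])
    det_center = -(geometry.source_detector_mm - D) * src_xy / D
    if geometry.mode == "fan2d":
        pts = det_center[None, :] + u[:, None] * e_t[None, :]
        dirs = pts - src_xy[None, :]
    else:
        pts_xy = det_center[None, None, :] + u[None, :, None] * e_t[None, None, :]
        pts_xy = np.broadcast_to(pts_xy, (w.size, u.size, 2))
        dz = np.broadcast_to(w[:, None], (w.size, u.size))
        dirs = np.concatenate(
            [
                (pts_xy - src_xy[None, None, :]).reshape(-1, 2),
                dz.reshape(-1, 1),
            ],
            axis=1,
        )
        src_xy = np.array([src_xy[0], src_xy[1], 0.0])
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    chords = _chords(spec, src_xy, dirs, module)
    if geometry.mode == "cone3d":
        chords = {m: v.reshape(w.size, u.size) for m, v in chords.items()}
    return chords


# ---------------------------------------------------------------------------
# forward model and noise
# ---------------------------------------------------------------------------


def simulate_pulse(
    paths: dict[str, np.ndarray],
    spectrum: Spectrum,
    mAs_per_pulse: float,
    fluence_scale: float = DEFAULT_FLUENCE_SCALE,
    detector: str = "ei",
):
    """Expected detector signal (I, I0) for one pulse through ``paths`` (cm)."""
    shape = None
    for t in paths.values():
        t = np.asarray(t, float)
        if np.any(t < -1e-9):
            raise ValidationError("negative path length")
        shape = t.shape
    weights = spectrum.fluence * detector_weights(spectrum.energies, detector)
    scale = mAs_per_pulse * fluence_scale
    if shape is None:
        return np.array(scale * weights.sum()), np.array(scale * weights.sum())
    exponent = np.zeros(shape + (spectrum.energies.size,))
    for mat, t in paths.items():
        mu = linear_attenuation(mat, spectrum.energies)
        exponent += np.asarray(t, float)[..., None] * mu
    i = scale * (np.exp(-exponent) @ weights)
    i0 = np.full(shape, scale * weights.sum())
    return i, i0


def add_noise(i: np.ndarray, i0: np.ndarray, seed) -> np.ndarray:
    """Poisson counting noise on the expected signal (reproducible per seed)."""
    if np.any(np.asarray(i) > np.asarray(i0) * (1.0 + 1e-9)):
        raise ValidationError("expected signal cannot exceed the open-field signal")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = rng.poisson(np.asarray(i, float)).astype(float)
    # photon-starved elements: floor at half a count so the log stays finite
    return np.maximum(noisy, 0.5)


def acquire(
    spec: PhantomSpec,
    protocol: ProtocolSpec,
    geometry: Geometry,
    spectrum: Spectrum | None = None,
    seed: int | None = None,
    noise: bool = True,
    module: str = SENSITOMETRY,
    fluence_scale: float = DEFAULT_FLUENCE_SCALE,
    detector: str = "ei",
    filtration_mm_al: float = 2.5,
) -> ProjectionSet:
    """Full noisy log-sinogram of the phantom under one protocol."""
    if spectrum is None:
        spectrum = generate_spectrum(protocol.kvp, filtration_mm_al)
    n = pulse_count(protocol)
    angles = np.arange(n) * protocol.arc_deg / n
    rng = np.random.default_rng(seed) if noise else None

    shape0 = raytrace(spec, geometry, 0.0, module)
    first_mat = next(iter(shape0))
    elem_shape = np.asarray(shape0[first_mat]).shape
    sino = np.empty((n,) + elem_shape)
    for k, ang in enumerate(angles):
        paths = shape0 if k == 0 else raytrace(spec, geometry, ang, module)
        i, i0 = simulate_pulse(
            paths, spectrum, protocol.mAs_per_pulse, fluence_scale, detector
        )
        if rng is not None:
            i = add_noise(i, i0, rng)
        sino[k] = np.log(i0 / i)
    return ProjectionSet(
        angles=angles,
        line_integrals=sino,
        kvp=protocol.kvp,
        mAs_per_pulse=protocol.mAs_per_pulse,
        seed=seed,
        meta={
            "module": module,
            "fluence_scale": fluence_scale,
            "detector": detector,
            "cumulative_mAs": protocol.cumulative_mAs,
            "framerate": protocol.framerate,
        },
    )


def require_paired(p80: ProjectionSet, p140: ProjectionSet) -> None:
    """Dual-energy scans must share trajectory and detector layout."""
    if p80.line_integrals.shape != p140.line_integrals.shape or not np.allclose(
        p80.angles, p140.angles
    ):
        raise PairingError("dual-energy projection sets are not aligned")
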