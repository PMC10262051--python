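"""Synthetic cardiac-gated phase-contrast datasets with known ground truth.

The study this package supports has no deposited scans, so validation runs on
digital phantoms: straight-tube vessels carrying pulsatile laminar flow,
voxelised onto a regular grid the way a 4D phase-contrast acquisition would
sample them, then corrupted with the artefacts the analysis pipeline is meant
to correct — static background phase offsets, Gaussian velocity noise, and
phase wraparound beyond ±venc.

Ground truth
------------
Each vessel carries a volumetric waveform ``Q(t) = mean_flow · [1 +
(pi_target/2) · w(t)]`` with ``w`` a zero-mean shape of peak-to-trough 2, so
the continuous-time pulsatility index (flow_max − flow_min)/flow_mean equals
``pi_target`` exactly.  Discrete sampling at the reconstructed timeframes
shifts the extremes, so :func:`realize_waveform` also reports the *realized*
discrete mean/max/min/PI — the recovery target for the pipeline.

Signal models
-------------
``AcquisitionSpec.signal_model`` selects how a voxel straddling the lumen
boundary averages the analytic velocity field:

* ``"ideal"`` (default): plain volume average over the voxel footprint.
  Flow is conserved exactly — summing voxel velocities × area over any
  perpendicular cross-section reproduces Q(t) to quadrature error — which is
  what the mass-conservation experiments assume.
* ``"complex"``: signal-magnitude-weighted average, emulating how the phase
  of a complex MR voxel is dominated by the bright lumen signal.  Boundary
  voxels then over-report velocity, reproducing the partial-volume flow
  overestimation seen at coarse resolution with threshold masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .geometry import FlowPlane, ObliqueSlice, project_velocity
from .quantify import FlowMetrics, FlowWaveform

__all__ = [
    "WaveformSpec",
    "VesselSpec",
    "AcquisitionSpec",
    "VelocityVolume",
    "RealizedWaveform",
    "realize_waveform",
    "rasterize",
    "corrupt",
    "wrap_phase",
    "simulate_2d",
    "make_straight_vessel",
    "make_circle_of_willis_phantom",
    "COW_INFLOW_NAMES",
    "COW_OUTFLOW_NAMES",
]

#: Systole occupies this fraction of the cardiac cycle in the pulse shape.
SYSTOLIC_FRACTION = 0.3

#: Magnitude contrast between lumen and background tissue (two-level model).
DEFAULT_LUMEN_CONTRAST = 10.0


# --------------------------------------------------------------------------
# Specifications
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class WaveformSpec:
    """Pulsatile volumetric waveform specification.

    ``shape`` is ``"sinusoid"`` (w(φ) = sin 2πφ) or ``"systolic_pulse"``
    (a sin² systolic bump over the first ``SYSTOLIC_FRACTION`` of the cycle,
    recentred to zero mean and scaled to peak-to-trough 2).
    """

    mean_flow: float  # ml/s
    pi_target: float = 0.0
    shape: str = "systolic_pulse"
    n_frames: int = 25
    cycle_duration: float = 1000.0  # ms

    def __post_init__(self) -> None:
        if self.mean_flow <= 0:
            raise ValueError("mean_flow must be positive")
        if self.pi_target < 0:
            raise ValueError("pi_target must be >= 0")
        if self.shape not in ("sinusoid", "systolic_pulse"):
            raise ValueError(f"unknown waveform shape {self.shape!r}")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.cycle_duration <= 0:
            raise ValueError("cycle_duration must be positive")


@dataclass(frozen=True)
class VesselSpec:
    """A straight or polyline tube carrying pulsatile laminar flow."""

    name: str
    centerline: np.ndarray  # (N, 3) points, mm
    radius: float  # mm
    waveform: WaveformSpec
    profile: str = "poiseuille"  # or "plug"

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.centerline, dtype=float))
        object.__setattr__(self, "centerline", pts)
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if pts.shape[0] < 2 or pts.shape[1] != 3:
            raise ValueError("centerline needs >= 2 3D points")
        seg = np.diff(pts, axis=0)
        if np.any(np.linalg.norm(seg, axis=1) == 0):
            raise ValueError("consecutive centerline points must not coincide")
        if self.profile not in ("poiseuille", "plug"):
            raise ValueError(f"unknown profile {self.profile!r}")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition geometry and corruption parameters.

    Defaults follow the study's 4D protocol: 1 mm isotropic voxels, 25
    reconstructed cardiac timeframes, venc 100 cm/s.  ``background_poly``
    holds (b0 [cm/s], b1, b2, b3 [cm/s per mm]) of a static linear phase
    offset b(x, y, z) added to every velocity component.  ``supersample``
    controls the midpoint sub-voxel quadrature (supersample³ samples per
    voxel).
    """

    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    grid_shape: tuple[int, int, int] = (48, 48, 24)
    n_frames: int = 25
    venc: float = 100.0  # cm/s
    noise_sigma: float = 0.0  # cm/s per velocity component
    background_poly: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    supersample: int = 4
    seed: int = 0
    signal_model: str = "ideal"  # or "complex"
    lumen_contrast: float = DEFAULT_LUMEN_CONTRAST

    def __post_init__(self) -> None:
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")
        if self.signal_model not in ("ideal", "complex"):
            raise ValueError(f"unknown signal_model {self.signal_model!r}")
        if self.lumen_contrast <= 1:
            raise ValueError("lumen_contrast must exceed the background level (1)")

    @property
    def frame_duration(self) -> float:
        """Timeframe duration in ms for a nominal 1 s cardiac cycle scaled
        per-vessel waveforms; studies using one cycle duration should derive
        it from the vessel waveform instead."""
        return 1000.0 / self.n_frames


@dataclass
class VelocityVolume:
    """Cardiac-gated three-component velocity field plus magnitude.

    All four arrays are indexed ``[x, y, z, t]``; velocities in cm/s,
    magnitude in arbitrary units (background ≈ 1).  ``affine`` maps 0-based
    voxel indices (voxel-centre convention) to world mm.
    """

    vx: np.ndarray
    vy: np.ndarray
    vz: np.ndarray
    magnitude: np.ndarray
    voxel_size: tuple[float, float, float]
    venc: float
    frame_duration: float  # ms
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.vx, self.vy, self.vz, self.magnitude)}
        if len(shapes) != 1:
            raise ValueError("all four arrays must share one shape")
        if self.vx.ndim != 4:
            raise ValueError("arrays must be [x, y, z, t]")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive")
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size, 1.0])

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.vx.shape

    @property
    def n_frames(self) -> int:
        return self.vx.shape[3]

    def voxel_centers_world(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-mm coordinate axes of voxel centres (diagonal affine only
        gives separable axes; general affines go through ``affine`` direct)."""
        nx, ny, nz, _ = self.shape
        idx = [np.arange(n, dtype=float) for n in (nx, ny, nz)]
        out = []
        for axis, arr in enumerate(idx):
            out.append(arr * self.affine[axis, axis] + self.affine[axis, 3])
        return out[0], out[1], out[2]


@dataclass(frozen=True)
class RealizedWaveform:
    """Ground-truth waveform with its realized discrete summary parameters."""

    waveform: FlowWaveform
    mean_flow: float
    flow_max: float
    flow_min: float
    pi: float

    @property
    def metrics(self) -> FlowMetrics:
        return FlowMetrics(mean_flow=self.mean_flow, flow_max=self.flow_max,
                           flow_min=self.flow_min, pi=self.pi,
                           vessel_name=self.waveform.vessel_name)


# --------------------------------------------------------------------------
# Waveforms
# --------------------------------------------------------------------------


def _shape_function(phase: np.ndarray, shape: str) -> np.ndarray:
    """Zero-mean, peak-to-trough-2 waveform shape w(φ), φ in cycles."""
    phase = np.mod(phase, 1.0)
    if shape == "sinusoid":
        return np.sin(2.0 * np.pi * phase)
    # systolic pulse: sin² bump over the systolic fraction d, zero in
    # diastole; continuous mean d/2, range [0, 1] → 2·(g − d/2) has zero mean
    # and peak-to-trough exactly 2.
    d = SYSTOLIC_FRACTION
    g = np.where(phase < d, np.sin(np.pi * phase / d) ** 2, 0.0)
    return 2.0 * (g - d / 2.0)


def realize_waveform(spec: WaveformSpec, name: str = "") -> RealizedWaveform:
    """Sample the ground-truth waveform at the reconstructed timeframes.

    Frames sample phases k/n_frames, k = 0..n_frames−1 (the frames tile one
    cardiac cycle).  The realized discrete mean/max/min/PI are computed from
    the sampled values; they differ from the continuous targets because the
    discrete grid rarely hits the continuous extremes.

    Raises
    ------
    ValueError
        If the spec produces negative flow at any sampled frame.
    """
    phases = np.arange(spec.n_frames) / spec.n_frames
    q = spec.mean_flow * (1.0 + 0.5 * spec.pi_target * _shape_function(phases, spec.shape))
    if np.any(q < 0):
        raise ValueError(
            f"waveform spec produces negative flow (min {q.min():.3g} ml/s); "
            "reduce pi_target or mean_flow imbalance"
        )
    wf = FlowWaveform(flow=q, frame_duration=spec.cycle_duration / spec.n_frames,
                      vessel_name=name)
    mean, fmax, fmin = float(q.mean()), float(q.max()), float(q.min())
    pi = (fmax - fmin) / mean if mean != 0 else float("nan")
    return RealizedWaveform(waveform=wf, mean_flow=mean, flow_max=fmax, flow_min=fmin, pi=pi)


# --------------------------------------------------------------------------
# Analytic vessel field
# --------------------------------------------------------------------------


def _vessel_profile(points: np.ndarray, vessel: VesselSpec) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the per-unit-flow velocity of ``vessel`` at world points.

    Returns ``(svel, inside)`` where ``svel[i] = s(p_i)·tangent`` is the
    velocity vector (cm/s) at unit flow (1 ml/s), zero outside the lumen.
    The profile is evaluated against the nearest centerline segment whose
    axial projection contains the point.
    """
    pts = points.reshape(-1, 3)
    n = pts.shape[0]
    best_d2 = np.full(n, np.inf)
    best_tan = np.zeros((n, 3))
    cl = vessel.centerline
    for a, b in zip(cl[:-1], cl[1:]):
        d = b - a
        L2 = float(d @ d)
        t = ((pts - a) @ d) / L2
        axial = (t >= 0.0) & (t <= 1.0)
        perp = pts - a - t[:, None] * d
        d2 = np.einsum("ij,ij->i", perp, perp)
        take = axial & (d2 < best_d2)
        best_d2[take] = d2[take]
        best_tan[take] = d / np.sqrt(L2)

    r2 = best_d2
    R = vessel.radius
    inside = r2 <= R * R
    area_cm2 = np.pi * (R / 10.0) ** 2  # lumen area in cm²
    if vessel.profile == "poiseuille":
        s = np.where(inside, (2.0 / area_cm2) * (1.0 - r2 / (R * R)), 0.0)
    else:  # plug
        s = np.where(inside, 1.0 / area_cm2, 0.0)
    svel = s[:, None] * best_tan
    return svel.reshape(points.shape), inside.reshape(points.shape[:-1])


def _subvoxel_offsets(supersample: int) -> np.ndarray:
    """Midpoint offsets (fractions of a voxel) of the supersample³ grid."""
    o = (np.arange(supersample) + 0.5) / supersample - 0.5
    return np.stack(np.meshgrid(o, o, o, indexing="ij"), axis=-1).reshape(-1, 3)


@dataclass
class RasterFields:
    """Precomputed spatial response of a vessel set on an acquisition grid.

    ``numerators[v]`` holds, for vessel ``v``, the (nx, ny, nz, 3) weighted
    mean of its per-unit-flow velocity field; ``denominator`` the weight sum.
    The as-acquired velocity for per-vessel flows Q_v(t) is
    ``Σ_v Q_v(t) · numerators[v] / denominator`` — linear in every Q, so one
    rasterisation serves any number of simulated subjects on the same
    geometry.
    """

    numerators: np.ndarray  # (nvessel, nx, ny, nz, 3)
    denominator: np.ndarray  # (nx, ny, nz)
    lumen_fraction: np.ndarray  # (nx, ny, nz)
    acq: AcquisitionSpec
    vessel_names: tuple[str, ...]


def precompute_fields(vessels: Sequence[VesselSpec], acq: AcquisitionSpec) -> RasterFields:
    """Supersampled voxel response of the analytic vessel fields.

    Raises if a vessel centerline leaves the grid or two lumens overlap
    (overlap makes the per-vessel ground truth ill-posed).
    """
    nx, ny, nz = acq.grid_shape
    vs = np.asarray(acq.voxel_size, dtype=float)
    extent = (np.array([nx, ny, nz]) - 0.5) * vs
    for v in vessels:
        if np.any(v.centerline < -0.5 * vs) or np.any(v.centerline > extent):
            raise ValueError(f"vessel {v.name!r} centerline leaves the grid")

    ax = np.arange(nx) * vs[0]
    ay = np.arange(ny) * vs[1]
    az = np.arange(nz) * vs[2]
    base = np.stack(np.meshgrid(ax, ay, az, indexing="ij"), axis=-1)  # (nx,ny,nz,3)

    nv = len(vessels)
    num = np.zeros((nv, nx, ny, nz, 3))
    den = np.zeros((nx, ny, nz))
    frac = np.zeros((nx, ny, nz))
    contrast = acq.lumen_contrast if acq.signal_model == "complex" else None

    if nv:
        # overlap check at voxel centres
        inside_count = np.zeros((nx, ny, nz), dtype=int)
        for v in vessels:
            _, ins = _vessel_profile(base, v)
            inside_count += ins
        if np.any(inside_count > 1):
            raise ValueError("vessel lumens overlap; ground truth is ill-posed")

    offsets = _subvoxel_offsets(acq.supersample) * vs[None, :]
    for off in offsets:
        pts = base + off[None, None, None, :]
        inside_any = np.zeros((nx, ny, nz), dtype=bool)
        svels = []
        for v in vessels:
            svel, ins = _vessel_profile(pts, v)
            svels.append(svel)
            inside_any |= ins
        w = 1.0 + (contrast - 1.0) * inside_any if contrast is not None else np.ones_like(den)
        den += w
        frac += inside_any
        for vi, svel in enumerate(svels):
            num[vi] += w[..., None] * svel

    n_sub = len(offsets)
    return RasterFields(numerators=num, denominator=den, lumen_fraction=frac / n_sub,
                        acq=acq, vessel_names=tuple(v.name for v in vessels))


def volume_from_fields(
    fields: RasterFields,
    waveforms: Sequence[FlowWaveform],
) -> VelocityVolume:
    """Assemble a clean :class:`VelocityVolume` from cached spatial fields and
    per-vessel flow waveforms (one waveform per rasterised vessel)."""
    acq = fields.acq
    if len(waveforms) != fields.numerators.shape[0]:
        raise ValueError("need exactly one waveform per rasterised vessel")
    n_frames = acq.n_frames
    for w in waveforms:
        if w.n_frames != n_frames:
            raise ValueError("waveform frame count must match the acquisition")

    nx, ny, nz = acq.grid_shape
    vel = np.zeros((nx, ny, nz, 3, n_frames))
    if waveforms:
        q = np.stack([w.flow for w in waveforms])  # (nv, nt)
        # (nv,nx,ny,nz,3) x (nv,nt) -> (nx,ny,nz,3,nt)
        vel = np.einsum("vxyzc,vt->xyzct", fields.numerators, q, optimize=True)
        vel /= fields.denominator[..., None, None]
    mag3 = 1.0 + (DEFAULT_LUMEN_CONTRAST - 1.0) * fields.lumen_fraction
    # magnitude uses the two-level contrast irrespective of the signal model
    mag = np.broadcast_to(mag3[..., None], (nx, ny, nz, n_frames)).copy()
    frame_duration = (waveforms[0].frame_duration if waveforms else 1000.0 / n_frames)
    return VelocityVolume(
        vx=vel[..., 0, :], vy=vel[..., 1, :], vz=vel[..., 2, :], magnitude=mag,
        voxel_size=tuple(acq.voxel_size), venc=acq.venc, frame_duration=frame_duration,
    )


def rasterize(vessels: Sequence[VesselSpec], acq: AcquisitionSpec) -> VelocityVolume:
    """Voxelise analytic vessels onto the acquisition grid (clean, unwrapped).

    Per-vessel waveforms are realized at the acquisition's frame count; each
    voxel averages the analytic velocity field over ``supersample³`` midpoint
    subsamples, weighted per ``acq.signal_model``.  An empty vessel list gives
    an all-zero volume at background magnitude.
    """
    fields = precompute_fields(vessels, acq)
    waveforms = [
        realize_waveform(replace(v.waveform, n_frames=acq.n_frames), name=v.name).waveform
        for v in vessels
    ]
    return volume_from_fields(fields, waveforms)


# --------------------------------------------------------------------------
# Corruption
# --------------------------------------------------------------------------


def wrap_phase(v: np.ndarray, venc: float) -> np.ndarray:
    """Alias velocities into the half-open interval [−venc, +venc).

    ``v_meas = ((v + venc) mod 2·venc) − venc``; the convention makes the
    boundary deterministic (−venc maps to itself, +venc wraps to −venc) and
    wrapping idempotent.  Implemented as ``v − 2·venc·⌊(v + venc)/(2·venc)⌋``
    so in-range values pass through bit-exactly (the floor is zero).
    """
    if venc <= 0:
        raise ValueError("venc must be positive")
    v = np.asarray(v, dtype=float)
    return v - 2.0 * venc * np.floor((v + venc) / (2.0 * venc))


def _magnitude_noise_sigma(acq: AcquisitionSpec) -> float:
    """Magnitude noise consistent with the velocity noise level.

    High-SNR phase-contrast velocity noise is σ_v = (√2/π)·venc/SNR; solving
    for SNR and applying it to the lumen level gives
    σ_mag = lumen_contrast · σ_v · π / (√2 · venc).
    """
    return acq.lumen_contrast * acq.noise_sigma * np.pi / (np.sqrt(2.0) * acq.venc)


def corrupt(volume: VelocityVolume, acq: AcquisitionSpec, seed: int | None = None) -> VelocityVolume:
    """Apply background phase offset, velocity noise and venc wrapping.

    The static linear offset ``b(x,y,z) = b0 + b1·x + b2·y + b3·z`` (world
    mm) is added to every velocity component at every timeframe, then i.i.d.
    Gaussian noise (``noise_sigma`` cm/s per component), then each component
    is wrapped into [−venc, +venc).  Magnitude receives Gaussian noise at the
    SNR implied by ``noise_sigma``.  Bit-reproducible for a fixed seed
    (default ``acq.seed``).
    """
    rng = np.random.default_rng(acq.seed if seed is None else seed)
    b0, b1, b2, b3 = acq.background_poly
    xs, ys, zs = volume.voxel_centers_world()
    bg = (b0 + b1 * xs[:, None, None] + b2 * ys[None, :, None]
          + b3 * zs[None, None, :])[..., None]  # broadcast over t

    out = {}
    for name in ("vx", "vy", "vz"):
        v = getattr(volume, name) + bg
        if acq.noise_sigma > 0:
            v = v + rng.normal(0.0, acq.noise_sigma, size=v.shape)
        out[name] = wrap_phase(v, acq.venc)
    mag = volume.magnitude
    sig_m = _magnitude_noise_sigma(acq)
    if sig_m > 0:
        mag = mag + rng.normal(0.0, sig_m, size=mag.shape)
    return VelocityVolume(
        vx=out["vx"], vy=out["vy"], vz=out["vz"], magnitude=mag,
        voxel_size=volume.voxel_size, venc=acq.venc,
        frame_duration=volume.frame_duration, affine=volume.affine.copy(),
    )


# --------------------------------------------------------------------------
# Direct 2D acquisition
# --------------------------------------------------------------------------


def simulate_2d(
    vessel: VesselSpec,
    plane: FlowPlane,
    acq2d: AcquisitionSpec,
    seed: int | None = None,
) -> ObliqueSlice:
    """Simulate a 2D phase-contrast slice through one vessel.

    The analytic field is sampled directly on the plane grid — no volumetric
    voxelisation — at the 2D acquisition's in-plane pixel size, averaging
    over the slice thickness (``acq2d.voxel_size[2]``) and in-plane pixel
    footprint with ``supersample`` subsamples per axis and the acquisition's
    signal model.  The slice is then corrupted (background offset, noise,
    wrap at the 2D venc) and projected onto the plane normal.
    """
    px = float(acq2d.voxel_size[0])
    thickness = float(acq2d.voxel_size[2])
    plane = plane.with_pixel_size(px)
    pts = plane.pixel_centers()
    n1, n2, _ = pts.shape

    o = (np.arange(acq2d.supersample) + 0.5) / acq2d.supersample - 0.5
    contrast = acq2d.lumen_contrast if acq2d.signal_model == "complex" else None
    num = np.zeros((n1, n2, 3))
    den = np.zeros((n1, n2))
    frac = np.zeros((n1, n2))
    n_sub = 0
    for oa in o:
        for ob in o:
            for oc in o:
                p = (pts + (oa * px) * plane.e1 + (ob * px) * plane.e2
                     + (oc * thickness) * plane.u)
                svel, inside = _vessel_profile(p, vessel)
                w = 1.0 + (contrast - 1.0) * inside if contrast is not None else np.ones((n1, n2))
                num += w[..., None] * svel
                den += w
                frac += inside
                n_sub += 1
    if not frac.any():
        warnings.warn(f"plane misses vessel {vessel.name!r}; slice is all zero")

    spec2d = replace(vessel.waveform, n_frames=acq2d.n_frames)
    realized = realize_waveform(spec2d, name=vessel.name)
    q = realized.waveform.flow  # (nt,)
    svel_mean = num / den[..., None]  # per-unit-flow velocity on pixels
    vel = svel_mean[..., None] * q[None, None, None, :]  # (n1,n2,3,nt)

    rng = np.random.default_rng(acq2d.seed if seed is None else seed)
    b0, b1, b2, b3 = acq2d.background_poly
    bg = (b0 + b1 * pts[..., 0] + b2 * pts[..., 1] + b3 * pts[..., 2])[..., None]
    comps = []
    for c in range(3):
        v = vel[..., c, :] + bg
        if acq2d.noise_sigma > 0:
            v = v + rng.normal(0.0, acq2d.noise_sigma, size=v.shape)
        comps.append(wrap_phase(v, acq2d.venc))
    mag2 = 1.0 + (DEFAULT_LUMEN_CONTRAST - 1.0) * frac / n_sub
    mag = np.broadcast_to(mag2[..., None], (n1, n2, acq2d.n_frames)).copy()
    sig_m = _magnitude_noise_sigma(acq2d)
    if sig_m > 0:
        mag = mag + rng.normal(0.0, sig_m, size=mag.shape)

    slc = ObliqueSlice(
        vx=comps[0], vy=comps[1], vz=comps[2], magnitude=mag, plane=plane,
        frame_duration=realized.waveform.frame_duration, venc=acq2d.venc,
    )
    return project_velocity(slc)


# --------------------------------------------------------------------------
# Phantoms
# --------------------------------------------------------------------------


def make_straight_vessel(
    name: str,
    center_xy: tuple[float, float],
    z_extent: tuple[float, float],
    radius: float,
    waveform: WaveformSpec,
    profile: str = "poiseuille",
) -> VesselSpec:
    """A straight tube along +z at in-plane position ``center_xy`` (mm)."""
    x, y = center_xy
    z0, z1 = z_extent
    return VesselSpec(
        name=name,
        centerline=np.array([[x, y, z0], [x, y, z1]]),
        radius=radius,
        waveform=waveform,
        profile=profile,
    )


COW_INFLOW_NAMES = ("ICA_L", "ICA_R", "BA")
COW_OUTFLOW_NAMES = ("MCA_L", "MCA_R", "ACA_L", "ACA_R", "PCA_L", "PCA_R")

# (radius mm, mean flow ml/s) — sizes typical of the circle of Willis; the
# three inflow means sum to 7.0 ml/s, as do the six outflow means.
_COW_GEOMETRY = {
    "ICA_L": (2.1, 2.5),
    "ICA_R": (2.1, 2.5),
    "BA": (1.7, 2.0),
    "MCA_L": (1.4, 1.4),
    "MCA_R": (1.4, 1.4),
    "ACA_L": (1.2, 0.9),
    "ACA_R": (1.2, 0.9),
    "PCA_L": (1.2, 1.2),
    "PCA_R": (1.2, 1.2),
}


def make_circle_of_willis_phantom(
    seed: int = 0,
    *,
    n_frames: int = 25,
    pi_target: float = 0.9,
    z_extent: tuple[float, float] = (0.0, 23.0),
    spacing: float = 13.0,
    jitter_mm: float = 1.0,
) -> list[VesselSpec]:
    """Nine parallel straight tubes balancing inflow against cerebral outflow.

    Two carotid-like and one basilar-like inflow (mean flows 2.5, 2.5,
    2.0 ml/s) against six cerebral-artery-like outflows summing to the same
    7.0 ml/s.  All vessels share one waveform shape and pulsatility target,
    so the ground-truth waveforms conserve mass at *every* timeframe, not
    just on average.  Tube positions sit on a 3×3 grid with a seeded sub-mm
    jitter; the same seed reproduces the same specs bit-for-bit.
    """
    rng = np.random.default_rng(seed)
    names = list(_COW_GEOMETRY)
    vessels = []
    for i, name in enumerate(names):
        radius, mean_flow = _COW_GEOMETRY[name]
        gx, gy = divmod(i, 3)
        jx, jy = rng.uniform(-jitter_mm, jitter_mm, size=2)
        center = (spacing * (gx + 0.75) + jx, spacing * (gy + 0.75) + jy)
        wf = WaveformSpec(mean_flow=mean_flow, pi_target=pi_target,
                          shape="systolic_pulse", n_frames=n_frames)
        vessels.append(make_straight_vessel(name, center, z_extent, radius, wf))
    return vessels


def cow_acquisition(**overrides) -> AcquisitionSpec:
    """Acquisition grid that fits the circle-of-Willis phantom at 1 mm."""
    defaults = dict(voxel_size=(1.0, 1.0, 1.0), grid_shape=(40, 40, 24),
                    n_frames=25, venc=100.0)
    defaults.update(overrides)
    return AcquisitionSpec(**defaults)
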