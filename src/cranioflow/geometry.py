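"""Vessel-perpendicular plane extraction from cardiac-gated velocity volumes.

A 4D phase-contrast acquisition stores three velocity components on a regular
3D grid for each cardiac timeframe.  Flow through a vessel is quantified on a
plane perpendicular to the vessel axis: this module constructs such planes
(:class:`FlowPlane`), resamples the velocity components and the magnitude
image onto the plane grid by trilinear interpolation (:func:`extract_slice`),
and projects the interpolated velocity vectors onto the vessel direction
(:func:`project_velocity`), i.e. ``v_parallel = v · u`` with ``u`` the unit
vector along the vessel.

Conventions
-----------
* World coordinates are in mm, obtained from voxel indices through the NIfTI
  affine; voxel indices are 0-based and refer to voxel centres.
* Velocities are in cm/s throughout.
* The in-plane basis is deterministic and right-handed: ``e1 × e2 = u``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np
from scipy.ndimage import map_coordinates

if TYPE_CHECKING:  # pragma: no cover - import only for type checkers
    from .synth import VelocityVolume

__all__ = ["FlowPlane", "ObliqueSlice", "plane_basis", "extract_slice", "project_velocity"]

_ORTHO_TOL = 1e-9


def plane_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic right-handed orthonormal in-plane basis for direction ``u``.

    The reference vector is the world z-axis unless ``u`` is closer than
    ~25 degrees to it (``|u·ẑ| > 0.9``), in which case the world x-axis is
    used; then ``e1 = normalize(r × u)`` and ``e2 = u × e1``.

    Parameters
    ----------
    u : (3,) array_like
        Direction along the vessel; need not be normalised.

    Returns
    -------
    (e1, e2) : pair of (3,) ndarrays
        Unit vectors spanning the plane, with ``e1 × e2 = u / |u|``.
    """
    u = np.asarray(u, dtype=float)
    norm = np.linalg.norm(u)
    if norm == 0 or not np.isfinite(norm):
        raise ValueError("plane direction must be a non-zero finite vector")
    u = u / norm
    r = np.array([0.0, 0.0, 1.0])
    if abs(u @ r) > 0.9:
        r = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(r, u)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


@dataclass(frozen=True)
class FlowPlane:
    """A vessel-perpendicular sampling plane.

    Attributes
    ----------
    origin : (3,) ndarray
        Plane centre in world mm.
    u : (3,) ndarray
        Unit vector along the vessel (the plane normal).
    e1, e2 : (3,) ndarray
        Orthonormal in-plane basis, right-handed with ``u``.
    fov : (2,) ndarray
        In-plane field of view (width along ``e1``, height along ``e2``), mm.
    pixel_size : float
        Plane pixel spacing in mm (square pixels).
    name : str
        Optional vessel label.
    """

    origin: np.ndarray
    u: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    fov: np.ndarray
    pixel_size: float
    name: str = ""

    def __post_init__(self) -> None:
        for attr in ("origin", "u", "e1", "e2"):
            object.__setattr__(self, attr, np.asarray(getattr(self, attr), dtype=float))
        object.__setattr__(self, "fov", np.asarray(self.fov, dtype=float))
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if np.any(self.fov <= 0):
            raise ValueError("fov must be positive")
        for v, name in ((self.u, "u"), (self.e1, "e1"), (self.e2, "e2")):
            if abs(np.linalg.norm(v) - 1.0) > _ORTHO_TOL:
                raise ValueError(f"{name} must be a unit vector")
        for a, b, name in (
            (self.u, self.e1, "u·e1"),
            (self.u, self.e2, "u·e2"),
            (self.e1, self.e2, "e1·e2"),
        ):
            if abs(float(a @ b)) > _ORTHO_TOL:
                raise ValueError(f"basis not orthogonal: {name} != 0")

    @classmethod
    def from_direction(
        cls,
        origin,
        direction,
        fov=(12.0, 12.0),
        pixel_size: float = 0.5,
        name: str = "",
    ) -> "FlowPlane":
        """Build a plane from a centre point and a (non-unit) direction vector."""
        direction = np.asarray(direction, dtype=float)
        u = direction / np.linalg.norm(direction)
        e1, e2 = plane_basis(u)
        return cls(origin=np.asarray(origin, float), u=u, e1=e1, e2=e2,
                   fov=np.asarray(fov, float), pixel_size=float(pixel_size), name=name)

    @property
    def shape(self) -> tuple[int, int]:
        """Plane grid shape ``(n1, n2)`` implied by fov and pixel size."""
        n1 = max(2, int(round(self.fov[0] / self.pixel_size)))
        n2 = max(2, int(round(self.fov[1] / self.pixel_size)))
        return n1, n2

    def pixel_centers(self) -> np.ndarray:
        """World coordinates (mm) of all pixel centres, shape ``(n1, n2, 3)``.

        Pixel (i, j) sits at ``origin + (i - ci)·px·e1 + (j - cj)·px·e2`` with
        the grid centred on the origin.
        """
        n1, n2 = self.shape
        ci, cj = (n1 - 1) / 2.0, (n2 - 1) / 2.0
        a = (np.arange(n1) - ci) * self.pixel_size
        b = (np.arange(n2) - cj) * self.pixel_size
        return (
            self.origin[None, None, :]
            + a[:, None, None] * self.e1[None, None, :]
            + b[None, :, None] * self.e2[None, None, :]
        )

    def with_pixel_size(self, pixel_size: float) -> "FlowPlane":
        return replace(self, pixel_size=float(pixel_size))


@dataclass
class ObliqueSlice:
    """Velocity components and magnitude resampled onto a :class:`FlowPlane`.

    Arrays are indexed ``[i, j, t]`` (plane pixel, timeframe), velocities in
    cm/s.  ``v_parallel`` is filled by :func:`project_velocity`.  ``inbounds``
    flags plane pixels whose world position fell inside the source volume;
    out-of-bounds pixels are zero-filled, mirroring clipped clinical volumes.
    """

    vx: np.ndarray
    vy: np.ndarray
    vz: np.ndarray
    magnitude: np.ndarray
    plane: FlowPlane
    frame_duration: float
    venc: float | None = None
    v_parallel: np.ndarray | None = None
    inbounds: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.vx, self.vy, self.vz, self.magnitude)}
        if len(shapes) != 1:
            raise ValueError("velocity and magnitude arrays must share one shape")
        if self.vx.ndim != 3:
            raise ValueError("slice arrays must be [i, j, t]")
        if self.inbounds is None:
            self.inbounds = np.ones(self.vx.shape[:2], dtype=bool)
        if self.v_parallel is not None and self.v_parallel.shape != self.vx.shape:
            raise ValueError("v_parallel shape must match component shapes")

    @property
    def pixel_area(self) -> float:
        """Plane pixel area in mm^2."""
        return float(self.plane.pixel_size) ** 2

    @property
    def n_frames(self) -> int:
        return self.vx.shape[2]


def extract_slice(volume: "VelocityVolume", plane: FlowPlane) -> ObliqueSlice:
    """Resample a velocity volume onto a plane by trilinear interpolation.

    Each velocity component and the magnitude image are interpolated
    independently at every plane pixel centre for every timeframe; components
    are interpolated *before* any projection so the slice stays reusable for
    other directions.  Pixels outside the volume are flagged in
    ``slice.inbounds`` and set to zero.

    Raises
    ------
    ValueError
        If the plane lies entirely outside the volume.
    """
    pts = plane.pixel_centers()  # (n1, n2, 3) world mm
    n1, n2, _ = pts.shape
    inv = np.linalg.inv(volume.affine)
    homo = np.concatenate([pts.reshape(-1, 3), np.ones((n1 * n2, 1))], axis=1)
    vox = (homo @ inv.T)[:, :3]  # fractional voxel indices, centre convention

    nx, ny, nz, nt = volume.vx.shape
    upper = np.array([nx - 1, ny - 1, nz - 1], dtype=float)
    inb = np.all((vox >= 0.0) & (vox <= upper[None, :]), axis=1).reshape(n1, n2)
    if not inb.any():
        raise ValueError("plane lies entirely outside the volume")

    # one interpolation call per component: spatial coords are trilinear,
    # the timeframe coordinate is an exact integer so no temporal blending
    npts = n1 * n2
    coords4 = np.empty((4, npts * nt))
    coords4[:3] = np.repeat(vox.T, nt, axis=1)
    coords4[3] = np.tile(np.arange(nt, dtype=float), npts)
    out = {}
    for name in ("vx", "vy", "vz", "magnitude"):
        src = getattr(volume, name)
        sampled = map_coordinates(src, coords4, order=1, mode="constant", cval=0.0)
        dst = sampled.reshape(n1, n2, nt)
        dst[~inb, :] = 0.0
        out[name] = dst

    return ObliqueSlice(
        vx=out["vx"], vy=out["vy"], vz=out["vz"], magnitude=out["magnitude"],
        plane=plane, frame_duration=volume.frame_duration, venc=volume.venc,
        inbounds=inb,
    )


def project_velocity(slc: ObliqueSlice) -> ObliqueSlice:
    """Fill ``v_parallel = v · u``, the through-plane velocity component.

    The projection is linear and uses the plane's unit vessel direction; it is
    applied after interpolation (the two orders are identical for a constant
    ``u``).  Returns the same slice object for chaining.
    """
    u = slc.plane.u
    slc.v_parallel = slc.vx * u[0] + slc.vy * u[1] + slc.vz * u[2]
    return slc
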