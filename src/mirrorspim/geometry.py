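"""Mirror-reflection transforms, stage-scan deskew and frame rotations.

The mirror lies in the plane ``z = -x tan(theta)`` through the physical
origin. Reflection across it maps a point (x, y, z) to

    (x cos 2θ - z sin 2θ,  y,  -z cos 2θ - x sin 2θ).

At θ = 45° and equal x/z pitch this is an exact on-grid index remap (an
involution); at other angles the volume is resampled by spline interpolation
with zero fill outside the grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import Volume

__all__ = [
    "MirrorGeometry",
    "CoordinateFrame",
    "reflect_volume",
    "reflect_array",
    "deskew_stage_scan",
    "rotate_to_coverslip",
    "view_separation_angle",
]


@dataclass(frozen=True)
class MirrorGeometry:
    """Reflective coverslip: plane ``z = -x tan(theta_deg)`` through the origin."""

    theta_deg: float = 45.0
    reflectivity: float = 1.0

    def __post_init__(self):
        if not 0 < self.theta_deg < 90:
            raise ValueError("theta_deg must lie in (0, 90)")
        if not 0 < self.reflectivity <= 1:
            raise ValueError("reflectivity must lie in (0, 1]")

    @property
    def theta_rad(self) -> float:
        return math.radians(self.theta_deg)

    def side(self, x: np.ndarray, z: np.ndarray) -> np.ndarray:
        """True on/above the mirror (the real half-space, z >= -x tanθ)."""
        return z >= -x * math.tan(self.theta_rad)


@dataclass(frozen=True)
class CoordinateFrame:
    """A named rigid frame, stored as a 4x4 homogeneous map to the fixed frame."""

    name: str
    transform: tuple = tuple(map(tuple, np.eye(4)))

    def matrix(self) -> np.ndarray:
        m = np.asarray(self.transform, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("transform must be a 4x4 homogeneous matrix")
        inv = np.linalg.inv(m)
        if not np.allclose(m @ inv, np.eye(4), atol=1e-9):
            raise ValueError("transform is not invertible to 1e-9")
        return m


def _is_exact_reflection(vol: Volume, theta_deg: float) -> bool:
    pz, _, px = vol.pitch
    oz, _, ox = vol.origin
    return (
        math.isclose(theta_deg, 45.0, abs_tol=1e-12)
        and math.isclose(pz, px, rel_tol=1e-12)
        and math.isclose((oz + ox) % 1.0, 0.0, abs_tol=1e-9)
        or math.isclose(theta_deg, 45.0, abs_tol=1e-12)
        and math.isclose(pz, px, rel_tol=1e-12)
        and math.isclose((oz + ox) % 1.0, 1.0, abs_tol=1e-9)
    )


def reflect_array(
    data: np.ndarray,
    pitch: tuple[float, float, float],
    origin: tuple[float, float, float],
    theta_deg: float = 45.0,
    order: int = 1,
) -> np.ndarray:
    """Reflection of a raw (z, y, x) array across ``z = -x tan(theta)``."""
    vol = Volume(data, pitch, origin)
    return _reflect(vol, theta_deg, order)


def _reflect(vol: Volume, theta_deg: float, order: int) -> np.ndarray:
    data = np.asarray(vol.data)
    nz, ny, nx = data.shape
    oz, oy, ox = vol.origin
    if _is_exact_reflection(vol, theta_deg):
        s = int(round(oz + ox))
        out = np.zeros_like(data)
        iz = np.arange(nz)[:, None]
        ix = np.arange(nx)[None, :]
        src_z = s - ix  # input z index feeding out[iz, :, ix]
        src_x = s - iz
        valid = (src_z >= 0) & (src_z < nz) & (src_x >= 0) & (src_x < nx)
        vz, vx = np.broadcast_arrays(src_z, src_x)
        izb, ixb = np.broadcast_arrays(iz, ix)
        out[izb[valid], :, ixb[valid]] = data[vz[valid], :, vx[valid]]
        return out

    # general angle: resample with an affine map in physical coordinates
    two = math.radians(2.0 * theta_deg)
    c2, s2 = math.cos(two), math.sin(two)
    # physical (x, z) reflection matrix applied to output coords gives input coords
    # x_in = x c2 - z s2 ; z_in = -z c2 - x s2
    pz, py, px = vol.pitch
    mat = np.zeros((3, 3))
    mat[1, 1] = 1.0
    # index-space map: i_in = o + P^-1 R P (i_out - o), axes ordered (z, y, x)
    mat[0, 0] = -c2
    mat[0, 2] = -s2 * px / pz
    mat[2, 0] = -s2 * pz / px
    mat[2, 2] = c2
    offset = np.array([oz, oy, ox]) - mat @ np.array([oz, oy, ox])
    out = ndimage.affine_transform(
        data, mat, offset=offset, order=order, mode="grid-constant", cval=0.0,
        prefilter=order > 1,
    )
    if order > 1:
        np.maximum(out, 0.0, out=out)  # spline ringing must not inject negatives
    return out


def reflect_volume(vol: Volume, mirror: MirrorGeometry, order: int = 1) -> Volume:
    """Resample ``vol`` at mirror-reflected coordinates (zero fill outside)."""
    return vol.with_data(_reflect(vol, mirror.theta_deg, order))


def deskew_stage_scan(
    planes: np.ndarray,
    step_um: float,
    theta_deg: float,
    pixel_um: tuple[float, float],
    pad: bool = True,
) -> Volume:
    """Convert a stage-scanned stack to light-sheet-scanning geometry.

    Plane ``k`` (acquired at stage offset k·δ) is shifted laterally by
    ``k·δ`` along x′; the axial coupling ξ = δ·tan(θ) becomes the plane
    spacing of the returned volume. Sub-voxel shifts use linear
    interpolation. With ``pad=True`` the x′ axis is zero-padded so no mass
    leaves the grid (per-plane sums are conserved exactly); otherwise a shift
    exceeding the grid raises an error naming the required pad.
    """
    planes = np.asarray(planes, dtype=float)
    if planes.ndim != 3:
        raise ValueError("expected a (n_steps, ny, nx) stack")
    if step_um < 0:
        raise ValueError("step_um must be >= 0")
    n_steps, ny, nx = planes.shape
    py, px = pixel_um
    max_shift = step_um * (n_steps - 1) / px
    if step_um == 0:
        out = planes.copy()
    else:
        need = int(math.ceil(max_shift))
        if pad:
            out = np.zeros((n_steps, ny, nx + need))
            work = np.concatenate([planes, np.zeros((n_steps, ny, need))], axis=2)
        else:
            if max_shift > 0:
                raise ValueError(
                    f"deskew shift of {max_shift:.1f} px exceeds the grid; "
                    f"pad x' by at least {need} pixels"
                )
            out = planes.copy()
            work = planes
        for k in range(n_steps):
            out[k] = ndimage.shift(
                work[k], (0.0, k * step_um / px), order=1, mode="grid-constant", cval=0.0
            )
    xi = step_um * math.tan(math.radians(theta_deg))
    pitch_z = xi if xi > 0 else px
    return Volume(out, (pitch_z, py, px), None, frame="camera_primed")


def rotate_to_coverslip(vol: Volume, tilt_deg: float, order: int = 1) -> Volume:
    """Rigid rotation about y′ by ``tilt_deg`` into the coverslip frame."""
    if tilt_deg == 0:
        out = vol.data.copy()
    else:
        out = ndimage.rotate(
            vol.data, tilt_deg, axes=(0, 2), reshape=False, order=order,
            mode="grid-constant", cval=0.0,
        )
        if order > 1:
            np.maximum(out, 0.0, out=out)
    return Volume(out, vol.pitch, vol.origin, frame="coverslip")


def view_separation_angle(tilt_deg: float) -> float:
    """Angle (degrees) between a detection axis tilted ``tilt_deg`` from the
    mirror normal and its mirror image: 180 - 2·tilt."""
    if not 0 <= tilt_deg < 90:
        raise ValueError("tilt_deg must lie in [0, 90)")
    return 180.0 - 2.0 * tilt_deg
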