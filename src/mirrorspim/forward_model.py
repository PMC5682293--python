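"""The shift-varying imaging operator of reflective light-sheet microscopy.

A camera looks down the fixed z axis; the mirrored coverslip lies in the
plane ``z = -x tan(theta)``. The measurement at stage/illumination offset δ is

    u(x', y', δ) = ∭ f̃(x,y,z) · I(x-δ, y, z+δ tanθ) · h(x-x', y-y', z+δ tanθ) dx dy dz

where f̃ is the object plus its (reflectivity-weighted) mirror image, I the
crossed-sheet illumination (incident sheet + its specular reflection + both
mirror images) and h the detection PSF focused at ``z = -δ tanθ``.

Per offset δ this is one 3D convolution of the illuminated object with h,
evaluated at the focal plane only; the transpose embeds a measured plane at
the focal depth, convolves with the flipped PSF and weights by the shifted
illumination. Both are implemented with zero-padded FFTs; the focal-plane
extraction/embedding is done in the Fourier domain so each stage step costs a
single 3D transform pair. An instrumented counter tallies these 3D
convolutions so algorithmic cost accounting can be audited.

Stage offsets are chosen so focal planes land exactly on grid planes
(ξ = δ tanθ equal to the z pitch), avoiding focal interpolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft

from .geometry import MirrorGeometry, reflect_array
from .optics import PSF, LightSheetSpec
from .volume import GridSpec, Volume

__all__ = [
    "AcquisitionPlan",
    "CameraStack",
    "ConvCounter",
    "ImagingOperator",
    "ReflectedOperator",
    "AxisSwappedOperator",
    "extended_object",
    "illumination_pattern",
    "simulate_acquisition",
    "dense_operator",
]


class ObjectBelowMirrorError(ValueError):
    """The physical object must live entirely on/above the mirror plane."""


@dataclass
class ConvCounter:
    """Tally of FFT convolutions executed by operators sharing this counter."""

    n3d: int = 0
    n2d: int = 0

    def reset(self) -> None:
        self.n3d = 0
        self.n2d = 0


@dataclass(frozen=True)
class AcquisitionPlan:
    """Stage-scanning plan.

    ``focal_indices`` are the z grid planes hit by the detection focus; the
    stage offsets δ follow from ``z_f = -δ tanθ``. ``n_steps`` defaults to one
    step per grid plane.
    """

    step_um: float
    n_steps: int
    views: tuple[str, ...] = ("A",)
    shutter_mode: str = "global"
    noise: str = "none"
    seed: int | None = None
    focal_indices: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.step_um <= 0:
            raise ValueError("step_um must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.shutter_mode not in ("global", "rolling_slit"):
            raise ValueError("shutter_mode must be 'global' or 'rolling_slit'")
        if self.noise not in ("none", "poisson"):
            raise ValueError("noise must be 'none' or 'poisson'")
        if self.noise == "poisson" and self.seed is None:
            raise ValueError("poisson noise requires a recorded seed")
        if self.focal_indices is not None and len(self.focal_indices) != self.n_steps:
            raise ValueError("focal_indices length must equal n_steps")

    @classmethod
    def full_coverage(cls, grid: GridSpec, theta_deg: float, **kw) -> "AcquisitionPlan":
        """One stage step per z plane; δ chosen so ξ = δ tanθ equals the z pitch."""
        step = grid.pitch[0] / math.tan(math.radians(theta_deg))
        return cls(step_um=step, n_steps=grid.shape[0],
                   focal_indices=tuple(range(grid.shape[0])), **kw)


@dataclass
class CameraStack:
    """2D camera images u(x', y', δ) indexed by stage offset."""

    planes: np.ndarray  # (n_steps, ny, nx)
    pixel_um: tuple[float, float]
    focal_indices: tuple[int, ...]
    step_um: float
    camera: str = "A"

    def __post_init__(self):
        self.planes = np.asarray(self.planes)
        if self.planes.ndim != 3:
            raise ValueError("CameraStack planes must be (n_steps, ny, nx)")
        if np.any(self.planes < 0):
            raise ValueError("camera data must be nonnegative")

    @property
    def n_steps(self) -> int:
        return self.planes.shape[0]

    def as_volume(self, grid: GridSpec) -> Volume:
        """Reinterpret the stack as a fixed-frame volume (full-coverage plans
        whose focal plane k is grid plane k)."""
        if self.focal_indices != tuple(range(grid.shape[0])):
            raise ValueError("stack does not cover the grid plane-per-plane")
        return Volume(self.planes, grid.pitch, grid.origin, frame="fixed")


def extended_object(f: Volume, mirror: MirrorGeometry, atol: float = 1e-9) -> Volume:
    """Object plus its reflectivity-weighted mirror image (f̃ of the model).

    ``f`` must be physical, i.e. carry no mass strictly below the mirror.
    """
    x = f.coords(2)[None, None, :]
    z = f.coords(0)[:, None, None]
    above = np.broadcast_to(mirror.side(x, z), f.shape)
    below_mass = float(f.data[~above].sum())
    total = float(f.data.sum())
    if below_mass > atol * max(total, 1.0):
        raise ObjectBelowMirrorError(
            f"object has mass {below_mass:.3e} below the mirror plane"
        )
    reflected = reflect_array(f.data, f.pitch, f.origin, mirror.theta_deg)
    return f.with_data(f.data + mirror.reflectivity * reflected)


def _sheet_gaussian(arg: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * (arg / sigma) ** 2)


def illumination_pattern(
    sheet: LightSheetSpec, mirror: MirrorGeometry, grid: GridSpec
) -> Volume:
    """Total illumination I = I1 + I2 + I3 + I4 at zero stage offset.

    I1 is the incident Gaussian sheet lying in the detection focal plane
    (z = 0) with its waist at the mirror, I2 its specular reflection, and
    I3/I4 their virtual mirror images; by construction the sum is symmetric
    under reflection across the mirror.
    """
    x = grid.coords(2)[None, None, :]
    z = grid.coords(0)[:, None, None]
    arr = _illumination_weight(x, z, 0.0, sheet, mirror)
    arr = np.broadcast_to(arr, grid.shape).copy()
    return Volume(arr, grid.pitch, grid.origin)


def _illumination_weight(
    x: np.ndarray, z: np.ndarray, z_focal_um: float,
    sheet: LightSheetSpec, mirror: MirrorGeometry,
) -> np.ndarray:
    """Shifted illumination I(x-δ, y, z+δ tanθ) on the (z, 1, x) grid.

    In the shifted pattern the incident sheet is the plane z = z_f (always in
    focus) and the reflected sheet its mirror image; below the mirror the
    sheet roles swap, which keeps the pattern reflection-symmetric for any
    reflectivity.
    """
    sigma = sheet.sigma_um
    theta = mirror.theta_rad
    two = 2.0 * theta
    s1 = _sheet_gaussian(z - z_focal_um, sigma)
    s2 = _sheet_gaussian(x * math.sin(two) + z * math.cos(two) + z_focal_um, sigma)
    r = mirror.reflectivity
    if r == 1.0:
        return s1 + s2
    above = mirror.side(x, z)
    return np.where(above, s1 + r * s2, s2 + r * s1)


class ImagingOperator:
    """Forward (M) and transpose (Mᵀ) actions of the reflective imaging model.

    Parameters
    ----------
    psf : detection PSF (odd-shaped kernel, unit sum). Use
        :func:`mirrorspim.optics.slit_effective_psf` for rolling-shutter mode.
    sheet : light-sheet spec, or None for spatially uniform illumination
        (the shift-invariant limit).
    mirror : mirror geometry (houses θ and the reflectivity).
    grid : object-space sampling grid.
    plan : acquisition plan; defaults to full plane-per-plane coverage.
    """

    def __init__(
        self,
        psf: PSF,
        sheet: LightSheetSpec | None,
        mirror: MirrorGeometry,
        grid: GridSpec,
        plan: AcquisitionPlan | None = None,
        dtype=np.float64,
        counter: ConvCounter | None = None,
    ):
        if tuple(psf.pitch) != tuple(grid.pitch):
            raise ValueError("PSF pitch must match the object grid pitch")
        self.psf = psf
        self.sheet = sheet
        self.mirror = mirror
        self.grid = grid
        self.plan = plan or AcquisitionPlan.full_coverage(grid, mirror.theta_deg)
        self.dtype = np.dtype(dtype)
        self.counter = counter or ConvCounter()

        nz, ny, nx = grid.shape
        if self.plan.focal_indices is not None:
            self.focal_indices = tuple(self.plan.focal_indices)
        else:
            self.focal_indices = tuple(range(self.plan.n_steps))
        if any(not 0 <= k < nz for k in self.focal_indices):
            raise ValueError("focal plane outside the grid")

        kernel = np.asarray(psf.kernel, dtype=self.dtype)
        if any(s % 2 == 0 for s in kernel.shape):
            raise ValueError("PSF kernel must have odd shape")
        self._kshape = kernel.shape
        self._pad = tuple(
            sfft.next_fast_len(n + k - 1) for n, k in zip(grid.shape, kernel.shape)
        )
        self._crop = tuple((k - 1) // 2 for k in kernel.shape)
        ctype = np.complex64 if self.dtype == np.float32 else np.complex128
        self._Hf = sfft.rfftn(kernel, self._pad).astype(ctype)
        self._Hb = sfft.rfftn(kernel[::-1, ::-1, ::-1], self._pad).astype(ctype)

        theta = mirror.theta_rad
        zc = grid.coords(0)
        self._zf_um = {k: zc[k] for k in set(self.focal_indices)}
        self._delta_um = {k: -self._zf_um[k] / math.tan(theta) for k in self._zf_um}
        self._x = grid.coords(2)[None, None, :]
        self._z = zc[:, None, None]
        self._weights: dict[int, np.ndarray] = {}
        self._normalization: Volume | None = None

    # -- illumination ------------------------------------------------------

    def delta_for(self, focal_index: int) -> float:
        """Stage offset δ (um) whose focal plane is grid plane ``focal_index``."""
        return self._delta_um[focal_index]

    def illumination_weight(self, focal_index: int) -> np.ndarray:
        """Shifted illumination for the given focal plane, broadcastable (nz,1,nx)."""
        if self.sheet is None:
            return np.ones((1, 1, 1), dtype=self.dtype)
        w = self._weights.get(focal_index)
        if w is None:
            w = _illumination_weight(
                self._x, self._z, self._zf_um[focal_index], self.sheet, self.mirror
            ).astype(self.dtype)
            self._weights[focal_index] = w
        return w

    # -- core FFT plumbing -------------------------------------------------

    def _forward_plane(self, F: np.ndarray, k: int) -> np.ndarray:
        """One 3D convolution with h, evaluated at focal plane k only."""
        nz, ny, nx = self.grid.shape
        Sz, Sy, Sx = self._pad
        G = F * self.illumination_weight(k)
        Ghat = sfft.rfftn(G, self._pad)
        Ghat *= self._Hf
        # inverse DFT along z evaluated at the single full-conv index k + crop_z
        m = np.arange(Sz)
        phase = np.exp(2j * np.pi * m * ((k + self._crop[0]) / Sz)) / Sz
        plane_hat = np.tensordot(phase, Ghat, axes=(0, 0))
        plane = sfft.irfftn(plane_hat, s=(Sy, Sx))
        self.counter.n3d += 1
        cy, cx = self._crop[1], self._crop[2]
        return plane[cy:cy + ny, cx:cx + nx]

    def _transpose_plane(self, r_plane: np.ndarray, k: int) -> np.ndarray:
        """Adjoint of :meth:`_forward_plane`: embed at plane k, convolve with
        the flipped PSF, weight by the shifted illumination."""
        nz, ny, nx = self.grid.shape
        Sz, Sy, Sx = self._pad
        Rhat2 = sfft.rfftn(np.asarray(r_plane, dtype=self.dtype), s=(Sy, Sx))
        m = np.arange(Sz)
        phase = np.exp(-2j * np.pi * m * (k / Sz))
        Xhat = phase[:, None, None] * Rhat2[None, :, :]
        Xhat *= self._Hb
        B = sfft.irfftn(Xhat, s=self._pad)
        self.counter.n3d += 1
        cz, cy, cx = self._crop
        B = B[cz:cz + nz, cy:cy + ny, cx:cx + nx]
        return self.illumination_weight(k) * B

    # -- public operator actions ------------------------------------------

    def forward_plane(self, F: Volume | np.ndarray, focal_index: int) -> np.ndarray:
        """M_δ action: the camera image for one stage offset."""
        arr = F.data if isinstance(F, Volume) else np.asarray(F)
        if arr.shape != self.grid.shape:
            raise ValueError("estimate shape does not match the operator grid")
        return self._forward_plane(arr.astype(self.dtype, copy=False), focal_index)

    def forward(self, F: Volume | np.ndarray) -> np.ndarray:
        """Full forward action M F̂: stack of camera planes over the plan."""
        arr = F.data if isinstance(F, Volume) else np.asarray(F)
        arr = arr.astype(self.dtype, copy=False)
        nz, ny, nx = self.grid.shape
        out = np.empty((len(self.focal_indices), ny, nx), dtype=self.dtype)
        for i, k in enumerate(self.focal_indices):
            out[i] = self._forward_plane(arr, k)
        return out

    def transpose(self, planes: np.ndarray) -> np.ndarray:
        """Transpose action Mᵀ on a stack of camera planes."""
        planes = np.asarray(planes, dtype=self.dtype)
        if planes.shape[0] != len(self.focal_indices):
            raise ValueError("plane count does not match the acquisition plan")
        acc = np.zeros(self.grid.shape, dtype=self.dtype)
        for i, k in enumerate(self.focal_indices):
            acc += self._transpose_plane(planes[i], k)
        return acc

    @property
    def normalization(self) -> Volume:
        """Sensitivity image V = Mᵀ 1 (cached)."""
        if self._normalization is None:
            ny, nx = self.grid.shape[1], self.grid.shape[2]
            ones = np.ones((len(self.focal_indices), ny, nx), dtype=self.dtype)
            n_before = self.counter.n3d
            V = self.transpose(ones)
            self.counter.n3d = n_before  # setup cost, not part of iteration audit
            self._normalization = Volume(V, self.grid.pitch, self.grid.origin)
        return self._normalization

    def stack(self, planes: np.ndarray, camera: str = "A") -> CameraStack:
        return CameraStack(
            planes, (self.grid.pitch[1], self.grid.pitch[2]),
            self.focal_indices, self.plan.step_um, camera,
        )


class ReflectedOperator:
    """The complementary-view operator M₂ = R ∘ M₁ ∘ R.

    The virtual view U₂ = R U₁ of a mirror-symmetric extended object obeys
    U₂ = (R M₁ R) f̃, so the second view's operator is the base operator
    conjugated by the mirror reflection; its PSF is thereby the reflected
    (complementary-orientation) detection PSF. Exact at θ = 45°; at other
    angles R resamples by interpolation and Rᵀ is approximated by R.
    """

    def __init__(self, base: ImagingOperator, order: int = 1):
        self.base = base
        self.grid = base.grid
        self.mirror = base.mirror
        self.counter = base.counter
        self.focal_indices = base.focal_indices
        self.plan = base.plan
        self.dtype = base.dtype
        self._order = order
        if base.focal_indices != tuple(range(base.grid.shape[0])):
            raise ValueError("reflected operator needs a full plane-per-plane plan")
        self._normalization: Volume | None = None

    def _R(self, arr: np.ndarray) -> np.ndarray:
        g = self.grid
        return reflect_array(arr, g.pitch, g.origin, self.mirror.theta_deg, self._order)

    def forward(self, F: Volume | np.ndarray) -> np.ndarray:
        arr = F.data if isinstance(F, Volume) else np.asarray(F)
        return self._R(self.base.forward(self._R(arr)))

    def transpose(self, planes: np.ndarray) -> np.ndarray:
        return self._R(self.base.transpose(self._R(np.asarray(planes))))

    @property
    def normalization(self) -> Volume:
        if self._normalization is None:
            V = self._R(self.base.normalization.data)
            self._normalization = Volume(V, self.grid.pitch, self.grid.origin)
        return self._normalization


class AxisSwappedOperator:
    """An operator viewed along the x axis: M = T ∘ M_base ∘ T with T the
    z↔x axis swap. Valid at θ = 45° on cubic grids (the swap maps the mirror
    plane and the crossed-sheet illumination onto themselves, exchanging the
    sheet roles), which turns a camera-B geometry into camera-A form."""

    def __init__(self, base: ImagingOperator):
        g = base.grid
        if g.shape[0] != g.shape[2] or g.pitch[0] != g.pitch[2] or g.origin[0] != g.origin[2]:
            raise ValueError("axis swap requires matching z/x sampling")
        if not math.isclose(base.mirror.theta_deg, 45.0):
            raise ValueError("axis-swapped views require theta = 45 deg")
        self.base = base
        self.grid = g
        self.mirror = base.mirror
        self.counter = base.counter
        self.focal_indices = base.focal_indices
        self.plan = base.plan
        self.dtype = base.dtype
        self._normalization: Volume | None = None

    @staticmethod
    def _T(arr: np.ndarray) -> np.ndarray:
        return np.ascontiguousarray(np.swapaxes(arr, 0, 2))

    def forward(self, F: Volume | np.ndarray) -> np.ndarray:
        arr = F.data if isinstance(F, Volume) else np.asarray(F)
        return self._T(self.base.forward(self._T(arr)))

    def transpose(self, planes: np.ndarray) -> np.ndarray:
        return self._T(self.base.transpose(self._T(np.asarray(planes))))

    @property
    def normalization(self) -> Volume:
        if self._normalization is None:
            V = self._T(self.base.normalization.data)
            self._normalization = Volume(V, self.grid.pitch, self.grid.origin)
        return self._normalization


def simulate_acquisition(
    f: Volume,
    ops: list[ImagingOperator] | ImagingOperator,
    noise: str | None = None,
    seed: int | None = None,
) -> list[CameraStack]:
    """Synthesize raw camera stacks from a physical object.

    ``f`` is mirrored into the extended object f̃ using each operator's
    mirror geometry, then projected through the forward model per stage step.
    ``noise='poisson'`` draws per-pixel Poisson counts (the plane values are
    interpreted as expected photons) with a recorded seed.
    """
    single = isinstance(ops, (ImagingOperator, ReflectedOperator, AxisSwappedOperator))
    op_list = [ops] if single else list(ops)
    stacks = []
    for i, op in enumerate(op_list):
        ftilde = extended_object(f, op.mirror)
        # FFT roundoff can leave tiny negative values in an exact-adjoint
        # forward projection; physical camera data are nonnegative
        planes = np.clip(op.forward(ftilde.data), 0.0, None)
        mode = noise or op.plan.noise
        if mode == "poisson":
            if seed is None:
                seed = op.plan.seed
            if seed is None:
                raise ValueError("poisson noise requires a seed")
            rng = np.random.default_rng(seed + i)
            planes = rng.poisson(np.clip(planes, 0, None)).astype(np.float64)
        cam = op.plan.views[0] if op.plan.views else "A"
        grid = op.grid
        stacks.append(
            CameraStack(planes, (grid.pitch[1], grid.pitch[2]),
                        tuple(op.focal_indices), getattr(op.plan, "step_um", 0.0), cam)
        )
    return stacks


def dense_operator(op: ImagingOperator, max_voxels: int = 4096) -> np.ndarray:
    """Explicit (J x K) matrix of the imaging operator, for oracle testing.

    Column k is the forward projection of the k-th unit impulse; restricted
    to tiny grids (≤ 16³ voxels by default) as a memory guard.
    """
    K = int(np.prod(op.grid.shape))
    if K > max_voxels:
        raise ValueError(
            f"dense operator refused for {K} voxels (> {max_voxels}); "
            "use a grid of at most 16^3 voxels"
        )
    ny, nx = op.grid.shape[1], op.grid.shape[2]
    J = len(op.focal_indices) * ny * nx
    M = np.empty((J, K))
    e = np.zeros(op.grid.shape)
    flat = e.ravel()
    for k in range(K):
        flat[k] = 1.0
        M[:, k] = op.forward(e).ravel()
        flat[k] = 0.0
    return M
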