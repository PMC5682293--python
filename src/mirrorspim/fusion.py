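"""Fusing registered raw views into U₁ and its virtual mirror view U₂.

U₁ is assembled from the registered raw views per half-space: its real
half-space (on/above the mirror) holds the 𝒜 content and the virtual
half-space the ℬ content. In the symmetric four-view geometry 𝒜 = A + A′ and
ℬ = B + B′ (sum mode), or the better of each pair by an image-quality metric
(select mode); with a single camera collecting both direct and reflected
views, 𝒜 = A and ℬ = B′ and U₁ is simply the acquired stack. The virtual
second view U₂ is U₁ reflected across the mirror.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .geometry import MirrorGeometry, reflect_volume
from .volume import Volume

__all__ = [
    "FusedView",
    "RegistrationError",
    "fuse_views",
    "make_virtual_view",
    "register_translation",
    "stripe_correct",
    "spectral_quality",
]


class RegistrationError(RuntimeError):
    """Raised when phase correlation finds no credible shift."""


@dataclass
class FusedView:
    """A fused volumetric view with provenance per half-space."""

    data: Volume
    provenance: dict

    def __post_init__(self):
        if np.any(self.data.data < 0):
            raise ValueError("fused view must be nonnegative")
        if not {"real", "virtual"} <= set(self.provenance):
            raise ValueError("provenance must cover both half-spaces")


def spectral_quality(arr: np.ndarray) -> float:
    """Image-quality metric: fraction of spectral energy above 1/4 Nyquist.

    Scale-invariant (energy ratios are unchanged by a global intensity
    factor); higher means more recoverable high-frequency content.
    """
    spec = np.abs(np.fft.fftn(arr)) ** 2
    total = spec.sum() - spec.flat[0]  # exclude DC
    if total <= 0:
        return 0.0
    freqs = [np.fft.fftfreq(n) for n in arr.shape]
    radius = np.sqrt(
        freqs[0][:, None, None] ** 2
        + freqs[1][None, :, None] ** 2
        + freqs[2][None, None, :] ** 2
    )
    high = spec[radius > 0.125].sum()  # 1/4 of the 0.5 Nyquist radius
    return float(high / total)


def _half_space_masks(vol: Volume, mirror: MirrorGeometry):
    x = vol.coords(2)[None, None, :]
    z = vol.coords(0)[:, None, None]
    above = np.broadcast_to(mirror.side(x, z), vol.shape)
    return above, ~above


def fuse_views(
    views: dict[str, Volume],
    mirror: MirrorGeometry,
    mode: str = "sum",
) -> FusedView:
    """Build U₁ from registered raw views.

    ``views`` maps names in {A, Ap, B, Bp} (Ap/Bp are the mirror views A′/B′)
    to registered fixed-frame volumes. Modes: ``sum`` (𝒜 = A + A′,
    ℬ = B + B′), ``select`` (best-quality member of each pair), or
    ``single_camera`` (𝒜 = A, ℬ = B′ — one camera already collects both the
    direct and the reflected image).
    """
    if mode == "single_camera":
        required = {"A", "Bp"}
    elif mode in ("sum", "select"):
        required = {"A", "Ap", "B", "Bp"}
    else:
        raise ValueError(f"unknown fusion mode {mode!r}")
    missing = required - set(views)
    if missing:
        raise ValueError(f"fusion mode {mode!r} needs views {sorted(missing)}")

    ref = views[next(iter(required))]
    above, below = _half_space_masks(ref, mirror)

    if mode == "sum":
        A = views["A"].data + views["Ap"].data
        B = views["B"].data + views["Bp"].data
        prov = {"real": ("A+Ap", "sum"), "virtual": ("B+Bp", "sum")}
    elif mode == "single_camera":
        A = views["A"].data
        B = views["Bp"].data
        prov = {"real": ("A", "single_camera"), "virtual": ("Bp", "single_camera")}
    else:  # select
        qa = {k: spectral_quality(views[k].data * above) for k in ("A", "Ap")}
        qb = {k: spectral_quality(views[k].data * below) for k in ("B", "Bp")}
        best_a = max(qa, key=qa.get)
        best_b = max(qb, key=qb.get)
        A = views[best_a].data
        B = views[best_b].data
        prov = {"real": (best_a, "select"), "virtual": (best_b, "select")}

    fused = np.where(above, A, B)
    return FusedView(ref.with_data(np.clip(fused, 0.0, None)), prov)


def make_virtual_view(U1: FusedView | Volume, mirror: MirrorGeometry,
                      order: int = 1) -> FusedView:
    """U₂: the fused view reflected across the mirror, seen from the
    complementary direction."""
    if isinstance(U1, FusedView):
        vol, prov = U1.data, U1.provenance
    else:
        vol, prov = U1, {"real": ("U1", "reflect"), "virtual": ("U1", "reflect")}
    reflected = reflect_volume(vol, mirror, order=order)
    swapped = {"real": prov["virtual"], "virtual": prov["real"]}
    return FusedView(reflected.with_data(np.clip(reflected.data, 0.0, None)), swapped)


def register_translation(
    moving: Volume, fixed: Volume, upsample_factor: int = 20,
    min_correlation: float = 0.2,
) -> tuple[np.ndarray, Volume]:
    """Translation-only registration by phase correlation.

    Returns the (z, y, x) shift in voxels that aligns ``moving`` onto
    ``fixed`` and the shifted volume (linear interpolation). Raises
    :class:`RegistrationError` when the aligned volumes remain uncorrelated
    (no credible correlation peak, e.g. pure noise inputs).
    """
    if moving.shape != fixed.shape:
        raise ValueError("volumes must share a grid for translation registration")
    shift, _, _ = phase_cross_correlation(
        fixed.data, moving.data, upsample_factor=upsample_factor,
    )
    registered = ndimage.shift(moving.data, shift, order=1, mode="grid-constant", cval=0.0)
    # Pearson correlation on the overlap region (outside it the shifted
    # volume is zero fill, not evidence against the registration)
    overlap = ndimage.shift(np.ones_like(moving.data), shift, order=1,
                            mode="grid-constant", cval=0.0) > 0.5
    if overlap.mean() < 0.5:
        raise RegistrationError("volumes overlap by less than 50% after alignment")
    a = registered[overlap] - registered[overlap].mean()
    b = fixed.data[overlap] - fixed.data[overlap].mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    corr = float(a @ b / denom) if denom > 0 else 0.0
    if corr < min_correlation:
        raise RegistrationError(
            f"aligned correlation {corr:.3f} below {min_correlation}; "
            "no credible registration"
        )
    return np.asarray(shift, dtype=float), moving.with_data(registered)


def stripe_correct(vol: Volume) -> Volume:
    """Remove y′-striping by dividing each y′ line by its mean.

    Each line along y′ is scaled by (global mean / line mean), so all line
    means are equal afterwards; zero-mean lines are left unchanged with a
    warning.
    """
    data = vol.data.astype(float)
    line_means = data.mean(axis=1)  # (z, x)
    global_mean = data.mean()
    zero = line_means <= 0
    if np.any(zero):
        warnings.warn("zero-mean y' lines left unchanged", stacklevel=2)
    safe = np.where(zero, 1.0, line_means)
    factor = np.where(zero, 1.0, global_mean / safe)
    return vol.with_data(data * factor[:, None, :])
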