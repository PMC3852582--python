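"""Phase-contrast optics model.

Under positive phase contrast, the effective point spread function of the
annular (centrally obscured) condenser/phase-ring combination is well
approximated by a Dirac delta minus an obscured Airy pattern,

    PSF(u, v) = delta(u, v) - airy(sqrt(u^2 + v^2)),

which is what turns a transparent cell into a dark body surrounded by a
bright halo.  This module constructs the discretized kernel and applies the
corresponding linear operator **P** to images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import j1

__all__ = [
    "PhaseContrastPSF",
    "make_obscured_airy",
    "make_psf",
    "apply_psf",
    "psf_to_dense",
    "save_kernel_csv",
    "load_kernel_csv",
]


def _jinc(x: np.ndarray) -> np.ndarray:
    """2*J1(x)/x with the analytic limit 1 at x = 0."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = x != 0
    out[nz] = 2.0 * j1(x[nz]) / x[nz]
    return out


def _check_psf_params(outer_radius: float, obscuration_ratio: float, half_width: int) -> None:
    if not outer_radius > 0:
        raise ValueError(f"outer_radius must be positive, got {outer_radius}")
    if not (0.0 <= obscuration_ratio < 1.0):
        raise ValueError(
            f"obscuration_ratio must lie in [0, 1), got {obscuration_ratio}"
        )
    if not (isinstance(half_width, (int, np.integer)) and half_width > 0):
        raise ValueError(f"half_width must be a positive integer, got {half_width}")


def make_obscured_airy(
    outer_radius: float, obscuration_ratio: float, half_width: int
) -> np.ndarray:
    """Discretized obscured-Airy amplitude on a (2*half_width+1)^2 grid.

    The annular-aperture amplitude at radius r is

        A(r) = [2 J1(a r)/(a r) - R^2 * 2 J1(R a r)/(R a r)] / (1 - R^2)

    with a = ``outer_radius``, R = ``obscuration_ratio`` and A(0) = 1 by the
    analytic limit.  The sampled array is rescaled to unit sum so that the
    delta-minus-airy kernel annihilates constant images (background maps to
    zero under **P**).
    """
    _check_psf_params(outer_radius, obscuration_ratio, half_width)
    hw = int(half_width)
    u, v = np.meshgrid(np.arange(-hw, hw + 1), np.arange(-hw, hw + 1), indexing="ij")
    r = np.sqrt(u.astype(float) ** 2 + v.astype(float) ** 2)
    a, big_r = float(outer_radius), float(obscuration_ratio)
    amp = (_jinc(a * r) - big_r**2 * _jinc(big_r * a * r)) / (1.0 - big_r**2)
    total = amp.sum()
    if abs(total) < 1e-12:
        raise ValueError("obscured-Airy sample sums to ~0; cannot normalize")
    return amp / total


@dataclass(frozen=True)
class PhaseContrastPSF:
    """Discretized delta-minus-airy kernel implementing the operator **P**."""

    outer_radius: float = 2.0
    obscuration_ratio: float = 0.5
    half_width: int = 5
    kernel: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "kernel",
            _delta_minus_airy(self.outer_radius, self.obscuration_ratio, self.half_width),
        )

    @property
    def size(self) -> int:
        return 2 * self.half_width + 1


def _delta_minus_airy(outer_radius: float, obscuration_ratio: float, half_width: int) -> np.ndarray:
    airy = make_obscured_airy(outer_radius, obscuration_ratio, half_width)
    kernel = -airy
    kernel[half_width, half_width] += 1.0
    return kernel


def make_psf(
    outer_radius: float = 2.0, obscuration_ratio: float = 0.5, half_width: int = 5
) -> PhaseContrastPSF:
    """Build the phase-contrast PSF (delta minus unit-sum obscured Airy)."""
    return PhaseContrastPSF(
        outer_radius=float(outer_radius),
        obscuration_ratio=float(obscuration_ratio),
        half_width=int(half_width),
    )


def apply_psf(image: np.ndarray, psf: PhaseContrastPSF) -> np.ndarray:
    """Apply the linear imaging operator **P** (2-D correlation, reflect edges).

    The kernel is symmetric under both flips and transpose, so correlation
    and convolution coincide; symmetric (reflect) boundary handling avoids an
    artificial dark frame at image edges.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a nonempty 2-D array")
    return ndimage.correlate(image, psf.kernel, mode="reflect")


def psf_to_dense(psf: PhaseContrastPSF, shape: tuple[int, int]) -> np.ndarray:
    """Materialize **P** as a dense N x N matrix (small images / tests only).

    Columns are apply_psf applied to pixel indicator images, so the dense
    path agrees with the convolution path by construction.
    """
    rows, cols = shape
    n = rows * cols
    dense = np.empty((n, n), dtype=float)
    basis = np.zeros(shape, dtype=float)
    for k in range(n):
        basis.flat[k] = 1.0
        dense[:, k] = apply_psf(basis, psf).ravel()
        basis.flat[k] = 0.0
    return dense


def save_kernel_csv(psf: PhaseContrastPSF, path) -> None:
    np.savetxt(path, psf.kernel, delimiter=",")


def load_kernel_csv(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", ndmin=2)
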