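"""Gaussian receptive subfields and their difference-of-Gaussians combination.

A model neuron's receptive field is built from two Gaussian subfields: a
narrow excitatory on-center and a broad inhibitory off-surround.  Each
subfield is parameterized by a peak amplitude ``h`` and a width ``sigma``
that can be adjusted independently: the kernel is

    g(k; h, sigma) = h * exp(-k**2 / (2 * sigma**2)),

i.e. ``h * sigma * sqrt(2*pi)`` times the normal density with standard
deviation ``sigma``, so changing ``sigma`` never changes the peak value.
The effective receptive field is the difference of the two subfields
(DoG): positive on-center, negative off-surround, provided the excitatory
kernel is narrower and taller than the inhibitory one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KernelSpec",
    "DiscreteKernel",
    "DoGProfile",
    "gaussian_value",
    "discretize_kernel",
    "make_subfields",
    "dog_profile",
]


class InvalidParameterError(ValueError):
    """A kernel or network parameter violates its domain constraint."""


@dataclass(frozen=True)
class KernelSpec:
    """Peak amplitude and width of one Gaussian subfield.

    Parameters
    ----------
    h : float
        Peak amplitude of the kernel (dimensionless, > 0).  This is the
        value of the kernel at offset 0 regardless of ``sigma``.
    sigma : float
        Width of the kernel, in grid (position) units, > 0.
    radius_sigmas : float
        Truncation half-width in multiples of ``sigma``.  The discretized
        kernel covers integer offsets in ``[-ceil(radius_sigmas*sigma),
        +ceil(radius_sigmas*sigma)]``.  Must be >= 3; the default 4 keeps
        more than 99.99% of the Gaussian mass.
    """

    h: float
    sigma: float
    radius_sigmas: float = 4.0

    def __post_init__(self) -> None:
        if not self.h > 0:
            raise InvalidParameterError(f"peak amplitude h must be > 0, got {self.h}")
        if not self.sigma > 0:
            raise InvalidParameterError(f"width sigma must be > 0, got {self.sigma}")
        if not self.radius_sigmas >= 3:
            raise InvalidParameterError(
                f"radius_sigmas must be >= 3, got {self.radius_sigmas}"
            )

    @property
    def radius(self) -> int:
        """Integer truncation radius in grid units."""
        return int(math.ceil(self.radius_sigmas * self.sigma))


@dataclass(frozen=True)
class DiscreteKernel:
    """A kernel sampled on an integer offset grid symmetric about 0."""

    values: np.ndarray
    center_index: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or len(v) != 2 * self.center_index + 1:
            raise InvalidParameterError(
                "kernel values must be a 1D vector symmetric about center_index"
            )

    @property
    def offsets(self) -> np.ndarray:
        r = self.center_index
        return np.arange(-r, r + 1)

    @property
    def radius(self) -> int:
        return self.center_index

    def scaled(self, factor: float) -> "DiscreteKernel":
        return DiscreteKernel(self.values * factor, self.center_index)


@dataclass(frozen=True)
class DoGProfile:
    """Difference of an excitatory and an inhibitory kernel on a common grid.

    Besides the raw profile, carries the shape descriptors of the
    on-center/off-surround organization: the span of the positive
    on-center (distance between the two zero crossings around 0), and the
    amplitude and position of the negative off-surround trough.
    """

    values: np.ndarray
    center_index: int
    on_center_width: float = field(default=float("nan"))
    trough_amplitude: float = field(default=float("nan"))
    trough_offset: float = field(default=float("nan"))

    @property
    def offsets(self) -> np.ndarray:
        r = self.center_index
        return np.arange(-r, r + 1)

    @property
    def center_value(self) -> float:
        return float(self.values[self.center_index])


def gaussian_value(k, spec: KernelSpec):
    """Evaluate the Gaussian kernel g(k; h, sigma) at offset(s) ``k``.

    Returns ``h * exp(-k**2 / (2 * sigma**2))``; equivalently
    ``h * sigma * sqrt(2*pi)`` times the normal pdf at ``k``, which is the
    formulation that keeps the peak at ``h`` while ``sigma`` varies.
    """
    k = np.asarray(k, dtype=float)
    out = spec.h * np.exp(-(k**2) / (2.0 * spec.sigma**2))
    return float(out) if out.ndim == 0 else out


def discretize_kernel(spec: KernelSpec) -> DiscreteKernel:
    """Sample the Gaussian at integer offsets within the truncation radius.

    The peak is not renormalized: ``values[center] == h`` exactly.  The sum
    of the samples approximates the continuous mass ``h*sigma*sqrt(2*pi)``
    (to well under 0.1% for sigma >= 2 at the default radius).
    """
    r = spec.radius
    offsets = np.arange(-r, r + 1)
    return DiscreteKernel(gaussian_value(offsets, spec), center_index=r)


def _pad_to_radius(kernel: DiscreteKernel, radius: int) -> np.ndarray:
    """Zero-pad a kernel's values out to a common truncation radius."""
    extra = radius - kernel.radius
    if extra < 0:
        raise InvalidParameterError("target radius smaller than kernel radius")
    return np.pad(kernel.values, extra)


def make_subfields(
    exc: KernelSpec,
    inh: KernelSpec,
    B: float,
    C: float,
    normalize: bool = True,
) -> tuple[DiscreteKernel, DiscreteKernel]:
    """Build the excitatory and inhibitory subfield kernels used in the dynamics.

    The shunting equation gates excitation by the headroom ``(B - x)`` and
    inhibition by ``(C + x)``; the subfields are correspondingly divided by
    the bounds, ``GEx = G(hEx, sigmaEx)/B`` and ``GInh = G(hInh, sigmaInh)/C``.
    Since this is a global rescaling absorbable into ``h``, ``normalize=False``
    skips it for sensitivity checks.
    """
    if not B > 0 or not C > 0:
        raise InvalidParameterError(f"bounds must be positive, got B={B}, C={C}")
    g_ex = discretize_kernel(exc)
    g_inh = discretize_kernel(inh)
    if normalize:
        g_ex = g_ex.scaled(1.0 / B)
        g_inh = g_inh.scaled(1.0 / C)
    return g_ex, g_inh


def dog_profile(g_ex: DiscreteKernel, g_inh: DiscreteKernel) -> DoGProfile:
    """Elementwise difference of the two subfields on a common offset grid.

    The narrower kernel is zero-padded to the wider one's radius.  Shape
    descriptors (on-center width, trough amplitude/position) are derived
    from the resulting profile; they are NaN when the profile has no zero
    crossing or no negative lobe (e.g. a purely excitatory profile).
    """
    radius = max(g_ex.radius, g_inh.radius)
    values = _pad_to_radius(g_ex, radius) - _pad_to_radius(g_inh, radius)

    offsets = np.arange(-radius, radius + 1)
    center = radius

    # first zero crossing to the right of the center, linearly interpolated
    right = values[center:]
    sign_change = np.nonzero((right[:-1] > 0) & (right[1:] <= 0))[0]
    if len(sign_change) and values[center] > 0:
        i = sign_change[0]
        frac = right[i] / (right[i] - right[i + 1])
        zero_cross = i + frac
        on_center_width = 2.0 * zero_cross
    else:
        on_center_width = float("nan")

    negative = values < 0
    if negative.any():
        trough_idx = int(np.argmin(values))
        trough_amplitude = float(-values[trough_idx])
        trough_offset = float(abs(offsets[trough_idx]))
    else:
        trough_amplitude = float("nan")
        trough_offset = float("nan")

    return DoGProfile(
        values=values,
        center_index=center,
        on_center_width=on_center_width,
        trough_amplitude=trough_amplitude,
        trough_offset=trough_offset,
    )


def dog_descriptor_frame(profile: DoGProfile):
    """Long-form (offset, value) table of a DoG profile, for CSV export."""
    import pandas as pd

    return pd.DataFrame({"offset": profile.offsets, "value": profile.values})
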