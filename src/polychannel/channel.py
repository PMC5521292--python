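"""Periodic cylindrical channel geometry with sinusoidal wall undulations.

The confinement is a cylinder of mean radius ``R0`` aligned with the z axis,
periodic in z with box length ``Lz``.  Undulating variants modulate the wall
radius sinusoidally, ``r(z) = R0 + A sin(k w0 z)`` with fundamental frequency
``w0 = 2 pi / L``; the smooth cylinder is the ``k = 0`` member of the family.
Walls are realised as a single layer of fixed, uncharged particles placed on
the analytic surface so that a sigma-sized sphere cannot pass between them.

Geometry naming follows the P/T convention: P means a purely longitudinal
applied field, T longitudinal plus transverse; the numeric index selects the
undulation harmonic (0 smooth, then harmonics 1, 2, 6, 8 for indices
2, 4, 12, 16).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChannelSpec",
    "GEOMETRY_HARMONICS",
    "radius_profile",
    "geometry_extrema",
    "build_wall_particles",
    "contains",
    "spec_for_geometry",
]

#: Map from geometry index (as used in the P0/T0 ... P16/T16 labels) to the
#: harmonic multiplier of the fundamental undulation frequency.
GEOMETRY_HARMONICS = {0: 0, 2: 1, 4: 2, 12: 6, 16: 8}

#: Undulation wavelength of the reference channel family, in sigma.
DEFAULT_WAVELENGTH = 57.11


@dataclass(frozen=True)
class ChannelSpec:
    """Geometric definition of a (possibly undulating) cylindrical channel.

    Parameters
    ----------
    mean_radius : float
        Mean channel radius ``R0`` in sigma (reference value 6).
    amplitude : float
        Undulation amplitude ``A`` in sigma (reference value 1.5, i.e. 25%
        of the mean radius).  Ignored when ``harmonic`` is 0.
    box_length : float
        Periodic box length ``Lz`` along the channel axis, in sigma.
    wavelength : float
        Fundamental undulation wavelength ``L`` in sigma (reference 57.11).
    harmonic : int
        Harmonic multiplier ``k`` of the fundamental frequency; 0 selects a
        smooth cylinder.
    wall_spacing : float
        Target inter-particle distance of the wall lattice, in sigma.
    """

    mean_radius: float = 6.0
    amplitude: float = 1.5
    box_length: float = DEFAULT_WAVELENGTH
    wavelength: float = DEFAULT_WAVELENGTH
    harmonic: int = 0
    wall_spacing: float = 1.0

    def __post_init__(self) -> None:
        if self.mean_radius <= 0:
            raise ValueError(f"mean_radius must be positive, got {self.mean_radius}")
        if self.harmonic < 0 or int(self.harmonic) != self.harmonic:
            raise ValueError(f"harmonic must be a non-negative integer, got {self.harmonic}")
        if self.harmonic > 0:
            if self.amplitude < 0:
                raise ValueError(f"amplitude must be non-negative, got {self.amplitude}")
            if self.amplitude >= self.mean_radius:
                raise ValueError(
                    f"amplitude {self.amplitude} must be smaller than mean_radius "
                    f"{self.mean_radius} (radius profile must stay positive)"
                )
            # The surface must be periodic over the box: Lz a multiple of L/k.
            period = self.wavelength / self.harmonic
            ratio = self.box_length / period
            if abs(ratio - round(ratio)) > 1e-9 * max(1.0, ratio):
                raise ValueError(
                    f"box_length {self.box_length} is not an integer multiple of the "
                    f"undulation period {period} (wavelength/harmonic)"
                )
        if self.box_length <= 0:
            raise ValueError(f"box_length must be positive, got {self.box_length}")
        if self.wavelength <= 0:
            raise ValueError(f"wavelength must be positive, got {self.wavelength}")

    @property
    def omega(self) -> float:
        """Angular frequency ``k * 2 pi / L`` of the radius modulation."""
        return self.harmonic * 2.0 * math.pi / self.wavelength


def spec_for_geometry(
    index: int,
    mean_radius: float = 6.0,
    amplitude: float | None = None,
    box_length: float = DEFAULT_WAVELENGTH,
    wavelength: float = DEFAULT_WAVELENGTH,
    wall_spacing: float = 1.0,
) -> ChannelSpec:
    """Build the :class:`ChannelSpec` of a named geometry index (0/2/4/12/16).

    The undulation depth defaults to 25% of the mean radius.
    """
    if index not in GEOMETRY_HARMONICS:
        raise ValueError(
            f"unknown geometry index {index}; valid indices: {sorted(GEOMETRY_HARMONICS)}"
        )
    k = GEOMETRY_HARMONICS[index]
    if amplitude is None:
        amplitude = 0.25 * mean_radius if k > 0 else 0.0
    return ChannelSpec(
        mean_radius=mean_radius,
        amplitude=amplitude,
        box_length=box_length,
        wavelength=wavelength,
        harmonic=k,
        wall_spacing=wall_spacing,
    )


def radius_profile(z, spec: ChannelSpec):
    """Wall radius at axial coordinate ``z`` (scalar or array), in sigma.

    ``r(z) = R0 + A sin(k w0 z)`` for an undulating channel, ``R0`` for the
    smooth cylinder.  The profile is periodic over the box length.
    """
    z = np.asarray(z, dtype=float)
    if spec.harmonic == 0:
        out = np.full_like(z, spec.mean_radius)
    else:
        out = spec.mean_radius + spec.amplitude * np.sin(spec.omega * z)
    return out if out.ndim else float(out)


def radius_slope(z, spec: ChannelSpec):
    """dr/dz of the radius profile (used for surface metric bookkeeping)."""
    z = np.asarray(z, dtype=float)
    if spec.harmonic == 0:
        out = np.zeros_like(z)
    else:
        out = spec.amplitude * spec.omega * np.cos(spec.omega * z)
    return out if out.ndim else float(out)


def geometry_extrema(spec: ChannelSpec, n_scan: int = 20001) -> tuple[float, float]:
    """(min, max) wall radius, by numeric scan over one undulation period.

    Agrees with the closed form ``(R0 - A, R0 + A)`` to better than 1e-9 for
    any harmonic; the smooth cylinder returns ``(R0, R0)``.
    """
    if spec.harmonic == 0 or spec.amplitude == 0.0:
        return (spec.mean_radius, spec.mean_radius)
    period = spec.wavelength / spec.harmonic
    z = np.linspace(0.0, period, n_scan)
    r = radius_profile(z, spec)
    # Refine the grid extrema against the closed form: the sinusoid's extrema
    # are attained exactly at quarter-period offsets, so evaluate there too.
    z_extra = np.array([0.25, 0.75]) * period
    r_extra = radius_profile(z_extra, spec)
    r = np.concatenate([r, r_extra])
    return (float(r.min()), float(r.max()))


def contains(point, spec: ChannelSpec, margin: float = 0.0):
    """True where the point lies inside the channel by at least ``margin``.

    ``point`` is a 3-vector or (n, 3) array; z is wrapped into [0, Lz).
    """
    p = np.atleast_2d(np.asarray(point, dtype=float))
    z = np.mod(p[:, 2], spec.box_length)
    rho = np.hypot(p[:, 0], p[:, 1])
    inside = rho < radius_profile(z, spec) - margin
    return bool(inside[0]) if np.asarray(point).ndim == 1 else inside


def build_wall_particles(spec: ChannelSpec) -> np.ndarray:
    """Place fixed wall particles on the channel surface.

    Returns an (n, 3) array of positions.  The lattice is approximately
    triangular: rings of particles are swept along z with the axial step
    chosen so that the meridional arc step matches ``wall_spacing``; within
    each ring the azimuthal count matches the local circumference, and
    consecutive rings are offset by half an azimuthal spacing.  A single
    layer of sigma-spaced WCA spheres is impermeable to sigma-sized mobile
    particles.
    """
    if not (0.7 <= spec.wall_spacing <= 1.3):
        raise ValueError(
            f"wall_spacing {spec.wall_spacing} outside the supported range [0.7, 1.3] sigma"
        )
    r_min, _ = geometry_extrema(spec)
    if r_min < 2.0:
        raise ValueError(
            f"radius profile dips to {r_min} sigma (< 2); channel would be impassable"
        )

    a = spec.wall_spacing
    Lz = spec.box_length
    # Meridional arc length of the surface over one box period.
    n_fine = max(2000, int(50 * Lz))
    zf = np.linspace(0.0, Lz, n_fine + 1)
    metric = np.sqrt(1.0 + radius_slope(zf, spec) ** 2)
    s = np.concatenate([[0.0], np.cumsum(0.5 * (metric[1:] + metric[:-1]) * np.diff(zf))])
    total_arc = s[-1]
    # Rows of a triangular lattice are spaced a*sqrt(3)/2 along the meridian.
    row_step = a * math.sqrt(3.0) / 2.0
    n_rows = max(3, int(round(total_arc / row_step)))
    s_rows = (np.arange(n_rows) + 0.5) * total_arc / n_rows
    z_rows = np.interp(s_rows, s, zf)

    positions = []
    for i, zr in enumerate(z_rows):
        radius = float(radius_profile(zr, spec))
        n_phi = max(3, int(round(2.0 * math.pi * radius / a)))
        phase = (i % 2) * math.pi / n_phi  # half-offset alternate rings
        phi = phase + 2.0 * math.pi * np.arange(n_phi) / n_phi
        ring = np.column_stack(
            [radius * np.cos(phi), radius * np.sin(phi), np.full(n_phi, zr)]
        )
        positions.append(ring)
    return np.concatenate(positions, axis=0)
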