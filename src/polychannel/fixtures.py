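"""Synthetic inputs with known statistics.

Every estimator in :mod:`polychannel.observables` can be validated without
running molecular dynamics: these generators produce trajectories and force
series whose expected observable values are known in closed form.

* :func:`ballistic_trajectory` — exact constant drift (plus optional white
  positional noise) for the drift-velocity estimator.
* :func:`ou_force_series` — Ornstein-Uhlenbeck force processes generated
  with the exact discrete-time transition kernel (never an Euler scheme), so
  the friction estimator's target ``3 s^2 tau_c`` per monomer carries only
  statistical error.
* :func:`radial_flow_scene` — tracers around a straight rod with a
  prescribed exponentially decaying axial flow, for the shell-averaging
  procedure.
* :func:`ideal_gas_scene` — uniform non-interacting particles inside a
  channel, for density maps and volume bookkeeping.

All fixtures are seed-deterministic and tag their output metadata with
``synthetic: True``.
"""

from __future__ import annotations

import math

import numpy as np

from .builder import SPECIES_CHARGE, ParticleSystem
from .channel import ChannelSpec, contains, radius_profile
from .integrator import Trajectory

__all__ = [
    "ballistic_trajectory",
    "ou_force_series",
    "radial_flow_scene",
    "ideal_gas_scene",
]


def _make_traj(
    positions_unwrapped: np.ndarray,
    velocities: np.ndarray,
    times: np.ndarray,
    species: np.ndarray,
    Lz: float,
    generator: str,
    extra_meta: dict | None = None,
    bonds: np.ndarray | None = None,
) -> Trajectory:
    wrapped = positions_unwrapped.copy()
    wrapped[:, :, 2] = np.mod(wrapped[:, :, 2], Lz)
    offsets = positions_unwrapped[:, :, 2] - wrapped[:, :, 2]
    charges = np.array([SPECIES_CHARGE.get(s, 0.0) for s in species])
    meta = {"synthetic": True, "generator": generator}
    if extra_meta:
        meta.update(extra_meta)
    traj = Trajectory(
        times=times,
        positions=wrapped,
        offsets=offsets,
        velocities=velocities,
        species=species,
        charges=charges,
        bonds=bonds if bonds is not None else np.empty((0, 2), dtype=np.intp),
        box_length=Lz,
        stride=1,
        dt=float(times[1] - times[0]) if len(times) > 1 else 1.0,
        metadata=meta,
    )
    traj.validate()
    return traj


def ballistic_trajectory(
    v,
    n_frames: int = 100,
    dt_frame: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_particles: int = 1,
    species: str = "M",
    Lz: float | None = None,
) -> Trajectory:
    """Rigid set of particles drifting at exactly ``v``, plus optional white
    positional noise; the unwrapped coordinates carry the exact drift."""
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    v = np.asarray(v, dtype=float)
    times = np.arange(n_frames) * dt_frame
    base = rng.uniform(0.0, 5.0, size=(n_particles, 3))
    pos = base[None, :, :] + times[:, None, None] * v[None, None, :]
    if noise_sd > 0:
        pos = pos + rng.normal(scale=noise_sd, size=pos.shape)
    vel = np.broadcast_to(v, pos.shape).copy()
    if Lz is None:
        Lz = float(max(10.0, np.abs(pos[:, :, 2]).max() * 2.0 + 10.0))
    sp = np.array([species] * n_particles)
    return _make_traj(
        pos, vel, times, sp, Lz, "ballistic", {"drift": v.tolist(), "noise_sd": noise_sd}
    )


def ou_force_series(
    s: float,
    tau_c: float,
    dt_sample: float,
    n_samples: int,
    n_monomers: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck 3-vector force series per monomer.

    Each component evolves by the exact discrete transition kernel
    ``F(t+dt) = a F(t) + s sqrt(1 - a^2) xi`` with ``a = exp(-dt/tau_c)``
    and a stationary ``N(0, s^2)`` start, independently across monomers and
    components.  The lag-k autocorrelation is exactly ``s^2 exp(-k dt /
    tau_c)``, so the friction integral per monomer is ``3 s^2 tau_c`` (and
    ``3 s^2 tau_c (1 - 1/n_monomers)`` after chain-mean subtraction).

    Returns shape ``(n_samples, n_monomers, 3)``.
    """
    if dt_sample >= tau_c / 5.0:
        raise ValueError("dt_sample must resolve the ACF: require dt < tau_c/5")
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    a = math.exp(-dt_sample / tau_c)
    b = s * math.sqrt(1.0 - a * a)
    out = np.empty((n_samples, n_monomers, 3))
    out[0] = rng.normal(scale=s, size=(n_monomers, 3))
    noise = rng.normal(size=(n_samples - 1, n_monomers, 3))
    for t in range(1, n_samples):
        out[t] = a * out[t - 1] + b * noise[t - 1]
    return out


def radial_flow_scene(
    v0: float,
    ell: float,
    rod_length: int = 10,
    tracer_density: float = 0.5,
    seed: int = 0,
    r_max: float = 10.0,
    bond: float = 1.0,
    n_frames: int = 1,
) -> Trajectory:
    """Tracers around a straight rod with a prescribed decaying axial flow.

    A rod of ``rod_length`` monomers spaced ``bond`` apart lies on the z
    axis; tracers are placed uniformly in the surrounding cylinder of radius
    ``r_max`` (excluding the axis) and assigned axial velocity
    ``v0 exp(-d / ell)`` where ``d`` is the tracer's minimum distance to the
    rod.  ``ell -> inf`` gives uniform flow.  The single frame is repeated
    ``n_frames`` times.
    """
    if v0 is None or ell <= 0 or tracer_density <= 0 or r_max <= 0:
        raise ValueError("parameters must be positive")
    rng = np.random.default_rng(seed)
    Lz = rod_length * bond
    rod = np.column_stack(
        [np.zeros(rod_length), np.zeros(rod_length), bond * (np.arange(rod_length) + 0.5)]
    )
    n_tracers = max(1, int(round(tracer_density * math.pi * r_max**2 * Lz)))
    rho = r_max * np.sqrt(rng.uniform(size=n_tracers))
    rho = np.maximum(rho, 1e-3)  # exclude the exact axis (distance must be > 0)
    phi = rng.uniform(0.0, 2.0 * math.pi, size=n_tracers)
    z = rng.uniform(0.0, Lz, size=n_tracers)
    tracers = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])

    d = tracers[:, None, :] - rod[None, :, :]
    d[:, :, 2] -= Lz * np.round(d[:, :, 2] / Lz)
    dmin = np.sqrt(np.einsum("ijk,ijk->ij", d, d)).min(axis=1)
    vz = v0 * np.exp(-dmin / ell)

    pos1 = np.concatenate([rod, tracers])
    vel1 = np.zeros_like(pos1)
    vel1[rod_length:, 2] = vz
    species = np.array(["M"] * rod_length + ["S"] * n_tracers)
    times = np.arange(n_frames, dtype=float)
    if n_frames == 1:
        times = np.array([0.0])
    pos = np.repeat(pos1[None, :, :], n_frames, axis=0)
    vel = np.repeat(vel1[None, :, :], n_frames, axis=0)
    bonds = np.column_stack([np.arange(rod_length - 1), np.arange(1, rod_length)])
    return _make_traj(
        pos,
        vel,
        times,
        species,
        Lz,
        "radial_flow",
        {"v0": v0, "ell": ell, "min_rod_distance": float(dmin.min())},
        bonds=bonds,
    )


def ideal_gas_scene(density: float, spec: ChannelSpec, seed: int = 0) -> ParticleSystem:
    """Uniform non-interacting particles inside a channel (rejection
    sampling against the analytic surface); mean count is
    ``density * accessible_volume(spec)`` with Poisson fluctuations."""
    if density <= 0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng(seed)
    Lz = spec.box_length
    r_hi = spec.mean_radius + (spec.amplitude if spec.harmonic else 0.0)
    # Poisson count over the bounding cylinder, thinned by rejection.
    n_box = rng.poisson(density * math.pi * r_hi**2 * Lz)
    rho = r_hi * np.sqrt(rng.uniform(size=n_box))
    phi = rng.uniform(0.0, 2.0 * math.pi, size=n_box)
    z = rng.uniform(0.0, Lz, size=n_box)
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    keep = rho < radius_profile(z, spec)
    pts = pts[keep]
    n = len(pts)
    return ParticleSystem(
        positions=pts,
        velocities=np.zeros((n, 3)),
        charges=np.zeros(n),
        species=np.array(["S"] * n),
        bonds=np.empty((0, 2), dtype=np.intp),
        box_length=Lz,
        spec=spec,
    )
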