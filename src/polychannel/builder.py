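"""Assembly of a neutral particle system inside a channel.

A built system holds one bead-spring polyelectrolyte chain (one negative
unit charge per bead), monovalent counterions at a prescribed concentration,
coions chosen so the mobile charge sums to zero, explicit neutral solvent at
a prescribed number density, and the fixed wall particles of the channel.
All particles have unit mass and diameter of order sigma.

Counts are referred to the accessible channel volume (the volume enclosed by
the analytic wall surface), not the bounding box.  By default the counterion
count is ``round(c V)`` and the coion count is reduced by the chain length to
achieve exact neutrality; the alternative convention (coions at ``round(c V)``
plus N extra counterions) is selectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

from .channel import ChannelSpec, build_wall_particles, contains, radius_profile

__all__ = [
    "ParticleSystem",
    "BuildConfig",
    "accessible_volume",
    "count_ions",
    "place_chain",
    "build_system",
]

#: Species labels: chain monomer, counterion, coion, solvent, wall.
SPECIES = ("M", "C+", "C-", "S", "W")
SPECIES_CHARGE = {"M": -1.0, "C+": 1.0, "C-": -1.0, "S": 0.0, "W": 0.0}

_MIN_SEPARATION = 0.85  # build-time hard-core distance, sigma


@dataclass
class ParticleSystem:
    """Positions, velocities, charges, species and bonds of all particles.

    Wall particles are included (species ``W``) with zero velocity; the
    ``mobile_mask`` property excludes them.  z is periodic over
    ``box_length``.
    """

    positions: np.ndarray
    velocities: np.ndarray
    charges: np.ndarray
    species: np.ndarray
    bonds: np.ndarray
    box_length: float
    spec: ChannelSpec | None = None

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def mobile_mask(self) -> np.ndarray:
        return self.species != "W"

    def indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.species == label)

    def validate(self) -> None:
        mob = self.mobile_mask
        total_q = float(self.charges[mob].sum())
        if abs(total_q) > 1e-9:
            raise ValueError(f"mobile charge sum {total_q} != 0")
        nm = int((self.species == "M").sum())
        if nm >= 2 and len(self.bonds) != nm - 1:
            raise ValueError("bonds do not form a single linear chain")


@dataclass(frozen=True)
class BuildConfig:
    """Recipe for :func:`build_system`.

    ``counterion_concentration`` (default 0.0291 / sigma^3) and
    ``solvent_density`` (default 0.82 / sigma^3) refer to the accessible
    channel volume.
    """

    spec: ChannelSpec
    chain_length: int = 30
    counterion_concentration: float = 0.0291
    solvent_density: float = 0.82
    seed: int = 0
    ion_convention: str = "counterion_excess"  # or "salt_pairs"

    def __post_init__(self) -> None:
        if self.chain_length < 2:
            raise ValueError("chain_length must be >= 2")
        if self.counterion_concentration <= 0:
            raise ValueError("counterion_concentration must be positive")
        if self.solvent_density <= 0:
            raise ValueError("solvent_density must be positive")
        if self.ion_convention not in ("counterion_excess", "salt_pairs"):
            raise ValueError(f"unknown ion_convention {self.ion_convention!r}")


def accessible_volume(spec: ChannelSpec) -> float:
    """Volume enclosed by the wall surface, by numeric quadrature of
    ``pi r(z)^2`` over the box length (relative error < 1e-6)."""
    if spec.harmonic == 0:
        return math.pi * spec.mean_radius**2 * spec.box_length
    val, _ = integrate.quad(
        lambda z: math.pi * float(radius_profile(z, spec)) ** 2,
        0.0,
        spec.box_length,
        epsrel=1e-9,
        limit=200,
    )
    return float(val)


def count_ions(V: float, c: float, N: int, convention: str = "counterion_excess"):
    """Counterion and coion counts for chain length ``N`` at concentration
    ``c`` in volume ``V``; the result is exactly charge neutral.

    Raises ``ValueError`` when neutrality is impossible (fewer counterions
    than chain charges).
    """
    n_salt = int(round(c * V))
    if convention == "counterion_excess":
        n_counter = n_salt
        n_co = n_counter - N
    else:  # salt_pairs: coions at the set concentration, N extra counterions
        n_co = n_salt
        n_counter = n_co + N
    if n_co < 0:
        raise ValueError(
            f"cannot neutralise chain of {N} charges with {n_salt} counterions "
            f"(c*V = {c * V:.2f}); enlarge the box or reduce N"
        )
    assert n_counter - n_co - N == 0
    return n_counter, n_co


class _CellGrid:
    """Uniform cell grid for build-time minimum-distance rejection, z-periodic."""

    def __init__(self, Lz: float, cell: float = _MIN_SEPARATION) -> None:
        self.Lz = Lz
        self.cell = cell
        self.nz = max(1, int(Lz / cell))
        self.dz = Lz / self.nz
        self.cells: dict[tuple[int, int, int], list[np.ndarray]] = {}

    def _key(self, p: np.ndarray) -> tuple[int, int, int]:
        return (
            int(math.floor(p[0] / self.cell)),
            int(math.floor(p[1] / self.cell)),
            int(math.floor((p[2] % self.Lz) / self.dz)) % self.nz,
        )

    def add(self, p: np.ndarray) -> None:
        self.cells.setdefault(self._key(p), []).append(np.asarray(p, dtype=float))

    def too_close(self, p: np.ndarray, min_dist: float = _MIN_SEPARATION) -> bool:
        kx, ky, kz = self._key(p)
        md2 = min_dist * min_dist
        for ix in (kx - 1, kx, kx + 1):
            for iy in (ky - 1, ky, ky + 1):
                for iz in (kz - 1, kz, kz + 1):
                    for q in self.cells.get((ix, iy, iz % self.nz), ()):
                        d = p - q
                        d[2] -= self.Lz * round(d[2] / self.Lz)
                        if d @ d < md2:
                            return True
        return False


def _random_point(spec: ChannelSpec, margin: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform point inside the channel, at least ``margin`` off the wall."""
    while True:
        z = rng.uniform(0.0, spec.box_length)
        rmax = float(radius_profile(z, spec)) - margin
        if rmax <= 0:
            continue
        rho = rmax * math.sqrt(rng.uniform())
        phi = rng.uniform(0.0, 2.0 * math.pi)
        return np.array([rho * math.cos(phi), rho * math.sin(phi), z])


def place_chain(
    spec: ChannelSpec,
    N: int,
    rng: np.random.Generator,
    grid: _CellGrid | None = None,
    bond_length: float = 0.97,
    margin: float = 1.0,
    max_attempts: int = 200,
) -> np.ndarray:
    """Grow a self-avoiding bonded chain of ``N`` beads inside the channel.

    Consecutive bead separations equal ``bond_length`` (within [0.8, 1.1]
    sigma); every bead keeps ``margin`` off the wall and at least 0.85 sigma
    from previously placed particles.  Deterministic for a given generator
    state.  Raises ``RuntimeError`` after ``max_attempts`` failed growths.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if not (0.8 <= bond_length <= 1.1):
        raise ValueError("bond_length outside [0.8, 1.1] sigma")
    for _ in range(max_attempts):
        own = _CellGrid(spec.box_length)
        beads = [_random_point(spec, margin, rng)]
        own.add(beads[0])
        ok = True
        for _i in range(1, N):
            placed = False
            for _try in range(60):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                cand = beads[-1] + bond_length * u
                cand[2] %= spec.box_length
                if not contains(cand, spec, margin):
                    continue
                if own.too_close(cand):
                    continue
                if grid is not None and grid.too_close(cand):
                    continue
                beads.append(cand)
                own.add(cand)
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return np.array(beads)
    raise RuntimeError(
        f"failed to grow a chain of {N} beads after {max_attempts} attempts "
        "(channel too narrow or too dense)"
    )


def _lattice_sites(
    spec: ChannelSpec,
    margin: float,
    rng: np.random.Generator,
    n_needed: int,
    grid: _CellGrid,
) -> np.ndarray:
    """Jittered cubic lattice sites inside the channel, >= 0.85 sigma apart
    and clear of previously placed particles; returns ``n_needed`` of them
    in random order."""
    Lz = spec.box_length
    r_hi = spec.mean_radius + (spec.amplitude if spec.harmonic else 0.0)
    for attempt in range(8):
        # shrink the spacing until enough clear sites exist
        surplus = 1.15 + 0.12 * attempt
        V_margin, _ = integrate.quad(
            lambda z: math.pi * max(float(radius_profile(z, spec)) - margin, 0.0) ** 2,
            0.0,
            Lz,
            limit=200,
        )
        a = (V_margin / (n_needed * surplus)) ** (1.0 / 3.0)
        nz = max(1, int(round(Lz / a)))
        az = Lz / nz
        a_min = min(a, az)
        if a_min < 0.855:
            raise RuntimeError(
                f"cannot place {n_needed} particles at >= 0.85 sigma separation "
                f"in accessible volume {V_margin:.0f} sigma^3; system too dense"
            )
        jitter = max(0.0, min(0.06, 0.5 * (a_min - 0.852)))
        nxy = int(math.ceil(2.0 * r_hi / a))
        xs = (np.arange(nxy) - (nxy - 1) / 2.0) * a
        X, Y, Z = np.meshgrid(xs, xs, (np.arange(nz) + 0.5) * az, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        if jitter > 0:
            u = rng.normal(size=pts.shape)
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            pts = pts + u * (jitter * rng.uniform(size=(len(pts), 1)))
        inside = contains(pts, spec, margin)
        pts = pts[inside]
        clear = np.fromiter(
            (not grid.too_close(p) for p in pts), dtype=bool, count=len(pts)
        )
        pts = pts[clear]
        if len(pts) >= n_needed:
            order = rng.permutation(len(pts))[:n_needed]
            chosen = pts[order]
            for p in chosen:
                grid.add(p)
            return chosen
    raise RuntimeError(
        f"could not fit {n_needed} lattice sites inside the channel "
        "(channel too narrow for the requested densities)"
    )


def build_system(cfg: BuildConfig) -> ParticleSystem:
    """Build a neutral system: chain + counterions + coions + solvent + walls.

    Solvent count is ``round(rho_s V)`` over the full accessible volume (the
    short push-off stage relaxes local overpacking); ion counts come from
    :func:`count_ions`.  Initial velocities are Maxwell-Boltzmann at
    ``kBT = 1`` with the mobile centre-of-mass momentum removed.  Identical
    configuration and seed give a bitwise-identical system.
    """
    rng = np.random.default_rng(cfg.seed)
    spec = cfg.spec
    V = accessible_volume(spec)
    N = cfg.chain_length
    n_counter, n_co = count_ions(V, cfg.counterion_concentration, N, cfg.ion_convention)
    n_solvent = int(round(cfg.solvent_density * V))

    walls = build_wall_particles(spec)
    grid = _CellGrid(spec.box_length)
    for w in walls:
        grid.add(w)

    chain = place_chain(spec, N, rng, grid=grid)
    for b in chain:
        grid.add(b)

    # Ions and solvent go on a jittered cubic lattice confined to the channel
    # interior: at the working solvent density random sequential insertion at
    # a 0.85 sigma hard core jams, while a lattice keeps the build-time
    # separation guarantee exactly; the push-off stage melts it.
    n_needed = n_counter + n_co + n_solvent
    sites = _lattice_sites(spec, 0.5, rng, n_needed, grid)
    counter = sites[:n_counter]
    co = sites[n_counter : n_counter + n_co]
    solvent = sites[n_counter + n_co :]

    positions = np.concatenate([chain, counter, co, solvent, walls])
    species = np.array(
        ["M"] * N + ["C+"] * n_counter + ["C-"] * n_co + ["S"] * n_solvent
        + ["W"] * len(walls)
    )
    charges = np.array([SPECIES_CHARGE[s] for s in species])
    bonds = np.column_stack([np.arange(N - 1), np.arange(1, N)])

    n_mobile = N + n_counter + n_co + n_solvent
    velocities = np.zeros_like(positions)
    v = rng.normal(scale=1.0, size=(n_mobile, 3))  # kBT = 1, m = 1
    v -= v.mean(axis=0)
    velocities[:n_mobile] = v

    system = ParticleSystem(
        positions=positions,
        velocities=velocities,
        charges=charges,
        species=species,
        bonds=bonds,
        box_length=spec.box_length,
        spec=spec,
    )
    system.validate()
    return system
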