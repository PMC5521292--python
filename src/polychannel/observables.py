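"""Trajectory observables.

Implements the measurements the study is built around:

* electrophoretic drift velocity of a species (slope of the unwrapped
  centre-of-mass z against time);
* the shell-averaged axial fluid velocity around the chain (lab frame):
  every fluid particle is assigned, once per frame, to the radial shell of
  its *minimum* distance to any chain monomer, and the axial velocities are
  averaged per shell over particles and frames;
* electrolyte friction from the Schurr-type force-autocorrelation integral:
  the bare Coulomb forces exerted on each monomer by the free ions inside a
  control radius are recorded in time, the instantaneous chain-average force
  is subtracted, each monomer's force autocorrelation is integrated over lag
  and divided by kBT, and the total friction is the monomer average;
* wall contacts per monomer, z-extension of the chain, and cross-sectional
  number-density maps.

Statistical errors on time averages use block averaging (10 blocks by
default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .forcefield import ForceFieldParams
from .integrator import ProbeRecord, Trajectory

__all__ = [
    "FlowProfile",
    "FrictionResult",
    "FrictionCurve",
    "block_error",
    "com_drift_velocity",
    "fluid_velocity_profile",
    "coulomb_force_on_monomers",
    "coulomb_force_series",
    "electrolyte_friction",
    "friction_vs_radius",
    "wall_contacts",
    "chain_extension",
    "density_map",
]


def block_error(series: np.ndarray, n_blocks: int = 10) -> float:
    """Standard error of the mean of a time series by block averaging."""
    series = np.asarray(series, dtype=float)
    if len(series) < n_blocks or n_blocks < 2:
        return float("nan")
    usable = (len(series) // n_blocks) * n_blocks
    blocks = series[:usable].reshape(n_blocks, -1).mean(axis=1)
    return float(blocks.std(ddof=1) / np.sqrt(n_blocks))


# ---------------------------------------------------------------------------
# drift velocity
# ---------------------------------------------------------------------------


def com_drift_velocity(traj: Trajectory, species: str = "M") -> tuple[float, float]:
    """Drift velocity of a species along +z, with a standard error.

    Least-squares slope of the unwrapped centre-of-mass z coordinate against
    time.  The error is the ordinary regression standard error of the slope
    (it understates the truth for correlated residuals; use paired seeds for
    run-to-run comparisons).
    """
    idx = traj.indices(species)
    if len(idx) == 0:
        raise ValueError(f"no particles of species {species!r}")
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames to fit a drift")
    z = traj.unwrapped_z()[:, idx].mean(axis=1)
    t = traj.times
    A = np.vstack([t, np.ones_like(t)]).T
    coef, res, *_ = np.linalg.lstsq(A, z, rcond=None)
    slope = float(coef[0])
    if traj.n_frames > 2 and res.size:
        s2 = float(res[0]) / (len(t) - 2)
        var = s2 / float(np.sum((t - t.mean()) ** 2))
        return slope, float(np.sqrt(var))
    return slope, float("nan")


# ---------------------------------------------------------------------------
# shell-averaged fluid flow
# ---------------------------------------------------------------------------


@dataclass
class FlowProfile:
    """Axial fluid velocity binned by minimum distance to the chain."""

    r: np.ndarray  # left shell edges
    dr: float
    v_z: np.ndarray  # mean axial velocity per shell (nan where empty)
    counts: np.ndarray
    sem: np.ndarray  # per-shell standard error over samples

    def populated(self) -> np.ndarray:
        return self.counts > 0


def _min_dist_to_set(points: np.ndarray, refs: np.ndarray, Lz: float) -> np.ndarray:
    """Minimum distance from each point to any reference, z-periodic."""
    d = points[:, None, :] - refs[None, :, :]
    d[:, :, 2] -= Lz * np.round(d[:, :, 2] / Lz)
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d)).min(axis=1)


def fluid_velocity_profile(
    traj: Trajectory,
    r_max: float,
    dr: float = 0.5,
    chain_species: str = "M",
    fluid_species: str = "S",
) -> FlowProfile:
    """Shell-averaged axial fluid velocity around the chain (lab frame).

    Per frame, each fluid particle is placed in the shell ``[r, r + dr)`` of
    its minimum distance to any chain monomer — each particle counts once
    per frame even where the per-monomer control spheres overlap.
    """
    if not (0.0 < dr <= 2.0):
        raise ValueError("dr must lie in (0, 2] sigma")
    mono = traj.indices(chain_species)
    fluid = traj.indices(fluid_species)
    if len(mono) == 0 or len(fluid) == 0:
        raise ValueError("trajectory lacks chain or fluid particles")
    edges = np.arange(0.0, r_max + dr, dr)
    nbins = len(edges) - 1
    sums = np.zeros(nbins)
    sq = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=np.int64)
    for f in range(traj.n_frames):
        dmin = _min_dist_to_set(
            traj.positions[f, fluid], traj.positions[f, mono], traj.box_length
        )
        vz = traj.velocities[f, fluid, 2]
        which = np.floor(dmin / dr).astype(np.intp)
        ok = (which >= 0) & (which < nbins)
        np.add.at(sums, which[ok], vz[ok])
        np.add.at(sq, which[ok], vz[ok] ** 2)
        np.add.at(counts, which[ok], 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        var = np.where(
            counts > 1,
            (sq - counts * mean**2) / np.maximum(counts - 1, 1),
            np.nan,
        )
        sem = np.sqrt(var / np.maximum(counts, 1))
    return FlowProfile(r=edges[:-1], dr=dr, v_z=mean, counts=counts, sem=sem)


# ---------------------------------------------------------------------------
# electrolyte friction (Schurr force-ACF estimator)
# ---------------------------------------------------------------------------


def coulomb_force_on_monomers(
    positions: np.ndarray,
    charges: np.ndarray,
    species: np.ndarray,
    Lz: float,
    r_control: float,
    lB: float = 1.0,
    kBT: float = 1.0,
) -> np.ndarray:
    """Bare Coulomb force of the free ions on each chain monomer.

    For each monomer, sums ``kBT lB q_i q_j / r^2`` over counterions and
    coions within ``r_control`` (z-periodic minimum image).  The bare
    inverse-square law is used here by definition of the estimator,
    independent of the truncation scheme the propagation engine uses.
    """
    mono = np.flatnonzero(species == "M")
    ions = np.flatnonzero((species == "C+") | (species == "C-"))
    out = np.zeros((len(mono), 3))
    if len(ions) == 0:
        return out
    d = positions[mono][:, None, :] - positions[ions][None, :, :]
    d[:, :, 2] -= Lz * np.round(d[:, :, 2] / Lz)
    r2 = np.einsum("ijk,ijk->ij", d, d)
    r = np.sqrt(r2)
    inside = r < r_control
    with np.errstate(divide="ignore", invalid="ignore"):
        mag = kBT * lB * charges[mono][:, None] * charges[ions][None, :] / r2
        fij = np.where(inside[..., None], (mag / r)[..., None] * d, 0.0)
    return fij.sum(axis=1)


def coulomb_force_series(
    probe: ProbeRecord | Trajectory,
    species: np.ndarray | None,
    charges: np.ndarray | None,
    Lz: float,
    r_control: float,
    lB: float = 1.0,
    kBT: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Coulomb-force time series on the monomers, from frames or a probe.

    Returns ``(series, dt_sample)`` with ``series`` of shape
    ``(n_frames, n_monomers, 3)``.  When given a :class:`Trajectory`, its
    own species/charges are used and ``species``/``charges`` may be None.
    """
    if isinstance(probe, Trajectory):
        species = probe.species
        charges = probe.charges
        frames = probe.positions
        times = probe.times
    else:
        frames = probe.positions
        times = probe.times
        if species is None or charges is None:
            raise ValueError("species and charges required with a ProbeRecord")
        species = np.asarray(species)[probe.indices]
        charges = np.asarray(charges)[probe.indices]
    out = np.array(
        [
            coulomb_force_on_monomers(frames[f], charges, species, Lz, r_control, lB, kBT)
            for f in range(len(frames))
        ]
    )
    dt_sample = float(times[1] - times[0]) if len(times) > 1 else float("nan")
    return out, dt_sample


@dataclass
class FrictionResult:
    """Output of the force-autocorrelation friction estimator."""

    xi_total: float
    xi_monomer: np.ndarray
    lags: np.ndarray
    acf: np.ndarray  # monomer-averaged residual-force ACF (3-vector dot)
    running_integral: np.ndarray
    plateaued: bool
    r_control: float | None = None


def _acf_fft(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased-normalisation autocorrelation of a 1-D series up to max_lag."""
    n = len(x)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(fx * np.conj(fx), nfft)[: max_lag + 1]
    return acov / (n - np.arange(max_lag + 1))


def electrolyte_friction(
    force_series: np.ndarray,
    dt_sample: float,
    kBT: float = 1.0,
    lag_cutoff: float | None = None,
    subtract_mean_force: bool = True,
) -> FrictionResult:
    """Friction coefficients from the time integral of the force ACF.

    Parameters
    ----------
    force_series : ndarray, shape (n_samples, n_monomers, 3)
        Coulomb force on each monomer at uniformly spaced times.
    dt_sample : float
        Sampling interval of the series, in tau.
    lag_cutoff : float, optional
        Upper integration limit in time units; defaults to 10% of the series
        duration.  The running integral is returned so the plateau (and the
        slow t^(-3/2) hydrodynamic tail) can be inspected.
    subtract_mean_force : bool
        Subtract the instantaneous chain-average force before correlating
        (the monomeric definition); False correlates each monomer's raw
        force about its time mean instead.

    Notes
    -----
    Per monomer, the stationary autocorrelation of the residual force vector
    (3-component dot product) is integrated by the trapezoid rule up to the
    lag cutoff and divided by kBT; the total friction is the monomer mean.
    A warning is issued when the running integral has not plateaued (more
    than 5% relative drift over the last decade of lags).
    """
    F = np.asarray(force_series, dtype=float)
    if F.ndim == 2:  # (n_samples, 3) single monomer
        F = F[:, None, :]
    n_samples, n_mono, _ = F.shape
    if n_samples < 10:
        raise ValueError("need at least 10 samples")
    if subtract_mean_force:
        resid = F - F.mean(axis=1, keepdims=True)
    else:
        resid = F.copy()
    resid = resid - resid.mean(axis=0, keepdims=True)

    duration = (n_samples - 1) * dt_sample
    if lag_cutoff is None:
        lag_cutoff = 0.1 * duration
    max_lag = min(n_samples - 2, max(2, int(round(lag_cutoff / dt_sample))))
    lags = np.arange(max_lag + 1) * dt_sample

    acf_i = np.zeros((n_mono, max_lag + 1))
    for m in range(n_mono):
        for c in range(3):
            acf_i[m] += _acf_fft(resid[:, m, c], max_lag)
    integrals = np.trapezoid(acf_i, dx=dt_sample, axis=1) / kBT
    acf_mean = acf_i.mean(axis=0)
    running = (
        np.concatenate(
            [[0.0], np.cumsum(0.5 * (acf_mean[1:] + acf_mean[:-1]) * dt_sample)]
        )
        / kBT
    )

    plateaued = True
    if max_lag >= 20:
        tail_start = max(1, int(max_lag / 10))
        tail = running[tail_start:]
        scale = max(abs(running[-1]), 1e-12 * max(abs(acf_mean[0]) * dt_sample, 1e-30))
        drift = abs(tail.max() - tail.min()) / max(abs(running[-1]), scale)
        if abs(running[-1]) > 0 and drift > 0.05:
            plateaued = False
            warnings.warn(
                "friction running integral has not plateaued over the last "
                f"decade of lags (relative drift {drift:.2f}); increase the "
                "series length or the lag cutoff",
                stacklevel=2,
            )
    return FrictionResult(
        xi_total=float(integrals.mean()),
        xi_monomer=integrals,
        lags=lags,
        acf=acf_mean,
        running_integral=running,
        plateaued=plateaued,
    )


@dataclass
class FrictionCurve:
    """Electrolyte friction versus control radius."""

    radii: np.ndarray
    xi: np.ndarray
    results: list[FrictionResult] = field(default_factory=list)

    @property
    def plateau(self) -> float:
        """Mean friction over the three largest control radii."""
        k = min(3, len(self.xi))
        return float(np.mean(self.xi[-k:]))


def friction_vs_radius(
    traj: Trajectory,
    radii,
    params: ForceFieldParams | None = None,
    lag_cutoff: float | None = None,
    use_probe: bool = True,
) -> FrictionCurve:
    """Electrolyte friction evaluated at each control radius.

    Uses the trajectory's fine-strided probe record when present (force
    autocorrelations need denser sampling than typical frame strides);
    otherwise falls back to the frames themselves.
    """
    radii = np.asarray(sorted(radii), dtype=float)
    if len(radii) == 0:
        raise ValueError("radii must be non-empty")
    p = params or ForceFieldParams()
    source: ProbeRecord | Trajectory
    if use_probe and traj.probe is not None:
        source = traj.probe
        species, charges = traj.species, traj.charges
    else:
        source = traj
        species = charges = None
    xi = np.empty(len(radii))
    results = []
    for i, r in enumerate(radii):
        series, dt_sample = coulomb_force_series(
            source, species, charges, traj.box_length, r, p.lB, p.kBT
        )
        res = electrolyte_friction(series, dt_sample, p.kBT, lag_cutoff=lag_cutoff)
        res.r_control = float(r)
        xi[i] = res.xi_total
        results.append(res)
    return FrictionCurve(radii=radii, xi=xi, results=results)


# ---------------------------------------------------------------------------
# wall contacts, extension, density maps
# ---------------------------------------------------------------------------


def wall_contacts(
    traj: Trajectory,
    wall_positions: np.ndarray | None = None,
    cutoff: float = 2.0 ** (1.0 / 6.0),
    chain_species: str = "M",
) -> tuple[float, float]:
    """Mean number of monomer-wall contacts per frame, normalised by N.

    A monomer is in contact when its minimum distance to any wall particle
    is below ``cutoff`` (default the WCA cut).  Returns (mean, block error).
    Wall positions default to the trajectory's own ``W`` particles.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    mono = traj.indices(chain_species)
    if wall_positions is None:
        w = traj.indices("W")
        if len(w) == 0:
            raise ValueError("trajectory has no wall particles; pass wall_positions")
        wall_positions = traj.positions[0, w]
    # static walls: one padded-periodic tree reused across frames
    Lz = traj.box_length
    pad = 100.0
    xy_min = wall_positions[:, :2].min(axis=0) - pad / 2.0
    box = np.array(
        [
            np.ptp(wall_positions[:, 0]) + pad,
            np.ptp(wall_positions[:, 1]) + pad,
            Lz,
        ]
    )
    shifted = wall_positions - np.array([xy_min[0], xy_min[1], 0.0])
    shifted[:, 2] %= Lz
    tree = cKDTree(shifted, boxsize=box)
    per_frame = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        pts = traj.positions[f, mono] - np.array([xy_min[0], xy_min[1], 0.0])
        pts[:, 2] %= Lz
        d, _ = tree.query(pts, k=1)
        per_frame[f] = np.count_nonzero(d < cutoff)
    per_frame /= len(mono)
    return float(per_frame.mean()), block_error(per_frame)


def _unwrap_chain_z(z_wrapped: np.ndarray, Lz: float) -> np.ndarray:
    """Make the chain whole in z by walking minimum-image bond steps."""
    dz = np.diff(z_wrapped)
    dz -= Lz * np.round(dz / Lz)
    if np.any(np.abs(dz) > Lz / 2):
        raise ValueError("chain cannot be made whole: a bond exceeds Lz/2")
    return z_wrapped[0] + np.concatenate([[0.0], np.cumsum(dz)])


def chain_extension(
    traj: Trajectory, b: float = 0.93, chain_species: str = "M"
) -> tuple[float, float]:
    """Mean z-extension |zmax - zmin| of the chain, normalised by b N.

    The chain is made whole across the periodic boundary (minimum-image walk
    along the bonds) before taking the extent.  Returns (mean, block error).
    """
    mono = traj.indices(chain_species)
    N = len(mono)
    if N < 2:
        raise ValueError("need at least 2 monomers")
    per_frame = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        z = _unwrap_chain_z(traj.positions[f, mono, 2], traj.box_length)
        per_frame[f] = z.max() - z.min()
    per_frame /= b * N
    return float(per_frame.mean()), block_error(per_frame)


def density_map(
    traj: Trajectory,
    species: str,
    extent: float | None = None,
    bins: int = 40,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cross-sectional (x, y) number-density map of a species.

    Counts per bin are averaged over frames and along z, then divided by the
    bin volume (bin area x box length), giving a density in sigma^-3.
    Returns ``(H, x_edges, y_edges)`` with ``H[i, j]`` the density in x-bin
    ``i``, y-bin ``j``.  A species with no particles gives an all-zero map.
    """
    idx = traj.indices(species)
    if extent is None:
        if traj.n_frames and len(idx):
            extent = float(
                np.abs(traj.positions[:, idx, :2]).max() * 1.05
            )
        else:
            extent = 1.0
        extent = max(extent, 1e-6)
    edges = np.linspace(-extent, extent, bins + 1)
    H = np.zeros((bins, bins))
    for f in range(traj.n_frames):
        h, _, _ = np.histogram2d(
            traj.positions[f, idx, 0], traj.positions[f, idx, 1], bins=(edges, edges)
        )
        H += h
    bin_area = (edges[1] - edges[0]) ** 2
    frames = max(traj.n_frames, 1)
    H /= frames * bin_area * traj.box_length
    return H, edges, edges
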