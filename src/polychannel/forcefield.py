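"""Pair interactions and the force engine.

All species are unit-mass WCA spheres.  Chain monomers are additionally
connected by FENE springs (bonded pairs keep their WCA repulsion, so the
equilibrium bond length emerges from the FENE/WCA/Coulomb balance), charged
species interact through a shifted-force truncated Coulomb potential with
Bjerrum length ``lB``, and charges feel the applied electric field.  Wall
particles exert WCA forces on mobile particles but are fixed and accumulate
none.

Everything is expressed in reduced Lennard-Jones units: sigma (length),
kBT (energy), m (mass), tau = sigma sqrt(m/kBT) (time).

The Coulomb sum is a shifted-force truncation (force and energy continuous
and zero at the cut).  At the working salt concentration the Debye length is
about 1.17 sigma, so interactions beyond the default 8-sigma cut are
screened to negligibility; the engine keeps the electrostatics behind a
single code path so a lattice-sum backend could be swapped in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels

__all__ = [
    "ForceFieldParams",
    "FeneBlowupError",
    "wca_pair",
    "fene_bond",
    "coulomb_pair",
    "field_force",
    "total_forces",
    "ForceEngine",
]


class FeneBlowupError(RuntimeError):
    """A FENE bond reached its maximum extension (integration blow-up)."""


@dataclass(frozen=True)
class ForceFieldParams:
    """Force-field constants in reduced LJ units.

    Defaults are the working values of the model: FENE spring constant
    ``k_FENE = 7 kBT/sigma^2`` with maximum extension ``R0_FENE = 2.4 sigma``,
    WCA with ``eps_LJ = 1 kBT`` cut at ``2^(1/6) sigma``, Bjerrum length
    ``lB = 1 sigma``, and a Coulomb cut of 8 sigma.
    """

    k_fene: float = 7.0
    r0_fene: float = 2.4
    eps_lj: float = 1.0
    sigma_lj: float = 1.0
    lB: float = 1.0
    coulomb_cut: float = 8.0
    kBT: float = 1.0

    def __post_init__(self) -> None:
        if self.r0_fene <= self.sigma_lj:
            raise ValueError("r0_fene must exceed sigma_lj")
        for name in ("k_fene", "eps_lj", "sigma_lj", "lB", "coulomb_cut", "kBT"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def wca_cut(self) -> float:
        return 2.0 ** (1.0 / 6.0) * self.sigma_lj


def wca_pair(r, p: ForceFieldParams):
    """WCA energy and radial force magnitude at separation ``r``.

    ``U = 4 eps [(s/r)^12 - (s/r)^6] + eps`` for ``r < 2^(1/6) s``, zero
    beyond; the force is ``-dU/dr`` and both vanish continuously at the cut.
    """
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    u = np.zeros_like(r)
    f = np.zeros_like(r)
    inside = r < p.wca_cut
    if np.any(inside):
        sr6 = (p.sigma_lj / r[inside]) ** 6
        u[inside] = 4.0 * p.eps_lj * (sr6 * sr6 - sr6) + p.eps_lj
        f[inside] = 24.0 * p.eps_lj * (2.0 * sr6 * sr6 - sr6) / r[inside]
    if scalar:
        return float(u[0]), float(f[0])
    return u, f


def fene_bond(r, p: ForceFieldParams):
    """FENE energy and attractive force magnitude at separation ``r``.

    ``U = -(k R0^2 / 2) ln(1 - (r/R0)^2)``; raises :class:`FeneBlowupError`
    at or beyond the maximum extension ``R0``.
    """
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    if np.any(r >= p.r0_fene) or np.any(r < 0):
        raise FeneBlowupError(
            f"FENE bond length {float(np.max(r)):.4f} >= maximum extension "
            f"{p.r0_fene}; the integration has blown up"
        )
    x2 = (r / p.r0_fene) ** 2
    u = -0.5 * p.k_fene * p.r0_fene**2 * np.log1p(-x2)
    f = p.k_fene * r / (1.0 - x2)
    if scalar:
        return float(u[0]), float(f[0])
    return u, f


def coulomb_pair(r, qi, qj, p: ForceFieldParams):
    """Shifted-force truncated Coulomb energy and radial force magnitude.

    Below the cut: ``U = kBT lB qi qj (1/r - 1/rc + (r - rc)/rc^2)`` and
    ``F = kBT lB qi qj (1/r^2 - 1/rc^2)``; both are continuous and vanish at
    ``rc``.  Positive force magnitude means repulsion.
    """
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    pref = p.kBT * p.lB * np.asarray(qi, dtype=float) * np.asarray(qj, dtype=float)
    rc = p.coulomb_cut
    u = np.zeros(np.broadcast_shapes(r.shape, np.shape(pref)))
    f = np.zeros_like(u)
    inside = np.broadcast_to(r < rc, u.shape)
    rr = np.broadcast_to(r, u.shape)[inside]
    pp = np.broadcast_to(pref, u.shape)[inside]
    u[inside] = pp * (1.0 / rr - 1.0 / rc + (rr - rc) / rc**2)
    f[inside] = pp * (1.0 / rr**2 - 1.0 / rc**2)
    if scalar and u.ndim <= 1 and u.size == 1:
        return float(u.ravel()[0]), float(f.ravel()[0])
    return u, f


def field_force(q, E):
    """Force ``q E`` of the applied electric field on charge(s) ``q``."""
    q = np.asarray(q, dtype=float)
    E = np.asarray(E, dtype=float)
    return q[..., None] * E if q.ndim else q * E


def _min_image_dz(dz: np.ndarray, Lz: float) -> np.ndarray:
    return dz - Lz * np.round(dz / Lz)


def _accumulate(n: int, i: np.ndarray, j: np.ndarray, fij: np.ndarray) -> np.ndarray:
    """Sum pairwise forces ``fij`` (acting on i, reaction on j) per particle."""
    out = np.empty((n, 3))
    for c in range(3):
        out[:, c] = np.bincount(i, weights=fij[:, c], minlength=n) - np.bincount(
            j, weights=fij[:, c], minlength=n
        )
    return out


class ForceEngine:
    """Neighbor-listed force/energy evaluator for a fixed particle set.

    Positions are (n, 3) with z periodic over ``Lz``; walls (``mobile`` mask
    false) never move, so wall-wall pairs are dropped from the lists.  Pair
    lists are Verlet lists with a skin, rebuilt when any particle has moved
    more than half the skin since the last build.
    """

    def __init__(
        self,
        charges: np.ndarray,
        bonds: np.ndarray,
        mobile: np.ndarray,
        Lz: float,
        params: ForceFieldParams,
        skin: float = 0.4,
        exclude_bonded_wca: bool = False,
        wall_positions: np.ndarray | None = None,
        spec=None,
    ) -> None:
        self.q = np.asarray(charges, dtype=float)
        self.bonds = np.asarray(bonds, dtype=np.intp).reshape(-1, 2)
        self.mobile = np.asarray(mobile, dtype=bool)
        self.n = len(self.q)
        self.Lz = float(Lz)
        self.p = params
        self.skin = float(skin)
        self.exclude_bonded_wca = bool(exclude_bonded_wca)
        self.charged_idx = np.flatnonzero(self.q != 0.0)
        self.mobile_idx = np.flatnonzero(self.mobile)
        self.wall_idx = np.flatnonzero(~self.mobile)
        self.spec = spec  # channel geometry; enables the near-wall filter
        self._wall_tree: cKDTree | None = None
        self._pairs_wca: np.ndarray | None = None
        self._pairs_coul: np.ndarray | None = None
        self._ref_pos: np.ndarray | None = None
        self._bonded_set: set[tuple[int, int]] = {
            (min(a, b), max(a, b)) for a, b in self.bonds
        }
        # Force cap used during push-off equilibration (None = full WCA).
        self.force_cap: float | None = None

    # -- neighbor lists ---------------------------------------------------

    def _tree(self, pos: np.ndarray, reach: float) -> cKDTree:
        # Only z is periodic.  cKDTree supports fully periodic boxes, so we
        # embed x and y in a padded box wide enough that spurious periodic
        # images lie far beyond the search radius.
        pad = 4.0 * reach + 1.0
        xy_min = pos[:, :2].min(axis=0)
        xy_extent = pos[:, :2].max(axis=0) - xy_min
        box = np.array([xy_extent[0] + pad, xy_extent[1] + pad, self.Lz])
        shifted = np.empty_like(pos)
        shifted[:, 0] = pos[:, 0] - xy_min[0] + pad / 2.0
        shifted[:, 1] = pos[:, 1] - xy_min[1] + pad / 2.0
        shifted[:, 2] = np.mod(pos[:, 2], self.Lz)
        return cKDTree(shifted, boxsize=box)

    def _wall_pairs(self, pos: np.ndarray, reach: float) -> np.ndarray:
        """Mobile-wall candidate pairs within ``reach`` of the wall surface.

        When the channel geometry is known, mobile particles further than
        ``reach`` from the analytic surface are skipped before querying the
        static wall tree; otherwise all mobile particles are queried.
        """
        wi = self.wall_idx
        if len(wi) == 0:
            return np.empty((0, 2), dtype=np.intp)
        if self._wall_tree is None:
            wp = pos[wi].copy()
            self._wall_xy_min = wp[:, :2].min(axis=0) - 2.0 * reach - 1.0
            wp[:, 0] -= self._wall_xy_min[0]
            wp[:, 1] -= self._wall_xy_min[1]
            wp[:, 2] = np.mod(wp[:, 2], self.Lz)
            extent = wp[:, :2].max(axis=0) + 2.0 * reach + 1.0
            self._wall_box = np.array([extent[0], extent[1], self.Lz])
            self._wall_tree = cKDTree(wp, boxsize=self._wall_box)
        cand = self.mobile_idx
        if self.spec is not None:
            from .channel import radius_profile

            z = np.mod(pos[cand, 2], self.Lz)
            rho = np.hypot(pos[cand, 0], pos[cand, 1])
            # the radial gap overestimates the true surface distance by at
            # most the surface metric factor sqrt(1 + max|dr/dz|^2)
            slope = self.spec.amplitude * self.spec.omega if self.spec.harmonic else 0.0
            factor = float(np.sqrt(1.0 + slope * slope))
            near = radius_profile(z, self.spec) - rho < (reach + 0.1) * factor
            cand = cand[near]
        if len(cand) == 0:
            return np.empty((0, 2), dtype=np.intp)
        pts = pos[cand].copy()
        pts[:, 0] -= self._wall_xy_min[0]
        pts[:, 1] -= self._wall_xy_min[1]
        pts[:, 2] = np.mod(pts[:, 2], self.Lz)
        # clip into the wall tree's box (points beyond it cannot have wall
        # neighbors within reach anyway)
        pts[:, 0] = np.clip(pts[:, 0], 0.0, self._wall_box[0] * (1 - 1e-12))
        pts[:, 1] = np.clip(pts[:, 1], 0.0, self._wall_box[1] * (1 - 1e-12))
        kmax = 32
        dist, idx = self._wall_tree.query(pts, k=kmax, distance_upper_bound=reach)
        hit = idx < len(wi)
        # saturated rows (all kmax neighbors within reach) fall back to an
        # exact ball query; concave undulation troughs can exceed kmax
        sat = hit.all(axis=1)
        rows_i, rows_j = np.nonzero(hit)
        out_i = [cand[rows_i]]
        out_j = [idx[rows_i, rows_j]]
        if np.any(sat):
            for k in np.flatnonzero(sat):
                lst = self._wall_tree.query_ball_point(pts[k], reach)
                extra = np.setdiff1d(np.array(lst, dtype=np.intp), idx[k][hit[k]])
                if len(extra):
                    out_i.append(np.full(len(extra), cand[k], dtype=np.intp))
                    out_j.append(extra)
        ii = np.concatenate(out_i)
        jj = np.concatenate(out_j)
        if len(ii) == 0:
            return np.empty((0, 2), dtype=np.intp)
        return np.column_stack([ii.astype(np.intp), wi[jj]])

    def rebuild(self, pos: np.ndarray) -> None:
        reach = self.p.wca_cut + self.skin
        mi = self.mobile_idx
        mtree = self._tree(pos[mi], reach)
        mpairs = mtree.query_pairs(reach, output_type="ndarray")
        pairs = mi[mpairs] if len(mpairs) else np.empty((0, 2), dtype=np.intp)
        if self.exclude_bonded_wca and len(pairs):
            mask = np.fromiter(
                ((min(a, b), max(a, b)) not in self._bonded_set for a, b in pairs),
                dtype=bool,
                count=len(pairs),
            )
            pairs = pairs[mask]
        wpairs = self._wall_pairs(pos, reach)
        if len(wpairs):
            pairs = np.concatenate([pairs, wpairs]) if len(pairs) else wpairs
        self._pairs_wca = np.ascontiguousarray(pairs, dtype=np.intp)

        ci = self.charged_idx
        if len(ci) > 1:
            ctree = self._tree(pos[ci], self.p.coulomb_cut + self.skin)
            cpairs = ctree.query_pairs(
                self.p.coulomb_cut + self.skin, output_type="ndarray"
            )
            self._pairs_coul = np.ascontiguousarray(
                ci[cpairs] if len(cpairs) else np.empty((0, 2)), dtype=np.intp
            )
        else:
            self._pairs_coul = np.empty((0, 2), dtype=np.intp)
        self._ref_pos = pos.copy()

    def _maybe_rebuild(self, pos: np.ndarray) -> None:
        if self._ref_pos is None or self._pairs_wca is None:
            self.rebuild(pos)
            return
        disp = pos - self._ref_pos
        disp[:, 2] = _min_image_dz(disp[:, 2], self.Lz)
        if np.max(np.abs(disp)) > 0.5 * self.skin:
            self.rebuild(pos)

    # -- evaluation -------------------------------------------------------

    def _pair_geometry(self, pos: np.ndarray, pairs: np.ndarray):
        d = pos[pairs[:, 0]] - pos[pairs[:, 1]]
        d[:, 2] = _min_image_dz(d[:, 2], self.Lz)
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        return d, r

    def forces(
        self,
        pos: np.ndarray,
        E: np.ndarray | None = None,
        with_energy: bool = False,
    ):
        """Total forces (n, 3); optionally also the potential energy.

        The energy excludes the applied-field term (the field is the
        external drive; runs that check energy conservation are field-free).
        """
        self._maybe_rebuild(pos)
        p = self.p
        f = np.zeros((self.n, 3))

        if _kernels.HAVE_NUMBA:
            energy = 0.0
            cap = self.force_cap if self.force_cap is not None else -1.0
            if len(self._pairs_wca):
                energy += _kernels.wca_kernel(
                    pos, self._pairs_wca, self.Lz, p.eps_lj, p.sigma_lj,
                    p.wca_cut, cap, f,
                )
            if len(self.bonds):
                e_fene, rmax = _kernels.fene_kernel(
                    pos, self.bonds, self.Lz, p.k_fene, p.r0_fene, f
                )
                if rmax >= p.r0_fene:
                    raise FeneBlowupError(
                        f"FENE bond stretched to {rmax:.4f} >= {p.r0_fene}"
                    )
                energy += e_fene
            if len(self._pairs_coul):
                energy += _kernels.coulomb_kernel(
                    pos, self._pairs_coul, self.q, self.Lz,
                    p.kBT * p.lB, p.coulomb_cut, f,
                )
            if E is not None:
                E = np.asarray(E, dtype=float)
                if np.any(E != 0.0):
                    f += self.q[:, None] * E
            f[~self.mobile] = 0.0
            if with_energy:
                return f, energy
            return f

        energy = 0.0
        pairs = self._pairs_wca
        if pairs is not None and len(pairs):
            d, r = self._pair_geometry(pos, pairs)
            inside = r < p.wca_cut
            if np.any(inside):
                pi = pairs[inside]
                ri = r[inside]
                di = d[inside]
                sr6 = (p.sigma_lj / ri) ** 6
                fmag = 24.0 * p.eps_lj * (2.0 * sr6 * sr6 - sr6) / ri
                if self.force_cap is not None:
                    fmag = np.minimum(fmag, self.force_cap)
                fij = (fmag / ri)[:, None] * di
                f += _accumulate(self.n, pi[:, 0], pi[:, 1], fij)
                if with_energy:
                    energy += float(
                        np.sum(4.0 * p.eps_lj * (sr6 * sr6 - sr6) + p.eps_lj)
                    )

        if len(self.bonds):
            d, r = self._pair_geometry(pos, self.bonds)
            if np.any(r >= p.r0_fene):
                raise FeneBlowupError(
                    f"FENE bond stretched to {float(r.max()):.4f} >= {p.r0_fene}"
                )
            x2 = (r / p.r0_fene) ** 2
            fmag = -p.k_fene * r / (1.0 - x2)  # attractive
            fij = (fmag / r)[:, None] * d
            f += _accumulate(self.n, self.bonds[:, 0], self.bonds[:, 1], fij)
            if with_energy:
                energy += float(np.sum(-0.5 * p.k_fene * p.r0_fene**2 * np.log1p(-x2)))

        pairs = self._pairs_coul
        if pairs is not None and len(pairs):
            d, r = self._pair_geometry(pos, pairs)
            inside = r < p.coulomb_cut
            if np.any(inside):
                pi = pairs[inside]
                ri = r[inside]
                di = d[inside]
                pref = p.kBT * p.lB * self.q[pi[:, 0]] * self.q[pi[:, 1]]
                rc = p.coulomb_cut
                fmag = pref * (1.0 / ri**2 - 1.0 / rc**2)
                fij = (fmag / ri)[:, None] * di
                f += _accumulate(self.n, pi[:, 0], pi[:, 1], fij)
                if with_energy:
                    energy += float(
                        np.sum(pref * (1.0 / ri - 1.0 / rc + (ri - rc) / rc**2))
                    )

        if E is not None:
            E = np.asarray(E, dtype=float)
            if np.any(E != 0.0):
                f += self.q[:, None] * E

        f[~self.mobile] = 0.0
        if with_energy:
            return f, energy
        return f


def total_forces(system, spec, params: ForceFieldParams, E=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Per-particle forces for a :class:`~polychannel.builder.ParticleSystem`.

    Convenience wrapper that assembles a fresh :class:`ForceEngine` over the
    system's particles (walls included); for stepping, build the engine once
    and reuse it.
    """
    engine = ForceEngine(
        charges=system.charges,
        bonds=system.bonds,
        mobile=system.mobile_mask,
        Lz=system.box_length,
        params=params,
        spec=getattr(system, "spec", None),
    )
    return engine.forces(system.positions, E=np.asarray(E, dtype=float))
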