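"""Pair potentials and the neighbor-listed force engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import polychannel as pc
from polychannel.forcefield import FeneBlowupError, ForceEngine, ForceFieldParams

P = ForceFieldParams()
WCA_CUT = 2.0 ** (1.0 / 6.0)


def brute_forces(pos, charges, bonds, mobile, Lz, p, E=None):
    """All-pairs double-loop reference (independent of the engine)."""
    n = len(pos)
    F = np.zeros((n, 3))
    for i in range(n):
        for j in range(i + 1, n):
            if not (mobile[i] or mobile[j]):
                continue
            d = pos[i] - pos[j]
            d[2] -= Lz * round(d[2] / Lz)
            r = np.linalg.norm(d)
            fmag = 0.0
            if r < p.wca_cut:
                sr6 = (p.sigma_lj / r) ** 6
                fmag += 24 * p.eps_lj * (2 * sr6**2 - sr6) / r
            if charges[i] != 0 and charges[j] != 0 and r < p.coulomb_cut:
                fmag += (
                    p.kBT
                    * p.lB
                    * charges[i]
                    * charges[j]
                    * (1 / r**2 - 1 / p.coulomb_cut**2)
                )
            fij = fmag * d / r
            F[i] += fij
            F[j] -= fij
    for a, b in bonds:
        d = pos[a] - pos[b]
        d[2] -= Lz * round(d[2] / Lz)
        r = np.linalg.norm(d)
        fmag = -p.k_fene * r / (1 - (r / p.r0_fene) ** 2)
        F[a] += fmag * d / r
        F[b] -= fmag * d / r
    if E is not None:
        F += charges[:, None] * np.asarray(E)
    F[~mobile] = 0.0
    return F


class TestWCA:
    def test_zero_at_and_beyond_cut(self):
        assert pc.wca_pair(WCA_CUT, P) == (0.0, 0.0)
        assert pc.wca_pair(1.5, P) == (0.0, 0.0)

    def test_contact_values(self):
        u, f = pc.wca_pair(1.0, P)
        assert u == pytest.approx(1.0)
        assert f == pytest.approx(24.0)

    def test_energy_force_consistency(self):
        r = np.linspace(0.8, WCA_CUT - 1e-3, 500)
        h = 1e-6
        f = pc.wca_pair(r, P)[1]
        cd = -(pc.wca_pair(r + h, P)[0] - pc.wca_pair(r - h, P)[0]) / (2 * h)
        assert np.allclose(cd, f, rtol=1e-6, atol=1e-6)

    def test_continuous_at_cut(self):
        u, f = pc.wca_pair(WCA_CUT - 1e-8, P)
        assert abs(u) < 1e-6 and abs(f) < 1e-6


class TestFENE:
    def test_zero_at_origin(self):
        assert pc.fene_bond(0.0, P) == (0.0, 0.0)

    def test_reference_point(self):
        u, f = pc.fene_bond(1.2, P)
        assert u == pytest.approx(-0.5 * 7 * 2.4**2 * np.log(0.75), rel=1e-12)
        assert u == pytest.approx(5.800, abs=1e-3)
        assert f == pytest.approx(11.2, rel=1e-12)

    def test_blowup_at_max_extension(self):
        with pytest.raises(FeneBlowupError):
            pc.fene_bond(2.4, P)

    def test_energy_force_consistency(self):
        r = np.linspace(0.01, 2.3, 500)
        h = 1e-7
        f = pc.fene_bond(r, P)[1]
        cd = (pc.fene_bond(r + h, P)[0] - pc.fene_bond(r - h, P)[0]) / (2 * h)
        assert np.allclose(cd, f, rtol=1e-5, atol=1e-6)  # attractive: dU/dr = |F|


class TestCoulomb:
    def test_force_magnitude_large_cut(self):
        p = ForceFieldParams(coulomb_cut=1000.0)
        u, f = pc.coulomb_pair(1.0, 1, 1, p)
        assert f == pytest.approx(1.0, rel=1e-5)

    def test_antisymmetry_in_charge(self):
        u1, f1 = pc.coulomb_pair(1.0, 1, -1, P)
        u2, f2 = pc.coulomb_pair(1.0, 1, 1, P)
        assert u1 == pytest.approx(-u2)
        assert f1 == pytest.approx(-f2)

    def test_zero_beyond_cut(self):
        assert pc.coulomb_pair(P.coulomb_cut, 1, 1, P) == (0.0, 0.0)
        assert pc.coulomb_pair(P.coulomb_cut + 1, 1, -1, P) == (0.0, 0.0)

    def test_shifted_force_continuity_at_cut(self):
        u, f = pc.coulomb_pair(P.coulomb_cut - 1e-7, 1, 1, P)
        assert abs(u) < 1e-10 and abs(f) < 1e-7

    def test_energy_force_consistency(self):
        r = np.linspace(0.5, P.coulomb_cut - 1e-3, 500)
        h = 1e-6
        f = pc.coulomb_pair(r, 1.0, 1.0, P)[1]
        cd = (
            -(
                pc.coulomb_pair(r + h, 1.0, 1.0, P)[0]
                - pc.coulomb_pair(r - h, 1.0, 1.0, P)[0]
            )
            / (2 * h)
        )
        assert np.allclose(cd, f, rtol=1e-5, atol=1e-6)


class TestFieldForce:
    @pytest.mark.parametrize(
        "q,E,expected",
        [
            (-1, (0, 0, 1), (0, 0, -1)),
            (1, (1, 0, 1), (1, 0, 1)),
            (0, (1, 1, 1), (0, 0, 0)),
        ],
    )
    def test_examples(self, q, E, expected):
        np.testing.assert_allclose(pc.field_force(q, np.array(E, float)), expected)


def _random_charged_system(rng, n=60, Lz=12.0, min_sep=0.9):
    """Random dilute configuration with a minimum separation (keeps forces
    moderate so engine-vs-oracle agreement at 1e-10 absolute is meaningful)."""
    pos = rng.uniform(0, Lz, size=(n, 3))
    pos[:, :2] = rng.uniform(-4, 4, size=(n, 2))
    keep = []
    for i in range(n):
        ok = True
        for j in keep:
            d = pos[i] - pos[j]
            d[2] -= Lz * round(d[2] / Lz)
            if np.linalg.norm(d) < min_sep:
                ok = False
                break
        if ok:
            keep.append(i)
    pos = pos[keep]
    n = len(pos)
    charges = rng.choice([-1.0, 0.0, 1.0], size=n)
    mobile = rng.uniform(size=n) > 0.2
    return pos, charges, mobile


class TestEngineAgainstBruteForce:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        Lz = 12.0
        pos, charges, mobile = _random_charged_system(rng, Lz=Lz)
        n = len(pos)
        # bond mobile pairs that happen to lie inside the FENE domain
        mob_idx = np.flatnonzero(mobile)
        bonds = []
        for a, b in zip(mob_idx[:-1], mob_idx[1:]):
            d = pos[a] - pos[b]
            d[2] -= Lz * round(d[2] / Lz)
            if np.linalg.norm(d) < 2.0:
                bonds.append((a, b))
        bonds = np.array(bonds, dtype=np.intp).reshape(-1, 2)
        eng = ForceEngine(charges, bonds, mobile, Lz, P)
        f = eng.forces(pos)
        ref = brute_forces(pos, charges, bonds, mobile, Lz, P)
        assert np.max(np.abs(f - ref)) < 1e-10

    def test_newtons_third_law(self, rng):
        pos, charges, mobile = _random_charged_system(rng, n=100)
        mobile[:] = True  # no walls: internal forces must sum to zero
        eng = ForceEngine(charges, np.empty((0, 2), int), mobile, 12.0, P)
        f = eng.forces(pos)
        assert np.abs(f.sum(axis=0)).max() < 1e-9

    def test_two_distant_solvent_particles_feel_nothing(self):
        pos = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.5]])
        eng = ForceEngine(
            np.zeros(2), np.empty((0, 2), int), np.ones(2, bool), 20.0, P
        )
        f = eng.forces(pos, E=np.array([0.0, 0.0, 1.0]))
        assert np.all(f == 0.0)

    def test_pair_list_reuse_after_small_displacement(self, rng):
        pos, charges, mobile = _random_charged_system(rng, n=80)
        mobile[:] = True
        eng = ForceEngine(charges, np.empty((0, 2), int), mobile, 12.0, P)
        eng.forces(pos)
        pos2 = pos + rng.normal(scale=0.02, size=pos.shape)
        f = eng.forces(pos2)  # reused Verlet list
        ref = brute_forces(pos2, charges, np.empty((0, 2), int), mobile, 12.0, P)
        assert np.max(np.abs(f - ref)) < 1e-10

    def test_energy_matches_pair_sums(self, rng):
        pos, charges, mobile = _random_charged_system(rng, n=40)
        mobile[:] = True
        eng = ForceEngine(charges, np.empty((0, 2), int), mobile, 12.0, P)
        _, e = eng.forces(pos, with_energy=True)
        ref = 0.0
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                d = pos[i] - pos[j]
                d[2] -= 12.0 * round(d[2] / 12.0)
                r = np.linalg.norm(d)
                ref += pc.wca_pair(r, P)[0]
                ref += pc.coulomb_pair(r, charges[i], charges[j], P)[0]
        assert e == pytest.approx(ref, rel=1e-9, abs=1e-9)

    def test_fene_blowup_propagates(self):
        pos = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 2.5]])
        eng = ForceEngine(
            np.zeros(2), np.array([[0, 1]]), np.ones(2, bool), 50.0, P
        )
        with pytest.raises(FeneBlowupError):
            eng.forces(pos)

    def test_wall_near_surface_filter_with_undulating_spec(self):
        # forces from fixed wall particles must match brute force when the
        # analytic near-surface prefilter is active
        spec = pc.ChannelSpec(mean_radius=4.0, amplitude=1.0, harmonic=8, box_length=57.11)
        walls = pc.build_wall_particles(spec)
        rng = np.random.default_rng(5)
        nm = 40
        mob_pos = []
        while len(mob_pos) < nm:
            p = rng.uniform([-4, -4, 0], [4, 4, spec.box_length])
            if not pc.contains(p, spec, 0.6):
                continue
            if any(np.linalg.norm(p - q) < 0.9 for q in mob_pos):
                continue
            mob_pos.append(p)
        pos = np.concatenate([np.array(mob_pos), walls])
        charges = np.zeros(len(pos))
        mobile = np.zeros(len(pos), bool)
        mobile[:nm] = True
        eng = ForceEngine(charges, np.empty((0, 2), int), mobile, spec.box_length, P, spec=spec)
        f = eng.forces(pos)
        ref = brute_forces(pos, charges, np.empty((0, 2), int), mobile, spec.box_length, P)
        assert np.max(np.abs(f - ref)) < 1e-10
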