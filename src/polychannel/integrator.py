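"""Time integration: velocity-Verlet with Nosé-Hoover NVT coupling.

The equations of motion are integrated with a velocity-Verlet core wrapped
in half-step Nosé-Hoover thermostat updates.  Because the applied field
drives steady streaming (electroosmotic flow of ions and solvent), the
thermostat is profile-unbiased by default: it measures and damps *peculiar*
velocities, i.e. velocities relative to the instantaneous mean velocity of
each mobile species (monomers, counterions, coions, solvent separately), so
that the drift the observables measure is not thermostatted away as heat.
A naive lab-frame coupling is available for comparison.

z is the periodic direction; wrapped coordinates are kept in [0, Lz) and an
additive unwrap offset is tracked per particle so drift observables can use
continuous coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .builder import ParticleSystem
from .channel import ChannelSpec
from .forcefield import ForceEngine, ForceFieldParams

__all__ = [
    "FieldSchedule",
    "ThermostatState",
    "Trajectory",
    "ProbeRecord",
    "field_at",
    "Simulation",
    "SimulationError",
    "nvt_step",
]


class SimulationError(RuntimeError):
    """A run failed mid-production; the partial trajectory recorded up to
    the failure is attached as ``partial_trajectory``."""

    def __init__(self, message: str, partial_trajectory: "Trajectory") -> None:
        super().__init__(message)
        self.partial_trajectory = partial_trajectory


@dataclass(frozen=True)
class FieldSchedule:
    """Applied electric field versus time, in units of kBT/(e sigma).

    ``constant`` mode applies ``(E_perp, 0, E_par)`` for all time (the
    transverse axis is fixed to laboratory x; the channel axis is z).
    ``pulsed`` mode alternates between ``(E_perp, 0, E_par)`` and
    ``(0, 0, -E_par)`` every ``half_period`` time units.
    """

    mode: str = "constant"
    E_par: float = 1.0
    E_perp: float = 0.0
    half_period: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "pulsed"):
            raise ValueError(f"unknown field mode {self.mode!r}")
        if self.mode == "pulsed" and self.half_period <= 0:
            raise ValueError("half_period must be positive in pulsed mode")


def field_at(t: float, s: FieldSchedule) -> np.ndarray:
    """Field vector at time ``t`` under schedule ``s``."""
    if s.mode == "constant":
        return np.array([s.E_perp, 0.0, s.E_par])
    if int(math.floor(t / s.half_period)) % 2 == 0:
        return np.array([s.E_perp, 0.0, s.E_par])
    return np.array([0.0, 0.0, -s.E_par])


@dataclass
class ThermostatState:
    """Nosé-Hoover friction variable and coupling mass."""

    zeta: float = 0.0
    Q: float = 1.0
    T_target: float = 1.0

    def __post_init__(self) -> None:
        if self.Q <= 0:
            raise ValueError("thermostat mass Q must be positive")


@dataclass
class ProbeRecord:
    """Fine-strided record of a particle subset during production."""

    indices: np.ndarray
    times: np.ndarray
    positions: np.ndarray  # (frames, len(indices), 3), wrapped
    stride: int = 0


@dataclass
class Trajectory:
    """Strided frames of a run plus the static particle metadata.

    ``positions`` are wrapped into [0, Lz) in z; ``offsets`` holds the
    per-particle additive z unwrap offset, so the continuous coordinate is
    ``positions[..., 2] + offsets``.
    """

    times: np.ndarray
    positions: np.ndarray  # (frames, n, 3)
    offsets: np.ndarray  # (frames, n)
    velocities: np.ndarray  # (frames, n, 3)
    species: np.ndarray
    charges: np.ndarray
    bonds: np.ndarray
    box_length: float
    stride: int = 1
    dt: float = 0.008
    metadata: dict = field(default_factory=dict)
    probe: ProbeRecord | None = None

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def unwrapped_z(self) -> np.ndarray:
        return self.positions[:, :, 2] + self.offsets

    def indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.species == label)

    def validate(self) -> None:
        if self.n_frames >= 2:
            dtimes = np.diff(self.times)
            if np.any(dtimes <= 0):
                raise ValueError("frame times must be strictly increasing")
        resid = np.mod(self.offsets, self.box_length)
        resid = np.minimum(resid, self.box_length - resid)
        if resid.size and np.max(resid) > 1e-6:
            raise ValueError("unwrap offsets are not multiples of the box length")


class Simulation:
    """Stateful integrator bound to one particle system.

    Parameters
    ----------
    system : ParticleSystem
        Built system (walls included); its arrays are copied.
    params : ForceFieldParams
        Interaction constants.
    schedule : FieldSchedule
        Applied-field protocol used while the field is switched on.
    dt : float
        Time step in tau (default 0.008).
    thermostat : bool
        False selects NVE (used for energy-conservation checks).
    profile_unbiased : bool
        Couple the thermostat to peculiar (species-streaming-subtracted)
        velocities; False couples to lab-frame velocities.
    tau_nh : float
        Thermostat time constant; the coupling mass is
        ``Q = g kBT tau_nh^2`` with ``g`` the thermal degrees of freedom.
    """

    def __init__(
        self,
        system: ParticleSystem,
        params: ForceFieldParams | None = None,
        schedule: FieldSchedule | None = None,
        dt: float = 0.008,
        thermostat: bool = True,
        profile_unbiased: bool = True,
        tau_nh: float | None = None,
        skin: float = 0.7,
        exclude_bonded_wca: bool = False,
    ) -> None:
        if dt > 0.01:
            raise ValueError("dt > 0.01 tau is unstable for this force field")
        self.params = params or ForceFieldParams()
        self.schedule = schedule or FieldSchedule()
        self.dt = float(dt)
        self.thermostat = thermostat
        self.profile_unbiased = profile_unbiased
        self.spec: ChannelSpec | None = system.spec
        self.Lz = float(system.box_length)

        self.pos = system.positions.copy()
        self.pos[:, 2] %= self.Lz
        self.offsets = system.positions[:, 2] - self.pos[:, 2]
        self.vel = system.velocities.copy()
        self.species = system.species.copy()
        self.charges = system.charges.copy()
        self.bonds = system.bonds.copy()
        self.mobile = system.mobile_mask.copy()
        self.n_mobile = int(self.mobile.sum())

        self._groups = [
            np.flatnonzero(self.species == lab)
            for lab in ("M", "C+", "C-", "S")
            if np.any(self.species == lab)
        ]
        gid = np.full(len(self.species), -1, dtype=np.intp)
        for g, idx in enumerate(self._groups):
            gid[idx] = g
        self._gidx = np.flatnonzero(gid >= 0)
        self._gid = gid[self._gidx]
        self._gcounts = np.bincount(self._gid).astype(float)[:, None]
        n_groups = len(self._groups) if profile_unbiased else 0
        # streaming modes removed from the thermal degrees of freedom
        self.g_dof = max(1, 3 * (self.n_mobile - n_groups))

        if tau_nh is None:
            tau_nh = 100.0 * self.dt
        self.thermo = ThermostatState(
            zeta=0.0, Q=self.g_dof * self.params.kBT * tau_nh**2, T_target=1.0
        )

        self.engine = ForceEngine(
            charges=self.charges,
            bonds=self.bonds,
            mobile=self.mobile,
            Lz=self.Lz,
            params=self.params,
            skin=skin,
            exclude_bonded_wca=exclude_bonded_wca,
            spec=self.spec,
        )
        self.t = 0.0
        self.step_count = 0
        self.field_on = False
        self._forces = self.engine.forces(self.pos, E=self._field())

    # -- helpers ----------------------------------------------------------

    def _field(self) -> np.ndarray | None:
        if not self.field_on:
            return None
        return field_at(self.t, self.schedule)

    def _group_means(self) -> np.ndarray:
        v = self.vel[self._gidx]
        sums = np.empty((len(self._gcounts), 3))
        for c in range(3):
            sums[:, c] = np.bincount(self._gid, weights=v[:, c])
        return sums / self._gcounts

    def _peculiar(self) -> np.ndarray:
        """Velocities with per-species streaming removed (mobile only)."""
        v = self.vel.copy()
        if self.profile_unbiased:
            v[self._gidx] -= self._group_means()[self._gid]
        return v

    def kinetic_temperature(self) -> float:
        """Instantaneous kinetic temperature of peculiar velocities."""
        v = self._peculiar()[self.mobile]
        return float(np.einsum("ij,ij->", v, v) / self.g_dof)

    def potential_energy(self) -> float:
        _, u = self.engine.forces(self.pos, E=None, with_energy=True)
        return u

    def total_energy(self) -> float:
        """Kinetic + potential (field term excluded); for NVE checks."""
        v = self.vel[self.mobile]
        return 0.5 * float(np.einsum("ij,ij->", v, v)) + self.potential_energy()

    def _thermo_half(self) -> None:
        if not self.thermostat:
            return
        dt = self.dt
        kBT = self.params.kBT
        if self.profile_unbiased:
            means = self._group_means()[self._gid]
            pec = self.vel[self._gidx] - means
            twoK = float(np.einsum("ij,ij->", pec, pec))
            self.thermo.zeta += 0.25 * dt * (twoK - self.g_dof * kBT) / self.thermo.Q
            scale = math.exp(-0.5 * dt * self.thermo.zeta)
            pec *= scale
            self.vel[self._gidx] = means + pec
            twoK *= scale * scale
        else:
            v = self.vel[self.mobile]
            twoK = float(np.einsum("ij,ij->", v, v))
            self.thermo.zeta += 0.25 * dt * (twoK - self.g_dof * kBT) / self.thermo.Q
            scale = math.exp(-0.5 * dt * self.thermo.zeta)
            self.vel[self.mobile] *= scale
            twoK *= scale * scale
        self.thermo.zeta += 0.25 * dt * (twoK - self.g_dof * kBT) / self.thermo.Q

    # -- stepping ---------------------------------------------------------

    def step(self, n: int = 1) -> None:
        """Advance ``n`` velocity-Verlet / Nosé-Hoover steps."""
        dt = self.dt
        mob = self.mobile
        for _ in range(n):
            self._thermo_half()
            self.vel[mob] += 0.5 * dt * self._forces[mob]
            self.pos[mob] += dt * self.vel[mob]
            # z-wrap with unwrap bookkeeping
            z = self.pos[mob, 2]
            with np.errstate(invalid="ignore"):  # non-finite z caught below
                wrapped = np.mod(z, self.Lz)
            self.offsets[mob] += z - wrapped
            self.pos[mob, 2] = wrapped
            self.t += dt
            self.step_count += 1
            self._forces = self.engine.forces(self.pos, E=self._field())
            self.vel[mob] += 0.5 * dt * self._forces[mob]
            self._thermo_half()
            if not np.all(np.isfinite(self.pos)) or not np.all(np.isfinite(self.vel)):
                raise FloatingPointError(
                    f"non-finite coordinates at step {self.step_count}; the run "
                    "has blown up (was the push-off long enough?)"
                )

    def pushoff(
        self,
        n_steps: int = 2000,
        cap_start: float = 200.0,
        cap_end: float = 2000.0,
        v_max: float = 4.0,
    ) -> None:
        """Capped-force push-off: relax build-time packing before production.

        The WCA force magnitude is capped (ramped from ``cap_start`` to
        ``cap_end``), speeds are clipped at ``v_max`` so no particle moves
        more than ~``v_max * dt`` per step, and velocities are rescaled to
        the target temperature every 25 steps to bleed off the heat released
        by relaxing overlaps.  The cap start is stiff enough that the wall
        layer stays impermeable throughout (the builder guarantees >= 0.85
        sigma separations, where the WCA force is well below the cap).
        """
        if n_steps <= 0:
            return
        for i in range(n_steps):
            frac = i / max(1, n_steps - 1)
            self.engine.force_cap = cap_start * (cap_end / cap_start) ** frac
            self.step(1)
            speed = np.sqrt(np.einsum("ij,ij->i", self.vel, self.vel))
            fast = speed > v_max
            if np.any(fast):
                self.vel[fast] *= (v_max / speed[fast])[:, None]
            if i % 25 == 0:
                T = self.kinetic_temperature()
                if T > 0:
                    self._rescale(1.0 / math.sqrt(T))
        self.engine.force_cap = None
        self.engine.rebuild(self.pos)
        self.thermo.zeta = 0.0
        self._forces = self.engine.forces(self.pos, E=self._field())

    def _rescale(self, s: float) -> None:
        if self.profile_unbiased:
            for idx in self._groups:
                mean = self.vel[idx].mean(axis=0)
                self.vel[idx] = mean + (self.vel[idx] - mean) * s
        else:
            self.vel[self.mobile] *= s

    # -- protocol ---------------------------------------------------------

    def run(
        self,
        steps: int,
        equil_steps: int = 0,
        pushoff_steps: int = 2000,
        stride: int = 1000,
        probe_species: tuple[str, ...] | None = None,
        probe_stride: int = 0,
        callback: Callable[["Simulation"], None] | None = None,
        metadata: dict | None = None,
    ) -> Trajectory:
        """Execute push-off -> field-off equilibration -> field-on production.

        Frames (all particles) are recorded every ``stride`` production
        steps, starting with the state at the beginning of production.  An
        optional probe records wrapped positions of a species subset every
        ``probe_stride`` steps (for estimators that need finer sampling than
        the frame stride, e.g. force autocorrelations).
        """
        self.pushoff(pushoff_steps)
        if equil_steps > 0:
            self.step(equil_steps)

        self.field_on = True
        self._forces = self.engine.forces(self.pos, E=self._field())

        times, frames_pos, frames_off, frames_vel = [], [], [], []
        probe_idx = None
        probe_times: list[float] = []
        probe_pos: list[np.ndarray] = []
        if probe_species and probe_stride > 0:
            probe_idx = np.flatnonzero(np.isin(self.species, probe_species))

        def _record() -> None:
            times.append(self.t)
            frames_pos.append(self.pos.copy())
            frames_off.append(self.offsets.copy())
            frames_vel.append(self.vel.copy())

        def _probe() -> None:
            if probe_idx is not None:
                probe_times.append(self.t)
                probe_pos.append(self.pos[probe_idx].copy())

        _record()
        _probe()
        failure: BaseException | None = None
        try:
            for s in range(1, steps + 1):
                self.step(1)
                if probe_idx is not None and s % probe_stride == 0:
                    _probe()
                if s % stride == 0:
                    _record()
                if callback is not None:
                    callback(self)
        except (FloatingPointError, RuntimeError) as exc:
            failure = exc  # partial trajectory below stays readable

        probe = None
        if probe_idx is not None:
            probe = ProbeRecord(
                indices=probe_idx,
                times=np.array(probe_times),
                positions=np.array(probe_pos),
                stride=probe_stride,
            )
        meta = {
            "steps": steps,
            "equil_steps": equil_steps,
            "pushoff_steps": pushoff_steps,
            "dt": self.dt,
            "schedule": {
                "mode": self.schedule.mode,
                "E_par": self.schedule.E_par,
                "E_perp": self.schedule.E_perp,
                "half_period": self.schedule.half_period,
            },
        }
        if metadata:
            meta.update(metadata)
        if failure is not None:
            meta["failed_at_step"] = self.step_count
        traj = Trajectory(
            times=np.array(times),
            positions=np.array(frames_pos),
            offsets=np.array(frames_off),
            velocities=np.array(frames_vel),
            species=self.species,
            charges=self.charges,
            bonds=self.bonds,
            box_length=self.Lz,
            stride=stride,
            dt=self.dt,
            metadata=meta,
            probe=probe,
        )
        traj.validate()
        if failure is not None:
            raise SimulationError(
                f"run failed at step {self.step_count}: {failure}", traj
            ) from failure
        return traj


def nvt_step(sim: Simulation, n: int = 1) -> Simulation:
    """Advance ``sim`` by ``n`` NVT (or NVE, if thermostat off) steps."""
    sim.step(n)
    return sim
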