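"""Run configuration: TOML loading, validation, defaults.

A run config has five sections — ``geometry``, ``system``, ``forcefield``,
``field`` and ``run`` — whose defaults are the reference model values
(channel mean radius 6 sigma with 25% undulation depth and wavelength
57.11 sigma; FENE k = 7, R0 = 2.4; eps_LJ = 1; lB = 1; counterion
concentration 0.0291 sigma^-3; solvent density 0.82 sigma^-3; dt = 0.008;
frame stride 1000; E_par = E_perp = 1).  An empty file therefore selects the
reference system.  Unknown keys are errors (no silent ignore) and every
override is validated by the domain types; the resolved config is echoed
into all outputs so any result file suffices to rebuild its run.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .builder import BuildConfig, ParticleSystem, build_system
from .channel import ChannelSpec, spec_for_geometry
from .forcefield import ForceFieldParams
from .integrator import FieldSchedule, Simulation

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class RunSection:
    dt: float = 0.008
    stride: int = 1000
    steps: int = 200_000
    equil_steps: int = 20_000
    pushoff_steps: int = 2000
    probe_stride: int = 0
    probe_species: list = field(default_factory=lambda: ["M", "C+", "C-"])
    seed: int = 0


@dataclass
class RunConfig:
    """Fully resolved run configuration."""

    spec: ChannelSpec
    geometry_label: str
    build: BuildConfig
    forcefield: ForceFieldParams
    schedule: FieldSchedule
    run: RunSection
    exclude_bonded_wca: bool = False

    def as_dict(self) -> dict:
        return {
            "geometry": {
                "label": self.geometry_label,
                "mean_radius": self.spec.mean_radius,
                "amplitude": self.spec.amplitude,
                "box_length": self.spec.box_length,
                "wavelength": self.spec.wavelength,
                "harmonic": self.spec.harmonic,
                "wall_spacing": self.spec.wall_spacing,
            },
            "system": {
                "chain_length": self.build.chain_length,
                "counterion_concentration": self.build.counterion_concentration,
                "solvent_density": self.build.solvent_density,
                "seed": self.build.seed,
                "ion_convention": self.build.ion_convention,
            },
            "forcefield": {
                **dataclasses.asdict(self.forcefield),
                "exclude_bonded_wca": self.exclude_bonded_wca,
            },
            "field": dataclasses.asdict(self.schedule),
            "run": dataclasses.asdict(self.run),
        }

    def build_system(self) -> ParticleSystem:
        return build_system(self.build)

    def simulation(self, system: ParticleSystem | None = None) -> Simulation:
        if system is None:
            system = self.build_system()
        return Simulation(
            system,
            params=self.forcefield,
            schedule=self.schedule,
            dt=self.run.dt,
            exclude_bonded_wca=self.exclude_bonded_wca,
        )


_GEOMETRY_KEYS = {
    "index",
    "transverse",
    "mean_radius",
    "amplitude",
    "box_length",
    "wavelength",
    "harmonic",
    "wall_spacing",
}
_SYSTEM_KEYS = {
    "chain_length",
    "counterion_concentration",
    "solvent_density",
    "seed",
    "ion_convention",
}
_FF_KEYS = {
    "k_fene",
    "r0_fene",
    "eps_lj",
    "sigma_lj",
    "lB",
    "coulomb_cut",
    "kBT",
    "exclude_bonded_wca",
}
_FIELD_KEYS = {"mode", "E_par", "E_perp", "half_period"}
_RUN_KEYS = {
    "dt",
    "stride",
    "steps",
    "equil_steps",
    "pushoff_steps",
    "probe_stride",
    "probe_species",
    "seed",
}


def _check_keys(section: str, data: dict, allowed: set) -> None:
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in [{section}]: {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}"
        )


def load_config(path_or_dict) -> RunConfig:
    """Load and validate a TOML run config (or an equivalent dict).

    An empty file yields the reference defaults.  Raises
    :class:`ConfigError` naming the offending section and field on any
    schema violation.
    """
    if isinstance(path_or_dict, dict):
        data = path_or_dict
    else:
        path = Path(path_or_dict)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path, "rb") as fh:
            try:
                data = tomllib.load(fh)
            except tomllib.TOMLDecodeError as exc:
                raise ConfigError(f"invalid TOML in {path}: {exc}") from exc

    known_sections = {"geometry", "system", "forcefield", "field", "run"}
    unknown = set(data) - known_sections
    if unknown:
        raise ConfigError(
            f"unknown section(s): {sorted(unknown)}; allowed: {sorted(known_sections)}"
        )

    geo = dict(data.get("geometry", {}))
    sys_ = dict(data.get("system", {}))
    ff = dict(data.get("forcefield", {}))
    fld = dict(data.get("field", {}))
    run = dict(data.get("run", {}))
    _check_keys("geometry", geo, _GEOMETRY_KEYS)
    _check_keys("system", sys_, _SYSTEM_KEYS)
    _check_keys("forcefield", ff, _FF_KEYS)
    _check_keys("field", fld, _FIELD_KEYS)
    _check_keys("run", run, _RUN_KEYS)

    transverse = bool(fld.get("E_perp", 1.0))
    try:
        if "index" in geo:
            idx = int(geo.pop("index"))
            transverse_flag = geo.pop("transverse", transverse)
            spec = spec_for_geometry(idx, **geo)
            label = ("T" if transverse_flag else "P") + str(idx)
        else:
            geo.pop("transverse", None)
            kwargs = {}
            for k_toml, k_py in (
                ("mean_radius", "mean_radius"),
                ("amplitude", "amplitude"),
                ("box_length", "box_length"),
                ("wavelength", "wavelength"),
                ("harmonic", "harmonic"),
                ("wall_spacing", "wall_spacing"),
            ):
                if k_toml in geo:
                    kwargs[k_py] = geo[k_toml]
            spec = ChannelSpec(**kwargs)
            label = ("T" if transverse else "P") + ("0" if spec.harmonic == 0 else "?")
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"[geometry] invalid: {exc}") from exc

    try:
        build = BuildConfig(
            spec=spec,
            chain_length=int(sys_.get("chain_length", 30)),
            counterion_concentration=float(sys_.get("counterion_concentration", 0.0291)),
            solvent_density=float(sys_.get("solvent_density", 0.82)),
            seed=int(sys_.get("seed", run.get("seed", 0))),
            ion_convention=sys_.get("ion_convention", "counterion_excess"),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"[system] invalid: {exc}") from exc

    exclude_bonded_wca = bool(ff.pop("exclude_bonded_wca", False))
    try:
        params = ForceFieldParams(**ff)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"[forcefield] invalid: {exc}") from exc

    try:
        schedule = FieldSchedule(
            mode=fld.get("mode", "constant"),
            E_par=float(fld.get("E_par", 1.0)),
            E_perp=float(fld.get("E_perp", 1.0)),
            half_period=float(fld.get("half_period", 0.0)),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"[field] invalid: {exc}") from exc

    try:
        run_sec = RunSection(
            dt=float(run.get("dt", 0.008)),
            stride=int(run.get("stride", 1000)),
            steps=int(run.get("steps", 200_000)),
            equil_steps=int(run.get("equil_steps", 20_000)),
            pushoff_steps=int(run.get("pushoff_steps", 2000)),
            probe_stride=int(run.get("probe_stride", 0)),
            probe_species=list(run.get("probe_species", ["M", "C+", "C-"])),
            seed=int(run.get("seed", sys_.get("seed", 0))),
        )
        if run_sec.dt <= 0 or run_sec.dt > 0.01:
            raise ConfigError("[run] dt must lie in (0, 0.01]")
        for fname in ("stride", "steps", "equil_steps", "pushoff_steps"):
            if getattr(run_sec, fname) < 0:
                raise ConfigError(f"[run] {fname} must be non-negative")
        if run_sec.stride == 0:
            raise ConfigError("[run] stride must be positive")
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"[run] invalid: {exc}") from exc

    return RunConfig(
        spec=spec,
        geometry_label=label,
        build=build,
        forcefield=params,
        schedule=schedule,
        run=run_sec,
        exclude_bonded_wca=exclude_bonded_wca,
    )
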