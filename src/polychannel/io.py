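"""Trajectory and snapshot I/O.

Three interchangeable formats:

* **extended XYZ** (``.xyz`` / ``.extxyz``): text, one block per frame with a
  ``Lattice``/``Properties`` comment line carrying species, position,
  velocity, charge and the z unwrap offset per atom;
* **LAMMPS-style dump** (``.dump`` / ``.lammpstrj``): text, standard
  ``ITEM:`` blocks with columns ``id type element q x y z vx vy vz iz``
  (``iz`` is the z image count, so ``z + iz*Lz`` is the unwrapped
  coordinate);
* **native HDF5** (``.h5`` / ``.hdf5``): bitwise round-trip of frames, probe
  records and metadata under ``/frames`` and ``/particles``.

Text round-trips preserve coordinates to ~1e-7 (they are written with 10
significant digits); chain bonds are stored explicitly in HDF5 and
reconstructed from consecutive monomer records in the text formats (the
package simulates a single linear chain).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .builder import SPECIES_CHARGE, ParticleSystem
from .integrator import ProbeRecord, Trajectory

__all__ = ["write_trajectory", "read_trajectory", "system_to_trajectory"]

_TYPE_OF = {"M": 1, "C+": 2, "C-": 3, "S": 4, "W": 5}
_SPECIES_OF = {v: k for k, v in _TYPE_OF.items()}

_FMT = "%.10g"


class TrajectoryIOError(RuntimeError):
    pass


def system_to_trajectory(system: ParticleSystem, time: float = 0.0) -> Trajectory:
    """Wrap a built system as a single-frame trajectory (for snapshots)."""
    pos = system.positions[None, :, :].copy()
    Lz = system.box_length
    wrapped_z = np.mod(pos[0, :, 2], Lz)
    offsets = (pos[0, :, 2] - wrapped_z)[None, :]
    pos[0, :, 2] = wrapped_z
    return Trajectory(
        times=np.array([time]),
        positions=pos,
        offsets=offsets,
        velocities=system.velocities[None, :, :].copy(),
        species=system.species.copy(),
        charges=system.charges.copy(),
        bonds=system.bonds.copy(),
        box_length=Lz,
        stride=1,
        metadata={"snapshot": True},
    )


def _infer_format(path: Path) -> str:
    suf = path.suffix.lower()
    if suf in (".h5", ".hdf5"):
        return "hdf5"
    if suf in (".xyz", ".extxyz"):
        return "extxyz"
    if suf in (".dump", ".lammpstrj"):
        return "lammps"
    raise TrajectoryIOError(f"cannot infer trajectory format from suffix {suf!r}")


def write_trajectory(traj: Trajectory, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "hdf5":
        _write_h5(traj, path)
    elif fmt == "extxyz":
        _write_extxyz(traj, path)
    elif fmt == "lammps":
        _write_lammps(traj, path)
    else:
        raise TrajectoryIOError(f"unknown format {fmt!r}")


def read_trajectory(path, format: str | None = None) -> Trajectory:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "hdf5":
        return _read_h5(path)
    if fmt == "extxyz":
        return _read_extxyz(path)
    if fmt == "lammps":
        return _read_lammps(path)
    raise TrajectoryIOError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# HDF5
# ---------------------------------------------------------------------------


def _write_h5(traj: Trajectory, path: Path) -> None:
    with h5py.File(path, "w") as f:
        fr = f.create_group("frames")
        fr.create_dataset("time", data=traj.times)
        fr.create_dataset("pos", data=traj.positions)
        fr.create_dataset("vel", data=traj.velocities)
        fr.create_dataset("offsets", data=traj.offsets)
        pt = f.create_group("particles")
        pt.create_dataset(
            "species", data=np.array([s.encode() for s in traj.species])
        )
        pt.create_dataset("charges", data=traj.charges)
        pt.create_dataset("bonds", data=np.asarray(traj.bonds, dtype=np.int64))
        f.attrs["box_length"] = traj.box_length
        f.attrs["stride"] = traj.stride
        f.attrs["dt"] = traj.dt
        f.attrs["metadata"] = json.dumps(traj.metadata, default=str)
        if traj.probe is not None:
            pr = f.create_group("probe")
            pr.create_dataset("indices", data=traj.probe.indices)
            pr.create_dataset("time", data=traj.probe.times)
            pr.create_dataset("pos", data=traj.probe.positions)
            pr.attrs["stride"] = traj.probe.stride


def _read_h5(path: Path) -> Trajectory:
    with h5py.File(path, "r") as f:
        probe = None
        if "probe" in f:
            probe = ProbeRecord(
                indices=f["probe/indices"][()],
                times=f["probe/time"][()],
                positions=f["probe/pos"][()],
                stride=int(f["probe"].attrs.get("stride", 0)),
            )
        return Trajectory(
            times=f["frames/time"][()],
            positions=f["frames/pos"][()],
            offsets=f["frames/offsets"][()],
            velocities=f["frames/vel"][()],
            species=np.array([s.decode() for s in f["particles/species"][()]]),
            charges=f["particles/charges"][()],
            bonds=f["particles/bonds"][()].astype(np.intp),
            box_length=float(f.attrs["box_length"]),
            stride=int(f.attrs["stride"]),
            dt=float(f.attrs["dt"]),
            metadata=json.loads(f.attrs["metadata"]),
            probe=probe,
        )


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------


def _write_extxyz(traj: Trajectory, path: Path) -> None:
    box = 1000.0  # nominal transverse lattice extent; only z is periodic
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{len(traj.species)}\n")
            meta = {
                "Time": float(traj.times[f]),
                "box_length": traj.box_length,
                "stride": traj.stride,
                "dt": traj.dt,
            }
            if f == 0:
                meta["metadata"] = traj.metadata
                meta["bonds"] = np.asarray(traj.bonds).tolist()
            lattice = f"{box:g} 0 0 0 {box:g} 0 0 0 {traj.box_length:.10g}"
            fh.write(
                f'Lattice="{lattice}" '
                "Properties=species:S:1:pos:R:3:vel:R:3:charge:R:1:zoff:R:1 "
                f"Info={json.dumps(meta, separators=(',', ':'))}\n"
            )
            for i, sp in enumerate(traj.species):
                p = traj.positions[f, i]
                v = traj.velocities[f, i]
                fh.write(
                    f"{sp} "
                    + " ".join(_FMT % x for x in (*p, *v))
                    + f" {_FMT % traj.charges[i]} {_FMT % traj.offsets[f, i]}\n"
                )


def _read_extxyz(path: Path) -> Trajectory:
    times, frames_pos, frames_vel, frames_off = [], [], [], []
    species = charges = None
    bonds = np.empty((0, 2), dtype=np.intp)
    box_length = None
    stride, dt = 1, 0.008
    metadata: dict = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
            comment = lines[i + 1]
            info_start = comment.index("Info=")
            meta = json.loads(comment[info_start + 5 :])
            if frame == 0:
                if "metadata" in meta:
                    metadata = meta["metadata"]
                if "bonds" in meta and meta["bonds"]:
                    bonds = np.asarray(meta["bonds"], dtype=np.intp)
                box_length = float(meta["box_length"])
                stride = int(meta.get("stride", 1))
                dt = float(meta.get("dt", 0.008))
            times.append(float(meta["Time"]))
            sp, pos, vel, q, off = [], [], [], [], []
            for k in range(n):
                parts = lines[i + 2 + k].split()
                sp.append(parts[0])
                vals = [float(x) for x in parts[1:9]]
                pos.append(vals[0:3])
                vel.append(vals[3:6])
                q.append(vals[6])
                off.append(vals[7])
            if species is None:
                species = np.array(sp)
                charges = np.array(q)
            frames_pos.append(pos)
            frames_vel.append(vel)
            frames_off.append(off)
            i += 2 + n
            frame += 1
        except (ValueError, IndexError, KeyError) as exc:
            raise TrajectoryIOError(
                f"malformed extended-XYZ frame {frame} in {path} "
                f"(last complete frame: {frame - 1}): {exc}"
            ) from exc
    if species is None:
        raise TrajectoryIOError(f"no frames found in {path}")
    return Trajectory(
        times=np.array(times),
        positions=np.array(frames_pos),
        offsets=np.array(frames_off),
        velocities=np.array(frames_vel),
        species=species,
        charges=charges,
        bonds=bonds,
        box_length=box_length,
        stride=stride,
        dt=dt,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# LAMMPS-style dump
# ---------------------------------------------------------------------------


def _write_lammps(traj: Trajectory, path: Path) -> None:
    ext = 500.0
    Lz = traj.box_length
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            step = int(round(traj.times[f] / traj.dt)) if traj.dt else f
            fh.write("ITEM: TIMESTEP\n%d\n" % step)
            fh.write("ITEM: TIME\n%s\n" % (_FMT % traj.times[f]))
            fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % len(traj.species))
            fh.write("ITEM: BOX BOUNDS ff ff pp\n")
            fh.write(f"{-ext:g} {ext:g}\n{-ext:g} {ext:g}\n0 {Lz:.10g}\n")
            fh.write("ITEM: ATOMS id type element q x y z vx vy vz iz\n")
            for i, sp in enumerate(traj.species):
                p = traj.positions[f, i]
                v = traj.velocities[f, i]
                iz = int(round(traj.offsets[f, i] / Lz))
                fh.write(
                    f"{i + 1} {_TYPE_OF[sp]} {sp} {_FMT % traj.charges[i]} "
                    + " ".join(_FMT % x for x in (*p, *v))
                    + f" {iz}\n"
                )


def _read_lammps(path: Path) -> Trajectory:
    with open(path) as fh:
        lines = fh.read().splitlines()
    times, frames_pos, frames_vel, frames_off = [], [], [], []
    species = charges = None
    Lz = None
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            assert lines[i].startswith("ITEM: TIMESTEP"), "expected ITEM: TIMESTEP"
            i += 2
            t = None
            if lines[i].startswith("ITEM: TIME"):
                t = float(lines[i + 1])
                i += 2
            assert lines[i].startswith("ITEM: NUMBER OF ATOMS")
            n = int(lines[i + 1])
            i += 2
            assert lines[i].startswith("ITEM: BOX BOUNDS")
            zlo, zhi = (float(x) for x in lines[i + 3].split()[:2])
            Lz = zhi - zlo
            i += 4
            assert lines[i].startswith("ITEM: ATOMS"), "expected ITEM: ATOMS"
            cols = lines[i].split()[2:]
            idx = {c: k for k, c in enumerate(cols)}
            i += 1
            sp = [""] * n
            pos = np.empty((n, 3))
            vel = np.zeros((n, 3))
            q = np.zeros(n)
            off = np.zeros(n)
            for k in range(n):
                parts = lines[i + k].split()
                a = int(parts[idx["id"]]) - 1
                sp[a] = (
                    parts[idx["element"]]
                    if "element" in idx
                    else _SPECIES_OF[int(parts[idx["type"]])]
                )
                pos[a] = [float(parts[idx[c]]) for c in ("x", "y", "z")]
                if "vx" in idx:
                    vel[a] = [float(parts[idx[c]]) for c in ("vx", "vy", "vz")]
                if "q" in idx:
                    q[a] = float(parts[idx["q"]])
                if "iz" in idx:
                    off[a] = int(parts[idx["iz"]]) * Lz
            i += n
            times.append(t if t is not None else float(frame))
            frames_pos.append(pos)
            frames_vel.append(vel)
            frames_off.append(off)
            if species is None:
                species = np.array(sp)
                charges = q
            frame += 1
        except (AssertionError, ValueError, IndexError) as exc:
            raise TrajectoryIOError(
                f"malformed LAMMPS dump frame {frame} in {path} "
                f"(last complete frame: {frame - 1}): {exc}"
            ) from exc
    if species is None:
        raise TrajectoryIOError(f"no frames found in {path}")
    # single linear chain convention: consecutive monomers are bonded
    mono = np.flatnonzero(species == "M")
    bonds = (
        np.column_stack([mono[:-1], mono[1:]])
        if len(mono) >= 2
        else np.empty((0, 2), dtype=np.intp)
    )
    return Trajectory(
        times=np.array(times),
        positions=np.array(frames_pos),
        offsets=np.array(frames_off),
        velocities=np.array(frames_vel),
        species=species,
        charges=charges,
        bonds=bonds,
        box_length=Lz,
        stride=1,
        metadata={"source": "lammps-dump"},
    )
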