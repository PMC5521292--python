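"""Per-run analysis tables and multi-run summary reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import observables as obs
from .forcefield import ForceFieldParams
from .integrator import Trajectory

__all__ = ["analyze_trajectory", "write_observables_tsv", "summary_report"]

_COLUMNS = [
    "geometry",
    "N",
    "v_drift",
    "v_drift_err",
    "xi_C_plateau",
    "contacts_per_N",
    "contacts_err",
    "extension",
    "extension_err",
]


def analyze_trajectory(
    traj: Trajectory,
    params: ForceFieldParams | None = None,
    friction_radii=(2.0, 4.0, 6.0, 8.0),
    b: float = 0.93,
    contact_cutoff: float = 2.0 ** (1.0 / 6.0),
) -> dict:
    """Compute the standard observable set of one trajectory.

    Returns a flat dict of scalars (missing observables are reported as
    ``nan`` with a note rather than dropped).
    """
    p = params or ForceFieldParams()
    out: dict = {"geometry": traj.metadata.get("geometry", "?")}
    out["N"] = int(np.sum(traj.species == "M"))
    notes = []
    try:
        v, verr = obs.com_drift_velocity(traj)
        out["v_drift"], out["v_drift_err"] = v, verr
    except ValueError as exc:
        out["v_drift"] = out["v_drift_err"] = float("nan")
        notes.append(f"v_drift: {exc}")
    try:
        curve = obs.friction_vs_radius(traj, friction_radii, p)
        out["xi_C_plateau"] = curve.plateau
    except (ValueError, IndexError) as exc:
        out["xi_C_plateau"] = float("nan")
        notes.append(f"xi_C: {exc}")
    try:
        c, cerr = obs.wall_contacts(traj, cutoff=contact_cutoff)
        out["contacts_per_N"], out["contacts_err"] = c, cerr
    except ValueError as exc:
        out["contacts_per_N"] = out["contacts_err"] = float("nan")
        notes.append(f"contacts: {exc}")
    try:
        e, eerr = obs.chain_extension(traj, b=b)
        out["extension"], out["extension_err"] = e, eerr
    except ValueError as exc:
        out["extension"] = out["extension_err"] = float("nan")
        notes.append(f"extension: {exc}")
    if notes:
        out["notes"] = "; ".join(notes)
    return out


def write_observables_tsv(results: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("observable\tvalue\n")
        for k, v in results.items():
            fh.write(f"{k}\t{v}\n")


def _read_observables_tsv(path: Path) -> dict:
    out = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            k, v = line.rstrip("\n").split("\t", 1)
            try:
                out[k] = float(v)
            except ValueError:
                out[k] = v
    return out


def summary_report(run_dirs, out_path=None) -> str:
    """One TSV row per run directory (stable column order).

    Each run directory is expected to hold ``observables.tsv`` (written by
    ``polychannel analyze``) and optionally ``config.json`` (the config
    echo).  Missing observables are reported as ``nan``; the row is still
    emitted.
    """
    rows = []
    for d in run_dirs:
        d = Path(d)
        row = {c: "nan" for c in _COLUMNS}
        cfg_path = d / "config.json"
        if cfg_path.exists():
            cfg = json.loads(cfg_path.read_text())
            row["geometry"] = cfg.get("geometry", {}).get("label", "?")
            row["N"] = cfg.get("system", {}).get("chain_length", "nan")
        tsv = d / "observables.tsv"
        if tsv.exists():
            vals = _read_observables_tsv(tsv)
            for c in _COLUMNS:
                if c in vals:
                    row[c] = vals[c]
        rows.append(row)
    lines = ["\t".join(_COLUMNS)]
    for row in rows:
        lines.append("\t".join(str(row[c]) for c in _COLUMNS))
    text = "\n".join(lines) + "\n"
    if out_path is not None:
        Path(out_path).write_text(text)
    return text
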