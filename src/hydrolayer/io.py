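"""Readers and writers: trajectories, topologies, spectra.

Supported trajectory sources
----------------------------
``fixture``
    Self-describing columnar text format (see :func:`write_fixture_trajectory`),
    used by the synthetic generators so that no binary dependency is needed
    for testing.  Header lines carry ``n_atoms``, ``dt_fs`` and the box;
    each frame block lists ``atom_id x y z vx vy vz`` (A, A/fs).
``trr``
    GROMACS TRR (binary, nm/ps dialect) via MDAnalysis; converted to A/fs.
``gro_series``
    A sorted sequence of single-frame GRO files with velocity columns
    (pass a glob pattern or a directory); frame times are taken from the
    GROMACS ``t=`` title field when present, otherwise ``dt_fs`` must be given.

Everything is converted to internal units (A, fs, amu, e) on read.
"""

from __future__ import annotations

import glob as _glob
import json
import os
import re
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    ROLES,
    Spectrum,
    Topology,
    TopologyError,
    Trajectory,
    TrajectoryError,
)
from .units import FS_TO_PS, PS_TO_FS

FIXTURE_MAGIC = "# hydrolayer fixture trajectory v1"


# --------------------------------------------------------------------------
# fixture trajectory format
# --------------------------------------------------------------------------

def write_fixture_trajectory(traj: Trajectory, path: str) -> None:
    """Write a trajectory in the plain-text fixture format (lossless read-back)."""
    with open(path, "w") as fh:
        fh.write(FIXTURE_MAGIC + "\n")
        fh.write(f"# n_atoms {traj.n_atoms}\n")
        fh.write(f"# n_frames {traj.n_frames}\n")
        dt = traj.dt if traj.n_frames > 1 else 0.0
        fh.write(f"# dt_fs {float(dt)!r}\n")
        fh.write(f"# has_velocities {int(traj.has_velocities)}\n")
        fh.write("# columns atom_id x y z vx vy vz\n")
        for f in range(traj.n_frames):
            bx = traj.box[f]
            fh.write(
                f"FRAME {f} time_fs {float(traj.times[f])!r} "
                f"box_A {float(bx[0])!r} {float(bx[1])!r} {float(bx[2])!r}\n"
            )
            pos = traj.positions[f]
            vel = traj.velocities[f] if traj.has_velocities else np.zeros_like(pos)
            for a in range(traj.n_atoms):
                row = pos[a].tolist() + vel[a].tolist()
                fh.write(f"{a} " + " ".join(repr(v) for v in row) + "\n")


def _read_fixture(path: str) -> Trajectory:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != FIXTURE_MAGIC:
        raise TrajectoryError(f"{path}: not a hydrolayer fixture trajectory")
    header = {}
    i = 1
    while i < len(lines) and lines[i].startswith("#"):
        parts = lines[i][1:].split()
        if len(parts) >= 2 and parts[0] != "columns":
            header[parts[0]] = parts[1]
        i += 1
    try:
        n_atoms = int(header["n_atoms"])
        n_frames = int(header["n_frames"])
        has_vel = bool(int(header.get("has_velocities", "1")))
    except KeyError as exc:
        raise TrajectoryError(f"{path}: missing fixture header field {exc}") from exc

    times = np.empty(n_frames)
    box = np.empty((n_frames, 3))
    pos = np.empty((n_frames, n_atoms, 3))
    vel = np.empty((n_frames, n_atoms, 3))
    f = -1
    for line in lines[i:]:
        if not line.strip():
            continue
        if line.startswith("FRAME"):
            parts = line.split()
            f += 1
            if f >= n_frames:
                raise TrajectoryError(f"{path}: more frames than declared ({n_frames})")
            times[f] = float(parts[3])
            box[f] = [float(x) for x in parts[5:8]]
            row = 0
            continue
        vals = line.split()
        a = int(vals[0])
        pos[f, a] = [float(x) for x in vals[1:4]]
        vel[f, a] = [float(x) for x in vals[4:7]]
        row += 1
    if f != n_frames - 1:
        raise TrajectoryError(f"{path}: expected {n_frames} frames, found {f + 1}")
    return Trajectory(
        times=times, positions=pos, velocities=vel if has_vel else None, box=box
    )


# --------------------------------------------------------------------------
# TRR / GRO via MDAnalysis
# --------------------------------------------------------------------------

def _read_trr(path: str) -> Trajectory:
    from MDAnalysis.coordinates.TRR import TRRReader

    reader = TRRReader(path)  # converts to MDAnalysis units: A, ps, A/ps
    times, pos, vel, box = [], [], [], []
    for ts in reader:
        if not ts.has_velocities:
            raise TrajectoryError(
                f"{path}: no velocities stored in frame {ts.frame}; "
                "position-only trajectories cannot drive spectral analysis"
            )
        dims = ts.dimensions
        if dims is None or not np.all(dims[:3] > 0):
            raise TrajectoryError(f"{path}: missing box in frame {ts.frame}")
        if not np.allclose(dims[3:], 90.0, atol=1e-3):
            raise TrajectoryError(
                f"{path}: triclinic box in frame {ts.frame}; only orthorhombic "
                "boxes are supported"
            )
        times.append(ts.time * PS_TO_FS)
        pos.append(ts.positions.astype(float))
        vel.append(ts.velocities.astype(float) * FS_TO_PS)  # A/ps -> A/fs
        box.append(dims[:3].astype(float))
    reader.close()
    times = np.asarray(times)
    # TRR stores float32 times; loosen the uniformity check accordingly
    traj = Trajectory.__new__(Trajectory)
    traj.times = times
    traj.positions = np.asarray(pos)
    traj.velocities = np.asarray(vel)
    traj.box = np.asarray(box)
    rtol = max(1e-6, 2e-6 * abs(times[-1]) / max(times[1] - times[0], 1e-30)
               ) if times.size > 1 else 1e-6
    traj.validate(time_rtol=rtol)
    return traj


_GRO_TIME_RE = re.compile(r"t=\s*([0-9.eE+-]+)")


def _read_gro_series(path: str, dt_fs: Optional[float]) -> Trajectory:
    import MDAnalysis as mda

    if os.path.isdir(path):
        files = sorted(_glob.glob(os.path.join(path, "*.gro")))
    else:
        files = sorted(_glob.glob(path))
    if not files:
        raise TrajectoryError(f"no GRO files match {path!r}")
    times, pos, vel, box = [], [], [], []
    for k, f in enumerate(files):
        u = mda.Universe(f)
        ts = u.trajectory.ts
        if not ts.has_velocities:
            raise TrajectoryError(
                f"{f}: no velocities (GRO must include velocity columns)"
            )
        with open(f) as fh:
            title = fh.readline()
        m = _GRO_TIME_RE.search(title)
        if m is not None:
            times.append(float(m.group(1)) * PS_TO_FS)
        elif dt_fs is not None:
            times.append(k * dt_fs)
        else:
            raise TrajectoryError(
                f"{f}: no 't=' in title and no dt_fs given; frame time unknown"
            )
        dims = ts.dimensions
        if not np.allclose(dims[3:], 90.0, atol=1e-3):
            raise TrajectoryError(f"{f}: only orthorhombic boxes are supported")
        pos.append(ts.positions.astype(float))
        vel.append(ts.velocities.astype(float) * FS_TO_PS)
        box.append(dims[:3].astype(float))
    return Trajectory(
        times=np.asarray(times),
        positions=np.asarray(pos),
        velocities=np.asarray(vel),
        box=np.asarray(box),
    )


def read_trajectory(path: str, format: str = "fixture",
                    dt_fs: Optional[float] = None) -> Trajectory:
    """Read a trajectory, converting to internal units (A, fs).

    Parameters
    ----------
    format : 'fixture' | 'trr' | 'gro_series'
    dt_fs : sampling interval for gro_series files without a ``t=`` title.
    """
    if format == "fixture":
        if not os.path.exists(path):
            raise TrajectoryError(f"no such file: {path}")
        return _read_fixture(path)
    if format == "trr":
        if not os.path.exists(path):
            raise TrajectoryError(f"no such file: {path}")
        return _read_trr(path)
    if format == "gro_series":
        return _read_gro_series(path, dt_fs)
    raise TrajectoryError(f"unsupported trajectory format {format!r}")


# --------------------------------------------------------------------------
# topology
# --------------------------------------------------------------------------

TOPOLOGY_COLUMNS = ["atom_id", "element", "mass", "charge", "molecule_id", "role"]


def read_topology(path: str) -> Topology:
    """Read a columnar topology file (CSV with header).

    Required columns: atom_id, element, mass (amu), charge (e),
    molecule_id, role in {protein, water, ion}.  Water is identified by the
    role column, never by residue-name heuristics.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TOPOLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise TopologyError(f"{path}: missing topology column(s) {missing}")
    role = df["role"].astype(str).str.strip().str.lower()
    bad = set(role) - set(ROLES)
    if bad:
        raise TopologyError(f"{path}: unknown role value(s) {bad}")
    return Topology(
        atom_id=df["atom_id"].to_numpy(),
        element=df["element"].astype(str).str.strip().to_numpy(dtype=object),
        mass=df["mass"].to_numpy(),
        charge=df["charge"].to_numpy(),
        molecule_id=df["molecule_id"].to_numpy(),
        role=role.to_numpy(dtype=object),
    )


def write_topology(topo: Topology, path: str) -> None:
    pd.DataFrame(
        {
            "atom_id": topo.atom_id,
            "element": topo.element,
            "mass": topo.mass,
            "charge": topo.charge,
            "molecule_id": topo.molecule_id,
            "role": topo.role,
        }
    ).to_csv(path, index=False)


# --------------------------------------------------------------------------
# spectra
# --------------------------------------------------------------------------

def write_spectrum(s: Spectrum, path: str, format: str = "csv") -> None:
    """Write a spectrum as two-column CSV (metadata in ``#`` header comments)
    or JSON (metadata in a ``meta`` object)."""
    if format == "csv":
        with open(path, "w") as fh:
            for key in sorted(s.meta):
                fh.write(f"# {key}: {json.dumps(s.meta[key])}\n")
            fh.write("wavenumber_cm-1,intensity\n")
            for w, i in zip(s.wavenumbers.tolist(), s.intensity.tolist()):
                fh.write(f"{w!r},{i!r}\n")
    elif format == "json":
        payload = {
            "wavenumbers_cm1": s.wavenumbers.tolist(),
            "intensity": s.intensity.tolist(),
            "meta": s.meta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValueError(f"unsupported spectrum format {format!r}")


def read_spectrum(path: str, format: str = "csv") -> Spectrum:
    if format == "csv":
        meta = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    key, _, val = line[1:].partition(":")
                    meta[key.strip()] = json.loads(val.strip())
                elif line and not line.startswith("wavenumber"):
                    w, i = line.split(",")
                    rows.append((float(w), float(i)))
        arr = np.asarray(rows)
        return Spectrum(wavenumbers=arr[:, 0], intensity=arr[:, 1], meta=meta)
    if format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        return Spectrum(
            wavenumbers=np.asarray(payload["wavenumbers_cm1"]),
            intensity=np.asarray(payload["intensity"]),
            meta=payload.get("meta", {}),
        )
    raise ValueError(f"unsupported spectrum format {format!r}")
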