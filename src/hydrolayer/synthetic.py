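"""Synthetic trajectories with known analytic structure.

Every pipeline stage can be exercised without external data:

* :func:`gen_harmonic_waters` — water-like molecules whose atomic velocities
  are exact superpositions of cosines at prescribed wavenumbers (the VDOS is
  a set of delta peaks at those wavenumbers);
* :func:`gen_ou_gas` — Ornstein-Uhlenbeck (Langevin) velocities with the
  closed-form exponential VACF exp(-t/tau) and Lorentzian VDOS;
* :func:`gen_layered_box` — static geometry with a prescribed radial
  mass-density profile around a solute proxy;
* :func:`gen_scripted_layers` — label matrices scripted per molecule, for
  exercising the residence rule;
* :func:`gen_harmonic_hydration_box` — harmonic waters planted in prescribed
  distance shells around a central solute atom, for end-to-end runs.

All generators are deterministic under a fixed seed (numpy PCG64); each
file-writing helper records the generator parameters and seed in a JSON
sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import (
    BULK,
    LayerLabels,
    LayeringError,
    Topology,
    Trajectory,
    TrajectoryError,
)
from .units import (
    BULK_WATER_DENSITY,
    C_CM_PER_FS,
    number_density_from_mass_density,
    wavenumber_to_angular_frequency,
)

#: SPC-like flexible-water point charges (e)
DEFAULT_WATER_CHARGES = (-0.82, 0.41)
O_MASS = 15.999
H_MASS = 1.008

#: default harmonic mode set (cm^-1): acoustic, libration onset, H-O-H bend,
#: bound-OH stretch shoulder, free-OH stretch
DEFAULT_MODES_CM1 = (50.0, 250.0, 1650.0, 3300.0, 3650.0)


@dataclass
class ModeSpec:
    """One harmonic mode: displacement amplitude * pattern * cos(w t + phase)."""

    wavenumber: float  # cm^-1
    amplitude: float = 0.05  # A
    pattern: Optional[np.ndarray] = None  # (3 atoms, 3) unit-normalised; None = random
    phase: object = "random"  # radians or "random"

    def __post_init__(self):
        if self.wavenumber <= 0:
            raise ValueError("mode wavenumber must be positive")
        if self.pattern is not None:
            self.pattern = np.asarray(self.pattern, dtype=float)
            if not np.all(np.isfinite(self.pattern)):
                raise ValueError("non-finite mode pattern")
            norm = np.linalg.norm(self.pattern)
            if norm == 0:
                raise ValueError("zero mode pattern")
            self.pattern = self.pattern / norm


def _as_mode_specs(modes) -> List[ModeSpec]:
    out = []
    for m in modes:
        out.append(m if isinstance(m, ModeSpec) else ModeSpec(wavenumber=float(m)))
    return out


def water_topology(n_molecules: int, charges: Tuple[float, float] =
                   DEFAULT_WATER_CHARGES, first_atom_id: int = 0,
                   first_molecule_id: int = 0) -> Topology:
    """Topology of n water molecules (O, H, H per molecule)."""
    qO, qH = charges
    if abs(qO + 2 * qH) > 1e-9:
        raise ValueError("water charges must sum to zero")
    n = 3 * n_molecules
    element = np.tile(np.array(["O", "H", "H"], dtype=object), n_molecules)
    mass = np.tile([O_MASS, H_MASS, H_MASS], n_molecules)
    charge = np.tile([qO, qH, qH], n_molecules)
    mol = np.repeat(np.arange(n_molecules) + first_molecule_id, 3)
    return Topology(
        atom_id=np.arange(n) + first_atom_id,
        element=element,
        mass=mass,
        charge=charge,
        molecule_id=mol,
        role=np.array(["water"] * n, dtype=object),
    )


def _water_geometry(o_positions: np.ndarray) -> np.ndarray:
    """Atom rest positions (n_mol*3, 3) from oxygen sites: rigid SPC-like
    geometry, fixed orientation (adequate for statistical fixtures)."""
    h1 = np.array([0.8165, 0.5774, 0.0]) * 0.9572
    h2 = np.array([-0.8165, 0.5774, 0.0]) * 0.9572
    n = o_positions.shape[0]
    pos = np.empty((3 * n, 3))
    pos[0::3] = o_positions
    pos[1::3] = o_positions + h1
    pos[2::3] = o_positions + h2
    return pos


def max_wavenumber_for_dt(dt_fs: float) -> float:
    """Nyquist limit of a stored sampling interval, cm^-1."""
    return 1.0 / (2.0 * dt_fs * C_CM_PER_FS)


# --------------------------------------------------------------------------
# harmonic waters
# --------------------------------------------------------------------------

def gen_harmonic_waters(n_molecules: int, modes, dt: float, duration: float,
                        box: float = 60.0,
                        charges: Tuple[float, float] = DEFAULT_WATER_CHARGES,
                        seed: int = 0,
                        o_positions: Optional[np.ndarray] = None
                        ) -> Tuple[Trajectory, Topology]:
    """Water molecules whose atomic velocities are exact cosine superpositions.

    Each molecule gets an independent random phase and (unless the mode fixes
    one) an independent random unit displacement pattern per mode, seeded.
    Positions are the analytic integrals of the velocities, so positions and
    velocities are mutually consistent.  ``o_positions`` optionally pins the
    oxygen rest sites (used by the hydration-box generator).
    """
    modes = _as_mode_specs(modes)
    nyq = max_wavenumber_for_dt(dt)
    worst = max(m.wavenumber for m in modes)
    if worst >= nyq:
        raise TrajectoryError(
            f"mode at {worst} cm^-1 violates Nyquist: dt={dt} fs resolves "
            f"at most {nyq:.0f} cm^-1"
        )
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration / dt)) + 1
    t = np.arange(n_frames) * dt
    box3 = np.full(3, float(box))
    if o_positions is None:
        o_positions = rng.uniform(0.0, box, size=(n_molecules, 3))
    else:
        o_positions = np.asarray(o_positions, dtype=float)
        if o_positions.shape != (n_molecules, 3):
            raise ValueError("o_positions shape mismatch")
    rest = _water_geometry(o_positions)
    n_atoms = 3 * n_molecules

    pos = np.broadcast_to(rest, (n_frames, n_atoms, 3)).copy()
    vel = np.zeros((n_frames, n_atoms, 3))
    for mode in modes:
        omega = float(wavenumber_to_angular_frequency(mode.wavenumber))
        if mode.phase == "random":
            phases = rng.uniform(0.0, 2.0 * np.pi, size=n_molecules)
        else:
            phases = np.full(n_molecules, float(mode.phase))
        if mode.pattern is None:
            pat = rng.normal(size=(n_molecules, 3, 3))
            pat /= np.linalg.norm(pat, axis=(1, 2), keepdims=True)
        else:
            pat = np.broadcast_to(mode.pattern, (n_molecules, 3, 3))
        pat_atoms = pat.reshape(n_atoms, 3)
        phase_atoms = np.repeat(phases, 3)
        arg = omega * t[:, None] + phase_atoms[None, :]  # (frames, atoms)
        # x(t) = A p cos(arg);  v(t) = -A w p sin(arg)
        pos += mode.amplitude * np.cos(arg)[:, :, None] * pat_atoms[None, :, :]
        vel += -mode.amplitude * omega * np.sin(arg)[:, :, None] * pat_atoms[None, :, :]

    traj = Trajectory(times=t, positions=pos, velocities=vel, box=box3)
    topo = water_topology(n_molecules, charges)
    return traj, topo


def gen_harmonic_hydration_box(shells: Sequence[Tuple[float, float, int, Sequence]],
                               dt: float, duration: float, box: float = 60.0,
                               charges: Tuple[float, float] = DEFAULT_WATER_CHARGES,
                               seed: int = 0) -> Tuple[Trajectory, Topology]:
    """Harmonic waters planted in distance shells around one solute atom.

    ``shells`` is a sequence of ``(r_lo, r_hi, n_molecules, modes)``; oxygen
    rest sites are sampled uniformly in each shell around a single solute
    pseudo-atom at the box centre, and each shell's molecules oscillate with
    its own mode set.  Mode amplitudes are small relative to shell widths so
    molecules keep their shell for the whole run.
    """
    rng = np.random.default_rng(seed)
    center = np.full(3, box / 2.0)
    trajs, topos = [], []
    for r_lo, r_hi, n_mol, modes in shells:
        if r_hi > box / 2.0:
            raise ValueError("shell extends beyond the half box")
        # uniform in the spherical shell
        u = rng.uniform(r_lo ** 3, r_hi ** 3, size=n_mol) ** (1.0 / 3.0)
        v = rng.normal(size=(n_mol, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        opos = center + u[:, None] * v
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        tr, _ = gen_harmonic_waters(n_mol, modes, dt, duration, box=box,
                                    charges=charges, seed=sub_seed,
                                    o_positions=opos)
        trajs.append(tr)
    n_tot = sum(s[2] for s in shells)
    topo_w = water_topology(n_tot, charges, first_atom_id=1, first_molecule_id=1)
    n_frames = trajs[0].n_frames
    times = trajs[0].times
    pos = np.concatenate(
        [np.broadcast_to(center, (n_frames, 1, 3))]
        + [tr.positions for tr in trajs], axis=1)
    vel = np.concatenate(
        [np.zeros((n_frames, 1, 3))] + [tr.velocities for tr in trajs], axis=1)
    topo = Topology(
        atom_id=np.arange(1 + 3 * n_tot),
        element=np.concatenate([["C"], topo_w.element]),
        mass=np.concatenate([[12.011], topo_w.mass]),
        charge=np.concatenate([[0.0], topo_w.charge]),
        molecule_id=np.concatenate([[0], topo_w.molecule_id]),
        role=np.concatenate([["protein"], topo_w.role]),
    )
    traj = Trajectory(times=times, positions=pos, velocities=vel,
                      box=np.full(3, float(box)))
    return traj, topo


# --------------------------------------------------------------------------
# Ornstein-Uhlenbeck gas
# --------------------------------------------------------------------------

def gen_ou_gas(n_atoms: int, tau: float, kT_over_m: float, dt: float,
               duration: float, box: float = 60.0,
               seed: int = 0) -> Tuple[Trajectory, Topology]:
    """Monatomic gas with Ornstein-Uhlenbeck velocities.

    Exact discrete update v(t+dt) = v(t) e^(-dt/tau) + xi with stationary
    per-component variance ``kT_over_m`` ((A/fs)^2), giving the analytic
    VACF exp(-t/tau).  ``tau=inf`` is the ballistic limit (constant
    velocities).  Atoms are labelled role=ion so they pass topology
    validation without water-geometry constraints.
    """
    if not np.isinf(tau) and dt > tau / 10.0:
        raise TrajectoryError(
            f"dt={dt} fs too coarse for tau={tau} fs (need dt <= tau/10)"
        )
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration / dt)) + 1
    decay = 0.0 if tau == 0 else float(np.exp(-dt / tau))
    noise_sd = np.sqrt(kT_over_m * (1.0 - decay ** 2))
    vel = np.empty((n_frames, n_atoms, 3))
    vel[0] = rng.normal(0.0, np.sqrt(kT_over_m), size=(n_atoms, 3))
    for f in range(1, n_frames):
        vel[f] = vel[f - 1] * decay
        if noise_sd > 0:
            vel[f] += rng.normal(0.0, noise_sd, size=(n_atoms, 3))
    pos = np.empty_like(vel)
    pos[0] = rng.uniform(0.0, box, size=(n_atoms, 3))
    np.cumsum(vel[:-1] * dt, axis=0, out=pos[1:])
    pos[1:] += pos[0]
    topo = Topology(
        atom_id=np.arange(n_atoms),
        element=np.array(["Ar"] * n_atoms, dtype=object),
        mass=np.full(n_atoms, 39.948),
        charge=np.zeros(n_atoms),
        molecule_id=np.arange(n_atoms),
        role=np.array(["ion"] * n_atoms, dtype=object),
    )
    traj = Trajectory(times=np.arange(n_frames) * dt, positions=pos,
                      velocities=vel, box=np.full(3, float(box)))
    return traj, topo


# --------------------------------------------------------------------------
# layered static box
# --------------------------------------------------------------------------

def gen_layered_box(profile_spec: Sequence[Tuple[float, float]],
                    box: float = 40.0, n_frames: int = 20,
                    solute_n_atoms: int = 1, solute_radius: float = 0.0,
                    charges: Tuple[float, float] = DEFAULT_WATER_CHARGES,
                    seed: int = 0) -> Tuple[Trajectory, Topology]:
    """Static frames with a prescribed radial water density around a solute.

    ``profile_spec`` is a list of ``(r_upper_A, density_g_cm3)`` breakpoints:
    the target density at distance d (to the nearest solute atom) is that of
    the first segment with ``d < r_upper``; beyond the last breakpoint the
    last density continues as bulk.  Each frame draws an independent
    configuration: the molecule count is fixed at the expectation implied by
    the profile and oxygen sites are sampled from the normalised profile
    density (rejection sampling), so binned densities match the target to
    sampling error.  Velocities are zero (geometry-only fixture).
    """
    profile_spec = [(float(r), float(d)) for r, d in profile_spec]
    if any(d < 0 for _, d in profile_spec):
        raise LayeringError("negative target density")
    if any(profile_spec[i][0] >= profile_spec[i + 1][0]
           for i in range(len(profile_spec) - 1)):
        raise LayeringError("profile breakpoints must be strictly increasing")
    rng = np.random.default_rng(seed)
    center = np.full(3, box / 2.0)
    if solute_n_atoms == 1 or solute_radius == 0.0:
        solute_pos = center.reshape(1, 3).copy()
        solute_n_atoms = 1
    else:
        v = rng.normal(size=(solute_n_atoms, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        solute_pos = center + solute_radius * v

    def target_density(d):
        out = np.full(d.shape, profile_spec[-1][1])
        for r_up, dens in reversed(profile_spec):
            out = np.where(d < r_up, dens, out)
        return out

    box3 = np.full(3, float(box))
    # expected molecule count from the mean intensity over the box (MC integral)
    probe = rng.uniform(0.0, box, size=(200_000, 3))
    dprobe = _min_dist(probe, solute_pos, box3)
    lam = number_density_from_mass_density(target_density(dprobe))
    n_expected = float(lam.mean() * box ** 3)
    n_mol = int(round(n_expected))
    if n_mol == 0:
        raise LayeringError("profile implies zero molecules in this box")
    lam_max = number_density_from_mass_density(max(d for _, d in profile_spec))
    if lam_max <= 0:
        raise LayeringError("infeasible (all-zero) density profile")

    frames = []
    for _ in range(n_frames):
        pts = np.empty((0, 3))
        while pts.shape[0] < n_mol:
            cand = rng.uniform(0.0, box, size=(4 * n_mol + 64, 3))
            d = _min_dist(cand, solute_pos, box3)
            accept = rng.uniform(0.0, 1.0, size=cand.shape[0]) < (
                number_density_from_mass_density(target_density(d)) / lam_max
            )
            pts = np.concatenate([pts, cand[accept]], axis=0)
        frames.append(pts[:n_mol])

    n_atoms = solute_n_atoms + 3 * n_mol
    pos = np.empty((n_frames, n_atoms, 3))
    for f, opos in enumerate(frames):
        pos[f, :solute_n_atoms] = solute_pos
        pos[f, solute_n_atoms:] = _water_geometry(opos)
    topo_w = water_topology(n_mol, charges, first_atom_id=solute_n_atoms,
                            first_molecule_id=1)
    topo = Topology(
        atom_id=np.arange(n_atoms),
        element=np.concatenate([["C"] * solute_n_atoms, topo_w.element]),
        mass=np.concatenate([[12.011] * solute_n_atoms, topo_w.mass]),
        charge=np.concatenate([[0.0] * solute_n_atoms, topo_w.charge]),
        molecule_id=np.concatenate([[0] * solute_n_atoms, topo_w.molecule_id]),
        role=np.concatenate([["protein"] * solute_n_atoms, topo_w.role]),
    )
    traj = Trajectory(times=np.arange(n_frames, dtype=float),
                      positions=pos, velocities=None, box=box3)
    return traj, topo


def _min_dist(points, ref, box):
    delta = points[:, None, :] - ref[None, :, :]
    delta -= box * np.round(delta / box)
    return np.sqrt((delta ** 2).sum(axis=-1)).min(axis=1)


# --------------------------------------------------------------------------
# scripted layer occupancy
# --------------------------------------------------------------------------

@dataclass
class LayerScript:
    """Per-molecule scripted occupancy: {molecule_id: [(start, stop, layer)]}.

    Frame ranges are half-open [start, stop) and must tile [0, n_frames)
    without overlap; unscripted molecules are BULK throughout.
    """

    ranges: Dict[int, List[Tuple[int, int, int]]] = field(default_factory=dict)

    def validate(self, n_frames: int) -> None:
        for mol, segs in self.ranges.items():
            segs = sorted(segs)
            cover = 0
            for start, stop, layer in segs:
                if layer < 0:
                    raise LayeringError(f"molecule {mol}: negative layer index")
                if start < cover:
                    raise LayeringError(
                        f"molecule {mol}: overlapping ranges at frame {start}"
                    )
                if start > cover:
                    raise LayeringError(
                        f"molecule {mol}: gap before frame {start} "
                        "(ranges must tile the trajectory)"
                    )
                cover = stop
            if cover != n_frames:
                raise LayeringError(
                    f"molecule {mol}: ranges cover {cover} of {n_frames} frames"
                )


def gen_scripted_layers(script: LayerScript, n_frames: int,
                        molecule_ids: Optional[Sequence[int]] = None,
                        dt: float = 1.0) -> LayerLabels:
    """Label matrix exactly as scripted (BULK for unscripted molecules)."""
    script.validate(n_frames)
    if molecule_ids is None:
        molecule_ids = sorted(script.ranges)
    molecule_ids = np.asarray(list(molecule_ids), dtype=np.int64)
    labels = np.full((n_frames, molecule_ids.size), BULK, dtype=np.int64)
    col = {int(m): j for j, m in enumerate(molecule_ids)}
    for mol, segs in script.ranges.items():
        if int(mol) not in col:
            raise LayeringError(f"scripted molecule {mol} not in molecule_ids")
        for start, stop, layer in segs:
            labels[start:stop, col[int(mol)]] = layer
    return LayerLabels(labels=labels, molecule_ids=molecule_ids,
                       times=np.arange(n_frames) * dt)


# --------------------------------------------------------------------------
# sidecar
# --------------------------------------------------------------------------

def write_sidecar(path: str, generator: str, seed: int, **params) -> None:
    """JSON sidecar recording generator name, parameters, seed and RNG."""
    payload = {"generator": generator, "seed": seed, "rng": "numpy PCG64",
               "params": params}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=str)
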