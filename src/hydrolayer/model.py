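"""Domain types for hydration-layer spectral analysis.

All containers are thin, validated wrappers around numpy arrays in the
package's internal units (A, fs, amu, e; wavenumbers in cm^-1; see
:mod:`hydrolayer.units`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class HydrolayerError(Exception):
    """Base class for all package errors."""


class TopologyError(HydrolayerError):
    pass


class TrajectoryError(HydrolayerError):
    pass


class SpectrumError(HydrolayerError):
    pass


class LayeringError(HydrolayerError):
    pass


ROLE_PROTEIN = "protein"
ROLE_WATER = "water"
ROLE_ION = "ion"
ROLES = (ROLE_PROTEIN, ROLE_WATER, ROLE_ION)

#: layer label used for water beyond the outermost boundary
BULK = 0


@dataclass
class Topology:
    """Per-atom identity table.

    Parameters
    ----------
    atom_id : (n,) int array — unique, dense (0..n-1 after sorting).
    element : (n,) str array — element symbol ('O', 'H', 'C', ...).
    mass : (n,) float array, amu.
    charge : (n,) float array, elementary charges.
    molecule_id : (n,) int array — grouping of atoms into molecules.
    role : (n,) str array — one of {'protein', 'water', 'ion'}.
    """

    atom_id: np.ndarray
    element: np.ndarray
    mass: np.ndarray
    charge: np.ndarray
    molecule_id: np.ndarray
    role: np.ndarray

    def __post_init__(self):
        self.atom_id = np.asarray(self.atom_id, dtype=np.int64)
        self.element = np.asarray(self.element, dtype=object)
        self.mass = np.asarray(self.mass, dtype=float)
        self.charge = np.asarray(self.charge, dtype=float)
        self.molecule_id = np.asarray(self.molecule_id, dtype=np.int64)
        self.role = np.asarray(self.role, dtype=object)
        self.validate()

    @property
    def n_atoms(self) -> int:
        return self.atom_id.size

    def validate(self) -> None:
        n = self.n_atoms
        for name in ("element", "mass", "charge", "molecule_id", "role"):
            if getattr(self, name).shape != (n,):
                raise TopologyError(f"field {name!r} length mismatch")
        uniq, counts = np.unique(self.atom_id, return_counts=True)
        if uniq.size != n:
            dup = uniq[counts > 1][:5]
            raise TopologyError(
                f"duplicate atom_id values: {[int(d) for d in dup]}")
        if n and self.atom_id.max() - self.atom_id.min() != n - 1:
            raise TopologyError("atom_ids must be dense (consecutive integers)")
        bad_role = set(self.role) - set(ROLES)
        if bad_role:
            raise TopologyError(f"unknown role(s): {bad_role}")
        # water molecules: exactly 1 oxygen + 2 hydrogens, net-neutral
        water = self.role == ROLE_WATER
        if water.any():
            wmols = self.molecule_id[water]
            mols, inverse = np.unique(wmols, return_inverse=True)
            if np.isin(self.molecule_id[~water], mols).any():
                bad = self.molecule_id[~water][
                    np.isin(self.molecule_id[~water], mols)][0]
                raise TopologyError(
                    f"molecule {bad} mixes water and non-water atoms")
            n_mol = mols.size
            counts = np.bincount(inverse, minlength=n_mol)
            n_o = np.bincount(inverse, weights=(self.element[water] == "O"),
                              minlength=n_mol)
            n_h = np.bincount(inverse, weights=(self.element[water] == "H"),
                              minlength=n_mol)
            bad = np.flatnonzero((counts != 3) | (n_o != 1) | (n_h != 2))
            if bad.size:
                m = int(mols[bad[0]])
                raise TopologyError(
                    f"water molecule {m} must contain exactly O + 2H")
            q = np.bincount(inverse, weights=self.charge[water], minlength=n_mol)
            bad = np.flatnonzero(np.abs(q) > 1e-9)
            if bad.size:
                raise TopologyError(
                    f"water molecule {int(mols[bad[0]])} has net charge "
                    f"{q[bad[0]]:+.3e} e")

    # --- selections -----------------------------------------------------
    def indices_by_role(self, role: str) -> np.ndarray:
        return np.flatnonzero(self.role == role)

    @property
    def water_molecule_ids(self) -> np.ndarray:
        """Sorted ids of all water molecules."""
        return np.unique(self.molecule_id[self.role == ROLE_WATER])

    def water_oxygen_indices(self) -> np.ndarray:
        """Atom indices of water oxygens, ordered by molecule id."""
        sel = (self.role == ROLE_WATER) & (self.element == "O")
        idx = np.flatnonzero(sel)
        return idx[np.argsort(self.molecule_id[idx], kind="stable")]

    def water_hydrogen_indices(self) -> np.ndarray:
        sel = (self.role == ROLE_WATER) & (self.element == "H")
        idx = np.flatnonzero(sel)
        return idx[np.argsort(self.molecule_id[idx], kind="stable")]

    def solute_heavy_indices(self, include_hydrogens: bool = False) -> np.ndarray:
        sel = self.role == ROLE_PROTEIN
        if not include_hydrogens:
            sel &= self.element != "H"
        return np.flatnonzero(sel)

    def atoms_of_molecules(self, molecule_ids) -> np.ndarray:
        return np.flatnonzero(np.isin(self.molecule_id, np.asarray(list(molecule_ids))))

    def molecule_mass(self, molecule_id: int) -> float:
        return float(self.mass[self.molecule_id == molecule_id].sum())


@dataclass
class Trajectory:
    """Uniformly sampled frames of positions (and velocities).

    times : (n_frames,) fs, uniformly spaced, starting at the first stored
        frame (frame 0 is time 0 by convention for generated data).
    positions : (n_frames, n_atoms, 3) A.
    velocities : (n_frames, n_atoms, 3) A/fs, or None for geometry-only
        fixtures (rejected by spectral operations).
    box : (n_frames, 3) orthorhombic box edge lengths, A.
    """

    times: np.ndarray
    positions: np.ndarray
    velocities: Optional[np.ndarray]
    box: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.box.ndim == 1:
            self.box = np.broadcast_to(self.box, (self.n_frames, 3)).copy()
        self.validate()

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float:
        """Sampling interval, fs."""
        if self.n_frames < 2:
            raise TrajectoryError("dt undefined for a single-frame trajectory")
        return float(self.times[1] - self.times[0])

    @property
    def has_velocities(self) -> bool:
        return self.velocities is not None

    def validate(self, time_rtol: float = 1e-6) -> None:
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise TrajectoryError("positions must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise TrajectoryError("non-finite positions")
        if self.times.shape != (self.n_frames,):
            raise TrajectoryError("times length mismatch")
        if self.velocities is not None:
            if self.velocities.shape != self.positions.shape:
                raise TrajectoryError("velocities shape mismatch")
            if not np.all(np.isfinite(self.velocities)):
                raise TrajectoryError("non-finite velocities")
        if self.box.shape != (self.n_frames, 3):
            raise TrajectoryError("box must have shape (n_frames, 3)")
        if not np.all(self.box > 0):
            raise TrajectoryError("box lengths must be positive")
        if self.n_frames >= 3:
            dts = np.diff(self.times)
            dt0 = dts[0]  # first spacing defines the sampling grid
            bad = np.flatnonzero(np.abs(dts - dt0) > time_rtol * abs(dt0))
            if bad.size:
                raise TrajectoryError(
                    f"non-uniform sampling: frame {int(bad[0]) + 1} at "
                    f"t={self.times[bad[0] + 1]:g} fs breaks spacing {dt0:g} fs"
                )

    def require_velocities(self) -> None:
        if self.velocities is None:
            raise TrajectoryError(
                "no velocities: trajectory is position-only and cannot be "
                "used for spectral operations"
            )

    def frame_slice(self, start: int, stop: int) -> "Trajectory":
        """Sub-trajectory covering frames [start, stop)."""
        if not (0 <= start < stop <= self.n_frames):
            raise TrajectoryError(f"invalid frame window [{start}, {stop})")
        vel = None if self.velocities is None else self.velocities[start:stop]
        return Trajectory(
            times=self.times[start:stop],
            positions=self.positions[start:stop],
            velocities=vel,
            box=self.box[start:stop],
        )

    def time_window(self, t0_fs: float, t1_fs: float) -> "Trajectory":
        """Sub-trajectory with times in [t0, t1) (half-open, fs)."""
        idx = np.flatnonzero((self.times >= t0_fs - 1e-9) & (self.times < t1_fs - 1e-9))
        if idx.size == 0:
            raise TrajectoryError(f"no frames in window [{t0_fs}, {t1_fs}) fs")
        return self.frame_slice(int(idx[0]), int(idx[-1]) + 1)


@dataclass
class ACFSeries:
    """One-sided autocorrelation estimate on a uniform lag grid.

    values are dimensionless for a normalised velocity ACF (1 at zero lag)
    or (e*A/fs)^2 for an unnormalised dipole-flux ACF.
    """

    lags: np.ndarray  # fs
    values: np.ndarray
    n_samples_per_lag: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.n_samples_per_lag = np.asarray(self.n_samples_per_lag, dtype=np.int64)
        if self.lags.shape != self.values.shape:
            raise SpectrumError("lags/values length mismatch")
        if np.any(np.diff(self.n_samples_per_lag) > 0):
            raise SpectrumError("n_samples_per_lag must be non-increasing with lag")
        if self.normalized and abs(self.values[0] - 1.0) > 0:
            raise SpectrumError("normalized ACF must equal 1 at zero lag")

    @property
    def dt(self) -> float:
        if self.lags.size < 2:
            raise SpectrumError("lag spacing undefined for a single lag")
        return float(self.lags[1] - self.lags[0])


@dataclass
class FluxSeries:
    """Time series of the dipole-moment derivative dM/dt = sum_j e_j v_j.

    times fs, flux (n_frames, 3) in e*A/fs.
    """

    times: np.ndarray
    flux: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.flux = np.asarray(self.flux, dtype=float)
        if self.flux.shape != (self.times.size, 3):
            raise SpectrumError("flux must have shape (n_frames, 3)")
        if not np.all(np.isfinite(self.flux)):
            raise SpectrumError("non-finite flux")


SPECTRUM_KINDS = ("vdos_H", "vdos_O", "vdos", "ir")


@dataclass
class Spectrum:
    """Intensity versus wavenumber (cm^-1) with provenance metadata."""

    wavenumbers: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavenumbers.shape != self.intensity.shape:
            raise SpectrumError("wavenumber/intensity length mismatch")
        if self.wavenumbers.size == 0:
            raise SpectrumError("empty spectrum")
        if self.wavenumbers[0] != 0.0:
            raise SpectrumError("wavenumber grid must start at 0")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise SpectrumError("wavenumber grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise SpectrumError("non-finite intensity")

    @property
    def grid_step(self) -> float:
        return float(self.wavenumbers[1] - self.wavenumbers[0])

    def peak_wavenumber(self, lo: float = None, hi: float = None) -> float:
        """Position of the intensity maximum, optionally within [lo, hi)."""
        sel = np.ones(self.wavenumbers.size, dtype=bool)
        if lo is not None:
            sel &= self.wavenumbers >= lo
        if hi is not None:
            sel &= self.wavenumbers < hi
        idx = np.flatnonzero(sel)
        return float(self.wavenumbers[idx[np.argmax(self.intensity[idx])]])


@dataclass
class DensityProfile:
    """Binned water mass density versus distance from the solute surface."""

    bin_edges: np.ndarray  # A, half-open bins [a, b)
    density: np.ndarray  # g cm^-3
    n_frames: int
    method: str  # 'voronoi' | 'bin_volume'

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.density.shape != (self.bin_edges.size - 1,):
            raise LayeringError("density length must be n_edges - 1")
        if np.any(self.density < 0):
            raise LayeringError("densities must be non-negative")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise LayeringError("bin edges must be strictly increasing")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class LayerPartition:
    """Layer boundaries in A: layer k covers [b_{k-1}, b_k), b_0 = 0 implicit.

    The final boundary is the bulk cutoff; distances beyond it are BULK.
    """

    boundaries: np.ndarray

    def __post_init__(self):
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.boundaries.size == 0:
            raise LayeringError("at least one boundary is required")
        if self.boundaries[0] <= 0 or np.any(np.diff(self.boundaries) <= 0):
            raise LayeringError("boundaries must be strictly increasing and positive")

    @property
    def n_layers(self) -> int:
        return self.boundaries.size


#: default four-layer partition bracketing the density features typical of a
#: protein hydration shell (first peak ~1.8 A, second ~2.6 A, narrow third
#: region, bulk onset ~7 A); always user-overridable.
DEFAULT_BOUNDARIES = (2.2, 3.4, 4.5, 7.0)


@dataclass
class LayerLabels:
    """Per-frame, per-water-molecule layer labels (BULK = 0)."""

    labels: np.ndarray  # (n_frames, n_waters) int
    molecule_ids: np.ndarray  # (n_waters,)
    times: np.ndarray  # (n_frames,) fs

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)
        if self.labels.shape != (self.times.size, self.molecule_ids.size):
            raise LayeringError("labels must have shape (n_frames, n_waters)")
        if np.any(self.labels < 0):
            raise LayeringError("labels must be >= 0 (0 = BULK)")

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]


@dataclass
class MemberSet:
    """Water molecules resident in one layer over one time interval."""

    interval: tuple  # (start fs, end fs), half-open
    layer: int
    molecule_ids: np.ndarray
    occupancy: dict  # molecule id -> fraction of interval frames in `layer`
    threshold: float

    def __post_init__(self):
        self.molecule_ids = np.asarray(sorted(self.molecule_ids), dtype=np.int64)
        for mid in self.molecule_ids:
            if self.occupancy[int(mid)] < self.threshold:
                raise LayeringError(
                    f"member {mid} occupancy {self.occupancy[int(mid)]:.3f} "
                    f"below threshold {self.threshold}"
                )

    @property
    def n_members(self) -> int:
        return self.molecule_ids.size


@dataclass
class BandMetrics:
    """Summary of one named spectral band."""

    band: str
    range_cm1: tuple
    peak_position: Optional[float]
    peak_intensity: Optional[float]
    fwhm: Optional[float]
    shoulder_positions: list = field(default_factory=list)

    def is_null(self) -> bool:
        return self.peak_position is None
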