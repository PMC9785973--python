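"""End-to-end orchestration: density profile -> layer boundaries ->
residence membership -> per-layer and cumulative VDOS/IR -> band report.

The default :class:`RunConfig` encodes the analysis protocol this package
implements: residence threshold 0.90, the final 200 ps analysed, 20 ps
collection intervals for layers 1-2 and 5 ps for outer layers, spectra
averaged over the first 10 intervals of each layer.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Union

import numpy as np
import yaml

from . import io as hio
from .layering import (
    build_interval_scheme,
    density_profile,
    detect_boundaries,
    label_trajectory,
    residence_membership,
)
from .model import (
    DEFAULT_BOUNDARIES,
    HydrolayerError,
    LayerPartition,
    Spectrum,
    Topology,
    Trajectory,
)
from .spectra import (
    DEFAULT_BANDS,
    band_summary,
    cumulative_layer_spectrum,
    layer_spectrum,
)

log = logging.getLogger(__name__)


class PipelineError(HydrolayerError):
    pass


@dataclass
class RunConfig:
    """Full configuration of one analysis run (defaults = standard protocol)."""

    trajectory: Optional[str] = None
    topology: Optional[str] = None
    trajectory_format: str = "fixture"
    out_dir: str = "hydrolayer_out"

    # protocol
    analysis_window_fs: float = 200_000.0  # last 200 ps
    interval_fs_inner: float = 20_000.0    # layers 1-2: 20 ps
    interval_fs_outer: float = 5_000.0     # layers 3+: 5 ps
    n_intervals: int = 10                  # intervals averaged per layer
    residence_threshold: float = 0.90

    # layering
    boundaries: Union[str, List[float]] = "auto"  # 'auto' or explicit list (A)
    bin_width: float = 0.2
    max_distance: float = 10.0
    density_method: str = "voronoi"
    include_solute_hydrogens: bool = False
    smoothing_window: int = 5
    bulk_tolerance: float = 0.05

    # spectra
    window: str = "hann"
    zero_pad_factor: int = 2
    ir_mode: str = "collective"
    max_lag_fs: Optional[float] = None
    bands: Dict[str, tuple] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_BANDS.items()})

    seed: int = 0

    def per_layer_intervals(self, n_layers: int) -> Dict[int, float]:
        return {k: (self.interval_fs_inner if k <= 2 else self.interval_fs_outer)
                for k in range(1, n_layers + 1)}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bands"] = {k: list(v) for k, v in d["bands"].items()}
        return d

    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location excluded, so
        re-running into a different directory reproduces the same hash)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config key(s): {sorted(unknown)}")
        if "bands" in data:
            data["bands"] = {k: tuple(v) for k, v in data["bands"].items()}
        return cls(**data)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def _frame_range(times: np.ndarray, interval) -> tuple:
    lo, hi = interval
    idx = np.flatnonzero((times >= lo - 1e-9) & (times < hi - 1e-9))
    if idx.size == 0:
        raise PipelineError(f"no frames in interval [{lo}, {hi}) fs")
    return int(idx[0]), int(idx[-1]) + 1


def run_pipeline(config: RunConfig, traj: Optional[Trajectory] = None,
                 topo: Optional[Topology] = None) -> dict:
    """Run the full workflow; returns a dict of output paths and key objects.

    ``traj``/``topo`` may be passed directly (e.g. from the synthetic
    generators); otherwise they are read from the configured paths.
    """
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    cfg_hash = config.config_hash()

    logfile = os.path.join(out, "run.log")
    handler = logging.FileHandler(logfile, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("hydrolayer")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    results = {"out_dir": out, "config_hash": cfg_hash}
    try:
        with open(os.path.join(out, "effective_config.yaml"), "w") as fh:
            fh.write(f"# config_hash: {cfg_hash}\n")
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

        if traj is None:
            traj = _stage("read_trajectory")(hio.read_trajectory)(
                config.trajectory, format=config.trajectory_format)
        if topo is None:
            topo = _stage("read_topology")(hio.read_topology)(config.topology)
        log.info("run %s: %d frames, %d atoms", cfg_hash, traj.n_frames,
                 traj.n_atoms)

        profile = _stage("density_profile")(density_profile)(
            traj, topo, config.bin_width, config.max_distance,
            method=config.density_method,
            include_solute_hydrogens=config.include_solute_hydrogens)
        ppath = os.path.join(out, "density_profile.csv")
        with open(ppath, "w") as fh:
            fh.write(f"# config_hash: {cfg_hash}\n")
            fh.write("distance_A,density_g_cm3\n")
            for c, d in zip(profile.bin_centers.tolist(),
                            profile.density.tolist()):
                fh.write(f"{c!r},{d!r}\n")
        results["density_profile"] = profile

        if config.boundaries == "auto":
            partition = _stage("detect_boundaries")(detect_boundaries)(
                profile, smoothing_window=config.smoothing_window,
                bulk_tolerance=config.bulk_tolerance)
        else:
            partition = LayerPartition(list(config.boundaries))
        log.info("boundaries (A): %s", partition.boundaries.tolist())
        results["partition"] = partition

        labels = _stage("label_trajectory")(label_trajectory)(
            traj, topo, partition,
            include_solute_hydrogens=config.include_solute_hydrogens)

        span = float(traj.times[-1] - traj.times[0])
        window_fs = min(config.analysis_window_fs, span)
        scheme = _stage("build_interval_scheme")(build_interval_scheme)(
            span, config.per_layer_intervals(partition.n_layers),
            analysis_window_fs=window_fs, n_intervals=config.n_intervals,
            t_end_fs=float(traj.times[-1]) + (traj.dt if traj.n_frames > 1 else 0))

        members: Dict[int, list] = {}
        layers_json: Dict = {"config_hash": cfg_hash,
                             "boundaries_A": partition.boundaries.tolist(),
                             "residence_threshold": config.residence_threshold,
                             "layers": {}}
        for layer in range(1, partition.n_layers + 1):
            members[layer] = []
            entries = []
            for iv in scheme.marked_intervals(layer):
                fr = _frame_range(traj.times, iv)
                ms = residence_membership(labels, layer,
                                          threshold=config.residence_threshold,
                                          frame_range=fr)
                ms = dataclasses.replace(ms, interval=iv)
                members[layer].append(ms)
                log.info("layer %d interval [%.0f, %.0f) fs: %d members",
                         layer, iv[0], iv[1], ms.n_members)
                entries.append({
                    "interval_fs": [iv[0], iv[1]],
                    "members": [int(m) for m in ms.molecule_ids],
                    "occupancy": {str(m): ms.occupancy[int(m)]
                                  for m in ms.molecule_ids},
                })
            layers_json["layers"][str(layer)] = entries
        lpath = os.path.join(out, "layers.json")
        with open(lpath, "w") as fh:
            json.dump(layers_json, fh, indent=1)
        results["members"] = members

        spectra: Dict[str, Spectrum] = {}
        for layer in range(1, partition.n_layers + 1):
            for kind in ("vdos_H", "vdos_O", "ir"):
                name = f"{kind}_layer{layer}"
                try:
                    s = _stage(f"spectrum {name}")(layer_spectrum)(
                        traj, topo, members[layer], kind,
                        window=config.window,
                        zero_pad_factor=config.zero_pad_factor,
                        max_lag_fs=config.max_lag_fs, ir_mode=config.ir_mode)
                except PipelineError as exc:
                    log.warning("%s skipped: %s", name, exc)
                    continue
                s.meta["config_hash"] = cfg_hash
                hio.write_spectrum(s, os.path.join(out, f"{name}.csv"), "csv")
                spectra[name] = s

        # cumulative spectra on a common (inner) interval scheme
        common = build_interval_scheme(
            span, {k: config.interval_fs_inner
                   for k in range(1, partition.n_layers + 1)},
            analysis_window_fs=window_fs, n_intervals=config.n_intervals,
            t_end_fs=float(traj.times[-1]) + (traj.dt if traj.n_frames > 1 else 0))
        common_members = {}
        for layer in range(1, partition.n_layers + 1):
            common_members[layer] = []
            for iv in common.marked_intervals(layer):
                fr = _frame_range(traj.times, iv)
                ms = residence_membership(labels, layer,
                                          threshold=config.residence_threshold,
                                          frame_range=fr)
                common_members[layer].append(dataclasses.replace(ms, interval=iv))
        for k in range(1, partition.n_layers + 1):
            per_layer = [common_members[layer] for layer in range(1, k + 1)]
            for kind in ("vdos_H", "vdos_O", "ir"):
                name = f"{kind}_cumulative{k}"
                try:
                    s = _stage(f"spectrum {name}")(cumulative_layer_spectrum)(
                        traj, topo, per_layer, kind, window=config.window,
                        zero_pad_factor=config.zero_pad_factor,
                        max_lag_fs=config.max_lag_fs, ir_mode=config.ir_mode)
                except PipelineError as exc:
                    log.warning("%s skipped: %s", name, exc)
                    continue
                s.meta["config_hash"] = cfg_hash
                hio.write_spectrum(s, os.path.join(out, f"{name}.csv"), "csv")
                spectra[name] = s
        results["spectra"] = spectra

        bands_json = {"config_hash": cfg_hash, "bands": {}}
        for name, s in spectra.items():
            try:
                metrics = band_summary(s, bands=config.bands)
            except HydrolayerError as exc:
                log.warning("band summary for %s skipped: %s", name, exc)
                continue
            bands_json["bands"][name] = [
                {"band": m.band, "range_cm1": list(m.range_cm1),
                 "peak_position_cm1": m.peak_position,
                 "peak_intensity": m.peak_intensity, "fwhm_cm1": m.fwhm,
                 "shoulders_cm1": m.shoulder_positions}
                for m in metrics
            ]
        bpath = os.path.join(out, "bands.json")
        with open(bpath, "w") as fh:
            json.dump(bands_json, fh, indent=1)
        results["bands"] = bands_json
    finally:
        root.removeHandler(handler)
        handler.close()
    return results
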