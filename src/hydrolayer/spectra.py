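"""Autocorrelation functions and vibrational / infrared spectra.

The vibrational density of states (VDOS) of an atom selection is the
one-sided cosine transform of its normalised velocity autocorrelation
function

    Z(t) = <v_j(t0 + t) . v_j(t0)> / <v_j(t0) . v_j(t0)>,
    Z(nu) = integral_0^inf Z(t) cos(2 pi c nu t) dt,

averaged over atoms j and all time origins t0.  The classical IR lineshape
is the analogous transform of the flux-flux autocorrelation of the dipole
derivative dM/dt = sum_j e_j v_j(t) (arbitrary intensity units; the
proportionality prefactor is not fixed here).

ACFs are estimated with all time origins via FFT and normalised per lag by
the number of contributing origins; the transform discretises the integral
with the trapezoidal rule (half weight on the zero-lag sample), which keeps
the transform of an exponential ACF on the analytic Lorentzian to
O((dt/tau)^2).
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .model import (
    ACFSeries,
    BandMetrics,
    FluxSeries,
    MemberSet,
    Spectrum,
    SpectrumError,
    Topology,
    Trajectory,
)
from .units import C_CM_PER_FS

#: default named bands (cm^-1): sub-acoustic, libration-rotation, H-O-H bend,
#: O-H stretch
DEFAULT_BANDS: Dict[str, tuple] = {
    "acoustic": (0.0, 130.0),
    "libration": (130.0, 1300.0),
    "bend": (1400.0, 1800.0),
    "stretch": (3250.0, 3750.0),
}


# --------------------------------------------------------------------------
# ACF estimation
# --------------------------------------------------------------------------

def _acf_fft_sum(series: np.ndarray, max_lag_idx: int) -> np.ndarray:
    """Sum over columns of the raw lag products sum_t x(t) x(t+k), via FFT.

    series: (n_frames, n_series) array.  Returns (max_lag_idx + 1,) sums,
    not yet normalised by the number of origins.
    """
    n = series.shape[0]
    nfft = 1
    while nfft < 2 * n:
        nfft *= 2
    f = np.fft.rfft(series, n=nfft, axis=0)
    corr = np.fft.irfft((f * f.conj()).real, n=nfft, axis=0)[: max_lag_idx + 1]
    return corr.sum(axis=1)


def autocorrelation(series: np.ndarray, dt: float, max_lag_idx: int,
                    normalize: bool = False) -> ACFSeries:
    """All-origins autocorrelation of one or more scalar series.

    series: (n_frames,) or (n_frames, n_series); components/atoms are
    averaged together (their lag products are pooled).  Each lag k is
    normalised by the n - k available origins times the series count.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
    n = series.shape[0]
    if not (0 < max_lag_idx < n):
        raise SpectrumError(f"max_lag must be in (0, interval length); got "
                            f"{max_lag_idx} of {n} frames")
    sums = _acf_fft_sum(series, max_lag_idx)
    origins = n - np.arange(max_lag_idx + 1)
    values = sums / (origins * series.shape[1])
    n_samples = origins * series.shape[1]
    if normalize:
        if values[0] == 0:
            raise SpectrumError("cannot normalise an identically-zero ACF")
        values = values / values[0]
        values[0] = 1.0  # exact by definition
    return ACFSeries(lags=np.arange(max_lag_idx + 1) * dt, values=values,
                     n_samples_per_lag=n_samples, normalized=normalize)


def velocity_acf(traj: Trajectory, atom_indices: Sequence[int],
                 max_lag_fs: Optional[float] = None,
                 normalize: bool = True) -> ACFSeries:
    """Velocity autocorrelation of an atom selection, all time origins.

    The x/y/z components of every selected atom are pooled into one
    estimate, so the ACF of a union of equal-size disjoint selections is the
    mean of the selections' ACFs by construction.  max_lag defaults to half
    the interval.
    """
    traj.require_velocities()
    atom_indices = np.asarray(list(atom_indices), dtype=np.int64)
    if atom_indices.size == 0:
        raise SpectrumError("empty atom selection")
    dt = traj.dt
    max_lag_idx = _lag_index(max_lag_fs, dt, traj.n_frames)
    vel = traj.velocities[:, atom_indices, :].reshape(traj.n_frames, -1)
    return autocorrelation(vel, dt, max_lag_idx, normalize=normalize)


def _lag_index(max_lag_fs: Optional[float], dt: float, n_frames: int) -> int:
    if max_lag_fs is None:
        return n_frames // 2
    idx = int(round(max_lag_fs / dt))
    if idx >= n_frames:
        raise SpectrumError(
            f"max_lag {max_lag_fs} fs >= interval ({n_frames} frames x {dt} fs)"
        )
    return max(idx, 1)


def dipole_flux(traj: Trajectory, topo: Topology,
                molecule_ids: Iterable[int]) -> FluxSeries:
    """dM/dt = sum_j e_j v_j(t) over the atoms of the selected molecules."""
    traj.require_velocities()
    mols = list(molecule_ids)
    if not mols:
        raise SpectrumError("empty molecule selection")
    atoms = topo.atoms_of_molecules(mols)
    charges = topo.charge[atoms]
    flux = np.einsum("j,fjc->fc", charges, traj.velocities[:, atoms, :])
    return FluxSeries(times=traj.times.copy(), flux=flux)


def flux_acf(flux: FluxSeries, max_lag_fs: Optional[float] = None,
             normalize: bool = False) -> ACFSeries:
    """Autocorrelation <dM/dt(t) . dM/dt(0)> of a single 3-vector series.

    Unlike the velocity ACF, the three Cartesian components are summed (dot
    product), not averaged, and the result is unnormalised by default.
    """
    n = flux.times.size
    if n < 2:
        raise SpectrumError("flux series too short")
    dt = float(flux.times[1] - flux.times[0])
    max_lag_idx = _lag_index(max_lag_fs, dt, n)
    sums = _acf_fft_sum(flux.flux, max_lag_idx)
    origins = n - np.arange(max_lag_idx + 1)
    values = sums / origins  # dot product: components summed
    if normalize and values[0] != 0:
        values = values / values[0]
        values[0] = 1.0
    return ACFSeries(lags=np.arange(max_lag_idx + 1) * dt, values=values,
                     n_samples_per_lag=origins, normalized=normalize)


# --------------------------------------------------------------------------
# cosine transform
# --------------------------------------------------------------------------

def _window_weights(n: int, window: str) -> np.ndarray:
    if window == "none":
        return np.ones(n)
    if window == "hann":
        # half Hann over the one-sided lag axis: 1 at lag 0, 0 at the last lag
        return 0.5 * (1.0 + np.cos(np.pi * np.arange(n) / (n - 1)))
    raise SpectrumError(f"unknown window {window!r}")


def acf_to_spectrum(acf: ACFSeries, window: str = "none",
                    zero_pad_factor: int = 1, method: str = "fft",
                    meta: Optional[dict] = None) -> Spectrum:
    """One-sided cosine transform of an ACF onto a cm^-1 grid.

    S(nu_m) = dt * sum_k w_k' Z(t_k) cos(2 pi c nu_m t_k)  with trapezoidal
    end weight (w_0' = w_0 / 2) and nu_m = m / (2 c K dt zero_pad_factor)
    for K lags.  ``method='fft'`` evaluates the sum as the real part of a
    zero-padded one-sided DFT; ``method='direct'`` uses the explicit cosine
    sum.  Both paths compute the same quantity.
    """
    if acf.lags.size < 2:
        raise SpectrumError("ACF too short to transform")
    dts = np.diff(acf.lags)
    if np.max(np.abs(dts - dts[0])) > 1e-9 * abs(dts[0]):
        raise SpectrumError("non-uniform lag spacing")
    if zero_pad_factor < 1:
        raise SpectrumError("zero_pad_factor must be >= 1")
    dt = acf.dt
    k = acf.lags.size
    y = acf.values * _window_weights(k, window)
    y = y.copy()
    y[0] *= 0.5
    m_bins = k * zero_pad_factor
    nfft = 2 * m_bins
    if method == "fft":
        intensity = dt * np.fft.rfft(y, n=nfft).real[:m_bins]
    elif method == "direct":
        t = acf.lags
        nu = np.arange(m_bins) / (nfft * dt)  # cycles / fs
        intensity = dt * (np.cos(2.0 * np.pi * nu[:, None] * t[None, :]) @ y)
    else:
        raise SpectrumError(f"unknown transform method {method!r}")
    wavenumbers = np.arange(m_bins) / (nfft * dt * C_CM_PER_FS)
    full_meta = {"window": window, "zero_pad_factor": zero_pad_factor,
                 "max_lag_fs": float(acf.lags[-1]), "dt_fs": dt}
    if meta:
        full_meta.update(meta)
    return Spectrum(wavenumbers=wavenumbers, intensity=intensity, meta=full_meta)


def ir_spectrum(facf: ACFSeries, window: str = "none", zero_pad_factor: int = 1,
                meta: Optional[dict] = None) -> Spectrum:
    """IR spectral density: cosine transform of the dipole-flux ACF
    (proportionality constant 1; arbitrary units)."""
    full_meta = {"kind": "ir"}
    if meta:
        full_meta.update(meta)
    return acf_to_spectrum(facf, window=window, zero_pad_factor=zero_pad_factor,
                           meta=full_meta)


# --------------------------------------------------------------------------
# per-layer and cumulative spectra
# --------------------------------------------------------------------------

def _interval_frames(traj: Trajectory, interval) -> Trajectory:
    return traj.time_window(interval[0], interval[1])


def _select_atoms(topo: Topology, molecule_ids, kind: str) -> np.ndarray:
    atoms = topo.atoms_of_molecules(molecule_ids)
    if kind == "vdos_H":
        atoms = atoms[topo.element[atoms] == "H"]
    elif kind == "vdos_O":
        atoms = atoms[topo.element[atoms] == "O"]
    elif kind not in ("ir", "vdos"):
        raise SpectrumError(f"unknown spectrum kind {kind!r}")
    if atoms.size == 0:
        raise SpectrumError(f"kind={kind}: selection contains no matching atoms")
    return atoms


def _interval_spectrum(traj: Trajectory, topo: Topology, molecule_ids,
                       kind: str, window: str, zero_pad_factor: int,
                       max_lag_fs: Optional[float], ir_mode: str) -> Spectrum:
    if kind == "ir":
        if ir_mode == "collective":
            flux = dipole_flux(traj, topo, molecule_ids)
            facf = flux_acf(flux, max_lag_fs=max_lag_fs)
            return ir_spectrum(facf, window=window,
                               zero_pad_factor=zero_pad_factor)
        if ir_mode == "molecular":
            acfs = []
            for mol in molecule_ids:
                flux = dipole_flux(traj, topo, [mol])
                acfs.append(flux_acf(flux, max_lag_fs=max_lag_fs))
            values = np.mean([a.values for a in acfs], axis=0)
            pooled = ACFSeries(lags=acfs[0].lags, values=values,
                               n_samples_per_lag=acfs[0].n_samples_per_lag)
            return ir_spectrum(pooled, window=window,
                               zero_pad_factor=zero_pad_factor)
        raise SpectrumError(f"unknown ir_mode {ir_mode!r}")
    atoms = _select_atoms(topo, molecule_ids, kind)
    acf = velocity_acf(traj, atoms, max_lag_fs=max_lag_fs, normalize=True)
    return acf_to_spectrum(acf, window=window, zero_pad_factor=zero_pad_factor,
                           meta={"kind": kind})


def layer_spectrum(traj: Trajectory, topo: Topology,
                   member_sets: Sequence[MemberSet], kind: str,
                   window: str = "hann", zero_pad_factor: int = 1,
                   max_lag_fs: Optional[float] = None,
                   ir_mode: str = "collective") -> Spectrum:
    """Spectrum of one layer: per-interval spectra over that interval's
    resident members, averaged (unweighted) across intervals.

    kind: 'vdos_H' | 'vdos_O' | 'ir'.  Intervals with no members are skipped
    with a warning; all-empty raises.
    """
    if not member_sets:
        raise SpectrumError("no member sets supplied")
    spectra, counts = [], []
    for ms in member_sets:
        if ms.n_members == 0:
            warnings.warn(
                f"layer {ms.layer}: interval {ms.interval} has no resident "
                "members; skipped"
            )
            continue
        sub = _interval_frames(traj, ms.interval)
        spectra.append(_interval_spectrum(sub, topo, ms.molecule_ids, kind,
                                          window, zero_pad_factor, max_lag_fs,
                                          ir_mode))
        counts.append(ms.n_members)
    if not spectra:
        raise SpectrumError("all intervals empty: no members to average")
    intensity = np.mean([s.intensity for s in spectra], axis=0)
    meta = dict(spectra[0].meta)
    meta.update({
        "kind": kind,
        "layer": int(member_sets[0].layer),
        "n_intervals": len(spectra),
        "member_counts": counts,
        "ir_mode": ir_mode if kind == "ir" else None,
    })
    return Spectrum(wavenumbers=spectra[0].wavenumbers, intensity=intensity,
                    meta=meta)


def cumulative_layer_spectrum(traj: Trajectory, topo: Topology,
                              member_sets_per_layer: Sequence[Sequence[MemberSet]],
                              kind: str, window: str = "hann",
                              zero_pad_factor: int = 1,
                              max_lag_fs: Optional[float] = None,
                              ir_mode: str = "collective") -> Spectrum:
    """Pooled spectrum of the union of layers 1..k.

    ``member_sets_per_layer[l][i]`` must share the i-th interval across
    layers; per interval the member unions are pooled into one selection
    (cross-molecular dipole correlations within the pool retained), then
    interval spectra are averaged.  Member sets must be disjoint per
    interval.
    """
    if not member_sets_per_layer:
        raise SpectrumError("no layers supplied")
    n_int = len(member_sets_per_layer[0])
    if any(len(layer) != n_int for layer in member_sets_per_layer):
        raise SpectrumError("layers disagree on the number of intervals")
    spectra, counts = [], []
    for i in range(n_int):
        sets = [layer[i] for layer in member_sets_per_layer]
        iv = sets[0].interval
        if any(abs(s.interval[0] - iv[0]) > 1e-6 or
               abs(s.interval[1] - iv[1]) > 1e-6 for s in sets):
            raise SpectrumError("cumulative pooling requires a common "
                                "interval scheme across layers")
        pooled: List[int] = []
        seen = set()
        for s in sets:
            ids = set(int(m) for m in s.molecule_ids)
            overlap = ids & seen
            if overlap:
                raise SpectrumError(
                    f"member sets overlap in interval {iv}: molecules "
                    f"{sorted(overlap)[:5]} claimed by two layers"
                )
            seen |= ids
            pooled.extend(sorted(ids))
        if not pooled:
            warnings.warn(f"interval {iv}: pooled member set empty; skipped")
            continue
        sub = _interval_frames(traj, iv)
        spectra.append(_interval_spectrum(sub, topo, sorted(pooled), kind,
                                          window, zero_pad_factor, max_lag_fs,
                                          ir_mode))
        counts.append(len(pooled))
    if not spectra:
        raise SpectrumError("all pooled intervals empty")
    intensity = np.mean([s.intensity for s in spectra], axis=0)
    meta = dict(spectra[0].meta)
    meta.update({
        "kind": kind,
        "layer": f"cumulative_1..{len(member_sets_per_layer)}",
        "n_intervals": len(spectra),
        "member_counts": counts,
        "ir_mode": ir_mode if kind == "ir" else None,
    })
    return Spectrum(wavenumbers=spectra[0].wavenumbers, intensity=intensity,
                    meta=meta)


# --------------------------------------------------------------------------
# band summaries
# --------------------------------------------------------------------------

def _fwhm(w: np.ndarray, y: np.ndarray, peak_idx: int) -> Optional[float]:
    """Full width at half maximum by linear interpolation at half max."""
    half = y[peak_idx] / 2.0
    left = None
    for i in range(peak_idx, 0, -1):
        if y[i - 1] <= half <= y[i]:
            frac = (y[i] - half) / max(y[i] - y[i - 1], 1e-300)
            left = w[i] - frac * (w[i] - w[i - 1])
            break
    right = None
    for i in range(peak_idx, y.size - 1):
        if y[i + 1] <= half <= y[i]:
            frac = (y[i] - half) / max(y[i] - y[i + 1], 1e-300)
            right = w[i] + frac * (w[i + 1] - w[i])
            break
    if left is None or right is None:
        return None
    return float(right - left)


def _shoulders(w: np.ndarray, y: np.ndarray, peak_idx: int,
               smooth_window: int) -> List[float]:
    """Shoulder positions: curvature minima (second derivative most negative)
    away from the main peak, plus secondary local maxima."""
    if y.size < smooth_window + 2:
        return []
    win = min(smooth_window, y.size - 1 - ((y.size - 1) % 2 == 0))
    if win % 2 == 0:
        win += 1
    if win < 5:
        return []
    ys = savgol_filter(y, win, polyorder=3)
    d2 = savgol_filter(y, win, polyorder=3, deriv=2)
    candidates = []
    for i in range(1, y.size - 1):
        is_curv_min = d2[i] < d2[i - 1] and d2[i] <= d2[i + 1] and d2[i] < 0
        is_local_max = ys[i] > ys[i - 1] and ys[i] >= ys[i + 1]
        if is_curv_min or is_local_max:
            candidates.append(i)
    peak_w = w[peak_idx]
    exclusion = max(3 * (w[1] - w[0]), 0.02 * (w[-1] - w[0]))
    out = []
    for i in candidates:
        if abs(w[i] - peak_w) <= exclusion:
            continue
        if ys[i] < 0.1 * ys[peak_idx]:
            continue
        out.append(float(w[i]))
    # merge candidates closer than the exclusion radius
    merged: List[float] = []
    for x in sorted(out):
        if merged and x - merged[-1] <= exclusion:
            continue
        merged.append(x)
    return merged


def band_summary(s: Spectrum, bands: Optional[Dict[str, tuple]] = None,
                 smooth_window: int = 11) -> List[BandMetrics]:
    """Per-band peak position, intensity, FWHM, and shoulder positions.

    Bands with identically zero intensity yield null metrics.
    """
    bands = DEFAULT_BANDS if bands is None else bands
    out = []
    for name, (lo, hi) in bands.items():
        sel = np.flatnonzero((s.wavenumbers >= lo) & (s.wavenumbers < hi))
        if sel.size < 3:
            raise SpectrumError(f"band {name!r} [{lo}, {hi}) outside spectrum grid")
        w = s.wavenumbers[sel]
        y = s.intensity[sel]
        if np.all(y == 0):
            out.append(BandMetrics(band=name, range_cm1=(lo, hi),
                                   peak_position=None, peak_intensity=None,
                                   fwhm=None, shoulder_positions=[]))
            continue
        peak_idx = int(np.argmax(y))
        out.append(BandMetrics(
            band=name,
            range_cm1=(lo, hi),
            peak_position=float(w[peak_idx]),
            peak_intensity=float(y[peak_idx]),
            fwhm=_fwhm(w, y, peak_idx),
            shoulder_positions=_shoulders(w, y, peak_idx, smooth_window),
        ))
    return out
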