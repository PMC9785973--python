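"""ACF estimators, cosine transforms, layer spectra, band summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hydrolayer as hl
from hydrolayer.units import C_CM_PER_FS

from conftest import direct_acf, solute_plus_waters_topology


def _vel_traj(vel, dt=1.0, box=60.0):
    """Trajectory from a (n_frames, n_atoms, 3) velocity array."""
    vel = np.asarray(vel, float)
    n_frames = vel.shape[0]
    return hl.Trajectory(times=np.arange(n_frames) * dt,
                         positions=np.zeros_like(vel),
                         velocities=vel, box=np.full(3, box))


# --------------------------------------------------------------------------
# velocity ACF
# --------------------------------------------------------------------------

def test_constant_velocity_gives_unit_acf():
    vel = np.ones((100, 5, 3)) * 0.3
    acf = hl.velocity_acf(_vel_traj(vel), np.arange(5), max_lag_fs=40.0)
    np.testing.assert_allclose(acf.values, 1.0, atol=1e-12)
    assert acf.values[0] == 1.0  # exact at zero lag


def test_cosine_velocity_acf_matches_closed_form():
    nu = 500.0  # cm^-1
    omega = 2 * np.pi * C_CM_PER_FS * nu
    period = 2 * np.pi / omega
    n = int(60 * period)  # >= 50 periods at dt=1 fs
    t = np.arange(n)
    vel = np.zeros((n, 1, 3))
    vel[:, 0, 0] = np.cos(omega * t)
    acf = hl.velocity_acf(_vel_traj(vel), [0], max_lag_fs=3 * period)
    expected = np.cos(omega * acf.lags)
    assert np.max(np.abs(acf.values - expected)) <= 0.02


def test_acf_estimator_contracts():
    vel = np.ones((10, 2, 3))
    traj = _vel_traj(vel)
    with pytest.raises(hl.SpectrumError, match="empty atom selection"):
        hl.velocity_acf(traj, [])
    with pytest.raises(hl.SpectrumError, match="max_lag"):
        hl.velocity_acf(traj, [0], max_lag_fs=10.0)


def test_fft_acf_equals_direct_lag_loop(rng):
    series = rng.normal(size=(1024, 4))
    acf = hl.autocorrelation(series, dt=1.0, max_lag_idx=512)
    oracle = direct_acf(series, 512)
    scale = np.max(np.abs(oracle))
    assert np.max(np.abs(acf.values - oracle)) <= 1e-10 * scale
    assert np.all(np.diff(acf.n_samples_per_lag) <= 0)


def test_acf_symmetric_under_time_reversal(rng):
    series = rng.normal(size=(512, 3))
    fwd = hl.autocorrelation(series, 1.0, 200).values
    rev = hl.autocorrelation(series[::-1], 1.0, 200).values
    np.testing.assert_allclose(fwd, rev, rtol=1e-10, atol=1e-14)


def test_union_acf_is_mean_of_equal_size_selections(rng):
    vel = rng.normal(0, 1e-3, size=(300, 8, 3))
    traj = _vel_traj(vel)
    a = hl.velocity_acf(traj, np.arange(4), max_lag_fs=100, normalize=False)
    b = hl.velocity_acf(traj, np.arange(4, 8), max_lag_fs=100, normalize=False)
    u = hl.velocity_acf(traj, np.arange(8), max_lag_fs=100, normalize=False)
    np.testing.assert_allclose(u.values, 0.5 * (a.values + b.values),
                               rtol=1e-12)


def test_normalized_vacf_bounded_for_ou_gas():
    traj, _ = hl.gen_ou_gas(400, tau=50.0, kT_over_m=1e-5, dt=5.0,
                            duration=10_000, seed=12)
    acf = hl.velocity_acf(traj, np.arange(400), max_lag_fs=2_000.0)
    assert acf.values[0] == 1.0
    assert np.max(np.abs(acf.values)) <= 1.0 + 0.05


# --------------------------------------------------------------------------
# cosine transform
# --------------------------------------------------------------------------

def test_cosine_acf_transforms_to_bend_frequency_peak():
    nu = 1650.0
    omega = 2 * np.pi * C_CM_PER_FS * nu
    lags = np.arange(4096) * 1.0
    acf = hl.ACFSeries(lags=lags, values=np.cos(omega * lags),
                       n_samples_per_lag=np.full(lags.size, 1000))
    s = hl.acf_to_spectrum(acf, window="hann")
    assert abs(s.peak_wavenumber() - nu) <= s.grid_step


def test_exponential_acf_transforms_to_lorentzian():
    tau = 50.0
    dt = 2.5
    lags = np.arange(int(20 * tau / dt) + 1) * dt  # t_max = 20 tau
    acf = hl.ACFSeries(lags=lags, values=np.exp(-lags / tau),
                       n_samples_per_lag=np.full(lags.size, 1000))
    s = hl.acf_to_spectrum(acf, window="none")
    omega = 2 * np.pi * C_CM_PER_FS * s.wavenumbers
    lorentzian = tau / (1.0 + (omega * tau) ** 2)
    decade = slice(1, s.wavenumbers.size // 10)
    rel = np.abs(s.intensity[decade] - lorentzian[decade]) / lorentzian[decade]
    assert rel.max() <= 0.02


def test_zero_acf_gives_zero_spectrum():
    acf = hl.ACFSeries(lags=np.arange(100.0), values=np.zeros(100),
                       n_samples_per_lag=np.full(100, 10))
    s = hl.acf_to_spectrum(acf)
    assert np.all(s.intensity == 0)


def test_fft_and_direct_transform_agree(rng):
    values = rng.normal(size=600)
    acf = hl.ACFSeries(lags=np.arange(600) * 2.0, values=values,
                       n_samples_per_lag=np.full(600, 5))
    s1 = hl.acf_to_spectrum(acf, window="hann", zero_pad_factor=2, method="fft")
    s2 = hl.acf_to_spectrum(acf, window="hann", zero_pad_factor=2,
                            method="direct")
    scale = np.max(np.abs(s1.intensity))
    assert np.max(np.abs(s1.intensity - s2.intensity)) <= 1e-10 * scale
    np.testing.assert_array_equal(s1.wavenumbers, s2.wavenumbers)


def test_nonuniform_lags_rejected():
    acf = hl.ACFSeries(lags=np.array([0.0, 1.0, 3.0]), values=np.zeros(3),
                       n_samples_per_lag=np.array([3, 2, 1]))
    with pytest.raises(hl.SpectrumError, match="non-uniform lag"):
        hl.acf_to_spectrum(acf)


def test_parseval_sum_rule_on_cosine():
    """Rectangular window: dnu * sum S = (1/2) Z(0) / (2c)."""
    traj, _ = hl.gen_harmonic_waters(50, [800.0], dt=1.0, duration=4000,
                                     seed=3)
    acf = hl.velocity_acf(traj, np.arange(150))
    s = hl.acf_to_spectrum(acf, window="none")
    lhs = s.grid_step * s.intensity.sum()
    rhs = 0.5 * acf.values[0] / (2.0 * C_CM_PER_FS)
    assert abs(lhs / rhs - 1.0) <= 0.02


@settings(max_examples=12, deadline=None, derandomize=True)
@given(nu=st.floats(100.0, 3750.0), seed=st.integers(0, 2 ** 20))
def test_frequency_recovery_property(nu, seed):
    """Any planted mode in [100, 3750] cm^-1 is recovered within one grid
    step at dt = 1 fs."""
    traj, _ = hl.gen_harmonic_waters(10, [nu], dt=1.0, duration=3000.0,
                                     seed=seed)
    acf = hl.velocity_acf(traj, np.arange(30))
    s = hl.acf_to_spectrum(acf, window="hann")
    assert abs(s.peak_wavenumber() - nu) <= s.grid_step


# --------------------------------------------------------------------------
# dipole flux and IR
# --------------------------------------------------------------------------

def test_zero_charges_give_zero_flux(rng):
    topo = solute_plus_waters_topology(0, 2, charges=(0.0, 0.0))
    vel = rng.normal(size=(50, 6, 3))
    flux = hl.dipole_flux(_vel_traj(vel), topo, [1, 2])
    assert np.all(flux.flux == 0)


def test_rigid_translation_of_neutral_water_has_zero_flux():
    topo = solute_plus_waters_topology(0, 3)
    vel = np.broadcast_to([0.01, -0.02, 0.005], (40, 9, 3)).copy()
    flux = hl.dipole_flux(_vel_traj(vel), topo, [1, 2, 3])
    np.testing.assert_allclose(flux.flux, 0.0, atol=1e-15)


def test_oscillating_hydrogens_flux_matches_hand_computation(rng):
    topo = solute_plus_waters_topology(0, 1)  # charges (-0.82, +0.41)
    n = 64
    u1 = rng.normal(size=(n, 3))
    u2 = rng.normal(size=(n, 3))
    vel = np.zeros((n, 3, 3))
    vel[:, 1] = u1
    vel[:, 2] = u2
    flux = hl.dipole_flux(_vel_traj(vel), topo, [1])
    np.testing.assert_allclose(flux.flux, 0.41 * (u1 + u2), rtol=1e-12)


def test_flux_acf_closed_forms():
    t = np.arange(2000) * 1.0
    const = hl.FluxSeries(times=t, flux=np.broadcast_to([0.3, -0.4, 0.0],
                                                        (2000, 3)).copy())
    acf = hl.flux_acf(const, max_lag_fs=500.0)
    np.testing.assert_allclose(acf.values, 0.25, rtol=1e-12)  # |c|^2

    omega = 2 * np.pi * C_CM_PER_FS * 600.0
    per = 2 * np.pi / omega
    n = int(80 * per)
    t = np.arange(n) * 1.0
    flux = np.zeros((n, 3))
    flux[:, 0] = 2.0 * np.cos(omega * t)
    acf = hl.flux_acf(hl.FluxSeries(times=t, flux=flux),
                      max_lag_fs=3 * per)
    expected = 2.0 * np.cos(omega * acf.lags)  # A^2/2 = 2
    assert np.max(np.abs(acf.values - expected)) <= 0.02 * 2.0

    zero = hl.FluxSeries(times=np.arange(100.0), flux=np.zeros((100, 3)))
    assert np.all(hl.flux_acf(zero, max_lag_fs=50.0).values == 0)


def test_ir_peak_at_planted_stretch_mode():
    pattern = np.zeros((3, 3))
    pattern[1, 0] = 1.0  # one hydrogen oscillating -> net charge flux
    mode = hl.ModeSpec(wavenumber=3300.0, amplitude=0.05, pattern=pattern)
    traj, topo = hl.gen_harmonic_waters(50, [mode], dt=1.0, duration=8000.0,
                                        seed=6)
    flux = hl.dipole_flux(traj, topo, topo.water_molecule_ids)
    s = hl.ir_spectrum(hl.flux_acf(flux), window="hann")
    assert abs(s.peak_wavenumber(1000.0) - 3300.0) <= s.grid_step


def test_ir_intensity_quadratic_in_charges():
    traj, topo1 = hl.gen_harmonic_waters(20, [1650.0], dt=1.0,
                                         duration=4000.0, seed=7,
                                         charges=(-0.82, 0.41))
    topo2 = hl.synthetic.water_topology(20, charges=(-1.64, 0.82))
    mols = topo1.water_molecule_ids
    s1 = hl.ir_spectrum(hl.flux_acf(hl.dipole_flux(traj, topo1, mols)))
    s2 = hl.ir_spectrum(hl.flux_acf(hl.dipole_flux(traj, topo2, mols)))
    np.testing.assert_allclose(s2.intensity, 4.0 * s1.intensity, rtol=1e-12)


# --------------------------------------------------------------------------
# layer and cumulative spectra
# --------------------------------------------------------------------------

def _member_set(interval, layer, mols):
    return hl.MemberSet(interval=interval, layer=layer,
                        molecule_ids=np.asarray(mols),
                        occupancy={int(m): 1.0 for m in mols}, threshold=0.9)


def _hydration_case(seed=8):
    shells = [(2.5, 4.0, 10, [1650.0]), (5.0, 7.0, 14, [1600.0])]
    traj, topo = hl.gen_harmonic_hydration_box(shells, dt=2.0, duration=4000,
                                               box=30.0, seed=seed)
    mols = topo.water_molecule_ids
    return traj, topo, mols[:10], mols[10:]


def test_identical_intervals_average_to_single_interval_spectrum():
    traj, topo, inner, _ = _hydration_case()
    ms = [_member_set((0.0, 2000.0), 1, inner)] * 3
    s_avg = hl.layer_spectrum(traj, topo, ms, "vdos_H", window="hann")
    s_one = hl.layer_spectrum(traj, topo, ms[:1], "vdos_H", window="hann")
    np.testing.assert_allclose(s_avg.intensity, s_one.intensity, rtol=1e-12)


def test_layer_members_dominate_layer_spectrum():
    traj, topo, inner, outer = _hydration_case()
    iv = (0.0, 4000.0)
    s1 = hl.layer_spectrum(traj, topo, [_member_set(iv, 1, inner)], "vdos_H",
                           window="hann")
    s2 = hl.layer_spectrum(traj, topo, [_member_set(iv, 2, outer)], "vdos_H",
                           window="hann")
    assert abs(s1.peak_wavenumber(1000.0) - 1650.0) <= 2 * s1.grid_step
    assert abs(s2.peak_wavenumber(1000.0) - 1600.0) <= 2 * s2.grid_step


def test_selection_without_matching_species_rejected():
    traj, topo = hl.gen_ou_gas(5, tau=50.0, kT_over_m=1e-5, dt=5.0,
                               duration=500.0, seed=1)
    ms = _member_set((0.0, 400.0), 1, [0, 1])
    with pytest.raises(hl.SpectrumError, match="no matching atoms"):
        hl.layer_spectrum(traj, topo, [ms], "vdos_O")


def test_cumulative_k1_equals_layer_spectrum():
    traj, topo, inner, _ = _hydration_case()
    ms = [_member_set((0.0, 4000.0), 1, inner)]
    s_layer = hl.layer_spectrum(traj, topo, ms, "vdos_H", window="hann")
    s_cum = hl.cumulative_layer_spectrum(traj, topo, [ms], "vdos_H",
                                         window="hann")
    np.testing.assert_allclose(s_cum.intensity, s_layer.intensity, rtol=1e-12)


@pytest.mark.parametrize("kind", ["vdos_H", "vdos_O", "ir"])
def test_cumulative_over_all_layers_equals_whole_selection(kind):
    traj, topo, inner, outer = _hydration_case()
    iv = (0.0, 4000.0)
    per_layer = [[_member_set(iv, 1, inner)], [_member_set(iv, 2, outer)]]
    s_cum = hl.cumulative_layer_spectrum(traj, topo, per_layer, kind,
                                         window="hann")
    s_all = hl.layer_spectrum(
        traj, topo, [_member_set(iv, 1, topo.water_molecule_ids)], kind,
        window="hann")
    scale = np.max(np.abs(s_all.intensity))
    assert np.max(np.abs(s_cum.intensity - s_all.intensity)) <= 1e-10 * scale


def test_overlapping_member_sets_rejected():
    traj, topo, inner, outer = _hydration_case()
    iv = (0.0, 2000.0)
    per_layer = [[_member_set(iv, 1, inner)],
                 [_member_set(iv, 2, list(outer) + [inner[0]])]]
    with pytest.raises(hl.SpectrumError, match="overlap"):
        hl.cumulative_layer_spectrum(traj, topo, per_layer, "vdos_H")


def test_pooled_mix_preserves_peak_intensity_ratio():
    """Two equal-size populations at 1650 / 3300 cm^-1: pooling keeps both
    peaks with amplitude-weighted intensities matching the 50/50 mix."""
    n = 64
    box = 30.0
    pattern = np.zeros((3, 3))
    pattern[1, 0] = pattern[2, 1] = 1.0  # hydrogens move, oxygen at rest
    m1 = hl.ModeSpec(wavenumber=1650.0, amplitude=0.05 * 2.0,  # equal A*w
                     pattern=pattern)
    m2 = hl.ModeSpec(wavenumber=3300.0, amplitude=0.05, pattern=pattern)
    t1, _ = hl.gen_harmonic_waters(n, [m1], dt=1.0, duration=8000.0, box=box,
                                   seed=10)
    t2, _ = hl.gen_harmonic_waters(n, [m2], dt=1.0, duration=8000.0, box=box,
                                   seed=11)
    vel = np.concatenate([t1.velocities, t2.velocities], axis=1)
    traj = _vel_traj(vel, dt=1.0, box=box)
    topo = hl.synthetic.water_topology(2 * n)
    iv = (0.0, 6000.0)
    mols = topo.water_molecule_ids
    per_layer = [[_member_set(iv, 1, mols[:n])], [_member_set(iv, 2, mols[n:])]]
    s = hl.cumulative_layer_spectrum(traj, topo, per_layer, "vdos_H",
                                     window="hann")
    # equal A*omega -> equal VACF weight; integrate each band so the check
    # is insensitive to how each mode falls relative to the frequency grid
    b1 = (np.abs(s.wavenumbers - 1650.0) <= 50.0)
    b2 = (np.abs(s.wavenumbers - 3300.0) <= 50.0)
    assert abs(s.intensity[b1].sum() / s.intensity[b2].sum() - 1.0) <= 0.02


def test_empty_interval_members_are_skipped_with_warning():
    traj, topo, inner, _ = _hydration_case()
    good = _member_set((0.0, 2000.0), 1, inner)
    empty = _member_set((2000.0, 4000.0), 1, [])
    with pytest.warns(UserWarning, match="no resident members"):
        s = hl.layer_spectrum(traj, topo, [good, empty], "vdos_H")
    assert s.meta["n_intervals"] == 1
    with pytest.raises(hl.SpectrumError, match="all intervals empty"):
        hl.layer_spectrum(traj, topo, [empty], "vdos_H")


# --------------------------------------------------------------------------
# band summaries
# --------------------------------------------------------------------------

def test_gaussian_band_metrics():
    w = np.arange(0.0, 4000.0, 2.0)
    sigma = 40.0
    s = hl.Spectrum(w, np.exp(-((w - 1650.0) ** 2) / (2 * sigma ** 2)), {})
    bend = [m for m in hl.band_summary(s) if m.band == "bend"][0]
    assert abs(bend.peak_position - 1650.0) <= 2.0
    assert bend.fwhm == pytest.approx(2 * np.sqrt(2 * np.log(2)) * sigma,
                                      abs=5.0)


def test_shoulder_detected_on_stretch_flank():
    w = np.arange(0.0, 4000.0, 2.0)
    y = (np.exp(-((w - 3450.0) ** 2) / (2 * 60.0 ** 2))
         + 0.35 * np.exp(-((w - 3300.0) ** 2) / (2 * 40.0 ** 2)))
    s = hl.Spectrum(w, y, {})
    stretch = [m for m in hl.band_summary(s) if m.band == "stretch"][0]
    assert stretch.peak_position == pytest.approx(3450.0, abs=4.0)
    assert any(abs(x - 3300.0) <= 20.0 for x in stretch.shoulder_positions)


def test_flat_spectrum_gives_null_metrics():
    w = np.arange(0.0, 4000.0, 2.0)
    s = hl.Spectrum(w, np.zeros_like(w), {})
    for m in hl.band_summary(s):
        assert m.is_null()
        assert m.shoulder_positions == []
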