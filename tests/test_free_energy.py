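"""FEP accumulation, gap-profile reconstruction, calibration, reweighting."""

import numpy as np
import pytest

from evbkit import (
    BinSpec,
    EVBParameters,
    GapProfile,
    HarmonicDiabatModel,
    SamplingSpec,
    TrajectoryWindow,
    analytic_adiabatic_extrema,
    analytic_window_free_energy,
    calibrate_parameters,
    extract_stationary_points,
    gap_profile,
    ground_state_profile,
    reweight_profile,
    simulate_window,
    zwanzig_accumulate,
)
from evbkit.core import R_GAS
from evbkit.exceptions import (
    InvalidInputError,
    MonotoneProfileError,
    ProfileCoverageError,
)

FINE_BINS = BinSpec(n_bins=301)  # resolves cusp-shaped maxima (see methods note)


def _constant_gap_windows(offset, n=400, temperature=300.0):
    """Synthetic windows where u2_raw - u1 is a constant offset."""
    rng = np.random.default_rng(0)
    windows = []
    for lam in np.linspace(0, 1, 6):
        u1 = rng.normal(10.0, 2.0, n)
        windows.append(
            TrajectoryWindow(
                lambda_m=float(lam), temperature=temperature,
                x=np.zeros(n), u1=u1, u2_raw=u1 + offset,
            )
        )
    return windows


def test_zwanzig_identical_states_gives_zero():
    mp = zwanzig_accumulate(_constant_gap_windows(0.0), EVBParameters(0.0, 0.0))
    np.testing.assert_allclose(mp.dg, 0.0, atol=1e-12)


def test_zwanzig_constant_perturbation_is_linear():
    c = 7.5
    mp = zwanzig_accumulate(_constant_gap_windows(c), EVBParameters(0.0, 0.0))
    np.testing.assert_allclose(mp.dg, c * mp.lambdas, atol=1e-10)


def test_zwanzig_matches_closed_form(sym_model, sym_windows_300):
    mp = zwanzig_accumulate(sym_windows_300, sym_model.parameters)
    for lam, dg in zip(mp.lambdas, mp.dg):
        assert dg == pytest.approx(
            analytic_window_free_energy(sym_model, lam, 300.0), abs=0.15
        )


def test_zwanzig_rejects_empty_window():
    w = TrajectoryWindow(0.0, 300.0, np.array([]), np.array([]), np.array([]))
    w2 = TrajectoryWindow(1.0, 300.0, np.zeros(5), np.zeros(5), np.zeros(5))
    with pytest.raises(InvalidInputError):
        zwanzig_accumulate([w, w2], EVBParameters(0.0))


def test_single_window_profile_is_pure_histogram(sym_model):
    """With h12 = 0 and one window at lambda = 0, Eg = U_map on the reactant
    branch, so the profile reduces to -RT ln p(bin) up to a constant."""
    spec = SamplingSpec(n_steps=30_000, n_burnin=3_000, seed=6)
    w = simulate_window(sym_model, 0.0, 300.0, spec)
    assert np.all(w.u1 < w.u2_raw)  # all frames on the reactant side
    prof = gap_profile([w], EVBParameters(0.0, 0.0), bins=BinSpec(25, min_frames=1))
    rt = R_GAS * 300.0
    ok = np.isfinite(prof.dg_ground)
    expected = -rt * np.log(prof.counts[ok] / w.n_frames)
    residual = prof.dg_ground[ok] - expected
    assert np.ptp(residual) < 1e-9  # equal up to one additive constant


def test_window_weights_normalised(sym_model, sym_windows_300):
    prof = ground_state_profile(sym_windows_300, sym_model.parameters)
    occupied = np.isfinite(prof.dg_ground)
    np.testing.assert_allclose(prof.window_weights.sum(axis=0)[occupied], 1.0)
    assert np.all(np.isnan(prof.dg_ground[~occupied]))


def test_symmetric_uncoupled_barrier_is_the_crossing(sym_model, sym_windows_300):
    """lambda_reorg = 148: the reconstructed barrier is the 37 kcal/mol crossing."""
    prof = ground_state_profile(sym_windows_300, sym_model.parameters, bins=FINE_BINS)
    s = extract_stationary_points(prof)
    assert s.dg_act == pytest.approx(37.0, abs=0.5)
    assert s.dg_rxn == pytest.approx(0.0, abs=0.3)
    assert s.reactant_position < s.ts_position < s.product_position


def test_uncoupled_ground_state_is_lower_diabat_envelope(sym_model, sym_windows_300):
    prof = gap_profile(sym_windows_300, sym_model.parameters, bins=FINE_BINS)
    ok = np.isfinite(prof.dg_ground) & np.isfinite(prof.dg_state1) & np.isfinite(
        prof.dg_state2
    )
    envelope = np.minimum(prof.dg_state1[ok], prof.dg_state2[ok])
    assert np.all(prof.dg_ground[ok] <= envelope + 1e-9)
    assert np.max(np.abs(prof.dg_ground[ok] - envelope)) < 0.25


def test_diabatic_profiles_mirror_symmetry(sym_model, sym_windows_300):
    """For the symmetric model, dG1(dU) = dG2(-dU) within estimator noise."""
    prof = gap_profile(sym_windows_300, sym_model.parameters, bins=FINE_BINS)
    ok = np.isfinite(prof.dg_state1) & np.isfinite(prof.dg_state2)
    c = prof.bin_centers[ok]
    g1, g2 = prof.dg_state1[ok], prof.dg_state2[ok]
    mirrored = np.interp(-c, c, g2)
    core = np.abs(c) < 150.0
    assert np.max(np.abs(g1[core] - mirrored[core])) < 0.4


def test_diabatic_intersection_height(sym_model, sym_windows_300):
    prof = gap_profile(sym_windows_300, sym_model.parameters, bins=FINE_BINS)
    ok = np.isfinite(prof.dg_state1) & np.isfinite(prof.dg_state2)
    c, g1, g2 = prof.bin_centers[ok], prof.dg_state1[ok], prof.dg_state2[ok]
    diff = g1 - g2
    i = np.flatnonzero(np.sign(diff[:-1]) != np.sign(diff[1:]))[0]
    x0 = np.interp(0.0, [diff[i], diff[i + 1]], [c[i], c[i + 1]])
    height = np.interp(x0, c, g1)
    assert height == pytest.approx(37.0, abs=0.5)


def _parabola_profile(centers, values):
    nb = len(centers)
    edges = np.concatenate([
        centers - (centers[1] - centers[0]) / 2,
        [centers[-1] + (centers[1] - centers[0]) / 2],
    ])
    return GapProfile(
        bin_centers=centers, bin_edges=edges, dg_ground=values,
        dg_state1=values.copy(), dg_state2=values.copy(),
        counts=np.full(nb, 100.0), window_weights=np.ones((1, nb)),
        window_lambdas=np.array([0.0]), mean_c2_sq=np.full(nb, np.nan),
        temperature=300.0, parameters=EVBParameters(0.0),
    )


def test_stationary_points_exact_on_discrete_parabolas():
    """A profile built from two exact parabolas is recovered at the vertices."""
    c = np.linspace(-10, 10, 21)
    left = 0.5 * (c + 6.0) ** 2          # reactant well, vertex (-6, 0)
    right = 0.7 * (c - 5.0) ** 2 + 2.0   # product well, vertex (5, 2)
    barrier = 12.0 - 0.4 * (c - 0.5) ** 2
    values = np.where(c < -2, left, np.where(c > 3, right, barrier))
    s = extract_stationary_points(_parabola_profile(c, values))
    assert s.reactant_position == pytest.approx(-6.0, abs=1e-9)
    assert s.ts_position == pytest.approx(0.5, abs=1e-9)
    assert s.product_position == pytest.approx(5.0, abs=1e-9)
    assert s.dg_act == pytest.approx(12.0, abs=1e-9)
    assert s.dg_rxn == pytest.approx(2.0, abs=1e-9)


def test_monotone_profile_raises():
    c = np.linspace(0, 10, 11)
    with pytest.raises(MonotoneProfileError):
        extract_stationary_points(_parabola_profile(c, c.copy()))


def test_ts_weights_symmetric_mixing(sym_model, sym_windows_300):
    """At the symmetric crossing with h12 = 20 the TS mixture is 50/50."""
    _, s = reweight_profile(
        sym_windows_300, sym_model.parameters, EVBParameters(20.0, 0.0),
        bins=FINE_BINS,
    )
    assert s.ts_weights.c1_sq == pytest.approx(0.5, abs=0.02)
    assert s.ts_weights.c2_sq == pytest.approx(0.5, abs=0.02)


def test_reweight_identity_is_bitwise(sym_model, sym_windows_300):
    par = sym_model.parameters
    base = gap_profile(sym_windows_300, par)
    again, _ = reweight_profile(sym_windows_300, par, par)
    np.testing.assert_array_equal(base.dg_ground, again.dg_ground)
    np.testing.assert_array_equal(base.dg_state1, again.dg_state1)
    np.testing.assert_array_equal(base.dg_state2, again.dg_state2)


def test_reweight_delta_alpha_shifts_product_diabat_exactly(sym_windows_300):
    delta = 12.5
    old = EVBParameters(0.0, 0.0)
    new = EVBParameters(0.0, delta)
    base = gap_profile(sym_windows_300, old)
    shifted, _ = reweight_profile(sym_windows_300, old, new)
    ok = np.isfinite(base.dg_state2) & np.isfinite(shifted.dg_state2)
    np.testing.assert_allclose(
        shifted.dg_state2[ok] - base.dg_state2[ok], delta, atol=1e-9
    )
    np.testing.assert_allclose(
        shifted.dg_state1[ok] - base.dg_state1[ok], 0.0, atol=1e-9
    )
    # the gap coordinate itself shifts by -delta, frame assignment unchanged
    np.testing.assert_allclose(
        shifted.bin_centers - base.bin_centers, -delta, atol=1e-9
    )


def test_importance_mode_matches_reevaluation(sym_model, sym_windows_300):
    """(h12, delta_alpha) changes leave within-window weights uniform, so the
    two reweighting modes coincide for this parameter family."""
    old = sym_model.parameters
    new = EVBParameters(20.0, 12.5)
    p_re, s_re = reweight_profile(sym_windows_300, old, new, mode="reevaluate")
    p_im, s_im = reweight_profile(sym_windows_300, old, new, mode="importance")
    ok = np.isfinite(p_re.dg_ground)
    np.testing.assert_allclose(p_im.dg_ground[ok], p_re.dg_ground[ok], atol=1e-8)
    assert p_im.mode == "importance" and p_re.mode == "reevaluate"
    assert s_im.dg_act == pytest.approx(s_re.dg_act, abs=1e-6)


def test_coupled_barrier_matches_adiabatic_oracle(sym_model, sym_windows_300):
    """h12 = 20 on the symmetric crossing: barrier from the analytic surface."""
    par = EVBParameters(20.0, 0.0)
    _, s = reweight_profile(sym_windows_300, sym_model.parameters, par)
    oracle_act, _ = analytic_adiabatic_extrema(
        HarmonicDiabatModel.symmetric(h12=20.0)
    )
    assert s.dg_act == pytest.approx(oracle_act, abs=0.3)


def test_profiles_invariant_under_uniform_energy_shift(sym_model, sym_windows_300):
    """Adding a constant to both U1 and U2_raw changes nothing downstream."""
    par = sym_model.parameters
    shift = 250.0
    shifted_windows = [
        TrajectoryWindow(w.lambda_m, w.temperature, w.x, w.u1 + shift,
                         w.u2_raw + shift, w.replicate)
        for w in sym_windows_300
    ]
    base = gap_profile(sym_windows_300, par)
    moved = gap_profile(shifted_windows, par)
    np.testing.assert_allclose(moved.bin_centers, base.bin_centers, atol=1e-9)
    ok = np.isfinite(base.dg_ground)
    np.testing.assert_allclose(moved.dg_ground[ok], base.dg_ground[ok], atol=1e-7)
    np.testing.assert_allclose(moved.dg_state2[ok], base.dg_state2[ok], atol=1e-7)


def test_unbridged_schedule_raises(sym_model):
    """Endpoint-only sampling leaves the barrier region unsampled."""
    spec = SamplingSpec(lambda_schedule=(0.0, 1.0), n_steps=8000, n_burnin=1000,
                        seed=4)
    windows = [
        simulate_window(sym_model, lam, 300.0, spec) for lam in (0.0, 1.0)
    ]
    with pytest.raises(ProfileCoverageError):
        gap_profile(windows, sym_model.parameters)


class TestCalibration:
    def test_fixed_point(self, sym_model, sym_windows_300):
        par = EVBParameters(20.0, 0.0)
        _, s = reweight_profile(sym_windows_300, sym_model.parameters, par)
        fitted, report = calibrate_parameters(
            sym_windows_300, None, (s.dg_act, s.dg_rxn), par0=par
        )
        assert report["converged"]
        assert fitted.h12 == pytest.approx(par.h12, abs=0.5)
        assert fitted.delta_alpha == pytest.approx(par.delta_alpha, abs=0.5)

    def test_recovers_coupling_from_analytic_targets(self, sym_windows_300):
        """Targets computed on the analytic h12 = 20 surface recover h12 ~ 20."""
        target = analytic_adiabatic_extrema(HarmonicDiabatModel.symmetric(h12=20.0))
        fitted, report = calibrate_parameters(sym_windows_300, None, target)
        assert report["converged"]
        assert fitted.h12 == pytest.approx(20.0, abs=0.5)
        assert fitted.delta_alpha == pytest.approx(0.0, abs=0.5)

    def test_round_trip_reproduces_targets(self, sym_windows_300):
        targets = (19.0, 5.0)
        fitted, _ = calibrate_parameters(sym_windows_300, None, targets)
        prof = gap_profile(sym_windows_300, fitted)
        s = extract_stationary_points(prof)
        assert s.dg_act == pytest.approx(targets[0], abs=0.05)
        assert s.dg_rxn == pytest.approx(targets[1], abs=0.05)
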