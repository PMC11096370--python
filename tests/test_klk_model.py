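"""The four-species spatial ODE system and its derived quantities."""

import numpy as np
import pytest

import cornekin as ck
from cornekin.klk_model import rhs

C0 = 1.0e-10


def _rk4_reference(params, profile, curves, n_steps=100_000):
    """Independent fixed-step classical Runge-Kutta integration.

    Rate functions are pre-evaluated on the half-step grid so the stepping
    loop shares no code with the adaptive solver path.
    """
    xs = np.linspace(0.0, 1.0, 2 * n_steps + 1)
    ph = profile(xs)
    a_klk = curves.a_klk(ph)
    a_meso = curves.a_meso(ph)
    ka = curves.binding.ka(ph)
    kd = curves.binding.kd(ph)
    inv_v = 1.0 / params.v

    def f(i, y):
        c_p, c_k, c_l, c_c = y
        act = c_p * (params.k_auto * a_klk[i] * c_k + params.k_meso * a_meso[i] * params.C_meso)
        b = ka[i] * c_k * c_l - kd[i] * c_c
        dg_l = params.k_deg * a_meso[i] * params.C_meso * c_l
        dg_c = params.k_deg * a_meso[i] * params.C_meso * c_c
        return np.array([-act, act - b + dg_c, -b - dg_l, b - dg_c]) * inv_v

    y = np.array([params.C_pKLK_boundary, 0.0, params.C_LEKTI_boundary, 0.0])
    h = 1.0 / n_steps
    for s in range(n_steps):
        i = 2 * s
        k1 = f(i, y)
        k2 = f(i + 1, y + 0.5 * h * k1)
        k3 = f(i + 1, y + 0.5 * h * k2)
        k4 = f(i + 2, y + h * k3)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return y


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------


def test_rhs_is_zero_without_reactions(stepwise_profile, inert_binding):
    params = ck.ModelParams(k_auto=0.0, k_meso=0.0, k_deg=0.0)
    curves = ck.RateFunctions(
        a_klk=ck.ActivityCurve(), a_meso=ck.ActivityCurve(), binding=inert_binding
    )
    state = np.array([C0, 0.3 * C0, C0, 0.1 * C0])
    # the inert binding table is ~1e-15, not exactly zero; derivatives are
    # negligible relative to the 1e-10 M concentration scale
    deriv = rhs(0.5, state, params, stepwise_profile, curves)
    np.testing.assert_allclose(deriv, 0.0, atol=1e-18)


def test_rhs_conserves_klk_moiety_termwise(stepwise_profile, curves):
    """d(pro-KLK + KLK + complex)/dx cancels exactly, term by term."""
    params = ck.ModelParams(k_auto=3e4, k_meso=2e5, k_deg=7e4)
    rng = np.random.default_rng(0)
    for x in (0.0, 0.1, 0.5, 0.99):
        state = rng.uniform(0.0, C0, size=4)
        deriv = rhs(x, state, params, stepwise_profile, curves)
        assert deriv[0] + deriv[1] + deriv[3] == pytest.approx(0.0, abs=1e-22)


def test_rhs_total_lekti_decay_matches_linear_law(stepwise_profile, curves):
    """d(C_LEKTI + C_KL)/dx = -k_deg * a_meso(pH) * C_meso * C_Ltotal / v."""
    params = ck.ModelParams(k_auto=3e4, k_meso=2e5, k_deg=7e4)
    state = np.array([0.5 * C0, 0.2 * C0, 0.6 * C0, 0.3 * C0])
    for x in (0.1, 0.5, 0.9):
        deriv = rhs(x, state, params, stepwise_profile, curves)
        expected = (
            -params.k_deg
            * curves.a_meso(stepwise_profile(x))
            * params.C_meso
            * (state[2] + state[3])
            / params.v
        )
        assert deriv[2] + deriv[3] == pytest.approx(expected, rel=1e-12)


def test_rhs_rejects_non_finite_state(stepwise_profile, curves):
    params = ck.ModelParams()
    with pytest.raises(ValueError):
        rhs(0.5, np.array([C0, np.nan, C0, 0.0]), params, stepwise_profile, curves)


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------


def test_no_activation_pathway_leaves_proklk_untouched(stepwise_profile, curves):
    params = ck.ModelParams(k_auto=0.0, k_meso=0.0, k_deg=0.0)
    traj = ck.simulate(params, stepwise_profile, curves)
    np.testing.assert_allclose(traj.C_pKLK, C0, rtol=1e-10)
    np.testing.assert_allclose(traj.C_KLK, 0.0, atol=1e-20)
    np.testing.assert_allclose(traj.E_KLK, 0.0, atol=1e-20)


def test_closed_form_exponential_decay_limit(inert_binding):
    """Mesotrypsin-only activation at uniform pH is a linear decay with
    known solution C_pKLK(1) = C0 * exp(-k_meso * a * C_meso / v)."""
    a_meso = ck.ActivityCurve(midpoint=6.5, slope=3.0)
    curves = ck.RateFunctions(
        a_klk=ck.ActivityCurve(form="flat", value=1.0), a_meso=a_meso, binding=inert_binding
    )
    profile = ck.make_named_profile("uniform_5.4")
    params = ck.ModelParams(k_auto=0.0, k_meso=3e5, k_deg=0.0)
    expected = C0 * np.exp(-params.k_meso * a_meso(5.4) * params.C_meso / params.v)
    traj = ck.simulate(params, profile, curves, method="DOP853")
    assert abs(traj.C_pKLK[-1] - expected) / expected < 1e-8
    # the default stiff-capable solver agrees to its own (looser) accuracy
    traj_default = ck.simulate(params, profile, curves)
    assert abs(traj_default.C_pKLK[-1] - expected) / expected < 1e-5


def test_klk_moiety_conserved_on_solved_trajectories(stepwise_profile, curves):
    for k_auto, k_meso, k_deg in [(1e4, 3e5, 0.0), (1e5, 1e3, 5e4), (1e6, 1e6, 7e5)]:
        params = ck.ModelParams(k_auto=k_auto, k_meso=k_meso, k_deg=k_deg)
        traj = ck.simulate(params, stepwise_profile, curves)
        total = traj.C_pKLK + traj.C_KLK + traj.C_KL
        assert np.max(np.abs(total - C0)) / C0 < 1e-6


def test_lekti_moiety_conserved_without_degradation(solved_trajectory):
    lt = solved_trajectory.C_Ltotal
    assert np.max(np.abs(lt - lt[0])) / lt[0] < 1e-6


def test_lekti_total_nonincreasing_with_degradation(stepwise_profile, curves):
    params = ck.ModelParams(k_auto=1e4, k_meso=3e5, k_deg=2e5)
    traj = ck.simulate(params, stepwise_profile, curves)
    assert np.all(np.diff(traj.C_Ltotal) <= 1e-18)


def test_adaptive_solution_matches_fixed_step_oracle(stepwise_profile, curves):
    """LSODA trajectory vs classical RK4 at 1e5 steps: < 1e-4 relative on
    all four species at the surface."""
    params = ck.ModelParams(k_auto=1e4, k_meso=3e5, k_deg=5e4)
    traj = ck.simulate(params, stepwise_profile, curves, np.array([0.0, 1.0]))
    final = np.array([traj.C_pKLK[-1], traj.C_KLK[-1], traj.C_LEKTI[-1], traj.C_KL[-1]])
    ref = _rk4_reference(params, stepwise_profile, curves)
    assert np.max(np.abs(final - ref) / np.maximum(np.abs(ref), 1e-16 * C0)) < 1e-4


def test_transit_nondimensionalization_scale_invariance(stepwise_profile, curves):
    """Scaling v and all rate constants together leaves pH(x)-space
    trajectories unchanged: only the ratios (rate / v) matter."""
    base = ck.ModelParams(k_auto=1e4, k_meso=3e5, k_deg=5e4)
    traj_a = ck.simulate(base, stepwise_profile, curves)
    factor = 3.7
    # scale binding rates through the table, other rates through the constants
    pts = curves.binding.points
    scaled_binding = ck.fit_binding_rates(
        ck.BindingRatePoints(ph=pts.ph, ka=pts.ka * factor, kd=pts.kd * factor)
    )
    scaled_curves = ck.RateFunctions(
        a_klk=curves.a_klk, a_meso=curves.a_meso, binding=scaled_binding
    )
    scaled = ck.ModelParams(
        k_auto=base.k_auto * factor,
        k_meso=base.k_meso * factor,
        k_deg=base.k_deg * factor,
        v=base.v * factor,
    )
    traj_b = ck.simulate(scaled, stepwise_profile, scaled_curves)
    for name in ("C_pKLK", "C_KLK", "C_LEKTI", "C_KL"):
        np.testing.assert_allclose(
            getattr(traj_b, name), getattr(traj_a, name), rtol=1e-6, atol=1e-16
        )


def test_simulate_rejects_bad_grid(default_params, stepwise_profile, curves):
    with pytest.raises(ValueError):
        ck.simulate(default_params, stepwise_profile, curves, np.array([0.1, 1.0]))
    with pytest.raises(ValueError):
        ck.simulate(default_params, stepwise_profile, curves, np.array([0.0, 0.5, 0.5, 1.0]))


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


def test_effective_activity_is_unity_weighted_at_optimum(curves, default_params):
    """At uniform pH 7.8 the activity weight is 1, so E_KLK == C_KLK."""
    profile = ck.PHProfile(kind="uniform", breakpoints=(0.0, 1.0), values=(7.8,))
    traj = ck.simulate(default_params, profile, curves)
    np.testing.assert_allclose(traj.E_KLK, traj.C_KLK, rtol=1e-12)


def test_effective_activity_smaller_at_acidic_ph(curves):
    """The same free-KLK profile scores lower at pH 5.4 than at pH 7.0."""
    a54 = curves.a_klk(5.4)
    a70 = curves.a_klk(7.0)
    assert a54 < a70
    c_klk = np.linspace(0, C0, 11)
    assert np.all(a54 * c_klk <= a70 * c_klk)


def test_surface_rise_zero_for_flat_profile_and_interpolates(solved_trajectory, curves):
    flat = ck.Trajectory(
        x=np.array([0.0, 0.6, 1.0]),
        C_pKLK=np.zeros(3),
        C_KLK=np.full(3, 0.5 * C0),
        C_LEKTI=np.zeros(3),
        C_KL=np.zeros(3),
        params=ck.ModelParams(),
        profile=ck.make_named_profile("uniform_5.4"),
        curves=curves,
    )
    assert ck.surface_rise(flat) == pytest.approx(0.0, abs=1e-25)
    rise = ck.surface_rise(solved_trajectory)
    e = solved_trajectory.E_KLK
    assert rise == pytest.approx(float(e[-1] - np.interp(0.7, solved_trajectory.x, e)))


@pytest.mark.parametrize(
    "days, expected",
    [(5.0, pytest.approx(2.3e-6, rel=0.01)), (1.0, 1.0 / 86400.0), (10.0, 0.5 / (5 * 86400.0))],
)
def test_transit_rate_from_days(days, expected):
    assert ck.transit_rate_from_days(days) == expected


def test_transit_rate_rejects_nonpositive_days():
    for bad in (0.0, -2.0):
        with pytest.raises(ValueError):
            ck.transit_rate_from_days(bad)


def test_trajectory_csv_and_manifest(tmp_path, solved_trajectory):
    csv = tmp_path / "traj.csv"
    solved_trajectory.to_csv(csv)
    import pandas as pd

    df = pd.read_csv(csv)
    assert list(df.columns) == [
        "x", "C_pKLK", "C_KLK", "C_LEKTI", "C_KL", "C_Ktotal", "C_Ltotal", "E_KLK",
    ]
    manifest = solved_trajectory.manifest({"rtol": 1e-8})
    assert manifest["params"]["C_pKLK_boundary"] == C0
    assert manifest["profile"]["kind"] == "stepwise"
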