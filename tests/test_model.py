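"""Unit and property tests for the daily soil-temperature recursion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as stn

import soiltherm as st
from soiltherm.model import CALIBRATABLE

from conftest import make_forcing


def layer(**overrides):
    base = dict(
        C_S=2e6, K_T=0.5, C_ICE=8e6, f_S=0.0, T_LOW=0.0,
        K_T_LOW=0.0, C_S_LOW=2e6, Z_S=0.1,
    )
    base.update(overrides)
    return st.SoilLayerParams(**base)


def reference_step(T, t_air, d_s, p, dt=86400.0, thr=0.0):
    """Independent scalar re-derivation of one update, used as oracle."""
    C_A = p.C_S + (p.C_ICE if T <= thr else 0.0)
    alpha = min(1.0, dt * p.K_T / (C_A * (2 * p.Z_S) ** 2))
    alpha *= math.exp(-p.f_S * d_s / 1000.0)
    beta = min(1.0, dt * p.K_T_LOW / (p.C_S_LOW * (2 * p.Z_l) ** 2))
    if alpha + beta > 1.0:
        scale = 1.0 / (alpha + beta)
        alpha, beta = alpha * scale, beta * scale
    return T + alpha * (t_air - T) + beta * (p.T_LOW - T)


# ---------------------------------------------------------------- units

@pytest.mark.parametrize(
    "C_S, C_ICE, T_prev, expected",
    [
        (2e6, 8e6, 5.0, 2e6),      # unfrozen: sensible heat only
        (2e6, 8e6, -1.0, 1e7),     # frozen: latent part active
        (0.5e6, 4e6, 0.0, 4.5e6),  # threshold itself counts as frozen
    ],
)
def test_apparent_heat_capacity(C_S, C_ICE, T_prev, expected):
    p = layer(C_S=C_S, C_ICE=C_ICE)
    assert st.apparent_heat_capacity(p, T_prev, 0.0) == expected


@pytest.mark.parametrize(
    "f_S, D_S, expected",
    [(0.0, 500.0, 1.0), (5.0, 0.0, 1.0), (5.0, 100.0, math.exp(-0.5))],
)
def test_snow_damping_factor(f_S, D_S, expected):
    assert st.snow_damping_factor(f_S, D_S) == pytest.approx(expected, abs=1e-12)


def test_snow_damping_rejects_negative_inputs():
    with pytest.raises(ValueError):
        st.snow_damping_factor(-1.0, 10.0)
    with pytest.raises(ValueError):
        st.snow_damping_factor(1.0, -10.0)


@pytest.mark.parametrize(
    "T_prev, t_air, d_s, overrides, expected",
    [
        (5.0, 10.0, 0.0, {}, 7.7),                       # alpha = 0.54
        (5.0, 10.0, 100.0, {"f_S": 5.0}, 5 + 2.7 * math.exp(-0.5)),
        (-1.0, 5.0, 0.0, {}, -0.352),                    # frozen: alpha = 0.108
    ],
)
def test_step_hand_examples(T_prev, t_air, d_s, overrides, expected):
    p = layer(**overrides)
    assert st.step_soil_temperature(T_prev, t_air, d_s, p) == pytest.approx(
        expected, abs=1e-9
    )


def test_invalid_params_rejected():
    for bad in (
        dict(C_S=0.0), dict(K_T=-0.1), dict(Z_S=-0.1), dict(C_ICE=-1.0),
    ):
        with pytest.raises(ValueError):
            layer(**bad)
    with pytest.raises(ValueError):
        layer(Z_l=0.05)  # Z_l must exceed Z_S


def test_z_l_defaults_to_twice_depth():
    assert layer(Z_S=0.2).Z_l == pytest.approx(0.4)


# ------------------------------------------------------------ simulation

def test_constant_forcing_is_a_fixed_point():
    forcing = make_forcing(np.full(50, 4.0))
    p = layer(K_T_LOW=0.0)
    out = st.simulate_series(forcing, p, st.SimulationConfig(T_init=4.0))
    np.testing.assert_allclose(out.values, 4.0, atol=0)


def test_simulation_matches_manual_recursion_over_ten_days():
    rng = np.random.default_rng(7)
    t_air = rng.uniform(-10, 15, size=10)
    d_s = rng.uniform(0, 400, size=10)
    p = layer(f_S=5.0, K_T_LOW=0.2, T_LOW=0.5)
    forcing = make_forcing(t_air, d_s)
    out = st.simulate_series(forcing, p, st.SimulationConfig(T_init=5.0))
    T = 5.0
    for i in range(10):
        T = reference_step(T, t_air[i], d_s[i], p)
        assert out.values[i] == pytest.approx(T, abs=1e-9)


def test_snow_free_run_equals_zero_snow_parameter():
    """f_S = 0 with any snow equals the same run with bare ground, exactly."""
    rng = np.random.default_rng(11)
    t_air = rng.uniform(-15, 15, size=120)
    d_s = rng.uniform(0, 600, size=120)
    p = layer(f_S=0.0, K_T_LOW=0.3, T_LOW=0.5)
    cfg = st.SimulationConfig(T_init=0.0)
    with_snow = st.simulate_series(make_forcing(t_air, d_s), p, cfg)
    bare = st.simulate_series(make_forcing(t_air, np.zeros(120)), p, cfg)
    np.testing.assert_array_equal(with_snow.values, bare.values)


def test_nesting_recovers_base_recursion_exactly():
    """K_T_LOW=0 and f_S=0 reduce to the plain air-driven relaxation."""
    rng = np.random.default_rng(13)
    t_air = rng.uniform(-15, 15, size=90)
    p = layer(f_S=0.0, K_T_LOW=0.0)
    out = st.simulate_series(
        make_forcing(t_air, rng.uniform(0, 500, 90)), p,
        st.SimulationConfig(T_init=2.0),
    )
    a_warm = min(1.0, 86400 * p.K_T / (p.C_S * (2 * p.Z_S) ** 2))
    a_cold = min(1.0, 86400 * p.K_T / ((p.C_S + p.C_ICE) * (2 * p.Z_S) ** 2))
    T = 2.0
    for i in range(90):
        T = T + (a_cold if T <= 0 else a_warm) * (t_air[i] - T)
        assert out.values[i] == T  # exact, not approximate


def test_gap_in_forcing_dates_names_first_gap():
    import pandas as pd

    dates = pd.DatetimeIndex(["2000-01-01", "2000-01-02", "2000-01-04"])
    with pytest.raises(ValueError, match="2000-01-02"):
        st.ForcingSeries(dates, np.zeros(3))


def test_spinup_dropped_and_aligned():
    forcing = make_forcing(np.linspace(-5, 10, 40))
    out = st.simulate_series(forcing, layer(), st.SimulationConfig(spinup_days=10))
    assert len(out.values) == 30
    assert (out.dates == forcing.dates[10:]).all()


def test_batch_agrees_with_scalar_path():
    rng = np.random.default_rng(17)
    t_air = rng.uniform(-10, 15, 60)
    d_s = rng.uniform(0, 300, 60)
    forcing = make_forcing(t_air, d_s)
    rows = []
    for _ in range(5):
        rows.append(
            dict(
                C_S=rng.uniform(0.5e6, 3.5e6), K_T=rng.uniform(0, 1),
                C_ICE=rng.uniform(4e6, 15e6), f_S=rng.uniform(0, 10),
                T_LOW=rng.uniform(0, 1), K_T_LOW=rng.uniform(0, 1),
                C_S_LOW=rng.uniform(0.5e6, 3.5e6),
            )
        )
    mat = np.array([[r[k] for k in CALIBRATABLE] for r in rows])
    cfg = st.SimulationConfig(T_init=1.0)
    batch = st.simulate_batch(forcing, mat, Z_S=0.29, config=cfg)
    for j, r in enumerate(rows):
        single = st.simulate_series(
            forcing, st.SoilLayerParams(Z_S=0.29, **r), cfg
        )
        np.testing.assert_allclose(batch[:, j], single.values, rtol=0, atol=0)


# ------------------------------------------------------------ properties

params_strategy = stn.fixed_dictionaries(
    dict(
        C_S=stn.floats(0.5e6, 3.5e6),
        K_T=stn.floats(0.0, 1.0),
        C_ICE=stn.floats(4e6, 15e6),
        f_S=stn.floats(0.0, 10.0),
        T_LOW=stn.floats(0.0, 1.0),
        K_T_LOW=stn.floats(0.0, 1.0),
        C_S_LOW=stn.floats(0.5e6, 3.5e6),
    )
)


@settings(max_examples=200, derandomize=True)
@given(
    p=params_strategy,
    T_prev=stn.floats(-20, 25),
    t_air=stn.floats(-30, 30),
    d_s=stn.floats(0, 1500),
    Z_S=stn.floats(0.01, 0.6),
)
def test_update_is_convex_combination(p, T_prev, t_air, d_s, Z_S):
    """Next temperature stays within the envelope of its three drivers."""
    params = st.SoilLayerParams(Z_S=Z_S, **p)
    T_next = st.step_soil_temperature(T_prev, t_air, d_s, params)
    lo = min(T_prev, t_air, params.T_LOW) - 1e-9
    hi = max(T_prev, t_air, params.T_LOW) + 1e-9
    assert lo <= T_next <= hi


@settings(max_examples=200, derandomize=True)
@given(
    p=params_strategy,
    T_prev=stn.floats(-20, 25),
    t_air=stn.floats(-30, 30),
    Z_S=stn.floats(0.01, 0.6),
)
def test_deeper_snow_weakens_air_coupling(p, T_prev, t_air, Z_S):
    """With the lower term off, the step displacement shrinks with snow depth."""
    params = st.SoilLayerParams(Z_S=Z_S, **{**p, "K_T_LOW": 0.0})
    disp = [
        abs(st.step_soil_temperature(T_prev, t_air, d, params) - T_prev)
        for d in (0.0, 50.0, 200.0, 800.0)
    ]
    assert all(a >= b - 1e-12 for a, b in zip(disp, disp[1:]))


@settings(max_examples=100, derandomize=True)
@given(
    p=params_strategy,
    T_prev=stn.floats(-20, -0.01),
    t_air=stn.floats(-30, 30),
)
def test_frozen_soil_responds_more_slowly(p, T_prev, t_air):
    """Below the ice threshold the latent capacity damps the surface step."""
    p = {**p, "K_T_LOW": 0.0}
    frozen = st.SoilLayerParams(Z_S=0.3, **p)
    no_latent = st.SoilLayerParams(Z_S=0.3, **{**p, "C_ICE": 1e-6})
    d_frozen = abs(st.step_soil_temperature(T_prev, t_air, 0.0, frozen) - T_prev)
    d_plain = abs(st.step_soil_temperature(T_prev, t_air, 0.0, no_latent) - T_prev)
    if p["K_T"] > 1e-9 and abs(t_air - T_prev) > 1e-9:
        # Z_S = 0.3 keeps the surface fraction below the cap, so the
        # contrast is strict.
        assert d_frozen < d_plain
    else:
        assert d_frozen <= d_plain


def steady_state_expectation(P, Z_S, a, d, dt=86400.0):
    """Closed-form limit of the recursion under constant forcing.

    Returns the expected steady states and the number of days needed to
    approach them to 1e-8, derived from the geometric contraction rate.
    """
    C_S, K_T, C_ICE, f_S, T_LOW, K_T_LOW, C_S_LOW = P.T
    alpha = np.minimum(1.0, dt * K_T / (C_S * (2 * Z_S) ** 2))
    alpha = alpha * np.exp(-f_S * d / 1000.0)
    beta = np.minimum(1.0, dt * K_T_LOW / (C_S_LOW * (2 * (2 * Z_S)) ** 2))
    expected = (alpha * a + beta * T_LOW) / (alpha + beta)
    rate = np.minimum(alpha + beta, 1.0 - 1e-12)
    n = int(np.max(np.ceil(np.log(1e-8) / np.log1p(-rate))))
    return expected, n


def test_steady_state_matches_closed_form():
    """Constant forcing converges to (alpha*a + beta*T_LOW)/(alpha+beta)."""
    rng = np.random.default_rng(5)
    a, d = 8.0, 150.0
    n_draws = 20
    P = np.column_stack(
        [
            rng.uniform(0.5e6, 3.5e6, n_draws),
            rng.uniform(0.05, 1, n_draws),  # K_T floor keeps convergence finite
            rng.uniform(4e6, 15e6, n_draws),
            rng.uniform(0, 10, n_draws),
            rng.uniform(0, 1, n_draws),
            rng.uniform(0, 1, n_draws),
            rng.uniform(0.5e6, 3.5e6, n_draws),
        ]
    )
    expected, n = steady_state_expectation(P, 0.3, a, d)
    forcing = make_forcing(np.full(n, a), np.full(n, d))
    out = st.simulate_batch(forcing, P, Z_S=0.3, config=st.SimulationConfig(T_init=a))
    np.testing.assert_allclose(out[-1], expected, atol=1e-6, rtol=0)
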