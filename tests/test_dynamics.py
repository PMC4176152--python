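import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

import tfdyn as td
from tfdyn.dynamics import (
    ATOL,
    CompiledModel,
    GrowthConfig,
    default_growth,
    default_translation_scaling,
)
from tfdyn.network import Reaction, ReactionNetwork, Species
from tfdyn.params import Parameter, ParameterSet


# ---------------------------------------------------------------------------
# auxiliary rate laws
# ---------------------------------------------------------------------------

def test_mass_action_flux_examples():
    r = Reaction({"A": 1, "B": 1}, {"C": 1}, "k")
    assert td.mass_action_flux(r, {"A": 3.0, "B": 2.0}, 2.0) == 12.0
    r2 = Reaction({"A": 2}, {"C": 1}, "k")
    assert td.mass_action_flux(r2, {"A": 3.0}, 1.0) == 9.0
    assert td.mass_action_flux(r, {"A": 0.0, "B": 5.0}, 2.0) == 0.0


def test_growth_rate_hill():
    g = GrowthConfig(mu_max=0.0046, k_mmu=30.0, n_hmu=2.0)
    assert td.growth_rate(0.0, g) == 0.0
    for h in (1.0, 2.0, 4.0):
        gh = GrowthConfig(mu_max=0.0046, k_mmu=30.0, n_hmu=h)
        assert td.growth_rate(30.0, gh) == pytest.approx(0.0023)
    assert td.growth_rate(1e9, g) == pytest.approx(g.mu_max, rel=1e-6)


def test_operator_occupancy(net_b42_4):
    c = np.zeros(29)
    i_ot, i_of = net_b42_4.index("O_TF"), net_b42_4.index("O_free")
    c[i_of] = 4.0
    assert td.operator_occupancy(c, net_b42_4) == 0.0
    c[i_ot] = 4.0
    assert td.operator_occupancy(c, net_b42_4) == 0.5
    c[i_of] = 0.0
    assert td.operator_occupancy(c, net_b42_4) == 1.0
    c[i_ot] = 0.0
    with pytest.raises(ValueError):
        td.operator_occupancy(c, net_b42_4)


def _exactly_one_occupied(p: float, n: int) -> float:
    """Brute force over all 2^n independent box configurations."""
    total = 0.0
    for config in itertools.product((0, 1), repeat=n):
        if sum(config) == 1:
            prob = 1.0
            for occ in config:
                prob *= p if occ else (1.0 - p)
            total += prob
    return total


@pytest.mark.parametrize("n", range(1, 9))
def test_recruitment_factor_matches_enumeration(n):
    for p in np.arange(0.0, 1.0001, 0.1):
        assert n * td.pol_binding_factor(p, n) == pytest.approx(
            _exactly_one_occupied(float(p), n), abs=1e-12
        )


def test_pol_binding_factor_examples():
    assert td.pol_binding_factor(0.5, 1) == 0.5
    assert td.pol_binding_factor(1.0, 4) == 0.0
    assert td.pol_binding_factor(0.25, 4) == pytest.approx(0.10546875)
    assert 4 * td.pol_binding_factor(0.25, 4) == pytest.approx(0.421875)


@given(st.floats(0.0, 1.0), st.integers(1, 8))
def test_pol_binding_factor_bounded(p, n):
    val = td.pol_binding_factor(p, n)
    assert 0.0 <= val <= 1.0
    assert 0.0 <= n * val <= 1.0  # probability of exactly one occupied box


def test_translation_scaling_normalisation_and_monotonicity():
    ts = default_translation_scaling()
    assert td.translation_scaling(ts.mu_ref, ts) == pytest.approx(1.0)
    assert td.translation_scaling(0.0, ts) == pytest.approx(ts.a0)
    grid = np.linspace(0.0, 1.5 * ts.mu_ref, 400)
    vals = [td.translation_scaling(m, ts) for m in grid]
    assert np.all(np.diff(vals) >= 0)
    assert all(v >= 0 for v in vals)


def test_pol_total_moiety_weighting(net_b42_4):
    c = np.zeros(29)
    assert td.pol_total(c, net_b42_4) == 0.0
    c[net_b42_4.index("Pol_nuc")] = 5.0
    assert td.pol_total(c, net_b42_4) == 5.0
    assert td.pol_total(c, net_b42_4, mode="free_nuclear") == 5.0
    c[net_b42_4.index("Pol_cyt")] = 1.0
    c[net_b42_4.index("TFHPol_nuc")] = 2.0
    c[net_b42_4.index("G_rep_Pol")] = 3.0
    assert td.pol_total(c, net_b42_4) == 11.0
    assert td.pol_total(c, net_b42_4, mode="free_nuclear") == 5.0


# ---------------------------------------------------------------------------
# toy-network oracle: compiled rhs vs hand-written ODEs
# ---------------------------------------------------------------------------

def _toy(diluted: bool):
    species = [
        Species("A", "cytoplasm", {"TF": 1}, diluted=diluted),
        Species("B", "cytoplasm", {"inhibitor": 1}, diluted=diluted),
        Species("C", "cytoplasm", {"Pol": 1}, diluted=diluted),
    ]
    reactions = [
        Reaction({"A": 1, "B": 1}, {"C": 1}, "k_on_toy"),
        Reaction({"C": 1}, {"A": 1, "B": 1}, "k_off_toy"),
    ]
    net = ReactionNetwork(species, reactions, n_boxes=1, variant="B42")
    p = ParameterSet(
        {
            "k_on_toy": Parameter(0.02, "per_nM_per_min"),
            "k_off_toy": Parameter(0.5, "per_min"),
        }
    )
    g = GrowthConfig(mu_max=0.004, k_mmu=1.0, n_hmu=2.0)
    return CompiledModel(net, p, g, default_translation_scaling())


def test_toy_rhs_matches_hand_written_odes():
    model = _toy(diluted=True)
    g = model.growth
    rng = np.random.default_rng(0)
    for _ in range(25):
        a, b, c = rng.uniform(0.0, 5.0, size=3)
        mu = g.mu_max * c**2 / (g.k_mmu**2 + c**2)
        flux = 0.02 * a * b - 0.5 * c
        expected = np.array([-flux - mu * a, -flux - mu * b, flux - mu * c])
        assert model.rhs(0.0, np.array([a, b, c])) == pytest.approx(
            expected, rel=1e-14, abs=1e-16
        )


def test_toy_equilibrium_matches_closed_form():
    model = _toy(diluted=False)
    a0, b0 = 2.0, 1.5
    kd = 0.5 / 0.02
    s = a0 + b0 + kd
    c_eq = (s - np.sqrt(s * s - 4 * a0 * b0)) / 2.0
    out = model.integrate(np.array([a0, b0, 0.0]), np.array([0.0, 50000.0]))[-1]
    assert out[2] == pytest.approx(c_eq, rel=1e-6)
    assert out[0] == pytest.approx(a0 - c_eq, rel=1e-6)


# ---------------------------------------------------------------------------
# full-model dynamics
# ---------------------------------------------------------------------------

def test_rhs_zero_state_with_zero_sources(params, net_b42_4):
    p0 = params.with_values({"k_red": 1e-30, "k_basal": 1e-30})
    dc = td.rhs(0.0, np.zeros(29), td.Condition("B42", 4, "SDC", 0.0), p0)
    assert np.allclose(dc, 0.0, atol=1e-25)


def test_clamped_hormone_row_is_zero(params, traj_b42_2000):
    net = traj_b42_2000.net
    dc = td.rhs(
        100.0, traj_b42_2000.states[3], td.Condition("B42", 4, "SDC", 2000.0), params
    )
    assert dc[net.index("H_ext")] == 0.0
    assert traj_b42_2000.series("H_ext") == pytest.approx(2000.0)


def test_conserved_totals_constant_along_trajectory(traj_b42_2000):
    net = traj_b42_2000.net
    for moiety, w, _ in td.conserved_totals(net):
        series = traj_b42_2000.states @ w
        drift = np.max(np.abs(series - series[0])) / series[0]
        assert drift < 1e-6, moiety


def test_nonnegative_concentrations(traj_b42_2000):
    assert traj_b42_2000.states.min() >= -10 * ATOL


def test_pre_equilibrate_properties(params, net_b42_4):
    cond = td.Condition("B42", 4, "SDC", 0.0)
    c0 = td.pre_equilibrate(cond, params)
    # no hormone anywhere without a hormone source
    for sid in ("H_cyt", "H_nuc", "TFH_cyt", "TFH_nuc", "TFHPol_nuc", "O_TF"):
        assert c0[net_b42_4.index(sid)] == pytest.approx(0.0, abs=1e-12)
    g = default_growth("SDC")
    mu0 = td.growth_rate(td.pol_total(c0, net_b42_4), g)
    assert 0.0 < mu0 < g.mu_max
    # the state reproduces itself under further integration
    traj = td.simulate(cond, params, np.array([0.0, 1000.0]))
    rel = np.abs(traj.states[-1] - traj.states[0]) / (np.abs(traj.states[0]) + 1e-9)
    assert np.max(rel[traj.states[0] > 1e-6]) < 1e-3


def test_uninduced_reporter_flat(params):
    traj = td.simulate(
        td.Condition("B42", 4, "SDC", 0.0), params,
        np.array([0.0, 300.0, 900.0, 1680.0]),
    )
    rep = traj.series("Rep_mat")
    assert np.max(np.abs(rep - rep[0])) / rep[0] < 1e-3


def test_dose_monotonicity_b42(params):
    tgrid = np.array([0.0, 300.0, 1680.0])
    doses = [0.0, 15.0, 125.0, 500.0, 2000.0]
    finals = []
    mids = []
    for d in doses:
        traj = td.simulate(td.Condition("B42", 4, "SDC", d), params, tgrid)
        mids.append(traj.series("Rep_mat")[1])
        finals.append(traj.series("Rep_mat")[2])
    assert np.all(np.diff(mids) > 0)
    assert np.all(np.diff(finals) > 0)


def test_reporter_mrna_steady_within_two_hours(traj_b42_2000):
    m = traj_b42_2000.series("mRNA_rep")
    t = traj_b42_2000.time
    ss = m[t == 1680.0][0]
    assert m[t == 120.0][0] == pytest.approx(ss, rel=0.05)


def test_vp16_growth_monotone_toxicity(params):
    tgrid = np.array([0.0, 300.0])
    mus = []
    for d in (0.0, 15.0, 62.0, 250.0, 1000.0, 2500.0):
        traj = td.simulate(td.Condition("VP16", 4, "SDC", d), params, tgrid)
        mus.append(traj.mu[-1])
    assert np.all(np.diff(mus) < 0)
    assert mus[-1] < 0.5 * mus[0]  # strong inhibition at saturating hormone


def test_dose_response_surface(params):
    doses = [0.0, 125.0, 2000.0]
    times = [300.0, 1680.0]
    surf = td.dose_response_surface("B42", 4, "SDC", doses, times, params)
    assert surf.shape == (2, 3)
    assert np.all(np.diff(surf, axis=1) > 0)  # monotone in dose
    zero = td.dose_response_surface("B42", 4, "SDC", [0.0], times, params)
    assert zero[0, 0] == pytest.approx(zero[1, 0], rel=1e-3)


def test_vp16_late_time_output_collapses(params):
    surf = td.dose_response_surface(
        "VP16", 4, "SDC", [2500.0], [300.0, 1680.0], params
    )
    assert surf[1, 0] < surf[0, 0]  # 28 h signal below the 5 h maximum


def test_box_number_scaling(params):
    tgrid = np.array([0.0, 1680.0])
    out = {}
    for nb in (1, 2, 3, 4, 8):
        traj = td.simulate(td.Condition("B42", nb, "SDC", 2000.0), params, tgrid)
        out[nb] = traj.series("Rep_mat")[-1]
    ratios = {nb: out[nb] / out[1] for nb in out}
    for nb in (2, 3, 4):
        assert ratios[nb] == pytest.approx(nb, rel=0.25)  # approximately linear
    assert ratios[8] < 8 * 0.8  # saturates beyond four boxes


def test_invalid_time_grid_rejected(params):
    with pytest.raises(ValueError):
        td.simulate(td.Condition("B42", 4, "SDC", 0.0), params, np.array([10.0, 20.0]))
    with pytest.raises(ValueError):
        td.simulate(td.Condition("B42", 4, "SDC", 0.0), params, np.array([0.0, 0.0]))
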