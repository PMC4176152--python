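import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

import tfdyn as td
from tfdyn.estimation import DataError, TimecourseDataset, goodness_of_fit


def _shifted(dataset, k_sigma=1.0):
    """Copy of a dataset with every value shifted by k_sigma standard deviations."""
    frame = dataset.frame.copy()
    frame["value"] = frame["value"] + k_sigma * frame["sd"]
    return TimecourseDataset(frame)


def test_chi_squared_perfect_fit_is_zero(params, tiny_dataset):
    assert td.chi_squared(params, tiny_dataset) == pytest.approx(0.0, abs=1e-12)


def test_chi_squared_unit_residuals(params, tiny_dataset):
    """Each residual at one sigma: the 1/n_i weighting gives 1 per experiment."""
    shifted = _shifted(tiny_dataset)
    n_exp = shifted.frame["experiment_id"].nunique()
    assert td.chi_squared(params, shifted) == pytest.approx(n_exp, rel=1e-9)


def test_chi_squared_additive_over_duplicated_experiments(params, tiny_dataset):
    shifted = _shifted(tiny_dataset)
    single = td.chi_squared(params, shifted)
    dup = shifted.frame.copy()
    dup["experiment_id"] = dup["experiment_id"] + "_copy"
    doubled = TimecourseDataset(
        pd.concat([shifted.frame, dup], ignore_index=True)
    )
    assert td.chi_squared(params, doubled) == pytest.approx(2 * single, rel=1e-9)


def test_chi_squared_invariant_under_row_order(params, tiny_dataset):
    shifted = _shifted(tiny_dataset, 0.7)
    ref = td.chi_squared(params, shifted)
    rng = np.random.default_rng(3)
    perm = shifted.frame.sample(frac=1.0, random_state=rng.integers(1 << 31))
    shuffled = TimecourseDataset(perm.reset_index(drop=True))
    assert td.chi_squared(params, shuffled) == pytest.approx(ref, rel=1e-12)


def test_chi_squared_penalises_failed_simulation(params, tiny_dataset, monkeypatch):
    # a failing simulation must not raise inside the optimiser loop
    import tfdyn.estimation as est

    def boom(*args, **kwargs):
        raise est.IntegrationError("stiff corner")

    monkeypatch.setattr(est, "simulate", boom)
    assert td.chi_squared(params, tiny_dataset) == est.SIM_FAILURE_PENALTY


def test_goodness_of_fit_published_statistics():
    dof, p = goodness_of_fit(101.2, 446, 45)
    assert dof == 401
    assert p < 1e-50
    dof, p = goodness_of_fit(860.5, 1014, 0)
    assert dof == 1014
    assert p == pytest.approx(1.7e-4, rel=0.05)


def test_goodness_of_fit_mean_behaviour():
    dof, p = goodness_of_fit(500.0, 520, 20)
    assert dof == 500
    assert p == pytest.approx(0.5, abs=0.02)
    with pytest.raises(DataError):
        goodness_of_fit(10.0, 5, 5)


@pytest.mark.parametrize("dof", [1, 2, 3, 5, 10])
def test_left_tail_matches_density_integration(dof):
    """Independent oracle: integrate the chi-squared density directly."""

    def pdf(x):
        return (
            x ** (dof / 2.0 - 1.0)
            * math.exp(-x / 2.0)
            / (2.0 ** (dof / 2.0) * math.gamma(dof / 2.0))
        )

    for chi2 in (0.5, float(dof), 2.0 * dof):
        expected, err = quad(pdf, 0.0, chi2, limit=200)
        _, p = goodness_of_fit(chi2, dof + 1, 1)
        assert p == pytest.approx(expected, rel=1e-6)


def test_split_train_validation_rule(params, tiny_dataset):
    frame = tiny_dataset.frame.copy()
    extra = frame.iloc[:4].copy()
    extra["n_boxes"] = 8
    extra["experiment_id"] = "boxes8"
    extra2 = frame.iloc[:4].copy()
    extra2["medium"] = "SGlyC"
    extra2["experiment_id"] = "glycerol"
    ds = TimecourseDataset(pd.concat([frame, extra, extra2], ignore_index=True))
    out = td.split_train_validation(ds)
    f = out.frame
    assert (f.loc[(f.n_boxes == 4) & (f.medium == "SDC"), "role"] == "training").all()
    assert (f.loc[f.experiment_id == "boxes8", "role"] == "validation").all()
    assert (f.loc[f.experiment_id == "glycerol", "role"] == "validation").all()


def test_predict_validation_zero_noise(params):
    design = td.DesignSpec(
        variants=("B42",),
        box_counts=(1, 4),
        media=("SDC",),
        doses_nM=(0.0, 2000.0),
        growth_doses_nM=(0.0, 2000.0),
        fluor_times_min=(300.0, 1200.0),
        mrna_times_min=(15.0, 60.0),
        seed=5,
        noise=False,
    )
    ds = td.generate(design, params)
    report = td.predict_validation(params, ds)
    assert report["chi2"] == pytest.approx(0.0, abs=1e-10)
    assert report["dof"] == report["n_points"]
    assert report["p_left"] == pytest.approx(0.0, abs=1e-12)


def test_evolutionary_fit_deterministic(params, tiny_dataset):
    shifted = _shifted(tiny_dataset, 0.3)
    kwargs = dict(
        dataset=shifted, free_ids=["kd_ad_b42"], params=params, seed=11, budget=48
    )
    a = td.evolutionary_fit(**kwargs)
    b = td.evolutionary_fit(**kwargs)
    assert a.theta["kd_ad_b42"] == b.theta["kd_ad_b42"]
    assert a.chi2 == b.chi2 and a.evaluations == b.evaluations


def test_single_parameter_recovery_noise_free(params, tiny_dataset):
    """The ES recovers a generating affinity from noise-free data within 5%."""
    start = params.with_values({"kd_ad_b42": params["kd_ad_b42"]})
    fit = td.evolutionary_fit(
        tiny_dataset, ["kd_ad_b42"], start, seed=2, budget=2000
    )
    assert fit.theta["kd_ad_b42"] == pytest.approx(params["kd_ad_b42"], rel=0.05)
    assert fit.chi2 < 1e-4
    assert fit.n_free == 1 and fit.dof == fit.n_points - 1


def test_fit_requires_free_parameters(params, tiny_dataset):
    with pytest.raises(DataError):
        td.evolutionary_fit(tiny_dataset, [], params, seed=1, budget=100)


@given(st.floats(1.0, 1e4), st.integers(2, 2000))
def test_p_left_is_probability(chi2, dof):
    _, p = goodness_of_fit(chi2, dof + 3, 3)
    assert 0.0 <= p <= 1.0
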