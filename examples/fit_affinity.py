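"""Recover an AD-polymerase affinity from synthetic data by evolutionary search.

Generates a small noise-free dataset from known parameters, then re-estimates
the B42 affinity with the CMA-type evolutionary strategy and reports the
chi-squared goodness of fit.
"""
import tfdyn as td

params = td.default_parameters()
design = td.DesignSpec(
    variants=("B42",),
    box_counts=(4,),
    media=("SDC",),
    doses_nM=(0.0, 125.0, 2000.0),
    growth_doses_nM=(0.0, 2000.0),
    fluor_times_min=(60.0, 300.0, 600.0, 1200.0),
    mrna_times_min=(15.0, 45.0, 120.0),
    seed=1,
    noise=False,
)
dataset = td.generate(design, params)
print(f"dataset: {dataset.n_points} points, "
      f"{dataset.frame.experiment_id.nunique()} experiments")

fit = td.evolutionary_fit(dataset, ["kd_ad_b42"], params, seed=1, budget=1500)
true = params["kd_ad_b42"]
est = fit.theta["kd_ad_b42"]
print(f"true B42 affinity : {true:9.0f} nM (0.8 mM)")
print(f"recovered         : {est:9.0f} nM ({est / true:.3f} x truth, "
      f"{fit.evaluations} objective evaluations)")
print(f"chi2 = {fit.chi2:.2e} on {fit.dof} degrees of freedom, "
      f"left-tail P = {fit.p_left:.3g}")
print()
print("With noise-free data the optimum is the generating value and chi2")
print("approaches zero; the tiny left-tail probability flags agreement far")
print("better than the assigned measurement errors would predict.")
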