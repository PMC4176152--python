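"""Generate the full synthetic study design and partition it for calibration.

The training partition (four lexA boxes, glucose medium) holds 446 points:
fluorescence dose-response time courses for all four activation-domain
variants, one reporter-mRNA time course and four growth-rate dose series.
Everything else - box-count series, alternative media, the high-dose VP16
course - is validation data.
"""
import tfdyn as td

params = td.default_parameters()
dataset = td.generate(td.default_design(seed=1), params)
td.write_dataset(dataset, "dataset.csv")

f = dataset.frame
print(f"wrote dataset.csv: {len(f)} points")
for role in ("training", "validation"):
    sub = f[f.role == role]
    print(f"  {role}: {len(sub)} points, {sub.experiment_id.nunique()} experiments")
print()
print("per-observable breakdown of the training partition:")
print(f[f.role == 'training'].groupby('observable').size().to_string())
print()
chi2 = td.chi_squared(params, dataset.subset(f.role == "training"))
print(f"chi2 of the generating model on its own noisy training data: {chi2:.1f}")
print("(about one per experiment, as expected from the 1/n_i weighting)")
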