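# tfdyn

Mechanistic model and estimation pipeline for a hormone-inducible synthetic
transcription factor (LexA-ER-AD) in budding yeast.

The LexA-ER-AD system fuses the bacterial LexA DNA-binding protein, the
hormone-binding domain of the human estrogen receptor, and an activation
domain (B42, B112, Gal4AD or VP16).  Beta-estradiol releases the factor from
cytoplasmic retention; it then binds 1-8 lexA operator boxes in a synthetic
promoter and recruits RNA polymerase II to express a fluorescent reporter.
Which activation domain is chosen decides everything interesting about the
system: its induction strength, the steepness of the dose response, and
whether the activated factor squelches the cell's general transcription
machinery and stops growth.

`tfdyn` is for people who want to reason quantitatively about such designs:
it compiles the 29-species mass-action reaction network into a fast ODE
system (dc/dt = N v(c, u, k)) with three auxiliary laws — a Hill-type growth
function of total polymerase, a steric operator-recruitment factor
n p (1-p)^(n-1), and a growth-dependent translation capacity — simulates
dose-response time courses, maps states to flow-cytometry / qRT-PCR / growth
observables with heteroscedastic error models, and estimates parameters by
minimising the weighted chi-squared

    chi2(theta) = sum_i (1/n_i) sum_j ((c_ij^obs - c_ij^model) / sd_ij)^2

with a seeded CMA-type evolutionary strategy in log-parameter space.  A
synthetic-data generator reproduces the statistical structure of the original
experimental design (dose ladders to 2500 nM, time courses to 28 h, three
growth media, 1-8 operator boxes) so the whole pipeline is testable without
any external data.  See `docs/methods.md` for the model, its assumptions and
the calibration rationale.

## Worked example

```python
import numpy as np
import tfdyn as td

params = td.default_parameters()
cfg = td.MeasurementConfig.from_params(params)
cond = td.Condition(variant="B42", n_boxes=4, medium="SDC", dose=2000.0)
traj = td.simulate(cond, params, np.array([0.0, 45.0, 120.0, 300.0, 1680.0]))
for i, t in enumerate(traj.time):
    print(f"t={t:6.0f} min  mRNA_rel={td.mrna_relative(traj.series('mRNA_rep')[i], cfg):6.3f}"
          f"  fluor={td.fluorescence_readout(traj.series('Rep_mat')[i], cfg):7.0f} A.U."
          f"  mu={traj.mu[i]:.5f}/min")
```

prints

```
t=     0 min  mRNA_rel= 0.005  fluor=    414 A.U.  mu=0.00414/min
t=    45 min  mRNA_rel= 0.820  fluor=    597 A.U.  mu=0.00414/min
t=   120 min  mRNA_rel= 1.148  fluor=   2134 A.U.  mu=0.00414/min
t=   300 min  mRNA_rel= 1.146  fluor=   3656 A.U.  mu=0.00414/min
t=  1680 min  mRNA_rel= 1.143  fluor=   3841 A.U.  mu=0.00414/min
```

Reporter mRNA reaches half its induced level within ~33 min and plateaus
inside the first hour; fluorescence lags it through translation and
maturation and saturates around 20 h; growth is untouched because the weak
B42 domain (0.8 mM polymerase affinity) cannot squelch.  Re-running with
`variant="VP16"` (27 nM affinity) drives the growth rate down to ~15% of the
hormone-free rate at saturating hormone — the model's toxicity prediction.

The `examples/` directory holds one short script per capability: a full
induction time course, box-number scaling of the output, dose-dependent
toxicity per activation domain, affinity recovery by evolutionary search,
and synthetic-dataset generation with the training/validation split.  A thin
CLI covers the same pipeline stages
(`tfdyn generate|simulate|fit|validate|predict-boxes`).

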