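"""Simulate one induction time course and print the observable readouts.

A strain carrying the weak-activation-domain construct (B42) and a four-box
target promoter is induced with 2000 nM beta-estradiol in glucose medium.
"""
import numpy as np

import tfdyn as td

params = td.default_parameters()
cfg = td.MeasurementConfig.from_params(params)
cond = td.Condition(variant="B42", n_boxes=4, medium="SDC", dose=2000.0)
tgrid = np.array([0.0, 15.0, 45.0, 60.0, 120.0, 300.0, 600.0, 1200.0, 1680.0])

traj = td.simulate(cond, params, tgrid)

print(f"condition: {cond.variant}, {cond.n_boxes} lexA boxes, "
      f"{cond.medium}, {cond.dose:.0f} nM beta-estradiol")
print(f"{'t (min)':>8} {'mRNA (rel.)':>12} {'fluor (A.U.)':>13} "
      f"{'growth (1/min)':>15} {'box occupancy':>14}")
for i, t in enumerate(tgrid):
    mrna = td.mrna_relative(float(traj.series('mRNA_rep')[i]), cfg)
    au = td.fluorescence_readout(float(traj.series('Rep_mat')[i]), cfg)
    print(f"{t:8.0f} {mrna:12.3f} {au:13.0f} {traj.mu[i]:15.5f} {traj.p_tf[i]:14.4f}")

print()
print("The reporter mRNA (relative to the constitutive reference) rises within")
print("the first hour and plateaus; the fluorescence readout lags behind it by")
print("translation and maturation, and growth is unaffected because the B42")
print("domain binds polymerase far too weakly to squelch it.")
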