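"""Dose-dependent growth inhibition (squelching toxicity) per activation domain.

Strong activation domains sequester RNA polymerase II into inactive complexes;
because polymerase expression is autocatalytic and growth follows total
polymerase through a Hill law, high-affinity domains depress growth at high
hormone doses.
"""
import numpy as np

import tfdyn as td

params = td.default_parameters()
doses = [0.0, 15.0, 62.0, 250.0, 1000.0, 2500.0]
tgrid = np.array([0.0, 300.0])  # growth read 5 h after induction

print("specific growth rate / hormone-free rate (5 h after induction, SDC):")
print(f"{'dose (nM)':>10}" + "".join(f"{v:>9}" for v in td.VARIANTS))
rows = {v: [] for v in td.VARIANTS}
for v in td.VARIANTS:
    for d in doses:
        traj = td.simulate(td.Condition(v, 4, "SDC", d), params, tgrid)
        rows[v].append(float(traj.mu[-1]))
for i, d in enumerate(doses):
    line = f"{d:10.0f}"
    for v in td.VARIANTS:
        line += f"{rows[v][i] / rows[v][0]:9.2f}"
    print(line)

print()
print("B42 (0.8 mM polymerase affinity) never inhibits growth; VP16 (27 nM)")
print("shuts growth down above ~15-60 nM hormone, Gal4AD (200 nM) is")
print("intermediate, B112 (4 uM) only mildly affected - matching the ranking")
print("of the domains' polymerase affinities.")
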