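"""Fit the exponential body-formation model to a simulated time course.

Three replicate experiments count body-positive cells (200 inspected per
timepoint) during glucose starvation; the replicate-mean fractions are fit
to A*(1 - e^(-t/tau)) + c.  A is the fraction of cells that form bodies
during the time course, tau the apparent time constant in minutes, and c
the starting fraction.  Compare the estimates with the printed truth.
"""

from kogbody import simulate as sim
from kogbody.kinetics import fit_formation, mean_fraction_series

truth = dict(A=0.49, tau=11.0, c=0.08)
dataset = sim.simulate_timecourse(
    sim.TimecourseSimSpec(model="formation", seed=42, **truth), condition="-Glu"
)
series = mean_fraction_series(dataset)
fit = fit_formation(series.times, series.mean)

print("t (min)  mean fraction  sd")
for t, m, s in zip(series.times, series.mean, series.sd):
    print(f"{t:7.0f}  {m:13.3f}  {s:.3f}")
print(f"\ntruth: A={truth['A']}, tau={truth['tau']} min, c={truth['c']}")
print(
    f"fit:   A={fit.A:.3f}+/-{fit.se_A:.3f}, "
    f"tau={fit.tau:.1f}+/-{fit.se_tau:.1f} min, c={fit.c:.3f}+/-{fit.se_c:.3f}"
)
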