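"""Estimate the protective effect of social ageing.

Runs the full pipeline — generate observations, fit edge posteriors, draw
networks, simulate the control epidemic, fit mixed models 1 and 2 — on a
desk-scale design (5 group-years x 50 draws, medium transmissibility) and
reports the protective effect with its model-3 age x centrality contrasts.
Takes ~20 s.
"""

from socage import ExperimentConfig, run_pipeline, cost_to_infections
from socage.epi import control_grid

grid = [p for p in control_grid() if p.si == 0.60]
config = ExperimentConfig(
    n_group_years=5, n_draws=50, grid=grid, master_seed=11, contrasts=True
)
result = run_pipeline(config)
r = result.reports[0]

print(f"simulation runs: {result.n_runs}")
print(f"model 1 (cost ~ age):            beta_age = {r.beta_age_m1:.3f} +/- {r.se_m1:.3f}")
print(f"model 2 (cost ~ age + sociality): beta_age = {r.beta_age_m2:.3f} +/- {r.se_m2:.3f}")
print(f"protective effect (m1 - m2): {r.protective_effect:.3f} cost units per year")
span = 22 * r.protective_effect
print(
    f"over the 6-28 year age span: {span:.1f} units "
    f"= {cost_to_infections(abs(span)):.1f} baseline infections avoided"
)
for metric, (young, old) in r.model3_contrasts.items():
    print(f"high -> average {metric}: {-young:.1f} units saved at age 8, {-old:.1f} at age 18")

# A negative protective effect means the age trend in infection cost
# flattens once social centrality is controlled for: older individuals'
# lower centrality absorbs part of their cost advantage.  The contrasts
# show that dropping from high to average centrality saves more cost when
# old than when young for strength and closeness.
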