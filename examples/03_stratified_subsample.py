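"""Bathymetric stratification and area-proportional image subsampling.

The terrain stack is clustered into four strata; images are then drawn
within strata in proportion to areal coverage, anchored on the stratum
with the fewest images per unit coverage so nothing is over-asked.
"""

from benthoscape import seascape as sc, stratify
from benthoscape.terrain import terrain_stack

spec = sc.SeascapeSpec(nrows=100, ncols=160, seed=0)
depth = sc.generate_bathymetry(spec)
env = sc.generate_env_layers(depth, spec)
niches = sc.calibrate_density(env, sc.make_community(seed=1))
table, _ = sc.simulate_survey(env, niches, sc.SurveyDesign(
    n_transects=20, images_per_transect=100, seed=2))

terrain = terrain_stack(depth)
terrain.add("backscatter", env["backscatter"].copy())
strata = stratify.cluster_strata(terrain, k=4, seed=3)
coverage = stratify.coverage_fractions(strata)
assignment = stratify.assign_strata(table, strata)
available = {lab: int((assignment == lab).sum()) for lab in coverage}
plan = stratify.allocate_subsample(available, coverage)
subsample = stratify.draw_subsample(table, strata, plan, seed=4)

print("stratum  coverage  available  allocated")
for lab in plan.strata:
    print(f"{lab:>7}  {plan.coverage[lab]:8.2%}  {plan.available[lab]:9d}  "
          f"{plan.allocated[lab]:9d}"
          + ("   <- anchor (fewest images per unit coverage)"
             if lab == plan.anchor else ""))
print(f"\nsubsample size: {len(subsample)} of {len(table)} images; "
      "allocated/coverage is constant across uncapped strata")
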