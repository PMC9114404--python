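"""Assemblage map from stacked probabilities, tested with PERMANOVA.

Cells are clustered by their morphotype probability vectors; the number
of assemblages is chosen by the Calinski-Harabasz criterion over a
k-means cascade, and the assemblages are compared pairwise with a
permutation MANOVA (Bonferroni-adjusted).
"""

import numpy as np

from benthoscape import sdm, seascape as sc, survey
from benthoscape.community_maps import assemblage_map
from benthoscape.stats_compare import pairwise_permanova, permanova_table
from benthoscape.survey import PresenceAbsenceMatrix

spec = sc.SeascapeSpec(nrows=80, ncols=130, seed=0)
depth = sc.generate_bathymetry(spec)
env = sc.generate_env_layers(depth, spec)
niches = sc.three_zone_community(env, n_per_zone=5, seed=1)
table, truth = sc.simulate_survey(env, niches, sc.SurveyDesign(
    n_transects=12, images_per_transect=100, seed=2))

filtered, _ = survey.prevalence_filter(survey.to_presence_absence(table), 10)
predictors, _ = sdm.build_predictor_table(table, env)
kept = PresenceAbsenceMatrix(
    filtered.values.loc[table.loc[predictors.index, "image_id"]])
stack, _ = sdm.fit_all(kept, predictors, env, sdm.RFConfig(n_trees=200, seed=3))

labels, cascade = assemblage_map(stack, k_range=range(2, 7), seed=4)
print("Calinski-Harabasz scores by k:",
      {k: round(s) for k, s in cascade.scores.items()})
print(f"selected k = {cascade.best_k} "
      "(three niche groups were planted, so 3 is the right answer)")

mask = stack.grids.joint_valid_mask
X = np.column_stack([stack[n].values[mask] for n in stack.names])
cell_labels = labels.grid.values[mask].astype(int)
rng = np.random.default_rng(5)
sel = np.concatenate([
    rng.choice(np.nonzero(cell_labels == g)[0], size=150, replace=False)
    for g in range(1, labels.k + 1)])
results = pairwise_permanova(X[sel], cell_labels[sel],
                             n_permutations=999, seed=6)
print(permanova_table(results).to_string(index=False))
print("adjusted p = 0.003 is the floor: 3 pairs x 1/(999+1)")
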