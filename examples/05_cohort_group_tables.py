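"""Small end-to-end cohort analysis with covariate-adjusted group tables.

Simulates 6 patients and 6 controls under the default group effects, runs
the full pipeline (temporal preprocessing; smoothing is left off at phantom
scale — see docs/methods.md) and prints the activated-voxel-count group
table: means ± SE, relative change, age/volume-adjusted p, BH-FDR flag,
Cohen's d and the partial UPSIT correlation.
"""

import dataclasses

from olfbold import RunConfig, analyze_cohort, default_config, make_atlas, simulate_cohort
from olfbold.preprocess import PreprocessConfig

sim = dataclasses.replace(default_config(seed=8), n_subjects={"PD": 6, "HC": 6})
cohort = simulate_cohort(sim, make_atlas(), RunConfig().paradigm)
res = analyze_cohort(
    cohort,
    RunConfig(simulation=sim, preprocess=PreprocessConfig(do_smooth=False)),
)

table = res.group_tables["n_active"]
cols = ["roi", "mean_pd", "se_pd", "mean_hc", "se_hc", "relative_change",
        "p_group", "fdr_significant", "cohens_d", "r_upsit"]
print(table[cols].round(2).to_string(index=False))
print("\ndirection matrix (patients vs controls, FDR-gated):")
print(res.direction.to_string())
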