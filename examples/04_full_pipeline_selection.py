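"""Run the complete evaluation pipeline and select adapted accessions.

Simulates a trial in which ten accessions carry genuinely favorable genotype
effects on all six index traits, runs model fits, heritability, the index,
grand-mean-difference tests and year-stability tests, and checks how many of
the planted accessions the final selection recovers.
"""

import numpy as np

from metsel import (
    PipelineConfig,
    default_trait_specs,
    default_variance_specs,
    generate_trial,
    run_pipeline,
)

INDEX_TRAITS = ["tkw", "seed_yield", "dtf", "plant_height", "mildew", "saponin"]

specs = default_variance_specs()
tspecs = default_trait_specs()
rng = np.random.default_rng(7)
planted = rng.choice(48, size=10, replace=False)
shifts = {}
for t in INDEX_TRAITS:
    s = np.zeros(48)
    s[planted] = 2.0 * np.sqrt(specs[t].sigma2_g) * tspecs[t].sign
    shifts[t] = s

data = generate_trial(seed=7, genotype_shifts=shifts)
truth = {data.accessions[i] for i in planted}
print("planted superior accessions:", sorted(truth))

config = PipelineConfig(seed=7, mc_draws=20_000, residual_structure="iid", k_select=10)
result = run_pipeline(config, data, out_dir="pipeline_out")

print("\nselected:", sorted(result.selected))
hit = truth & set(result.selected)
print(f"recovered {len(hit)}/10 planted accessions")
print("\nper-accession rationale for the top 3:")
for _, row in result.selection.head(3).iterrows():
    print(f"  {row['accession']}: {row['rationale']}")
print(
    "\nAll stage tables (fits, correlations, components, index, GMD,"
    "\nstability, selection) and a manifest are in pipeline_out/."
)
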