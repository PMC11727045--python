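"""Marker-trait association and candidate-gene windows.

Simulates a cohort with one planted QTL (15% of trait variance), runs
the three association models (GLM, MLM(K), MLM(K+Q)), keeps markers
significant in at least two models, and looks up genes in the 1 Mb
window around the stable marker.
"""

from indelssr import (
    GeneRecord,
    PlantedQTL,
    SimConfig,
    candidate_gene_window,
    effect_for_variance_fraction,
    glm_assoc,
    mlm_assoc,
    significant_markers,
    simulate_cohort,
    simulate_traits,
    trait_summaries,
)

beta = effect_for_variance_fraction(0.15)
cfg = SimConfig(seed=6, n_individuals=121, n_markers=40, missing_rate=0.0,
                trait_names=("leaf_area", "cormel_number"),
                planted_qtl=(PlantedQTL("m003", "leaf_area", beta),))
cohort = simulate_cohort(cfg)
traits = simulate_traits(cfg, cohort)

print(trait_summaries(traits).round(3).to_string(index=False))

kin = cohort.grm_excluding(["m003"])  # leave the candidate out of the GRM
results = [
    glm_assoc(cohort.band_matrix, traits),
    mlm_assoc(cohort.band_matrix, traits, kin),
    mlm_assoc(cohort.band_matrix, traits, kin, q=cohort.q_truth),
]
import pandas as pd

all_res = pd.concat(results, ignore_index=True)
qtl = all_res[(all_res.marker_id == "m003") & (all_res.trait == "leaf_area")]
print("\nplanted QTL m003 vs leaf_area:")
print(qtl[["model", "year", "p_value", "r2"]].to_string(index=False))

stable = significant_markers(all_res, alpha=0.05, min_models=2)
print(f"\nmarkers significant in >=2 models: "
      f"{sorted(set(stable.marker_id))}")

# a toy annotation: the marker maps to Chr1:2,000,000 with genes nearby
genes = [
    GeneRecord("gene_at_anchor", "Chr1", 1_999_500, 2_000_800, "+"),
    GeneRecord("gene_400kb_away", "Chr1", 2_400_000, 2_401_500, "-"),
    GeneRecord("gene_600kb_away", "Chr1", 2_600_000, 2_601_500, "+"),
]
hits = candidate_gene_window("Chr1", 2_000_000, genes)
print(f"candidate genes within the 1 Mb window (+/-500 kb): "
      f"{[g.gene_id for g in hits]}")
print(
    "\nThe planted marker reaches significance in all three models (the"
    "\nmixed models correct for kinship/structure); the 600 kb gene falls"
    "\noutside the total-1 Mb window and is excluded."
)
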