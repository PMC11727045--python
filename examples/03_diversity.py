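"""Diversity analysis of a structured cohort of dominant markers.

Simulates the study-shaped cohort (121 individuals from 3 admixed
subpopulations, 219 multi-allelic markers), computes per-marker allele
statistics (Na, Ne, Ho, He, PIC, Shannon I), Nei distances + UPGMA,
PCA, kinship, and picks the number of clusters with the Evanno delta-K
statistic.
"""

import numpy as np

from indelssr import (
    SimConfig,
    evanno_delta_k,
    individual_freq_profiles,
    kinship,
    marker_summary,
    nei_distance,
    pca_binary,
    simulate_cohort,
    structure_pseudo_lnp,
    upgma,
)

cfg = SimConfig(seed=4)  # defaults: 121 individuals, 219 markers, 3 subpops
cohort = simulate_cohort(cfg)

stats, summary = marker_summary(cohort.band_matrix)
print(f"{summary['n_markers']} polymorphic markers, "
      f"{summary['total_alleles']} alleles total")
print(f"mean Na {summary['mean_Na']:.2f}  mean Ne {summary['mean_Ne']:.2f}  "
      f"mean Ho {summary['mean_Ho']:.3f}  mean He {summary['mean_He']:.3f}")
print(f"mean PIC {summary['mean_PIC']:.3f} (max {summary['max_PIC']:.3f}); "
      f"{100 * summary['frac_pic_gt_0.25']:.1f}% of markers have PIC > 0.25")

d = nei_distance(individual_freq_profiles(cohort.band_matrix))
tree = upgma(d)
print(f"\nUPGMA tree over {len(tree.ids)} individuals, "
      f"root height {max(tree.merge_heights) / 1:.3f} "
      f"(half the largest merge distance)")

p = pca_binary(cohort.band_matrix, n_components=2)
print(f"PCA: first two components explain "
      f"{100 * p.explained[0]:.1f}% and {100 * p.explained[1]:.1f}% of variance")

k = kinship(cohort.band_matrix)
print(f"kinship (allele sharing, rescaled): off-diagonal mean "
      f"{k.values[~np.eye(len(k.ids), dtype=bool)].mean():.3f}")

lnp = structure_pseudo_lnp(cohort.band_matrix, range(1, 11), n_replicates=10, seed=5)
res = evanno_delta_k(lnp)
print(f"\nEvanno delta-K over K=1..10: optimal K = {res.optimal_k}")
print("  " + "  ".join(f"K={k}: {v:.1f}" for k, v in sorted(res.delta_k.items())))
print(
    "\nHe above Ho reflects the Wahlund effect of the 3-subpopulation"
    "\nstructure, and delta-K peaks at the true number of subpopulations."
)
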