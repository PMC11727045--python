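"""Design primers for a marker locus, screen it, and predict bands.

For one discovered InDel-SSR locus: enumerate primer pairs (16-24 nt,
product 100-300 bp spanning the InDel, Tm 50-60 C, pair Tm gap <= 3 C),
apply the product-level screen (>= 18 bp of AT-rich SSR tract and the
InDel inside the product), then run in-silico PCR over a tiny cohort to
show how the InDel's length difference separates individuals into band
patterns.
"""

from indelssr import (
    PrimerConstraints,
    SimConfig,
    call_indel_ssrs,
    design_candidates,
    band_matrix_from_predictions,
    in_silico_pcr,
    screen_marker,
    simulate_genome,
)

cfg = SimConfig(seed=8, n_chromosomes=1, chrom_len=40_000,
                n_indels_per_chromosome=20, frac_indels_near_ssr=1.0,
                near_indel_max_offset=220)
sim = simulate_genome(cfg)
loci = call_indel_ssrs(sim.indels, sim.genome)

chosen = None
for locus in loci:
    for pair in design_candidates(locus, sim.genome, PrimerConstraints(top_k=10)):
        result = screen_marker(pair, locus)
        if result.passed:
            chosen = (locus, pair, result)
            break
    if chosen:
        break

assert chosen, "no screened marker in this simulation"
locus, pair, result = chosen
print(f"locus {locus.chrom_id}:{locus.indel.pos} ({locus.repeat_class} repeat)")
print(f"  forward 5'-{pair.fwd_seq}-3'  Tm {pair.tm_fwd:.1f} C")
print(f"  reverse 5'-{pair.rev_seq}-3'  Tm {pair.tm_rev:.1f} C")
print(f"  reference product {pair.product_len_ref} bp, "
      f"SSR tract inside product {result.repeat_span} bp "
      f"(AT fraction {result.at_frac:.2f})")

# a 4-genotype mini-cohort at this locus: ref/ref, ref/alt, alt/alt, missing
locus.indel.per_sample_genotypes = {
    "acc1": (0, 0), "acc2": (0, 1), "acc3": (1, 1), "acc4": (None, None),
}
bands = band_matrix_from_predictions(in_silico_pcr(pair, locus.indel))
print("\nPredicted band matrix (1 band present, 0 absent, NA failed):")
print(bands.scores.to_string())
print(
    "\nHomozygotes show one band, the heterozygote two bands differing by"
    "\nexactly the InDel length; this binary matrix is what the diversity"
    "\nstatistics consume."
)
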