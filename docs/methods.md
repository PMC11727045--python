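# Methods

This note documents the models and procedures `indelssr` implements,
the parameter choices that matter, what the synthetic-data generator
does and does not emulate, and the numerical conventions that make
results bit-reproducible.

## SSR detection

A perfect SSR is a maximal tandem repeat of a primitive motif of
length 1–6 bp.  Detection thresholds follow the MISA convention used
throughout plant marker development: at least **10** repeats for
mononucleotide motifs, **5** for dinucleotide, and **4** for tri- to
hexanucleotide motifs.  The tract semantics are defined precisely so an
independent brute-force enumeration can agree exactly:

- for each motif length *L*, a character-maximal period-*L* run is an
  interval where every base equals the base *L* positions earlier,
  extendable in neither direction;
- the reported tract consists of the run's complete motif copies from
  its left end (`end − start = L × n_repeats`); a trailing partial
  period is not counted;
- a tract is reported once, at the smallest qualifying *L* (the motif
  must be primitive — `AAAA…` is mono, never di `AA`); among equal
  phases the leftmost start wins;
- motifs containing N are never emitted, so tracts cannot cross
  assembly gaps.

Two SSRs separated by **< 100 bp** (strict) chain into one *compound*
locus; compound loci count once in all totals as their own repeat
class.  Motif composition pools a motif with its reverse complement but
not with its rotations (AG/CT and GA/TC are distinct classes).

## InDel-SSR loci

InDels are consumed from VCF (any record whose REF/ALT length
difference is ≥ `min_len`, default 1; multi-allelic records stay one
locus).  The anchor is the VCF POS.  An InDel becomes a marker locus
when at least one SSR tract **overlaps** the window anchor ± 500 bp
(overlap, not containment — tracts are detected chromosome-wide first,
so a tract straddling the window edge still qualifies).  One InDel with
several in-window SSRs is one marker; its repeat class comes from the
member nearest the anchor.  Per-chromosome reports give density
(count / length in Mb, printed to 2 decimals) and the InDel→marker
conversion ratio; the genome summary's average density is the
*unweighted* mean of per-chromosome densities, and totals are sums.

## Primer design and screening

Candidates are enumerated exhaustively under the design constraints:
primer length 16–24 nt, product 100–300 bp spanning the anchor
(forward primer ends at or before it, reverse starts after it, so
neither overlaps the variant), Tm 50–60 °C, pair Tm difference ≤ 3 °C.
Tm is the Wallace rule 2(A+T) + 4(G+C) below 14 nt and
64.9 + 41·(GC − 16.4)/L otherwise — a deliberately simple, monotone,
documented formula; full nearest-neighbor thermodynamics (hairpins,
dimers, salt correction) is out of scope because only the constraint
logic depends on Tm.  Ranking is |Tm − 55| summed over the pair, then
|product − 200| bp, then leftmost coordinates; this tie-break order is
an implementation convention, stated for reproducibility.

The product-level screen keeps a marker iff (i) SSR tract bases inside
the product total ≥ 18 bp, (ii) the AT fraction of those tract bases
(motif-weighted) is ≥ 0.5 — the operationalization of "AT-rich", and
(iii) the InDel anchor lies inside the product.  All three thresholds
are parameters.

In-silico PCR maps each individual's genotype to product lengths:
allele *k* amplifies at reference length + (len(alt_k) − len(ref)).
Homozygotes show one band, heterozygotes two; the band matrix rows are
the union of observed lengths per marker, scored 1/0 with NA for
missing genotypes.

## Diversity statistics

Band patterns are read codominantly: one present band = homozygote,
two = heterozygote, zero or more than two = missing (the cohort this
emulates may contain triploids, but the statistics are diploid-style;
this is a documented limitation, not a polyploid model).  Frequencies
are complete-case per marker.  He is the uncorrected 1 − Σp²
(an unbiased 2N/(2N−1) variant is available, off by default), PIC is
the definitional double-sum formula, I is −Σp ln p.

Nei (1972) distance treats each individual as a two-allele-sample
population (homozygote → frequency 1, heterozygote → 0.5/0.5) and
averages J terms over shared loci; pairs with no shared alleles
anywhere (Jxy = 0) are capped at D = 10 with a warning.  A binary Dice
distance on raw band vectors is offered as the NTSYS-style
alternative.  UPGMA uses average linkage with cluster-size weights;
node height is half the merge distance (so the tree is exactly
ultrametric), and ties break on the smallest active-cluster index pair.
PCA imputes NA by band mean, centers, and fixes each component's sign
so its largest-magnitude loading is positive.

Kinship defaults to allele sharing: the mean over markers of the Dice
fraction of shared bands, linearly rescaled so the minimum off-diagonal
is 0 and self-kinship 1.  The Ritland (1996) frequency-weighted
estimator is available as an option.

## Delta-K

`evanno_delta_k` consumes any replicates-by-K table of model
log-likelihoods and computes ΔK(K) = |mean L(K+1) − 2 mean L(K) +
mean L(K−1)| / sd(L(K)) for interior K with positive sd (zero-sd
columns are excluded with a warning); the optimal K is the argmax.
Bayesian admixture inference itself is not implemented.  For running
the statistic on data, `structure_pseudo_lnp` builds a surrogate table:
k-means on imputed band vectors scored by the profile log-likelihood of
an isotropic Gaussian mixture with hard assignments, with replicate
spread from bootstrapping band columns.  On the default synthetic
cohort this selects the true K; it is a surrogate for cluster-number
diagnostics, not a posterior.

## Association models

Traits are analyzed per year, never pooled.  Marker genotypes enter as
band-allele dosage columns (0/1/2), last column dropped for
identifiability.  GLM is OLS with a partial F-test of the marker block
(optionally with Q admixture covariates, one column dropped); R² is the
incremental variance explained by the marker given the covariates.  No
multiple-testing correction is applied by default (the workflow this
reproduces used raw p < 0.05); Benjamini–Hochberg can be applied
downstream on the returned p-values.

MLM fits y = Xβ + u + e with u ~ N(0, σu²K) EMMA-style: one spectral
decomposition of K per trait, REML profile over δ = σe²/σu² by bounded
scalar minimization of the exact REML log-likelihood on
log δ ∈ [ln 10⁻⁵, ln 10⁵].  Per-marker tests use generalized least
squares in the rotated basis with variance components fixed at the
null model (**P3D**); exact per-marker REML is available via
`p3d=False` and agrees with P3D to within an order of magnitude in p
while never flipping significance in our fixtures.  Heritability is
reported as σu²/(σu²+σe²) = 1/(1+δ).  K must be PSD up to a 10⁻⁶
relative tolerance (slightly negative eigenvalues are clipped).
Missing marker dosages are mean-imputed inside the MLM so the per-trait
rotation is reusable; GLM drops incomplete rows instead.  With
K = identity the MLM F-test reduces exactly to the GLM — a test asserts
agreement to 10⁻⁶.

"Stable" markers are those significant (p < α, default 0.05) in at
least `min_models` models (default 2) for a trait/year.  Candidate
genes are those overlapping a **total** 1 Mb window (± 500 kb) around
the marker anchor — the phrase "a 1 Mb region surrounding" is
ambiguous, so ± 1 Mb is available behind a flag — sorted by distance.

## Synthetic data

The generator's defaults are the study conditions the package is
exercised under: **121 individuals** drawn from **3 admixed
subpopulations**, **219 dominant markers** with 2–6 alleles each, two
replicate years, heritability 0.5.

- *Genome*: i.i.d. uniform background with planted repeat tracts whose
  copy numbers cycle through threshold −1, 0, +2 and +8 (so plants sit
  below, at and well above detection, and some tracts exceed the 18 bp
  screening span, as long tracts do in real genomes); motif bases are
  AT-biased (P(A/T) = 0.7) to mirror the AT-rich repeat landscape of
  plant genomes.  Planted tracts get guard bases so they are exactly
  character-maximal, and spontaneous above-threshold repeats in the
  background are broken by point mutation — recall *and* precision
  against the truth tables are therefore exactly measurable.
  Chromosomes are desk-scale (tens of kb); all statistics scale per Mb.
- *InDels*: 1–8 bp insertions/deletions; a configured fraction is
  placed within the flank window of an above-threshold SSR (within
  `near_indel_max_offset` of it), the rest farther than flank + spacing
  from any planted tract.
- *Cohort*: per marker, ancestral allele frequencies ~ Dirichlet(1),
  subpopulation frequencies ~ Dirichlet(ancestral·(1−Fst)/Fst)
  (Balding–Nichols-style, Fst = 0.3), individual admixture
  ~ Dirichlet(α = 0.05, near-hard assignment), genotypes drawn from the
  admixture-mixed frequencies, 2% missing calls.  The truth kinship is
  the realized dosage GRM (PSD by construction, unit mean diagonal).
- *Traits*: latent value = planted marker effects on standardized
  dosage + polygenic term ~ MVN(0, h²·K) shared across years +
  independent yearly noise ~ N(0, 1−h²), affinely mapped to mean 50,
  scale 10 (so CVs are in the realistic ~20% range).  The polygenic
  term is drawn from the GRM **excluding** QTL-hosting markers, so a
  planted variance fraction is realized exactly rather than being
  partially cancelled or double-counted through the kinship
  (`CohortSim.grm_excluding` exposes the same leave-out kinship for
  fitting).
- A single integer seed drives one `numpy.random.Generator`; identical
  configs give byte-identical outputs.

What the generator does **not** emulate: linkage disequilibrium and
recombination maps, triploid genotypes, genotyping artifacts beyond
missingness, gel-mobility noise, or any taro-specific biology.  Tests
passing on this generator demonstrate the correctness and calibration
of the algorithms under the stated statistical model, not performance
on real resequencing data.

## Problem sizes and numerical conventions

Test and validation workloads are sized for a single CPU: oracle
equivalence on 200 random 2 kb sequences; closed-form agreement on 10⁴
random frequency vectors; UPGMA recovery on 50 random ultrametric
trees (n ≤ 12); GLM null calibration on ≥ 2000 marker–trait pairs at
n = 121; heritability recovery over 20 replicates at n = 200; QTL power
over 50 replicates at n = 121 with a biallelic QTL explaining 15% of
variance.  Internal coordinates are 0-based half-open; all emitted
coordinates are 1-based inclusive (VCF/GFF3 dialects).  Distance
symmetry is enforced to 10⁻¹²; PSD clipping and the Nei cap are the
only places values are adjusted, and both log a warning.

## Known limitations

- The banding model ignores co-migrating products from off-target
  priming; screened primers are not checked for genome-wide uniqueness.
- The codominant reading discards >2-band patterns instead of modeling
  polyploidy.
- P3D shares variance components across markers; for markers with very
  large effects the exact mode is preferable.
- The pseudo-likelihood ΔK surrogate is a diagnostic for cluster
  number on well-separated groups; it is not a replacement for Bayesian
  admixture posteriors.
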