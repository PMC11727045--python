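"""Synthetic inputs with known ground truth.

Generates everything the pipeline consumes, at desk scale but with the
study's statistical shape: genomes with planted SSR tracts and InDels
(a controlled fraction within SSR flanking distance), a three-
subpopulation admixed cohort of 121 individuals scored at 219
multi-allelic markers, and normally distributed two-year trait tables
with planted marker effects on top of a polygenic background.

Ground-truth bookkeeping is strict: every planted feature appears in
exactly one truth-table row, planted tracts are guarded so they cannot
extend at character level, and spontaneous above-threshold repeats in
the random background are broken by point mutation — so discovery
recall and precision against the truth tables are exactly measurable.
A single integer seed drives one ``numpy.random.Generator``; identical
configs give identical outputs, byte for byte.

The cohort model is Dirichlet admixture over Balding-Nichols
subpopulation allele frequencies with binomial genotype sampling — the
minimal model exhibiting the Q/K structure the association models
assume; it is a stand-in, not a claim about taro.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .band_matrix import BandMatrix
from .diversity import KinshipMatrix
from .io_formats import GenomeSequence, IndelLocus
from .ssr_discovery import DEFAULT_MIN_REPEATS

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_TRAITS = (
    "leaf_area", "leaf_length", "leaf_width", "leaf_shape_index",
    "posterior_segment_length", "cormel_number", "avg_cormel_weight",
    "cormel_diameter", "cormel_length", "cormel_shape_index",
)


@dataclass(frozen=True)
class PlantedQTL:
    marker_id: str
    trait: str
    effect_sd: float  # effect per standardized allele dosage, in trait sd units


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generator.

    Cohort defaults mirror the study design this package emulates: 121
    individuals drawn from 3 admixed subpopulations, 219 multi-allelic
    dominant markers (2-6 alleles), two replicate years.  Genome
    defaults are desk-scale chromosomes with planted features straddling
    the detection thresholds.
    """

    seed: int = 0
    # genome
    n_chromosomes: int = 2
    chrom_len: int = 50_000
    n_planted_ssrs_by_motif_len: dict[int, int] = field(
        default_factory=lambda: {1: 4, 2: 4, 3: 4, 4: 3, 5: 3, 6: 3}
    )
    plant_repeat_offsets: tuple[int, ...] = (-1, 0, 2, 8)  # relative to threshold
    motif_at_bias: float = 0.7  # P(A or T) per motif base; plant genomes are AT-rich
    n_indels_per_chromosome: int = 20
    frac_indels_near_ssr: float = 0.5
    near_indel_max_offset: int | None = None  # bp from host SSR; None = flank_size
    min_feature_spacing: int = 120
    indel_max_len: int = 8
    flank_size: int = 500
    # cohort
    n_individuals: int = 121
    n_subpops: int = 3
    admixture_alpha: float = 0.05
    fst: float = 0.3
    n_markers: int = 219
    min_alleles: int = 2
    max_alleles: int = 6
    missing_rate: float = 0.02
    # traits
    trait_names: tuple[str, ...] = DEFAULT_TRAITS
    years: tuple[int, ...] = (2021, 2022)
    planted_qtl: tuple[PlantedQTL, ...] = ()
    h2_polygenic: float = 0.5
    trait_mean: float = 50.0
    trait_scale: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2_polygenic <= 1.0:
            raise ValueError("h2_polygenic must be in [0, 1]")
        if not 0.0 <= self.frac_indels_near_ssr <= 1.0:
            raise ValueError("frac_indels_near_ssr must be in [0, 1]")
        if min(self.n_planted_ssrs_by_motif_len.values(), default=0) < 0:
            raise ValueError("planted SSR counts must be >= 0")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class GenomeSim:
    genome: list[GenomeSequence]
    truth_ssrs: pd.DataFrame    # chrom, start, motif, motif_len, n_repeats, above_threshold
    truth_indels: pd.DataFrame  # chrom, pos(1-based), ref, alt, near_ssr
    indels: list[IndelLocus]


@dataclass
class CohortSim:
    band_matrix: BandMatrix
    q_truth: pd.DataFrame            # individuals x subpops, rows sum to 1
    kinship_truth: KinshipMatrix     # realized dosage GRM (PSD)
    genotypes: dict[str, dict[str, tuple[int, int] | None]]  # marker -> ind -> allele idx pair
    subpop_freqs: dict[str, np.ndarray]  # marker -> (n_subpops, n_alleles)
    dosage: pd.DataFrame             # individuals x "marker:allele" dosage columns

    def grm_excluding(self, marker_ids: tuple[str, ...] | list[str]) -> KinshipMatrix:
        """Dosage GRM leaving out the given markers' columns (the
        leave-out kinship used around candidate loci so a planted
        marker effect is not also part of the polygenic covariance)."""
        drop = set(marker_ids)
        cols = [c for c in self.dosage.columns if c.split(":")[0] not in drop]
        if not cols:
            raise ValueError("cannot exclude every marker from the GRM")
        return _dosage_grm(self.dosage[cols], tuple(self.dosage.index))


def effect_for_variance_fraction(v: float) -> float:
    """Effect size (sd units, standardized dosage) explaining fraction v
    of trait variance when the rest of the trait has unit variance."""
    if not 0 <= v < 1:
        raise ValueError("variance fraction must be in [0, 1)")
    return float(np.sqrt(v / (1.0 - v)))


# --------------------------------------------------------------------------
# genome simulation
# --------------------------------------------------------------------------

def _random_primitive_motif(rng: np.random.Generator, L: int, at_bias: float = 0.5) -> str:
    p = np.array([at_bias / 2, (1 - at_bias) / 2, (1 - at_bias) / 2, at_bias / 2])
    while True:
        m = "".join("ACGT"[i] for i in rng.choice(4, size=L, p=p))
        ok = all(
            not (L % d == 0 and m == m[:d] * (L // d)) for d in range(1, L)
        )
        if ok:
            return m


def _free_position(
    rng: np.random.Generator, occupied: list[tuple[int, int]],
    length: int, chrom_len: int, spacing: int,
    lo: int = 0, hi: int | None = None,
) -> int:
    hi = chrom_len if hi is None else hi
    for _ in range(2000):
        pos = int(rng.integers(max(1, lo), max(2, hi - length - 1)))
        if all(pos - spacing >= e or pos + length + spacing <= s for s, e in occupied):
            return pos
    raise ValueError("overcrowded config: could not place a feature")


def _guard(arr: np.ndarray, idx: int, forbidden: int) -> None:
    """Set arr[idx] to a base different from `forbidden`."""
    if 0 <= idx < arr.size and arr[idx] == forbidden:
        choices = BASES[BASES != forbidden]
        arr[idx] = choices[idx % 3]


def _break_spontaneous_repeats(
    arr: np.ndarray, protected: list[tuple[int, int]], rng: np.random.Generator
) -> None:
    """Point-mutate the background until no unplanted tract reaches its
    detection threshold (planted intervals, with guards, untouched)."""
    prot = sorted(protected)

    def overlaps_protected(s: int, e: int) -> bool:
        return any(s < pe + 2 and e > ps - 2 for ps, pe in prot)

    for _ in range(20):
        dirty = False
        for L, thr in DEFAULT_MIN_REPEATS.items():
            match = arr[L:] == arr[:-L]
            padded = np.concatenate(([False], match, [False]))
            diff = np.diff(padded.astype(np.int8))
            for a, b in zip(np.nonzero(diff == 1)[0], np.nonzero(diff == -1)[0]):
                tract_len = (b - a) + L
                if tract_len // L < thr:
                    continue
                if overlaps_protected(int(a), int(a + tract_len)):
                    continue
                mid = int(a + tract_len // 2)
                old = arr[mid]
                arr[mid] = BASES[(int(np.where(BASES == old)[0][0]) + 1 + int(rng.integers(0, 3))) % 4]
                dirty = True
        if not dirty:
            return
    raise RuntimeError("could not sanitize background repeats")


def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None) -> GenomeSim:
    """Random genome with planted SSR tracts and InDels.

    Planted repeat counts cycle through threshold + ``plant_repeat_offsets``
    so some tracts fall just below, at, and above the detection
    threshold.  A ``frac_indels_near_ssr`` fraction of InDels is placed
    within the flank window of an above-threshold planted SSR; the rest
    are placed farther than flank + spacing from any planted tract.
    """
    rng = rng or np.random.default_rng(config.seed)
    genome: list[GenomeSequence] = []
    ssr_rows, indel_rows = [], []
    indels: list[IndelLocus] = []
    for ci in range(config.n_chromosomes):
        chrom = f"Chr{ci + 1}"
        arr = rng.choice(BASES, size=config.chrom_len)
        occupied: list[tuple[int, int]] = []
        planted: list[dict] = []
        offset_cycle = 0
        for L in sorted(config.n_planted_ssrs_by_motif_len):
            thr = DEFAULT_MIN_REPEATS[L]
            for _ in range(config.n_planted_ssrs_by_motif_len[L]):
                n_rep = thr + config.plant_repeat_offsets[
                    offset_cycle % len(config.plant_repeat_offsets)
                ]
                offset_cycle += 1
                motif = _random_primitive_motif(rng, L, config.motif_at_bias)
                tract = np.frombuffer((motif * n_rep).encode(), dtype=np.uint8)
                pos = _free_position(
                    rng, occupied, tract.size, config.chrom_len, config.min_feature_spacing
                )
                arr[pos : pos + tract.size] = tract
                # guards: the tract must be character-maximal on both sides
                _guard(arr, pos - 1, tract[L - 1] if L <= tract.size else tract[-1])
                _guard(arr, pos + tract.size, tract[0])
                occupied.append((pos, pos + tract.size))
                planted.append(
                    {
                        "chrom": chrom, "start": pos, "end": pos + tract.size,
                        "motif": motif, "motif_len": L, "n_repeats": n_rep,
                        "above_threshold": n_rep >= thr,
                    }
                )
        # sanitize the background before InDel REF alleles are read off it
        _break_spontaneous_repeats(arr, [(p["start"], p["end"]) for p in planted], rng)
        above = [p for p in planted if p["above_threshold"]]
        n_near = round(config.frac_indels_near_ssr * config.n_indels_per_chromosome)
        for k in range(config.n_indels_per_chromosome):
            near = k < n_near and above
            ilen = int(rng.integers(1, config.indel_max_len + 1))
            if near:
                host = above[k % len(above)]
                offset = config.near_indel_max_offset or config.flank_size
                lo = max(1, host["end"] + 5)
                hi = min(config.chrom_len - ilen - 2, host["start"] + offset - 5)
                pos0 = _free_position(rng, occupied, ilen + 1, config.chrom_len, 4, lo=lo, hi=hi)
            else:
                for _ in range(2000):
                    pos0 = _free_position(
                        rng, occupied, ilen + 1, config.chrom_len, 4
                    )
                    far = all(
                        pos0 + config.flank_size + config.min_feature_spacing < p["start"]
                        or pos0 - config.flank_size - config.min_feature_spacing > p["end"]
                        for p in planted
                    )
                    if far:
                        break
                else:
                    raise ValueError("overcrowded config: no InDel site far from SSRs")
            occupied.append((pos0, pos0 + ilen + 1))
            if rng.random() < 0.5:  # deletion relative to reference
                ref = "".join(chr(c) for c in arr[pos0 : pos0 + ilen + 1])
                alt = ref[0]
            else:  # insertion
                ref = chr(arr[pos0])
                alt = ref + "".join("ACGT"[i] for i in rng.integers(0, 4, size=ilen))
            indel_rows.append(
                {"chrom": chrom, "pos": pos0 + 1, "ref": ref, "alt": alt,
                 "near_ssr": bool(near)}
            )
            indels.append(
                IndelLocus(chrom_id=chrom, pos=pos0 + 1, ref_allele=ref, alt_alleles=[alt])
            )
        ssr_rows.extend(planted)
        genome.append(GenomeSequence(chrom_id=chrom, sequence=arr.tobytes().decode("ascii")))
    return GenomeSim(
        genome=genome,
        truth_ssrs=pd.DataFrame(ssr_rows),
        truth_indels=pd.DataFrame(indel_rows),
        indels=indels,
    )


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

def _dosage_grm(dosage: pd.DataFrame, ids: tuple[str, ...]) -> KinshipMatrix:
    """Realized dosage GRM (PSD by construction), unit mean diagonal."""
    X = dosage.to_numpy(dtype=float)
    col_mean = np.nanmean(X, axis=0)
    Xc = np.where(np.isnan(X), 0.0, X - col_mean)
    G = Xc @ Xc.T
    G /= np.mean(np.diag(G))
    return KinshipMatrix(ids=ids, values=G, estimator="dosage_grm_truth")


def simulate_cohort(config: SimConfig, rng: np.random.Generator | None = None) -> CohortSim:
    """Three-subpopulation admixed cohort scored at multi-allelic markers.

    Per marker: ancestral allele frequencies ~ Dirichlet(1), subpop
    frequencies ~ Dirichlet(ancestral x (1 - Fst)/Fst) (Balding-Nichols
    style), individual admixture ~ Dirichlet(admixture_alpha), and two
    allele draws from the individual's mixed frequencies.  Bands follow
    the codominant model (one band per carried allele); a configurable
    fraction of genotype calls is set missing.
    """
    rng = rng or np.random.default_rng(config.seed)
    n, s = config.n_individuals, config.n_subpops
    individuals = [f"T{i + 1}" for i in range(n)]
    q = rng.dirichlet(np.full(s, config.admixture_alpha), size=n)
    q_df = pd.DataFrame(q, index=individuals, columns=[f"pop{j + 1}" for j in range(s)])

    genotypes: dict[str, dict[str, tuple[int, int] | None]] = {}
    subpop_freqs: dict[str, np.ndarray] = {}
    index, rows = [], []
    dosage_cols: dict[str, np.ndarray] = {}
    scale = (1.0 - config.fst) / config.fst
    for mi in range(config.n_markers):
        marker = f"m{mi + 1:03d}"
        k = int(rng.integers(config.min_alleles, config.max_alleles + 1))
        ancestral = rng.dirichlet(np.ones(k))
        pf = np.vstack([rng.dirichlet(np.maximum(ancestral * scale, 1e-3)) for _ in range(s)])
        subpop_freqs[marker] = pf
        ind_freq = q @ pf  # n x k
        draws = np.empty((n, 2), dtype=int)
        for i in range(n):
            draws[i] = rng.choice(k, size=2, p=ind_freq[i])
        miss = rng.random(n) < config.missing_rate
        per_ind: dict[str, tuple[int, int] | None] = {}
        for i, ind in enumerate(individuals):
            per_ind[ind] = None if miss[i] else (int(draws[i, 0]), int(draws[i, 1]))
        genotypes[marker] = per_ind
        observed = sorted(
            {a for gt in per_ind.values() if gt is not None for a in gt}
        )
        for a in observed:
            index.append((marker, f"a{a + 1}"))
            row = np.full(n, np.nan)
            for i, ind in enumerate(individuals):
                gt = per_ind[ind]
                if gt is not None:
                    row[i] = 1.0 if a in gt else 0.0
            rows.append(row)
            dose = np.full(n, np.nan)
            for i, ind in enumerate(individuals):
                gt = per_ind[ind]
                if gt is not None:
                    dose[i] = float(gt.count(a))
            dosage_cols[f"{marker}:a{a + 1}"] = dose
    scores = pd.DataFrame(
        np.array(rows),
        index=pd.MultiIndex.from_tuples(index, names=["marker_id", "band_id"]),
        columns=individuals, dtype=float,
    )
    matrix = BandMatrix(scores=scores, _marker_order=sorted(genotypes))
    dosage = pd.DataFrame(dosage_cols, index=individuals)

    kin = _dosage_grm(dosage, tuple(individuals))
    return CohortSim(
        band_matrix=matrix, q_truth=q_df, kinship_truth=kin,
        genotypes=genotypes, subpop_freqs=subpop_freqs, dosage=dosage,
    )


# --------------------------------------------------------------------------
# trait simulation
# --------------------------------------------------------------------------

def simulate_traits(
    config: SimConfig,
    cohort: CohortSim,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Two-year trait table: planted marker effects + polygenic value +
    independent yearly noise.

    Each trait's latent value is  sum_qtl beta * z  +  g  +  e_year,
    with z the standardized dosage of the QTL marker's first allele,
    g ~ MVN(0, h2 K) shared across years, and e_year ~ N(0, 1 - h2)
    drawn independently per year; the result is affinely mapped to
    ``trait_mean`` +/- ``trait_scale``.

    K is the cohort GRM with the QTL-hosting markers left out, so the
    planted effects and the polygenic background are orthogonal in
    expectation and a planted variance fraction is realized exactly.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    h2 = config.h2_polygenic
    individuals = list(cohort.q_truth.index)
    n = len(individuals)
    qtl_markers = {q.marker_id for q in config.planted_qtl}
    if qtl_markers:
        K = cohort.grm_excluding(tuple(qtl_markers)).values
    else:
        K = cohort.kinship_truth.values
    # symmetric PSD square root via eigendecomposition
    d, U = np.linalg.eigh(K)
    root = U @ np.diag(np.sqrt(np.clip(d, 0, None))) @ U.T
    qtl_by_trait: dict[str, list[PlantedQTL]] = {}
    for qtl in config.planted_qtl:
        qtl_by_trait.setdefault(qtl.trait, []).append(qtl)
    rows = []
    for trait in config.trait_names:
        g = root @ rng.standard_normal(n) * np.sqrt(h2)
        base = g.copy()
        for qtl in qtl_by_trait.get(trait, ()):
            first_col = next(
                c for c in cohort.dosage.columns if c.startswith(f"{qtl.marker_id}:")
            )
            z = cohort.dosage[first_col].to_numpy(dtype=float)
            z = np.where(np.isnan(z), np.nanmean(z), z)
            sd = z.std()
            if sd == 0:
                raise ValueError(f"QTL marker {qtl.marker_id} has no dosage variation")
            base = base + qtl.effect_sd * (z - z.mean()) / sd
        for year in config.years:
            e = rng.standard_normal(n) * np.sqrt(max(0.0, 1.0 - h2))
            vals = config.trait_mean + config.trait_scale * (base + e)
            for ind, v in zip(individuals, vals):
                rows.append(
                    {"individual_id": ind, "trait": trait, "year": year, "value": v}
                )
    return pd.DataFrame(rows, columns=["individual_id", "trait", "year", "value"])


# --------------------------------------------------------------------------
# file emission
# --------------------------------------------------------------------------

def write_fasta(genome: list[GenomeSequence], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    recs = [SeqRecord(Seq(g.sequence), id=g.chrom_id, description="") for g in genome]
    SeqIO.write(recs, str(path), "fasta")


def write_vcf(
    indels: list[IndelLocus],
    genome: list[GenomeSequence],
    path: str | Path,
    sample_genotypes: dict[str, dict[str, tuple[int, int] | None]] | None = None,
) -> None:
    """Write InDel records as an uncompressed VCF (optionally with GTs).

    ``sample_genotypes`` maps a key ``"chrom:pos"`` to per-sample allele
    index pairs; records without an entry get ./. for every sample.
    """
    import pysam

    header = pysam.VariantHeader()
    for g in genome:
        header.contigs.add(g.chrom_id, length=g.length)
    header.formats.add("GT", 1, "String", "Genotype")
    samples: list[str] = []
    if sample_genotypes:
        seen: dict[str, None] = {}
        for per_ind in sample_genotypes.values():
            for ind in per_ind:
                seen.setdefault(ind, None)
        samples = list(seen)
        for s in samples:
            header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for ind_locus in sorted(indels, key=lambda x: (x.chrom_id, x.pos)):
            rec = out.new_record(
                contig=ind_locus.chrom_id, start=ind_locus.pos - 1,
                alleles=[ind_locus.ref_allele, *ind_locus.alt_alleles],
            )
            if samples:
                key = f"{ind_locus.chrom_id}:{ind_locus.pos}"
                per_ind = (sample_genotypes or {}).get(key, {})
                for s in samples:
                    gt = per_ind.get(s)
                    rec.samples[s]["GT"] = gt if gt is not None else (None, None)
            out.write(rec)


@dataclass
class StudySim:
    genome_sim: GenomeSim
    cohort: CohortSim
    traits: pd.DataFrame
    marker_indels: dict[str, IndelLocus]  # cohort marker id -> genome InDel


def simulate_study(config: SimConfig, rng: np.random.Generator | None = None) -> StudySim:
    """Genome + cohort + traits wired together.

    Cohort markers are mapped onto InDels planted near SSRs (cycling if
    there are fewer such InDels than markers); each marker's alleles
    become length variants of its InDel so that in-silico PCR on the
    emitted VCF reproduces the cohort's band structure.
    """
    rng = rng or np.random.default_rng(config.seed)
    gsim = simulate_genome(config, rng)
    cohort = simulate_cohort(config, rng)
    traits = simulate_traits(config, cohort, rng)
    near = [
        ind for ind, row in zip(gsim.indels, gsim.truth_indels.itertuples())
        if row.near_ssr
    ]
    if not near:
        raise ValueError("no InDel near a planted SSR to host cohort markers")
    marker_indels: dict[str, IndelLocus] = {}
    used: set[int] = set()
    for mi, marker in enumerate(sorted(cohort.genotypes)):
        host = near[mi % len(near)]
        if id(host) in used:
            continue  # more markers than hosts: extra markers stay band-only
        used.add(id(host))
        k = cohort.subpop_freqs[marker].shape[1]
        base = host.ref_allele[0]
        # allele j has a distinct length: ref plus j extra inserted bases
        alts = [
            base + "".join("ACGT"[i] for i in rng.integers(0, 4, size=j))
            for j in range(1, k)
        ]
        host.alt_alleles = alts if alts else host.alt_alleles
        host.per_sample_genotypes = cohort.genotypes[marker]
        marker_indels[marker] = host
    # keep the truth table's alleles consistent with the rewritten hosts
    gsim.truth_indels = gsim.truth_indels.assign(
        ref=[x.ref_allele for x in gsim.indels],
        alt=[",".join(x.alt_alleles) for x in gsim.indels],
    )
    return StudySim(genome_sim=gsim, cohort=cohort, traits=traits, marker_indels=marker_indels)


def write_study(study: StudySim, outdir: str | Path, config: SimConfig) -> dict[str, Path]:
    """Emit FASTA, VCF, band matrix, traits, Q and truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fa",
        "vcf": outdir / "indels.vcf",
        "bands": outdir / "bands.tsv",
        "traits": outdir / "traits.tsv",
        "q": outdir / "q.tsv",
        "truth_ssrs": outdir / "truth_ssrs.tsv",
        "truth_indels": outdir / "truth_indels.tsv",
    }
    write_fasta(study.genome_sim.genome, paths["fasta"])
    gt_by_key = {
        f"{ind.chrom_id}:{ind.pos}": ind.per_sample_genotypes
        for ind in study.marker_indels.values()
        if ind.per_sample_genotypes is not None
    }
    write_vcf(study.genome_sim.indels, study.genome_sim.genome, paths["vcf"], gt_by_key)
    study.cohort.band_matrix.to_tsv(paths["bands"])
    study.traits.to_csv(paths["traits"], sep="\t", index=False, na_rep="NA")
    study.cohort.q_truth.to_csv(paths["q"], sep="\t", na_rep="NA", index_label="individual_id")
    study.genome_sim.truth_ssrs.to_csv(paths["truth_ssrs"], sep="\t", index=False)
    study.genome_sim.truth_indels.to_csv(paths["truth_indels"], sep="\t", index=False)
    return paths
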