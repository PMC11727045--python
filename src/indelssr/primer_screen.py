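"""Primer candidate enumeration, marker screening and in-silico PCR.

Candidate primer pairs around an InDel-SSR locus are enumerated
exhaustively under the design constraints (length 16-24 nt, product
100-300 bp spanning the InDel anchor, Tm 50-60 C, pair Tm difference
<= 3 C) and ranked by closeness to the 55 C optimum and the 200 bp
product midpoint.  Screening keeps a marker only if its predicted
product contains >= 18 bp of SSR tract, those tracts are AT-rich, and
the product spans the InDel.  In-silico PCR turns per-sample InDel
genotypes into electrophoretic band lengths (ref product length shifted
by each allele's length difference) and assembles the binary band
matrix the diversity statistics consume.

The melting temperature is the Wallace rule 2(A+T) + 4(G+C) for primers
shorter than 14 nt and the GC-fraction formula 64.9 + 41 x (GC - 16.4/L)
otherwise; both are monotone in GC content at fixed length, which is all
the constraint logic relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import at_fraction, revcomp
from .band_matrix import BandMatrix
from .io_formats import GenomeSequence, IndelLocus
from .ssr_discovery import InDelSSRLocus, SSRLocus


@dataclass(frozen=True)
class PrimerConstraints:
    """Design window for candidate enumeration."""

    min_len: int = 16
    max_len: int = 24
    min_product: int = 100
    max_product: int = 300
    tm_min: float = 50.0
    tm_max: float = 60.0
    tm_opt: float = 55.0
    max_tm_diff: float = 3.0
    product_opt: int = 200
    top_k: int = 3


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair and its reference product."""

    marker_id: str
    fwd_seq: str
    rev_seq: str
    fwd_start: int  # 0-based genomic start of the forward primer
    rev_end: int    # 0-based exclusive genomic end of the reverse primer site
    tm_fwd: float
    tm_rev: float

    @property
    def product_len_ref(self) -> int:
        return self.rev_end - self.fwd_start

    @property
    def product_interval(self) -> tuple[int, int]:
        return (self.fwd_start, self.rev_end)


@dataclass(frozen=True)
class ScreenCriteria:
    """Marker-level screening thresholds."""

    min_repeat_span: int = 18
    min_at_fraction: float = 0.5
    require_indel_in_product: bool = True

    def __post_init__(self) -> None:
        if self.min_repeat_span < 0 or not 0 <= self.min_at_fraction <= 1:
            raise ValueError("invalid screen criteria")


@dataclass(frozen=True)
class ScreenResult:
    passed: bool
    reasons: tuple[str, ...]
    repeat_span: int
    at_frac: float


@dataclass(frozen=True)
class BandPrediction:
    marker_id: str
    individual_id: str
    band_lengths: tuple[int, ...]  # empty => missing genotype


def melting_temperature(seq: str) -> float:
    """Deterministic primer Tm in degrees C (see module docstring)."""
    if not seq:
        raise ValueError("empty primer sequence")
    if "N" in seq:
        raise ValueError("primer contains N")
    n_gc = seq.count("G") + seq.count("C")
    L = len(seq)
    if L < 14:
        return 2.0 * (L - n_gc) + 4.0 * n_gc
    return 64.9 + 41.0 * (n_gc - 16.4) / L


def _candidate_windows(
    seq_codes: np.ndarray, lo: int, hi: int, c: PrimerConstraints
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All (start, length, Tm) windows within [lo, hi) passing the Tm
    band and containing no N, vectorized over prefix sums."""
    is_gc = (seq_codes == ord("G")) | (seq_codes == ord("C"))
    is_n = seq_codes == ord("N")
    cum_gc = np.concatenate(([0], np.cumsum(is_gc)))
    cum_n = np.concatenate(([0], np.cumsum(is_n)))
    starts_all, lens_all, tms_all = [], [], []
    for L in range(c.min_len, c.max_len + 1):
        starts = np.arange(lo, hi - L + 1)
        if starts.size == 0:
            continue
        gc = cum_gc[starts + L] - cum_gc[starts]
        nn = cum_n[starts + L] - cum_n[starts]
        tm = 64.9 + 41.0 * (gc - 16.4) / L if L >= 14 else 2.0 * L + 2.0 * gc
        ok = (nn == 0) & (tm >= c.tm_min) & (tm <= c.tm_max)
        starts_all.append(starts[ok])
        lens_all.append(np.full(ok.sum(), L))
        tms_all.append(tm[ok])
    if not starts_all:
        return np.array([], int), np.array([], int), np.array([], float)
    return (
        np.concatenate(starts_all),
        np.concatenate(lens_all),
        np.concatenate(tms_all),
    )


def design_candidates(
    locus: InDelSSRLocus,
    genome: list[GenomeSequence] | dict[str, GenomeSequence],
    constraints: PrimerConstraints | None = None,
    marker_id: str | None = None,
) -> list[PrimerPair]:
    """Enumerate and rank primer pairs whose product spans the anchor.

    The forward primer ends at or before the anchor and the reverse
    primer starts after it, so neither overlaps the variant.  Pairs are
    ranked by |Tm - 55| summed over the pair, then |product - 200|, then
    leftmost forward start, then leftmost reverse end; the top-k
    (default 3) are returned.  An empty list means no feasible pair.
    """
    c = constraints or PrimerConstraints()
    by_chrom = {g.chrom_id: g for g in genome} if not isinstance(genome, dict) else genome
    g = by_chrom[locus.chrom_id]
    anchor = locus.anchor0
    marker_id = marker_id or f"{locus.chrom_id}:{locus.indel.pos}"
    codes = np.frombuffer(g.sequence.encode("ascii"), dtype=np.uint8)

    f_lo = max(0, anchor - c.max_product + 1)
    fs, flen, ftm = _candidate_windows(codes, f_lo, anchor + 1, c)
    keep_f = fs + flen <= anchor + 1  # forward primer ends at/before the anchor
    fs, flen, ftm = fs[keep_f], flen[keep_f], ftm[keep_f]
    r_hi = min(g.length, anchor + c.max_product)
    rs, rlen, rtm = _candidate_windows(codes, anchor + 1, r_hi, c)
    if fs.size == 0 or rs.size == 0:
        return []
    re_ = rs + rlen  # exclusive product end

    prod = re_[None, :] - fs[:, None]
    ok = (
        (prod >= c.min_product)
        & (prod <= c.max_product)
        & (np.abs(ftm[:, None] - rtm[None, :]) <= c.max_tm_diff)
    )
    fi, ri = np.nonzero(ok)
    if fi.size == 0:
        return []
    cost_tm = np.abs(ftm[fi] - c.tm_opt) + np.abs(rtm[ri] - c.tm_opt)
    cost_prod = np.abs(prod[fi, ri] - c.product_opt)
    order = np.lexsort((re_[ri], fs[fi], cost_prod, cost_tm))[: c.top_k]
    pairs = []
    for idx in order:
        i, j = fi[idx], ri[idx]
        f0, fL = int(fs[i]), int(flen[i])
        r0, rL = int(rs[j]), int(rlen[j])
        pairs.append(
            PrimerPair(
                marker_id=marker_id,
                fwd_seq=g.sequence[f0 : f0 + fL],
                rev_seq=revcomp(g.sequence[r0 : r0 + rL]),
                fwd_start=f0, rev_end=r0 + rL,
                tm_fwd=float(ftm[i]), tm_rev=float(rtm[j]),
            )
        )
    return pairs


def _perfect_members(ssr: SSRLocus):
    return ssr.members if ssr.kind == "compound" else (ssr,)


def screen_marker(
    pair: PrimerPair, locus: InDelSSRLocus, criteria: ScreenCriteria | None = None
) -> ScreenResult:
    """Product-level marker screen.

    Pass iff the SSR tract bases inside the product total >= the minimum
    repeat span, the AT fraction of those tract bases (motif-weighted)
    meets the threshold, and the anchor lies inside the product.
    """
    criteria = criteria or ScreenCriteria()
    p_lo, p_hi = pair.product_interval
    span = 0
    at_bp = 0.0
    for ssr in locus.ssrs:
        for m in _perfect_members(ssr):
            ov = min(m.end, p_hi) - max(m.start, p_lo)
            if ov > 0:
                span += ov
                at_bp += ov * at_fraction(m.motif)
    at_frac = at_bp / span if span else 0.0
    reasons = []
    if span < criteria.min_repeat_span:
        reasons.append(f"repeat span {span} bp < {criteria.min_repeat_span} bp")
    if span and at_frac < criteria.min_at_fraction:
        reasons.append(f"AT fraction {at_frac:.2f} < {criteria.min_at_fraction:.2f}")
    if criteria.require_indel_in_product and not (p_lo <= locus.anchor0 < p_hi):
        reasons.append("InDel anchor outside product")
    return ScreenResult(
        passed=not reasons, reasons=tuple(reasons), repeat_span=span, at_frac=at_frac
    )


def in_silico_pcr(
    pair: PrimerPair,
    indel: IndelLocus,
    genotypes: dict[str, tuple[int | None, int | None]] | None = None,
) -> list[BandPrediction]:
    """Predict band lengths per individual from InDel genotypes.

    Allele 0 amplifies at the reference product length; alt allele k at
    ref length + (len(alt_k) - len(ref)).  A homozygote shows one band,
    a heterozygote two; a missing genotype yields an empty prediction.
    """
    genotypes = genotypes if genotypes is not None else indel.per_sample_genotypes
    if genotypes is None:
        raise ValueError(f"no genotypes available for {pair.marker_id}")
    ref_len = pair.product_len_ref
    allele_len = [ref_len] + [
        ref_len + (len(a) - len(indel.ref_allele)) for a in indel.alt_alleles
    ]
    out = []
    for ind, gt in genotypes.items():
        if gt is None or gt[0] is None or gt[1] is None:
            bands: tuple[int, ...] = ()
        else:
            bands = tuple(sorted({allele_len[gt[0]], allele_len[gt[1]]}))
        out.append(BandPrediction(pair.marker_id, ind, bands))
    return out


def band_matrix_from_predictions(predictions: list[BandPrediction]) -> BandMatrix:
    """Assemble the binary band matrix from per-marker predictions.

    Band rows are the union of observed lengths per marker (id
    ``b<length>``); individuals with an empty prediction are NA for that
    marker's bands.
    """
    if not predictions:
        raise ValueError("no band predictions")
    individuals = list(dict.fromkeys(p.individual_id for p in predictions))
    markers = list(dict.fromkeys(p.marker_id for p in predictions))
    by_marker: dict[str, list[BandPrediction]] = {m: [] for m in markers}
    for p in predictions:
        by_marker[p.marker_id].append(p)
    index = []
    rows = []
    for m in markers:
        lengths = sorted({b for p in by_marker[m] for b in p.band_lengths})
        present = {p.individual_id: set(p.band_lengths) for p in by_marker[m]}
        for length in lengths:
            index.append((m, f"b{length}"))
            row = []
            for ind in individuals:
                bands = present.get(ind)
                if bands is None or not bands:
                    row.append(np.nan)
                else:
                    row.append(1.0 if length in bands else 0.0)
            rows.append(row)
    scores = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["marker_id", "band_id"]),
        columns=individuals, dtype=float,
    )
    return BandMatrix(scores=scores, _marker_order=markers)
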