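"""MISA-style SSR detection and InDel/SSR co-localization.

A perfect SSR is a maximal tandem repeat of a primitive 1-6 bp motif
meeting a per-motif-length minimum repeat count (defaults: mono >= 10,
di >= 5, tri/tetra/penta/hexa >= 4).  Two SSRs separated by fewer than
100 bp form a compound locus.  An InDel-SSR locus is an InDel with at
least one SSR tract overlapping the +/-500 bp window around its anchor:
the composite marker unit whose PCR product shifts with the InDel while
the SSR supplies multi-allelic length variation.

Repeat-tract semantics
----------------------
For each motif length L, a character-maximal period-L run is an interval
in which every base equals the base L positions before it, extendable
neither left nor right.  The reported tract is the run's complete motif
copies from its left end (so ``end - start == L * n_repeats``), the motif
is the first L bases, and a tract is reported only at the smallest L at
which it qualifies (the motif must not itself be periodic: ``AAAA...`` is
mono, never di ``AA``).  Motifs containing N are never emitted, so tracts
cannot cross N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import canonical_motif_class
from .io_formats import GenomeSequence, IndelLocus

REPEAT_CLASS_BY_MOTIF_LEN = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}
REPEAT_CLASSES = ["mono", "di", "tri", "tetra", "penta", "hexa", "compound"]

DEFAULT_MIN_REPEATS = {1: 10, 2: 5, 3: 4, 4: 4, 5: 4, 6: 4}


@dataclass(frozen=True)
class SSRSearchParams:
    """Thresholds for SSR detection and locus assembly.

    min_repeats_by_motif_len maps motif length (1-6) to the minimum
    number of complete repeats; compound_max_gap is the strict upper
    bound (bp) on the spacer between compound members; flank_size is the
    half-width (bp) of the window searched around each InDel anchor.
    """

    min_repeats_by_motif_len: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )
    compound_max_gap: int = 100
    flank_size: int = 500

    def __post_init__(self) -> None:
        if set(self.min_repeats_by_motif_len) != {1, 2, 3, 4, 5, 6}:
            raise ValueError("min_repeats_by_motif_len must cover motif lengths 1..6")
        if any(v < 2 for v in self.min_repeats_by_motif_len.values()):
            raise ValueError("repeat-count thresholds must be >= 2")
        if self.compound_max_gap < 0 or self.flank_size < 0:
            raise ValueError("compound_max_gap and flank_size must be >= 0")


@dataclass(frozen=True)
class SSRLocus:
    """A perfect or compound repeat tract (0-based half-open span)."""

    chrom_id: str
    start: int
    end: int
    motif: str
    motif_len: int
    n_repeats: int
    kind: str  # "perfect" | "compound"
    members: tuple["SSRLocus", ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "perfect" and self.end - self.start != self.motif_len * self.n_repeats:
            raise ValueError(f"perfect SSR span != motif_len * n_repeats: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def distance_to(self, pos0: int) -> int:
        """Distance (bp) from a point to this tract; 0 if the point is inside."""
        if pos0 < self.start:
            return self.start - pos0
        if pos0 >= self.end:
            return pos0 - self.end + 1
        return 0


@dataclass(frozen=True)
class InDelSSRLocus:
    """An InDel with >=1 SSR inside its flank window: one marker locus."""

    indel: IndelLocus
    ssrs: tuple[SSRLocus, ...]
    repeat_class: str

    def __post_init__(self) -> None:
        if not self.ssrs:
            raise ValueError("InDelSSRLocus requires at least one member SSR")

    @property
    def chrom_id(self) -> str:
        return self.indel.chrom_id

    @property
    def anchor0(self) -> int:
        return self.indel.anchor0

    @property
    def nearest_ssr(self) -> SSRLocus:
        return min(self.ssrs, key=lambda s: (s.distance_to(self.anchor0), s.start))


@dataclass(frozen=True)
class ChromosomeReport:
    """Per-chromosome InDel-SSR counts, density and recovery ratio."""

    chrom_id: str
    chrom_len: int
    n_indels: int
    n_indel_ssrs: int

    @property
    def density_per_mb(self) -> float:
        return self.n_indel_ssrs / (self.chrom_len / 1e6)

    @property
    def ratio(self) -> float:
        return self.n_indel_ssrs / self.n_indels if self.n_indels else 0.0


def _is_primitive(motif: str) -> bool:
    """True iff the motif is not a repetition of a shorter unit."""
    L = len(motif)
    for d in range(1, L):
        if L % d == 0 and motif == motif[: d] * (L // d):
            return False
    return True


def find_perfect_ssrs(
    seq: GenomeSequence, params: SSRSearchParams | None = None
) -> list[SSRLocus]:
    """All maximal perfect SSR tracts in a sequence, sorted by start.

    Each qualifying tract is reported exactly once, at the smallest motif
    length whose threshold it meets; among equal-length phases the
    leftmost start wins (the tract begins at the run's left end).
    """
    params = params or SSRSearchParams()
    s = seq.sequence
    n = len(s)
    if n == 0:
        raise ValueError(f"{seq.chrom_id}: empty sequence")
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    out: list[SSRLocus] = []
    for L, min_rep in sorted(params.min_repeats_by_motif_len.items()):
        if n <= L:
            continue
        match = arr[L:] == arr[:-L]
        if not match.any():
            continue
        # boundaries of maximal True runs in `match`
        padded = np.concatenate(([False], match, [False]))
        diff = np.diff(padded.astype(np.int8))
        run_starts = np.nonzero(diff == 1)[0]
        run_ends = np.nonzero(diff == -1)[0]  # exclusive, in match-index space
        for a, b in zip(run_starts, run_ends):
            tract_len = (b - a) + L  # chars with period L: [a, b + L)
            n_rep = tract_len // L
            if n_rep < min_rep:
                continue
            motif = s[a : a + L]
            if "N" in motif or not _is_primitive(motif):
                continue
            out.append(
                SSRLocus(
                    chrom_id=seq.chrom_id, start=int(a), end=int(a + n_rep * L),
                    motif=motif, motif_len=L, n_repeats=int(n_rep), kind="perfect",
                )
            )
    out.sort(key=lambda x: (x.start, x.motif_len))
    return out


def merge_compound(
    ssrs: list[SSRLocus], params: SSRSearchParams | None = None
) -> list[SSRLocus]:
    """Chain perfect SSRs whose successive gaps are < compound_max_gap.

    Maximal chains of >=2 members become one compound locus; isolated
    SSRs pass through unchanged.  Input must be start-sorted and on one
    chromosome.
    """
    params = params or SSRSearchParams()
    if any(b.start < a.start for a, b in zip(ssrs, ssrs[1:])):
        raise ValueError("merge_compound requires start-sorted input")
    if len({x.chrom_id for x in ssrs}) > 1:
        raise ValueError("merge_compound requires a single chromosome")
    out: list[SSRLocus] = []
    chain: list[SSRLocus] = []

    def flush() -> None:
        if not chain:
            return
        if len(chain) == 1:
            out.append(chain[0])
        else:
            out.append(
                SSRLocus(
                    chrom_id=chain[0].chrom_id,
                    start=chain[0].start, end=max(x.end for x in chain),
                    motif="-".join(x.motif for x in chain),
                    motif_len=0, n_repeats=0, kind="compound",
                    members=tuple(chain),
                )
            )

    for ssr in ssrs:
        if chain and ssr.start - max(x.end for x in chain) < params.compound_max_gap:
            chain.append(ssr)
        else:
            flush()
            chain = [ssr]
    flush()
    return out


def _repeat_class(ssr: SSRLocus) -> str:
    return "compound" if ssr.kind == "compound" else REPEAT_CLASS_BY_MOTIF_LEN[ssr.motif_len]


def call_indel_ssrs(
    indels: list[IndelLocus],
    genome: list[GenomeSequence],
    params: SSRSearchParams | None = None,
    _ssr_cache: dict[str, list[SSRLocus]] | None = None,
) -> list[InDelSSRLocus]:
    """Pair each InDel with the SSRs overlapping its flank window.

    The window is [anchor - flank, anchor + flank] (clipped to the
    chromosome); an InDel with >=1 overlapping SSR yields exactly one
    InDelSSRLocus whose repeat class comes from the member nearest the
    anchor.  SSR tracts are detected once per chromosome and compound
    loci are assembled before windowing, so a tract may extend beyond the
    window as long as it overlaps it.
    """
    params = params or SSRSearchParams()
    by_chrom = {g.chrom_id: g for g in genome}
    cache = _ssr_cache if _ssr_cache is not None else {}
    out: list[InDelSSRLocus] = []
    for indel in indels:
        g = by_chrom.get(indel.chrom_id)
        if g is None:
            raise ValueError(f"InDel {indel.chrom_id}:{indel.pos} on unknown chromosome")
        if indel.anchor0 >= g.length:
            raise ValueError(
                f"InDel {indel.chrom_id}:{indel.pos} beyond chromosome end ({g.length} bp)"
            )
        if indel.chrom_id not in cache:
            cache[indel.chrom_id] = merge_compound(find_perfect_ssrs(g, params), params)
        lo = max(0, indel.anchor0 - params.flank_size)
        hi = min(g.length, indel.anchor0 + params.flank_size + 1)  # half-open
        members = tuple(s for s in cache[indel.chrom_id] if s.start < hi and s.end > lo)
        if not members:
            continue
        nearest = min(members, key=lambda s: (s.distance_to(indel.anchor0), s.start))
        out.append(
            InDelSSRLocus(indel=indel, ssrs=members, repeat_class=_repeat_class(nearest))
        )
    return out


def classify_repeat_types(loci: list[InDelSSRLocus]) -> pd.DataFrame:
    """Composition of InDel-SSR loci by repeat class and canonical motif.

    Returns one row per (repeat_class, motif_class) with count and
    percentage of all loci; percentages sum to 100.  A motif is pooled
    with its reverse complement but not its rotations (AG/CT and GA/TC
    are distinct classes); compound loci form their own class.
    """
    if not loci:
        raise ValueError("classify_repeat_types requires at least one locus")
    rows: dict[tuple[str, str], int] = {}
    for locus in loci:
        cls = locus.repeat_class
        motif = "" if cls == "compound" else canonical_motif_class(locus.nearest_ssr.motif)
        rows[(cls, motif)] = rows.get((cls, motif), 0) + 1
    df = pd.DataFrame(
        [(c, m, k) for (c, m), k in rows.items()],
        columns=["repeat_class", "motif_class", "count"],
    )
    df["percent"] = 100.0 * df["count"] / len(loci)
    order = {c: i for i, c in enumerate(REPEAT_CLASSES)}
    return df.sort_values(
        ["repeat_class", "count"], key=lambda s: s.map(order) if s.name == "repeat_class" else s,
        ascending=[True, False],
    ).reset_index(drop=True)


def chromosome_report(
    loci: list[InDelSSRLocus],
    indels: list[IndelLocus],
    genome: list[GenomeSequence],
) -> tuple[list[ChromosomeReport], dict]:
    """Per-chromosome marker distribution plus genome summary.

    The summary's average density is the unweighted mean of per-
    chromosome densities; totals are sums over chromosomes.
    """
    for g in genome:
        if g.length == 0:
            raise ValueError(f"zero-length chromosome {g.chrom_id}")
    n_loci = {g.chrom_id: 0 for g in genome}
    n_ind = {g.chrom_id: 0 for g in genome}
    for x in loci:
        n_loci[x.chrom_id] += 1
    for x in indels:
        n_ind[x.chrom_id] += 1
    reports = [
        ChromosomeReport(g.chrom_id, g.length, n_ind[g.chrom_id], n_loci[g.chrom_id])
        for g in genome
    ]
    total_ssr = sum(r.n_indel_ssrs for r in reports)
    total_ind = sum(r.n_indels for r in reports)
    summary = {
        "total_indels": total_ind,
        "total_indel_ssrs": total_ssr,
        "mean_indel_ssrs_per_chromosome": total_ssr / len(reports),
        "mean_density_per_mb": float(np.mean([r.density_per_mb for r in reports])),
        "overall_ratio": total_ssr / total_ind if total_ind else 0.0,
    }
    return reports, summary


def report_table(reports: list[ChromosomeReport], summary: dict) -> pd.DataFrame:
    """Chromosome-distribution table with density and ratio formatted
    to two decimals (ratio as percent), plus Sum and Average rows."""
    rows = [
        {
            "chromosome": r.chrom_id,
            "chromosome_length": r.chrom_len,
            "n_indels": r.n_indels,
            "n_indel_ssrs": r.n_indel_ssrs,
            "density_per_mb": round(r.density_per_mb, 2),
            "indel_ssr_per_indel_pct": round(100.0 * r.ratio, 2),
        }
        for r in reports
    ]
    rows.append(
        {
            "chromosome": "Sum",
            "chromosome_length": sum(r.chrom_len for r in reports),
            "n_indels": summary["total_indels"],
            "n_indel_ssrs": summary["total_indel_ssrs"],
            "density_per_mb": round(summary["mean_density_per_mb"], 2),
            "indel_ssr_per_indel_pct": round(100.0 * summary["overall_ratio"], 2),
        }
    )
    rows.append(
        {
            "chromosome": "Average",
            "chromosome_length": round(sum(r.chrom_len for r in reports) / len(reports)),
            "n_indels": round(summary["total_indels"] / len(reports)),
            "n_indel_ssrs": round(summary["mean_indel_ssrs_per_chromosome"]),
            "density_per_mb": round(summary["mean_density_per_mb"], 2),
            "indel_ssr_per_indel_pct": round(100.0 * summary["overall_ratio"], 2),
        }
    )
    return pd.DataFrame(rows)
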