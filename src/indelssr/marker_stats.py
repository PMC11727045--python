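"""Per-marker allele statistics from binary band matrices.

Band patterns are read codominantly: one present band is a homozygote
for that band-allele, two bands a heterozygote, zero or more than two
bands missing (a documented limitation for possible triploids).  From
the resulting allele frequencies p_i the module computes

    Na  observed allele count            |{p_i > 0}|
    Ne  effective allele count           1 / sum p_i^2
    Ho  observed heterozygosity          het / non-missing individuals
    He  expected heterozygosity          1 - sum p_i^2
    PIC polymorphism information content 1 - sum p_i^2
                                           - sum_{i<j} 2 p_i^2 p_j^2
    I   Shannon's diversity index        -sum p_i ln p_i

He is the uncorrected 1 - sum p^2; an unbiased 2N/(2N-1) variant is
available via ``unbiased_he=True``.  Frequencies use available
(complete-case) genotypes per marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import logger
from .band_matrix import BandMatrix


@dataclass(frozen=True)
class MarkerAlleleStats:
    marker_id: str
    na: int
    ne: float
    ho: float
    he: float
    pic: float
    shannon_i: float
    allele_freqs: dict[str, float]
    n_genotyped: int


def bands_to_genotypes(
    matrix: BandMatrix, marker_id: str
) -> dict[str, tuple[str, str] | None]:
    """Codominant genotypes per individual for one marker.

    One present band -> homozygote, two -> heterozygote, zero or more
    than two -> None (missing for genotype-based statistics).
    """
    sub = matrix.bands_for(marker_id)
    out: dict[str, tuple[str, str] | None] = {}
    for ind in sub.columns:
        col = sub[ind]
        if col.isna().all():
            out[ind] = None
            continue
        present = [str(b) for b, v in col.items() if v == 1.0]
        if len(present) == 1:
            out[ind] = (present[0], present[0])
        elif len(present) == 2:
            out[ind] = (present[0], present[1])
        else:
            out[ind] = None
    return out


def allele_frequencies(
    genotypes: dict[str, tuple[str, str] | None]
) -> dict[str, float]:
    """Allele frequencies p_i = allele count / (2 x non-missing)."""
    counts: dict[str, int] = {}
    n = 0
    for gt in genotypes.values():
        if gt is None:
            continue
        n += 1
        for a in gt:
            counts[a] = counts.get(a, 0) + 1
    if n == 0:
        raise ValueError("no non-missing genotypes")
    return {a: c / (2 * n) for a, c in sorted(counts.items())}


def pic_from_freqs(p: np.ndarray) -> float:
    """PIC = 1 - sum p^2 - sum_{i<j} 2 p_i^2 p_j^2."""
    p = np.asarray(p, dtype=float)
    sum_p2 = float(np.sum(p**2))
    sum_p4 = float(np.sum(p**4))
    cross = (sum_p2**2 - sum_p4)  # sum_{i != j} p_i^2 p_j^2
    return 1.0 - sum_p2 - cross


def stats_from_freqs(
    marker_id: str,
    freqs: dict[str, float],
    ho: float,
    n_genotyped: int,
    unbiased_he: bool = False,
) -> MarkerAlleleStats:
    p = np.array([v for v in freqs.values() if v > 0], dtype=float)
    sum_p2 = float(np.sum(p**2))
    he = 1.0 - sum_p2
    if unbiased_he and n_genotyped > 0:
        n2 = 2 * n_genotyped
        he *= n2 / (n2 - 1)
    return MarkerAlleleStats(
        marker_id=marker_id,
        na=int(p.size),
        ne=1.0 / sum_p2,
        ho=ho,
        he=he,
        pic=pic_from_freqs(p),
        shannon_i=float(-np.sum(p * np.log(p))),
        allele_freqs=freqs,
        n_genotyped=n_genotyped,
    )


def marker_stats(
    matrix: BandMatrix, marker_id: str, unbiased_he: bool = False
) -> MarkerAlleleStats | None:
    """All six statistics for one marker; None if every genotype is missing."""
    genotypes = bands_to_genotypes(matrix, marker_id)
    usable = {k: v for k, v in genotypes.items() if v is not None}
    if not usable:
        logger.warning("marker %s: all genotypes missing, skipped", marker_id)
        return None
    freqs = allele_frequencies(genotypes)
    n_het = sum(1 for gt in usable.values() if gt[0] != gt[1])
    return stats_from_freqs(
        marker_id, freqs, ho=n_het / len(usable), n_genotyped=len(usable),
        unbiased_he=unbiased_he,
    )


def marker_summary(
    matrix: BandMatrix, unbiased_he: bool = False
) -> tuple[pd.DataFrame, dict]:
    """Per-marker statistics table plus unweighted panel means.

    The panel summary reports mean Na/Ne/Ho/He/PIC/I across markers and
    the fractions of markers with PIC > 0.5 (highly polymorphic) and
    PIC > 0.25 (reasonably polymorphic).
    """
    rows = []
    for m in matrix.marker_ids:
        st = marker_stats(matrix, m, unbiased_he=unbiased_he)
        if st is None:
            continue
        rows.append(
            {
                "marker_id": st.marker_id, "Na": st.na, "Ne": st.ne,
                "Ho": st.ho, "He": st.he, "PIC": st.pic, "I": st.shannon_i,
                "n_genotyped": st.n_genotyped,
            }
        )
    if not rows:
        raise ValueError("no marker with a non-missing genotype")
    df = pd.DataFrame(rows).set_index("marker_id")
    summary = {
        "n_markers": len(df),
        "total_alleles": int(df["Na"].sum()),
        "mean_Na": float(df["Na"].mean()),
        "mean_Ne": float(df["Ne"].mean()),
        "mean_Ho": float(df["Ho"].mean()),
        "mean_He": float(df["He"].mean()),
        "mean_PIC": float(df["PIC"].mean()),
        "mean_I": float(df["I"].mean()),
        "max_PIC": float(df["PIC"].max()),
        "frac_pic_gt_0.5": float((df["PIC"] > 0.5).mean()),
        "frac_pic_gt_0.25": float((df["PIC"] > 0.25).mean()),
    }
    return df, summary
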