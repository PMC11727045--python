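"""Readers and writers for the external formats the pipeline touches.

Conventions: FASTA/VCF/GFF3 through Biopython, pysam and gffutils; all
external coordinates 1-based inclusive (the standard dialects), all
internal computation 0-based half-open.  TSV tables are tab-separated
UTF-8 with "NA" as the missing-value token.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO
from skbio import TreeNode

from ._util import logger
from .band_matrix import BandMatrix

_NON_ACGTN = re.compile(r"[^ACGTN]")


@dataclass(frozen=True)
class GenomeSequence:
    """One reference chromosome/contig: uppercase A/C/G/T/N."""

    chrom_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class IndelLocus:
    """A length-polymorphic variant record anchored at its VCF POS.

    ``pos`` is the 1-based position of the first reference base (VCF
    convention); ``anchor0`` is the same point 0-based, the single
    reference point used for flank windows.
    """

    chrom_id: str
    pos: int
    ref_allele: str
    alt_alleles: list[str]
    per_sample_genotypes: dict[str, tuple[int | None, int | None]] | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"InDel pos must be >= 1, got {self.pos}")

    @property
    def anchor0(self) -> int:
        return self.pos - 1

    @property
    def max_length_change(self) -> int:
        return max(abs(len(a) - len(self.ref_allele)) for a in self.alt_alleles)


@dataclass(frozen=True)
class GeneRecord:
    """A gene feature with 1-based inclusive coordinates."""

    gene_id: str
    chrom_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file into uppercase GenomeSequences.

    IUPAC ambiguity codes other than N are replaced by N (with a logged
    warning); duplicate headers and empty files are errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or not a FASTA file")
    seen: set[str] = set()
    out: list[GenomeSequence] = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA header id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        n_ambig = len(_NON_ACGTN.findall(seq))
        if n_ambig:
            logger.warning(
                "%s: %d non-ACGTN ambiguity bases in %s replaced by N",
                path, n_ambig, rec.id,
            )
            seq = _NON_ACGTN.sub("N", seq)
        out.append(GenomeSequence(chrom_id=rec.id, sequence=seq))
    return out


def read_indels_from_vcf(path: str | Path, min_len: int = 1) -> list[IndelLocus]:
    """Select length-polymorphic records from a VCF.

    A record is kept iff max over alt alleles of the REF/ALT length
    difference is >= ``min_len``; SNP-only records are excluded.  Record
    order is preserved.  Malformed genotype fields are skipped with a
    warning count; genotypes are returned when the file has samples.
    """
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    out: list[IndelLocus] = []
    n_bad_gt = 0
    for rec in vcf:
        if rec.alts is None:
            continue
        alts = [a for a in rec.alts if a is not None and "<" not in a]
        if not alts:
            continue
        if max(abs(len(a) - len(rec.ref)) for a in alts) < min_len:
            continue
        genotypes: dict[str, tuple[int | None, int | None]] | None = None
        if samples:
            genotypes = {}
            for s in samples:
                try:
                    gt = rec.samples[s]["GT"]
                except (KeyError, ValueError):
                    n_bad_gt += 1
                    genotypes[s] = (None, None)
                    continue
                if gt is None or len(gt) != 2:
                    genotypes[s] = (None, None)
                else:
                    genotypes[s] = (gt[0], gt[1])
        out.append(
            IndelLocus(
                chrom_id=rec.chrom,
                pos=rec.pos,
                ref_allele=rec.ref,
                alt_alleles=alts,
                per_sample_genotypes=genotypes,
            )
        )
    if n_bad_gt:
        logger.warning("%s: %d malformed genotype fields skipped", path, n_bad_gt)
    return out


def read_gff_genes(path: str | Path) -> list[GeneRecord]:
    """Extract gene features from a GFF3 file (non-gene types ignored)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        out.append(
            GeneRecord(
                gene_id=gene_id, chrom_id=feat.seqid,
                start=feat.start, end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
            )
        )
    return out


def read_band_matrix(path: str | Path) -> BandMatrix:
    """Read a band matrix TSV (marker_id, band_id, then individual columns)."""
    return BandMatrix.from_tsv(path)


def write_band_matrix(matrix: BandMatrix, path: str | Path) -> None:
    matrix.to_tsv(path)


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    """Read a generic TSV (phenotypes, Q matrix, lnP(D) replicates)."""
    return pd.read_csv(
        path, sep="\t", index_col=index_col,
        na_values=["NA"], keep_default_na=False,
    )


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index=index)


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Write a tree with branch lengths as Newick (terminated by ';')."""
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
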