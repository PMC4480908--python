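"""Gene models, promoter/gene-body regions, and fragment counting.

A gene's "region" is the union of its body (TSS to stop codon) with a
symmetric window around the transcription start site (default 2 kb each
side), clipped at the chromosome origin.  Fragments are assigned to a gene
when their midpoint falls inside the gene's region; a fragment whose
midpoint lies in two overlapping regions counts once for each gene.

All internal coordinates are 0-based half-open (BED convention); GTF input
(1-based closed) is converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "GeneRegion",
    "CountMatrix",
    "GeneModelError",
    "read_gene_models",
    "write_gene_models_bed",
    "build_gene_region",
    "build_gene_regions",
    "assign_fragments",
    "read_fragments_bed",
]


class GeneModelError(ValueError):
    """Raised on malformed or inconsistent gene-model input."""


@dataclass(frozen=True)
class GeneModel:
    """One gene: identifier, chromosome, strand, TSS and stop-codon boundary.

    ``tss`` and ``cds_end`` are the two boundaries of the half-open gene
    body.  For + strand genes ``tss < cds_end``; for − strand genes the TSS
    is the rightmost coordinate, so ``tss > cds_end``.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GeneModelError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.body_start >= self.body_end:
            raise GeneModelError(f"gene {self.gene_id!r}: empty gene body")
        if self.strand == "+" and self.tss > self.cds_end:
            raise GeneModelError(f"gene {self.gene_id!r}: + strand requires tss < cds_end")
        if self.strand == "-" and self.tss < self.cds_end:
            raise GeneModelError(f"gene {self.gene_id!r}: - strand requires tss > cds_end")

    @property
    def body_start(self) -> int:
        return min(self.tss, self.cds_end)

    @property
    def body_end(self) -> int:
        return max(self.tss, self.cds_end)


@dataclass(frozen=True)
class GeneRegion:
    """Merged half-open intervals covering a gene body plus its TSS window."""

    gene_id: str
    chrom: str
    intervals: tuple[tuple[int, int], ...]
    window_bp: int = 2000

    def __post_init__(self) -> None:
        prev_end = None
        for start, end in self.intervals:
            if start >= end or start < 0:
                raise GeneModelError(f"region {self.gene_id!r}: bad interval [{start}, {end})")
            if prev_end is not None and start <= prev_end:
                raise GeneModelError(f"region {self.gene_id!r}: intervals not sorted/merged")
            prev_end = end

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def contains(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.intervals)


@dataclass
class CountMatrix:
    """Per-gene fragment counts for a set of named samples.

    ``counts`` is a genes × samples DataFrame of non-negative integers;
    ``library_sizes`` holds the total fragments sequenced per sample (not
    the column sum, since fragments may be unassigned or multiply assigned).
    """

    counts: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        self.library_sizes = self.library_sizes.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.library_sizes.index)
        if missing:
            raise ValueError(f"samples missing library sizes: {sorted(missing)}")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path) -> None:
        """Write a gene × sample table with a ``#library_sizes`` header line."""
        path = Path(path)
        sizes = "\t".join(str(int(self.library_sizes[s])) for s in self.counts.columns)
        with open(path, "w") as fh:
            fh.write(f"#library_sizes\t{sizes}\n")
            self.counts.to_csv(fh, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        path = Path(path)
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
            if not header.startswith("#library_sizes"):
                raise ValueError(f"{path}: first line must be a #library_sizes header")
            sizes = [int(x) for x in header.split("\t")[1:]]
            counts = pd.read_csv(fh, sep="\t", index_col="gene_id")
        if len(sizes) != counts.shape[1]:
            raise ValueError(f"{path}: {len(sizes)} library sizes for {counts.shape[1]} samples")
        return cls(counts=counts, library_sizes=pd.Series(sizes, index=counts.columns))


def _gene_model_from_bounds(gene_id: str, chrom: str, strand: str, start0: int, end0: int) -> GeneModel:
    if strand == "+":
        return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, tss=start0, cds_end=end0)
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, tss=end0, cds_end=start0)


def read_gene_models(path: str | Path, format: str | None = None) -> list[GeneModel]:
    """Read gene models from a GTF (ensembl dialect) or BED6 file.

    GTF coordinates (1-based closed) are converted to 0-based half-open.
    Only GTF features of type ``gene`` are used; the ``gene_id`` attribute
    is required.  Duplicate gene ids are an error.
    """
    path = Path(path)
    if format is None:
        format = "gtf" if path.suffix.lower() in (".gtf", ".gff") else "bed"
    if format not in ("gtf", "bed"):
        raise ValueError(f"unknown gene-model format {format!r}")

    models: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            try:
                if format == "gtf":
                    feature = gffutils.feature.feature_from_line(line)
                    if feature.featuretype != "gene":
                        continue
                    gene_id = feature.attributes["gene_id"][0]
                    model = _gene_model_from_bounds(
                        gene_id, feature.seqid, feature.strand, feature.start - 1, feature.end
                    )
                else:
                    fields = line.split("\t")
                    if len(fields) < 6:
                        raise GeneModelError("BED6 requires 6 columns")
                    chrom, start, end, gene_id, _score, strand = fields[:6]
                    model = _gene_model_from_bounds(gene_id, chrom, strand, int(start), int(end))
            except GeneModelError:
                raise
            except Exception as exc:
                raise GeneModelError(f"{path}:{lineno}: malformed {format} line: {exc}") from exc
            if model.gene_id in seen:
                raise GeneModelError(f"{path}:{lineno}: duplicate gene_id {model.gene_id!r}")
            seen.add(model.gene_id)
            models.append(model)
    return models


def write_gene_models_bed(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as BED6 (round-trips with :func:`read_gene_models`)."""
    with open(path, "w") as fh:
        for m in models:
            fh.write(f"{m.chrom}\t{m.body_start}\t{m.body_end}\t{m.gene_id}\t0\t{m.strand}\n")


def build_gene_region(gene: GeneModel, window_bp: int = 2000) -> GeneRegion:
    """Union of the gene body with a ±``window_bp`` window around the TSS.

    The window is symmetric and clipped at coordinate 0; overlapping pieces
    are merged, so most genes yield a single interval.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    pieces = [
        (max(0, gene.tss - window_bp), gene.tss + window_bp),
        (gene.body_start, gene.body_end),
    ]
    pieces = sorted((s, e) for s, e in pieces if s < e)
    merged: list[tuple[int, int]] = []
    for s, e in pieces:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return GeneRegion(
        gene_id=gene.gene_id, chrom=gene.chrom, intervals=tuple(merged), window_bp=window_bp
    )


def build_gene_regions(models: Sequence[GeneModel], window_bp: int = 2000) -> list[GeneRegion]:
    return [build_gene_region(m, window_bp) for m in models]


@dataclass
class AssignmentResult:
    """Counts column from fragment assignment plus bookkeeping tallies."""

    counts: pd.Series
    n_fragments: int
    n_unassigned: int
    n_unknown_chrom: int
    n_multi_assigned: int = 0


def read_fragments_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read fragments as (chrom, start, end) from a BED3+ file."""
    frags = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED requires >= 3 columns")
            frags.append((fields[0], int(fields[1]), int(fields[2])))
    return frags


def assign_fragments(
    fragments: Iterable[tuple[str, int, int]],
    regions: Sequence[GeneRegion],
) -> AssignmentResult:
    """Count fragments per gene by midpoint membership.

    A fragment increments a gene's count iff its midpoint,
    ``floor((start + end) / 2)``, lies in the gene's (half-open) region.
    Fragments may hit several overlapping genes and then count for each.
    Fragments on chromosomes absent from the annotation are skipped and
    tallied.
    """
    trees: dict[str, IntervalTree] = {}
    for region in regions:
        tree = trees.setdefault(region.chrom, IntervalTree())
        for start, end in region.intervals:
            tree[start:end] = region.gene_id

    counts = {r.gene_id: 0 for r in regions}
    n_frag = n_unassigned = n_unknown = n_multi = 0
    for chrom, start, end in fragments:
        if start >= end:
            raise ValueError(f"fragment [{start}, {end}) on {chrom} is not half-open with start < end")
        n_frag += 1
        tree = trees.get(chrom)
        if tree is None:
            n_unknown += 1
            continue
        mid = (start + end) // 2
        hits = tree[mid]
        if not hits:
            n_unassigned += 1
            continue
        if len(hits) > 1:
            n_multi += 1
        for hit in hits:
            counts[hit.data] += 1

    if n_unknown:
        logger.warning("assign_fragments: %d fragments on unknown chromosomes skipped", n_unknown)
    logger.info(
        "assign_fragments: %d fragments, %d unassigned, %d multi-assigned",
        n_frag, n_unassigned, n_multi,
    )
    return AssignmentResult(
        counts=pd.Series(counts, dtype=np.int64),
        n_fragments=n_frag,
        n_unassigned=n_unassigned,
        n_unknown_chrom=n_unknown,
        n_multi_assigned=n_multi,
    )
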