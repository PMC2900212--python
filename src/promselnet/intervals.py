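"""Genomic interval arithmetic for promoter windows and intronic reference regions.

Coordinates are 0-based, half-open (BED convention) throughout.  A gene model
carries the TSS, the end of the terminal exon and the exon intervals of all
transcripts; introns are obtained by merging overlapping exons and
complementing within the gene body.  The intronic reference used to calibrate
neutral evolution excludes the first intron (transcription order), drops
introns outside a length band, and trims both ends of each survivor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "IntronFilterParams",
    "merge_exons",
    "intronic_intervals",
    "promoter_window",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a chromosome strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """Gene coordinates: TSS, end of the terminal exon and all exon intervals.

    ``tss`` is the 0-based position of the first transcribed base.  On the
    minus strand the TSS is numerically *larger* than ``gene_end``.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    gene_end: int
    exons: tuple[GenomicInterval, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        lo, hi = self.body_span
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError(f"{self.gene_id}: exon chrom {ex.chrom} != {self.chrom}")
            if ex.strand != self.strand:
                raise ValueError(f"{self.gene_id}: exon strand inconsistent")
            if ex.start < lo or ex.end > hi + 1:
                raise ValueError(
                    f"{self.gene_id}: exon [{ex.start},{ex.end}) outside gene span [{lo},{hi}]"
                )

    @property
    def body_span(self) -> tuple[int, int]:
        """(min, max) bound of the gene body on the chromosome."""
        return min(self.tss, self.gene_end), max(self.tss, self.gene_end)


@dataclass(frozen=True)
class IntronFilterParams:
    """Filters applied when building the intronic neutral reference.

    min_len/max_len are applied to the *untrimmed* intron; end_trim bases are
    then removed from both ends of each surviving intron.  Flanks (default 0)
    optionally extend the complementation region beyond the gene body.
    """

    min_len: int = 600
    max_len: int = 6200
    end_trim: int = 100
    exclude_first_intron: bool = True
    upstream_flank: int = 0
    downstream_flank: int = 0

    def __post_init__(self) -> None:
        if not self.min_len < self.max_len:
            raise ValueError("min_len must be < max_len")
        if self.end_trim < 0:
            raise ValueError("end_trim must be >= 0")


def merge_exons(exons: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/nested intervals into a disjoint sorted list.

    All intervals must share a chromosome (and strand); the union of covered
    base pairs is preserved exactly.  Abutting intervals ([0,5)+[5,9)) are
    merged as well since their base-pair union is contiguous.
    """
    if not exons:
        return []
    chroms = {e.chrom for e in exons}
    if len(chroms) > 1:
        raise ValueError(f"cannot merge exons from multiple chromosomes: {sorted(chroms)}")
    strands = {e.strand for e in exons}
    if len(strands) > 1:
        raise ValueError("cannot merge exons with inconsistent strands")
    out: list[GenomicInterval] = []
    for iv in sorted(exons, key=lambda e: (e.start, e.end)):
        if out and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = replace(out[-1], end=iv.end)
        else:
            out.append(iv)
    return out


def intronic_intervals(
    gene: GeneModel, params: IntronFilterParams | None = None
) -> list[GenomicInterval]:
    """Intronic reference intervals of a gene, in transcription order.

    The complement of the merged exons within the (optionally flanked) gene
    body gives the introns; the first intron in transcription order is
    excluded, introns outside [min_len, max_len] (pre-trim) are removed, and
    survivors are trimmed by ``end_trim`` on both sides.  An empty list is a
    valid result (e.g. single-exon genes).
    """
    params = params or IntronFilterParams()
    if not gene.exons:
        raise ValueError(f"{gene.gene_id}: gene model has no exons")
    merged = merge_exons(list(gene.exons))
    lo, hi = gene.body_span
    if gene.strand == "+":
        lo = max(0, lo - params.upstream_flank)
        hi = hi + params.downstream_flank
    else:
        lo = max(0, lo - params.downstream_flank)
        hi = hi + params.upstream_flank

    # complement of merged exons within [lo, hi)
    gaps: list[GenomicInterval] = []
    cursor = lo
    for ex in merged:
        if ex.start > cursor:
            gaps.append(GenomicInterval(gene.chrom, cursor, ex.start, gene.strand))
        cursor = max(cursor, ex.end)
    if cursor < hi:
        gaps.append(GenomicInterval(gene.chrom, cursor, hi, gene.strand))

    if gene.strand == "-":
        gaps = gaps[::-1]  # transcription order
    if params.exclude_first_intron and gaps:
        gaps = gaps[1:]

    out = []
    for iv in gaps:
        if not (params.min_len <= iv.length <= params.max_len):
            continue
        start = iv.start + params.end_trim
        end = iv.end - params.end_trim
        if end > start:
            out.append(replace(iv, start=start, end=end))
    return out


def promoter_window(
    gene: GeneModel,
    upstream: int = 1100,
    downstream: int = 150,
    analysis_upstream: int = 1000,
) -> tuple[GenomicInterval, GenomicInterval]:
    """Raw download window and 1-kb analysis window around the TSS.

    Relative coordinate of absolute position p: r = p - tss on '+',
    r = tss - p on '-'.  The raw window covers r in [-upstream, +downstream)
    and the analysis window r in [-analysis_upstream, 0) — the proximal
    promoter immediately upstream of the TSS.
    """
    t = gene.tss
    if gene.strand == "+":
        raw = (t - upstream, t + downstream)
        ana = (t - analysis_upstream, t)
    else:
        # r = t - p in [a, b)  <=>  p in (t - b, t - a]  <=>  [t - b + 1, t - a + 1)
        raw = (t - downstream + 1, t + upstream + 1)
        ana = (t + 1, t + analysis_upstream + 1)
    if raw[0] < 0 or ana[0] < 0:
        raise ValueError(
            f"{gene.gene_id}: promoter window extends beyond chromosome start "
            f"(tss={t}, strand={gene.strand})"
        )
    return (
        GenomicInterval(gene.chrom, raw[0], raw[1], gene.strand),
        GenomicInterval(gene.chrom, ana[0], ana[1], gene.strand),
    )
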