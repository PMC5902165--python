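"""Per-gene exonic and intronic region construction from transcript models.

A genomic base belongs to a gene's *exonic* region if it falls inside an
exon of at least one transcript of that gene.  It belongs to the *intronic*
region if it is covered by the span of at least one transcript and lies in
an exon of none, i.e. it is intronic in every transcript that covers it.
Bases inside the merged gene body but covered by no transcript span (gaps
between disjoint transcripts) are neither exonic nor intronic.

Coordinates: the public API and GTF I/O use 1-based closed intervals
(the GTF convention); all internal interval algebra uses 0-based half-open
intervals.  The converters are exact integer maps and are tested both ways.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

Interval = tuple[int, int]

# ---------------------------------------------------------------------------
# interval algebra (0-based half-open)


def closed_to_halfopen(iv: Interval) -> Interval:
    """1-based closed [start, end] -> 0-based half-open [start-1, end)."""
    return (iv[0] - 1, iv[1])


def halfopen_to_closed(iv: Interval) -> Interval:
    """0-based half-open [start, end) -> 1-based closed [start+1, end]."""
    return (iv[0] + 1, iv[1])


def union_intervals(intervals: list[Interval]) -> list[Interval]:
    """Union of half-open intervals, returned sorted and merged.

    Adjacent intervals ([a,b) and [b,c)) are merged: the base sets they
    describe are contiguous.
    """
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_intervals(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Set difference a \\ b for half-open interval lists (each pre-merged)."""
    out: list[Interval] = []
    j = 0
    b = union_intervals(b)
    for s, e in union_intervals(a):
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def total_length(intervals: list[Interval]) -> int:
    return sum(e - s for s, e in intervals)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: an ordered set of exons on a single strand.

    ``exons`` are 1-based closed intervals, sorted by start and
    non-overlapping within the transcript.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.transcript_id}: exon start {s} > end {e}")
            if prev_end is not None and s <= prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap or are unsorted near position {s}"
                )
            prev_end = e

    @property
    def span(self) -> Interval:
        """1-based closed span from first exon start to last exon end."""
        return (self.exons[0][0], self.exons[-1][1])


@dataclass(frozen=True)
class GeneRegions:
    """Exonic/intronic interval sets (1-based closed) and their lengths."""

    gene_id: str
    chrom: str
    strand: str
    exonic: tuple[Interval, ...]
    intronic: tuple[Interval, ...]
    exonic_length: int
    intronic_length: int


# ---------------------------------------------------------------------------
# operations


def _check_gene(transcripts: list[TranscriptModel]) -> None:
    if not transcripts:
        raise ValueError("empty transcript list")
    gene = transcripts[0].gene_id
    chroms = {t.chrom for t in transcripts}
    strands = {t.strand for t in transcripts}
    genes = {t.gene_id for t in transcripts}
    if len(genes) > 1:
        raise ValueError(f"transcripts from multiple genes: {sorted(genes)}")
    if len(chroms) > 1 or len(strands) > 1:
        raise ValueError(
            f"gene {gene}: transcripts on mixed chromosomes/strands "
            f"({sorted(chroms)}, {sorted(strands)})"
        )


def merge_gene_body(transcripts: list[TranscriptModel]) -> list[Interval]:
    """Union of transcript spans, as 1-based closed intervals.

    Disjoint transcripts yield one interval per connected component.
    """
    _check_gene(transcripts)
    spans = [closed_to_halfopen(t.span) for t in transcripts]
    return [halfopen_to_closed(iv) for iv in union_intervals(spans)]


def build_gene_regions(transcripts: list[TranscriptModel]) -> GeneRegions:
    """Label each covered base exonic, intronic, or neither (see module doc)."""
    _check_gene(transcripts)
    t0 = transcripts[0]
    exons = union_intervals(
        [closed_to_halfopen(iv) for t in transcripts for iv in t.exons]
    )
    spans = union_intervals([closed_to_halfopen(t.span) for t in transcripts])
    introns = subtract_intervals(spans, exons)
    return GeneRegions(
        gene_id=t0.gene_id,
        chrom=t0.chrom,
        strand=t0.strand,
        exonic=tuple(halfopen_to_closed(iv) for iv in exons),
        intronic=tuple(halfopen_to_closed(iv) for iv in introns),
        exonic_length=total_length(exons),
        intronic_length=total_length(introns),
    )


# ---------------------------------------------------------------------------
# GTF I/O

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr))


def read_gtf(path) -> list[TranscriptModel]:
    """Parse exon features of a GTF file into TranscriptModels.

    Requires ``gene_id`` and ``transcript_id`` attributes on every exon line;
    non-exon features are ignored.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            attrs = _parse_attributes(f[8])
            try:
                rows.append(
                    (
                        attrs["gene_id"],
                        attrs["transcript_id"],
                        f[0],
                        f[6],
                        int(f[3]),
                        int(f[4]),
                    )
                )
            except KeyError as exc:
                raise ValueError(f"GTF exon line missing attribute {exc}") from exc
    df = pd.DataFrame(
        rows, columns=["gene_id", "transcript_id", "chrom", "strand", "start", "end"]
    )
    transcripts = []
    for (gid, tid, chrom, strand), grp in df.groupby(
        ["gene_id", "transcript_id", "chrom", "strand"], sort=True
    ):
        exons = tuple(
            sorted((int(s), int(e)) for s, e in zip(grp["start"], grp["end"]))
        )
        transcripts.append(TranscriptModel(gid, tid, chrom, strand, exons))
    return transcripts


def write_gtf(transcripts: list[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            for s, e in t.exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{t.chrom}\tcircamyo\texon\t{s}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def regions_to_bed(regions: list[GeneRegions]) -> pd.DataFrame:
    """BED-like table (0-based half-open) of exonic/intronic regions."""
    rows = []
    for r in regions:
        for kind, ivs in (("exonic", r.exonic), ("intronic", r.intronic)):
            for iv in ivs:
                s, e = closed_to_halfopen(iv)
                rows.append((r.chrom, s, e, r.gene_id, kind, r.strand))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gene_id", "region", "strand"]
    )


def region_lengths(regions: list[GeneRegions]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in regions],
            "exonic_length": [r.exonic_length for r in regions],
            "intronic_length": [r.intronic_length for r in regions],
        }
    ).set_index("gene_id")
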