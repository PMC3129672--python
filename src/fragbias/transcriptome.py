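"""Transcript models: annotation parsing, spliced sequences, locus grouping.

Internally all coordinates are 0-based half-open; the 1-based closed GTF
convention is converted at the parsing boundary.  A locus is a connected
component of the transcript-overlap graph on a chromosome (strand ignored
by default, matching the general unstranded-library case).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from gffutils.iterators import DataIterator

from fragbias._seq import reverse_complement


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation records."""


@dataclass
class Transcript:
    """A spliced transcript: exon structure plus (optionally) its sequence.

    ``exons`` are 0-based half-open genomic intervals sorted in genomic
    order; ``sequence`` reads 5'->3' in transcript orientation (i.e. it is
    reverse-complemented for '-' strand transcripts).
    """

    id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    sequence: str | None = None
    locus_id: str | None = None
    gene_id: str | None = None

    def __post_init__(self) -> None:
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in self.exons:
            if b <= a:
                raise AnnotationError(f"transcript {self.id}: empty exon [{a},{b})")
        for (_, b0), (a1, _) in zip(self.exons, self.exons[1:]):
            if a1 < b0:
                raise AnnotationError(f"transcript {self.id}: overlapping exons")
        if self.strand not in "+-":
            raise AnnotationError(f"transcript {self.id}: bad strand {self.strand!r}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise AnnotationError(
                f"transcript {self.id}: sequence length {len(self.sequence)} "
                f"!= exon length {self.length}"
            )

    @property
    def length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    # --- coordinate projection -------------------------------------------
    def genomic_to_transcript(self, gpos: int) -> int | None:
        """Map a genomic position to a transcript coordinate (None if intronic)."""
        off = 0
        for a, b in self.exons:
            if a <= gpos < b:
                plus_off = off + (gpos - a)
                return plus_off if self.strand == "+" else self.length - 1 - plus_off
            off += b - a
        return None

    def transcript_to_genomic(self, tpos: int) -> int:
        """Inverse of :meth:`genomic_to_transcript` for exonic coordinates."""
        if not 0 <= tpos < self.length:
            raise IndexError(f"transcript coordinate {tpos} out of range")
        plus_off = tpos if self.strand == "+" else self.length - 1 - tpos
        for a, b in self.exons:
            if plus_off < b - a:
                return a + plus_off
            plus_off -= b - a
        raise AssertionError("unreachable")

    def transcript_interval_to_blocks(self, start: int, end: int) -> list[tuple[int, int]]:
        """Project a transcript-space interval [start, end) onto genomic blocks.

        Blocks are returned in genomic order and respect exon boundaries.
        """
        if not 0 <= start < end <= self.length:
            raise IndexError(f"interval [{start},{end}) out of transcript range")
        if self.strand == "+":
            lo, hi = start, end
        else:
            lo, hi = self.length - end, self.length - start
        blocks: list[tuple[int, int]] = []
        off = 0
        for a, b in self.exons:
            exon_len = b - a
            s = max(lo, off)
            e = min(hi, off + exon_len)
            if s < e:
                blocks.append((a + (s - off), a + (e - off)))
            off += exon_len
        return blocks


@dataclass
class Locus:
    """A genomic region containing a set of overlapping transcripts."""

    id: str
    transcript_ids: set[str] = field(default_factory=set)
    chrom: str = ""
    span: tuple[int, int] = (0, 0)


def parse_annotation(annotation: str | io.TextIOBase) -> list[Transcript]:
    """Parse a GTF annotation into Transcript models (sequences unset).

    Exon features are grouped by ``transcript_id``; GTF's 1-based closed
    coordinates become 0-based half-open.  Malformed records raise
    :class:`AnnotationError` naming the offending line.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    order: list[str] = []
    if hasattr(annotation, "read"):
        iterator = DataIterator(annotation.read(), from_string=True)
    else:
        iterator = DataIterator(str(annotation))
    for lineno, feature in enumerate(iterator, start=1):
        try:
            if feature.featuretype != "exon":
                continue
            tid = feature.attributes["transcript_id"][0]
            gid = feature.attributes.get("gene_id", [tid])[0]
        except (KeyError, IndexError) as exc:
            raise AnnotationError(
                f"annotation line {lineno}: exon lacks transcript_id"
            ) from exc
        if feature.start is None or feature.end is None or feature.start > feature.end:
            raise AnnotationError(f"annotation line {lineno}: bad coordinates")
        if tid not in meta:
            meta[tid] = (feature.seqid, feature.strand, gid)
            order.append(tid)
        elif meta[tid][0] != feature.seqid or meta[tid][1] != feature.strand:
            raise AnnotationError(
                f"annotation line {lineno}: transcript {tid} spans "
                "chromosomes or strands"
            )
        exons.setdefault(tid, []).append((feature.start - 1, feature.end))
    transcripts = []
    for tid in order:
        if not exons.get(tid):
            raise AnnotationError(f"transcript {tid} has zero exons")
        chrom, strand, gid = meta[tid]
        merged = _merge_exons(exons[tid])
        transcripts.append(
            Transcript(id=tid, chrom=chrom, strand=strand, exons=merged, gene_id=gid)
        )
    return transcripts


def _merge_exons(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge abutting/overlapping exon intervals."""
    out: list[tuple[int, int]] = []
    for a, b in sorted(intervals):
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def extract_spliced_sequence(
    transcript: Transcript, genome: Mapping[str, object]
) -> str:
    """Concatenate exon sequences, reverse-complementing for '-' strand.

    ``genome`` may be a ``pyfaidx.Fasta`` or any mapping of chromosome name
    to a sliceable sequence (e.g. plain strings for tests).
    """
    try:
        chrom = genome[transcript.chrom]
    except KeyError as exc:
        raise AnnotationError(f"chromosome {transcript.chrom} not in genome") from exc
    chrom_len = len(chrom)
    parts = []
    for a, b in transcript.exons:
        if a < 0 or b > chrom_len:
            raise AnnotationError(
                f"transcript {transcript.id}: exon [{a},{b}) outside "
                f"{transcript.chrom} (length {chrom_len})"
            )
        parts.append(str(chrom[a:b]))
    seq = "".join(parts).upper()
    return reverse_complement(seq) if transcript.strand == "-" else seq


def attach_sequences(transcripts: Iterable[Transcript], genome) -> None:
    """Populate ``sequence`` on every transcript in place."""
    for t in transcripts:
        t.sequence = extract_spliced_sequence(t, genome)


def group_loci(
    transcripts: Sequence[Transcript], stranded: bool = False
) -> list[Locus]:
    """Group transcripts into loci: connected components of span overlap.

    With ``stranded=False`` (default) overlapping transcripts on opposite
    strands share a locus; ``stranded=True`` separates them.
    """
    keyed: dict[tuple, list[Transcript]] = {}
    for t in transcripts:
        key = (t.chrom, t.strand) if stranded else (t.chrom,)
        keyed.setdefault(key, []).append(t)
    loci: list[Locus] = []
    for key in sorted(keyed):
        group = sorted(keyed[key], key=lambda t: t.span)
        cluster: list[Transcript] = []
        hi = -1
        for t in group:
            a, b = t.span
            if cluster and a >= hi:
                loci.append(_make_locus(cluster, len(loci)))
                cluster = []
                hi = -1
            cluster.append(t)
            hi = max(hi, b)
        if cluster:
            loci.append(_make_locus(cluster, len(loci)))
    return loci


def _make_locus(cluster: list[Transcript], index: int) -> Locus:
    lid = f"locus_{index + 1}"
    span = (min(t.span[0] for t in cluster), max(t.span[1] for t in cluster))
    for t in cluster:
        t.locus_id = lid
    return Locus(
        id=lid,
        transcript_ids={t.id for t in cluster},
        chrom=cluster[0].chrom,
        span=span,
    )


def transcripts_from_fasta(fasta) -> list[Transcript]:
    """Treat each FASTA record as a single-exon transcript on its own contig.

    Used when alignments are made directly against transcript sequences and
    no annotation is supplied.
    """
    transcripts = []
    for name in fasta.keys() if hasattr(fasta, "keys") else fasta:
        seq = str(fasta[name][:]).upper()
        transcripts.append(
            Transcript(
                id=name,
                chrom=name,
                strand="+",
                exons=[(0, len(seq))],
                sequence=seq,
            )
        )
    return transcripts


def write_gtf(transcripts: Sequence[Transcript], path: str) -> None:
    """Write transcripts as GTF exon features (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for t in transcripts:
            gene = t.gene_id or t.id
            for a, b in t.exons:
                attrs = f'gene_id "{gene}"; transcript_id "{t.id}";'
                fh.write(
                    f"{t.chrom}\tfragbias\texon\t{a + 1}\t{b}\t.\t{t.strand}\t.\t{attrs}\n"
                )
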