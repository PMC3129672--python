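"""Fragment alignment parsing and 5'/3' end resolution.

A sequenced fragment is observed only through its read alignments.  For
paired-end data both fragment ends are revealed: the 5' end ``i`` and the
3' end ``j`` (transcript coordinates, 0-based, inclusive) give the implied
length ``I_t(f) = j - i + 1``.  For single-end data only one end is seen
and its identity (5' vs 3') depends on the library protocol:

* ``second-strand``  — reads are sense to the transcript; the read start
  is the fragment 5' end.
* ``first-strand``   — reads are antisense (dUTP-style); the read's last
  transcript base is the fragment 3' end.
* ``unstranded``     — the end identity follows the read's mapped strand:
  sense-mapping reads contribute a 5' end, antisense reads a 3' end.
"""

from __future__ import annotations

import bisect
import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pysam

from fragbias.transcriptome import Transcript

log = logging.getLogger(__name__)


class LibraryType(enum.Enum):
    UNSTRANDED = "unstranded"
    FIRST_STRAND = "first-strand"
    SECOND_STRAND = "second-strand"

    @classmethod
    def from_string(cls, name: str) -> "LibraryType":
        return cls(name.lower().replace("_", "-"))


class ReadRecord(NamedTuple):
    """Minimal view of one aligned read (one SAM record)."""

    name: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]  # genomic, 0-based half-open, sorted
    is_reverse: bool
    is_read1: bool
    is_paired: bool


@dataclass
class Hit:
    """A fragment's placement on one transcript.

    Either end may be unknown (None) for single-end data; the likelihood
    then marginalizes over the fragment-length distribution.
    """

    transcript_id: str
    five_prime: int | None
    three_prime: int | None

    @property
    def implied_length(self) -> int | None:
        if self.five_prime is None or self.three_prime is None:
            return None
        return self.three_prime - self.five_prime + 1


@dataclass
class FragmentAlignment:
    fragment_id: str
    hits: list[Hit] = field(default_factory=list)

    @property
    def multiplicity(self) -> int:
        return len({h.transcript_id for h in self.hits})


class AlignmentParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# coordinate projection
# ---------------------------------------------------------------------------

def project_blocks(transcript: Transcript, blocks: Sequence[tuple[int, int]]):
    """Project genomic alignment blocks into transcript coordinates.

    Returns the half-open transcript-orientation interval ``(s, e)`` covered
    by the read, or None when the alignment is incompatible with the
    transcript's exon structure (a block leaves the exons, or the blocks are
    not contiguous in spliced coordinates, i.e. the read implies a junction
    the transcript does not have).
    """
    plus_intervals = []
    for a, b in blocks:
        off = 0
        placed = None
        for ea, eb in transcript.exons:
            if ea <= a and b <= eb:
                placed = (off + (a - ea), off + (b - ea))
                break
            off += eb - ea
        if placed is None:
            return None
        plus_intervals.append(placed)
    plus_intervals.sort()
    for (_, e0), (s1, _) in zip(plus_intervals, plus_intervals[1:]):
        if s1 != e0:
            return None
    lo, hi = plus_intervals[0][0], plus_intervals[-1][1]
    if transcript.strand == "+":
        return lo, hi
    return transcript.length - hi, transcript.length - lo


def _read_sense(transcript: Transcript, read: ReadRecord) -> bool:
    """True when the read maps to the transcript's sense strand."""
    genomic_strand = "-" if read.is_reverse else "+"
    return genomic_strand == transcript.strand


def assign_ends(
    pair: tuple[ReadRecord, ReadRecord],
    transcript: Transcript,
    library_type: LibraryType,
) -> tuple[int, int] | None:
    """Resolve (i, j) fragment ends for a read pair on one transcript.

    Returns None when either mate fails to project or the pair's mate/strand
    configuration is inconsistent with the library type.
    """
    r1, r2 = pair
    p1 = project_blocks(transcript, r1.blocks)
    p2 = project_blocks(transcript, r2.blocks)
    if p1 is None or p2 is None:
        return None
    s1 = _read_sense(transcript, r1)
    s2 = _read_sense(transcript, r2)
    if s1 == s2:  # mates must map to opposite strands
        return None
    sense_read, sense_iv = (r1, p1) if s1 else (r2, p2)
    if library_type is LibraryType.FIRST_STRAND and sense_read.is_read1:
        return None  # dUTP: read1 is antisense
    if library_type is LibraryType.SECOND_STRAND and not sense_read.is_read1:
        return None
    anti_iv = p2 if s1 else p1
    i = sense_iv[0]
    j = anti_iv[1] - 1
    if i > j or sense_iv[1] - 1 > j or anti_iv[0] < i:
        return None  # outward-facing pair
    return i, j


def assign_single_end(
    read: ReadRecord, transcript: Transcript, library_type: LibraryType
) -> Hit | None:
    """Resolve the known fragment end for a single-end read."""
    iv = project_blocks(transcript, read.blocks)
    if iv is None:
        return None
    sense = _read_sense(transcript, read)
    if sense:
        if library_type is LibraryType.FIRST_STRAND:
            return None
        return Hit(transcript.id, five_prime=iv[0], three_prime=None)
    if library_type is LibraryType.SECOND_STRAND:
        return None
    return Hit(transcript.id, five_prime=None, three_prime=iv[1] - 1)


# ---------------------------------------------------------------------------
# SAM/BAM parsing
# ---------------------------------------------------------------------------

class _TranscriptIndex:
    """Per-chromosome sorted span index for overlap queries."""

    def __init__(self, transcripts: Sequence[Transcript]):
        self.by_chrom: dict[str, list[tuple[int, int, Transcript]]] = {}
        self.by_id = {t.id: t for t in transcripts}
        for t in transcripts:
            self.by_chrom.setdefault(t.chrom, []).append((*t.span, t))
        for lst in self.by_chrom.values():
            lst.sort(key=lambda x: (x[0], x[1]))
        self._starts = {c: [x[0] for x in lst] for c, lst in self.by_chrom.items()}

    def overlapping(self, chrom: str, start: int, end: int) -> list[Transcript]:
        lst = self.by_chrom.get(chrom, [])
        # transcripts are short relative to chromosomes; scan back from the
        # first span starting beyond `end`
        hi = bisect.bisect_right(self._starts.get(chrom, []), end)
        out = []
        for a, b, t in lst[:hi]:
            if b > start:
                out.append(t)
        return out


def parse_alignments(
    alignments,
    transcripts: Sequence[Transcript],
    library_type: LibraryType = LibraryType.UNSTRANDED,
    transcriptome_space: bool = False,
    min_read_length: int = 1,
) -> tuple[list[FragmentAlignment], dict]:
    """Parse SAM/BAM into per-fragment transcript hits.

    ``alignments`` may be a path or an open ``pysam.AlignmentFile``.  With
    ``transcriptome_space=True`` reference names are transcript ids and no
    exon projection is applied.  Returns (fragments, stats); fragments with
    no compatible hit are dropped and counted.
    """
    close = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        close = True
    index = _TranscriptIndex(transcripts)
    known_refs = set(index.by_id) if transcriptome_space else set(index.by_chrom)

    groups: dict[str, list[ReadRecord]] = {}
    order: list[str] = []
    try:
        for seg in alignments:
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                continue
            ref = seg.reference_name
            if ref not in known_refs:
                raise AlignmentParseError(f"unknown reference {ref!r} in alignments")
            rec = ReadRecord(
                name=seg.query_name,
                chrom=ref,
                blocks=tuple(seg.get_blocks()),
                is_reverse=seg.is_reverse,
                is_read1=not seg.is_read2,
                is_paired=seg.is_paired,
            )
            if rec.name not in groups:
                groups[rec.name] = []
                order.append(rec.name)
            groups[rec.name].append(rec)
    finally:
        if close:
            alignments.close()

    stats = {
        "fragments": 0,
        "no_hit": 0,
        "missing_mate": 0,
        "orientation_skipped": 0,
        "min_read_length": min(
            (sum(b - a for a, b in r.blocks) for recs in groups.values() for r in recs),
            default=0,
        ),
    }
    fragments: list[FragmentAlignment] = []
    for name in order:
        recs = groups[name]
        frag = FragmentAlignment(fragment_id=name)
        paired = any(r.is_paired for r in recs)
        if paired:
            r1s = [r for r in recs if r.is_read1]
            r2s = [r for r in recs if not r.is_read1]
            if not r1s or not r2s:
                stats["missing_mate"] += 1
                continue
            for r1 in r1s:
                for r2 in r2s:
                    if r1.chrom != r2.chrom:
                        continue
                    for t in _candidates(index, r1, transcriptome_space):
                        ends = _assign_pair(r1, r2, t, library_type, transcriptome_space)
                        if ends is None:
                            stats["orientation_skipped"] += 1
                            continue
                        frag.hits.append(Hit(t.id, ends[0], ends[1]))
        else:
            for r in recs:
                for t in _candidates(index, r, transcriptome_space):
                    hit = (
                        _assign_single_ts(r, t)
                        if transcriptome_space
                        else assign_single_end(r, t, library_type)
                    )
                    if hit is not None:
                        frag.hits.append(hit)
        stats["fragments"] += 1
        if frag.hits:
            fragments.append(frag)
        else:
            stats["no_hit"] += 1
    if stats["missing_mate"]:
        log.warning("%d fragments skipped: missing mate", stats["missing_mate"])
    if stats["no_hit"]:
        log.warning("%d fragments had no compatible transcript hit", stats["no_hit"])
    return fragments, stats


def _candidates(index, read: ReadRecord, transcriptome_space: bool):
    if transcriptome_space:
        return [index.by_id[read.chrom]]
    start, end = read.blocks[0][0], read.blocks[-1][1]
    return index.overlapping(read.chrom, start, end)


def _assign_pair(r1, r2, t, library_type, transcriptome_space):
    if transcriptome_space:
        p1 = _contiguous_interval(r1)
        p2 = _contiguous_interval(r2)
        if p1 is None or p2 is None or r1.is_reverse == r2.is_reverse:
            return None
        fwd_iv = p2 if r1.is_reverse else p1
        rev_iv = p1 if r1.is_reverse else p2
        fwd_read = r2 if r1.is_reverse else r1
        if library_type is LibraryType.FIRST_STRAND and fwd_read.is_read1:
            return None
        if library_type is LibraryType.SECOND_STRAND and not fwd_read.is_read1:
            return None
        i, j = fwd_iv[0], rev_iv[1] - 1
        return (i, j) if i <= j else None
    return assign_ends((r1, r2), t, library_type)


def _contiguous_interval(read: ReadRecord):
    blocks = read.blocks
    for (_, e0), (s1, _) in zip(blocks, blocks[1:]):
        if s1 != e0:
            return None
    return blocks[0][0], blocks[-1][1]


def _assign_single_ts(read: ReadRecord, t) -> Hit | None:
    iv = _contiguous_interval(read)
    if iv is None:
        return None
    if read.is_reverse:
        return Hit(t.id, five_prime=None, three_prime=iv[1] - 1)
    return Hit(t.id, five_prime=iv[0], three_prime=None)


# ---------------------------------------------------------------------------
# array-form hits for the numerical pipeline
# ---------------------------------------------------------------------------

class HitTable:
    """Column-oriented hit store used by bias learning and the EM.

    ``i``/``j`` hold transcript coordinates of the fragment 5'/3' ends,
    with -1 marking an unknown end (single-end data).
    """

    def __init__(self, frag: np.ndarray, t: np.ndarray, i: np.ndarray, j: np.ndarray,
                 n_fragments: int):
        order = np.lexsort((t, frag))
        self.frag = np.asarray(frag, dtype=np.int64)[order]
        self.t = np.asarray(t, dtype=np.int64)[order]
        self.i = np.asarray(i, dtype=np.int64)[order]
        self.j = np.asarray(j, dtype=np.int64)[order]
        self.n_fragments = int(n_fragments)
        # fragment group boundaries (self.frag is sorted)
        if len(self.frag):
            change = np.flatnonzero(np.diff(self.frag)) + 1
            self.starts = np.concatenate(([0], change))
        else:
            self.starts = np.zeros(0, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.frag)

    @classmethod
    def from_fragment_alignments(
        cls, fragments: Iterable[FragmentAlignment], transcript_ids: Sequence[str]
    ) -> "HitTable":
        tindex = {tid: k for k, tid in enumerate(transcript_ids)}
        fr, tt, ii, jj = [], [], [], []
        n = 0
        for n, f in enumerate(fragments, start=1):
            for h in f.hits:
                fr.append(n - 1)
                tt.append(tindex[h.transcript_id])
                ii.append(-1 if h.five_prime is None else h.five_prime)
                jj.append(-1 if h.three_prime is None else h.three_prime)
        return cls(
            np.array(fr, dtype=np.int64),
            np.array(tt, dtype=np.int64),
            np.array(ii, dtype=np.int64),
            np.array(jj, dtype=np.int64),
            n_fragments=n,
        )
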