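"""Synthetic transcriptomes and biased fragment data with known ground truth.

The generator is the exact inverse of the quantification likelihood: a
fragment picks its source transcript with probability proportional to
rho_t * e~(t), then its (length, 5' position) jointly proportional to
D(l) * w5[i] * w3[i + l - 1], where the planted per-position weights
combine an order-0 per-offset sequence table (nonzero log-weights at
offsets -5..+5 by default, where real protocols show bias) and an
optional positional profile over transcript twentiles.  Sampling uses
exact enumeration of the (i, l) joint per transcript — no approximation —
so recovered parameters can be compared against analytic expectations.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from fragbias._seq import N_CODE, encode, reverse_complement
from fragbias.alignments import HitTable, LibraryType
from fragbias.bias import (
    FIVE,
    OFFSET_MAX,
    OFFSET_MIN,
    THREE,
    WINDOW,
    PosBiasModel,
    window_bases,
)
from fragbias.fraglen import FragLenDist, truncated_gaussian
from fragbias.transcriptome import Transcript, attach_sequences

TRUTH_SCHEMA = "fragbias_truth_v1"


@dataclass
class SimulationConfig:
    n_transcripts: int = 50
    n_fragments: int = 100_000
    seed: int = 0
    # transcript structure
    length_log_mean: float = 7.2  # lognormal; median ~1340 nt
    length_log_sd: float = 0.35
    min_length: int = 500
    max_length: int = 4000
    gc_content: float = 0.5
    max_exons: int = 3
    isoform_pairs: int = 0
    # abundances
    abundance_log_sd: float = 1.5
    abundances: np.ndarray | None = None  # explicit true rho overrides
    # fragment lengths
    fld_mean: float = 200.0
    fld_sd: float = 80.0
    fld_max: int = 800
    read_length: int = 50
    # library
    library_type: LibraryType = LibraryType.UNSTRANDED
    paired: bool = True
    # planted bias
    seq_bias_strength: float = 0.0  # sd of log-weights at offsets -5..+5
    seq5_table: np.ndarray | None = None  # (21, 4) per-offset weight ratios
    seq3_table: np.ndarray | None = None
    pos5_profile: np.ndarray | None = None  # (20,) twentile weights
    pos3_profile: np.ndarray | None = None

    @property
    def fld_min(self) -> int:
        # no fragment shorter than the read length
        return self.read_length

    def fld(self) -> FragLenDist:
        return truncated_gaussian(self.fld_mean, self.fld_sd, self.fld_min, self.fld_max)


def planted_seq_table(
    rng: np.random.Generator,
    strength: float,
    active: tuple[int, int] = (-5, 5),
) -> np.ndarray:
    """A random (21, 4) per-offset weight table with unit mean per offset.

    Log-weights ~ Normal(0, strength) at offsets in ``active``; 1 elsewhere.
    Rows are normalized to mean 1 under uniform base composition so the
    planted model neither inflates nor deflates overall fragment counts.
    """
    table = np.ones((WINDOW, 4))
    for w, off in enumerate(range(OFFSET_MIN, OFFSET_MAX + 1)):
        if active[0] <= off <= active[1]:
            r = np.exp(rng.normal(0.0, strength, size=4))
            table[w] = r / r.mean()
    return table


def _seq_weights_from_table(enc: np.ndarray, table: np.ndarray, end: str) -> np.ndarray:
    """Per-position planted sequence weight (order-0 product over the window)."""
    B = window_bases(enc, np.arange(len(enc)), end)
    w = np.ones(len(enc))
    for k in range(WINDOW):
        valid = B[:, k] < N_CODE
        w[valid] *= table[k, B[valid, k]]
    return w


def planted_position_weights(
    transcript: Transcript, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """The true per-position w5/w3 implied by the planted bias tables."""
    enc = encode(transcript.sequence)
    L = len(enc)
    w5 = np.ones(L)
    w3 = np.ones(L)
    if config.seq5_table is not None:
        w5 = w5 * _seq_weights_from_table(enc, config.seq5_table, FIVE)
    if config.seq3_table is not None:
        w3 = w3 * _seq_weights_from_table(enc, config.seq3_table, THREE)
    tw = PosBiasModel.twentile(np.arange(L), L)
    if config.pos5_profile is not None:
        w5 = w5 * np.asarray(config.pos5_profile)[tw]
    if config.pos3_profile is not None:
        w3 = w3 * np.asarray(config.pos3_profile)[tw]
    return w5, w3


# ---------------------------------------------------------------------------
# transcriptome generation
# ---------------------------------------------------------------------------

def generate_transcriptome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[Transcript], dict[str, str]]:
    """Random multi-exon transcripts embedded in a synthetic chromosome.

    Returns (transcripts, chromosomes); transcript sequences are attached.
    ``isoform_pairs`` loci contain a second, exon-skipped isoform sharing
    exons with the first, for multi-isoform tests.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    bases = np.array(list("ACGT"))
    p_gc = config.gc_content
    probs = np.array([(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2])

    transcripts: list[Transcript] = []
    chrom_parts: list[str] = []
    cursor = 0
    chrom = "chrS1"
    n_singles = config.n_transcripts - 2 * config.isoform_pairs
    if n_singles < 0:
        raise ValueError("isoform_pairs exceed n_transcripts / 2")

    def draw_length() -> int:
        L = int(rng.lognormal(config.length_log_mean, config.length_log_sd))
        return int(np.clip(L, config.min_length, config.max_length))

    def layout(exon_lengths: list[int]) -> list[tuple[int, int]]:
        exons = []
        pos = cursor
        for k, el in enumerate(exon_lengths):
            exons.append((pos, pos + el))
            pos += el
            if k < len(exon_lengths) - 1:
                pos += int(rng.integers(60, 400))
        return exons

    def split_exons(L: int, n_exons: int) -> list[int]:
        if n_exons == 1:
            return [L]
        cuts = np.sort(rng.choice(np.arange(1, L // 50), size=n_exons - 1, replace=False)) * 50
        edges = np.concatenate(([0], cuts, [L]))
        return list(np.diff(edges).astype(int))

    idx = 0
    for _ in range(n_singles):
        idx += 1
        L = draw_length()
        n_exons = int(rng.integers(1, config.max_exons + 1))
        exons = layout(split_exons(L, min(n_exons, max(1, L // 100))))
        strand = "+" if rng.random() < 0.5 else "-"
        t = Transcript(id=f"T{idx:04d}", chrom=chrom, strand=strand,
                       exons=exons, gene_id=f"G{idx:04d}")
        transcripts.append(t)
        cursor = t.span[1] + int(rng.integers(200, 500))

    for _ in range(config.isoform_pairs):
        idx += 1
        L = draw_length()
        exons = layout(split_exons(L, 3))
        strand = "+" if rng.random() < 0.5 else "-"
        gene = f"G{idx:04d}"
        t1 = Transcript(id=f"T{idx:04d}", chrom=chrom, strand=strand,
                        exons=exons, gene_id=gene)
        # second isoform skips the middle exon, sharing the flanking ones
        t2 = Transcript(id=f"T{idx:04d}b", chrom=chrom, strand=strand,
                        exons=[exons[0], exons[2]], gene_id=gene)
        transcripts.append(t1)
        transcripts.append(t2)
        cursor = t1.span[1] + int(rng.integers(200, 500))

    genome_len = cursor + 200
    seq = "".join(rng.choice(bases, size=genome_len, p=probs))
    chromosomes = {chrom: seq}
    attach_sequences(transcripts, chromosomes)
    return transcripts, chromosomes


# ---------------------------------------------------------------------------
# fragment simulation
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    """Sampled fragments plus per-transcript ground truth."""

    transcripts: list[Transcript]
    config: SimulationConfig
    fld: FragLenDist
    t_idx: np.ndarray  # per fragment: transcript index
    i: np.ndarray  # fragment 5' end (transcript coords)
    j: np.ndarray  # fragment 3' end
    true_rho: np.ndarray
    e_true: np.ndarray  # effective length under the planted bias
    counts: np.ndarray  # realized fragments per transcript
    seq5_table: np.ndarray | None = None
    seq3_table: np.ndarray | None = None

    @property
    def n_fragments(self) -> int:
        return len(self.t_idx)

    @property
    def true_fpkm(self) -> np.ndarray:
        denom = float(np.dot(self.true_rho, self.e_true))
        return 1e9 * self.true_rho / denom

    def hit_table(self, single_end: bool | None = None) -> HitTable:
        """Unique-mapping hit table straight from the truth (no SAM round trip).

        With ``single_end`` the unknown end is masked according to the
        library type: first-strand keeps the 3' end, second-strand the 5',
        unstranded keeps one end chosen by the (seeded) coin flips stored
        at simulation time.
        """
        n = self.n_fragments
        frag = np.arange(n)
        if single_end is None:
            single_end = not self.config.paired
        ii, jj = self.i.copy(), self.j.copy()
        if single_end:
            lt = self.config.library_type
            if lt is LibraryType.FIRST_STRAND:
                ii[:] = -1
            elif lt is LibraryType.SECOND_STRAND:
                jj[:] = -1
            else:
                flip = np.random.default_rng(
                    np.random.SeedSequence([self.config.seed, 3])
                ).random(n) < 0.5
                # flip=True -> the sense (5'-end) read was kept
                jj[flip] = -1
                ii[~flip] = -1
        return HitTable(frag, self.t_idx, ii, jj, n_fragments=n)

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "transcript_id": [t.id for t in self.transcripts],
                "length": [t.length for t in self.transcripts],
                "true_rho": self.true_rho,
                "true_eff_length": self.e_true,
                "true_counts": self.counts,
                "true_fpkm": self.true_fpkm,
            }
        )

    def write_truth(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"#schema={TRUTH_SCHEMA}\n")
            self.truth_frame().to_csv(fh, sep="\t", index=False)


def simulate_fragments(
    transcripts: Sequence[Transcript],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimResult:
    """Sample fragments from the planted-bias generative model."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    cfg = config
    if cfg.seq_bias_strength > 0 and cfg.seq5_table is None:
        table_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
        cfg = replace(
            cfg,
            seq5_table=planted_seq_table(table_rng, cfg.seq_bias_strength),
            seq3_table=planted_seq_table(table_rng, cfg.seq_bias_strength),
        )
    fld = cfg.fld()

    n_t = len(transcripts)
    if cfg.abundances is not None:
        rho = np.asarray(cfg.abundances, float)
        if len(rho) != n_t:
            raise ValueError("abundances length != n_transcripts")
    else:
        rho = rng.lognormal(0.0, cfg.abundance_log_sd, size=n_t)
    rho = rho / rho.sum()

    joints = []
    e_true = np.zeros(n_t)
    sampleable = np.ones(n_t, bool)
    for k, t in enumerate(transcripts):
        L = t.length
        if L < fld.min_len:
            sampleable[k] = False
            joints.append(None)
            continue
        w5, w3 = planted_position_weights(t, cfg)
        rows = []
        lengths = []
        for l in range(fld.min_len, min(fld.max_len, L) + 1):
            d = fld.pmf[l - fld.min_len]
            rows.append(d * w5[: L - l + 1] * w3[l - 1:])
            lengths.append(l)
        flat = np.concatenate(rows)
        e_true[k] = flat.sum()
        joints.append((flat, lengths, [len(r) for r in rows]))

    alpha = rho * e_true
    if alpha.sum() <= 0:
        raise ValueError("no sampleable transcripts")
    alpha = alpha / alpha.sum()
    counts = rng.multinomial(cfg.n_fragments, alpha)

    t_all, i_all, j_all = [], [], []
    for k in range(n_t):
        c = int(counts[k])
        if c == 0 or not sampleable[k]:
            continue
        flat, lengths, sizes = joints[k]
        p = flat / flat.sum()
        draws = rng.choice(len(p), size=c, p=p)
        offsets = np.concatenate(([0], np.cumsum(sizes)))
        row = np.searchsorted(offsets, draws, side="right") - 1
        i = draws - offsets[row]
        l = np.asarray(lengths)[row]
        t_all.append(np.full(c, k))
        i_all.append(i)
        j_all.append(i + l - 1)

    t_idx = np.concatenate(t_all) if t_all else np.zeros(0, int)
    i_arr = np.concatenate(i_all) if i_all else np.zeros(0, int)
    j_arr = np.concatenate(j_all) if j_all else np.zeros(0, int)
    order = np.arange(len(t_idx))  # already deterministic; keep sampling order
    return SimResult(
        transcripts=list(transcripts), config=cfg, fld=fld,
        t_idx=t_idx[order], i=i_arr[order], j=j_arr[order],
        true_rho=rho, e_true=e_true, counts=counts,
        seq5_table=cfg.seq5_table, seq3_table=cfg.seq3_table,
    )


# ---------------------------------------------------------------------------
# SAM output
# ---------------------------------------------------------------------------

def write_sam(
    sim: SimResult,
    chromosomes: dict[str, str],
    path: str,
    transcriptome_space: bool = False,
) -> None:
    """Write simulated fragments as genome- or transcriptome-space SAM.

    Read/strand/mate roles follow the library type: the sense (5'-end) read
    is read1 under second-strand, read2 under first-strand, and a seeded
    coin flip under unstranded chemistry.
    """
    cfg = sim.config
    rl = cfg.read_length
    if transcriptome_space:
        refs = [t.id for t in sim.transcripts]
        lengths = [t.length for t in sim.transcripts]
    else:
        refs = list(chromosomes)
        lengths = [len(chromosomes[c]) for c in refs]
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": r, "LN": ln} for r, ln in zip(refs, lengths)],
        }
    )
    ref_id = {r: k for k, r in enumerate(refs)}
    flips = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 3])
    ).random(sim.n_fragments) < 0.5

    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for n in range(sim.n_fragments):
            t = sim.transcripts[sim.t_idx[n]]
            i, j = int(sim.i[n]), int(sim.j[n])
            name = f"frag{n:08d}"
            sense_is_read1 = {
                LibraryType.SECOND_STRAND: True,
                LibraryType.FIRST_STRAND: False,
                LibraryType.UNSTRANDED: bool(flips[n]),
            }[cfg.library_type]
            r5 = _make_read(t, i, i + rl, sense=True, header=header,
                            ref_id=ref_id, transcriptome_space=transcriptome_space)
            r3 = _make_read(t, j - rl + 1, j + 1, sense=False, header=header,
                            ref_id=ref_id, transcriptome_space=transcriptome_space)
            if cfg.paired:
                first, second = (r5, r3) if sense_is_read1 else (r3, r5)
                _pair(first, second, name)
                out.write(first)
                out.write(second)
            else:
                # single-end: first-strand keeps the antisense (3') read,
                # second-strand the sense (5') read, unstranded a coin flip
                keep_five = {
                    LibraryType.SECOND_STRAND: True,
                    LibraryType.FIRST_STRAND: False,
                    LibraryType.UNSTRANDED: bool(flips[n]),
                }[cfg.library_type]
                read = r5 if keep_five else r3
                read.query_name = name
                out.write(read)


def _make_read(t: Transcript, start: int, end: int, sense: bool, header,
               ref_id, transcriptome_space: bool) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    read_seq = t.sequence[start:end]
    if transcriptome_space:
        seg.reference_id = ref_id[t.id]
        seg.reference_start = start
        seg.cigartuples = [(0, end - start)]
        genomic_reverse = not sense
        seg.query_sequence = read_seq if sense else reverse_complement(read_seq)
    else:
        blocks = t.transcript_interval_to_blocks(start, end)
        seg.reference_id = ref_id[t.chrom]
        seg.reference_start = blocks[0][0]
        cig = []
        for (a, b), nxt in zip(blocks, blocks[1:] + [None]):
            cig.append((0, b - a))
            if nxt is not None:
                cig.append((3, nxt[0] - b))
        seg.cigartuples = cig
        genomic_strand_plus = (t.strand == "+") == sense
        genomic_reverse = not genomic_strand_plus
        plus_seq = read_seq if t.strand == "+" else reverse_complement(read_seq)
        # SAM stores the read as aligned to the forward genomic strand
        seg.query_sequence = plus_seq
    seg.is_reverse = genomic_reverse
    seg.mapping_quality = 255
    seg.query_qualities = pysam.qualitystring_to_array("I" * len(read_seq))
    return seg


def _pair(first: pysam.AlignedSegment, second: pysam.AlignedSegment, name: str) -> None:
    for seg, mate, is1 in ((first, second, True), (second, first, False)):
        seg.query_name = name
        seg.is_paired = True
        seg.is_proper_pair = True
        seg.is_read1 = is1
        seg.is_read2 = not is1
        seg.next_reference_id = mate.reference_id
        seg.next_reference_start = mate.reference_start
        seg.mate_is_reverse = mate.is_reverse
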