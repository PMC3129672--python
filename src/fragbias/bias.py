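"""Sequence-specific and positional fragment-bias models.

Sequence bias
-------------
Each fragment end (5', 3') gets a pair of Markov sequence models —
foreground (windows observed at fragment ends) and background (all
possible window placements) — over a 21-base window spanning offsets
-8..+12 relative to the end base (offset 0 is the first base of the end
sequence; only non-negative offsets are internal to the fragment).  The
context order ramps up from 0 at the window start and is capped at a
configurable maximum (default 1: nearest-neighbor dependencies — higher
orders demand far more training fragments than a desk-scale run has; see
``order_schedule``).  The bias weight of a window is the likelihood ratio

    s(window) = prod_w P_fg(base_w | context_w) / P_bg(base_w | context_w).

Windows for the 3' end read the *complement* (not reverse-complement) of
the transcript walking outward from the end base (transcript coordinate
j - offset), so both end models read in the orientation of the primer
during first- or second-strand synthesis.

The abundance confound — highly expressed transcripts dominating the end
counts — is removed by weighting every *background* position by the
initial (uniform-bias) abundance estimate rho0 of its transcript, so that
the foreground/background ratio cancels expression and isolates bias.

Positional bias
---------------
Fragment-end location effects depend on transcript length, so positions
are modeled with 20 windows (twentiles of the transcript) x 5 transcript-
length bins, separately per end.  Each parameter is the ratio of the
observed (abundance-normalized) end density in a twentile to the density
expected under the uniform-bias model — which accounts for the fact that
e.g. a 5' end cannot lie closer than one fragment length to the 3' end.

Both bias factors multiply into the per-position weights w5[i], w3[j];
the total bias weight of a fragment is b(t,i,j) = w5[i] * w3[j], and the
bias-adjusted effective length is

    e~(t) = sum_l D(l) * sum_i w5[i] * w3[i + l - 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from fragbias._seq import N_CODE, complement_codes, encode
from fragbias.fraglen import FragLenDist

log = logging.getLogger(__name__)

OFFSET_MIN = -8
OFFSET_MAX = 12
WINDOW = OFFSET_MAX - OFFSET_MIN + 1  # 21
OFFSETS = np.arange(OFFSET_MIN, OFFSET_MAX + 1)
DEFAULT_MAX_ORDER = 1
DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_SHRINKAGE = 25.0  # prior strength pulling sparse contexts toward ratio 1


def order_schedule(max_order: int = DEFAULT_MAX_ORDER) -> tuple[int, ...]:
    """Context order per window position: ramp 0,1,... capped at max_order.

    Higher orders capture longer-range dependencies but need far more
    training data; with limited fragments they allow individual hot windows
    to be memorized through near-unique contexts, exploding their weights.
    """
    if not 0 <= max_order <= 3:
        raise ValueError("max_order must be in 0..3")
    return tuple(min(w, max_order) for w in range(WINDOW))
N_POS_WINDOWS = 20
N_LEN_BINS = 5
FIVE = "five"
THREE = "three"


# ---------------------------------------------------------------------------
# window extraction
# ---------------------------------------------------------------------------

def _pad_five(enc: np.ndarray) -> np.ndarray:
    """Transcript codes padded so 5'-window position w of end i is pad[i+w]."""
    return np.concatenate(
        [np.full(-OFFSET_MIN, N_CODE, np.uint8), enc,
         np.full(OFFSET_MAX, N_CODE, np.uint8)]
    )


def _pad_three(enc: np.ndarray) -> np.ndarray:
    """Complemented codes padded so 3'-window position w of end j is pad[j+20-w].

    Window position w corresponds to offset o = w - 8 and reads
    complement(seq[j - o]).
    """
    return np.concatenate(
        [np.full(OFFSET_MAX, N_CODE, np.uint8), complement_codes(enc),
         np.full(-OFFSET_MIN, N_CODE, np.uint8)]
    )


def window_bases(enc: np.ndarray, positions: np.ndarray, end: str) -> np.ndarray:
    """(n, 21) window base codes for the given end positions on a transcript."""
    positions = np.asarray(positions, dtype=np.int64)
    w = np.arange(WINDOW)
    if end == FIVE:
        return _pad_five(enc)[positions[:, None] + w[None, :]]
    if end == THREE:
        return _pad_three(enc)[positions[:, None] + (WINDOW - 1 - w)[None, :]]
    raise ValueError(f"end must be {FIVE!r} or {THREE!r}")


def _contexts(B: np.ndarray, w: int, orders: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Context ids and validity for window position w given base matrix B.

    The context id encodes the ``order`` preceding window bases in base 4,
    most recent base in the least-significant digit.
    """
    k = orders[w]
    base = B[:, w]
    ctx = np.zeros(len(B), dtype=np.int64)
    valid = base < 4
    for m in range(1, k + 1):
        prev = B[:, w - m]
        valid &= prev < 4
        ctx += prev.astype(np.int64) << (2 * (m - 1))
    ctx[~valid] = 0  # placeholder; invalid rows are masked by callers
    return ctx, valid


# ---------------------------------------------------------------------------
# sequence bias model
# ---------------------------------------------------------------------------

@dataclass
class SeqBiasModel:
    """Foreground/background variable-order Markov models for one fragment end."""

    end: str
    fg_counts: list[np.ndarray]
    bg_counts: list[np.ndarray]
    orders: tuple[int, ...] = field(default_factory=order_schedule)
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    shrinkage: float = DEFAULT_SHRINKAGE
    log_ratio: list[np.ndarray] = field(default_factory=list, repr=False)

    @classmethod
    def empty(
        cls,
        end: str,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        orders: tuple[int, ...] | None = None,
    ) -> "SeqBiasModel":
        orders = order_schedule() if orders is None else tuple(orders)
        fg = [np.zeros((4 ** k, 4)) for k in orders]
        bg = [np.zeros((4 ** k, 4)) for k in orders]
        return cls(end=end, fg_counts=fg, bg_counts=bg, orders=orders,
                   pseudocount=pseudocount)

    @classmethod
    def identity(cls, end: str) -> "SeqBiasModel":
        """A no-op model: every weight ratio is exactly 1."""
        m = cls.empty(end)
        m.finalize()
        for lr in m.log_ratio:
            lr[:] = 0.0
        return m

    def finalize(self) -> "SeqBiasModel":
        """Normalize counts into log weight ratios.

        Background counts are rescaled to the foreground's total mass so the
        pseudocount perturbs both comparably, and foreground conditionals are
        shrunk toward the background (a Dirichlet prior of ``shrinkage``
        effective observations per context row centered on the background
        distribution): contexts without foreground evidence get ratio 1
        instead of an arbitrary, variance-exploding estimate.
        """
        self.log_ratio = []
        for fg, bg in zip(self.fg_counts, self.bg_counts):
            fg_tot, bg_tot = fg.sum(), bg.sum()
            scale = fg_tot / bg_tot if bg_tot > 0 and fg_tot > 0 else 1.0
            bg_p = bg * scale + self.pseudocount
            bg_p /= bg_p.sum(axis=1, keepdims=True)
            fg_p = fg + self.shrinkage * bg_p
            fg_p /= fg_p.sum(axis=1, keepdims=True)
            self.log_ratio.append(np.log(fg_p) - np.log(bg_p))
        return self

    # -- evaluation --------------------------------------------------------
    def weights_at(self, enc: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Bias weight s(end at position p) for each position on a transcript."""
        if not self.log_ratio:
            self.finalize()
        B = window_bases(enc, positions, self.end)
        total = np.zeros(len(B))
        for w in range(WINDOW):
            ctx, valid = _contexts(B, w, self.orders)
            lw = self.log_ratio[w][ctx, np.where(valid, B[:, w], 0)]
            total += np.where(valid, lw, 0.0)  # N / out-of-range: ratio 1
        return np.exp(total)

    def position_weights(self, enc: np.ndarray) -> np.ndarray:
        """Weight at every position 0..L-1 of an encoded transcript."""
        return self.weights_at(enc, np.arange(len(enc)))

    def weight_of_window(self, codes: np.ndarray) -> float:
        """Weight ratio of one explicit 21-base window (model orientation)."""
        if not self.log_ratio:
            self.finalize()
        B = np.asarray(codes)[None, :]
        total = 0.0
        for w in range(WINDOW):
            ctx, valid = _contexts(B, w, self.orders)
            if valid[0]:
                total += self.log_ratio[w][ctx[0], B[0, w]]
        return float(np.exp(total))

    def marginal_ratios(self) -> np.ndarray:
        """(21, 4) per-offset marginal foreground/background frequency ratios.

        Contexts are marginalized out; this is the order-0 projection used
        for reporting and for comparison against planted per-offset tables.
        """
        out = np.empty((WINDOW, 4))
        for w in range(WINDOW):
            fg = self.fg_counts[w].sum(axis=0) + self.pseudocount
            bg = self.bg_counts[w].sum(axis=0) + self.pseudocount
            out[w] = (fg / fg.sum()) / (bg / bg.sum())
        return out

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "end": self.end,
            "offsets": [int(o) for o in OFFSETS],
            "orders": list(self.orders),
            "pseudocount": self.pseudocount,
            "shrinkage": self.shrinkage,
            "fg_counts": [c.tolist() for c in self.fg_counts],
            "bg_counts": [c.tolist() for c in self.bg_counts],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SeqBiasModel":
        m = cls(
            end=d["end"],
            fg_counts=[np.asarray(c, float) for c in d["fg_counts"]],
            bg_counts=[np.asarray(c, float) for c in d["bg_counts"]],
            orders=tuple(d["orders"]),
            pseudocount=float(d["pseudocount"]),
            shrinkage=float(d.get("shrinkage", DEFAULT_SHRINKAGE)),
        )
        return m.finalize()


def seq_weight(model: SeqBiasModel, context) -> float:
    """Evaluate the weight ratio of a single 21-base window.

    ``context`` is the window in the model's own orientation (for the 3'
    end: complemented bases walking outward from the end), as a string or
    encoded array; 'N' and padding contribute ratio 1.
    """
    codes = encode(context) if isinstance(context, str) else np.asarray(context)
    if len(codes) != WINDOW:
        raise ValueError(f"context must cover {WINDOW} positions")
    return model.weight_of_window(codes)


def null_position_density(length: int, fld: FragLenDist | None, end: str) -> np.ndarray:
    """Unnormalized null density of a fragment end at each transcript position.

    Under uniform bias a 5' end at i requires a fragment length l <= L - i
    (a 3' end at j requires l <= j + 1), so the null end density is the
    fragment-length CDF evaluated at the available room — not uniform.
    With ``fld=None`` every position gets weight 1.
    """
    if fld is None:
        return np.ones(length)
    cdf = np.concatenate(([0.0], np.cumsum(fld.pmf)))

    def upto(maxlen):
        k = np.clip(maxlen - fld.min_len + 1, 0, len(fld.pmf))
        return cdf[k]

    pos = np.arange(length)
    return upto(length - pos) if end == FIVE else upto(pos + 1)


def learn_seq_bias(
    hit_table,
    transcripts,
    rho0: np.ndarray,
    end: str = FIVE,
    fld: FragLenDist | None = None,
    posterior: np.ndarray | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    max_obs: int | None = 10_000_000,
    seed: int = 0,
    exclude_transcripts: set[int] | frozenset = frozenset(),
    encoded: Sequence[np.ndarray] | None = None,
    max_order: int = DEFAULT_MAX_ORDER,
    shrinkage: float = DEFAULT_SHRINKAGE,
) -> SeqBiasModel:
    """Learn one end's sequence-bias model, normalized by abundance.

    Foreground: windows at observed fragment ends, each hit weighted by its
    posterior assignment probability (uniform split over a fragment's hits
    when ``posterior`` is None).  Background: every possible window
    placement on every transcript, weighted by the transcript's initial
    abundance rho0 — this is what cancels expression out of the ratio.
    """
    model = SeqBiasModel.empty(end, pseudocount, orders=order_schedule(max_order))
    model.shrinkage = shrinkage
    if encoded is None:
        encoded = [encode(t.sequence) for t in transcripts]
    coords = hit_table.i if end == FIVE else hit_table.j
    weights = posterior if posterior is not None else _uniform_posterior(hit_table)

    sel = coords >= 0
    if exclude_transcripts:
        sel &= ~np.isin(hit_table.t, list(exclude_transcripts))
    idx = np.flatnonzero(sel)
    if max_obs is not None and len(idx) > max_obs:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(idx, size=max_obs, replace=False))
    if len(idx) == 0 or float(np.sum(weights[idx])) <= 0:
        raise ValueError("no usable fragment-end observations for bias learning")

    # foreground: group end observations by transcript
    t_of = hit_table.t[idx]
    order = np.argsort(t_of, kind="stable")
    idx = idx[order]
    t_of = t_of[order]
    bounds = np.searchsorted(t_of, np.arange(len(transcripts) + 1))
    for k in range(len(transcripts)):
        s, e = bounds[k], bounds[k + 1]
        if s == e:
            continue
        B = window_bases(encoded[k], coords[idx[s:e]], end)
        wts = weights[idx[s:e]]
        _accumulate(model.fg_counts, B, wts, orders=model.orders)

    # background: every possible end position of every expressed transcript,
    # weighted by rho0 times the null end density (where a fragment fits)
    for k, enc in enumerate(encoded):
        if rho0[k] <= 0 or k in exclude_transcripts:
            continue
        B = window_bases(enc, np.arange(len(enc)), end)
        wpos = null_position_density(len(enc), fld, end)
        _accumulate(model.bg_counts, B, wpos, scale=float(rho0[k]), orders=model.orders)
    return model.finalize()


def _uniform_posterior(hit_table) -> np.ndarray:
    sizes = np.diff(np.concatenate((hit_table.starts, [len(hit_table)])))
    out = np.empty(len(hit_table))
    for s, n in zip(hit_table.starts, sizes):
        out[s:s + n] = 1.0 / n
    return out


def _accumulate(counts, B, weights, scale: float = 1.0,
                orders: tuple[int, ...] | None = None) -> None:
    if orders is None:
        orders = order_schedule()
    for w in range(WINDOW):
        ctx, valid = _contexts(B, w, orders)
        flat = ctx[valid] * 4 + B[valid, w]
        n = counts[w].size
        if weights is None:
            add = np.bincount(flat, minlength=n) * scale
        else:
            add = np.bincount(flat, weights=weights[valid], minlength=n) * scale
        counts[w] += add.reshape(counts[w].shape)


# ---------------------------------------------------------------------------
# positional bias model
# ---------------------------------------------------------------------------

@dataclass
class PosBiasModel:
    """20-twentile x 5-length-bin positional weight tables, one per end."""

    bin_edges: np.ndarray  # inner edges (len n_len_bins - 1), data-derived
    table5: np.ndarray  # (n_len_bins, 20)
    table3: np.ndarray

    @classmethod
    def identity(cls, bin_edges=None) -> "PosBiasModel":
        edges = np.asarray(bin_edges if bin_edges is not None else [np.inf] * (N_LEN_BINS - 1), float)
        ones = np.ones((len(edges) + 1, N_POS_WINDOWS))
        return cls(bin_edges=edges, table5=ones.copy(), table3=ones.copy())

    def length_bin(self, length: int) -> int:
        return int(np.searchsorted(self.bin_edges, length, side="right"))

    @staticmethod
    def twentile(pos, length: int) -> np.ndarray:
        pos = np.asarray(pos)
        return np.minimum(pos * N_POS_WINDOWS // length, N_POS_WINDOWS - 1)

    def position_weights(self, length: int, end: str) -> np.ndarray:
        table = self.table5 if end == FIVE else self.table3
        row = table[self.length_bin(length)]
        return row[self.twentile(np.arange(length), length)]

    def weight(self, pos: int, length: int, end: str) -> float:
        table = self.table5 if end == FIVE else self.table3
        return float(table[self.length_bin(length), int(self.twentile(pos, length))])

    def to_dict(self) -> dict:
        return {
            "bin_edges": [float(e) for e in self.bin_edges],
            "table5": self.table5.tolist(),
            "table3": self.table3.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PosBiasModel":
        return cls(
            bin_edges=np.asarray(d["bin_edges"], float),
            table5=np.asarray(d["table5"], float),
            table3=np.asarray(d["table3"], float),
        )


def length_bin_edges(
    lengths: np.ndarray, rho0: np.ndarray | None = None, n_bins: int = N_LEN_BINS
) -> np.ndarray:
    """Empirical length-quantile bin edges over expressed transcripts."""
    lengths = np.asarray(lengths, float)
    if rho0 is not None:
        expressed = lengths[np.asarray(rho0) > 0]
        if expressed.size:
            lengths = expressed
    qs = np.arange(1, n_bins) / n_bins
    return np.quantile(lengths, qs)


def null_end_distribution(length: int, fld: FragLenDist, end: str) -> np.ndarray:
    """Twentile distribution of an end under the uniform-bias model.

    For a 5' end at i the fragment must fit: i <= L - l; for a 3' end at j:
    l <= j + 1.  Under the uniform-bias likelihood every feasible (i, l)
    placement has probability D(l) / e~0(t), so the null end density at a
    position is the total fragment-length probability that fits there;
    aggregating positions into twentiles gives the null against which the
    observed end density is ratioed.
    """
    L = length
    ls = fld.lengths
    c = np.where(ls <= L, fld.pmf, 0.0)
    cum = np.concatenate(([0.0], np.cumsum(c)))  # cum[k] = sum over first k lengths

    def upto(maxlen):
        k = np.clip(maxlen - fld.min_len + 1, 0, len(ls))
        return cum[k]

    pos = np.arange(L)
    if end == FIVE:
        dens = upto(L - pos)
    else:
        dens = upto(pos + 1)
    tw = PosBiasModel.twentile(pos, L)
    out = np.bincount(tw, weights=dens, minlength=N_POS_WINDOWS)
    total = out.sum()
    return out / total if total > 0 else np.full(N_POS_WINDOWS, 1.0 / N_POS_WINDOWS)


def learn_pos_bias(
    hit_table,
    transcripts,
    rho0: np.ndarray,
    fld: FragLenDist,
    end: str = FIVE,
    bin_edges: np.ndarray | None = None,
    posterior: np.ndarray | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    exclude_transcripts: set[int] | frozenset = frozenset(),
) -> PosBiasModel:
    """Learn one end's positional-bias table.

    The observed twentile distribution of fragment ends (posterior-weighted)
    in each transcript-length bin is divided by the uniform-bias null
    distribution (mixture over the bin's transcripts, weighted by observed
    end mass).  Empty bins keep weight 1 everywhere.
    """
    lengths = np.array([t.length for t in transcripts])
    if bin_edges is None:
        bin_edges = length_bin_edges(lengths, rho0)
    model = PosBiasModel.identity(bin_edges)
    coords = hit_table.i if end == FIVE else hit_table.j
    weights = posterior if posterior is not None else _uniform_posterior(hit_table)

    sel = coords >= 0
    if exclude_transcripts:
        sel &= ~np.isin(hit_table.t, list(exclude_transcripts))
    idx = np.flatnonzero(sel)
    t_of = hit_table.t[idx]
    bins_of_t = np.searchsorted(bin_edges, lengths, side="right")

    n_bins = len(bin_edges) + 1
    fg = np.zeros((n_bins, N_POS_WINDOWS))
    per_t_mass = np.bincount(t_of, weights=weights[idx], minlength=len(transcripts))
    tw = np.minimum(coords[idx] * N_POS_WINDOWS // lengths[t_of], N_POS_WINDOWS - 1)
    np.add.at(fg, (bins_of_t[t_of], tw), weights[idx])

    table = np.ones((n_bins, N_POS_WINDOWS))
    for b in range(n_bins):
        total = fg[b].sum()
        if total <= 0:
            log.warning("positional bias: length bin %d has no fragments", b)
            continue
        null = np.zeros(N_POS_WINDOWS)
        for k in np.flatnonzero((bins_of_t == b) & (per_t_mass > 0)):
            if k in exclude_transcripts:
                continue
            null += per_t_mass[k] * null_end_distribution(int(lengths[k]), fld, end)
        null /= null.sum()
        prob = (fg[b] + pseudocount) / (total + N_POS_WINDOWS * pseudocount)
        good = null > 0
        table[b, good] = prob[good] / null[good]
    if end == FIVE:
        model.table5 = table
    else:
        model.table3 = table
    return model


def merge_pos_models(m5: PosBiasModel, m3: PosBiasModel) -> PosBiasModel:
    """Combine two single-end learns (sharing bin edges) into one model."""
    if not np.allclose(m5.bin_edges, m3.bin_edges):
        raise ValueError("positional models have differing length-bin edges")
    return PosBiasModel(bin_edges=m5.bin_edges, table5=m5.table5, table3=m3.table3)


# ---------------------------------------------------------------------------
# combined weights, effective length
# ---------------------------------------------------------------------------

@dataclass
class BiasWeights:
    """Per-position combined sequence x positional weights for one transcript."""

    w5: np.ndarray
    w3: np.ndarray

    @classmethod
    def uniform(cls, length: int) -> "BiasWeights":
        return cls(w5=np.ones(length), w3=np.ones(length))


def compute_bias_weights(
    transcript_or_enc,
    seq5: SeqBiasModel | None = None,
    seq3: SeqBiasModel | None = None,
    pos: PosBiasModel | None = None,
) -> BiasWeights:
    """Evaluate w5[i], w3[j] at every position of a transcript.

    Passing None for a component leaves that factor at 1.
    """
    enc = (
        transcript_or_enc
        if isinstance(transcript_or_enc, np.ndarray)
        else encode(transcript_or_enc.sequence)
    )
    L = len(enc)
    w5 = seq5.position_weights(enc) if seq5 is not None else np.ones(L)
    w3 = seq3.position_weights(enc) if seq3 is not None else np.ones(L)
    if pos is not None:
        w5 = w5 * pos.position_weights(L, FIVE)
        w3 = w3 * pos.position_weights(L, THREE)
    return BiasWeights(w5=w5, w3=w3)


def total_bias_weight(
    transcript,
    i: int,
    j: int,
    seq5: SeqBiasModel | None = None,
    seq3: SeqBiasModel | None = None,
    pos5: PosBiasModel | None = None,
    pos3: PosBiasModel | None = None,
) -> float:
    """b(t,i,j) = s5(t,i) * p5(bin(L), tw(i)) * s3(t,j) * p3(bin(L), tw(j))."""
    enc = encode(transcript.sequence)
    L = len(enc)
    if not (0 <= i <= j < L):
        raise ValueError(f"require 0 <= i <= j < L; got i={i}, j={j}, L={L}")
    b = 1.0
    if seq5 is not None:
        b *= float(seq5.weights_at(enc, np.array([i]))[0])
    if seq3 is not None:
        b *= float(seq3.weights_at(enc, np.array([j]))[0])
    if pos5 is not None:
        b *= pos5.weight(i, L, FIVE)
    if pos3 is not None:
        b *= pos3.weight(j, L, THREE)
    return b


def effective_length(bias_weights: BiasWeights, fld: FragLenDist) -> float:
    """Bias-adjusted effective length e~(t) = sum_l D(l) sum_i w5[i] w3[i+l-1]."""
    w5, w3 = bias_weights.w5, bias_weights.w3
    L = len(w5)
    total = 0.0
    for k, l in enumerate(range(fld.min_len, min(fld.max_len, L) + 1)):
        d = fld.pmf[l - fld.min_len]
        if d == 0:
            continue
        total += d * float(np.dot(w5[: L - l + 1], w3[l - 1:]))
    return total


def effective_length_uniform(length: int, fld: FragLenDist) -> float:
    """Classical effective length sum_l D(l) (L - l + 1) (all weights 1)."""
    ls = fld.lengths
    ok = ls <= length
    return float(np.dot(fld.pmf[ok], length - ls[ok] + 1))


def transcript_bias_metric(e_corrected: float, e_uniform: float) -> float:
    """log2 fold change in effective length; NaN when undefined."""
    if e_uniform <= 0 or e_corrected <= 0:
        return float("nan")
    return float(np.log2(e_corrected / e_uniform))
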