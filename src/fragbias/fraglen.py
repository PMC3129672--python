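"""Fragment-length distribution D.

D(l) is the marginal prior on fragment length.  It is estimated empirically
from paired-end fragments in single-isoform loci when enough are available,
and otherwise falls back to a discretized truncated Gaussian (defaults:
mean 200 nt, sd 80 nt) with zero mass below the minimum read length.  The
within-transcript position normalization (a fragment of length l has
L - l + 1 placements) lives in the effective-length computation, not here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import ndimage, stats

log = logging.getLogger(__name__)

DEFAULT_MEAN = 200.0
DEFAULT_SD = 80.0
DEFAULT_MAX_LEN = 800
DEFAULT_MIN_EMPIRICAL = 10_000
DEFAULT_BANDWIDTH = 5.0


@dataclass
class FragLenDist:
    """Probability mass function over integer fragment lengths."""

    min_len: int
    pmf: np.ndarray  # pmf[k] = P(length == min_len + k)
    source: str = "unspecified"

    def __post_init__(self) -> None:
        self.pmf = np.asarray(self.pmf, dtype=float)
        total = self.pmf.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("fragment-length pmf has no mass")
        self.pmf = self.pmf / total

    @property
    def max_len(self) -> int:
        return self.min_len + len(self.pmf) - 1

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(self.min_len, self.max_len + 1)

    @property
    def mean(self) -> float:
        return float(np.dot(self.lengths, self.pmf))

    @property
    def sd(self) -> float:
        return float(np.sqrt(np.dot((self.lengths - self.mean) ** 2, self.pmf)))

    def prob(self, length) -> np.ndarray | float:
        """D(l); zero outside [min_len, max_len]. Accepts scalars or arrays."""
        length = np.asarray(length)
        idx = length - self.min_len
        ok = (idx >= 0) & (idx < len(self.pmf))
        out = np.zeros(length.shape, dtype=float)
        out[ok] = self.pmf[idx[ok]]
        if length.ndim == 0:
            return float(out)
        return out


def truncated_gaussian(
    mean: float = DEFAULT_MEAN,
    sd: float = DEFAULT_SD,
    min_len: int = 1,
    max_len: int = DEFAULT_MAX_LEN,
) -> FragLenDist:
    """Discretized Gaussian on integers in [min_len, max_len], renormalized.

    The mass at integer l is the normal density integrated over the unit bin
    [l - 1/2, l + 1/2]; lengths below ``min_len`` get zero probability and
    the remainder is renormalized.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if min_len > max_len:
        raise ValueError(f"degenerate length range [{min_len}, {max_len}]")
    lengths = np.arange(min_len, max_len + 1)
    upper = stats.norm.cdf(lengths + 0.5, loc=mean, scale=sd)
    lower = stats.norm.cdf(lengths - 0.5, loc=mean, scale=sd)
    return FragLenDist(min_len=min_len, pmf=upper - lower, source="truncated-gaussian")


def estimate_empirical(
    lengths: Iterable[int] | np.ndarray,
    min_len: int = 1,
    max_len: int = DEFAULT_MAX_LEN,
    bandwidth: float = DEFAULT_BANDWIDTH,
    min_count: int = DEFAULT_MIN_EMPIRICAL,
    fallback_mean: float = DEFAULT_MEAN,
    fallback_sd: float = DEFAULT_SD,
) -> FragLenDist:
    """Empirical fragment-length distribution from observed implied lengths.

    ``lengths`` are implied fragment lengths (paired-end hits in
    single-isoform loci; see :func:`single_isoform_lengths`).  Lengths
    outside [min_len, max_len] are excluded.  The histogram is smoothed
    with a small Gaussian kernel (``bandwidth`` in nt; 0 disables) to avoid
    zero-probability holes.  With fewer than ``min_count`` qualifying
    observations the truncated-Gaussian fallback is returned instead.
    """
    arr = np.asarray(list(lengths) if not isinstance(lengths, np.ndarray) else lengths)
    arr = arr[(arr >= min_len) & (arr <= max_len)]
    if arr.size < min_count:
        log.warning(
            "only %d qualifying fragments (< %d); falling back to truncated "
            "Gaussian(mean=%g, sd=%g)",
            arr.size, min_count, fallback_mean, fallback_sd,
        )
        return truncated_gaussian(fallback_mean, fallback_sd, min_len, max_len)
    hist = np.bincount(arr - min_len, minlength=max_len - min_len + 1).astype(float)
    if bandwidth > 0:
        hist = ndimage.gaussian_filter1d(hist, sigma=bandwidth, mode="constant")
    return FragLenDist(min_len=min_len, pmf=hist, source="empirical")


def estimate_from_hits(hit_table, transcripts, loci, **kwargs) -> FragLenDist:
    """Spec-level convenience: empirical FLD from single-isoform-locus hits."""
    return estimate_empirical(single_isoform_lengths(hit_table, transcripts, loci), **kwargs)


def single_isoform_lengths(hit_table, transcripts, loci) -> np.ndarray:
    """Implied lengths of fragments hitting only one single-isoform locus.

    Qualifying fragments have exactly one hit, with both ends known, on a
    transcript that is alone in its locus.
    """
    single = {
        next(iter(l.transcript_ids)) for l in loci if len(l.transcript_ids) == 1
    }
    single_idx = {k for k, t in enumerate(transcripts) if t.id in single}
    out = []
    starts = hit_table.starts
    ends = np.concatenate((starts[1:], [len(hit_table)])) if len(starts) else starts
    for s, e in zip(starts, ends):
        if e - s != 1:
            continue
        t, i, j = hit_table.t[s], hit_table.i[s], hit_table.j[s]
        if t in single_idx and i >= 0 and j >= 0:
            out.append(j - i + 1)
    return np.asarray(out, dtype=np.int64)
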