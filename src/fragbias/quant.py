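"""Likelihood model and abundance estimation.

A fragment f aligned to transcript t with 5'/3' ends (i, j) contributes

    P(f | t) = D(I_t(f)) * b(t, i, j) / e~(t)

where D is the fragment-length distribution, b the total bias weight and
e~(t) the bias-adjusted effective length (the per-transcript normalizer:
summing P over every feasible (i, j) gives exactly 1).  For single-end
data where one end is unknown, P marginalizes D over the unknown end.

Relative abundances rho_t (decomposed per locus as rho_t = beta_g *
gamma_t) are maximized by EM: the fraction of fragments deriving from t
is alpha_t = rho_t * e~(t) / sum_u rho_u * e~(u); the E-step assigns each
fragment across its hits proportionally to alpha_t * P(f|t) and the
M-step re-estimates alpha from the posterior masses.  The model is linear
in rho for fixed bias, so this converges to the global maximum.

The full procedure is a coordinate ascent: (1) maximize rho with uniform
bias weights -> rho0; (2) learn sequence and positional bias weighted by
rho0; (3) recompute effective lengths and re-maximize rho.  A single
round is the default; further rounds buy little likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from fragbias._seq import encode
from fragbias.alignments import Hit, HitTable
from fragbias.bias import (
    FIVE,
    THREE,
    BiasWeights,
    PosBiasModel,
    SeqBiasModel,
    compute_bias_weights,
    effective_length,
    effective_length_uniform,
    learn_pos_bias,
    learn_seq_bias,
    length_bin_edges,
    merge_pos_models,
    transcript_bias_metric,
)
from fragbias.fraglen import FragLenDist
from fragbias.transcriptome import Locus, Transcript

log = logging.getLogger(__name__)


@dataclass
class QuantConfig:
    no_seq_bias: bool = False
    no_pos_bias: bool = False
    iterations: int = 1
    tol: float = 1e-6
    max_iter: int = 1000
    learn_single_isoform_only: bool = False
    max_learn_obs: int | None = 10_000_000
    pseudocount: float = 1.0
    vlmm_max_order: int = 1  # context-order cap of the sequence bias models
    shrinkage: float = 25.0  # prior obs/row pulling sparse contexts to ratio 1
    seed: int = 0
    # transcript indices whose fragments are withheld from bias learning
    # (cross-validation of per-transcript bias tracks)
    exclude_from_learning: frozenset = frozenset()


@dataclass
class AbundanceEstimate:
    """Maximum-likelihood abundance estimate over a fixed bias model."""

    alpha: np.ndarray  # fraction of fragments deriving from each transcript
    rho: np.ndarray  # relative molar abundance (alpha / e~, normalized)
    beta: np.ndarray  # per-locus abundance
    gamma: np.ndarray  # within-locus proportion
    expected_counts: np.ndarray
    loglik: float
    loglik_trace: list[float] = field(default_factory=list)
    n_fragments_used: int = 0
    n_dropped: int = 0


def fragment_likelihood(
    hit: Hit | tuple, bias_weights: BiasWeights, fld: FragLenDist, eff_len: float
) -> float:
    """P(f | t) for one hit; marginalizes over an unknown end (single-end)."""
    if isinstance(hit, Hit):
        i, j = hit.five_prime, hit.three_prime
    else:
        i, j = hit
    w5, w3 = bias_weights.w5, bias_weights.w3
    L = len(w5)
    if eff_len <= 0:
        return 0.0
    if i is not None and j is not None:
        d = fld.prob(j - i + 1)
        return float(d * w5[i] * w3[j] / eff_len)
    if i is not None:
        js = i + fld.lengths - 1
        ok = js < L
        return float(w5[i] * np.dot(fld.pmf[ok], w3[js[ok]]) / eff_len)
    if j is not None:
        is_ = j - fld.lengths + 1
        ok = is_ >= 0
        return float(w3[j] * np.dot(fld.pmf[ok], w5[is_[ok]]) / eff_len)
    raise ValueError("hit must have at least one known end")


def compute_hit_probs(
    hit_table: HitTable,
    weights: Sequence[BiasWeights],
    eff_lens: np.ndarray,
    fld: FragLenDist,
) -> np.ndarray:
    """Vectorized P(f|t) for every row of a hit table."""
    probs = np.zeros(len(hit_table))
    order = np.argsort(hit_table.t, kind="stable")
    bounds = np.searchsorted(hit_table.t[order], np.arange(len(eff_lens) + 1))
    for k in range(len(eff_lens)):
        rows = order[bounds[k]:bounds[k + 1]]
        if len(rows) == 0:
            continue
        if eff_lens[k] <= 0:
            continue
        bw = weights[k]
        L = len(bw.w5)
        ii = hit_table.i[rows]
        jj = hit_table.j[rows]
        both = (ii >= 0) & (jj >= 0)
        if both.any():
            r = rows[both]
            d = fld.prob(hit_table.j[r] - hit_table.i[r] + 1)
            probs[r] = d * bw.w5[hit_table.i[r]] * bw.w3[hit_table.j[r]] / eff_lens[k]
        only5 = (ii >= 0) & (jj < 0)
        if only5.any():
            s3 = _length_marginal(bw.w3, fld, from_five=True)
            r = rows[only5]
            probs[r] = bw.w5[hit_table.i[r]] * s3[hit_table.i[r]] / eff_lens[k]
        only3 = (ii < 0) & (jj >= 0)
        if only3.any():
            s5 = _length_marginal(bw.w5, fld, from_five=False)
            r = rows[only3]
            probs[r] = bw.w3[hit_table.j[r]] * s5[hit_table.j[r]] / eff_lens[k]
    return probs


def _length_marginal(w: np.ndarray, fld: FragLenDist, from_five: bool) -> np.ndarray:
    """sum_l D(l) * w[other end] as a function of the known end position."""
    L = len(w)
    out = np.zeros(L)
    for l in range(fld.min_len, min(fld.max_len, L) + 1):
        d = fld.pmf[l - fld.min_len]
        if d == 0:
            continue
        if from_five:  # known i, other end j = i + l - 1
            out[: L - l + 1] += d * w[l - 1:]
        else:  # known j, other end i = j - l + 1
            out[l - 1:] += d * w[: L - l + 1]
    return out


def em_maximize(
    hit_table: HitTable,
    probs: np.ndarray,
    eff_lens: np.ndarray,
    locus_of: np.ndarray,
    n_loci: int,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> AbundanceEstimate:
    """EM maximization of abundances for fixed bias parameters.

    ``probs`` are precomputed P(f|t) per hit row.  Initialization is
    deterministic: beta uniform over loci, gamma uniform within each locus.
    The log-likelihood is asserted non-decreasing every iteration.
    """
    n_t = len(eff_lens)
    starts = hit_table.starts
    sizes = np.diff(np.concatenate((starts, [len(hit_table)])))
    group_of_row = np.repeat(np.arange(len(starts)), sizes)

    # drop fragments whose every hit has zero probability
    gsum = np.bincount(group_of_row, weights=probs, minlength=len(starts))
    dead = gsum <= 0
    n_dropped = int(dead.sum())
    if n_dropped:
        log.warning("%d fragments dropped: zero probability under every hit", n_dropped)
        keep_rows = ~dead[group_of_row]
        sub = HitTable(
            hit_table.frag[keep_rows], hit_table.t[keep_rows],
            hit_table.i[keep_rows], hit_table.j[keep_rows],
            hit_table.n_fragments,
        )
        return _em_core(sub, probs[keep_rows], eff_lens, locus_of, n_loci,
                        tol, max_iter, n_dropped)
    return _em_core(hit_table, probs, eff_lens, locus_of, n_loci, tol, max_iter, 0)


def _em_core(hit_table, probs, eff_lens, locus_of, n_loci, tol, max_iter, n_dropped):
    n_t = len(eff_lens)
    starts = hit_table.starts
    n_frags = len(starts)
    sizes = np.diff(np.concatenate((starts, [len(hit_table)])))
    group_of_row = np.repeat(np.arange(n_frags), sizes)
    t_rows = hit_table.t

    if n_frags == 0:
        log.warning("no fragments: returning uniform abundances")
        rho = np.zeros(n_t)
        ok = eff_lens > 0
        rho[ok] = 1.0 / max(ok.sum(), 1)
        beta, gamma = _decompose(rho, locus_of, n_loci)
        return AbundanceEstimate(
            alpha=rho.copy(), rho=rho, beta=beta, gamma=gamma,
            expected_counts=np.zeros(n_t), loglik=0.0, n_dropped=n_dropped,
        )

    rho = _uniform_locus_init(locus_of, n_loci, eff_lens)
    alpha = rho * eff_lens
    alpha /= alpha.sum()

    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        v = alpha[t_rows] * probs
        gsum = np.bincount(group_of_row, weights=v, minlength=n_frags)
        ll = float(np.log(gsum).sum())
        assert not trace or ll >= trace[-1] - 1e-9 * max(1.0, abs(trace[-1])), (
            "EM log-likelihood decreased"
        )
        trace.append(ll)
        post = v / gsum[group_of_row]
        counts = np.bincount(t_rows, weights=post, minlength=n_t)
        alpha = counts / n_frags
        if prev > -np.inf and (ll - prev) <= tol * abs(prev):
            break
        prev = ll

    counts = np.bincount(t_rows, weights=post, minlength=n_t)
    rho = np.zeros(n_t)
    ok = (eff_lens > 0) & (alpha > 0)
    rho[ok] = alpha[ok] / eff_lens[ok]
    total = rho.sum()
    if total > 0:
        rho /= total
    beta, gamma = _decompose(rho, locus_of, n_loci)
    return AbundanceEstimate(
        alpha=alpha, rho=rho, beta=beta, gamma=gamma,
        expected_counts=counts, loglik=trace[-1], loglik_trace=trace,
        n_fragments_used=n_frags, n_dropped=n_dropped,
    )


def _uniform_locus_init(locus_of, n_loci, eff_lens) -> np.ndarray:
    rho = np.zeros(len(locus_of))
    usable = eff_lens > 0
    locus_sizes = np.bincount(locus_of[usable], minlength=n_loci)
    live_loci = (locus_sizes > 0).sum()
    if live_loci == 0:
        return rho
    rho[usable] = 1.0 / (live_loci * locus_sizes[locus_of[usable]])
    return rho


def _decompose(rho, locus_of, n_loci):
    beta = np.bincount(locus_of, weights=rho, minlength=n_loci)
    gamma = np.zeros_like(rho)
    ok = beta[locus_of] > 0
    gamma[ok] = rho[ok] / beta[locus_of[ok]]
    return beta, gamma


def posterior_weights(hit_table: HitTable, probs: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """E-step posterior assignment weight for every hit row."""
    starts = hit_table.starts
    sizes = np.diff(np.concatenate((starts, [len(hit_table)])))
    group_of_row = np.repeat(np.arange(len(starts)), sizes)
    v = alpha[hit_table.t] * probs
    gsum = np.bincount(group_of_row, weights=v, minlength=len(starts))
    out = np.zeros(len(hit_table))
    ok = gsum[group_of_row] > 0
    out[ok] = v[ok] / gsum[group_of_row][ok]
    return out


def compute_fpkm(counts: np.ndarray, eff_lens: np.ndarray, n_total: int) -> np.ndarray:
    """FPKM = 1e9 * expected_counts / (e~(t) * N); NaN where e~ = 0."""
    out = np.full(len(counts), np.nan)
    ok = eff_lens > 0
    if n_total > 0:
        out[ok] = 1e9 * counts[ok] / (eff_lens[ok] * n_total)
    return out


@dataclass
class QuantResult:
    transcripts: list[Transcript]
    loci: list[Locus]
    initial: AbundanceEstimate
    final: AbundanceEstimate
    eff_len_uniform: np.ndarray
    eff_len_corrected: np.ndarray
    fpkm_uncorrected: np.ndarray
    fpkm_corrected: np.ndarray
    bias_metric: np.ndarray
    seq5: SeqBiasModel | None
    seq3: SeqBiasModel | None
    pos: PosBiasModel | None
    fld: FragLenDist
    n_total_fragments: int

    def as_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "transcript_id": [t.id for t in self.transcripts],
                "locus_id": [t.locus_id for t in self.transcripts],
                "length": [t.length for t in self.transcripts],
                "effective_length_uniform": self.eff_len_uniform,
                "effective_length_corrected": self.eff_len_corrected,
                "est_counts": self.final.expected_counts,
                "fpkm_uncorrected": self.fpkm_uncorrected,
                "fpkm_corrected": self.fpkm_corrected,
                "bias_metric_log2": self.bias_metric,
            }
        )


def coordinate_ascent(
    hit_table: HitTable,
    transcripts: Sequence[Transcript],
    loci: Sequence[Locus],
    fld: FragLenDist,
    config: QuantConfig = QuantConfig(),
) -> QuantResult:
    """Full joint estimation: uniform-bias EM, bias learning, corrected EM."""
    n_t = len(transcripts)
    locus_index = {l.id: k for k, l in enumerate(loci)}
    locus_of = np.array([locus_index[t.locus_id] for t in transcripts])
    encoded = [encode(t.sequence) for t in transcripts]

    e_unif = np.array([effective_length_uniform(t.length, fld) for t in transcripts])
    for k, t in enumerate(transcripts):
        if e_unif[k] <= 0:
            log.warning("transcript %s shorter than min fragment length; excluded", t.id)

    uniform_weights = [BiasWeights.uniform(t.length) for t in transcripts]
    probs0 = compute_hit_probs(hit_table, uniform_weights, e_unif, fld)
    est0 = em_maximize(hit_table, probs0, e_unif, locus_of, len(loci),
                       config.tol, config.max_iter)
    log.info("stage 1 (uniform bias) log-likelihood: %.4f", est0.loglik)

    learn_bias = not (config.no_seq_bias and config.no_pos_bias)
    if not learn_bias:
        fpkm_unc = compute_fpkm(est0.expected_counts, e_unif, hit_table.n_fragments)
        return QuantResult(
            transcripts=list(transcripts), loci=list(loci), initial=est0, final=est0,
            eff_len_uniform=e_unif, eff_len_corrected=e_unif.copy(),
            fpkm_uncorrected=fpkm_unc, fpkm_corrected=fpkm_unc.copy(),
            bias_metric=np.zeros(n_t), seq5=None, seq3=None, pos=None,
            fld=fld, n_total_fragments=hit_table.n_fragments,
        )

    exclude: frozenset = frozenset(config.exclude_from_learning)
    if config.learn_single_isoform_only:
        exclude = exclude | frozenset(
            k for k, t in enumerate(transcripts)
            if len(loci[locus_of[k]].transcript_ids) > 1
        )

    est = est0
    probs = probs0
    seq5 = seq3 = None
    pos = None
    weights = uniform_weights
    e_corr = e_unif.copy()
    for it in range(config.iterations):
        post = posterior_weights(hit_table, probs, est.alpha)
        rho0 = est.rho
        if not config.no_seq_bias:
            seq5 = learn_seq_bias(
                hit_table, transcripts, rho0, end=FIVE, fld=fld, posterior=post,
                pseudocount=config.pseudocount, max_obs=config.max_learn_obs,
                seed=config.seed, exclude_transcripts=exclude, encoded=encoded,
                max_order=config.vlmm_max_order, shrinkage=config.shrinkage,
            )
            seq3 = learn_seq_bias(
                hit_table, transcripts, rho0, end=THREE, fld=fld, posterior=post,
                pseudocount=config.pseudocount, max_obs=config.max_learn_obs,
                seed=config.seed, exclude_transcripts=exclude, encoded=encoded,
                max_order=config.vlmm_max_order, shrinkage=config.shrinkage,
            )
        if not config.no_pos_bias:
            edges = length_bin_edges(np.array([t.length for t in transcripts]), rho0)
            p5 = learn_pos_bias(hit_table, transcripts, rho0, fld, end=FIVE,
                                bin_edges=edges, posterior=post,
                                pseudocount=config.pseudocount,
                                exclude_transcripts=exclude)
            p3 = learn_pos_bias(hit_table, transcripts, rho0, fld, end=THREE,
                                bin_edges=edges, posterior=post,
                                pseudocount=config.pseudocount,
                                exclude_transcripts=exclude)
            pos = merge_pos_models(p5, p3)
        weights = [
            compute_bias_weights(encoded[k], seq5, seq3, pos) for k in range(n_t)
        ]
        e_corr = np.array(
            [effective_length(weights[k], fld) for k in range(n_t)]
        )
        probs = compute_hit_probs(hit_table, weights, e_corr, fld)
        est = em_maximize(hit_table, probs, e_corr, locus_of, len(loci),
                          config.tol, config.max_iter)
        log.info("iteration %d corrected log-likelihood: %.4f", it + 1, est.loglik)

    n_total = hit_table.n_fragments
    fpkm_unc = compute_fpkm(est0.expected_counts, e_unif, n_total)
    fpkm_corr = compute_fpkm(est.expected_counts, e_corr, n_total)
    metric = np.array(
        [transcript_bias_metric(e_corr[k], e_unif[k]) for k in range(n_t)]
    )
    return QuantResult(
        transcripts=list(transcripts), loci=list(loci), initial=est0, final=est,
        eff_len_uniform=e_unif, eff_len_corrected=e_corr,
        fpkm_uncorrected=fpkm_unc, fpkm_corrected=fpkm_corr,
        bias_metric=metric, seq5=seq5, seq3=seq3, pos=pos,
        fld=fld, n_total_fragments=n_total,
    )
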