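import numpy as np
import pytest

from fragbias._seq import encode
from fragbias.alignments import HitTable
from fragbias.bias import (
    FIVE,
    OFFSET_MIN,
    THREE,
    WINDOW,
    BiasWeights,
    PosBiasModel,
    SeqBiasModel,
    compute_bias_weights,
    effective_length,
    effective_length_uniform,
    learn_pos_bias,
    learn_seq_bias,
    null_end_distribution,
    order_schedule,
    seq_weight,
    total_bias_weight,
    transcript_bias_metric,
    window_bases,
)
from fragbias.fraglen import truncated_gaussian
from fragbias.simulate import (
    SimulationConfig,
    planted_position_weights,
    simulate_fragments,
)
from tests.conftest import make_transcript, random_transcript


def order0_model(end, table, rng=None):
    """Build a sequence model whose ratios equal a per-offset table exactly."""
    m = SeqBiasModel.empty(end, orders=order_schedule(0))
    m.finalize()
    for w in range(WINDOW):
        m.log_ratio[w][:] = np.log(table[w])[None, :]
    return m


class TestSeqWeight:
    def test_identity_model_gives_one(self):
        m = SeqBiasModel.identity(FIVE)
        assert seq_weight(m, "ACGT" * 5 + "A") == pytest.approx(1.0)

    def test_order0_equals_hand_rolled_product(self):
        rng = np.random.default_rng(1)
        table = rng.uniform(0.5, 2.0, size=(WINDOW, 4))
        m = order0_model(FIVE, table)
        ctx = "".join(rng.choice(list("ACGT"), size=WINDOW))
        codes = encode(ctx)
        oracle = 1.0
        for w, b in enumerate(codes):
            oracle *= table[w, b]
        assert seq_weight(m, ctx) == pytest.approx(oracle, rel=1e-12)

    def test_log_and_linear_paths_agree(self):
        rng = np.random.default_rng(2)
        table = rng.uniform(0.2, 5.0, size=(WINDOW, 4))
        m = order0_model(FIVE, table)
        ctx = "".join(rng.choice(list("ACGT"), size=WINDOW))
        codes = encode(ctx)
        log_sum = sum(np.log(table[w, b]) for w, b in enumerate(codes))
        assert seq_weight(m, ctx) == pytest.approx(np.exp(log_sum), rel=1e-12)

    def test_n_bases_contribute_ratio_one(self):
        rng = np.random.default_rng(3)
        table = rng.uniform(0.5, 2.0, size=(WINDOW, 4))
        m = order0_model(FIVE, table)
        ctx = "N" * WINDOW
        assert seq_weight(m, ctx) == pytest.approx(1.0)


class TestWindowOrientation:
    def test_five_prime_window_offsets(self):
        # offset o reads seq[i + o]; mark a single offset and find it
        seq = "A" * 50
        enc = encode(seq[:20] + "G" + seq[21:])  # G at position 20
        B = window_bases(enc, np.array([25]), FIVE)
        # G should appear at window position for offset -5: w = -5 - OFFSET_MIN
        assert B[0, -5 - OFFSET_MIN] == 2
        assert (B[0] == 2).sum() == 1

    def test_three_prime_window_is_complemented_not_reversed(self):
        # 3' end at j: offset o reads complement(seq[j - o])
        seq = ["A"] * 50
        seq[28] = "G"  # j=25, offset -3 -> position j+3 = 28
        B = window_bases(encode("".join(seq)), np.array([25]), THREE)
        w = -3 - OFFSET_MIN
        assert B[0, w] == 1  # complement of G is C
        # everything else is complement of A = T
        others = np.delete(B[0], w)
        assert (others == 3).all()


def _unique_hits(t_idx, i, j, n):
    return HitTable(np.arange(n), t_idx, i, j, n_fragments=n)


class TestLearnSeqBias:
    def test_null_simulation_ratios_near_one(self):
        rng = np.random.default_rng(10)
        t = random_transcript(rng, 2000)
        cfg = SimulationConfig(n_transcripts=1, n_fragments=100_000, seed=4,
                               abundances=np.array([1.0]))
        sim = simulate_fragments([t], cfg)
        m = learn_seq_bias(sim.hit_table(), [t], np.array([1.0]), end=FIVE,
                           fld=sim.fld)
        log_ratios = np.log(m.marginal_ratios())
        # 3 Monte-Carlo SEs of a log frequency with ~25k counts per cell
        counts = np.array([m.fg_counts[w].sum(axis=0) for w in range(WINDOW)])
        tol = 3 * np.sqrt(1 / counts + 1 / counts.sum(axis=1, keepdims=True))
        assert (np.abs(log_ratios) < tol + 0.02).all()

    def test_planted_g_preference_recovered(self):
        rng = np.random.default_rng(11)
        t = random_transcript(rng, 3000)
        table5 = np.ones((WINDOW, 4))
        w_minus1 = -1 - OFFSET_MIN
        table5[w_minus1] = [0.02, 0.02, 3.94, 0.02]  # G almost mandatory
        cfg = SimulationConfig(n_transcripts=1, n_fragments=50_000, seed=5,
                               abundances=np.array([1.0]), seq5_table=table5)
        sim = simulate_fragments([t], cfg)
        m = learn_seq_bias(sim.hit_table(), [t], np.array([1.0]), end=FIVE,
                           fld=sim.fld)
        ratios = m.marginal_ratios()[w_minus1]
        assert ratios[2] > 3.0
        assert ratios[[0, 1, 3]].max() < 0.3

    def test_abundance_rescaling_invariance_identical_sequences(self):
        """The Fig-2-style correction: rescaling expression does not move the
        learned weights beyond Monte-Carlo noise when sequence content is
        held fixed (identical transcripts)."""
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGT"), size=1500))
        ts = [make_transcript(seq, "A", "cA"), make_transcript(seq, "B", "cB")]
        models = []
        for k, ab in enumerate([[0.5, 0.5], [0.9, 0.1]]):
            cfg = SimulationConfig(n_transcripts=2, n_fragments=60_000, seed=6,
                                   seq_bias_strength=0.5,
                                   abundances=np.array(ab))
            sim = simulate_fragments(ts, cfg, rng=np.random.default_rng(60 + k))
            m = learn_seq_bias(sim.hit_table(), ts, sim.true_rho, end=FIVE,
                               fld=sim.fld)
            models.append(m)
        lr = [np.log(m.marginal_ratios()) for m in models]
        counts = [np.array([m.fg_counts[w].sum(axis=0) for w in range(WINDOW)])
                  for m in models]
        se = np.sqrt(1 / np.maximum(counts[0], 1) + 1 / np.maximum(counts[1], 1))
        # allow the usual excursion of a max over many cells
        assert (np.abs(lr[0] - lr[1]) / se).max() < 4.5


class TestPosBias:
    def _sim(self, profile, n_frag=80_000, seed=8, lengths=(2000,) * 12):
        rng = np.random.default_rng(seed)
        ts = [random_transcript(rng, L, tid=f"T{k}")
              for k, L in enumerate(lengths)]
        cfg = SimulationConfig(n_transcripts=len(ts), n_fragments=n_frag,
                               seed=seed, pos5_profile=profile)
        sim = simulate_fragments(ts, cfg)
        return ts, sim

    def test_uniform_simulation_all_parameters_near_one(self):
        ts, sim = self._sim(profile=None)
        rho0 = sim.true_rho
        m = learn_pos_bias(sim.hit_table(), ts, rho0, sim.fld, end=FIVE)
        row = m.table5[m.length_bin(2000)]
        # sampling tolerance per window: the null mass in the terminal
        # twentiles is tiny (a 5' end needs room for the whole fragment),
        # so their Monte-Carlo error is much larger than the bulk's
        null = null_end_distribution(2000, sim.fld, FIVE)
        expected_counts = null * sim.n_fragments
        tol = 4 / np.sqrt(np.maximum(expected_counts, 1)) + 0.02
        assert (np.abs(row - 1) < tol).all()

    def test_planted_density_matches_exact_expectation(self):
        profile = np.ones(20)
        profile[-1] = 2.0
        ts, sim = self._sim(profile=profile)
        m = learn_pos_bias(sim.hit_table(), ts, sim.true_rho, sim.fld, end=FIVE)
        # exact-expectation oracle from the planted joint distribution
        fg = np.zeros(20)
        null = np.zeros(20)
        for k, t in enumerate(ts):
            w5, w3 = planted_position_weights(t, sim.config)
            L = t.length
            marg = np.zeros(L)
            for l in range(sim.fld.min_len, min(sim.fld.max_len, L) + 1):
                d = sim.fld.pmf[l - sim.fld.min_len]
                marg[: L - l + 1] += d * w5[: L - l + 1] * w3[l - 1:]
            tw = PosBiasModel.twentile(np.arange(L), L)
            mass = sim.true_rho[k] * marg.sum()
            fg += mass * np.bincount(tw, weights=marg / marg.sum(), minlength=20)
            null += mass * null_end_distribution(L, sim.fld, FIVE)
        expected = (fg / fg.sum()) / (null / null.sum())
        row = m.table5[m.length_bin(2000)]
        counts = fg / fg.sum() * sim.n_fragments
        tol = 4 * expected / np.sqrt(np.maximum(counts, 1)) + 0.02
        assert (np.abs(row - expected) < tol).all()

    def test_bins_without_transcripts_stay_at_one(self):
        ts, sim = self._sim(profile=None, n_frag=20_000)
        edges = np.array([500.0, 1000.0, 1500.0, 2500.0])  # all L=2000 in bin 3
        m = learn_pos_bias(sim.hit_table(), ts, sim.true_rho, sim.fld,
                           end=FIVE, bin_edges=edges)
        for b in (0, 1, 2, 4):
            np.testing.assert_array_equal(m.table5[b], np.ones(20))


class TestTotalBiasWeight:
    def test_all_factors_one(self, short_fld):
        t = make_transcript("ACGT" * 25)
        assert total_bias_weight(t, 3, 60) == pytest.approx(1.0)

    def test_factor_product(self):
        t = make_transcript("ACGT" * 25)
        pos = PosBiasModel.identity()
        pos.table5[:, :] = 2.0
        pos.table3[:, :] = 0.5
        b = total_bias_weight(t, 10, 70, pos5=pos, pos3=pos)
        assert b == pytest.approx(2.0 * 0.5)

    def test_matches_brute_force_on_all_pairs(self):
        rng = np.random.default_rng(21)
        t = random_transcript(rng, 50)
        enc = encode(t.sequence)
        table5 = rng.uniform(0.5, 2.0, size=(WINDOW, 4))
        table3 = rng.uniform(0.5, 2.0, size=(WINDOW, 4))
        m5, m3 = order0_model(FIVE, table5), order0_model(THREE, table3)
        pos = PosBiasModel.identity()
        pos.table5[0] = rng.uniform(0.5, 2.0, size=20)
        pos.table3[0] = rng.uniform(0.5, 2.0, size=20)
        bw = compute_bias_weights(enc, m5, m3, pos)
        for i in range(0, 50, 7):
            for j in range(i, 50, 5):
                direct = total_bias_weight(t, i, j, seq5=m5, seq3=m3,
                                           pos5=pos, pos3=pos)
                assert direct == pytest.approx(bw.w5[i] * bw.w3[j], rel=1e-9)


class TestEffectiveLength:
    def test_uniform_weights_give_classical_value(self, short_fld):
        L = 120
        bw = BiasWeights.uniform(L)
        expected = sum(
            short_fld.prob(l) * (L - l + 1)
            for l in range(short_fld.min_len, L + 1)
        )
        assert effective_length(bw, short_fld) == pytest.approx(expected, rel=1e-12)
        assert effective_length_uniform(L, short_fld) == pytest.approx(
            expected, rel=1e-12)

    def test_point_mass_at_full_length(self):
        L = 80
        fld = truncated_gaussian(mean=L, sd=1e-9, min_len=L, max_len=L)
        rng = np.random.default_rng(31)
        bw = BiasWeights(w5=rng.uniform(0.5, 2, L), w3=rng.uniform(0.5, 2, L))
        assert effective_length(bw, fld) == pytest.approx(
            bw.w5[0] * bw.w3[L - 1], rel=1e-12)

    def test_matches_exhaustive_double_loop(self, short_fld):
        rng = np.random.default_rng(32)
        L = 120
        bw = BiasWeights(w5=rng.uniform(0.2, 3, L), w3=rng.uniform(0.2, 3, L))
        oracle = 0.0
        for i in range(L):
            for j in range(i, L):
                oracle += short_fld.prob(j - i + 1) * bw.w5[i] * bw.w3[j]
        assert effective_length(bw, short_fld) == pytest.approx(oracle, rel=1e-9)

    def test_short_transcript_gets_zero(self, short_fld):
        assert effective_length_uniform(10, short_fld) == 0.0


class TestBiasMetric:
    def test_uniform_model_metric_zero(self):
        assert transcript_bias_metric(100.0, 100.0) == 0.0

    def test_doubling_five_prime_weights_adds_one(self, short_fld):
        rng = np.random.default_rng(33)
        L = 150
        bw = BiasWeights(w5=rng.uniform(0.5, 2, L), w3=rng.uniform(0.5, 2, L))
        e1 = effective_length(bw, short_fld)
        e2 = effective_length(BiasWeights(2 * bw.w5, bw.w3), short_fld)
        m1 = transcript_bias_metric(e1, 100.0)
        m2 = transcript_bias_metric(e2, 100.0)
        assert m2 - m1 == pytest.approx(1.0, abs=1e-12)

    def test_undefined_for_zero_uniform_length(self):
        assert np.isnan(transcript_bias_metric(10.0, 0.0))


def test_serialization_round_trip(small_sim):
    transcripts, _, _, sim = small_sim
    ht = sim.hit_table()
    m = learn_seq_bias(ht, transcripts, sim.true_rho, end=FIVE, fld=sim.fld)
    m2 = SeqBiasModel.from_dict(m.to_dict())
    enc = encode(transcripts[0].sequence)
    np.testing.assert_allclose(m.position_weights(enc),
                               m2.position_weights(enc), rtol=1e-12)
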