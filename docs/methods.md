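# Methods

## The generative model

A sequenced fragment is modeled in three steps: a source transcript is
drawn with probability proportional to ρ_t·ẽ(t); a fragment length l is
drawn from the length distribution D; the fragment's placement is drawn
proportionally to the product of end-specific bias weights.  Writing i
and j for the transcript coordinates of the fragment's 5' and 3' ends
(0-based, inclusive, so the implied length is I = j − i + 1),

    P(f | t) = D(I_t(f)) · b(t, i, j) / ẽ(t),
    b(t, i, j) = s5(t, i) · p5(binL(t), tw(i)) · s3(t, j) · p3(binL(t), tw(j)),
    ẽ(t) = Σ_l D(l) · Σ_{i=0}^{L−l} w5[i] · w3[i+l−1],

where w5/w3 are the per-position products of sequence and positional
weights and ẽ(t) — the bias-adjusted effective length — normalizes the
per-transcript fragment distribution exactly (the test suite checks
Σ_{(i,j)} P = 1 to 1e-9 against dense enumeration).  With all weights at
1, ẽ reduces to the classical Σ_l D(l)(L−l+1).

Single-end reads reveal only one fragment end; the likelihood then
marginalizes D over the unknown end.  Which end a read reveals follows
the protocol: second-strand libraries sequence the transcript sense
strand (read start = 5' end), first-strand (dUTP-style) the antisense
strand (read end = 3' end), and for unstranded single-end data the
mapped strand of each read decides which end model it informs.

## Fragment-length distribution

D is estimated as a smoothed histogram of implied lengths from fragments
mapping uniquely to single-isoform loci (Gaussian kernel, default
bandwidth 5 nt, to avoid zero-probability holes; disable with
bandwidth 0).  Below 10,000 qualifying fragments (configurable) it falls
back to a discretized truncated Gaussian — unit-bin integrals of a
normal density, zero mass below the minimum read length, renormalized —
with defaults mean 200 nt, sd 80 nt, support capped at 800 nt.  The
"fragment of length l has L−l+1 placements" conditioning lives in ẽ,
not in D: D is the marginal length prior.

## Sequence-specific bias

Each end gets a foreground and a background Markov sequence model over a
21-base window at offsets −8..+12 from the end base (offset 0 is the
first base of the end sequence; only non-negative offsets are inside the
fragment).  Windows for the 3' end read the complement — not the
reverse-complement — of the transcript walking outward from the end
(coordinate j − o at offset o), so both end models read in the
orientation of the primer during strand synthesis.

The foreground accumulates windows at observed fragment ends, each hit
weighted by its posterior assignment probability from the current
abundance estimate.  The background accumulates every possible window
placement, weighted by ρ₀_t (the uniform-bias abundance estimate) times
the null end density at that position — the fragment-length CDF of the
room left for the fragment, which is why end contexts depleted near
transcript termini for purely geometric reasons are not mistaken for
chemistry.  Weighting the background by abundance is what removes the
expression confound: a highly expressed transcript dominates both the
numerator and the denominator of the weight ratio, so rescaling
abundances leaves the learned model unchanged (tested to within
Monte-Carlo error).

The bias weight of a window is the likelihood ratio
Π_w P_fg(b_w | ctx_w) / P_bg(b_w | ctx_w).  Context order ramps up from 0
at the window start and is capped at a configurable maximum, default 1
(nearest-neighbor dependencies).  The default is deliberately low: at
desk-scale training sizes (10⁵–10⁶ fragments over tens to hundreds of
transcripts) order-3 conditionals can effectively memorize individual
high-weight windows through near-unique contexts and amplify their
weights multiplicatively across the 21 positions — we observed
effective-length inflation of several orders of magnitude — while the
per-offset signal itself is recovered equally well at low order.  The cap
is a parameter (`vlmm_max_order`, 0–3) for data-rich settings.

Numerical choices: background counts are rescaled to the foreground's
total mass before the pseudocount (1 per cell) is applied, so the
pseudocount perturbs both comparably; foreground conditionals are shrunk
toward the background distribution with a Dirichlet prior of 25
effective observations per context row, so contexts without foreground
evidence get ratio exactly 1 rather than a variance-exploding estimate.
'N' bases and positions beyond the transcript ends contribute ratio 1.

## Positional bias

Fragment-end location effects depend on transcript length, so positions
are modeled by 20 twentile windows × 5 transcript-length bins per end
(100 parameters per end).  Bin edges are empirical quintiles of the
expressed-transcript length distribution, computed per dataset and
serialized with the model.  Each parameter is the ratio of the observed
(posterior-weighted) end density in a twentile to the uniform-bias null
density — again the feasibility-aware null, so a 5'-end depletion next to
the 3' terminus is not reported as bias.  Empty bins keep weight 1.

Because the positional weight of a transcript depends only on its length,
positional-only correction multiplies the effective length of every
same-length transcript in a bin by the same factor and therefore cannot
change their relative expression (tested to 1e-6); for transcripts of
different lengths within a bin the factor is equal only asymptotically
(L ≫ fragment length), and positional correction can move relative
estimates in multi-isoform loci, where end positions map differently
onto the isoforms.

## Estimation

Coordinate ascent with a single round by default:

1. EM over abundances with all bias weights at 1 → ρ₀.  The EM runs in
   "fragment share" space α_t = ρ_t ẽ_t / Σ ρ ẽ; initialization is
   deterministic (β uniform over loci, γ uniform within locus);
   convergence at relative log-likelihood change < 1e-6, cap 1000
   iterations; the log-likelihood is asserted non-decreasing at every
   step.  Fragments whose every hit has probability 0 (e.g. implied
   length outside D's support) are dropped and counted.
2. Bias learning weighted by ρ₀ (above).  A flag restricts learning to
   single-isoform loci; a cap (default 10⁷ end observations, subsampled
   deterministically by seed) bounds memory.
3. Recompute ẽ(t) and re-run the EM → final abundances.

Further rounds are available (`--iterations`); because the bias update
is a moment estimator rather than an exact joint-likelihood M-step, the
likelihood is approximately (not exactly) stationary after round one,
which is why one round is the default.  FPKM_t = 10⁹·counts_t/(ẽ_t·N);
the uncorrected FPKM uses stage-1 counts with uniform-bias ẽ, and both
columns are emitted together with the per-transcript bias metric
log2(ẽ_corrected/ẽ_uniform), the summary used for GC-vs-bias reporting.

## The simulator

`fragbias.simulate` inverts the likelihood exactly: transcripts are
drawn ∝ ρ_t·ẽ(t) and (l, i) by exact enumeration of D(l)·w5[i]·w3[j] —
no approximate sampling — so recovered parameters can be compared to
analytic expectations.  Default study conditions: 50 transcripts with
lognormal lengths (median ≈ 1.3 kb, clipped to 0.5–4 kb), uniform base
composition at GC 0.5, lognormal abundances (σ = 1.5, a realistic bulk
RNA-seq dynamic range), truncated-Gaussian fragment lengths (200 ± 80,
min = read length 50), paired 50 nt reads.  Planted sequence bias places
Normal(0, 0.5) log-weights per base at offsets −5..+5 (the window where
real protocols show bias), rows normalized to mean 1 — per-position
weights then span roughly e^±2, comparable to strongly biased priming
chemistries.  Positional profiles per twentile can be planted as well.
Reads are emitted as genome-space spliced SAM (or transcriptome-space),
with mate/strand roles per library type, plus a schema-versioned truth
table; every artifact is byte-reproducible from the seed.

What the simulator does *not* emulate: sequencing errors and quality
variation, PCR duplication, intron signal, annotation errors, secondary
structure, and GC-dependent amplification beyond what end-context bias
induces.  Passing tests therefore demonstrate correctness of the
estimator under its own model class and robust recovery of planted bias —
not performance on the full messiness of real libraries.

## Known limitations

* The bias learner shares one window shape (−8..+12) and one order
  schedule across ends and datasets; protocols with bias outside this
  window need a wider window.
* Positional "constant adjustment" across a length bin is exact only for
  equal-length transcripts; bias metrics for short transcripts
  (L comparable to fragment length) mix positional and length effects.
* Multi-mapped fragments are resolved probabilistically by the EM; reads
  whose mates map to different loci are dropped with a logged count.
* At very low depth the sequence model shrinks toward no correction by
  construction; it will under-correct rather than hallucinate bias.
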