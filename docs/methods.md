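# Methods

This note documents the models implemented in `pupilvol`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish.

## The generative task model

The stimulus is a stream of digits shown for 250 ms each, separated by
250 ms blanks, in sequences of eight followed by a 1 s break. Because the
display alternates digit/blank and the break must be distinguishable from
an ordinary blank, the hidden chain needs 20 states: number states
`n1..n8`, post-number absence states `a1..a8`, and break states `b1..b4`.
The likelihood matrix **A** is deterministic: number states emit their
digit, all other states emit a blank.

The source transition matrix **B** (column-stochastic, `B[i, j] =
P(next=i | current=j)`) encodes: every number state enters its own absence
state with probability 1; each absence state `aK` advances to the next
number with probability `p_correct = 0.99`, with the remaining mass split
equally among the allowed alternatives — back to the previous number
always, and additionally into the break from `a5`, `a6`, `a7` so that
too-long realisations can still finish on schedule. `a8` enters the break
with `p_correct`, else falls back to `n8`. Break transitions
`b1→b2→b3→b4→n1` are deterministic at every precision (they are one-hot
columns, which the precision exponent leaves fixed).

Volatility is manipulated by an inverse-temperature exponent ω applied
column-wise on the support of **B** and renormalised. `0^ω` is never
evaluated: zero entries stay exactly zero, which both preserves the
support and avoids the divergence of naive log-space exponentiation for
ω < 1. Precisions at or above `1e5` (the serialisable infinity sentinel)
return the argmax limit.

**Generative precision levels.** Sequences are rejection-sampled: the
chain is iterated 20 steps from `n1` and kept only if it emitted exactly
eight digits (cap 1000 attempts). The four per-set levels are calibrated
against the target of roughly 0, 1, 2 and 3 aberrant transitions per
sequence: ω = {1e5, 0.39, 0.195, 0.04} give means ≈ {0, 0.8, 1.9, 2.4}.
The 3-error level is unreachable under the acceptance constraint — a path
with many aberrations rarely fits exactly 8 digits into 20 steps, so the
conditional mean saturates near 2.5 — and the lowest level is therefore
the saturated value. The default per-set ordering
`[∞, 0.39, 0.195, 0.04, 0.04, 0.195, 0.39, ∞]` creates
rising-then-falling volatility across the block; any 8-vector is
accepted.

Blocks hold 25 sequences (the first always 1..8, then 8 contiguous sets
of 3); experiments hold 16 blocks, the first half basic, the second half
"combination" sequences in which two digits per sequence are swapped for
random different digits (an imprecise state-to-outcome mapping realised at
the stimulus level). Schedules are frozen: every block within a condition
shows byte-identical digit sequences, and the incidental-task target digit
cycles 1..8 across blocks.

## The ideal observer

State inference is a gradient flow on log-space potentials `v` with
posteriors `s = softmax(v)`:

    dv_t = omega * (ln(B̄ s_{t-1}) + ln(B̄ᵀ s_{t+1})) + ln(A[o_t,:]) - ln(s_t)

The precision ω scales only the two empirical-prior messages: a volatile
world (small ω) makes the observer lean on sensory evidence, a stable one
on its own predictions. Edge steps drop the missing message. Numerics:
explicit Euler with step 0.25 of the unit flow, at most 64 iterations per
window, convergence at mean absolute posterior change below 1e-6;
logarithms are floored at −32. Blank steps are informative observations
of the absence states, and the 1 s breaks are part of the inference
window.

This scheme is *approximate*: its fixed point uses the neighbouring
smoothed marginals as messages, which double-counts evidence relative to
exact forward–backward smoothing. Against a brute-force path-enumeration
oracle on random small HMMs the median total-variation error is ≈ 0.02,
but adversarial draws (diffuse transition and likelihood matrices) can
deviate by ≈ 0.2. On the peaked, structured matrices of this task the
agreement is much tighter (median ≈ 1e-3). The approximation is retained
deliberately — it is the model of neuronal inference being tested, not a
numerical shortcut.

Volatility β = ω⁻¹ evolves on a slower timescale: once per sequence
window (20 steps; configurable) one explicit-Euler step (step 0.25) of

    dbeta = beta0 - sum_t ln(B̄) · eps_t - beta

is taken, with the elementwise log restricted to the support of B̄ and the
prediction errors `eps_{i,t} = (s_{t+1} - B̄_{:,i}) s_{t,i}` summed over
the window. With zero errors the fixed point is the prior β₀; surprising
transitions (mass on low-log-probability entries) push β above it. β is
floored at 1e-3 to keep ω = 1/β finite. Between updates the inferred
precision is held constant, giving a 4 Hz step trace that is linearly
up-sampled to 10 Hz for comparison with the pupil series. Note the
equilibrium under confirmation sits slightly above the prior precision
(confirmed predictions carry a small negative drive); excursions during
volatile sets, and their dependence on β₀, are the behaviour of interest:
observers with volatile priors (large β₀) track brief volatility changes
less — the excursions they show are shallower in relative terms.

## Pupillometry preprocessing

1. **Blink removal** — samples equal to zero, padded 150 ms on each side,
   replaced by linear interpolation between flanking valid samples;
   overlapping pads merge; edge runs take the nearest valid value.
   Detection is strictly "pupil value is zero"; no velocity criterion.
2. **Nuisance regression** — per-block OLS on a constant, a linear drift,
   and violation / likelihood-violation / target event regressors (250 ms
   boxcars convolved with the widest gamma kernel as a stand-in pupillary
   response). Residuals keep the fitted constant. The
   likelihood-violation column exists only where such events occur
   (combination blocks). Collinear columns are dropped with a warning.
3. **Filtering** — mean-centring, 4th-order Butterworth low-pass at 10 Hz
   applied forward–backward (zero phase), then decimation by keeping every
   100th sample (1000 → 10 Hz). Aliasing is tolerated by design: the
   analysis is in the time domain.
4. **Averaging** — each block z-scored, blocks averaged within participant
   over the identical schedule (an event-related average), participants
   averaged for the grand mean.

**Design-side consistency.** Because step 2 removes nuisance components
from the *data*, model fitting applies the same projection to both the
preprocessed series and the design-matrix columns (Frisch–Waugh
residualisation, `preprocess.nuisance_projector`). For a series averaged
over blocks the projector spans the union of the per-block nuisance
columns — each block's regression removed that block's own target
direction. Omitting either side of this projection leaves
violation-correlated signal asymmetrically in data or design and
measurably biases the simulate-and-recover loop; with it, recovery is
cleanly diagonal. Within the package, averaged fits are further scored
per condition (basic / combination) and their log evidences summed, since
the two conditions have different digit streams and hence different
observer traces.

## Convolution GLMs and model evidence

Six models of the 10 Hz series, each variable convolved causally with
five gamma kernels (peaks at 0.5, 1, 2, 4, 8 s, shape 3, peak-normalised,
truncated at 1e-4 tail mass) plus a constant:

1. photic boxcar (digit presence) — the null;
2. photic + interaction (centred precision × photic, centred again, so a
   constant precision trace contributes nothing);
3. photic + inferred precision (centred before convolution);
4. photic + interaction + precision;
5. photic + exponential return-to-baseline after unexpected events
   (τ = 5 s, configurable);
6. photic + the generative ("adjusted") volatility of the schedule as a
   z-scored step trace — an observer who knows the volatility without
   inferring it.

Evidence is the closed-form log marginal likelihood of a Bayesian linear
model with zero-mean coefficient priors of sd 10 (conjugate scaling — in
units of the noise sd, which is marginalised under a weak inverse-gamma
prior, a₀ = b₀ = 1e-3; a plug-in noise mode is available). The closed
form is verified against an adaptive-quadrature oracle to 1e-3 nats.
Absolute evidences shift with the prior sd (each well-determined
coefficient contributes a −ln(prior sd) complexity term), but model
rankings and the estimated prior precision are invariant to a tenfold
change, which is the operative robustness.

Softmax over the model-3 evidences across a β⁻¹ grid (default 40
log-spaced points, 0.3–20) gives the posterior over a subject's prior
precision; models 1, 5, 6 are grid-invariant and computed once.

## Synthetic data

The generator inverts the analysis: observer at a ground-truth β⁻¹,
signal composed from the generating model's regressors (model 3 by
default; photic weight +0.5, precision weight −1.0 in z-units — the sign
convention takes pupil diameter to rise with volatility), convolved with
the widest kernel, up-sampled to 1000 Hz, plus a baseline of 10 raw
units, drift of 0.2 z-units/min, Gaussian noise of sd 0.5, and blink gaps
(Poisson 15/min, lognormal ~200 ms, inserted after signal synthesis so
ground truth under the gaps is known). Defaults mirror the study design:
16 blocks, 9 participants.

What the generator does *not* emulate: genuine pupillary responses to
violations and targets (the nuisance regressors therefore remove true
signal share, which the design-side projection accounts for), gaze- or
saccade-related artifacts, non-linear drift, or any hardware-specific
file format. Passing the recovery tests shows the pipeline is internally
consistent and identifiable under these idealisations — not that real
pupils obey the model.

## Validation sizes

The packaged checks run on one CPU in a few minutes: model recovery uses
50 synthetic participants (25 each generated from models 1 and 3) at the
full 16-block design; the confusion matrix uses 5 prior precisions × 2
repetitions; closed-loop recovery uses 20 participants at β⁻¹ ∈
{1, 1.5, 3.25} against a 9-point grid. Larger replications only sharpen
the same comparisons.

## Known limitations

- State inference is the approximate marginal scheme discussed above;
  exact smoothing is available only through the enumeration oracle used in
  tests.
- The volatility update is a single Euler step per window; its magnitude
  interacts with the window length (both configurable).
- The supplementary data format of the original recordings is
  undocumented; real data must be converted to the plain CSV/TSV dialects
  (`time_s,pupil` at 1000 Hz; tab-separated event trains).
- Model evidence assumes white Gaussian residuals at 10 Hz; strongly
  autocorrelated residuals flatter richer models, which is why recovery
  is validated at realistic averaging depths.
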