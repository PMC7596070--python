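# Model and methods

## Overview

`flydec` simulates the two-pathway visual decision-making system of the
fruit fly as a clock-driven spiking neural network. A five-channel visual
layer (`[R, G, B, upright, inverted]`) feeds two parallel circuits:

- a **linear pathway** through the central complex (CC): a 5-neuron input
  layer relaying the visual drive one-to-one, fully connected to two
  behaviour neurons with mutual inhibition. Its feed-forward weights are
  the learned memory and support fast, single-cue decisions.
- a **nonlinear pathway** through the mushroom body (MB): five Kenyon
  cells (KC) receiving the visual drive one-to-one, fully connected to two
  mushroom-body output neurons (MBON, mutually inhibiting), with two
  GABAergic APL interneurons in reciprocal connection with the KC layer
  and one dopaminergic (DA) neuron that inhibits APL and excites the
  MBONs. The DA–APL–KC loop implements a gain-gating mechanism that
  amplifies small saliency differences between conflicting cues.

A conflict monitor routes each choice: with `s1`, `s2` the summed memory
weights from the active input channels to the two behaviour neurons, the
linear pathway decides iff `|s1 − s2| > th` (default `th = 3`); otherwise
the nonlinear pathway is engaged.

## Neuron and synapse model

Leaky integrate-and-fire point neurons, `τ_m dv/dt = −v + R·I(t)` with
`τ_m = 20 ms`, `R = 1`, threshold `v_th = 0.1`, reset `v_r = 0`,
integrated by forward Euler. Everything except time is dimensionless.

Synaptic events are delta impulses of fixed charge: a presynaptic spike
changes the postsynaptic potential by `±w·R/τ_m` on the next step
(positive for excitatory, negative for inhibitory connections; stored
magnitudes are non-negative). At the default training step `dt = 1 ms`
this is identical to a one-step current pulse of magnitude `w`; defining
it as fixed charge keeps synaptic efficacy independent of `dt`. There are
no conduction delays, refractory periods or noise currents.

Step order within the engine: integrate potentials → detect threshold
crossings → queue synaptic currents (delivered next step) → apply
plasticity → record. Plastic weights are hard-clipped to `[0, 10]` after
every update (bounds configurable per connection).

**Integration steps.** Training runs at `dt = 1 ms` (the membrane constant
of 20 ms makes this stable). Choice phases run at `dt = 0.1 ms`: the
choice readout compares first-spike latencies of inputs whose saliencies
may differ by a few percent, and at 1 ms resolution those latencies
quantize into ties across much of the conflict sweep.

**Winner-take-all tie break.** The two behaviour layers (CC output and
MBON) are symmetric at initialization, so both neurons would cross
threshold on exactly the same step and remain in deterministic lock-step.
When that happens, one of the simultaneous crossers (chosen uniformly
with the model RNG) spikes; the others are held just below threshold and
the winner's mutual inhibition, arriving next step, decides the
competition. This is the only stochastic element of the dynamics.

## Plasticity

**STDP.** The pair-based exponential window
`Δw = A₊·e^(−Δt/τ₊)` for post-after-pre and `−A₋·e^(−Δt/τ₋)` for
pre-after-post, with `A₊ = 0.925`, `A₋ = 0.9`, `τ₊ = τ₋ = 20 ms`;
simultaneous spikes produce no change. In the network loop, updates are
triggered by postsynaptic spikes only, each pairing with the most recent
presynaptic spike on the synapse (the causal branch). With near-balanced
learning rates and tonically firing inputs, triggering on both spike
types makes depression dominate at high presynaptic rates and collapses
every weight, so the loop uses the post-triggered rule; the depression
branch remains part of the primitive and its unit tests.

**Dopamine-gated punishment.** A punishment event launches a phasic trace
`DA(t) = DA_peak·e^(−(t−t_pun)/τ_t)` with `DA_peak = 10`, `τ_t = 2 ms`.
While the trace exceeds `0.01·DA_peak`, the weights from the currently
active input channels onto the chosen behaviour neuron are decremented by
the exact per-step integral of `DA(t)/τ_t`, so the cumulative decrement
approaches `DA_peak` regardless of `dt` — one punishment erases a
saturated weight. Only the active→chosen weights are touched.

## Training phase

Each pattern is presented for 1 s (one epoch trains both patterns, 2 s
total). The non-attended pattern inhibits the attended one channel by
channel (rectified subtraction), so shared cues cancel. The first
behaviour spike fixes the chosen behaviour; choosing to stay with a
punished pattern, or to abandon a safe one, triggers punishment.

Training uses action-selection semantics: from the first output spike the
non-chosen behaviour neuron is clamped (constant current −30, exceeding
any feed-forward drive), so plasticity binds only the expressed action;
on punishment the clamp swaps, the punished action is abandoned and the
alternative is expressed and re-associated within the same episode. The
behaviour layer also receives a small exploration drive (0.12) during
training so that some action is always expressed even when all learned
weights onto both behaviours have been depressed to the lower bound —
without it, a pattern punished under both contingencies across reversals
could never be re-learned. Episodes with no output spike (possible only
for a fully cancelled input) record a uniformly random choice.

Training is identical for the CC and MB pathways, so a single 5→2
feed-forward learner is simulated per episode and the learned matrix is
written to both the CC and the KC→MBON memory; the two stores therefore
agree elementwise by construction, which is also asserted in tests.

## Choice phase

The 2-s choice phase is divided into 20 sub-trials of 100 ms with
membrane state reset in between (the sub-trial length matches the DA
activation window; PI resolution is 2/20). Within a sub-trial, the first
behaviour spike casts one vote; `PI = (t1 − t2)/(t1 + t2)` over the
votes. A silent sub-trial is an indifferent one; indifferent sub-trials
alternate their votes (starting side drawn once per phase), so a fully
indifferent phase spends equal time on both behaviours and scores exactly
PI = 0. An outcome with no spike in any sub-trial is flagged undecided.

Memory weights (CC input→output, KC→MBON) are frozen during choice. The
gating connections of the nonlinear pathway — visual→KC, APL→KC, APL→DA,
DA→MBON — stay plastic. When the nonlinear pathway is engaged on a
non-empty input, the DA neuron is driven externally (current 3.0) for the
first 100 ms of the phase; its spikes inhibit APL and excite the MBONs.
During this window the KC relay freely and spike-timing plasticity
potentiates the visual→KC gate toward its bound (2.0, at which a single
visual spike crosses threshold). When the window closes, the tonically
driven APL interneurons (drive 0.15) resume their feedback inhibition;
cues whose gate was imprinted during the window pass, weaker cues are
suppressed disproportionately — the gain-gating amplification.

The KC→MBON synapses act at an efficacy scale of 0.15 relative to the
stored weights, so an MBON integrates several KC spikes before deciding.
This makes the nonlinear readout sensitive to KC firing rate (and hence
to the gating state) rather than to single spikes; it is also what makes
a too-short DA window fail: without the imprint, the tonically inhibited
KC cannot sustain the rate an MBON needs. A too-long window fails
differently — persistent DA→MBON excitation floods both MBONs equally and
their races end in coin-flip ties.

## Calibration parameters

The wiring and signs of the circuits are fixed by anatomy; the magnitudes
are calibration parameters exposed in the configuration. Defaults:

| parameter | value | role |
|---|---|---|
| `input_gain` | 0.105 | current per unit channel saliency; places the colour-learning threshold at CI = 0.1 (channel value 1.0 is the smallest whose asymptotic potential `0.105·v` exceeds `v_th`) |
| `init_plastic` | 0.5 | symmetric untrained memory |
| `visual_cc` | 2.0 | one-to-one relay into CC input (single-spike threshold crossing) |
| `visual_kc` / bound | 0.5 / 2.0 | plastic KC gate, imprinted during the DA window |
| `mutual_inh` | 2.0 | behaviour-layer winner-take-all |
| `kc_apl` / `apl_kc` | 3.0 / 1.5 | KC–APL feedback loop |
| `da_apl` / `apl_da` | 3.0 / 1.5 | DA–APL mutual suppression |
| `da_mbon` | 0.5 | DA excitation of MBONs during the window |
| `mbon_gain` | 0.15 | KC→MBON efficacy scale in the choice phase |
| `apl_drive` | 0.15 | tonic APL activity outside the DA window |
| `da_drive` / `da_duration` | 3.0 / 100 ms | external DA activation at choice onset |

These were tuned once so that the conditioning, threshold, conflict
and gating behaviours emerge together, and then frozen; they are ordinary
config entries and can be overridden per experiment.

## Agent tasks

**Window crossing.** A 9×9 grid with the goal at the centre; the two cues
are the remaining horizontal and vertical distances, normalized to
[1, 20] by `p = 1 + 19·x/x_max`. At each step the movement axis is drawn
from the policy's follow-probabilities (`p_i = t_i/Σt_j` over per-cue
spike counts for the circuit policies, 0.5/0.5 for the uniform policy);
axes with zero remaining distance are excluded from the draw. Every step
moves one cell toward the goal, so from a corner every policy needs
exactly the Manhattan distance in steps and the policy ordering
(nonlinear ≤ linear ≤ uniform) holds with equality; the step count serves
as a consistency bound rather than a discriminating statistic here.

**Obstacle avoidance.** Four distances (left, up, right, down) are
normalized, passed through the gain gate, and converted to
follow-probabilities. The nonlinear circuit concentrates the most
probability on the most salient direction; APL-only sharpens less;
the linear relay reproduces the input ratios.

**Online reversal.** Patterns are presented alternately with live
training updates; a block ends when both patterns have been answered
correctly twice in a row (the convergence criterion; the study counts
incorrect choices but does not define one). Consecutive blocks swap the
punished pattern.

## What the simulations do and do not show

All inputs are the synthetic five-channel saliency vectors defined by the
encoding; there is no image processing, and channel saliencies are exact
numbers, not noisy percepts. Dynamics are deterministic up to tie-breaks,
so preference indices saturate at ±1 where a real fly's would plateau
below; the linear pathway's conflict curve is consequently step-like
rather than gradually linear, and the sign pattern (not the slope) is the
meaningful comparison. Population sizes are minimal (5 KC rather than
~2000); the gain-gating mechanism operates per-channel rather than over a
sparse code. Passing tests show that the circuit mechanisms produce the
qualitative behavioural phenomena and the printed quantitative outcomes
at desk scale, not that the parameter values are biologically measured
quantities.

## Problem sizes

The test suite runs reduced protocols (3–6 seeds per condition, reduced
CI grids, 20 seeds for the learning-bound check); the acceptance script
runs the full published grids (10 seeds per condition; the shape sweep
uses 5 seeds × 11 CI values). Sizes are stated in each test.
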