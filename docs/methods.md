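# Model and methods

This note records what the package actually computes, which quantities are
assumptions or calibrated choices, and what the simulations can and cannot
show.

## Network model

Each of the three structures (OFC, LPFC, ACC) is a three-layer sheet:

* a **feedforward inhibitory** layer, 5×5 units, decay constant τ = 70 ms;
* an **excitatory** layer, 10×10 units on a 1 mm grid, τ = 10 ms;
* a **feedback inhibitory** layer, 5×5 units, τ = 7 ms, each unit centred
  over a 2×2 excitatory patch.

Units are rate units with the asymmetric activation
`g(u) = C·Q·(1 − exp(−exp(u/Q)))` (C = 1 throughout; the free overall scale
is carried by the external drive amplitude instead). `g` has a substantial
baseline (`g(0) ≈ 0.63·Q`), so inhibitory layers are tonically active and
excitatory units rest well below zero potential; external drive has to
overcome that tonic inhibition, which is why the calibrated drive amplitude
is large (93 potential-units/ms) relative to the unit scale.

Connectivity classes, within each structure:

* excitatory → excitatory, all pairs, space constant 5 mm, **plastic**;
* excitatory → feedback-inhibitory and back, all pairs, space constant 5 mm;
* feedforward-inhibitory → excitatory, patch-local.

Each realised connection carries a learnable weight
`clip(|N(0,1)|, 0, 1)·exp(−d/λ)·w_max` and a fixed **coupling gain**. For
the plastic excitatory class the coupling gain is a plain multiplier, so
learned weight changes feed straight back into the dynamics. For the fixed
inhibitory classes the coupling gains are row-normalized so that every
postsynaptic unit receives the same summed effective weight from the class
(the `CouplingScales` value *is* that afferent load), and each feedback
interneuron is additionally balanced across the tagged assembly groups.
This per-neuron synaptic scaling is essential: without it the random weight
draw scatters unit operating points over a range that is two orders of
magnitude wider than the activation function's responsive region, and no
coherent population rhythm exists. It is also what makes the dominant
frequencies reproducible to ±0.5 Hz across weight-initialization seeds.

Delays are 0.8 ms at all connections, plus `d / (0.5 m/s)` between
excitatory units, rounded to whole 1 ms integration steps (minimum one).
The integrator is forward Euler, `u(t+Δt) = u(t) + Δt·du/dt`, with a ring
buffer of past activations. **Delay convention:** the explicit-Euler update
itself carries one step of latency — an activation computed at step *t*
first acts on the update to *t+1* — so a connection with a k-step delay
reads the buffer k−1 positions back. With 0.8 ms delays and 1 ms steps this
is the more faithful discretization (total loop latency ≈ 2 ms rather than
4 ms); it matters, because the excitatory ↔ feedback-inhibitory loop's
oscillation frequency is set jointly by the two membrane time constants and
this loop latency.

Optional white noise enters Euler–Maruyama style (`sd·√Δt·N(0,1)` per
step), is fully seeded, and defaults to zero: with the seed fixed every
simulation in this package is bit-reproducible.

## Oscillation mechanism and the gain–frequency mapping

With constant drive to an assembly, the assembly's excitatory units and the
structure's feedback-inhibitory layer form a delayed negative-feedback loop
that crosses a Hopf-type instability once the loop gain exceeds threshold.
Near threshold the cycle is fast (the linear crossing sits near 79 Hz for
these time constants and latencies); deeper into the supercritical regime
the cycle grows and slows. The arousal gain Q moves the system along that
family: at the calibrated drive, Q = 6 yields a deep ≈50 Hz cycle, Q = 8 a
≈60 Hz cycle, and Q = 10 a small ≈77–80 Hz cycle near the upper edge of the
oscillatory window. Q is applied to the excitatory (principal) units;
interneurons keep a fixed reference excitability (Q = 6). Letting Q scale
the interneurons too makes tonic inhibition grow linearly with Q and
collapses the rhythm well before Q = 10, which is incompatible with the
gain sweep the model is meant to exhibit.

A consequence of this mechanism worth stating plainly: **as Q rises, the
limit-cycle amplitude falls while its frequency rises.** Raw oscillatory
energy `E = A²·f` therefore *declines* at high gain even though frequency
and synaptic weights increase. In the transport session the growth of the
attended option's value is carried by the weight factor `W`, not by `E`.

## Trust estimation

The observed action–outcome pair of each trial is coded as a binary symbol
(`r` rewarded, `n` not); the alphabet is deliberately minimal because the
predictability that matters for trust is whether following the expert pays
off. Transition probabilities are add-1 (Laplace) smoothed bigram counts
over the whole history; the predictability estimate is the probability that
the next association is rewarded given the current symbol; and trust is an
exponential smoother over that estimate with rate η = 0.2. The trust value
feeds (a) the trust-modulated Hebbian rule directly and (b) the affine
trust → arousal-gain maps, so the same scalar drives both plasticity and
excitability.

Two properties of this estimator shape the learning curve. First, the
Laplace prior makes early estimates conservative (a single rewarded trial
gives DBP = 0.5), so trust dips briefly below its initial value before
rising — the cost of not trusting a one-observation history. Second, the
bigram estimate moves by O(1/t) on every surprising outcome, so with a
fallible expert (competence < 1) the trust curve keeps receiving
perturbations above 10⁻³ well past trial 40. The default scenario therefore
uses a maximally competent expert (reward probability 1.0, action
repeat probability 0.95): outcomes are deterministic, actions still vary,
and the trust curve rises smoothly from 0.70 to ≈0.99, meeting the
steady-state criterion (|Δβ| < 10⁻³ for 5 consecutive trials) at trial 37
for every seed. With a stochastic expert the same machinery recovers the
expert's stationary reward probability to within 0.05 by trial 100 (median
over 500 sequences), which the test suite checks.

## Plasticity and the two learning channels

Weight updates are applied once per trial using post-transient trial-mean
activations, so the learning rate α is a per-trial quantity independent of
trial duration. Only excitatory–excitatory weights inside the tagged
assemblies are plastic; inhibitory weights and the inter-structure bundles
are fixed. The rational (LPFC) channel uses α = 0.2 with ceiling
w_max = 1.0; the emotional (OFC) channel learns more slowly (α = 0.03) and
against a lower ceiling (w_max = 0.6), and its arousal gain follows trust
with a lag (rate 0.08 per trial toward a map topping out near Q = 9). This
produces the intended asymmetry: rational weights for the observed option
saturate first and at a higher level; emotional weights follow over roughly
twice the timescale.

The β-scaled saturation term of the trust-modulated rule means the fixed
point `w_max/β` *decreases* as trust grows. The model's association of high
trust with *strong* weights is therefore routed through the gains: higher
trust → higher Q → larger activations → faster, larger updates. Both literal
behaviours of the rule are unit-tested separately.

Entries whose initial (value-encoding) weights exceed the current ceiling
are left untouched by clipping rather than truncated; the rule itself then
relaxes them toward the ceiling.

## Trial layout and value readout

A trial is 1000 ms (1000 Euler steps): a 200 ms transient is discarded, the
outcome is presented from 600 ms, predicted values are read from the
200–600 ms window and actual values from 700–1000 ms. The observed action's
assemblies (OFC and LPFC) and the expert's LPFC assembly receive the
calibrated constant drive (the expert assembly on the same footing as the
action's, drive + probe); all option assemblies receive a weak tonic probe;
rewarded outcomes add an extra boost after outcome onset.

Option values are `V = W · E / E_ref`: the assembly's mean plastic weight
times its last-measured oscillatory energy, normalized by the pinned
reference energy of a freshly driven assembly at Q = 6 (124 for the
rational channel, 236 for the emotional one, which differ because the two
structures sit at different operating points). An option that is not being
observed retains the energy of its last activation — a memory readout — so
its value moves only through its weights. At trial 1 this puts the reported
values exactly on the configured initial preference scale.

Session arousal gains follow trust through affine maps pinned at
(q_lo = −0.53, q_hi = 8.8) for the rational channel, i.e. Q runs from 6 at
β = 0.7 to ≈8.7 at full trust. The upper end is deliberately kept below 10:
with several assemblies co-active the oscillatory window's death edge sits
lower than in the single-assembly gain experiment, and driving session
gains to 10 silences the LPFC rhythm late in the session. The explicit
gain-sweep experiment (`expert_gain_frequency`) sets Q directly and is not
affected by this map.

## Calibration

The free parameters the governing equations do not determine — drive and
probe amplitudes, the per-class coupling loads, α, η, the gain maps and the
reference energies — are pinned as a bundle (`DEFAULT_CALIBRATION`) against
two anchors: the expert assembly's dominant frequency at Q = 6 (≈50 Hz, with
60 and 79 Hz at Q = 8 and 10 following from the model's own gain–frequency
scaling) and the saturation of the trust-related curves around trial 40.
`trustdyn.calibration.calibrate` re-derives the drive amplitude and learning
rate from those anchors by a coarse grid search; everything else in the
bundle is treated as structural.

## What the synthetic scenario does and does not show

The expert generator emulates exactly two behavioural dimensions:
consistency (probability of repeating the previous action) and competence
(probability of a rewarding outcome, independent per trial). It does not
model context-dependent action choice, outcome magnitudes, observer fatigue
or attention, multiple experts, or any feedback from the observer's own
choices (the session is purely observational). Passing tests therefore show
that the closed loop — predictability → trust → gain and plasticity →
valuation — behaves as designed under these idealized statistics; they say
nothing about fits to human behavioural or electrophysiological data, and
the EEG-like signals are abstract signatures, not predictions of recorded
EEG.

## Numerical choices and degenerate inputs

* Δt = 1 ms, guarded against the fastest time constant (integration refuses
  Δt ≥ min τ); non-finite states abort with the offending step index.
* Spectral readouts use a Hann-tapered periodogram on the analysis window,
  zero-padded to ≤1 Hz grid resolution, band 1–100 Hz; frequencies with
  fewer than two observed cycles in the window are excluded from the peak
  search, so an 800 ms window effectively starts at 2.5 Hz. Flat signals
  (variance < 10⁻¹⁸) raise a flat-signal error, which the assembly-energy
  readout converts into a zero-energy, undefined-frequency result.
* Ties in the argmax decision rule break toward the lowest option index.
* The steady-state detector returns the earliest 1-based trial index whose
  k consecutive per-trial changes stay below ε, `None` if none exists, and
  refuses series shorter than k + 1.
* An empty observation history yields the smoothed uniform transition model
  (DBP = 0.5); a context never observed under zero smoothing falls back to
  a uniform row.

## Known limitations

* The amplitude–frequency trade-off described above: raw assembly energy is
  not monotone in trust under the pinned calibration.
* The steady-state criterion with ε = 10⁻³ is only reachable by trial 40
  with a deterministic-outcome expert; fallible experts saturate later and
  more raggedly.
* Within-session arousal gains top out near 8.7 (see above), so the
  session-time rhythm reaches ≈75 Hz rather than 79 Hz; the full 50→79 Hz
  sweep is exhibited by the controlled gain experiment.
* Action switches by a less-than-fully-consistent expert pause the attended
  option's weight growth; with unlucky seeds an early switch streak can
  satisfy the weight steady-state detector spuriously (the trust curve is
  unaffected, as it depends only on outcomes).
* The three structures share one architecture; no laminar, anatomical or
  conduction realism beyond the three-layer abstraction is intended.
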