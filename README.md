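# flydec

A spiking-circuit model of visual decision-making in *Drosophila*: a fast
**linear** pathway through the central complex that reads out learned
stimulus–behaviour associations, and a value-based **nonlinear** pathway
through the mushroom body whose dopamine–APL–Kenyon-cell loop amplifies
small saliency differences between conflicting cues. The package is for
computational neuroscientists and roboticists who want a small, fully
tested reference implementation of this two-pathway architecture —
aversive conditioning, conflict choice, ablations, reversal learning and
multi-cue gain-gating — on leaky integrate-and-fire neurons.

## The model in brief

Neurons follow `τ_m dv/dt = −v + R·I(t)` (`τ_m = 20 ms`, `v_th = 0.1`,
`v_r = 0`), integrated by forward Euler. Visual stimuli are five-channel
saliency vectors `[R, G, B, upright, inverted]` — e.g. `[0, 10, 0, 10, 0]`
is an upright green T and `[0, 10·CI, 0, 10, 0]` scales its colour
saliency by the colour intensity CI. When two patterns are shown, the
non-attended one inhibits the attended one channel-by-channel, so shared
cues cancel.

Learning combines spike-timing-dependent plasticity
(`Δw = A₊e^(−Δt/τ₊)` / `−A₋e^(−Δt/τ₋)`, `A₊ = 0.925`, `A₋ = 0.9`,
`τ± = 20 ms`) with punishment-triggered phasic dopamine
(`DA(t) = DA_peak·e^(−(t−t_pun)/τ_t)`, `DA_peak = 10`, `τ_t = 2`), which
depresses exactly the weights from active inputs onto the chosen
behaviour. Choices are read out by first spike; preference over a 2-s
choice phase is the index `PI = (t₁ − t₂)/(t₁ + t₂)`. A conflict monitor
routes each choice: linear if `|s₁ − s₂| > th` (summed active-input
weights to the two behaviours, `th = 3`), nonlinear otherwise.

See `docs/methods.md` for the full model description and the calibration
parameters.

## Worked example

```python
from flydec import build_model, encode, train_task, choose

model = build_model(seed=0)
green = encode("green", "upright")     # [0, 10, 0, 10, 0], safe
blue = encode("blue", "inverted")      # [0, 0, 10, 0, 10], punished

episodes = train_task(model, safe=green, punished=blue, epochs=1)
print([(e.pattern, e.chosen_behavior, e.punishment_applied)
       for e in episodes])

out = choose(model, green, blue)
print(out.pathway, out.pi)
out = choose(model, encode("blue", "upright"), encode("green", "upright"))
print(out.pathway, out.pi)
```

prints

```
[('upright-green-T', 2, True), ('inverted-blue-T', 2, False)]
linear 1.0
linear -1.0
```

In this run the model's first (untrained) guess on the safe pattern was
behaviour 2 — abandoning a safe pattern — so it was punished once, then
re-learned within the same episode; the punished pattern was answered
correctly at once. After this single epoch the colour test gives full
preference for the safe colour (`PI = 1.0`) and full avoidance of the
punished one (`PI = −1.0`), both through the linear pathway because the
learned weights separate the behaviours clearly.

The named experiments (conflict sweep, DA/APL ablations, DA-duration
sweep, window and obstacle tasks, online reversal, …) run from the CLI:

```sh
flydec run conflict_sweep --seed 0 --out results/
flydec dump-config          # fully resolved defaults, YAML
flydec fixtures --out fixtures/
```

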