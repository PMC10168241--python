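# illusionet

A two-layer shunting neural-field model of how early vision represents two
visual illusions — the **contrast–contrast illusion** (a patch embedded in a
high-contrast surround looks lower-contrast than it is) and **two-flash
apparent motion** (alternately flashing bars are seen as one moving object) —
and of how those representations weaken when the excitation/inhibition
balance of receptive fields or the top-down feedback gain is altered, as has
been reported for observers with schizophrenia.

The package is for computational-neuroscience researchers who want to
regenerate and extend the model's parameter-sweep results: how the illusion
metrics move as the inhibitory subfield width/amplitude, the excitatory
subfield width/amplitude, or the feedback gain are scaled.

## Model

Each layer is a 1D array of neurons with shunting (membrane-style) dynamics

```
dx/dt = -A·x + (B - x) ∘ (I ⊛ G_Ex) - (C + x) ∘ (I ⊛ G_Inh)
```

where `A` is the decay rate, `B`/`C` the upper/lower activation bounds, `∘`
the elementwise product and `⊛` spatial convolution. The receptive subfields
are Gaussians `g(k; h, σ) = h·exp(-k²/2σ²)` whose peak amplitude `h` and
width `σ` are adjustable independently; the excitatory minus the inhibitory
subfield forms an on-center/off-surround difference-of-Gaussians profile
(baseline ratios `h_Ex/h_Inh = 2`, `σ_Ex/σ_Inh = 1/2`). Layer 1 (model LGN)
is driven by the stimulus plus `α` times the fed-back layer-2 activity;
layer 2 (model V1) is driven by the layer-1 output. Static stimuli are
processed by a five-stage settle–feedback loop, time-varying stimuli by
continuous co-integration of both layers.

Illusion representation is quantified by

- `r = s1 - s2` — the center–surround response difference for the
  contrast–contrast grating (`s1`: max layer-2 response over the surround
  region, `s2`: over the center analysis window); and
- `Φ = c1·c2·P(U > V) = Σ_{u>v} x_p(u)·x_q(v)` — the temporal overlap of the
  layer-2 response time courses at the two bars' edges for apparent motion,
  with `c1`, `c2` the curves' integrals.

## Worked example

```python
import illusionet as il

config = il.resolve_config()          # committed calibrated baseline
r = il.run_cc(config)                 # contrast-contrast representation
rows, peak_freq, peak_phi = il.run_am(config)  # apparent-motion profile
print(f"r = {r:.4f}")
print(f"peak phi = {peak_phi:.4f} at {peak_freq} Hz")
for sd, freq, phi in rows:
    print(f"  SD={sd:>2} steps  {freq:>5.2f} Hz  phi={phi:.4f}")
```

prints

```
r = 0.0101
peak phi = 1.5846 at 3.12 Hz
  SD=75 steps   0.75 Hz  phi=0.1722
  SD=54 steps   1.04 Hz  phi=0.4020
  SD=41 steps   1.37 Hz  phi=0.7524
  SD=33 steps   1.70 Hz  phi=1.0772
  SD=24 steps   2.34 Hz  phi=1.4704
  SD=18 steps   3.12 Hz  phi=1.5846
  SD=15 steps   3.75 Hz  phi=1.5167
  SD=12 steps   4.69 Hz  phi=1.3140
  SD= 9 steps   6.25 Hz  phi=0.9516
  SD= 6 steps   9.38 Hz  phi=0.4695
```

`r > 0` says the surround suppresses the model's response to the
low-contrast patch (the illusion is represented), and the Φ-vs-frequency
profile rises to its peak at a presentation frequency of 3.12 Hz — the
frequency at which apparent motion is perceived most strongly — then falls.

A command-line interface wraps the same operations:

```
illusionet simulate --illusion am --out out/
illusionet sweep --spec sweep.yaml --out out/     # parameters: {alpha: [...]}
illusionet classify --out out/                    # six-phenotype table
```

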