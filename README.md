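# rivalnorm

Firing-rate models of **binocular rivalry** and **cross-orientation
suppression** under divisive normalization.

When orthogonal gratings are shown one to each eye (dichoptic gratings),
perception alternates strongly between them. When the same two gratings are
superimposed and shown to both eyes (a binocular plaid), the components
barely rival — they merely suppress each other weakly. Conventional rivalry
models built on strong mutual inhibition between orientation channels get
the first phenomenon right and the second badly wrong: they predict strong
plaid rivalry. This package implements and compares two models of the
underlying circuit:

- a **conventional model** — four monocular neurons (eye x orientation) and
  two binocular summation neurons, with competition implemented by divisive
  normalization within each layer;
- an **ocular opponency model** — the same circuit plus four opponency
  neurons that compute the rectified interocular difference per orientation
  (R−L and L−R) and, through feedback, subtractively inhibit both monocular
  neurons of the eye they receive inhibition from. Opponency neurons are
  silent for binocular stimuli and active for monocular/dichoptic ones, so
  they amplify competition exactly when rivalry should occur.

Every neuron follows a dynamical normalization equation

```
tau dR_i/dt = -R_i + |E_i|+^2 / (sigma^2 + sum_j w_ij |E_j|+^2)
```

where `|x|+ = max(x, 0)`, `E_i` is the neuron's drive (stimulus contrast,
feedforward input, or interocular difference, plus lowpass-filtered Gaussian
noise and minus scaled long-term adaptation), and `j` ranges over the
neuron's normalization pool. Rivalry strength is measured by the
winner-take-all index `WTA = <|R_A - R_B| / (R_A + R_B)>_t` on the summation
neurons (0 = identical responses, 1 = complete rivalry), and mixed
perception by the fraction of time the pointwise percept index
`P(t) = |R_A - R_B| / (R_A + R_B)` stays below a cutoff (default 0.4).

The package provides stimulus construction (five canonical conditions plus
orientation-alternating adaptors), seeded noise generation, forward-Euler
simulation (batched over replicates or parameterizations), the rivalry
metrics, an exhaustive grid search over conventional-model weights with
two-round acceptance criteria and a monocular-grating plausibility test,
and the adaptation-experiment protocol that separates the two models'
psychophysical predictions.

## Worked example

```python
from rivalnorm import ModelParams, make_condition, simulate, wta_index, count_switches

params = ModelParams()   # sigma=0.5, sigma_opp=0.9, tau=50 ms, noise SD 0.05
for cond in ("dichoptic_gratings", "binocular_plaid"):
    stim = make_condition(cond, contrast=0.5, duration_s=160.0)
    res = simulate("opponency", stim, params, dt_ms=2.0, seed=42)
    rA, rB = res.r_sum[:, 0], res.r_sum[:, 1]
    print(f"{cond}: WTA = {wta_index(rA, rB):.3f}, "
          f"switches = {count_switches(rA, rB)}")
```

prints

```
dichoptic_gratings: WTA = 0.639, switches = 53
binocular_plaid: WTA = 0.155, switches = 49
```

The opponency model rivals strongly for dichoptic gratings (WTA 0.64, with
dozens of dominance alternations over 160 s) but only weakly for the
binocular plaid (WTA 0.16) — about a four-fold difference, the behavior
that conventional mutual-inhibition models cannot reproduce at any point of
an exhaustive weight/noise grid. The same stimuli drive rivalry through the
command line:

```
rivalnorm simulate --model opponency --condition dichoptic_gratings \
    --contrast 0.5 --duration 160 --dt 2 --seed 42 --out traces.csv
rivalnorm metrics traces.csv
rivalnorm gridsearch --subgrid 3 --seed 0 --out report.json
rivalnorm adapt-experiment --model opponency --blocks 100 --out adapt.json
```

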