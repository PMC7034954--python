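# dendroclock

Biophysical simulation of **time-interval learning in a Purkinje-cell
dendrite**.

In delay eyeblink conditioning, a neutral conditioned stimulus (CS, carried
by parallel fibres) is followed after a fixed inter-stimulus interval (ISI)
by an unconditioned stimulus (US, carried by the climbing fibre), and the
cerebellum learns to time its response just before the expected US.
Experiments show this timing survives changes in CS drive strength,
duration and frequency, and persists when ionotropic receptors are blocked
— pointing to an *intracellular* timing mechanism rather than synaptic
weights.  `dendroclock` implements a molecular-cascade model of that
mechanism for the researcher who wants to simulate, probe or refit it:

* a **calcium store** (Somogyi–Stucki-type pool/cytosol exchange with a
  CICR gate `f(y) = yⁿ/(yⁿ+hⁿ)`) acts as the clock started by the CS;
* **adenylyl cyclase** is the coincidence detector: its activation rate
  `r1 = r1_bl + r_cag·[Gs]·Ca³/(K³+Ca³)·K_Gi/(K_Gi+Gi)` rises above
  baseline only when CS-driven calcium and US-driven stimulatory G protein
  (Gs) are present together;
* the **cAMP→PKA** pathway is the positive feedback and the memory: PKA
  multiplies the synaptic calcium read-out `[Ca²⁺] = (1+10·[PKA])·y`, so
  each pairing speeds the clock;
* a calcium-gated **RGS switch** (`α = 1 if z > 0.1`, with
  `dz/dt = r3(1−z) − r4·z`, `r3 = r3_bl·Ca²/(K+Ca)`) is the timed output
  and the negative feedback: once it anticipates the US it suppresses Gs
  and learning converges.

The integrator is the published scheme — fixed-step backward Euler at
25 µs (Newton-solved, with an explicit RK4 oracle for cross-validation) —
and the protocol engine runs single pairings, training series and ISI
sweeps with the slow species carried across trials.  See
`docs/methods.md` for the full model description, parameter provenance
(the shipped set is re-calibrated, not transcribed) and known limitations.

## Worked example

Train the naive model with eleven CS–US pairings at a 150 ms ISI:

```sh
dendroclock train --isi-ms 150 --pairings 11 --out out_train
```

which prints the per-pairing table (abbreviated):

```
 index  isi  rgs_activation_time  anticipated  peak_Ca  Ca_integral  end_PKA ...
     1 0.15                  NaN        False 0.974644     0.775317 0.106270
     2 0.15             0.371103        False 2.212253     1.569054 0.190504
     3 0.15             0.251146        False 2.864000     1.983686 0.235339
     ...
    10 0.15             0.154138        False 4.326533     2.948087 0.370639
    11 0.15             0.149585         True 4.451384     3.031772 0.383264
final trial anticipated = True; first anticipating trial = 11
```

Reading it: on the first pairing the RGS gate never trips; from the second
pairing on, the activation latency (seconds after CS onset) shrinks
monotonically — 0.371, 0.251, … — as PKA accumulates and amplifies the
calcium signal, until on pairing 11 the switch fires at 149.6 ms, *before*
the US at 150 ms: the interval has been learned.  `peak_Ca` and
`Ca_integral` show the released calcium roughly doubling from pairing 1 to
pairing 2 (the ~100 % second-pairing amplification: +102.4 % by the
window-integral metric).

The same things are available as a library:

```python
from dendroclock import (ModelParameters, IntegratorConfig,
                         StimulusProtocol, run_training, calcium_amplification)

params = ModelParameters()                       # shipped re-calibrated set
config = IntegratorConfig()                      # backward Euler, 25 µs
proto = StimulusProtocol.pairing_series(2, isi=0.150)
result = run_training(proto, params, config)
print(calcium_amplification(result))             # -> 102.4 (percent)
```

Other entry points: `dendroclock simulate` (full traces of every species,
single/second-pairing runs, `--no-us` for CS-alone probes),
`dendroclock sweep` (pairings-to-learn across an ISI grid) and
`dendroclock calibrate` (seeded constraint-guided parameter search).

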