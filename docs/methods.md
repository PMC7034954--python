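# Methods

## The model

`dendroclock` simulates the molecular cascade by which a single dendritic
microdomain of a cerebellar Purkinje cell can learn the delay between a
parallel-fibre input (the conditioned stimulus, CS) and a climbing-fibre
input (the unconditioned stimulus, US) in a delay-conditioning task.  The
cascade has five functional elements, each implemented by one or two
coupled ODEs over a well-mixed microdomain (concentrations in µM, time in
seconds):

**Calcium store — the clock.**  A two-pool store oscillator exchanges
calcium between a pool `x` and the cytosol `y`:

    dx/dt = k1·y − k2·x − α·f(y)·x
    dy/dt = k2·x − k1·y + α·f(y)·x + γ − β·y,   f(y) = yⁿ/(yⁿ + hⁿ)

`f(y)` is the calcium-induced calcium-release (CICR) gate.  The exchange
terms cancel pairwise, so total calcium obeys d(x+y)/dt = γ − β·y exactly
— an identity the test suite asserts along every trace.  A CS sets the
pool to its release set-point (x = 25 µM); the resulting cytosolic
transient is the time base of the clock.

**Synaptic read-out and decoupling.**  The synaptic calcium seen by the
downstream enzymes is basal (`B_Ca`) except for a 2 s window after the
CS, during which

    [Ca²⁺] = (1 + 10·[PKA])·y .

Because the CS acts only through its onset (the receptors saturate within
the first milliseconds of drive), the drive duration and strength are
carried on `Trial` purely as descriptors and verified to have no effect —
the decoupling property observed experimentally with interrupted or
re-frequenced CSs.

**Coincidence detector.**  Active adenylyl cyclase follows
d[AC]/dt = r1·[ACi] − r2·[AC] with

    r1 = r1_bl + r_cag·[Gs]·Ca³/(K_ca_AC³+Ca³)·K_Gi/(K_Gi+Gi)
    r2 = r2_bl + r_ca·Ca .

The synergy term vanishes when Gs = 0: calcium alone never activates AC
above baseline.  Gs is produced only for 200 ms after the US, with
amplitude 5·K_g³/(K_g³+[RGS]³) — suppressed once the RGS feedback is
active.  Gi rises exponentially (a·e^{b·t}) for 1.2 s after the CS, is
held until 2 s, then shuts off; because Gi grows with time, a later US
meets a more strongly inhibited cyclase, which is one of the two
mechanisms making longer intervals slower to learn (the other is the
decay of the calcium transient).

**Positive feedback.**  AC drives the cAMP→PKA loop
(d[cAMP]/dt = k8·[AC] − k10·[PDE]·[cAMP]/(km+[cAMP]),
d[PKA]/dt = ka7·[PKAi]·[cAMP] − k7·[PKA]), with a PKA-activated
phosphodiesterase (d[PDE]/dt = k13 + k14·[PKA]·[PDEi]/(km2+[PDEi]) −
k15·[PDE]) closing a negative loop inside it.  PKA is the memory: it
decays slowly (k7 = 2·10⁻⁴ s⁻¹) and multiplies the calcium read-out, so
each pairing speeds the clock seen by the output stage.  Inactive pools
are closed by strict conservation ([ACi] = AC_total − [AC], and likewise
for PKA and PDE); the printed initial concentrations fix the totals.

**Timed output.**  A calcium-gated variable z
(dz/dt = r3·(1−z) − r4·z, r3 = r3_bl·Ca²/(K_ca_RGS+Ca), implemented
exactly in that printed form) trips a hard switch at z > 0.1 that turns
on RGS (d[RGS]/dt = (r5+α)·(1−[RGS]) − r6·[RGS]).  The first post-CS
switch time is the model's timed response; training moves it earlier
until it precedes the US ("anticipation"), at which point RGS suppresses
Gs and learning self-limits.

## Integration

The production scheme is fixed-step backward Euler at 25 µs, the scheme
under which the cascade was originally studied.  Each implicit step is
solved by Newton iteration on a finite-difference Jacobian of the full
8-species right-hand side (tolerance 10⁻¹⁰ relative to state scale,
≤ 12 iterations; the explicit Euler value seeds the iteration and, at
25 µs, one or two Newton steps suffice).  Stimulus windows and the z
switch are evaluated at the end time of each step inside the implicit
solve; if the switch flips during the iteration the step is accepted
with the flipped value.  Nothing is clamped — invariant violations
raise.  Stimulus onsets are snapped to the step grid (exact for ms-scale
onsets at 25 µs).  A classical explicit RK4 run on a finer grid is built
in as an independent accuracy oracle; backward Euler at 25 µs agrees
with RK4 at 1 µs within 0.5 % of each species' dynamic range over a full
pairing, and halving the step changes trajectories by < 1 %.

Unstimulated inter-trial relaxation segments use a coarser 1 ms step
(configurable `relax_dt`): between trials every drive is off and the
dynamics are smooth slow decays for which the L-stable backward Euler
scheme is accurate at that resolution; trial segments always use the
production step.

## Protocols

A trial places a CS onset (default 0.1 s into the trial) and optionally
a US onset; the inter-stimulus interval (ISI) is onset-to-onset, the
delay-conditioning convention.  Trials last until all 2 s windows close
(last onset + 2.5 s).  Between trials the slow species (AC, cAMP, PKA,
PDE, RGS, z) persist and relax for the inter-trial interval (default
10 s; the original description is silent on trial spacing), while the
stimulus-driven quantities (x, y, Gi, Gs, stimulus clocks) are
re-initialised at each CS, x by the hard reset to 25 µM stated for the
pool.  CS-alone probes are trials with no US (the Gs equation is left
untouched).

Anticipation is read from the model's own switch — the first post-CS
time at which z exceeds 0.1 — because that is the quantity the feedback
actually uses; an RGS-fraction criterion is available for figure-style
comparisons.  The scalar "calcium released" per pairing is the integral
of the synaptic calcium over the 2 s post-CS window (the peak is kept as
a secondary metric); the original account plots full traces and does not
define the scalar.

## Parameters

No usable parameter table accompanies the published description of this
cascade, so the shipped defaults are **re-calibrated and
non-authoritative**: a working set derived with the constraint suite in
`dendroclock.calibration` so that the model reproduces the documented
behaviours —

* resting stationarity (an unstimulated run stays put after settling);
* ≈100 % more calcium released on the second pairing of a 150 ms-ISI
  run (shipped set: 102 %);
* anticipation of a 150 ms ISI after 11 pairings (shipped set: exactly
  11);
* every ISI in 150–1000 ms learned within 70 pairings (shipped set:
  maximum 60 on the grid {150, 300, 500, 750, 1000} ms);
* no learning for ISIs shorter than the calcium-signal onset lag
  (≈ 90 ms with the shipped set), and no RGS activation from basal
  calcium alone.

Values fixed by the published equations are used verbatim: the PKA gain
of 10 in the read-out, the pool set-point of 25 µM, the 2 s calcium
window, the 1.2 s Gi rise and 2 s Gi cut-off, the 200 ms Gs window with
amplitude scale 5, the switch threshold z > 0.1, and the initial
concentrations.  The printed initial-condition list assigns both 0.1 and
5 µM to the inactive-AC symbol; the package exposes the two
self-consistent readings as presets (`pde_pool`, the default, takes
5 µM as the inactive PDE pool, matching the Michaelis dependence of PDE
activation on a sizeable reservoir; `ac_pool` takes it as inactive AC)
and does not silently choose.

The calibrated constants produce a synaptic calcium transient that rises
within ~25 ms of the CS, peaks near 0.9 µM at ~150 ms and decays with a
~0.55 s time constant, and a z-drive in the quasi-linear regime of the
printed r3 form.  Calibration itself is a seeded Latin-hypercube search
(log-scale bounds, rate constants span decades) with multiplicative
coordinate refinement; it is deterministic given the seed and idempotent
at feasible points.

## Known limitations

* **First-pairing latency.**  In the documented behaviour the RGS
  response appears on the very first pairing, about 1 s after the US.
  With the shipped defaults the gating variable z peaks at ~0.06 on the
  first pairing — below the switch threshold — and the first
  supra-threshold activation appears on pairing 2 (at ~0.37 s post-CS,
  then moving monotonically earlier).  The trade-off is structural: with
  the read-out gain fixed at 10, a ~100 % second-pairing amplification
  pins the first-trial PKA increment near 0.12 µM, and any z-drive close
  enough to threshold to fire ~1 s after the first US lets that single
  increment anticipate every sub-second interval within 2–3 pairings.
  The shipped set favours the quantitative targets (11 pairings, ~100 %,
  70-pairing bound).  A `first_pairing_delay` calibration constraint is
  provided for exploring the other corner of this trade-off.
* **Short-end monotonicity of the learning curve.**  Pairings-to-learn
  with the shipped set is 11, 4, 5, 15, 60 over {150, 300, 500, 750,
  1000} ms: monotone non-decreasing from 300 ms upward but largest at
  150 ms, whereas the documented curve increases over the whole range.
  The same structural coupling is responsible: the amplification-pinned
  early PKA increments cover the (lower) anticipation thresholds of the
  300–500 ms intervals within a few pairings, while 150 ms anticipation
  needs several-fold more PKA.  The Gi transient being a single
  exponential, no slope suppresses the 300 ms gain 5-fold relative to
  150 ms without pushing the 1000 ms interval past the 70-pairing
  budget.  The corresponding monotonicity test is left failing rather
  than weakened.
* The model is a single well-mixed microdomain: no spatial diffusion, no
  membrane potential or spiking, no multi-synapse stochastic learning,
  and no long-term consolidation.
* Synthetic protocols exercise exactly the idealised stimulus timing the
  equations assume (instantaneous onsets on a 25 µs grid); passing tests
  say nothing about robustness to jittered or graded stimuli in real
  dendrites.

## Numerical choices

* Newton tolerance 10⁻¹⁰ (relative to state scale), ≤ 12 iterations;
  non-convergence raises with the failing step time.
* Recording stride 1 ms by default; crossing times are linearly
  interpolated inside the stride.
* Degenerate ISIs (US inside the first integration step after the CS)
  are a configuration error.
* The ISI sweep may be run at a 100 µs step: the step-halving check
  bounds the resulting drift below 1 %, and the sweep outcome on the
  standard grid is identical at 25 µs and 100 µs.
* Traces are validated after integration: finiteness, non-negativity,
  conservation bounds (tolerance 10⁻⁸) — violations raise rather than
  clamp.
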