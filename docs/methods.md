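# Methods

This note documents the models, parameters and design choices behind
`fescycle`: what the controller computes, what the synthetic environment
does and does not emulate, and which decisions were genuinely open.

## Control architecture

The loop runs at 10 Hz (the rate at which the stimulation hardware this
design targets exchanges data). Each tick: measure the crank through the
encoder model → update the moving-average cadence error → PI step → agent
bookkeeping (only at 5 s interaction boundaries) → build per-channel
stimulation commands → advance the plant → append one log record.

### PI amplitude modulation

A single shared output `u` (mA) is added to every enabled channel's
agent-adjusted amplitude baseline — the different muscle groups are
modulated simultaneously, not individually (a per-channel-gain variant
would be a straightforward extension; the shared form is the default
because a single cadence error signal drives all channels). Discrete
forward-Euler PI at 10 Hz:

```
e  = reference − measured          (rpm)
u  = kp·e + ki·∫e dt, clipped to [0, u_max]
```

`u_max` is recomputed each tick as `100 mA − max_c(a_c + α_c·k_a)` so that
no channel command ever exceeds the ceiling; anti-windup freezes the
integrator whenever integrating would push further into a saturated limit.
Defaults `kp = 1.2 mA/rpm`, `ki = 0.35 mA/(rpm·s)` were tuned once against
the default M1 plant (fatigue off) for settling within ±1 rpm of 35 rpm in
under 30 s, and then frozen. They are plant-specific plumbing, not a tuned
claim about any physical trike.

### Epsilon-greedy baseline adaptation

Per channel, the nine delta actions are indexed lexicographically over
`(α, ω)` with `D3` ordered `(−0.5, 0, 1)`; index 4 is the identity `(0, 0)`.
The index map is stable and documented because the action numbering used in
informal descriptions of such controllers varies; only the tuple matters.

Selection: with probability ε, a uniform draw over the *admissible* subset;
otherwise the admissible action with the greatest sample-average value,
ties broken by a seeded uniform draw among the maxima. Admissibility
combines the range rule (amplitude baseline within `a0 ± Δa`, `Δa = 10 mA`,
intersected with [0, 100] mA, relative to the session's initial baseline
`a0`; width within the hard [450, 600] µs bounds — the nominal ±100 µs/−50 µs
excursion is subsumed by those bounds from a 500 µs start) and the
saturation rule (no width decrease while the commanded amplitude sits at
the ceiling; width increases remain allowed). The saturation rule is
evaluated against the amplitude each *candidate* action would command, so
a width decrease can never take effect at the ceiling; this is slightly
stronger than checking the pre-action amplitude and makes the logged
invariant exact at interaction boundaries. Mid-interaction the held action
is not revisited, so a saturation onset within a 5 s window can briefly
coincide with a held width-decreasing action; the selection rule itself is
never violated.

Rewards: the instantaneous reward is evaluated every tick from the measured
crank angle and the window-10 moving-average cadence error, and pooled over
the 5 s interaction as the **mean of the in-window samples** (zero if the
crank never entered the channel's window). Averaging rather than summing
keeps Q magnitudes comparable across cadences and window widths; this
pooling choice was open and is fixed here.

Scaling: the reward uses normalized parameters (`width × 1e−4`,
`amplitude × 1e−3`, so 500 µs → 0.05 and 100 mA → 0.1). Only the ordering
of rewards matters to the argmax, so the absolute scale is cosmetic; both
scale factors live in `RewardParams` and can be changed. `PK = 100` is
treated as being in width units (µs) before scaling, since it combines
additively with `Pmax + Pmin − P`. With the defaults the reflected width
`P̄` spans [350, 500] µs over the admissible range and is never negative.
The moving-average error enters as `1/ē` and is clamped below at
`error_floor_rpm = 0.1` so perfect tracking does not blow up the reward;
the absolute value of the signed moving average is used.

Value estimates are per-action only (a bandit formulation): the state
(crank angle, mean error) conditions the reward through gating and `1/ē`,
but Q is not tabulated per state. Q initializes to zero — rewards are
non-negative, so zero is a pessimistic-neutral start — and both Q and the
counts reset at each episode boundary, making consecutive episodes
independent evaluations from the newly promoted baseline. At the boundary
the greedy admissible action per channel is applied once to the baseline;
when every admissible estimate is equal (e.g. an episode with no in-window
reward), the promotion prefers the identity action so baselines do not
random-walk while unrewarded (option `prefer_noop_on_tie`, on by default
for promotion, off for within-episode selection). The first action of a new
episode is selected immediately after promotion; interaction and episode
clocks are tick-based (50 and 450 ticks at 10 Hz).

A consequence of the per-episode reset worth stating explicitly: with nine
selections per 45 s episode and zero-initialized estimates, a single
episode visits the globally best action only with probability
`1/9 + (8/9)·(1 − (1 − ε/9)^8)` (≈ 0.38 at ε = 0.4) in a stationary
deterministic bandit, because the greedy rule locks onto the first arm that
returns any positive reward. Reliable identification of the best arm within
one episode would require optimistic initialization or persistent
estimates; with this design, learning across a session instead comes from
the gradual accumulation of promotions over many episodes.

## Synthetic environment

The plant exists to exercise the controller; it is deliberately not a
validated musculoskeletal model. Omitted on purpose: calcium/activation
dynamics, Hill-type force–length/velocity relations, joint geometry,
spasticity, day-to-day variability. What it does emulate — angle-gated
torque, charge-dependent recruitment, progressive fatigue, quantized
measurement — is the structure the controller's logic actually relies on.
Consequently, passing tests show the control and learning logic behaves as
designed under that structure; they are not evidence about torque or power
magnitudes in any real rider.

* **Crank**: `J dω/dt = τ_muscle − b·ω − τ_load`, semi-implicit Euler with
  10 ms internal sub-steps under the 100 ms control tick. The load torque
  only resists motion (stiction-like at rest) and cadence is floored at 0.
* **Torque profiles**: one raised-cosine bump per channel, 120° wide,
  centers 60° apart (right leg VL+RF 20°, VM 80°, HAM 140°; left leg +180°),
  peak 13 N·m for quadriceps channels and 9 N·m for hamstrings at full
  activation. At 50% overlap the bumps sum nearly flat (ripple ≈ ±17%),
  which keeps cadence ripple within the tracking band at the default
  inertia. Channel stimulation windows default to the bump supports.
* **Recruitment**: activation = clipped linear ramp in the charge rate
  (amplitude × width × frequency) between 200 µC/s (threshold) and
  2500 µC/s (saturation). The default baseline (45 mA, 500 µs, 35 Hz →
  787.5 µC/s) recruits ≈ 0.26; the maximum command (100 mA, 600 µs) ≈ 0.83,
  leaving the PI roughly a factor 3 of authority.
* **Fatigue**: per-channel fitness `φ ∈ [0.25, 1]` scaling the produced
  torque, `dφ/dt = −λ·act·(φ − φ_min) + ρ·(1 − act)·(1 − φ)` with
  `λ = 6e−4 /s`, `ρ = 1e−4 /s`, driven only while the channel is actually
  stimulating inside its window.
* **Measurement**: floor quantization of the angle at 1440 counts/rev (a
  360-ppr incremental encoder read in 4× quadrature); cadence from count
  differences per 100 ms window, i.e. a resolution of ≈ 0.42 rpm, which is
  what makes the measured-cadence signal visibly discrete.
* **Noise**: optional relative Gaussian torque noise, off by default so the
  default sessions are deterministic given the seed.

Gear presets: M1 `J = 8 kg·m²`, `τ_load = 3 N·m`, 2.05 m per crank
revolution; M2 (heavier) `J = 10 kg·m²`, `τ_load = 5 N·m`, 2.30 m/rev.
The damping is 0.5 N·m·s/rad in both. These constants were calibrated once,
jointly with the fatigue rate, so that (i) PI-only on M1 with fatigue off
settles and holds 35 ± 1 rpm, (ii) PI-only on M2 saturates the amplitude at
≈ 23 simulated minutes (within the intended 20–40 min band) with tracking
degrading afterwards, and (iii) M1 sustains tracking much longer than M2.
Under these conditions the 60%@.99 agent on M2 promotes pulse widths toward
600 µs within the first few episodes and postpones amplitude saturation to
≈ 56 min (median over seeds) — the charge-headroom effect the reward was
designed to produce. No constant was revisited after that calibration.

## Sessions, logging, metrics

Sessions are reproducible: a single `SeedSequence` derived from the config
seed feeds separate agent and environment generators, and identical
config + seed yields byte-identical CSV logs. The log carries, per tick,
the app-style fields (channel on/off, start/end angles implicit in the
config header, frequency, width, amplitude, reference and measured cadence,
crank angle) plus epsilon, episode index, action index, per-tick reward,
PI output, and synthetic-only diagnostics (true cadence, fitness, crank
power). The header is a single JSON line with the fully resolved config.

Metrics are computed from logs, never from privileged simulator state:
trailing moving averages use the partial prefix for the first samples (so
curves start at t = 0); the stimulation cost sums `amplitude × width ×
frequency` over channels gated by their on-flags, with optional window-100
smoothing for presentation; accumulated reward/|error| are running sums at
10 Hz. Because per-tick rewards are non-negative, the cumulative reward
curve cannot decrease; a *windowed rate* variant is provided alongside it,
since that is the natural quantity to watch fall once amplitude saturation
breaks tracking. Injected charge counts the leading phase of the symmetric
biphasic pulse only (the second phase is charge-balancing); a `both_phases`
switch doubles it. Time-to-saturation is the first instant any channel's
effective amplitude holds the 100 mA ceiling for a sustained interval
(5 s default).

## Degenerate inputs and numerical choices

Window boundaries are closed at both ends and windows may wrap through
0°/360°; equal endpoints (or 0–360) denote the full circle. The admissible
action set is never empty because the identity action always passes both
rules. Non-finite plant states raise immediately with a diagnostic rather
than propagating NaNs. Floating-point admissibility comparisons use a 1e−9
slack so exact boundary parameters (e.g. width exactly 600 µs) behave as
specified. Epsilon decay is applied by repeated multiplication, so logged
epsilon follows the exact recurrence `ε_{k+1} = ε_k · dr`.

## Known limitations

* The plant's power numbers are proxies; only orderings and timings
  (saturation delays, relative charge between gears) are meaningful.
* The agent's within-episode learning is deliberately shallow (nine
  selections per episode, estimates reset at the boundary); it adapts on
  the timescale of episodes, not interactions.
* The PI acts on the quantized measured cadence; at very low encoder
  resolutions the quantization noise visibly enters the amplitude command.
* Frequency and stimulation-window actions are supported by the action
  enumeration (3ⁿ deltas) but are not wired into the default agent, whose
  action set covers amplitude and width only.
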