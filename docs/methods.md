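# Methods

## Model and assumptions

`riskperc` implements a discrete-time, deterministic model of an
individual's risk-perception level `y_t` driven by a per-period information
schedule `(N_t, S_t)`. The modelling assumptions are:

- The individual is a *complete information audience*: every released item
  is received. `N_t > 0` items arrive in period `t`, evenly spaced, each
  carrying the same stimulus `S_t` (stimulus differs across periods, not
  within one).
- **Recency (forgetting):** perception decays multiplicatively by the
  memory rate `ρ` per period — the discrete counterpart of the exponential
  forgetting curve `M(t) = e^(−ρt)`. Within a period, consecutive items are
  separated by `1/N_t` of a period, hence the `ρ^(1/N_t)` factors.
- **Association:** each new item re-awakens a fraction `k` of the
  perception formed from past information, decayed per elapsed period. The
  association sum `A_t = Σ_{i=1..t} g(k,N_i)·k^(t−i)` includes the current
  period `i = t`; the first period has no association term.
- The retelling effect (memory reinforcement through repetition) is *not*
  parameterised; nor is any behavioural feedback of perception onto
  information demand.

The recursion is linear in the stimulus sequence, contains no randomness,
and permits negative `y_t` under strongly declining stimuli; such values
are logged as warnings but never clamped, because the model itself places
no floor (a declining-stimulus regime driving perception below zero is a
recognised artefact of the linearity assumption, not an error).

Equality `ρ = k` is a removable singularity of the kernel denominators.
Profiles with `|ρ − k| < 1e-6` are rejected (`EPSILON_PK`) rather than
handled by a limit formula: no study configuration approaches it, and the
analytic limit would add unexercised complexity. Both orderings `ρ > k`
and `ρ < k` are valid.

## Parameters

| parameter | meaning | units | domain | study defaults |
|---|---|---|---|---|
| `ρ` | memory rate: fraction of perception retained per period | — | (0,1) | grids: 0.4–0.6 (five-combo), {0.5, 0.8} (case study) |
| `k` | association rate: fraction of past perception re-awakened | — | (0,1) | 0.2–0.4 |
| `N_t` | information items received in period `t` | items/period | > 0, real | 10 (baseline), 40 (stimulus studies) |
| `S_t` | perception stimulus of one item | perception units | real | 2 (count studies) |
| `T` | horizon | periods | ≥ 1 | 20 (synthetic), 32 (`T1`), 60 (`T2`) |

Perception units are arbitrary; outputs are raw model values.

## Schedule generators and fixtures

The generators reproduce the canonical release regimes: constant; linear
counts `N_t = a·t + b` (defaults a=5, b=5 rising; a=−5, b=105 falling);
Gaussian counts `N_t = C·exp(−(t−μ)²/2σ²)/(σ√2π)` (defaults C=1000, μ=10,
σ=5); sinusoidal counts `N_t = A·sin(πt/5) + offset` (defaults A=30,
offset=50, period 10); linear and Gaussian stimuli with the count held at
40. Positivity of every `N_t` is validated at construction, naming the
first offending period. Generated counts are real-valued by default; an
optional `rounding="nearest"` reproduces integer-count variants, since
whether the original study rounded is not determinable from the published
material — the packaged default follows the reference listing, which uses
the values unrounded.

The COVID-19 case-study schedules `T1` (32 four-day cycles) and `T2` (60
eight-day cycles) are verbatim transcriptions stored as decimal strings so
they remain auditable; calendar date ranges are carried as period labels
only. One internal inconsistency in the source material is preserved
rather than repaired: the prose analysis of the short-period study places
the stimulus peak at cycle 12, while the transcribed table's maximum
stimulus (5) sits at cycle 11; the fixture follows the table. Likewise the
five-combo grid discussion refers once to an association rate of 0.5 that
the grid does not contain; reports treat it as the grid's 0.3.

These schedules are stylised emulations — smooth functional forms and a
hand-assigned outbreak timeline — not measured media-exposure data. Tests
passing on them show that the recursion, its closed-form steady state, and
the peak/lag machinery are implemented correctly and reproduce the study's
qualitative findings; they do not validate the model against real
perception measurements (the search-frequency comparison in the original
study used undeposited data and is out of scope).

## Analysis conventions

- Periods are 1-based everywhere; peak reporting uses 1-based indices.
- `peak_period` is the global argmax with ties broken toward the earliest
  period. `perception_lag` is `peak_period(y) − peak_period(N)`; for a
  constant schedule the count peak degenerates to period 1 and the lag is
  reported but not meaningful.
- For oscillating schedules the global argmax is ill-posed, so the lag
  property is assessed on *local* maxima: strict interior maxima, with a
  plateau resolving to its first index.
- `shape_diagnostics` classifies a trajectory from its first-difference
  sign pattern (differences below `1e-9·max|y|` count as flat):
  no falls → `monotone-increasing-saturating` (the reverse-L);
  one rise→fall change → `rise-then-fall`; two or more changes →
  `oscillating`; anything else → `other`. For constant schedules the
  report adds the relative distance of `y_T` to the closed-form limit.
- Sweeps preserve grid order and annotate failures with the combo label.
  Steady states are reported only for constant schedules. The sweep
  summary also reports each combo's lag and final value; the claim that
  association-rate changes outweigh memory-rate changes is thereby
  computable but is not asserted as an invariant, because the relevant
  orderings (e.g. (0.5,0.4) vs (0.6,0.3)) are numerically close and
  direction-sensitive in both transient and asymptotic regimes.

## Numerical choices

- The recursion is evaluated in IEEE double precision in the literal
  operation order of the reference implementation (association sum
  accumulated `i = 1 → t`), so arbitrary-precision transcriptions agree
  term by term and runs are bit-reproducible.
- The test suite checks the implementation against an independent 60-digit
  `mpmath` transcription of the recursion (relative tolerance 1e-10 across
  random valid problems) and against closed forms: `F(ρ,k,1) = 1`, the
  geometric association limit `g/(1−k)`, and the steady state `y*`.
- Convergence under constant input is geometric at rate `max(ρ,k)`: the
  steady-state error follows `e_t = ρ·e_{t−1} + β·k^t` with
  `β = s·(ρ−k)·g(k,n)/(u−v)`, which the tests verify in closed form. The
  geometric *prefactor* is combo-dependent (≈1.45–2.55 on the five-combo
  grid), so no universal constant multiplies `max(ρ,k)^T`.
- CSV output serialises floats with `repr` (shortest round-trip), so
  re-parsing written artifacts reproduces values bit-for-bit and repeated
  runs of one configuration are byte-identical.

## Known limitations

- Single representative individual; no population heterogeneity beyond the
  `(ρ, k)` grids, no interaction between individuals.
- No fitting of `(ρ, k)` to observed data and no statistical inference —
  the package is a forward simulator.
- The linear-in-stimulus assumption makes perception unbounded in `S` and
  allows negative values under declining stimuli.
- Calendar dates in the fixtures are labels only; no date arithmetic.
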