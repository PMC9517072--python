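# riskperc

Deterministic simulation of how an individual's **risk perception** of an
epidemic evolves as they receive a stream of risk information, under a
limited-memory model of cognition. The intended users are researchers in
risk communication and public-health emergency management who want to
explore how the *shape* of an information-release schedule (a ramp, a wave,
a real outbreak timeline) interacts with individual memory characteristics
to produce perception peaks and lags.

## The model

The state variable is the perception level `y_t` (arbitrary units) after
period `t`. In period `t` the individual receives `N_t` information items,
each with stimulus `S_t`, evenly spaced within the period. Two parameters
describe the individual:

- **memory rate** `ρ ∈ (0,1)` — fraction of the previous period's
  perception retained one period later (discrete analogue of the Ebbinghaus
  exponential forgetting curve);
- **association rate** `k ∈ (0,1)` — fraction of past perception
  re-awakened by newly received information.

With `u_t = ρ^(1/N_t)`, `v_t = k^(1/N_t)` the recursion is

```
y_1 = S_1 · F(ρ, k, N_1)
y_t = ρ·y_{t−1} + S_t · [ (ρ−k)/(u_t−v_t) · (1−k) · Σ_{i=1}^{t} g(k,N_i)·k^(t−i)  +  F(ρ, k, N_t) ]
```

where `g(k,n) = k^(1/n)/(1−k^(1/n))` and the stimulus kernel is

```
F(ρ,k,n) = u·ρ/((u−v)(u−1)) − v·k/((u−v)(v−1)) + 1/((u−1)(v−1)),
```

with `F(ρ,k,1) = 1` identically. Under constant `N, S` the trajectory rises
strictly toward the closed-form limit
`y* = s·((ρ−k)·g(k,n)/(u−v) + F(ρ,k,n)) / (1−ρ)` (the "reverse-L" shape).
The model is linear in the stimulus sequence and contains no randomness.

The package ships generators for the standard release regimes (constant,
linear, Gaussian, sinusoidal counts; linear and Gaussian stimuli), a
transcribed COVID-19 case-study schedule in two resolutions (`T1`: 32
four-day cycles from late December 2019; `T2`: 60 eight-day cycles), the
two memory-parameter study grids, and analysis helpers for peak detection,
perception-vs-information lag, parameter sweeps and trajectory-shape
classification.

## Worked example

Sweep the four case-study memory profiles over the 32-cycle COVID schedule:

```sh
$ riskperc scenario --fixture T1 --grid table12 --out out --stem case
csv: out/case_T1_trajectories.csv
json: out/case_T1_summary.json
```

The summary JSON reports, per combo, the peak cycle and its lag behind the
information-count peak (cycle 14):

```
[('1', 16, 2), ('2', 14, 0), ('3', 16, 2), ('4', 14, 0)]   # (label, peak_period, lag_vs_N_peak)
```

Combos 1 and 3 (`ρ = 0.8`) peak at cycle 16, two cycles after the
information wave; combos 2 and 4 (`ρ = 0.5`) peak with it at cycle 14: a
higher memory rate both delays and (in the full summary) raises the
perception peak. The same library call is
`parameter_sweep(memory_grid("table12"), covid_fixture("T1"))`.

A single profile on the constant baseline:

```sh
$ riskperc simulate --rho 0.5 --k 0.3 --scenario constant --N 10 --S 2 --T 20 --out out
```

writes a 20-row trajectory rising from `y_1 = 64.3608` toward the
steady-state limit `263.2898` (peak at period 20, since the trajectory is
monotone).

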