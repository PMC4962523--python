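# actinet

Executable-biology modelling of cellular signalling networks: nodes with
discrete activity levels, interactions with a single rate constant each,
and timed nondeterministic firing windows — a modelling layer between
fuzzy logic and full ODE kinetics, aimed at biologists who think in
network diagrams rather than rate equations.

A network is a set of species, each carrying an *activity level*
ℓ ∈ {0, …, L} (the fraction of its pool in active form, discretised at a
user-chosen granularity L, reported on a 0–100 scale), and a set of
signed interactions.  An interaction with rate law r — one of
r = k·a (source-only), r = k·a·(1−y) / k·a·y (source × available
substrate, for activation/inhibition), or r = k·a₁·a₂ (two-source AND
gate) — advances its target one level per firing, with each firing
constrained to the time window

    [Δt·(1−u), Δt·(1+u)],   Δt = (1/L)/r,

the guard and invariant of the interaction viewed as a one-clock timed
automaton.  Effects are additive (an OR is two parallel edges), the
total pool per species is constant, and as L grows the center-mode
semantics converges to the ODE dy/dt = Σ±r.  On top of the simulator the
package provides exhaustive bounded reachability checking over the
tick-quantised state space (with replayable witness traces and dose
search), in-silico experiment protocols (knock-outs, state-copy
continuation, light/dark phase-shift, parameter sweeps against reference
time courses), and two case-study models built entirely in code: the
*Drosophila* circadian clock entrained by a repressilator day/night
driver, and the TNFα/EGF signalling network of HT-29 colon carcinoma
cells in its staged construction variants.

## Worked example

```python
from actinet.engine import simulate
from actinet.experiments import detect_oscillation, knockout
from actinet.fixtures import build_circadian, build_tnf_egf, with_stimulus

net = build_circadian()                       # 24 h light/dark driver
series = simulate(net, 5 * 24, mode="uniform", seed=1)
period, amplitude = detect_oscillation(series, "TIM")
print(f"TIM period  : {period:.2f} h")
print(f"TIM amplitude: {amplitude:.1f} activity units")

ko = simulate(knockout(net, ["CLK"]), 5 * 24, mode="uniform", seed=1)
print("after CLK knock-out:", detect_oscillation(ko, "TIM"))

hyp1 = with_stimulus(build_tnf_egf("hyp1"), {"TGFa": 1.0})
day = simulate(hyp1, 24 * 60, mode="center")
print("hyp1, TGFa only, max IL-1a:", day.activity("IL-1a").max())
```

prints

```
TIM period  : 23.67 h
TIM amplitude: 39.0 activity units
after CLK knock-out: None
hyp1, TGFa only, max IL-1a: 0.0
```

The clock locks to the 24-hour day (period within 2 % here); knocking
out CLK removes the oscillation entirely (`None` = fewer than two peaks
survive), reproducing the knock-out experiment; and in the
first-hypothesis signalling model — IL-1α expression AND-gated on the
JNK1 and ERK branches via c-Jun/c-Fos/AP-1 — a TGFα-only stimulus can
never induce IL-1α, because the JNK1 branch is structurally silent.

The same operations are available from a shell:

```
actinet fixture mek_erk -o toy.json
actinet simulate toy.json -d 2000 -m lo -o out.csv     # steps every 18 tu
actinet check toy.json "ERK >= 100 within 2000"        # witness trace
actinet fixture circadian -o clock.json
actinet resync clock.json --advance 12 --post-days 10 -o resync.csv
```

Networks live in a small JSON schema (see `actinet.io`), topology
skeletons can be imported from Cytoscape SIF files, and all time courses
use one CSV dialect, so a file written by `simulate` feeds directly into
`sweep` as reference data.

## Layout

| path | contents |
|---|---|
| `src/actinet/netmodel.py` | domain types, network construction/validation, qualitative rate scale |
| `src/actinet/kinetics.py` | rate laws, firing windows, deterministic drift |
| `src/actinet/engine.py` | discrete-event simulator, time series, state-copy continuation |
| `src/actinet/checker.py` | bounded reachability, witness traces, dose search |
| `src/actinet/experiments.py` | knock-outs, phase-shift protocol, sweeps, oscillation metrics |
| `src/actinet/fixtures/` | programmatic model builders (no data files) |
| `src/actinet/io.py`, `cli.py` | network JSON, SIF import, CSV dialect, command line |
| `docs/methods.md` | the model, its semantics, tuning rationale, limitations |
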