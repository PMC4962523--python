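# Methods

## The model class

`actinet` simulates signalling networks in which each molecular species
(node) carries a single dynamical variable: the fraction of its pool in
the active form, discretised to an integer *activity level*
ℓ ∈ {0, …, L}.  The granularity L is chosen per node (default L = 100,
so one level is one percent and trajectories are reported on a 0–100
scale).  The total pool per species is constant; production and
degradation of a species are represented as activation/inhibition of its
node, which is also how mRNA and protein concentrations are abstracted
in the circadian model.

Interactions carry a sign (activation/inhibition), a rate constant k
(fractions of the full activity range per time unit), an uncertainty
u ∈ [0, 1), and one of three rate-law shapes:

| scenario | rate | use |
|---|---|---|
| S1 | r = k·a | source-driven step, substrate never limiting |
| S2 (activation) | r = k·a·(1−y) | enzyme × free substrate |
| S2 (inhibition) | r = k·a·y | enzyme × convertible (active) substrate |
| AND | r = k·a₁·a₂ | two-source product gate |

a, a₁, a₂ are source activity fractions, y the target's.  Reaction
effects are additive: an OR gate is simply two parallel edges, and the
net deterministic drift of a node is the signed sum of its incoming
rates — the right-hand side of the piecewise-smooth ODE the discrete
system approximates.  Disabled (knocked-out) nodes contribute zero
activity everywhere, never receive firings, and keep their stored level.

## Timed firing semantics

An interaction with rate r steps its target by one level after an
expected wait Δt = (1/L)/r, so a full 0→L traversal at constant rate
takes 1/r independent of L.  The wait is nondeterministic within the
window [Δt(1−u), Δt(1+u)] — the guard and location-invariant of the
interaction viewed as a one-clock timed automaton.  The engine resolves
the nondeterminism with one of four schedulers: `center` (midpoint,
deterministic; the ODE-approximation semantics), `uniform` (seeded
uniform draw; the default), and `lo`/`hi` (extremal).  Events are kept
in a priority queue; ties are broken by interaction id so runs are
reproducible bit-for-bit for a fixed (network, duration, mode, seed,
sample_step).

When a firing changes a level, every pending interaction whose rate
inputs changed has its remaining wait rescaled by Δt_new/Δt_old,
preserving its elapsed progress fraction.  A full restart instead of a
rescale would systematically inflate waits under fluctuating rates and
break the ODE limit.  Firings that are clamped at a level bound still
consume their event and reschedule, keeping the schedule live for when
an opposing influence releases the clamp.  With L = 100, u = 0 and the
center scheduler, a single S2 activation matches 1−e^(−k·a·t) to within
~0.01 sup-norm; the test suite checks ≤ 0.05 against an independent
numerical integration of the drift.

Default sampling grid: duration/240 (a 24 h run sampled every 6 min).

## Reachability checking

Quantising firing times to a tick grid makes the behaviour set finite:
each pending interaction holds an integer countdown chosen anywhere in
its window, and the checker explores *all* such choices with a
Dijkstra-style search on elapsed time, memoised on (levels, countdowns)
and bounded by a state budget (exceeding it raises, never silently
truncates).  Queries are bounded reachability — "NODE ⋛ LEVEL within
TIME" — and positive answers return a minimal-time witness trace that
replays exactly through the engine's firing rule.  The default tick is a
quarter of the smallest guard among enabled interactions.  Firings
strictly between grid points are not represented, so the check
under-approximates the continuous semantics between ticks; witnesses are
exact, non-reachability is relative to the quantisation.  A dose-search
wrapper enumerates stimulus-dose combinations (doses enter as initial
activity fractions) and reports every satisfying combination.

## Experiment protocols and metrics

* **Knock-out** disables nodes (see above).
* **State-copy continuation** sets each enabled node's initial level
  from a sampled trajectory point; disabled nodes keep their stored
  level.  Because every automaton's clock is reset at the copy point,
  splicing is exact only when the copy time coincides with firing
  instants (the test suite uses such a point).
* **Phase-shift protocol**: simulate one day; copy at a CRY minimum
  ("night"); disable all but CRY's ancestor subnetwork (the light
  driver); run it alone for the phase advance; copy; re-enable; run the
  post-period.  Times are in hours, the circadian model's unit.
* **Fit score**: mean squared error between reference points and the
  simulation linearly interpolated at the reference times, averaged over
  points × shared columns.  The paper-style workflow ("manual fitting")
  needs only a ranking, so MSE is the minimal defensible choice; it is a
  plain function and can be swapped.
* **Parameter sweep**: exhaustive product grid over interaction ids,
  center-mode simulation per point, ranked ascending by fit score.
* **Oscillation detection**: discard the leading transient (default
  20 %), find local maxima with prominence ≥ 10 activity units, then
  merge consecutive peaks whose connecting trough is shallower than the
  prominence threshold below the lower of the two.  The merge step
  matters at finite L: a plateau top that wobbles by one level produces
  equal-height twin maxima to which plain prominence assigns full
  weight, halving the apparent period.  Period = mean peak-to-peak
  interval; amplitude = mean peak-to-following-trough drop; fewer than
  two peaks ⇒ no oscillation.
* **Phase difference**: per cycle of node a, the signed offset to the
  nearest peak of node b, wrapped into [−period/2, period/2].
* **Data normalisation**: per-column scaling to max = 100 (for
  semi-quantitative data where only relative levels are meaningful) and
  the 100−x complement for precursor-vs-product series.

## The bundled models

**MEK→ERK toy.**  One S1 edge with k = 1/(19·L) and u = 1/19, so each
level step has the window 18 < t < 20 regardless of granularity: the
minimal clocked-step example, and the fixture for checker/engine
cross-validation at small L.

**Circadian clock (time unit: hours, L = 100).**  The day/night input is
a three-node repressilator tuned to the requested day length; its ring
inhibitions use the AND scenario with a duplicated source (cooperative,
rate ∝ activity²).  This cooperativity is necessary, not cosmetic: a
ring of bilinear saturating stages has sub-unity log-gain per stage and
settles to its fixed point, while the squared repression is unstable at
the symmetric fixed point whenever repression outweighs production.
LIGHT drives CRY, whose only output is light-gated degradation of TIM.

The core loop is a relaxation oscillator: BASAL→CLK production,
CLK+CYC → CLK/CYC complex (AND), CLK/CYC transcribes per/tim/cwo, the
proteins are translated from their mRNAs, CWO represses the mRNAs, PER
represses CLK (sequestration of the free pool, cooperative), DBT drives
PER turnover, and TIM shields PER by suppressing DBT.  Every node has a
negative self-loop so levels decay when inputs vanish.  Two tuning facts
shape the rate constants: (i) the free-running period is set to ≈ 27 h,
*above* the 24 h day, because CRY's action on TIM is purely degradative
— it can only advance the clock, so locking requires a clock that runs
slow; with a fast-running clock the system slips instead of entraining.
(ii) CRY's readout kinetics (cry_on/cry_deg) are slowed so CRY's peak
coincides with the locked CLK peak, making the steady CRY–CLK offset
≈ 1 h.  Entrained, TIM oscillates at 24 ± 1 h; knocking out CLK or CYC
silences transcription and all downstream nodes decay to a fixed point,
and knocking out DBT lets PER saturate and clamp CLK down — in both
cases the TIM rhythm collapses.  Doubling all rate constants downstream
of CLK/CYC roughly halves the free period, leaves the entrainment
window, and visibly changes the detected period.  After a 12 h phase
advance of the driver the clock re-locks with the CRY–CLK offset inside
15 % of the period within ~3–4 days (median over seeds).

**TNFα/EGF signalling in HT-29 cells (time unit: minutes, L = 100).**
Built in the staged variants described in `fixtures/tnf_egf.py`, from
the three-node direct-activation sketch to the final two-hypothesis
network.  Transient kinase peaks require both mechanisms jointly:
constitutive phosphatases *and* a delayed receptor-internalisation
feedback strong enough to pull TNFR down against a persistent ligand.
Stimulus doses map linearly onto initial activity fractions
(min(1, dose/reference), reference 100 ng/ml), so 5 ng/ml TNFα is
initial activity 5.  The EGFR-blocking antibody C225 is an ordinary
always-active node with a single strong inhibition edge onto EGFR; its
rate constant is chosen ≫ the TGFα→EGFR activation constant so the
blocked receptor's time-averaged activity is too small for Ras to
accumulate one level step within the two-hour observation window.  The
two structural claims are then mode-independent: with IL-1α expression
AND-gated through c-Jun/c-Fos/AP-1, a TGFα-only stimulus leaves IL-1α
at zero (the JNK1 branch is never activated), and with MEKK1 AND-gated
on the TNF branch and Ras, TNFα + C225 leaves JNK1 at zero.

## Synthetic references and what tests show

`synthetic_reference` simulates a network at known rate constants
(center mode), samples at chosen times, and adds seeded Gaussian noise
clipped to [0, 100].  It emulates a nondimensionalised, per-protein
max-normalised time course with homoscedastic measurement noise — the
form of semi-quantitative western-blot data after normalisation.  It
does not emulate systematic biases, heteroscedastic or multiplicative
error, missing observations, or model misspecification; parameter
recovery under it demonstrates that the sweep machinery is correct and
informative, not that the models are identifiable from real data.

## Numerical choices and limitations

* Event ties are broken by interaction id (lexicographic); determinism
  over physical plausibility, as nothing observable depends on the order
  of simultaneous unit steps.
* Sample-grid semantics: a sample at time t reflects all events with
  firing time ≤ t.
* `continue_from` rounds the 0–100 activity back to integer levels;
  exact because the grid stores level/L·100.
* The checker's rescaling rounds countdowns to whole ticks (minimum 0),
  which can drift from the engine's real-valued rescale by up to one
  tick per rate change.
* Problem sizes used throughout the suite: 5-day circadian runs
  (~10⁵ events), 10-day resynchronisation runs over 5 seeds, 20-point
  sweeps on a 2-node model, and reachability at L ≤ 4.  These are desk
  scales chosen so the whole battery runs in seconds while every claim
  is still exercised end-to-end.
* Known limitations: no compartments, molecule counts, stoichiometry or
  reversible mass-action kinetics; no Michaelis–Menten/Hill or arbitrary
  user rate expressions; the checker covers bounded reachability only
  (no liveness/fairness, no temporal-logic language).
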