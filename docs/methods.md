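# Methods

`kaisim` models the cyanobacterial KaiABC post-translational oscillator at two
scales: sub-second single-molecule KaiA–KaiC binding, and the hour-scale
population dynamics of KaiC phosphorylation.  The link between the scales is
phosphoform-dependent differential affinity (PDDA): KaiA's affinity for a KaiC
hexamer weakens as the hexamer's protomers accumulate phosphates, so the
phospho-state feeds back onto the fast binding events that drive further
phosphorylation.

## 1. Phosphoforms and binding kinetics (`kinetics`)

Each KaiC protomer carries two phosphosites (S431, T432) and traverses the
ordered cycle S/T → S/pT → pS/pT → pS/T → S/T.  The default lifetime table
uses the single-molecule values measured on phosphomimic mutants:

| form  | mimic | τ_bound (s) | τ_unbound (s) |
|-------|-------|-------------|----------------|
| S/T   | AA    | 3.0 (placeholder) | 5.47 |
| S/pT  | AE    | 1.00 ± 0.15 | 6.685 (interpolated) |
| pS/pT | DE    | 0.26 ± 0.05 | 7.90 |
| pS/T  | DA    | 0.43 ± 0.14 | 6.685 (interpolated) |

The S/T bound lifetime was too slow to determine experimentally; 3.0 s is a
conservative lower-bound placeholder exposed as `tau_bound_aa`.  Per-form
unbound lifetimes are interpolated linearly in the number of phosphorylated
sites per protomer (0, 1, 2) between the native-KaiC endpoints measured on
hypo- (27 %, 5.47 s) and hyper-phosphorylated (81 %, 7.90 s) preparations —
the simplest monotone rule consistent with those two aggregates.

Rates follow from first-order kinetics: k_off = 1/τ_bound,
k_on = 1/(τ_unbound·[A₂]), K_d = k_off/k_on, with [A₂] = 0.4 µM (the KaiA
dimer concentration of the native-KaiC measurements).  A hexamer's affinity is
the composition-weighted arithmetic mean of per-form k_off and k_on
(weights n_f/6); rates, not energies, add for independent tentacle contacts.
A geometric-mean mixing rule is selectable.  With PDDA disabled every
composition receives the plain four-form average, which preserves the mean
affinity so that ±PDDA comparisons isolate the differential effect.

## 2. Dwell-time analysis (`dwell`)

Binary traces are run-length encoded; runs touching either trace boundary are
censored and excluded (matching the simple first-order histogram fits used on
the experimental movies; a censoring-aware estimator was judged unnecessary at
the event counts involved).  Two estimators are provided: MLE (τ = sample
mean, SE = τ/√n) and least-squares histogram fitting of A·e^(−t/τ) with SE
from the fit covariance; on well-sampled exponential data they agree within
combined errors.

**Detection-limit correction.**  Events shorter than the detection limit L
(default one frame) are invisible.  This biases observed dwells in two ways:
a surviving dwell's leading sojourn is conditioned on being ≥ L (mean L + τ by
memorylessness), and every sub-limit blip of the opposite state splices an
extra full sojourn onto the observed dwell.  To first order in the blip
probabilities p = 1 − e^(−L/τ),

    m_b = L + τ_b + q_u·(E[U | U < L] + τ_b),    q_u = p_u/(1 − p_u),

and symmetrically for m_u.  `fit_dwell_pair` inverts this pair by fixed-point
iteration; at 10 frames/s and the measured lifetimes the residual bias is
about one standard error at n ≈ 1000 events.  Frame quantization itself is
mean-unbiased under midpoint sampling and needs no correction; the geometric
correction τ = −Δt/ln(1 − Δt/mean) is available for edge-sampled data.

## 3. Synthetic traces (`tracegen`)

The generator emulates frame-sampled single-molecule movies as a two-state
alternating-renewal (telegraph) process: exponential sojourns, stationary
initial state, midpoint frame sampling (default 10 frames/s, as in the
lifetime-quantification movies), and detection-limit merging applied to the
continuous path before sampling — sub-frame blips are absorbed into the
surrounding state, emulating eye-based event calling.  Phase-dependent
mixtures assign each molecule of a lawn one phosphoform for the whole (short)
assay.  What the generator does **not** emulate: drift and intensity noise of
real movies, molecule-to-molecule heterogeneity beyond the phosphoform, and
phospho-turnover during an assay.  Passing the recovery tests therefore
demonstrates correctness of the extraction/fitting pipeline under the stated
stochastic model, not robustness to instrument artifacts.

## 4. Stochastic population model (`population`)

State: counts of hexamers over all 84 protomer compositions, split into an
ACTIVE pool and a SEQUESTERING pool (KaiB-bound complexes holding KaiA), plus
free KaiA, sequestered KaiA and free KaiB concentrations.  Concentrations
mirror the standard in vitro reaction: 3.43 µM KaiC monomer (0.58 µM hexamer),
4.27 µM KaiB monomer, KaiA set by the dimer:hexamer ratio (standard 1.33).

Each step of length dt (default 0.01 h):

1. **KaiA partitioning.**  Binding equilibrates within seconds, far below
   hour-scale phospho-kinetics, so the KaiA-bound fraction of each hexamer
   state comes from a pseudo-steady-state 1:1 model A₂+C₆ ⇌ A₂C₆ with
   state-dependent K_d.  The conservation equation is solved by bisection to
   10⁻⁹ relative; which hexamers are bound is then resampled binomially.
2. **Phosphoform transitions** as binomial tau-leaps over aggregated protomer
   counts: KaiA-bound protomers advance S/T→S/pT→pS/pT and run the
   pS/T→pS/pT back reaction; unbound and sequestering protomers run
   pS/pT→pS/T→S/T (and S/pT→S/T).  Double transitions of one hexamer within
   a step are neglected (probability < 10⁻⁴ at the default dt).
3. **KaiB switching, sequestration, release.**  KaiA-unbound ACTIVE hexamers
   whose composition passes the switch rule convert to SEQUESTERING at
   `kb_switch`, consuming six KaiB monomers each.  Standing complexes absorb
   free KaiA continuously up to g dimers per complex (binding is fast on the
   hour scale), so free KaiA is titrated to zero whenever total capacity
   exceeds the pool.  Complexes reaching all-S/T release their KaiA and KaiB
   and rejoin the active pool.

**Why this oscillates.**  The limit cycle is a relaxation oscillation built on
two nonlinearities: titration (free KaiA collapses when sequestration capacity
crosses the total) and an avalanche in the switch flux.  While KaiA is
abundant, the bound-state back reaction pS/T→pS/pT holds the population just
short of the KaiB-binding state; as the first complexes form and capacity
eats into free KaiA, the back reaction weakens, pS/T accumulates faster, more
complexes form — a positive feedback that sequesters most of the population
within a few hours.  Free KaiA then stays at zero until enough complexes have
completed dephosphorylation, which resynchronizes the population every cycle.
PDDA strengthens the fast (hypo-affine) start of the phosphorylation
half-cycle and weakens KaiA's hold on hyper-phosphorylated hexamers, which is
why +PDDA tolerates both lower and higher KaiA:KaiC ratios than −PDDA and
keeps the period near 22 h where −PDDA's period inflates.

**Switch rule.**  The default is `pST_only` with a threshold of 2 of 6
protomers in pS/T: the KaiB-binding state is gated by the S431-phosphorylated,
T432-dephosphorylated form, whose formation is KaiA-independent — this is
what lets sequestration continue through the KaiA-free phase and is, in this
architecture, required for a sustained population rhythm.  The
`pST_and_pSpT` rule (both hyper forms bind KaiB) is selectable; under it the
eligible pool grows while KaiA is still abundant, the switch flux turns into a
smooth conveyor, and the population relaxes to a desynchronized steady state
for every parameter combination we examined.

**Calibration.**  The hour-scale rate constants are not derivable from the
single-molecule data and were calibrated once to the in vitro regime:

| parameter | value | rationale |
|-----------|-------|-----------|
| kdephos | 0.22 h⁻¹ | two per-protomer dephospho steps ≈ 9 h ⇒ KaiA-free dephosphorylation of fully phosphorylated KaiC over ≈ 10 h |
| kphos | 0.9 h⁻¹ | realized phosphorylation half-cycle ≈ 12 h under standard +PDDA conditions |
| kb_switch | 2.0 h⁻¹ | prompt switching of eligible hexamers |
| seq_capacity g | 4.2 dimers/complex | places the upper edge of the common ±PDDA oscillatory band near ratio 2.6 |
| kd_scale | 0.055 | uniform scaling of all dissociation constants: preserves the measured ~10× relative PDDA span while calibrating the absolute effective bulk affinity (surface-measured K_d on mica need not equal the effective affinity in the bulk reaction) |
| dt | 0.01 h | per-event probabilities ≤ 0.02 per step |

With these defaults (5000 hexamers): +PDDA rhythmic over ratios ≈ 0.2–3.2,
−PDDA over ≈ 0.3–2.7, period at ratio 1.33 of 22.7 h (+PDDA) vs 24.7 h
(−PDDA), with the −PDDA period inflating toward 40 h near its upper edge.

The production path is a numba-compiled kernel; the same update rules exist
as plain numpy functions (`phospho_step`, `sequestration_step`) for unit
testing and custom initial states.  Hexamer count is conserved exactly; KaiA
and KaiB pools to 10⁻⁹ relative (checked every step; violation aborts).  If a
fluctuation protocol removes KaiA below the sequestered amount, the free pool
is emptied first and the remainder comes out of the sequestered pool.

## 5. Rhythmicity and resilience readouts (`metrics`)

`estimate_period` smooths %P with a 2-h moving average, detects peaks with
prominence ≥ 10 %P after a 30-h burn-in (parabolic sub-sample refinement),
and reports the mean successive-peak interval.  A record is *rhythmic* iff it
has ≥ 3 such peaks and a ≥ 10 %P peak-to-trough excursion in its second half;
arrhythmic records report period 0.  These thresholds are package choices
(exposed in the configuration); peak-interval averaging was preferred over
FFT/autocorrelation for short, noisy, non-sinusoidal records.

The stoichiometry scan classifies each (ratio, PDDA setting) by majority over
seeds (default 5) because boundary ratios flicker.  The step driver reports
post-step rhythmicity in a window starting 10 h after the step; the pre-step
window of the standard protocol (27 h) is too short for the 3-peak rule, so
the no-step control period is reported alongside instead.  The fluctuation
driver resamples total KaiA from a uniform band every 6 h.

## 6. Differential-affinity ladder model (`vanzon`)

A deterministic skeleton of the allosteric differential-affinity oscillator:
hexamers occupy phosphorylation levels 0..6 on a phosphorylating front branch
(KaiA-driven, K_d = kd0·α^level) and a KaiA-independent dephosphorylating
back branch, with flips at the extremes.  The total off-rate span of the
ladder is α⁶ (729 at α = 3).  Fixed-step RK4 (dt 0.01 h) integrates the
occupancies; KaiC mass is conserved to 10⁻⁹ and enforced.

The mean-field limit cycle requires KaiA to be strongly sub-stoichiometric
(defaults: A₂ = 0.1 µM against 0.58 µM hexamer, kd0 = 2·10⁻⁴ µM): laggards at
low levels out-compete leaders for KaiA, so the population crosses the
weak-affinity top of the ladder as a coherent pulse.  With the default rates
the permissive window is α ∈ [2, 4] (contiguous), period 24.0 h at α = 3.
At α = 1 the population settles at a level-mixed steady state (no
synchronization); at large α it stalls arrhythmically at the level where the
ladder outruns the available KaiA — in this skeleton that stall sits at
partial phosphorylation (~70 %P) rather than near zero, because lower levels
always retain enough affinity to hold their ground.

## 7. AFM image simulation (`afm`)

Surfaces are hard-sphere height maps: h(x,y) = max over atoms of
z + √(r² − d²) above a flat substrate at 0.  Structures are read from PDB
files (Å→nm; element van der Waals radii, default 0.17 nm; optional
per-residue coarse spheres of 0.33 nm; chain and residue-range filters
support tentacle truncation).  The probe is a sphere-capped cone (apex radius
0.5 nm, cone angle 10°, interpreted as the half-angle — the full-angle
reading is a flag) whose spherical apex continues tangentially into the cone
at lateral distance R·cosθ.  The image is the grayscale dilation
image(x) = max_u [surface(u) − tip(x−u)], computed with a tip footprint
truncated where the tip profile exceeds the surface relief (provably exact)
and substrate padding at the borders.  No tip–sample deformation, feedback
artifacts, or scan-line effects are modeled.

## 8. Numerical and degenerate-input conventions

* Bisection everywhere for the KaiA conservation equation (60–80 iterations;
  monotone, bracketing, no derivatives).
* Tau-leap probabilities are validated: any per-event probability ≥ 0.5
  aborts with "dt too large"; defaults keep them ≤ 0.02.
* All-one-state traces yield empty dwell sets plus censoring counts; fits on
  fewer than 2 (MLE) or 10 (histogram) events raise an "insufficient events"
  error that the time-course driver converts to ND rows.
* τ_unbound = ∞ in the generator produces an all-unbound trace.
* Random sources take explicit seeds/generators; fixed seeds give
  bit-identical traces and trajectories.

## 9. Problem sizes

Default experiment sizes were chosen to resolve the quantities of interest on
a single desktop core: 25 molecules × 400 s at 10 frames/s (~1300 bound
events) for lifetime recovery; 5000 hexamers × 200 h for population runs;
5 seeds per scan point over ratios 0.1–4.0 in steps of 0.1.

## 10. Known limitations

* KaiB fold-switching is collapsed into the effective first-order
  `kb_switch`; no explicit KaiB•C intermediate.
* No monomer exchange between hexamers and no ATPase bookkeeping.
* The hour-scale rates and the affinity scale are calibrated, not measured;
  conclusions should be read as properties of the calibrated regime.
* The per-phase phosphoform proportions of the in vitro cycle are not
  available as data; phase schedules are user-supplied or model-derived.
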