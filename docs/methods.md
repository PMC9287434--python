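# Methods

`fenestra` couples a mechanistic generator of NMDA-receptor (NMDAR)
whole-cell currents under two-path channel block to the quantification
pipeline used for such recordings. This note documents the model, its
assumptions and parameters, the numerical choices, and what the synthetic
data do and do not establish about real recordings.

## The two-path block model

Channel blockers such as memantine reach their blocking site (the "deep
site" near the tips of the M2 re-entrant loops) by two routes:

1. **Aqueous path (traditional open-channel block).** The charged form of
   the blocker enters the open channel from the extracellular solution at
   rate `kon_aq · [charged]`.
2. **Membrane path (membrane-to-channel inhibition, MCI).** The uncharged
   form partitions into the plasma membrane and transits through a
   membrane-facing fenestration into the open pore at rate `kon_mem · m`,
   where `m` is the occupancy of a membrane reservoir.

Both routes are gated by the open state: a closed channel admits no block
and releases none.

### Speciation

Titratable amines follow dilute-solution Henderson–Hasselbalch:

    f_uncharged(pH) = 1 / (1 + 10^(pKa − pH))

pKa is always an input (memantine 10.4, dimethyl-memantine 10.7);
activity-coefficient and ionic-strength corrections are ignored.
Quaternary ammoniums (trimethyl-memantine, TMM) have `f_uncharged ≡ 0` and
therefore no membrane path. Charged blocker associated with lipid
headgroups is not modeled as part of the reservoir; the reservoir is fed by
the uncharged fraction only.

### Membrane reservoir

A single linear (unsaturable) compartment:

    dm/dt = k_in · [uncharged]_out(t) − k_out · m

`1/k_out` is the reservoir drain constant: 2 s for memantine (the measured
recovery constant of memantine MCI), 10 s for MK-801, whose recovery
required a prolonged depolarizing step in the source experiments and is
therefore necessarily slower than the protocol's washes. `m` carries an
arbitrary "reservoir unit"; only the product `kon_mem · m` is observable,
so `k_in = 1 /μM/s` by convention.

### Gating and trapping

Receptor gating is a lumped three-state cartoon — closed (C), open (O),
desensitized-like (D) — driven by a Hill-saturating agonist occupancy
`a(t)` (EC50 3 μM glutamate, slope 1.4). Defaults `β = 50 /s`, `α = 50 /s`,
`kd+ = 2 /s`, `kd− = 0.5 /s` give a 30–40 ms rise at saturating glutamate
and a desensitizing sag, the qualitative shape of whole-cell GluN1/2A
responses.

Blockers are modeled as **trapping** blockers: a blocked receptor keeps
gating through mirrored states (C*, O*, D*, same rates) but can release its
blocker only through the blocked-open state:

    O  → O*  at  kon_aq·[charged](t) + kon_mem·m(t)
    O* → O   at  koff(V) = koff0 · exp(V / v_efold)

with `v_efold = 40 mV`, so depolarization relieves block. Trapping is not
an incidental choice. A scheme in which the blocked state exchanges only
with O (i) lets blocker unbind during agonist-free washes, contradicting
open-state-only unbinding, and (ii) makes depolarization-driven unblock
flood the open state and over-populate D, so the ratio measured 200 ms
after a depolarizing step deviates from the step-free protocol by far more
than the experimentally observed equality. With trapping, block commutes
with gating and that readout agrees within ~1.4% (the measured equality
this model must reproduce). Trapping is also the textbook phenotype of
memantine and MK-801.

The reported blocked occupancy `B` aggregates C* + O* + D*. Whole-cell
current is carried by unblocked open receptors only:

    I(t) = g_total · O(t) · (V(t) − E_rev) + leak + noise

with defaults `g_total = 30 nS`, `E_rev = 0 mV`, `leak = −20 pA`, optional
Gaussian noise and a multiplicative per-application run-down factor
(default 1, i.e. none). Drug mass balance is not tracked: the bath and
cell volumes dwarf the channel-bound amount.

### Solution exchange

Every solution component relaxes first-order toward the flowing pipe's
nominal value with τ = 27 ms (the measured exchange constant of the
perfusion system emulated here); pH relaxes as a proton concentration.
This is why a 1 s wash (>30 τ) removes aqueous blocker to ~10⁻¹³ of its
applied concentration, isolating the membrane path.

## Protocols

The MCI protocol applies blocker only in the absence of agonist: 20 s
glutamate (I_Control1), 10 s wash, 30 s blocker at the drug pH, 1 s wash,
20–30 s glutamate (I_MCI; default 25 s), 41 s wash, 20 s glutamate
(I_Control2), all at −65 mV (voltages taken as junction-corrected). pH-jump
variants change pH only during the blocker application. The traditional
protocol co-applies blocker and agonist through an ascending concentration
ladder with bracketing controls. The reblock variant splits the recovery
application with depolarizing steps and places a readout marker 200 ms
after the final step ends. Scenario presets prepend a 2 s control segment
so every sweep has a pre-onset baseline window.

Acquisition defaults to 20 kHz; scenario presets simulate on a 2 kHz output
grid, which fully resolves every analyzed quantity (30 ms windows, decay
constants ≥ 46 ms) at desk-scale array sizes.

## Quantification pipeline

1. Baseline-subtract each sweep (mean over 500 ms before agonist onset).
2. Average the two control sweeps point-by-point.
3. Point-by-point ratio I_MCI/I_Control, aligned to the commanded agonist
   application time (not measured current onset), masked wherever
   |I_Control| < 5% of its peak.
4. **Min I_MCI/I_Control**: minimum over all placements of a centered
   30 ms moving-average window (odd sample count, truncated at
   valid-region edges), searched from 54 ms (= 2 τ_exchange, skipping
   exchange artifacts) and, in stepped protocols, only up to the first
   voltage step. The minimum of the windowed series is used rather than
   "window centered on the located minimum" — the two agree on smooth
   ratios, and the former equals an exhaustive window scan on any input.
5. Normalization: the windowed minimum is divided by the mean of the
   windowed minima of I_Control2/I_Control1 and I_Control1/I_Control2 (or,
   for pH-jump experiments, by the same statistic from zero-drug jump
   runs). Selecting a minimum biases the raw value below 1 even with no
   inhibition; this normalization cancels most of that bias. It does not
   cancel it exactly: the three-trace MCI ratio carries noise variance
   1.5σ² against the control ratio's 2σ², leaving a small positive
   residual (≈ +0.14% at realistic noise against a −1.1% raw bias).
6. Preinhibition peak: first local maximum of the 5 ms-smoothed current
   magnitude after onset (edge-trimmed); absent for monotone traces.
7. **τ_M**: single-exponential least-squares fit of the ratio from the
   preinhibition peak to the windowed-minimum time.
8. QC: a cell is excluded if the control peaks differ by >20%, peak
   current exceeds 2.5 nA, series resistance exceeds 20 MΩ, holding
   current is more negative than −200 pA, or holding-current segment
   means range over more than 100 pA. Decisions are pure functions of the
   record, one reason code per violated rule.

The 50 Hz zero-phase Bessel filter is presentation-only; quantification
always runs on as-sampled data.

## Concentration–response fitting

MCI curves use `Min([B]) = A + (1−A)/(1 + ([B]/IC50)^nH)` fit to mean Min
values (A absorbs residual inhibition at saturation; the 1 s wash lets some
blocker leave the membrane). With only two concentrations, A is fixed to 0
and nH to 1, leaving IC50 the single free parameter; for a single point the
closed form IC50 = c·r/(1−r) is exact. Traditional curves use
`1/(1 + ([B]/IC50)^nH)` per cell with cohort mean ± SEM. Fitting is bounded
least squares (IC50 > 0, 0 ≤ A < 1, 0.1 ≤ nH ≤ 5) with three log-spaced
IC50 starts; weighted fits (1/SEM²) use absolute-sigma covariance for the
parameter SE, unweighted fits scale the covariance by the residual
variance. Data with no resolvable inhibition (all values ≥ 0.98) are
flagged non-identifiable rather than assigned a huge IC50. Published MCI
studies do not print fitted Hill slopes, so round-trip tests plant nH
anywhere in [0.8, 1.5] as a free choice.

## Calibration

`kon_mem` and `koff0` are not directly observable; scenarios are calibrated
against measured observables. In the fast-gating quasi-steady-state limit
the ratio relaxes at `p_o·(kon_mem·m + koff)` toward `koff/(koff +
kon_mem·m)`, and that algebra provides starting values — but the actual
calibration root-finds on the full simulate-then-quantify pipeline, so the
matched quantities are exactly what the pipeline reports, with reservoir
drainage, the desensitization transient and solution exchange included:

* memantine: (kon_mem, koff0) solved jointly so the 100 μM pH 7.2 scenario
  has ground-truth ratio minimum 0.611 and fitted decay constant 46.4 ms;
* MK-801: (kon_mem, koff0) solved so the fitted onset constants at 1 and
  10 μM equal 1002 and 311 ms. The sub-proportional concentration scaling
  (~3-fold for 10-fold) emerges from the additive koff term, not from
  reservoir saturation (the reservoir is linear).

MK-801 scenarios include a 20 s step to +30 mV during the recovery
application — without it, trapped blocker survives the 41 s wash and
contaminates I_Control2.

## Numerical choices

* ODE integration: LSODA per protocol segment, rtol 1e-8, atol 1e-10, hard
  restart at every segment boundary so discontinuous drivers never cross an
  internal solver step; exchange drivers are evaluated analytically.
* Stochastic oracle: exact population SSA over the six channel states with
  thinning against per-segment propensity bounds; the reservoir (which is
  deterministic and independent of channel state) is precomputed from its
  ODE. Desk scale is capped at 10⁴ channels.
* Decay fits: `scipy.optimize.curve_fit` on `r∞ + (r₀−r∞)e^(−t/τ)` with
  τ bounded positive; non-decaying inputs are flagged, not fitted.
* Windowed minima use cumulative sums per contiguous valid run; ties
  resolve to the earliest window.
* All stochastic entry points take explicit seeds, recorded in output
  metadata.

## What the synthetic data do not show

The generator emulates agonist-gated currents with solution-exchange
kinetics, desensitization-like sag, recording noise, holding current and
run-down. It does not emulate series-resistance error, capacitance
transients, proton-activated or other off-target conductances (amiloride,
glycine, TTX and APV are carried as metadata only), triheteromeric or
mutant receptor kinetics, Mg²⁺/Ca²⁺ permeation, or spontaneous channel
openings. Passing tests therefore establish that the pipeline correctly
recovers planted kinetics from currents of realistic shape and noise — not
that the three-state gating cartoon is an adequate model of NMDAR gating,
nor that calibrated rate constants are transferable to real cells.

Known limitations: with 1 mM of a permanently charged blocker the model
predicts a ~0.4% residual inhibition (receptors still draining through the
desensitized tail when the blocker arrives are captured through the
aqueous path and trapped), so the permanent-cation scenario yields a
minimum of ~0.996 rather than exactly 1 — comfortably above the measured
equality bound, and a real contamination channel that protocol designers
guard against. The calibrated MK-801 scenarios reproduce measured onset
constants but overestimate the corresponding minima; matching both
jointly would need a richer reservoir/gating model. Why ketamine shows no
MCI is not modeled; its library entry simply sets `kon_mem = 0`.
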