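# Methods

This note documents the models implemented in `dropjet`, their assumptions,
the defaults and why, and what the synthetic-data generators do and do not
emulate.

## Droplet generation frequency

A cylindrical dispersed-phase channel (Ø 50 µm, aqueous crystal suspension)
meets a rectangular continuous-phase channel (W × depth = 100 × 75 µm,
fluorinated oil) at a T-junction. For capillary numbers around 10⁻² — the
transient regime between squeezing and dripping — the generation frequency
follows

    f_d = (K / W) · Ca^{4/3} · v_d / v_tot,    Ca = η v_c / σ.

**Velocity convention.** Both `v_d` and `v_c` are *superficial* velocities
through the main-channel cross-section `A = W · depth`, i.e.
`v_d = Q_aq/A`, `v_c = Q_oil/A`. This makes the velocity ratio in the law
identical to the flow-rate ratio, `v_d/v_tot = Q_aq/Q_tot = p_aq`, so the
frequency law and the hit-fraction model share one aqueous fraction. Other
conventions (e.g. the dispersed velocity through its own channel) would
rescale `K`; since `K` is fitted per device, the choice is internally
consistent as long as it is fixed, and this one is the simplest.

Constructors accept bench units (µL/min, mPa·s, mN/m, µm) and convert to SI
on ingestion; everything internal is SI.

**Prefactor fit.** The law is linear in `K` through the regressor
`z = Ca^{4/3} (v_d/v_tot) / W`, so the fit is one-parameter zero-intercept
least squares (the law has no intercept: no flow, no droplets). Each
measured frequency comes from counting 60–80 droplets, giving a relative
error ∝ 1/√n and hence variance ∝ f²/n; the default weights are n/f².
An unweighted fit is available (`weighted=False`). The standard error is
the usual 1-parameter LS expression `sqrt(s²/Σw z²)` with weighted residual
variance `s²` on n−1 degrees of freedom. A fit with fewer than two points
or with all regressors identical raises a degenerate-fit error: a single
design point cannot exhibit the power law the fit presumes.

**Flow solver.** `solve_flow_for_frequency` holds the ratio `Q_aq/Q_oil`
fixed and searches the total flow. At fixed ratio `f_d ∝ Q_tot^{4/3}`, so
the objective is strictly monotone and the root unique when the bracket
(10⁻² to 10³ µL/min total flow) contains it; Brent's method is used and the
round trip is verified to a relative 10⁻⁶.

**Degenerate inputs.** `Q_oil = 0` is a valid state ("continuous mode", a
plain jet) carried by the `FlowCondition`; evaluating the droplet frequency
on it raises, since no droplets form without shearing oil.

**A note on regimes.** The characterisation design spans total velocities
10–20 mm/s; beamtime operation used total flows of 8–50 µL/min, which
through the 100 × 75 µm cross-section correspond to 18–111 mm/s. The two
regimes are not reconciled here: the package exposes both constructors
(`flow_condition` from flows, `flow_condition_from_velocities` from
velocities) and leaves the operating point to the user.

## Pulse schedules and duty cycle

A `PulseSchedule` is (train period, pulses per train, intra-train spacing,
calibration pulses, record stride). The EuXFEL preset is 0.1 s trains of 32
pulses spaced 889 ns; the first two pulses are calibration pulses and every
second pulse from pulse 3 is recorded, giving ids 3, 5, …, 31 — 15 recorded
patterns per train (pulse 32 is never recorded under this scheme). The
quoted intra-train rate of 1.1 MHz would give 909 ns; the explicit 889 ns
spacing is adopted and the discrepancy noted here. Single-pulse facilities
(LCLS 120 Hz, SACLA 30/60 Hz, PAL-XFEL 60 Hz, SwissFEL 100 Hz) are 1-pulse
trains.

Train duration is defined first-pulse-to-last-pulse, `(n−1)·spacing`
(27.559 µs ≈ 30 µs for the EuXFEL preset). The continuous-injection waste
fraction is `1 − span/period` with pulses treated as instantaneous, so a
single-pulse facility wastes fraction 1 by convention; an optional
per-train `probe_window` refines this for users who want to credit the
beam-transit time.

## Jet and hit fraction

Mass conservation fixes the jet radius, `π r_j² v_j = Q_tot`, with the jet
speed set by the sheath-gas pressure drop — default 50 m/s, the speed scale
required to replenish the jet between MHz pulses; the achieved speed was
not measured, so it is a free parameter. The expected hits per pulse under
plug flow are `⟨N⟩ = π r_j² D_b n p_aq`, algebraically `D_b n Q_aq / v_j`.
A literature reduced form omitting `v_j` is dimensionally inconsistent and
is not implemented; both implemented forms are tested to agree to machine
precision. The beam is a single scalar diameter (default 20 µm, the larger
axis of the 15 × 20 µm² focus); `n` is an effective crystal number density
treated purely as a calibration parameter, because nominal counting-chamber
densities (~5×10⁹/mL of 8–10 µm crystals) are not self-consistent as solid
fractions.

Plug timing: a droplet of volume `V_d` passes the interaction point in
`V_d/Q_tot`; the oil slug carries `V_d·Q_oil/Q_aq`, so one cycle lasts
`V_d/Q_aq = 1/f_d` and the aqueous time fraction equals `p_aq` identically.
A plug "spans the train" when its duration ≥ the train span (≥ convention
at the boundary).

## Monte Carlo injection simulation

The plug timeline starts an aqueous plug at `t = phase`; unsynchronised
mode draws the phase uniformly over one plug period per simulation (the
generator and the accelerator share no clock). Each pulse is classified
aqueous/oil by its offset within the cycle; an optional `interface_window`
labels pulses within that half-width of a phase boundary as `boundary`,
modelling the rare oil signatures attributed to hitting a droplet's edge —
boundary pulses score zero hits. Optional period jitter multiplies each
cycle by a unit-mean lognormal with the given CV (default 0: generation is
stable after pressure equilibration). Aqueous pulses draw independent
Poisson counts with the configured mean; one named generator per
simulation, seed mandatory.

Synchronised mode returns a train at the schedule's train rate with the
aqueous plug centred on the train; if the plug is shorter than the train
span the returned train carries a warning flag rather than raising.

**Commensurability.** When `f_d` and the pulse (or train) period are
rationally related, pulse phases cycle through finitely many values instead
of equidistributing — the extreme case, `f_d` = train rate, samples a
single phase and is exactly what synchronisation exploits. Statistical
convergence checks in the test suite therefore use an irrational frequency
ratio (e.g. `f_d = 10·√2 Hz`), for which the phase sequence
equidistributes and the observed aqueous fraction falls within binomial
error bands of `p_aq`.

**Accounting.** `summarize_run` reports hits on *recorded* pulses (what a
beamtime counts) plus the all-pulse total, the observed aqueous fraction,
and the per-pulse-id hit histogram, whose flatness under plug flow reflects
a jet fast enough to replenish between pulses. `consumption_report`
computes hits/µL, fold-change vs a reference condition, and the percent
volume reduction on a per-unit-time basis (volumes at matched duration).

## Detector traces and panel profiles

The in-line droplet detector transmits a 1550 nm laser across the capillary;
oil and aqueous phases transmit differently, giving a two-level voltage
trace. Segmentation uses the midpoint of the robust 10th/90th-percentile
levels with a hysteresis band of 20% of the separation and a minimum dwell
of 3 samples; all three are configurable. Which level is aqueous is a
configuration (`aqueous_level`); the default maps low transmission to
aqueous since water absorbs at 1550 nm — an assumption, not a measured
fact. Frequency is (aqueous events − 1)/(span of aqueous starts); dwell
means use interior events only, since the first and last runs are truncated
by the observation window. Constant traces return an empty, flagged result.
Frequency estimation is invariant to affine transforms of the voltage
(offset, gain, inversion) because thresholds derive from percentiles.

Panel analysis: images are projected horizontally (row-wise *sums*, left
unscaled), averaged over the stack; the ring score is the excess of the
in-band maximum over the median out-of-band baseline, clipped at zero. An
oil scattering ring appears as a large positive score; aqueous-only stacks
score near zero.

## Synthetic data

The generators define the conditions under which the package is validated:

* **Frequency datasets** — 70 points by default: 7 aqueous fractions
  (0.15–0.5) × 10 total velocities spanning 10–20 mm/s, generating
  prefactor 3.7 m/s, multiplicative Gaussian noise with 5% CV, droplet
  counts uniform on 60–80. A "counting" noise mode (CV = 1/√n, the pure
  counting error) is provided as the alternative error model, since the
  per-point error bars of real characterisations are under-specified.
* **Traces** — two-level square waves (defaults: 10 kHz sampling, 1 V
  swing — oscilloscope-scale choices, since the real amplitude/rate are
  unspecified) with a linear rise over 1% of the period and additive
  Gaussian noise; ground-truth event tables are returned alongside.
* **Hit streams** — the Monte Carlo simulator itself;
  `mean_hit_for_rate` calibrates the Poisson mean to a target hits/µL.
* **Panel stacks** — Gaussian background plus an optional row-direction
  Gaussian ridge standing in for the oil ring.

All generators are deterministic given their seed. What they do **not**
emulate: real droplet coalescence or break-up in 2.5 m of capillary,
crystal settling and size dispersity, detector gain artefacts, hit-finder
behaviour, or any diffraction physics — so passing tests validate the
models' internal consistency and statistical behaviour, not instrument
performance.

## Problem sizes and numerics

Statistical tests use 10⁵ single-pulse trains (fraction convergence),
2000 EuXFEL trains (flatness), 200 fit replicates (estimator calibration),
and ≤ 10⁶-sample traces; each suite runs in seconds on one CPU. Root
finding uses Brent with a generous fixed bracket; fits are closed-form.
Chi-square flatness is tested at α = 0.01; convergence identities at 3σ.

## Known limitations

* The prefactor fit weights use observed frequencies (`n/f_obs²`), which
  at 5% noise introduces negligible but nonzero bias; weights from model
  frequencies would require iterating the fit.
* The hysteresis segmenter assumes a genuinely bimodal trace; slow drifts
  comparable to the level separation defeat the global percentile
  thresholds (a windowed variant would be needed).
* The waste-fraction convention makes single-pulse facilities look
  maximally wasteful (fraction 1); use `probe_window` for a finite
  estimate.
* Hit statistics are independent Poisson draws; crystal clustering,
  settling, or nozzle clogging would over-disperse real counts.
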