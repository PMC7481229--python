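# dropjet

Modelling and simulation of **segmented-flow (droplet-in-oil) sample
injection** for serial femtosecond crystallography (SFX) at pulsed X-ray
free-electron lasers.

Pulsed XFELs probe a liquid jet only a tiny fraction of the time: the
European XFEL fires ~30 µs bursts ("trains") of pulses spaced 889 ns, with
trains repeating at 10 Hz, so a continuously flowing crystal-suspension jet
wastes >99% of the sample between trains. Compartmentalising the aqueous
crystal suspension into sub-nL droplets separated by an immiscible
fluorinated oil lets the precious sample arrive only when (or mostly when)
pulses do. `dropjet` is a toolkit for scientists planning and analysing such
experiments: it predicts droplet generation rates from flow rates, fits the
device-specific prefactor to characterisation data, accounts for pulse-train
timing and duty cycle, simulates droplet–pulse overlap, analyses in-line
droplet-detector traces, and does the hits-per-microlitre bookkeeping that
quantifies the sample saving.

## The models

**T-junction droplet frequency.** In the transient regime between squeezing
and dripping, the droplet generation frequency follows a capillary-number
power law

```
f_d = (K / W) · Ca^(4/3) · v_d / v_tot,      Ca = η v_c / σ
```

where `W` is the continuous-phase channel width, `v_d`, `v_c` the
superficial phase velocities (`v_tot = v_d + v_c`), `η` the oil viscosity,
`σ` the interfacial tension, and `K` a prefactor characteristic of the fluid
pair and junction, fitted to measured frequencies by weighted zero-intercept
least squares. The bundled preset describes a fluorinated-oil (PFD:PFO 10:1)
system: `η = 13.3 mPa·s`, `σ = 12 mN/m`, `W = 100 µm`, with fitted
`K = 3.7 m/s`. Inverting the law at a fixed flow ratio tunes `f_d` to a
facility repetition rate (10 Hz trains at EuXFEL, 120 Hz at LCLS, ...).

**Plug-flow hit fraction.** A gas-focused jet of speed `v_j` carrying total
flow `Q_tot` has radius `r_j = sqrt(Q_tot/(π v_j))`; with beam diameter
`D_b`, crystal number density `n` and aqueous volume fraction
`p_aq = Q_aq/Q_tot`, the expected crystal hits per pulse are

```
⟨N⟩ = π r_j² D_b n p_aq  =  D_b n Q_aq / v_j
```

— proportional to the aqueous flow rate alone at fixed beam and jet speed.

**Monte Carlo overlap.** The plug stream (aqueous span `p_aq/f_d`, oil span
`(1−p_aq)/f_d`, optional period jitter and boundary zones) is sampled at
every pulse time; aqueous pulses draw Poisson crystal counts. Unsynchronised
generation means a uniform random phase; `synchronized_mode` phase-locks one
plug onto each train.

## Worked example

```python
from dropjet import (FLUID_PFD_PFO, K_PFD_PFO, EUXFEL, SyntheticSpec,
                     fit_prefactor, make_frequency_dataset,
                     solve_flow_for_frequency, composite_term)

# recover the prefactor from a noisy 70-point characterisation
fit = fit_prefactor(make_frequency_dataset(SyntheticSpec(seed=1), FLUID_PFD_PFO),
                    FLUID_PFD_PFO)
print(f"K = {fit.k_hat:.3f} ± {fit.k_se:.3f} m/s")   # K = 3.671 ± 0.019 m/s

# flows that tune droplets to the EuXFEL 10 Hz train rate
cond = solve_flow_for_frequency(FLUID_PFD_PFO, K_PFD_PFO, 10.0, flow_ratio=0.3)
print(f"x = {composite_term(cond):.2e}")             # x = 2.70e-04
```

The fitted `K` recovers the generating 3.7 m/s within its standard error;
the composite term `Ca^(4/3)·v_d/v_tot ≈ 2.7×10⁻⁴` is the operating point
at which the junction produces one droplet per pulse train. The scripts in
`examples/` walk through each capability (frequency fit, beamtime planning,
overlap simulation, trace/panel analysis, consumption accounting) and print
the numbers with one-line interpretations; the output shown above and in the
example headers is what the code actually prints.

A thin CLI wraps the same functions:

```
dropjet plan --facility euxfel --out plan.json
dropjet fit-k --measurements measurements.csv --out fit.json
dropjet simulate --seed 1 --out-dir run/
dropjet compare --table accounting.csv --reference continuous --out cmp.json
dropjet make-demo-data --out-dir demo/ --seed 1
```

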