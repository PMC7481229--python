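"""Plan flow rates that tune droplet generation to a facility's pulse rate.

Inverts the frequency law at a fixed aqueous/oil flow ratio to hit the
EuXFEL 10 Hz train rate, then reports the droplet volume, plug duration and
whether one aqueous plug spans the whole ~27.6 us pulse train.
"""

from dropjet import (
    EUXFEL,
    FLUID_PFD_PFO,
    K_PFD_PFO,
    JetParams,
    composite_term,
    continuous_waste_fraction,
    droplet_volume,
    plug_geometry,
    solve_flow_for_frequency,
    spans_train,
)
from dropjet.units import m3_s_to_ul_min, m3_to_pl, s_to_us

schedule = EUXFEL.schedule
target = schedule.train_rate  # 10 Hz

cond = solve_flow_for_frequency(FLUID_PFD_PFO, K_PFD_PFO, target, flow_ratio=0.3)
v_d = droplet_volume(cond.q_aq, target)
jet = JetParams(q_tot=cond.q_tot, jet_speed=50.0)
plug = plug_geometry(v_d, cond.q_aq, cond.q_oil, jet)

print(f"target droplet frequency: {target:.0f} Hz (EuXFEL train rate)")
print(f"Q_aq  = {m3_s_to_ul_min(cond.q_aq):.2f} uL/min")
print(f"Q_oil = {m3_s_to_ul_min(cond.q_oil):.2f} uL/min")
print(f"composite term Ca^(4/3)*v_d/v_tot = {composite_term(cond):.2e}")
print(f"droplet volume: {m3_to_pl(v_d):.0f} pL")
print(f"plug duration at the jet: {s_to_us(plug.aqueous_duration):.0f} us")
print(f"plug spans the {s_to_us(schedule.train_span):.1f} us train: "
      f"{spans_train(plug, schedule)}")
print(f"continuous-injection waste fraction: "
      f"{100 * continuous_waste_fraction(schedule):.2f}%")
# The composite term ~2.7e-4 is the operating point where the T-junction
# produces one droplet per pulse train; a plug lasting longer than the train
# span can cover all 32 pulses with aqueous sample.
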