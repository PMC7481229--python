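"""Bundled parameter presets for the studied droplet-injection system."""

from .droplet_model import FluidSystem

#: Fluorinated-oil continuous phase (PFD:PFO 10:1) against crystal-suspension
#: mother liquor at the printed T-junction: viscosity 13.3 mPa·s, interfacial
#: tension 12 mN/m, 100 µm × 75 µm main channel, 50 µm dispersed channel.
FLUID_PFD_PFO = FluidSystem.from_bench_units(
    viscosity_mpa_s=13.3,
    tension_mn_m=12.0,
    width_um=100.0,
    depth_um=75.0,
    dispersed_diameter_um=50.0,
)

#: Fitted frequency-law prefactor for this fluid pair and junction, m/s.
K_PFD_PFO = 3.7

#: Standard error of the fitted prefactor, m/s.
K_PFD_PFO_SE = 0.2
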