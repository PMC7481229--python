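"""T-junction droplet generation model.

A dispersed aqueous phase (crystal suspension) is sheared into droplets by a
continuous fluorinated-oil phase at a microfluidic T-junction. In the
transient regime between squeezing and dripping the generation frequency
follows a capillary-number power law

    f_d = (K / W) * Ca^(4/3) * (v_d / v_tot)

where ``Ca = eta * v_c / sigma`` is the capillary number of the continuous
phase, ``W`` the continuous-phase channel width, ``v_d`` and ``v_c`` the
superficial phase velocities, ``v_tot = v_d + v_c``, and ``K`` a prefactor
characteristic of the fluid pair and junction geometry, obtained by fitting
measured frequencies.

Both phase velocities are defined as superficial velocities through the main
(continuous-phase) channel cross-section, so the velocity ratio ``v_d/v_tot``
equals the flow-rate ratio ``Q_aq/Q_tot`` exactly.

All quantities are SI; see :mod:`dropjet.units` for bench-unit conversions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import DegenerateFitError, InvalidParameterError, NoSolutionError
from . import units

#: Exponent of the capillary number in the frequency law.
CA_EXPONENT = 4.0 / 3.0


@dataclass(frozen=True)
class FluidSystem:
    """Continuous-phase fluid properties and T-junction geometry.

    Parameters
    ----------
    continuous_viscosity : float
        Dynamic viscosity of the continuous (oil) phase, Pa·s.
    interfacial_tension : float
        Interfacial tension between the phases, N/m.
    channel_width : float
        Width ``W`` of the rectangular continuous-phase channel, m.
    channel_depth : float
        Depth of the continuous-phase channel, m.
    dispersed_channel_diameter : float
        Diameter of the cylindrical dispersed-phase channel, m.
    """

    continuous_viscosity: float
    interfacial_tension: float
    channel_width: float
    channel_depth: float
    dispersed_channel_diameter: float

    def __post_init__(self) -> None:
        for name in (
            "continuous_viscosity",
            "interfacial_tension",
            "channel_width",
            "channel_depth",
            "dispersed_channel_diameter",
        ):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be strictly positive")

    @property
    def main_cross_section(self) -> float:
        """Cross-sectional area of the main channel, m²."""
        return self.channel_width * self.channel_depth

    @classmethod
    def from_bench_units(
        cls,
        viscosity_mpa_s: float,
        tension_mn_m: float,
        width_um: float,
        depth_um: float,
        dispersed_diameter_um: float,
    ) -> "FluidSystem":
        """Build a :class:`FluidSystem` from mPa·s, mN/m and µm values."""
        return cls(
            continuous_viscosity=units.mpa_s_to_pa_s(viscosity_mpa_s),
            interfacial_tension=units.mn_m_to_n_m(tension_mn_m),
            channel_width=units.um_to_m(width_um),
            channel_depth=units.um_to_m(depth_um),
            dispersed_channel_diameter=units.um_to_m(dispersed_diameter_um),
        )


@dataclass(frozen=True)
class FlowCondition:
    """A single operating point of the droplet generator.

    Velocities are superficial velocities through the main-channel
    cross-section; ``v_d / v_tot == q_aq / (q_aq + q_oil)`` by construction.
    """

    q_aq: float  # aqueous flow rate, m³/s
    q_oil: float  # oil flow rate, m³/s
    v_d: float  # dispersed-phase superficial velocity, m/s
    v_c: float  # continuous-phase superficial velocity, m/s
    v_tot: float  # total superficial velocity, m/s
    ca: float  # capillary number of the continuous phase
    p_aq: float  # aqueous volume fraction q_aq / (q_aq + q_oil)

    @property
    def q_tot(self) -> float:
        """Total flow rate, m³/s."""
        return self.q_aq + self.q_oil

    @property
    def is_continuous_mode(self) -> bool:
        """True when no oil flows: a plain continuous jet, no droplets."""
        return self.q_oil == 0.0


@dataclass(frozen=True)
class FrequencyMeasurement:
    """One measured droplet-generation frequency at a known flow condition."""

    condition: FlowCondition
    measured_frequency: float  # Hz
    n_droplets: int  # droplets counted for this point

    def __post_init__(self) -> None:
        if not self.measured_frequency > 0:
            raise InvalidParameterError("measured_frequency must be positive")
        if self.n_droplets < 1:
            raise InvalidParameterError("n_droplets must be >= 1")


@dataclass(frozen=True)
class PrefactorFit:
    """Result of fitting the frequency-law prefactor ``K``."""

    k_hat: float  # fitted prefactor, m/s
    k_se: float  # standard error of k_hat, m/s
    n_points: int
    residual_summary: float  # weighted root-mean-square residual, Hz
    weighted: bool = field(default=True)


def capillary_number(fluid: FluidSystem, v_c: float) -> float:
    """Capillary number ``Ca = eta * v_c / sigma`` of the continuous phase.

    Ratio of viscous shear to interfacial forces; the droplet break-up
    regime is governed by this number, and only ``v_c`` varies at fixed
    fluid pair.
    """
    if v_c < 0:
        raise InvalidParameterError("continuous-phase velocity must be >= 0")
    return fluid.continuous_viscosity * v_c / fluid.interfacial_tension


def flow_condition(fluid: FluidSystem, q_aq: float, q_oil: float) -> FlowCondition:
    """Derive velocities, capillary number and aqueous fraction from flows.

    ``q_aq`` and ``q_oil`` are volumetric flow rates in m³/s. Zero oil flow
    is accepted and flagged as continuous mode (no droplet generation);
    both flows zero is an error.
    """
    if q_aq < 0 or q_oil < 0:
        raise InvalidParameterError("flow rates must be non-negative")
    if q_aq + q_oil == 0:
        raise InvalidParameterError("at least one flow rate must be positive")
    area = fluid.main_cross_section
    v_d = q_aq / area
    v_c = q_oil / area
    return FlowCondition(
        q_aq=q_aq,
        q_oil=q_oil,
        v_d=v_d,
        v_c=v_c,
        v_tot=v_d + v_c,
        ca=capillary_number(fluid, v_c),
        p_aq=q_aq / (q_aq + q_oil),
    )


def flow_condition_from_velocities(
    fluid: FluidSystem, v_d: float, v_c: float
) -> FlowCondition:
    """Build a :class:`FlowCondition` directly from superficial velocities.

    Convenient for frequency-characterisation designs quoted as total
    velocities (e.g. 10–20 mm/s) rather than flow rates.
    """
    area = fluid.main_cross_section
    return flow_condition(fluid, v_d * area, v_c * area)


def composite_term(condition: FlowCondition) -> float:
    """The dimensionless driver ``x = Ca^(4/3) * v_d / v_tot`` of the law."""
    if condition.v_tot == 0:
        raise InvalidParameterError("total velocity is zero")
    return condition.ca ** CA_EXPONENT * condition.v_d / condition.v_tot


def droplet_frequency(fluid: FluidSystem, condition: FlowCondition, k: float) -> float:
    """Predicted droplet-generation frequency, Hz.

    ``f_d = (k / W) * Ca^(4/3) * v_d / v_tot``; zero when no aqueous phase
    flows. Raises on continuous mode (no oil): the frequency is undefined
    for a plain jet.
    """
    if not k > 0:
        raise InvalidParameterError("prefactor k must be positive")
    if condition.v_tot == 0:
        raise InvalidParameterError("total velocity is zero")
    if condition.v_d == 0:
        return 0.0
    if condition.is_continuous_mode:
        raise InvalidParameterError(
            "continuous mode (q_oil = 0): droplet frequency is undefined"
        )
    return k * composite_term(condition) / fluid.channel_width


def fit_prefactor(
    measurements: list[FrequencyMeasurement],
    fluid: FluidSystem,
    weighted: bool = True,
) -> PrefactorFit:
    """Fit the prefactor ``K`` by zero-intercept least squares.

    The model is linear in the regressor ``z = x / W`` with
    ``x = Ca^(4/3) v_d / v_tot``: ``f = K z``. With per-point relative
    counting error shrinking as ``1/sqrt(n_droplets)``, the variance of a
    measured frequency is proportional to ``f² / n``, so the default weights
    are ``n_droplets / f²``. Pass ``weighted=False`` for an ordinary
    (unweighted) zero-intercept fit.

    Raises
    ------
    DegenerateFitError
        Fewer than two points, or all composite terms identical.
    """
    if len(measurements) < 2:
        raise DegenerateFitError("need at least 2 measurements")
    z = np.array([composite_term(m.condition) for m in measurements])
    z = z / fluid.channel_width
    f = np.array([m.measured_frequency for m in measurements])
    n = np.array([m.n_droplets for m in measurements], dtype=float)
    if np.ptp(z) == 0:
        raise DegenerateFitError("all composite terms identical: cannot fit")
    w = n / f**2 if weighted else np.ones_like(f)
    szz = float(np.sum(w * z * z))
    k_hat = float(np.sum(w * z * f)) / szz
    resid = f - k_hat * z
    dof = len(f) - 1
    # residual variance on the weighted scale; se of a 1-parameter LS slope
    s2 = float(np.sum(w * resid**2)) / dof if dof > 0 else 0.0
    k_se = math.sqrt(s2 / szz)
    rms = math.sqrt(float(np.sum(w * resid**2)) / np.sum(w))
    return PrefactorFit(
        k_hat=k_hat, k_se=k_se, n_points=len(f), residual_summary=rms, weighted=weighted
    )


#: Bracket for the total-flow search, µL/min (converted internally).
FLOW_BRACKET_UL_MIN = (1e-2, 1e3)


def solve_flow_for_frequency(
    fluid: FluidSystem,
    k: float,
    target_f: float,
    flow_ratio: float,
    bracket_ul_min: tuple[float, float] = FLOW_BRACKET_UL_MIN,
) -> FlowCondition:
    """Invert the frequency law: find flows giving ``target_f`` at fixed ratio.

    ``flow_ratio = q_aq / q_oil`` is held constant while the total flow is
    varied; because ``f_d`` is strictly increasing in total flow at fixed
    ratio (f ∝ Q_tot^(4/3)), the root is unique when it exists. A bracketed
    scalar search (Brent) is used with a relative round-trip tolerance of
    1e-6.
    """
    if not target_f > 0:
        raise InvalidParameterError("target frequency must be positive")
    if not flow_ratio > 0:
        raise InvalidParameterError("flow ratio q_aq/q_oil must be positive")

    def condition_at(q_tot: float) -> FlowCondition:
        q_aq = q_tot * flow_ratio / (1.0 + flow_ratio)
        return flow_condition(fluid, q_aq, q_tot - q_aq)

    def objective(q_tot: float) -> float:
        return droplet_frequency(fluid, condition_at(q_tot), k) - target_f

    lo = units.ul_min_to_m3_s(bracket_ul_min[0])
    hi = units.ul_min_to_m3_s(bracket_ul_min[1])
    f_lo, f_hi = objective(lo), objective(hi)
    if f_lo > 0 or f_hi < 0:
        raise NoSolutionError(
            f"no total flow in [{bracket_ul_min[0]}, {bracket_ul_min[1]}] µL/min "
            f"reaches {target_f} Hz at ratio {flow_ratio}"
        )
    q_root = brentq(objective, lo, hi, xtol=1e-18, rtol=1e-12)
    cond = condition_at(q_root)
    achieved = droplet_frequency(fluid, cond, k)
    if abs(achieved - target_f) > 1e-6 * target_f:
        raise NoSolutionError("root refinement did not converge to tolerance")
    return cond


def droplet_volume(q_aq: float, f_d: float) -> float:
    """Droplet volume from volume conservation: ``V_d = q_aq / f_d`` (m³).

    Every second, ``f_d`` droplets carry away exactly the injected aqueous
    volume, so ``f_d · V_d = q_aq`` holds identically.
    """
    if not f_d > 0:
        raise InvalidParameterError("droplet frequency must be positive")
    if q_aq < 0:
        raise InvalidParameterError("aqueous flow rate must be >= 0")
    return q_aq / f_d
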