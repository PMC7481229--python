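"""Jet geometry and the expected crystal hit fraction of a segmented jet.

A gas dynamic virtual nozzle stretches the segmented flow into a thin free
jet whose speed ``v_j`` is set by the sheath-gas pressure drop, so mass
conservation fixes the radius: ``pi * r_j**2 * v_j = Q_tot``. Under a
plug-flow model, with the droplet generator unsynchronised to the pulses,
the expected number of crystal diffraction events per pulse is

    <N> = pi * r_j**2 * D_b * n * p_aq  =  D_b * n * Q_aq / v_j

with ``D_b`` the X-ray beam diameter, ``n`` the crystal number density and
``p_aq = Q_aq / Q_tot`` the aqueous volume fraction. The second form follows
by substituting ``r_j**2 = Q_tot / (pi * v_j)``: the hit fraction is
proportional to the aqueous flow rate alone at fixed beam and jet speed.
The crystal density ``n`` is treated as a calibration parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .beam_schedule import PulseSchedule
from .errors import InvalidParameterError


def jet_radius(q_tot: float, jet_speed: float) -> float:
    """Free-jet radius from mass conservation, ``sqrt(Q_tot/(pi v_j))`` (m)."""
    if not q_tot > 0:
        raise InvalidParameterError("total flow must be positive")
    if not jet_speed > 0:
        raise InvalidParameterError("jet speed must be positive")
    return math.sqrt(q_tot / (math.pi * jet_speed))


@dataclass(frozen=True)
class JetParams:
    """Liquid-jet operating point: total flow and jet speed (radius derived)."""

    q_tot: float  # m³/s
    jet_speed: float  # m/s; default operating assumption ~50 m/s for MHz replenishment

    def __post_init__(self) -> None:
        jet_radius(self.q_tot, self.jet_speed)  # validates both

    @property
    def radius(self) -> float:
        """Jet radius, m."""
        return jet_radius(self.q_tot, self.jet_speed)


#: Default jet speed (m/s): the replenishment requirement between MHz pulses.
DEFAULT_JET_SPEED = 50.0


@dataclass(frozen=True)
class BeamCrystalParams:
    """X-ray beam diameter and crystal number density.

    The nominal focus is elliptical (15 × 20 µm²); the model uses a single
    scalar diameter, by default the 20 µm width. ``crystal_density`` is the
    effective number of crystals per m³ of suspension and acts as a free
    calibration parameter.
    """

    beam_diameter: float  # m
    crystal_density: float  # m^-3

    def __post_init__(self) -> None:
        if not self.beam_diameter > 0:
            raise InvalidParameterError("beam diameter must be positive")
        if not self.crystal_density > 0:
            raise InvalidParameterError("crystal density must be positive")


def mean_hit_fraction(jet: JetParams, beam: BeamCrystalParams, p_aq: float) -> float:
    """Expected crystal hits per pulse, ``pi r_j² D_b n p_aq``.

    Algebraically identical to ``D_b n Q_aq / v_j``; see
    :func:`mean_hit_fraction_from_flow`.
    """
    if not 0 <= p_aq <= 1:
        raise InvalidParameterError("p_aq must lie in [0, 1]")
    return math.pi * jet.radius**2 * beam.beam_diameter * beam.crystal_density * p_aq


def mean_hit_fraction_from_flow(
    q_aq: float, jet_speed: float, beam: BeamCrystalParams
) -> float:
    """Expected hits per pulse in the substituted form ``D_b n Q_aq / v_j``."""
    if q_aq < 0:
        raise InvalidParameterError("aqueous flow must be >= 0")
    if not jet_speed > 0:
        raise InvalidParameterError("jet speed must be positive")
    return beam.beam_diameter * beam.crystal_density * q_aq / jet_speed


@dataclass(frozen=True)
class PlugGeometry:
    """Timing and extent of one aqueous plug (stretched droplet) in the jet."""

    aqueous_duration: float  # s the aqueous volume spends at the interaction point
    oil_duration: float  # s per oil slug
    aqueous_length: float  # plug length in the jet, m

    @property
    def period(self) -> float:
        """One full aqueous+oil cycle, s (equals 1/f_d)."""
        return self.aqueous_duration + self.oil_duration

    @property
    def aqueous_fraction(self) -> float:
        """Time fraction spent aqueous; equals p_aq identically."""
        return self.aqueous_duration / self.period


def plug_geometry(
    droplet_volume: float, q_aq: float, q_oil: float, jet: JetParams
) -> PlugGeometry:
    """Plug durations and length from droplet volume and flows.

    The aqueous plug passes the interaction point in ``V_d / Q_tot``; the
    oil slug between plugs carries volume ``V_d * Q_oil / Q_aq``, so one full
    cycle lasts ``V_d / Q_aq = 1 / f_d`` and the aqueous time fraction equals
    ``p_aq`` exactly.
    """
    if not droplet_volume > 0:
        raise InvalidParameterError("droplet volume must be positive")
    if not q_aq > 0:
        raise InvalidParameterError("aqueous flow must be positive")
    if q_oil < 0:
        raise InvalidParameterError("oil flow must be >= 0")
    q_tot = q_aq + q_oil
    aq = droplet_volume / q_tot
    oil = droplet_volume * q_oil / q_aq / q_tot
    return PlugGeometry(
        aqueous_duration=aq,
        oil_duration=oil,
        aqueous_length=jet.jet_speed * aq,
    )


def spans_train(plug: PlugGeometry, schedule: PulseSchedule) -> bool:
    """True if one aqueous plug lasts at least the whole pulse-train span.

    A plug that spans the train can, when phased correctly, put aqueous
    sample in front of every pulse of the train.
    """
    return plug.aqueous_duration >= schedule.train_span
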