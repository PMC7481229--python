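"""Synthetic data generation for every input the analysis consumes.

The generators emulate the statistical structure of the study's raw
measurements so the whole pipeline is testable without instrument data:

* frequency-characterisation tables — power-law frequencies with
  multiplicative noise approximating the counting error of 60–80 analysed
  droplets per condition;
* two-level droplet-detector voltage traces with finite rise time and
  additive Gaussian noise;
* per-pulse hit streams from the Monte Carlo injection simulator;
* small detector-panel image stacks with or without an oil scattering ring.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beam_schedule import PulseSchedule, recorded_pulse_ids
from .droplet_model import (
    FlowCondition,
    FluidSystem,
    FrequencyMeasurement,
    droplet_frequency,
    flow_condition_from_velocities,
)
from .errors import InvalidParameterError
from .mc_injection import DropletTrain, simulate_injection
from .trace_analysis import DetectorTrace


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic-data generators.

    The defaults mirror the study conditions: generating prefactor
    3.7 m/s, 70 measurement points spanning total velocities 10–20 mm/s,
    5% relative frequency noise, 60–80 droplets counted per point.
    """

    seed: int
    k_true: float = 3.7  # m/s
    noise_cv: float = 0.05  # relative sd of measured frequencies
    droplets_per_point: tuple[int, int] = (60, 80)  # inclusive range
    noise_mode: str = "multiplicative"  # or "counting": cv = 1/sqrt(n_droplets)
    # frequency-characterisation grid: every (p_aq, v_tot) combination
    v_tot_range: tuple[float, float] = (0.010, 0.020)  # m/s
    n_v_tot: int = 10
    p_aq_values: tuple[float, ...] = (0.15, 0.2, 0.25, 0.3, 1.0 / 3.0, 0.4, 0.5)
    grid: tuple[FlowCondition, ...] | None = None  # overrides the built-in grid
    # detector-trace parameters (oscilloscope defaults; 1 V swing)
    trace_sample_rate: float = 10_000.0  # Hz
    trace_low_v: float = 0.1
    trace_high_v: float = 1.1
    trace_noise_sd: float = 0.0  # V
    trace_rise_fraction: float = 0.01  # rise time as a fraction of the period
    # hit-stream parameters
    mean_hit: float = 0.05  # expected crystals per aqueous pulse
    p_aq: float = 0.3

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise InvalidParameterError("noise_cv must be >= 0")
        if self.noise_mode not in ("multiplicative", "counting"):
            raise InvalidParameterError("noise_mode must be multiplicative|counting")
        lo, hi = self.droplets_per_point
        if not (1 <= lo <= hi):
            raise InvalidParameterError("invalid droplets_per_point range")


def default_grid(spec: SyntheticSpec, fluid: FluidSystem) -> list[FlowCondition]:
    """The built-in characterisation grid: p_aq × v_tot full factorial."""
    v_tots = np.linspace(*spec.v_tot_range, spec.n_v_tot)
    grid = []
    for p_aq in spec.p_aq_values:
        for v_tot in v_tots:
            grid.append(
                flow_condition_from_velocities(fluid, p_aq * v_tot, (1 - p_aq) * v_tot)
            )
    return grid


def make_frequency_dataset(
    spec: SyntheticSpec, fluid: FluidSystem
) -> list[FrequencyMeasurement]:
    """Generate a noisy droplet-frequency measurement table.

    Observed frequencies are ``f_true * (1 + eps)`` with ``eps`` Gaussian:
    sd ``noise_cv`` in multiplicative mode, or ``1/sqrt(n_droplets)`` in
    counting mode (pure droplet-counting error). Droplet counts are drawn
    uniformly over ``droplets_per_point``.
    """
    rng = np.random.default_rng(spec.seed)
    grid = list(spec.grid) if spec.grid is not None else default_grid(spec, fluid)
    if not grid:
        raise InvalidParameterError("empty flow-condition grid")
    lo, hi = spec.droplets_per_point
    measurements = []
    for cond in grid:
        f_true = droplet_frequency(fluid, cond, spec.k_true)
        n = int(rng.integers(lo, hi + 1))
        cv = spec.noise_cv if spec.noise_mode == "multiplicative" else 1.0 / np.sqrt(n)
        f_obs = f_true * (1.0 + cv * rng.standard_normal())
        f_obs = max(f_obs, 1e-12)  # frequencies are physically positive
        measurements.append(
            FrequencyMeasurement(condition=cond, measured_frequency=f_obs, n_droplets=n)
        )
    return measurements


def make_trace(
    spec: SyntheticSpec,
    f_d: float,
    p_aq: float,
    duration: float,
    aqueous_level: str = "low",
) -> tuple[DetectorTrace, pd.DataFrame]:
    """Generate a two-level detector trace plus its ground-truth events.

    The trace alternates between the low and high voltage levels with duty
    ``p_aq`` on the aqueous level, linear transitions lasting
    ``trace_rise_fraction`` of a period, and additive Gaussian noise of sd
    ``trace_noise_sd``. Returns the trace and a DataFrame of the true
    events (start_s, end_s, phase_label).
    """
    if not f_d > 0:
        raise InvalidParameterError("f_d must be positive")
    if not 0 <= p_aq <= 1:
        raise InvalidParameterError("p_aq must lie in [0, 1]")
    if duration * f_d < 1:
        raise InvalidParameterError("trace must contain at least one full period")
    rng = np.random.default_rng(spec.seed)
    n = int(round(duration * spec.trace_sample_rate))
    t = np.arange(n) / spec.trace_sample_rate
    period = 1.0 / f_d
    tau = np.mod(t, period)
    aqueous = tau < p_aq * period  # trace starts with an aqueous plug at t = 0

    aq_v, oil_v = (
        (spec.trace_low_v, spec.trace_high_v)
        if aqueous_level == "low"
        else (spec.trace_high_v, spec.trace_low_v)
    )
    square = np.where(aqueous, aq_v, oil_v)
    rise_samples = max(int(round(spec.trace_rise_fraction * period * spec.trace_sample_rate)), 1)
    if rise_samples > 1 and 0 < p_aq < 1:
        kernel = np.ones(rise_samples) / rise_samples
        # pad with edge values so the ends are not pulled toward zero
        padded = np.concatenate(
            [np.full(rise_samples, square[0]), square, np.full(rise_samples, square[-1])]
        )
        square = np.convolve(padded, kernel, mode="same")[rise_samples:-rise_samples]
    volts = square + rng.normal(0.0, spec.trace_noise_sd, size=n)

    # ground-truth event table over the trace window
    starts, labels = [], []
    k = 0
    while k * period < duration:
        if p_aq > 0:
            starts.append(k * period)
            labels.append("aqueous")
        if p_aq < 1:
            starts.append(k * period + p_aq * period)
            labels.append("oil")
        k += 1
    ends = starts[1:] + [duration]
    truth = pd.DataFrame({"start_s": starts, "end_s": ends, "phase_label": labels})
    truth = truth[truth["start_s"] < duration].reset_index(drop=True)
    trace = DetectorTrace(
        sample_rate=spec.trace_sample_rate,
        voltages=volts,
        meta={"f_d_true": f_d, "p_aq_true": p_aq, "aqueous_level": aqueous_level},
    )
    return trace, truth


def make_hit_stream(
    spec: SyntheticSpec,
    schedule: PulseSchedule,
    n_trains: int,
    frequency: float = 10.0,
    phase: float | None = None,
) -> pd.DataFrame:
    """Per-pulse outcome stream from the Monte Carlo injection simulator."""
    train = DropletTrain(frequency=frequency, p_aq=spec.p_aq, phase=phase)
    return simulate_injection(
        train, schedule, mean_hit=spec.mean_hit, n_trains=n_trains, seed=spec.seed
    )


def mean_hit_for_rate(
    schedule: PulseSchedule, q_aq_ul_min: float, p_aq: float, hits_per_ul: float
) -> float:
    """Mean hits per aqueous pulse giving a target recorded hits/µL rate.

    Inverts ``hits_per_ul = r_rec * 60 * p_aq * mean_hit / q_aq_ul_min``
    where ``r_rec`` is the recorded-pulse rate (pulses/s). Useful for
    calibrating simulations to observed consumption tables.
    """
    if not (q_aq_ul_min > 0 and 0 < p_aq <= 1 and hits_per_ul >= 0):
        raise InvalidParameterError("invalid calibration inputs")
    rec_per_s = len(recorded_pulse_ids(schedule)) * schedule.train_rate
    return hits_per_ul * q_aq_ul_min / (rec_per_s * 60.0 * p_aq)


def make_panel_stack(
    n_images: int,
    shape: tuple[int, int] = (128, 64),
    with_ring: bool = True,
    ring_center: int = 40,
    ring_sigma: float = 3.0,
    ring_amplitude: float = 5.0,
    background: float = 10.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic detector-panel images, optionally with an oil scattering ring.

    The ring is modelled as a Gaussian ridge in the row direction (constant
    across columns), the signature an oil ring leaves in the horizontally
    projected diffuse-scattering profile.
    """
    if n_images < 1:
        raise InvalidParameterError("n_images must be >= 1")
    rng = np.random.default_rng(seed)
    rows = np.arange(shape[0])
    images = background + rng.normal(0.0, noise_sd, size=(n_images, *shape))
    if with_ring:
        ridge = ring_amplitude * np.exp(-0.5 * ((rows - ring_center) / ring_sigma) ** 2)
        images += ridge[None, :, None]
    return images
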