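"""Droplet-detector trace analysis and detector-panel projection profiles.

An in-line optical detector (1550 nm laser diode + photodetector across the
capillary) produces a two-level voltage trace as aqueous plugs and oil slugs
alternate through the beam. Segmenting that trace yields the achieved
droplet frequency and per-phase dwell times in real time, which can be
compared against the T-junction model prediction.

Separately, oil presence in diffraction data shows up as a diffuse
scattering ring; projecting detector-panel images horizontally (row-wise
sums) gives an unscaled profile in which the ring appears as a bump at the
corresponding rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError

#: Fraction of the low/high level separation used as the hysteresis band.
HYSTERESIS_FRACTION = 0.2
#: Events shorter than this many samples are rejected as noise glitches.
MIN_DWELL_SAMPLES = 3

FLAG_NO_LEVELS = "no-two-levels"


@dataclass(frozen=True)
class DetectorTrace:
    """A photodetector voltage time series."""

    sample_rate: float  # Hz
    voltages: np.ndarray  # V
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_rate > 0:
            raise InvalidParameterError("sample_rate must be positive")
        if len(self.voltages) < 2:
            raise InvalidParameterError("trace must contain at least 2 samples")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.voltages)) / self.sample_rate


@dataclass(frozen=True)
class DropletEventList:
    """Segmented droplet events and the frequency/dwell statistics."""

    events: pd.DataFrame  # columns: start_s, end_s, phase_label
    estimated_frequency: float  # Hz; nan if < 2 aqueous events
    mean_aqueous_dwell: float  # s; nan if no interior aqueous event
    mean_oil_dwell: float  # s; nan if no interior oil event
    flags: tuple[str, ...] = ()

    @property
    def n_events(self) -> int:
        return len(self.events)


def _hysteresis_states(v: np.ndarray, th_lo: float, th_hi: float) -> np.ndarray:
    """0/1 state per sample with hysteresis: switch high above th_hi, low below th_lo."""
    raw = np.where(v > th_hi, 1, np.where(v < th_lo, 0, -1))
    # forward-fill the undecided (-1) samples from the last decided state
    decided = raw >= 0
    idx = np.where(decided, np.arange(len(raw)), 0)
    np.maximum.accumulate(idx, out=idx)
    states = raw[idx]
    # samples before the first decision adopt the first decided state
    first = np.argmax(decided) if decided.any() else 0
    states[: first + 1] = raw[idx[first]] if decided.any() else 0
    return states


def detect_droplets(
    trace: DetectorTrace,
    aqueous_level: str = "low",
    min_dwell_samples: int = MIN_DWELL_SAMPLES,
) -> DropletEventList:
    """Segment a two-level trace into aqueous/oil events.

    The threshold is the midpoint of the robust low/high levels (10th/90th
    voltage percentiles) with a hysteresis band of 20% of the level
    separation; events shorter than ``min_dwell_samples`` are rejected.
    ``aqueous_level`` says which transmission level is the aqueous phase;
    water absorbs at 1550 nm, so the default maps the low level to aqueous.

    A trace with no two discernible levels (constant or pure noise) returns
    an empty event list flagged :data:`FLAG_NO_LEVELS` rather than raising.
    """
    if aqueous_level not in ("low", "high"):
        raise InvalidParameterError("aqueous_level must be 'low' or 'high'")
    v = np.asarray(trace.voltages, dtype=float)
    lo, hi = np.percentile(v, [10, 90])
    sep = hi - lo
    empty = pd.DataFrame(columns=["start_s", "end_s", "phase_label"])
    # a separation indistinguishable from zero at float precision, or buried
    # in the overall spread, means there are no two levels to segment
    if sep <= 1e-12 * max(1.0, abs(hi), abs(lo)):
        return DropletEventList(empty, np.nan, np.nan, np.nan, flags=(FLAG_NO_LEVELS,))
    mid = 0.5 * (lo + hi)
    th_lo = mid - 0.5 * HYSTERESIS_FRACTION * sep
    th_hi = mid + 0.5 * HYSTERESIS_FRACTION * sep
    states = _hysteresis_states(v, th_lo, th_hi)
    if states.min() == states.max():
        return DropletEventList(empty, np.nan, np.nan, np.nan, flags=(FLAG_NO_LEVELS,))

    # run-length encode, dropping runs shorter than the minimum dwell
    change = np.flatnonzero(np.diff(states)) + 1
    bounds = np.concatenate([[0], change, [len(states)]])
    runs = [(bounds[i], bounds[i + 1], states[bounds[i]]) for i in range(len(bounds) - 1)]
    kept: list[tuple[int, int, int]] = []
    for start, end, state in runs:
        if end - start < min_dwell_samples:
            continue
        if kept and kept[-1][2] == state:
            kept[-1] = (kept[-1][0], end, state)
        else:
            kept.append((start, end, state))
    if not kept:
        return DropletEventList(empty, np.nan, np.nan, np.nan, flags=(FLAG_NO_LEVELS,))

    aq_state = 0 if aqueous_level == "low" else 1
    dt = 1.0 / trace.sample_rate
    events = pd.DataFrame(
        {
            "start_s": [s * dt for s, _, _ in kept],
            "end_s": [e * dt for _, e, _ in kept],
            "phase_label": ["aqueous" if st == aq_state else "oil" for _, _, st in kept],
        }
    )

    aq_starts = events.loc[events["phase_label"] == "aqueous", "start_s"].to_numpy()
    if len(aq_starts) >= 2:
        freq = (len(aq_starts) - 1) / (aq_starts[-1] - aq_starts[0])
    else:
        freq = np.nan
    # interior events only: the first and last runs are truncated by the window
    interior = events.iloc[1:-1] if len(events) > 2 else events.iloc[0:0]
    dur = interior["end_s"] - interior["start_s"]
    aq_dwell = float(dur[interior["phase_label"] == "aqueous"].mean())
    oil_dwell = float(dur[interior["phase_label"] == "oil"].mean())
    return DropletEventList(
        events=events,
        estimated_frequency=float(freq),
        mean_aqueous_dwell=aq_dwell,
        mean_oil_dwell=oil_dwell,
    )


def compare_to_model(events: DropletEventList, predicted_f: float) -> float:
    """Relative deviation of the measured frequency from the model prediction."""
    if not predicted_f > 0:
        raise InvalidParameterError("predicted frequency must be positive")
    if not events.estimated_frequency > 0:
        raise InvalidParameterError("no valid estimated frequency in events")
    return (events.estimated_frequency - predicted_f) / predicted_f


@dataclass(frozen=True)
class PanelProfile:
    """Horizontally projected (row-summed) diffuse-scattering profile."""

    profile: np.ndarray  # mean over images of the per-row pixel sums
    n_hits: int  # images aggregated
    ring_score: float  # prominence of the in-band maximum over the baseline


def panel_horizontal_profile(
    images: np.ndarray, ring_band: tuple[int, int] | None = None
) -> PanelProfile:
    """Project a stack of 2-D panel images horizontally.

    Each image's pixel values are summed along rows (axis 1) and the
    per-image profiles are averaged over the stack, left unscaled. The
    ``ring_score`` is the excess of the maximum profile value inside
    ``ring_band`` (row index range, half-open) over the median of the
    out-of-band baseline, clipped at zero; with no band given, the whole
    profile is searched and the baseline is the profile median.
    """
    images = np.asarray(images, dtype=float)
    if images.ndim == 2:
        images = images[None, ...]
    if images.ndim != 3 or images.size == 0:
        raise InvalidInputError("need a non-empty stack of 2-D images")
    profile = images.sum(axis=2).mean(axis=0)
    n_rows = profile.shape[0]
    if ring_band is None:
        band = np.ones(n_rows, dtype=bool)
        baseline = float(np.median(profile))
    else:
        lo, hi = ring_band
        if not (0 <= lo < hi <= n_rows):
            raise InvalidInputError("ring_band outside the panel row range")
        band = np.zeros(n_rows, dtype=bool)
        band[lo:hi] = True
        baseline = float(np.median(profile[~band])) if (~band).any() else 0.0
    score = max(float(profile[band].max()) - baseline, 0.0)
    return PanelProfile(profile=profile, n_hits=images.shape[0], ring_score=score)
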