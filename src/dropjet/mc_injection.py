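"""Monte Carlo overlap of the droplet plug train with the X-ray pulse schedule.

The jet carries a periodic alternating sequence of aqueous plugs (duration
``p_aq / f_d``) and oil slugs (duration ``(1 - p_aq) / f_d``). Droplet
generation is, by default, not synchronised with the pulse trains, so the
plug phase relative to the pulses is a uniform random offset over one plug
period. Each pulse is classified by the phase it strikes; pulses striking
aqueous sample illuminate a Poisson-distributed number of crystals with a
mean given by the hit-fraction model. Run-level summaries reproduce the
hits-per-microlitre bookkeeping used to compare segmented against
continuous injection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .beam_schedule import PulseSchedule, pulse_times, recorded_pulse_ids
from .errors import InvalidInputError, InvalidParameterError
from . import units

PHASE_AQUEOUS = "aqueous"
PHASE_OIL = "oil"
PHASE_BOUNDARY = "boundary"

#: Columns of the outcome table produced by :func:`simulate_injection`.
OUTCOME_COLUMNS = ("train_index", "pulse_id", "time_s", "phase_label", "hit", "recorded")


@dataclass(frozen=True)
class DropletTrain:
    """Periodic aqueous/oil plug stream arriving at the interaction point.

    Parameters
    ----------
    frequency : float
        Droplet (plug-cycle) frequency f_d, Hz.
    p_aq : float
        Aqueous volume (= time) fraction of the cycle.
    phase : float or None
        Start time of the first aqueous plug relative to t = 0, s. ``None``
        means unsynchronised: the simulator draws the phase uniformly on one
        plug period.
    period_jitter_cv : float
        Coefficient of variation of the plug period (lognormal multiplier),
        0 = perfectly periodic.
    interface_window : float
        Half-width of the zone around each aqueous/oil interface classified
        as ``boundary`` (mixed phase), s.
    flags : tuple of str
        Diagnostic flags attached by constructors (e.g. synchronisation
        warnings).
    """

    frequency: float
    p_aq: float
    phase: float | None = None
    period_jitter_cv: float = 0.0
    interface_window: float = 0.0
    flags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.frequency > 0:
            raise InvalidParameterError("frequency must be positive")
        if not 0 <= self.p_aq <= 1:
            raise InvalidParameterError("p_aq must lie in [0, 1]")
        if self.period_jitter_cv < 0:
            raise InvalidParameterError("period_jitter_cv must be >= 0")
        if self.interface_window < 0:
            raise InvalidParameterError("interface_window must be >= 0")

    @property
    def period(self) -> float:
        """One aqueous+oil cycle, s."""
        return 1.0 / self.frequency


@dataclass(frozen=True)
class PulseOutcome:
    """Outcome of a single pulse (one row of the outcome table)."""

    train_index: int
    pulse_id: int  # 1-based in-train index
    time_s: float
    phase_label: str
    hit: int  # crystals illuminated; 0 unless phase_label == "aqueous"
    recorded: bool


def _classify_periodic(
    tau: np.ndarray, period: float, aqueous: float, window: float
) -> np.ndarray:
    """Label offsets within one plug cycle. tau in [0, period)."""
    labels = np.where(tau < aqueous, PHASE_AQUEOUS, PHASE_OIL).astype(object)
    if window > 0:
        d0 = np.minimum(tau, period - tau)  # distance to cycle start/end interface
        d1 = np.abs(tau - aqueous)  # distance to aqueous->oil interface
        labels[np.minimum(d0, d1) <= window] = PHASE_BOUNDARY
    return labels


def _classify_jittered(
    t: np.ndarray, train: DropletTrain, phase: float, rng: np.random.Generator
) -> np.ndarray:
    """Labels for a jittered plug timeline built cycle by cycle."""
    period = train.period
    cv = train.period_jitter_cv
    sigma2 = np.log1p(cv**2)
    mu = -0.5 * sigma2  # unit-mean lognormal

    t_min, t_max = float(t.min()), float(t.max())
    n_back = int(np.ceil(max(phase - t_min, 0.0) / period * (1 + 5 * cv))) + 2
    n_fwd = int(np.ceil(max(t_max - phase, 0.0) / period * (1 + 5 * cv))) + 2
    periods = period * rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n_back + n_fwd)
    starts = phase - periods[:n_back][::-1].cumsum()[::-1]
    starts = np.concatenate([starts, phase + np.concatenate([[0.0], periods[n_back:-1].cumsum()])])
    periods = np.concatenate([periods[:n_back], periods[n_back:]])
    idx = np.searchsorted(starts, t, side="right") - 1
    idx = np.clip(idx, 0, len(starts) - 1)
    tau = t - starts[idx]
    labels = np.empty(len(t), dtype=object)
    for i in range(len(t)):
        labels[i] = _classify_periodic(
            np.array([tau[i]]), periods[idx[i]], train.p_aq * periods[idx[i]],
            train.interface_window,
        )[0]
    return labels


def simulate_injection(
    train: DropletTrain,
    schedule: PulseSchedule,
    mean_hit: float,
    n_trains: int,
    seed: int,
) -> pd.DataFrame:
    """Simulate every pulse of ``n_trains`` trains against the plug stream.

    Returns a DataFrame with columns ``train_index, pulse_id, time_s,
    phase_label, hit, recorded``; deterministic given ``seed``. Crystal
    counts on aqueous pulses are Poisson with the given mean; oil and
    boundary pulses score zero.
    """
    if mean_hit < 0:
        raise InvalidParameterError("mean_hit must be >= 0")
    if n_trains < 1:
        raise InvalidParameterError("n_trains must be >= 1")
    rng = np.random.default_rng(seed)
    t = pulse_times(schedule, n_trains)
    phase = train.phase
    if phase is None:
        phase = float(rng.uniform(0.0, train.period))

    if train.p_aq == 1.0:
        labels = np.full(len(t), PHASE_AQUEOUS, dtype=object)
    elif train.p_aq == 0.0:
        labels = np.full(len(t), PHASE_OIL, dtype=object)
    elif train.period_jitter_cv == 0.0:
        tau = np.mod(t - phase, train.period)
        labels = _classify_periodic(
            tau, train.period, train.p_aq * train.period, train.interface_window
        )
    else:
        labels = _classify_jittered(t, train, phase, rng)

    hits = np.zeros(len(t), dtype=int)
    aqueous = labels == PHASE_AQUEOUS
    if mean_hit > 0 and aqueous.any():
        hits[aqueous] = rng.poisson(mean_hit, size=int(aqueous.sum()))

    pulse_ids = np.tile(np.arange(1, schedule.pulses_per_train + 1), n_trains)
    recorded = np.isin(pulse_ids, recorded_pulse_ids(schedule))
    return pd.DataFrame(
        {
            "train_index": np.repeat(np.arange(n_trains), schedule.pulses_per_train),
            "pulse_id": pulse_ids,
            "time_s": t,
            "phase_label": labels,
            "hit": hits,
            "recorded": recorded,
        }
    )


def iter_outcomes(outcomes: pd.DataFrame):
    """Yield :class:`PulseOutcome` rows from an outcome table."""
    for row in outcomes.itertuples(index=False):
        yield PulseOutcome(
            train_index=int(row.train_index),
            pulse_id=int(row.pulse_id),
            time_s=float(row.time_s),
            phase_label=str(row.phase_label),
            hit=int(row.hit),
            recorded=bool(row.recorded),
        )


SYNC_PLUG_TOO_SHORT = "plug-shorter-than-train-span"


def synchronized_mode(train: DropletTrain, schedule: PulseSchedule) -> DropletTrain:
    """Phase-lock the plug stream to the pulse trains.

    Returns a train at the schedule's train repetition rate whose aqueous
    plug is centred on each pulse train. If the plug (duration
    ``p_aq / f_d``) is shorter than the train span, full coverage is
    impossible and the returned train carries the
    :data:`SYNC_PLUG_TOO_SHORT` flag.
    """
    f_sync = schedule.train_rate
    plug_duration = train.p_aq / f_sync
    phase = 0.5 * schedule.train_span - 0.5 * plug_duration
    flags = train.flags
    if plug_duration < schedule.train_span:
        flags = flags + (SYNC_PLUG_TOO_SHORT,)
    return replace(train, frequency=f_sync, phase=phase, flags=flags)


@dataclass(frozen=True)
class RunSummary:
    """Aggregate statistics of a simulated (or tabulated) injection run."""

    n_pulses: int
    n_recorded: int
    aqueous_fraction_observed: float
    total_hits: int  # hits on recorded pulses (what a beamtime counts)
    total_hits_all_pulses: int  # hits on every pulse, recorded or not
    hits_per_ul: float  # recorded hits per µL of crystal suspension injected
    volume_ul: float
    per_pulse_id_hits: pd.Series  # recorded hits summed per in-train pulse id


def summarize_run(outcomes: pd.DataFrame, q_aq: float, duration: float) -> RunSummary:
    """Aggregate an outcome table into run-level statistics.

    ``q_aq`` is the aqueous flow in m³/s and ``duration`` the run length in
    seconds; the injected suspension volume is their product. Hits-per-µL is
    computed from recorded pulses only, mirroring experimental accounting.
    """
    if len(outcomes) == 0:
        raise InvalidInputError("empty outcome table")
    if q_aq < 0 or duration <= 0:
        raise InvalidParameterError("need q_aq >= 0 and duration > 0")
    recorded = outcomes[outcomes["recorded"]]
    volume_ul = units.m3_to_ul(q_aq * duration)
    total_recorded_hits = int(recorded["hit"].sum())
    per_id = recorded.groupby("pulse_id")["hit"].sum()
    return RunSummary(
        n_pulses=len(outcomes),
        n_recorded=len(recorded),
        aqueous_fraction_observed=float((outcomes["phase_label"] == PHASE_AQUEOUS).mean()),
        total_hits=total_recorded_hits,
        total_hits_all_pulses=int(outcomes["hit"].sum()),
        hits_per_ul=total_recorded_hits / volume_ul if volume_ul > 0 else 0.0,
        volume_ul=volume_ul,
        per_pulse_id_hits=per_id,
    )


@dataclass(frozen=True)
class ConsumptionReport:
    """Continuous-vs-segmented sample-consumption comparison table.

    ``table`` has one row per condition with columns ``minutes, volume_ul,
    hits, hits_per_ul, q_aq_ul_min, fold_change, percent_reduction``;
    fold-change is in hits/µL relative to the reference condition, and the
    percent reduction compares injected volume per unit time against the
    reference (i.e. volumes at matched duration).
    """

    table: pd.DataFrame
    reference: str


def consumption_report(
    rows: list[tuple[str, float, float, float]], reference_label: str
) -> ConsumptionReport:
    """Build a consumption comparison from (label, minutes, volume_ul, hits) rows."""
    if not rows:
        raise InvalidInputError("no rows given")
    df = pd.DataFrame(rows, columns=["label", "minutes", "volume_ul", "hits"])
    if (df["volume_ul"] <= 0).any() or (df["minutes"] <= 0).any():
        raise InvalidInputError("volumes and durations must be positive")
    if reference_label not in set(df["label"]):
        raise InvalidInputError(f"reference label {reference_label!r} not in table")
    df = df.set_index("label")
    df["hits_per_ul"] = df["hits"] / df["volume_ul"]
    df["q_aq_ul_min"] = df["volume_ul"] / df["minutes"]
    ref = df.loc[reference_label]
    df["fold_change"] = df["hits_per_ul"] / ref["hits_per_ul"]
    df["percent_reduction"] = 100.0 * (1.0 - df["q_aq_ul_min"] / ref["q_aq_ul_min"])
    return ConsumptionReport(table=df, reference=reference_label)


def hit_rate_percent(n_hits: int, n_images: int) -> float:
    """Hit rate as a percentage of collected images."""
    if n_images <= 0:
        raise InvalidParameterError("n_images must be positive")
    if n_hits < 0 or n_hits > n_images:
        raise InvalidParameterError("n_hits must lie in [0, n_images]")
    return 100.0 * n_hits / n_images
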