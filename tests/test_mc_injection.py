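"""Tests of the Monte Carlo droplet–pulse overlap simulator and run accounting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dropjet import (
    DropletTrain,
    InvalidInputError,
    PulseSchedule,
    consumption_report,
    hit_rate_percent,
    simulate_injection,
    summarize_run,
    synchronized_mode,
)
from dropjet.mc_injection import SYNC_PLUG_TOO_SHORT
from dropjet.units import ul_min_to_m3_s

SINGLE_PULSE_10MS = PulseSchedule(train_period=0.01, pulses_per_train=1)


class TestSimulateInjection:
    def test_all_aqueous_when_no_oil(self):
        train = DropletTrain(frequency=10.0, p_aq=1.0)
        df = simulate_injection(train, SINGLE_PULSE_10MS, 0.5, 500, seed=1)
        assert (df["phase_label"] == "aqueous").all()

    def test_zero_mean_hit_gives_zero_hits(self):
        train = DropletTrain(frequency=10.0, p_aq=0.5)
        df = simulate_injection(train, SINGLE_PULSE_10MS, 0.0, 500, seed=1)
        assert (df["hit"] == 0).all()

    def test_hits_only_on_aqueous_pulses(self, euxfel):
        train = DropletTrain(frequency=10 * np.sqrt(2), p_aq=0.3)
        df = simulate_injection(train, euxfel, 2.0, 300, seed=4)
        assert (df.loc[df["phase_label"] != "aqueous", "hit"] == 0).all()

    def test_seed_reproducibility(self, euxfel):
        train = DropletTrain(frequency=13.7, p_aq=0.4, period_jitter_cv=0.05)
        a = simulate_injection(train, euxfel, 0.7, 100, seed=42)
        b = simulate_injection(train, euxfel, 0.7, 100, seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_injection(train, euxfel, 0.7, 100, seed=43)
        assert not a.equals(c)

    def test_aqueous_fraction_converges_to_p_aq(self):
        # droplet period incommensurate with the pulse period, so pulse
        # phases equidistribute over the plug cycle; the observed aqueous
        # fraction must sit within 3 binomial standard errors of p_aq
        p_aq, n = 0.3, 100_000
        train = DropletTrain(frequency=10 * np.sqrt(2), p_aq=p_aq)
        df = simulate_injection(train, SINGLE_PULSE_10MS, 0.0, n, seed=5)
        frac = (df["phase_label"] == "aqueous").mean()
        assert abs(frac - p_aq) <= 3 * np.sqrt(p_aq * (1 - p_aq) / n)

    def test_poisson_mean_identity(self):
        # total hits ~ n_aqueous_pulses * mean_hit, within 3 sigma
        mean_hit = 0.4
        train = DropletTrain(frequency=10 * np.sqrt(2), p_aq=0.3)
        df = simulate_injection(train, SINGLE_PULSE_10MS, mean_hit, 50_000, seed=6)
        n_aq = int((df["phase_label"] == "aqueous").sum())
        expected = n_aq * mean_hit
        assert abs(df["hit"].sum() - expected) <= 3 * np.sqrt(expected)

    def test_boundary_classification_window(self):
        train = DropletTrain(
            frequency=10.0, p_aq=0.3, phase=0.0, interface_window=1e-3
        )
        sched = PulseSchedule(train_period=0.0101, pulses_per_train=1)
        df = simulate_injection(train, sched, 0.0, 5000, seed=7)
        counts = df["phase_label"].value_counts()
        assert counts.get("boundary", 0) > 0
        # boundary zone is 2 windows per interface, 2 interfaces per period
        expected_boundary_frac = 4 * 1e-3 / 0.1
        assert counts["boundary"] / len(df) == pytest.approx(expected_boundary_frac, rel=0.3)

    def test_jittered_timeline_keeps_duty(self):
        train = DropletTrain(frequency=10.0, p_aq=0.3, period_jitter_cv=0.1)
        df = simulate_injection(train, SINGLE_PULSE_10MS, 0.0, 5000, seed=8)
        frac = (df["phase_label"] == "aqueous").mean()
        assert frac == pytest.approx(0.3, abs=0.05)

    def test_per_pulse_id_hit_flatness(self, euxfel):
        # plug flow has no within-train structure: recorded hits per pulse id
        # are uniform; chi-square flatness not rejected at alpha = 0.01
        train = DropletTrain(frequency=10 * np.sqrt(2), p_aq=0.3)
        df = simulate_injection(train, euxfel, 0.5, 2000, seed=3)
        s = summarize_run(df, q_aq=ul_min_to_m3_s(4.2), duration=200.0)
        h = s.per_pulse_id_hits.to_numpy(dtype=float)
        chi2 = ((h - h.mean()) ** 2 / h.mean()).sum()
        assert stats.chi2.sf(chi2, len(h) - 1) > 0.01


class TestSynchronizedMode:
    def test_full_coverage_with_spanning_plug(self, euxfel):
        train = DropletTrain(frequency=10.0, p_aq=0.005)  # 500 µs plug at 10 Hz
        sync = synchronized_mode(train, euxfel)
        assert sync.frequency == pytest.approx(euxfel.train_rate)
        assert SYNC_PLUG_TOO_SHORT not in sync.flags
        df = simulate_injection(sync, euxfel, 0.5, 200, seed=9)
        rec = df[df["recorded"]]
        assert (rec["phase_label"] == "aqueous").all()

    def test_short_plug_flagged(self, euxfel):
        train = DropletTrain(frequency=10.0, p_aq=1e-4)  # 10 µs plug < 27.6 µs span
        sync = synchronized_mode(train, euxfel)
        assert SYNC_PLUG_TOO_SHORT in sync.flags

    def test_single_pulse_facility_always_covered(self):
        train = DropletTrain(frequency=120.0, p_aq=0.05)
        sync = synchronized_mode(train, PulseSchedule(train_period=1 / 120, pulses_per_train=1))
        df = simulate_injection(sync, PulseSchedule(train_period=1 / 120, pulses_per_train=1),
                                0.0, 1000, seed=10)
        assert (df["phase_label"] == "aqueous").all()

    def test_synchronized_beats_unsynchronized_per_microlitre(self, euxfel):
        # same aqueous flow; phase-locking concentrates hits on recorded pulses
        q_aq, duration = ul_min_to_m3_s(4.2), 100.0
        unsync = DropletTrain(frequency=10 * np.sqrt(2), p_aq=0.1)
        sync = synchronized_mode(DropletTrain(frequency=10.0, p_aq=0.005), euxfel)
        s_un = summarize_run(
            simulate_injection(unsync, euxfel, 0.5, 1000, seed=11), q_aq, duration
        )
        s_sy = summarize_run(
            simulate_injection(sync, euxfel, 0.5, 1000, seed=11), q_aq, duration
        )
        assert s_sy.hits_per_ul > s_un.hits_per_ul


class TestSummarizeRun:
    def test_all_zero_hits(self):
        train = DropletTrain(frequency=10.0, p_aq=0.5)
        df = simulate_injection(train, SINGLE_PULSE_10MS, 0.0, 100, seed=1)
        s = summarize_run(df, q_aq=ul_min_to_m3_s(4.2), duration=1.0)
        assert s.total_hits == 0 and s.hits_per_ul == 0.0

    def test_totals_consistent_with_outcomes(self, euxfel):
        train = DropletTrain(frequency=10 * np.sqrt(2), p_aq=0.3)
        df = simulate_injection(train, euxfel, 0.5, 100, seed=2)
        s = summarize_run(df, q_aq=ul_min_to_m3_s(4.2), duration=10.0)
        assert s.n_pulses == len(df)
        assert s.n_recorded == int(df["recorded"].sum())
        assert s.total_hits == int(df.loc[df["recorded"], "hit"].sum())
        assert s.total_hits_all_pulses == int(df["hit"].sum())
        assert s.per_pulse_id_hits.sum() == s.total_hits

    def test_hits_per_microlitre_division(self):
        # 735 hits from 110 µL is 6.68 hits/µL
        train = DropletTrain(frequency=10.0, p_aq=1.0)
        df = simulate_injection(train, SINGLE_PULSE_10MS, 0.0, 10, seed=1)
        df.loc[:, "hit"] = 0
        df.iloc[0, df.columns.get_loc("hit")] = 735
        # 110 µL over the duration: pick q_aq * duration = 110 µL
        s = summarize_run(df, q_aq=110e-9 / 60.0, duration=60.0)
        assert s.volume_ul == pytest.approx(110.0)
        assert s.hits_per_ul == pytest.approx(735 / 110, rel=1e-12)
        assert s.hits_per_ul == pytest.approx(6.68, abs=0.005)

    def test_empty_outcomes_rejected(self):
        with pytest.raises(InvalidInputError):
            summarize_run(pd.DataFrame(columns=["hit"]), 1e-10, 1.0)


class TestConsumptionReport:
    ROWS = [
        ("continuous", 26.0, 260.0, 577),
        ("segmented-subset", 26.0, 110.0, 735),
        ("segmented-all", 134.0, 962.0, 5770),
    ]

    def test_observed_campaign_rates(self):
        rep = consumption_report(self.ROWS, "continuous")
        t = rep.table
        assert round(t.loc["continuous", "hits_per_ul"], 1) == 2.2
        assert round(t.loc["segmented-all", "hits_per_ul"], 1) == 6.0
        assert round(t.loc["segmented-subset", "hits_per_ul"], 1) == 6.7

    def test_fold_change_and_reduction(self):
        rep = consumption_report(self.ROWS, "continuous")
        t = rep.table
        assert round(t.loc["segmented-subset", "fold_change"]) == 3
        # ~60% volume reduction at the nearest ten percent
        assert round(t.loc["segmented-subset", "percent_reduction"], -1) == 60
        assert t.loc["segmented-subset", "q_aq_ul_min"] == pytest.approx(4.2, abs=0.05)

    def test_reference_against_itself(self):
        rep = consumption_report(self.ROWS, "continuous")
        assert rep.table.loc["continuous", "fold_change"] == pytest.approx(1.0)
        assert rep.table.loc["continuous", "percent_reduction"] == pytest.approx(0.0)

    def test_missing_reference(self):
        with pytest.raises(InvalidInputError):
            consumption_report(self.ROWS, "no-such-label")

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(InvalidInputError):
            consumption_report([("bad", 10.0, 0.0, 5)], "bad")


class TestHitRate:
    def test_campaign_hit_rate(self):
        assert hit_rate_percent(37_000, 4_100_000) == pytest.approx(0.9, abs=0.005)

    def test_bounds(self):
        with pytest.raises(Exception):
            hit_rate_percent(5, 0)
        with pytest.raises(Exception):
            hit_rate_percent(10, 5)
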