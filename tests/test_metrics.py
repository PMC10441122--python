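import numpy as np
import pandas as pd
import pytest

from mearf import PhaseProtocol, ScenarioConfig, SpikeTrainSet, generate_scenario
from mearf.burst_analysis import BurstTrain, ElectrodeBursts, detect_bursts
from mearf.metrics import (
    UnusableCultureError,
    active_electrodes,
    combine_cultures,
    compute_phase_metrics,
    electrode_phase_rates,
    mbr_timecourse,
    normalize_metrics,
)
from mearf.pipeline import analyze_culture, culture_seeds


def _empty_bursts(spikes):
    return BurstTrain(
        electrodes={
            el: ElectrodeBursts(
                starts=np.empty(0), ends=np.empty(0),
                counts=np.empty(0, dtype=int), threshold_s=None,
                in_burst=np.zeros(len(spikes.trains[el]), dtype=bool),
            )
            for el in spikes.electrode_ids
        }
    )


def _regular_train(rate_hz, duration, phase_offset=0.0):
    n = int(rate_hz * duration)
    return phase_offset + (np.arange(n) + 0.5) / rate_hz


class TestActiveElectrodes:
    def _rates(self, fr_by_el, br_by_el=None):
        rows = []
        for el, fr in fr_by_el.items():
            br = (br_by_el or {}).get(el, 0.0)
            rows.append((el, "S1", fr, br * 60.0, np.nan, fr))
        return pd.DataFrame(
            rows,
            columns=["electrode", "phase", "fr_hz", "br_per_min", "mean_bd_s", "obfr_hz"],
        )

    def test_boundary_is_inclusive(self):
        rates = self._rates({0: 0.1, 1: 0.0999, 2: 0.05})
        assert active_electrodes(rates, "spiking") == {0}

    def test_bursting_threshold_is_0p04_hz(self):
        rates = self._rates({0: 1, 1: 1}, {0: 0.04, 1: 0.039})
        assert active_electrodes(rates, "bursting") == {0}

    def test_counting_excluded_electrodes(self):
        fr = {el: 1.0 for el in range(50)} | {el: 0.05 for el in range(50, 60)}
        assert len(active_electrodes(self._rates(fr), "spiking")) == 50


class TestPhaseMetrics:
    def test_mfr_excludes_inactive_from_sum_and_count(self, short_protocol):
        """Electrodes at 1, 0.5 and 0.05 Hz: MFR = (1+0.5)/2 = 0.75 Hz."""
        dur = short_protocol.total_duration_s
        spikes = SpikeTrainSet(
            trains={
                0: _regular_train(1.0, dur),
                1: _regular_train(0.5, dur),
                2: _regular_train(0.05, dur),
            },
            duration_s=dur,
        )
        # give electrode 0 a token bursting record so the culture is usable;
        # MFR counts spikes by time, so burst bookkeeping cannot affect it
        bursts = _empty_bursts(spikes)
        starts = np.arange(0.0, dur, 10.0)
        bursts.electrodes[0].starts = starts
        bursts.electrodes[0].ends = starts + 0.05
        bursts.electrodes[0].counts = np.full(len(starts), 3)
        table = compute_phase_metrics(spikes, bursts, short_protocol)
        mfr = table[(table.metric == "mfr") & (table.phase == "S1")].value.iloc[0]
        assert mfr == pytest.approx(0.75, rel=1e-6)
        assert table.n_active_spiking.iloc[0] == 2

    def test_mbr_from_burst_counts(self, short_protocol):
        """36 bursts per 900 s on every active electrode -> 2.4 bursts/min."""
        proto = PhaseProtocol(durations_s=(900.0,) * 5)
        trains, ebs = {}, {}
        for el in range(3):
            motifs = []
            for ph in range(5):
                base = 900.0 * ph
                motifs.extend(base + np.arange(36) * 24.0 + np.array([0.0]))
            onsets = np.array(motifs)
            t = np.sort(
                np.concatenate([onsets + k * 0.01 for k in range(5)])
            )
            trains[el] = t
            ebs[el] = detect_bursts(t, threshold_s=0.1, min_spikes=3)
        spikes = SpikeTrainSet(trains=trains, duration_s=proto.total_duration_s)
        table = compute_phase_metrics(spikes, BurstTrain(electrodes=ebs), proto)
        mbr = table[(table.metric == "mbr")].set_index("phase").value
        assert mbr["S1"] == pytest.approx(2.4)
        assert mbr["P2"] == pytest.approx(2.4)

    def test_unusable_culture_raises(self, short_protocol):
        dur = short_protocol.total_duration_s
        spikes = SpikeTrainSet(
            trains={0: _regular_train(0.01, dur)}, duration_s=dur
        )
        with pytest.raises(UnusableCultureError):
            compute_phase_metrics(spikes, _empty_bursts(spikes), short_protocol)

    def test_conservation_fr_equals_inburst_plus_obfr(self, analyzed_sham, protocol):
        dataset, bursts, _, _ = analyzed_sham
        rates = electrode_phase_rates(dataset.spike_trains, bursts, protocol)
        assert (rates.fr_hz + 1e-12 >= rates.obfr_hz).all()
        for el in dataset.spike_trains.electrode_ids:
            t = dataset.spike_trains.trains[el]
            in_burst = bursts[el].in_burst
            for i, lb in enumerate(protocol.labels):
                a, b = protocol.bounds_of(lb)
                sel = (t >= a) & (t < b)
                row = rates[(rates.electrode == el) & (rates.phase == lb)].iloc[0]
                n_in = int((sel & in_burst).sum())
                dur = protocol.duration_of(lb)
                assert row.fr_hz * dur == pytest.approx(n_in + row.obfr_hz * dur)

    def test_active_sets_frozen_at_baseline(self, protocol):
        """Suppression later in the run must not change the denominators."""
        cfg = ScenarioConfig.exposure_like(0.3)
        ds = generate_scenario(cfg, protocol, seed=21)
        _, table, _ = analyze_culture(ds.spike_trains, protocol)
        assert table.n_active_spiking.nunique() == 1
        assert table.n_active_bursting.nunique() == 1

    def test_mbd_denominator_switch(self, analyzed_sham, protocol):
        dataset, bursts, _, _ = analyzed_sham
        t_s1 = compute_phase_metrics(
            dataset.spike_trains, bursts, protocol, mbd_denominator="s1"
        )
        t_pp = compute_phase_metrics(
            dataset.spike_trains, bursts, protocol, mbd_denominator="per_phase"
        )
        mbd_s1 = t_s1[t_s1.metric == "mbd"].value
        mbd_pp = t_pp[t_pp.metric == "mbd"].value
        assert (mbd_s1 <= mbd_pp + 1e-12).all()  # N_B(S1) >= per-phase count


class TestNormalization:
    def _table(self):
        rows = []
        for culture, scale in [(0, 1.0), (1, 2.0)]:
            for phase, v in [("S1", 1.0), ("S2", 1.1), ("E", 0.6), ("P1", 1.0), ("P2", 0.9)]:
                rows.append((culture, phase, "mfr", scale * v, 5, 5))
        return pd.DataFrame(
            rows,
            columns=["culture", "phase", "metric", "value", "n_active_spiking", "n_active_bursting"],
        )

    def test_baseline_is_exactly_100(self):
        norm = normalize_metrics(self._table())
        s1 = norm[norm.phase == "S1"].normalized_pct
        assert (s1 == 100.0).all()

    def test_ratio_to_baseline(self):
        norm = normalize_metrics(self._table())
        e = norm[norm.phase == "E"].normalized_pct
        np.testing.assert_allclose(e, 60.0)

    def test_idempotence(self):
        once = normalize_metrics(self._table())
        twice = normalize_metrics(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_zero_baseline_excluded(self, caplog):
        table = self._table()
        table.loc[(table.culture == 0) & (table.phase == "S1"), "value"] = 0.0
        norm = normalize_metrics(table)
        assert norm[norm.culture == 0].normalized_pct.isna().all()
        assert norm[norm.culture == 1].normalized_pct.notna().all()


class TestMbrTimecourse:
    def test_series_length_is_protocol_minutes(self, analyzed_sham, protocol):
        dataset, bursts, _, _ = analyzed_sham
        tc = mbr_timecourse([(dataset.spike_trains, bursts)], protocol)
        assert len(tc) == 75

    def test_step_suppression_visible_in_exposure_minutes(self, protocol):
        cfg = ScenarioConfig.exposure_like(0.5)
        per_culture = []
        for s in culture_seeds(2, 4):
            ds = generate_scenario(cfg, protocol, seed=s)
            bursts, _, _ = analyze_culture(ds.spike_trains, protocol)
            per_culture.append((ds.spike_trains, bursts))
        tc = mbr_timecourse(per_culture, protocol)
        a, b = protocol.bounds_of("E")
        in_e = (tc.t_center_s >= a) & (tc.t_center_s < b)
        assert tc.mean_pct[in_e].mean() == pytest.approx(50.0, abs=10.0)
        assert tc.mean_pct[~in_e].mean() == pytest.approx(100.0, abs=10.0)

    def test_stationary_sham_has_no_trend(self, protocol):
        per_culture = []
        for s in culture_seeds(4, 6):
            ds = generate_scenario(ScenarioConfig(), protocol, seed=s)
            bursts, _, _ = analyze_culture(ds.spike_trains, protocol)
            per_culture.append((ds.spike_trains, bursts))
        tc = mbr_timecourse(per_culture, protocol)
        from scipy import stats as sps

        res = sps.linregress(tc.t_center_s, tc.mean_pct)
        ci = 1.96 * res.stderr
        assert res.slope - ci <= 0.0 <= res.slope + ci

    def test_bin_must_divide_protocol(self, analyzed_sham, protocol):
        dataset, bursts, _, _ = analyzed_sham
        with pytest.raises(ValueError):
            mbr_timecourse([(dataset.spike_trains, bursts)], protocol, bin_s=47.0)
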