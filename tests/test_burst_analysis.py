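import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mearf.burst_analysis import (
    ElectrodeBursts,
    detect_bursts,
    detect_bursts_adaptive,
    detect_network_bursts,
    interval_threshold,
    logisi_threshold,
)


def brute_force_valley(intervals_s, bin_width=0.1, max_ms=100.0, smooth=3):
    """Independent oracle: rebuild the smoothed log-histogram and scan it."""
    log_ms = np.log10(np.asarray(intervals_s) * 1000.0)
    lo = np.floor(log_ms.min() / bin_width) * bin_width
    hi = np.ceil(log_ms.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    hist, _ = np.histogram(log_ms, bins=edges)
    sm = np.convolve(hist, np.ones(smooth) / smooth, mode="same")
    centers = (edges[:-1] + edges[1:]) / 2
    peaks = [
        i
        for i in range(1, len(sm) - 1)
        if sm[i] > sm[i - 1] and sm[i] >= sm[i + 1]
    ]
    below = [i for i in peaks if centers[i] < np.log10(max_ms)]
    p1 = max(below, key=lambda i: sm[i])
    later = [i for i in peaks if i > p1]
    p2 = max(later, key=lambda i: sm[i])
    valley = p1 + int(np.argmin(sm[p1 : p2 + 1]))
    return 10 ** centers[valley] / 1000.0


class TestLogisiThreshold:
    def test_bimodal_mixture_threshold_sits_in_the_valley(self):
        rng = np.random.default_rng(0)
        isis = np.concatenate(
            [
                10 ** rng.normal(1.0, 0.15, 500) / 1000.0,  # ~10 ms
                10 ** rng.normal(3.3, 0.15, 500) / 1000.0,  # ~2000 ms
            ]
        )
        rng.shuffle(isis)
        times = np.concatenate([[0.0], np.cumsum(isis)])
        thr = logisi_threshold(times)
        assert 0.010 < thr < 2.0
        # within one histogram bin (0.1 log10 units) of the brute-force valley
        oracle = brute_force_valley(isis)
        assert abs(np.log10(thr) - np.log10(oracle)) <= 0.1 + 1e-9

    def test_unimodal_slow_train_falls_back_to_100_ms(self):
        rng = np.random.default_rng(1)
        times = np.cumsum(rng.normal(1.0, 0.05, 200))
        assert logisi_threshold(times) == pytest.approx(0.1)

    def test_log_domain_equivariance(self):
        rng = np.random.default_rng(2)
        isis = np.concatenate(
            [
                10 ** rng.normal(0.8, 0.1, 400) / 1000.0,
                10 ** rng.normal(3.0, 0.1, 400) / 1000.0,
            ]
        )
        times = np.concatenate([[0.0], np.cumsum(isis)])
        thr = logisi_threshold(times, max_threshold_ms=100.0)
        thr10 = logisi_threshold(times * 10.0, max_threshold_ms=1000.0)
        assert np.log10(thr10 / thr) == pytest.approx(1.0, abs=0.1)

    def test_too_few_isis_gives_none(self):
        assert logisi_threshold(np.arange(5, dtype=float)) is None


class TestDetectBursts:
    def test_slow_regular_train_has_no_bursts(self):
        eb = detect_bursts(np.arange(0, 100, 1.0), threshold_s=0.1)
        assert eb.n_bursts == 0
        assert not eb.in_burst.any()

    def test_burst_motifs_forced_by_definition(self):
        """5 spikes at 10 ms ISI every 5 s: one burst per motif, BD 40 ms."""
        motif = np.arange(5) * 0.010
        times = np.concatenate([motif + 5.0 * k for k in range(20)])
        eb = detect_bursts(times, threshold_s=0.1, min_spikes=3)
        assert eb.n_bursts == 20
        np.testing.assert_allclose(eb.durations, 0.040)
        np.testing.assert_array_equal(eb.counts, 5)
        assert eb.in_burst.all()

    def test_min_spikes_excludes_short_runs(self):
        times = np.array([0.0, 0.01, 5.0, 5.01, 5.02, 5.03])
        eb = detect_bursts(times, threshold_s=0.1, min_spikes=3)
        assert eb.n_bursts == 1
        assert eb.counts.tolist() == [4]
        assert eb.in_burst.tolist() == [False, False, True, True, True, True]

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=1e-4, max_value=2.0), min_size=2, max_size=300
        ),
        st.floats(min_value=0.005, max_value=0.5),
    )
    def test_conservation_and_internal_isi_bound(self, isis, threshold):
        """In-burst + outside-burst spikes always sum to the total; every
        internal ISI of a burst is below threshold; bursts are disjoint."""
        times = np.cumsum(np.asarray(isis))
        eb = detect_bursts(times, threshold_s=threshold, min_spikes=3)
        n_in = int(eb.counts.sum())
        assert n_in == int(eb.in_burst.sum())
        assert n_in + int((~eb.in_burst).sum()) == len(times)
        assert np.all(eb.starts[1:] >= eb.ends[:-1])  # disjoint, ordered
        for a, b in zip(eb.starts, eb.ends):
            inside = times[(times >= a) & (times <= b)]
            assert np.all(np.diff(inside) <= threshold + 1e-12)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        times = np.cumsum(rng.exponential(0.05, 500))
        counts = [
            int(detect_bursts(times, thr, 3).in_burst.sum())
            for thr in (0.01, 0.03, 0.1, 0.3, 1.0)
        ]
        assert counts == sorted(counts)

    def test_ground_truth_bursts_recovered(self, sham_dataset, protocol):
        """>= 90% of injected bursts matched with Jaccard overlap >= 0.5."""
        bursts = detect_bursts_adaptive(sham_dataset.spike_trains)
        gt = sham_dataset.ground_truth
        matched = total = 0
        for el, iv in gt.burst_intervals.items():
            det = bursts[el]
            for start, end, _ in iv:
                total += 1
                if det.n_bursts == 0:
                    continue
                inter = np.minimum(det.ends, end) - np.maximum(det.starts, start)
                union = np.maximum(det.ends, end) - np.minimum(det.starts, start)
                with np.errstate(divide="ignore", invalid="ignore"):
                    jac = np.where(union > 0, inter / union, inter >= 0)
                if np.any(jac >= 0.5):
                    matched += 1
        assert matched / total >= 0.90


class TestNetworkBursts:
    def _bursts_from_onsets(self, onsets_by_el, width=0.03):
        return {
            el: ElectrodeBursts(
                starts=np.asarray(v, dtype=float),
                ends=np.asarray(v, dtype=float) + width,
                counts=np.full(len(v), 5),
                threshold_s=0.1,
                in_burst=np.ones(5 * len(v), dtype=bool),
            )
            for el, v in onsets_by_el.items()
        }

    def test_co_onset_groups_become_network_bursts(self):
        from mearf.burst_analysis import BurstTrain

        events = np.arange(0, 200, 10.0)
        onsets = {el: events + 0.01 * el for el in range(5)}
        onsets.update({el: [] for el in range(5, 10)})
        bt = BurstTrain(electrodes=self._bursts_from_onsets(onsets))
        nb = detect_network_bursts(bt, active_set=set(range(10)))
        assert len(nb) == len(events)
        assert all(b.fraction == pytest.approx(0.5) for b in nb)
        assert all(len(b.electrodes) == 5 for b in nb)

    def test_single_bursting_electrode_is_not_a_network_burst(self):
        from mearf.burst_analysis import BurstTrain

        onsets = {0: np.arange(0, 100, 5.0)}
        onsets.update({el: [] for el in range(1, 10)})
        bt = BurstTrain(electrodes=self._bursts_from_onsets(onsets))
        assert detect_network_bursts(bt, active_set=set(range(10))) == []

    def test_empty_active_set_rejected(self):
        from mearf.burst_analysis import BurstTrain

        with pytest.raises(ValueError):
            detect_network_bursts(BurstTrain(), active_set=set())

    def test_generator_events_recovered(self, analyzed_sham, protocol):
        """>= 90% of injected network events match a detected network burst."""
        dataset, bursts, table, network = analyzed_sham
        events = dataset.ground_truth.event_times
        starts = np.array([b.start_s for b in network])
        ends = np.array([b.end_s for b in network])
        hit = 0
        for ev in events:
            if np.any((starts - 0.1 <= ev) & (ev <= ends + 0.1)):
                hit += 1
        assert hit / len(events) >= 0.90


def test_interval_threshold_requires_positive_bin():
    with pytest.raises(ValueError):
        interval_threshold(np.ones(50), bin_width=0.0)
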