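"""Adaptive burst detection and network-burst detection.

Per-electrode bursts are found with the logarithmic-ISI-histogram method:
the histogram of log10(ISI) is smoothed, and when it shows a fast
(intra-burst) peak below a cutoff (default 100 ms) followed by a slower
peak, the ISI at the valley between them becomes the electrode's burst
threshold; otherwise a fixed fallback threshold is used.  Maximal runs of
consecutive spikes whose ISIs stay at or below the threshold, with at least
``min_spikes`` spikes, are bursts; every other spike is an outside-burst
spike, so in-burst and outside-burst spike counts always sum to the total.

Network bursts are found by the analogous procedure on the pooled
per-electrode burst onsets: an adaptive inter-onset threshold groups onsets
into candidate network events, and events recruiting at least a minimum
fraction (default 20%) of the active electrodes are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("mearf")

DEFAULT_BIN_WIDTH_LOG10MS = 0.1
DEFAULT_MAX_INTRA_ISI_MS = 100.0
DEFAULT_SMOOTH_BINS = 3
DEFAULT_MIN_SPIKES = 3
DEFAULT_MIN_FRACTION = 0.2
MIN_ISIS_FOR_HISTOGRAM = 10


@dataclass
class ElectrodeBursts:
    """Bursts of one electrode plus the per-spike classification."""

    starts: np.ndarray
    ends: np.ndarray
    counts: np.ndarray
    threshold_s: float | None
    in_burst: np.ndarray  #: boolean mask over the electrode's spikes

    @property
    def n_bursts(self) -> int:
        return len(self.starts)

    @property
    def durations(self) -> np.ndarray:
        return self.ends - self.starts


@dataclass
class BurstTrain:
    """Per-electrode burst trains over one recording."""

    electrodes: dict = field(default_factory=dict)  #: id -> ElectrodeBursts

    def __getitem__(self, el) -> ElectrodeBursts:
        return self.electrodes[el]

    def __contains__(self, el) -> bool:
        return el in self.electrodes

    @property
    def electrode_ids(self) -> list:
        return sorted(self.electrodes)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for el in self.electrode_ids:
            eb = self.electrodes[el]
            for s, e, c in zip(eb.starts, eb.ends, eb.counts):
                rows.append((el, s, e, int(c)))
        return pd.DataFrame(rows, columns=["electrode_id", "start_s", "end_s", "n_spikes"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class NetworkBurst:
    start_s: float
    end_s: float
    electrodes: frozenset
    fraction: float


# ---------------------------------------------------------------------------
# adaptive threshold (logISI valley)
# ---------------------------------------------------------------------------

def _smooth(y: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return y.astype(float)
    kernel = np.ones(width) / width
    return np.convolve(y, kernel, mode="same")


def _peak_indices(y: np.ndarray) -> np.ndarray:
    """Local maxima; for plateaus the leftmost bin wins (deterministic)."""
    n = len(y)
    if n < 3:
        return np.empty(0, dtype=int)
    peaks = []
    i = 1
    while i < n - 1:
        if y[i] > y[i - 1]:
            j = i
            while j < n - 1 and y[j + 1] == y[j]:
                j += 1
            if j < n - 1 and y[j + 1] < y[j]:
                peaks.append(i)
            i = j + 1
        else:
            i += 1
    return np.asarray(peaks, dtype=int)


def interval_threshold(
    intervals_s: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH_LOG10MS,
    max_threshold_ms: float = DEFAULT_MAX_INTRA_ISI_MS,
    smooth_bins: int = DEFAULT_SMOOTH_BINS,
) -> float | None:
    """Adaptive threshold from the log10 histogram of intervals.

    Builds the histogram of ``log10(interval in ms)`` at the stated bin
    width, smooths it with a moving average, and when a peak below
    ``max_threshold_ms`` is followed by a later peak, returns the interval
    (seconds) at the leftmost minimum between them.  Otherwise returns the
    fallback ``min(max_threshold_ms, 100 ms)``.  ``None`` when there are too
    few intervals to build a meaningful histogram.
    """
    intervals_s = np.asarray(intervals_s, dtype=float)
    intervals_s = intervals_s[intervals_s > 0]
    if len(intervals_s) < MIN_ISIS_FOR_HISTOGRAM:
        return None
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    fallback = min(max_threshold_ms, 100.0) / 1000.0
    log_ms = np.log10(intervals_s * 1000.0)
    lo = np.floor(log_ms.min() / bin_width) * bin_width
    hi = np.ceil(log_ms.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if len(edges) < 4:
        return fallback
    hist, edges = np.histogram(log_ms, bins=edges)
    smoothed = _smooth(hist, smooth_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    peaks = _peak_indices(smoothed)
    intra = peaks[centers[peaks] < np.log10(max_threshold_ms)]
    if len(intra) == 0:
        return fallback
    # the intra-burst peak: largest peak below the cutoff (leftmost on ties)
    p1 = int(intra[np.argmax(smoothed[intra])])
    later = peaks[peaks > p1]
    if len(later) == 0:
        return fallback
    # the slow (inter-burst) peak: largest of the later peaks
    p2 = int(later[np.argmax(smoothed[later])])
    valley_rel = int(np.argmin(smoothed[p1 : p2 + 1]))
    valley = p1 + valley_rel
    return float(10 ** centers[valley] / 1000.0)


def logisi_threshold(
    spike_times: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH_LOG10MS,
    max_threshold_ms: float = DEFAULT_MAX_INTRA_ISI_MS,
    smooth_bins: int = DEFAULT_SMOOTH_BINS,
) -> float | None:
    """Adaptive ISI threshold (seconds) for one electrode's spike train."""
    spike_times = np.asarray(spike_times, dtype=float)
    if len(spike_times) < MIN_ISIS_FOR_HISTOGRAM + 1:
        return None
    return interval_threshold(
        np.diff(spike_times), bin_width, max_threshold_ms, smooth_bins
    )


# ---------------------------------------------------------------------------
# burst extraction
# ---------------------------------------------------------------------------

def detect_bursts(
    spike_times: np.ndarray,
    threshold_s: float,
    min_spikes: int = DEFAULT_MIN_SPIKES,
) -> ElectrodeBursts:
    """Maximal runs of spikes with ISI <= threshold and >= min_spikes spikes."""
    if threshold_s <= 0:
        raise ValueError("threshold must be positive")
    if min_spikes < 2:
        raise ValueError("min_spikes must be at least 2")
    t = np.asarray(spike_times, dtype=float)
    in_burst = np.zeros(len(t), dtype=bool)
    if len(t) < min_spikes:
        return ElectrodeBursts(
            starts=np.empty(0), ends=np.empty(0),
            counts=np.empty(0, dtype=int), threshold_s=threshold_s,
            in_burst=in_burst,
        )
    close = (np.diff(t) <= threshold_s).astype(np.int8)
    padded = np.concatenate(([0], close, [0]))
    flips = np.flatnonzero(np.diff(padded))
    run_starts, run_ends = flips[::2], flips[1::2]  # ISI runs [start, end)
    n_spk = run_ends - run_starts + 1
    ok = n_spk >= min_spikes
    run_starts, run_ends, n_spk = run_starts[ok], run_ends[ok], n_spk[ok]
    for a, b in zip(run_starts, run_ends):
        in_burst[a : b + 1] = True
    return ElectrodeBursts(
        starts=t[run_starts],
        ends=t[run_ends],
        counts=n_spk.astype(int),
        threshold_s=threshold_s,
        in_burst=in_burst,
    )


def detect_bursts_adaptive(
    spikes,
    bin_width: float = DEFAULT_BIN_WIDTH_LOG10MS,
    max_threshold_ms: float = DEFAULT_MAX_INTRA_ISI_MS,
    smooth_bins: int = DEFAULT_SMOOTH_BINS,
    min_spikes: int = DEFAULT_MIN_SPIKES,
) -> BurstTrain:
    """Per-electrode logISI threshold + burst extraction over a SpikeTrainSet."""
    out = {}
    for el in spikes.electrode_ids:
        t = spikes.trains[el]
        thr = logisi_threshold(t, bin_width, max_threshold_ms, smooth_bins)
        if thr is None:
            out[el] = ElectrodeBursts(
                starts=np.empty(0), ends=np.empty(0),
                counts=np.empty(0, dtype=int), threshold_s=None,
                in_burst=np.zeros(len(t), dtype=bool),
            )
        else:
            out[el] = detect_bursts(t, thr, min_spikes)
    return BurstTrain(electrodes=out)


# ---------------------------------------------------------------------------
# network bursts
# ---------------------------------------------------------------------------

def detect_network_bursts(
    bursts: BurstTrain,
    active_set,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    bin_width: float = DEFAULT_BIN_WIDTH_LOG10MS,
    max_threshold_ms: float = DEFAULT_MAX_INTRA_ISI_MS,
    smooth_bins: int = DEFAULT_SMOOTH_BINS,
) -> list[NetworkBurst]:
    """Group pooled burst onsets into network bursts.

    The pooled onsets of all electrodes in ``active_set`` are clustered by
    the same adaptive valley threshold applied to their inter-onset
    intervals; a cluster whose distinct-electrode fraction (relative to
    ``active_set``) reaches ``min_fraction`` is a network burst spanning
    from the earliest member burst start to the latest member burst end.
    """
    active = sorted(active_set)
    if not active:
        raise ValueError("active_set must be non-empty")
    onsets, offs, els = [], [], []
    for el in active:
        if el not in bursts:
            continue
        eb = bursts[el]
        onsets.append(eb.starts)
        offs.append(eb.ends)
        els.append(np.full(eb.n_bursts, el, dtype=object))
    if not onsets:
        return []
    onsets = np.concatenate(onsets)
    if len(onsets) == 0:
        return []
    offs = np.concatenate(offs)
    els = np.concatenate(els)
    order = np.argsort(onsets, kind="stable")
    onsets, offs, els = onsets[order], offs[order], els[order]

    gaps = np.diff(onsets)
    thr = interval_threshold(gaps, bin_width, max_threshold_ms, smooth_bins)
    if thr is None:
        thr = min(max_threshold_ms, 100.0) / 1000.0
    breaks = np.flatnonzero(gaps > thr) + 1
    groups = np.split(np.arange(len(onsets)), breaks)
    out = []
    n_active = len(active)
    for g in groups:
        members = set(els[g].tolist())
        frac = len(members) / n_active
        if frac >= min_fraction:
            out.append(
                NetworkBurst(
                    start_s=float(onsets[g].min()),
                    end_s=float(offs[g].max()),
                    electrodes=frozenset(members),
                    fraction=frac,
                )
            )
    return out
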