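"""Peak-to-peak threshold spike detection on raw multichannel recordings.

A spike is declared on a channel when the peak-to-peak excursion of the
signal within a short sliding window (default 2 ms) exceeds a multiple
(default 8x) of that channel's biological-noise standard deviation, with the
noise SD estimated robustly over a reference window (by default the first
baseline phase).  The spike is timestamped at the negative peak of the
qualifying excursion, and candidate events closer than a refractory period
are merged into one.

Containers
----------
:class:`RawRecording` holds a channels x samples voltage matrix in microvolts
with its sampling rate; :class:`SpikeTrainSet` holds per-electrode sorted
spike times in seconds and is the exchange object consumed by the burst and
metrics stages.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d

logger = logging.getLogger("mearf")

#: multiplier converting a median absolute deviation to a Gaussian SD
MAD_TO_SD = 1.4826

DEFAULT_THRESHOLD_FACTOR = 8.0
DEFAULT_WINDOW_MS = 2.0
DEFAULT_REFRACTORY_MS = 1.0


@dataclass
class RawRecording:
    """Multichannel extracellular voltage recording.

    ``samples`` is a (n_channels, n_samples) float array in microvolts;
    ``fs`` the per-channel sampling rate in Hz (default 10 kHz); ``t0`` the
    recording start time in seconds.
    """

    samples: np.ndarray
    fs: float = 10_000.0
    t0: float = 0.0
    channel_ids: tuple = ()

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.channel_ids:
            self.channel_ids = tuple(range(self.samples.shape[0]))
        elif len(self.channel_ids) != self.samples.shape[0]:
            raise ValueError("channel_ids length mismatch")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("waveforms", data=self.samples.astype(np.float32))
            ds.attrs["fs"] = self.fs
            ds.attrs["t0"] = self.t0
            fh.create_dataset(
                "channel_ids", data=np.asarray(self.channel_ids, dtype=np.int64)
            )

    @classmethod
    def from_hdf5(cls, path) -> "RawRecording":
        with h5py.File(path, "r") as fh:
            ds = fh["waveforms"]
            return cls(
                samples=ds[...].astype(float),
                fs=float(ds.attrs["fs"]),
                t0=float(ds.attrs.get("t0", 0.0)),
                channel_ids=tuple(int(c) for c in fh["channel_ids"][...]),
            )

    @classmethod
    def from_binary(cls, path, sidecar) -> "RawRecording":
        """Read a flat binary matrix with a JSON sidecar.

        The sidecar declares ``n_channels``, ``fs``, ``dtype`` and
        ``scale_uv_per_lsb`` (microvolts per integer step).
        """
        with open(sidecar) as fh:
            meta = json.load(fh)
        raw = np.fromfile(path, dtype=np.dtype(meta["dtype"]))
        n_ch = int(meta["n_channels"])
        raw = raw.reshape(n_ch, -1).astype(float) * float(
            meta.get("scale_uv_per_lsb", 1.0)
        )
        return cls(samples=raw, fs=float(meta["fs"]), t0=float(meta.get("t0", 0.0)))


@dataclass
class SpikeTrainSet:
    """Per-electrode sorted spike times (seconds from recording start)."""

    trains: dict = field(default_factory=dict)
    duration_s: float = 0.0
    noise_sd_uv: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for el, t in self.trains.items():
            t = np.asarray(t, dtype=float)
            if np.any(np.diff(t) < 0):
                t = np.sort(t)
            clean[el] = t
        self.trains = clean
        if self.duration_s <= 0 and self.trains:
            self.duration_s = float(
                max((t[-1] if len(t) else 0.0) for t in self.trains.values())
            )

    @property
    def electrode_ids(self) -> list:
        return sorted(self.trains)

    def n_spikes(self) -> int:
        return int(sum(len(t) for t in self.trains.values()))

    def to_hdf5(self, path_or_group, culture: int | None = None) -> None:
        """Write ``electrodes/<id>/spike_times`` datasets (seconds).

        When ``culture`` is given, data are nested under
        ``/cultures/<culture>/``.
        """
        own = isinstance(path_or_group, (str, bytes)) or hasattr(
            path_or_group, "__fspath__"
        )
        fh = h5py.File(path_or_group, "a") if own else path_or_group
        try:
            grp = fh.require_group(f"cultures/{culture}") if culture is not None else fh
            grp.attrs["duration_s"] = self.duration_s
            for el, t in self.trains.items():
                g = grp.require_group(f"electrodes/{el}")
                if "spike_times" in g:
                    del g["spike_times"]
                g.create_dataset("spike_times", data=t)
                if el in self.noise_sd_uv:
                    g.attrs["noise_sd_uv"] = self.noise_sd_uv[el]
        finally:
            if own:
                fh.close()

    @classmethod
    def from_hdf5(cls, path_or_group, culture: int | None = None) -> "SpikeTrainSet":
        own = isinstance(path_or_group, (str, bytes)) or hasattr(
            path_or_group, "__fspath__"
        )
        fh = h5py.File(path_or_group, "r") if own else path_or_group
        try:
            grp = fh[f"cultures/{culture}"] if culture is not None else fh
            trains, noise = {}, {}
            for key, g in grp["electrodes"].items():
                el = int(key)
                trains[el] = g["spike_times"][...]
                if "noise_sd_uv" in g.attrs:
                    noise[el] = float(g.attrs["noise_sd_uv"])
            return cls(
                trains=trains,
                duration_s=float(grp.attrs.get("duration_s", 0.0)),
                noise_sd_uv=noise,
            )
        finally:
            if own:
                fh.close()

    def to_csv(self, path) -> None:
        rows = [
            (el, t)
            for el in self.electrode_ids
            for t in self.trains[el]
        ]
        pd.DataFrame(rows, columns=["electrode_id", "spike_time_s"]).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, duration_s: float = 0.0) -> "SpikeTrainSet":
        df = pd.read_csv(path)
        trains = {
            int(el): grp["spike_time_s"].to_numpy()
            for el, grp in df.groupby("electrode_id")
        }
        return cls(trains=trains, duration_s=duration_s)


# ---------------------------------------------------------------------------
# noise estimation
# ---------------------------------------------------------------------------

def estimate_noise_sd(
    recording: RawRecording, window: tuple[float, float] | None = None
) -> np.ndarray:
    """Robust per-channel noise SD in microvolts.

    Uses the median absolute deviation scaled to a Gaussian SD
    (``MAD * 1.4826``) over the given ``(t_start, t_end)`` window, so sparse
    large-amplitude spikes embedded in the signal barely affect the
    estimate.  Channels with zero variance are reported as 0 with a warning;
    their threshold would be degenerate and they are skipped downstream.
    """
    if window is None:
        window = (recording.t0, recording.t0 + recording.duration_s)
    a = int(round((window[0] - recording.t0) * recording.fs))
    b = int(round((window[1] - recording.t0) * recording.fs))
    a, b = max(a, 0), min(b, recording.samples.shape[1])
    if b - a < recording.fs:
        raise ValueError("noise window must be at least 1 s of samples")
    seg = recording.samples[:, a:b]
    med = np.median(seg, axis=1, keepdims=True)
    sd = MAD_TO_SD * np.median(np.abs(seg - med), axis=1)
    for ch, s in zip(recording.channel_ids, sd):
        if s == 0.0:
            warnings.warn(
                f"channel {ch}: zero noise variance; channel flagged", stacklevel=2
            )
    return sd


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _local_minima(x: np.ndarray) -> np.ndarray:
    """Indices of strict-or-plateau local minima (leftmost sample of ties)."""
    n = len(x)
    if n < 3:
        return np.empty(0, dtype=int)
    prev = x[:-2]
    cur = x[1:-1]
    nxt = x[2:]
    cand = np.flatnonzero((cur < prev) & (cur <= nxt)) + 1
    return cand


def detect_spikes(
    recording: RawRecording,
    noise_sd: np.ndarray | float,
    threshold_factor: float = DEFAULT_THRESHOLD_FACTOR,
    window_ms: float = DEFAULT_WINDOW_MS,
    refractory_ms: float = DEFAULT_REFRACTORY_MS,
) -> SpikeTrainSet:
    """Detect spikes by the peak-to-peak threshold rule.

    For each channel, a candidate trough (local minimum) becomes a spike
    when the signal maximum within +/- ``window_ms``/2 of the trough exceeds
    the trough by more than ``threshold_factor`` times the channel noise SD.
    Candidates are then merged with a refractory rule: troughs are accepted
    deepest-first, and a candidate within ``refractory_ms`` of an already
    accepted spike is dropped.  Spike times are the times of the accepted
    negative peaks.

    Raising ``threshold_factor`` never increases the number of spikes, and
    rescaling signal and ``noise_sd`` jointly leaves the output unchanged.
    """
    noise_sd = np.broadcast_to(
        np.asarray(noise_sd, dtype=float), (recording.n_channels,)
    )
    w = int(round(window_ms * 1e-3 * recording.fs))
    if w < 2:
        raise ValueError("window must span at least 2 samples at this fs")
    refr_samp = max(int(round(refractory_ms * 1e-3 * recording.fs)), 1)

    trains: dict = {}
    noise_out: dict = {}
    for ci, ch in enumerate(recording.channel_ids):
        sd = noise_sd[ci]
        if sd <= 0:
            logger.warning("channel %s skipped: zero noise SD", ch)
            continue
        x = recording.samples[ci]
        thr = threshold_factor * sd
        # centered rolling maximum over the sliding window
        rollmax = maximum_filter1d(x, size=w, mode="nearest")
        troughs = _local_minima(x)
        qual = troughs[(rollmax[troughs] - x[troughs]) > thr]
        if len(qual) == 0:
            trains[ch] = np.empty(0)
            noise_out[ch] = sd
            continue
        # refractory merge, deepest trough first (deterministic: depth, time)
        order = np.lexsort((qual, x[qual]))
        accepted: list[int] = []
        taken = np.zeros(recording.samples.shape[1] + 2 * refr_samp, dtype=bool)
        for idx in qual[order]:
            lo = idx  # offset by refr_samp in the padded mask
            if taken[lo : lo + 2 * refr_samp + 1].any():
                continue
            accepted.append(idx)
            taken[lo + refr_samp] = True
        accepted_arr = np.sort(np.asarray(accepted, dtype=int))
        trains[ch] = recording.t0 + accepted_arr / recording.fs
        noise_out[ch] = sd

    return SpikeTrainSet(
        trains=trains, duration_s=recording.t0 + recording.duration_s,
        noise_sd_uv=noise_out,
    )
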