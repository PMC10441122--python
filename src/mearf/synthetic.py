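"""Synthetic MEA datasets and temperature transients.

The generator emulates the activity regime of dissociated cortical cultures
at the age where spiking is balanced between tonic (random) spikes and
synchronized network bursts.  It is a doubly stochastic, network-burst-driven
model:

* network-burst *events* are drawn as a (possibly inhomogeneous) Poisson
  process whose rate is the baseline ``network_burst_rate`` scaled by a
  per-phase multiplier, optionally relaxed exponentially at phase
  transitions (onset/recovery time constants);
* each event recruits each active electrode independently with
  ``participation_prob``; a recruited electrode emits a burst whose spike
  count is negative-binomial and whose intra-burst ISIs are jittered around
  a configurable mean;
* tonic out-of-burst spikes are independent Poisson per electrode;
* a configurable fraction of electrodes is near-silent (below the activity
  thresholds used by the metrics stage);
* an optional per-phase *spike retention* probability thins every spike
  uniformly, emulating a global firing suppression that acts on spikes
  rather than on burst initiation.

Suppression applied to the burst-initiation rate only (the default
exposure-like scenario) leaves burst duration and tonic firing untouched;
the persistent flag extends the exposure-phase multipliers through the
post-exposure phases (heat-like, non-reversible scenario).

Everything is reproducible: the same config and seed yield a byte-identical
dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import yaml

from .protocol import PhaseProtocol, default_protocol
from .spike_detection import RawRecording, SpikeTrainSet

logger = logging.getLogger("mearf")

EXPOSURE_PHASE = "E"

#: culture-medium specific heat used throughout dosimetry, J/(kg K)
DEFAULT_HEAT_CAPACITY = 4196.8


class ScenarioError(ValueError):
    """Degenerate or inconsistent generator configuration."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Generative parameters of one synthetic culture.

    Rates are baselines; per-phase multipliers scale them during the phase
    they are keyed by.  ``persistent=True`` extends the exposure-phase
    multipliers to every later phase.
    """

    n_electrodes: int = 60
    network_burst_rate: float = 15.0  #: network-burst events per minute
    participation_prob: float = 0.6  #: P(active electrode joins an event)
    spikes_per_burst_mean: float = 12.0
    spikes_per_burst_dispersion: float = 5.0  #: negative-binomial size
    intra_burst_isi_s: float = 0.008
    intra_burst_isi_jitter_s: float = 0.003
    onset_jitter_s: float = 0.010  #: SD of per-electrode burst-onset jitter
    tonic_rate_hz: float = 0.5  #: out-of-burst Poisson rate per electrode
    inactive_fraction: float = 0.1
    inactive_tonic_rate_hz: float = 0.02  #: sub-threshold rate of silent electrodes
    burst_rate_multipliers: dict = field(default_factory=dict)
    tonic_rate_multipliers: dict = field(default_factory=dict)
    spike_retention_multipliers: dict = field(default_factory=dict)
    persistent: bool = False
    onset_tau_s: float = 0.0
    recovery_tau_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_electrodes <= 0:
            raise ScenarioError("n_electrodes must be positive")
        for name in (
            "network_burst_rate",
            "spikes_per_burst_mean",
            "spikes_per_burst_dispersion",
            "intra_burst_isi_s",
            "tonic_rate_hz",
            "inactive_tonic_rate_hz",
            "onset_tau_s",
            "recovery_tau_s",
        ):
            if getattr(self, name) < 0:
                raise ScenarioError(f"{name} must be non-negative")
        for name in ("participation_prob", "inactive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ScenarioError(f"{name} must be a probability")
        for mult in (
            self.burst_rate_multipliers,
            self.tonic_rate_multipliers,
            self.spike_retention_multipliers,
        ):
            if any(m < 0 for m in mult.values()):
                raise ScenarioError("multipliers must be non-negative")

    # -- convenience constructors -------------------------------------------

    @classmethod
    def sham(cls, **kw) -> "ScenarioConfig":
        """Stationary culture: all multipliers 1 in every phase."""
        return cls(**kw)

    @classmethod
    def exposure_like(cls, burst_multiplier: float, **kw) -> "ScenarioConfig":
        """Reversible suppression of burst initiation during E only."""
        return cls(
            burst_rate_multipliers={EXPOSURE_PHASE: burst_multiplier},
            persistent=False,
            **kw,
        )

    @classmethod
    def heat_like(cls, spike_retention: float, **kw) -> "ScenarioConfig":
        """Persistent uniform spike thinning from E onward."""
        return cls(
            spike_retention_multipliers={EXPOSURE_PHASE: spike_retention},
            persistent=True,
            **kw,
        )

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return replace(self, seed=int(seed))

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)


@dataclass
class GroundTruth:
    """Injected structure of a synthetic dataset, for oracle-based tests."""

    event_times: np.ndarray  #: network-burst event times, seconds
    burst_intervals: dict  #: electrode -> (n_bursts, 3) array [start, end, count]
    event_membership: dict  #: electrode -> event index of each of its bursts
    per_phase_event_counts: dict  #: phase label -> realized event count
    expected_event_rate_per_min: dict  #: phase label -> expected events/min
    expected_multipliers: dict  #: kind -> {phase: mean effective multiplier}
    active_electrodes: np.ndarray  #: ids of burst-capable electrodes


@dataclass
class SyntheticDataset:
    spike_trains: SpikeTrainSet
    ground_truth: GroundTruth
    config: ScenarioConfig
    protocol: PhaseProtocol
    seed: int


# ---------------------------------------------------------------------------
# per-phase multiplier schedule
# ---------------------------------------------------------------------------

def _phase_targets(
    multipliers: dict, protocol: PhaseProtocol, persistent: bool
) -> np.ndarray:
    """Target multiplier of each phase, honoring the persistent flag."""
    targets = np.ones(len(protocol.labels))
    for phase, m in multipliers.items():
        if phase not in protocol.labels:
            raise ScenarioError(f"multiplier for unknown phase {phase!r}")
        targets[protocol.labels.index(phase)] = m
    if persistent and EXPOSURE_PHASE in protocol.labels:
        e_idx = protocol.labels.index(EXPOSURE_PHASE)
        explicit = set(multipliers)
        for j in range(e_idx + 1, len(protocol.labels)):
            if protocol.labels[j] not in explicit:
                targets[j] = targets[e_idx]
    return targets


def multiplier_profile(
    multipliers: dict, protocol: PhaseProtocol, persistent: bool,
    onset_tau_s: float, recovery_tau_s: float,
):
    """Return ``m(t)``, the effective multiplier as a vectorized callable.

    Within each phase the multiplier relaxes exponentially from its value at
    the phase start toward the phase target; the time constant is
    ``onset_tau_s`` when moving down (suppression setting in) and
    ``recovery_tau_s`` when moving up.  Zero taus give an instantaneous
    step.
    """
    targets = _phase_targets(multipliers, protocol, persistent)
    edges = protocol.edges
    # multiplier value reached at the start of each phase
    start_vals = np.empty(len(targets))
    cur = 1.0
    for i, tg in enumerate(targets):
        start_vals[i] = cur
        tau = onset_tau_s if tg < cur else recovery_tau_s
        dur = protocol.durations_s[i]
        cur = tg if tau <= 0 else tg + (cur - tg) * np.exp(-dur / tau)

    def m(t):
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(targets) - 1)
        tg = targets[idx]
        sv = start_vals[idx]
        tau = np.where(tg < sv, onset_tau_s, recovery_tau_s)
        dt = t - edges[idx]
        with np.errstate(divide="ignore", invalid="ignore", over="ignore", under="ignore"):
            rel = np.where(tau > 0, np.exp(-dt / np.maximum(tau, 1e-300)), 0.0)
        return tg + (sv - tg) * rel

    return m, targets


def _mean_multiplier_per_phase(m, protocol: PhaseProtocol, dt: float = 1.0) -> dict:
    out = {}
    for label, (a, b) in zip(protocol.labels, protocol.bounds):
        grid = np.arange(a, b, dt) + dt / 2
        out[label] = float(np.mean(m(grid)))
    return out


def _inhomogeneous_poisson(rng, m, base_rate_hz: float, total_s: float) -> np.ndarray:
    """Event times of a Poisson process with rate ``base * m(t)`` (thinning)."""
    grid = np.linspace(0, total_s, 512)
    peak = base_rate_hz * max(float(np.max(m(grid))), 1e-12)
    n = rng.poisson(peak * total_s)
    t = np.sort(rng.uniform(0, total_s, n))
    accept = rng.uniform(0, 1, n) * peak <= base_rate_hz * m(t)
    return t[accept]


# ---------------------------------------------------------------------------
# spike-train generation
# ---------------------------------------------------------------------------

def generate_scenario(
    config: ScenarioConfig,
    protocol: PhaseProtocol | None = None,
    seed: int | None = None,
) -> SyntheticDataset:
    """Draw one synthetic culture under ``config``.

    See the module docstring for the generative model.  ``seed`` overrides
    ``config.seed`` when given.
    """
    protocol = protocol or default_protocol()
    seed = int(config.seed if seed is None else seed)
    rng = np.random.default_rng(seed)
    total = protocol.total_duration_s
    if total <= 0:
        raise ScenarioError("protocol has zero duration")

    m_burst, _ = multiplier_profile(
        config.burst_rate_multipliers, protocol, config.persistent,
        config.onset_tau_s, config.recovery_tau_s,
    )
    m_tonic, _ = multiplier_profile(
        config.tonic_rate_multipliers, protocol, config.persistent,
        config.onset_tau_s, config.recovery_tau_s,
    )
    m_keep, _ = multiplier_profile(
        config.spike_retention_multipliers, protocol, config.persistent,
        config.onset_tau_s, config.recovery_tau_s,
    )

    n_el = config.n_electrodes
    n_inactive = int(round(config.inactive_fraction * n_el))
    perm = rng.permutation(n_el)
    inactive = np.sort(perm[:n_inactive])
    active = np.sort(perm[n_inactive:])

    # --- network-burst events ---------------------------------------------
    base_hz = config.network_burst_rate / 60.0
    events = _inhomogeneous_poisson(rng, m_burst, base_hz, total)
    n_ev = len(events)

    trains = {int(el): [] for el in range(n_el)}
    burst_intervals = {int(el): [] for el in active}
    membership = {int(el): [] for el in active}

    if n_ev and len(active):
        join = rng.random((n_ev, len(active))) < config.participation_prob
        ev_idx, el_pos = np.nonzero(join)
        nb = len(ev_idx)
        onsets = events[ev_idx] + rng.normal(0.0, config.onset_jitter_s, nb)
        # negative-binomial spike counts, floored at 2 so a burst is a burst
        p_nb = config.spikes_per_burst_dispersion / (
            config.spikes_per_burst_dispersion + config.spikes_per_burst_mean
        )
        counts = rng.negative_binomial(
            config.spikes_per_burst_dispersion, p_nb, nb
        )
        counts = np.maximum(counts, 2)
        tot = int(counts.sum())
        isis = rng.normal(
            config.intra_burst_isi_s, config.intra_burst_isi_jitter_s, tot
        )
        isis = np.clip(isis, 1e-3, None)
        first = np.concatenate(([0], np.cumsum(counts)[:-1]))
        isis[first] = 0.0  # first spike of each burst sits at the onset
        cs = np.cumsum(isis)
        grp = np.repeat(np.arange(nb), counts)
        within = cs - np.concatenate(([0.0], cs[first[1:] - 1]))[grp]
        times = onsets[grp] + within
        # per-burst bookkeeping
        ends = times[np.cumsum(counts) - 1]
        for k in range(nb):
            el = int(active[el_pos[k]])
            burst_intervals[el].append((onsets[k], ends[k], int(counts[k])))
            membership[el].append(int(ev_idx[k]))
        el_of_spike = el_pos[grp]
        for el_p in range(len(active)):
            trains[int(active[el_p])].append(times[el_of_spike == el_p])

    # --- tonic out-of-burst spikes ------------------------------------------
    inactive_set = set(inactive.tolist())
    for el in range(n_el):
        rate = (
            config.inactive_tonic_rate_hz
            if el in inactive_set
            else config.tonic_rate_hz
        )
        if rate > 0:
            t = _inhomogeneous_poisson(rng, m_tonic, rate, total)
            trains[el].append(t)

    # --- assemble, thin, clip ------------------------------------------------
    out_trains = {}
    for el in range(n_el):
        t = np.sort(np.concatenate(trains[el])) if trains[el] else np.empty(0)
        t = t[(t >= 0) & (t < total)]
        if config.spike_retention_multipliers:
            keep = rng.uniform(0, 1, len(t)) < m_keep(t)
            t = t[keep]
        out_trains[el] = t

    # --- ground truth ---------------------------------------------------------
    ev_phase = protocol.phase_indices(events)
    per_phase_counts = {
        lb: int(np.sum(ev_phase == i)) for i, lb in enumerate(protocol.labels)
    }
    mean_mult = _mean_multiplier_per_phase(m_burst, protocol)
    expected = {
        lb: config.network_burst_rate * mean_mult[lb] for lb in protocol.labels
    }
    gt = GroundTruth(
        event_times=events,
        burst_intervals={
            el: np.array(v, dtype=float).reshape(-1, 3)
            for el, v in burst_intervals.items()
        },
        event_membership={el: np.asarray(v, dtype=int) for el, v in membership.items()},
        per_phase_event_counts=per_phase_counts,
        expected_event_rate_per_min=expected,
        expected_multipliers={
            "burst_rate": mean_mult,
            "tonic_rate": _mean_multiplier_per_phase(m_tonic, protocol),
            "spike_retention": _mean_multiplier_per_phase(m_keep, protocol),
        },
        active_electrodes=active,
    )
    sts = SpikeTrainSet(trains=out_trains, duration_s=total)
    return SyntheticDataset(
        spike_trains=sts, ground_truth=gt, config=config, protocol=protocol,
        seed=seed,
    )


def save_cultures_hdf5(path, datasets: list[SyntheticDataset]) -> None:
    """Write several cultures to ``/cultures/<i>/electrodes/<j>/spike_times``."""
    with h5py.File(path, "w") as fh:
        for i, ds in enumerate(datasets):
            ds.spike_trains.to_hdf5(fh, culture=i)
            fh[f"cultures/{i}"].attrs["seed"] = ds.seed


# ---------------------------------------------------------------------------
# waveform synthesis
# ---------------------------------------------------------------------------

def biphasic_template(fs: float, duration_ms: float = 1.0) -> np.ndarray:
    """Unit peak-to-peak biphasic spike template (negative lobe first)."""
    n = max(int(round(duration_ms * 1e-3 * fs)), 3)
    t = np.linspace(0, 1, n)
    w = -np.sin(np.pi * t) * np.exp(-3 * t) + 0.45 * np.sin(np.pi * t) ** 2 * (t > 0.25)
    w -= w.mean() * 0  # keep baseline at 0; template is transient
    return w / (w.max() - w.min())


def synthesize_waveforms(
    spikes: SpikeTrainSet | SyntheticDataset,
    amplitude_uv: float = 50.0,
    noise_sd_uv: float = 5.0,
    fs: float = 10_000.0,
    template: np.ndarray | None = None,
    seed: int = 0,
    duration_s: float | None = None,
) -> RawRecording:
    """Render spike trains as raw voltage traces.

    Each spike time becomes one instance of a biphasic template with the
    stated peak-to-peak amplitude (microvolts), aligned so the template's
    negative peak falls on the spike time, added to white Gaussian noise of
    SD ``noise_sd_uv``.  Spikes too close to the recording end get a
    truncated template (with a warning).
    """
    if isinstance(spikes, SyntheticDataset):
        spikes = spikes.spike_trains
    if fs < 1000:
        raise ValueError("fs must be at least 1 kHz")
    if template is None:
        template = biphasic_template(fs)
    if len(template) > 0.002 * fs:
        raise ValueError("template longer than 2 ms")
    tpl = template * amplitude_uv
    neg = int(np.argmin(tpl))
    dur = duration_s if duration_s is not None else spikes.duration_s
    n_samp = int(round(dur * fs))
    rng = np.random.default_rng(seed)
    ids = spikes.electrode_ids
    samples = (
        rng.normal(0.0, noise_sd_uv, (len(ids), n_samp))
        if noise_sd_uv > 0
        else np.zeros((len(ids), n_samp))
    )
    truncated = 0
    for row, el in enumerate(ids):
        for t in spikes.trains[el]:
            i0 = int(round(t * fs)) - neg
            a, b = max(i0, 0), min(i0 + len(tpl), n_samp)
            if b - a < len(tpl):
                truncated += 1
            if b > a:
                samples[row, a:b] += tpl[a - i0 : b - i0]
    if truncated:
        logger.warning("%d spike templates truncated at recording edges", truncated)
    return RawRecording(samples=samples, fs=fs, channel_ids=tuple(ids))


# ---------------------------------------------------------------------------
# temperature transients
# ---------------------------------------------------------------------------

def generate_temperature_trace(
    sar_w_per_kg: float,
    tau_s: float,
    heat_capacity: float = DEFAULT_HEAT_CAPACITY,
    duration_s: float = 900.0,
    fs_hz: float = 1.0,
    noise_sd_c: float = 0.0,
    seed: int = 0,
    baseline_c: float = 37.0,
    t_on: float = 0.0,
):
    """Sampled first-order heating curve with measurement noise.

    The deterministic part is ``dT(t) = (SAR*tau/C) * (1 - exp(-t/tau))``
    after exposure onset, whose initial slope is exactly ``SAR/C``; Gaussian
    noise of SD ``noise_sd_c`` is added to every sample.
    Returns a :class:`mearf.dosimetry.TemperatureTrace`.
    """
    from .dosimetry import TemperatureTrace, first_order_delta_t

    if tau_s <= 0 or heat_capacity <= 0:
        raise ValueError("tau and heat capacity must be positive")
    t = np.arange(0.0, duration_s, 1.0 / fs_hz)
    dt = first_order_delta_t(
        np.maximum(t - t_on, 0.0), sar_w_per_kg, tau_s, heat_capacity
    )
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd_c, len(t)) if noise_sd_c > 0 else 0.0
    return TemperatureTrace(
        time_s=t,
        temperature_c=baseline_c + dt + noise,
        t_on=t_on,
        t_off=min(duration_s, float(t[-1])),
        baseline_c=baseline_c,
    )
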