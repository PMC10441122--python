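"""End-to-end orchestration: simulate or ingest, detect, summarize, report.

:func:`run_analysis` executes the full chain — spike trains (simulated,
loaded, or detected from waveforms) -> adaptive burst detection -> per-phase
metrics with baseline normalization -> nonparametric phase statistics and
the per-minute bursting-rate time course — persisting every intermediate
(spikes, bursts, metrics) so each stage is independently auditable, plus a
manifest recording all parameters, seeds and the package version.  Runs are
deterministic given the config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .burst_analysis import (
    DEFAULT_BIN_WIDTH_LOG10MS,
    DEFAULT_MAX_INTRA_ISI_MS,
    DEFAULT_MIN_FRACTION,
    DEFAULT_MIN_SPIKES,
    BurstTrain,
    detect_bursts_adaptive,
    detect_network_bursts,
)
from .metrics import (
    UnusableCultureError,
    active_electrodes,
    combine_cultures,
    compute_phase_metrics,
    electrode_phase_rates,
    mbr_timecourse,
    normalize_metrics,
)
from .phase_stats import compare_phases
from .protocol import PhaseProtocol, default_protocol
from .spike_detection import (
    DEFAULT_THRESHOLD_FACTOR,
    DEFAULT_WINDOW_MS,
    RawRecording,
    SpikeTrainSet,
    detect_spikes,
    estimate_noise_sd,
)
from .synthetic import ScenarioConfig, generate_scenario

logger = logging.getLogger("mearf")


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    scenario: ScenarioConfig | None = None  #: simulate when given
    spikes_csv: list | None = None  #: else: per-culture spike-time CSVs
    waveforms_h5: list | None = None  #: or per-culture raw recordings
    n_cultures: int = 1
    protocol: PhaseProtocol = field(default_factory=default_protocol)
    out_dir: str = "mearf_out"
    seed: int = 0
    # detection / burst parameters
    threshold_factor: float = DEFAULT_THRESHOLD_FACTOR
    window_ms: float = DEFAULT_WINDOW_MS
    bin_width: float = DEFAULT_BIN_WIDTH_LOG10MS
    max_isi_ms: float = DEFAULT_MAX_INTRA_ISI_MS
    min_spikes: int = DEFAULT_MIN_SPIKES
    net_fraction: float = DEFAULT_MIN_FRACTION
    mbd_denominator: str = "s1"
    timecourse_bin_s: float = 60.0
    make_figure: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "scenario" in raw and raw["scenario"] is not None:
            raw["scenario"] = ScenarioConfig(**raw["scenario"])
        if "protocol" in raw and raw["protocol"] is not None:
            raw["protocol"] = PhaseProtocol.from_dict(raw["protocol"])
        return cls(**raw)


def culture_seeds(seed: int, n: int) -> list[int]:
    """Per-culture seeds derived deterministically from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def analyze_culture(
    spikes: SpikeTrainSet,
    protocol: PhaseProtocol,
    culture: int = 0,
    bin_width: float = DEFAULT_BIN_WIDTH_LOG10MS,
    max_isi_ms: float = DEFAULT_MAX_INTRA_ISI_MS,
    min_spikes: int = DEFAULT_MIN_SPIKES,
    net_fraction: float = DEFAULT_MIN_FRACTION,
    mbd_denominator: str = "s1",
):
    """Burst detection + metrics for one culture.

    Returns ``(bursts, metrics_table, network_bursts)``; the metrics table
    is the raw (unnormalized) tidy table.
    """
    bursts = detect_bursts_adaptive(
        spikes, bin_width=bin_width, max_threshold_ms=max_isi_ms,
        min_spikes=min_spikes,
    )
    table = compute_phase_metrics(
        spikes, bursts, protocol, culture=culture, mbd_denominator=mbd_denominator
    )
    rates = electrode_phase_rates(spikes, bursts, protocol)
    bursting = active_electrodes(rates, "bursting", phase=protocol.baseline)
    network = (
        detect_network_bursts(bursts, bursting, min_fraction=net_fraction)
        if bursting
        else []
    )
    return bursts, table, network


def run_analysis(config: RunConfig) -> dict:
    """Execute the configured run; returns the in-memory report bundle.

    Persists per-culture spikes (CSV), bursts (CSV), the combined
    raw+normalized metrics table (CSV), the stats report (JSON), the
    per-minute MBR time course (CSV), an optional figure (PNG) and a
    manifest (JSON).  Cultures with no baseline-active electrodes are
    flagged in the manifest and excluded from the tables.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    protocol = config.protocol

    # --- stage 1: obtain spike trains --------------------------------------
    cultures: list[SpikeTrainSet] = []
    if config.scenario is not None:
        for s in culture_seeds(config.seed, config.n_cultures):
            cultures.append(
                generate_scenario(config.scenario, protocol, seed=s).spike_trains
            )
    elif config.waveforms_h5:
        for path in config.waveforms_h5:
            rec = RawRecording.from_hdf5(path)
            base = protocol.bounds_of(protocol.baseline)
            noise = estimate_noise_sd(rec, window=base)
            cultures.append(
                detect_spikes(
                    rec, noise, config.threshold_factor, config.window_ms
                )
            )
    elif config.spikes_csv:
        for path in config.spikes_csv:
            cultures.append(
                SpikeTrainSet.from_csv(path, duration_s=protocol.total_duration_s)
            )
    else:
        raise ValueError("config provides no input source")

    # --- stage 2-3: bursts + metrics per culture ----------------------------
    tables, per_culture, networks, flagged = [], [], [], []
    for i, spikes in enumerate(cultures):
        spikes.to_csv(out / f"spikes_culture{i}.csv")
        try:
            bursts, table, network = analyze_culture(
                spikes,
                protocol,
                culture=i,
                bin_width=config.bin_width,
                max_isi_ms=config.max_isi_ms,
                min_spikes=config.min_spikes,
                net_fraction=config.net_fraction,
                mbd_denominator=config.mbd_denominator,
            )
        except UnusableCultureError as exc:
            logger.warning("culture %d unusable: %s", i, exc)
            flagged.append(i)
            continue
        bursts.to_csv(out / f"bursts_culture{i}.csv")
        n_s = int(table["n_active_spiking"].iloc[0])
        n_b = int(table["n_active_bursting"].iloc[0])
        logger.info(
            "culture %d: N_S=%d N_B=%d network_bursts=%d", i, n_s, n_b, len(network)
        )
        tables.append(table)
        per_culture.append((spikes, bursts))
        networks.append(network)
    if not tables:
        raise UnusableCultureError("no usable cultures in this run")

    # --- stage 4: normalization + stats + time course -----------------------
    metrics_table = normalize_metrics(
        combine_cultures(tables), baseline=protocol.baseline
    )
    metrics_table.to_csv(out / "metrics.csv", index=False)
    report = compare_phases(metrics_table, phases=protocol.labels)
    report.to_json(out / "stats.json")
    report.to_frame().to_csv(out / "stats.csv", index=False)
    timecourse = mbr_timecourse(per_culture, protocol, bin_s=config.timecourse_bin_s)
    timecourse.to_csv(out / "mbr_timecourse.csv", index=False)

    if config.make_figure:
        _timecourse_figure(timecourse, protocol, out / "mbr_timecourse.png")

    manifest = {
        "package": "mearf",
        "version": __version__,
        "seed": config.seed,
        "n_cultures_requested": len(cultures),
        "n_cultures_used": len(tables),
        "flagged_cultures": flagged,
        "protocol": protocol.to_dict(),
        "scenario": (
            config.scenario.to_dict() if config.scenario is not None else None
        ),
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in ("scenario", "protocol")
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return {
        "metrics": metrics_table,
        "stats": report,
        "timecourse": timecourse,
        "network_bursts": networks,
        "manifest": manifest,
    }


def _timecourse_figure(timecourse: pd.DataFrame, protocol: PhaseProtocol, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.2))
    t_min = timecourse["t_center_s"] / 60.0
    ax.fill_between(
        t_min,
        timecourse["mean_pct"] - timecourse["sem_pct"],
        timecourse["mean_pct"] + timecourse["sem_pct"],
        alpha=0.3,
        lw=0,
    )
    ax.plot(t_min, timecourse["mean_pct"])
    if "E" in protocol.labels:
        a, b = protocol.bounds_of("E")
        ax.axvspan(a / 60.0, b / 60.0, color="0.85", zorder=0)
    ax.axhline(100.0, ls=":", c="k", lw=0.8)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("MBR$_{1\\,\\mathrm{min}}$ (% of baseline)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
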