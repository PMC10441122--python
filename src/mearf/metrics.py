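"""Per-phase network activity metrics with baseline normalization.

Four metrics summarize a culture in each protocol phase:

* **MFR** (mean firing rate, Hz) — total spikes per second summed over the
  electrodes that were spiking-active in the baseline phase, divided by the
  number of those electrodes, ``N_S(S1)``;
* **MBR** (mean bursting rate, bursts/min) — summed burst rate over the
  baseline bursting-active electrodes divided by ``N_B(S1)``;
* **MBD** (mean burst duration, s) — average burst duration across the
  bursting-active electrodes;
* **MOBFR** (mean outside-burst firing rate, Hz) — rate of spikes falling
  outside any burst, over the bursting-active set, divided by ``N_B(S1)``.

An electrode is spiking-active when its baseline firing rate is at least
0.1 Hz, and bursting-active when its baseline burst rate is at least
0.04 Hz.  Active sets are computed once, from the baseline phase only, and
reused for every phase, so later suppression cannot change the
denominators.  Metrics are normalized per culture with the baseline phase
set to 100%.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .burst_analysis import BurstTrain
from .protocol import PhaseProtocol
from .spike_detection import SpikeTrainSet

logger = logging.getLogger("mearf")

SPIKING_ACTIVE_MIN_HZ = 0.1
BURSTING_ACTIVE_MIN_HZ = 0.04

METRIC_NAMES = ("mfr", "mbr", "mbd", "mobfr")


class UnusableCultureError(RuntimeError):
    """No active electrodes in the baseline phase; metrics undefined."""


# ---------------------------------------------------------------------------
# per-electrode, per-phase rates
# ---------------------------------------------------------------------------

def electrode_phase_rates(
    spikes: SpikeTrainSet, bursts: BurstTrain, protocol: PhaseProtocol
) -> pd.DataFrame:
    """Tidy frame of per-electrode, per-phase rates.

    Columns: ``electrode``, ``phase``, ``fr_hz`` (all spikes / s), ``br_per_min``
    (bursts starting in the phase / min), ``mean_bd_s`` (NaN when no burst
    starts in the phase), ``obfr_hz`` (outside-burst spikes / s).  Spikes are
    assigned to phases by spike time; bursts by their start time.  In-burst
    classification is per spike, so ``fr = in-burst rate + obfr`` holds
    exactly in every phase.
    """
    labels = protocol.labels
    durations = np.asarray(protocol.durations_s)
    rows = []
    for el in spikes.electrode_ids:
        t = spikes.trains[el]
        ph = protocol.phase_indices(t)
        eb = bursts[el] if el in bursts else None
        if eb is not None and len(eb.in_burst) == len(t):
            in_burst = eb.in_burst
        else:
            in_burst = np.zeros(len(t), dtype=bool)
        n_spk = np.bincount(ph[ph >= 0], minlength=len(labels))
        n_out = np.bincount(ph[(ph >= 0) & (~in_burst)], minlength=len(labels))
        if eb is not None and eb.n_bursts:
            bph = protocol.phase_indices(eb.starts)
            n_bursts = np.bincount(bph[bph >= 0], minlength=len(labels))
            sum_bd = np.bincount(
                bph[bph >= 0], weights=eb.durations[bph >= 0], minlength=len(labels)
            )
        else:
            n_bursts = np.zeros(len(labels), dtype=int)
            sum_bd = np.zeros(len(labels))
        for i, lb in enumerate(labels):
            mean_bd = sum_bd[i] / n_bursts[i] if n_bursts[i] else np.nan
            rows.append(
                (
                    el,
                    lb,
                    n_spk[i] / durations[i],
                    n_bursts[i] / (durations[i] / 60.0),
                    mean_bd,
                    n_out[i] / durations[i],
                )
            )
    return pd.DataFrame(
        rows,
        columns=["electrode", "phase", "fr_hz", "br_per_min", "mean_bd_s", "obfr_hz"],
    )


def active_electrodes(
    rates: pd.DataFrame,
    kind: str,
    phase: str = "S1",
    spiking_min_hz: float = SPIKING_ACTIVE_MIN_HZ,
    bursting_min_hz: float = BURSTING_ACTIVE_MIN_HZ,
) -> set:
    """Baseline-active electrode set.

    ``kind='spiking'``: firing rate in ``phase`` at least 0.1 Hz;
    ``kind='bursting'``: burst rate at least 0.04 Hz (2.4 bursts/min).
    Boundary values are inclusive ("at least").
    """
    sub = rates[rates["phase"] == phase]
    if sub.empty:
        raise ValueError(f"phase {phase!r} not present in rates")
    if kind == "spiking":
        sel = sub["fr_hz"] >= spiking_min_hz
    elif kind == "bursting":
        sel = sub["br_per_min"] / 60.0 >= bursting_min_hz
    else:
        raise ValueError("kind must be 'spiking' or 'bursting'")
    return set(sub.loc[sel, "electrode"].tolist())


# ---------------------------------------------------------------------------
# culture-level metrics
# ---------------------------------------------------------------------------

def compute_phase_metrics(
    spikes: SpikeTrainSet,
    bursts: BurstTrain,
    protocol: PhaseProtocol,
    culture: int = 0,
    mbd_denominator: str = "s1",
) -> pd.DataFrame:
    """Tidy per-phase metrics table for one culture.

    Columns: ``culture``, ``phase``, ``metric`` (mfr|mbr|mbd|mobfr),
    ``value`` (Hz, bursts/min, s, Hz respectively), ``n_active_spiking``,
    ``n_active_bursting``.  Sums run over the baseline-active sets; MBD's
    denominator is the baseline bursting-active count (``mbd_denominator=
    's1'``) or the per-phase count of those electrodes that actually burst
    (``'per_phase'``).  Raises :class:`UnusableCultureError` when either
    baseline active set is empty.
    """
    if mbd_denominator not in ("s1", "per_phase"):
        raise ValueError("mbd_denominator must be 's1' or 'per_phase'")
    baseline = protocol.baseline
    rates = electrode_phase_rates(spikes, bursts, protocol)
    spiking = active_electrodes(rates, "spiking", phase=baseline)
    bursting = active_electrodes(rates, "bursting", phase=baseline)
    n_s, n_b = len(spiking), len(bursting)
    if n_s == 0 or n_b == 0:
        raise UnusableCultureError(
            f"culture {culture}: N_S({baseline})={n_s}, N_B({baseline})={n_b}"
        )
    rows = []
    for lb in protocol.labels:
        sub = rates[rates["phase"] == lb].set_index("electrode")
        spk = sub.loc[sorted(spiking)]
        bst = sub.loc[sorted(bursting)]
        mfr = spk["fr_hz"].sum() / n_s
        mbr = bst["br_per_min"].sum() / n_b
        mobfr = bst["obfr_hz"].sum() / n_b
        bd = bst["mean_bd_s"].dropna()
        if len(bd) == 0:
            mbd = np.nan
            logger.info("culture %s phase %s: no bursts, MBD undefined", culture, lb)
        else:
            denom = n_b if mbd_denominator == "s1" else len(bd)
            mbd = bd.sum() / denom
        for name, val in zip(METRIC_NAMES, (mfr, mbr, mbd, mobfr)):
            rows.append((culture, lb, name, val, n_s, n_b))
    return pd.DataFrame(
        rows,
        columns=[
            "culture",
            "phase",
            "metric",
            "value",
            "n_active_spiking",
            "n_active_bursting",
        ],
    )


def normalize_metrics(table: pd.DataFrame, baseline: str = "S1") -> pd.DataFrame:
    """Add ``normalized_pct``: per culture and metric, baseline = 100%.

    A metric whose baseline value is 0 (or undefined) gets NaN for every
    phase of that culture, with a log record.  Re-normalizing a normalized
    table recomputes the identical column, so the operation is idempotent.
    """
    out = table.copy()
    out["normalized_pct"] = np.nan
    for (culture, metric), grp in out.groupby(["culture", "metric"]):
        base = grp.loc[grp["phase"] == baseline, "value"]
        if base.empty or not np.isfinite(base.iloc[0]) or base.iloc[0] == 0:
            logger.warning(
                "culture %s metric %s: baseline value undefined or zero; "
                "normalized values excluded",
                culture,
                metric,
            )
            continue
        # divide first: v/v is exactly 1.0, so the baseline lands on 100.0
        out.loc[grp.index, "normalized_pct"] = 100.0 * (grp["value"] / base.iloc[0])
    return out


def combine_cultures(tables: list[pd.DataFrame]) -> pd.DataFrame:
    return pd.concat(tables, ignore_index=True)


# ---------------------------------------------------------------------------
# per-minute bursting-rate time course
# ---------------------------------------------------------------------------

def mbr_timecourse(
    per_culture: list[tuple[SpikeTrainSet, BurstTrain]],
    protocol: PhaseProtocol,
    bin_s: float = 60.0,
) -> pd.DataFrame:
    """Normalized MBR per time bin, aggregated over cultures.

    Per culture, bursts are counted per ``bin_s`` bin over the baseline
    bursting-active electrodes, converted to bursts/min per electrode and
    normalized so the culture's mean over the baseline phase is 100%.
    Returns a frame with ``t_center_s``, ``mean_pct``, ``sem_pct`` and one
    column per culture.
    """
    total = protocol.total_duration_s
    if not np.isclose((total / bin_s) % 1.0, 0.0) and not float(total / bin_s).is_integer():
        raise ValueError("bin must divide the protocol duration")
    n_bins = int(round(total / bin_s))
    edges = np.arange(n_bins + 1) * bin_s
    centers = (edges[:-1] + edges[1:]) / 2
    base_a, base_b = protocol.bounds_of(protocol.baseline)
    series = []
    for spikes, bursts in per_culture:
        rates = electrode_phase_rates(spikes, bursts, protocol)
        bursting = active_electrodes(rates, "bursting", phase=protocol.baseline)
        onsets = np.concatenate(
            [bursts[el].starts for el in sorted(bursting) if el in bursts]
            or [np.empty(0)]
        )
        counts, _ = np.histogram(onsets, bins=edges)
        per_min = counts / max(len(bursting), 1) / (bin_s / 60.0)
        in_base = (centers >= base_a) & (centers < base_b)
        base_mean = per_min[in_base].mean()
        series.append(
            100.0 * per_min / base_mean if base_mean > 0 else np.full(n_bins, np.nan)
        )
    mat = np.vstack(series)
    out = pd.DataFrame({"t_center_s": centers})
    out["mean_pct"] = np.nanmean(mat, axis=0)
    n = mat.shape[0]
    out["sem_pct"] = (
        np.nanstd(mat, axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.nan
    )
    for i, s in enumerate(series):
        out[f"culture_{i}"] = s
    return out
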