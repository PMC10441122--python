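"""Thermometric exposure characterization.

The specific absorption rate (SAR, W/kg) of an exposed culture medium is
estimated from its temperature transient: the initial heating phase is fit
with a saturating exponential ``dT(t) = A * (1 - exp(-(t - t_on)/tau))``,
whose initial slope is ``A/tau`` (K/s), and

    SAR = C * dT/dt |_{t=t_on}

with ``C`` the sample heat capacity (default 4196.8 J/(kg K) for culture
medium).  The same single-compartment first-order model simulates heating
curves (and the post-exposure cool-down, a symmetric exponential decay),
and incident-power bookkeeping converts a target SAR into the required
input power in dBm given a SAR-per-watt calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger("mearf")

#: culture-medium specific heat capacity, J/(kg K)
DEFAULT_HEAT_CAPACITY = 4196.8

#: longest initial segment used for the exponential fit, seconds
DEFAULT_FIT_WINDOW_S = 300.0


class DosimetryError(RuntimeError):
    """Fit failure or non-heating transient."""


@dataclass
class TemperatureTrace:
    """Sampled temperature transient with its exposure window."""

    time_s: np.ndarray
    temperature_c: np.ndarray
    t_on: float = 0.0
    t_off: float | None = None
    baseline_c: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.temperature_c = np.asarray(self.temperature_c, dtype=float)
        if len(self.time_s) != len(self.temperature_c):
            raise ValueError("time and temperature lengths differ")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.t_off is None:
            self.t_off = float(self.time_s[-1])
        if not (self.time_s[0] <= self.t_on <= self.t_off <= self.time_s[-1]):
            raise ValueError("exposure window must lie within the trace span")
        if self.baseline_c is None:
            pre = self.temperature_c[self.time_s <= self.t_on]
            self.baseline_c = float(
                np.median(pre) if len(pre) else self.temperature_c[0]
            )

    @property
    def delta_t(self) -> np.ndarray:
        return self.temperature_c - self.baseline_c

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# t_on={self.t_on}\n# t_off={self.t_off}\n")
            fh.write(f"# baseline_c={self.baseline_c}\n")
            pd.DataFrame(
                {"time_s": self.time_s, "temp_C": self.temperature_c}
            ).to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "TemperatureTrace":
        meta = {}
        skip = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                skip += 1
                if "=" in line:
                    key, val = line.lstrip("# ").split("=", 1)
                    meta[key.strip()] = float(val)
        df = pd.read_csv(path, skiprows=skip)
        return cls(
            time_s=df["time_s"].to_numpy(),
            temperature_c=df["temp_C"].to_numpy(),
            t_on=meta.get("t_on", 0.0),
            t_off=meta.get("t_off"),
            baseline_c=meta.get("baseline_c"),
        )


@dataclass
class DosimetryResult:
    slope_k_per_s: float
    heat_capacity: float
    sar_w_per_kg: float
    amplitude_c: float = np.nan
    tau_s: float = np.nan
    residual_rms_c: float = np.nan
    method: str = "exponential"

    @property
    def sar_rounded(self) -> float:
        """SAR to three significant figures (the raw value stays available)."""
        if self.sar_w_per_kg == 0:
            return 0.0
        mag = int(np.floor(np.log10(abs(self.sar_w_per_kg))))
        return round(self.sar_w_per_kg, 2 - mag)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def first_order_delta_t(
    t, sar_w_per_kg: float, tau_s: float, heat_capacity: float = DEFAULT_HEAT_CAPACITY
):
    """``dT(t) = (SAR*tau/C) * (1 - exp(-t/tau))`` — initial slope SAR/C."""
    t = np.asarray(t, dtype=float)
    return (sar_w_per_kg * tau_s / heat_capacity) * (1.0 - np.exp(-t / tau_s))


def simulate_heating(
    sar_w_per_kg: float,
    tau_s: float,
    heat_capacity: float = DEFAULT_HEAT_CAPACITY,
    duration_s: float = 900.0,
    fs_hz: float = 1.0,
    cooldown_s: float = 0.0,
    baseline_c: float = 37.0,
) -> TemperatureTrace:
    """Noise-free first-order heating curve, optional cool-down tail.

    Heating runs for ``duration_s`` (the exposure window); if ``cooldown_s``
    is positive the trace continues with a symmetric exponential decay back
    toward baseline.
    """
    if tau_s <= 0 or heat_capacity <= 0 or duration_s <= 0:
        raise ValueError("tau, heat capacity and duration must be positive")
    t = np.arange(0.0, duration_s + cooldown_s, 1.0 / fs_hz)
    dt = np.where(
        t <= duration_s,
        first_order_delta_t(t, sar_w_per_kg, tau_s, heat_capacity),
        first_order_delta_t(duration_s, sar_w_per_kg, tau_s, heat_capacity)
        * np.exp(-(t - duration_s) / tau_s),
    )
    return TemperatureTrace(
        time_s=t,
        temperature_c=baseline_c + dt,
        t_on=0.0,
        t_off=min(duration_s, float(t[-1])),
        baseline_c=baseline_c,
    )


# ---------------------------------------------------------------------------
# SAR estimation
# ---------------------------------------------------------------------------

def fit_initial_slope(
    trace: TemperatureTrace,
    fit_window_s: float = DEFAULT_FIT_WINDOW_S,
    fallback_linear: bool = False,
) -> DosimetryResult:
    """Initial heating slope (K/s) from a saturating-exponential fit.

    Fits ``dT = A*(1 - exp(-(t - t_on)/tau))`` by least squares over the
    segment from exposure onset to ``t_on + min(fit_window_s, exposure
    duration)`` and returns ``A/tau`` with fit diagnostics.  A
    non-convergent fit or non-positive amplitude raises
    :class:`DosimetryError`, unless ``fallback_linear`` is set, in which
    case a straight-line fit over the first 30 s stands in (flagged in the
    result's ``method``).
    """
    end = trace.t_on + min(fit_window_s, trace.t_off - trace.t_on)
    sel = (trace.time_s >= trace.t_on) & (trace.time_s <= end)
    t = trace.time_s[sel] - trace.t_on
    y = trace.delta_t[sel]
    if len(t) < 10:
        raise DosimetryError("need at least 10 samples after exposure onset")

    def _linear() -> DosimetryResult:
        sel30 = t <= 30.0
        if sel30.sum() < 2:
            raise DosimetryError("not enough samples for the linear fallback")
        slope, intercept = np.polyfit(t[sel30], y[sel30], 1)
        resid = y[sel30] - (slope * t[sel30] + intercept)
        return DosimetryResult(
            slope_k_per_s=float(slope),
            heat_capacity=np.nan,
            sar_w_per_kg=np.nan,
            residual_rms_c=float(np.sqrt(np.mean(resid**2))),
            method="linear-30s",
        )

    a0 = float(max(y.max(), 1e-6))
    tau0 = max((t[-1] - t[0]) / 3.0, 1.0)
    try:
        popt, _ = curve_fit(
            lambda tt, a, tau: a * (1.0 - np.exp(-tt / tau)),
            t,
            y,
            p0=(a0, tau0),
            bounds=((0.0, 1e-3), (np.inf, np.inf)),
            maxfev=10_000,
        )
    except (RuntimeError, ValueError) as exc:
        if fallback_linear:
            logger.warning("exponential fit failed (%s); linear fallback", exc)
            return _linear()
        raise DosimetryError(f"exponential fit did not converge: {exc}") from exc
    a, tau = float(popt[0]), float(popt[1])
    resid = y - a * (1.0 - np.exp(-t / tau))
    rms = float(np.sqrt(np.mean(resid**2)))
    if a <= 0 or (rms > 0 and a < 2 * rms):
        if fallback_linear:
            return _linear()
        raise DosimetryError(
            f"no heating detected (A={a:.3g}, residual RMS={rms:.3g})"
        )
    return DosimetryResult(
        slope_k_per_s=a / tau,
        heat_capacity=np.nan,
        sar_w_per_kg=np.nan,
        amplitude_c=a,
        tau_s=tau,
        residual_rms_c=rms,
    )


def sar_from_slope(
    slope_k_per_s: float, heat_capacity: float = DEFAULT_HEAT_CAPACITY
) -> float:
    """SAR (W/kg) = heat capacity x initial temperature slope."""
    if heat_capacity <= 0:
        raise ValueError("heat capacity must be positive")
    return heat_capacity * slope_k_per_s


def estimate_sar(
    trace: TemperatureTrace,
    heat_capacity: float = DEFAULT_HEAT_CAPACITY,
    fit_window_s: float = DEFAULT_FIT_WINDOW_S,
    fallback_linear: bool = False,
) -> DosimetryResult:
    """Fit the transient and convert its initial slope to SAR."""
    res = fit_initial_slope(trace, fit_window_s, fallback_linear)
    res.heat_capacity = heat_capacity
    res.sar_w_per_kg = sar_from_slope(res.slope_k_per_s, heat_capacity)
    return res


# ---------------------------------------------------------------------------
# incident-power bookkeeping
# ---------------------------------------------------------------------------

def watts_to_dbm(p_w: float) -> float:
    if p_w <= 0:
        raise ValueError("power must be positive")
    return 10.0 * np.log10(p_w * 1000.0)


def dbm_to_watts(p_dbm: float) -> float:
    return 10.0 ** (p_dbm / 10.0) / 1000.0


def required_input_power_dbm(
    target_sar_w_per_kg: float, sar_per_watt: float
) -> float:
    """Input power (dBm, to 0.1 dB) delivering a target SAR.

    ``sar_per_watt`` is the thermometric calibration of the exposure
    chamber: the SAR obtained per watt of incident power.
    """
    if target_sar_w_per_kg <= 0 or sar_per_watt <= 0:
        raise ValueError("target SAR and calibration must be positive")
    return float(round(watts_to_dbm(target_sar_w_per_kg / sar_per_watt), 1))
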