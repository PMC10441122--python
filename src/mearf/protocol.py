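"""Phased exposure timeline.

A recording session is segmented into an ordered sequence of contiguous
phases.  The default protocol is the five-phase design used throughout the
package: two pre-exposure baselines (S1, S2), the exposure phase (E) and two
post-exposure phases (P1, P2), each lasting 15 minutes, for a 75-minute
session.  Phase intervals are half-open ``[start, end)`` in seconds from
recording start, so a spike landing exactly on a boundary belongs to the
later phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

DEFAULT_PHASE_LABELS = ("S1", "S2", "E", "P1", "P2")
DEFAULT_PHASE_DURATION_S = 900.0


class ProtocolError(ValueError):
    """Invalid protocol definition or out-of-range time."""


@dataclass(frozen=True)
class PhaseProtocol:
    """Ordered contiguous phase segmentation of a recording.

    Parameters
    ----------
    labels
        Phase identifiers, in temporal order.  Must be unique.
    durations_s
        Duration of each phase in seconds; one entry per label.
    """

    labels: tuple[str, ...] = DEFAULT_PHASE_LABELS
    durations_s: tuple[float, ...] = field(
        default=(DEFAULT_PHASE_DURATION_S,) * 5
    )

    def __post_init__(self) -> None:
        if len(self.labels) == 0:
            raise ProtocolError("protocol needs at least one phase")
        if len(self.labels) != len(self.durations_s):
            raise ProtocolError(
                f"{len(self.labels)} labels but {len(self.durations_s)} durations"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ProtocolError("phase labels must be unique")
        if any(d <= 0 for d in self.durations_s):
            raise ProtocolError("phase durations must be positive")
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        object.__setattr__(
            self, "durations_s", tuple(float(d) for d in self.durations_s)
        )

    @property
    def total_duration_s(self) -> float:
        return float(sum(self.durations_s))

    @property
    def bounds(self) -> tuple[tuple[float, float], ...]:
        """Half-open ``[start, end)`` interval of each phase, in seconds."""
        edges = np.concatenate([[0.0], np.cumsum(self.durations_s)])
        return tuple((float(a), float(b)) for a, b in zip(edges[:-1], edges[1:]))

    @property
    def edges(self) -> np.ndarray:
        """Phase boundary times including 0 and total duration."""
        return np.concatenate([[0.0], np.cumsum(self.durations_s)])

    @property
    def baseline(self) -> str:
        """The reference (normalization) phase: the first phase."""
        return self.labels[0]

    def duration_of(self, label: str) -> float:
        return self.durations_s[self.labels.index(label)]

    def bounds_of(self, label: str) -> tuple[float, float]:
        return self.bounds[self.labels.index(label)]

    def phase_of(self, t: float) -> str:
        """Phase containing time ``t`` (seconds from recording start)."""
        if not (0.0 <= t < self.total_duration_s):
            raise ProtocolError(
                f"t={t} outside recording span [0, {self.total_duration_s})"
            )
        idx = int(np.searchsorted(self.edges, t, side="right")) - 1
        return self.labels[idx]

    def phase_indices(self, times: np.ndarray) -> np.ndarray:
        """Vectorized phase index for an array of times.

        Times outside ``[0, total)`` get index -1.
        """
        times = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.edges, times, side="right") - 1
        idx[(times < 0) | (times >= self.total_duration_s)] = -1
        return idx

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "phases": [
                {"label": lb, "duration_s": d}
                for lb, d in zip(self.labels, self.durations_s)
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhaseProtocol":
        phases = d["phases"]
        return cls(
            labels=tuple(p["label"] for p in phases),
            durations_s=tuple(float(p["duration_s"]) for p in phases),
        )

    @classmethod
    def from_yaml(cls, path) -> "PhaseProtocol":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)


def default_protocol() -> PhaseProtocol:
    """The built-in five-by-15-minute protocol (S1, S2, E, P1, P2)."""
    return PhaseProtocol()


def phase_of(t: float, protocol: PhaseProtocol) -> str:
    """Functional alias for :meth:`PhaseProtocol.phase_of`."""
    return protocol.phase_of(t)
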