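"""In-memory containers: continuous recordings and stimulus schedules.

Time is sample-indexed internally (0-based); seconds appear only at
interfaces. Signal values are in microvolts throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from . import montage


@dataclass
class Recording:
    """Continuous multichannel signal, channels x time, in microvolts."""

    data: np.ndarray
    fs: float
    labels: list[str]
    roles: dict[str, str] = field(default_factory=dict)
    acquisition_band: tuple[float, float] = (0.1, 70.0)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x time")
        if self.data.shape[0] != len(self.labels):
            raise ValueError("label count does not match channel count")
        if len(set(l.lower() for l in self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaN samples")
        if not self.roles:
            self.roles = {lab: montage.role_of(lab) for lab in self.labels}

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def index_of(self, label: str) -> int:
        want = label.strip().lower()
        for i, lab in enumerate(self.labels):
            if lab.lower() == want:
                return i
        raise KeyError(f"channel {label!r} not in recording "
                       f"(have {self.labels})")

    def channel(self, label: str) -> np.ndarray:
        """Single-channel view sharing the recording's time base."""
        return self.data[self.index_of(label)]

    def has_channel(self, label: str) -> bool:
        try:
            self.index_of(label)
            return True
        except KeyError:
            return False

    def require_channels(self, labels: list[str]) -> None:
        missing = [l for l in labels if not self.has_channel(l)]
        if missing:
            raise ValueError(f"recording lacks required channels: {missing}")

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy(), labels=list(self.labels),
                       roles=dict(self.roles), meta=dict(self.meta))

    def eeg_labels(self) -> list[str]:
        return [l for l in self.labels if self.roles.get(l) == "eeg"]


@dataclass(frozen=True)
class StimulusEvent:
    onset_sample: int
    type: str
    attrs: dict[str, Any] = field(default_factory=dict)

    @property
    def train_rate_hz(self) -> float | None:
        return self.attrs.get("train_rate_hz")


@dataclass
class StimulusSchedule:
    """Timed, typed stimulus events with strictly increasing onsets."""

    events: list[StimulusEvent]
    fs: float

    def __post_init__(self) -> None:
        onsets = [e.onset_sample for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.events)

    def onset_samples(self) -> np.ndarray:
        return np.array([e.onset_sample for e in self.events], dtype=int)

    def onset_seconds(self) -> np.ndarray:
        return self.onset_samples() / self.fs

    def types(self) -> list[str]:
        return [e.type for e in self.events]

    def of_type(self, *types: str) -> "StimulusSchedule":
        return StimulusSchedule(
            [e for e in self.events if e.type in types], self.fs)

    def trains_at_rate(self, rate_hz: float | None = None
                       ) -> "StimulusSchedule":
        """Train-onset events (first click of each train), optionally
        restricted to one stimulation rate."""
        picked = [e for e in self.events
                  if e.type == "click" and e.attrs.get("click_index") == 0
                  and (rate_hz is None or e.train_rate_hz == rate_hz)]
        return StimulusSchedule(picked, self.fs)

    @property
    def end_sample(self) -> int:
        return self.events[-1].onset_sample if self.events else 0
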