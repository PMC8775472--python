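"""Core containers: multi-channel EEG recordings and hypnograms.

Conventions: signal amplitudes in microvolts, time in seconds internally,
sleep stages scored on 30-s epochs with the five-stage AASM alphabet
(wake N0, NREM N1-N3, REM).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import DataError

#: Fixed stage order; ties and argmax decisions resolve to the earlier stage.
STAGES: tuple[str, ...] = ("N0", "N1", "N2", "N3", "REM")
STAGE_TO_CODE = {s: i for i, s in enumerate(STAGES)}

#: Default scoring-epoch duration in seconds (AASM).
EPOCH_SECONDS = 30.0


@dataclass
class EEGRecording:
    """Multi-channel time series with per-channel labels.

    data : (n_channels, n_samples) float array, microvolts.
    channels : channel labels (10-20 names, derivations like "Pz-Oz", EOG1/EOG2).
    rate : sampling rate in Hz.
    lights_off_s : lights-off time in seconds from record start.
    """

    data: np.ndarray
    channels: list[str]
    rate: float
    lights_off_s: float = 0.0
    subject_id: str = ""
    group: str = "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.channels):
            raise DataError(
                f"{self.data.shape[0]} rows but {len(self.channels)} channel labels"
            )
        if self.rate <= 0:
            raise DataError("sampling rate must be positive")
        if not (0.0 <= self.lights_off_s <= self.duration_s):
            raise DataError("lights-off time outside the record")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise DataError(f"channel {label!r} not in {self.channels}") from None

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    def copy_with(self, **kw) -> "EEGRecording":
        if "data" in kw and "meta" not in kw:
            kw["meta"] = dict(self.meta)
        return replace(self, **kw)

    @property
    def eeg_channels(self) -> list[str]:
        return [c for c in self.channels if not c.upper().startswith("EOG")]

    @property
    def eog_channels(self) -> list[str]:
        return [c for c in self.channels if c.upper().startswith("EOG")]


@dataclass
class Hypnogram:
    """Per-epoch sleep-stage labels.

    stages : integer codes into :data:`STAGES`, one per 30-s epoch.
    lights_off_epoch : 0-based epoch index at which lights went off.
    """

    stages: np.ndarray
    epoch_s: float = EPOCH_SECONDS
    lights_off_epoch: int = 0

    def __post_init__(self):
        self.stages = np.asarray(self.stages, dtype=np.int8)
        if self.stages.ndim != 1:
            raise DataError("stages must be one-dimensional")
        if self.stages.size and not (
            (self.stages >= 0).all() and (self.stages < len(STAGES)).all()
        ):
            raise DataError("stage codes outside the 5-stage alphabet")
        if not (0 <= self.lights_off_epoch <= max(0, self.stages.size - 1)):
            raise DataError("lights-off epoch outside the hypnogram")

    def __len__(self) -> int:
        return self.stages.size

    @property
    def labels(self) -> list[str]:
        return [STAGES[c] for c in self.stages]

    @classmethod
    def from_labels(cls, labels, epoch_s: float = EPOCH_SECONDS,
                    lights_off_epoch: int = 0) -> "Hypnogram":
        try:
            codes = np.array([STAGE_TO_CODE[str(l)] for l in labels], dtype=np.int8)
        except KeyError as e:
            raise DataError(f"unknown stage label {e.args[0]!r}") from None
        return cls(codes, epoch_s=epoch_s, lights_off_epoch=lights_off_epoch)
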