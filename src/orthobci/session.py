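"""EEG session containers and on-disk session bundles.

A session couples a continuous multichannel recording (channels x samples,
microvolts) with its stimulus event log and free-form metadata.  Signals are
stored as headered CSV (rows = samples, columns = channels) or EDF/EDF+
(read-only, via :mod:`mne` when available); events are a tab-separated table;
metadata travels in a JSON sidecar next to the signal file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONDITION_TAGS",
    "DEFAULT_CHANNELS",
    "Montage",
    "StimulusEvent",
    "Recording",
    "SessionFormatError",
    "SessionValidationError",
    "read_session",
    "write_session",
    "epoch_samples",
]

#: Electrode labels of the default eight-channel montage (10-20 positions).
DEFAULT_CHANNELS = ("Fz", "Cz", "P3", "Pz", "P4", "PO7", "PO8", "Oz")

#: Recognized experimental condition tags for stimulus events.
CONDITION_TAGS = ("calibration", "online_without_orthosis", "online_with_orthosis")

#: Columns of the events TSV, in the fixed on-disk order.
EVENT_COLUMNS = ("onset_sample", "option_id", "run_id", "cued_target", "condition_tag")

#: Post-stimulus epoch length in seconds.
EPOCH_SECONDS = 0.800


class SessionFormatError(ValueError):
    """Raised when a session file does not match the expected format."""


class SessionValidationError(ValueError):
    """Raised when session contents violate an invariant."""


def epoch_samples(sampling_rate: float) -> int:
    """Number of samples in the post-stimulus epoch window (floor of 800 ms)."""
    return int(np.floor(EPOCH_SECONDS * sampling_rate))


@dataclass(frozen=True)
class Montage:
    """Electrode montage: ordered channel labels plus reference/ground and rate."""

    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    reference: str = "right earlobe"
    ground: str = "AFz"
    sampling_rate: float = 256.0

    def __post_init__(self) -> None:
        names = tuple(self.channel_names)
        object.__setattr__(self, "channel_names", names)
        if len(set(names)) != len(names):
            raise SessionValidationError("montage channel names must be unique")
        if not self.sampling_rate > 0:
            raise SessionValidationError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


@dataclass(frozen=True)
class StimulusEvent:
    """One flashing event: which option flashed, where in the signal, and context.

    ``cued_target`` is the option the subject was instructed to attend (None for
    free selections); ``condition_tag`` distinguishes calibration from the two
    online conditions.
    """

    onset_sample: int
    option_id: int
    run_id: int
    cued_target: int | None = None
    condition_tag: str = "calibration"

    def __post_init__(self) -> None:
        if self.onset_sample < 0:
            raise SessionValidationError("onset_sample must be non-negative")
        if self.option_id < 0:
            raise SessionValidationError("option_id must be non-negative")
        if self.condition_tag not in CONDITION_TAGS:
            raise SessionValidationError(
                f"unknown condition_tag {self.condition_tag!r}; "
                f"expected one of {CONDITION_TAGS}"
            )

    @property
    def is_target(self) -> bool | None:
        """Whether this flash hit the cued option (None when no cue is set)."""
        if self.cued_target is None:
            return None
        return self.option_id == self.cued_target


@dataclass
class Recording:
    """Continuous EEG (channels x samples, microvolts) with events and metadata."""

    signals: np.ndarray
    montage: Montage = field(default_factory=Montage)
    events: list[StimulusEvent] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise SessionValidationError("signals must be a 2-D channels x samples array")
        if self.signals.shape[0] != self.montage.n_channels:
            raise SessionFormatError(
                f"signal has {self.signals.shape[0]} channels but montage lists "
                f"{self.montage.n_channels}"
            )
        self.events = sorted(self.events, key=lambda ev: ev.onset_sample)

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.montage.sampling_rate

    def with_signals(self, signals: np.ndarray) -> "Recording":
        """Copy of this recording with ``signals`` replaced (same events/montage)."""
        return Recording(signals=signals, montage=self.montage,
                         events=list(self.events), metadata=dict(self.metadata))

    def validate_events(self) -> None:
        """Check every event's epoch window fits inside the recording."""
        n_t = epoch_samples(self.montage.sampling_rate)
        for i, ev in enumerate(self.events):
            if ev.onset_sample + n_t > self.n_samples:
                raise SessionValidationError(
                    f"event row {i}: onset_sample {ev.onset_sample} leaves no room "
                    f"for a {n_t}-sample epoch in a {self.n_samples}-sample signal"
                )


def _events_to_frame(events: Iterable[StimulusEvent]) -> pd.DataFrame:
    rows = [
        {
            "onset_sample": ev.onset_sample,
            "option_id": ev.option_id,
            "run_id": ev.run_id,
            "cued_target": "NA" if ev.cued_target is None else ev.cued_target,
            "condition_tag": ev.condition_tag,
        }
        for ev in events
    ]
    return pd.DataFrame(rows, columns=list(EVENT_COLUMNS))


def _events_from_frame(frame: pd.DataFrame, path: Path) -> list[StimulusEvent]:
    missing = set(EVENT_COLUMNS) - set(frame.columns)
    if missing:
        raise SessionFormatError(f"{path}: events file lacks columns {sorted(missing)}")
    events = []
    for i, row in frame.iterrows():
        cued = row["cued_target"]
        if pd.isna(cued) or str(cued).upper() == "NA":
            cued_target: int | None = None
        else:
            cued_target = int(cued)
        try:
            events.append(
                StimulusEvent(
                    onset_sample=int(row["onset_sample"]),
                    option_id=int(row["option_id"]),
                    run_id=int(row["run_id"]),
                    cued_target=cued_target,
                    condition_tag=str(row["condition_tag"]),
                )
            )
        except SessionValidationError as exc:
            raise SessionValidationError(f"{path}: events row {i}: {exc}") from exc
    return events


def _metadata_sidecar(signal_path: Path) -> Path:
    return signal_path.with_suffix(signal_path.suffix + ".meta.json")


def _read_edf(path: Path) -> tuple[np.ndarray, Montage]:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is normally present
        raise SessionFormatError(
            f"{path}: reading EDF requires the optional 'mne' dependency"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    # MNE returns volts for EEG channels; internal unit is microvolts.
    signals = raw.get_data() * 1e6
    montage = Montage(channel_names=tuple(raw.ch_names),
                      sampling_rate=float(raw.info["sfreq"]))
    return signals, montage


def _read_csv_signals(path: Path) -> tuple[np.ndarray, tuple[str, ...]]:
    frame = pd.read_csv(path)
    if frame.shape[1] == 0:
        raise SessionFormatError(f"{path}: empty signal CSV")
    channels = tuple(str(c) for c in frame.columns)
    return frame.to_numpy(dtype=float).T, channels


def read_session(signal_path: str | Path, events_path: str | Path,
                 montage: Montage | None = None) -> Recording:
    """Load a session bundle from disk.

    Parameters
    ----------
    signal_path
        EDF/EDF+ file or headered CSV (rows = samples, columns = channels,
        values in microvolts).
    events_path
        Tab-separated event log with columns ``onset_sample``, ``option_id``,
        ``run_id``, ``cued_target`` ("NA" for none) and ``condition_tag``.
    montage
        Expected montage; defaults to the standard eight-channel layout for
        CSV input.  A channel-count mismatch raises :class:`SessionFormatError`.
    """
    signal_path = Path(signal_path)
    events_path = Path(events_path)

    if signal_path.suffix.lower() in {".edf", ".bdf"}:
        signals, file_montage = _read_edf(signal_path)
        if montage is not None:
            if montage.n_channels != file_montage.n_channels:
                raise SessionFormatError(
                    f"{signal_path}: {file_montage.n_channels} channels on disk, "
                    f"montage expects {montage.n_channels}"
                )
            file_montage = montage
        montage = file_montage
    else:
        signals, channels = _read_csv_signals(signal_path)
        if montage is None:
            montage = Montage(channel_names=channels) if channels != tuple(
                DEFAULT_CHANNELS) else Montage()
        elif montage.n_channels != len(channels):
            raise SessionFormatError(
                f"{signal_path}: {len(channels)} channels on disk, montage "
                f"expects {montage.n_channels}"
            )

    events_frame = pd.read_csv(events_path, sep="\t")
    events = _events_from_frame(events_frame, events_path)

    metadata: dict[str, Any] = {}
    sidecar = _metadata_sidecar(signal_path)
    if sidecar.exists():
        metadata = json.loads(sidecar.read_text())

    recording = Recording(signals=signals, montage=montage, events=events,
                          metadata=metadata)
    recording.validate_events()
    return recording


def write_session(recording: Recording, signal_path: str | Path,
                  events_path: str | Path) -> None:
    """Write a session bundle (CSV signals + TSV events + JSON metadata sidecar).

    Signals must be finite; non-finite samples indicate an upstream bug and are
    refused rather than silently serialized.
    """
    if not np.all(np.isfinite(recording.signals)):
        raise SessionValidationError("signals contain non-finite values")
    signal_path = Path(signal_path)
    events_path = Path(events_path)

    frame = pd.DataFrame(recording.signals.T,
                         columns=list(recording.montage.channel_names))
    frame.to_csv(signal_path, index=False, float_format="%.8g")

    _events_to_frame(recording.events).to_csv(events_path, sep="\t", index=False)

    if recording.metadata:
        _metadata_sidecar(signal_path).write_text(
            json.dumps(recording.metadata, indent=1, sort_keys=True))
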