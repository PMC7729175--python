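"""Band-limited filtering, epoch extraction, artifact validation, decimation.

The front end of the pipeline extracts three band-limited versions of the raw
EEG (4-14 Hz for classification features, 20-40 Hz and 4-40 Hz for artifact
screening), cuts 800 ms post-stimulus epochs, flags artifact-contaminated
epochs from per-channel amplitude/variance/high-frequency-power statistics,
and decimates the 4-14 Hz epoch by four for the feature stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .session import Recording, StimulusEvent, epoch_samples

__all__ = [
    "SYSTEM_BANDS",
    "BandSpec",
    "ArtifactThresholds",
    "Epoch",
    "EpochQuality",
    "DownsampledEpoch",
    "design_bandpass",
    "filter_recording",
    "filter_bands",
    "extract_epoch",
    "assess_quality",
    "downsample",
]

#: Default FIR order (number of taps minus one) at 256 Hz.
DEFAULT_FILTER_ORDER = 256

#: Decimation factor applied to the 4-14 Hz epoch.
DECIMATION_FACTOR = 4


@dataclass(frozen=True)
class BandSpec:
    """Pass band in Hz for the FIR band-pass filter."""

    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(f"invalid band ({self.low_hz}, {self.high_hz}) Hz")

    def validate_nyquist(self, sampling_rate: float) -> None:
        if self.high_hz >= sampling_rate / 2:
            raise ValueError(
                f"band edge {self.high_hz} Hz violates Nyquist for "
                f"{sampling_rate} Hz sampling"
            )


#: The three system bands: features (4-14), muscle screen (20-40), broad (4-40).
SYSTEM_BANDS = {
    "4-14": BandSpec(4.0, 14.0),
    "20-40": BandSpec(20.0, 40.0),
    "4-40": BandSpec(4.0, 40.0),
}


@dataclass(frozen=True)
class ArtifactThresholds:
    """Rejection thresholds; an epoch is an artifact when ANY channel reaches one.

    Semantics are "greater or equal": peak-to-peak >= 200 uV, standard
    deviation >= 50 uV, or 20-40/4-40 power ratio >= 0.7.
    """

    v_pp_uv: float = 200.0
    sigma_uv: float = 50.0
    power_ratio: float = 0.7


@dataclass
class Epoch:
    """One flashing event's band-filtered signal matrices (n_channels x n_t, uV)."""

    X_4_14: np.ndarray
    X_20_40: np.ndarray
    X_4_40: np.ndarray
    source_event: StimulusEvent

    def __post_init__(self) -> None:
        shapes = {self.X_4_14.shape, self.X_20_40.shape, self.X_4_40.shape}
        if len(shapes) != 1:
            raise ValueError(f"band matrices disagree in shape: {shapes}")

    @property
    def n_channels(self) -> int:
        return self.X_4_40.shape[0]

    @property
    def n_t(self) -> int:
        return self.X_4_40.shape[1]


@dataclass(frozen=True)
class EpochQuality:
    """Per-channel artifact metrics and the resulting verdict."""

    v_pp: np.ndarray
    sigma: np.ndarray
    power_ratio: np.ndarray
    verdict: str  # "valid" or "artifact"

    @property
    def is_valid(self) -> bool:
        return self.verdict == "valid"


@dataclass
class DownsampledEpoch:
    """Decimated 4-14 Hz epoch (n_channels x ceil(n_t/4), uV)."""

    Y: np.ndarray
    source_event: StimulusEvent | None = None

    @property
    def n_channels(self) -> int:
        return self.Y.shape[0]

    @property
    def n_hat_t(self) -> int:
        return self.Y.shape[1]


def design_bandpass(band: BandSpec, sampling_rate: float,
                    order: int = DEFAULT_FILTER_ORDER) -> np.ndarray:
    """Hamming-window linear-phase FIR band-pass taps for ``band``."""
    band.validate_nyquist(sampling_rate)
    return sps.firwin(order + 1, [band.low_hz, band.high_hz], pass_zero=False,
                      window="hamming", fs=sampling_rate)


def filter_recording(recording: Recording, band: BandSpec,
                     order: int = DEFAULT_FILTER_ORDER) -> Recording:
    """Band-pass every channel, compensating the FIR group delay.

    The filter is a causal linear-phase FIR; applied offline, its constant
    group delay (order/2 samples) is removed by shifting, so epoch windows
    indexed by stimulus onset stay stimulus-locked.  The tail is zero-padded,
    matching what a causal online implementation would have seen mid-stream.
    """
    taps = design_bandpass(band, recording.montage.sampling_rate, order)
    delay = order // 2
    padded = np.pad(recording.signals, ((0, 0), (0, delay)))
    filtered = sps.lfilter(taps, 1.0, padded, axis=1)[:, delay:]
    return recording.with_signals(filtered)


def filter_bands(recording: Recording,
                 order: int = DEFAULT_FILTER_ORDER) -> dict[str, Recording]:
    """The three system band-limited recordings keyed by band name."""
    return {name: filter_recording(recording, band, order)
            for name, band in SYSTEM_BANDS.items()}


def extract_epoch(filtered_bands: dict[str, Recording],
                  event: StimulusEvent) -> Epoch:
    """Cut the half-open window [onset, onset + n_t) from all three bands."""
    ref = filtered_bands["4-40"]
    n_t = epoch_samples(ref.montage.sampling_rate)
    start, stop = event.onset_sample, event.onset_sample + n_t
    if stop > ref.n_samples:
        raise IndexError(
            f"epoch window [{start}, {stop}) overruns {ref.n_samples}-sample signal"
        )
    return Epoch(
        X_4_14=filtered_bands["4-14"].signals[:, start:stop].copy(),
        X_20_40=filtered_bands["20-40"].signals[:, start:stop].copy(),
        X_4_40=filtered_bands["4-40"].signals[:, start:stop].copy(),
        source_event=event,
    )


def assess_quality(epoch: Epoch,
                   thresholds: ArtifactThresholds = ArtifactThresholds()
                   ) -> EpochQuality:
    """Per-channel artifact statistics of an epoch.

    On the broad-band (4-40 Hz) matrix: peak-to-peak voltage and the sample
    standard deviation (n_t - 1 denominator).  The power ratio is the 20-40 Hz
    energy over the 4-40 Hz energy per channel; a zero broad-band denominator
    marks a dead/disconnected channel and yields an artifact verdict (the
    ratio is reported as NaN).
    """
    X = epoch.X_4_40
    v_pp = X.max(axis=1) - X.min(axis=1)
    sigma = X.std(axis=1, ddof=1)
    denom = np.sum(X ** 2, axis=1)
    numer = np.sum(epoch.X_20_40 ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), np.nan)

    degenerate = denom == 0
    bad = (
        (v_pp >= thresholds.v_pp_uv)
        | (sigma >= thresholds.sigma_uv)
        | (np.nan_to_num(ratio, nan=np.inf) >= thresholds.power_ratio)
        | degenerate
    )
    verdict = "artifact" if bool(bad.any()) else "valid"
    return EpochQuality(v_pp=v_pp, sigma=sigma, power_ratio=ratio, verdict=verdict)


def downsample(epoch: Epoch, quality: EpochQuality | None = None,
               factor: int = DECIMATION_FACTOR) -> DownsampledEpoch:
    """Decimate the 4-14 Hz epoch by plain subsampling (stride ``factor``, phase 0).

    The 4-14 Hz content is far below the post-decimation Nyquist (32 Hz at
    the default geometry), so no extra anti-alias filtering is applied.  The
    caller must not decimate artifact-flagged epochs; passing their quality
    enforces the contract.
    """
    if quality is not None and not quality.is_valid:
        raise ValueError("refusing to downsample an artifact-flagged epoch")
    return DownsampledEpoch(Y=epoch.X_4_14[:, ::factor].copy(),
                            source_event=epoch.source_event)
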