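"""Synthetic EEG session generation and online replay.

The simulator emulates the statistical structure the pipeline assumes: a
stimulus-locked evoked deflection (positive peak ~350 ms, optional early
negativity ~220 ms) added on target flashes with a posterior-weighted scalp
topography, on top of spatially correlated 1/f-shaped background noise with
an alpha-band bump, plus occasional high-amplitude raised-cosine artifact
bursts.  It is a statistical stand-in for oddball EEG, not a biophysical
forward model.

The replay engine re-executes the full online pipeline (filter -> epoch ->
validate -> downsample -> project -> classify -> controller) over any
recording carrying online events, which makes simulated online attempts and
offline re-scoring share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import preprocessing as pp
from .calibration import CalibrationSchedule, ScheduleConfig, TrainedSystem, \
    _balanced_flash_order, build_schedule
from .classification import classify
from .controller import ARTIFACT, AttemptResult, ControllerConfig, run_attempt
from .session import Montage, Recording, StimulusEvent, epoch_samples
from .spatial import apply_filters

__all__ = [
    "SimulationParams",
    "SimulatedSession",
    "ReplayedAttempt",
    "erp_template",
    "colored_noise",
    "simulate_calibration",
    "simulate_online_session",
    "simulate_online_attempt",
    "replay",
]

#: Default scalp gains (Fz, Cz, P3, Pz, P4, PO7, PO8, Oz): centro-parietal focus.
DEFAULT_TOPOGRAPHY = (0.6, 0.9, 0.8, 1.0, 0.8, 0.7, 0.7, 0.6)


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings; defaults define the standard study conditions.

    Amplitudes are in microvolts.  ``erp_width_ms`` and the early-negativity
    width are full widths at half maximum of the Gaussian lobes.  Noise is
    1/f^exponent-shaped with an alpha (10 Hz) bump and fixed inter-channel
    correlation; artifacts are raised-cosine bursts on a random channel.
    """

    erp_amplitude: float = 5.0
    erp_latency_ms: float = 350.0
    erp_width_ms: float = 120.0
    early_negativity_amplitude: float = 2.0
    early_negativity_latency_ms: float = 220.0
    early_negativity_width_ms: float = 60.0
    topography: tuple[float, ...] = DEFAULT_TOPOGRAPHY
    noise_rms: float = 3.5
    noise_exponent: float = 1.0
    alpha_bump_gain: float = 1.0
    channel_correlation: float = 0.3
    artifact_rate_per_min: float = 2.0
    artifact_amplitude: float = 300.0
    artifact_duration_ms: float = 200.0

    def __post_init__(self) -> None:
        if self.erp_amplitude < 0 or self.early_negativity_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.erp_latency_ms + self.erp_width_ms / 2 > 800.0:
            raise ValueError("evoked peak must fit inside the 800 ms window")


@dataclass(frozen=True)
class GroundTruth:
    """Per-event truth of a simulated session."""

    event_classes: tuple[str, ...]       # target / non-target per event
    artifact_flags: tuple[bool, ...]     # epoch window touched by a burst
    cued_targets: dict[int, int]         # run_id -> cued option


@dataclass
class SimulatedSession:
    """A synthetic recording together with its generation ground truth."""

    recording: Recording
    ground_truth: GroundTruth


@dataclass(frozen=True)
class ReplayedAttempt:
    """One replayed online run; ``result`` is None when the recording was
    truncated before the run's epochs were complete."""

    run_id: int
    cued_target: int
    result: AttemptResult | None

    @property
    def valid(self) -> bool:
        return self.result is not None


def erp_template(params: SimulationParams, sampling_rate: float) -> np.ndarray:
    """Single-channel evoked waveform over the 800 ms post-stimulus window."""
    n_t = epoch_samples(sampling_rate)
    t_ms = np.arange(n_t) / sampling_rate * 1000.0

    def lobe(amplitude: float, latency: float, fwhm: float) -> np.ndarray:
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return amplitude * np.exp(-0.5 * ((t_ms - latency) / sigma) ** 2)

    wave = lobe(params.erp_amplitude, params.erp_latency_ms, params.erp_width_ms)
    if params.early_negativity_amplitude > 0:
        wave = wave - lobe(params.early_negativity_amplitude,
                           params.early_negativity_latency_ms,
                           params.early_negativity_width_ms)
    return wave


def colored_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                  sampling_rate: float, params: SimulationParams) -> np.ndarray:
    """Spatially correlated, spectrally shaped Gaussian background noise.

    Independent white channels are shaped in the frequency domain with
    amplitude  f^(-exponent/2) * (1 + alpha_gain * gauss(f; 10 Hz, 2 Hz)),
    mixed to the configured uniform inter-channel correlation, and scaled to
    the configured per-channel RMS.
    """
    white = rng.standard_normal((n_channels, n_samples))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    f = np.maximum(freqs, 0.5)  # flatten the shape below 0.5 Hz
    shape = f ** (-params.noise_exponent / 2.0)
    shape = shape * (1.0 + params.alpha_bump_gain
                     * np.exp(-0.5 * ((freqs - 10.0) / 2.0) ** 2))
    shape[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(np.fft.rfft(white, axis=1) * shape, n=n_samples, axis=1)

    rho = params.channel_correlation
    corr = (1.0 - rho) * np.eye(n_channels) + rho * np.ones((n_channels,
                                                             n_channels))
    mixed = np.linalg.cholesky(corr) @ shaped
    std = mixed.std(axis=1).mean()
    if std > 0:
        mixed *= params.noise_rms / std
    return mixed


def _place_artifacts(rng: np.random.Generator, signals: np.ndarray,
                     sampling_rate: float, params: SimulationParams
                     ) -> list[tuple[int, int]]:
    """Add raised-cosine bursts in place; returns their [start, stop) spans."""
    n_channels, n_samples = signals.shape
    duration = int(params.artifact_duration_ms / 1000.0 * sampling_rate)
    minutes = n_samples / sampling_rate / 60.0
    n_bursts = rng.poisson(params.artifact_rate_per_min * minutes)
    spans = []
    if duration < 2:
        return spans
    # Raised-cosine envelope modulating a 7 Hz oscillation: bursts keep their
    # full amplitude inside the 4-40 Hz analysis band (a plain hump would be
    # mostly DC and get attenuated before the artifact screening sees it).
    t = np.arange(duration)
    envelope = 0.5 * (1.0 - np.cos(2.0 * np.pi * t / (duration - 1)))
    window = params.artifact_amplitude * envelope * np.cos(
        2.0 * np.pi * 7.0 * t / sampling_rate)
    for _ in range(n_bursts):
        start = int(rng.integers(0, max(n_samples - duration, 1)))
        channel = int(rng.integers(0, n_channels))
        signals[channel, start:start + duration] += window
        spans.append((start, start + duration))
    return spans


def _flag_artifacts(events: list[StimulusEvent], spans: list[tuple[int, int]],
                    n_t: int) -> tuple[bool, ...]:
    flags = []
    for ev in events:
        lo, hi = ev.onset_sample, ev.onset_sample + n_t
        flags.append(any(start < hi and stop > lo for start, stop in spans))
    return tuple(flags)


def _synthesize(events: list[StimulusEvent], n_samples: int, montage: Montage,
                params: SimulationParams, seed_sequence: np.random.SeedSequence,
                metadata: dict) -> SimulatedSession:
    """Shared signal synthesis for calibration and online sessions."""
    noise_ss, artifact_ss = seed_sequence.spawn(2)
    signals = colored_noise(np.random.default_rng(noise_ss),
                            montage.n_channels, n_samples,
                            montage.sampling_rate, params)
    template = erp_template(params, montage.sampling_rate)
    gains = np.asarray(params.topography, dtype=float)
    if gains.size != montage.n_channels:
        raise ValueError("topography length must match the channel count")
    n_t = template.size
    classes = []
    for ev in events:
        is_target = ev.option_id == ev.cued_target
        classes.append("target" if is_target else "non-target")
        if is_target and params.erp_amplitude > 0:
            stop = min(ev.onset_sample + n_t, n_samples)
            width = stop - ev.onset_sample
            signals[:, ev.onset_sample:stop] += np.outer(gains,
                                                         template[:width])
    spans = _place_artifacts(np.random.default_rng(artifact_ss), signals,
                             montage.sampling_rate, params)
    recording = Recording(signals=signals, montage=montage, events=events,
                          metadata=metadata)
    truth = GroundTruth(
        event_classes=tuple(classes),
        artifact_flags=_flag_artifacts(events, spans,
                                       epoch_samples(montage.sampling_rate)),
        cued_targets={ev.run_id: ev.cued_target for ev in events
                      if ev.cued_target is not None},
    )
    return SimulatedSession(recording=recording, ground_truth=truth)


def simulate_calibration(schedule: CalibrationSchedule,
                         params: SimulationParams = SimulationParams(),
                         seed: int = 0) -> SimulatedSession:
    """Synthesize the continuous recording of a calibration session."""
    montage = Montage(sampling_rate=schedule.config.sampling_rate)
    fs = montage.sampling_rate
    events = schedule.to_events()
    n_samples = int(np.ceil(schedule.config.session_s * fs)) + epoch_samples(fs)
    return _synthesize(events, n_samples, montage, params,
                       np.random.SeedSequence([seed, 0x5E551]),
                       metadata={"kind": "simulated_calibration", "seed": seed})


def _online_events(rng: np.random.Generator, cued_target: int, run_id: int,
                   start_sample: int, config: ControllerConfig,
                   cycle_s: float, sampling_rate: float,
                   condition_tag: str) -> list[StimulusEvent]:
    n_flashes = int(np.ceil(config.attempt_timeout_s / cycle_s)) + config.n_c
    n_rounds = int(np.ceil(n_flashes / config.n_c))
    options = _balanced_flash_order(rng, n_rounds, config.n_c)
    return [StimulusEvent(
        onset_sample=start_sample + int(round(i * cycle_s * sampling_rate)),
        option_id=opt, run_id=run_id, cued_target=cued_target,
        condition_tag=condition_tag) for i, opt in enumerate(options)]


def simulate_online_session(cued_targets: list[int],
                            params: SimulationParams = SimulationParams(),
                            config: ControllerConfig = ControllerConfig(),
                            seed: int = 0, cycle_s: float = 0.150,
                            sampling_rate: float = 256.0,
                            condition_tag: str = "online_without_orthosis"
                            ) -> SimulatedSession:
    """Synthesize a sequence of online attempts, one run per cued target.

    Each run carries a full timeout's worth of flashing (the replay engine
    stops early once a selection fires), separated by the post-selection
    pause plus rest interval.
    """
    ss = np.random.SeedSequence([seed, 0x0B1])
    sched_rng = np.random.default_rng(ss.spawn(1)[0])
    montage = Montage(sampling_rate=sampling_rate)
    run_gap = int((config.selection_pause_s + config.rest_s) * sampling_rate)
    run_len = int(np.ceil((config.attempt_timeout_s + 1.0) * sampling_rate))

    events: list[StimulusEvent] = []
    for run_id, cue in enumerate(cued_targets):
        start = run_id * (run_len + run_gap)
        events.extend(_online_events(sched_rng, cue, run_id, start, config,
                                     cycle_s, sampling_rate, condition_tag))
    n_samples = len(cued_targets) * (run_len + run_gap) + epoch_samples(
        sampling_rate)
    return _synthesize(events, n_samples, montage, params, ss,
                       metadata={"kind": "simulated_online", "seed": seed,
                                 "condition": condition_tag})


def _label_event(bands: dict[str, Recording], ev: StimulusEvent,
                 trained: TrainedSystem,
                 thresholds: pp.ArtifactThresholds) -> str:
    epoch = pp.extract_epoch(bands, ev)
    quality = pp.assess_quality(epoch, thresholds)
    if not quality.is_valid:
        return ARTIFACT
    projected = apply_filters(pp.downsample(epoch, quality),
                              trained.filter_bank)
    return classify(projected, trained.model)


def replay(recording: Recording, trained: TrainedSystem,
           config: ControllerConfig = ControllerConfig(),
           thresholds: pp.ArtifactThresholds = pp.ArtifactThresholds(),
           filter_order: int = pp.DEFAULT_FILTER_ORDER
           ) -> list[ReplayedAttempt]:
    """Deterministically re-run the online pipeline over a recorded session.

    Events are grouped into attempts by run id.  Within a run, each flash is
    labeled once its 800 ms epoch is complete; the label-stream timestamp is
    the epoch-completion time relative to the run's first flash, so selection
    times include the processing lag a live system would incur.  Runs whose
    epochs overrun a truncated recording are reported invalid.
    """
    online = [ev for ev in recording.events
              if ev.condition_tag.startswith("online")]
    if not online:
        raise ValueError("recording has no online events")
    if any(ev.cued_target is None for ev in online):
        raise ValueError("online events must carry cued_target")

    bands = pp.filter_bands(recording, order=filter_order)
    fs = recording.montage.sampling_rate
    n_t = epoch_samples(fs)
    lag_s = n_t / fs

    attempts: list[ReplayedAttempt] = []
    run_ids = sorted({ev.run_id for ev in online})
    for run_id in run_ids:
        run_events = [ev for ev in online if ev.run_id == run_id]
        cue = run_events[0].cued_target
        t0 = run_events[0].onset_sample / fs
        if run_events[0].onset_sample + n_t > recording.n_samples:
            attempts.append(ReplayedAttempt(run_id=run_id, cued_target=cue,
                                            result=None))
            continue

        truncated = False

        def stream():
            nonlocal truncated
            for ev in run_events:
                if ev.onset_sample + n_t > recording.n_samples:
                    truncated = True  # mid-run truncation: no further labels
                    return
                label = _label_event(bands, ev, trained, thresholds)
                yield (ev.onset_sample / fs - t0 + lag_s, ev.option_id, label)

        result = run_attempt(stream(), config)
        if truncated and result.timed_out:
            # A timeout verdict cannot be trusted when the run was cut short.
            result = None
        attempts.append(ReplayedAttempt(run_id=run_id, cued_target=cue,
                                        result=result))
    return attempts


def simulate_online_attempt(trained: TrainedSystem, cued_target: int,
                            params: SimulationParams = SimulationParams(),
                            config: ControllerConfig = ControllerConfig(),
                            seed: int = 0) -> AttemptResult:
    """Synthesize one online attempt and run the full pipeline over it."""
    session = simulate_online_session([cued_target], params=params,
                                      config=config, seed=seed)
    replayed = replay(session.recording, trained, config)
    assert replayed and replayed[0].result is not None
    return replayed[0].result
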