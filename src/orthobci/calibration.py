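"""Calibration-session scheduling and end-to-end system training.

A calibration session is eight 40 s runs.  Each run cues one target option,
then flashes the six options in 33 balanced random rounds (one flash per
option per round) at a 150 ms stimulus cycle - 29.7 s of flashing per run -
yielding exactly 264 target and 1,320 non-target epochs per session.
Training pre-processes the whole session, fits the CCA spatial filter bank on
the artifact-free target epochs, projects both classes through it, and runs
the stepwise RLDA search on the projected features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import preprocessing as pp
from .classification import ClassifierModel, StepwiseConfig, flatten_features, \
    stepwise_select_and_fit
from .session import Montage, Recording, StimulusEvent
from .spatial import DEFAULT_N_W, SpatialFilterBank, TargetEpochSet, \
    apply_filters, fit_cca_filters

__all__ = [
    "ScheduleConfig",
    "CalibrationRun",
    "CalibrationSchedule",
    "TrainingConfig",
    "TrainedSystem",
    "build_schedule",
    "assemble_training_set",
    "project_features",
    "train_system",
]


@dataclass(frozen=True)
class ScheduleConfig:
    """Geometry and timing of a calibration session.

    The non-flashing phase durations (fixation/cue/preparation/rest) pad each
    run to 40 s so the eight-run session lasts 320 s.
    """

    n_runs: int = 8
    rounds_per_run: int = 33
    n_c: int = 6
    cycle_s: float = 0.150
    fixation_s: float = 3.0
    cue_s: float = 2.0
    preparation_s: float = 2.0
    rest_s: float = 3.3
    sampling_rate: float = 256.0
    balanced_targets: bool = False

    @property
    def flashes_per_run(self) -> int:
        return self.rounds_per_run * self.n_c

    @property
    def flashing_s(self) -> float:
        return self.flashes_per_run * self.cycle_s

    @property
    def run_s(self) -> float:
        return (self.fixation_s + self.cue_s + self.preparation_s
                + self.flashing_s + self.rest_s)

    @property
    def session_s(self) -> float:
        return self.n_runs * self.run_s


@dataclass(frozen=True)
class CalibrationRun:
    """One training run: its cued target and the ordered flash list."""

    run_id: int
    cued_target: int
    flash_options: tuple[int, ...]
    flash_times_s: tuple[float, ...]  # absolute, from session start


@dataclass
class CalibrationSchedule:
    """Full calibration session schedule."""

    runs: list[CalibrationRun]
    config: ScheduleConfig
    seed: int

    @property
    def n_target_flashes(self) -> int:
        return sum(sum(1 for o in run.flash_options if o == run.cued_target)
                   for run in self.runs)

    @property
    def n_nontarget_flashes(self) -> int:
        return sum(len(run.flash_options) for run in self.runs) \
            - self.n_target_flashes

    def to_events(self) -> list[StimulusEvent]:
        fs = self.config.sampling_rate
        events = []
        for run in self.runs:
            for opt, t in zip(run.flash_options, run.flash_times_s):
                events.append(StimulusEvent(
                    onset_sample=int(round(t * fs)), option_id=opt,
                    run_id=run.run_id, cued_target=run.cued_target,
                    condition_tag="calibration"))
        return events


def _balanced_flash_order(rng: np.random.Generator, n_rounds: int,
                          n_c: int) -> list[int]:
    """Rounds of random option permutations, no option flashing twice in a row."""
    order: list[int] = []
    for _ in range(n_rounds):
        perm = rng.permutation(n_c)
        while order and perm[0] == order[-1]:
            perm = rng.permutation(n_c)
        order.extend(int(o) for o in perm)
    return order


def build_schedule(seed: int, config: ScheduleConfig = ScheduleConfig()
                   ) -> CalibrationSchedule:
    """Reproducible calibration schedule for ``seed``.

    Every option flashes exactly once per round (balanced randomization - the
    only flashing scheme consistent with the fixed per-class epoch counts),
    and never twice consecutively across round boundaries.  Cued targets are
    drawn uniformly per run, or as a balanced shuffle when
    ``config.balanced_targets`` is set.
    """
    rng = np.random.default_rng(seed)
    if config.balanced_targets:
        pool = np.tile(np.arange(config.n_c),
                       int(np.ceil(config.n_runs / config.n_c)))[:config.n_runs]
        targets = rng.permutation(pool)
    else:
        targets = rng.integers(0, config.n_c, size=config.n_runs)

    runs = []
    flash_offset = config.fixation_s + config.cue_s + config.preparation_s
    for r in range(config.n_runs):
        run_start = r * config.run_s
        options = _balanced_flash_order(rng, config.rounds_per_run, config.n_c)
        times = tuple(run_start + flash_offset + i * config.cycle_s
                      for i in range(len(options)))
        runs.append(CalibrationRun(run_id=r, cued_target=int(targets[r]),
                                   flash_options=tuple(options),
                                   flash_times_s=times))
    return CalibrationSchedule(runs=runs, config=config, seed=seed)


@dataclass(frozen=True)
class TrainingConfig:
    """End-to-end training knobs."""

    n_w: int = DEFAULT_N_W
    filter_order: int = pp.DEFAULT_FILTER_ORDER
    thresholds: pp.ArtifactThresholds = field(
        default_factory=pp.ArtifactThresholds)
    stepwise: StepwiseConfig = field(default_factory=StepwiseConfig)
    min_target_epochs: int = 20
    compute_cv: bool = True
    cv_seed: int = 0


@dataclass
class TrainedSystem:
    """Spatial filter bank + classifier + training report, from one session."""

    filter_bank: SpatialFilterBank
    model: ClassifierModel
    report: dict


def assemble_training_set(recording: Recording,
                          config: TrainingConfig = TrainingConfig()
                          ) -> tuple[TargetEpochSet, list[pp.DownsampledEpoch], int]:
    """Pre-process a calibration recording into labeled artifact-free epochs.

    Returns the target epoch set, the non-target epochs, and the number of
    epochs rejected as artifacts.  Class labels come from comparing each
    flashed option with the run's cued target.
    """
    events = [ev for ev in recording.events if ev.condition_tag == "calibration"]
    if not events:
        raise ValueError("recording has no calibration events")
    if any(ev.cued_target is None for ev in events):
        raise ValueError("calibration events must carry cued_target")

    bands = pp.filter_bands(recording, order=config.filter_order)
    targets: list[pp.DownsampledEpoch] = []
    non_targets: list[pp.DownsampledEpoch] = []
    n_artifacts = 0
    for ev in events:
        epoch = pp.extract_epoch(bands, ev)
        quality = pp.assess_quality(epoch, config.thresholds)
        if not quality.is_valid:
            n_artifacts += 1
            continue
        down = pp.downsample(epoch, quality)
        (targets if ev.is_target else non_targets).append(down)

    if len(targets) < config.min_target_epochs:
        raise ValueError(
            f"only {len(targets)} valid target epochs; need at least "
            f"{config.min_target_epochs} to train")
    return TargetEpochSet(targets), non_targets, n_artifacts


def project_features(epochs: list[pp.DownsampledEpoch],
                     bank: SpatialFilterBank) -> np.ndarray:
    """Spatially filter and flatten epochs into an n_obs x (n_w*n_hat_t) matrix."""
    return np.vstack([flatten_features(apply_filters(ep, bank))
                      for ep in epochs])


def train_system(recording: Recording,
                 config: TrainingConfig = TrainingConfig()) -> TrainedSystem:
    """Full training flow: preprocess, fit CCA bank, project, stepwise RLDA.

    The cross-validation report (when ``config.compute_cv``) re-runs the
    stepwise+RLDA stage inside each fold on the projected features.
    """
    target_set, non_targets, n_artifacts = assemble_training_set(recording, config)
    bank = fit_cca_filters(target_set, n_w=config.n_w)

    X = np.vstack([project_features(target_set.epochs, bank),
                   project_features(non_targets, bank)])
    y = np.concatenate([np.ones(target_set.n_target, dtype=int),
                        np.zeros(len(non_targets), dtype=int)])
    model = stepwise_select_and_fit(X, y, config.stepwise)

    report = {
        "n_target": target_set.n_target,
        "n_nontarget": len(non_targets),
        "n_artifacts": n_artifacts,
        "n_features_selected": len(model.selected),
        "cca_correlations": bank.correlations.tolist(),
    }
    if config.compute_cv:
        from .evaluation import crossval
        cv = crossval(X, y, k=5, seed=config.cv_seed,
                      stepwise_config=config.stepwise)
        report["cv"] = {
            "acc_target": cv.acc_target,
            "acc_nontarget": cv.acc_nontarget,
            "acc_weighted": cv.acc_weighted,
        }
    return TrainedSystem(filter_bank=bank, model=model, report=report)
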