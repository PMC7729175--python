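"""Online selection controller and orthosis movement planning.

Single-epoch labels are too error-prone to drive an orthosis directly, so the
controller accumulates, per flashing option, a ring buffer of the most recent
artifact-free labels and only fires a selection when three conditions hold at
once: the candidate option has enough valid epochs (default 5), a large
fraction of them are labeled target (default 70%), and every other option
with buffered evidence is labeled non-target often enough (default 60%).
With the default thresholds at most one option can qualify at a time: an
option at >= 70% target sits at <= 30% non-target, below the 60% veto bar.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "ControllerConfig",
    "ControllerState",
    "Decision",
    "AttemptResult",
    "MovementPlan",
    "update",
    "run_attempt",
    "plan_movement",
]

TARGET, NON_TARGET, ARTIFACT = "target", "non-target", "artifact"

FINGERS = ("thumb", "index", "middle", "ring", "little")


@dataclass(frozen=True)
class ControllerConfig:
    """Decision thresholds and timing constants of the online controller."""

    window: int = 10
    min_epochs: int = 5
    target_threshold: float = 0.70
    nontarget_threshold: float = 0.60
    n_c: int = 6
    selection_pause_s: float = 4.0
    attempt_timeout_s: float = 30.0
    rest_s: float = 5.0

    def __post_init__(self) -> None:
        if not 1 <= self.min_epochs <= self.window:
            raise ValueError("min_epochs must lie in [1, window]")
        for th in (self.target_threshold, self.nontarget_threshold):
            if not 0.5 < th <= 1.0:
                raise ValueError("thresholds must lie in (0.5, 1]")
        if self.target_threshold + self.nontarget_threshold <= 1.0:
            raise ValueError(
                "target_threshold + nontarget_threshold must exceed 1 so that "
                "at most one option can satisfy the selection conditions")


@dataclass
class ControllerState:
    """Per-option ring buffers of recent valid labels plus discard counters."""

    config: ControllerConfig = field(default_factory=ControllerConfig)
    buffers: list[deque] = field(default_factory=list)
    discarded_artifacts: int = 0
    elapsed_s: float = 0.0

    def __post_init__(self) -> None:
        if not self.buffers:
            self.buffers = [deque(maxlen=self.config.window)
                            for _ in range(self.config.n_c)]

    def counts(self, option_id: int) -> tuple[int, int]:
        """(target, non-target) counts currently buffered for an option."""
        buf = self.buffers[option_id]
        n_target = sum(1 for lab in buf if lab == TARGET)
        return n_target, len(buf) - n_target

    def reset_buffers(self) -> None:
        for buf in self.buffers:
            buf.clear()


@dataclass(frozen=True)
class Decision:
    """Outcome of one controller update: nothing yet, a selection, or timeout."""

    kind: str  # "none", "select", "timeout"
    option_id: int | None = None
    evidence: tuple[tuple[int, int], ...] = ()


@dataclass(frozen=True)
class AttemptResult:
    """One online attempt: the selected option (or None on timeout) and timing."""

    selected: int | None
    selection_time_s: float
    timed_out: bool = False

    def is_correct(self, cued_target: int) -> bool:
        return self.selected == cued_target


@dataclass(frozen=True)
class MovementPlan:
    """Actuation plan the orthosis executes for a selected option."""

    option_id: int
    actuators: tuple[str, ...]
    action: str = "flexion-extension"
    duration_s: float = 4.0


def _evaluate(state: ControllerState) -> Decision:
    cfg = state.config
    evidence = tuple(state.counts(o) for o in range(cfg.n_c))
    for o, (n_t, n_nt) in enumerate(evidence):
        total = n_t + n_nt
        if total < cfg.min_epochs:
            continue
        if n_t / total < cfg.target_threshold:
            continue
        vetoed = False
        for other, (m_t, m_nt) in enumerate(evidence):
            if other == o:
                continue
            m_total = m_t + m_nt
            # Options with no buffered evidence cannot veto.
            if m_total == 0:
                continue
            if m_nt / m_total < cfg.nontarget_threshold:
                vetoed = True
                break
        if not vetoed:
            return Decision(kind="select", option_id=o, evidence=evidence)
    return Decision(kind="none", evidence=evidence)


def update(state: ControllerState, option_id: int, label: str,
           config: ControllerConfig | None = None) -> tuple[ControllerState, Decision]:
    """Feed one labeled flashing event; returns the (mutated) state and decision.

    Artifact labels are counted but never buffered, so they contribute neither
    to the minimum-epoch condition nor to the class-fraction thresholds.
    """
    cfg = config or state.config
    if not 0 <= option_id < cfg.n_c:
        raise ValueError(f"option_id {option_id} out of range [0, {cfg.n_c})")
    if label == ARTIFACT:
        state.discarded_artifacts += 1
        return state, Decision(kind="none",
                               evidence=tuple(state.counts(o)
                                              for o in range(cfg.n_c)))
    if label not in (TARGET, NON_TARGET):
        raise ValueError(f"unknown label {label!r}")
    state.buffers[option_id].append(label)
    decision = _evaluate(state)
    if decision.kind == "select":
        state.reset_buffers()
    return state, decision


def run_attempt(label_stream: Iterable[tuple[float, int, str]],
                config: ControllerConfig | None = None) -> AttemptResult:
    """Run one selection attempt over a timed label stream.

    ``label_stream`` yields ``(time_s, option_id, label)`` with non-decreasing
    times measured from flashing start.  The attempt ends at the first
    selection, or times out once ``attempt_timeout_s`` of flashing has elapsed
    (an empty stream times out at the full timeout).
    """
    cfg = config or ControllerConfig()
    state = ControllerState(config=cfg)
    last_t = 0.0
    for t, option_id, label in label_stream:
        if t < last_t:
            raise ValueError("label stream timestamps must be non-decreasing")
        last_t = t
        if t >= cfg.attempt_timeout_s:
            break
        state, decision = update(state, option_id, label, cfg)
        if decision.kind == "select":
            return AttemptResult(selected=decision.option_id,
                                 selection_time_s=t)
    return AttemptResult(selected=None, selection_time_s=cfg.attempt_timeout_s,
                         timed_out=True)


def plan_movement(option_id: int) -> MovementPlan:
    """Map a selected option to its orthosis movement.

    Options 0-4 flex-extend one digit each (thumb through little finger);
    option 5 flex-extends all five digits simultaneously.
    """
    if not 0 <= option_id < 6:
        raise ValueError(f"unknown option {option_id}; expected 0-5")
    actuators = FINGERS if option_id == 5 else (FINGERS[option_id],)
    return MovementPlan(option_id=option_id, actuators=tuple(actuators))


def movement_command_frames(plan: MovementPlan, rate_hz: float = 10.0
                            ) -> list[dict]:
    """JSON-serializable per-motor position frames for a movement plan.

    Emits a flexion ramp to full closure and back at ``rate_hz`` over the
    plan's duration, mirroring a wireless motor-position channel; no device
    I/O is performed.
    """
    n = max(int(plan.duration_s * rate_hz), 2)
    frames = []
    for i in range(n):
        phase = i / (n - 1)
        position = 1.0 - abs(2.0 * phase - 1.0)  # 0 -> 1 -> 0 triangle
        frames.append({
            "t_s": round(i / rate_hz, 3),
            "positions": {f: (round(position, 4) if f in plan.actuators else 0.0)
                          for f in FINGERS},
        })
    return frames
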