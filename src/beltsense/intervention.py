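"""Context-aware intervention state machine.

Activity recognition output gates posture monitoring: only while the
current activity is ``sit`` is the posture stream assessed. Poor posture
sustained for at least ``posture_debounce`` seconds fires a vibration
event; a continuous sit/lie streak of at least ``sedentary_limit`` minutes
fires a walk-prompt notification. Each cause has its own refractory period
so bursts of the same condition produce at most one event per refractory
window. Leaving the triggering state resets that trigger's timer.

The machine is pure: replaying the same input yields the same events, and
the BLE/vibrator transport of the real device is abstracted as the
returned event list (an event sink can consume it in real time or batch).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "InterventionEvent",
    "EngineConfig",
    "EngineState",
    "step",
    "run",
]

SEDENTARY_ACTIVITIES = frozenset({"sit", "lay_down"})


@dataclass(frozen=True)
class InterventionEvent:
    """One emitted cue: belt vibration or smartphone notification."""

    timestamp: float
    channel: str  # "vibration" | "notification"
    cause: str  # "poor_posture" | "prolonged_sedentary"
    pattern: str


@dataclass(frozen=True)
class EngineConfig:
    """Timing policy of the intervention engine (all durations > 0)."""

    posture_debounce: float = 5.0  # seconds of sustained poor posture
    sedentary_limit: float = 30.0  # minutes of continuous sit/lie
    refractory: float = 60.0  # seconds between events of one cause
    posture_pattern: str = "double_buzz"
    sedentary_pattern: str = "walk_prompt"

    def __post_init__(self) -> None:
        if min(self.posture_debounce, self.sedentary_limit, self.refractory) <= 0:
            raise ValueError("all engine durations must be positive")


@dataclass(frozen=True)
class EngineState:
    """Timers of the pure state machine; ``initial()`` starts a session."""

    last_t: float = float("-inf")
    poor_since: float | None = None
    sedentary_since: float | None = None
    last_fired: dict = field(default_factory=dict)  # cause -> timestamp

    @classmethod
    def initial(cls) -> "EngineState":
        return cls()


def _may_fire(state: EngineState, cause: str, t: float, config: EngineConfig) -> bool:
    last = state.last_fired.get(cause)
    return last is None or t - last >= config.refractory


def step(
    state: EngineState,
    activity: str,
    posture: str | None,
    t: float,
    config: EngineConfig = EngineConfig(),
) -> tuple[EngineState, list[InterventionEvent]]:
    """Advance the machine one sample; returns new state and emitted events.

    ``posture`` is ``"good"``/``"poor"`` or None when not assessed; it is
    only consulted while ``activity == "sit"``. Timestamps must be strictly
    increasing across calls.
    """
    if t <= state.last_t:
        raise ValueError(f"time must advance: {t} after {state.last_t}")

    events: list[InterventionEvent] = []
    fired = dict(state.last_fired)

    # posture monitoring mode: active only while sitting
    if activity == "sit" and posture == "poor":
        poor_since = state.poor_since if state.poor_since is not None else t
        if t - poor_since >= config.posture_debounce and _may_fire(
            state, "poor_posture", t, config
        ):
            events.append(
                InterventionEvent(t, "vibration", "poor_posture", config.posture_pattern)
            )
            fired["poor_posture"] = t
    else:
        poor_since = None

    # prolonged sedentary streak (sit or lie)
    if activity in SEDENTARY_ACTIVITIES:
        sed_since = (
            state.sedentary_since if state.sedentary_since is not None else t
        )
        if t - sed_since >= config.sedentary_limit * 60.0 and _may_fire(
            state, "prolonged_sedentary", t, config
        ):
            events.append(
                InterventionEvent(
                    t, "notification", "prolonged_sedentary", config.sedentary_pattern
                )
            )
            fired["prolonged_sedentary"] = t
    else:
        sed_since = None

    new_state = replace(
        state,
        last_t=t,
        poor_since=poor_since,
        sedentary_since=sed_since,
        last_fired=fired,
    )
    return new_state, events


def run(
    activities,
    postures,
    times,
    config: EngineConfig = EngineConfig(),
) -> tuple[list[InterventionEvent], dict[str, int]]:
    """Fold :func:`step` over aligned activity/posture/time series.

    Returns the full event list plus per-cause counts.
    """
    activities = list(activities)
    postures = list(postures)
    times = list(times)
    if not len(activities) == len(postures) == len(times):
        raise ValueError(
            "activity, posture and time series must have equal lengths"
        )
    state = EngineState.initial()
    events: list[InterventionEvent] = []
    for act, pos, t in zip(activities, postures, times):
        state, new = step(state, act, pos, float(t), config)
        events.extend(new)
    counts: dict[str, int] = {}
    for e in events:
        counts[e.cause] = counts.get(e.cause, 0) + 1
    return events, counts
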