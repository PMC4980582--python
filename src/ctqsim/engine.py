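"""Event-driven kernel for the single-scanner examination queue.

One replication is one terminating working day: the system opens empty,
arrivals occur over ``open_minutes`` (default 780, i.e. 8:00-21:00), and
the scanner keeps working past closing until the line drains, so every
arrival is served exactly once. Service is non-preemptive; the policy
layer decides where a new arrival stands and who is called next.

Deterministic tie-breaking at equal timestamps: a service completion is
processed before an arrival, and the completion's dispatch happens
before the simultaneous arrival joins the line; simultaneous arrivals
join in draw order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .generators import (
    EP_EXAM_DURATIONS,
    GP_EXAM_DURATIONS,
    ArrivalProfile,
    ServiceDistribution,
    sample_day,
)
from .patients import Patient, PatientClass
from .policies import PolicyConfig, insertion_index, selection_index


@dataclass
class QueueState:
    """Ordered waiting line plus the patient on the scanner."""

    waiting: list[Patient] = field(default_factory=list)
    in_service: Patient | None = None
    clock: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    """Everything needed to reproduce a replication set bit-exactly."""

    policy: PolicyConfig
    profile: ArrivalProfile
    open_minutes: float = 780.0
    n_reps: int = 100
    master_seed: int = 12345
    gp_durations: ServiceDistribution = GP_EXAM_DURATIONS
    ep_durations: ServiceDistribution = EP_EXAM_DURATIONS

    def __post_init__(self) -> None:
        if self.open_minutes <= 0:
            raise ValueError("open_minutes must be positive")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


def dispatch(queue: QueueState, policy: PolicyConfig, now: float) -> Patient:
    """Remove and return the patient the policy serves next at ``now``."""
    if queue.in_service is not None:
        raise RuntimeError("dispatch while the scanner is busy")
    idx = selection_index(queue.waiting, now, policy)
    return queue.waiting.pop(idx)


def simulate_day(arrivals: Sequence[Patient], policy: PolicyConfig) -> list[Patient]:
    """Run one day's event loop over a pre-sampled arrival stream.

    ``arrivals`` must be sorted by arrival time (stable draw order for
    ties) and is not mutated: served copies are returned, in arrival
    (id) order. The same stream can therefore be replayed under several
    policies for a common-random-numbers comparison.
    """
    stream = [p.fresh() for p in arrivals]
    if any(stream[i].arrival > stream[i + 1].arrival for i in range(len(stream) - 1)):
        raise ValueError("arrival stream must be sorted by arrival time")

    queue = QueueState()
    served: list[Patient] = []
    i, n = 0, len(stream)

    def admit_all_at(t: float) -> None:
        nonlocal i
        while i < n and stream[i].arrival == t:
            p = stream[i]
            queue.waiting.insert(insertion_index(queue.waiting, p, policy), p)
            i += 1

    while i < n or queue.waiting or queue.in_service is not None:
        t_arr = stream[i].arrival if i < n else math.inf
        t_done = queue.in_service.service_end if queue.in_service is not None else math.inf

        if queue.in_service is None:
            if queue.waiting:
                # completion-then-dispatch is atomic: patients arriving at
                # exactly this instant are not yet eligible
                p = dispatch(queue, policy, queue.clock)
                p.service_start = queue.clock
                p.service_end = queue.clock + p.duration
                queue.in_service = p
            else:
                queue.clock = t_arr
                admit_all_at(t_arr)
        elif t_done <= t_arr:
            queue.clock = t_done
            served.append(queue.in_service)
            queue.in_service = None
        else:
            queue.clock = t_arr
            p = stream[i]
            queue.waiting.insert(insertion_index(queue.waiting, p, policy), p)
            i += 1

    served.sort(key=lambda p: p.id)
    return served


def run_day(config: SimConfig, rep_index: int):
    """Sample one day's stream and simulate it; returns a DayResult."""
    from .metrics import DayResult  # metrics sits above the engine

    stream = sample_day(
        config.profile,
        config.open_minutes,
        config.gp_durations,
        config.ep_durations,
        config.master_seed,
        rep_index,
    )
    served = simulate_day(stream, config.policy)
    return DayResult.from_patients(served, config.policy)


def run_replications(config: SimConfig) -> list:
    """All ``n_reps`` terminating replications of ``config``."""
    return [run_day(config, rep) for rep in range(config.n_reps)]
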