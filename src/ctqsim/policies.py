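"""Queue disciplines for the single-CT examination queue.

Three disciplines are implemented, all non-preemptive and purely
positional (the waiting line is an ordered list; position 0 is served
next):

``base``
    Historical practice: every emergency-class patient (EP, and UP when
    a three-class stream is run through this policy) joins the line
    immediately behind the last emergency-class patient, i.e. ahead of
    every general patient; general patients append at the end. FIFO
    holds within each group.

``fixed``
    Fixed-interval wedging. EPs keep absolute precedence (they join
    behind the last EP, ahead of all UPs and GPs). A newly arriving UP
    is wedged into the GP tail: let the *marker* be the last UP in the
    line, else the last EP, else the head; if more than ``P`` GPs stand
    behind the marker the UP is placed behind exactly ``P`` of them,
    otherwise it appends at the end. ``P`` ranges over 0..10, one scheme
    per value.

``dynamic``
    Aging priority. Each waiting patient carries a priority value
    f = threshold / wait, clamped at 1 (EPs are always 1); the patient
    with the smallest f is served next, so priority improves as waiting
    accumulates and saturates at the emergency rank once the class
    threshold (20 min for UPs, 40 min for GPs) is reached. Ties at
    equal f are broken by urgency class, then arrival, then id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .patients import Patient, PatientClass

POLICY_KINDS = ("base", "fixed", "dynamic")
TIE_BREAKS = ("class", "arrival")

#: Largest number of GPs a UP may be wedged ahead of.
MAX_INTERVAL = 10


class PolicyError(ValueError):
    """Invalid policy configuration."""


@dataclass(frozen=True)
class PolicyConfig:
    """Discipline selector plus its parameters.

    Parameters
    ----------
    kind
        One of ``"base"``, ``"fixed"``, ``"dynamic"``.
    P
        Interval number of the fixed discipline: how many GPs a newly
        arriving UP may be wedged ahead of (0..10). Ignored otherwise.
    t_up_threshold, t_gp_threshold
        Waiting-time thresholds in minutes (defaults 20 and 40). They
        drive both the aging rule of the dynamic discipline and the
        satisfaction rates reported by the metrics layer.
    tie_break
        How equal dynamic priority values are resolved: ``"class"``
        (urgency class first, then arrival — the default) or
        ``"arrival"`` (global FIFO among tied patients).
    """

    kind: str = "base"
    P: int = 1
    t_up_threshold: float = 20.0
    t_gp_threshold: float = 40.0
    tie_break: str = "class"

    def __post_init__(self) -> None:
        if self.kind not in POLICY_KINDS:
            raise PolicyError(f"policy.kind must be one of {POLICY_KINDS}, got {self.kind!r}")
        if not (0 <= int(self.P) <= MAX_INTERVAL) or int(self.P) != self.P:
            raise PolicyError(f"policy.P must be an integer in 0..{MAX_INTERVAL}, got {self.P!r}")
        if not (self.t_up_threshold > 0 and self.t_gp_threshold > 0):
            raise PolicyError("policy thresholds must be positive")
        if self.tie_break not in TIE_BREAKS:
            raise PolicyError(f"policy.tie_break must be one of {TIE_BREAKS}, got {self.tie_break!r}")


def insert_base(waiting: Sequence[Patient], p: Patient) -> int:
    """Insertion index for ``p`` under the base (historical) discipline.

    GPs append; emergency-class patients (EP/UP alike) go immediately
    behind the last emergency-class patient, ahead of all GPs.
    """
    if p.cls is PatientClass.GP:
        return len(waiting)
    for i in range(len(waiting) - 1, -1, -1):
        if waiting[i].cls is not PatientClass.GP:
            return i + 1
    return 0


def insert_fixed(waiting: Sequence[Patient], p: Patient, P: int) -> int:
    """Insertion index for ``p`` under the fixed-interval discipline.

    See the module docstring for the wedging rule. The patient currently
    on the scanner is not part of ``waiting`` and never counts toward the
    wedged GPs.
    """
    if not 0 <= P <= MAX_INTERVAL:
        raise PolicyError(f"P must be in 0..{MAX_INTERVAL}, got {P}")
    if p.cls is PatientClass.GP:
        return len(waiting)
    if p.cls is PatientClass.EP:
        # behind the last EP, ahead of every UP and GP
        for i in range(len(waiting) - 1, -1, -1):
            if waiting[i].cls is PatientClass.EP:
                return i + 1
        return 0
    # UP: find the marker (last UP, else last EP, else the head)
    marker = -1
    for i in range(len(waiting) - 1, -1, -1):
        if waiting[i].cls is PatientClass.UP:
            marker = i
            break
    if marker < 0:
        for i in range(len(waiting) - 1, -1, -1):
            if waiting[i].cls is PatientClass.EP:
                marker = i
                break
    n_gp_behind = sum(1 for q in waiting[marker + 1 :] if q.cls is PatientClass.GP)
    if n_gp_behind > P:
        return marker + 1 + P
    return len(waiting)


def dynamic_priority_value(cls: PatientClass, wait: float, cfg: PolicyConfig) -> float:
    """Aging priority value f; smaller f is served earlier.

    EPs are pinned at 1. A UP (GP) reaches 1 once it has waited its
    class threshold, and carries threshold/wait before that. A wait of
    zero maps to +inf: a just-arrived non-emergency patient outranks
    nobody (the limit of threshold/t as t -> 0+).
    """
    if wait < 0:
        raise ValueError(f"negative wait {wait}")
    if cls is PatientClass.EP:
        return 1.0
    threshold = cfg.t_up_threshold if cls is PatientClass.UP else cfg.t_gp_threshold
    if wait >= threshold:
        return 1.0
    if wait == 0:
        return math.inf
    return threshold / wait


def _dynamic_key(p: Patient, now: float, cfg: PolicyConfig):
    f = dynamic_priority_value(p.cls, now - p.arrival, cfg)
    if cfg.tie_break == "class":
        return (f, int(p.cls), p.arrival, p.id)
    return (f, p.arrival, int(p.cls), p.id)


def select_dynamic(waiting: Sequence[Patient], now: float, cfg: PolicyConfig) -> int:
    """Index of the patient to serve next under the dynamic discipline."""
    if not waiting:
        raise PolicyError("select_dynamic on an empty queue")
    return min(range(len(waiting)), key=lambda i: _dynamic_key(waiting[i], now, cfg))


def insertion_index(waiting: Sequence[Patient], p: Patient, cfg: PolicyConfig) -> int:
    """Policy-dispatched insertion position for a new arrival.

    Under the dynamic discipline the line order is immaterial (selection
    rescans priorities at each dispatch), so arrivals simply append.
    """
    if cfg.kind == "base":
        return insert_base(waiting, p)
    if cfg.kind == "fixed":
        return insert_fixed(waiting, p, cfg.P)
    return len(waiting)


def selection_index(waiting: Sequence[Patient], now: float, cfg: PolicyConfig) -> int:
    """Policy-dispatched index of the next patient to serve."""
    if not waiting:
        raise PolicyError("selection on an empty queue")
    if cfg.kind == "dynamic":
        return select_dynamic(waiting, now, cfg)
    return 0
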