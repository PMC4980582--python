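"""Patient records shared by the sampling, policy, and engine layers."""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace


class PatientClass(enum.IntEnum):
    """Urgency class of an examinee.

    The integer value encodes the urgency order used to break priority
    ties: emergency (EP) before urgent (UP) before general (GP).
    """

    EP = 0
    UP = 1
    GP = 2


@dataclass
class Patient:
    """One examinee in a simulated day.

    Times are real minutes since the department opens (8:00). ``duration``
    is the sampled examination time; ``service_start``/``service_end`` are
    filled in by the engine when the patient is served.
    """

    id: int
    cls: PatientClass
    arrival: float
    duration: float
    service_start: float | None = None
    service_end: float | None = None

    @property
    def wait(self) -> float | None:
        """Waiting time in minutes, or None if not yet served."""
        if self.service_start is None:
            return None
        return self.service_start - self.arrival

    def fresh(self) -> "Patient":
        """Copy with service times cleared, for replay under another policy."""
        return replace(self, service_start=None, service_end=None)
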