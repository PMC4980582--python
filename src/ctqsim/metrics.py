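"""Output indicators: waits, satisfaction rates, throughput, CIs.

Per-day indicators mirror the comparison tables of the study design:
mean waiting time per class and overall, satisfaction rate (fraction of
a class whose wait is within — inclusively — its threshold: 20 min for
UPs, 40 min for GPs; EPs have no finite threshold), daily examination
quantity, and the fraction of UPs kept waiting beyond their threshold.
Across replications each indicator is summarized by its mean, standard
deviation, and a Student-t 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import SimConfig, simulate_day
from .generators import sample_day
from .patients import Patient, PatientClass
from .policies import PolicyConfig

#: Canonical indicator order for reports.
INDICATORS = (
    "wait_ep",
    "wait_up",
    "wait_gp",
    "wait_overall",
    "sat_gp",
    "sat_up",
    "daily_quantity",
    "frac_up_over_threshold",
)


def satisfaction_rate(waits: Sequence[float], threshold: float) -> float | None:
    """Fraction of waits within (<=) the threshold; None for no patients."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    waits = list(waits)
    if not waits:
        return None
    if any(w < 0 for w in waits):
        raise ValueError("negative waiting time in input")
    return sum(1 for w in waits if w <= threshold) / len(waits)


@dataclass(frozen=True)
class DayResult:
    """Indicators of one simulated day plus the per-patient records."""

    records: tuple[Patient, ...]
    mean_wait: dict  # keys "EP", "UP", "GP", "overall" (None if class absent)
    satisfaction: dict  # keys "UP", "GP"
    daily_quantity: int
    frac_up_over_threshold: float | None

    @classmethod
    def from_patients(cls, served: Sequence[Patient], policy: PolicyConfig) -> "DayResult":
        waits = {c: [] for c in PatientClass}
        for p in served:
            if p.wait is None or p.wait < 0:
                raise ValueError(f"patient {p.id} has invalid service record")
            waits[p.cls].append(p.wait)
        all_waits = [w for ws in waits.values() for w in ws]

        def _mean(ws):
            return float(np.mean(ws)) if ws else None

        sat_up = satisfaction_rate(waits[PatientClass.UP], policy.t_up_threshold)
        return cls(
            records=tuple(served),
            mean_wait={
                "EP": _mean(waits[PatientClass.EP]),
                "UP": _mean(waits[PatientClass.UP]),
                "GP": _mean(waits[PatientClass.GP]),
                "overall": _mean(all_waits),
            },
            satisfaction={
                "UP": sat_up,
                "GP": satisfaction_rate(waits[PatientClass.GP], policy.t_gp_threshold),
            },
            daily_quantity=len(served),
            frac_up_over_threshold=None if sat_up is None else 1.0 - sat_up,
        )

    def indicators(self) -> dict:
        """Flat indicator vector (None where a class was absent)."""
        return {
            "wait_ep": self.mean_wait["EP"],
            "wait_up": self.mean_wait["UP"],
            "wait_gp": self.mean_wait["GP"],
            "wait_overall": self.mean_wait["overall"],
            "sat_gp": self.satisfaction["GP"],
            "sat_up": self.satisfaction["UP"],
            "daily_quantity": float(self.daily_quantity),
            "frac_up_over_threshold": self.frac_up_over_threshold,
        }


@dataclass(frozen=True)
class ReplicationSummary:
    """Across-day mean, sd, and 95% t-interval for each indicator."""

    table: pd.DataFrame  # index: indicator; columns: mean, sd, ci_lo, ci_hi, n

    def mean(self, indicator: str) -> float:
        return float(self.table.loc[indicator, "mean"])

    def ci(self, indicator: str) -> tuple[float, float]:
        row = self.table.loc[indicator]
        return float(row["ci_lo"]), float(row["ci_hi"])


def t_interval(values: Sequence[float], level: float = 0.95) -> tuple[float, float, float, float]:
    """(mean, sd, ci_lo, ci_hi) with a Student-t interval, n-1 df."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 replications for a confidence interval")
    m = float(x.mean())
    sd = float(x.std(ddof=1))
    half = float(stats.t.ppf(0.5 + level / 2, n - 1)) * sd / np.sqrt(n)
    return m, sd, m - half, m + half


def summarize_replications(days: Sequence[DayResult], level: float = 0.95) -> ReplicationSummary:
    """Summarize per-day indicators across replications.

    Days on which an indicator is undefined (no patient of that class)
    are excluded from that indicator's average.
    """
    if len(days) < 2:
        raise ValueError("need at least 2 replicated days")
    rows = {}
    per_day = [d.indicators() for d in days]
    for ind in INDICATORS:
        vals = [d[ind] for d in per_day if d[ind] is not None]
        if len(vals) < 2:
            rows[ind] = dict(mean=np.nan, sd=np.nan, ci_lo=np.nan, ci_hi=np.nan, n=len(vals))
            continue
        m, sd, lo, hi = t_interval(vals, level)
        rows[ind] = dict(mean=m, sd=sd, ci_lo=lo, ci_hi=hi, n=len(vals))
    return ReplicationSummary(pd.DataFrame.from_dict(rows, orient="index"))


@dataclass(frozen=True)
class PolicyComparison:
    """Common-random-numbers comparison of several disciplines."""

    labels: tuple[str, ...]
    days: dict  # label -> list[DayResult]
    summaries: dict  # label -> ReplicationSummary

    def table(self, stat: str = "mean") -> pd.DataFrame:
        """Indicator x policy table of the requested statistic."""
        return pd.DataFrame(
            {lab: self.summaries[lab].table[stat] for lab in self.labels}
        ).loc[list(INDICATORS)]

    def long_frame(self) -> pd.DataFrame:
        """Tidy frame: indicator, policy, mean, sd, ci_lo, ci_hi, n."""
        parts = []
        for lab in self.labels:
            t = self.summaries[lab].table.reset_index(names="indicator")
            t.insert(1, "policy", lab)
            parts.append(t)
        return pd.concat(parts, ignore_index=True)


def compare_policies(
    config: SimConfig,
    policy_list: Sequence[PolicyConfig],
    labels: Sequence[str] | None = None,
) -> PolicyComparison:
    """Replay every policy on identical arrival/duration streams.

    Streams are sampled once per replication from ``config``'s master
    seed and shared by all policies (common random numbers), which is
    what makes the per-indicator differences between columns directly
    comparable.
    """
    if labels is None:
        labels = []
        for pc in policy_list:
            labels.append(f"fixed_P{pc.P}" if pc.kind == "fixed" else pc.kind)
    if len(labels) != len(policy_list) or len(set(labels)) != len(labels):
        raise ValueError("labels must be unique and match policy_list")

    days: dict[str, list[DayResult]] = {lab: [] for lab in labels}
    for rep in range(config.n_reps):
        stream = sample_day(
            config.profile,
            config.open_minutes,
            config.gp_durations,
            config.ep_durations,
            config.master_seed,
            rep,
        )
        for lab, pc in zip(labels, policy_list):
            served = simulate_day(stream, pc)
            days[lab].append(DayResult.from_patients(served, pc))

    summaries = {lab: summarize_replications(days[lab]) for lab in labels}
    return PolicyComparison(labels=tuple(labels), days=days, summaries=summaries)
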