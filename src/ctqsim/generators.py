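"""Arrival and service-time generators, plus profile calibration.

The examination durations of general and emergency-class patients are
empirical discrete distributions on whole minutes (shipped as built-in
constants). Emergency-stream arrivals form a homogeneous Poisson process
(exponential interarrivals, 7-minute mean by default) whose arrivals are
independently labelled urgent with probability 0.7. General-patient
arrivals — whose real-world profile is not published — are modelled as a
nonhomogeneous Poisson process with piecewise-constant hourly rates; a
built-in default profile carries a morning peak, and :func:`calibrate`
rescales it until pilot runs of the base discipline reproduce a target
congestion level (historical mean GP wait and daily throughput).

All randomness flows through named substreams keyed by
``(master_seed, replication_index, stream)``, so that different
disciplines replayed on the same replication share identical arrival and
duration draws (common random numbers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .patients import Patient, PatientClass


class CalibrationError(RuntimeError):
    """The rate search could not meet its targets in bounded iterations."""


# ---------------------------------------------------------------------------
# Service-duration distributions


@dataclass(frozen=True)
class ServiceDistribution:
    """Empirical distribution of examination durations (whole minutes)."""

    support: tuple[int, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.support) != len(self.probs) or not self.support:
            raise ValueError("support and probs must be nonempty and equal-length")
        if any(s <= 0 for s in self.support):
            raise ValueError("durations must be positive")
        if list(self.support) != sorted(set(self.support)):
            raise ValueError("support must be strictly increasing")
        if any(p < 0 for p in self.probs):
            raise ValueError("probabilities must be nonnegative")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {sum(self.probs)}, not 1")

    @property
    def mean(self) -> float:
        return float(np.dot(self.support, self.probs))

    def cdf(self, x: float) -> float:
        """P(duration <= x)."""
        return float(sum(p for s, p in zip(self.support, self.probs) if s <= x))

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw durations by inverse-CDF lookup."""
        cum = np.cumsum(self.probs)
        u = rng.random(size)
        idx = np.searchsorted(cum, u, side="right")
        idx = np.minimum(idx, len(self.support) - 1)  # guard u ~ 1 round-off
        out = np.asarray(self.support)[idx]
        return int(out) if size is None else out

    def to_dict(self) -> dict:
        return {"support": list(self.support), "probs": list(self.probs)}

    @classmethod
    def from_dict(cls, d: dict) -> "ServiceDistribution":
        return cls(tuple(int(s) for s in d["support"]), tuple(float(p) for p in d["probs"]))


#: Examination durations of general patients (mean 2.26 min).
GP_EXAM_DURATIONS = ServiceDistribution(
    support=(1, 2, 3, 4),
    probs=(0.111, 0.579, 0.249, 0.061),
)

#: Examination durations of emergency-stream patients (mean 3.195 min),
#: used for both EPs and UPs (UPs are a relabelled share of that stream).
EP_EXAM_DURATIONS = ServiceDistribution(
    support=(1, 2, 3, 4, 5, 6, 7),
    probs=(0.024, 0.341, 0.320, 0.155, 0.075, 0.061, 0.024),
)


# ---------------------------------------------------------------------------
# Arrival profile


@dataclass(frozen=True)
class ArrivalProfile:
    """Arrival-rate description for one working day.

    ``gp_rates`` is a piecewise-constant GP arrival-rate profile: tuples
    ``(start, end, rate_per_minute)`` partitioning ``[0, horizon)``.
    ``ep_mean_interarrival`` is the exponential mean (minutes) of the
    emergency stream; each emergency arrival is urgent with probability
    ``urgent_fraction`` (else a true EP).
    """

    gp_rates: tuple[tuple[float, float, float], ...]
    ep_mean_interarrival: float = 7.0
    urgent_fraction: float = 0.7

    def __post_init__(self) -> None:
        if not self.gp_rates:
            raise ValueError("gp_rates must be nonempty")
        prev_end = 0.0
        for a, b, r in self.gp_rates:
            if a != prev_end or b <= a:
                raise ValueError("gp_rates intervals must partition [0, horizon)")
            if r < 0:
                raise ValueError("rates must be nonnegative")
            prev_end = b
        if self.ep_mean_interarrival <= 0:
            raise ValueError("ep_mean_interarrival must be positive")
        if not 0.0 <= self.urgent_fraction <= 1.0:
            raise ValueError("urgent_fraction must lie in [0, 1]")

    @property
    def horizon(self) -> float:
        return self.gp_rates[-1][1]

    @property
    def expected_gp_count(self) -> float:
        return float(sum(r * (b - a) for a, b, r in self.gp_rates))

    @property
    def expected_ep_count(self) -> float:
        return self.horizon / self.ep_mean_interarrival

    def scaled(self, factor: float) -> "ArrivalProfile":
        """Profile with every GP rate multiplied by ``factor``."""
        if factor < 0:
            raise ValueError("scale factor must be nonnegative")
        return replace(
            self, gp_rates=tuple((a, b, r * factor) for a, b, r in self.gp_rates)
        )

    def to_dict(self) -> dict:
        return {
            "gp_rates": [[a, b, r] for a, b, r in self.gp_rates],
            "ep_mean_interarrival": self.ep_mean_interarrival,
            "urgent_fraction": self.urgent_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArrivalProfile":
        return cls(
            gp_rates=tuple((float(a), float(b), float(r)) for a, b, r in d["gp_rates"]),
            ep_mean_interarrival=float(d.get("ep_mean_interarrival", 7.0)),
            urgent_fraction=float(d.get("urgent_fraction", 0.7)),
        )


#: Expected GP arrivals per hour in the default (uncalibrated) profile.
#: Front-loaded: appointment load peaks mid-morning and tapers through
#: the evening; the total of 162 GPs/day matches a ~65.8% GP share of a
#: ~246-patient day.
DEFAULT_GP_HOURLY_COUNTS = (26, 30, 28, 22, 14, 8, 6, 6, 6, 5, 4, 4, 3)


def default_profile() -> ArrivalProfile:
    """Built-in 13-hour (8:00-21:00) arrival profile with a morning peak."""
    rates = tuple(
        (60.0 * i, 60.0 * (i + 1), c / 60.0)
        for i, c in enumerate(DEFAULT_GP_HOURLY_COUNTS)
    )
    return ArrivalProfile(gp_rates=rates)


# ---------------------------------------------------------------------------
# Random substreams

_STREAMS = {"gp_arrivals": 0, "ep_arrivals": 1, "gp_durations": 2, "ep_durations": 3}


def substream(master_seed: int, rep_index: int, name: str) -> np.random.Generator:
    """Named, reproducible substream for one replication.

    Streams are keyed by ``(master_seed, rep_index, stream_id)`` so that
    every discipline replayed on replication ``rep_index`` sees the same
    arrivals and durations.
    """
    return np.random.default_rng([int(master_seed), int(rep_index), _STREAMS[name]])


# ---------------------------------------------------------------------------
# Sampling


def sample_gp_arrivals(
    profile: ArrivalProfile, horizon: float, rng: np.random.Generator
) -> list[float]:
    """Realize the nonhomogeneous Poisson GP arrival stream on [0, horizon).

    Unit-rate exponential gaps are mapped through the inverse cumulative
    intensity of the piecewise-constant profile (exponential gaps with
    boundary carryover), so per-interval counts are Poisson with mean
    rate x length and increments over disjoint intervals are independent.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    times: list[float] = []
    target = rng.exponential()  # next cumulative-intensity level to hit
    acc = 0.0  # cumulative intensity at the start of the current interval
    for a, b, r in profile.gp_rates:
        a, b = max(a, 0.0), min(b, horizon)
        if b <= a:
            continue
        seg = r * (b - a)
        while r > 0 and target <= acc + seg:
            t = a + (target - acc) / r
            if t >= horizon:
                return times
            times.append(t)
            target += rng.exponential()
        acc += seg
    return times


def sample_ep_arrivals(
    profile: ArrivalProfile, horizon: float, rng: np.random.Generator
) -> list[tuple[float, PatientClass]]:
    """Realize the emergency stream: exponential gaps, UP/EP labelling."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if profile.ep_mean_interarrival <= 0:
        raise ValueError("ep_mean_interarrival must be positive")
    out: list[tuple[float, PatientClass]] = []
    t = rng.exponential(profile.ep_mean_interarrival)
    while t < horizon:
        cls = PatientClass.UP if rng.random() < profile.urgent_fraction else PatientClass.EP
        out.append((t, cls))
        t += rng.exponential(profile.ep_mean_interarrival)
    return out


def sample_duration(dist: ServiceDistribution, rng: np.random.Generator) -> int:
    """One examination duration drawn from ``dist``."""
    return dist.sample(rng)


def sample_day(
    profile: ArrivalProfile,
    horizon: float,
    gp_durations: ServiceDistribution,
    ep_durations: ServiceDistribution,
    master_seed: int,
    rep_index: int,
) -> list[Patient]:
    """Full patient stream for one replicated day, sorted by arrival.

    The stream depends only on ``(master_seed, rep_index)`` — never on
    the discipline it will be replayed under. Simultaneous arrivals keep
    draw order (stable sort); ids run 0..n-1 in arrival order.
    """
    gp_rng = substream(master_seed, rep_index, "gp_arrivals")
    ep_rng = substream(master_seed, rep_index, "ep_arrivals")
    gpd_rng = substream(master_seed, rep_index, "gp_durations")
    epd_rng = substream(master_seed, rep_index, "ep_durations")

    patients: list[Patient] = []
    for t in sample_gp_arrivals(profile, horizon, gp_rng):
        patients.append(
            Patient(id=-1, cls=PatientClass.GP, arrival=t,
                    duration=sample_duration(gp_durations, gpd_rng))
        )
    for t, cls in sample_ep_arrivals(profile, horizon, ep_rng):
        patients.append(
            Patient(id=-1, cls=cls, arrival=t,
                    duration=sample_duration(ep_durations, epd_rng))
        )
    patients.sort(key=lambda p: p.arrival)  # stable: ties keep draw order
    for i, p in enumerate(patients):
        p.id = i
    return patients


# ---------------------------------------------------------------------------
# Calibration


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of :func:`calibrate`.

    ``profile`` is the calibrated arrival profile; ``scale`` the factor
    applied to the input GP rates; the ``achieved_*`` figures are the
    pilot-run means under the base discipline.
    """

    profile: ArrivalProfile
    scale: float
    achieved_gp_wait: float
    achieved_daily_quantity: float
    iterations: int
    n_pilot: int
    seed: int


def _pilot_means(
    profile: ArrivalProfile, n_pilot: int, seed: int
) -> tuple[float, float]:
    """(mean GP wait, mean daily quantity) over n_pilot base-policy days."""
    from .engine import SimConfig, run_day  # deferred: engine imports this module
    from .policies import PolicyConfig

    cfg = SimConfig(
        policy=PolicyConfig(kind="base"),
        profile=profile,
        open_minutes=profile.horizon,
        n_reps=n_pilot,
        master_seed=seed,
    )
    waits, totals = [], []
    for rep in range(n_pilot):
        day = run_day(cfg, rep)
        if day.mean_wait["GP"] is not None:
            waits.append(day.mean_wait["GP"])
        totals.append(day.daily_quantity)
    return float(np.mean(waits)), float(np.mean(totals))


def calibrate(
    profile: ArrivalProfile,
    target_gp_wait: float = 66.8,
    target_daily_total: float = 245.0,
    n_pilot: int = 100,
    seed: int = 20120201,
    emergency_share: float = 0.342,
    ep_mean_bounds: tuple[float, float] = (7.0, 9.3),
    wait_rtol: float = 0.10,
    total_rtol: float = 0.05,
    max_iter: int = 40,
) -> CalibrationResult:
    """Scale the GP profile until base-discipline pilots hit the targets.

    The emergency interarrival mean is first set so the emergency stream
    supplies ``emergency_share`` of the target daily total (clamped to
    ``ep_mean_bounds``); a scalar multiplier on the GP rates is then
    bisected against the pilot-run mean GP waiting time, which is
    monotone in load. Pilot replications reuse a fixed seed, so the
    whole search is deterministic given ``seed``.

    Raises
    ------
    CalibrationError
        If the targets are infeasible (e.g. zero wait at positive load)
        or the search does not converge within ``max_iter`` bisections.
    """
    if target_gp_wait <= 0 or target_daily_total <= 0:
        raise CalibrationError("calibration targets must be positive")
    if n_pilot < 1:
        raise ValueError("n_pilot must be >= 1")

    horizon = profile.horizon
    ep_mean = min(
        max(horizon / (emergency_share * target_daily_total), ep_mean_bounds[0]),
        ep_mean_bounds[1],
    )
    base = replace(profile, ep_mean_interarrival=ep_mean)

    evals = 0

    def pilot(scale: float) -> tuple[float, float]:
        nonlocal evals
        evals += 1
        return _pilot_means(base.scaled(scale), n_pilot, seed)

    lo, hi = 0.05, 1.0
    w_lo, _ = pilot(lo)
    if w_lo > target_gp_wait:
        raise CalibrationError(
            f"target GP wait {target_gp_wait} min is below the wait at minimal load ({w_lo:.1f} min)"
        )
    w_hi, _ = pilot(hi)
    expand = 0
    while w_hi < target_gp_wait:
        lo, w_lo = hi, w_hi
        hi *= 1.5
        w_hi, _ = pilot(hi)
        expand += 1
        if expand > 12:
            raise CalibrationError("GP-wait target unreachable: load expansion did not converge")

    scale, w_mid, q_mid = hi, w_hi, math.nan
    for it in range(max_iter):
        scale = 0.5 * (lo + hi)
        w_mid, q_mid = pilot(scale)
        if abs(w_mid - target_gp_wait) <= 0.01 * target_gp_wait:
            break
        if w_mid < target_gp_wait:
            lo = scale
        else:
            hi = scale
    if math.isnan(q_mid):
        _, q_mid = pilot(scale)

    if abs(w_mid - target_gp_wait) > wait_rtol * target_gp_wait:
        raise CalibrationError(
            f"calibrated GP wait {w_mid:.1f} outside +/-{wait_rtol:.0%} of {target_gp_wait}"
        )
    if abs(q_mid - target_daily_total) > total_rtol * target_daily_total:
        raise CalibrationError(
            f"calibrated daily quantity {q_mid:.1f} outside +/-{total_rtol:.0%} of {target_daily_total}"
        )
    return CalibrationResult(
        profile=base.scaled(scale),
        scale=scale,
        achieved_gp_wait=w_mid,
        achieved_daily_quantity=q_mid,
        iterations=evals,
        n_pilot=n_pilot,
        seed=seed,
    )
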