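"""Treatment schedules and their mapping onto time-varying effective fitness.

A course reduces the reproductive fitness of the cancer and/or mutant clone
by an efficacy in [0, 1]: constant within a window (maximum tolerated dose
style), or waning from the moment of administration as ``eff * 2^(-dt/t_half)``
to mimic first-order pharmacokinetic clearance.  Healthy fitness is never
modified.  When several courses act on the same clone at the same time their
efficacies add and saturate at 1 (linear pharmacokinetics with effect
saturation), so re-administered waning doses superpose naturally.

All times are measured in cell divisions; :class:`TimeMapping` converts from
wall-clock time using the population-level division rate (N/8 divisions per
hour for cells with an 8-hour cycle).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .moran import FitnessParams

__all__ = [
    "TreatmentCourse",
    "Schedule",
    "TimeMapping",
    "effective_fitness",
    "superpose_doses",
    "make_preset",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class TreatmentCourse:
    """One administration: efficacies per clone, timing and decay mode."""

    eff_c: float
    eff_m: float
    t_start: float
    t_length: float | None = None
    mode: str = "constant"
    t_half: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.eff_c <= 1.0 and 0.0 <= self.eff_m <= 1.0):
            raise ValueError("efficacies must lie in [0, 1]")
        if self.mode == "constant":
            if self.t_length is None or self.t_length <= 0:
                raise ValueError("constant-mode course requires t_length > 0")
        elif self.mode == "waning":
            if self.t_half is None or self.t_half <= 0:
                raise ValueError("waning-mode course requires t_half > 0")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")

    def efficacy_at(self, t: float) -> tuple[float, float]:
        """Instantaneous (eff_c, eff_m) contribution of this course at time t."""
        if t < self.t_start:
            return (0.0, 0.0)
        if self.mode == "constant":
            if t <= self.t_start + self.t_length:
                return (self.eff_c, self.eff_m)
            return (0.0, 0.0)
        decay = 2.0 ** (-(t - self.t_start) / self.t_half)
        return (self.eff_c * decay, self.eff_m * decay)


@dataclass(frozen=True)
class Schedule:
    """Ordered list of treatment courses (possibly empty)."""

    courses: tuple[TreatmentCourse, ...] = ()

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.courses, key=lambda c: c.t_start))
        object.__setattr__(self, "courses", ordered)

    def __len__(self) -> int:
        return len(self.courses)

    def efficacies(self, t: float) -> tuple[float, float]:
        """Combined (eff_c, eff_m) at time t: summed over courses, capped at 1."""
        ec = em = 0.0
        for course in self.courses:
            c, m = course.efficacy_at(t)
            ec += c
            em += m
        return (min(1.0, ec), min(1.0, em))

    def efficacy_profiles(self, M: int) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised combined efficacies at division indices 0..M-1."""
        t = np.arange(M, dtype=float)
        ec = np.zeros(M)
        em = np.zeros(M)
        for course in self.courses:
            if course.mode == "constant":
                active = (t >= course.t_start) & (t <= course.t_start + course.t_length)
                ec += np.where(active, course.eff_c, 0.0)
                em += np.where(active, course.eff_m, 0.0)
            else:
                dt = t - course.t_start
                decay = np.where(dt >= 0, 2.0 ** (-np.maximum(dt, 0.0) / course.t_half), 0.0)
                ec += course.eff_c * decay
                em += course.eff_m * decay
        return (np.minimum(ec, 1.0), np.minimum(em, 1.0))

    def fitness_profiles(self, fitness: FitnessParams, M: int) -> tuple[np.ndarray, np.ndarray]:
        """Effective (f_c, f_m) arrays at division indices 0..M-1."""
        ec, em = self.efficacy_profiles(M)
        return (fitness.f_c * (1.0 - ec), fitness.f_m * (1.0 - em))


def effective_fitness(t: float, fitness: FitnessParams, schedule: Schedule | None) -> FitnessParams:
    """Treatment-modified fitness at time ``t`` (in cell divisions).

    Constant mode gives ``f_c (1 - eff_c)`` inside the window and the
    baseline elsewhere; waning mode gives ``f_c (1 - eff_c 2^(-dt/t_half))``
    for t past the administration.  Healthy fitness is returned unchanged.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if schedule is None or len(schedule) == 0:
        return fitness
    ec, em = schedule.efficacies(t)
    return replace(fitness, f_c=fitness.f_c * (1.0 - ec), f_m=fitness.f_m * (1.0 - em))


def superpose_doses(courses, t: float) -> tuple[float, float]:
    """Instantaneous per-clone efficacy of repeated waning doses at time t.

    ``min(1, sum_k eff * 2^(-(t - t_start_k)/t_half))`` over administered
    doses; a single dose reduces to the plain waning form.
    """
    for course in courses:
        if course.mode != "waning":
            raise ValueError("superpose_doses expects waning-mode courses")
    return Schedule(tuple(courses)).efficacies(t)


@dataclass(frozen=True)
class TimeMapping:
    """Conversion between wall-clock time and cell divisions.

    One division step advances the whole population by one birth-death event,
    so a cell cycle of ``hours_per_cell_cycle`` in a population of size N
    corresponds to ``N / hours_per_cell_cycle`` divisions per hour.
    """

    hours_per_division: float

    def __post_init__(self) -> None:
        if self.hours_per_division <= 0:
            raise ValueError("hours_per_division must be positive")

    @classmethod
    def for_population(cls, N: int, hours_per_cell_cycle: float = 8.0) -> "TimeMapping":
        return cls(hours_per_division=hours_per_cell_cycle / N)

    @property
    def divisions_per_hour(self) -> float:
        return 1.0 / self.hours_per_division

    def divisions_from_hours(self, hours) -> np.ndarray | float:
        return np.asarray(hours, dtype=float) * self.divisions_per_hour

    def divisions_from_days(self, days) -> np.ndarray | float:
        return self.divisions_from_hours(np.asarray(days, dtype=float) * 24.0)

    def hours_from_divisions(self, divisions) -> np.ndarray | float:
        return np.asarray(divisions, dtype=float) * self.hours_per_division


PRESET_NAMES = ("mtd", "early-mtd", "dual", "sustained", "waning")


def make_preset(
    name: str,
    *,
    eff_c: float = 0.8,
    eff_m: float = 0.4,
    t_start: float = 5000.0,
    t_length: float = 5000.0,
    early_t_start: float = 500.0,
    eff_scale: float = 1.0 / 5.0,
    length_scale: float = 5.0,
    t_half: float = 5000.0,
    dual_eff: float = 0.8,
) -> Schedule:
    """Named treatment strategies.

    mtd        one constant high dose after the mutant clone typically arises
    early-mtd  the same dose shifted before mutant emergence
    dual       a dose targeting the mutant, then one targeting the cancer
    sustained  the MTD with efficacy scaled by ``eff_scale`` and length by
               ``length_scale`` (defaults 1/5 and 5; a 1/3 and 5 variant is
               used for mutation-rate scans)
    waning     one dose decaying with half-life ``t_half`` from ``t_start``

    The default efficacy pair (0.8 against the cancer clone, 0.4 against the
    mutant) and timing are reconstructions exposed as keyword arguments.
    """
    if name == "mtd":
        return Schedule(
            (TreatmentCourse(eff_c=eff_c, eff_m=eff_m, t_start=t_start, t_length=t_length),)
        )
    if name == "early-mtd":
        return Schedule(
            (
                TreatmentCourse(
                    eff_c=eff_c, eff_m=eff_m, t_start=early_t_start, t_length=t_length
                ),
            )
        )
    if name == "dual":
        half = t_length / 2.0
        return Schedule(
            (
                TreatmentCourse(eff_c=0.0, eff_m=dual_eff, t_start=t_start, t_length=half),
                TreatmentCourse(
                    eff_c=dual_eff, eff_m=0.0, t_start=t_start + half, t_length=half
                ),
            )
        )
    if name == "sustained":
        return Schedule(
            (
                TreatmentCourse(
                    eff_c=eff_c * eff_scale,
                    eff_m=eff_m * eff_scale,
                    t_start=t_start,
                    t_length=t_length * length_scale,
                ),
            )
        )
    if name == "waning":
        return Schedule(
            (
                TreatmentCourse(
                    eff_c=eff_c,
                    eff_m=eff_m,
                    t_start=t_start,
                    mode="waning",
                    t_half=t_half,
                ),
            )
        )
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def repeated_waning_doses(
    *,
    eff_c: float,
    eff_m: float = 0.0,
    n_doses: int = 4,
    interval: float,
    t_half: float,
    t_first: float = 0.0,
) -> Schedule:
    """Schedule of ``n_doses`` identical waning doses ``interval`` apart.

    Mirrors a weekly-injection regimen (e.g. four weekly antibody doses with
    a 5.8-day plasma half-life, converted to divisions via TimeMapping).
    """
    courses = tuple(
        TreatmentCourse(
            eff_c=eff_c,
            eff_m=eff_m,
            t_start=t_first + k * interval,
            mode="waning",
            t_half=t_half,
        )
        for k in range(n_doses)
    )
    return Schedule(courses)
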