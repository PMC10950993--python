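"""Discrete-time Moran birth-death process for healthy, cancer and mutant cells.

The population has fixed size ``N``.  Each division (one timestep) a cell is
chosen to reproduce with probability proportional to ``N_i * f_i`` and a cell
is chosen to die with probability ``N_i / N``; the dying cell is replaced by
the offspring.  A cancer birth is converted into a driver-mutant birth with
probability ``r_m`` (no back-mutation, healthy cells never mutate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernel import DegenerateSelectionError, run_lockstep

__all__ = [
    "PopulationState",
    "FitnessParams",
    "MutationParams",
    "EventDistribution",
    "SimulationConfig",
    "Trajectory",
    "EnsembleSummary",
    "InvalidStateError",
    "DegenerateSelectionError",
    "transition_probabilities",
    "step",
    "simulate",
    "simulate_ensemble",
    "EVENT_NAMES",
]


class InvalidStateError(ValueError):
    """A population state violating the model invariants."""


EVENT_NAMES = (
    "c_birth_h_death",
    "h_birth_c_death",
    "m_birth_h_death",
    "m_birth_c_death",
    "h_birth_m_death",
    "c_birth_m_death",
    "mut_birth_h_death",
    "mut_birth_c_death",
    "mut_birth_m_death",
    "no_change",
)

# (dh, dc, dm) applied to (n_healthy, n_cancer, n_mutant) for each event.
_EVENT_DELTAS = {
    "c_birth_h_death": (-1, 1, 0),
    "h_birth_c_death": (1, -1, 0),
    "m_birth_h_death": (-1, 0, 1),
    "m_birth_c_death": (0, -1, 1),
    "h_birth_m_death": (1, 0, -1),
    "c_birth_m_death": (0, 1, -1),
    "mut_birth_h_death": (-1, 0, 1),
    "mut_birth_c_death": (0, -1, 1),
    "mut_birth_m_death": (0, 0, 0),
    "no_change": (0, 0, 0),
}


@dataclass(frozen=True)
class PopulationState:
    """Counts of the three cell types at a given division index."""

    n_healthy: int
    n_cancer: int
    n_mutant: int = 0
    division_index: int = 0

    def __post_init__(self) -> None:
        if min(self.n_healthy, self.n_cancer, self.n_mutant) < 0:
            raise InvalidStateError("cell counts must be non-negative")
        if self.N == 0:
            raise InvalidStateError("total population must be positive")

    @property
    def N(self) -> int:
        return self.n_healthy + self.n_cancer + self.n_mutant

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_healthy, self.n_cancer, self.n_mutant)


@dataclass(frozen=True)
class FitnessParams:
    """Reproductive weights; the healthy fitness is conventionally 1.

    Baseline fitnesses are strictly positive; treatment may drive an
    *effective* cancer or mutant fitness to exactly zero, so only
    non-negativity is enforced here.
    """

    f_h: float = 1.0
    f_c: float = 1.0
    f_m: float = 1.0

    def __post_init__(self) -> None:
        if min(self.f_h, self.f_c, self.f_m) < 0:
            raise ValueError("fitness values must be non-negative")


@dataclass(frozen=True)
class MutationParams:
    """Driver-mutation probability per cancer birth."""

    r_m: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_m <= 1.0:
            raise ValueError("r_m must lie in [0, 1]")


@dataclass(frozen=True)
class EventDistribution:
    """Categorical distribution over the ten one-division events."""

    probs: tuple[float, ...]

    def __getitem__(self, name: str) -> float:
        return self.probs[EVENT_NAMES.index(name)]

    def total(self) -> float:
        return float(sum(self.probs))

    def as_dict(self) -> dict[str, float]:
        return dict(zip(EVENT_NAMES, self.probs))


def transition_probabilities(
    state: PopulationState, eff_fitness: FitnessParams, mut: MutationParams
) -> EventDistribution:
    """Full event distribution for one division.

    Birth weight of type *i* is ``N_i f_i / W`` with ``W = sum_j N_j f_j``;
    death weight is ``N_i / N``.  A fraction ``r_m`` of the cancer-birth
    weight is diverted to mutant offspring; no-change takes the remaining
    mass (same-type birth/death, plus a mutant born onto a dying mutant).
    """
    N = state.N
    nh, nc, nm = state.as_tuple()
    W = nh * eff_fitness.f_h + nc * eff_fitness.f_c + nm * eff_fitness.f_m
    if W <= 0.0:
        raise DegenerateSelectionError(
            "all effective fitnesses are zero with cells present"
        )
    bh = nh * eff_fitness.f_h / W
    bc = (1.0 - mut.r_m) * nc * eff_fitness.f_c / W
    bmut = mut.r_m * nc * eff_fitness.f_c / W
    bm = nm * eff_fitness.f_m / W
    dh, dc, dm = nh / N, nc / N, nm / N
    probs = {
        "c_birth_h_death": bc * dh,
        "h_birth_c_death": bh * dc,
        "m_birth_h_death": bm * dh,
        "m_birth_c_death": bm * dc,
        "h_birth_m_death": bh * dm,
        "c_birth_m_death": bc * dm,
        "mut_birth_h_death": bmut * dh,
        "mut_birth_c_death": bmut * dc,
        "mut_birth_m_death": bmut * dm,
    }
    probs["no_change"] = 1.0 - sum(probs.values())
    return EventDistribution(tuple(probs[name] for name in EVENT_NAMES))


def step(
    state: PopulationState,
    eff_fitness: FitnessParams,
    mut: MutationParams,
    rng: np.random.Generator,
) -> PopulationState:
    """Sample one event and apply it; the division index advances by one."""
    dist = transition_probabilities(state, eff_fitness, mut)
    u = rng.random()
    acc = 0.0
    event = EVENT_NAMES[-1]
    for name, p in zip(EVENT_NAMES, dist.probs):
        acc += p
        if u < acc:
            event = name
            break
    dh, dc, dm = _EVENT_DELTAS[event]
    return PopulationState(
        n_healthy=state.n_healthy + dh,
        n_cancer=state.n_cancer + dc,
        n_mutant=state.n_mutant + dm,
        division_index=state.division_index + 1,
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Run parameters: population size, divisions, replicates and base seed."""

    N: int
    M: int
    n_total: int = 1
    seed: int = 0
    initial_state: PopulationState = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.M < 1 or self.n_total < 1:
            raise ValueError("M and n_total must be >= 1")
        if self.initial_state is None:
            raise ValueError("initial_state is required")
        if self.initial_state.N != self.N:
            raise InvalidStateError(
                f"initial state sums to {self.initial_state.N}, expected N={self.N}"
            )

    @classmethod
    def from_counts(
        cls,
        N: int,
        M: int,
        n_cancer: int = 0,
        n_mutant: int = 0,
        n_total: int = 1,
        seed: int = 0,
    ) -> "SimulationConfig":
        state = PopulationState(N - n_cancer - n_mutant, n_cancer, n_mutant)
        return cls(N=N, M=M, n_total=n_total, seed=seed, initial_state=state)


@dataclass
class Trajectory:
    """Per-division state sequence for one replicate."""

    states: np.ndarray          # (M+1, 3) integer counts (h, c, m)
    N: int
    seed: tuple[int, int]       # (base seed, replicate index)
    absorbed_at: int | None     # division index the state became absorbing

    def __len__(self) -> int:
        return self.states.shape[0]

    def state_at(self, index: int) -> PopulationState:
        h, c, m = (int(x) for x in self.states[index])
        return PopulationState(h, c, m, division_index=index)

    def to_frame(self, hours_per_division: float | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "division_index": np.arange(len(self)),
                "n_healthy": self.states[:, 0],
                "n_cancer": self.states[:, 1],
                "n_mutant": self.states[:, 2],
            }
        )
        if hours_per_division is not None:
            df.insert(1, "time_hours", df["division_index"] * hours_per_division)
        return df


_FIX_LABELS = ("healthy", "cancer", "mutant", "none")


@dataclass
class EnsembleSummary:
    """Per-step mean/std and per-replicate outcomes over an ensemble."""

    N: int
    M: int
    n_total: int
    base_seed: int
    mean: np.ndarray            # (M+1, 3)
    std: np.ndarray             # (M+1, 3)
    final_states: np.ndarray    # (n_total, 3)
    fixated_type: np.ndarray    # (n_total,) labels from _FIX_LABELS
    t_fix_c: np.ndarray
    t_fix_m: np.ndarray
    t_fix_h: np.ndarray
    t_thresh_m: np.ndarray      # first division N_m >= mutant_threshold (-1 never)
    mutant_threshold: int | None

    def fixation_fraction(self, label: str) -> float:
        return float(np.mean(self.fixated_type == label))

    def to_frame(self, hours_per_division: float | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "division_index": np.arange(self.M + 1),
                "mean_h": self.mean[:, 0],
                "mean_c": self.mean[:, 1],
                "mean_m": self.mean[:, 2],
                "std_h": self.std[:, 0],
                "std_c": self.std[:, 1],
                "std_m": self.std[:, 2],
            }
        )
        if hours_per_division is not None:
            df.insert(1, "time_hours", df["division_index"] * hours_per_division)
        return df

    def final_frame(self) -> pd.DataFrame:
        n = self.final_states.shape[0]
        return pd.DataFrame(
            {
                "replicate": np.arange(n),
                "seed": [f"({self.base_seed},{k})" for k in range(n)],
                "final_h": self.final_states[:, 0],
                "final_c": self.final_states[:, 1],
                "final_m": self.final_states[:, 2],
                "fixated_type": self.fixated_type,
            }
        )


def _fitness_profiles(fitness, schedule, M):
    if schedule is None or not getattr(schedule, "courses", ()):
        return (
            np.full(M, fitness.f_c, dtype=float),
            np.full(M, fitness.f_m, dtype=float),
        )
    return schedule.fitness_profiles(fitness, M)


def simulate(
    config: SimulationConfig,
    fitness: FitnessParams,
    mut: MutationParams = MutationParams(),
    schedule=None,
    replicate: int = 0,
) -> Trajectory:
    """Run one replicate for ``M`` divisions and record every state.

    The replicate's stream is keyed by ``(config.seed, replicate)``, so
    individual trajectories are reproducible independently of ensemble size.
    Absorbed trajectories are padded with the absorbing state out to M.
    """
    fc_prof, fm_prof = _fitness_profiles(fitness, schedule, config.M)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, replicate)))
    res = run_lockstep(
        config.initial_state.as_tuple(),
        config.N,
        config.M,
        fitness.f_h,
        fc_prof,
        fm_prof,
        mut.r_m,
        n_rep=1,
        rng=rng,
        record_states=True,
    )
    absorbed = int(res.absorbed_at[0])
    return Trajectory(
        states=res.states[:, 0, :],
        N=config.N,
        seed=(config.seed, replicate),
        absorbed_at=absorbed if absorbed >= 0 else None,
    )


def _classify_fixation(t_fix_c, t_fix_m, t_fix_h, initial_all_healthy: bool):
    """First type to reach N wins; 'none' if no type fixates within M.

    An all-healthy start trivially 'fixates' healthy at division 0; that label
    is kept only if nothing else ever fixates.
    """
    n = len(t_fix_c)
    labels = np.full(n, "none", dtype=object)
    tc = np.where(t_fix_c < 0, np.iinfo(np.int64).max, t_fix_c)
    tm = np.where(t_fix_m < 0, np.iinfo(np.int64).max, t_fix_m)
    th = np.where(t_fix_h < 0, np.iinfo(np.int64).max, t_fix_h)
    if initial_all_healthy:
        th = np.where(th == 0, np.iinfo(np.int64).max - 1, th)
    best = np.minimum(np.minimum(tc, tm), th)
    hit = best < np.iinfo(np.int64).max - 1
    labels[hit & (best == tc)] = "cancer"
    labels[hit & (best == tm)] = "mutant"
    labels[hit & (best == th)] = "healthy"
    # an all-healthy start that stayed all-healthy is a healthy fixation
    if initial_all_healthy:
        labels[(~hit) & (t_fix_h == 0)] = "healthy"
    return labels


def simulate_ensemble(
    config: SimulationConfig,
    fitness: FitnessParams,
    mut: MutationParams = MutationParams(),
    schedule=None,
    mutant_threshold: int | None = None,
) -> EnsembleSummary:
    """Run ``config.n_total`` replicates and summarise them.

    Replicates advance in lock-step through one vectorised kernel keyed by
    ``config.seed``; results are deterministic given (seed, n_total).
    """
    fc_prof, fm_prof = _fitness_profiles(fitness, schedule, config.M)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    res = run_lockstep(
        config.initial_state.as_tuple(),
        config.N,
        config.M,
        fitness.f_h,
        fc_prof,
        fm_prof,
        mut.r_m,
        n_rep=config.n_total,
        rng=rng,
        mutant_threshold=mutant_threshold,
    )
    labels = _classify_fixation(
        res.t_fix_c,
        res.t_fix_m,
        res.t_fix_h,
        initial_all_healthy=config.initial_state.n_healthy == config.N,
    )
    return EnsembleSummary(
        N=config.N,
        M=config.M,
        n_total=config.n_total,
        base_seed=config.seed,
        mean=res.mean,
        std=res.std,
        final_states=res.final,
        fixated_type=labels,
        t_fix_c=res.t_fix_c,
        t_fix_m=res.t_fix_m,
        t_fix_h=res.t_fix_h,
        t_thresh_m=res.t_thresh_m,
        mutant_threshold=mutant_threshold,
    )
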