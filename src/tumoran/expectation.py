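"""Deterministic recursion for the expected type counts of the Moran model.

One iteration applies the exact one-step conditional expectation of the
three-type event distribution: with ``W = sum_i N_i f_i``,

    dE[N_h] = N_h f_h / W - N_h / N
    dE[N_c] = (1 - r_m) N_c f_c / W - N_c / N
    dE[N_m] = (N_m f_m + r_m N_c f_c) / W - N_m / N

which reduces to the classical two-type form when ``r_m = 0`` and
``N_m = 0``.  Counts are propagated as real numbers without rounding: the
recursion is a mean field, not a state, so it never absorbs and is a good
surrogate for the ensemble mean only while stochastic extinction is rare
(in practice, when every nonzero initial count is at least ~10% of N).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernel import DegenerateSelectionError
from .moran import FitnessParams, MutationParams, SimulationConfig, _fitness_profiles

__all__ = ["ExpectedTrajectory", "expected_step", "expected_trajectory"]

#: fraction of N below which a nonzero initial count makes the mean-field
#: recursion diverge from the ensemble mean (stochastic die-out matters)
VALIDITY_FRACTION = 0.1


@dataclass
class ExpectedTrajectory:
    """Real-valued expected counts per division index."""

    counts: np.ndarray          # (M+1, 3) expected (h, c, m)
    N: int
    below_validity_threshold: bool

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def burden(self) -> np.ndarray:
        """Expected tumour burden N_c + N_m per division."""
        return self.counts[:, 1] + self.counts[:, 2]

    def to_frame(self, hours_per_division: float | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "division_index": np.arange(len(self)),
                "n_healthy": self.counts[:, 0],
                "n_cancer": self.counts[:, 1],
                "n_mutant": self.counts[:, 2],
            }
        )
        if hours_per_division is not None:
            df.insert(1, "time_hours", df["division_index"] * hours_per_division)
        return df


def expected_step(
    counts: np.ndarray,
    eff_fitness: FitnessParams,
    mut: MutationParams = MutationParams(),
    N: float | None = None,
) -> np.ndarray:
    """One mean-field iteration; ``counts`` is (..., 3) as (h, c, m)."""
    counts = np.asarray(counts, dtype=float)
    nh, nc, nm = counts[..., 0], counts[..., 1], counts[..., 2]
    if N is None:
        N = float(np.sum(counts[..., :3], axis=-1).flat[0])
    W = nh * eff_fitness.f_h + nc * eff_fitness.f_c + nm * eff_fitness.f_m
    if np.any(W <= 0.0):
        raise DegenerateSelectionError("total reproductive weight is zero")
    new = np.empty_like(counts)
    new[..., 0] = nh + nh * eff_fitness.f_h / W - nh / N
    new[..., 1] = nc + (1.0 - mut.r_m) * nc * eff_fitness.f_c / W - nc / N
    new[..., 2] = nm + (nm * eff_fitness.f_m + mut.r_m * nc * eff_fitness.f_c) / W - nm / N
    return new


def expected_trajectory(
    config: SimulationConfig,
    fitness: FitnessParams,
    mut: MutationParams = MutationParams(),
    schedule=None,
) -> ExpectedTrajectory:
    """Iterate the recursion for ``config.M`` divisions.

    The validity flag is raised when any nonzero initial count is below
    10% of N, the regime where the stochastic ensemble mean is dragged down
    by trajectories that die out.
    """
    fc_prof, fm_prof = _fitness_profiles(fitness, schedule, config.M)
    init = np.asarray(config.initial_state.as_tuple(), dtype=float)
    N = float(config.N)
    out = np.empty((config.M + 1, 3))
    out[0] = init
    cur = init.copy()
    for t in range(config.M):
        fc, fm = fc_prof[t], fm_prof[t]
        nh, nc, nm = cur
        W = nh * fitness.f_h + nc * fc + nm * fm
        if W <= 0.0:
            raise DegenerateSelectionError("total reproductive weight is zero")
        cur = np.array(
            [
                nh + nh * fitness.f_h / W - nh / N,
                nc + (1.0 - mut.r_m) * nc * fc / W - nc / N,
                nm + (nm * fm + mut.r_m * nc * fc) / W - nm / N,
            ]
        )
        out[t + 1] = cur
    below = bool(np.any((init > 0) & (init < VALIDITY_FRACTION * N)))
    return ExpectedTrajectory(counts=out, N=config.N, below_validity_threshold=below)


def expected_burden_grid(
    N: float,
    initial: tuple[float, float, float],
    M: int,
    f_h: float,
    fc: np.ndarray,
    fm: np.ndarray,
    rm: np.ndarray,
    record_steps: np.ndarray,
    eff_profile: np.ndarray | None = None,
    eff_scale_c: np.ndarray | None = None,
    eff_scale_m: np.ndarray | None = None,
) -> np.ndarray:
    """Expected burden (N_c + N_m) at selected divisions for a parameter grid.

    ``fc, fm, rm`` are flat arrays of equal length G (one entry per grid
    point).  When ``eff_profile`` (length M, the summed per-dose decay at
    each division) is given, the instantaneous efficacy of grid point g is
    ``min(1, eff_scale_c[g] * eff_profile[t])`` against the cancer clone and
    analogously for the mutant.  Returns an array of shape (G, K) where K is
    ``len(record_steps)`` (sorted, unique division indices).

    This is the grid engine behind the RMSE calibration: it propagates all
    candidate parameter combinations through the recursion simultaneously.
    """
    fc = np.asarray(fc, dtype=float)
    fm = np.asarray(fm, dtype=float)
    rm = np.asarray(rm, dtype=float)
    G = fc.shape[0]
    record_steps = np.asarray(record_steps, dtype=int)
    out = np.empty((G, record_steps.shape[0]))
    rec_pos = {int(s): i for i, s in enumerate(record_steps)}

    nh = np.full(G, initial[0], dtype=float)
    nc = np.full(G, initial[1], dtype=float)
    nm = np.full(G, initial[2], dtype=float)
    if 0 in rec_pos:
        out[:, rec_pos[0]] = nc + nm
    for t in range(M):
        if eff_profile is not None:
            w = eff_profile[t]
            fce = fc * (1.0 - np.minimum(1.0, eff_scale_c * w))
            fme = fm * (1.0 - np.minimum(1.0, eff_scale_m * w))
        else:
            fce, fme = fc, fm
        W = nh * f_h + nc * fce + nm * fme
        if np.any(W <= 0.0):
            raise DegenerateSelectionError("total reproductive weight is zero")
        dh = nh * f_h / W - nh / N
        dm = (nm * fme + rm * nc * fce) / W - nm / N
        nc = nc + (1.0 - rm) * nc * fce / W - nc / N
        nh = nh + dh
        nm = nm + dm
        if (t + 1) in rec_pos:
            out[:, rec_pos[t + 1]] = nc + nm
    return out
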