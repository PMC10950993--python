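"""Vectorised lock-step engine for ensembles of Moran birth-death replicates.

All replicates advance together, one division per iteration, drawing from a
single NumPy Generator.  Per step and replicate three uniforms are consumed:
one to pick the reproducing type (fitness-weighted), one for the driver
mutation (cancer births only), one to pick the dying cell (count-weighted).
Same-type birth/death collapses to a no-change event, which reproduces the
product-form transition probabilities of the two- and three-type model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KernelResult", "run_lockstep", "DegenerateSelectionError"]


class DegenerateSelectionError(ValueError):
    """All effective fitnesses are zero while cells remain: no cell can reproduce."""


@dataclass
class KernelResult:
    """Raw per-ensemble output of :func:`run_lockstep`."""

    N: int
    M: int
    n_rep: int
    sum_counts: np.ndarray     # (M+1, 3) per-step sum over replicates of (h, c, m)
    sumsq_counts: np.ndarray   # (M+1, 3) per-step sum of squares
    final: np.ndarray          # (n_rep, 3) state at division M
    t_fix_c: np.ndarray        # (n_rep,) first division with N_c == N, -1 if never
    t_fix_m: np.ndarray        # (n_rep,) first division with N_m == N, -1 if never
    t_fix_h: np.ndarray        # (n_rep,) first division with N_h == N, -1 if never
    t_thresh_m: np.ndarray     # (n_rep,) first division with N_m >= threshold, -1
    absorbed_at: np.ndarray    # (n_rep,) first division the state became absorbing
    states: np.ndarray | None  # (M+1, n_rep, 3) only when recorded

    @property
    def mean(self) -> np.ndarray:
        return self.sum_counts / self.n_rep

    @property
    def std(self) -> np.ndarray:
        var = self.sumsq_counts / self.n_rep - self.mean**2
        return np.sqrt(np.clip(var, 0.0, None))


def _absorbing_mask(nh, nc, nm, N, r_m):
    # All-healthy and all-mutant states are absorbing regardless of fitness;
    # all-cancer is absorbing only when driver mutation is switched off.
    mask = (nh == N) | (nm == N)
    if r_m == 0.0:
        mask = mask | (nc == N)
    return mask


def run_lockstep(
    initial: tuple[int, int, int],
    N: int,
    M: int,
    f_h: float,
    fc_profile: np.ndarray,
    fm_profile: np.ndarray,
    r_m: float,
    n_rep: int,
    rng: np.random.Generator,
    *,
    record_states: bool = False,
    mutant_threshold: int | None = None,
    check_interval: int = 64,
) -> KernelResult:
    """Advance ``n_rep`` replicates for ``M`` divisions.

    ``fc_profile`` / ``fm_profile`` hold the effective cancer and mutant
    fitness at every division index (length ``M``); the healthy fitness is
    constant.  Early exit occurs once every replicate sits in an absorbing
    state, after which all summaries are padded with the frozen values.
    """
    nh0, nc0, nm0 = initial
    if nh0 + nc0 + nm0 != N:
        raise ValueError(f"initial counts sum to {nh0 + nc0 + nm0}, expected N={N}")
    fc_profile = np.asarray(fc_profile, dtype=float)
    fm_profile = np.asarray(fm_profile, dtype=float)
    if fc_profile.shape != (M,) or fm_profile.shape != (M,):
        raise ValueError("fitness profiles must have length M")

    nh = np.full(n_rep, nh0, dtype=np.int64)
    nc = np.full(n_rep, nc0, dtype=np.int64)
    nm = np.full(n_rep, nm0, dtype=np.int64)

    sum_counts = np.empty((M + 1, 3), dtype=float)
    sumsq_counts = np.empty((M + 1, 3), dtype=float)
    t_fix_c = np.full(n_rep, -1, dtype=np.int64)
    t_fix_m = np.full(n_rep, -1, dtype=np.int64)
    t_fix_h = np.full(n_rep, -1, dtype=np.int64)
    t_thresh_m = np.full(n_rep, -1, dtype=np.int64)
    absorbed_at = np.full(n_rep, -1, dtype=np.int64)
    states = np.empty((M + 1, n_rep, 3), dtype=np.int64) if record_states else None

    thr = mutant_threshold if mutant_threshold is not None else N + 1

    def _mark(t: int) -> None:
        counts = np.stack([nh, nc, nm], axis=1).astype(float)
        sum_counts[t] = counts.sum(axis=0)
        sumsq_counts[t] = (counts**2).sum(axis=0)
        if states is not None:
            states[t, :, 0] = nh
            states[t, :, 1] = nc
            states[t, :, 2] = nm
        for arr, hit in (
            (t_fix_c, nc == N),
            (t_fix_m, nm == N),
            (t_fix_h, nh == N),
            (t_thresh_m, nm >= thr),
        ):
            np.copyto(arr, t, where=(arr < 0) & hit)
        newly = (absorbed_at < 0) & _absorbing_mask(nh, nc, nm, N, r_m)
        np.copyto(absorbed_at, t, where=newly)

    _mark(0)

    t_stop = M
    for t in range(M):
        fc = fc_profile[t]
        fm = fm_profile[t]
        wh = nh * f_h
        wc = nc * fc
        wm = nm * fm
        W = wh + wc + wm
        if np.any(W <= 0.0):
            raise DegenerateSelectionError(
                "total reproductive weight is zero in at least one replicate"
            )
        u = rng.random((3, n_rep))
        pc = wc / W
        pm = wm / W
        rep_c = u[0] < pc
        rep_m = ~rep_c & (u[0] < pc + pm)
        mut = rep_c & (u[1] < r_m) if r_m > 0.0 else np.zeros(n_rep, dtype=bool)
        ud = u[2] * N
        die_h = ud < nh
        die_c = ~die_h & (ud < nh + nc)
        die_m = ~(die_h | die_c)

        born_m = rep_m | mut
        born_c = rep_c & ~mut
        born_h = ~(rep_c | rep_m)
        nh += born_h
        nc += born_c
        nm += born_m
        nh -= die_h
        nc -= die_c
        nm -= die_m
        _mark(t + 1)

        if (t + 1) % check_interval == 0 and bool(np.all(absorbed_at >= 0)):
            t_stop = t + 1
            break

    if t_stop < M:  # pad: absorbed states never change again
        sum_counts[t_stop + 1 :] = sum_counts[t_stop]
        sumsq_counts[t_stop + 1 :] = sumsq_counts[t_stop]
        if states is not None:
            states[t_stop + 1 :] = states[t_stop]

    final = np.stack([nh, nc, nm], axis=1)
    return KernelResult(
        N=N,
        M=M,
        n_rep=n_rep,
        sum_counts=sum_counts,
        sumsq_counts=sumsq_counts,
        final=final,
        t_fix_c=t_fix_c,
        t_fix_m=t_fix_m,
        t_fix_h=t_fix_h,
        t_thresh_m=t_thresh_m,
        absorbed_at=absorbed_at,
        states=states,
    )
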