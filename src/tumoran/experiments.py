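"""Reproducible drivers for the quantitative experiments.

Covers stochastic-tunneling estimation, two-parameter fixation-region scans,
the minimum-fitness-versus-time curve for a single founding cancer cell, and
paired comparisons of treatment strategies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .moran import (
    EnsembleSummary,
    FitnessParams,
    MutationParams,
    SimulationConfig,
    simulate_ensemble,
)
from .treatment import Schedule, make_preset

__all__ = [
    "TunnelingResult",
    "RegionScan",
    "MinFitnessCurve",
    "StrategyReport",
    "estimate_tunneling",
    "scan_fixation_regions",
    "min_fitness_curve",
    "compare_strategies",
    "scan_treatment",
]


@dataclass
class TunnelingResult:
    """Binomial estimate of the probability the mutant fixates first."""

    probability: float
    n_total: int
    std_error: float
    outcomes: np.ndarray        # per-replicate labels {mutant, cancer, none, healthy}
    t_fix_m: np.ndarray

    def summary(self) -> str:
        counts = pd.Series(self.outcomes).value_counts()
        lines = [
            "Tunneling estimate",
            f"  P(mutant fixates first) = {self.probability:.4f} "
            f"+/- {self.std_error:.4f} (binomial SE, n={self.n_total})",
            "  outcomes: "
            + ", ".join(f"{k}={v}" for k, v in counts.items()),
        ]
        return "\n".join(lines)


def estimate_tunneling(
    config: SimulationConfig,
    fitness: FitnessParams,
    mut: MutationParams,
    schedule: Schedule | None = None,
) -> TunnelingResult:
    """Fraction of replicates in which the mutant clone reaches N first.

    A replicate tunnels iff ``N_m`` hits N within M divisions before the
    original cancer does; replicates where neither type fixates count
    against tunneling.
    """
    ens = simulate_ensemble(config, fitness, mut, schedule)
    p = ens.fixation_fraction("mutant")
    se = float(np.sqrt(p * (1.0 - p) / config.n_total))
    return TunnelingResult(
        probability=p,
        n_total=config.n_total,
        std_error=se,
        outcomes=ens.fixated_type,
        t_fix_m=ens.t_fix_m,
    )


@dataclass
class RegionScan:
    """Fixation proportions and majority classification over an (f_m, f_c) grid."""

    fm_grid: np.ndarray
    fc_grid: np.ndarray
    prop_mutant: np.ndarray     # (len(fm), len(fc))
    prop_cancer: np.ndarray
    classification: np.ndarray  # object array {mutant, cancer, none}

    def to_frame(self) -> pd.DataFrame:
        fm, fc = np.meshgrid(self.fm_grid, self.fc_grid, indexing="ij")
        return pd.DataFrame(
            {
                "f_m": fm.ravel(),
                "f_c": fc.ravel(),
                "prop_mutant_fix": self.prop_mutant.ravel(),
                "prop_cancer_fix": self.prop_cancer.ravel(),
                "classification": self.classification.ravel(),
            }
        )

    def boundary_ratio(self) -> float:
        """Mean f_c/f_m along the upper edge of the mutant-classified region.

        For each f_m row the boundary is the midpoint between the highest
        f_c still classified mutant and the lowest f_c classified cancer.
        When the scan contains no cancer-classified cell (at large N the
        continuous mutant influx makes exact cancer fixation unreachable)
        the edge against the unclassified region is used instead: the
        mutant-success region is bounded either way.  Rows without a mutant
        cell or with an interleaved boundary are skipped; NaN if no row
        qualifies.
        """
        ratios = []
        for i, fm in enumerate(self.fm_grid):
            col = self.classification[i]
            mut_idx = np.flatnonzero(col == "mutant")
            can_idx = np.flatnonzero(col == "cancer")
            if can_idx.size == 0:
                can_idx = np.flatnonzero(col != "mutant")
            if mut_idx.size == 0 or can_idx.size == 0:
                continue
            above = can_idx[can_idx > mut_idx.max()]
            if above.size == 0 or above.min() != mut_idx.max() + 1:
                continue
            lo = self.fc_grid[mut_idx.max()]
            hi = self.fc_grid[above.min()]
            ratios.append(0.5 * (lo + hi) / fm)
        if not ratios:
            return float("nan")
        return float(np.mean(ratios))


def scan_fixation_regions(
    fm_grid: np.ndarray,
    fc_grid: np.ndarray,
    config: SimulationConfig,
    mut: MutationParams,
    f_h: float = 1.0,
) -> RegionScan:
    """Classify each (f_m, f_c) cell by the cancer type most likely to fixate.

    Runs ``config.n_total`` replicates per cell (each cell seeded from the
    base seed and its grid position); the classification is the majority
    among fixating replicates, or ``none`` when no replicate fixates.
    """
    fm_grid = np.asarray(fm_grid, dtype=float)
    fc_grid = np.asarray(fc_grid, dtype=float)
    if np.any(np.diff(fm_grid) <= 0) or np.any(np.diff(fc_grid) <= 0):
        raise ValueError("grids must be strictly increasing")
    shape = (fm_grid.size, fc_grid.size)
    prop_m = np.zeros(shape)
    prop_c = np.zeros(shape)
    cls = np.full(shape, "none", dtype=object)
    for i, fm in enumerate(fm_grid):
        for j, fc in enumerate(fc_grid):
            cell_cfg = replace(config, seed=config.seed + 1_000_003 * i + 7_019 * j)
            ens = simulate_ensemble(
                cell_cfg, FitnessParams(f_h=f_h, f_c=fc, f_m=fm), mut
            )
            pm = ens.fixation_fraction("mutant")
            pc = ens.fixation_fraction("cancer")
            prop_m[i, j] = pm
            prop_c[i, j] = pc
            if pm == 0.0 and pc == 0.0:
                cls[i, j] = "none"
            else:
                cls[i, j] = "mutant" if pm >= pc else "cancer"
    return RegionScan(fm_grid, fc_grid, prop_m, prop_c, cls)


@dataclass
class MinFitnessCurve:
    """Minimum cancer fitness needed for the ensemble mean to pass 0.5N, per M."""

    M_grid: np.ndarray
    min_fc: np.ndarray          # NaN where no grid fitness suffices
    fc_grid: np.ndarray
    threshold: float

    @property
    def min_feasible_M(self) -> float:
        """Smallest M at which any grid fitness reaches the threshold."""
        ok = np.flatnonzero(~np.isnan(self.min_fc))
        return float(self.M_grid[ok.min()]) if ok.size else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"M": self.M_grid, "min_f_c": self.min_fc})


def min_fitness_curve(
    M_grid: np.ndarray,
    fc_grid: np.ndarray,
    config: SimulationConfig,
    f_h: float = 1.0,
) -> MinFitnessCurve:
    """Smallest grid f_c whose 0-mutation ensemble mean exceeds 0.5N by division M.

    The ensemble (default: a single founding cancer cell in N=100) is run
    once per f_c out to max(M_grid); feasibility at smaller M is read off the
    recorded mean curve.  The threshold is on the ensemble mean, matching
    the averaged-simulation methodology of the final-proportion scans.
    """
    M_grid = np.asarray(M_grid, dtype=int)
    fc_grid = np.asarray(fc_grid, dtype=float)
    M_max = int(M_grid.max())
    threshold = 0.5 * config.N
    mean_c = np.empty((fc_grid.size, M_max + 1))
    for k, fc in enumerate(fc_grid):
        cfg = replace(config, M=M_max, seed=config.seed + 7_919 * k)
        ens = simulate_ensemble(cfg, FitnessParams(f_h=f_h, f_c=fc), MutationParams(0.0))
        mean_c[k] = ens.mean[:, 1]
    min_fc = np.full(M_grid.size, np.nan)
    for idx, M in enumerate(M_grid):
        feasible = np.flatnonzero(mean_c[:, M] > threshold)
        if feasible.size:
            min_fc[idx] = fc_grid[feasible.min()]
    return MinFitnessCurve(M_grid=M_grid, min_fc=min_fc, fc_grid=fc_grid, threshold=threshold)


@dataclass
class StrategyReport:
    """Paired ensemble comparison of treatment strategies."""

    summaries: dict[str, EnsembleSummary]
    final_proportions: pd.DataFrame       # long format: strategy, replicate, type, proportion
    prop_mutant_above_half: dict[str, float]
    prop_healthy_fixation: dict[str, float]

    def summary(self) -> str:
        lines = ["Strategy comparison (fraction of replicates)"]
        for name in self.summaries:
            lines.append(
                f"  {name:12s} mutant >= 0.5N: {self.prop_mutant_above_half[name]:.3f}   "
                f"healthy fixation: {self.prop_healthy_fixation[name]:.3f}"
            )
        return "\n".join(lines)


def compare_strategies(
    strategies: Mapping[str, Schedule | None],
    config: SimulationConfig,
    fitness: FitnessParams,
    mut: MutationParams,
    paired: bool = True,
) -> StrategyReport:
    """Run every strategy over a common ensemble and collect outcome statistics.

    With ``paired=True`` all arms share the base seed so replicate k consumes
    the same uniform stream in every arm, reducing comparison variance; an
    unpaired mode draws an independent stream per arm.
    """
    summaries: dict[str, EnsembleSummary] = {}
    rows = []
    above = {}
    healthy = {}
    thr = int(np.ceil(0.5 * config.N))
    for a, (name, schedule) in enumerate(strategies.items()):
        cfg = config if paired else replace(config, seed=config.seed + 104_729 * (a + 1))
        ens = simulate_ensemble(cfg, fitness, mut, schedule, mutant_threshold=thr)
        summaries[name] = ens
        props = ens.final_states / config.N
        for tname, col in (("healthy", 0), ("cancer", 1), ("mutant", 2)):
            rows.append(
                pd.DataFrame(
                    {
                        "strategy": name,
                        "replicate": np.arange(config.n_total),
                        "cell_type": tname,
                        "proportion": props[:, col],
                    }
                )
            )
        above[name] = float(np.mean(ens.t_thresh_m >= 0))
        healthy[name] = float(np.mean(ens.final_states[:, 0] == config.N))
    return StrategyReport(
        summaries=summaries,
        final_proportions=pd.concat(rows, ignore_index=True),
        prop_mutant_above_half=above,
        prop_healthy_fixation=healthy,
    )


def scan_treatment(
    rm_grid: np.ndarray,
    effm_grid: np.ndarray,
    strategy: str | Callable[[float], Schedule],
    config: SimulationConfig,
    fitness: FitnessParams | None = None,
    preset_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Proportion of replicates with ``N_m >= 0.5N`` over an (r_m, eff_m) grid.

    ``strategy`` is a preset name (rebuilt per grid point with the scanned
    eff_m) or a callable mapping eff_m to a Schedule.  The default fitness
    uses a moderately fit mutant (f_m = 1.6) over a weakly advantaged cancer.
    """
    if fitness is None:
        fitness = FitnessParams(f_h=1.0, f_c=1.1, f_m=1.6)
    preset_kwargs = dict(preset_kwargs or {})
    if callable(strategy):
        build = strategy
    else:
        def build(effm: float, _name=strategy) -> Schedule:
            kw = dict(preset_kwargs)
            kw["eff_m"] = effm
            return make_preset(_name, **kw)

    thr = int(np.ceil(0.5 * config.N))
    rows = []
    # seed varies only with eff_m so cells are paired across the r_m axis
    for i, rm in enumerate(np.asarray(rm_grid, dtype=float)):
        for j, effm in enumerate(np.asarray(effm_grid, dtype=float)):
            cfg = replace(config, seed=config.seed + 613 * j)
            ens = simulate_ensemble(
                cfg, fitness, MutationParams(rm), build(effm), mutant_threshold=thr
            )
            rows.append(
                {
                    "r_m": rm,
                    "eff_m": effm,
                    "prop_mutant_above_half": float(np.mean(ens.t_thresh_m >= 0)),
                }
            )
    return pd.DataFrame(rows)
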