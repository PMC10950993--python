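"""Grid-search RMSE calibration of the mean-field Moran model to growth data.

The workflow is two-stage, mirroring a vehicle/treated animal experiment:

1. :class:`MoranGrowthModel` fits the fitness ratios ``f_c/f_h``, ``f_m/f_h``
   and the driver-mutation probability ``r_m`` to an untreated (vehicle)
   growth series by exhaustively scanning a parameter grid, scoring each
   combination by the root-mean-square error between the observed burden and
   the expectation recursion interpolated at the observation times.
2. :class:`TreatmentEfficacyModel` holds the stage-1 parameters fixed and
   scans the treatment efficacies ``(eff_c, eff_m)`` under a regimen of
   repeated waning doses (exponential decay with the drug's half-life,
   contributions from successive doses adding and saturating at 1).

Observed sizes are normalised by the model's carrying capacity ``N`` so the
fit operates on proportions; observation times are converted to division
indices at ``N / hours-per-cell-cycle`` divisions per hour (8-hour cycle by
default) and the model curve is linearly interpolated between divisions.
Ties in the grid scan break to the first-encountered combination in
lexicographic (f_c, f_m, r_m) order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .expectation import expected_burden_grid
from .treatment import TimeMapping

__all__ = [
    "GrowthSeries",
    "GridSpec",
    "EfficacyGridSpec",
    "DoseRegimen",
    "MoranGrowthModel",
    "MoranGrowthResults",
    "TreatmentEfficacyModel",
    "TreatmentEfficacyResults",
    "rmse_objective",
    "fit_growth",
    "fit_treatment",
]


@dataclass
class GrowthSeries:
    """Observed (time, size) tumour-growth records for one experimental arm."""

    time_days: np.ndarray
    size: np.ndarray
    label: str = "vehicle"
    dose_times_days: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_days = np.asarray(self.time_days, dtype=float)
        self.size = np.asarray(self.size, dtype=float)
        if self.time_days.size == 0:
            raise ValueError("growth series must contain at least one record")
        if self.time_days.shape != self.size.shape:
            raise ValueError("time and size must have equal length")
        if np.any(np.diff(self.time_days) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.size < 0):
            raise ValueError("sizes must be non-negative")
        if self.dose_times_days is not None:
            self.dose_times_days = np.asarray(self.dose_times_days, dtype=float)

    def __len__(self) -> int:
        return self.time_days.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_days": self.time_days, "size": self.size, "label": self.label}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str | None = None) -> "GrowthSeries":
        required = {"time_days", "size"}
        if not required.issubset(df.columns):
            raise ValueError(f"growth series frame needs columns {sorted(required)}")
        if label is not None:
            df = df[df["label"] == label]
        lab = label or (str(df["label"].iloc[0]) if "label" in df else "vehicle")
        return cls(df["time_days"].to_numpy(), df["size"].to_numpy(), label=lab)


def _grid(start: float, stop: float, step: float) -> np.ndarray:
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


@dataclass
class GridSpec:
    """Stage-1 search grid over (f_c/f_h, f_m/f_h, r_m).

    The full-resolution fitness grid spans 1 to 2 in steps of 0.001; the
    default here is a coarser 0.01 step for interactive use (``fine()``
    restores the full resolution).  The mutation grid is logarithmic over
    the range reported for driver mutations (1e-9 .. 1e-3) plus zero.
    """

    fc: np.ndarray = field(default_factory=lambda: _grid(1.0, 2.0, 0.01))
    fm: np.ndarray = field(default_factory=lambda: _grid(1.0, 2.0, 0.05))
    rm: np.ndarray = field(
        default_factory=lambda: np.concatenate(([0.0], np.logspace(-9, -3, 7)))
    )

    def __post_init__(self) -> None:
        self.fc = np.atleast_1d(np.asarray(self.fc, dtype=float))
        self.fm = np.atleast_1d(np.asarray(self.fm, dtype=float))
        self.rm = np.atleast_1d(np.asarray(self.rm, dtype=float))
        if min(self.fc.size, self.fm.size, self.rm.size) == 0:
            raise ValueError("grid axes must be non-empty")

    @classmethod
    def fine(cls) -> "GridSpec":
        return cls(fc=_grid(1.0, 2.0, 0.001), fm=_grid(1.0, 2.0, 0.001))

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.fc.size, self.fm.size, self.rm.size)


@dataclass
class EfficacyGridSpec:
    """Stage-2 search grid over (eff_c, eff_m); full resolution is 0.1% steps."""

    eff_c: np.ndarray = field(default_factory=lambda: _grid(0.0, 1.0, 0.001))
    eff_m: np.ndarray = field(default_factory=lambda: _grid(0.0, 1.0, 0.05))

    def __post_init__(self) -> None:
        self.eff_c = np.atleast_1d(np.asarray(self.eff_c, dtype=float))
        self.eff_m = np.atleast_1d(np.asarray(self.eff_m, dtype=float))
        if min(self.eff_c.size, self.eff_m.size) == 0:
            raise ValueError("grid axes must be non-empty")


@dataclass
class DoseRegimen:
    """Repeated identical doses with exponentially waning effect."""

    dose_times_days: np.ndarray
    half_life_days: float = 5.8

    def __post_init__(self) -> None:
        self.dose_times_days = np.atleast_1d(
            np.asarray(self.dose_times_days, dtype=float)
        )
        if self.half_life_days <= 0:
            raise ValueError("half-life must be positive")

    def decay_profile(self, mapping: TimeMapping, M: int) -> np.ndarray:
        """Summed per-dose decay factor at each division index 0..M-1."""
        t = np.arange(M, dtype=float)
        starts = mapping.divisions_from_days(self.dose_times_days)
        t_half = float(mapping.divisions_from_days(self.half_life_days))
        prof = np.zeros(M)
        for s in np.atleast_1d(starts):
            dt = t - s
            prof += np.where(dt >= 0, 2.0 ** (-np.maximum(dt, 0.0) / t_half), 0.0)
        return prof


class _GrowthData:
    """Shared data plumbing: time conversion and interpolation weights."""

    def __init__(
        self,
        series: GrowthSeries,
        N: int,
        hours_per_cell_cycle: float = 8.0,
        initial_burden: float | None = None,
    ):
        self.series = series
        self.N = int(N)
        self.mapping = TimeMapping.for_population(N, hours_per_cell_cycle)
        t_div = np.asarray(self.mapping.divisions_from_days(series.time_days))
        if np.any(t_div < 0):
            raise ValueError("observation times must be non-negative")
        self.M = int(np.ceil(t_div.max())) if t_div.max() > 0 else 1
        lo = np.floor(t_div).astype(int)
        self.frac = t_div - lo
        self.lo = lo
        steps = np.unique(np.concatenate([lo, np.minimum(lo + 1, self.M)]))
        self.record_steps = steps
        self._pos = {int(s): i for i, s in enumerate(steps)}
        burden0 = float(series.size[0]) if initial_burden is None else float(initial_burden)
        if not 0 <= burden0 <= N:
            raise ValueError("initial burden must lie in [0, N]")
        self.initial = (N - burden0, burden0, 0.0)
        self.target = series.size / N  # fit on proportions

    def interp(self, burden_at_steps: np.ndarray) -> np.ndarray:
        """(G, K) recorded burdens -> proportions of N at the data times."""
        i0 = np.array([self._pos[int(s)] for s in self.lo])
        i1 = np.array([self._pos[int(min(s + 1, self.M))] for s in self.lo])
        b0 = burden_at_steps[:, i0]
        b1 = burden_at_steps[:, i1]
        return (b0 + self.frac * (b1 - b0)) / self.N


@dataclass
class MoranGrowthResults:
    """Stage-1 estimates with the full RMSE surface for diagnostics."""

    fc_ratio: float
    fm_ratio: float
    r_m: float
    rmse: float
    rmse_grid: np.ndarray       # shape grid.shape, lexicographic (fc, fm, rm)
    grid: GridSpec
    model: "MoranGrowthModel"

    @property
    def params(self) -> dict[str, float]:
        return {"fc_ratio": self.fc_ratio, "fm_ratio": self.fm_ratio, "r_m": self.r_m}

    def predict(self, time_days: np.ndarray | None = None) -> pd.DataFrame:
        """Fitted expected burden (proportion of N) at the given times."""
        data = self.model._data
        t = data.series.time_days if time_days is None else np.asarray(time_days, float)
        pred = self.model._burden_on_grid(
            np.array([self.fc_ratio]), np.array([self.fm_ratio]), np.array([self.r_m]),
            time_days=t,
        )[0]
        return pd.DataFrame({"time_days": t, "burden_proportion": pred})

    def identifiability_profile(self) -> pd.DataFrame:
        """Profile RMSE over (f_m/f_h, r_m), minimised over f_c/f_h.

        The near-flat valley running across this surface is the practical
        non-identifiability between the mutant fitness ratio and the
        mutation probability: many (f_m, r_m) pairs produce almost the same
        burden curve.
        """
        prof = self.rmse_grid.min(axis=0)
        fm, rm = np.meshgrid(self.grid.fm, self.grid.rm, indexing="ij")
        return pd.DataFrame(
            {"fm_ratio": fm.ravel(), "r_m": rm.ravel(), "rmse": prof.ravel()}
        )

    def summary(self) -> str:
        d = self.model._data
        lines = [
            "Moran growth model (vehicle fit, grid-search RMSE)",
            "=" * 52,
            f"observations: {len(d.series):4d}    N (carrying capacity): {d.N}",
            f"grid points:  {int(np.prod(self.grid.shape)):4d}    divisions/hour: "
            f"{d.mapping.divisions_per_hour:.3f}",
            "-" * 52,
            f"f_c / f_h  {self.fc_ratio:10.4f}",
            f"f_m / f_h  {self.fm_ratio:10.4f}",
            f"r_m        {self.r_m:10.3e}",
            f"RMSE       {self.rmse:10.6f}  (burden as proportion of N)",
            "=" * 52,
        ]
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = self.model._data
        ax.plot(d.series.time_days, d.target, "o", label="observed")
        tt = np.linspace(d.series.time_days[0], d.series.time_days[-1], 200)
        ax.plot(tt, self.predict(tt)["burden_proportion"], "-", label="fitted model")
        ax.set_xlabel("time (days)")
        ax.set_ylabel("tumour burden (proportion of N)")
        ax.legend()
        return ax


class MoranGrowthModel:
    """Mean-field Moran growth model for an untreated tumour-growth series.

    Parameters
    ----------
    series
        Observed (time, size) records; sizes are in cells and are divided by
        ``N`` internally.
    N
        Carrying capacity (fixed total cell count of the Moran model).
    hours_per_cell_cycle
        Average single-cell division time; sets the division rate N/cycle.
    initial_burden
        Cancer burden (cells) at time zero; defaults to the first observation.
    grid
        Stage-1 search grid; defaults to :class:`GridSpec` defaults.
    """

    def __init__(
        self,
        series: GrowthSeries,
        N: int,
        hours_per_cell_cycle: float = 8.0,
        initial_burden: float | None = None,
        grid: GridSpec | None = None,
    ):
        self._data = _GrowthData(series, N, hours_per_cell_cycle, initial_burden)
        self.grid = grid if grid is not None else GridSpec()

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, N: int, label: str | None = None, **kwargs
    ) -> "MoranGrowthModel":
        return cls(GrowthSeries.from_frame(df, label=label), N=N, **kwargs)

    def _burden_on_grid(self, fc, fm, rm, time_days=None, eff_profile=None,
                        eff_c=None, eff_m=None) -> np.ndarray:
        data = self._data
        if time_days is None:
            burdens = expected_burden_grid(
                data.N, data.initial, data.M, 1.0, fc, fm, rm, data.record_steps,
                eff_profile=eff_profile, eff_scale_c=eff_c, eff_scale_m=eff_m,
            )
            return data.interp(burdens)
        # arbitrary prediction times: rebuild the interpolation plumbing
        tmp = _GrowthData(
            GrowthSeries(time_days, np.zeros_like(np.asarray(time_days, float)),
                         label="predict"),
            data.N, data.mapping.hours_per_division * data.N,
            initial_burden=data.initial[1],
        )
        burdens = expected_burden_grid(
            data.N, data.initial, tmp.M, 1.0, fc, fm, rm, tmp.record_steps,
            eff_profile=eff_profile, eff_scale_c=eff_c, eff_scale_m=eff_m,
        )
        return tmp.interp(burdens)

    def rmse(self, fc_ratio: float, fm_ratio: float, r_m: float) -> float:
        """RMSE of the expected burden (proportion of N) at the data times."""
        pred = self._burden_on_grid(
            np.array([fc_ratio]), np.array([fm_ratio]), np.array([r_m])
        )[0]
        return float(np.sqrt(np.mean((pred - self._data.target) ** 2)))

    def fit(self) -> MoranGrowthResults:
        """Exhaustive scan of the grid; first-encountered minimum wins ties."""
        g = self.grid
        FC, FM, RM = np.meshgrid(g.fc, g.fm, g.rm, indexing="ij")
        pred = self._burden_on_grid(FC.ravel(), FM.ravel(), RM.ravel())
        resid = pred - self._data.target[None, :]
        rmse = np.sqrt(np.mean(resid**2, axis=1)).reshape(g.shape)
        idx = np.unravel_index(np.argmin(rmse), g.shape)
        return MoranGrowthResults(
            fc_ratio=float(g.fc[idx[0]]),
            fm_ratio=float(g.fm[idx[1]]),
            r_m=float(g.rm[idx[2]]),
            rmse=float(rmse[idx]),
            rmse_grid=rmse,
            grid=g,
            model=self,
        )


@dataclass
class TreatmentEfficacyResults:
    """Stage-2 efficacy estimates under the waning-dose regimen."""

    eff_c: float
    eff_m: float
    rmse: float
    rmse_surface: np.ndarray    # (len(eff_c grid), len(eff_m grid))
    grid: EfficacyGridSpec
    eff_m_unidentifiable: bool
    model: "TreatmentEfficacyModel"

    @property
    def params(self) -> dict[str, float]:
        return {"eff_c": self.eff_c, "eff_m": self.eff_m}

    def summary(self) -> str:
        lines = [
            "Treatment efficacy fit (waning superposed doses)",
            "=" * 52,
            f"doses: {self.model.regimen.dose_times_days.size}   "
            f"half-life: {self.model.regimen.half_life_days} days",
            "-" * 52,
            f"eff_c      {self.eff_c:10.4f}",
            f"eff_m      {self.eff_m:10.4f}"
            + ("   [flat RMSE surface: not identifiable]" if self.eff_m_unidentifiable else ""),
            f"RMSE       {self.rmse:10.6f}  (burden as proportion of N)",
            "=" * 52,
        ]
        return "\n".join(lines)


class TreatmentEfficacyModel:
    """Fits (eff_c, eff_m) to a treated series with stage-1 parameters fixed."""

    def __init__(
        self,
        series: GrowthSeries,
        growth_params: MoranGrowthResults | dict,
        regimen: DoseRegimen,
        N: int,
        hours_per_cell_cycle: float = 8.0,
        initial_burden: float | None = None,
        grid: EfficacyGridSpec | None = None,
    ):
        if isinstance(growth_params, MoranGrowthResults):
            growth_params = growth_params.params
        missing = {"fc_ratio", "fm_ratio", "r_m"} - set(growth_params)
        if missing:
            raise ValueError(f"stage-1 parameters missing: {sorted(missing)}")
        self._data = _GrowthData(series, N, hours_per_cell_cycle, initial_burden)
        self.growth_params = dict(growth_params)
        self.regimen = regimen
        self.grid = grid if grid is not None else EfficacyGridSpec()

    def rmse(self, eff_c: float, eff_m: float) -> float:
        pred = self._predict_grid(np.array([eff_c]), np.array([eff_m]))[0]
        return float(np.sqrt(np.mean((pred - self._data.target) ** 2)))

    def _predict_grid(self, eff_c: np.ndarray, eff_m: np.ndarray) -> np.ndarray:
        data = self._data
        G = eff_c.size
        gp = self.growth_params
        prof = self.regimen.decay_profile(data.mapping, data.M)
        burdens = expected_burden_grid(
            data.N,
            data.initial,
            data.M,
            1.0,
            np.full(G, gp["fc_ratio"]),
            np.full(G, gp["fm_ratio"]),
            np.full(G, gp["r_m"]),
            data.record_steps,
            eff_profile=prof,
            eff_scale_c=eff_c,
            eff_scale_m=eff_m,
        )
        return data.interp(burdens)

    def fit(self) -> TreatmentEfficacyResults:
        g = self.grid
        EC, EM = np.meshgrid(g.eff_c, g.eff_m, indexing="ij")
        pred = self._predict_grid(EC.ravel(), EM.ravel())
        resid = pred - self._data.target[None, :]
        rmse = np.sqrt(np.mean(resid**2, axis=1)).reshape(EC.shape)
        idx = np.unravel_index(np.argmin(rmse), rmse.shape)
        # flat along eff_m => mutants never mattered within the horizon
        along_m = rmse[idx[0], :]
        flat = bool(np.ptp(along_m) <= 1e-12 * max(1.0, float(np.max(rmse))))
        return TreatmentEfficacyResults(
            eff_c=float(g.eff_c[idx[0]]),
            eff_m=float(g.eff_m[idx[1]]),
            rmse=float(rmse[idx]),
            rmse_surface=rmse,
            grid=g,
            eff_m_unidentifiable=flat,
            model=self,
        )


def rmse_objective(
    series: GrowthSeries,
    params: dict,
    N: int,
    hours_per_cell_cycle: float = 8.0,
    initial_burden: float | None = None,
) -> float:
    """RMSE of the expectation model against a series for one parameter set."""
    model = MoranGrowthModel(
        series, N=N, hours_per_cell_cycle=hours_per_cell_cycle,
        initial_burden=initial_burden,
    )
    return model.rmse(params["fc_ratio"], params["fm_ratio"], params["r_m"])


def fit_growth(
    series_vehicle: GrowthSeries,
    grid: GridSpec | None = None,
    *,
    N: int,
    hours_per_cell_cycle: float = 8.0,
    initial_burden: float | None = None,
) -> MoranGrowthResults:
    """Stage-1 grid-search fit of (f_c/f_h, f_m/f_h, r_m) to a vehicle series."""
    return MoranGrowthModel(
        series_vehicle, N=N, hours_per_cell_cycle=hours_per_cell_cycle,
        initial_burden=initial_burden, grid=grid,
    ).fit()


def fit_treatment(
    series_treated: GrowthSeries,
    stage1: MoranGrowthResults | dict,
    regimen: DoseRegimen,
    grid: EfficacyGridSpec | None = None,
    *,
    N: int,
    hours_per_cell_cycle: float = 8.0,
    initial_burden: float | None = None,
) -> TreatmentEfficacyResults:
    """Stage-2 grid-search fit of (eff_c, eff_m) with stage-1 parameters fixed."""
    return TreatmentEfficacyModel(
        series_treated, stage1, regimen, N=N,
        hours_per_cell_cycle=hours_per_cell_cycle,
        initial_burden=initial_burden, grid=grid,
    ).fit()
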