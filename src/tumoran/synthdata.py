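"""Synthetic tumour-growth fixtures with the structure the calibration assumes.

Generates paired vehicle/treated growth series from the mean-field Moran
model: the vehicle arm grows untreated, the treated arm receives a regimen of
repeated waning doses (weekly antibody injections by default, half-life 5.8
days), and multiplicative Gaussian noise models caliper measurement error.
The generating parameters are returned as a truth record so recovery tests
can check the fitting pipeline round-trip.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .expectation import expected_burden_grid
from .fitting import DoseRegimen, GrowthSeries
from .treatment import TimeMapping

__all__ = ["SynthSpec", "generate_growth_series", "herceptin_like_spec"]


@dataclass
class SynthSpec:
    """True parameters and design of a synthetic growth experiment.

    Defaults emulate a trastuzumab-style mouse experiment: ~5 weeks of
    twice-weekly caliper measurements, four weekly doses with a 5.8-day
    half-life, cells cycling every 8 hours, tumour starting at 10% of the
    carrying capacity (inside the validity region of the mean-field model).
    """

    fc_ratio: float = 1.2
    fm_ratio: float = 1.4
    r_m: float = 0.0
    eff_c: float = 0.05
    eff_m: float = 0.0
    N: int = 200
    horizon_days: float = 35.0
    sample_interval_days: float = 3.5
    noise_sigma: float = 0.0
    n_doses: int = 4
    dose_interval_days: float = 7.0
    half_life_days: float = 5.8
    hours_per_cell_cycle: float = 8.0
    initial_cancer_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.sample_interval_days <= 0 or self.sample_interval_days > self.horizon_days:
            raise ValueError("sampling interval must lie within the horizon")

    def sampling_times(self) -> np.ndarray:
        return np.arange(0.0, self.horizon_days + 1e-9, self.sample_interval_days)

    def regimen(self) -> DoseRegimen:
        return DoseRegimen(
            dose_times_days=self.dose_interval_days * np.arange(self.n_doses),
            half_life_days=self.half_life_days,
        )

    def truth(self) -> dict:
        return asdict(self)


def herceptin_like_spec(**overrides) -> SynthSpec:
    """Spec with the fitted breast-cancer case-study parameter regime.

    Weak cancer advantage, a fitter but late-arising mutant at a driver-range
    mutation probability, and ~5% treatment efficacy under four weekly
    waning doses.
    """
    base = dict(
        fc_ratio=1.033,
        fm_ratio=1.289,
        r_m=1.1e-6,
        eff_c=0.052,
        eff_m=0.0,
    )
    base.update(overrides)
    return SynthSpec(**base)


def _burden_curve(spec: SynthSpec, treated: bool) -> np.ndarray:
    mapping = TimeMapping.for_population(spec.N, spec.hours_per_cell_cycle)
    times = spec.sampling_times()
    t_div = np.asarray(mapping.divisions_from_days(times))
    M = max(1, int(np.ceil(t_div.max())))
    lo = np.floor(t_div).astype(int)
    frac = t_div - lo
    steps = np.unique(np.concatenate([lo, np.minimum(lo + 1, M)]))
    pos = {int(s): i for i, s in enumerate(steps)}
    burden0 = spec.initial_cancer_fraction * spec.N
    init = (spec.N - burden0, burden0, 0.0)
    if treated:
        prof = spec.regimen().decay_profile(mapping, M)
        kw = dict(
            eff_profile=prof,
            eff_scale_c=np.array([spec.eff_c]),
            eff_scale_m=np.array([spec.eff_m]),
        )
    else:
        kw = {}
    at_steps = expected_burden_grid(
        spec.N, init, M, 1.0,
        np.array([spec.fc_ratio]), np.array([spec.fm_ratio]), np.array([spec.r_m]),
        steps, **kw,
    )[0]
    i0 = np.array([pos[int(s)] for s in lo])
    i1 = np.array([pos[int(min(s + 1, M))] for s in lo])
    return at_steps[i0] + frac * (at_steps[i1] - at_steps[i0])


def generate_growth_series(
    spec: SynthSpec,
) -> tuple[GrowthSeries, GrowthSeries, dict]:
    """Vehicle and treated series (burden in cells) plus the truth record.

    With ``noise_sigma == 0`` both series lie exactly on the expectation
    model's curve, so an on-grid grid-search fit recovers the generating
    parameters exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    times = spec.sampling_times()
    vehicle_curve = _burden_curve(spec, treated=False)
    treated_curve = _burden_curve(spec, treated=True)
    if spec.noise_sigma > 0:
        vehicle_curve = vehicle_curve * (
            1.0 + spec.noise_sigma * rng.standard_normal(times.size)
        )
        treated_curve = treated_curve * (
            1.0 + spec.noise_sigma * rng.standard_normal(times.size)
        )
        vehicle_curve = np.clip(vehicle_curve, 0.0, None)
        treated_curve = np.clip(treated_curve, 0.0, None)
    vehicle = GrowthSeries(times, vehicle_curve, label="vehicle")
    treated = GrowthSeries(
        times,
        treated_curve,
        label="treated",
        dose_times_days=spec.regimen().dose_times_days,
    )
    return vehicle, treated, spec.truth()


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
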