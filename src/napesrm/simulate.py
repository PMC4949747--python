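"""Synthetic scheduled-SRM chromatogram generator with known ground truth.

Emulates a triple-quadrupole acquisition of a NAPE method: per transition a
uniform time grid over the run, Gaussian peaks at the scheduled retention
time (plus optional jitter), peak area proportional to the analyte amount,
a fixed qualifier/quantifier ion ratio per species, non-negative baseline
noise, and scheduled acquisition (signal only inside each transition's RT
window).  Sample-preparation yield variability is modeled as one lognormal
recovery factor per sample shared by every species including the internal
standard, which is precisely the error structure a one-point internal
standard calibration cancels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .transitions import FragmentKind, MethodTable

__all__ = [
    "SamplePlan",
    "SrmTrace",
    "CalibrationSample",
    "simulate_sample",
    "simulate_calibration",
    "inject_interference",
    "write_traces",
    "read_traces",
]

DEFAULT_IS_NAME = "PE 18:1/18:1-N-19:0"

#: Default instrument response (peak area counts*seconds per pmol); sized so
#: a 50 pmol internal standard gives a ~1e4-count peak over single-digit
#: baseline noise, as on a modern triple quadrupole.
DEFAULT_RESPONSE_FACTOR = 2000.0


@dataclass(frozen=True)
class SrmTrace:
    """One transition's chromatogram: uniform time grid (minutes) + intensities."""

    transition_id: str
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.size != y.size:
            raise ValueError("times and intensities must have equal length")
        if t.size >= 2:
            dt = np.diff(t)
            if not (dt > 0).all():
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ValueError("times must be uniformly spaced")
        if not np.isfinite(y).all():
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)

    @property
    def sampling_interval_s(self) -> float:
        return float((self.times[1] - self.times[0]) * 60.0)


@dataclass
class SamplePlan:
    """Ground truth for one simulated sample.

    Amounts are pmol in the final extract; areas come out as
    ``amount * response_factor`` in counts*seconds (ion-ratio-scaled for the
    qualifier).  ``response_factors`` and ``ion_ratio`` accept either one
    number for all species or a per-species-name mapping.
    """

    species_amounts: dict[str, float] = field(default_factory=dict)
    tissue_mass_g: float = 0.1
    is_name: str = DEFAULT_IS_NAME
    is_amount_pmol: float = 50.0
    response_factors: Mapping[str, float] | float = DEFAULT_RESPONSE_FACTOR
    ion_ratio: Mapping[str, float] | float = 0.35
    peak_sigma_s: float = 4.0
    noise_sd: float = 5.0
    baseline_level: float | None = None  # counts; default 4 x noise_sd
    rt_jitter_sd_s: float = 1.0
    prep_cv: float = 0.0
    sampling_interval_s: float = 0.5
    run_length_min: float = 18.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tissue_mass_g <= 0:
            raise ValueError("tissue_mass_g must be positive")
        if self.peak_sigma_s <= 0:
            raise ValueError("peak_sigma_s must be positive")
        if self.is_amount_pmol < 0 or any(v < 0 for v in self.species_amounts.values()):
            raise ValueError("amounts must be >= 0")
        for name in self.species_amounts:
            if self.response_factor(name) <= 0:
                raise ValueError(f"response factor for {name} must be positive")
            r = self.f2_ratio(name)
            if not (0 < r <= 1):
                raise ValueError(f"ion ratio for {name} must be in (0, 1]")

    @property
    def baseline(self) -> float:
        """Chemical-background level inside acquisition windows.

        Defaults to four noise SDs so the zero-clipping of the noise is a
        rare tail event rather than a distortion of the baseline statistics.
        """
        if self.baseline_level is not None:
            return float(self.baseline_level)
        return 4.0 * self.noise_sd

    def response_factor(self, name: str) -> float:
        if isinstance(self.response_factors, Mapping):
            return float(self.response_factors.get(name, DEFAULT_RESPONSE_FACTOR))
        return float(self.response_factors)

    def f2_ratio(self, name: str) -> float:
        if isinstance(self.ion_ratio, Mapping):
            return float(self.ion_ratio.get(name, 0.35))
        return float(self.ion_ratio)

    def all_amounts(self) -> dict[str, float]:
        amounts = dict(self.species_amounts)
        amounts[self.is_name] = amounts.get(self.is_name, 0.0) + self.is_amount_pmol
        return amounts


def _time_grid(plan: SamplePlan) -> np.ndarray:
    n = int(round(plan.run_length_min * 60.0 / plan.sampling_interval_s)) + 1
    return np.arange(n) * (plan.sampling_interval_s / 60.0)


def _gaussian(times_min: np.ndarray, center_min: float, area_cs: float, sigma_s: float) -> np.ndarray:
    dt_s = (times_min - center_min) * 60.0
    return area_cs / (sigma_s * math.sqrt(2.0 * math.pi)) * np.exp(
        -0.5 * (dt_s / sigma_s) ** 2
    )


def simulate_sample(
    plan: SamplePlan,
    method: MethodTable,
    rt_model=None,
) -> dict[str, SrmTrace]:
    """Simulate every transition of ``method`` for one sample.

    Peaks sit at each transition's scheduled window center (from the
    retention model used at method-build time; ``rt_model`` overrides it
    when given) plus a per-species jitter shared by both transitions so the
    pair genuinely co-elutes.  Reproducible from ``plan.seed``.
    """
    method_species = set(method.species_names())
    missing = sorted(set(plan.all_amounts()) - method_species)
    if missing:
        raise ValueError(f"plan species missing from method: {missing}")

    rng = np.random.default_rng(plan.seed)
    times = _time_grid(plan)
    amounts = plan.all_amounts()

    # One lognormal recovery factor per sample (preparation yield), shared by
    # all species; mean 1 by construction.
    if plan.prep_cv > 0:
        sig = math.sqrt(math.log(1.0 + plan.prep_cv**2))
        prep = float(rng.lognormal(mean=-0.5 * sig * sig, sigma=sig))
    else:
        prep = 1.0

    jitter: dict[str, float] = {}
    for name in method.species_names():
        j = rng.normal(0.0, plan.rt_jitter_sd_s) if plan.rt_jitter_sd_s > 0 else 0.0
        jitter[name] = j / 60.0  # minutes

    traces: dict[str, SrmTrace] = {}
    for t in method.transitions:
        name = t.species.name
        center = (
            rt_model.predict_rt(t.species) if rt_model is not None else t.rt_center
        ) + jitter[name]
        mask = (times >= t.rt_start) & (times <= t.rt_end)
        signal = np.zeros_like(times)
        amount = amounts.get(name, 0.0)
        if amount > 0:
            area = amount * plan.response_factor(name) * prep
            if t.product_kind is FragmentKind.NAE_LIKE:
                area *= plan.f2_ratio(name)
            signal = _gaussian(times, center, area, plan.peak_sigma_s)
        if plan.noise_sd > 0:
            noise = rng.normal(0.0, plan.noise_sd, size=times.size)
        else:
            noise = np.zeros_like(times)
        intensities = np.where(
            mask, np.clip(signal + plan.baseline + noise, 0.0, None), 0.0
        )
        traces[t.transition_id] = SrmTrace(t.transition_id, times, intensities)
    return traces


def inject_interference(
    traces: Mapping[str, SrmTrace],
    method: MethodTable,
    target_transition: str,
    rt_offset_min: float,
    area: float,
    peak_sigma_s: float = 4.0,
) -> dict[str, SrmTrace]:
    """Add a co-eluting interferent peak to exactly one transition.

    Models an isobar that shares the precursor and one product ion only:
    the extra Gaussian (offset from the transition's scheduled center) is
    added to the named transition, masked to its acquisition window; all
    other transitions are untouched.
    """
    if target_transition not in traces:
        raise KeyError(f"unknown transition {target_transition!r}")
    t = method.by_id(target_transition)
    out = dict(traces)
    if area == 0:
        return out
    trace = traces[target_transition]
    extra = _gaussian(trace.times, t.rt_center + rt_offset_min, area, peak_sigma_s)
    mask = (trace.times >= t.rt_start) & (trace.times <= t.rt_end)
    out[target_transition] = SrmTrace(
        trace.transition_id,
        trace.times,
        np.where(mask, trace.intensities + extra, trace.intensities),
    )
    return out


@dataclass
class CalibrationSample:
    """One level x replicate simulated sample with its ground truth."""

    level_pmol_per_g: float
    level_index: int
    replicate: int
    seed: int
    plan: SamplePlan
    traces: dict[str, SrmTrace]

    @property
    def truth(self) -> dict:
        return {
            "level_pmol_per_g": self.level_pmol_per_g,
            "replicate": self.replicate,
            "seed": self.seed,
            "species_amounts_pmol": dict(self.plan.species_amounts),
            "is_amount_pmol": self.plan.is_amount_pmol,
            "tissue_mass_g": self.plan.tissue_mass_g,
        }


def derive_seed(base_seed: int, level_index: int, replicate: int) -> int:
    """Deterministic per-sample seed from (base seed, level, replicate)."""
    ss = np.random.SeedSequence(entropy=(int(base_seed), int(level_index), int(replicate)))
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_calibration(
    levels: Sequence[float],
    replicates: int,
    template: SamplePlan,
    method: MethodTable,
    rt_model=None,
) -> list[CalibrationSample]:
    """Simulate a spiked calibration series (levels in pmol/g x replicates).

    The species named in ``template.species_amounts`` are the spiked
    analytes; at each level their amount becomes ``level * tissue_mass``.
    The internal standard amount stays constant.  Per-sample seeds derive
    deterministically from (template.seed, level index, replicate index).
    """
    if not levels or any(lv <= 0 for lv in levels):
        raise ValueError("levels must be positive and non-empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    spiked = sorted(template.species_amounts)
    samples: list[CalibrationSample] = []
    for li, level in enumerate(levels):
        for ri in range(replicates):
            seed = derive_seed(template.seed, li, ri)
            plan = replace(
                template,
                species_amounts={n: level * template.tissue_mass_g for n in spiked},
                seed=seed,
            )
            samples.append(
                CalibrationSample(
                    level_pmol_per_g=float(level),
                    level_index=li,
                    replicate=ri,
                    seed=seed,
                    plan=plan,
                    traces=simulate_sample(plan, method, rt_model=rt_model),
                )
            )
    return samples


def write_traces(traces: Mapping[str, SrmTrace], destination: str | Path) -> None:
    """Write traces as long-format CSV: transition_id, time_min, intensity."""
    frames = [
        pd.DataFrame(
            {
                "transition_id": tid,
                "time_min": tr.times,
                "intensity": tr.intensities,
            }
        )
        for tid, tr in traces.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(destination, index=False)


def read_traces(source: str | Path) -> dict[str, SrmTrace]:
    """Read a long-format trace CSV back into per-transition traces."""
    frame = pd.read_csv(source)
    required = {"transition_id", "time_min", "intensity"}
    if not required.issubset(frame.columns):
        raise ValueError(f"trace CSV must have columns {sorted(required)}")
    if frame.empty:
        raise ValueError("trace CSV contains no data rows")
    out: dict[str, SrmTrace] = {}
    for tid, grp in frame.groupby("transition_id", sort=False):
        out[str(tid)] = SrmTrace(
            str(tid),
            grp["time_min"].to_numpy(dtype=float),
            grp["intensity"].to_numpy(dtype=float),
        )
    return out
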