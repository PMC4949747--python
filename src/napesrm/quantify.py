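"""Peak integration, two-transition confirmation, and one-point IS quantification.

The assay reports a tissue concentration for each NAPE species as

    conc [pmol/g] = (quantifier area / IS quantifier area) * IS amount / tissue mass

with the spiked, nonendogenous internal standard (IS) carried through the
entire preparation.  Identity is confirmed per species by requiring both
transitions to show co-eluting peaks whose qualifier/quantifier area ratio
matches the expected ion ratio.  Validation statistics mirror targeted-assay
practice: unweighted linearity of response ratio vs nominal concentration,
back-calculated accuracy at QC levels, replicate RSD precision, and an LLOQ
defined by signal-to-noise at the lowest calibration level.

Numerical conventions: baseline noise is the MAD-based robust SD of the
peak-free region; S/N is peak height over that SD (capped at a sentinel for
noiseless traces); areas are trapezoidal integrals (counts*seconds) of the
chord-baseline-subtracted signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

from .simulate import SrmTrace
from .transitions import MethodTable

__all__ = [
    "Peak",
    "SpeciesResult",
    "LinearityFit",
    "ValidationReport",
    "SNR_CAP",
    "estimate_noise",
    "detect_peaks",
    "integrate",
    "confirm_species",
    "quantify_sample",
    "fit_linearity",
    "accuracy",
    "precision",
    "lloq",
]

#: Reported S/N when the baseline noise estimate is exactly zero.
SNR_CAP = 1e6


@dataclass
class Peak:
    transition_id: str
    rt_apex: float  # minutes
    area: float  # counts * seconds
    height: float  # counts above local baseline
    snr: float
    bounds: tuple[float, float]  # minutes

    def __post_init__(self) -> None:
        if not (self.bounds[0] < self.rt_apex < self.bounds[1]):
            raise ValueError("apex must lie strictly inside the peak bounds")
        if self.area <= 0 or self.height <= 0:
            raise ValueError("peak area and height must be positive")


@dataclass
class SpeciesResult:
    species_name: str
    detected: bool
    quantifier_area: float | None = None
    qualifier_area: float | None = None
    ion_ratio: float | None = None
    rt_apex: float | None = None
    snr: float | None = None
    concentration_pmol_per_g: float | None = None
    flags: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "name": self.species_name,
            "detected": self.detected,
            "rt_apex_min": self.rt_apex,
            "quantifier_area": self.quantifier_area,
            "ion_ratio": self.ion_ratio,
            "snr": self.snr,
            "conc_pmol_per_g": self.concentration_pmol_per_g,
            "flags": ";".join(sorted(self.flags)),
        }


def _robust_sd(values: np.ndarray) -> float:
    med = np.median(values)
    return float(1.4826 * np.median(np.abs(values - med)))


def estimate_noise(
    trace: SrmTrace,
    exclusion: tuple[float, float] | None = None,
    window: tuple[float, float] | None = None,
    min_points: int = 20,
) -> float:
    """Robust baseline SD: 1.4826 x MAD of points outside the excluded peak.

    ``window`` restricts the estimate to the acquisition window of a
    scheduled transition (points outside it are hard zeros, not baseline).
    """
    keep = np.ones(trace.times.size, dtype=bool)
    if window is not None:
        keep &= (trace.times >= window[0]) & (trace.times <= window[1])
    if exclusion is not None:
        keep &= ~((trace.times >= exclusion[0]) & (trace.times <= exclusion[1]))
    if keep.sum() < min_points:
        raise ValueError(
            f"only {int(keep.sum())} baseline points available; need >= {min_points}"
        )
    return _robust_sd(trace.intensities[keep])


def _parabolic_apex(t: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Apex (time, height) by parabola through the top three samples."""
    if i == 0 or i == y.size - 1:
        return float(t[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(t[i]), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    dt = t[1] - t[0]
    apex_t = float(t[i] + delta * dt)
    apex_y = float(y1 - 0.25 * (y0 - y2) * delta)
    return apex_t, apex_y


def detect_peaks(
    trace: SrmTrace,
    window: tuple[float, float],
    min_width_points: int = 3,
    snr_threshold_detect: float = 3.0,
) -> list[Peak]:
    """Find chromatographic peaks inside ``window``, largest area first.

    A local maximum qualifies when it exceeds baseline + 3x noise SD and its
    immediate neighbors both clear baseline + 2 SD — i.e. the signal stays
    elevated for at least ``min_width_points`` consecutive samples, which
    single-sample noise spikes essentially never do.  Bounds extend outward
    until the signal decays to baseline + 1 SD or a significant local
    minimum; the apex is refined by parabolic interpolation of the top
    three samples.
    """
    sel = (trace.times >= window[0]) & (trace.times <= window[1])
    if sel.sum() < 5:
        raise ValueError("window contains too few samples")
    t = trace.times[sel]
    y = trace.intensities[sel]
    base = float(np.median(y))
    sd = _robust_sd(y)

    height_min = base + snr_threshold_detect * sd
    idx, _ = _signal.find_peaks(y, height=height_min if sd > 0 else base)
    if sd > 0 and idx.size:
        shoulder = base + 2.0 * sd
        half = max(1, (min_width_points - 1) // 2)
        keep = []
        for i in idx:
            lo, hi = max(0, i - half), min(y.size - 1, i + half)
            if np.all(y[lo : hi + 1] >= shoulder):
                keep.append(i)
        idx = np.asarray(keep, dtype=int)
    if idx.size == 0:
        return []

    floor = base + sd

    def _walk(i: int, step: int) -> int:
        """Bound index: outward from the apex to baseline or to the valley
        before an adjacent peak (signal climbing >= 3 SD above the running
        minimum)."""
        j = i
        min_j, min_v = i, y[i]
        while 0 < j < y.size - 1:
            j += step
            if y[j] < min_v:
                min_j, min_v = j, y[j]
            if y[j] <= floor:
                return j
            if y[j] > min_v + 3 * sd and min_j != i:
                return min_j
        return j

    peaks: list[Peak] = []
    for i in idx:
        lo = _walk(int(i), -1)
        hi = _walk(int(i), +1)
        if hi - lo < 2:
            continue
        apex_t, apex_y = _parabolic_apex(t, y, int(i))
        bounds = (float(t[lo]), float(t[hi]))
        if not (bounds[0] < apex_t < bounds[1]):
            apex_t = float(t[i])
        area = integrate(trace, bounds, baseline_level=base)
        height = apex_y - base
        if area <= 0 or height <= 0:
            continue
        try:
            noise = estimate_noise(trace, exclusion=bounds, window=window, min_points=10)
        except ValueError:
            noise = sd
        snr = height / noise if noise > 0 else SNR_CAP
        peaks.append(
            Peak(
                transition_id=trace.transition_id,
                rt_apex=apex_t,
                area=area,
                height=height,
                snr=min(snr, SNR_CAP),
                bounds=bounds,
            )
        )
    # Suppress flank bumps: drop any candidate whose apex falls inside the
    # bounds of a taller accepted peak.
    accepted: list[Peak] = []
    for p in sorted(peaks, key=lambda p: p.height, reverse=True):
        if any(a.bounds[0] <= p.rt_apex <= a.bounds[1] for a in accepted):
            continue
        accepted.append(p)
    return sorted(accepted, key=lambda p: p.area, reverse=True)


def integrate(
    trace: SrmTrace,
    bounds: tuple[float, float],
    baseline_level: float | None = None,
) -> float:
    """Trapezoidal area (counts*seconds) over ``bounds``, baseline removed.

    By default the baseline is the chord between the signal values at the
    two bound endpoints (each taken as the median of a 3-sample
    neighborhood so one noisy sample cannot tilt the chord).  When
    ``baseline_level`` is given — e.g. the robust level of the surrounding
    peak-free region of a scheduled trace — that constant is subtracted
    instead, which is far less noisy for small peaks.  A negative net area
    is clipped to zero.
    """
    start, end = bounds
    if end < start:
        raise ValueError("inverted integration bounds")
    sel = (trace.times >= start) & (trace.times <= end)
    if sel.sum() < 2:
        return 0.0
    t = trace.times[sel] * 60.0  # seconds
    y = trace.intensities[sel]
    if baseline_level is None:
        k = min(3, y.size)
        y0 = float(np.median(y[:k]))
        y1 = float(np.median(y[-k:]))
        baseline = np.interp(t, [t[0], t[-1]], [y0, y1])
    else:
        baseline = float(baseline_level)
    area = float(np.trapezoid(y - baseline, t))
    return max(area, 0.0)


@dataclass
class Confirmation:
    detected: bool
    flags: set[str]
    quantifier: Peak | None
    qualifier: Peak | None
    ion_ratio: float | None


def confirm_species(
    quantifier_peaks: Sequence[Peak],
    qualifier_peaks: Sequence[Peak],
    expected_ratio: float,
    rt_delta: float = 0.05,
    ratio_rel_tol: float = 0.30,
    qualifier_trace: SrmTrace | None = None,
    qualifier_baseline: float | None = None,
) -> Confirmation:
    """Two-transition identity confirmation.

    Detected iff a quantifier peak exists, a qualifier peak co-elutes within
    ``rt_delta`` minutes, and the qualifier/quantifier area ratio lies within
    ``ratio_rel_tol`` (relative) of the expected ion ratio.  Every failed
    criterion is named in the flags.

    When ``qualifier_trace`` is given, the qualifier area for the ratio is
    re-integrated over the quantifier peak's bounds (mirrored integration),
    so that bound-placement noise cancels between the two transitions; this
    also makes partially co-eluting interference on the qualifier visibly
    inflate the ratio.
    """
    if expected_ratio <= 0:
        raise ValueError("expected_ratio must be positive")
    flags: set[str] = set()
    quant = quantifier_peaks[0] if quantifier_peaks else None
    if quant is None:
        return Confirmation(False, {"missing_quantifier"}, None, None, None)

    qual = None
    if qualifier_peaks:
        qual = min(qualifier_peaks, key=lambda p: abs(p.rt_apex - quant.rt_apex))
    if qual is None:
        return Confirmation(False, {"missing_qualifier"}, quant, None, None)

    if abs(qual.rt_apex - quant.rt_apex) > rt_delta:
        flags.add("rt_mismatch")
    if qualifier_trace is not None:
        qual_area = integrate(
            qualifier_trace, quant.bounds, baseline_level=qualifier_baseline
        )
    else:
        qual_area = qual.area
    ratio = qual_area / quant.area
    if abs(ratio - expected_ratio) > ratio_rel_tol * expected_ratio:
        flags.add("ion_ratio_fail")
    return Confirmation(not flags, flags, quant, qual, ratio)


class InternalStandardError(RuntimeError):
    """The internal standard was not detected; the sample cannot be quantified."""


def quantify_sample(
    traces: Mapping[str, SrmTrace],
    method: MethodTable,
    is_name: str,
    is_amount_pmol: float,
    tissue_mass_g: float,
    expected_ratios: Mapping[str, float] | float = 0.35,
    rt_delta: float = 0.05,
    ratio_rel_tol: float = 0.30,
    snr_threshold: float = 10.0,
) -> list[SpeciesResult]:
    """One-point internal-standard quantification of every method species.

    Concentrations are quantifier-area ratios to the IS scaled by the IS
    amount and tissue mass.  Raises :class:`InternalStandardError` when the
    IS quantifier peak is absent (the sample is invalid).  Species whose
    quantifier S/N falls below ``snr_threshold`` carry a ``below_loq`` flag.
    """
    if tissue_mass_g <= 0:
        raise ValueError("tissue_mass_g must be positive")
    if is_name not in method.species_names():
        raise ValueError(f"internal standard {is_name!r} not in method")

    def _expected(name: str) -> float:
        if isinstance(expected_ratios, Mapping):
            return float(expected_ratios.get(name, 0.35))
        return float(expected_ratios)

    def _confirm(name: str) -> Confirmation:
        tq = method.quantifier(name)
        tl = method.qualifier(name)
        qual_trace = traces[tl.transition_id]
        quant = detect_peaks(traces[tq.transition_id], (tq.rt_start, tq.rt_end))
        qual = detect_peaks(qual_trace, (tl.rt_start, tl.rt_end))
        win = (qual_trace.times >= tl.rt_start) & (qual_trace.times <= tl.rt_end)
        qual_base = float(np.median(qual_trace.intensities[win]))
        return confirm_species(
            quant,
            qual,
            _expected(name),
            rt_delta,
            ratio_rel_tol,
            qualifier_trace=qual_trace,
            qualifier_baseline=qual_base,
        )

    is_conf = _confirm(is_name)
    if is_conf.quantifier is None:
        raise InternalStandardError(f"internal standard {is_name!r} not detected")
    is_area = is_conf.quantifier.area

    results: list[SpeciesResult] = []
    for name in method.species_names():
        conf = is_conf if name == is_name else _confirm(name)
        res = SpeciesResult(species_name=name, detected=conf.detected, flags=set(conf.flags))
        if conf.quantifier is not None:
            res.quantifier_area = conf.quantifier.area
            res.rt_apex = conf.quantifier.rt_apex
            res.snr = conf.quantifier.snr
            if conf.quantifier.snr < snr_threshold:
                res.flags.add("below_loq")
        if conf.qualifier is not None:
            res.qualifier_area = conf.qualifier.area
            res.ion_ratio = conf.ion_ratio
        if conf.detected:
            res.concentration_pmol_per_g = (
                res.quantifier_area / is_area * is_amount_pmol / tissue_mass_g
            )
        results.append(res)
    return results


@dataclass
class LinearityFit:
    slope: float
    intercept: float
    r2: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("linearity needs >= 3 points")
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError("r2 must lie in [0, 1]")


def fit_linearity(
    levels: Sequence[float],
    response_ratios: Sequence[float],
    weighted: bool = False,
) -> LinearityFit:
    """Unweighted OLS of response ratio (area/IS area) on nominal concentration."""
    if weighted:
        raise ValueError("only unweighted linear regression is supported")
    x = np.asarray(levels, dtype=float)
    y = np.asarray(response_ratios, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct concentration levels")
    if np.ptp(y) == 0.0:
        # Degenerate flat response: slope 0 by definition, no variance explained.
        return LinearityFit(0.0, float(y[0]), 0.0, x.size)
    fit = _stats.linregress(x, y)
    return LinearityFit(
        float(fit.slope), float(fit.intercept), float(fit.rvalue**2), x.size
    )


def accuracy(
    fit: LinearityFit,
    qc_points: Sequence[tuple[float, float]],
) -> dict[float, float]:
    """Back-calculated accuracy per QC level: mean 100*|back - nominal|/nominal.

    ``qc_points`` are (nominal level, observed response ratio) pairs;
    replicates at the same level are averaged after back-calculation.
    """
    if fit.slope == 0:
        raise ValueError("cannot back-calculate with zero slope")
    per_level: dict[float, list[float]] = {}
    for level, ratio in qc_points:
        if level <= 0:
            raise ValueError("QC levels must be positive")
        back = (ratio - fit.intercept) / fit.slope
        if back < 0:
            import warnings

            warnings.warn(
                f"negative back-calculated concentration at level {level}",
                stacklevel=2,
            )
        per_level.setdefault(float(level), []).append(
            100.0 * abs(back - level) / level
        )
    return {lvl: float(np.mean(v)) for lvl, v in sorted(per_level.items())}


def precision(replicate_concentrations: Sequence[float]) -> float:
    """Relative standard deviation (%) of replicate concentrations."""
    x = np.asarray(replicate_concentrations, dtype=float)
    if x.size < 2:
        raise ValueError("precision needs >= 2 replicates")
    mean = float(x.mean())
    if mean == 0:
        return float("nan")
    return float(100.0 * x.std(ddof=1) / mean)


@dataclass
class LloqResult:
    lloq_pmol_per_g: float | None
    snr_table: dict[float, float]  # level -> min S/N over replicates/analytes
    above_highest_tested: bool = False


def lloq(
    per_level_snr: Mapping[float, Sequence[float]],
    snr_threshold: float = 10.0,
) -> LloqResult:
    """Lowest calibration level whose replicates all reach the S/N threshold.

    ``per_level_snr`` maps level (pmol/g) to the replicate quantifier S/N
    values (``nan``/``None`` for undetected replicates).  When no level
    qualifies the result says so explicitly rather than inventing a value.
    """
    if len(per_level_snr) < 2:
        raise ValueError("calibration must span >= 2 levels")
    table: dict[float, float] = {}
    for level in sorted(per_level_snr):
        vals = [
            float(v) if v is not None else float("nan") for v in per_level_snr[level]
        ]
        table[float(level)] = float(np.min(vals)) if vals else float("nan")
    for level, min_snr in table.items():
        if math.isfinite(min_snr) and min_snr >= snr_threshold:
            return LloqResult(level, table)
    return LloqResult(None, table, above_highest_tested=True)


@dataclass
class ValidationReport:
    """Bundle of the assay validation statistics."""

    linearity: dict[str, LinearityFit]
    accuracy_pct: dict[float, float] = field(default_factory=dict)
    precision_rsd_pct: dict[str, float] = field(default_factory=dict)
    lloq: LloqResult | None = None

    def to_dict(self) -> dict:
        return {
            "linearity": {
                name: {
                    "slope": f.slope,
                    "intercept": f.intercept,
                    "r2": f.r2,
                    "n_points": f.n_points,
                }
                for name, f in self.linearity.items()
            },
            "accuracy_pct": {str(k): v for k, v in self.accuracy_pct.items()},
            "precision_rsd_pct": dict(self.precision_rsd_pct),
            "lloq_pmol_per_g": None if self.lloq is None else self.lloq.lloq_pmol_per_g,
            "lloq_snr_table": {}
            if self.lloq is None
            else {str(k): v for k, v in self.lloq.snr_table.items()},
        }

    def table(self) -> str:
        """Human-readable linearity table: Analyte, Slope, Intercept, R2."""
        lines = [f"{'Analyte':<24}{'Slope':>10}{'Intercept':>12}{'R2':>9}"]
        for name, f in self.linearity.items():
            lines.append(f"{name:<24}{f.slope:>10.4f}{f.intercept:>12.4f}{f.r2:>9.4f}")
        return "\n".join(lines)
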