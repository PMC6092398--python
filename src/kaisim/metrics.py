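"""Period, amplitude and rhythmicity estimation plus resilience experiments.

Implements the readouts used to characterize oscillator resilience: peak-based
period estimation with an explicit rhythmicity classifier, stoichiometry scans
over the KaiA-dimer : KaiC-hexamer ratio for both PDDA settings, acute KaiA
step protocols, and randomly fluctuating KaiA runs.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .population import (
    KaiAProtocol,
    ModelParams,
    Trajectory,
    kaia_protocol,
    run_simulation,
)

__all__ = [
    "PeriodEstimate",
    "ScanResult",
    "estimate_period",
    "scan_stoichiometry",
    "step_experiment",
    "fluctuation_experiment",
]


@dataclass(frozen=True)
class PeriodEstimate:
    """Peak-interval period estimate; arrhythmic records report period 0.

    Rhythmicity requires at least ``min_peaks`` detected peaks after burn-in
    and a peak-to-trough excursion of at least ``amplitude_threshold`` %P in
    the second half of the record.
    """

    period: float  # h; 0 if arrhythmic
    period_sd: float  # h
    amplitude: float  # %P peak-to-trough in the record's second half
    rhythmic: bool
    n_cycles: int
    peak_times: tuple = field(default=(), repr=False)

    def __post_init__(self):
        if self.period < 0:
            raise ValueError("period must be non-negative")
        if not self.rhythmic and self.period != 0:
            raise ValueError("arrhythmic estimates must report period 0")


def _refine_peak(t: np.ndarray, y: np.ndarray, i: int) -> float:
    """Parabolic sub-sample refinement of a peak location."""
    if i <= 0 or i >= len(y) - 1:
        return t[i]
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom >= 0:
        return t[i]
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return t[i] + delta * (t[1] - t[0])


def estimate_period(
    traj: Trajectory | tuple[np.ndarray, np.ndarray],
    burn_in_h: float = 30.0,
    smooth_window_h: float = 2.0,
    amplitude_threshold: float = 10.0,
    min_peaks: int = 3,
) -> PeriodEstimate:
    """Estimate the oscillation period of a %P time series.

    The trace is smoothed with a moving average (default 2 h window), peaks
    with prominence >= ``amplitude_threshold`` after ``burn_in_h`` are
    detected, and the period is the mean successive peak interval (sd over
    intervals).  A record is rhythmic iff >= ``min_peaks`` peaks are found and
    the peak-to-trough range in the second half of the record reaches the
    amplitude threshold; otherwise period is reported as 0.
    """
    if isinstance(traj, Trajectory):
        t, y = traj.time_h, traj.percent_p
    else:
        t, y = traj
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t[-1] <= burn_in_h:
        raise ValueError("trajectory shorter than burn-in")
    dt = float(np.median(np.diff(t)))
    w = max(1, int(round(smooth_window_h / dt)))
    if w > 1:
        kernel = np.ones(w) / w
        ys = np.convolve(y, kernel, mode="same")
        # undo edge attenuation of the boxcar
        norm = np.convolve(np.ones_like(y), kernel, mode="same")
        ys = ys / norm
    else:
        ys = y
    idx, _ = find_peaks(ys, prominence=amplitude_threshold)
    idx = idx[t[idx] > burn_in_h]
    peak_times = np.array([_refine_peak(t, ys, i) for i in idx])
    second_half = y[t >= t[-1] / 2.0]
    amplitude = float(second_half.max() - second_half.min()) if second_half.size else 0.0
    rhythmic = len(peak_times) >= min_peaks and amplitude >= amplitude_threshold
    if not rhythmic:
        return PeriodEstimate(0.0, 0.0, amplitude, False, len(peak_times),
                              tuple(peak_times))
    intervals = np.diff(peak_times)
    return PeriodEstimate(
        period=float(intervals.mean()),
        period_sd=float(intervals.std(ddof=1)) if intervals.size > 1 else 0.0,
        amplitude=amplitude,
        rhythmic=True,
        n_cycles=len(peak_times),
        peak_times=tuple(peak_times),
    )


@dataclass
class ScanResult:
    """Stoichiometry-scan outcome for both PDDA settings.

    ``table`` holds one row per (ratio, pdda, seed); ``band`` maps each PDDA
    setting to its (lower, upper) rhythmic-ratio endpoints under the
    majority-of-seeds classification, and ``common_band`` to the endpoints of
    the ratios rhythmic under both settings (None if empty).
    """

    ratios: np.ndarray
    table: pd.DataFrame
    band: dict
    common_band: tuple | None

    def rhythmic_set(self, pdda: bool) -> set[float]:
        sub = self.table[self.table.pdda == pdda]
        out = set()
        for ratio, grp in sub.groupby("ratio"):
            if grp.rhythmic.sum() * 2 > len(grp):
                out.add(float(ratio))
        return out


def _run_and_estimate(
    params: ModelParams,
    duration_h: float,
    seed: int,
    burn_in_h: float,
    protocol: KaiAProtocol | None = None,
) -> tuple[Trajectory, PeriodEstimate]:
    traj = run_simulation(params, duration_h, protocol=protocol, seed=seed)
    return traj, estimate_period(traj, burn_in_h=burn_in_h)


def scan_stoichiometry(
    ratios: Sequence[float],
    params: ModelParams | None = None,
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    duration_h: float = 200.0,
    burn_in_h: float = 30.0,
) -> ScanResult:
    """Scan the [A2]/[C6] ratio for both PDDA settings.

    One simulation per (ratio, PDDA setting, seed); a ratio is classified
    rhythmic for a setting when the majority of seeds are rhythmic.  Band
    endpoints are the extreme rhythmic ratios per setting; the common band is
    taken over ratios rhythmic under both.
    """
    if params is None:
        params = ModelParams()
    ratios = np.asarray(sorted(ratios), dtype=float)
    if (ratios < 0).any():
        raise ValueError("ratios must be non-negative")
    rows = []
    for ratio in ratios:
        for pdda in (True, False):
            p = replace(params, a2_ratio=float(ratio), pdda_enabled=pdda)
            for seed in seeds:
                _, est = _run_and_estimate(p, duration_h, seed, burn_in_h)
                rows.append(
                    dict(
                        ratio=float(ratio),
                        pdda=pdda,
                        seed=seed,
                        rhythmic=est.rhythmic,
                        period_h=est.period,
                        period_sd_h=est.period_sd,
                        amplitude=est.amplitude,
                        n_cycles=est.n_cycles,
                    )
                )
    table = pd.DataFrame(rows)
    result = ScanResult(ratios=ratios, table=table, band={}, common_band=None)
    band = {}
    for pdda in (True, False):
        rset = result.rhythmic_set(pdda)
        band[pdda] = (min(rset), max(rset)) if rset else None
    result.band = band
    common = result.rhythmic_set(True) & result.rhythmic_set(False)
    result.common_band = (min(common), max(common)) if common else None
    return result


def step_experiment(
    base_ratio: float = 1.33,
    step_ratios: Sequence[float] = (1.9, 2.4, 3.0, 4.1),
    step_hour: float = 27.0,
    params: ModelParams | None = None,
    duration_h: float = 200.0,
    seeds: Sequence[int] = (0, 1, 2),
    post_burn_h: float = 10.0,
) -> pd.DataFrame:
    """Acute KaiA-addition protocol: step the ratio at ``step_hour``.

    For each (step ratio, PDDA setting) runs the step protocol and reports the
    post-step rhythmicity/period (majority and mean over seeds) alongside the
    no-step control period.  Rows: step_ratio, pdda, control_period_h,
    post_rhythmic, post_period_h.
    """
    if params is None:
        params = ModelParams()
    c6 = params.c6_uM
    rows = []
    for pdda in (True, False):
        p = replace(params, pdda_enabled=pdda, a2_ratio=base_ratio)
        control_periods = []
        for seed in seeds:
            _, est = _run_and_estimate(p, duration_h, seed, burn_in_h=30.0)
            control_periods.append(est.period if est.rhythmic else np.nan)
        control = float(np.nanmean(control_periods)) if control_periods else np.nan
        for step_ratio in step_ratios:
            protocol = kaia_protocol(
                "step",
                before_uM=base_ratio * c6,
                after_uM=step_ratio * c6,
                step_hour=step_hour,
            )
            rhythmics, periods = [], []
            for seed in seeds:
                traj = run_simulation(p, duration_h, protocol=protocol, seed=seed)
                est = estimate_period(traj, burn_in_h=step_hour + post_burn_h)
                rhythmics.append(est.rhythmic)
                if est.rhythmic:
                    periods.append(est.period)
            rows.append(
                dict(
                    step_ratio=float(step_ratio),
                    pdda=pdda,
                    control_period_h=control,
                    post_rhythmic=sum(rhythmics) * 2 > len(rhythmics),
                    post_period_h=float(np.mean(periods)) if periods else 0.0,
                    n_rhythmic_seeds=int(sum(rhythmics)),
                    n_seeds=len(seeds),
                )
            )
    return pd.DataFrame(rows)


def fluctuation_experiment(
    params: ModelParams | None = None,
    band_ratio: tuple[float, float] = (0.8, 2.0),
    resample_interval_h: float = 6.0,
    duration_h: float = 240.0,
    seeds: Sequence[int] = (0, 1, 2),
    burn_in_h: float = 30.0,
) -> pd.DataFrame:
    """Randomly fluctuating KaiA concentration, both PDDA settings.

    The total KaiA is resampled every ``resample_interval_h`` from a uniform
    band of ratios (converted to µM).  Reports per-setting cycle-to-cycle
    period dispersion (sd of successive peak intervals, pooled over seeds).
    Rows: pdda, seed, rhythmic, period_h, period_sd_h, n_cycles.
    """
    if params is None:
        params = ModelParams()
    lo, hi = band_ratio
    if lo < 0 or hi < lo:
        raise ValueError("fluctuation band must satisfy 0 <= lo <= hi")
    c6 = params.c6_uM
    rows = []
    for pdda in (True, False):
        p = replace(params, pdda_enabled=pdda)
        for seed in seeds:
            if hi == lo:
                protocol = kaia_protocol("constant", a2_uM=lo * c6)
            else:
                protocol = kaia_protocol(
                    "random_walk",
                    lo_uM=lo * c6,
                    hi_uM=hi * c6,
                    resample_interval_h=resample_interval_h,
                    duration_h=duration_h,
                    seed=seed + 1000,
                )
            traj = run_simulation(p, duration_h, protocol=protocol, seed=seed)
            est = estimate_period(traj, burn_in_h=burn_in_h)
            rows.append(
                dict(
                    pdda=pdda,
                    seed=seed,
                    rhythmic=est.rhythmic,
                    period_h=est.period,
                    period_sd_h=est.period_sd,
                    n_cycles=est.n_cycles,
                )
            )
    return pd.DataFrame(rows)
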