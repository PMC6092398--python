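"""Dwell-time extraction and single-exponential lifetime fitting.

Binary bound/unbound traces (one per immobilized KaiC hexamer) are run-length
encoded into dwell durations; runs touching either end of a trace are censored
and excluded.  Lifetimes are estimated either by maximum likelihood (the sample
mean, with SE tau/sqrt(n)) or by least-squares fitting of the dwell-time
histogram to A*exp(-t/tau), mirroring the single-exponential histogram fits
used for the experimental data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "BinaryTrace",
    "DwellSet",
    "ExpFit",
    "InsufficientEventsError",
    "extract_dwells",
    "merge_dwell_sets",
    "fit_exponential",
    "fit_dwell_pair",
    "lifetime_time_course",
    "read_traces",
    "write_traces",
    "write_fits",
]


class InsufficientEventsError(ValueError):
    """Raised when a dwell set has too few events for the requested fit (ND)."""


@dataclass
class BinaryTrace:
    """Frame-sampled bound/unbound states of a single molecule."""

    frame_interval: float  # s
    flags: np.ndarray  # bool, True = bound
    molecule_id: str = ""

    def __post_init__(self):
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 1 or self.flags.size < 1:
            raise ValueError("flags must be a non-empty 1-D sequence")

    def __len__(self) -> int:
        return self.flags.size


@dataclass
class DwellSet:
    """Uncensored dwell durations of one state plus censoring bookkeeping.

    ``censored_frames`` holds the total frame count of the excluded boundary
    runs so that frame conservation can be checked against the source trace.
    """

    durations: np.ndarray  # s, all > 0
    censored_left: int = 0
    censored_right: int = 0
    censored_frames: int = 0

    def __post_init__(self):
        self.durations = np.asarray(self.durations, dtype=float)
        if self.durations.size and not (self.durations > 0).all():
            raise ValueError("dwell durations must be positive")

    @property
    def n_events(self) -> int:
        return int(self.durations.size)


@dataclass
class ExpFit:
    """Result of a single-exponential lifetime fit."""

    tau: float  # s
    se: float  # s
    n_events: int
    method: str  # "mle" or "histogram"
    bin_width: float | None = None  # s, histogram method only

    def __post_init__(self):
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if self.se < 0:
            raise ValueError("se must be non-negative")


def _run_lengths(flags: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode a boolean array -> (states, lengths)."""
    change = np.flatnonzero(np.diff(flags.view(np.int8))) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [flags.size]))
    return flags[starts], ends - starts


def extract_dwells(trace: BinaryTrace) -> tuple[DwellSet, DwellSet]:
    """Split a trace into bound and unbound dwell sets.

    Dwell duration = run length x frame interval.  The first and last runs of
    the trace are censored (their true duration extends beyond the record) and
    are excluded from the durations; a single-run trace is censored on both
    sides.  Kept plus censored run lengths always sum to the trace length.
    """
    states, lengths = _run_lengths(trace.flags)
    n_runs = states.size
    out: dict[bool, dict] = {
        True: dict(durs=[], cl=0, cr=0, cf=0),
        False: dict(durs=[], cl=0, cr=0, cf=0),
    }
    for i in range(n_runs):
        s = bool(states[i])
        first, last = i == 0, i == n_runs - 1
        if first or last:
            out[s]["cl"] += int(first)
            out[s]["cr"] += int(last)
            out[s]["cf"] += int(lengths[i])
        else:
            out[s]["durs"].append(lengths[i] * trace.frame_interval)
    bound = DwellSet(
        durations=np.array(out[True]["durs"]),
        censored_left=out[True]["cl"],
        censored_right=out[True]["cr"],
        censored_frames=out[True]["cf"],
    )
    unbound = DwellSet(
        durations=np.array(out[False]["durs"]),
        censored_left=out[False]["cl"],
        censored_right=out[False]["cr"],
        censored_frames=out[False]["cf"],
    )
    return bound, unbound


def merge_dwell_sets(sets: Iterable[DwellSet]) -> DwellSet:
    """Pool dwell sets from several molecules into one."""
    sets = list(sets)
    return DwellSet(
        durations=np.concatenate([s.durations for s in sets]) if sets else np.array([]),
        censored_left=sum(s.censored_left for s in sets),
        censored_right=sum(s.censored_right for s in sets),
        censored_frames=sum(s.censored_frames for s in sets),
    )


def fit_exponential(
    dwells: DwellSet,
    method: str = "mle",
    bin_width: float | None = None,
    frame_interval: float | None = None,
    discrete_correction: bool = False,
) -> ExpFit:
    """Fit a single-exponential lifetime to a dwell set.

    ``mle``: tau is the sample mean, se = tau/sqrt(n) (needs >= 2 events).
    ``histogram``: least-squares fit of the binned counts to A*exp(-t/tau)
    with se taken from the fit covariance (needs >= 10 events); ``bin_width``
    defaults to ``frame_interval`` when given.

    With ``discrete_correction`` the geometric-sampling bias of frame-quantized
    dwells is removed via tau = -dt/ln(1 - dt/mean); requires
    ``frame_interval``.  Off by default.
    """
    n = dwells.n_events
    if method == "mle":
        if n < 2:
            raise InsufficientEventsError(f"insufficient events for MLE fit (n={n})")
        mean = float(dwells.durations.mean())
        if discrete_correction:
            if frame_interval is None:
                raise ValueError("discrete_correction requires frame_interval")
            dt = frame_interval
            if mean <= dt:
                raise ValueError("mean dwell not above one frame; cannot correct")
            tau = -dt / math.log1p(-dt / mean)
        else:
            tau = mean
        return ExpFit(tau=tau, se=tau / math.sqrt(n), n_events=n, method="mle")
    if method == "histogram":
        if n < 10:
            raise InsufficientEventsError(f"insufficient events for histogram fit (n={n})")
        if bin_width is None:
            bin_width = frame_interval
        if bin_width is None or not bin_width > 0:
            raise ValueError("histogram method requires a positive bin_width")
        durs = dwells.durations
        n_bins = max(3, int(np.ceil(durs.max() / bin_width)))
        edges = np.arange(n_bins + 1) * bin_width
        counts, _ = np.histogram(durs, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        mean = durs.mean()

        def model(t, a, tau):
            return a * np.exp(-t / tau)

        popt, pcov = curve_fit(
            model, centers, counts, p0=(counts.max() or 1.0, mean), maxfev=10000
        )
        tau = float(abs(popt[1]))
        se = float(np.sqrt(abs(pcov[1, 1])))
        return ExpFit(tau=tau, se=se, n_events=n, method="histogram", bin_width=bin_width)
    raise ValueError(f"unknown fit method {method!r}")


def fit_dwell_pair(
    bound: DwellSet,
    unbound: DwellSet,
    frame_interval: float,
    detection_limit_frames: int = 1,
    correct_detection_limit: bool = True,
) -> tuple[ExpFit, ExpFit]:
    """Joint MLE of bound/unbound lifetimes with a detection-limit correction.

    Events shorter than the detection limit L are invisible, which biases the
    observed dwells in two ways: (i) truncation - a surviving dwell starts
    from a sojourn >= L, so its leading segment has mean L + tau by
    memorylessness; (ii) fusion - each sub-limit blip of the opposite state
    splices an extra full sojourn onto the observed dwell.  To first order in
    the blip probabilities p = 1 - exp(-L/tau), the observed means obey

        m_b = L + tau_b + q_u * (E[U | U < L] + tau_b),  q_u = p_u/(1 - p_u)

    (and symmetrically for m_u), inverted here by fixed-point iteration.
    With the correction disabled this reduces to two independent MLE fits.
    """
    if bound.n_events < 2 or unbound.n_events < 2:
        raise InsufficientEventsError("insufficient events for paired fit")
    m_b = float(bound.durations.mean())
    m_u = float(unbound.durations.mean())
    if not correct_detection_limit:
        tau_b, tau_u = m_b, m_u
    else:
        limit = detection_limit_frames * frame_interval
        tau_b, tau_u = m_b, m_u

        def _short_mean(tau: float) -> tuple[float, float]:
            # P(dwell < L) and E[dwell | dwell < L]
            p = -math.expm1(-limit / tau)
            cond = tau - limit * math.exp(-limit / tau) / p if p > 0 else 0.0
            return p, cond

        for _ in range(100):
            p_u, u_s = _short_mean(tau_u)
            p_b, b_s = _short_mean(tau_b)
            q_u = p_u / (1.0 - p_u)
            q_b = p_b / (1.0 - p_b)
            new_b = max((m_b - limit - q_u * u_s) / (1.0 + q_u), 1e-12)
            new_u = max((m_u - limit - q_b * b_s) / (1.0 + q_b), 1e-12)
            if abs(new_b - tau_b) < 1e-12 and abs(new_u - tau_u) < 1e-12:
                tau_b, tau_u = new_b, new_u
                break
            tau_b, tau_u = new_b, new_u
    fit_b = ExpFit(tau=tau_b, se=tau_b / math.sqrt(bound.n_events),
                   n_events=bound.n_events, method="mle")
    fit_u = ExpFit(tau=tau_u, se=tau_u / math.sqrt(unbound.n_events),
                   n_events=unbound.n_events, method="mle")
    return fit_b, fit_u


def lifetime_time_course(
    per_timepoint: Mapping[float, DwellSet],
    method: str = "mle",
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit one lifetime per timepoint of a phase series.

    Returns a DataFrame sorted by time with columns (time, tau_s, se_s,
    n_events, nd).  Timepoints with too few events are kept as ND rows
    (tau and se NaN) rather than aborting the course.
    """
    rows = []
    for time in sorted(per_timepoint):
        dwells = per_timepoint[time]
        try:
            fit = fit_exponential(dwells, method=method, **fit_kwargs)
            rows.append(
                dict(time=time, tau_s=fit.tau, se_s=fit.se, n_events=fit.n_events, nd=False)
            )
        except InsufficientEventsError:
            rows.append(
                dict(time=time, tau_s=np.nan, se_s=np.nan, n_events=dwells.n_events, nd=True)
            )
    return pd.DataFrame(rows, columns=["time", "tau_s", "se_s", "n_events", "nd"])


# ---------------------------------------------------------------------------
# Trace table I/O (TSV dialect shared with the synthetic-trace generator)

def write_traces(traces: Sequence[BinaryTrace], path: str | Path) -> None:
    frames = []
    for tr in traces:
        idx = np.arange(len(tr))
        frames.append(
            pd.DataFrame(
                {
                    "frame_index": idx,
                    "time_s": idx * tr.frame_interval,
                    "bound": tr.flags.astype(int),
                    "molecule_id": tr.molecule_id,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_traces(path: str | Path) -> list[BinaryTrace]:
    df = pd.read_csv(path, sep="\t")
    traces = []
    for mol, grp in df.groupby("molecule_id", sort=False):
        grp = grp.sort_values("frame_index")
        times = grp["time_s"].to_numpy()
        dt = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
        traces.append(
            BinaryTrace(
                frame_interval=dt,
                flags=grp["bound"].to_numpy().astype(bool),
                molecule_id=str(mol),
            )
        )
    return traces


def write_fits(fits: Mapping[str, ExpFit], path: str | Path) -> None:
    rows = [
        dict(
            label=label,
            tau_s=f.tau,
            se_s=f.se,
            n_events=f.n_events,
            method=f.method,
            bin_width_s=f.bin_width,
        )
        for label, f in fits.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
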