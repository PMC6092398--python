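"""Synthetic single-molecule binding traces (telegraph-process generator).

Emulates frame-sampled HS-AFM observations of KaiA binding to immobilized KaiC
hexamers: a two-state alternating-renewal (telegraph) process with exponential
bound/unbound sojourns, a finite detection limit that absorbs sub-frame blips
(mimicking eye-based event calling), and phase-dependent mixtures of KaiC
phosphoforms across a lawn of molecules.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .dwell import BinaryTrace
from .kinetics import CYCLE_ORDER, PddaTable, PhosphoForm

__all__ = [
    "TelegraphParams",
    "PhaseMixture",
    "simulate_trace",
    "mixture_trace_set",
    "phase_series",
]


@dataclass(frozen=True)
class TelegraphParams:
    """Generator settings for one telegraph trace.

    Default acquisition mirrors the lifetime-quantification movies: 10 frames
    per second.  ``tau_unbound`` may be ``inf`` to disable binding entirely.
    """

    tau_bound: float  # s
    tau_unbound: float  # s (may be inf)
    frame_rate: float = 10.0  # frames / s
    duration: float = 600.0  # s
    detection_limit_frames: int = 1

    def __post_init__(self):
        if not self.tau_bound > 0:
            raise ValueError("tau_bound must be positive")
        if not self.tau_unbound > 0:
            raise ValueError("tau_unbound must be positive")
        if not self.frame_rate > 0 or not self.duration > 0:
            raise ValueError("frame_rate and duration must be positive")
        if self.detection_limit_frames < 1:
            raise ValueError("detection_limit_frames must be >= 1")


@dataclass(frozen=True)
class PhaseMixture:
    """Weights over KaiC phosphoforms present at one circadian phase."""

    weights: Mapping[PhosphoForm, float]

    def __post_init__(self):
        w = np.array([self.weights.get(f, 0.0) for f in CYCLE_ORDER])
        if (w < 0).any():
            raise ValueError("mixture weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {w.sum()}")

    @property
    def weight_vector(self) -> np.ndarray:
        return np.array([self.weights.get(f, 0.0) for f in CYCLE_ORDER])

    @property
    def percent_phosphorylated(self) -> float:
        """Weight-based percentage of protomers carrying >= 1 phosphate."""
        return 100.0 * sum(
            w for f, w in self.weights.items() if f is not PhosphoForm.ST
        )


def _merge_short_dwells(
    states: list[bool], durs: list[float], limit: float
) -> tuple[list[bool], list[float]]:
    """Absorb dwells shorter than ``limit`` into their surrounding state.

    Operates on the continuous path before frame sampling: an interior short
    dwell is merged with both neighbors (which share a state); a boundary short
    dwell is merged into its single neighbor.  Repeats until stable.
    """
    states, durs = list(states), list(durs)
    while len(states) > 1:
        idx = next((i for i, d in enumerate(durs) if d < limit), None)
        if idx is None:
            break
        if idx == 0:
            durs[1] += durs[0]
            del states[0], durs[0]
        elif idx == len(states) - 1:
            durs[-2] += durs[-1]
            del states[-1], durs[-1]
        else:
            durs[idx - 1] += durs[idx] + durs[idx + 1]
            del states[idx : idx + 2], durs[idx : idx + 2]
    return states, durs


def simulate_trace(
    p: TelegraphParams, rng: np.random.Generator, molecule_id: str = ""
) -> BinaryTrace:
    """Simulate one frame-sampled telegraph trace.

    The continuous path starts from the stationary state distribution
    tau_bound/(tau_bound + tau_unbound) and alternates exponential sojourns.
    Dwells shorter than the detection limit are absorbed into the surrounding
    state before sampling; each frame reports the state at its midpoint.
    """
    n_frames = int(round(p.duration * p.frame_rate))
    dt = 1.0 / p.frame_rate
    if np.isinf(p.tau_unbound):
        return BinaryTrace(
            frame_interval=dt, flags=np.zeros(n_frames, bool), molecule_id=molecule_id
        )
    taus = {True: p.tau_bound, False: p.tau_unbound}
    p_bound = p.tau_bound / (p.tau_bound + p.tau_unbound)
    state = bool(rng.random() < p_bound)
    states: list[bool] = []
    durs: list[float] = []
    t = 0.0
    while t < p.duration:
        d = rng.exponential(taus[state])
        states.append(state)
        durs.append(d)
        t += d
        state = not state
    limit = p.detection_limit_frames * dt
    states, durs = _merge_short_dwells(states, durs, limit)
    boundaries = np.cumsum(durs)
    midpoints = (np.arange(n_frames) + 0.5) * dt
    idx = np.searchsorted(boundaries, midpoints, side="right")
    idx = np.minimum(idx, len(states) - 1)
    flags = np.array(states, dtype=bool)[idx]
    return BinaryTrace(frame_interval=dt, flags=flags, molecule_id=molecule_id)


def mixture_trace_set(
    mix: PhaseMixture,
    table: PddaTable,
    n_molecules: int,
    p: TelegraphParams,
    rng: np.random.Generator,
    id_prefix: str = "mol",
) -> list[BinaryTrace]:
    """Simulate a lawn of molecules whose phosphoforms are drawn from ``mix``.

    Each molecule draws one phosphoform and keeps it for the whole trace
    (assays are short relative to phospho-turnover); its telegraph lifetimes
    come from the lifetime table.
    """
    weights = mix.weight_vector
    forms = rng.choice(len(CYCLE_ORDER), size=n_molecules, p=weights)
    traces = []
    for i, fi in enumerate(forms):
        form = CYCLE_ORDER[fi]
        dp = table[form]
        if dp.tau_unbound is None:
            raise ValueError(f"form {form} has no unbound lifetime in table")
        pm = replace(p, tau_bound=dp.tau_bound, tau_unbound=dp.tau_unbound)
        traces.append(simulate_trace(pm, rng, molecule_id=f"{id_prefix}{i}"))
    return traces


def phase_series(
    schedule: Mapping[float, PhaseMixture],
    table: PddaTable,
    n_molecules: int,
    p: TelegraphParams,
    rng: np.random.Generator,
) -> dict[float, list[BinaryTrace]]:
    """One mixture trace set per timepoint of a circadian phase schedule.

    ``schedule`` maps hours (phase of the in vitro cycle) to the phosphoform
    mixture present at that phase; mixtures may come from the population model.
    Deterministic for a fixed generator state.
    """
    if not schedule:
        raise ValueError("schedule must be non-empty")
    out = {}
    for hour in sorted(schedule):
        out[hour] = mixture_trace_set(
            schedule[hour], table, n_molecules, p, rng, id_prefix=f"t{hour}_mol"
        )
    return out
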