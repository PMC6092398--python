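"""Stochastic population model of the KaiABC oscillator with PDDA.

The simulator tracks counts of KaiC hexamers over all 84 protomer-form
compositions, split into an ACTIVE pool (free to bind KaiA and phosphorylate)
and a SEQUESTERING pool (KaiB-bound complexes that hold KaiA dimers and only
dephosphorylate).  Within each time step:

1. KaiA partitioning: binding equilibrates on sub-second timescales, far below
   the hour-scale phospho-kinetics, so the KaiA-bound fraction of each hexamer
   state is computed from a pseudo-steady-state 1:1 binding model
   A2 + C6 <-> A2C6 with a state-dependent Kd (PDDA) or a fixed Kd (-PDDA).
2. Phosphoform transitions: per-protomer steps along the cycle
   S/T -> S/pT -> pS/pT (KaiA-bound, autokinase) and
   pS/pT -> pS/T -> S/T (unbound, autophosphatase), applied as binomial
   tau-leaps over aggregated protomer counts.
3. KaiB switching and KaiA sequestration: hexamers rich in C-terminally
   phosphorylated (pS-carrying) protomers switch to the sequestering state,
   consuming free KaiB and capturing free KaiA dimers; fully dephosphorylated
   complexes release their KaiA and KaiB and rejoin the active pool.

The production path is a numba-compiled kernel (`run_simulation`); the
individual operations also exist as plain numpy functions for unit testing
and small-scale work.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit

from .kinetics import (
    CYCLE_ORDER,
    HexamerComposition,
    PddaTable,
    default_pdda_table,
    hexamer_affinity,
)

__all__ = [
    "N_COMPOSITIONS",
    "enumerate_compositions",
    "composition_index",
    "kaia_partition",
    "ModelParams",
    "PopulationState",
    "Trajectory",
    "KaiAProtocol",
    "kaia_protocol",
    "phospho_step",
    "sequestration_step",
    "run_simulation",
]

N_COMPOSITIONS = 84  # C(9,3): multisets of 6 protomers over 4 forms


def enumerate_compositions() -> list[HexamerComposition]:
    """All 84 hexamer compositions, lexicographic from the all-S/T state.

    The first element is (6,0,0,0); ordering is descending-lexicographic in
    (n_ST, n_SpT, n_pSpT, n_pST).
    """
    comps = [
        HexamerComposition(a, b, c, 6 - a - b - c)
        for a in range(7)
        for b in range(7 - a)
        for c in range(7 - a - b)
    ]
    return sorted(comps, reverse=True)


_COMPS = enumerate_compositions()
_COMP_INDEX = {tuple(c): i for i, c in enumerate(_COMPS)}
_COMP_ARRAY = np.array(_COMPS, dtype=np.int64)


def composition_index(comp: Sequence[int]) -> int:
    return _COMP_INDEX[tuple(comp)]


# Transition channels: (source form, destination form, needs-KaiA-bound)
# c0..c2 run in the KaiA-bound subpopulation (autokinase, incl. the
# pS/T -> pS/pT back reaction); c3..c5 in the unbound/sequestering
# subpopulation (autophosphatase).
_CHAN_SRC = np.array([0, 1, 3, 2, 3, 1], dtype=np.int64)
_CHAN_DST = np.array([1, 2, 2, 3, 0, 0], dtype=np.int64)
_CHAN_BOUND = np.array([1, 1, 1, 0, 0, 0], dtype=np.int64)
N_CHANNELS = 6


def _build_channel_tables() -> tuple[np.ndarray, np.ndarray]:
    """Per-composition protomer counts and target indices for each channel."""
    count_src = np.zeros((N_COMPOSITIONS, N_CHANNELS), dtype=np.int64)
    target = np.full((N_COMPOSITIONS, N_CHANNELS), -1, dtype=np.int64)
    for i, comp in enumerate(_COMPS):
        for c in range(N_CHANNELS):
            src, dst = _CHAN_SRC[c], _CHAN_DST[c]
            n = comp[src]
            count_src[i, c] = n
            if n > 0:
                new = list(comp)
                new[src] -= 1
                new[dst] += 1
                target[i, c] = _COMP_INDEX[tuple(new)]
    return count_src, target


_COUNT_SRC, _TARGET = _build_channel_tables()
_ALL_ST_INDEX = _COMP_INDEX[(6, 0, 0, 0)]


# ---------------------------------------------------------------------------
# KaiA pseudo-steady-state partitioning

def kaia_partition(
    a_avail: float, hexamer_conc: np.ndarray, kd: np.ndarray, rel_tol: float = 1e-9
) -> tuple[np.ndarray, float]:
    """Partition available KaiA dimers over competing hexamer states.

    Solves the conservation equation
        A_free + sum_i C_i * A_free / (kd_i + A_free) = A_avail
    by bisection to ``rel_tol`` relative accuracy and returns the per-state
    bound fraction A_free/(kd_i + A_free) together with the free concentration.
    KaiA is conserved exactly: free + sum(bound) = A_avail.
    """
    hexamer_conc = np.asarray(hexamer_conc, dtype=float)
    kd = np.asarray(kd, dtype=float)
    if a_avail < 0 or (hexamer_conc < 0).any():
        raise ValueError("pools must be non-negative")
    if (kd <= 0).any():
        raise ValueError("kd must be strictly positive")
    if a_avail == 0:
        return np.zeros_like(kd), 0.0
    lo, hi = 0.0, a_avail
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        excess = mid + np.sum(hexamer_conc * mid / (kd + mid)) - a_avail
        if excess > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo <= rel_tol * a_avail:
            break
    a_free = 0.5 * (lo + hi)
    return a_free / (kd + a_free), a_free


# ---------------------------------------------------------------------------
# Parameters, state, trajectory

@dataclass(frozen=True)
class ModelParams:
    """Population-model parameters.

    Hour-scale kinetics (defaults from the documented calibration):
      * ``kdephos`` is set so KaiA-free dephosphorylation of fully
        phosphorylated KaiC (two per-protomer steps) takes about 10 h.
      * ``kphos`` is set so the phosphorylation half-cycle under standard
        +PDDA conditions lasts about 12 h, giving a circa-22 h period at the
        standard dimer:hexamer ratio 1.33.
    Concentrations mirror the standard in vitro reaction: 3.43 µM KaiC
    monomer = 0.58 µM hexamer, 4.27 µM KaiB monomer, KaiA set via
    ``a2_ratio`` (dimers per hexamer; 1.33 is the standard reaction).
    """

    kphos: float = 0.9  # h^-1 per protomer step when KaiA-bound
    kdephos: float = 0.22  # h^-1 per protomer step when unbound
    kb_switch: float = 2.0  # h^-1 ACTIVE -> SEQUESTERING for eligible hexamers
    seq_capacity: float = 4.2  # KaiA dimers captured per sequestering hexamer (g)
    switch_rule: str = "pST_only"  # or "pST_and_pSpT"
    switch_threshold: int = 2  # protomers (out of 6) required to switch
    a2_ratio: float = 1.33  # [A2]/[C6]
    c6_uM: float = 0.58  # KaiC hexamer concentration
    b_uM: float = 4.27  # KaiB monomer concentration
    n_hexamers: int = 5000
    pdda_enabled: bool = True
    dt: float = 0.01  # h
    allow_spt_dephos: bool = True  # direct S/pT -> S/T when unbound
    bound_back_reaction: bool = True  # pS/T -> pS/pT while KaiA-bound
    require_unbound_switch: bool = True  # only KaiA-free hexamers engage KaiB
    tau_bound_aa: float = 3.0  # s, placeholder bound lifetime of the S/T form
    kd_scale: float = 0.055  # effective-affinity calibration (see methods note)
    dephos_active_factor: float = 1.0  # autophosphatase attenuation in ACTIVE state
    seed: int = 0

    def __post_init__(self):
        if min(self.kphos, self.kdephos, self.kb_switch) < 0:
            raise ValueError("rates must be non-negative")
        if self.switch_rule not in ("pST_and_pSpT", "pST_only"):
            raise ValueError(f"unknown switch_rule {self.switch_rule!r}")
        pmax = max(self.kphos, self.kdephos, self.kb_switch) * self.dt
        if pmax >= 0.5:
            raise ValueError(f"dt too large: per-event probability {pmax:.2f} >= 0.5")
        if self.a2_ratio < 0 or self.c6_uM <= 0 or self.b_uM < 0:
            raise ValueError("concentrations must be non-negative ([C6] positive)")
        if self.n_hexamers < 1:
            raise ValueError("need at least one hexamer")

    @property
    def a2_uM(self) -> float:
        return self.a2_ratio * self.c6_uM

    @property
    def conc_per_hexamer(self) -> float:
        """µM of hexamer represented by one simulated hexamer count."""
        return self.c6_uM / self.n_hexamers

    def pdda_table(self) -> PddaTable:
        return default_pdda_table(
            tau_bound_aa=self.tau_bound_aa, pdda_enabled=self.pdda_enabled
        )

    def kd_per_composition(self) -> np.ndarray:
        """Per-composition dissociation constant (µM), affinity-calibrated.

        ``kd_scale`` multiplies every Kd uniformly: the relative (~10x) PDDA
        span between hypo- and hyper-phosphorylated compositions is exactly
        the measured one, while the absolute scale of the effective bulk
        affinity is a calibrated quantity.
        """
        table = self.pdda_table()
        return self.kd_scale * np.array(
            [hexamer_affinity(c, table).kd for c in _COMPS], dtype=float
        )

    def eligibility(self) -> np.ndarray:
        comps = _COMP_ARRAY
        if self.switch_rule == "pST_and_pSpT":
            n_switchy = comps[:, 2] + comps[:, 3]
        else:
            n_switchy = comps[:, 3]
        return (n_switchy >= self.switch_threshold).astype(np.int64)


@dataclass
class PopulationState:
    """Counts of hexamers per (composition x phase flag) plus the KaiA/B pools.

    ``a2_total`` is the instantaneous total KaiA dimer concentration (µM);
    free-plus-transiently-bound KaiA is ``a2_total - seq_a2``.
    """

    active: np.ndarray  # int64[84]
    sequestering: np.ndarray  # int64[84]
    a2_total: float  # µM
    seq_a2: float  # µM
    free_b: float  # µM monomers
    time: float = 0.0  # h

    def __post_init__(self):
        self.active = np.asarray(self.active, dtype=np.int64)
        self.sequestering = np.asarray(self.sequestering, dtype=np.int64)
        if (self.active < 0).any() or (self.sequestering < 0).any():
            raise ValueError("hexamer counts must be non-negative")
        if min(self.a2_total, self.seq_a2, self.free_b) < -1e-12:
            raise ValueError("concentration pools must be non-negative")

    @property
    def n_hexamers(self) -> int:
        return int(self.active.sum() + self.sequestering.sum())

    @property
    def avail_a2(self) -> float:
        return self.a2_total - self.seq_a2

    def percent_p(self) -> float:
        total = self.active + self.sequestering
        phos = np.sum(total * (6 - _COMP_ARRAY[:, 0]))
        return 100.0 * phos / (6.0 * self.n_hexamers)

    def form_fractions(self) -> np.ndarray:
        total = self.active + self.sequestering
        return (total @ _COMP_ARRAY) / (6.0 * self.n_hexamers)

    @classmethod
    def initial(cls, params: ModelParams) -> "PopulationState":
        active = np.zeros(N_COMPOSITIONS, dtype=np.int64)
        active[_ALL_ST_INDEX] = params.n_hexamers
        return cls(
            active=active,
            sequestering=np.zeros(N_COMPOSITIONS, dtype=np.int64),
            a2_total=params.a2_uM,
            seq_a2=0.0,
            free_b=params.b_uM,
        )


@dataclass
class Trajectory:
    """Recorded time series of a population run."""

    time_h: np.ndarray
    percent_p: np.ndarray
    form_fractions: np.ndarray  # (n, 4) protomer fractions per form
    free_a2: np.ndarray  # µM, from the partition at each record
    bound_a2: np.ndarray  # µM, transiently bound
    seq_a2: np.ndarray  # µM, sequestered in KaiA-B-C complexes
    n_sequestering: np.ndarray
    a2_total: np.ndarray
    final_active: np.ndarray = field(default=None, repr=False)
    final_sequestering: np.ndarray = field(default=None, repr=False)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "time_h": self.time_h,
                "percentP": self.percent_p,
                "freeA2_uM": self.free_a2,
                "boundA2_uM": self.bound_a2,
                "seqA2_uM": self.seq_a2,
                "totalA2_uM": self.a2_total,
                "n_sequestering": self.n_sequestering,
            }
        )
        for k, form in enumerate(CYCLE_ORDER):
            df[f"frac_{form.value}"] = self.form_fractions[:, k]
        return df


# ---------------------------------------------------------------------------
# KaiA concentration protocols

@dataclass(frozen=True)
class KaiAProtocol:
    """Time course of total KaiA dimer concentration (µM)."""

    kind: str
    times: np.ndarray  # breakpoint times (h), piecewise-constant from each
    values: np.ndarray  # µM at/after each breakpoint

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.searchsorted(self.times, t, side="right") - 1, 0, None)
        out = self.values[idx]
        return float(out) if out.ndim == 0 else out


def kaia_protocol(kind: str, **kwargs) -> KaiAProtocol:
    """Build a KaiA concentration protocol.

    kinds:
      * ``constant``: ``a2_uM``.
      * ``step``: ``before_uM`` -> ``after_uM`` at ``step_hour``.
      * ``random_walk``: piecewise-constant resampling every
        ``resample_interval_h`` from Uniform(``lo_uM``, ``hi_uM``) over
        ``duration_h``, seeded by ``seed``.
    """
    if kind == "constant":
        a = float(kwargs["a2_uM"])
        if a < 0:
            raise ValueError("negative concentration")
        return KaiAProtocol(kind, np.array([0.0]), np.array([a]))
    if kind == "step":
        before, after = float(kwargs["before_uM"]), float(kwargs["after_uM"])
        hour = float(kwargs["step_hour"])
        if before < 0 or after < 0:
            raise ValueError("negative concentration")
        return KaiAProtocol(kind, np.array([0.0, hour]), np.array([before, after]))
    if kind == "random_walk":
        lo, hi = float(kwargs["lo_uM"]), float(kwargs["hi_uM"])
        if lo < 0 or hi < lo:
            raise ValueError("band must satisfy 0 <= lo <= hi")
        interval = float(kwargs["resample_interval_h"])
        duration = float(kwargs["duration_h"])
        rng = np.random.default_rng(int(kwargs.get("seed", 0)))
        times = np.arange(0.0, duration + interval, interval)
        values = rng.uniform(lo, hi, size=times.size)
        return KaiAProtocol(kind, times, values)
    raise ValueError(f"unknown protocol kind {kind!r}")


# ---------------------------------------------------------------------------
# Reference (numpy) single-step operations

def _channel_rates(params: ModelParams, pool: str = "active") -> np.ndarray:
    """Per-channel rates; the ACTIVE pool's autophosphatase is attenuated by
    ``dephos_active_factor`` relative to the sequestering complexes."""
    kdp = params.kdephos
    if pool == "active":
        kdp *= params.dephos_active_factor
    rates = np.zeros(N_CHANNELS)
    rates[0] = rates[1] = params.kphos
    rates[2] = params.kphos if params.bound_back_reaction else 0.0
    rates[3] = rates[4] = kdp
    rates[5] = kdp if params.allow_spt_dephos else 0.0
    return rates


def _leap_moves(
    counts: np.ndarray,
    sub: np.ndarray,
    channels: Sequence[int],
    rates: np.ndarray,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binomial tau-leap: move hexamers along transition channels.

    ``sub`` is the subpopulation (per composition) the channels act on; at
    most ``sub`` hexamers leave a composition per step (sequential capping).
    Returns the delta to add to ``counts``.
    """
    delta = np.zeros_like(counts)
    for i in np.flatnonzero(sub):
        remaining = int(sub[i])
        for c in channels:
            p = rates[c] * dt
            if p <= 0.0 or remaining <= 0:
                continue
            n_trials = int(sub[i]) * int(_COUNT_SRC[i, c])
            if n_trials == 0:
                continue
            ev = int(rng.binomial(n_trials, min(p, 1.0)))
            ev = min(ev, remaining)
            if ev:
                j = _TARGET[i, c]
                delta[i] -= ev
                delta[j] += ev
                remaining -= ev
    return delta


def phospho_step(
    state: PopulationState,
    params: ModelParams,
    rng: np.random.Generator,
    kd: np.ndarray | None = None,
) -> tuple[PopulationState, dict]:
    """Advance phosphoform transitions by one time step (reference path).

    The KaiA-bound subset of each active composition is drawn binomially from
    the pseudo-steady-state bound fraction; bound protomers step forward
    (S/T->S/pT, S/pT->pS/pT, and the pS/T->pS/pT back reaction), unbound and
    sequestering protomers step backward.  Returns the new state plus the
    partition diagnostics.
    """
    if kd is None:
        kd = params.kd_per_composition()
    rates = _channel_rates(params, "active")
    rates_seq = _channel_rates(params, "sequestering")
    pmax = max(rates.max(), rates_seq.max()) * params.dt
    if pmax > 0.5:
        raise ValueError("dt too large")
    conc = state.active * params.conc_per_hexamer
    frac, a_free = kaia_partition(max(state.avail_a2, 0.0), conc, kd)
    n_bound = rng.binomial(state.active, frac)
    n_unbound = state.active - n_bound
    bound_channels = [c for c in range(N_CHANNELS) if _CHAN_BOUND[c]]
    unbound_channels = [c for c in range(N_CHANNELS) if not _CHAN_BOUND[c]]
    delta = _leap_moves(state.active, n_bound, bound_channels, rates, params.dt, rng)
    delta += _leap_moves(state.active, n_unbound, unbound_channels, rates, params.dt, rng)
    dseq = _leap_moves(
        state.sequestering, state.sequestering, unbound_channels, rates_seq, params.dt, rng
    )
    new = replace(
        state,
        active=state.active + delta,
        sequestering=state.sequestering + dseq,
        time=state.time + params.dt,
    )
    bound_conc = float(np.sum(n_bound) * params.conc_per_hexamer)
    return new, {"a_free": a_free, "bound_frac": frac, "bound_conc": bound_conc}


def sequestration_step(
    state: PopulationState,
    params: ModelParams,
    rng: np.random.Generator,
    bound_frac: np.ndarray | None = None,
) -> PopulationState:
    """KaiB switching, KaiA capture and complex release (reference path).

    Eligible active hexamers (composition past the switch threshold; only the
    KaiA-unbound ones when ``require_unbound_switch``) convert to the
    sequestering state at ``kb_switch``, limited by free KaiB (6 monomers per
    hexamer).  Each batch of conversions captures up to g free KaiA dimers per
    hexamer.  Sequestering hexamers that have reached all-S/T release their
    KaiA and KaiB and rejoin the active pool.
    """
    unit = params.conc_per_hexamer
    elig = params.eligibility()
    q = params.kb_switch * params.dt
    if params.require_unbound_switch and bound_frac is not None:
        q_i = (1.0 - bound_frac) * q
    else:
        q_i = np.full(N_COMPOSITIONS, q)
    active = state.active.copy()
    seq = state.sequestering.copy()
    free_b = state.free_b
    seq_a2 = state.seq_a2
    budget = int(free_b / (6.0 * unit) + 1e-9)
    switched = 0
    for i in np.flatnonzero(elig & (active > 0)):
        if budget <= 0:
            break
        ev = int(rng.binomial(active[i], min(q_i[i], 1.0)))
        ev = min(ev, budget)
        active[i] -= ev
        seq[i] += ev
        budget -= ev
        switched += ev
    if switched:
        free_b -= switched * 6.0 * unit
    m = int(seq[_ALL_ST_INDEX])
    if m:
        n_seq = int(seq.sum())
        released = seq_a2 * m / n_seq
        seq_a2 -= released
        free_b += m * 6.0 * unit
        seq[_ALL_ST_INDEX] = 0
        active[_ALL_ST_INDEX] += m
    # Continuous KaiA absorption: standing KaiA-B-C complexes soak up free
    # KaiA dimers up to g per complex (binding is fast on the hour scale).
    capacity = seq.sum() * params.seq_capacity * unit
    avail = max(state.a2_total - seq_a2, 0.0)
    if seq_a2 < capacity:
        seq_a2 += min(capacity - seq_a2, avail)
    return replace(
        state, active=active, sequestering=seq, seq_a2=seq_a2, free_b=free_b
    )


# ---------------------------------------------------------------------------
# Numba production kernel

@njit(cache=False)
def _kernel(
    seed,
    n_steps,
    record_every,
    dt,
    comp_nst,  # int64[84]: n_ST per composition
    count_src,  # int64[84,6]
    target,  # int64[84,6]
    chan_bound,  # int64[6]
    rates,  # float64[6], ACTIVE pool
    rates_seq,  # float64[6], SEQUESTERING pool
    kd,  # float64[84]
    elig,  # int64[84]
    i_all_st,
    n_hex,
    unit,
    a_tot_steps,  # float64[n_steps]
    b_tot,
    kb_switch,
    g_capacity,
    require_unbound,
):
    np.random.seed(seed)
    n84 = kd.shape[0]
    N = np.zeros(n84, dtype=np.int64)
    S = np.zeros(n84, dtype=np.int64)
    N[i_all_st] = n_hex
    seq_a2 = 0.0
    free_b = b_tot
    n_rec = n_steps // record_every + 1
    rec_t = np.zeros(n_rec)
    rec_pp = np.zeros(n_rec)
    rec_forms = np.zeros((n_rec, 4))
    rec_free = np.zeros(n_rec)
    rec_bound = np.zeros(n_rec)
    rec_seq = np.zeros(n_rec)
    rec_nseq = np.zeros(n_rec, dtype=np.int64)
    rec_atot = np.zeros(n_rec)
    dN = np.zeros(n84, dtype=np.int64)
    dS = np.zeros(n84, dtype=np.int64)
    n_bound = np.zeros(n84, dtype=np.int64)
    frac = np.zeros(n84)
    comp_counts = np.zeros((n84, 4), dtype=np.int64)
    # rebuild per-form counts from n_ST and channel tables is awkward; the
    # caller passes comp_nst only for %P, full form counts via count_src:
    # channel 0 source is ST, 1 is SpT, 3 is pSpT, 2 is pST.
    for i in range(n84):
        comp_counts[i, 0] = count_src[i, 0]
        comp_counts[i, 1] = count_src[i, 1]
        comp_counts[i, 2] = count_src[i, 3]
        comp_counts[i, 3] = count_src[i, 2]
    rec = 0
    status = 0
    a_free = 0.0
    bound_conc = 0.0
    for step in range(n_steps + 1):
        a_tot = a_tot_steps[min(step, n_steps - 1)]
        if seq_a2 > a_tot:
            seq_a2 = a_tot  # protocol removed KaiA beyond the free pool
        a_avail = a_tot - seq_a2
        # --- KaiA pseudo-steady-state partition (bisection) ---
        if a_avail <= 0.0:
            a_free = 0.0
        else:
            lo = 0.0
            hi = a_avail
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                s = mid - a_avail
                for i in range(n84):
                    if N[i] > 0:
                        s += N[i] * unit * mid / (kd[i] + mid)
                if s > 0.0:
                    hi = mid
                else:
                    lo = mid
            a_free = 0.5 * (lo + hi)
        bound_conc = 0.0
        for i in range(n84):
            frac[i] = a_free / (kd[i] + a_free)
            if N[i] > 0:
                n_bound[i] = np.random.binomial(N[i], frac[i])
                bound_conc += N[i] * unit * frac[i]
            else:
                n_bound[i] = 0
        # --- record (state at start of step) ---
        if step % record_every == 0 and rec < n_rec:
            rec_t[rec] = step * dt
            phos = 0
            for i in range(n84):
                tot = N[i] + S[i]
                phos += tot * (6 - comp_nst[i])
                for k in range(4):
                    rec_forms[rec, k] += tot * comp_counts[i, k]
            rec_pp[rec] = 100.0 * phos / (6.0 * n_hex)
            for k in range(4):
                rec_forms[rec, k] /= 6.0 * n_hex
            rec_free[rec] = a_free
            rec_bound[rec] = bound_conc
            rec_seq[rec] = seq_a2
            rec_nseq[rec] = S.sum()
            rec_atot[rec] = a_tot
            rec += 1
        if step == n_steps:
            break
        # --- phosphoform transitions (binomial tau-leaping) ---
        for i in range(n84):
            dN[i] = 0
            dS[i] = 0
        for i in range(n84):
            if N[i] > 0:
                nb = n_bound[i]
                nu = N[i] - nb
                rem_b = nb
                rem_u = nu
                for c in range(6):
                    p = rates[c] * dt
                    if p <= 0.0 or count_src[i, c] == 0:
                        continue
                    if chan_bound[c] == 1:
                        if rem_b <= 0:
                            continue
                        ev = np.random.binomial(nb * count_src[i, c], p)
                        if ev > rem_b:
                            ev = rem_b
                        rem_b -= ev
                    else:
                        if rem_u <= 0:
                            continue
                        ev = np.random.binomial(nu * count_src[i, c], p)
                        if ev > rem_u:
                            ev = rem_u
                        rem_u -= ev
                    if ev > 0:
                        dN[i] -= ev
                        dN[target[i, c]] += ev
            if S[i] > 0:
                rem = S[i]
                for c in range(3, 6):
                    p = rates_seq[c] * dt
                    if p <= 0.0 or count_src[i, c] == 0 or rem <= 0:
                        continue
                    ev = np.random.binomial(S[i] * count_src[i, c], p)
                    if ev > rem:
                        ev = rem
                    rem -= ev
                    if ev > 0:
                        dS[i] -= ev
                        dS[target[i, c]] += ev
        for i in range(n84):
            N[i] += dN[i]
            S[i] += dS[i]
            if N[i] < 0 or S[i] < 0:
                status = 1
        # --- KaiB switching and KaiA sequestration ---
        budget = int(free_b / (6.0 * unit) + 1e-9)
        switched = 0
        for i in range(n84):
            if elig[i] == 1 and N[i] > 0 and budget > 0:
                if require_unbound == 1:
                    q = (1.0 - frac[i]) * kb_switch * dt
                else:
                    q = kb_switch * dt
                ev = np.random.binomial(N[i], q)
                if ev > budget:
                    ev = budget
                N[i] -= ev
                S[i] += ev
                budget -= ev
                switched += ev
        if switched > 0:
            free_b -= switched * 6.0 * unit
        # --- release of fully dephosphorylated complexes ---
        m = S[i_all_st]
        if m > 0:
            n_seq = S.sum()
            released = seq_a2 * m / n_seq
            seq_a2 -= released
            free_b += m * 6.0 * unit
            S[i_all_st] = 0
            N[i_all_st] += m
        # --- continuous KaiA absorption by standing complexes (up to g each) ---
        capacity = S.sum() * g_capacity * unit
        if seq_a2 < capacity:
            take = capacity - seq_a2
            avail_now = a_tot - seq_a2
            if take > avail_now:
                take = avail_now
            if take > 0.0:
                seq_a2 += take
        # --- conservation guard ---
        total = 0
        for i in range(n84):
            total += N[i] + S[i]
        if total != n_hex:
            status = 2
        if seq_a2 < -1e-9 or free_b < -1e-9 or free_b > b_tot + 1e-9:
            status = 3
        if status != 0:
            break
    return (
        status,
        rec_t[:rec],
        rec_pp[:rec],
        rec_forms[:rec],
        rec_free[:rec],
        rec_bound[:rec],
        rec_seq[:rec],
        rec_nseq[:rec],
        rec_atot[:rec],
        N,
        S,
    )


def run_simulation(
    params: ModelParams,
    duration_h: float,
    protocol: KaiAProtocol | None = None,
    record_every_h: float = 0.1,
    seed: int | None = None,
) -> Trajectory:
    """Run the stochastic population model and record a trajectory.

    Fixed-step loop (KaiA partition -> phospho transitions -> KaiB switching /
    sequestration / release) starting from an all-S/T active population.
    Deterministic per seed.  ``protocol`` overrides the constant KaiA total
    set by ``params.a2_ratio``.
    """
    if seed is None:
        seed = params.seed
    n_steps = int(round(duration_h / params.dt))
    record_every = max(1, int(round(record_every_h / params.dt)))
    if protocol is None:
        protocol = kaia_protocol("constant", a2_uM=params.a2_uM)
    step_times = np.arange(n_steps) * params.dt
    a_tot_steps = np.asarray(protocol(step_times), dtype=float)
    if a_tot_steps.ndim == 0:
        a_tot_steps = np.full(n_steps, float(a_tot_steps))
    if (a_tot_steps < 0).any():
        raise ValueError("negative KaiA concentration in protocol")
    out = _kernel(
        np.int64(seed % (2**31)),
        n_steps,
        record_every,
        params.dt,
        _COMP_ARRAY[:, 0].copy(),
        _COUNT_SRC,
        _TARGET,
        _CHAN_BOUND,
        _channel_rates(params, "active"),
        _channel_rates(params, "sequestering"),
        params.kd_per_composition(),
        params.eligibility(),
        _ALL_ST_INDEX,
        params.n_hexamers,
        params.conc_per_hexamer,
        a_tot_steps,
        params.b_uM,
        params.kb_switch,
        params.seq_capacity,
        1 if params.require_unbound_switch else 0,
    )
    status = out[0]
    if status != 0:
        reasons = {1: "negative hexamer count", 2: "hexamer count not conserved",
                   3: "KaiA/KaiB pool conservation violated"}
        raise RuntimeError(f"simulation aborted: {reasons.get(status, status)}")
    return Trajectory(
        time_h=out[1],
        percent_p=out[2],
        form_fractions=out[3],
        free_a2=out[4],
        bound_a2=out[5],
        seq_a2=out[6],
        n_sequestering=out[7],
        a2_total=out[8],
        final_active=out[9],
        final_sequestering=out[10],
    )
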