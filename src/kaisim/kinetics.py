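"""Phospho-cycle state definitions and KaiA-KaiC binding kinetics.

KaiC protomers carry two phosphorylation sites (S431, T432) and traverse the
ordered cycle S/T -> S/pT -> pS/pT -> pS/T -> S/T over a circadian day.  The
affinity of the KaiA dimer for a KaiC hexamer depends on where the hexamer's
protomers sit in this cycle: KaiA dwells longest on hypophosphorylated KaiC and
shortest on hyperphosphorylated KaiC (phosphoform-dependent differential
affinity, PDDA).  This module holds the per-form lifetime tables measured by
single-molecule imaging of the phosphomimic mutants, the conversion from mean
bound/unbound lifetimes to rate constants, and the composition-weighted
hexamer-level affinity used by the population model.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "PhosphoForm",
    "CYCLE_ORDER",
    "HexamerComposition",
    "DwellParams",
    "RateConstants",
    "PddaTable",
    "rates_from_dwells",
    "default_pdda_table",
    "hexamer_affinity",
    "read_lifetime_table",
    "write_lifetime_table",
]


class PhosphoForm(enum.Enum):
    """Phosphorylation state of a single KaiC protomer (S431/T432).

    The phosphomimic mutants used to measure per-form binding lifetimes are
    AA (S/T), AE (S/pT), DE (pS/pT) and DA (pS/T).
    """

    ST = "ST"
    SpT = "SpT"
    pSpT = "pSpT"
    pST = "pST"

    @property
    def mimic(self) -> str:
        return _MIMICS[self]

    @property
    def n_phosphosites(self) -> int:
        """Number of phosphorylated sites on this protomer (0, 1 or 2)."""
        return _N_SITES[self]

    @property
    def next_in_cycle(self) -> "PhosphoForm":
        i = CYCLE_ORDER.index(self)
        return CYCLE_ORDER[(i + 1) % 4]


_MIMICS = {
    PhosphoForm.ST: "AA",
    PhosphoForm.SpT: "AE",
    PhosphoForm.pSpT: "DE",
    PhosphoForm.pST: "DA",
}
_N_SITES = {
    PhosphoForm.ST: 0,
    PhosphoForm.SpT: 1,
    PhosphoForm.pSpT: 2,
    PhosphoForm.pST: 1,
}

#: Ordered phospho-cycle: S/T -> S/pT -> pS/pT -> pS/T -> S/T
CYCLE_ORDER = (PhosphoForm.ST, PhosphoForm.SpT, PhosphoForm.pSpT, PhosphoForm.pST)


class HexamerComposition(tuple):
    """Counts ``(n_ST, n_SpT, n_pSpT, n_pST)`` of protomer forms in one hexamer.

    Immutable; the six protomers are exchangeable so only the counts matter.
    """

    __slots__ = ()

    def __new__(cls, n_ST: int, n_SpT: int = 0, n_pSpT: int = 0, n_pST: int = 0):
        counts = (int(n_ST), int(n_SpT), int(n_pSpT), int(n_pST))
        if any(c < 0 for c in counts):
            raise ValueError(f"negative protomer count in {counts}")
        if sum(counts) != 6:
            raise ValueError(f"hexamer composition must sum to 6, got {counts}")
        return super().__new__(cls, counts)

    @property
    def n_ST(self) -> int:
        return self[0]

    @property
    def n_SpT(self) -> int:
        return self[1]

    @property
    def n_pSpT(self) -> int:
        return self[2]

    @property
    def n_pST(self) -> int:
        return self[3]

    @property
    def percent_phosphorylated(self) -> float:
        """Fraction of protomers carrying at least one phosphate, in percent."""
        return 100.0 * (6 - self[0]) / 6.0


@dataclass(frozen=True)
class DwellParams:
    """Measured mean lifetimes of the KaiA-bound and KaiA-unbound states.

    ``kaia_dimer_conc`` is the free KaiA dimer concentration at which
    ``tau_unbound`` was measured; it is needed to convert the unbound lifetime
    into a bimolecular on-rate.
    """

    tau_bound: float  # s
    tau_bound_se: float = 0.0  # s
    tau_unbound: float | None = None  # s
    kaia_dimer_conc: float | None = None  # µM

    def __post_init__(self):
        if not self.tau_bound > 0:
            raise ValueError(f"tau_bound must be positive, got {self.tau_bound}")
        if self.tau_bound_se < 0:
            raise ValueError("tau_bound_se must be non-negative")
        if self.tau_unbound is not None and not self.tau_unbound > 0:
            raise ValueError(f"tau_unbound must be positive, got {self.tau_unbound}")


@dataclass(frozen=True)
class RateConstants:
    """First-order off-rate, bimolecular on-rate and dissociation constant."""

    koff: float  # s^-1
    kon: float  # µM^-1 s^-1
    kd: float  # µM

    def __post_init__(self):
        if not (self.koff > 0 and self.kon > 0 and self.kd > 0):
            raise ValueError("rate constants must be strictly positive")
        if abs(self.kd * self.kon - self.koff) > 1e-12 * self.koff:
            raise ValueError("kd must equal koff/kon")

    @classmethod
    def from_on_off(cls, koff: float, kon: float) -> "RateConstants":
        return cls(koff=koff, kon=kon, kd=koff / kon)


def rates_from_dwells(params: DwellParams) -> RateConstants:
    """Convert mean dwell lifetimes into kinetic rate constants.

    koff = 1/tau_bound, kon = 1/(tau_unbound * [KaiA dimer]), kd = koff/kon.
    Requires the unbound lifetime and the KaiA concentration of the measurement.
    """
    if params.tau_unbound is None:
        raise ValueError("unbound lifetime unavailable")
    if params.kaia_dimer_conc is None or not params.kaia_dimer_conc > 0:
        raise ValueError("KaiA dimer concentration must be positive")
    koff = 1.0 / params.tau_bound
    kon = 1.0 / (params.tau_unbound * params.kaia_dimer_conc)
    return RateConstants.from_on_off(koff=koff, kon=kon)


@dataclass(frozen=True)
class PddaTable:
    """Per-phosphoform dwell parameters plus the PDDA on/off switch.

    With ``pdda_enabled`` the hexamer-level affinity is the composition-weighted
    mean of the per-form rates; with it off every composition gets the same
    fixed rates (the plain average of the four forms), so that +/-PDDA
    comparisons share the same mean affinity.
    """

    params: Mapping[PhosphoForm, DwellParams]
    pdda_enabled: bool = True
    mixing: str = "arithmetic"  # or "geometric"

    def __post_init__(self):
        missing = [f for f in PhosphoForm if f not in self.params]
        if missing:
            raise ValueError(f"PddaTable missing forms: {missing}")
        if self.mixing not in ("arithmetic", "geometric"):
            raise ValueError(f"unknown mixing rule {self.mixing!r}")

    def __getitem__(self, form: PhosphoForm) -> DwellParams:
        return self.params[form]

    def form_rates(self, form: PhosphoForm) -> RateConstants:
        return rates_from_dwells(self.params[form])

    def fixed_rates(self) -> RateConstants:
        """Composition-independent rates used when PDDA is disabled.

        Defined as the per-form average of koff and kon (the hexamer-level
        affinity of the all-forms-equal composition under arithmetic mixing).
        """
        rates = [self.form_rates(f) for f in CYCLE_ORDER]
        koff = sum(r.koff for r in rates) / 4.0
        kon = sum(r.kon for r in rates) / 4.0
        return RateConstants.from_on_off(koff=koff, kon=kon)

    def with_pdda(self, enabled: bool) -> "PddaTable":
        return PddaTable(params=self.params, pdda_enabled=enabled, mixing=self.mixing)


#: Fig-derived defaults (seconds): bound lifetimes of the phosphomimics and the
#: unbound-lifetime endpoints of hypo-/hyper-phosphorylated native KaiC.
TAU_BOUND_MIMIC = {
    PhosphoForm.SpT: (1.00, 0.15),  # AE
    PhosphoForm.pSpT: (0.26, 0.05),  # DE
    PhosphoForm.pST: (0.43, 0.14),  # DA
}
TAU_UNBOUND_HYPO = 5.47  # s, 27%-phosphorylated native KaiC
TAU_UNBOUND_HYPER = 7.90  # s, 81%-phosphorylated native KaiC
KAIA_CONC_WT = 0.4  # µM KaiA dimer in the native-KaiC lifetime measurements


def default_pdda_table(
    tau_bound_aa: float = 3.0,
    kaia_dimer_conc: float = KAIA_CONC_WT,
    pdda_enabled: bool = True,
    mixing: str = "arithmetic",
) -> PddaTable:
    """Default lifetime table from the phosphomimic measurements.

    The S/T (AA) bound lifetime was too slow to determine experimentally; it is
    represented by a configurable conservative placeholder (default 3.0 s).
    Per-form unbound lifetimes are linearly interpolated in the number of
    phosphorylated sites per protomer (0, 1, 2) between the hypo- and
    hyper-phosphorylated native-KaiC endpoints (5.47 s and 7.90 s).
    """
    if not tau_bound_aa > 0:
        raise ValueError("tau_bound_aa must be positive")
    params: dict[PhosphoForm, DwellParams] = {}
    for form in CYCLE_ORDER:
        if form is PhosphoForm.ST:
            tau_b, se = tau_bound_aa, 0.0
        else:
            tau_b, se = TAU_BOUND_MIMIC[form]
        frac = form.n_phosphosites / 2.0
        tau_u = TAU_UNBOUND_HYPO + frac * (TAU_UNBOUND_HYPER - TAU_UNBOUND_HYPO)
        params[form] = DwellParams(
            tau_bound=tau_b,
            tau_bound_se=se,
            tau_unbound=tau_u,
            kaia_dimer_conc=kaia_dimer_conc,
        )
    return PddaTable(params=params, pdda_enabled=pdda_enabled, mixing=mixing)


def hexamer_affinity(comp: HexamerComposition, table: PddaTable) -> RateConstants:
    """Hexamer-level KaiA binding rates for a given protomer composition.

    With PDDA enabled the per-form rates are mixed with composition weights
    n_f/6 (arithmetic mean by default; rates, not energies, add for independent
    tentacle contacts).  With PDDA disabled the same fixed rates are returned
    for every composition.
    """
    comp = HexamerComposition(*comp)
    if not table.pdda_enabled:
        return table.fixed_rates()
    weights = [c / 6.0 for c in comp]
    rates = [table.form_rates(f) for f in CYCLE_ORDER]
    if table.mixing == "arithmetic":
        koff = sum(w * r.koff for w, r in zip(weights, rates))
        kon = sum(w * r.kon for w, r in zip(weights, rates))
    else:  # geometric
        koff = math.exp(sum(w * math.log(r.koff) for w, r in zip(weights, rates)))
        kon = math.exp(sum(w * math.log(r.kon) for w, r in zip(weights, rates)))
    return RateConstants.from_on_off(koff=koff, kon=kon)


_TSV_COLUMNS = ["form", "tau_bound_s", "tau_bound_se_s", "tau_unbound_s", "kaia_conc_uM"]


def write_lifetime_table(table: PddaTable, path: str | Path) -> None:
    """Write the per-form lifetime table as TSV."""
    rows = []
    for form in CYCLE_ORDER:
        p = table[form]
        rows.append(
            {
                "form": form.value,
                "tau_bound_s": p.tau_bound,
                "tau_bound_se_s": p.tau_bound_se,
                "tau_unbound_s": p.tau_unbound,
                "kaia_conc_uM": p.kaia_dimer_conc,
            }
        )
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_lifetime_table(path: str | Path, pdda_enabled: bool = True) -> PddaTable:
    """Read a per-form lifetime table written by :func:`write_lifetime_table`."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"lifetime table missing columns: {sorted(missing)}")
    params = {}
    for _, row in df.iterrows():
        form = PhosphoForm(row["form"])
        tau_u = row["tau_unbound_s"]
        params[form] = DwellParams(
            tau_bound=float(row["tau_bound_s"]),
            tau_bound_se=float(row["tau_bound_se_s"]),
            tau_unbound=None if pd.isna(tau_u) else float(tau_u),
            kaia_dimer_conc=float(row["kaia_conc_uM"]),
        )
    return PddaTable(params=params, pdda_enabled=pdda_enabled)
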