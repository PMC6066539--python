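"""Chlorophyll-fluorescence / gas-exchange parameter derivation and
physiological memory classification.

Fluorescence yields follow the standard Genty-style definitions:
phiPSII = (Fm' - Fs)/Fm' (PSII operating efficiency), Fv'/Fm' =
(Fm' - Fo')/Fm' (efficiency were all centres open), qP = (Fm' - Fs)/
(Fm' - Fo') (fraction of open centres), so phiPSII = qP x Fv'/Fm'
identically.  When the light-adapted minimal fluorescence Fo' is not
measured it is estimated as Fo / (Fv/Fm + Fo/Fm') (Oxborough-Baker).
ETR = phiPSII x PPFD x psii_fraction x absorptance; NPQ = Fm/Fm' - 1.
Energy-dependent quenching qE is isolated from NPQ via the maximal
fluorescence after relaxation of the rapidly reversible component
(relaxed Fm'): qE = Fm/Fm' - Fm/Fm'_relaxed and its quantum-yield form
phi_qE = Fs/Fm' - Fs/Fm'_relaxed; absent a relaxation measurement all
NPQ is attributed to qE (flagged).

Gas exchange: gross assimilation A_G = P_N + R_d; phiCO2 = A_G /
(PPFD x absorptance).  Total chlorophyll (mg per g dry weight) from
80%-acetone extract absorbances: (8.02 x A663 + 20.2 x A645) / DW.

A parameter's memory pattern uses the same two-position sign scheme as
genes: first sign from S1 vs W, second from S2 vs S1, each a two-sided
two-sample t test (Welch by default) at alpha_phys with the sign of the
mean difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .io import PhysiologyTable
from .memory import PATTERN_CATEGORY, pattern_label

__all__ = [
    "FluorescenceReading",
    "GasExchangeReading",
    "derive_fluorescence",
    "qe_partition",
    "chlorophyll_concentration",
    "derive_table",
    "classify_physiology_memory",
    "classify_all_physiology",
    "PhysiologyMemoryCall",
]


@dataclass(frozen=True)
class FluorescenceReading:
    """One PAM fluorescence record (arbitrary units) at light level PPFD."""

    Fs: float
    Fm_prime: float
    Fo: float
    Fm: float
    PPFD: float
    Fo_prime: float | None = None

    def __post_init__(self) -> None:
        pairs = [
            ("Fs", self.Fs, "Fm_prime", self.Fm_prime),
            ("Fm_prime", self.Fm_prime, "Fm", self.Fm),
            ("Fo", self.Fo, "Fs", self.Fs),
        ]
        if self.Fs <= 0:
            raise ValueError("Fs must be positive")
        for lo_name, lo, hi_name, hi in pairs:
            if lo > hi:
                raise ValueError(f"ordering violated: {lo_name} > {hi_name}")
        if self.Fo_prime is not None and self.Fo_prime > self.Fs:
            raise ValueError("ordering violated: Fo_prime > Fs")

    def estimated_fo_prime(self) -> float:
        """Measured Fo' when present, else the Oxborough-Baker estimate."""
        if self.Fo_prime is not None:
            return self.Fo_prime
        fv_fm = (self.Fm - self.Fo) / self.Fm
        return self.Fo / (fv_fm + self.Fo / self.Fm_prime)


@dataclass(frozen=True)
class GasExchangeReading:
    """Simultaneous infrared gas-analyser record."""

    P_N: float
    g_s: float
    E: float
    C_i: float
    R_d: float = 0.0

    def __post_init__(self) -> None:
        if self.g_s < 0 or self.E < 0:
            raise ValueError("g_s and E must be non-negative")
        if self.R_d < 0:
            raise ValueError("R_d must be non-negative")


def derive_fluorescence(
    reading: FluorescenceReading,
    gas: GasExchangeReading,
    config: RunConfig | None = None,
    relaxed_fm_prime: float | None = None,
) -> dict[str, float]:
    """All derived photosynthetic parameters for one plant x stage record.

    Returns a dict with keys phiPSII, FvFm_prime, qP, ETR, NPQ, A_G,
    phiCO2, phiPSII/phiCO2, ETR/A_G, and (qE, phi_qE, qE/ETR,
    qe_from_relaxation) — the last flag is False when no relaxed Fm' was
    supplied and qE defaults to the whole of NPQ.
    """
    config = config or RunConfig()
    f = reading
    fo_prime = f.estimated_fo_prime()
    if f.Fm_prime - fo_prime <= 0:
        raise ValueError("Fm_prime - Fo_prime must be positive")
    phi_psii = (f.Fm_prime - f.Fs) / f.Fm_prime
    fv_fm_prime = (f.Fm_prime - fo_prime) / f.Fm_prime
    qp = (f.Fm_prime - f.Fs) / (f.Fm_prime - fo_prime)
    etr = phi_psii * f.PPFD * config.psii_fraction * config.absorptance
    npq = f.Fm / f.Fm_prime - 1.0
    a_g = gas.P_N + gas.R_d
    phi_co2 = a_g / (f.PPFD * config.absorptance)
    qe, phi_qe = qe_partition(f, relaxed_fm_prime)
    out = {
        "phiPSII": phi_psii,
        "FvFm_prime": fv_fm_prime,
        "qP": qp,
        "ETR": etr,
        "NPQ": npq,
        "A_G": a_g,
        "phiCO2": phi_co2,
        "qE": qe,
        "phi_qE": phi_qe,
        "qe_from_relaxation": relaxed_fm_prime is not None,
        "P_N": gas.P_N,
        "g_s": gas.g_s,
        "E": gas.E,
        "C_i": gas.C_i,
    }
    out["qE/ETR"] = qe / etr if etr != 0 else math.nan
    out["phiPSII/phiCO2"] = phi_psii / phi_co2 if phi_co2 != 0 else math.nan
    out["ETR/A_G"] = etr / a_g if a_g != 0 else math.nan
    return out


def qe_partition(
    reading: FluorescenceReading, relaxed_fm_prime: float | None = None
) -> tuple[float, float]:
    """Energy-dependent quenching (qE, phi_qE) from a relaxation record.

    ``relaxed_fm_prime`` is the maximal fluorescence after the rapidly
    reversible quenching has relaxed; it must lie in [Fm', Fm].  When
    absent it defaults to Fm, i.e. all NPQ is attributed to qE.
    """
    f = reading
    if relaxed_fm_prime is None:
        relaxed_fm_prime = f.Fm
    if relaxed_fm_prime < f.Fm_prime:
        raise ValueError("relaxed Fm' below Fm'")
    if relaxed_fm_prime > f.Fm:
        raise ValueError("relaxed Fm' above Fm")
    qe = f.Fm / f.Fm_prime - f.Fm / relaxed_fm_prime
    phi_qe = f.Fs / f.Fm_prime - f.Fs / relaxed_fm_prime
    return qe, phi_qe


def chlorophyll_concentration(A663: float, A645: float, DW: float) -> float:
    """Total chlorophyll, mg per g dry weight, from 663/645 nm absorbances."""
    if DW <= 0:
        raise ValueError("DW must be positive")
    if A663 < 0 or A645 < 0:
        raise ValueError("absorbances must be non-negative")
    return (8.02 * A663 + 20.2 * A645) / DW


def derive_table(
    raw: pd.DataFrame, config: RunConfig | None = None
) -> PhysiologyTable:
    """Derive a long-format physiology table from raw instrument rows.

    ``raw`` needs one row per plant x stage with columns plant_id,
    stage, Fs, Fm_prime, Fo, Fm, PPFD, P_N, g_s, E, C_i and optionally
    Fo_prime, Fm_relaxed and R_d.
    """
    config = config or RunConfig()
    records = []
    for _, row in raw.iterrows():
        reading = FluorescenceReading(
            Fs=row["Fs"], Fm_prime=row["Fm_prime"], Fo=row["Fo"],
            Fm=row["Fm"], PPFD=row["PPFD"],
            Fo_prime=row.get("Fo_prime"),
        )
        gas = GasExchangeReading(
            P_N=row["P_N"], g_s=row["g_s"], E=row["E"], C_i=row["C_i"],
            R_d=float(row.get("R_d", 0.0) or 0.0),
        )
        derived = derive_fluorescence(
            reading, gas, config, relaxed_fm_prime=row.get("Fm_relaxed")
        )
        derived.pop("qe_from_relaxation")
        for name, value in derived.items():
            records.append(
                {"plant_id": row["plant_id"], "stage": row["stage"],
                 "parameter": name, "value": value}
            )
    return PhysiologyTable(pd.DataFrame(records))


def _two_sample_t(x: np.ndarray, y: np.ndarray, welch: bool = True):
    """Two-sided two-sample t, stable in the zero-variance limit."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 observations per group")
    d = x.mean() - y.mean()
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        if d == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, d), 0.0
    if welch:
        res = stats.ttest_ind(x, y, equal_var=False)
    else:
        res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class PhysiologyMemoryCall:
    parameter: str
    first_sign: str
    second_sign: str
    pattern: str
    category: str
    t_first: float
    p_first: float
    t_second: float
    p_second: float


def classify_physiology_memory(
    table: PhysiologyTable,
    parameter: str,
    config: RunConfig | None = None,
    welch: bool = True,
) -> PhysiologyMemoryCall:
    """Memory pattern of one physiological parameter.

    First sign: S1 vs W; second sign: S2 vs S1; each significant at
    alpha_phys under a two-sided t test with the sign of the mean
    difference.  The rehydration stage (R1) does not enter the pattern.
    """
    config = config or RunConfig()
    groups = {}
    for stage in ("W", "S1", "S2"):
        v = table.values_for(parameter, stage)
        if len(v) < 2:
            raise ValueError(
                f"parameter {parameter!r}: need >= 2 plants at stage {stage!r}"
            )
        groups[stage] = v

    def contrast(treat: str, base: str):
        t, p = _two_sample_t(groups[treat], groups[base], welch)
        if p <= config.alpha_phys:
            sign = "+" if groups[treat].mean() > groups[base].mean() else "-"
        else:
            sign = "="
        return sign, t, p

    s1, t1, p1 = contrast("S1", "W")
    s2, t2, p2 = contrast("S2", "S1")
    pat = pattern_label(s1, s2)
    return PhysiologyMemoryCall(
        parameter, s1, s2, pat, PATTERN_CATEGORY[pat], t1, p1, t2, p2
    )


def classify_all_physiology(
    table: PhysiologyTable, config: RunConfig | None = None, welch: bool = True
) -> pd.DataFrame:
    """Memory calls for every parameter in a physiology table."""
    rows = [
        classify_physiology_memory(table, p, config, welch)
        for p in table.parameters
    ]
    return pd.DataFrame(
        [
            {
                "parameter": c.parameter,
                "first_sign": c.first_sign,
                "second_sign": c.second_sign,
                "pattern": c.pattern,
                "category": c.category,
                "t_first": c.t_first,
                "p_first": c.p_first,
                "t_second": c.t_second,
                "p_second": c.p_second,
            }
            for c in rows
        ]
    ).set_index("parameter")
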