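"""Potential methane production rates (PMPRs) from anaerobic vial incubations.

A soil slurry is incubated anaerobically in a sealed serum vial and the
headspace CH4 mixing ratio is measured at two time points.  The production
rate per gram of dry soil follows from the ideal gas law: the headspace
holds ``n = PA * VH / (R * T)`` moles of gas, so a mixing-ratio change
``dc/dt`` corresponds to ``dc/dt * n`` moles of CH4 per day, converted to
mass with the molar mass of CH4 and normalized by soil dry weight:

    PMPR = (dc/dt) * MM * (VH * PA) / (R * (T_ST + T)) / Ws

with PMPR in ng CH4 g^-1 (dry weight) day^-1, ``dc/dt`` in mmol mol^-1
day^-1 (or ppm day^-1, see ``units``), ``VH`` in litres, ``PA`` in kPa,
``T`` the incubation temperature in deg C and ``T_ST`` = 273.15 K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "IncubationRecord",
    "FluxResult",
    "compute_pmpr",
    "batch_pmpr",
    "read_incubation_csv",
    "write_incubation_csv",
]

#: scale from one mixing-ratio unit to mol CH4 per mol of headspace gas
_UNIT_SCALE = {"mmol-per-mol": 1e-3, "ppm": 1e-6}

NG_PER_G = 1e9


@dataclass(frozen=True)
class IncubationRecord:
    """Physical measurements of one incubation vial.

    ``c_t0``/``c_t1`` are headspace CH4 mixing ratios at incubation days
    ``t0``/``t1`` in the unit named by ``units``.  ``is_control`` marks the
    N2-only blank vial used for blank subtraction.
    """

    sample_id: str
    c_t0: float
    c_t1: float
    t0: float
    t1: float
    vh: float          # headspace volume, L
    pa: float          # atmospheric pressure, kPa
    ws: float          # soil dry weight, g
    temp_c: float      # incubation temperature, deg C
    units: Literal["mmol-per-mol", "ppm"] = "mmol-per-mol"
    is_control: bool = False
    mm: float = 16.04          # molar mass of CH4, g mol^-1
    t_st: float = 273.15       # standard temperature, K
    r_gas: float = 8.314       # gas constant, J mol^-1 K^-1

    def validate(self) -> None:
        for name in ("c_t0", "c_t1", "t0", "t1", "vh", "pa", "ws", "temp_c"):
            v = getattr(self, name)
            if not math.isfinite(float(v)):
                raise ValueError(f"{self.sample_id}: field {name!r} is not finite")
        if self.t1 <= self.t0:
            raise ValueError(f"{self.sample_id}: t1 must exceed t0 (t0={self.t0}, t1={self.t1})")
        if self.vh <= 0:
            raise ValueError(f"{self.sample_id}: vh must be > 0")
        if self.pa <= 0:
            raise ValueError(f"{self.sample_id}: pa must be > 0")
        if self.ws <= 0:
            raise ValueError(f"{self.sample_id}: ws must be > 0")
        if self.temp_c <= -273.15:
            raise ValueError(f"{self.sample_id}: temp_c below absolute zero")
        if self.c_t0 < 0 or self.c_t1 < 0:
            raise ValueError(f"{self.sample_id}: mixing ratios must be nonnegative")
        if self.units not in _UNIT_SCALE:
            raise ValueError(f"{self.sample_id}: unknown units {self.units!r}")


@dataclass(frozen=True)
class FluxResult:
    sample_id: str
    pmpr: float        # ng CH4 g^-1 dry soil day^-1
    dc_dt: float       # mixing-ratio change per day, in the record's units
    is_control: bool = False


def compute_pmpr(record: IncubationRecord) -> FluxResult:
    """CH4 production rate of one vial, ng CH4 g^-1 dry soil day^-1."""
    record.validate()
    dc_dt = (record.c_t1 - record.c_t0) / (record.t1 - record.t0)
    # moles of headspace gas at incubation temperature (PA kPa -> Pa, VH L -> m3)
    n_gas = (record.pa * 1e3) * (record.vh * 1e-3) / (record.r_gas * (record.t_st + record.temp_c))
    mol_ch4_per_day = dc_dt * _UNIT_SCALE[record.units] * n_gas
    pmpr = mol_ch4_per_day * record.mm * NG_PER_G / record.ws
    return FluxResult(record.sample_id, pmpr, dc_dt, record.is_control)


def invert_dc_dt(pmpr: float, record: IncubationRecord) -> float:
    """Mixing-ratio change per day producing ``pmpr`` in ``record``'s vial.

    Exact algebraic inverse of :func:`compute_pmpr`; used by the synthetic
    generator to back-compute incubation records from target rates.
    """
    n_gas = (record.pa * 1e3) * (record.vh * 1e-3) / (record.r_gas * (record.t_st + record.temp_c))
    return pmpr * record.ws / (record.mm * NG_PER_G * _UNIT_SCALE[record.units] * n_gas)


def batch_pmpr(
    records: Iterable[IncubationRecord],
    blank_subtract: bool | Literal["auto"] = "auto",
) -> pd.DataFrame:
    """Sample-level PMPRs from replicate vials.

    Replicates share a ``sample_id``; the sample rate is the mean of the
    replicate fluxes, minus the blank-control flux when a control vial is
    present (``blank_subtract='auto'``, the default) or always/never for
    True/False.  Returns a frame indexed by sample_id with columns
    ``pmpr``, ``n_replicates``, ``cv`` (replicate coefficient of variation)
    and ``blank``.
    """
    by_sample: dict[str, list[FluxResult]] = {}
    for rec in records:
        by_sample.setdefault(rec.sample_id, []).append(compute_pmpr(rec))

    rows = []
    for sample_id, results in by_sample.items():
        reps = [r.pmpr for r in results if not r.is_control]
        blanks = [r.pmpr for r in results if r.is_control]
        if not reps:
            continue  # a sample with only control vials carries no signal
        blank = float(np.mean(blanks)) if blanks else 0.0
        subtract = bool(blanks) if blank_subtract == "auto" else bool(blank_subtract)
        mean = float(np.mean(reps))
        pmpr = mean - blank if subtract else mean
        sd = float(np.std(reps, ddof=1)) if len(reps) > 1 else 0.0
        cv = sd / abs(mean) if mean != 0 else np.nan
        rows.append(
            {"sample_id": sample_id, "pmpr": pmpr, "n_replicates": len(reps),
             "cv": cv, "blank": blank if subtract else 0.0}
        )
    return pd.DataFrame(rows).set_index("sample_id")


_CSV_COLUMNS = [
    "sample_id", "c_t0", "c_t1", "t0", "t1", "vh", "pa", "ws", "temp_c",
    "units", "is_control",
]


def write_incubation_csv(records: Iterable[IncubationRecord], path) -> None:
    df = pd.DataFrame([{c: getattr(r, c) for c in _CSV_COLUMNS} for r in records])
    df.to_csv(path, index=False)


def read_incubation_csv(path) -> list[IncubationRecord]:
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing incubation columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            IncubationRecord(
                sample_id=str(row.sample_id), c_t0=float(row.c_t0), c_t1=float(row.c_t1),
                t0=float(row.t0), t1=float(row.t1), vh=float(row.vh), pa=float(row.pa),
                ws=float(row.ws), temp_c=float(row.temp_c), units=str(row.units),
                is_control=bool(row.is_control),
            )
        )
    return records
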