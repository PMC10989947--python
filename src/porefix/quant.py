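"""Quantitative formulas: RPKM, gas-series slope fitting, static-chamber flux.

RPKM_g = mapped_reads_g / ((gene_length_g / 1000) * (total_mapped / 1e6)).

Static-chamber flux: R_gas = (dC/dt) * P * V / (R * T * A) with the slope in
ppm/h (ppm = umol/mol), P in atm, V in L, R = 0.0821 L atm K^-1 mol^-1, T in
K and A either the chamber footprint in m^2 (field mode) or the incubated
soil mass in kg (incubation mode). Because ppm is umol/mol, the ideal-gas
term P*V/(R*T) converts the slope directly to umol per A-unit per hour with
no further constants. A positive rate is emission, a negative rate is
consumption by the soil.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .errors import InputError

GAS_CONSTANT = 0.0821  # L atm K^-1 mol^-1


@dataclass
class GasSeries:
    """Timed gas concentrations plus chamber parameters."""

    times: list[float]  # hours, strictly increasing
    concentrations: list[float]  # ppm
    P: float = 1.0  # atm
    V: float = 10.0  # L
    T: float = 288.0  # K
    A: float = 0.1  # m^2 (area mode) or kg (mass mode)
    mode: str = "area"  # 'area' | 'mass'

    def __post_init__(self) -> None:
        if len(self.times) != len(self.concentrations):
            raise InputError("times and concentrations must have equal length")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise InputError("times must be strictly increasing")
        if min(self.P, self.V, self.T, self.A) <= 0:
            raise InputError("P, V, T and A must all be positive")
        if self.mode not in ("area", "mass"):
            raise InputError("mode must be 'area' or 'mass'")


@dataclass
class FluxResult:
    slope: float  # ppm/h
    slope_se: float | None  # standard error; None with only 2 points
    rate: float  # umol m^-2 h^-1 (area) or umol kg^-1 h^-1 (mass)
    direction: str  # 'emission' | 'consumption' | 'none'
    mode: str = "area"


def compute_rpkm(
    table: pd.DataFrame, total_mapped: int | None = None
) -> pd.Series:
    """RPKM per gene from a counts table.

    ``table`` needs columns gene_id, mapped_reads, gene_length.
    ``total_mapped`` defaults to the sum of mapped_reads (it may be larger,
    e.g. when the table is a subset of the library).
    """
    required = {"gene_id", "mapped_reads", "gene_length"}
    if not required.issubset(table.columns):
        raise InputError(f"counts table needs columns {sorted(required)}")
    if (table["gene_length"] < 1).any():
        raise InputError("gene_length must be >= 1")
    if (table["mapped_reads"] < 0).any():
        raise InputError("mapped_reads must be non-negative")
    if total_mapped is None:
        total_mapped = int(table["mapped_reads"].sum())
    if total_mapped <= 0:
        raise InputError("total_mapped must be positive")
    if total_mapped < table["mapped_reads"].max():
        raise InputError("total_mapped smaller than a per-gene count")
    rpkm = table["mapped_reads"] / (
        (table["gene_length"] / 1000.0) * (total_mapped / 1e6)
    )
    return pd.Series(rpkm.values, index=table["gene_id"], name="rpkm")


def fit_slope(series: GasSeries) -> tuple[float, float | None]:
    """Ordinary least-squares slope (ppm/h) with residual standard error.

    With exactly two points the slope is the finite difference and the
    standard error is undefined (returned as None).
    """
    if len(series.times) < 2:
        raise InputError("need at least two points to fit a slope")
    res = stats.linregress(series.times, series.concentrations)
    se = None if len(series.times) == 2 else float(res.stderr)
    return float(res.slope), se


def gas_flux(
    slope: float,
    P: float,
    V: float,
    T: float,
    A: float,
    R: float = GAS_CONSTANT,
    mode: str = "area",
    slope_se: float | None = None,
) -> FluxResult:
    """Static-chamber (or incubation-bottle) gas exchange rate."""
    if min(P, V, T, A, R) <= 0:
        raise InputError("P, V, T, A and R must all be positive")
    rate = slope * P * V / (R * T * A)
    if rate > 0:
        direction = "emission"
    elif rate < 0:
        direction = "consumption"
    else:
        direction = "none"
    return FluxResult(slope=slope, slope_se=slope_se, rate=rate, direction=direction, mode=mode)


def series_flux(series: GasSeries) -> FluxResult:
    """Fit the slope of a series and convert it to a flux in one step."""
    slope, se = fit_slope(series)
    res = gas_flux(slope, series.P, series.V, series.T, series.A, mode=series.mode)
    res.slope_se = se
    return res
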