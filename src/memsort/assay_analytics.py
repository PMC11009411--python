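"""Liposome and cell-free assay statistics.

Implements the arithmetic behind the wet-lab readouts of hydrophobic
mismatch experiments:

* GFP folding kinetics: the 0 -> 3 h fluorescence increase, normalised per
  construct by its maximum across membrane conditions;
* calcein leakage: percent release relative to detergent lysis,
  ``100 * (I_3h - I_0) / (I_triton - I_0)``, optionally per unit expressed
  protein (western-blot band intensity);
* inter-vesicle sorting by flow cytometry: the thick/thin enrichment ratio
  from population MFIs, and from percent-AF488-positive fractions after
  rectangular single-dye gating with background subtraction;
* lipid-protein FRET: ``C_D/C_H = ln(F/F_o)_D / ln(F/F_o)_H`` (donor
  quenching in domain-forming vs homogeneous membranes) and its total change
  over a 20 -> 45 °C ramp;
* split-luciferase: rapamycin-induced luminescence (+Rap / -Rap) and
  relative hetero-pair assembly
  ``Lum(20-50) / (0.5 * (Lum(20-20) + Lum(50-50)))`` with optional
  room-temperature normalisation;
* the linear expression-vs-compression fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KineticsTrace",
    "CalceinAssay",
    "FretSample",
    "LuminescenceSet",
    "GateThresholds",
    "LinearFit",
    "gfp_increase",
    "normalize_by_max",
    "calcein_release",
    "enrichment_mfi",
    "gate_single_dye",
    "enrichment_positive",
    "fret_cdch",
    "delta_cdch",
    "rapamycin_induced",
    "relative_nanobit",
    "correlate_expression_compression",
]


@dataclass
class KineticsTrace:
    """One well's fluorescence/luminescence time course (time in hours)."""

    time_h: np.ndarray
    signal: np.ndarray
    well: str = ""
    construct: str = ""
    membrane: str = ""

    def __post_init__(self):
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_h.shape != self.signal.shape:
            raise ValueError("time_h and signal must have equal length")
        if not np.all(np.diff(self.time_h) > 0):
            raise ValueError("times must be strictly increasing")
        if (self.signal < 0).any():
            raise ValueError("signal must be non-negative")


@dataclass(frozen=True)
class CalceinAssay:
    """Calcein endpoint intensities; ``band_intensity`` is optional densitometry."""

    I_t0: float
    I_t3: float
    I_triton: float
    band_intensity: Optional[float] = None

    def __post_init__(self):
        if self.I_triton < self.I_t0:
            raise ValueError("I_triton must be >= I_t0 for a valid assay")


@dataclass(frozen=True)
class FretSample:
    """Donor intensity with acceptor (F) and after trypsin/Triton (F_o)."""

    F: float
    F_o: float
    condition: str          # "D" domain-forming, "H" homogeneous
    temperature_C: float

    def __post_init__(self):
        if self.F <= 0 or self.F_o <= 0:
            raise ValueError("intensities must be positive")

    @property
    def quench_ratio(self) -> float:
        return self.F / self.F_o


@dataclass(frozen=True)
class LuminescenceSet:
    """Split-luciferase luminescence readings at one temperature."""

    lum_plus_rap: Optional[float] = None
    lum_minus_rap: Optional[float] = None
    lum_20_50: Optional[float] = None
    lum_20_20: Optional[float] = None
    lum_50_50: Optional[float] = None
    temperature_C: float = 22.0


@dataclass(frozen=True)
class GateThresholds:
    """Rectangular gate thresholds for the three flow channels."""

    rhodamine: float
    cy55: float
    af488: float


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    pearson_r: float
    r_squared: float


def _nearest(times: np.ndarray, target: float, tol: float) -> int:
    idx = int(np.argmin(np.abs(times - target)))
    if abs(times[idx] - target) > tol:
        raise ValueError(f"no sample within {tol} of t = {target}")
    return idx


def gfp_increase(trace: KineticsTrace, t_start: float = 0.0, t_end: float = 3.0,
                 tol_h: float = 5.0 / 60.0) -> float:
    """Fluorescence at 3 h minus fluorescence at t = 0 (nearest sample within 5 min)."""
    i0 = _nearest(trace.time_h, t_start, tol_h)
    i1 = _nearest(trace.time_h, t_end, tol_h)
    return float(trace.signal[i1] - trace.signal[i0])


def normalize_by_max(df: pd.DataFrame, value_col: str = "delta_f",
                     group_col: str = "construct") -> pd.DataFrame:
    """Divide each construct's values by that construct's maximum.

    Groups are normalised independently, so the maximum in every group maps
    to 1 and within-group ratios are preserved.
    """
    if df.empty:
        raise ValueError("empty table")
    out = df.copy()
    maxima = out.groupby(group_col)[value_col].transform("max")
    if (maxima <= 0).any():
        bad = out.loc[maxima <= 0, group_col].unique()
        raise ValueError(f"non-positive group maximum for {list(bad)}")
    out["normalized"] = out[value_col] / maxima
    return out


def calcein_release(assay: CalceinAssay, per_protein: bool = False) -> float:
    """Percent calcein release; optionally per unit western-blot band intensity."""
    denom = assay.I_triton - assay.I_t0
    if denom == 0:
        raise ZeroDivisionError("I_triton equals I_t0; release undefined")
    pct = 100.0 * (assay.I_t3 - assay.I_t0) / denom
    if per_protein:
        if assay.band_intensity is None or assay.band_intensity <= 0:
            raise ValueError("per-protein release requires a positive band_intensity")
        pct = pct / assay.band_intensity
    return float(pct)


def enrichment_mfi(mfi_rhodamine_22_1: float, mfi_cy55_14_1: float) -> float:
    """Thick-membrane enrichment: MFI(Rhodamine, 22:1 PC) / MFI(Cy5.5, 14:1 PC)."""
    if mfi_cy55_14_1 <= 0:
        raise ZeroDivisionError("denominator MFI must be positive")
    return float(mfi_rhodamine_22_1 / mfi_cy55_14_1)


def enrichment_positive(pct_af488_thick: float, pct_af488_thin: float) -> float:
    """Percent-positive enrichment: AF488+ fraction of thick over thin vesicles."""
    if pct_af488_thin <= 0:
        raise ZeroDivisionError("denominator percent-positive must be positive")
    return float(pct_af488_thick / pct_af488_thin)


def classify_events(events: pd.DataFrame, thresholds: GateThresholds) -> pd.Series:
    """Rectangular-threshold classification into single-dye populations.

    Returns one of ``rhodamine_only``, ``cy55_only``, ``double``, ``neither``
    per event.
    """
    rhod = events["rhodamine"].to_numpy() > thresholds.rhodamine
    cy = events["cy55"].to_numpy() > thresholds.cy55
    out = np.where(rhod & ~cy, "rhodamine_only",
                   np.where(cy & ~rhod, "cy55_only",
                            np.where(rhod & cy, "double", "neither")))
    return pd.Series(out, index=events.index, name="population")


def _population_stats(events: pd.DataFrame, pop: pd.Series, thresholds: GateThresholds,
                      mfi: str) -> pd.DataFrame:
    rows = []
    for name in ("rhodamine_only", "cy55_only"):
        sub = events[pop == name]
        if sub.empty:
            raise ValueError(f"population {name!r} is empty after gating")
        positive = sub["af488"].to_numpy() > thresholds.af488
        vals = sub.loc[positive, "af488"].to_numpy()
        if vals.size == 0:
            m = 0.0
        elif mfi == "geometric":
            m = float(np.exp(np.log(vals).mean()))
        else:
            m = float(vals.mean())
        rows.append({"population": name, "n": len(sub),
                     "pct_positive": 100.0 * positive.mean(), "mfi_af488": m})
    return pd.DataFrame(rows).set_index("population")


def gate_single_dye(events: pd.DataFrame, thresholds: GateThresholds,
                    background: Optional[pd.DataFrame] = None,
                    mfi: str = "arithmetic") -> pd.DataFrame:
    """Single-dye gating with AF488 statistics and background subtraction.

    Events are classified by rectangular thresholds on the rhodamine and
    Cy5.5 channels; the AF488-positive fraction and AF488 MFI are reported
    per single-dye population.  When a protein-free ``background`` sample is
    supplied, its corresponding statistics are subtracted, floored at zero
    (a ``floored`` flag marks populations whose subtraction went negative).
    """
    if mfi not in ("arithmetic", "geometric"):
        raise ValueError("mfi must be 'arithmetic' or 'geometric'")
    for col in ("rhodamine", "cy55", "af488"):
        if col not in events.columns:
            raise ValueError(f"events table lacks column {col!r}")
    pop = classify_events(events, thresholds)
    out = _population_stats(events, pop, thresholds, mfi)
    out["pct_positive_bgsub"] = out["pct_positive"]
    out["mfi_af488_bgsub"] = out["mfi_af488"]
    out["floored"] = False
    if background is not None:
        bpop = classify_events(background, thresholds)
        bstats = _population_stats(background, bpop, thresholds, mfi)
        for name in out.index:
            for col, bcol in (("pct_positive_bgsub", "pct_positive"),
                              ("mfi_af488_bgsub", "mfi_af488")):
                val = out.loc[name, col.replace("_bgsub", "")] - bstats.loc[name, bcol]
                if val < 0:
                    val = 0.0
                    out.loc[name, "floored"] = True
                out.loc[name, col] = val
    return out


def fret_cdch(domain: FretSample, homogeneous: FretSample) -> float:
    """Relative FRET ``C_D/C_H = ln(F/F_o)_D / ln(F/F_o)_H``.

    High values mean the protein and the acceptor-labelled lipid partition
    into the same lipid domain.  Invariant under common rescaling of
    (F, F_o) within a sample.
    """
    rd, rh = domain.quench_ratio, homogeneous.quench_ratio
    if rh == 1.0:
        raise ZeroDivisionError("homogeneous sample shows no quenching; ln(F/F_o)_H = 0")
    return float(np.log(rd) / np.log(rh))


def delta_cdch(curve: Mapping, t_low: float = 20.0, t_high: float = 45.0,
               tol_C: float = 2.0) -> float:
    """Total change in C_D/C_H across a temperature ramp: C(t_high) - C(t_low).

    ``curve`` maps temperature (°C) to C_D/C_H; endpoints are matched to the
    nearest sampled temperature within ``tol_C``.
    """
    temps = np.array(sorted(curve.keys()), dtype=float)
    i_lo = _nearest(temps, t_low, tol_C)
    i_hi = _nearest(temps, t_high, tol_C)
    return float(curve[temps[i_hi]] - curve[temps[i_lo]])


def rapamycin_induced(lum: LuminescenceSet) -> float:
    """Rapamycin-induced luminescence: Lum(+Rap) / Lum(-Rap)."""
    if lum.lum_plus_rap is None or lum.lum_minus_rap is None:
        raise ValueError("both +Rap and -Rap luminescence required")
    if lum.lum_minus_rap <= 0:
        raise ZeroDivisionError("-Rap luminescence must be positive")
    return float(lum.lum_plus_rap / lum.lum_minus_rap)


def relative_nanobit(lum: LuminescenceSet,
                     room_temp_reference: Optional[float] = None) -> float:
    """Relative hetero-pair assembly: Lum(20-50) / (0.5 * (Lum(20-20) + Lum(50-50))).

    When ``room_temp_reference`` (the same statistic at room temperature) is
    supplied, the value is divided by it, so the room-temperature point of a
    ramp equals 1 by construction.
    """
    for name in ("lum_20_50", "lum_20_20", "lum_50_50"):
        if getattr(lum, name) is None:
            raise ValueError(f"{name} required")
    homo_mean = 0.5 * (lum.lum_20_20 + lum.lum_50_50)
    if homo_mean <= 0:
        raise ZeroDivisionError("mean homo-pair luminescence must be positive")
    val = lum.lum_20_50 / homo_mean
    if room_temp_reference is not None:
        if room_temp_reference <= 0:
            raise ZeroDivisionError("room-temperature reference must be positive")
        val = val / room_temp_reference
    return float(val)


def correlate_expression_compression(pairs: Sequence) -> LinearFit:
    """OLS fit of normalised expression increase against membrane compression.

    ``pairs`` is a sequence of (compression Å, normalised increase); returns
    slope, intercept, Pearson r and R².
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least three (compression, expression) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: compression values are all equal")
    res = stats.linregress(x, y)
    r = float(res.rvalue)
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                     pearson_r=r, r_squared=r * r)
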