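"""Headspace methane quantification from raw multi-ion RGA scans.

The processing chain per bottle and timepoint is

1. average the last *n* readouts of each scan (:func:`stable_average`),
2. form signal ratios CH4:N2 (m/z 15:28) and CO2:N2 (44:28) and apply the
   linear calibration (:func:`calibrated_ratio`),
3. convert ratios to headspace mole fractions (:func:`headspace_fractions`),
4. convert fractions to moles at 1 atm / 298 K ideal gas
   (:func:`moles_in_headspace`) over a headspace volume that grows with
   every liquid withdrawal (:func:`headspace_volume`),
5. correct cumulative production for methane carried away by the analyzer's
   own gas consumption (:func:`cumulative_methane`).

Bookkeeping conventions (all configurable):

* Total headspace pressure is fixed at 1 atm.  Gas consumed by the analyzer
  is assumed to have the headspace composition measured at the same
  timepoint and is *not* subtracted from the headspace volume (removal is
  treated as replaced at ambient pressure).
* The current measurement's own gas consumption **is** added back into that
  timepoint's cumulative production (``include_current_removal=True``),
  except at the very first timepoint where production equals the methane
  present.
* A liquid withdrawal enlarges the headspace for *later* measurements only:
  the volume at a timepoint sums withdrawals from strictly earlier events
  (the initial headspace applies unchanged at the first timepoint).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MZ_CHANNELS",
    "MZ_CH4",
    "MZ_CO2",
    "MZ_N2",
    "RGAScan",
    "CalibrationCurve",
    "SamplingEvent",
    "HeadspaceState",
    "GasSample",
    "stable_average",
    "calibrated_ratio",
    "headspace_fractions",
    "headspace_volume",
    "moles_in_headspace",
    "rga_gas_consumed",
    "cumulative_methane",
    "production_rate",
    "max_rate_window",
    "process_bottle",
]

#: m/z channels recorded per readout (H2, CH4, CH4/O2, H2O, N2, O2, CO2).
MZ_CHANNELS: tuple[int, ...] = (2, 15, 16, 18, 28, 32, 44)
MZ_CH4 = 15  # sole CH4 quantitation channel; 16 is ambiguous with O2
MZ_CO2 = 44
MZ_N2 = 28

R_GAS_L_ATM = 0.082057  # L atm mol^-1 K^-1
DEFAULT_T_K = 298.0
DEFAULT_P_ATM = 1.0
#: syringe-timed analyzer intake: 1 mL per 26 s
DEFAULT_RGA_RATE_ML_PER_S = 1.0 / 26.0
NOMINAL_GAS_ML = 7.0
NOMINAL_LIQUID_ML = 6.0
INITIAL_HEADSPACE_ML = 300.0


@dataclass(frozen=True)
class RGAScan:
    """One timed sequence of multi-ion readouts on one bottle."""

    bottle: str
    day: float
    readouts: tuple[tuple[float, Mapping[int, float]], ...]

    def __post_init__(self) -> None:
        times = [t for t, _ in self.readouts]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError(f"scan {self.bottle!r} day {self.day}: readouts not time-ordered")
        for t, channels in self.readouts:
            for mz, sig in channels.items():
                if sig < 0:
                    raise ValueError(
                        f"scan {self.bottle!r} day {self.day}: negative signal at m/z {mz}"
                    )

    @property
    def duration_s(self) -> float:
        if not self.readouts:
            return 0.0
        return self.readouts[-1][0] - self.readouts[0][0]


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear map from measured analyte:N2 signal ratio to true molar ratio."""

    analyte: str  # "CH4" | "CO2"
    mz: int
    slope: float
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.analyte not in ("CH4", "CO2"):
            raise ValueError(f"unknown analyte {self.analyte!r}")
        if not self.slope > 0:
            raise ValueError("calibration slope must be positive")


@dataclass(frozen=True)
class SamplingEvent:
    """Volumes exchanged at one sampling timepoint."""

    day: float
    liquid_ml: float = NOMINAL_LIQUID_ML
    gas_ml: float = NOMINAL_GAS_ML
    readout_count: int | None = None

    def __post_init__(self) -> None:
        if self.liquid_ml < 0 or self.gas_ml < 0:
            raise ValueError("sampling volumes must be non-negative")


@dataclass(frozen=True)
class GasSample:
    """Calibrated per-timepoint input to :func:`cumulative_methane`."""

    day: float
    f_ch4: float
    f_co2: float
    volume_ml: float
    gas_removed_ml: float = NOMINAL_GAS_ML


@dataclass(frozen=True)
class HeadspaceState:
    """Fully reduced headspace bookkeeping at one timepoint."""

    day: float
    volume_ml: float
    f_ch4: float
    f_co2: float
    f_n2: float
    n_present: float       # mol CH4 in headspace at measurement
    n_removed_cum: float   # mol CH4 carried away by analyzer, cumulative
    n_produced: float      # withdrawal-corrected cumulative production, mol


def stable_average(scan: RGAScan, n_last: int = 5) -> dict[int, float]:
    """Per-channel arithmetic mean of the final *n_last* readouts."""
    if n_last < 1:
        raise ValueError("n_last must be >= 1")
    if len(scan.readouts) < n_last:
        raise ValueError(
            f"scan {scan.bottle!r} day {scan.day}: "
            f"{len(scan.readouts)} readouts < n_last={n_last}"
        )
    tail = scan.readouts[-n_last:]
    channels = sorted({mz for _, ch in tail for mz in ch})
    out: dict[int, float] = {}
    for mz in channels:
        vals = [ch[mz] for _, ch in tail if mz in ch]
        if len(vals) != n_last:
            raise ValueError(
                f"scan {scan.bottle!r} day {scan.day}: m/z {mz} missing from some readouts"
            )
        out[mz] = float(np.mean(vals))
    return out


def calibrated_ratio(
    signal_analyte: float, signal_n2: float, curve: CalibrationCurve
) -> float:
    """True molar ratio analyte:N2 from raw signals via the linear curve.

    Negative calibrated ratios are clamped to 0 with a warning.
    """
    if signal_n2 <= 0:
        raise ValueError("N2 reference signal must be positive")
    r = curve.slope * (signal_analyte / signal_n2) + curve.intercept
    if r < 0:
        warnings.warn(
            f"calibrated {curve.analyte}:N2 ratio {r:.3g} < 0; clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return r


def headspace_fractions(r_ch4: float, r_co2: float) -> tuple[float, float, float]:
    """Mole fractions (F_CH4, F_CO2, F_N2) from calibrated ratios.

    F_CH4 = R_CH4 / (R_CH4 + R_CO2 + 1), analogously for CO2 with R_CO2 in
    the numerator, and F_N2 takes the remainder; the three sum to 1.
    """
    if r_ch4 < 0 or r_co2 < 0:
        raise ValueError("calibrated ratios must be non-negative")
    denom = r_ch4 + r_co2 + 1.0
    return r_ch4 / denom, r_co2 / denom, 1.0 / denom


def headspace_volume(
    events: Sequence[SamplingEvent],
    day: float | None = None,
    initial_ml: float = INITIAL_HEADSPACE_ML,
    include_same_day: bool = False,
) -> float:
    """Headspace volume (mL): initial plus liquid withdrawn at prior events.

    With the default strict-before convention an event on *day* itself does
    not enlarge the headspace for that day's measurement (the initial
    300 mL applies unchanged at the first timepoint).
    """
    days = [e.day for e in events]
    if any(b < a for a, b in zip(days, days[1:])):
        raise ValueError("sampling events must be time-ordered")
    total = initial_ml
    for e in events:
        if day is None:
            take = True
        elif include_same_day:
            take = e.day <= day
        else:
            take = e.day < day
        if take:
            total += e.liquid_ml
    return total


def moles_in_headspace(
    fraction: float,
    volume_ml: float,
    temperature_k: float = DEFAULT_T_K,
    pressure_atm: float = DEFAULT_P_ATM,
) -> float:
    """Ideal-gas moles of an analyte: n = F * P * V / (R * T).

    Volume is taken in mL and converted to litres; R = 0.082057
    L atm mol^-1 K^-1 throughout the package.
    """
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction must be within [0, 1], got {fraction}")
    if volume_ml < 0 or pressure_atm <= 0 or temperature_k <= 0:
        raise ValueError("non-physical volume, pressure or temperature")
    return fraction * pressure_atm * (volume_ml / 1000.0) / (R_GAS_L_ATM * temperature_k)


def rga_gas_consumed(
    duration_s: float,
    rate_ml_per_s: float = DEFAULT_RGA_RATE_ML_PER_S,
    nominal: bool = False,
) -> float:
    """Gas volume (mL) drawn by the analyzer over *duration_s*.

    With ``nominal=True`` a standard 3-minute sampling reports the rounded
    nominal 7 mL instead of 180/26 ~= 6.92 mL.
    """
    if duration_s < 0:
        raise ValueError("duration must be non-negative")
    ml = duration_s * rate_ml_per_s
    if nominal:
        return float(round(ml))
    return ml


def cumulative_methane(
    samples: Sequence[GasSample],
    include_current_removal: bool = True,
    temperature_k: float = DEFAULT_T_K,
    pressure_atm: float = DEFAULT_P_ATM,
) -> list[HeadspaceState]:
    """Withdrawal-corrected cumulative methane production.

    For timepoint k the production is the methane present plus the methane
    carried off by the analyzer at every timepoint up to and including k
    (``include_current_removal=True``, the default) or strictly before k.
    At the first timepoint only the methane present counts, although that
    measurement's own removal still enters later corrections.
    """
    days = [s.day for s in samples]
    if any(b < a for a, b in zip(days, days[1:])):
        raise ValueError("gas samples must be time-ordered")
    states: list[HeadspaceState] = []
    removed_cum = 0.0
    for k, s in enumerate(samples):
        f_n2 = 1.0 - s.f_ch4 - s.f_co2
        if s.f_ch4 < 0 or s.f_co2 < 0 or f_n2 < -1e-12:
            raise ValueError(f"invalid fractions at day {s.day}")
        n_present = moles_in_headspace(s.f_ch4, s.volume_ml, temperature_k, pressure_atm)
        removed_here = moles_in_headspace(
            s.f_ch4, s.gas_removed_ml, temperature_k, pressure_atm
        )
        removed_before = removed_cum
        removed_cum += removed_here
        if k == 0:
            n_produced = n_present
        elif include_current_removal:
            n_produced = n_present + removed_cum
        else:
            n_produced = n_present + removed_before
        states.append(
            HeadspaceState(
                day=s.day,
                volume_ml=s.volume_ml,
                f_ch4=s.f_ch4,
                f_co2=s.f_co2,
                f_n2=max(f_n2, 0.0),
                n_present=n_present,
                n_removed_cum=removed_cum,
                n_produced=n_produced,
            )
        )
    return states


def _interp_produced(series: Sequence[HeadspaceState], day: float) -> float:
    days = np.array([s.day for s in series])
    produced = np.array([s.n_produced for s in series])
    if day < days[0] or day > days[-1]:
        raise ValueError(
            f"day {day} outside measured span [{days[0]}, {days[-1]}]"
        )
    return float(np.interp(day, days, produced))


def production_rate(
    series: Sequence[HeadspaceState], window: tuple[float, float]
) -> float:
    """Average methane production rate over *window*, in mmol/day.

    Off-grid endpoints are linearly interpolated between adjacent
    measurements.
    """
    day_a, day_b = window
    if not day_b > day_a:
        raise ValueError("window end must exceed window start")
    if len(series) < 2:
        raise ValueError("rate requires at least two timepoints")
    delta = _interp_produced(series, day_b) - _interp_produced(series, day_a)
    return 1000.0 * delta / (day_b - day_a)


def max_rate_window(
    series: Sequence[HeadspaceState], width_days: float
) -> tuple[tuple[float, float], float]:
    """Sliding window of maximal production rate, anchored at measurement
    days; the first-occurring window wins ties.  Returns ((start, end), rate
    in mmol/day)."""
    days = [s.day for s in series]
    if not days or days[-1] - days[0] < width_days:
        raise ValueError("series span shorter than window width")
    best: tuple[tuple[float, float], float] | None = None
    for d in days:
        if d + width_days > days[-1] + 1e-12:
            break
        window = (d, min(d + width_days, days[-1]))
        rate = production_rate(series, window)
        if best is None or rate > best[1] + 1e-12:
            best = (window, rate)
    assert best is not None
    return best


def process_bottle(
    scans: Sequence[RGAScan],
    events: Sequence[SamplingEvent],
    curves: Mapping[str, CalibrationCurve],
    n_last: int = 5,
    initial_headspace_ml: float = INITIAL_HEADSPACE_ML,
    include_current_removal: bool = True,
    include_same_day_liquid: bool = False,
    temperature_k: float = DEFAULT_T_K,
    pressure_atm: float = DEFAULT_P_ATM,
) -> list[HeadspaceState]:
    """Full per-bottle reduction: scans + events + calibration -> states.

    Scans are matched to events by day; every scan needs a same-day event
    supplying the gas volume the analyzer consumed.
    """
    scans = sorted(scans, key=lambda s: s.day)
    events = sorted(events, key=lambda e: e.day)
    by_day = {e.day: e for e in events}
    gas_samples: list[GasSample] = []
    for scan in scans:
        try:
            event = by_day[scan.day]
        except KeyError:
            raise ValueError(
                f"no sampling event for bottle {scan.bottle!r} day {scan.day}"
            ) from None
        signals = stable_average(scan, n_last=n_last)
        r_ch4 = calibrated_ratio(signals[MZ_CH4], signals[MZ_N2], curves["CH4"])
        r_co2 = calibrated_ratio(signals[MZ_CO2], signals[MZ_N2], curves["CO2"])
        f_ch4, f_co2, _ = headspace_fractions(r_ch4, r_co2)
        volume = headspace_volume(
            events,
            day=scan.day,
            initial_ml=initial_headspace_ml,
            include_same_day=include_same_day_liquid,
        )
        gas_samples.append(
            GasSample(
                day=scan.day,
                f_ch4=f_ch4,
                f_co2=f_co2,
                volume_ml=volume,
                gas_removed_ml=event.gas_ml,
            )
        )
    return cumulative_methane(
        gas_samples,
        include_current_removal=include_current_removal,
        temperature_k=temperature_k,
        pressure_atm=pressure_atm,
    )
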