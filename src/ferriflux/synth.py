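"""Seeded forward models of whole incubations for end-to-end testing.

:func:`simulate_incubation` produces a noise-free latent truth — cumulative
methane on a logistic curve, saturating Fe(II) growth, an acetate pool with
an early fermentation pulse and stoichiometric drawdown — under exactly the
same constant-pressure headspace bookkeeping that the processing pipeline
assumes, so the pipeline recovers the truth to machine precision at zero
noise.  :func:`forward_rga` and :func:`forward_wetchem` then render the
truth as instrument-style outputs (multi-ion RGA readouts with a settling
transient and additive noise; diluted wet-chemistry readings).

All randomness flows through ``numpy.random.default_rng(seed)`` (PCG64),
so identical parameters and seed give bitwise-identical outputs on every
platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ferriflux.headspace import (
    DEFAULT_P_ATM,
    DEFAULT_T_K,
    MZ_CH4,
    MZ_CO2,
    MZ_N2,
    CalibrationCurve,
    RGAScan,
    SamplingEvent,
    headspace_volume,
    moles_in_headspace,
)

__all__ = [
    "CONDITIONS",
    "IncubationParams",
    "SyntheticTruth",
    "InfeasibleParamsError",
    "PRESETS",
    "preset",
    "default_schedule",
    "default_calibration",
    "simulate_incubation",
    "forward_rga",
    "forward_wetchem",
]

CONDITIONS = ("ferrihydrite", "hematite", "goethite", "control")


class InfeasibleParamsError(ValueError):
    """Parameter combination over-consumes the acetate pool."""


@dataclass(frozen=True)
class IncubationParams:
    """Generator parameters for one incubation condition.

    Cumulative methane follows a logistic curve with the given plateau,
    maximum rate and midpoint; Fe(II) follows ``plateau * (1 - exp(-k t))``;
    acetate starts at ``acetate_initial_mM``, receives a saturating
    fermentation pulse and is drawn down by ``CH4 + Fe(II)/8`` stoichiometry
    on a fixed liquid-volume basis.
    """

    condition: str
    ch4_plateau_mol: float = 2.0e-3
    ch4_max_rate_mol_per_day: float = 2.5e-4
    ch4_midpoint_day: float = 14.5
    fe2_plateau_mM: float = 0.5
    fe2_rate_per_day: float = 0.3
    fe_total_hcl_mM: float = 10.0
    acetate_initial_mM: float = 10.0
    acetate_pulse_mM: float = 5.0
    acetate_pulse_tau_day: float = 1.0
    liquid_volume_L: float = 0.2
    initial_headspace_ml: float = 300.0
    co2_headspace_per_ch4: float = 0.25
    aqueous_fe_fraction: float = 1.0 / 3.0
    aqueous_ferrous_fraction: float = 1.0
    rga_noise_sd: float = 0.002
    fe_noise_sd_mM: float = 0.05
    acetate_noise_sd_mM: float = 0.2

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        for name in (
            "ch4_plateau_mol",
            "ch4_max_rate_mol_per_day",
            "fe2_plateau_mM",
            "fe2_rate_per_day",
            "rga_noise_sd",
            "fe_noise_sd_mM",
            "acetate_noise_sd_mM",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.fe2_plateau_mM > self.fe_total_hcl_mM:
            raise ValueError("Fe(II) plateau exceeds total HCl-extractable Fe")
        if not 0 <= self.aqueous_fe_fraction <= 1:
            raise ValueError("aqueous_fe_fraction must lie in [0, 1]")
        if not 0 <= self.aqueous_ferrous_fraction <= 1:
            raise ValueError("aqueous_ferrous_fraction must lie in [0, 1]")

    @property
    def logistic_rate_per_day(self) -> float:
        """Logistic steepness giving the configured maximum daily rate."""
        if self.ch4_plateau_mol == 0:
            return 0.0
        return 4.0 * self.ch4_max_rate_mol_per_day / self.ch4_plateau_mol

    def cumulative_ch4_mol(self, day: float | np.ndarray) -> float | np.ndarray:
        r = self.logistic_rate_per_day
        if r == 0 or self.ch4_plateau_mol == 0:
            return np.zeros_like(np.asarray(day, dtype=float)) + 0.0
        return self.ch4_plateau_mol / (1.0 + np.exp(-r * (np.asarray(day, dtype=float) - self.ch4_midpoint_day)))

    def fe2_hcl_mM(self, day: float | np.ndarray) -> float | np.ndarray:
        t = np.asarray(day, dtype=float)
        return self.fe2_plateau_mM * (1.0 - np.exp(-self.fe2_rate_per_day * t))


#: ~30-day, ~2 mmol CH4 presets; ferrihydrite gets the delayed midpoint and
#: the ~6 mM Fe(II) plateau reached by ~day 10.
PRESETS: dict[str, IncubationParams] = {
    "ferrihydrite": IncubationParams(
        condition="ferrihydrite",
        ch4_midpoint_day=17.5,
        fe2_plateau_mM=6.0,
        fe2_rate_per_day=0.45,
    ),
    "goethite": IncubationParams(condition="goethite", fe2_plateau_mM=0.6),
    "hematite": IncubationParams(condition="hematite", fe2_plateau_mM=0.6),
    "control": IncubationParams(
        condition="control", fe2_plateau_mM=0.3, fe_total_hcl_mM=1.0
    ),
}


def preset(condition: str, **overrides) -> IncubationParams:
    return replace(PRESETS[condition], **overrides)


#: sampling cadence similar to a twice-to-thrice-weekly 30-day course
DEFAULT_SAMPLING_DAYS: tuple[float, ...] = (
    0.0, 2.0, 4.0, 7.0, 9.0, 11.0, 13.0, 16.0, 18.0, 20.0, 23.0, 25.0, 27.0, 30.0,
)


def default_schedule(
    days: Sequence[float] = DEFAULT_SAMPLING_DAYS,
    liquid_ml: float = 6.0,
    gas_ml: float = 7.0,
) -> tuple[SamplingEvent, ...]:
    return tuple(SamplingEvent(day=d, liquid_ml=liquid_ml, gas_ml=gas_ml) for d in days)


def default_calibration() -> dict[str, CalibrationCurve]:
    """Plausible linear instrument responses (exactly invertible)."""
    return {
        "CH4": CalibrationCurve("CH4", MZ_CH4, slope=1.18, intercept=0.0),
        "CO2": CalibrationCurve("CO2", MZ_CO2, slope=0.92, intercept=0.0),
    }


@dataclass(frozen=True)
class SyntheticTruth:
    """Noise-free latent incubation state at every scheduled timepoint."""

    params: IncubationParams
    schedule: tuple[SamplingEvent, ...]
    bottle: str
    states: pd.DataFrame
    removal_during_measurement: bool

    def check_balance(self, rtol: float = 1e-12) -> None:
        """Carbon/electron balance: acetate consumed equals CH4 produced
        plus Fe(II) produced / 8, and the headspace CH4 inventory equals
        production minus cumulative removals."""
        s = self.states
        lhs = s["acetate_consumed_mol"].to_numpy()
        rhs = (s["cum_ch4_mol"] + s["fe2_produced_mol"] / 8.0).to_numpy()
        if not np.allclose(lhs, rhs, rtol=rtol, atol=1e-18):
            raise AssertionError("acetate/electron balance violated")
        inventory = s["n_ch4_headspace"].to_numpy()
        if self.removal_during_measurement:
            expect = (s["cum_ch4_mol"] - s["n_ch4_removed_cum"]).to_numpy()
        else:
            removed_before = s["n_ch4_removed_cum"].to_numpy() - s[
                "n_ch4_removed_event"
            ].to_numpy()
            expect = s["cum_ch4_mol"].to_numpy() - removed_before
        if not np.allclose(inventory, expect, rtol=rtol, atol=1e-18):
            raise AssertionError("headspace CH4 inventory inconsistent")


def simulate_incubation(
    params: IncubationParams,
    schedule: Sequence[SamplingEvent] | None = None,
    seed: int = 0,
    bottle: str | None = None,
    removal_during_measurement: bool = True,
    temperature_k: float = DEFAULT_T_K,
    pressure_atm: float = DEFAULT_P_ATM,
) -> SyntheticTruth:
    """Deterministic latent trajectories with gas removals at each event.

    The headspace is held at *pressure_atm*; its volume grows with liquid
    withdrawals from strictly earlier events.  With
    ``removal_during_measurement=True`` (default) the analyzer's gas
    consumption at an event is reflected in that event's own measured
    fractions, matching the pipeline's default of crediting the current
    removal back to the same timepoint.  The *seed* is accepted for
    interface symmetry; the latent truth itself is noise-free.
    """
    del seed  # latent truth is deterministic
    events = tuple(schedule) if schedule is not None else default_schedule()
    days = [e.day for e in events]
    if any(b < a for a, b in zip(days, days[1:])):
        raise ValueError("schedule must be time-ordered")
    bottle = bottle if bottle is not None else f"{params.condition}-1"

    rows = []
    removed_ch4 = 0.0
    removed_co2 = 0.0
    for event in events:
        t = event.day
        volume_ml = headspace_volume(
            events, day=t, initial_ml=params.initial_headspace_ml
        )
        n_total = moles_in_headspace(1.0, volume_ml, temperature_k, pressure_atm)
        n_gas = moles_in_headspace(1.0, event.gas_ml, temperature_k, pressure_atm)

        cum_ch4 = float(params.cumulative_ch4_mol(t))
        cum_co2 = params.co2_headspace_per_ch4 * cum_ch4
        avail_ch4 = cum_ch4 - removed_ch4
        avail_co2 = cum_co2 - removed_co2
        if removal_during_measurement:
            denom = n_total + n_gas
        else:
            denom = n_total
        f_ch4 = avail_ch4 / denom
        f_co2 = avail_co2 / denom
        f_n2 = 1.0 - f_ch4 - f_co2
        if f_n2 < 0:
            raise InfeasibleParamsError("gas production exceeds headspace capacity")
        rem_ch4 = f_ch4 * n_gas
        rem_co2 = f_co2 * n_gas
        removed_ch4 += rem_ch4
        removed_co2 += rem_co2

        fe2_mM = float(params.fe2_hcl_mM(t))
        fe2_mol = fe2_mM / 1000.0 * params.liquid_volume_L
        aqueous = params.aqueous_fe_fraction * fe2_mM
        aqueous_fe2 = params.aqueous_ferrous_fraction * aqueous
        acetate_consumed = cum_ch4 + fe2_mol / 8.0
        pulse = params.acetate_pulse_mM * (
            1.0 - math.exp(-t / params.acetate_pulse_tau_day)
            if params.acetate_pulse_tau_day > 0
            else 1.0
        )
        acetate_mM = (
            params.acetate_initial_mM
            + pulse
            - acetate_consumed / params.liquid_volume_L * 1000.0
        )
        if acetate_mM < 0:
            raise InfeasibleParamsError(
                f"acetate over-consumed below 0 mM at day {t}"
            )
        rows.append(
            {
                "bottle": bottle,
                "day": t,
                "headspace_ml": volume_ml,
                "cum_ch4_mol": cum_ch4,
                "cum_co2_mol": cum_co2,
                "f_ch4": f_ch4,
                "f_co2": f_co2,
                "f_n2": f_n2,
                "n_ch4_headspace": f_ch4 * n_total,
                "n_co2_headspace": f_co2 * n_total,
                "n_n2_headspace": f_n2 * n_total,
                "n_ch4_removed_event": rem_ch4,
                "n_ch4_removed_cum": removed_ch4,
                "fe2_hcl_mM": fe2_mM,
                "fe_total_hcl_mM": params.fe_total_hcl_mM,
                "aqueous_fe_mM": aqueous,
                "aqueous_fe2_mM": aqueous_fe2,
                "acetate_mM": acetate_mM,
                "fe2_produced_mol": fe2_mol,
                "acetate_consumed_mol": acetate_consumed,
            }
        )
    truth = SyntheticTruth(
        params=params,
        schedule=events,
        bottle=bottle,
        states=pd.DataFrame(rows),
        removal_during_measurement=removal_during_measurement,
    )
    truth.check_balance()
    return truth


def forward_rga(
    truth: SyntheticTruth,
    calibration: Mapping[str, CalibrationCurve] | None = None,
    noise_sd: float | None = None,
    seed: int = 0,
    n_readouts: int = 10,
    readout_interval_s: tuple[float, float] = (15.0, 20.0),
    n2_signal: float = 1.0,
    settle_amplitude: float = 0.2,
    settle_tau_s: float = 20.0,
) -> list[RGAScan]:
    """Render the truth as per-event multi-ion RGA scans.

    The stable (late-readout) signals are the exact inverse of the
    calibration applied to the truth's headspace ratios; readouts earlier
    than the final five carry a decaying settling transient so that only
    last-five averaging recovers the truth.  Additive Gaussian noise of
    standard deviation *noise_sd* (in signal units; N2 reads ~1) is applied
    per readout and channel, and signals are clipped at zero.
    """
    if calibration is None:
        calibration = default_calibration()
    if noise_sd is None:
        noise_sd = truth.params.rga_noise_sd
    rng = np.random.default_rng(seed)
    scans: list[RGAScan] = []
    for row in truth.states.itertuples():
        r_ch4 = row.f_ch4 / row.f_n2
        r_co2 = row.f_co2 / row.f_n2
        ch4_curve = calibration["CH4"]
        co2_curve = calibration["CO2"]
        s_ch4 = (r_ch4 - ch4_curve.intercept) / ch4_curve.slope * n2_signal
        s_co2 = (r_co2 - co2_curve.intercept) / co2_curve.slope * n2_signal
        if s_ch4 < 0 or s_co2 < 0:
            raise ValueError("calibration not invertible at truth ratios")
        stable = {
            2: 0.001 * n2_signal,
            MZ_CH4: s_ch4,
            16: 0.8 * s_ch4,          # fragment channel, QC only
            18: 0.02 * n2_signal,     # water vapor
            MZ_N2: n2_signal,
            32: 0.0005 * n2_signal,
            MZ_CO2: s_co2,
        }
        spacing = rng.uniform(*readout_interval_s, size=n_readouts)
        times = np.cumsum(spacing)
        readouts = []
        for i, t_s in enumerate(times):
            settling = i < n_readouts - 5
            channels: dict[int, float] = {}
            for mz, value in stable.items():
                v = value
                if settling:
                    v *= 1.0 + settle_amplitude * math.exp(-t_s / settle_tau_s)
                if noise_sd > 0:
                    v += rng.normal(0.0, noise_sd)
                channels[mz] = max(v, 0.0)
            readouts.append((float(t_s), channels))
        scans.append(RGAScan(bottle=row.bottle, day=row.day, readouts=tuple(readouts)))
    return scans


def forward_wetchem(
    truth: SyntheticTruth,
    noise_sd_mM: float | None = None,
    seed: int = 0,
    dilution: float = 2.0,
    acetate_noise_sd_mM: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render the truth as raw iron and acetate tables.

    Iron readings are divided by *dilution* (the acid-addition convention
    run in reverse) before additive noise, so the speciation pipeline's
    dilution correction recovers the truth exactly at zero noise.  Returns
    ``(fe_samples, acetate)`` data frames in the CSV dialects the pipeline
    consumes.
    """
    if noise_sd_mM is None:
        noise_sd_mM = truth.params.fe_noise_sd_mM
    if acetate_noise_sd_mM is None:
        acetate_noise_sd_mM = truth.params.acetate_noise_sd_mM
    rng = np.random.default_rng(seed)
    s = truth.states
    n = len(s)

    def noisy(values: np.ndarray, sd: float) -> np.ndarray:
        if sd > 0:
            values = values + rng.normal(0.0, sd, size=len(values))
        return np.clip(values, 0.0, None)

    fe = pd.DataFrame(
        {
            "bottle": s["bottle"],
            "day": s["day"],
            "fe2_raw_mM": noisy(s["fe2_hcl_mM"].to_numpy() / dilution, noise_sd_mM),
            "fetot_raw_mM": noisy(
                s["fe_total_hcl_mM"].to_numpy() / dilution, noise_sd_mM
            ),
            "aqueous_mM": noisy(s["aqueous_fe_mM"].to_numpy(), noise_sd_mM),
            "dilution": np.full(n, dilution),
        }
    )
    acetate = pd.DataFrame(
        {
            "bottle": s["bottle"],
            "day": s["day"],
            "acetate_mM": noisy(s["acetate_mM"].to_numpy(), acetate_noise_sd_mM),
        }
    )
    return fe, acetate
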