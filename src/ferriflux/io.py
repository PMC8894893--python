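"""Readers/writers for the package's CSV dialects.

All tables are long-format CSV with a header row; days are floats,
concentrations mM, moles mol.  Column schemas:

* scans: ``bottle, day, elapsed_s, mz, signal``
* events: ``bottle, day, liquid_mL, gas_mL``
* calibration: ``analyte, mz, slope, intercept``
* iron samples: ``bottle, day, fe2_raw_mM, fetot_raw_mM, aqueous_mM, dilution``
* gas output: per-bottle time series of volume, fractions and moles

Numeric output is formatted to 12 significant digits so reruns on identical
inputs are byte-identical.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ferriflux.headspace import (
    MZ_CHANNELS,
    CalibrationCurve,
    HeadspaceState,
    RGAScan,
    SamplingEvent,
)
from ferriflux.iron import FeSample, FeSpeciation

__all__ = [
    "SchemaError",
    "FLOAT_FORMAT",
    "read_scans",
    "write_scans",
    "read_events",
    "write_events",
    "read_calibration",
    "write_calibration",
    "read_fe_samples",
    "write_fe_samples",
    "write_gas_states",
    "write_fe_speciation",
]

FLOAT_FORMAT = "%.12g"


class SchemaError(ValueError):
    """An input table does not match its documented column schema."""


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")


def read_scans(path: str | Path) -> dict[str, list[RGAScan]]:
    """Long-format scan table -> per-bottle time-ordered scan lists."""
    df = pd.read_csv(path)
    _require_columns(df, ["bottle", "day", "elapsed_s", "mz", "signal"], "scans")
    bad_mz = set(df["mz"].unique()) - set(MZ_CHANNELS)
    if bad_mz:
        raise SchemaError(f"scans: unknown m/z channels {sorted(bad_mz)}")
    scans: dict[str, list[RGAScan]] = defaultdict(list)
    for (bottle, day), group in df.groupby(["bottle", "day"], sort=True):
        readouts = []
        for elapsed, sub in group.groupby("elapsed_s", sort=True):
            readouts.append(
                (float(elapsed), dict(zip(sub["mz"].astype(int), sub["signal"])))
            )
        scans[str(bottle)].append(
            RGAScan(bottle=str(bottle), day=float(day), readouts=tuple(readouts))
        )
    return {b: sorted(s, key=lambda x: x.day) for b, s in scans.items()}


def write_scans(scans: Iterable[RGAScan], path: str | Path) -> None:
    rows = []
    for scan in scans:
        for elapsed, channels in scan.readouts:
            for mz, signal in sorted(channels.items()):
                rows.append(
                    {
                        "bottle": scan.bottle,
                        "day": scan.day,
                        "elapsed_s": elapsed,
                        "mz": mz,
                        "signal": signal,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_events(path: str | Path) -> dict[str, list[SamplingEvent]]:
    df = pd.read_csv(path)
    _require_columns(df, ["bottle", "day", "liquid_mL", "gas_mL"], "events")
    events: dict[str, list[SamplingEvent]] = defaultdict(list)
    for row in df.sort_values(["bottle", "day"]).itertuples():
        events[str(row.bottle)].append(
            SamplingEvent(
                day=float(row.day),
                liquid_ml=float(row.liquid_mL),
                gas_ml=float(row.gas_mL),
            )
        )
    return dict(events)


def write_events(events: Mapping[str, Sequence[SamplingEvent]], path: str | Path) -> None:
    rows = [
        {
            "bottle": bottle,
            "day": e.day,
            "liquid_mL": e.liquid_ml,
            "gas_mL": e.gas_ml,
        }
        for bottle, evs in events.items()
        for e in evs
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_calibration(path: str | Path) -> dict[str, CalibrationCurve]:
    df = pd.read_csv(path)
    _require_columns(df, ["analyte", "mz", "slope", "intercept"], "calibration")
    curves = {}
    for row in df.itertuples():
        curves[str(row.analyte)] = CalibrationCurve(
            analyte=str(row.analyte),
            mz=int(row.mz),
            slope=float(row.slope),
            intercept=float(row.intercept),
        )
    for analyte in ("CH4", "CO2"):
        if analyte not in curves:
            raise SchemaError(f"calibration: missing curve for {analyte}")
    return curves


def write_calibration(curves: Mapping[str, CalibrationCurve], path: str | Path) -> None:
    rows = [
        {"analyte": c.analyte, "mz": c.mz, "slope": c.slope, "intercept": c.intercept}
        for c in curves.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_fe_samples(path: str | Path) -> list[FeSample]:
    df = pd.read_csv(path)
    _require_columns(
        df,
        ["bottle", "day", "fe2_raw_mM", "fetot_raw_mM", "aqueous_mM", "dilution"],
        "iron samples",
    )
    return [
        FeSample(
            bottle=str(row.bottle),
            day=float(row.day),
            fe2_hcl_raw_mM=float(row.fe2_raw_mM),
            fe_total_hcl_raw_mM=float(row.fetot_raw_mM),
            aqueous_fe_mM=float(row.aqueous_mM),
            dilution=float(row.dilution),
        )
        for row in df.sort_values(["bottle", "day"]).itertuples()
    ]


def write_fe_samples(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_gas_states(
    states: Mapping[str, Sequence[HeadspaceState]], path: str | Path
) -> None:
    rows = [
        {
            "bottle": bottle,
            "day": s.day,
            "volume_mL": s.volume_ml,
            "f_ch4": s.f_ch4,
            "f_co2": s.f_co2,
            "f_n2": s.f_n2,
            "n_present_mol": s.n_present,
            "n_removed_cum_mol": s.n_removed_cum,
            "n_produced_mol": s.n_produced,
        }
        for bottle, series in states.items()
        for s in series
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_fe_speciation(
    samples: Sequence[FeSample], speciations: Sequence[FeSpeciation], path: str | Path
) -> None:
    rows = []
    for sample, spec in zip(samples, speciations):
        rows.append(
            {
                "bottle": sample.bottle,
                "day": sample.day,
                "fe2_hcl_mM": spec.fe2_hcl_mM,
                "fe3_hcl_mM": spec.fe3_hcl_mM,
                "aqueous_fe_mM": spec.aqueous_fe_mM,
                "solid_total_mM": spec.solid_total_mM,
                "solid_fe2_lo_mM": spec.solid_fe2_mM[0],
                "solid_fe2_hi_mM": spec.solid_fe2_mM[1],
                "solid_fe2_fraction_lo": spec.solid_fe2_fraction[0],
                "solid_fe2_fraction_hi": spec.solid_fe2_fraction[1],
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)
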