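"""Fe(II)/Fe(III) speciation bookkeeping and the acetate electron budget.

HCl-extractable Fe(II) is assayed without reductant, total HCl-extractable
Fe with hydroxylamine hydrochloride, and aqueous Fe on a filtered/acidified
split.  Because the valence of the aqueous pool is not determined, the
solid-phase Fe(II) content is reported as an interval spanning the two
extreme assumptions (aqueous pool all ferrous vs. all ferric).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "DEFAULT_DILUTION",
    "FeSample",
    "FeSpeciation",
    "AcetateBudget",
    "InconsistentSpeciationError",
    "dilution_correct",
    "ferrozine_split",
    "solid_phase_bounds",
    "speciate",
    "acetate_budget",
    "FE_PER_ACETATE",
]

#: 1.5 mL sample into 1.5 mL acid
DEFAULT_DILUTION = 2.0
#: clamping tolerance for assay noise, as a fraction of total Fe
DEFAULT_TOL_FRACTION = 0.02
#: moles of Fe(III) reduced per mole of acetate oxidized
FE_PER_ACETATE = 8.0


class InconsistentSpeciationError(ValueError):
    """Measured pools disagree beyond assay tolerance."""


@dataclass(frozen=True)
class FeSample:
    """Raw (pre-dilution-correction) readings for one bottle/timepoint."""

    bottle: str
    day: float
    fe2_hcl_raw_mM: float
    fe_total_hcl_raw_mM: float
    aqueous_fe_mM: float
    dilution: float = DEFAULT_DILUTION

    def __post_init__(self) -> None:
        for name in ("fe2_hcl_raw_mM", "fe_total_hcl_raw_mM", "aqueous_fe_mM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.dilution < 1:
            raise ValueError("dilution factor must be >= 1")


@dataclass(frozen=True)
class FeSpeciation:
    """Dilution-corrected speciation with interval-valued solid-phase pools.

    ``solid_fe2_mM`` brackets the solid Fe(II): the lower bound treats the
    aqueous pool as entirely ferrous, the upper as entirely ferric.
    """

    fe2_hcl_mM: float
    fe3_hcl_mM: float
    aqueous_fe_mM: float
    solid_total_mM: float
    solid_fe2_mM: tuple[float, float]
    solid_fe2_fraction: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.solid_fe2_mM
        if lo > hi + 1e-12:
            raise ValueError("solid Fe(II) interval inverted")
        flo, fhi = self.solid_fe2_fraction
        if not (-1e-12 <= flo <= fhi <= 1 + 1e-12):
            raise ValueError("solid Fe(II) fraction interval outside [0, 1]")


def dilution_correct(measured_mM: float, factor: float = DEFAULT_DILUTION) -> float:
    """Undo the acid-addition dilution: measured concentration times factor."""
    if factor < 1:
        raise ValueError("dilution factor must be >= 1")
    return measured_mM * factor


def ferrozine_split(
    fe2_mM: float,
    total_mM: float,
    tol_fraction: float = DEFAULT_TOL_FRACTION,
) -> tuple[float, float]:
    """Split total HCl-extractable Fe into (Fe(II), Fe(III)).

    Fe(III) = total - Fe(II).  If Fe(II) exceeds total by at most
    *tol_fraction* of total (assay noise), Fe(III) is clamped to 0 with a
    warning; larger excesses raise :class:`InconsistentSpeciationError`.
    Fe(II) + Fe(III) always equals the (possibly clamped) total exactly.
    """
    if fe2_mM < 0 or total_mM < 0:
        raise ValueError("concentrations must be non-negative")
    fe3 = total_mM - fe2_mM
    if fe3 < 0:
        if fe2_mM - total_mM <= tol_fraction * total_mM:
            warnings.warn(
                f"Fe(II) {fe2_mM} mM exceeds total {total_mM} mM within "
                "tolerance; Fe(III) clamped to 0",
                stacklevel=2,
            )
            return fe2_mM, 0.0
        raise InconsistentSpeciationError(
            f"Fe(II) {fe2_mM} mM exceeds total Fe {total_mM} mM beyond "
            f"{tol_fraction:.0%} tolerance"
        )
    return fe2_mM, fe3


def solid_phase_bounds(
    fe2_hcl_mM: float,
    total_hcl_mM: float,
    aqueous_mM: float,
    tol_fraction: float = DEFAULT_TOL_FRACTION,
) -> FeSpeciation:
    """Interval-valued solid-phase speciation.

    The HCl-extractable pools include the aqueous Fe, whose valence is
    unknown, so the solid Fe(II) lies between ``fe2_hcl - aqueous`` (aqueous
    all ferrous) and ``min(fe2_hcl, solid total)`` (aqueous all ferric).
    """
    fe2, fe3 = ferrozine_split(fe2_hcl_mM, total_hcl_mM, tol_fraction)
    total = fe2 + fe3
    if aqueous_mM > total + tol_fraction * total:
        raise InconsistentSpeciationError(
            f"aqueous Fe {aqueous_mM} mM exceeds total HCl-extractable "
            f"{total} mM"
        )
    aqueous = min(aqueous_mM, total)
    solid_total = total - aqueous
    lo = max(0.0, fe2 - aqueous)
    hi = min(fe2, solid_total)
    hi = max(hi, lo)  # guard against float dust
    if solid_total > 0:
        frac = (lo / solid_total, hi / solid_total)
    else:
        frac = (0.0, 0.0)
    return FeSpeciation(
        fe2_hcl_mM=fe2,
        fe3_hcl_mM=fe3,
        aqueous_fe_mM=aqueous,
        solid_total_mM=solid_total,
        solid_fe2_mM=(lo, hi),
        solid_fe2_fraction=frac,
    )


def speciate(sample: FeSample, tol_fraction: float = DEFAULT_TOL_FRACTION) -> FeSpeciation:
    """Full reduction of one raw sample: dilution correction then bounds."""
    fe2 = dilution_correct(sample.fe2_hcl_raw_mM, sample.dilution)
    total = dilution_correct(sample.fe_total_hcl_raw_mM, sample.dilution)
    return solid_phase_bounds(fe2, total, sample.aqueous_fe_mM, tol_fraction)


class AcetateBudget(NamedTuple):
    acetate_to_fe: float
    acetate_to_ch4: float
    ratio: float | None


def acetate_budget(delta_fe2_mol: float, delta_ch4_mol: float) -> AcetateBudget:
    """Acetate consumed by iron reduction vs. methanogenesis.

    Eight moles of Fe(III) reduction oxidize one mole of acetate, while one
    mole of methane consumes one mole of acetate, so
    ``acetate_to_fe = delta_fe2 / 8`` and ``acetate_to_ch4 = delta_ch4``.
    ``ratio`` is their quotient (``None`` when no methane was produced).
    """
    if delta_fe2_mol < 0 or delta_ch4_mol < 0:
        raise ValueError("cumulative changes must be non-negative")
    acetate_to_fe = delta_fe2_mol / FE_PER_ACETATE
    acetate_to_ch4 = delta_ch4_mol
    ratio = None if acetate_to_ch4 == 0 else acetate_to_fe / acetate_to_ch4
    return AcetateBudget(acetate_to_fe, acetate_to_ch4, ratio)
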