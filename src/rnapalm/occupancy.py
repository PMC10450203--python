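"""Growth-rate bookkeeping: rrn gene dosage and RNAP occupancy per operon.

The number of RNAPs engaged on rRNA operons per cell, N_r, scales with
growth rate; it is interpolated across doubling times by fitting a single
exponential to a calibration table (by default the strain/medium table
shipped with the package, whose (doubling time, N_r) pairs follow
``N_r = A * exp(beta * ln tau)``, i.e. a power law in the doubling time, to
within ~1.5%).

Per-cell gene copy numbers follow the replication-dependent dosage formula

    copies(m') = 2^((C (1 - m') + D) / tau)

where C and D are the replication and division periods (minutes), tau the
doubling time and m' the gene's fractional map distance from oriC along
the replication arm (0 at the origin, 1 at the terminus).  At m' = 0 this
is the oriC copy number 2^((C+D)/tau), which lets C+D be inverted from a
measured origin copy number.  Summing the dosage over a strain's rrn
offsets gives its expected rrn copies per cell, and N_r divided by that
count gives the mean RNAP loading per operon; fractional occupancy is
reported relative to the 72 RNAPs/operon observed at the maximal E. coli
growth rate (24 min doubling time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import ARM_LENGTH_KB, RRN_OFFSETS_KB, STRAIN_OPERONS

__all__ = [
    "StrainProfile",
    "DosageParams",
    "OccupancyEstimate",
    "CALIBRATION_TABLE",
    "MAX_OCCUPANCY_REF",
    "fit_rrnap_exponential",
    "gene_dosage",
    "operon_copies",
    "rnap_per_rrn_and_occupancy",
    "physical_max_occupancy",
    "ori_ter_from_ct",
    "build_occupancy_table",
    "round_half_away",
]

#: RNAPs per operon at the maximal growth rate (24 min): the 100% reference.
MAX_OCCUPANCY_REF = 72.0

#: rRNA elongation speed (nt/s) underlying the N_r = r_r / c_r definition.
RRNA_ELONGATION_NT_S = 85.0


@dataclass(frozen=True)
class StrainProfile:
    """A strain/medium condition for the occupancy bookkeeping."""

    name: str
    medium: str
    doubling_time: float  # minutes
    rrn_offsets_kb: tuple[float, ...]
    ori_copies: float | None = None  # measured/expected oriC copies per cell
    plasmid_rrn_copies: float = 0.0

    def __post_init__(self) -> None:
        if self.doubling_time <= 0:
            raise ValueError("doubling time must be positive")
        if any(o < 0 for o in self.rrn_offsets_kb):
            raise ValueError("offsets must be non-negative")


def _offsets(strain: str) -> tuple[float, ...]:
    return tuple(RRN_OFFSETS_KB[o] for o in STRAIN_OPERONS[strain])


#: Reference calibration: (strain, medium, doubling time min, N_r per cell,
#: oriC copies per cell, rrn copies per cell).
CALIBRATION_TABLE = (
    ("WT", "M9Glu", 47.0, 397.0, 2.9, 17.5),
    ("D5", "M9Glu", 57.0, 238.0, 2.5, 4.8),
    ("D6", "M9Glu", 73.0, 122.0, 2.2, 2.0),
    ("WT", "RDM", 36.0, 805.0, 3.7, 22.0),
    ("D5", "RDM", 46.0, 420.0, 2.9, 5.6),
    ("D6", "RDM", 51.0, 320.0, 2.7, 2.5),
)


def default_calibration() -> list[tuple[float, float]]:
    """(doubling time, N_r) pairs from the shipped calibration table."""
    return [(row[2], row[3]) for row in CALIBRATION_TABLE]


def fit_rrnap_exponential(calibration, query_tau: float) -> float:
    """Interpolate N_r at a doubling time by a single-exponential fit.

    ``calibration`` is a sequence of ``(tau_min, N_r)`` pairs.  ln N_r is
    fitted by least squares as a linear function of ln tau (a single
    exponential in log doubling time, equivalently the power law
    ``N_r = A * tau**beta``), and the fit is evaluated at ``query_tau``.
    """
    cal = [(float(t), float(n)) for t, n in calibration]
    if len(cal) < 2:
        raise ValueError("need at least 2 calibration points")
    if query_tau <= 0:
        raise ValueError("query doubling time must be positive")
    if any(n <= 0 or t <= 0 for t, n in cal):
        raise ValueError("calibration requires positive tau and N_r")
    x = np.log([t for t, _ in cal])
    y = np.log([n for _, n in cal])
    beta, alpha = np.polyfit(x, y, 1)
    return float(np.exp(alpha + beta * math.log(query_tau)))


@dataclass(frozen=True)
class DosageParams:
    """Replication-dependent gene dosage parameters."""

    C: float  # replication period, min
    D: float  # division period, min
    m_prime: float  # fractional map distance from oriC, 0..1
    tau: float  # doubling time, min

    def __post_init__(self) -> None:
        if self.C < 0 or self.D < 0:
            raise ValueError("C and D must be non-negative")
        if not 0.0 <= self.m_prime <= 1.0:
            raise ValueError("m_prime must lie in [0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def gene_dosage(params: DosageParams) -> float:
    """Copies per cell of a gene at map position m': 2^((C(1-m')+D)/tau)."""
    return 2.0 ** ((params.C * (1.0 - params.m_prime) + params.D) / params.tau)


def operon_copies(
    tau: float,
    ori_copies: float,
    rrn_offsets_kb,
    arm_length_kb: float = ARM_LENGTH_KB,
    cd_ratio: float = 2.0,
) -> float:
    """Expected rrn copies per cell from the dosage formula.

    C + D is inverted from the oriC copy number (``ori = 2^((C+D)/tau)``)
    and split ``C : D = cd_ratio : 1``; the dosage is summed over the
    strain's operon offsets.
    """
    if ori_copies <= 0:
        raise ValueError("ori_copies must be positive")
    cd_sum = tau * math.log2(ori_copies)
    c = cd_sum * cd_ratio / (cd_ratio + 1.0)
    d = cd_sum - c
    total = 0.0
    for off in rrn_offsets_kb:
        m = float(off) / arm_length_kb
        total += gene_dosage(DosageParams(C=c, D=d, m_prime=m, tau=tau))
    return total


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (report convention)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class OccupancyEstimate:
    """Per-operon loading and fractional occupancy for one condition."""

    n_rrnap: float
    ori_copies: float
    rrn_copies: float
    rnap_per_rrn: float
    occupancy_pct: float

    @property
    def rnap_per_rrn_rounded(self) -> int:
        return round_half_away(self.rnap_per_rrn)

    @property
    def occupancy_pct_rounded(self) -> int:
        return round_half_away(self.occupancy_pct)


def rnap_per_rrn_and_occupancy(
    n_r: float, rrn_copies: float, max_ref: float = MAX_OCCUPANCY_REF
) -> tuple[float, float]:
    """Mean RNAP loading per operon and % of the maximal-growth reference.

    Returned unrounded; integer rounding (half away from zero) is applied
    only at report time.
    """
    if rrn_copies <= 0:
        raise ValueError("rrn_copies must be positive")
    per_rrn = n_r / rrn_copies
    return per_rrn, 100.0 * per_rrn / max_ref


def physical_max_occupancy(
    operon_length_bp: float = 5400.0, footprint_bp: float = 40.0
) -> int:
    """Maximal number of elongating RNAPs that physically fit on one operon."""
    if operon_length_bp <= 0 or footprint_bp <= 0:
        raise ValueError("lengths must be positive")
    return int(math.floor(operon_length_bp / footprint_bp))


def ori_ter_from_ct(ct_ori: float, ct_ter: float) -> float:
    """ori:ter marker ratio from qPCR cycle thresholds (2^-ΔCt method)."""
    if not (math.isfinite(ct_ori) and math.isfinite(ct_ter)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** (ct_ter - ct_ori)


def default_strains() -> list[StrainProfile]:
    return [
        StrainProfile(
            name=s,
            medium=m,
            doubling_time=tau,
            rrn_offsets_kb=_offsets(s),
            ori_copies=ori,
        )
        for s, m, tau, _, ori, _ in CALIBRATION_TABLE
    ]


def build_occupancy_table(
    strains: list[StrainProfile] | None = None,
    calibration=None,
    n_rrnap: dict | None = None,
    rrn_copies: dict | None = None,
    max_ref: float = MAX_OCCUPANCY_REF,
) -> pd.DataFrame:
    """Occupancy bookkeeping table for a set of strain/medium conditions.

    For each strain, N_r is taken from ``n_rrnap`` (keyed by (name, medium))
    when supplied, otherwise interpolated from the calibration; rrn copies
    come from ``rrn_copies`` when supplied, otherwise from the dosage
    formula with C+D inverted from the strain's oriC copies.
    """
    if strains is None:
        strains = default_strains()
    if calibration is None:
        calibration = default_calibration()
    rows = []
    for sp in strains:
        key = (sp.name, sp.medium)
        n_r = (
            float(n_rrnap[key])
            if n_rrnap and key in n_rrnap
            else fit_rrnap_exponential(calibration, sp.doubling_time)
        )
        if rrn_copies and key in rrn_copies:
            copies = float(rrn_copies[key])
        else:
            if sp.ori_copies is None:
                raise ValueError(f"{key}: need ori_copies or explicit rrn_copies")
            copies = operon_copies(sp.doubling_time, sp.ori_copies, sp.rrn_offsets_kb)
            copies += sp.plasmid_rrn_copies
        per_rrn, pct = rnap_per_rrn_and_occupancy(n_r, copies, max_ref)
        rows.append(
            {
                "strain": sp.name,
                "medium": sp.medium,
                "doubling_time_min": sp.doubling_time,
                "n_rrnap": n_r,
                "ori_copies": sp.ori_copies,
                "rrn_copies": copies,
                "rnap_per_rrn": round_half_away(per_rrn),
                "occupancy_pct": round_half_away(pct),
            }
        )
    return pd.DataFrame(rows)
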