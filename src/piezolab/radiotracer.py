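"""Bulk leucine incorporation rates from radiotracer incubations.

Converts liquid-scintillation counts (disintegrations per minute, DPM) of
live and formaldehyde-killed ³H-leucine incubations into bulk leucine
incorporation rates (pmol Leu l⁻¹ h⁻¹), and normalizes in-situ rates to the
mean rate measured in the same water under atmospheric pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Disintegrations per minute per Curie.
DPM_PER_CURIE = 2.22e12

IN_SITU = "in_situ"
ATMOSPHERIC = "atmospheric"
CONDITIONS = (IN_SITU, ATMOSPHERIC)


@dataclass(frozen=True)
class BulkIncubation:
    """One bottle set (live replicates + killed controls) of one condition.

    Parameters
    ----------
    station : str
        Station / deployment identifier.
    depth_m : float
        Incubation depth in metres (0 allowed for instrument tests).
    condition : str
        ``"in_situ"`` (pressure maintained) or ``"atmospheric"``.
    dpm_live, dpm_killed : sequence of float
        Scintillation counts of live replicates and killed (T0) controls.
    specific_activity : float
        Tracer specific activity, Ci mmol⁻¹.
    volume_l : float
        Filtered sample volume per bottle, litres.
    duration_h : float
        Incubation time, hours.
    temperature_c : float, optional
        In-situ temperature (metadata only).
    """

    station: str
    depth_m: float
    condition: str
    dpm_live: tuple[float, ...]
    dpm_killed: tuple[float, ...]
    specific_activity: float
    volume_l: float
    duration_h: float
    temperature_c: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "dpm_live", tuple(float(x) for x in self.dpm_live))
        object.__setattr__(self, "dpm_killed", tuple(float(x) for x in self.dpm_killed))
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.depth_m < 0:
            raise ValueError("depth_m must be >= 0")
        if not self.dpm_live or not self.dpm_killed:
            raise ValueError("need at least one live and one killed replicate")
        if self.specific_activity <= 0:
            raise ValueError("specific_activity must be > 0")
        if self.volume_l <= 0:
            raise ValueError("volume_l must be > 0")
        if self.duration_h <= 0:
            raise ValueError("duration_h must be > 0")


@dataclass(frozen=True)
class LeucineRate:
    """Bulk leucine incorporation rate, pmol Leu l⁻¹ h⁻¹."""

    station: str
    depth_m: float
    condition: str
    value: float
    below_detection: bool = False


@dataclass(frozen=True)
class RatioPoint:
    """In-situ rate as a percentage of the mean atmospheric-pressure rate."""

    depth_m: float
    percent: float
    n_atm: int = 1
    below_detection: bool = False

    @property
    def regression_eligible(self) -> bool:
        """Usable in the depth power-law fit (positive depth and ratio)."""
        return self.depth_m > 0 and self.percent > 0 and not self.below_detection


def leucine_rate(incubation: BulkIncubation) -> LeucineRate:
    """Convert an incubation's DPM counts to a bulk leucine incorporation rate.

    The killed-control mean is subtracted from the live mean; the net DPM is
    converted to moles of leucine through the tracer specific activity
    (1 Ci = 2.22×10¹² dpm) and normalized by filtered volume and incubation
    time:

        rate = net_dpm / 2.22e12 / SA[Ci mmol⁻¹] × 1e9 [pmol mmol⁻¹]
               / volume[l] / duration[h]

    Non-positive net rates are retained but flagged ``below_detection`` so
    downstream exclusion stays explicit.
    """
    net_dpm = float(np.mean(incubation.dpm_live)) - float(np.mean(incubation.dpm_killed))
    value = (
        net_dpm
        / DPM_PER_CURIE
        / incubation.specific_activity
        * 1e9
        / incubation.volume_l
        / incubation.duration_h
    )
    return LeucineRate(
        station=incubation.station,
        depth_m=incubation.depth_m,
        condition=incubation.condition,
        value=value,
        below_detection=value <= 0,
    )


def ratio_percent(rate_insitu: LeucineRate, rates_atm: Sequence[LeucineRate]) -> RatioPoint:
    """Normalize an in-situ rate to the mean atmospheric rate, in percent.

    All rates must come from the same station and depth. A below-detection
    in-situ rate propagates its flag (the point is excluded from regression).
    """
    if not rates_atm:
        raise ValueError("need at least one atmospheric rate")
    for r in rates_atm:
        if (r.station, r.depth_m) != (rate_insitu.station, rate_insitu.depth_m):
            raise ValueError("all rates must share station and depth")
    mean_atm = float(np.mean([r.value for r in rates_atm]))
    if mean_atm <= 0:
        raise ValueError("mean atmospheric rate must be > 0 to form a ratio")
    return RatioPoint(
        depth_m=rate_insitu.depth_m,
        percent=100.0 * rate_insitu.value / mean_atm,
        n_atm=len(rates_atm),
        below_detection=rate_insitu.below_detection,
    )


# ---------------------------------------------------------------------------
# CSV interface (incubations.csv -> rates.csv, ratio points)
# ---------------------------------------------------------------------------

def incubations_from_frame(df: pd.DataFrame) -> list[BulkIncubation]:
    """Parse an incubations table (wide replicate columns, NaN = absent)."""
    live_cols = sorted(c for c in df.columns if c.startswith("dpm_live_"))
    killed_cols = sorted(c for c in df.columns if c.startswith("dpm_killed_"))
    out = []
    for _, row in df.iterrows():
        live = tuple(float(row[c]) for c in live_cols if pd.notna(row[c]))
        killed = tuple(float(row[c]) for c in killed_cols if pd.notna(row[c]))
        out.append(
            BulkIncubation(
                station=str(row["station"]),
                depth_m=float(row["depth_m"]),
                condition=str(row["condition"]),
                dpm_live=live,
                dpm_killed=killed,
                specific_activity=float(row["sa_ci_per_mmol"]),
                volume_l=float(row["volume_l"]),
                duration_h=float(row["duration_h"]),
            )
        )
    return out


def rates_to_frame(rates: Sequence[LeucineRate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "station": [r.station for r in rates],
            "depth_m": [r.depth_m for r in rates],
            "condition": [r.condition for r in rates],
            "rate_pmol_l_h": [r.value for r in rates],
            "below_detection": [r.below_detection for r in rates],
        }
    )


def ratio_points_from_rates(rates: Sequence[LeucineRate]) -> list[RatioPoint]:
    """Pair each in-situ rate with same-station/depth atmospheric rates."""
    atm: dict[tuple[str, float], list[LeucineRate]] = {}
    for r in rates:
        if r.condition == ATMOSPHERIC:
            atm.setdefault((r.station, r.depth_m), []).append(r)
    points = []
    for r in rates:
        if r.condition != IN_SITU:
            continue
        partners = atm.get((r.station, r.depth_m))
        if partners:
            points.append(ratio_percent(r, partners))
    return points
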