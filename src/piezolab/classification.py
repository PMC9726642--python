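"""Piezo-class decomposition of paired activity histograms.

The two conditions (in-situ pressure maintained vs depressurized at
atmospheric pressure) are observed on *different* filters, so cells cannot
be tracked individually. Cells whose activity falls in the same log10
uptake bin under both conditions are piezotolerant; the remaining
(unmatched) histogram mass must have moved between bins upon
depressurization — upward moves are piezosensitive, downward moves
piezophilic. Because the transport plan between the unmatched masses is
not identified, only minimum and maximum abundances of the two moving
classes are defined; both bounds are computed exactly from cumulative
boundary mass balances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autoradiography import ActivityHistogram

MASS_TOL = 1e-9  # tolerance for mass-balance checks, fraction of total


@dataclass(frozen=True)
class PiezoClassification:
    """Tolerant fraction plus bounds for the sensitive and philic classes.

    All fractions refer to active cells. Exact sum rules:
    moved_mass M = 1 − tolerant; sensitive_min + philic_max = M;
    sensitive_max + philic_min = M. Midpoints are reported when a single
    number per class is needed.
    """

    tolerant: float
    sensitive_min: float
    sensitive_max: float
    philic_min: float
    philic_max: float
    moved_mass: float
    width: float
    anchor: float

    def __post_init__(self) -> None:
        for name in ("tolerant", "sensitive_min", "sensitive_max", "philic_min", "philic_max", "moved_mass"):
            v = getattr(self, name)
            if not (-MASS_TOL <= v <= 1 + MASS_TOL):
                raise ValueError(f"{name}={v} outside [0,1]")
        if abs(self.moved_mass - (1.0 - self.tolerant)) > MASS_TOL:
            raise ValueError("moved_mass must equal 1 - tolerant")
        if self.sensitive_min > self.sensitive_max + MASS_TOL:
            raise ValueError("sensitive bounds out of order")
        if self.philic_min > self.philic_max + MASS_TOL:
            raise ValueError("philic bounds out of order")
        if abs(self.sensitive_min + self.philic_max - self.moved_mass) > MASS_TOL:
            raise ValueError("sensitive_min + philic_max must equal moved_mass")
        if abs(self.sensitive_max + self.philic_min - self.moved_mass) > MASS_TOL:
            raise ValueError("sensitive_max + philic_min must equal moved_mass")

    @property
    def sensitive_mid(self) -> float:
        return 0.5 * (self.sensitive_min + self.sensitive_max)

    @property
    def philic_mid(self) -> float:
        return 0.5 * (self.philic_min + self.philic_max)

    def to_dict(self) -> dict:
        return {
            "tolerant": self.tolerant,
            "sensitive_min": self.sensitive_min,
            "sensitive_max": self.sensitive_max,
            "sensitive_mid": self.sensitive_mid,
            "philic_min": self.philic_min,
            "philic_max": self.philic_max,
            "philic_mid": self.philic_mid,
            "moved_mass": self.moved_mass,
            "bin_width": self.width,
            "anchor": self.anchor,
        }


def match_tolerant(
    hist_in: ActivityHistogram, hist_atm: ActivityHistogram
) -> tuple[float, np.ndarray, np.ndarray]:
    """Histogram intersection: the same-bin (piezotolerant) mass.

    Both histograms are normalized to their own active-cell totals (the two
    filters observe different numbers of cells). Returns the tolerant
    fraction Σ_b min(p_in, p_atm) and the per-bin residual (unmatched)
    masses of each condition; at every bin at most one residual is nonzero
    and both residuals total the moved mass M.
    """
    if hist_in.width != hist_atm.width or hist_in.anchor != hist_atm.anchor:
        raise ValueError("histograms must share bin width and anchor")
    if len(hist_in.counts) != len(hist_atm.counts) or not np.allclose(
        hist_in.edges, hist_atm.edges
    ):
        raise ValueError("histograms must share bin edges")
    p_in = hist_in.proportions
    p_atm = hist_atm.proportions
    matched = np.minimum(p_in, p_atm)
    return float(matched.sum()), p_in - matched, p_atm - matched


def transport_bounds(
    residual_in: np.ndarray, residual_atm: np.ndarray, tol: float = MASS_TOL
) -> tuple[float, float, float, float]:
    """Bounds on upward- and downward-moved mass over all transport plans.

    A transport plan moves the in-situ residual mass onto the atmospheric
    residual mass bin-by-bin; mass arriving in a higher bin moved *up*
    (higher activity when depressurized → piezosensitive), in a lower bin
    *down* (piezophilic). For each bin boundary k let I_{>k} and A_{>k} be
    the residual masses strictly above k. Any feasible plan must move at
    least (I_{>k} − A_{>k})⁺ downward and (A_{>k} − I_{>k})⁺ upward across
    k, so

        down_min = max_k (I_{>k} − A_{>k})⁺,   up_min = max_k (A_{>k} − I_{>k})⁺,
        up_max = M − down_min,                 down_max = M − up_min,

    and all four bounds are attained (verified against an exact
    linear-program oracle in the test suite).

    Returns ``(up_min, up_max, down_min, down_max)``.
    """
    i = np.asarray(residual_in, dtype=float)
    a = np.asarray(residual_atm, dtype=float)
    if i.shape != a.shape:
        raise ValueError("residuals must share the binning")
    if np.any(i < -tol) or np.any(a < -tol):
        raise ValueError("residual masses must be non-negative")
    total_i, total_a = float(i.sum()), float(a.sum())
    if abs(total_i - total_a) > max(tol, tol * max(total_i, total_a, 1.0)):
        raise ValueError("residual totals differ beyond tolerance")
    m = total_i
    if m <= tol:
        return 0.0, 0.0, 0.0, 0.0
    # suffix sums: mass strictly above boundary k (k = index of the bin below)
    i_above = np.cumsum(i[::-1])[::-1]
    a_above = np.cumsum(a[::-1])[::-1]
    diff = i_above[1:] - a_above[1:]  # boundaries between consecutive bins
    down_min = float(max(0.0, diff.max(initial=0.0)))
    up_min = float(max(0.0, (-diff).max(initial=0.0)))
    return up_min, m - down_min, down_min, m - up_min


def classify(hist_in: ActivityHistogram, hist_atm: ActivityHistogram) -> PiezoClassification:
    """Full decomposition: intersection match then transport bounds."""
    tolerant, res_in, res_atm = match_tolerant(hist_in, hist_atm)
    up_min, up_max, down_min, down_max = transport_bounds(res_in, res_atm)
    return PiezoClassification(
        tolerant=tolerant,
        sensitive_min=up_min,
        sensitive_max=up_max,
        philic_min=down_min,
        philic_max=down_max,
        moved_mass=1.0 - tolerant,
        width=hist_in.width,
        anchor=hist_in.anchor,
    )
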