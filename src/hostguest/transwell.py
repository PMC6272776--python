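"""Apparent permeability (P_app) from Transwell time-courses.

A Transwell assay measures transport across a cell monolayer from an apical
(donor) to a basolateral (acceptor) chamber.  At each sampling time an
aliquot is drawn from the basolateral chamber and replaced with fresh
medium, so the measured concentrations must be corrected for the mass
removed earlier before they describe cumulative transport:

    Q_i = V_b · C_i + V_sample · Σ_{j<i} C_j     (μg)

The cumulative concentration Q_i / V_b is fitted with a quadratic in time
(transport curves flatten as the acceptor fills), the initial slope dQ/dt
is taken — by default as the fit's derivative at t = 0 — and

    P_app = (dQ/dt) · V_b / (A · C_0)            (cm·s⁻¹)

Classification follows the Caco-2 conventions: P_app above 1×10⁻⁶ cm·s⁻¹
indicates high absorption/permeation potential and above 2×10⁻⁶ cm·s⁻¹ a
bioavailability over 90 %.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "PAPP_HIGH",
    "PAPP_HIGH_BIOAVAILABLE",
    "TranswellGeometry",
    "TimeCourse",
    "PappResult",
    "read_time_course",
    "write_time_course",
    "cumulative_amounts",
    "fit_cumulative",
    "initial_slope",
    "compute_papp",
    "classify_permeability",
    "dose_equivalent",
]

#: P_app thresholds, cm·s⁻¹
PAPP_HIGH = 1.0e-6
PAPP_HIGH_BIOAVAILABLE = 2.0e-6

SlopeMode = Literal["derivative-at-zero", "first-k-points"]


@dataclass(frozen=True)
class TranswellGeometry:
    """Chamber geometry: area (cm²) and volumes (mL)."""

    area: float = 0.336
    v_basolateral: float = 0.9
    v_apical: float = 0.3
    v_sample: float = 0.1

    def __post_init__(self) -> None:
        if min(self.area, self.v_basolateral, self.v_apical, self.v_sample) <= 0:
            raise ValueError("geometry values must be positive")
        if self.v_sample >= self.v_basolateral:
            raise ValueError("sample volume must be smaller than the basolateral volume")


@dataclass
class TimeCourse:
    """Sampled basolateral concentrations over time.

    ``times`` in minutes (strictly increasing), ``conc_basolateral`` in
    μg·mL⁻¹ as measured in each drawn aliquot, ``c0_apical`` the initial
    donor concentration in μg·mL⁻¹.
    """

    times: np.ndarray
    conc_basolateral: np.ndarray
    c0_apical: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.conc_basolateral = np.asarray(self.conc_basolateral, dtype=float).ravel()
        if len(self.times) != len(self.conc_basolateral):
            raise ValueError("times and concentrations must have equal length")
        if len(self.times) < 2:
            raise ValueError("need at least 2 samples")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.conc_basolateral < 0):
            raise ValueError("concentrations must be non-negative")
        if not self.c0_apical > 0:
            raise ValueError("c0_apical must be positive")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class PappResult:
    papp_cm_s: float
    slope: float                       # μg·mL⁻¹·s⁻¹, cumulative concentration
    fit_coefficients: tuple[float, float, float]   # Q(t) = a + b t + c t², t in s
    n_points_used: int
    permeation_class: str

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# I/O


def read_time_course(path: str | Path, c0_apical: float) -> TimeCourse:
    """Read a `time_min,conc_ug_per_ml` CSV into a TimeCourse."""
    df = pd.read_csv(path)
    if not {"time_min", "conc_ug_per_ml"} <= set(df.columns):
        raise ValueError(f"{path}: need 'time_min' and 'conc_ug_per_ml' columns")
    return TimeCourse(df["time_min"].to_numpy(), df["conc_ug_per_ml"].to_numpy(),
                      c0_apical)


def write_time_course(tc: TimeCourse, path: str | Path) -> None:
    pd.DataFrame({"time_min": tc.times, "conc_ug_per_ml": tc.conc_basolateral}
                 ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# analysis steps


def cumulative_amounts(tc: TimeCourse, geom: TranswellGeometry = TranswellGeometry(),
                       correct_sampling: bool = True) -> np.ndarray:
    """Cumulative transported amounts (μg), sampling-replacement corrected.

    The drawn aliquot (``geom.v_sample``) is assumed replaced by drug-free
    medium, so the amount removed at each earlier draw is added back.  With
    ``correct_sampling=False`` the raw chamber contents ``V_b · C_i`` are
    returned for comparison.
    """
    c = tc.conc_basolateral
    present = geom.v_basolateral * c
    if not correct_sampling:
        return present
    removed_before = geom.v_sample * np.concatenate([[0.0], np.cumsum(c)[:-1]])
    return present + removed_before


def fit_cumulative(times_min: np.ndarray, q: np.ndarray) -> tuple[float, float, float]:
    """Least-squares quadratic fit Q(t) = a + b·t + c·t², t in seconds.

    Falls back to a line (c = 0) for exactly 2 points.
    """
    t = np.asarray(times_min, dtype=float) * 60.0
    q = np.asarray(q, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 points to fit")
    deg = 2 if len(t) >= 3 else 1
    # fit on t/t_max for conditioning; back-transform is exact
    scale = np.max(np.abs(t)) or 1.0
    coeffs = np.polynomial.polynomial.polyfit(t / scale, q, deg)
    a, b = float(coeffs[0]), float(coeffs[1] / scale)
    c = float(coeffs[2] / scale**2) if deg == 2 else 0.0
    return (a, b, c)


def initial_slope(fit: tuple[float, float, float],
                  times_min: np.ndarray | None = None,
                  q: np.ndarray | None = None,
                  mode: SlopeMode = "derivative-at-zero",
                  k: int = 3) -> float:
    """Initial slope dQ/dt (per second) of a cumulative curve.

    ``derivative-at-zero`` returns the quadratic fit's linear coefficient;
    ``first-k-points`` refits a line through the first ``k`` raw points
    (default 3), for when the quadratic's extrapolation to t = 0 is not
    trusted.
    """
    if mode == "derivative-at-zero":
        slope = fit[1]
    elif mode == "first-k-points":
        if times_min is None or q is None:
            raise ValueError("first-k-points mode needs the raw points")
        t = np.asarray(times_min, dtype=float)[:k] * 60.0
        qq = np.asarray(q, dtype=float)[:k]
        if len(t) < 2:
            raise ValueError("first-k-points mode needs at least 2 points")
        slope = float(np.polynomial.polynomial.polyfit(t, qq, 1)[1])
    else:
        raise ValueError(f"unknown slope mode {mode!r}")
    if slope < 0:
        warnings.warn("negative initial slope: flux reversal in the time-course",
                      stacklevel=2)
    return float(slope)


def compute_papp(tc: TimeCourse, geom: TranswellGeometry = TranswellGeometry(),
                 mode: SlopeMode = "derivative-at-zero", k: int = 3,
                 max_time_min: float | None = None,
                 correct_sampling: bool = True) -> PappResult:
    """Full P_app pipeline: correction → fit → initial slope → Eq. scaling.

    ``max_time_min`` drops late samples (e.g. after flux reversal) before
    fitting.
    """
    times, conc = tc.times, tc.conc_basolateral
    if max_time_min is not None:
        keep = times <= max_time_min
        if keep.sum() < 2:
            raise ValueError("max_time_min leaves fewer than 2 points")
        tc = TimeCourse(times[keep], conc[keep], tc.c0_apical)
        times = tc.times
    q_conc = cumulative_amounts(tc, geom, correct_sampling) / geom.v_basolateral
    fit = fit_cumulative(times, q_conc)
    slope = initial_slope(fit, times, q_conc, mode=mode, k=k)
    papp = slope * geom.v_basolateral / (geom.area * tc.c0_apical)
    cls = classify_permeability(max(papp, 0.0))
    return PappResult(float(papp), slope, fit, len(times), cls)


def classify_permeability(papp: float, high: float = PAPP_HIGH,
                          high_bioavailable: float = PAPP_HIGH_BIOAVAILABLE) -> str:
    """'low' (≤1e-6), 'high' (≤2e-6) or 'high_bioavailable' (>2e-6 cm·s⁻¹)."""
    if papp < 0:
        raise ValueError("P_app must be non-negative")
    if papp <= high:
        return "low"
    if papp <= high_bioavailable:
        return "high"
    return "high_bioavailable"


def dose_equivalent(drug_conc: float, drug_mass_fraction: float) -> float:
    """Complex concentration (μg·mL⁻¹) delivering a target free-drug dose.

    For a complex loaded with a mass fraction ``f`` of drug, a drug dose of
    ``c`` μg·mL⁻¹ requires ``c / f`` μg·mL⁻¹ of complex (e.g. 40 μg·mL⁻¹ at
    8.6 w% → ≈465 μg·mL⁻¹ of complex).
    """
    if not (0.0 < drug_mass_fraction <= 1.0):
        raise ValueError("drug mass fraction must lie in (0, 1]")
    if drug_conc < 0:
        raise ValueError("drug concentration must be non-negative")
    return drug_conc / drug_mass_fraction
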