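"""Molecular lipophilicity potential (MLP) fields and logP back-calculation.

The MLP at a spatial point *k* is the sum over molecular fragments *i* of
the fragment's lipophilic constant weighted by a decreasing function of the
fragment–point distance:

    MLP(k) = sum_i f_i * fct(d_ik)

Positive values mark hydrophobic regions, negative values polar ones.
Splitting a field into its hydrophobic and polar sums (Σ⁺, Σ⁻) supports two
downstream quantities: the pocket lipophilicity index (see
:mod:`hostguest.pocket`) and a back-calculated octanol/water partition
coefficient

    logP_MLP = Σ⁺ · w⁺ + Σ⁻ · w⁻ + C

whose weights (w⁺, w⁻, C) are calibrated by ordinary least squares against
molecules with experimentally known logP.  No pre-calibrated weights are
shipped: the defaults (1, 1, 0) give relative, not absolute, logP_MLP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structures import FragmentSystem, Molecule, assign_constants

__all__ = [
    "DistanceWeight",
    "MLPField",
    "LogPCalibration",
    "CalibrationError",
    "mlp_at_points",
    "mlp_sums",
    "logp_mlp",
    "calibrate_logp",
    "write_field_csv",
    "read_field_csv",
    "write_field_pdb",
]


@dataclass(frozen=True)
class DistanceWeight:
    """Distance weighting ``fct``: exponential exp(-d/2) or hyperbolic 1/(1+d).

    Contributions beyond ``cutoff`` (Å) are zero; ``cutoff=inf`` disables
    truncation.
    """

    form: str = "exponential"
    cutoff: float = 10.0

    def __post_init__(self) -> None:
        if self.form not in ("exponential", "hyperbolic"):
            raise ValueError(f"unknown distance-weight form {self.form!r}")
        if not self.cutoff > 0:
            raise ValueError("cutoff must be positive")

    def __call__(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        if self.form == "exponential":
            w = np.exp(-d / 2.0)
        else:
            w = 1.0 / (1.0 + d)
        return np.where(d > self.cutoff, 0.0, w)


@dataclass
class MLPField:
    """MLP values sampled at a set of fitting points."""

    points: np.ndarray
    values: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.points) != len(self.values):
            raise ValueError("points and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("MLP values must be finite")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class LogPCalibration:
    """Weights of the logP back-calculation: logP = Σ⁺·w⁺ + Σ⁻·w⁻ + C."""

    w_plus: float = 1.0
    w_minus: float = 1.0
    intercept_C: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.w_plus, self.w_minus, self.intercept_C):
            if not np.isfinite(v):
                raise ValueError("calibration parameters must be finite")


class CalibrationError(ValueError):
    """Raised when the logP calibration design is unusable."""


def mlp_at_points(points: np.ndarray, mol: Molecule, fs: FragmentSystem,
                  weight: DistanceWeight = DistanceWeight(),
                  mode: str = "strict") -> MLPField:
    """Evaluate the MLP field of ``mol`` at ``points``.

    Vectorised over the full point x atom distance matrix; atoms farther
    than the weight's cutoff contribute zero.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) == 0:
        raise ValueError("points must be non-empty")
    f = assign_constants(mol, fs, mode=mode)
    d = cdist(points, mol.coordinates)
    values = weight(d) @ f
    return MLPField(points, values, source=f"{mol.name}/{fs.name}/{weight.form}")


def mlp_sums(fld: MLPField) -> tuple[float, float]:
    """Hydrophobic and polar sums (Σ⁺ ≥ 0, Σ⁻ ≤ 0) of a field."""
    v = fld.values
    return float(np.sum(v[v > 0])), float(np.sum(v[v < 0]))


def logp_mlp(fld: MLPField, calib: LogPCalibration = LogPCalibration()) -> float:
    """Back-calculate logP from a field under a calibration."""
    if calib == LogPCalibration():
        warnings.warn(
            "using uncalibrated weights (1, 1, 0); absolute logP_MLP requires "
            "calibration against experimental logP values",
            stacklevel=2,
        )
    s_plus, s_minus = mlp_sums(fld)
    return s_plus * calib.w_plus + s_minus * calib.w_minus + calib.intercept_C


def calibrate_logp(training: Sequence[tuple[MLPField, float]]) -> tuple[LogPCalibration, float]:
    """Least-squares fit of (w⁺, w⁻, C) to (field, experimental logP) pairs.

    Returns the calibration and the residual sum of squares.  Requires at
    least 3 records and a full-rank design (both Σ⁺ and Σ⁻ must vary).
    """
    if len(training) < 3:
        raise CalibrationError("calibration needs at least 3 training records")
    sums = np.array([mlp_sums(fld) for fld, _ in training])
    y = np.array([logp for _, logp in training], dtype=float)
    X = np.column_stack([sums[:, 0], sums[:, 1], np.ones(len(y))])
    if np.linalg.matrix_rank(X) < 3:
        raise CalibrationError("rank-deficient design: Σ⁺/Σ⁻ columns do not vary independently")
    beta, residual, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(residual[0]) if residual.size else float(np.sum((X @ beta - y) ** 2))
    return LogPCalibration(*map(float, beta)), rss


# ---------------------------------------------------------------------------
# field I/O


def write_field_csv(fld: MLPField, path: str | Path) -> None:
    df = pd.DataFrame(fld.points, columns=["x", "y", "z"])
    df["mlp"] = fld.values
    df.to_csv(path, index=False)


def read_field_csv(path: str | Path) -> MLPField:
    df = pd.read_csv(path)
    return MLPField(df[["x", "y", "z"]].to_numpy(), df["mlp"].to_numpy(),
                    source=str(path))


def write_field_pdb(fld: MLPField, path: str | Path) -> None:
    """Point cloud as PDB HETATM pseudo-atoms with MLP in the B-factor column.

    Visualization aid only; B-factors are clipped to the column's fixed
    width.
    """
    lines = []
    for i, (p, v) in enumerate(zip(fld.points, fld.values), start=1):
        serial = i % 100000
        b = float(np.clip(v, -99.99, 999.99))
        lines.append(
            f"HETATM{serial:5d}  MLP PNT A{i % 10000:4d}    "
            f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}{1.0:6.2f}{b:6.2f}           X"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
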