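"""Docking-pose post-processing: clustering, summaries, ΔG ↔ K conversion.

Poses carry an estimated Gibbs free energy of binding ΔG_bind (kcal·mol⁻¹)
and, optionally, guest coordinates in the shared receptor frame.  The
energy-to-constant conversion uses the dissociation-scale convention

    K = exp(ΔG / RT),   R = 1.9872e-3 kcal·mol⁻¹·K⁻¹

so that weaker binding (less negative ΔG) maps to a larger constant; a
ΔG of about −1.7 kcal·mol⁻¹ lands in the tens of millimolar.  ΔG_bind at or
below −6.0 kcal·mol⁻¹ is classed as high affinity.

RMSD between poses is computed without superposition: docked poses share
the receptor frame, and aligning them would erase exactly the translational
diversity a distance-threshold clustering is meant to detect.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "R_KCAL",
    "DG_HIGH_AFFINITY",
    "Pose",
    "PoseCluster",
    "BindingSummary",
    "PoseTableError",
    "read_pose_table",
    "write_pose_table",
    "pose_rmsd",
    "cluster_poses",
    "delta_g_to_k",
    "k_to_delta_g",
    "summarize_top_poses",
    "classify_affinity",
]

#: gas constant, kcal·mol⁻¹·K⁻¹
R_KCAL = 1.9872e-3

#: ΔG_bind threshold (kcal·mol⁻¹): at or below → high affinity
DG_HIGH_AFFINITY = -6.0


class PoseTableError(ValueError):
    """Raised on malformed pose tables."""


@dataclass
class Pose:
    """One docking pose: binding free energy and optional guest coordinates."""

    delta_g: float
    coordinates: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_g):
            raise ValueError("delta_g must be finite")
        if self.coordinates is not None:
            self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)


@dataclass
class PoseCluster:
    representative: Pose
    members: list[Pose]


@dataclass
class BindingSummary:
    """Mean/sd of ΔG over the selected poses and of the per-pose constants (mM)."""

    n_poses: int
    mean_dg: float
    sd_dg: float
    mean_k_mM: float
    sd_k_mM: float
    temperature_K: float

    @property
    def affinity_class(self) -> str:
        return classify_affinity(self.mean_dg)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["affinity_class"] = self.affinity_class
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# pose table I/O
#
# CSV dialect: header `label,delta_g[,x0,y0,z0,x1,...]`; coordinate columns
# optional but, when present, complete for every row.


def read_pose_table(path: str | Path) -> list[Pose]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise PoseTableError(f"{path}: cannot parse CSV: {exc}") from exc
    if "delta_g" not in df.columns or "label" not in df.columns:
        raise PoseTableError(f"{path}: need 'label' and 'delta_g' columns")
    coord_cols = [c for c in df.columns if c not in ("label", "delta_g")]
    if len(coord_cols) % 3:
        raise PoseTableError(f"{path}: coordinate columns not a multiple of 3")
    poses = []
    for row_idx, row in df.iterrows():
        try:
            dg = float(row["delta_g"])
        except (TypeError, ValueError) as exc:
            raise PoseTableError(
                f"{path}: non-numeric delta_g in data row {row_idx + 1}") from exc
        coords = None
        if coord_cols:
            vals = row[coord_cols].to_numpy(dtype=float)
            if np.isnan(vals).any():
                raise PoseTableError(
                    f"{path}: missing coordinates in data row {row_idx + 1}")
            coords = vals.reshape(-1, 3)
        poses.append(Pose(dg, coords, str(row["label"])))
    _check_atom_counts(poses)
    return poses


def write_pose_table(poses: Sequence[Pose], path: str | Path) -> None:
    _check_atom_counts(poses)
    records = []
    for p in poses:
        rec: dict = {"label": p.label, "delta_g": p.delta_g}
        if p.coordinates is not None:
            for i, (x, y, z) in enumerate(p.coordinates):
                rec.update({f"x{i}": x, f"y{i}": y, f"z{i}": z})
        records.append(rec)
    pd.DataFrame(records).to_csv(path, index=False)


def _check_atom_counts(poses: Sequence[Pose]) -> None:
    counts = {0 if p.coordinates is None else len(p.coordinates) for p in poses}
    if len(counts) > 1:
        raise PoseTableError(f"inconsistent atom counts across poses: {sorted(counts)}")


# ---------------------------------------------------------------------------
# geometry and clustering


def pose_rmsd(a: Pose, b: Pose) -> float:
    """Root-mean-square atomic distance between two poses, Å (no alignment)."""
    if a.coordinates is None or b.coordinates is None:
        raise ValueError("both poses need coordinates for RMSD")
    if a.coordinates.shape != b.coordinates.shape:
        raise ValueError("atom-count mismatch between poses")
    diff = a.coordinates - b.coordinates
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def cluster_poses(poses: Sequence[Pose], threshold: float = 2.0) -> list[PoseCluster]:
    """Greedy energy-ordered clustering at an RMSD threshold (default 2 Å).

    The lowest-ΔG unassigned pose seeds a cluster and absorbs every
    unassigned pose within ``threshold`` RMSD of it; clusters come out
    ordered by seed energy.
    """
    if not poses:
        raise ValueError("need at least one pose")
    order = sorted(range(len(poses)), key=lambda i: (poses[i].delta_g, i))
    unassigned = set(order)
    clusters: list[PoseCluster] = []
    for seed_idx in order:
        if seed_idx not in unassigned:
            continue
        seed = poses[seed_idx]
        members = [seed_idx]
        unassigned.discard(seed_idx)
        for j in order:
            if j in unassigned and pose_rmsd(seed, poses[j]) <= threshold:
                members.append(j)
                unassigned.discard(j)
        clusters.append(PoseCluster(seed, [poses[j] for j in members]))
    return clusters


# ---------------------------------------------------------------------------
# thermodynamics


def delta_g_to_k(delta_g: float, temperature: float = 298.15) -> float:
    """Dissociation-scale constant (molar) from ΔG_bind (kcal·mol⁻¹)."""
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    return math.exp(delta_g / (R_KCAL * temperature))


def k_to_delta_g(k: float, temperature: float = 298.15) -> float:
    """ΔG_bind (kcal·mol⁻¹) from a dissociation-scale constant (molar)."""
    if not k > 0:
        raise ValueError("constant must be positive")
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    return R_KCAL * temperature * math.log(k)


def classify_affinity(delta_g: float, threshold: float = DG_HIGH_AFFINITY) -> str:
    """'high' for ΔG_bind ≤ −6.0 kcal·mol⁻¹, else 'low'."""
    if not math.isfinite(delta_g):
        raise ValueError("delta_g must be finite")
    return "high" if delta_g <= threshold else "low"


def summarize_top_poses(poses: Sequence[Pose], k: int = 3,
                        temperature: float = 298.15,
                        cluster_first: bool = False,
                        rmsd_threshold: float = 2.0) -> BindingSummary:
    """Mean ± sd of ΔG over the k lowest-energy poses, with K conversion.

    Constants are converted per pose and then averaged (mM scale).  With
    ``cluster_first`` the k poses are the representatives of the lowest-
    energy RMSD clusters instead of the k raw lowest energies.
    """
    if not poses:
        raise ValueError("need at least one pose")
    if k < 1:
        raise ValueError("k must be >= 1")
    pool: Sequence[Pose] = poses
    if cluster_first:
        pool = [c.representative for c in cluster_poses(poses, rmsd_threshold)]
    if k > len(pool):
        warnings.warn(f"requested top {k} poses but only {len(pool)} available",
                      stacklevel=2)
        k = len(pool)
    top = sorted(pool, key=lambda p: p.delta_g)[:k]
    dgs = np.array([p.delta_g for p in top])
    ks_mM = np.array([delta_g_to_k(dg, temperature) * 1e3 for dg in dgs])
    sd = float(np.std(dgs, ddof=1)) if len(dgs) > 1 else 0.0
    sd_k = float(np.std(ks_mM, ddof=1)) if len(ks_mM) > 1 else 0.0
    return BindingSummary(len(dgs), float(np.mean(dgs)), sd,
                          float(np.mean(ks_mM)), sd_k, temperature)
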