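"""Binding-pocket fitting points and the lipophilicity index (LI).

A pocket is scored by placing fitting points on a cubic grid inside a
sphere, discarding points buried in the molecule's van der Waals volume,
evaluating the MLP there, and computing

    LI = |Σ⁺| / (|Σ⁺| + |Σ⁻|) × 100 %

LI below 10 % marks a polar binding site; at or above 10 %, non-polar (the
boundary is assigned to non-polar because polar is defined strictly as
LI < 10 %).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np
from scipy.spatial.distance import cdist

from .mlp import DistanceWeight, MLPField, mlp_at_points, mlp_sums
from .structures import FragmentSystem, Molecule

__all__ = [
    "PocketDefinition",
    "PocketProfile",
    "EmptyPocketError",
    "UndefinedLIError",
    "LI_POLAR_THRESHOLD",
    "DEFAULT_POCKET_CENTER",
    "generate_fitting_points",
    "lipophilicity_index",
    "classify_site",
    "profile_pocket",
]

#: LI threshold (%) separating polar (<) from non-polar sites
LI_POLAR_THRESHOLD = 10.0

#: default pocket center, matching the docking-box convention used for the
#: cyclodextrin host (Å)
DEFAULT_POCKET_CENTER = np.array([56.49, 12.97, 9.29])


class EmptyPocketError(ValueError):
    """No grid point survives the van der Waals exclusion."""


class UndefinedLIError(ValueError):
    """LI is undefined for an all-zero MLP field."""


@dataclass(frozen=True)
class PocketDefinition:
    """Spherical pocket: center (Å), radius (Å), cubic-grid spacing (Å)."""

    center: tuple[float, float, float] = tuple(DEFAULT_POCKET_CENTER)
    radius: float = 5.0
    spacing: float = 1.0

    def __post_init__(self) -> None:
        if not (self.radius >= self.spacing > 0):
            raise ValueError("need radius >= spacing > 0")


@dataclass
class PocketProfile:
    li_percent: float
    sum_plus: float
    sum_minus: float
    n_points: int
    site_class: Literal["polar", "non-polar"]

    def to_dict(self) -> dict:
        return asdict(self)


def generate_fitting_points(pocket: PocketDefinition,
                            mol: Molecule | None = None) -> np.ndarray:
    """Cubic-grid fitting points inside the pocket sphere.

    Grid nodes are spaced ``pocket.spacing`` apart, anchored at the center,
    kept if within ``pocket.radius`` of the center and outside every atom's
    van der Waals sphere.  Points are ordered lexicographically by
    (x, y, z).
    """
    center = np.asarray(pocket.center, dtype=float)
    n = int(np.floor(pocket.radius / pocket.spacing))
    offsets = np.arange(-n, n + 1) * pocket.spacing
    gx, gy, gz = np.meshgrid(offsets, offsets, offsets, indexing="ij")
    pts = center + np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    inside = np.linalg.norm(pts - center, axis=1) <= pocket.radius + 1e-9
    pts = pts[inside]
    if mol is not None and len(mol):
        d = cdist(pts, mol.coordinates)
        buried = (d < mol.vdw_radii[None, :]).any(axis=1)
        pts = pts[~buried]
    if len(pts) == 0:
        raise EmptyPocketError("no fitting point survives the vdW exclusion")
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
    return pts[order]


def lipophilicity_index(fld: MLPField) -> float:
    """LI in percent: hydrophobic share of the field's absolute MLP."""
    s_plus, s_minus = mlp_sums(fld)
    denom = abs(s_plus) + abs(s_minus)
    if denom == 0:
        raise UndefinedLIError("all MLP values are zero; LI undefined")
    return abs(s_plus) / denom * 100.0


def classify_site(li_percent: float, threshold: float = LI_POLAR_THRESHOLD) -> str:
    if not (0.0 <= li_percent <= 100.0):
        raise ValueError(f"LI must lie in [0, 100], got {li_percent}")
    return "polar" if li_percent < threshold else "non-polar"


def profile_pocket(mol: Molecule, fs: FragmentSystem,
                   pocket: PocketDefinition = PocketDefinition(),
                   weight: DistanceWeight = DistanceWeight(),
                   mode: str = "strict") -> PocketProfile:
    """End-to-end pocket polarity profile: points → MLP → LI → class."""
    pts = generate_fitting_points(pocket, mol)
    fld = mlp_at_points(pts, mol, fs, weight, mode=mode)
    li = lipophilicity_index(fld)
    s_plus, s_minus = mlp_sums(fld)
    return PocketProfile(li, s_plus, s_minus, len(fld), classify_site(li))
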