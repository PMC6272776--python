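"""Synthetic inputs with the structure the analysis pipeline assumes.

Three generators cover the three data streams:

* :func:`make_cage_host` — a torus-like pseudo-molecule of two concentric
  atom rings around an empty central cavity, standing in for an amphiphilic
  cage host (cyclodextrin-like) whose interior/exterior polarity is set by
  two fragment constants.
* :func:`simulate_transwell` — basolateral concentration time-courses with
  periodic aliquot sampling and medium replacement, either strictly linear
  (sink conditions) or as a two-compartment exponential approach to
  equilibrium that rises linearly at first and then flattens.
* :func:`make_pose_ensemble` — docking-pose sets with normally distributed
  binding energies around a target mean and coordinate jitter around a
  template guest.

All randomness derives from the spec's seed; identical specs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .binding import Pose
from .structures import Atom, FragmentSystem, Molecule, read_structure, sevoflurane_path
from .transwell import TimeCourse, TranswellGeometry

__all__ = [
    "CageSpec",
    "TranswellSpec",
    "PoseSpec",
    "SyntheticSpec",
    "LLOQ_UG_PER_ML",
    "make_cage_host",
    "cage_fragment_system",
    "simulate_transwell",
    "make_pose_ensemble",
]

#: lower limit of quantification (μg·mL⁻¹) used when censoring is enabled,
#: matching LC-MS/MS-style detection floors
LLOQ_UG_PER_ML = 2.5


@dataclass(frozen=True)
class CageSpec:
    """Geometry and polarity of the synthetic cage host.

    ``n_atoms`` pseudo-atoms per ring; the central cavity of radius
    ``ring_radius / 2`` stays atom-free.
    """

    n_atoms: int = 8
    ring_radius: float = 6.0
    interior_constant: float = -0.4
    exterior_constant: float = -0.4

    def __post_init__(self) -> None:
        if self.n_atoms < 4:
            raise ValueError("need at least 4 atoms per ring")
        if not self.ring_radius > 0:
            raise ValueError("ring_radius must be positive")


@dataclass(frozen=True)
class TranswellSpec:
    """True permeability and measurement model of the simulated assay.

    Defaults mirror the study conditions this generator emulates: a high
    true permeability (1.232e-5 cm·s⁻¹), a 100 mg·mL⁻¹ donor load,
    sampling at 5/15/30/60/120 min and 5 % multiplicative measurement
    noise.
    """

    papp_true: float = 12.32e-6
    c0: float = 1.0e5
    times_min: tuple[float, ...] = (5.0, 15.0, 30.0, 60.0, 120.0)
    noise_sd: float = 0.05
    model: str = "sink_linear"

    def __post_init__(self) -> None:
        if self.papp_true < 0:
            raise ValueError("papp_true must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.model not in ("sink_linear", "two_compartment"):
            raise ValueError(f"unknown transport model {self.model!r}")


@dataclass(frozen=True)
class PoseSpec:
    """Docking-pose ensemble: Normal(mean_dg, sd_dg) energies, jittered coordinates."""

    mean_dg: float = -1.727
    sd_dg: float = 0.042
    n: int = 100
    coordinate_jitter: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("need at least one pose")
        if self.sd_dg < 0 or self.coordinate_jitter < 0:
            raise ValueError("scales must be non-negative")


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int = 0
    cage: CageSpec = field(default_factory=CageSpec)
    transwell: TranswellSpec = field(default_factory=TranswellSpec)
    poses: PoseSpec = field(default_factory=PoseSpec)

    def with_seed(self, seed: int) -> "SyntheticSpec":
        return replace(self, seed=seed)


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    # independent child streams so e.g. pose draws don't shift transwell noise
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), stream]))


# ---------------------------------------------------------------------------
# cage host


def make_cage_host(spec: SyntheticSpec) -> Molecule:
    """Two concentric rings of pseudo-atoms around an empty cavity.

    Inner-ring atoms carry fragment type ``cage_interior``, outer-ring atoms
    ``cage_exterior``; resolve them with :func:`cage_fragment_system`.  The
    construction is deterministic (the seed is carried for provenance
    only).
    """
    cage = spec.cage
    vdw = min(1.5, cage.ring_radius / 2.0)  # keeps the half-radius cavity atom-free
    angles = 2.0 * np.pi * np.arange(cage.n_atoms) / cage.n_atoms
    atoms: list[Atom] = []
    for radius, z, ftype in ((cage.ring_radius, 0.0, "cage_interior"),
                             (1.8 * cage.ring_radius, 0.0, "cage_exterior")):
        for a in angles:
            pos = np.array([radius * np.cos(a), radius * np.sin(a), z])
            atoms.append(Atom("C", pos, vdw, ftype))
    return Molecule(f"cage-host-n{cage.n_atoms}", atoms)


def cage_fragment_system(spec: SyntheticSpec) -> FragmentSystem:
    cage = spec.cage
    return FragmentSystem(
        "cage",
        {"cage_interior": cage.interior_constant,
         "cage_exterior": cage.exterior_constant},
        fallback={"C": cage.exterior_constant},
    )


# ---------------------------------------------------------------------------
# transwell time-courses


def _transported_amount(tw: TranswellSpec, geom: TranswellGeometry,
                        t_s: np.ndarray) -> np.ndarray:
    """Cumulative amount (μg) moved across the barrier by time t (seconds)."""
    flux0 = tw.papp_true * geom.area * tw.c0           # μg·s⁻¹, sink limit
    if tw.model == "sink_linear":
        return flux0 * t_s
    # two-compartment: exponential approach to the mixing equilibrium
    k = tw.papp_true * geom.area * (1.0 / geom.v_apical + 1.0 / geom.v_basolateral)
    q_eq = flux0 / k if k > 0 else np.zeros_like(t_s)
    return q_eq * (1.0 - np.exp(-k * t_s))


def simulate_transwell(spec: SyntheticSpec,
                       geom: TranswellGeometry = TranswellGeometry(),
                       censor_lloq: bool = False) -> TimeCourse:
    """Simulate a sampled basolateral time-course under the spec's model.

    At each sampling time the chamber concentration reflects the transported
    amount minus every previously drawn aliquot (which is replaced by blank
    medium).  Multiplicative Gaussian noise of sd ``noise_sd`` is applied to
    the measured concentrations; with ``censor_lloq`` readings below the
    quantification limit are reported as 0.
    """
    tw = spec.transwell
    t_s = np.asarray(tw.times_min, dtype=float) * 60.0
    q = _transported_amount(tw, geom, t_s)
    conc_true = np.empty_like(q)
    removed = 0.0
    for i, qi in enumerate(q):
        ci = (qi - removed) / geom.v_basolateral
        conc_true[i] = max(ci, 0.0)
        removed += geom.v_sample * conc_true[i]
    conc = conc_true
    if tw.noise_sd > 0:
        rng = _rng(spec, stream=2)
        conc = conc_true * (1.0 + tw.noise_sd * rng.standard_normal(len(conc_true)))
        conc = np.clip(conc, 0.0, None)
    if censor_lloq:
        conc = np.where(conc < LLOQ_UG_PER_ML, 0.0, conc)
    return TimeCourse(np.asarray(tw.times_min, dtype=float), conc, tw.c0)


# ---------------------------------------------------------------------------
# docking poses


def _template_guest() -> np.ndarray:
    return read_structure(sevoflurane_path(), format="sdf").coordinates


def make_pose_ensemble(spec: SyntheticSpec,
                       template: np.ndarray | None = None) -> list[Pose]:
    """Pose set with Normal(mean_dg, sd_dg) energies and jittered geometry.

    The template defaults to the packaged guest conformer; each pose's
    coordinates are the template plus isotropic Gaussian per-atom
    displacements of scale ``coordinate_jitter`` (Å).
    """
    ps = spec.poses
    coords0 = _template_guest() if template is None else np.asarray(template, float)
    rng = _rng(spec, stream=3)
    energies = ps.mean_dg + ps.sd_dg * rng.standard_normal(ps.n)
    poses = []
    for i, dg in enumerate(energies):
        jitter = ps.coordinate_jitter * rng.standard_normal(coords0.shape)
        poses.append(Pose(float(dg), coords0 + jitter, label=f"pose{i:03d}"))
    return poses
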