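"""Molecular structures, file readers and fragment lipophilic constants.

The lipophilicity-potential machinery needs three things from a structure:
heavy-atom coordinates in Å, a van der Waals radius per atom, and a
*fragment type* per atom that keys into a table of lipophilic fragment
constants ``f_i`` (positive = hydrophobic, negative = polar).  This module
provides the :class:`Atom` / :class:`Molecule` containers, readers for the
common small-molecule formats (SDF/MOL V2000 and PDB via RDKit, XYZ via a
small built-in reader), the packaged element tables, and a deterministic
solvent-accessible surface-point sampler.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np

__all__ = [
    "Atom",
    "Molecule",
    "FragmentSystem",
    "StructureParseError",
    "AtomTypingError",
    "DEFAULT_VDW_RADIUS",
    "load_vdw_radii",
    "load_fragment_table",
    "default_fragment_system",
    "read_structure",
    "read_fragment_table",
    "assign_constants",
    "surface_points",
    "sevoflurane_path",
]

#: radius assigned to elements missing from the packaged table (lenient mode)
DEFAULT_VDW_RADIUS = 1.7

Mode = Literal["strict", "lenient"]


class StructureParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


class AtomTypingError(KeyError):
    """Raised when an atom's fragment type cannot be resolved to a constant."""


@dataclass
class Atom:
    """A heavy atom: element symbol, position (Å), vdW radius (Å), type key."""

    element: str
    position: np.ndarray
    vdw_radius: float
    fragment_type: str

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be a finite 3-vector")
        if not self.element:
            raise ValueError("atom element symbol must be non-empty")
        if not (self.vdw_radius > 0):
            raise ValueError("vdw_radius must be positive")


@dataclass
class Molecule:
    """An ordered collection of atoms; atom order follows the input file."""

    name: str
    atoms: list[Atom]
    bonds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("a Molecule needs at least one atom")
        n = len(self.atoms)
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond index ({i}, {j}) out of range for {n} atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) array of positions in Å, in file order."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Molecule":
        """Return a rigidly transformed copy (rotation applied first)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        atoms = [Atom(a.element, R @ a.position + t, a.vdw_radius, a.fragment_type)
                 for a in self.atoms]
        return Molecule(self.name, atoms, list(self.bonds))


@dataclass
class FragmentSystem:
    """Mapping from fragment type to lipophilic constant ``f_i``.

    ``constants`` is the primary lookup; ``fallback`` maps bare element
    symbols and is consulted only in lenient mode.
    """

    name: str
    constants: dict[str, float]
    fallback: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for table in (self.constants, self.fallback):
            for key, value in table.items():
                if not math.isfinite(value):
                    raise ValueError(f"non-finite constant for {key!r}")

    def lookup(self, atom: Atom, index: int, mode: Mode = "strict") -> float:
        if atom.fragment_type in self.constants:
            return self.constants[atom.fragment_type]
        if mode == "lenient" and atom.element in self.fallback:
            return self.fallback[atom.element]
        raise AtomTypingError(
            f"atom {index} (element {atom.element!r}, type {atom.fragment_type!r}) "
            f"has no constant in fragment system {self.name!r}"
        )


# ---------------------------------------------------------------------------
# packaged tables


def _data_path(name: str) -> Path:
    return Path(str(resources.files("hostguest").joinpath("data", name)))


def sevoflurane_path() -> Path:
    """Path of the packaged sevoflurane heavy-atom conformer (SDF).

    A generated conformer (embedded and force-field minimized), not an
    experimental geometry; 12 heavy atoms, C4F7O skeleton.
    """
    return _data_path("sevoflurane.sdf")


def _read_two_column_tsv(path: Path) -> dict[str, float]:
    table: dict[str, float] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise StructureParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        try:
            table[parts[0]] = float(parts[1])
        except ValueError as exc:
            raise StructureParseError(f"{path}:{lineno}: non-numeric constant") from exc
    return table


def load_vdw_radii() -> dict[str, float]:
    """Packaged Bondi-style van der Waals radii, Å, keyed by element."""
    return _read_two_column_tsv(_data_path("vdw_radii.tsv"))


def read_fragment_table(path: str | Path, name: str | None = None) -> FragmentSystem:
    """Read a 2-column TSV (fragment_type, constant; '#' comments) table."""
    path = Path(path)
    constants = _read_two_column_tsv(path)
    # element-keyed entries double as the lenient fallback
    fallback = {k: v for k, v in constants.items() if k.isalpha() and len(k) <= 2}
    return FragmentSystem(name or path.stem, constants, fallback)


def load_fragment_table() -> FragmentSystem:
    """The packaged element-level default fragment system."""
    return read_fragment_table(_data_path("default.tsv"), name="default")


def default_fragment_system() -> FragmentSystem:
    return load_fragment_table()


# ---------------------------------------------------------------------------
# file readers


def _resolve_radius(element: str, radii: dict[str, float], mode: Mode) -> float:
    if element in radii:
        return radii[element]
    if mode == "strict":
        raise StructureParseError(f"unknown element {element!r} (strict mode)")
    warnings.warn(
        f"element {element!r} not in the vdW table; using {DEFAULT_VDW_RADIUS} Å",
        stacklevel=3,
    )
    return DEFAULT_VDW_RADIUS


def _read_xyz(path: Path, radii: dict[str, float], mode: Mode) -> Molecule:
    lines = [ln for ln in path.read_text().splitlines()]
    if not lines:
        raise StructureParseError(f"{path}: empty file")
    # XYZ dialects: with or without the count/comment header
    try:
        declared = int(lines[0].split()[0])
        body = lines[2:2 + declared]
        if len(body) < declared:
            raise StructureParseError(f"{path}: fewer atom records than declared")
    except (ValueError, IndexError):
        declared = None
        body = [ln for ln in lines if ln.strip()]
    atoms = []
    for lineno, line in enumerate(body, start=1):
        parts = line.split()
        if len(parts) < 4:
            raise StructureParseError(f"{path}: malformed atom record on line {lineno}")
        element = parts[0]
        try:
            pos = np.array([float(x) for x in parts[1:4]])
        except ValueError as exc:
            raise StructureParseError(f"{path}: bad coordinates on line {lineno}") from exc
        radius = _resolve_radius(element, radii, mode)
        atoms.append(Atom(element, pos, radius, element))
    if not atoms:
        raise StructureParseError(f"{path}: no atom records")
    return Molecule(path.stem, atoms)


def _read_rdkit(path: Path, fmt: str, radii: dict[str, float], mode: Mode) -> Molecule:
    from rdkit import Chem

    if path.stat().st_size == 0:
        raise StructureParseError(f"{path}: empty file")
    if fmt == "sdf":
        rdmol = Chem.MolFromMolFile(str(path), sanitize=False, removeHs=False)
    else:  # pdb
        rdmol = Chem.MolFromPDBFile(str(path), sanitize=False, removeHs=False)
    if rdmol is None or rdmol.GetNumAtoms() == 0:
        raise StructureParseError(f"{path}: could not parse {fmt.upper()} content")
    conf = rdmol.GetConformer()
    atoms = []
    for i, rdatom in enumerate(rdmol.GetAtoms()):
        element = rdatom.GetSymbol()
        pos = np.array(conf.GetAtomPosition(i))
        radius = _resolve_radius(element, radii, mode)
        atoms.append(Atom(element, pos, radius, element))
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in rdmol.GetBonds()]
    name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") and rdmol.GetProp("_Name") else path.stem
    return Molecule(name, atoms, bonds)


def read_structure(path: str | Path, format: str | None = None,
                   mode: Mode = "strict") -> Molecule:
    """Read an SDF/MOL, PDB or XYZ file into a :class:`Molecule`.

    Atom order follows the file; fragment types are initialised to the
    element symbol (retype against a richer table with
    :func:`assign_constants` input preparation if needed).  Unknown elements
    raise in strict mode and get a default 1.7 Å radius with a warning in
    lenient mode.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".sdf": "sdf", ".mol": "sdf", ".pdb": "pdb", ".xyz": "xyz"}.get(
            path.suffix.lower(), "")
    format = format.lower()
    if format not in {"sdf", "mol", "pdb", "xyz"}:
        raise ValueError(f"unsupported structure format {format!r}")
    radii = load_vdw_radii()
    if format == "xyz":
        return _read_xyz(path, radii, mode)
    return _read_rdkit(path, "sdf" if format in {"sdf", "mol"} else "pdb", radii, mode)


# ---------------------------------------------------------------------------
# constants assignment and surface sampling


def assign_constants(mol: Molecule, fs: FragmentSystem, mode: Mode = "strict") -> np.ndarray:
    """One lipophilic constant ``f_i`` per atom, in atom order."""
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown mode {mode!r}")
    return np.array([fs.lookup(a, i, mode) for i, a in enumerate(mol.atoms)], dtype=float)


def _golden_spiral(n: int) -> np.ndarray:
    """n deterministic, near-uniform unit-sphere points (Fibonacci lattice)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = k * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _molecular_frame(coords: np.ndarray) -> np.ndarray:
    """Right-handed principal-axes frame of a coordinate set.

    Axis signs are fixed by the coordinate skewness along each axis, so for
    generic (non-symmetric) molecules the frame rotates with the molecule.
    Degenerate inputs (single atom, perfectly symmetric sets) fall back to
    a deterministic but arbitrary orientation.
    """
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    if not np.any(np.abs(cov) > 1e-12):
        return np.eye(3)
    _, vecs = np.linalg.eigh(cov)
    axes = vecs[:, ::-1]  # descending variance
    for k in range(2):
        skew = float(np.sum((centered @ axes[:, k]) ** 3))
        if skew < -1e-12:
            axes[:, k] = -axes[:, k]
    axes[:, 2] = np.cross(axes[:, 0], axes[:, 1])
    return axes


def surface_points(mol: Molecule, probe_radius: float = 1.4,
                   points_per_atom: int = 100,
                   frame: np.ndarray | None = None) -> np.ndarray:
    """Solvent-accessible surface points by deterministic sphere sampling.

    ``frame`` overrides the lattice orientation (a 3x3 rotation; default:
    the molecule's principal-axes frame).

    Each atom's sphere of radius ``vdw + probe`` is sampled on a fixed
    golden-spiral lattice expressed in the molecule's principal-axes frame
    (so the point set is rigid-motion covariant for generic molecules); a
    point survives if it is not inside any other atom's probe-expanded
    sphere (Shrake–Rupley criterion).  Points exactly on another sphere's
    surface (within 1e-9 Å) are kept only for the lowest-index atom, so
    duplicated atoms contribute one sphere, not two.
    """
    if points_per_atom < 1:
        raise ValueError("points_per_atom must be >= 1")
    centers = mol.coordinates
    radii = mol.vdw_radii + probe_radius
    if frame is None:
        frame = _molecular_frame(centers)
    unit = _golden_spiral(points_per_atom) @ np.asarray(frame, dtype=float).T
    kept: list[np.ndarray] = []
    for i in range(len(mol)):
        pts = centers[i] + radii[i] * unit
        keep = np.ones(len(pts), dtype=bool)
        for j in range(len(mol)):
            if j == i:
                continue
            d = np.linalg.norm(pts - centers[j], axis=1)
            buried = d < radii[j] - 1e-9
            if j < i:
                buried |= np.abs(d - radii[j]) <= 1e-9  # tie goes to the earlier atom
            keep &= ~buried
        if keep.any():
            kept.append(pts[keep])
    if not kept:
        return np.empty((0, 3))
    return np.vstack(kept)
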