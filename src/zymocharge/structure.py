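"""Structural model handling: PDB parsing, solvent accessibility, distances.

A :class:`Structure` wraps a biotite ``AtomArray`` (heavy atoms only by
default) together with an ordered residue index keyed by
``(chain_id, residue_number, insertion_code)``.

Solvent-accessible surface area is computed with the Shrake-Rupley
test-point method on a deterministic golden-spiral point set, so repeated
runs with the same ``n_sphere_points`` give bit-identical results.  Relative
exposure divides the per-residue sum by the theoretical Gly-X-Gly maximum of
the residue type, the quantity against which the "on the surface" design
filter is applied.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
import biotite.structure as _bstruc
from biotite.structure.io.pdb import PDBFile

from .tables import MAX_ACCESSIBILITY, THREE_TO_ONE, VDW_RADII

__all__ = [
    "Structure",
    "SASAProfile",
    "read_pdb",
    "write_pdb",
    "shrake_rupley_sasa",
    "relative_sasa",
    "min_distance_to_region",
    "golden_spiral_points",
]

ResidueKey = tuple  # (chain_id, residue_number, insertion_code)

_WATER_NAMES = {"HOH", "WAT", "DOD"}


class PDBFormatError(ValueError):
    """Raised for malformed PDB input (with the offending line number)."""


class UnknownElementError(KeyError):
    """Raised when no van der Waals radius is tabulated for an element."""


class Structure:
    """Atomic coordinates plus an ordered per-residue index."""

    def __init__(self, atoms: _bstruc.AtomArray):
        if atoms.array_length() == 0:
            raise ValueError("structure has no atoms")
        self.atoms = atoms
        self._index: dict[ResidueKey, np.ndarray] = {}
        ins = (
            atoms.ins_code
            if "ins_code" in atoms.get_annotation_categories()
            else np.full(atoms.array_length(), "", dtype="U1")
        )
        keys = list(zip(atoms.chain_id, atoms.res_id, ins))
        order: list[ResidueKey] = []
        buckets: dict[ResidueKey, list[int]] = {}
        for i, key in enumerate(keys):
            key = (str(key[0]), int(key[1]), str(key[2]).strip())
            if key not in buckets:
                buckets[key] = []
                order.append(key)
            buckets[key].append(i)
        self._index = {k: np.asarray(buckets[k], dtype=int) for k in order}

    # -- residue-level access ------------------------------------------------
    def residue_keys(self) -> list[ResidueKey]:
        return list(self._index)

    def __contains__(self, key: ResidueKey) -> bool:
        return tuple(key) in self._index

    def atom_indices(self, key: ResidueKey) -> np.ndarray:
        try:
            return self._index[tuple(key)]
        except KeyError:
            raise KeyError(f"residue {key} not in structure") from None

    def coords_of(self, key: ResidueKey) -> np.ndarray:
        return self.atoms.coord[self.atom_indices(key)]

    def res_name(self, key: ResidueKey) -> str:
        return str(self.atoms.res_name[self.atom_indices(key)[0]])

    def chains(self) -> list[str]:
        seen: list[str] = []
        for c, _, _ in self._index:
            if c not in seen:
                seen.append(c)
        return seen

    def n_residues(self) -> int:
        return len(self._index)

    def radii(self, table: dict[str, float] | None = None) -> np.ndarray:
        """Per-atom van der Waals radii from the element column."""
        table = table or VDW_RADII
        out = np.empty(self.atoms.array_length())
        for i, el in enumerate(self.atoms.element):
            key = str(el).strip().upper()
            if key not in table:
                raise UnknownElementError(f"no vdW radius for element {el!r}")
            out[i] = table[key]
        return out


def _check_atom_lines(text: str) -> int:
    """Pre-scan fixed-column ATOM/HETATM records; return their count."""
    n = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        n += 1
        if len(line) < 54:
            raise PDBFormatError(f"line {lineno}: truncated coordinate record")
        for col in (slice(30, 38), slice(38, 46), slice(46, 54)):
            try:
                float(line[col])
            except ValueError:
                raise PDBFormatError(
                    f"line {lineno}: malformed coordinate field {line[col]!r}"
                ) from None
    return n


def read_pdb(
    source,
    include_hydrogens: bool = False,
    include_waters: bool = False,
) -> Structure:
    """Parse a PDB file (path, or a string containing PDB text).

    Fixed-column ATOM/HETATM records are read; waters and hydrogens are
    excluded by default.  Alternate locations are resolved to the
    highest-occupancy conformer (ties broken by altloc letter).
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        text = Path(source).read_text()
    else:
        text = str(source)
    if _check_atom_lines(text) == 0:
        raise PDBFormatError("no ATOM/HETATM records in input")
    pdb = PDBFile.read(io.StringIO(text))
    atoms = pdb.get_structure(
        model=1, altloc="occupancy", extra_fields=["b_factor", "occupancy"]
    )
    mask = np.ones(atoms.array_length(), bool)
    if not include_hydrogens:
        mask &= ~np.isin(atoms.element, ("H", "D"))
    if not include_waters:
        mask &= ~np.isin(atoms.res_name, tuple(_WATER_NAMES))
    atoms = atoms[mask]
    if atoms.array_length() == 0:
        raise PDBFormatError("no atoms left after filtering waters/hydrogens")
    return Structure(atoms)


def write_pdb(structure: Structure, path) -> None:
    """Write ATOM records with 3-decimal coordinates."""
    pdb = PDBFile()
    pdb.set_structure(structure.atoms)
    pdb.write(str(path))


# --------------------------------------------------------------------------
# Shrake-Rupley SASA
# --------------------------------------------------------------------------

def golden_spiral_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform points on the unit sphere (deterministic)."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class SASAProfile:
    """Per-atom and per-residue solvent-accessible surface areas (A^2)."""

    atom_sasa: np.ndarray
    residue_sasa: dict
    probe_radius: float
    n_sphere_points: int

    @property
    def total(self) -> float:
        return float(self.atom_sasa.sum())


def shrake_rupley_sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    radii_table: dict[str, float] | None = None,
) -> SASAProfile:
    """Shrake-Rupley SASA by test-point counting.

    For each atom, ``n_sphere_points`` are placed on a golden-spiral sphere
    of radius ``r_vdw + probe`` and counted as accessible unless they fall
    inside any neighbour's probe-expanded sphere.
    """
    if n_sphere_points < 100:
        raise ValueError("n_sphere_points must be >= 100")
    coords = structure.atoms.coord.astype(float)
    radii = structure.radii(radii_table)
    n_atoms = len(coords)
    unit = golden_spiral_points(n_sphere_points)
    expanded = radii + probe_radius
    tree = cKDTree(coords)
    max_cut = 2.0 * expanded.max()
    neighbor_lists = tree.query_ball_point(coords, r=max_cut)

    atom_sasa = np.empty(n_atoms)
    for i in range(n_atoms):
        ri = expanded[i]
        pts = coords[i] + ri * unit
        nbrs = [j for j in neighbor_lists[i] if j != i]
        if nbrs:
            nbrs = np.asarray(nbrs)
            d = np.linalg.norm(coords[nbrs] - coords[i], axis=1)
            close = nbrs[d < ri + expanded[nbrs]]
        else:
            close = np.empty(0, dtype=int)
        if len(close):
            d2 = cdist(pts, coords[close], "sqeuclidean")
            buried = (d2 < (expanded[close] ** 2)[None, :]).any(axis=1)
            n_free = int((~buried).sum())
        else:
            n_free = n_sphere_points
        atom_sasa[i] = 4.0 * np.pi * ri * ri * n_free / n_sphere_points

    residue_sasa = {
        key: float(atom_sasa[idx].sum())
        for key, idx in ((k, structure.atom_indices(k)) for k in structure.residue_keys())
    }
    return SASAProfile(atom_sasa, residue_sasa, probe_radius, n_sphere_points)


def relative_sasa(
    profile: SASAProfile,
    structure: Structure,
    maxima: dict[str, float] | None = None,
) -> dict:
    """Per-residue relative exposure: absolute SASA over the residue-type
    theoretical maximum (extended Gly-X-Gly values).  May slightly exceed 1
    for highly exposed residues."""
    maxima = maxima or MAX_ACCESSIBILITY
    out = {}
    for key, area in profile.residue_sasa.items():
        name3 = structure.res_name(key)
        one = THREE_TO_ONE.get(name3)
        if one is None or one not in maxima:
            raise KeyError(f"no accessibility maximum for residue type {name3!r}")
        out[key] = area / maxima[one]
    return out


def min_distance_to_region(
    structure: Structure, residue_key: ResidueKey, region) -> float:
    """Minimum heavy-atom distance (A) from a residue to a set of residues.

    A residue that is itself part of the region is at distance 0.
    """
    region = [tuple(k) for k in region]
    if not region:
        raise ValueError("empty region")
    if tuple(residue_key) in region:
        return 0.0
    a = structure.coords_of(residue_key)
    b = np.vstack([structure.coords_of(k) for k in region])
    return float(cdist(a, b).min())
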