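"""Charge profiles and screened-Coulomb surface potentials.

The electrostatic potential is evaluated with the Debye-Hueckel
(screened-Coulomb) approximation

    phi(p) = l_B * sum_i  q_i * exp(-kappa * d_i) / d_i        [kT/e]

with distances in Angstrom, the Bjerrum length ``l_B`` (7.1 A in water at
298 K) and the inverse Debye screening length ``kappa`` set by the ionic
strength.  This is a deliberate, documented approximation to a full
Poisson-Boltzmann solve: there is no low-dielectric protein interior and no
dielectric boundary, but linear superposition holds exactly and the salt
dependence has the correct Debye form.  Unit formal charges sit on a single
representative side-chain atom per charged residue, keeping the map free of
any force-field dependency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

from .tables import CHARGE, CHARGE_BEARING_ATOM, THREE_TO_ONE, charge_of
from .structure import Structure, SASAProfile

__all__ = [
    "BJERRUM_LENGTH_298",
    "bjerrum_length",
    "debye_kappa",
    "ChargeProfile",
    "PointCharge",
    "PotentialMap",
    "charge_profile",
    "assign_point_charges",
    "sample_surface_points",
    "screened_coulomb_potential",
    "potential_similarity",
]

#: Bjerrum length of water at 298 K (eps = 78.5), in Angstrom.
BJERRUM_LENGTH_298 = 7.1

#: Avogadro constant (1/mol).
_N_A = 6.02214076e23


def bjerrum_length(temperature: float = 298.0) -> float:
    """Bjerrum length in Angstrom; the 1/T Coulomb scaling is kept while the
    temperature dependence of the dielectric constant is ignored."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return BJERRUM_LENGTH_298 * 298.0 / temperature


def debye_kappa(ionic_strength: float, temperature: float = 298.0) -> float:
    """Inverse Debye screening length in 1/Angstrom.

    ``kappa^2 = 8 pi l_B N_A I * 1e-27`` with the ionic strength ``I`` in
    mol/L (about 0.104 1/A at 0.1 mol/L and 298 K).
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be non-negative")
    lb = bjerrum_length(temperature)
    return float(np.sqrt(8.0 * np.pi * lb * _N_A * ionic_strength * 1e-27))


@dataclass(frozen=True)
class ChargeProfile:
    """Counts of formally charged residues and the resulting net charge."""

    n_negative: int
    n_positive: int

    def __post_init__(self) -> None:
        if self.n_negative < 0 or self.n_positive < 0:
            raise ValueError("counts must be non-negative")

    @property
    def net_charge(self) -> int:
        return self.n_positive - self.n_negative

    @property
    def n_charged(self) -> int:
        return self.n_positive + self.n_negative


def charge_profile(sequence) -> ChargeProfile:
    """Charge composition of a sequence (Asp/Glu negative, Lys/Arg positive,
    His neutral; terminal charges ignored)."""
    residues = getattr(sequence, "residues", sequence)
    neg = sum(1 for r in residues if CHARGE.get(r, 0) < 0)
    pos = sum(1 for r in residues if CHARGE.get(r, 0) > 0)
    return ChargeProfile(n_negative=neg, n_positive=pos)


@dataclass(frozen=True)
class PointCharge:
    """A unit formal charge at a fixed position (Angstrom)."""

    position: tuple
    charge: float
    residue_number: int | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.position)):
            raise ValueError("charge position must be finite")
        if self.charge == 0:
            raise ValueError("point charge must be non-zero")


@dataclass
class PotentialMap:
    """Sampled electrostatic potential values in kT/e."""

    points: np.ndarray
    values: np.ndarray
    anchor_residues: np.ndarray | None
    ionic_strength: float
    temperature: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("potential map contains non-finite values")


def assign_point_charges(
    structure: Structure,
    residue_charges: dict | None = None,
) -> list[PointCharge]:
    """One unit charge per charged residue, on its charge-bearing side-chain
    atom (Asp CG, Glu CD, Lys NZ, Arg CZ) with C-alpha fallback.

    ``residue_charges`` optionally overrides the charge assignment: a map
    from residue number to one-letter residue code, useful for placing the
    charges of a mutant or homolog sequence on the same model geometry.
    """
    charges = []
    for key in structure.residue_keys():
        name3 = structure.res_name(key)
        if residue_charges is not None:
            one = residue_charges.get(key[1])
            if one is None:
                continue
            q = charge_of(one)
        else:
            q = CHARGE.get(THREE_TO_ONE.get(name3, ""), 0)
        if q == 0:
            continue
        idx = structure.atom_indices(key)
        names = structure.atoms.atom_name[idx]
        target_atom = CHARGE_BEARING_ATOM.get(name3)
        pos = None
        if target_atom is not None and target_atom in names:
            pos = structure.atoms.coord[idx[list(names).index(target_atom)]]
        elif "CA" in names:
            pos = structure.atoms.coord[idx[list(names).index("CA")]]
        else:
            pos = structure.atoms.coord[idx[0]]
        charges.append(
            PointCharge(position=tuple(float(x) for x in pos), charge=float(q),
                        residue_number=int(key[1]))
        )
    return charges


def sample_surface_points(
    structure: Structure,
    relative_exposure: dict,
    min_relative_sasa: float = 0.2,
    push_distance: float = 1.4,
):
    """Potential sample points: heavy atoms of solvent-exposed residues,
    pushed outward (away from the molecular centroid) by one probe radius.

    Returns ``(points, anchor_residue_numbers)``; deterministic.
    """
    centroid = structure.atoms.coord.mean(axis=0)
    points, anchors = [], []
    for key, rel in relative_exposure.items():
        if rel < min_relative_sasa:
            continue
        for xyz in structure.coords_of(key):
            v = xyz - centroid
            norm = np.linalg.norm(v)
            if norm == 0:
                continue
            points.append(xyz + push_distance * v / norm)
            anchors.append(key[1])
    if not points:
        raise ValueError("no exposed residues to sample")
    return np.asarray(points), np.asarray(anchors)


def screened_coulomb_potential(
    charges,
    points,
    ionic_strength: float = 0.0,
    temperature: float = 298.0,
    min_separation: float = 0.5,
    anchor_residues=None,
) -> PotentialMap:
    """Debye-Hueckel potential of a set of point charges at sample points.

    Distances below ``min_separation`` (A) between any sample point and any
    charge are rejected to keep the map finite and meaningful.
    """
    if len(charges) == 0:
        values = np.zeros(len(points))
        return PotentialMap(np.asarray(points, float), values,
                            None if anchor_residues is None else np.asarray(anchor_residues),
                            ionic_strength, temperature)
    pts = np.asarray(points, dtype=float)
    pos = np.array([c.position for c in charges], dtype=float)
    q = np.array([c.charge for c in charges], dtype=float)
    d = cdist(pts, pos)
    if d.min() < min_separation:
        raise ValueError(
            f"sample point within {d.min():.3f} A of a charge "
            f"(minimum allowed {min_separation} A)"
        )
    lb = bjerrum_length(temperature)
    kappa = debye_kappa(ionic_strength, temperature)
    values = lb * (q[None, :] * np.exp(-kappa * d) / d).sum(axis=1)
    return PotentialMap(
        pts, values,
        None if anchor_residues is None else np.asarray(anchor_residues),
        ionic_strength, temperature,
    )


def potential_similarity(a: PotentialMap, b: PotentialMap, correspondence=None) -> float:
    """Pearson correlation of two potential maps over corresponding points.

    ``correspondence`` is a list of ``(index_in_a, index_in_b)`` pairs; if
    omitted the maps must have equal length and are paired by index.
    """
    if correspondence is None:
        if len(a.values) != len(b.values):
            raise ValueError("maps differ in length; give an explicit correspondence")
        correspondence = list(zip(range(len(a.values)), range(len(b.values))))
    if len(correspondence) < 3:
        raise ValueError("need at least 3 corresponding point pairs")
    ia, ib = zip(*correspondence)
    va = a.values[list(ia)]
    vb = b.values[list(ib)]
    if np.allclose(va, vb):
        return 1.0
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("zero variance in potential values")
    return float(pearsonr(va, vb).statistic)
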