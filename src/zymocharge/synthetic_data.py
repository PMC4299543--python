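"""Synthetic inputs for every stage of the pipeline.

Nothing here is meant to be physical: the goal is *planted truth* - fixtures
whose correct answer is known by construction - so that sequence analysis,
structural filtering, design and kinetics can be exercised end to end
without any external download.

The toy structures place one C-alpha pseudo-atom per residue on two kinds of
sites: an outer spherical shell whose atoms are spaced widely enough to be
fully solvent exposed, and buried sites at the centre of icosahedral cages
of 12 "filler" residues each, which occlude the central atom completely.
The exposure gap between the two classes is therefore large and stable
(relative SASA >= ~0.4 outside versus exactly 0 inside), comfortably
bracketing the 0.20 surface threshold used by the design filter.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import biotite.structure as _bstruc

from .tables import ONE_TO_THREE
from .sequences import ProteinSequence
from .structure import Structure, golden_spiral_points
from .kinetics import (
    CascadeParams,
    EnzymeSpec,
    MMDataset,
    TimeCourse,
    UNIT_ACTIVITY,
    UNIT_CONC,
    concentration_to_activity,
    simulate_cascade,
)

__all__ = [
    "NoiseSpec",
    "PlantedDesignTruth",
    "build_two_shell_structure",
    "gen_homolog_pair",
    "gen_timecourse",
    "gen_mm_data",
]

#: Neutral, non-hydroxyl, non-cysteine residues used as substitution targets.
_NEUTRAL_POOL = "AFGHILMNPQVW"
_CHARGED = "DEKR"
_ALL_AA = "ACDEFGHIKLMNPQRSTVWY"


class InfeasiblePlantingError(ValueError):
    """Raised when the requested planting counts cannot fit the chain."""


@dataclass(frozen=True)
class NoiseSpec:
    """Seeded Gaussian noise, additive or multiplicative."""

    kind: str = "multiplicative"
    sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("additive", "multiplicative"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def apply(self, values: np.ndarray) -> np.ndarray:
        if self.sigma == 0:
            return values.copy()
        rng = np.random.default_rng(self.seed)
        eps = rng.normal(0.0, self.sigma, size=len(values))
        if self.kind == "multiplicative":
            noisy = values * (1.0 + eps)
        else:
            noisy = values + eps
        return np.clip(noisy, 0.0, None)


@dataclass(frozen=True)
class PlantedDesignTruth:
    """A homolog pair + model with known surface/buried charge differences."""

    target: ProteinSequence
    homolog: ProteinSequence
    structure: Structure
    surface_positions: tuple  # canonical numbers, ascending
    buried_positions: tuple
    first_residue_number: int

    def __post_init__(self) -> None:
        if set(self.surface_positions) & set(self.buried_positions):
            raise ValueError("planted surface/buried positions overlap")


# --------------------------------------------------------------------------
# toy geometry
# --------------------------------------------------------------------------

def _icosahedron_vertices() -> np.ndarray:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            v += [(0, a, b), (a, b, 0), (b, 0, a)]
    v = np.array(v)
    return v / np.linalg.norm(v[0])


def _cage_centers(n: int, step: float = 9.0) -> np.ndarray:
    """First ``n`` points of a cubic grid around the origin, nearest first."""
    k = 0
    while (2 * k + 1) ** 3 < n:
        k += 1
    axis = np.arange(-k, k + 1) * step
    grid = np.array([(x, y, z) for x in axis for y in axis for z in axis])
    order = np.lexsort((grid[:, 2], grid[:, 1], grid[:, 0],
                        np.linalg.norm(grid, axis=1)))
    return grid[order][:n]


def build_two_shell_structure(
    sequence: ProteinSequence,
    buried_positions,
    filler_positions=None,
    north_positions=(),
    south_positions=(),
    shell_spacing: float = 7.5,
    cage_radius: float = 3.2,
    chain_id: str = "A",
) -> Structure:
    """One C-alpha pseudo-atom per residue, on a two-shell toy geometry.

    ``buried_positions`` go to cage centres (SASA 0 by construction); each
    cage consumes 12 ``filler_positions`` as vertices.  ``north_positions``
    (e.g. the activation peptide) occupy the northern pole of the outer
    shell and ``south_positions`` the southern pole, guaranteeing a large
    mutual distance.  All positions are canonical residue numbers.
    """
    buried = [int(p) for p in buried_positions]
    north = [int(p) for p in north_positions]
    south = [int(p) for p in south_positions]
    all_positions = list(sequence.canonical_numbers())
    special = set(buried) | set(north) | set(south)
    if len(special) != len(buried) + len(north) + len(south):
        raise ValueError("buried/north/south position sets overlap")

    n_fill = 12 * len(buried)
    if filler_positions is None:
        free = [p for p in all_positions if p not in special]
        if len(free) < n_fill:
            raise InfeasiblePlantingError(
                f"need {n_fill} filler residues, only {len(free)} available"
            )
        filler_positions = free[-n_fill:]
    fillers = [int(p) for p in filler_positions]
    if len(fillers) != n_fill or set(fillers) & special:
        raise ValueError("filler positions must be 12 per cage and disjoint")

    shell = [p for p in all_positions if p not in set(buried) | set(fillers)]
    n_shell = len(shell)
    if len(north) + len(south) > n_shell:
        raise InfeasiblePlantingError("not enough shell sites for north/south")

    centers = _cage_centers(len(buried)) if buried else np.zeros((0, 3))
    extent = (np.linalg.norm(centers, axis=1).max() + cage_radius) if buried else 0.0
    r_out = max(extent + 7.5, shell_spacing * np.sqrt(n_shell / (4.0 * np.pi)))

    spiral = golden_spiral_points(n_shell) * r_out  # index 0 = north pole
    middle = [p for p in shell if p not in set(north) | set(south)]
    ordered_shell = north + middle + south  # north first, south last

    coords: dict[int, np.ndarray] = {}
    for pos, xyz in zip(ordered_shell, spiral):
        coords[pos] = xyz
    ico = _icosahedron_vertices() * cage_radius
    fill_iter = iter(fillers)
    for center, pos in zip(centers, buried):
        coords[pos] = center
        for vertex in ico:
            coords[next(fill_iter)] = center + vertex

    n_atoms = len(all_positions)
    atoms = _bstruc.AtomArray(n_atoms)
    order = sorted(coords)
    atoms.coord = np.array([coords[p] for p in order])
    atoms.chain_id = np.full(n_atoms, chain_id, dtype="U4")
    atoms.res_id = np.array(order)
    atoms.res_name = np.array(
        [ONE_TO_THREE[sequence.residue_at(p)] for p in order], dtype="U5"
    )
    atoms.atom_name = np.full(n_atoms, "CA", dtype="U6")
    atoms.element = np.full(n_atoms, "C", dtype="U2")
    atoms.hetero = np.zeros(n_atoms, dtype=bool)
    return Structure(atoms)


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def gen_homolog_pair(
    n_residues: int,
    n_surface_diffs: int,
    n_buried_diffs: int,
    seed: int,
    first_residue_number: int = 1,
) -> PlantedDesignTruth:
    """A target/homolog pair with planted charge-class differences.

    Planted sites carry a charged residue in the target and a residue of a
    different charge class in the homolog.  Surface sites sit on the exposed
    shell (southern hemisphere, far from the 8-residue activation peptide at
    the northern pole); buried sites sit inside occluding cages.  The pair is
    identical everywhere else.  Deterministic per seed.
    """
    if n_surface_diffs + n_buried_diffs > n_residues / 4:
        raise InfeasiblePlantingError(
            "planted sites must not exceed a quarter of the chain"
        )
    if 8 + n_surface_diffs + 13 * n_buried_diffs > n_residues:
        raise InfeasiblePlantingError(
            "chain too short for the requested cages and peptide"
        )
    rng = np.random.default_rng(seed)
    positions = list(
        range(first_residue_number, first_residue_number + n_residues)
    )
    activation = positions[:8]
    pool = np.array(positions[8:])
    rng.shuffle(pool)
    buried = sorted(int(p) for p in pool[:n_buried_diffs])
    fillers = sorted(int(p) for p in pool[n_buried_diffs:n_buried_diffs + 12 * n_buried_diffs])
    rest = pool[n_buried_diffs + 12 * n_buried_diffs:]
    surface = sorted(int(p) for p in rest[:n_surface_diffs])

    residues = rng.choice(list(_ALL_AA), size=n_residues)
    target_map = dict(zip(positions, residues))
    for p in list(buried) + list(surface):
        target_map[p] = rng.choice(list(_CHARGED))
    target = ProteinSequence(
        f"synthetic_target_seed{seed}",
        "".join(target_map[p] for p in positions),
        first_residue_number,
    )

    homolog_map = dict(target_map)
    for p in list(buried) + list(surface):
        if target_map[p] in "DE":
            choices = list("KR" + _NEUTRAL_POOL)
        else:
            choices = list("DE" + _NEUTRAL_POOL)
        homolog_map[p] = rng.choice(choices)
    homolog = ProteinSequence(
        f"synthetic_homolog_seed{seed}",
        "".join(homolog_map[p] for p in positions),
        first_residue_number,
    )

    structure = build_two_shell_structure(
        target,
        buried_positions=buried,
        filler_positions=fillers,
        north_positions=activation,
        south_positions=surface,
    )
    return PlantedDesignTruth(
        target=target,
        homolog=homolog,
        structure=structure,
        surface_positions=tuple(surface),
        buried_positions=tuple(buried),
        first_residue_number=first_residue_number,
    )


def gen_timecourse(
    params: CascadeParams,
    t_grid,
    noise: NoiseSpec | None = None,
    as_activity: EnzymeSpec | None = None,
) -> TimeCourse:
    """Simulated cascade time course, optionally noisy and/or converted to
    volumetric activity (U/mL) via an :class:`EnzymeSpec`."""
    tc = simulate_cascade(params, t_grid)
    values = tc.values
    if noise is not None:
        values = noise.apply(values)
    if as_activity is not None:
        values = np.array(
            [concentration_to_activity(v / 1000.0, as_activity) for v in values]
        )
        return TimeCourse(times=tc.times, values=values, unit=UNIT_ACTIVITY)
    return TimeCourse(times=tc.times, values=values, unit=UNIT_CONC)


def gen_mm_data(
    km_umol: float,
    kcat_per_s: float,
    e0_nmol: float,
    substrate_levels,
    noise: NoiseSpec | None = None,
) -> MMDataset:
    """Michaelis-Menten velocities v = kcat E0 S / (Km + S), plus noise."""
    s = np.asarray(substrate_levels, float)
    if np.any(s <= 0):
        raise ValueError("substrate levels must be positive")
    v = kcat_per_s * (e0_nmol / 1000.0) * s / (km_umol + s)
    if noise is not None:
        v = noise.apply(v)
    return MMDataset(substrate_umol=s, velocity_umol_per_s=v, e0_nmol=e0_nmol)
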