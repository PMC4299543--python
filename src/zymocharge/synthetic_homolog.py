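"""SYNTHETIC stand-ins for the guinea-pig homolog and the structural model.

The autoactivation-defective guinea-pig trypsinogen sequence and a refined
3-D model of human trypsinogen are external inputs that must be supplied by
the user for a real design run.  For offline demonstration and testing this
module constructs *synthetic* replacements that reproduce, by construction,
the homolog's distinguishing statistics:

- 75% sequence identity to the human zymogen chain (174/232 identical),
- 26 charged residues versus 42 in human cationic trypsinogen,
- guinea-pig-like residues at the ten transfer positions (including the
  hydroxyl-bearing Thr/Ser that trigger the PTM-safe fallbacks K138L and
  E31A, the charge-conserving Lys at position 122 and the charge-neutral
  context residues at 33 and 154),
- eleven additional charge differences placed at positions that the toy
  model buries, so that the structural filter removes them.

Running :func:`zymocharge.design.propose_charge_transfer` in ``extended``
mode on this case yields exactly the ten designed PRSS1-sc substitutions.
None of these objects is the real guinea-pig sequence or a real structure;
they are labelled synthetic throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables import charge_of
from .sequences import ProteinSequence
from .structure import Structure
from .design import DesignConstraints
from .synthetic_data import build_two_shell_structure
from .trypsinogen import ACTIVATION_PEPTIDE, human_zymogen

__all__ = [
    "GP_LIKE_RESIDUES",
    "DemoDesignCase",
    "synthetic_guinea_pig_homolog",
    "demo_design_case",
]

#: Homolog residues at the ten transfer positions (guinea-pig-like pattern:
#: hydroxyls at 31 and 138, charge-conserving Lys at 122, neutral context
#: residues at 33 and 154).
GP_LIKE_RESIDUES = {
    31: "S",
    32: "A",
    33: "H",
    79: "K",
    122: "K",
    138: "T",
    153: "K",
    154: "N",
    157: "L",
    162: "N",
}

#: Charge-neutralising replacements for the buried charge differences.
_BURIED_SUBS = {"D": "N", "E": "Q", "K": "M", "R": "Q"}

#: Neutral-for-neutral replacements used to dilute identity to 75%.
_NEUTRAL_SUBS = {
    "A": "G", "G": "A", "L": "I", "I": "V", "V": "L", "F": "L",
    "N": "Q", "Q": "N", "S": "A", "T": "A", "Y": "F", "P": "A",
    "M": "L", "W": "F", "H": "Q",
}

_N_BURIED = 11
_TOTAL_DIFFS = 58  # 58/232 differing -> identity exactly 0.75

#: Catalytic triad of the trypsin fold in precursor numbering; never touched.
_CATALYTIC_TRIAD = (63, 107, 200)


@dataclass(frozen=True)
class DemoDesignCase:
    """Target, synthetic homolog, synthetic model and planted truth."""

    target: ProteinSequence
    homolog: ProteinSequence
    structure: Structure
    constraints: DesignConstraints
    buried_positions: tuple
    transfer_positions: tuple


def _excluded_neighbourhood() -> set[int]:
    """Positions reserved for the transfer sites and their +-1 context."""
    out = set()
    for p in GP_LIKE_RESIDUES:
        out.update((p - 1, p, p + 1))
    return out


def _buried_charge_positions(target: ProteinSequence) -> list[int]:
    """The eleven charged positions that receive buried (filtered-out)
    charge differences: the first eligible charged positions outside the
    activation peptide, the transfer neighbourhood and the catalytic triad."""
    excluded = _excluded_neighbourhood() | set(_CATALYTIC_TRIAD)
    start, end = ACTIVATION_PEPTIDE
    chosen = []
    for p in target.canonical_numbers():
        if start <= p <= end or p in excluded:
            continue
        if charge_of(target.residue_at(p)) != 0:
            chosen.append(p)
        if len(chosen) == _N_BURIED:
            break
    return chosen


def _neutral_diff_positions(target: ProteinSequence, buried: list[int]) -> list[int]:
    """Evenly spread neutral-for-neutral substitution positions."""
    n_needed = _TOTAL_DIFFS - len(GP_LIKE_RESIDUES) - len(buried)
    excluded = (
        _excluded_neighbourhood()
        | set(_CATALYTIC_TRIAD)
        | set(buried)
        | {p for b in buried for p in (b - 1, b + 1)}
    )
    start, end = ACTIVATION_PEPTIDE
    eligible = [
        p
        for p in target.canonical_numbers()
        if not (start <= p <= end)
        and p not in excluded
        and target.residue_at(p) in _NEUTRAL_SUBS
    ]
    if len(eligible) < n_needed:
        raise RuntimeError("not enough neutral positions for the demo homolog")
    idx = np.linspace(0, len(eligible) - 1, n_needed).astype(int)
    return [eligible[i] for i in sorted(set(idx))]


def synthetic_guinea_pig_homolog() -> ProteinSequence:
    """A synthetic homolog of the human zymogen chain (NOT the real
    guinea-pig sequence) with 75% identity and 26 charged residues."""
    target = human_zymogen()
    buried = _buried_charge_positions(target)
    neutral = _neutral_diff_positions(target, buried)
    residues = {p: target.residue_at(p) for p in target.canonical_numbers()}
    residues.update(GP_LIKE_RESIDUES)
    for p in buried:
        residues[p] = _BURIED_SUBS[residues[p]]
    for p in neutral:
        residues[p] = _NEUTRAL_SUBS[residues[p]]
    return ProteinSequence(
        "synthetic_gp_like_trypsinogen",
        "".join(residues[p] for p in target.canonical_numbers()),
        target.first_residue_number,
    )


def demo_design_case() -> DemoDesignCase:
    """The complete offline design demonstration.

    The synthetic model buries the eleven planted off-target charge
    differences in occluding cages, keeps the activation peptide (16-23) at
    the northern pole of the outer shell and the ten transfer positions at
    the southern pole (> 10 A away), so the design filters reproduce the
    published ten-mutation transfer set.
    """
    target = human_zymogen()
    homolog = synthetic_guinea_pig_homolog()
    buried = _buried_charge_positions(target)
    start, end = ACTIVATION_PEPTIDE
    peptide = list(range(start, end + 1))
    structure = build_two_shell_structure(
        target,
        buried_positions=buried,
        north_positions=peptide,
        south_positions=sorted(GP_LIKE_RESIDUES),
    )
    constraints = DesignConstraints(activation_peptide=tuple(peptide))
    return DemoDesignCase(
        target=target,
        homolog=homolog,
        structure=structure,
        constraints=constraints,
        buried_positions=tuple(buried),
        transfer_positions=tuple(sorted(GP_LIKE_RESIDUES)),
    )
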