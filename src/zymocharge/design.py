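"""Rational surface-charge transfer design.

Given a *target* sequence, a *homolog* sequence whose surface-charge pattern
is to be transplanted, and a structural model of the target, the pipeline

1. globally aligns the pair and collects positions whose formal charge
   class differs (optionally also charge-conserving substitutions at charged
   positions, e.g. Arg -> Lys),
2. filters every candidate on the structure: the site must be solvent
   exposed (relative SASA at or above a threshold) and far from the
   activation peptide (minimum heavy-atom distance strictly above a cutoff),
3. optionally adds homolog-matching substitutions at positions directly
   adjacent to an accepted charge-difference site (a heuristic that
   reconstructs how charge-neutral context residues end up in a transfer
   set), subject to the same structural filters,
4. replaces any proposed hydroxyl-bearing residue (Ser/Thr/Tyr) with a
   PTM-safe fallback (S->A, T->L, Y->N),
5. assembles the final mutation set, recomputes the charge profile and
   scores the predicted surface-potential similarity of the designed
   variant against the homolog charge pattern on the same model geometry.

Every candidate - accepted or rejected - is retained in the report with its
measured filter values; the audit trail is part of the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tables import HYDROXYL_RESIDUES, PTM_SAFE_FALLBACK, charge_of
from .sequences import (
    Mutation,
    PairwiseAlignment,
    ProteinSequence,
    apply_mutations,
    charge_diff_sites,
    global_align,
)
from .structure import (
    Structure,
    min_distance_to_region,
    relative_sasa,
    shrake_rupley_sasa,
)
from .electrostatics import (
    ChargeProfile,
    assign_point_charges,
    charge_profile,
    potential_similarity,
    sample_surface_points,
    screened_coulomb_potential,
)

__all__ = [
    "DesignConstraints",
    "CandidateMutation",
    "DesignReport",
    "DesignAuditError",
    "ptm_safe_substitution",
    "propose_charge_transfer",
    "audit_design",
]

ORIGIN_CHARGE_DIFF = "charge-diff"
ORIGIN_HOMOLOG_MATCH = "homolog-match"


class DesignAuditError(RuntimeError):
    """Raised when a design report fails its independent consistency audit."""


@dataclass(frozen=True)
class DesignConstraints:
    """Structural and chemical constraints applied to candidate mutations.

    ``activation_peptide`` lists the canonical residue numbers of the
    activation peptide; if ``None`` the first eight residues of the target
    numbering are used (the length of the classical trypsinogen activation
    peptide).
    """

    min_relative_sasa: float = 0.20
    min_distance_to_activation_peptide: float = 10.0  # Angstrom, strict
    activation_peptide: tuple | None = None
    forbid_hydroxyl_introduction: bool = True
    similarity_threshold: float = 0.7
    ionic_strength: float = 0.15  # mol/L, for the potential similarity score

    def __post_init__(self) -> None:
        if self.min_relative_sasa < 0 or self.min_distance_to_activation_peptide < 0:
            raise ValueError("thresholds must be non-negative")
        if self.activation_peptide is not None and len(self.activation_peptide) == 0:
            raise ValueError("activation peptide must be non-empty")

    def resolved_activation_peptide(self, target: ProteinSequence) -> tuple:
        if self.activation_peptide is not None:
            return tuple(self.activation_peptide)
        first = target.first_residue_number
        return tuple(range(first, first + 8))


@dataclass
class CandidateMutation:
    """A candidate substitution with full filter provenance."""

    canonical_position: int
    from_residue: str
    proposed_residue: str  # homolog residue before any PTM fallback
    to_residue: str  # final residue after PTM fallback
    origin: str  # ORIGIN_CHARGE_DIFF or ORIGIN_HOMOLOG_MATCH
    relative_sasa: float | None = None
    distance_to_activation_peptide: float | None = None
    passed_sasa: bool = False
    passed_distance: bool = False
    fallback_reason: str | None = None
    reject_reason: str | None = None

    @property
    def accepted(self) -> bool:
        return self.reject_reason is None

    @property
    def mutation(self) -> Mutation:
        return Mutation(self.canonical_position, self.from_residue, self.to_residue)


@dataclass
class DesignReport:
    """Outcome of a charge-transfer design run."""

    target_id: str
    homolog_id: str
    mutations: list  # final accepted Mutation objects, ascending position
    candidates: list  # every CandidateMutation with provenance
    profile_before: ChargeProfile
    profile_after: ChargeProfile
    similarity_before: float | None
    similarity_after: float | None
    constraints: DesignConstraints

    @property
    def matched(self) -> bool | None:
        """Whether the designed variant's potential pattern matches the
        homolog at the configured similarity threshold."""
        if self.similarity_after is None:
            return None
        return self.similarity_after >= self.constraints.similarity_threshold

    def rejected(self) -> list:
        return [c for c in self.candidates if not c.accepted]

    def to_dict(self) -> dict:
        return {
            "target": self.target_id,
            "homolog": self.homolog_id,
            "mutations": [str(m) for m in self.mutations],
            "charge_profile_before": {
                "n_negative": self.profile_before.n_negative,
                "n_positive": self.profile_before.n_positive,
                "net_charge": self.profile_before.net_charge,
            },
            "charge_profile_after": {
                "n_negative": self.profile_after.n_negative,
                "n_positive": self.profile_after.n_positive,
                "net_charge": self.profile_after.net_charge,
            },
            "similarity_before": self.similarity_before,
            "similarity_after": self.similarity_after,
            "matched": self.matched,
            "constraints": {
                "min_relative_sasa": self.constraints.min_relative_sasa,
                "min_distance_to_activation_peptide":
                    self.constraints.min_distance_to_activation_peptide,
                "forbid_hydroxyl_introduction":
                    self.constraints.forbid_hydroxyl_introduction,
                "similarity_threshold": self.constraints.similarity_threshold,
            },
            "candidates": [
                {
                    "position": c.canonical_position,
                    "from": c.from_residue,
                    "proposed": c.proposed_residue,
                    "to": c.to_residue,
                    "origin": c.origin,
                    "relative_sasa": c.relative_sasa,
                    "distance_to_activation_peptide":
                        c.distance_to_activation_peptide,
                    "accepted": c.accepted,
                    "fallback_reason": c.fallback_reason,
                    "reject_reason": c.reject_reason,
                }
                for c in self.candidates
            ],
        }


def ptm_safe_substitution(homolog_residue: str) -> str:
    """Map a proposed residue to a PTM-safe one.

    Residues without a side-chain hydroxyl pass through unchanged; Ser, Thr
    and Tyr are replaced by Ala, Leu and Asn respectively so that the design
    never introduces a new O-glycosylation/phosphorylation site.
    """
    return PTM_SAFE_FALLBACK.get(homolog_residue, homolog_residue)


def _structure_key(model: Structure, canonical_position: int):
    """Residue key in the model for a canonical position (first chain)."""
    chain = model.chains()[0]
    for key in ((chain, canonical_position, ""),):
        if key in model:
            return key
    raise KeyError(
        f"canonical position {canonical_position} not present in the model "
        "(numbering offset error?)"
    )


def propose_charge_transfer(
    target: ProteinSequence,
    homolog: ProteinSequence,
    model: Structure,
    constraints: DesignConstraints | None = None,
    transfer_mode: str = "strict",
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> DesignReport:
    """Design a charge-transfer mutation set for ``target`` from ``homolog``.

    ``transfer_mode``:

    - ``"strict"``: only positions whose formal charge class differs are
      candidates.
    - ``"extended"``: additionally propose (a) charge-conserving homolog
      residues at charged positions (e.g. Arg -> Lys) and (b) differing
      homolog residues directly adjacent (+-1) to an accepted
      charge-difference site.  This reconstructs how charge-neutral context
      substitutions enter a transfer set and is a documented heuristic.
    """
    if transfer_mode not in ("strict", "extended"):
        raise ValueError(f"unknown transfer_mode {transfer_mode!r}")
    constraints = constraints or DesignConstraints()

    aln = global_align(target, homolog, matrix, gap_open, gap_extend)
    sites = charge_diff_sites(aln)

    # structural context, computed once
    sasa = shrake_rupley_sasa(model)
    rel = relative_sasa(sasa, model)
    peptide_positions = constraints.resolved_activation_peptide(target)
    chain = model.chains()[0]
    peptide_keys = [
        (chain, int(p), "") for p in peptide_positions if (chain, int(p), "") in model
    ]
    if not peptide_keys:
        raise ValueError("activation peptide residues not found in the model")

    homolog_by_target_pos = {
        target.first_residue_number + i: homolog.residues[j]
        for i, j in aln.paired_columns()
    }

    def evaluate(position: int, proposed: str, origin: str) -> CandidateMutation:
        from_res = target.residue_at(position)
        cand = CandidateMutation(
            canonical_position=position,
            from_residue=from_res,
            proposed_residue=proposed,
            to_residue=proposed,
            origin=origin,
        )
        key = _structure_key(model, position)
        cand.relative_sasa = float(rel[key])
        cand.distance_to_activation_peptide = min_distance_to_region(
            model, key, peptide_keys
        )
        cand.passed_sasa = cand.relative_sasa >= constraints.min_relative_sasa
        cand.passed_distance = (
            cand.distance_to_activation_peptide
            > constraints.min_distance_to_activation_peptide
        )
        if not cand.passed_sasa:
            cand.reject_reason = (
                f"buried: relative SASA {cand.relative_sasa:.3f} < "
                f"{constraints.min_relative_sasa}"
            )
            return cand
        if not cand.passed_distance:
            cand.reject_reason = (
                f"too close to activation peptide: "
                f"{cand.distance_to_activation_peptide:.1f} A <= "
                f"{constraints.min_distance_to_activation_peptide} A"
            )
            return cand
        if constraints.forbid_hydroxyl_introduction and proposed in HYDROXYL_RESIDUES:
            safe = ptm_safe_substitution(proposed)
            cand.to_residue = safe
            cand.fallback_reason = (
                f"homolog residue {proposed} carries a hydroxyl; replaced by {safe}"
            )
        if cand.to_residue == from_res:
            cand.reject_reason = "substitution is a no-op after PTM fallback"
        return cand

    candidates: list[CandidateMutation] = []
    seen_positions: set[int] = set()
    for site in sites:
        candidates.append(
            evaluate(site.canonical_position, site.homolog_residue, ORIGIN_CHARGE_DIFF)
        )
        seen_positions.add(site.canonical_position)

    if transfer_mode == "extended":
        # charge-conserving homolog residues at charged positions (R<->K etc.)
        for i, j in aln.paired_columns():
            pos = target.first_residue_number + i
            ra, rb = target.residues[i], homolog.residues[j]
            if pos in seen_positions or ra == rb:
                continue
            if charge_of(ra) != 0 and charge_of(ra) == charge_of(rb):
                candidates.append(evaluate(pos, rb, ORIGIN_HOMOLOG_MATCH))
                seen_positions.add(pos)
        # differing residues adjacent to an accepted charge-difference site
        accepted_cd = [
            c.canonical_position
            for c in candidates
            if c.origin == ORIGIN_CHARGE_DIFF and c.accepted
        ]
        for pos in sorted({p + d for p in accepted_cd for d in (-1, 1)}):
            if pos in seen_positions or pos not in homolog_by_target_pos:
                continue
            try:
                ra = target.residue_at(pos)
            except IndexError:
                continue
            rb = homolog_by_target_pos[pos]
            if ra == rb:
                continue
            candidates.append(evaluate(pos, rb, ORIGIN_HOMOLOG_MATCH))
            seen_positions.add(pos)

    candidates.sort(key=lambda c: c.canonical_position)
    mutations = [c.mutation for c in candidates if c.accepted]

    profile_before = charge_profile(target)
    mutant = apply_mutations(target, mutations) if mutations else target
    profile_after = charge_profile(mutant)

    similarity_before, similarity_after = _potential_similarities(
        model, target, homolog_by_target_pos, mutant, rel, constraints
    )

    return DesignReport(
        target_id=target.id,
        homolog_id=homolog.id,
        mutations=mutations,
        candidates=candidates,
        profile_before=profile_before,
        profile_after=profile_after,
        similarity_before=similarity_before,
        similarity_after=similarity_after,
        constraints=constraints,
    )


def _potential_similarities(model, target, homolog_by_target_pos, mutant, rel,
                            constraints):
    """Pearson similarity of the homolog's charge-pattern potential with the
    wild-type and the designed variant, all placed on the model geometry."""
    try:
        points, anchors = sample_surface_points(
            model, rel, min_relative_sasa=constraints.min_relative_sasa
        )
    except ValueError:
        return None, None

    def potential_for(sequence_by_pos: dict):
        charges = assign_point_charges(model, residue_charges=sequence_by_pos)
        return screened_coulomb_potential(
            charges, points,
            ionic_strength=constraints.ionic_strength,
            anchor_residues=anchors,
        )

    target_by_pos = {p: target.residue_at(p) for p in target.canonical_numbers()}
    mutant_by_pos = {p: mutant.residue_at(p) for p in mutant.canonical_numbers()}
    map_hom = potential_for(homolog_by_target_pos)
    map_wt = potential_for(target_by_pos)
    map_mut = potential_for(mutant_by_pos)
    try:
        before = potential_similarity(map_wt, map_hom)
        after = potential_similarity(map_mut, map_hom)
    except ValueError:
        return None, None
    return before, after


def audit_design(report: DesignReport, target: ProteinSequence) -> DesignReport:
    """Independently re-check a design report.

    Re-applies the mutation set, recomputes the charge profile and compares
    it against the report; verifies that every final mutation passed all
    structural filters.  Any inconsistency raises :class:`DesignAuditError`
    naming the offending site.
    """
    positions = [m.canonical_position for m in report.mutations]
    if len(positions) != len(set(positions)):
        raise DesignAuditError("duplicate positions in final mutation set")

    accepted_by_pos = {
        c.canonical_position: c for c in report.candidates if c.accepted
    }
    for m in report.mutations:
        cand = accepted_by_pos.get(m.canonical_position)
        if cand is None:
            raise DesignAuditError(
                f"mutation {m} has no accepted candidate record"
            )
        if not (cand.passed_sasa and cand.passed_distance):
            raise DesignAuditError(
                f"mutation at position {m.canonical_position} did not pass "
                "all structural filters"
            )
    mutant = apply_mutations(target, report.mutations)
    recomputed = charge_profile(mutant)
    if recomputed != report.profile_after:
        raise DesignAuditError(
            "charge profile mismatch: report "
            f"({report.profile_after.n_negative} neg / "
            f"{report.profile_after.n_positive} pos) vs recomputed "
            f"({recomputed.n_negative} neg / {recomputed.n_positive} pos)"
        )
    if charge_profile(target) != report.profile_before:
        raise DesignAuditError("charge profile of the target changed")
    return report
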