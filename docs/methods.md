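# Methods

This note documents the models, conventions and design choices behind
`zymocharge`, in the spirit of a methods section: what is computed, under
which assumptions, with which defaults, and what the synthetic fixtures do
and do not demonstrate.

## Sequences and alignment

Sequences are strings over the 20 standard one-letter codes with a
*canonical numbering offset*, so that a chain fragment (e.g. the trypsinogen
zymogen chain starting at residue 16) reports positions in the conventional
precursor numbering in which substitutions like E79K or R122K are cited.
Internally everything is 0-based; all I/O and reports use canonical numbers.

Global alignment uses the Gotoh affine-gap recursion. A gap of length L
costs `gap_open + (L − 1) · gap_extend`, terminal gaps included; defaults
are BLOSUM62 with gap open 10 and extend 0.5, chosen to approximate the
classic ClustalW protein defaults. Substitution matrices are taken by name
from biotite's collection. The dynamic programming is implemented in the
package rather than delegated: the external aligner truncates fractional
gap penalties to integers, which cannot express the 0.5 extend default (it
is still used as an independent cross-check at integer penalties in the
tests, alongside an exhaustive path-enumeration oracle at short lengths).
Among co-optimal alignments the traceback deterministically prefers
substitution columns, then gaps in the second sequence ("high-road").

Percent identity divides identical columns by the number of
residue–residue columns (gap columns excluded). Alternative denominators
(shorter sequence, all columns) are selectable; with the default, the
bundled human/homolog demonstration pair sits at exactly 75%.

The charge table is Asp/Glu = −1, Lys/Arg = +1, His = 0, termini ignored.
His neutrality is deliberate: the charge bookkeeping of the designed
trypsinogen variant (22→16 negative, 20→21 positive) is only consistent if
N33H leaves the positive count untouched.

## Structure, accessibility, distances

PDB files are parsed through biotite (fixed-column ATOM/HETATM records;
waters and hydrogens dropped by default; alternate locations resolved to
the highest-occupancy conformer, ties by altloc letter). A thin `Structure`
wrapper adds an ordered residue index keyed by (chain, residue number,
insertion code).

Solvent-accessible surface area is computed with the Shrake–Rupley
test-point method implemented in the package: 960 points per atom on a
deterministic golden-spiral sphere of radius r_vdW + 1.4 Å, with
Bondi/Chothia-style heavy-atom radii (C 1.70, N 1.55, O 1.52, S 1.80 Å).
No randomness is involved, so results are bit-reproducible; the golden
spiral is orientation-dependent at the ~1–2% level, which the tests treat
as the sampling tolerance. Relative exposure divides the per-residue sum by
a theoretical Gly-X-Gly maximum (Tien-style table); values may slightly
exceed 1 for highly exposed residues. The "on the surface" design filter
uses relative SASA ≥ 0.20, a common exposure cutoff; it is configurable.

Distances to the activation peptide are minimum heavy-atom distances; a
residue inside the region is at distance 0. The activation peptide defaults
to the first eight residues of the chain numbering (the length of the
trypsinogen activation peptide) and can be overridden explicitly.

## Electrostatics

The surface potential is the linear Debye–Hückel screened-Coulomb sum
φ(p) = ℓ_B Σ qᵢ exp(−κdᵢ)/dᵢ in kT/e, with ℓ_B = 7.1 Å at 298 K (ε = 78.5,
only the 1/T Coulomb scaling retained) and κ = √(8π ℓ_B N_A I·10⁻²⁷) ≈
0.104 Å⁻¹ at 0.1 mol/L. This is an intentional, clearly-labelled
approximation to a Poisson–Boltzmann solve: there is no low-dielectric
interior and no dielectric boundary, but superposition is exact, the salt
dependence has the correct Debye form, and the map is free of any
force-field dependency because unit formal charges sit on one
representative side-chain atom per charged residue (Asp Cγ, Glu Cδ, Lys Nζ,
Arg Cζ, Cα fallback).

Sample points are the heavy atoms of exposed residues (relative SASA
≥ 0.20) pushed one probe radius outward from the molecular centroid —
deterministic and cheap. Pattern similarity between two proteins is the
Pearson correlation of potentials over corresponding points; "matched" is
declared at ≥ 0.7, an explicit package convention (no experimental number
exists for it). For design reports, the wild-type, variant and homolog
charge patterns are all placed on the *same* model geometry (homolog
charges mapped through the alignment), so the similarity isolates the
charge pattern from conformational differences. The default ionic strength
for this score is 0.15 mol/L.

## Design pipeline

Candidates arise from charge-class differences in the alignment
(`strict` mode). `extended` mode adds two documented heuristics needed to
reconstruct how charge-neutral context substitutions enter a transfer set:
charge-conserving homolog residues at charged positions (R→K), and
differing homolog residues directly adjacent (±1) to an accepted
charge-difference site (N33H next to E32A, Y154N next to D153K). Both are
off in `strict` mode.

Filters are applied per candidate with full provenance: relative SASA
≥ 0.20, distance to the activation peptide strictly > 10 Å. Surviving
proposals pass through the PTM-safe substitution map (S→A, T→L, Y→N) when
hydroxyl introduction is forbidden (default), so no Ser/Thr/Tyr ever
appears as a designed residue; a proposal that becomes a no-op after the
fallback is dropped. Rejected candidates stay in the report with their
measured values — the audit trail is part of the contract, and
`audit_design` independently re-applies the mutation set, recomputes the
charge profile and re-checks every filter flag.

## Kinetics

The cascade model is irreversible bimolecular mass action,
d[Tr]/dt = (k_auto[Tr] + k_ep[EP])[Tg], with [EP] constant and [Tg]+[Tr]
conserved; no Michaelian saturation in the activation step and no
degradation term (the surface-charged variant shows no degradation; a
degradation extension would go beyond what the model is meant to capture).
Internally concentrations are µmol/L and time minutes; the single-state
reduction [Tg] = total − [Tr] is integrated with LSODA at rtol 1e-10 /
atol 1e-12, which keeps the two-state conservation identity to well below
1e-6 (verified against an independent two-state integration and, for the
activator-only case, against the closed form Tg₀(1 − e^(−k_ep·EP₀·t))).

The experimentally quoted "activation rate constant" (nmol/L/min) is the
*initial linear slope* of active enzyme versus time, a rate, not a
bimolecular constant; at t = 0 the two are related by
rate = k_auto·Tr₀·Tg₀. `estimate_activation_rate` implements the slope
convention: ordinary least squares over the longest initial window, grown
greedily from the first three points, subject to conversion ≤ 10% of the
zymogen pool and R² ≥ 0.99. Because an autocatalytic course is convex, the
OLS slope of any finite window overestimates the t = 0 rate by roughly half
the window length in units of the e-folding time 1/(k_auto·(Tg₀+Tr₀));
the estimate therefore reproduces the generating rate only when the course
is sampled well inside the linear regime (the worked examples use windows
of ≈ 3% of an e-folding time, giving ≈ 1.5% bias). When the bimolecular
constant itself is wanted, `fit_cascade` avoids the windowing question
entirely by nonlinear least squares on the integrated model (initialised
from a coarse log-scale scan so that saturated, gradient-flat starts are
avoided); it recovers k_auto exactly on noiseless courses and to ~3% median
at 5% multiplicative noise.

Michaelis–Menten fitting is nonlinear least squares on
v = kcat·E₀·S/(Km+S), initialised from a Hanes–Woolf linearisation, with
positivity constraints; the fit is deterministic given the data. Catalytic
efficiency is kcat/Km (L/µmol/s). Activity↔concentration conversions use
1 U = 1 µmol/min: U/mL ÷ (U/mg) ÷ (g/mol) → mol/L. Plateau activities after
complete activation are computed with the mature-chain molar mass derived
from sequence, since the assayed species is the processed enzyme; this
yields 2.65 and 3.32 U/mL for the wild-type-like and variant-like
demonstrations, a few percent from the nominal 2.5 / 3.5 values, which were
evidently derived with a slightly different effective molar mass.

## Synthetic data and the bundled demonstration

The generators exist to provide *planted truth*. Toy structures place one
Cα pseudo-atom per residue: an outer spherical shell spaced so widely
(≈ 7.5 Å) that every shell atom is essentially fully exposed (relative
SASA ≈ 0.4–1.2 depending on residue type), and buried sites at the centres
of icosahedral cages of twelve filler atoms at 3.2 Å, which occlude the
central atom completely (SASA exactly 0). The exposure gap between the two
classes is therefore ≥ 0.25 in relative SASA for every seed, comfortably
bracketing the 0.20 filter. The activation peptide occupies the northern
pole of the shell and planted surface sites the southern pole, placing them
far beyond the 10 Å distance cutoff. Noise is multiplicative Gaussian with
σ = 0.05 by default — a typical activity-assay coefficient of variation —
and every generator is a pure function of its arguments including the seed.

These fixtures are geometric caricatures: they have no backbone, no
side-chain packing, no realistic burial continuum, and their exposure
classes are binary by construction. Passing the planted-truth tests shows
that the pipeline's bookkeeping, filtering and thresholds behave exactly as
specified — not that the 0.20/10 Å thresholds are optimal for real
proteins, nor that a real homology model would classify any particular
residue the same way.

The bundled demonstration pairs the real human cationic trypsinogen zymogen
chain (pinned by segment lengths, charge composition 22/20, catalytic triad
His63/Asp107/Ser200 and the mature-chain extinction coefficient 37525
L/mol/cm) with a **synthetic** guinea-pig-like homolog and a **synthetic**
model structure. The homolog is engineered to exhibit the homolog's known
statistics — 75% identity, 26 charged residues, hydroxyl-bearing residues
at the fallback positions, the charge-conserving Lys at 122 — and eleven
further charge differences that the toy model buries. Recovery of the
ten-substitution transfer set by the pipeline is therefore a demonstration
and regression anchor, not an independent reproduction from the real
homolog sequence and a real structural model; those remain user-supplied
inputs for production runs.

## Numerical conventions and edge cases

- R² of an exact fit to zero-variance data is defined as 1 (a constant
  course has slope 0, R² 1); otherwise 1 − SS_res/SS_tot clipped at 0.
- Potential maps reject sample points closer than 0.5 Å to a charge;
  identical value vectors short-circuit to similarity 1.0 before the
  zero-variance check.
- Charge placement falls back to Cα (then the first atom) when the
  representative side-chain atom is absent — the Cα-only toy structures
  rely on this.
- The greedy rate-estimation window requires at least three points and
  raises a dedicated error when no window satisfies the criteria.
- Mutation application validates the wild-type residue at every position
  and reports a mismatch as a probable numbering-offset error.

## Problem sizes

Default test and demonstration sizes are chosen for fast, deterministic
runs: 960 sphere points per atom (≤ 1% sampling error against the analytic
sphere), 232-residue demonstration chain, 60-residue planted fixtures, 50
fixtures for precision/recall statistics, 100 noise replicates for recovery
medians, 200 random pairs against the alignment enumeration oracle (lengths
≤ 6, where exhaustive enumeration is exact and cheap).

## Known limitations

- The electrostatics is linear Debye–Hückel with a uniform dielectric; it
  cannot reproduce Poisson–Boltzmann surface maps quantitatively, only the
  pattern and its salt response.
- The cascade model omits trypsin degradation/autolysis, so simulated
  wild-type courses saturate and stay saturated; observed courses of
  degradation-prone enzymes eventually decline.
- The initial-slope estimator is windowing-biased on strongly curved
  courses by design (it mirrors the experimental convention); use
  `fit_cascade` for unbiased constants.
- The design heuristics of `extended` mode (±1 neighbours,
  charge-conserving swaps) are a reconstruction of narrative design
  practice, not an algorithm with a unique answer; they are off by default.
- Only single-model, single-conformer structures are considered; no
  ensemble averaging of SASA or potentials.
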