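"""Human cationic trypsinogen (PRSS1) reference data.

The precursor sequence below is the 247-residue human cationic trypsinogen
(PRSS1): signal peptide (residues 1-15), the eight-residue activation
peptide APFDDDDK (16-23) and the mature trypsin chain (24-247).  Canonical
numbering is precursor numbering, the convention in which the classical
pancreatitis positions (R122, E79, ...) and the designed substitutions are
cited.  Several internal consistency checks pin the sequence down: the
zymogen chain carries exactly 22 Asp/Glu and 20 Lys/Arg (42 charged
residues, net charge -2), the catalytic triad sits at His63/Asp107/Ser200,
the autolysis bond is Arg122-Val123, and the mature-chain molar extinction
coefficient computes to 37525 L/mol/cm (4 Trp, 10 Tyr, 5 cystines).

Also collected here are the designed surface-charge transfer mutations and
the experimentally determined activation and Michaelis-Menten parameters of
the wild type (PRSS1-WT) and the surface-charged variant (PRSS1-sc), used
as reference inputs by the worked examples.
"""

from __future__ import annotations

from .sequences import Mutation, ProteinSequence, parse_mutations

__all__ = [
    "HUMAN_CATIONIC_TRYPSINOGEN",
    "SIGNAL_PEPTIDE",
    "ACTIVATION_PEPTIDE",
    "MATURE_CHAIN",
    "DESIGNED_MUTATIONS",
    "designed_mutations",
    "human_zymogen",
    "human_mature",
    "REFERENCE",
]

_PRECURSOR = (
    "MNPLLILTFVAAALA"  # signal peptide, 1-15
    "APFDDDDK"  # activation peptide, 16-23
    "IVGGYNCEENSVPYQVSLNSGYHFCGGSLINEQWVVSAGHCYKSRIQVRLGEHNIEVLE"
    "GNEQFINAAKIIRHPQYDRKTLNNDIMLIKLSSRAVINARVSTISLPTAPPATGTKCLI"
    "SGWGNTASSGADYPDELQCLDAPVLSQAKCEASYPGKITSNMFCVGFLEGGKDSCQGDS"
    "GGPVVCNGQLQGVVSWGDGCAQKNKPGVYTKVYNYVKWIKNTIAANS"
)

#: Full precursor in canonical (precursor) numbering.
HUMAN_CATIONIC_TRYPSINOGEN = ProteinSequence("PRSS1_HUMAN", _PRECURSOR, 1)

#: Canonical number ranges of the precursor segments (inclusive).
SIGNAL_PEPTIDE = (1, 15)
ACTIVATION_PEPTIDE = (16, 23)
MATURE_CHAIN = (24, 247)

#: The ten surface-charge transfer substitutions of the PRSS1-sc variant.
DESIGNED_MUTATIONS = "E31A E32A N33H E79K R122K K138L D153K Y154N E157L D162N"


def designed_mutations() -> list[Mutation]:
    """The PRSS1-sc mutation set as parsed :class:`Mutation` objects."""
    return parse_mutations(DESIGNED_MUTATIONS)


def human_zymogen() -> ProteinSequence:
    """The zymogen chain (activation peptide + mature chain, residues
    16-247), i.e. the species whose charge composition is reported."""
    return HUMAN_CATIONIC_TRYPSINOGEN.subsequence(*map(int, (16, 247)))


def human_mature() -> ProteinSequence:
    """The mature trypsin chain (residues 24-247)."""
    return HUMAN_CATIONIC_TRYPSINOGEN.subsequence(*map(int, (24, 247)))


#: Experimentally determined reference values for PRSS1-WT and PRSS1-sc
#: (activation assays at pH 8, 37 C, with 2 umol/L trypsinogen; activity
#: with Cbz-GPR-pNA substrate).  Used as inputs to the worked examples and
#: comparisons, not as fitted outputs.
REFERENCE = {
    # initial activation rates, nmol/L/min
    "wt_autoactivation_rate": 30.9,  # 10 nmol/L trypsin start
    "sc_autoactivation_rate": 0.00545,
    "wt_enteropeptidase_rate": 86.4,  # 1 nmol/L enteropeptidase
    "sc_enteropeptidase_rate": 13.3,
    # assay conditions
    "tg0_umol": 2.0,
    "tr0_nmol": 10.0,
    "ep0_nmol": 1.0,
    # Michaelis-Menten parameters with Cbz-GPR-pNA
    "wt_km_umol": 78.0,
    "wt_kcat_per_s": 324.1,
    "sc_km_umol": 129.8,
    "sc_kcat_per_s": 489.0,
    # specific activities, U/mg
    "wt_specific_activity": 54.6,
    "sc_specific_activity": 69.0,
    # plateau activities after complete enteropeptidase activation, U/mL
    "wt_plateau_activity": 2.5,
    "sc_plateau_activity": 3.5,
}
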