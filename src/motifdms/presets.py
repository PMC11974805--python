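"""Packaged motif presets.

The Rad54 Rad51-interaction motif (S. cerevisiae Rad54 residues T101-L144)
and the Hed1 Rad51-interaction peptide (residues P118-P156) with the modeled
span K121-L153.  The peptide sequences and residue spans are experimental
values; the DNA reference codons and constant amplicon flanks are SYNTHETIC
stand-ins (the screen's actual plasmid sequence is not packaged): codons are
the most common S. cerevisiae codon per residue, flanks are fixed arbitrary
20-nt sequences.
"""

from __future__ import annotations

from .motif import MotifSpec, span_length

# Rad54 Rad51-interaction motif, residues 101-144 (44 aa), FxxP at F131-P134.
RAD54_MOTIF_FIRST_RESIDUE = 101
RAD54_MOTIF_LAST_RESIDUE = 144
RAD54_MOTIF_AA = "TKRRKDALSAQRLAKDPTRLSHIQYTLRRSFTVPIKGYVQRHSL"

# Hed1 Rad51-interaction peptide, residues 118-156 (39 aa); the structurally
# modeled portion spans residues 121-153 (33 aa).
HED1_PEPTIDE_FIRST_RESIDUE = 118
HED1_PEPTIDE_LAST_RESIDUE = 156
HED1_PEPTIDE_AA = "PRKKKSLKDLIYETNKTFYQVDSNKVKYKVGLSKKQLLP"
HED1_MODELED_FIRST_RESIDUE = 121
HED1_MODELED_LAST_RESIDUE = 153

# most common S. cerevisiae codon per amino acid (synthetic back-translation)
_YEAST_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "TTG",
    "M": "ATG", "N": "AAT", "P": "CCA", "Q": "CAA", "R": "AGA",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

# synthetic constant amplicon flanks (20 nt each side of the motif)
RAD54_UPSTREAM_FLANK = "ACGGATTACGCTGGTCCAGT"
RAD54_DOWNSTREAM_FLANK = "TGACCAGCTTGAGGCATTCA"


def back_translate(aa_sequence: str) -> str:
    """Synthetic coding sequence using the most common yeast codon per residue."""
    return "".join(_YEAST_CODON[a] for a in aa_sequence)


def rad54_motif_spec() -> MotifSpec:
    """The 44-codon Rad54 screen motif with synthetic codons and flanks."""
    return MotifSpec(
        protein_name="Rad54",
        first_residue=RAD54_MOTIF_FIRST_RESIDUE,
        aa_sequence=RAD54_MOTIF_AA,
        dna_reference=back_translate(RAD54_MOTIF_AA),
        upstream_flank=RAD54_UPSTREAM_FLANK,
        downstream_flank=RAD54_DOWNSTREAM_FLANK,
    )


def toy_motif_spec(aa_sequence: str = "TKR", first_residue: int = 101) -> MotifSpec:
    """A small synthetic motif (default: the screen motif's first window)."""
    return MotifSpec(
        protein_name="toy",
        first_residue=first_residue,
        aa_sequence=aa_sequence,
        dna_reference=back_translate(aa_sequence),
        upstream_flank=RAD54_UPSTREAM_FLANK,
        downstream_flank=RAD54_DOWNSTREAM_FLANK,
    )


assert span_length(RAD54_MOTIF_FIRST_RESIDUE, RAD54_MOTIF_LAST_RESIDUE) == len(RAD54_MOTIF_AA)
assert span_length(HED1_PEPTIDE_FIRST_RESIDUE, HED1_PEPTIDE_LAST_RESIDUE) == len(HED1_PEPTIDE_AA)
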