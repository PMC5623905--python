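"""Amino-acid and nucleotide reference data shared across the package.

Holds the one-/three-letter code tables, the reverse codon table used by the
synthetic gene generator, a theoretical maximum accessible-surface-area scale
(Gly-X-Gly tripeptide values) used to normalise residue SASA into relative
solvent accessibility, and the five-factor physico-chemical descriptor table
(Atchley et al., PNAS 2005) used for chemical substitution distances.
"""

from __future__ import annotations

AA1 = "ACDEFGHIKLMNPQRSTVWY"

AA3_TO_1 = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

# Standard genetic code, forward direction only; the reverse table is used to
# draw a coding sequence consistent with a protein sequence.
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

CODONS_FOR_AA: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TABLE.items():
    CODONS_FOR_AA.setdefault(_aa, ())
    CODONS_FOR_AA[_aa] = CODONS_FOR_AA[_aa] + (_codon,)

STOP_CODONS = ("TAA", "TAG", "TGA")
NUCLEOTIDES = "ACGT"

# Theoretical maximum ASA per residue type (Gly-X-Gly extended tripeptide),
# in A^2.  Relative solvent accessibility = residue ASA / MAX_ASA * 100.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# Five physico-chemical factors per amino acid (Atchley et al. 2005):
# I polarity/accessibility, II secondary-structure propensity, III molecular
# size, IV codon composition, V electrostatic charge.  Factors are
# standardised across residues (mean ~0, sd ~1).
ATCHLEY_FACTORS = {
    "A": (-0.591, -1.302, -0.733,  1.570, -0.146),
    "C": (-1.343,  0.465, -0.862, -1.020, -0.255),
    "D": ( 1.050,  0.302, -3.656, -0.259, -3.242),
    "E": ( 1.357, -1.453,  1.477,  0.113, -0.837),
    "F": (-1.006, -0.590,  1.891, -0.397,  0.412),
    "G": (-0.384,  1.652,  1.330,  1.045,  2.064),
    "H": ( 0.336, -0.417, -1.673, -1.474, -0.078),
    "I": (-1.239, -0.547,  2.131,  0.393,  0.816),
    "K": ( 1.831, -0.561,  0.533, -0.277,  1.648),
    "L": (-1.019, -0.987, -1.505,  1.266, -0.912),
    "M": (-0.663, -1.524,  2.219, -1.005,  1.212),
    "N": ( 0.945,  0.828,  1.299, -0.169,  0.933),
    "P": ( 0.189,  2.081, -1.628,  0.421, -1.392),
    "Q": ( 0.931, -0.179, -3.005, -0.503, -1.853),
    "R": ( 1.538, -0.055,  1.502,  0.440,  2.897),
    "S": (-0.228,  1.399, -4.760,  0.670, -2.647),
    "T": (-0.032,  0.326,  2.213,  0.908,  1.313),
    "V": (-1.337, -0.279, -0.544,  1.242, -1.262),
    "W": (-0.595,  0.009,  0.672, -2.128, -0.184),
    "Y": ( 0.260,  0.830,  3.097, -0.838,  1.512),
}

# DNA / RNA residue names as found in PDB polymer chains.
DNA_RES_NAMES = {"DA", "DC", "DG", "DT", "DI", "DU"}
RNA_RES_NAMES = {"A", "C", "G", "U", "I"}

# Common crystallographic buffer / cryoprotectant components stripped from the
# ligand list.  Metal and halide ions are deliberately NOT here: they often
# play a functional role and mutations at their binding sites matter.
DEFAULT_BUFFER_CODES = frozenset({
    "HOH", "DOD", "GOL", "EDO", "PEG", "PGE", "PG4", "SO4", "PO4", "ACT",
    "DMS", "MPD", "TRS", "FMT", "NO3", "BME", "IMD", "EOH", "MOH", "ACY",
})


def translate_cds(cds: str) -> str:
    """Translate a coding sequence (with terminal stop) to a protein string."""
    protein = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa = CODON_TABLE[cds[i:i + 3].upper()]
        if aa == "*":
            break
        protein.append(aa)
    return "".join(protein)
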