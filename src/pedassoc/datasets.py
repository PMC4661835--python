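"""Published summary statistics for the PDE9A 5' regulatory SNP panel.

A candidate-gene study of PDE9A in Chinese Holstein (506 daughters from 8
sire families, daughter design) published per-marker genotype and allele
frequencies, per-genotype least-squares means of EBVs, and haplotype-block
frequencies for the six 5' regulatory SNPs.  Those printed values serve two
roles here: they are the calibration targets of the synthetic daughter-design
generator, and they are worked-example inputs for the frequency arithmetic,
Hardy-Weinberg and effect-decomposition routines (which operate on summary
statistics directly).

Individual-level data from that study were never deposited; nothing in this
module is individual-level.
"""

from __future__ import annotations

from .genotypes import Marker

# The six 5' regulatory SNPs; allele_first is the first-listed allele of the
# substitution label, allele_second the variant.
PDE9A_MARKERS: list[Marker] = [
    Marker("c.-2012 T>C", "T", "C", "rs42140305"),
    Marker("c.-2005 A>G", "A", "G", "rs381951806"),
    Marker("c.-1762 T>C", "T", "C", "rs136803034"),
    Marker("c.-1621 T>G", "T", "G", "rs133033048"),
    Marker("c.-1376 G>A", "G", "A", "rs210080144"),
    Marker("c.-724 A>G", "A", "G", "rs135748250"),
]

MARKER_IDS = [m.marker_id for m in PDE9A_MARKERS]

# Published genotype frequencies (proportions, 2 dp as printed)
GENOTYPE_FREQUENCIES: dict[str, dict[str, float]] = {
    "c.-2012 T>C": {"TT": 0.40, "CT": 0.48, "CC": 0.12},
    "c.-2005 A>G": {"AA": 0.56, "AG": 0.37, "GG": 0.07},
    "c.-1762 T>C": {"TT": 0.37, "CT": 0.49, "CC": 0.14},
    "c.-1621 T>G": {"TT": 0.52, "GT": 0.38, "GG": 0.10},
    "c.-1376 G>A": {"GG": 0.65, "AG": 0.32, "AA": 0.03},
    "c.-724 A>G": {"AA": 0.38, "AG": 0.52, "GG": 0.10},
}

# Published allele frequencies
ALLELE_FREQUENCIES: dict[str, dict[str, float]] = {
    "c.-2012 T>C": {"T": 0.64, "C": 0.36},
    "c.-2005 A>G": {"A": 0.74, "G": 0.26},
    "c.-1762 T>C": {"T": 0.61, "C": 0.39},
    "c.-1621 T>G": {"T": 0.72, "G": 0.28},
    "c.-1376 G>A": {"G": 0.81, "A": 0.19},
    "c.-724 A>G": {"A": 0.64, "G": 0.36},
}

# Published per-genotype sample sizes (daughters with a call at the marker)
GENOTYPE_COUNTS: dict[str, dict[str, int]] = {
    "c.-2012 T>C": {"CC": 59, "CT": 239, "TT": 198},
    "c.-2005 A>G": {"AA": 275, "AG": 183, "GG": 38},
    "c.-1762 T>C": {"CC": 71, "CT": 240, "TT": 185},
    "c.-1621 T>G": {"GG": 48, "GT": 186, "TT": 262},
    "c.-1376 G>A": {"AA": 14, "AG": 162, "GG": 320},
    "c.-724 A>G": {"AA": 185, "AG": 262, "GG": 49},
}

# Published least-squares means (EBV units) per genotype class, by trait.
# Genotype keys are alphabetically ordered class labels.
LSMEANS: dict[str, dict[str, dict[str, float]]] = {
    "MY": {
        "c.-2012 T>C": {"CC": 531.94, "CT": 363.53, "TT": 192.65},
        "c.-2005 A>G": {"AA": 242.80, "AG": 361.60, "GG": 596.23},
        "c.-1762 T>C": {"CC": 620.74, "CT": 432.42, "TT": 237.05},
        "c.-1621 T>G": {"GG": 500.63, "GT": 240.61, "TT": 312.57},
        "c.-1376 G>A": {"AA": 113.67, "AG": 158.20, "GG": 459.43},
        "c.-724 A>G": {"AA": 547.23, "AG": 282.30, "GG": 36.21},
    },
    "FY": {
        "c.-2012 T>C": {"CC": 11.44, "CT": 3.62, "TT": 0.91},
        "c.-2005 A>G": {"AA": 6.24, "AG": 6.77, "GG": 11.44},
        "c.-1762 T>C": {"CC": 15.84, "CT": 7.81, "TT": 3.67},
        "c.-1621 T>G": {"GG": 11.59, "GT": 4.37, "TT": 6.77},
        "c.-1376 G>A": {"AA": -2.48, "AG": 1.22, "GG": 9.06},
        "c.-724 A>G": {"AA": 10.08, "AG": 5.26, "GG": -3.01},
    },
    "PY": {
        "c.-2012 T>C": {"CC": 15.89, "CT": 10.82, "TT": 7.10},
        "c.-2005 A>G": {"AA": 9.72, "AG": 12.42, "GG": 18.84},
        "c.-1762 T>C": {"CC": 19.10, "CT": 14.93, "TT": 9.35},
        "c.-1621 T>G": {"GG": 17.44, "GT": 8.99, "TT": 10.39},
        "c.-1376 G>A": {"AA": 3.64, "AG": 4.86, "GG": 14.71},
        "c.-724 A>G": {"AA": 16.55, "AG": 9.65, "GG": 0.50},
    },
}

# Published haplotype blocks over the panel (strings follow marker order
# within the block).  Block 1 spans markers 1-4, block 2 markers 5-6.
BLOCK1_MARKERS = MARKER_IDS[:4]
BLOCK2_MARKERS = MARKER_IDS[4:]

# The three major block-1 haplotypes as published; the <5% remainder (7.6%)
# was published only as a pooled class listing three member strings.  The
# split below across those members reproduces every published block-1 allele
# frequency exactly and is the generator default.
BLOCK1_HAPLOTYPE_FREQUENCIES: dict[str, float] = {
    "CACT": 0.348,
    "TATT": 0.319,
    "TGTG": 0.257,
    "TACT": 0.040,
    "TATG": 0.024,
    "CATT": 0.012,
}
BLOCK1_MAJOR = ("CACT", "TATT", "TGTG")

BLOCK2_HAPLOTYPE_FREQUENCIES: dict[str, float] = {
    "GA": 0.638,
    "AG": 0.190,
    "GG": 0.172,
}

# Panel-wide Bonferroni denominator: six genotyped SNPs
N_MARKERS = 6
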