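"""Published breed-survey reference values for the three-marker haplotype system.

The three polymorphisms (dbSNP ss1714766385, ss1714766398, ss1714766400 on
BTA10) form the haplotype used to track the high-ovulation-rate allele in
descendants of the carrier sire. The tables below are the published breed
survey: per-breed sample sizes, haplotype frequencies (alleles written as
"+"/"-" for the indel and nucleotide letters for the SNPs), and pairwise
LD. They serve as inputs for the LD/marginalization computations and as
fixtures for cross-checking the frequency formulas.
"""

from __future__ import annotations

from .popgen import HaplotypeFreqTable

TRACKING_LOCI = ("ss1714766385", "ss1714766398", "ss1714766400")

# breed -> (n animals, {(allele1, allele2, allele3): frequency})
BREED_HAPLOTYPES: dict[str, tuple[int, dict[tuple[str, str, str], float]]] = {
    "Angus": (40, {
        ("+", "A", "A"): 0.063,
        ("+", "C", "G"): 0.113,
        ("-", "A", "A"): 0.025,
        ("-", "C", "A"): 0.025,
        ("-", "C", "G"): 0.775,
    }),
    "Hereford": (23, {
        ("+", "C", "G"): 0.136,
        ("-", "A", "A"): 0.045,
        ("-", "A", "G"): 0.045,
        ("-", "C", "G"): 0.773,
    }),
    "Holstein": (53, {
        ("+", "A", "A"): 0.019,
        ("-", "A", "A"): 0.019,
        ("-", "C", "A"): 0.019,
        ("-", "C", "G"): 0.943,
    }),
    "Jersey": (48, {
        ("+", "A", "A"): 0.020,
        ("-", "C", "A"): 0.020,
        ("-", "C", "G"): 0.960,
    }),
    "Simmental": (24, {
        ("+", "A", "A"): 0.064,
        ("+", "C", "G"): 0.085,
        ("-", "A", "G"): 0.064,
        ("-", "C", "G"): 0.787,
    }),
}

# breed -> (n animals, frequency of the high-associated allele at each locus
#           with printed SE)
BREED_ALLELE_FREQS: dict[str, tuple[int, dict[str, tuple[float, float]]]] = {
    "Angus": (40, {"ss1714766385": (0.175, 0.060), "ss1714766398": (0.077, 0.042),
                   "ss1714766400": (0.113, 0.050)}),
    "Hereford": (23, {"ss1714766385": (0.196, 0.083), "ss1714766398": (0.109, 0.065),
                      "ss1714766400": (0.087, 0.059)}),
    "Holstein": (53, {"ss1714766385": (0.030, 0.024), "ss1714766398": (0.048, 0.030),
                      "ss1714766400": (0.057, 0.033)}),
    "Jersey": (48, {"ss1714766385": (0.022, 0.022), "ss1714766398": (0.021, 0.021),
                    "ss1714766400": (0.042, 0.029)}),
    "Simmental": (24, {"ss1714766385": (0.136, 0.073), "ss1714766398": (0.130, 0.072),
                       "ss1714766400": (0.083, 0.059)}),
}


def breed_haplotype_table(breed: str) -> HaplotypeFreqTable:
    """The published three-locus haplotype frequency table for one breed.

    Printed frequencies are rounded to three decimals, so the table is
    renormalized to sum exactly to one before use.
    """
    n, freqs = BREED_HAPLOTYPES[breed]
    total = sum(freqs.values())
    return HaplotypeFreqTable(
        TRACKING_LOCI, {h: f / total for h, f in freqs.items()}, n_animals=n
    )
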