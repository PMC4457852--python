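"""Allele and haplotype frequency estimation and two-locus LD.

Covers the population-survey statistics used to characterize the marker
haplotype tracking the high-ovulation allele across breeds: direct
allele-count frequencies with binomial standard errors, pooled-sequencing
peak-height frequency estimates, a small multilocus EM for unphased
genotypes (up to three biallelic loci), marginalization of haplotype
tables, and the classical D / r-squared linkage-disequilibrium measures.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HaplotypeFreqTable",
    "LDResult",
    "allele_freq_count",
    "pooled_peak_freq",
    "haplotype_freq_em",
    "marginalize",
    "ld_r2",
]


@dataclass
class HaplotypeFreqTable:
    """Multilocus haplotype frequencies with standard errors.

    ``freqs`` maps an allele tuple (one allele label per locus, in
    ``locus_ids`` order) to its frequency; ``ses`` holds matching standard
    errors, binomial on 2n gametes. Frequencies must sum to 1.
    """

    locus_ids: tuple[str, ...]
    freqs: dict[tuple, float]
    ses: dict[tuple, float] = field(default_factory=dict)
    n_animals: int = 0
    converged: bool = True

    def __post_init__(self):
        self.locus_ids = tuple(self.locus_ids)
        total = sum(self.freqs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")
        if any(f < -1e-12 for f in self.freqs.values()):
            raise ValueError("negative haplotype frequency")
        if not self.ses and self.n_animals > 0:
            self.ses = {
                h: binomial_se(f, 2 * self.n_animals) for h, f in self.freqs.items()
            }

    def allele_freq(self, locus: str, allele) -> float:
        i = self.locus_ids.index(locus)
        return sum(f for h, f in self.freqs.items() if h[i] == allele)

    def alleles(self, locus: str) -> list:
        i = self.locus_ids.index(locus)
        return sorted({h[i] for h in self.freqs}, key=str)


@dataclass(frozen=True)
class LDResult:
    locus_a: str
    locus_b: str
    D: float
    r2: float
    defined: bool = True


def binomial_se(p: float, n: int) -> float:
    return math.sqrt(max(p * (1.0 - p), 0.0) / n)


def allele_freq_count(genotypes: np.ndarray) -> tuple[float, float]:
    """Allele frequency by direct counting, with its standard error.

    ``genotypes`` are 0/1/2 codes (count of the allele of interest; negative
    = missing, dropped). Returns (p, SE) with p = count / 2n and
    SE = sqrt(p(1-p)/n) on n animals — the convention that reproduces the
    published breed-survey tables, where the binomial unit is the animal.
    """
    g = np.asarray(genotypes)
    g = g[g >= 0]
    n = len(g)
    if n == 0:
        raise ValueError("no called genotypes")
    p = float(g.sum()) / (2 * n)
    return p, binomial_se(p, n)


def pooled_peak_freq(height_a: float, height_b: float) -> float:
    """Allele frequency from relative sequencing-trace peak heights of a DNA pool."""
    if height_a < 0 or height_b < 0:
        raise ValueError("peak heights must be non-negative")
    total = height_a + height_b
    if total == 0:
        raise ValueError("both peak heights are zero")
    return height_a / total


def _compatible_pairs(g: tuple[int, ...]) -> list[tuple[tuple, tuple]]:
    """Ordered haplotype pairs consistent with an unphased 0/1/2 genotype vector."""
    per_locus = []
    for gl in g:
        if gl == 0:
            per_locus.append([(0, 0)])
        elif gl == 2:
            per_locus.append([(1, 1)])
        else:
            per_locus.append([(0, 1), (1, 0)])
    out = []
    for combo in itertools.product(*per_locus):
        h1 = tuple(c[0] for c in combo)
        h2 = tuple(c[1] for c in combo)
        out.append((h1, h2))
    return out


def haplotype_freq_em(
    genotypes: np.ndarray,
    locus_ids: tuple[str, ...] | None = None,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> HaplotypeFreqTable:
    """EM estimate of haplotype frequencies from unphased biallelic genotypes.

    ``genotypes`` is (n, L) with 0/1/2 codes, L <= 3 (at most 8 haplotypes);
    animals with any missing call are dropped. Uniform initialization;
    iteration stops when the largest frequency change is below ``tol``.
    Non-convergence within ``max_iter`` flags the result instead of raising.
    SEs are binomial on 2n gametes.
    """
    g = np.asarray(genotypes)
    if g.ndim != 2 or g.shape[1] > 3:
        raise ValueError("genotypes must be (n, L) with L <= 3")
    g = g[(g >= 0).all(axis=1)]
    n, L = g.shape
    if n == 0:
        raise ValueError("no complete genotype vectors")
    if locus_ids is None:
        locus_ids = tuple(f"locus{i + 1}" for i in range(L))

    haps = list(itertools.product((0, 1), repeat=L))
    hidx = {h: i for i, h in enumerate(haps)}
    pair_lists = [
        [(hidx[h1], hidx[h2]) for h1, h2 in _compatible_pairs(tuple(row))] for row in g
    ]
    f = np.full(len(haps), 1.0 / len(haps))
    converged = False
    for _ in range(max_iter):
        counts = np.zeros(len(haps))
        for pairs in pair_lists:
            w = np.array([f[i] * f[j] for i, j in pairs])
            tot = w.sum()
            w = np.full(len(pairs), 1.0 / len(pairs)) if tot == 0 else w / tot
            for (i, j), wk in zip(pairs, w):
                counts[i] += wk
                counts[j] += wk
        new_f = counts / (2 * n)
        if np.max(np.abs(new_f - f)) < tol:
            f = new_f
            converged = True
            break
        f = new_f
    freqs = {h: float(f[hidx[h]]) for h in haps if f[hidx[h]] > 0}
    # renormalize away the tiny mass lost to dropped zero-frequency cells
    total = sum(freqs.values())
    freqs = {h: v / total for h, v in freqs.items()}
    return HaplotypeFreqTable(locus_ids, freqs, n_animals=n, converged=converged)


def em_loglik(freqs: dict[tuple, float], genotypes: np.ndarray) -> float:
    """Log-likelihood of unphased genotypes under given haplotype frequencies."""
    ll = 0.0
    for row in np.asarray(genotypes):
        prob = 0.0
        for h1, h2 in _compatible_pairs(tuple(row)):
            prob += freqs.get(h1, 0.0) * freqs.get(h2, 0.0)
        if prob <= 0:
            return -math.inf
        ll += math.log(prob)
    return ll


def marginalize(table: HaplotypeFreqTable, pair: tuple[str, str]) -> HaplotypeFreqTable:
    """Sum a haplotype table down to two loci (dropping the others)."""
    try:
        idx = [table.locus_ids.index(p) for p in pair]
    except ValueError as e:
        raise ValueError(f"locus not in table: {e}") from None
    out: dict[tuple, float] = {}
    for h, fr in table.freqs.items():
        key = tuple(h[i] for i in idx)
        out[key] = out.get(key, 0.0) + fr
    return HaplotypeFreqTable(tuple(pair), out, n_animals=table.n_animals)


def ld_r2(table: HaplotypeFreqTable) -> LDResult:
    """D and r-squared from a two-locus haplotype frequency table.

    D = P(AB) - p_A p_B for the first allele (sorted order) at each locus;
    r2 = D^2 / (p_A(1-p_A) p_B(1-p_B)). A monomorphic locus yields a
    flagged undefined result. r2 is invariant to which allele is designated.
    """
    if len(table.locus_ids) != 2:
        raise ValueError("ld_r2 needs a two-locus table")
    la, lb = table.locus_ids
    alleles_a, alleles_b = table.alleles(la), table.alleles(lb)
    if len(alleles_a) < 2 or len(alleles_b) < 2:
        return LDResult(la, lb, 0.0, float("nan"), defined=False)
    a0, b0 = alleles_a[0], alleles_b[0]
    pa = table.allele_freq(la, a0)
    pb = table.allele_freq(lb, b0)
    pab = sum(f for h, f in table.freqs.items() if h[0] == a0 and h[1] == b0)
    D = pab - pa * pb
    denom = pa * (1 - pa) * pb * (1 - pb)
    if denom <= 0:
        return LDResult(la, lb, D, float("nan"), defined=False)
    return LDResult(la, lb, D, D * D / denom)
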