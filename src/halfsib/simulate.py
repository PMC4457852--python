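"""Synthetic single-sire half-sib families with full ground truth.

The generator emulates the study design the linkage analysis assumes: one
sire heterozygous for a major ovulation-rate allele, ~131 daughters from
unrelated dams spread over four birth-year cohorts, a genome-wide low-density
SNP panel, and a biallelic QTL that is *not* itself on the panel. Meioses
follow a no-interference (Haldane) model on the genetic map. Phenotypes are
animal-mean ovulation rates drawn from carrier/non-carrier normal
distributions with genotype-specific spread, shifted by cohort effects and
floored at 1 (one corpus luteum defines a recorded cycle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GenotypeTable, PhenotypeRecord, SnpMap
import pandas as pd

__all__ = ["SimConfig", "TruthSet", "simulate_gamete", "simulate_family", "default_chrom_lengths"]


# approximate bovine autosome lengths (Mb), UMD3.1 scale, ~2.5 Gb total
_BTA_MB = [158, 137, 121, 120, 121, 119, 113, 113, 105, 104, 107, 91, 84, 84,
           85, 81, 75, 66, 64, 72, 71, 61, 52, 62, 42, 51, 45, 46, 51]


def default_chrom_lengths(n_chrom: int = 29) -> dict[str, int]:
    """Bovine autosome lengths in bp (approximate assembly scale)."""
    return {str(i + 1): _BTA_MB[i] * 1_000_000 for i in range(n_chrom)}


@dataclass
class SimConfig:
    """Parameters of the synthetic half-sib family.

    Defaults reproduce the mapped study's conditions: 131 daughters in
    cohorts of 33/55/28/15 (2008-2011), ~3,000 autosomal SNPs (29 chromosomes,
    ~104 markers each), a QTL on chromosome 10 at 14.2 Mb, carrier phenotype
    mean 2.19 (SD 0.57) versus non-carrier 1.11 (SD 0.22) ova per cycle.
    """

    n_daughters: int = 131
    year_sizes: dict[int, int] = field(
        default_factory=lambda: {2008: 33, 2009: 55, 2010: 28, 2011: 15}
    )
    chrom_lengths: dict[str, int] = field(default_factory=default_chrom_lengths)
    n_markers_per_chrom: int = 104
    cM_per_Mb: float = 1.0
    qtl_chrom: str = "10"
    qtl_pos_bp: int = 14_200_000
    carrier_mean: float = 2.19
    noncarrier_mean: float = 1.11
    carrier_sd: float = 0.57
    noncarrier_sd: float = 0.22
    year_effects: dict[int, float] = field(default_factory=dict)
    geno_error_rate: float = 0.001
    missing_rate: float = 0.01
    maf: float = 0.5  # maternal-population frequency used for every marker
    allele_freqs: np.ndarray | None = None  # overrides maf when given (len = n markers)
    seed: int = 0

    def validate(self) -> None:
        for name in ("geno_error_rate", "missing_rate", "maf"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.carrier_sd <= 0 or self.noncarrier_sd <= 0:
            raise ValueError("phenotype SDs must be positive")
        if self.qtl_chrom not in self.chrom_lengths:
            raise ValueError(f"qtl_chrom {self.qtl_chrom!r} not among chromosomes")
        if not 0 < self.qtl_pos_bp < self.chrom_lengths[self.qtl_chrom]:
            raise ValueError("qtl_pos_bp outside its chromosome")
        if self.n_daughters < 1:
            raise ValueError("need at least one daughter")
        if sum(self.year_sizes.values()) != self.n_daughters:
            raise ValueError("year_sizes must sum to n_daughters")
        if self.n_markers_per_chrom < 1:
            raise ValueError("need at least one marker per chromosome")


@dataclass
class TruthSet:
    """Ground truth of a simulated family, for testing the inference stack.

    ``sire_haplotypes[chrom]`` is a (2, m) allele array (haplotype 1 carries
    the high QTL allele). ``paternal_states[chrom]`` is (n_daughters, m) with
    0/1 = sire haplotype copied at each marker. ``crossovers_bp[d][chrom]``
    lists crossover positions of daughter d's paternal gamete. ``carrier``
    flags daughters whose paternal state at the QTL position is haplotype 1.
    """

    sire_haplotypes: dict[str, np.ndarray]
    paternal_states: dict[str, np.ndarray]
    crossovers_bp: list[dict[str, np.ndarray]]
    carrier: np.ndarray
    daughter_ids: list[str]


def simulate_gamete(
    haplos: np.ndarray, snp_map_chrom: pd.DataFrame, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one paternal gamete along a chromosome.

    Crossover count is Poisson(L/100) for genetic length L in cM, positions
    uniform on the genetic map (Haldane, no interference); the starting
    haplotype is a fair coin. Returns the transmitted allele sequence and the
    crossover positions in cM.

    ``haplos`` is (2, m); ``snp_map_chrom`` provides pos_cM per marker.
    """
    pos_cM = snp_map_chrom["pos_cM"].to_numpy()
    if len(pos_cM) == 0:
        raise ValueError("empty marker map")
    lo, hi = pos_cM[0], pos_cM[-1]
    length = hi - lo
    n_x = rng.poisson(length / 100.0)
    xpos = np.sort(rng.uniform(lo, hi, size=n_x))
    start = rng.integers(0, 2)
    # active haplotype at each marker = start XOR (number of crossovers to the left)
    state = (start + np.searchsorted(xpos, pos_cM, side="left")) % 2
    return haplos[state, np.arange(len(pos_cM))], xpos


def _states_at(pos_cM_query: float, xpos: np.ndarray, start: int) -> int:
    return (start + np.searchsorted(xpos, pos_cM_query)) % 2


def simulate_family(cfg: SimConfig) -> tuple[GenotypeTable, SnpMap, list[PhenotypeRecord], TruthSet]:
    """Simulate the full family: genotypes (sire first), map, phenotypes, truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # marker map: evenly spaced with jitter, per chromosome
    rows = []
    for chrom, length in cfg.chrom_lengths.items():
        m = cfg.n_markers_per_chrom
        base = np.linspace(length / (m + 1), length * m / (m + 1), m)
        jitter = rng.uniform(-0.3, 0.3, size=m) * (length / (m + 1))
        pos = np.unique(np.clip((base + jitter).astype(np.int64), 1, length))
        for k, p in enumerate(pos):
            rows.append((f"snp{chrom}_{k}", chrom, int(p), p / 1e6 * cfg.cM_per_Mb))
    snp_map = SnpMap(pd.DataFrame(rows, columns=["marker_id", "chrom", "pos_bp", "pos_cM"]))

    n_mark = snp_map.n_markers
    if cfg.allele_freqs is not None:
        freqs = np.asarray(cfg.allele_freqs, dtype=float)
        if freqs.shape != (n_mark,):
            raise ValueError(f"allele_freqs must have length {n_mark}")
    else:
        freqs = np.full(n_mark, cfg.maf)

    # sire haplotypes per chromosome (haplotype 1 carries the high QTL allele
    # at the ungenotyped QTL locus)
    sire_h: dict[str, np.ndarray] = {}
    for chrom in snp_map.chromosomes():
        idx = snp_map.chrom_indices(chrom)
        sire_h[chrom] = (rng.random((2, len(idx))) < freqs[idx]).astype(np.int8)

    n = cfg.n_daughters
    daughter_ids = [f"D{i:03d}" for i in range(1, n + 1)]
    qtl_cM = cfg.qtl_pos_bp / 1e6 * cfg.cM_per_Mb

    codes = np.zeros((n + 1, n_mark), dtype=np.int8)
    states: dict[str, np.ndarray] = {}
    xovers: list[dict[str, np.ndarray]] = [dict() for _ in range(n)]
    carrier = np.zeros(n, dtype=bool)

    for chrom in snp_map.chromosomes():
        idx = snp_map.chrom_indices(chrom)
        sub = snp_map.df.iloc[idx]
        pos_cM = sub["pos_cM"].to_numpy()
        st = np.empty((n, len(idx)), dtype=np.int8)
        for d in range(n):
            lo, hi = pos_cM[0], pos_cM[-1]
            n_x = rng.poisson((hi - lo) / 100.0)
            xpos = np.sort(rng.uniform(lo, hi, size=n_x))
            start = int(rng.integers(0, 2))
            st[d] = (start + np.searchsorted(xpos, pos_cM, side="left")) % 2
            xbp = (xpos / cfg.cM_per_Mb * 1e6).astype(np.int64)
            xovers[d][chrom] = xbp
            if chrom == cfg.qtl_chrom:
                carrier[d] = _states_at(qtl_cM, xpos, start) == 0
        # paternal allele + maternal allele drawn from the population
        pat = sire_h[chrom][st, np.arange(len(idx))]
        mat = (rng.random((n, len(idx))) < freqs[idx]).astype(np.int8)
        codes[1:, idx] = pat + mat
        codes[0, idx] = sire_h[chrom].sum(axis=0)
        states[chrom] = st

    # genotyping error: flip one allele of the called genotype
    if cfg.geno_error_rate > 0:
        err = rng.random(codes.shape) < cfg.geno_error_rate
        direction = rng.integers(0, 2, size=codes.shape)
        flipped = np.where(codes == 1, np.where(direction == 0, 0, 2), 1)
        codes = np.where(err, flipped, codes).astype(np.int8)
    if cfg.missing_rate > 0:
        miss = rng.random(codes.shape) < cfg.missing_rate
        codes[miss] = -1

    gt = GenotypeTable(["SIRE"] + daughter_ids, snp_map, codes)

    # phenotypes: cohort effect + heteroscedastic major-gene normal, floor 1
    years = np.repeat(
        list(cfg.year_sizes.keys()), list(cfg.year_sizes.values())
    ).astype(int)
    mu = np.where(carrier, cfg.carrier_mean, cfg.noncarrier_mean)
    sd = np.where(carrier, cfg.carrier_sd, cfg.noncarrier_sd)
    offs = np.array([cfg.year_effects.get(int(y), 0.0) for y in years])
    pheno = np.maximum(1.0, offs + rng.normal(mu, sd))
    records = [
        PhenotypeRecord(did, float(p), int(y))
        for did, p, y in zip(daughter_ids, pheno, years)
    ]

    truth = TruthSet(sire_h, states, xovers, carrier, daughter_ids)
    return gt, snp_map, records, truth
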