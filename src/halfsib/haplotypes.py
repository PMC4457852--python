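"""Sire phasing and paternal-haplotype deduction in a half-sib family.

Within a single half-sib family only markers at which the sire is
heterozygous ("informative" markers) reveal which sire chromosome a
daughter inherited. The stack here is:

1. ``assign_paternal_allele`` — at an informative marker, a homozygous
   daughter pins down the paternal allele; a heterozygous or missing
   daughter is ambiguous (dams are not genotyped).
2. ``phase_sire`` — chain the sire's two alleles across adjacent
   informative markers by majority vote over daughters informative at both;
   weakly supported or tied links break the phase into independent blocks.
3. ``call_states`` — per daughter, a minimum-cost dynamic program assigns a
   sire-haplotype state (H1/H2) at every informative marker, trading
   haplotype switches against marker mismatches so an isolated bad call is
   absorbed as a genotyping error rather than a double crossover.
4. ``detect_breakpoints`` — state changes become closed bp intervals bounded
   by the flanking informative markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GenotypeTable, SnpMap

__all__ = [
    "AMBIGUOUS",
    "UNKNOWN",
    "ChromPhase",
    "SirePhase",
    "PaternalTracks",
    "Breakpoint",
    "informative_markers",
    "assign_paternal_allele",
    "paternal_allele_calls",
    "phase_sire",
    "call_states",
    "call_all_states",
    "detect_breakpoints",
    "phase_family",
]

AMBIGUOUS = np.int8(-1)  # paternal allele not determined
UNKNOWN = np.int8(-1)  # haplotype state not determined


def informative_markers(gt: GenotypeTable, sire_id: str) -> dict[str, np.ndarray]:
    """Global marker indices, per chromosome, where the sire is heterozygous."""
    sire = gt.row(sire_id)
    out = {}
    for chrom in gt.snp_map.chromosomes():
        idx = gt.snp_map.chrom_indices(chrom)
        out[chrom] = idx[sire[idx] == 1]
    return out


def assign_paternal_allele(sire_gt: int, daughter_gt: int) -> int:
    """Paternal allele at a sire-heterozygous marker: 0, 1 or AMBIGUOUS.

    A homozygous daughter must have received that allele from the sire; a
    heterozygous or missing daughter could have received either.
    """
    if sire_gt != 1:
        raise ValueError("marker is not informative (sire not heterozygous)")
    if daughter_gt == 0:
        return 0
    if daughter_gt == 2:
        return 1
    return int(AMBIGUOUS)


def paternal_allele_calls(daughter_codes: np.ndarray) -> np.ndarray:
    """Vectorized ``assign_paternal_allele`` over informative-marker codes."""
    calls = np.full(daughter_codes.shape, AMBIGUOUS, dtype=np.int8)
    calls[daughter_codes == 0] = 0
    calls[daughter_codes == 2] = 1
    return calls


@dataclass
class ChromPhase:
    """Sire phase over one chromosome's informative markers.

    ``hap1`` holds haplotype-1 alleles (haplotype 2 is the complement); the
    H1/H2 labelling is arbitrary within each phase block (``block_ids``).
    ``support`` holds, per adjacent gap, the number of daughters backing the
    adopted orientation; ``implied_recombinants`` the minority count.
    """

    marker_indices: np.ndarray  # global indices into the SnpMap
    hap1: np.ndarray  # (m,) alleles 0/1
    block_ids: np.ndarray  # (m,) consecutive block labels
    phase_break: np.ndarray  # (m-1,) bool per gap
    support: np.ndarray  # (m-1,) int
    implied_recombinants: np.ndarray  # (m-1,) int

    @property
    def n_markers(self) -> int:
        return len(self.hap1)


SirePhase = dict[str, ChromPhase]


def phase_sire(calls: np.ndarray, marker_indices: np.ndarray, min_informative: int = 5) -> ChromPhase:
    """Phase the sire along one chromosome from daughters' paternal-allele calls.

    ``calls`` is (n_daughters, m) over the chromosome's informative markers,
    entries 0/1/AMBIGUOUS. For each adjacent marker pair, daughters
    unambiguous at both vote for the "same haplotype carries equal alleles"
    vs "opposite" orientation; the majority is adopted. If the majority
    support is below ``min_informative`` or the vote ties, a phase break
    starts a new block (the inter-block orientation is left undetermined).
    """
    calls = np.asarray(calls, dtype=np.int8)
    m = calls.shape[1]
    if m == 0:
        z = np.zeros(0, dtype=np.int8)
        return ChromPhase(np.asarray(marker_indices), z, z.astype(int),
                          np.zeros(0, bool), np.zeros(0, int), np.zeros(0, int))
    hap1 = np.zeros(m, dtype=np.int8)
    block = np.zeros(m, dtype=int)
    brk = np.zeros(max(m - 1, 0), dtype=bool)
    support = np.zeros(max(m - 1, 0), dtype=int)
    implied = np.zeros(max(m - 1, 0), dtype=int)
    for j in range(m - 1):
        ok = (calls[:, j] != AMBIGUOUS) & (calls[:, j + 1] != AMBIGUOUS)
        same = int(np.sum(calls[ok, j] == calls[ok, j + 1]))
        opp = int(ok.sum()) - same
        win, lose = max(same, opp), min(same, opp)
        support[j], implied[j] = win, lose
        if same == opp or win < min_informative:
            brk[j] = True
            block[j + 1:] += 1
            hap1[j + 1] = 0  # new block starts with an arbitrary label
            continue
        # same-orientation: the allele pattern travels with the haplotype
        hap1[j + 1] = hap1[j] if same > opp else 1 - hap1[j]
    return ChromPhase(np.asarray(marker_indices), hap1, block, brk, support, implied)


def _viterbi_block(
    calls: np.ndarray, hap1: np.ndarray, switch_penalty: float, mismatch_penalty: float
) -> np.ndarray:
    """Minimum-cost H1/H2 path per daughter over one phase block.

    ``calls`` (n, m), ``hap1`` (m,). Cost = switch_penalty per state change
    + mismatch_penalty per unambiguous call contradicting the active
    haplotype. Ties break toward fewer switches, then lexicographically
    toward H1 (earliest marker first). Daughters with no unambiguous call in
    the block get all-UNKNOWN. Vectorized over daughters; backward DP plus
    forward reconstruction yields the lexicographically first optimum.
    """
    n, m = calls.shape
    e = np.zeros((n, m, 2))
    obs = calls != AMBIGUOUS
    e[:, :, 0] = np.where(obs & (calls != hap1), mismatch_penalty, 0.0)
    e[:, :, 1] = np.where(obs & (calls != (1 - hap1)), mismatch_penalty, 0.0)

    cost = e[:, m - 1, :].copy()  # best completion cost from marker j in state s
    nsw = np.zeros((n, 2), dtype=np.int32)
    choice = np.zeros((n, m - 1, 2), dtype=np.int8)  # chosen state at j+1
    for j in range(m - 2, -1, -1):
        new_cost = np.empty_like(cost)
        new_nsw = np.empty_like(nsw)
        for s in (0, 1):
            stay_c, stay_n = cost[:, s], nsw[:, s]
            sw_c, sw_n = cost[:, 1 - s] + switch_penalty, nsw[:, 1 - s] + 1
            # prefer smaller cost, then fewer switches, then next state H1
            take_sw = (sw_c < stay_c) | (
                (sw_c == stay_c) & ((sw_n < stay_n) | ((sw_n == stay_n) & (1 - s < s)))
            )
            choice[:, j, s] = np.where(take_sw, 1 - s, s)
            new_cost[:, s] = e[:, j, s] + np.where(take_sw, sw_c, stay_c)
            new_nsw[:, s] = np.where(take_sw, sw_n, stay_n)
        cost, nsw = new_cost, new_nsw

    states = np.empty((n, m), dtype=np.int8)
    better0 = (cost[:, 0] < cost[:, 1]) | (
        (cost[:, 0] == cost[:, 1]) & (nsw[:, 0] <= nsw[:, 1])
    )
    states[:, 0] = np.where(better0, 0, 1)
    for j in range(m - 1):
        states[:, j + 1] = choice[np.arange(n), j, states[:, j]]

    # An ambiguous run flanked by unambiguous calls of *different* state
    # contains a crossover whose position within the run is undetermined:
    # the DP's placement there is arbitrary, so those markers are UNKNOWN.
    # Runs flanked by equal states are interpolated; terminal runs extend
    # the flanking state (no evidence of a crossover beyond the last call).
    cols = np.arange(m)
    prev = np.maximum.accumulate(np.where(obs, cols, -1), axis=1)
    nxt = np.minimum.accumulate(np.where(obs, cols, m)[:, ::-1], axis=1)[:, ::-1]
    sp = np.take_along_axis(states, np.clip(prev, 0, None), axis=1)
    sn = np.take_along_axis(states, np.clip(nxt, 0, m - 1), axis=1)
    interior = (prev >= 0) & (nxt < m)
    states[~obs & interior & (sp != sn)] = UNKNOWN
    states[~obs.any(axis=1)] = UNKNOWN
    return states


def call_states(
    phase: ChromPhase,
    calls: np.ndarray,
    switch_penalty: float = 2.0,
    mismatch_penalty: float = 3.0,
) -> np.ndarray:
    """Assign H1/H2 states at every informative marker for each daughter.

    ``calls`` may be (m,) for one daughter or (n, m). Phase blocks are
    processed independently (no switch cost across a phase break). Returns
    int8 states 0 (=H1), 1 (=H2) or UNKNOWN, same leading shape as input.
    """
    calls = np.asarray(calls, dtype=np.int8)
    single = calls.ndim == 1
    if single:
        calls = calls[None, :]
    if calls.shape[1] != phase.n_markers:
        raise ValueError("calls do not align with the phase's informative markers")
    out = np.empty_like(calls)
    for b in np.unique(phase.block_ids):
        sel = phase.block_ids == b
        out[:, sel] = _viterbi_block(
            calls[:, sel], phase.hap1[sel], switch_penalty, mismatch_penalty
        )
    return out[0] if single else out


@dataclass(frozen=True)
class Breakpoint:
    """Closed bp interval between the informative markers flanking a state change."""

    chrom: str
    left_bp: int
    right_bp: int
    left_marker: str
    right_marker: str

    def overlaps(self, start_bp: int, end_bp: int) -> bool:
        return self.left_bp <= end_bp and self.right_bp >= start_bp


@dataclass
class PaternalTracks:
    """Per-daughter H1/H2 state tracks over informative markers, all chromosomes."""

    daughter_ids: list[str]
    phase: SirePhase
    states: dict[str, np.ndarray] = field(repr=False)  # chrom -> (n, m_inf)
    snp_map: SnpMap = None

    def breakpoints(self, daughter: str, chrom: str | None = None) -> list[Breakpoint]:
        d = self.daughter_ids.index(daughter)
        chroms = [chrom] if chrom else list(self.phase)
        out = []
        for c in chroms:
            out.extend(detect_breakpoints(self.states[c][d], self.phase[c], self.snp_map, c))
        return out

    def is_recombinant_in(self, daughter: str, chrom: str, start_bp: int, end_bp: int) -> bool:
        return any(
            bp.overlaps(start_bp, end_bp) for bp in self.breakpoints(daughter, chrom)
        )


def detect_breakpoints(
    states: np.ndarray, phase: ChromPhase, snp_map: SnpMap, chrom: str
) -> list[Breakpoint]:
    """Breakpoint intervals of one daughter's track on one chromosome.

    Within each phase block, a state change between consecutive markers of
    *known* state yields one interval bounded by those two markers' bp
    positions; intervening UNKNOWN markers (the undetermined crossover
    region) fall inside the interval. No interval is called across a phase
    break.
    """
    pos = snp_map.df["pos_bp"].to_numpy()[phase.marker_indices]
    ids = snp_map.df["marker_id"].to_numpy()[phase.marker_indices]
    out = []
    for b in np.unique(phase.block_ids):
        sel = np.flatnonzero(phase.block_ids == b)
        known = sel[states[sel] != UNKNOWN]
        for k1, k2 in zip(known[:-1], known[1:]):
            if states[k1] != states[k2]:
                out.append(
                    Breakpoint(chrom, int(pos[k1]), int(pos[k2]), str(ids[k1]), str(ids[k2]))
                )
    return out


def call_all_states(
    gt: GenotypeTable,
    sire_id: str,
    min_informative: int = 5,
    switch_penalty: float = 2.0,
    mismatch_penalty: float = 3.0,
) -> PaternalTracks:
    """Full deduction for a family: phase the sire and call every daughter."""
    info = informative_markers(gt, sire_id)
    daughters = [a for a in gt.animal_ids if a != sire_id]
    drows = [gt.animal_ids.index(a) for a in daughters]
    phase: SirePhase = {}
    states: dict[str, np.ndarray] = {}
    for chrom, idx in info.items():
        calls = paternal_allele_calls(gt.codes[np.ix_(drows, idx)])
        ph = phase_sire(calls, idx, min_informative)
        phase[chrom] = ph
        if len(idx):
            states[chrom] = call_states(ph, calls, switch_penalty, mismatch_penalty)
        else:
            states[chrom] = np.zeros((len(daughters), 0), dtype=np.int8)
    return PaternalTracks(daughters, phase, states, gt.snp_map)


phase_family = call_all_states  # convenience alias
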