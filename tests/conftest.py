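import numpy as np
import pandas as pd
import pytest

from halfsib import SimConfig, simulate_family
from halfsib.haplotypes import ChromPhase, PaternalTracks, UNKNOWN
from halfsib.io import SnpMap


def small_config(**overrides) -> SimConfig:
    """A two-chromosome family small enough for fast unit tests."""
    base = dict(
        n_daughters=60,
        year_sizes={2008: 30, 2009: 30},
        chrom_lengths={"1": 80_000_000, "2": 60_000_000},
        n_markers_per_chrom=90,
        qtl_chrom="1",
        qtl_pos_bp=40_000_000,
        geno_error_rate=0.0,
        missing_rate=0.0,
        seed=11,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def clean_small_family():
    """Error-free small family with ground truth."""
    return simulate_family(small_config())


@pytest.fixture(scope="session")
def noisy_small_family():
    return simulate_family(small_config(geno_error_rate=0.002, missing_rate=0.01, seed=5))


def make_tracks(pos_mb, states, chrom="10", hap1=None):
    """Hand-built single-chromosome PaternalTracks for constructed examples.

    ``pos_mb``: informative marker positions in Mb. ``states``: (n, m) array
    of 0/1/UNKNOWN.
    """
    pos_mb = np.asarray(pos_mb, dtype=float)
    m = len(pos_mb)
    snp_map = SnpMap(
        pd.DataFrame(
            {
                "marker_id": [f"m{i}" for i in range(m)],
                "chrom": chrom,
                "pos_bp": (pos_mb * 1e6).astype(np.int64),
                "pos_cM": pos_mb,
            }
        )
    )
    phase = ChromPhase(
        marker_indices=np.arange(m),
        hap1=np.zeros(m, np.int8) if hap1 is None else np.asarray(hap1, np.int8),
        block_ids=np.zeros(m, dtype=int),
        phase_break=np.zeros(max(m - 1, 0), dtype=bool),
        support=np.full(max(m - 1, 0), 99),
        implied_recombinants=np.zeros(max(m - 1, 0), dtype=int),
    )
    states = np.asarray(states, dtype=np.int8)
    daughters = [f"D{i:03d}" for i in range(1, states.shape[0] + 1)]
    return PaternalTracks(daughters, {chrom: phase}, {chrom: states}, snp_map)


def truth_state_accuracy(gt, snp_map, truth, tracks):
    """Compare called tracks with simulation truth.

    Returns (phase_exact, acc_at_determinable, acc_at_known, known_fraction):
    determinable = markers where the daughter's own call pins the paternal
    allele; known = markers where the caller reports a state.
    """
    from halfsib.haplotypes import informative_markers, paternal_allele_calls

    info = informative_markers(gt, "SIRE")
    drows = [gt.animal_ids.index(d) for d in tracks.daughter_ids]
    phase_exact = True
    tot = wrong_k = tot_k = wrong_u = tot_u = 0
    for chrom, idx in info.items():
        ph = tracks.phase[chrom]
        cidx = snp_map.chrom_indices(chrom)
        within = np.searchsorted(cidx, idx)
        th1 = truth.sire_haplotypes[chrom][0, within]
        flip = np.zeros(len(idx), bool)
        for b in np.unique(ph.block_ids):
            sel = ph.block_ids == b
            if np.all(ph.hap1[sel] == th1[sel]):
                flip[sel] = False
            elif np.all(ph.hap1[sel] == 1 - th1[sel]):
                flip[sel] = True
            else:
                phase_exact = False
        st = tracks.states[chrom]
        ts = truth.paternal_states[chrom][:, within]
        calls = paternal_allele_calls(gt.codes[np.ix_(drows, idx)])
        mapped = np.where(flip[None, :], 1 - st, st)
        known = st != UNKNOWN
        tot += known.size
        tot_k += int(known.sum())
        wrong_k += int(np.sum((mapped != ts) & known))
        unamb = calls != -1
        tot_u += int(unamb.sum())
        wrong_u += int(np.sum((mapped != ts) & unamb))
    return (
        phase_exact,
        1 - wrong_u / tot_u,
        1 - wrong_k / tot_k,
        tot_k / tot,
    )
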