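"""Marker-bracket linkage scan for a half-sib family.

Each pair of consecutive informative markers (a "bracket") defines a 0/1
covariate: which sire haplotype a daughter carries across the bracket.
Daughters recombinant inside the bracket, or of unknown state at either
end, are excluded from that bracket's fit. Mean ovulation rate is regressed
on the covariate with birth year as a categorical effect; the profile of
-log10 p across brackets localizes the major gene.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .haplotypes import UNKNOWN, PaternalTracks
from .io import PhenotypeRecord, SnpMap

logger = logging.getLogger(__name__)

__all__ = ["FitResult", "bracket_covariate", "fit_linear", "genome_scan", "plot_scan"]

EXCLUDED = np.int8(-1)

SCAN_COLUMNS = [
    "bracket_left_id",
    "bracket_right_id",
    "chrom",
    "mid_bp",
    "n_used",
    "beta",
    "se",
    "t",
    "p",
    "neglog10p",
    "estimable",
]


@dataclass(frozen=True)
class FitResult:
    """OLS result for the haplotype covariate in one bracket."""

    beta: float
    se: float
    t: float
    p: float
    n_used: int
    df_resid: int
    estimable: bool = True


def bracket_covariate(tracks: PaternalTracks, chrom: str, j: int) -> np.ndarray:
    """Per-daughter 0/1 covariate for the bracket (marker j, marker j+1).

    1 = haplotype H1 at both ends, 0 = H2 at both ends; EXCLUDED (-1) when
    the daughter is recombinant within the bracket, unknown at either end,
    or the bracket spans a phase break.
    """
    st = tracks.states[chrom]
    if j < 0 or j + 1 >= st.shape[1]:
        raise IndexError("bracket index out of range")
    a, b = st[:, j], st[:, j + 1]
    x = np.full(st.shape[0], EXCLUDED, dtype=np.int8)
    if tracks.phase[chrom].phase_break[j]:
        return x  # phase relation across the gap unknown
    ok = (a != UNKNOWN) & (b != UNKNOWN) & (a == b)
    x[ok & (a == 0)] = 1
    x[ok & (a == 1)] = 0
    return x


def fit_linear(
    y: np.ndarray, year: np.ndarray, x: np.ndarray
) -> FitResult:
    """OLS of phenotype on intercept + year indicators + haplotype covariate.

    The two-sided p-value for the covariate uses the t distribution with
    n - rank(design) degrees of freedom. A constant covariate among the
    included animals yields a flagged non-estimable result with p = 1.
    Redundant year columns (cohorts absent from the subset) are dropped.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    year = np.asarray(year)
    n = len(y)
    if len(np.unique(x)) < 2:
        return FitResult(0.0, np.nan, 0.0, 1.0, n, 0, estimable=False)
    levels = np.unique(year)
    cols = [np.ones(n)]
    kept = []
    for lv in levels[1:]:
        ind = (year == lv).astype(float)
        if 0 < ind.sum() < n:
            cols.append(ind)
            kept.append(lv)
    if len(kept) < len(levels) - 1:
        logger.info("fit_linear: dropped %d empty/degenerate year columns",
                    len(levels) - 1 - len(kept))
    X = np.column_stack(cols + [x])
    k = X.shape[1]
    if n <= k:
        return FitResult(0.0, np.nan, 0.0, 1.0, n, 0, estimable=False)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        return FitResult(0.0, np.nan, 0.0, 1.0, n, 0, estimable=False)
    resid = y - X @ coef
    df = n - k
    sigma2 = float(resid @ resid) / df
    XtX_inv = np.linalg.inv(X.T @ X)
    se = math.sqrt(sigma2 * XtX_inv[-1, -1])
    beta = float(coef[-1])
    if se == 0.0:
        # perfect fit: infinite t; report p at the floor
        return FitResult(beta, 0.0, math.inf, 0.0, n, df)
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return FitResult(beta, se, t, p, n, df)


def genome_scan(
    tracks: PaternalTracks,
    phenotypes: list[PhenotypeRecord],
    snp_map: SnpMap,
) -> pd.DataFrame:
    """Bracket-by-bracket association scan over all chromosomes.

    Returns one row per consecutive informative-marker bracket with the
    schema (bracket ids, chrom, midpoint bp, n used, beta, se, t, p,
    -log10 p, estimable). Chromosomes with fewer than two informative
    markers are skipped with a log entry. p-values are floored at the
    smallest positive float so -log10 p stays finite.
    """
    ph = {r.animal_id: r for r in phenotypes}
    common = [d for d in tracks.daughter_ids if d in ph]
    if not common:
        raise ValueError("no phenotyped daughters in the tracks")
    rows_idx = [tracks.daughter_ids.index(d) for d in common]
    y = np.array([ph[d].mean_or for d in common])
    year = np.array([ph[d].birth_year for d in common])

    recs = []
    for chrom, phase in tracks.phase.items():
        m = phase.n_markers
        if m < 2:
            logger.info("genome_scan: chromosome %s skipped (<2 informative markers)", chrom)
            continue
        pos = snp_map.df["pos_bp"].to_numpy()[phase.marker_indices]
        ids = snp_map.df["marker_id"].to_numpy()[phase.marker_indices]
        for j in range(m - 1):
            xall = bracket_covariate(tracks, chrom, j)[rows_idx]
            use = xall != EXCLUDED
            fit = fit_linear(y[use], year[use], xall[use]) if use.sum() else FitResult(
                0.0, np.nan, 0.0, 1.0, 0, 0, estimable=False
            )
            p = max(fit.p, np.nextafter(0, 1))
            recs.append(
                (
                    ids[j],
                    ids[j + 1],
                    chrom,
                    int((pos[j] + pos[j + 1]) // 2),
                    fit.n_used,
                    fit.beta,
                    fit.se,
                    fit.t,
                    fit.p,
                    -math.log10(p) if fit.estimable else 0.0,
                    fit.estimable,
                )
            )
    return pd.DataFrame(recs, columns=SCAN_COLUMNS)


def scan_peak(scan: pd.DataFrame) -> pd.Series:
    """The bracket with the largest -log10 p among estimable brackets.

    Adjacent brackets with no recombinant between them carry identical
    covariates and hence exactly tied p-values; within such a tied plateau
    the middle bracket is reported as the peak.
    """
    est = scan[scan["estimable"]]
    if est.empty:
        raise ValueError("no estimable bracket in scan")
    v = est["neglog10p"].to_numpy()
    tied = np.flatnonzero(np.isclose(v, v.max(), rtol=0, atol=1e-12))
    # restrict to the contiguous run of ties on the same chromosome
    chroms = est["chrom"].to_numpy()
    run = [tied[0]]
    for i in tied[1:]:
        if i == run[-1] + 1 and chroms[i] == chroms[run[0]]:
            run.append(i)
        else:
            break
    return est.iloc[run[len(run) // 2]]


def plot_scan(scan: pd.DataFrame, path, bonferroni: float = 0.05) -> None:
    """Per-chromosome paneled -log10 p profile with a Bonferroni guide line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(dict.fromkeys(scan["chrom"]))
    n_tests = int(scan["estimable"].sum())
    thresh = -math.log10(bonferroni / max(n_tests, 1))
    fig, axes = plt.subplots(
        1, len(chroms), figsize=(max(8, 0.6 * len(chroms)), 4),
        sharey=True, squeeze=False,
    )
    for ax, chrom in zip(axes[0], chroms):
        sub = scan[(scan["chrom"] == chrom) & scan["estimable"]]
        ax.plot(sub["mid_bp"] / 1e6, sub["neglog10p"], lw=0.8)
        ax.axhline(thresh, color="red", lw=0.5, ls="--")
        ax.set_title(str(chrom), fontsize=7)
        ax.tick_params(labelsize=6)
        ax.set_xticks([])
    axes[0][0].set_ylabel(r"$-\log_{10}\,p$")
    fig.suptitle("Within-family marker-bracket scan")
    fig.savefig(path, dpi=150)
    plt.close(fig)
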