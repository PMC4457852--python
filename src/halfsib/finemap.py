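"""Recombinant-based fine-mapping of the QTL interval.

Each daughter recombinant inside the candidate region carries the high
sire haplotype on exactly one side of her breakpoint. Her carrier status
therefore constrains the causative position to one side of the breakpoint
interval; intersecting these one-sided constraints over all informative
recombinants narrows the region. Breakpoint uncertainty (the gap between
flanking informative markers) is kept inside the bound, so reported
regions are conservative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .haplotypes import UNKNOWN, PaternalTracks
from .io import PhenotypeRecord
from .scan import scan_peak

logger = logging.getLogger(__name__)

__all__ = ["CandidateRegion", "CarrierCall", "classify_carriers", "refine_region"]


@dataclass
class CandidateRegion:
    chrom: str
    start_bp: int
    end_bp: int
    left_marker: str | None = None
    right_marker: str | None = None
    supporting_daughters: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.start_bp >= self.end_bp:
            raise ValueError(f"degenerate region {self.start_bp}..{self.end_bp}")

    @property
    def width_bp(self) -> int:
        return self.end_bp - self.start_bp

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom,
            "start_bp": self.start_bp,
            "end_bp": self.end_bp,
            "width_bp": self.width_bp,
            "left_marker": self.left_marker,
            "right_marker": self.right_marker,
            "supporting_daughters": self.supporting_daughters,
        }


@dataclass
class CarrierCall:
    """Carrier classification at the scan peak.

    ``status`` is "carrier", "noncarrier" or "recombinant_at_peak"; for
    recombinants ``label`` holds a lower-confidence phenotype-threshold
    call (the two genotype-group means' midpoint), flagged by
    ``from_phenotype``.
    """

    daughter: str
    status: str
    label: str | None = None
    from_phenotype: bool = False


def classify_carriers(
    tracks: PaternalTracks,
    scan: pd.DataFrame,
    phenotypes: list[PhenotypeRecord],
    peak: pd.Series | None = None,
) -> tuple[list[CarrierCall], int]:
    """Label each daughter at the scan peak bracket.

    The "high" sire haplotype is the one with the larger phenotype mean at
    the peak (the sign of the peak beta: covariate 1 codes H1). Daughters
    with a consistent state across the peak bracket are carriers or
    non-carriers; daughters recombinant within the bracket (or unknown at
    an end) are flagged and given a provisional phenotype-threshold label.

    Returns the calls plus the high haplotype's state code (0=H1, 1=H2).
    """
    if peak is None:
        peak = scan_peak(scan)
    if not peak["estimable"]:
        raise ValueError("peak bracket is non-estimable")
    chrom = str(peak["chrom"])
    phase = tracks.phase[chrom]
    snp = tracks.snp_map
    j = int(np.flatnonzero(
        snp.df["marker_id"].to_numpy()[phase.marker_indices] == peak["bracket_left_id"]
    )[0])
    high_state = 0 if peak["beta"] > 0 else 1  # covariate 1 == H1
    ph = {r.animal_id: r.mean_or for r in phenotypes}

    st = tracks.states[chrom]
    calls: list[CarrierCall] = []
    means = {True: [], False: []}
    for d, did in enumerate(tracks.daughter_ids):
        a, b = st[d, j], st[d, j + 1]
        if a != UNKNOWN and a == b and not phase.phase_break[j]:
            is_carrier = a == high_state
            status = "carrier" if is_carrier else "noncarrier"
            calls.append(CarrierCall(did, status, status))
            if did in ph:
                means[is_carrier].append(ph[did])
        else:
            calls.append(CarrierCall(did, "recombinant_at_peak", from_phenotype=True))
    if any(c.status == "recombinant_at_peak" for c in calls):
        if not means[True] or not means[False]:
            raise ValueError("cannot threshold recombinants: a genotype group is empty")
        cut = (float(np.mean(means[True])) + float(np.mean(means[False]))) / 2.0
        logger.info("classify_carriers: phenotype threshold %.3f for recombinants", cut)
        for c in calls:
            if c.status == "recombinant_at_peak" and c.daughter in ph:
                c.label = "carrier" if ph[c.daughter] > cut else "noncarrier"
    return calls, high_state


def refine_region(
    initial: CandidateRegion,
    tracks: PaternalTracks,
    carrier_labels: dict[str, str],
    high_state: int,
) -> CandidateRegion:
    """Intersect recombinant daughters' constraints with the initial region.

    ``carrier_labels`` maps recombinant daughter ids to "carrier"/
    "noncarrier". Each daughter must have exactly one breakpoint interval
    inside the initial region (others are excluded with a log entry). A
    carrier's causative position lies within her high-haplotype segment
    plus her breakpoint interval; a non-carrier's lies outside her high
    segment. Raises on an empty intersection, listing the daughters whose
    constraints conflict.
    """
    chrom = initial.chrom
    phase = tracks.phase[chrom]
    pos = tracks.snp_map.df["pos_bp"].to_numpy()[phase.marker_indices]
    ids = tracks.snp_map.df["marker_id"].to_numpy()[phase.marker_indices]

    lo, hi = initial.start_bp, initial.end_bp
    lo_by, hi_by = None, None
    supporters = []
    for did, label in carrier_labels.items():
        bps = [
            bp for bp in tracks.breakpoints(did, chrom)
            if bp.overlaps(initial.start_bp, initial.end_bp)
        ]
        if len(bps) != 1:
            logger.info(
                "refine_region: %s excluded (%d breakpoints in region)", did, len(bps)
            )
            continue
        bp = bps[0]
        d = tracks.daughter_ids.index(did)
        jl = int(np.searchsorted(pos, bp.left_bp))
        state_left = tracks.states[chrom][d, jl]
        high_on_left = state_left == high_state
        # carrier: QTL on the high side (incl. the uncertain interval);
        # noncarrier: QTL on the low side (incl. the interval)
        qtl_left = high_on_left if label == "carrier" else not high_on_left
        if qtl_left:
            if bp.right_bp < hi:
                hi, hi_by = bp.right_bp, did
        else:
            if bp.left_bp > lo:
                lo, lo_by = bp.left_bp, did
        supporters.append(did)
    if lo >= hi:
        conflict = sorted({x for x in (lo_by, hi_by) if x})
        raise ValueError(
            f"inconsistent recombinant set: constraints from {conflict} leave an "
            f"empty region ({lo} >= {hi})"
        )
    left_m = str(ids[np.searchsorted(pos, lo)]) if lo in pos else initial.left_marker
    right_m = str(ids[np.searchsorted(pos, hi)]) if hi in pos else initial.right_marker
    return CandidateRegion(chrom, int(lo), int(hi), left_m, right_m, supporters)
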