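"""Selection of the single most plausible peptide assignment per cluster.

The selection discipline, applied in order:

1. drop candidates below the total-score threshold;
2. drop candidates whose members' delta-RT values (member apex RT minus
   peptide RT) all fall outside the allowed window — peptides with unknown
   RT (rt = 0) pass this step unconditionally;
3. keep the highest-scoring survivor;
4. if several candidates tie on the top score the cluster is excluded;
5. the survivor must have a strictly greater than 50% (configurable)
   fraction of cluster members carrying positive glycan points.

Members of an accepted candidate whose delta RT or mass error falls outside
the windows are flagged for inspection, never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .formats_io import CorePeptide
from .matching import MatchCandidate
from .peak_detection import MonoisotopicPeak

STATUS_ASSIGNED = "assigned"
STATUS_TIE = "excluded-tie"
STATUS_LOW_RATIO = "excluded-low-ratio"
STATUS_NO_CANDIDATE = "excluded-no-candidate"


@dataclass(frozen=True)
class SelectionThresholds:
    min_total_score: float = 4.0
    delta_rt_window: tuple[float, float] = (-10.0, 10.0)
    delta_mass_ppm: float = 5.0
    min_point_ratio: float = 0.5  # strict >

    def __post_init__(self) -> None:
        lo, hi = self.delta_rt_window
        if lo >= hi:
            raise ValueError("delta_rt_window must be a nonempty interval")
        if not 0 <= self.min_point_ratio < 1:
            raise ValueError("min_point_ratio must be in [0, 1)")


@dataclass
class ClusterAssignment:
    """Outcome of selection for one cluster."""

    cluster_id: int
    status: str
    peptide_id: str | None = None
    candidate: MatchCandidate | None = None
    flagged_members: list[int] = field(default_factory=list)
    confidence: str | None = None  # filled by the MS2 stage

    @property
    def assigned(self) -> bool:
        return self.status == STATUS_ASSIGNED


def point_ratio(candidate: MatchCandidate, cluster_size: int) -> float:
    """Fraction of cluster members whose matched composition earned points."""
    with_points = sum(1 for m in candidate.member_matches if m.points_awarded > 0)
    return with_points / cluster_size


def _member_delta_rts(candidate: MatchCandidate, peaks: dict[int, MonoisotopicPeak],
                      peptide: CorePeptide) -> list[float] | None:
    if not peptide.rt_known:
        return None
    return [peaks[m.peak_no].apex_rt - peptide.rt for m in candidate.member_matches]


def select_assignment(
    cluster_id: int,
    cluster_size: int,
    candidates: list[MatchCandidate],
    peaks: dict[int, MonoisotopicPeak],
    peptides: dict[str, CorePeptide],
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> ClusterAssignment:
    """Apply the selection discipline to one cluster's match candidates."""
    lo, hi = thresholds.delta_rt_window
    viable: list[MatchCandidate] = []
    for cand in candidates:
        if cand.total_score < thresholds.min_total_score:
            continue
        drts = _member_delta_rts(cand, peaks, peptides[cand.peptide_id])
        if drts is not None and not any(lo <= d <= hi for d in drts):
            continue
        viable.append(cand)
    if not viable:
        return ClusterAssignment(cluster_id, STATUS_NO_CANDIDATE)

    top_score = max(c.total_score for c in viable)
    top = [c for c in viable if c.total_score == top_score]
    if len(top) > 1:
        return ClusterAssignment(cluster_id, STATUS_TIE)
    winner = top[0]

    if point_ratio(winner, cluster_size) <= thresholds.min_point_ratio:
        return ClusterAssignment(cluster_id, STATUS_LOW_RATIO,
                                 peptide_id=winner.peptide_id, candidate=winner)

    flagged: list[int] = []
    pep = peptides[winner.peptide_id]
    for m in winner.member_matches:
        out_of_mass = abs(m.mass_error_ppm) > thresholds.delta_mass_ppm
        out_of_rt = False
        if pep.rt_known:
            drt = peaks[m.peak_no].apex_rt - pep.rt
            out_of_rt = not (lo <= drt <= hi)
        if out_of_mass or out_of_rt:
            flagged.append(m.peak_no)
    return ClusterAssignment(
        cluster_id, STATUS_ASSIGNED, peptide_id=winner.peptide_id,
        candidate=winner, flagged_members=flagged,
    )


def select_all(
    clusters_candidates: dict[int, tuple[int, list[MatchCandidate]]],
    peaks: dict[int, MonoisotopicPeak],
    peptides: dict[str, CorePeptide],
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> list[ClusterAssignment]:
    """Run selection for every cluster; deterministic order by cluster id."""
    out = []
    for cluster_id in sorted(clusters_candidates):
        size, candidates = clusters_candidates[cluster_id]
        out.append(select_assignment(cluster_id, size, candidates, peaks,
                                     peptides, thresholds))
    return out


def build_final_table(
    assignments: list[ClusterAssignment],
    peaks: dict[int, MonoisotopicPeak],
    peptides: dict[str, CorePeptide],
) -> pd.DataFrame:
    """Site-specific glycoform table: one row per (protein, site, peptide, composition).

    Members of the same cluster mapping to the same glycoform are
    deduplicated, keeping the most intense peak. Distinct peptide sequences
    covering the same site keep separate rows; site-level rollups should
    count (protein, site, composition) once.
    """
    rows = []
    for assignment in assignments:
        if not assignment.assigned or assignment.candidate is None:
            continue
        pep = peptides[assignment.peptide_id]
        best: dict[tuple, tuple] = {}
        for m in assignment.candidate.member_matches:
            peak = peaks[m.peak_no]
            key = (pep.protein_id, pep.site, pep.peptide_id, m.composition)
            current = best.get(key)
            if current is None or peak.intensity > current[0].intensity:
                best[key] = (peak, m)
        for (protein, site, peptide_id, comp), (peak, m) in sorted(best.items()):
            rows.append(
                {
                    "cluster_id": assignment.cluster_id,
                    "protein_id": protein,
                    "site": site,
                    "peptide_id": peptide_id,
                    "hex": comp[0],
                    "hexnac": comp[1],
                    "dhex": comp[2],
                    "neuac": comp[3],
                    "peak_no": m.peak_no,
                    "intensity": peak.intensity,
                    "delta_rt": peak.apex_rt - pep.rt if pep.rt_known else float("nan"),
                    "mass_error_ppm": m.mass_error_ppm,
                    "flagged": m.peak_no in assignment.flagged_members,
                    "confidence": assignment.confidence or "",
                }
            )
    columns = ["cluster_id", "protein_id", "site", "peptide_id", "hex", "hexnac",
               "dhex", "neuac", "peak_no", "intensity", "delta_rt",
               "mass_error_ppm", "flagged", "confidence"]
    return pd.DataFrame(rows, columns=columns)
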