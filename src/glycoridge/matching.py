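"""Accurate-mass matching of clusters to core peptides and glycan compositions.

For every cluster member the observed neutral glycopeptide mass minus a
candidate peptide's calculated mass is explained as

    i * M(Hex) + j * M(HexNAc) + k * M(dHex) + l * M(NeuAc)

with integer counts inside configurable ranges. Each matched member earns
the glycan point list's points for its composition; the candidate's total
score is the sum over members. A companion inter-cluster analysis flags
cluster pairs offset by a constant non-proton adduct shift (ammonium or
Fe(III)), which explains detected-but-unmatched satellite clusters.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

from .constants import ADDUCT_SHIFTS, DHEX, HEX, HEXNAC, NEUAC, composition_mass
from .clustering import Cluster
from .formats_io import CorePeptide, GlycanCompositionEntry
from .peak_detection import MonoisotopicPeak

Composition = tuple[int, int, int, int]


@dataclass(frozen=True)
class CompositionRanges:
    """Inclusive per-unit count ranges searched during enumeration.

    Defaults cover the plausible N-glycan space: Hex 0-12, HexNAc 1-12,
    dHex 0-4, NeuAc 0-4. dHex is capped at 4 because dHex(5) is nearly
    isobaric with Hex(2)HexNAc(2) (0.025 Da apart, ~5 ppm at 5000 Da).
    """

    hex: tuple[int, int] = (0, 12)
    hexnac: tuple[int, int] = (1, 12)
    dhex: tuple[int, int] = (0, 4)
    neuac: tuple[int, int] = (0, 4)

    def __post_init__(self) -> None:
        for lo, hi in (self.hex, self.hexnac, self.dhex, self.neuac):
            if lo > hi or lo < 0:
                raise ValueError("invalid composition range")


@dataclass(frozen=True)
class MemberMatch:
    peak_no: int
    composition: Composition
    mass_error_ppm: float
    points_awarded: float
    is_listed: bool


@dataclass
class MatchCandidate:
    """One (cluster, peptide) explanation with per-member compositions."""

    cluster_id: int
    peptide_id: str
    member_matches: list[MemberMatch]
    total_score: float
    coverage: float
    delta_rt_range: tuple[float, float] | None

    @property
    def n_matched(self) -> int:
        return len(self.member_matches)


@dataclass(frozen=True)
class AdductRelation:
    """Cluster B is a non-proton adduct satellite of cluster A."""

    cluster_a: int
    cluster_b: int
    adduct: str
    mass_shift: float
    n_member_pairs: int


# ---------------------------------------------------------------------------
# composition enumeration
# ---------------------------------------------------------------------------

def enumerate_compositions(
    delta_mass: float,
    tol: float,
    ranges: CompositionRanges = CompositionRanges(),
) -> list[Composition]:
    """All (i, j, k, l) with composition mass within ``tol`` Da of ``delta_mass``.

    Enumerated in lexicographic order with partial-sum pruning: inner loops
    are skipped as soon as the remaining mass cannot be reached with the
    remaining units' ranges.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    out: list[Composition] = []
    for i in range(ranges.hex[0], ranges.hex[1] + 1):
        base_i = i * HEX
        if base_i - tol > delta_mass - ranges.hexnac[0] * HEXNAC:
            break
        for j in range(ranges.hexnac[0], ranges.hexnac[1] + 1):
            base_j = base_i + j * HEXNAC
            if base_j - tol > delta_mass:
                break
            for k in range(ranges.dhex[0], ranges.dhex[1] + 1):
                base_k = base_j + k * DHEX
                if base_k - tol > delta_mass:
                    break
                # solve the NeuAc count directly from the remainder
                rem = delta_mass - base_k
                l_lo = max(ranges.neuac[0], int((rem - tol) / NEUAC - 1))
                l_hi = min(ranges.neuac[1], int((rem + tol) / NEUAC + 1))
                for l in range(max(l_lo, 0), l_hi + 1):
                    if abs(base_k + l * NEUAC - delta_mass) <= tol:
                        out.append((i, j, k, l))
    return out


def _best_composition(
    candidates: list[Composition], delta_mass: float
) -> tuple[Composition, float]:
    """Resolve multiple solutions: min |error|, then fewer residues, then lexicographic."""
    def key(c: Composition):
        err = abs(composition_mass(*c) - delta_mass)
        return (err, sum(c), c)

    best = min(candidates, key=key)
    return best, composition_mass(*best) - delta_mass


# ---------------------------------------------------------------------------
# cluster matching
# ---------------------------------------------------------------------------

def match_cluster(
    cluster: Cluster,
    peaks: dict[int, MonoisotopicPeak],
    peptides: list[CorePeptide],
    glycan_list: list[GlycanCompositionEntry],
    tol_ppm: float = 5.0,
    rt_gate: float = 30.0,
    ranges: CompositionRanges = CompositionRanges(),
    use_negative_points: bool = False,
) -> list[MatchCandidate]:
    """Enumerate peptide explanations for one cluster.

    Peptides with a known RT are pre-filtered to
    ``|median member RT - peptide RT| <= rt_gate`` (peptides with rt = 0
    bypass the gate). A candidate is emitted when at least one member
    matches. Unusual compositions carry negative points only when
    ``use_negative_points`` is set, mirroring the default of scoring them
    as zero.
    """
    members = [peaks[p] for p in cluster.members]
    median_rt = statistics.median(p.apex_rt for p in members)
    points_by_key = {e.key: e for e in glycan_list}
    candidates: list[MatchCandidate] = []
    for pep in peptides:
        if pep.rt_known and abs(median_rt - pep.rt) > rt_gate:
            continue
        matches: list[MemberMatch] = []
        for peak in members:
            delta = peak.neutral_mass - pep.calc_mass
            tol = tol_ppm * peak.neutral_mass * 1e-6
            solutions = enumerate_compositions(delta, tol, ranges)
            if not solutions:
                continue
            comp, err = _best_composition(solutions, delta)
            entry = points_by_key.get(comp)
            if entry is None:
                points = 0.0
                listed = False
            else:
                listed = True
                points = entry.points
                if entry.points < 0 and not use_negative_points:
                    points = 0.0
            matches.append(
                MemberMatch(
                    peak_no=peak.peak_no,
                    composition=comp,
                    mass_error_ppm=err / peak.neutral_mass * 1e6,
                    points_awarded=points,
                    is_listed=listed,
                )
            )
        if not matches:
            continue
        if pep.rt_known:
            drts = [peaks[m.peak_no].apex_rt - pep.rt for m in matches]
            delta_rt_range: tuple[float, float] | None = (min(drts), max(drts))
        else:
            delta_rt_range = None
        candidates.append(
            MatchCandidate(
                cluster_id=cluster.cluster_id,
                peptide_id=pep.peptide_id,
                member_matches=matches,
                total_score=sum(m.points_awarded for m in matches),
                coverage=len(matches) / cluster.size,
                delta_rt_range=delta_rt_range,
            )
        )
    candidates.sort(key=lambda c: (-c.total_score, c.peptide_id))
    return candidates


# ---------------------------------------------------------------------------
# inter-cluster adduct analysis
# ---------------------------------------------------------------------------

def inter_cluster_adducts(
    clusters: list[Cluster],
    peaks: dict[int, MonoisotopicPeak],
    adduct_table: dict[str, float] | None = None,
    pair_tol_ppm: float = 10.0,
    rt_tol: float = 1.0,
    min_pairs: int = 3,
) -> list[AdductRelation]:
    """Find cluster pairs offset by a constant non-proton adduct shift.

    For every ordered cluster pair (A, B) and adduct shift, member pairs
    ``(a in A, b in B)`` with ``mass(b) - mass(a)`` within ``pair_tol_ppm``
    of the shift and ``|rt(b) - rt(a)| <= rt_tol`` are counted; a relation
    is emitted when at least ``min_pairs`` pairs agree. B (the heavier,
    shifted cluster) is reported as the satellite of A.
    """
    if adduct_table is None:
        adduct_table = dict(ADDUCT_SHIFTS)
    relations: list[AdductRelation] = []
    for a_cluster in clusters:
        a_peaks = [peaks[p] for p in a_cluster.members]
        for b_cluster in clusters:
            if b_cluster.cluster_id == a_cluster.cluster_id:
                continue
            b_peaks = [peaks[p] for p in b_cluster.members]
            for adduct, shift in adduct_table.items():
                n = 0
                for a in a_peaks:
                    tol = pair_tol_ppm * a.mono_mass * 1e-6
                    for b in b_peaks:
                        if abs(b.mono_mass - a.mono_mass - shift) <= tol and \
                                abs(b.apex_rt - a.apex_rt) <= rt_tol:
                            n += 1
                            break
                if n >= min_pairs:
                    relations.append(
                        AdductRelation(
                            cluster_a=a_cluster.cluster_id,
                            cluster_b=b_cluster.cluster_id,
                            adduct=adduct,
                            mass_shift=shift,
                            n_member_pairs=n,
                        )
                    )
    relations.sort(key=lambda r: (r.cluster_a, r.cluster_b, r.adduct))
    return relations
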