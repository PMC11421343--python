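"""Selection discipline: thresholds, RT windows, ties, point ratio."""

import pytest

from glycoridge.constants import PROTON_MASS, composition_mass
from glycoridge.formats_io import CorePeptide
from glycoridge.matching import MatchCandidate, MemberMatch
from glycoridge.peak_detection import MonoisotopicPeak
from glycoridge.selection import (
    STATUS_ASSIGNED,
    STATUS_LOW_RATIO,
    STATUS_NO_CANDIDATE,
    STATUS_TIE,
    SelectionThresholds,
    build_final_table,
    point_ratio,
    select_assignment,
)


def _peak(no, rt, mass=4000.0, intensity=100.0):
    return MonoisotopicPeak(no, mass, rt, intensity, 0, rt, rt)


def _candidate(peptide_id, peak_nos, score_each=1.0, comp=(5, 4, 0, 2),
               cluster_id=1, err=0.5):
    matches = [
        MemberMatch(no, comp, err, score_each, score_each > 0) for no in peak_nos
    ]
    return MatchCandidate(
        cluster_id=cluster_id,
        peptide_id=peptide_id,
        member_matches=matches,
        total_score=score_each * len(matches),
        coverage=1.0,
        delta_rt_range=None,
    )


class TestWorkedExamples:
    def test_in_window_high_score_beats_out_of_window_candidate(self):
        """Scores 28 vs 11 where the losing peptide's members all sit more
        than 15 min away in RT: the 28-score peptide is selected."""
        peptides = {
            "A1AG1": CorePeptide("A1AG1", 2000.0, 40.0),
            "HPT": CorePeptide("HPT", 2500.0, 20.0),
        }
        peaks = {no: _peak(no, rt=37.0 + 0.5 * no) for no in range(1, 8)}
        # members lie within -6.5..+5.1 min of A1AG1 but > 15 min from HPT
        good = _candidate("A1AG1", list(range(1, 8)), score_each=4.0)  # 28
        bad = _candidate("HPT", list(range(1, 8)), score_each=11 / 7)  # 11
        result = select_assignment(1, 7, [good, bad], peaks, peptides,
                                   SelectionThresholds())
        assert result.status == STATUS_ASSIGNED
        assert result.peptide_id == "A1AG1"

    def test_higher_total_score_selected_among_in_window_candidates(self):
        """Two in-window candidates with scores 21 and 4: 21 wins."""
        peptides = {
            "X": CorePeptide("X", 2000.0, 40.0),
            "Y": CorePeptide("Y", 2010.0, 41.0),
        }
        peaks = {no: _peak(no, rt=40.0 + 0.1 * no) for no in range(1, 8)}
        a = _candidate("X", list(range(1, 8)), score_each=3.0)  # 21
        b = _candidate("Y", list(range(1, 5)), score_each=1.0)  # 4
        result = select_assignment(3, 7, [a, b], peaks, peptides,
                                   SelectionThresholds())
        assert result.status == STATUS_ASSIGNED
        assert result.peptide_id == "X"
        assert result.candidate.total_score == 21.0

    def test_tied_top_scores_exclude_the_cluster(self):
        peptides = {
            "X": CorePeptide("X", 2000.0, 40.0),
            "Y": CorePeptide("Y", 2010.0, 41.0),
        }
        peaks = {no: _peak(no, rt=40.0) for no in range(1, 6)}
        a = _candidate("X", list(range(1, 6)), score_each=2.0)
        b = _candidate("Y", list(range(1, 6)), score_each=2.0)
        result = select_assignment(65, 5, [a, b], peaks, peptides,
                                   SelectionThresholds())
        assert result.status == STATUS_TIE
        assert result.peptide_id is None


class TestThresholds:
    PEPTIDES = {"X": CorePeptide("X", 2000.0, 40.0)}

    def test_below_score_threshold_gives_no_candidate(self):
        peaks = {1: _peak(1, 40.0), 2: _peak(2, 40.2)}
        cand = _candidate("X", [1, 2], score_each=1.0)  # score 2 < 4
        result = select_assignment(1, 2, [cand], peaks, self.PEPTIDES,
                                   SelectionThresholds(min_total_score=4.0))
        assert result.status == STATUS_NO_CANDIDATE

    def test_all_members_outside_rt_window_dropped(self):
        peaks = {no: _peak(no, rt=75.0) for no in (1, 2, 3, 4)}  # +35 min away
        cand = _candidate("X", [1, 2, 3, 4], score_each=2.0)
        result = select_assignment(1, 4, [cand], peaks, self.PEPTIDES,
                                   SelectionThresholds())
        assert result.status == STATUS_NO_CANDIDATE

    def test_members_outside_windows_flagged_not_dropped(self):
        peaks = {1: _peak(1, 41.0), 2: _peak(2, 42.0), 3: _peak(3, 39.0),
                 4: _peak(4, 75.0)}  # member 4 far outside the RT window
        cand = _candidate("X", [1, 2, 3, 4], score_each=2.0)
        result = select_assignment(1, 4, [cand], peaks, self.PEPTIDES,
                                   SelectionThresholds())
        assert result.status == STATUS_ASSIGNED
        assert result.flagged_members == [4]
        assert result.candidate.n_matched == 4


class TestPointRatio:
    def test_all_members_listed(self):
        cand = _candidate("X", [1, 2, 3], score_each=1.0)
        assert point_ratio(cand, 3) == 1.0

    def test_exact_half_fails_strict_rule(self):
        cand = _candidate("X", [1, 2, 3, 4, 5], score_each=1.0)
        assert point_ratio(cand, 10) == 0.5
        peptides = {"X": CorePeptide("X", 2000.0, 40.0)}
        peaks = {no: _peak(no, 40.0) for no in range(1, 6)}
        result = select_assignment(1, 10, [cand], peaks, peptides,
                                   SelectionThresholds())
        assert result.status == STATUS_LOW_RATIO

    def test_seven_of_ten_passes(self):
        cand = _candidate("X", list(range(1, 8)), score_each=1.0)
        assert point_ratio(cand, 10) == pytest.approx(0.7)


class TestFinalTable:
    def test_empty_assignments_give_empty_table(self):
        table = build_final_table([], {}, {})
        assert len(table) == 0

    def test_one_row_per_site_specific_glycoform(self):
        peptides = {"X": CorePeptide("X", 2000.0, 40.0, protein_id="P", site="56")}
        comps = [(5, 4, 0, s) for s in range(3)]
        peaks, matches = {}, []
        for i, c in enumerate(comps, start=1):
            peaks[i] = _peak(i, 40.0, 2000.0 + composition_mass(*c) + PROTON_MASS)
            matches.append(MemberMatch(i, c, 0.1, 1.0, True))
        cand = MatchCandidate(1, "X", matches, 3.0, 1.0, None)
        from glycoridge.selection import ClusterAssignment
        assignment = ClusterAssignment(1, STATUS_ASSIGNED, "X", cand)
        table = build_final_table([assignment], peaks, peptides)
        assert len(table) == 3
        assert set(zip(table.hex, table.neuac)) == {(5, 0), (5, 1), (5, 2)}

    def test_same_site_two_sequences_rolls_up_once(self):
        """Two peptide forms covering one site keep separate rows but a
        (protein, site, composition) rollup counts the glycoform once."""
        peptides = {
            "long": CorePeptide("long", 2000.0, 40.0, protein_id="P", site="103"),
            "short": CorePeptide("short", 1500.0, 30.0, protein_id="P", site="103"),
        }
        comp = (5, 4, 0, 2)
        peaks = {
            1: _peak(1, 40.0, 2000.0 + composition_mass(*comp) + PROTON_MASS),
            2: _peak(2, 30.0, 1500.0 + composition_mass(*comp) + PROTON_MASS),
        }
        from glycoridge.selection import ClusterAssignment
        assignments = [
            ClusterAssignment(1, STATUS_ASSIGNED, "long",
                              MatchCandidate(1, "long",
                                             [MemberMatch(1, comp, 0.1, 1.0, True)],
                                             1.0, 1.0, None)),
            ClusterAssignment(2, STATUS_ASSIGNED, "short",
                              MatchCandidate(2, "short",
                                             [MemberMatch(2, comp, 0.1, 1.0, True)],
                                             1.0, 1.0, None)),
        ]
        table = build_final_table(assignments, peaks, peptides)
        assert len(table) == 2
        rollup = table.groupby(["protein_id", "site", "hex", "hexnac", "dhex",
                                "neuac"]).size()
        assert len(rollup) == 1

    def test_deterministic(self):
        peptides = {"X": CorePeptide("X", 2000.0, 40.0, protein_id="P", site="1")}
        comp = (5, 4, 0, 0)
        peaks = {1: _peak(1, 40.0, 2000.0 + composition_mass(*comp) + PROTON_MASS)}
        from glycoridge.selection import ClusterAssignment
        a = ClusterAssignment(
            1, STATUS_ASSIGNED, "X",
            MatchCandidate(1, "X", [MemberMatch(1, comp, 0.1, 1.0, True)],
                           1.0, 1.0, None))
        t1 = build_final_table([a], peaks, peptides)
        t2 = build_final_table([a], peaks, peptides)
        assert t1.equals(t2)
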