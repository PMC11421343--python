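"""Glycan-unit edges, cluster components, parallel merge, presets."""

import numpy as np
import pytest

from glycoridge.clustering import (
    Cluster,
    ClusteringSetting,
    build_edges,
    cluster_peaks,
    default_settings,
    find_clusters,
    make_unit,
    merge_parallel,
    sialo_series_linking,
)
from glycoridge.constants import DHEX, HEX, NEUAC, RESIDUE_MASSES
from glycoridge.peak_detection import MonoisotopicPeak


def _peak(no, mass, rt):
    return MonoisotopicPeak(no, mass, rt, 100.0, 0, rt, rt)


def _neutral_setting(min_members=2, tol=10.0):
    units = [make_unit(n, (-1.0, 0.0)) for n in ("Hex", "HexNAc", "dHex", "LacNAc")]
    return ClusteringSetting(1, units, tol, min_members)


def _full_setting(min_members=2):
    units = [make_unit(n, (-1.0, 0.0)) for n in ("Hex", "HexNAc", "dHex", "LacNAc")]
    units.append(make_unit("NeuAc", (1.0, 4.0)))
    return ClusteringSetting(2, units, 10.0, min_members)


def _clustering_oracle(peaks, setting):
    """Pairwise-difference + union-find reference implementation."""
    parent = {p.peak_no: p.peak_no for p in peaks}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        parent[find(a)] = find(b)

    for a in peaks:
        for b in peaks:
            if b.mono_mass <= a.mono_mass:
                continue
            for unit in setting.units:
                tol = b.mono_mass * setting.mass_tol_ppm * 1e-6
                if abs(b.mono_mass - a.mono_mass - unit.residue_mass) <= tol and \
                        unit.rt_shift_min <= b.apex_rt - a.apex_rt <= unit.rt_shift_max:
                    union(a.peak_no, b.peak_no)
    groups = {}
    for p in peaks:
        groups.setdefault(find(p.peak_no), []).append(p.peak_no)
    return sorted(
        sorted(g) for g in groups.values() if len(g) >= setting.min_members
    )


class TestEdges:
    def test_exact_hex_edge_inside_neutral_window(self):
        peaks = [_peak(1, 2000.0, 30.0), _peak(2, 2000.0 + HEX, 29.5)]
        edges = build_edges(peaks, _neutral_setting())
        assert len(edges) == 1
        assert edges[0].unit == "Hex"
        assert edges[0].rt_shift == pytest.approx(-0.5)

    def test_positive_shift_outside_neutral_window(self):
        peaks = [_peak(1, 2000.0, 30.0), _peak(2, 2000.0 + HEX, 30.5)]
        assert build_edges(peaks, _neutral_setting()) == []

    def test_neuac_edge_with_positive_shift(self):
        peaks = [_peak(1, 3000.0, 30.0), _peak(2, 3000.0 + NEUAC, 32.0)]
        edges = build_edges(peaks, _full_setting())
        assert [e.unit for e in edges] == ["NeuAc"]

    @pytest.mark.parametrize("shift", [1.0, 4.0])
    def test_neuac_window_is_closed(self, shift):
        peaks = [_peak(1, 3000.0, 30.0), _peak(2, 3000.0 + NEUAC, 30.0 + shift)]
        assert len(build_edges(peaks, _full_setting())) == 1

    def test_hex_dhex_isobar_pair_not_connected(self):
        """A mass gap of Hex+dHex (~308.11 Da) with a +2 min shift matches
        no single unit under any default setting."""
        peaks = [_peak(1, 3000.0, 30.0), _peak(2, 3000.0 + HEX + DHEX, 32.0)]
        for setting in default_settings():
            assert build_edges(peaks, setting) == []


class TestComponents:
    def _chain(self, n, start=2000.0, rt=30.0):
        return [_peak(i + 1, start + i * HEX, rt - 0.2 * i) for i in range(n)]

    def test_chain_below_min_members_dropped(self):
        assert find_clusters(self._chain(3), _neutral_setting(min_members=4)) == []

    def test_chain_at_min_members_kept(self):
        clusters = find_clusters(self._chain(3), _neutral_setting(min_members=3))
        assert len(clusters) == 1
        assert clusters[0].members == [1, 2, 3]

    @pytest.mark.parametrize("seed", [0, 3, 9])
    def test_equals_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        peaks, mass, rt = [], 2000.0, 40.0
        units = list(RESIDUE_MASSES.values())
        for no in range(1, 101):
            peaks.append(_peak(no, mass, rt))
            if rng.random() < 0.25:  # break the chain: unrelated jump
                mass += float(rng.uniform(30.0, 120.0))
                rt = float(rng.uniform(20.0, 60.0))
            else:
                mass += units[rng.integers(len(units))]
                rt += float(rng.uniform(-1.5, 0.5))
        setting = _full_setting(min_members=3)
        got = sorted(c.members for c in find_clusters(peaks, setting))
        assert got == _clustering_oracle(peaks, setting)


class TestParallelMerge:
    def _cluster(self, cid, members, sids=(1,)):
        return Cluster(cid, sorted(members), [], list(sids))

    def test_disjoint_sets_concatenate(self):
        merged = merge_parallel([
            [self._cluster(1, [1, 2, 3])],
            [self._cluster(1, [7, 8, 9], sids=(2,))],
        ])
        assert [c.members for c in merged] == [[1, 2, 3], [7, 8, 9]]

    def test_shared_member_unions_clusters(self):
        merged = merge_parallel([
            [self._cluster(1, [1, 2, 3, 4])],
            [self._cluster(1, [4, 5, 6], sids=(2,))],
        ])
        assert len(merged) == 1
        assert merged[0].members == [1, 2, 3, 4, 5, 6]
        assert merged[0].setting_ids == [1, 2]

    def test_order_invariance(self):
        sets = [
            [self._cluster(1, [1, 2, 3, 4])],
            [self._cluster(1, [4, 5, 6], sids=(2,))],
            [self._cluster(1, [10, 11, 12], sids=(3,))],
        ]
        a = merge_parallel(sets)
        b = merge_parallel(list(reversed(sets)))
        assert [c.members for c in a] == [c.members for c in b]
        assert [c.setting_ids for c in a] == [c.setting_ids for c in b]

    def test_more_than_five_settings_rejected(self):
        with pytest.raises(ValueError):
            merge_parallel([[] for _ in range(6)])


class TestSialoSeries:
    def _series(self, n_sialo=5, base=3000.0, rt=30.0):
        """One glycan in 0..n_sialo-1 sialylation states (+2 min/NeuAc)."""
        return [
            _peak(s + 1, base + s * NEUAC, rt + 2.0 * s) for s in range(n_sialo)
        ]

    def test_series_unifies_into_single_cluster(self):
        peaks = self._series()
        # neutral-only plus an acidic-aware setting, as in parallel search
        settings = [_neutral_setting(min_members=4), _full_setting(min_members=3)]
        merged = cluster_peaks(peaks, settings)
        assert len(merged) == 1
        assert merged[0].members == [1, 2, 3, 4, 5]

    def test_degenerate_neuac_window_leaves_series_split(self):
        peaks = self._series()
        units = [make_unit(n, (-1.0, 0.0)) for n in ("Hex", "HexNAc", "dHex")]
        units.append(make_unit("NeuAc", (0.0, 0.0)))
        setting = ClusteringSetting(1, units, 10.0, 2)
        assert find_clusters(peaks, setting) == []

    def test_sialo_series_linking_restricts_to_neuac(self):
        peaks = self._series()
        edges = sialo_series_linking(peaks, _full_setting())
        assert len(edges) == 4
        assert all(e.unit == "NeuAc" for e in edges)

    def test_sialo_series_linking_requires_neuac_unit(self):
        with pytest.raises(ValueError):
            sialo_series_linking(self._series(), _neutral_setting())


class TestOligoMannosePreset:
    def test_hex_only_min3_recovers_short_mannose_ladder(self):
        """An M5-M7 ladder (3 members) is found by the Hex-only/min-3
        setting but not by the neutral/min-4 setting alone."""
        peaks = [_peak(i + 1, 2300.0 + i * HEX, 35.0 - 0.3 * i) for i in range(3)]
        settings = default_settings()
        neutral4 = settings[0]
        hex_only3 = settings[2]
        assert find_clusters(peaks, neutral4) == []
        clusters = find_clusters(peaks, hex_only3)
        assert len(clusters) == 1
        assert clusters[0].members == [1, 2, 3]


class TestFixtureClustering:
    def test_every_planted_glycoform_in_exactly_one_cluster(self, hagp_data, hagp_state):
        """Each planted (non-adduct) glycoform's peak appears in exactly one
        merged cluster, and each site yields one cluster."""
        truth = hagp_data.truth
        planted = truth[truth.adduct == ""]
        idx = hagp_state.peak_index
        # map planted mono masses to clusters
        cluster_of = {}
        for c in hagp_state.clusters:
            for p in c.members:
                cluster_of[round(idx[p].mono_mass, 2)] = cluster_of.get(
                    round(idx[p].mono_mass, 2), set()
                ) | {c.cluster_id}
        hits = []
        for mono in planted.mono_mh:
            key = round(mono, 2)
            assert key in cluster_of, f"planted glycoform {mono} not clustered"
            assert len(cluster_of[key]) == 1
            hits.append(next(iter(cluster_of[key])))
        # one cluster per peptide site
        site_clusters = {}
        for pep, cid in zip(planted.peptide_id, hits):
            site_clusters.setdefault(pep, set()).add(cid)
        for pep, cids in site_clusters.items():
            assert len(cids) == 1, f"{pep} split across clusters {cids}"
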