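"""Glycopeptide cluster detection from monoisotopic peaks.

Two peaks are connected when their mass difference equals one glycan unit
(Hex, HexNAc, dHex, the Hex+HexNAc motif, or NeuAc) within a ppm tolerance
AND their apex-RT difference lies inside that unit's window. Neutral units
shift RT slightly earlier (default window -1..0 min per unit) while each
NeuAc shifts it later (+1..+4 min), so sialylated series chain into the
same cluster as their asialo parent. Up to five independent settings are
searched in parallel and their clusters merged on shared members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .constants import RESIDUE_MASSES
from .peak_detection import MonoisotopicPeak

NEUTRAL_UNITS = ("Hex", "HexNAc", "dHex", "LacNAc")
ACIDIC_UNITS = ("NeuAc",)

MAX_PARALLEL_SETTINGS = 5


@dataclass(frozen=True)
class GlycanUnit:
    """A saccharide extension unit with its residue mass and RT-shift window."""

    name: str
    residue_mass: float
    rt_shift_min: float
    rt_shift_max: float

    def __post_init__(self) -> None:
        if self.rt_shift_min > self.rt_shift_max:
            raise ValueError("rt_shift_min must be <= rt_shift_max")
        if self.residue_mass <= 0:
            raise ValueError("residue_mass must be positive")

    @property
    def kind(self) -> str:
        return "acidic" if self.name in ACIDIC_UNITS else "neutral"


def make_unit(name: str, rt_window: tuple[float, float]) -> GlycanUnit:
    return GlycanUnit(name, RESIDUE_MASSES[name], rt_window[0], rt_window[1])


@dataclass
class ClusteringSetting:
    """One parallel search setting: enabled units, tolerance, size floor."""

    setting_id: int
    units: list[GlycanUnit]
    mass_tol_ppm: float = 10.0
    min_members: int = 2

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError("at least one glycan unit must be enabled")
        if self.min_members < 2:
            raise ValueError("min_members must be >= 2")


@dataclass(frozen=True)
class ClusterEdge:
    """A glycan-unit relation between two peaks (lighter -> heavier)."""

    from_peak: int
    to_peak: int
    unit: str
    mass_error_ppm: float
    rt_shift: float


@dataclass
class Cluster:
    """A connected component of glycan-unit edges."""

    cluster_id: int
    members: list[int]
    edges: list[ClusterEdge]
    setting_ids: list[int] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


def default_settings(
    neutral_window: tuple[float, float] = (-1.0, 0.0),
    neuac_window: tuple[float, float] = (1.0, 4.0),
    mass_tol_ppm: float = 10.0,
) -> list[ClusteringSetting]:
    """The standard three-setting bundle.

    * setting 1: all neutral units, minimum 4 members (maximises detected
      clusters while limiting misdetection);
    * setting 2: neutral units plus NeuAc, minimum 10 members (links the
      asialo/mono/di/tri/tetra-sialo series into one cluster);
    * setting 3: Hex only, minimum 3 members (oligo-mannose series M5-M9).
    """
    neutral = [make_unit(u, neutral_window) for u in NEUTRAL_UNITS]
    return [
        ClusteringSetting(1, list(neutral), mass_tol_ppm, min_members=4),
        ClusteringSetting(2, list(neutral) + [make_unit("NeuAc", neuac_window)],
                          mass_tol_ppm, min_members=10),
        ClusteringSetting(3, [make_unit("Hex", neutral_window)], mass_tol_ppm,
                          min_members=3),
    ]


# ---------------------------------------------------------------------------
# edges and components
# ---------------------------------------------------------------------------

def build_edges(peaks: list[MonoisotopicPeak], setting: ClusteringSetting) -> list[ClusterEdge]:
    """Emit an edge for every peak pair differing by one enabled glycan unit.

    The mass criterion is ``|mass(B) - mass(A) - unit|`` within
    ``mass_tol_ppm`` of the heavier mass; the RT criterion is
    ``rt(B) - rt(A)`` inside the unit's closed window (B the heavier peak).
    """
    ordered = sorted(peaks, key=lambda p: p.mono_mass)
    edges: list[ClusterEdge] = []
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            delta = b.mono_mass - a.mono_mass
            if delta > max(u.residue_mass for u in setting.units) + 1.0:
                break
            for unit in setting.units:
                tol = b.mono_mass * setting.mass_tol_ppm * 1e-6
                if abs(delta - unit.residue_mass) > tol:
                    continue
                rt_shift = b.apex_rt - a.apex_rt
                if not (unit.rt_shift_min <= rt_shift <= unit.rt_shift_max):
                    continue
                err_ppm = (delta - unit.residue_mass) / b.mono_mass * 1e6
                edges.append(
                    ClusterEdge(a.peak_no, b.peak_no, unit.name, err_ppm, rt_shift)
                )
    return edges


def find_clusters(peaks: list[MonoisotopicPeak], setting: ClusteringSetting) -> list[Cluster]:
    """Connected components of the glycan-unit edge graph, size-filtered."""
    edges = build_edges(peaks, setting)
    graph = nx.Graph()
    graph.add_nodes_from(p.peak_no for p in peaks)
    for e in edges:
        graph.add_edge(e.from_peak, e.to_peak)
    clusters: list[Cluster] = []
    for component in nx.connected_components(graph):
        if len(component) < setting.min_members:
            continue
        members = sorted(component)
        comp_edges = [e for e in edges if e.from_peak in component]
        clusters.append(Cluster(0, members, comp_edges, [setting.setting_id]))
    _canonicalise(clusters)
    return clusters


def sialo_series_linking(peaks: list[MonoisotopicPeak],
                         setting: ClusteringSetting) -> list[ClusterEdge]:
    """NeuAc-only edges under the given setting (sialo-series preset)."""
    neuac_units = [u for u in setting.units if u.name == "NeuAc"]
    if not neuac_units:
        raise ValueError("setting has no NeuAc unit enabled")
    restricted = ClusteringSetting(
        setting.setting_id, neuac_units, setting.mass_tol_ppm, setting.min_members
    )
    return build_edges(peaks, restricted)


def merge_parallel(cluster_sets: list[list[Cluster]]) -> list[Cluster]:
    """Union clusters from parallel settings that share any member peak.

    The result is invariant to the order of the input sets; contributing
    setting ids are accumulated and cluster ids canonicalised by the
    smallest member peak number.
    """
    if len(cluster_sets) > MAX_PARALLEL_SETTINGS:
        raise ValueError(f"at most {MAX_PARALLEL_SETTINGS} parallel settings supported")
    graph = nx.Graph()
    payload: list[Cluster] = [c for cs in cluster_sets for c in cs]
    for idx, cluster in enumerate(payload):
        node = ("cluster", idx)
        graph.add_node(node)
        for peak in cluster.members:
            graph.add_edge(node, ("peak", peak))
    merged: list[Cluster] = []
    for component in nx.connected_components(graph):
        cluster_idxs = [i for kind, i in component if kind == "cluster"]
        if not cluster_idxs:
            continue
        members = sorted({p for i in cluster_idxs for p in payload[i].members})
        edge_seen: set[tuple] = set()
        edges: list[ClusterEdge] = []
        for i in cluster_idxs:
            for e in payload[i].edges:
                key = (e.from_peak, e.to_peak, e.unit)
                if key not in edge_seen:
                    edge_seen.add(key)
                    edges.append(e)
        setting_ids = sorted({sid for i in cluster_idxs for sid in payload[i].setting_ids})
        edges.sort(key=lambda e: (e.from_peak, e.to_peak, e.unit))
        merged.append(Cluster(0, members, edges, setting_ids))
    _canonicalise(merged)
    return merged


def _canonicalise(clusters: list[Cluster]) -> None:
    """Sort clusters by smallest member and assign 1-based ids."""
    clusters.sort(key=lambda c: c.members[0])
    for i, c in enumerate(clusters, start=1):
        c.cluster_id = i


def cluster_peaks(
    peaks: list[MonoisotopicPeak],
    settings: list[ClusteringSetting],
) -> list[Cluster]:
    """Run every setting independently and merge (parallel clustering)."""
    if len(settings) > MAX_PARALLEL_SETTINGS:
        raise ValueError(f"at most {MAX_PARALLEL_SETTINGS} parallel settings supported")
    return merge_parallel([find_clusters(peaks, s) for s in settings])
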