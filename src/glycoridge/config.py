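"""Run configuration: defaults, YAML loading, and persistence.

The YAML layout mirrors the stage structure::

    range:     {rt: [0, 90], mass: [0, 10000], min_intensity: 0}
    peaks:     {trace_tol_ppm: 10, max_gap_scans: 1, flank_scans: 2}
    clustering:
      settings:
        - {id: 1, units: {Hex: [-1, 0], HexNAc: [-1, 0], dHex: [-1, 0],
                          LacNAc: [-1, 0]}, mass_tol_ppm: 10, min_members: 4}
        - ...
    matching:  {tol_ppm: 5, rt_gate: 30, ranges: {hex: [0, 12], ...},
                adducts: true, pair_tol_ppm: 10, adduct_rt_tol: 1.0,
                min_pairs: 3, use_negative_points: false}
    selection: {min_total_score: 4, delta_rt_window: [-10, 10],
                delta_mass_ppm: 5, min_point_ratio: 0.5}
    ms2:       {enabled: true, frag_tol: 0.02, precursor_tol_ppm: 5,
                rt_tol: 0.5}

At most five clustering settings may be given.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .clustering import (
    MAX_PARALLEL_SETTINGS,
    ClusteringSetting,
    default_settings,
    make_unit,
)
from .matching import CompositionRanges
from .peak_detection import RangeSetting
from .selection import SelectionThresholds


@dataclass
class PeakConfig:
    trace_tol_ppm: float = 10.0
    max_gap_scans: int = 1
    flank_scans: int = 2


@dataclass
class MatchingConfig:
    tol_ppm: float = 5.0
    rt_gate: float = 30.0
    ranges: CompositionRanges = field(default_factory=CompositionRanges)
    adducts: bool = True
    pair_tol_ppm: float = 10.0
    adduct_rt_tol: float = 1.0
    min_pairs: int = 3
    use_negative_points: bool = False


@dataclass
class MS2Config:
    enabled: bool = True
    frag_tol: float = 0.02
    precursor_tol_ppm: float = 5.0
    rt_tol: float = 0.5


@dataclass
class RunConfig:
    range: RangeSetting = field(default_factory=RangeSetting)
    peaks: PeakConfig = field(default_factory=PeakConfig)
    clustering: list[ClusteringSetting] = field(default_factory=default_settings)
    matching: MatchingConfig = field(default_factory=MatchingConfig)
    selection: SelectionThresholds = field(default_factory=SelectionThresholds)
    ms2: MS2Config = field(default_factory=MS2Config)

    def __post_init__(self) -> None:
        if len(self.clustering) > MAX_PARALLEL_SETTINGS:
            raise ValueError(
                f"at most {MAX_PARALLEL_SETTINGS} clustering settings allowed"
            )


def _pair(value, cast=float) -> tuple:
    lo, hi = value
    return (cast(lo), cast(hi))


def config_from_dict(data: dict) -> RunConfig:
    cfg = RunConfig()
    if "range" in data:
        r = data["range"]
        rt = _pair(r.get("rt", (0.0, 90.0)))
        mass = _pair(r.get("mass", (0.0, 10000.0)))
        cfg.range = RangeSetting(rt[0], rt[1], mass[0], mass[1],
                                 float(r.get("min_intensity", 0.0)))
    if "peaks" in data:
        p = data["peaks"]
        cfg.peaks = PeakConfig(
            float(p.get("trace_tol_ppm", 10.0)),
            int(p.get("max_gap_scans", 1)),
            int(p.get("flank_scans", 2)),
        )
    if "clustering" in data and data["clustering"].get("settings"):
        if len(data["clustering"]["settings"]) > MAX_PARALLEL_SETTINGS:
            raise ValueError(
                f"at most {MAX_PARALLEL_SETTINGS} clustering settings allowed"
            )
        settings = []
        for s in data["clustering"]["settings"]:
            units = [make_unit(name, _pair(win)) for name, win in s["units"].items()]
            settings.append(
                ClusteringSetting(
                    int(s.get("id", len(settings) + 1)),
                    units,
                    float(s.get("mass_tol_ppm", 10.0)),
                    int(s.get("min_members", 2)),
                )
            )
        cfg.clustering = settings
    if "matching" in data:
        m = data["matching"]
        ranges = CompositionRanges(
            **{
                k: _pair(v, int)
                for k, v in m.get("ranges", {}).items()
                if k in {"hex", "hexnac", "dhex", "neuac"}
            }
        ) if m.get("ranges") else CompositionRanges()
        cfg.matching = MatchingConfig(
            tol_ppm=float(m.get("tol_ppm", 5.0)),
            rt_gate=float(m.get("rt_gate", 30.0)),
            ranges=ranges,
            adducts=bool(m.get("adducts", True)),
            pair_tol_ppm=float(m.get("pair_tol_ppm", 10.0)),
            adduct_rt_tol=float(m.get("adduct_rt_tol", 1.0)),
            min_pairs=int(m.get("min_pairs", 3)),
            use_negative_points=bool(m.get("use_negative_points", False)),
        )
    if "selection" in data:
        s = data["selection"]
        cfg.selection = SelectionThresholds(
            min_total_score=float(s.get("min_total_score", 4.0)),
            delta_rt_window=_pair(s.get("delta_rt_window", (-10.0, 10.0))),
            delta_mass_ppm=float(s.get("delta_mass_ppm", 5.0)),
            min_point_ratio=float(s.get("min_point_ratio", 0.5)),
        )
    if "ms2" in data:
        m = data["ms2"]
        cfg.ms2 = MS2Config(
            enabled=bool(m.get("enabled", True)),
            frag_tol=float(m.get("frag_tol", 0.02)),
            precursor_tol_ppm=float(m.get("precursor_tol_ppm", 5.0)),
            rt_tol=float(m.get("rt_tol", 0.5)),
        )
    return cfg


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config; ``None`` yields the defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def config_to_dict(cfg: RunConfig) -> dict:
    return {
        "range": {
            "rt": [cfg.range.rt_min, cfg.range.rt_max],
            "mass": [cfg.range.mass_min, cfg.range.mass_max],
            "min_intensity": cfg.range.min_intensity,
        },
        "peaks": {
            "trace_tol_ppm": cfg.peaks.trace_tol_ppm,
            "max_gap_scans": cfg.peaks.max_gap_scans,
            "flank_scans": cfg.peaks.flank_scans,
        },
        "clustering": {
            "settings": [
                {
                    "id": s.setting_id,
                    "units": {u.name: [u.rt_shift_min, u.rt_shift_max] for u in s.units},
                    "mass_tol_ppm": s.mass_tol_ppm,
                    "min_members": s.min_members,
                }
                for s in cfg.clustering
            ]
        },
        "matching": {
            "tol_ppm": cfg.matching.tol_ppm,
            "rt_gate": cfg.matching.rt_gate,
            "ranges": {
                "hex": list(cfg.matching.ranges.hex),
                "hexnac": list(cfg.matching.ranges.hexnac),
                "dhex": list(cfg.matching.ranges.dhex),
                "neuac": list(cfg.matching.ranges.neuac),
            },
            "adducts": cfg.matching.adducts,
            "pair_tol_ppm": cfg.matching.pair_tol_ppm,
            "adduct_rt_tol": cfg.matching.adduct_rt_tol,
            "min_pairs": cfg.matching.min_pairs,
            "use_negative_points": cfg.matching.use_negative_points,
        },
        "selection": {
            "min_total_score": cfg.selection.min_total_score,
            "delta_rt_window": list(cfg.selection.delta_rt_window),
            "delta_mass_ppm": cfg.selection.delta_mass_ppm,
            "min_point_ratio": cfg.selection.min_point_ratio,
        },
        "ms2": {
            "enabled": cfg.ms2.enabled,
            "frag_tol": cfg.ms2.frag_tol,
            "precursor_tol_ppm": cfg.ms2.precursor_tol_ppm,
            "rt_tol": cfg.ms2.rt_tol,
        },
    }


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Persist the effective configuration verbatim into the output dir."""
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))
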