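"""Ground-truthed synthetic LC/MS1 + MS2 fixture generation.

The generator emulates the signal-level structure of an intact
glycopeptide LC/MS run on a purified, heavily sialylated glycoprotein:

* a handful of core peptides, each carrying a connected family of 10-40
  glycoforms drawn from an N-glycan lattice (antenna extension by
  Hex+HexNAc, core/antenna fucosylation by dHex, sialylation by NeuAc);
* retention behaviour follows the additive per-unit shift model: every
  neutral residue shifts RT slightly earlier, every NeuAc shifts it later
  by 1-4 min, with per-peptide unit coefficients drawn once from the
  interior of those windows so single-unit neighbours always satisfy the
  clustering windows;
* each glycoform is rendered as an averagine isotope envelope times a
  Gaussian elution profile on a fixed scan grid;
* optional ammonium / Fe(III) adduct satellite copies, uniform decoy
  signals, and MGF spectra carrying oxonium and Y-series ions plus decoy
  fragments.

Everything is reproducible from the seed, and a truth table of every
planted glycoform accompanies the data.
"""

from __future__ import annotations

import base64
import math
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import ADDUCT_SHIFTS, DIAGNOSTIC_IONS, HEXNAC, ISOTOPE_SPACING, PROTON_MASS, composition_mass
from .formats_io import (
    CorePeptide,
    GlycanCompositionEntry,
    MS1Signal,
    MS2Spectrum,
    write_signal_table,
)
from .matching import Composition
from .peak_detection import averagine_envelope

# ---------------------------------------------------------------------------
# fixture specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedPeptide:
    peptide_id: str
    calc_mass: float
    rt: float
    protein_id: str = ""
    site: str = ""
    sequence: str = ""


@dataclass(frozen=True)
class AdductSpec:
    """Plant a satellite cluster: copies of the first ``n_members`` glycoforms
    of ``peptide_id`` shifted by the adduct mass at a fraction of the
    intensity."""

    peptide_id: str
    adduct: str  # "NH4" or "FeIII"
    n_members: int = 6
    intensity_fraction: float = 0.3


@dataclass
class FixtureSpec:
    """Declarative description of one synthetic run."""

    seed: int = 1
    peptides: list[PlantedPeptide] = field(default_factory=list)
    glycoforms: dict[str, list[Composition]] = field(default_factory=dict)
    decoy_peptides: list[PlantedPeptide] = field(default_factory=list)
    # chromatography / scan grid
    scan_interval_min: float = 0.01
    run_length_min: float = 90.0
    elution_sigma_scans: float = 2.0
    elution_halfwidth_sigmas: float = 3.0
    # additive RT-shift model (min per residue unit)
    neutral_shift_range: tuple[float, float] = (-0.45, -0.05)
    neuac_shift_range: tuple[float, float] = (1.1, 3.9)
    # intensity model
    abundance_median: float = 1e6
    abundance_sigma: float = 1.0
    intensity_floor: float = 50.0
    envelope_min_rel: float = 1e-3
    # decoy noise signals
    noise_signals: int = 0
    noise_mass_range: tuple[float, float] = (1500.0, 6000.0)
    noise_rt_range: tuple[float, float] = (10.0, 80.0)
    noise_intensity_median: float = 3e3
    noise_intensity_sigma: float = 0.5
    # adduct satellites
    adducts: list[AdductSpec] = field(default_factory=list)
    # MS2 generation
    ms2_fraction: float = 1.0
    ms2_y_series: bool = True
    ms2_charge: int = 2
    ms2_decoy_fragments: int = 30

    def validate(self) -> None:
        ids = [p.peptide_id for p in self.peptides + self.decoy_peptides]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate peptide ids in fixture spec")
        for pep in self.peptides:
            comps = self.glycoforms.get(pep.peptide_id)
            if not comps:
                raise ValueError(f"no glycoforms for peptide {pep.peptide_id}")
            for c in comps:
                if len(c) != 4 or any(x < 0 for x in c):
                    raise ValueError(f"bad composition {c}")
                if c[1] < 1:
                    raise ValueError(f"composition {c} has no HexNAc (hexnac >= 1 required)")
        for a in self.adducts:
            if a.adduct not in ADDUCT_SHIFTS:
                raise ValueError(f"unknown adduct {a.adduct}")
            if a.peptide_id not in self.glycoforms:
                raise ValueError(f"adduct references unknown peptide {a.peptide_id}")


@dataclass
class FixtureData:
    """Generated artefacts plus the ground truth."""

    spec: FixtureSpec
    signals: list[MS1Signal]
    peptides: list[CorePeptide]
    glycans: list[GlycanCompositionEntry]
    spectra: list[MS2Spectrum]
    truth: pd.DataFrame
    n_signals: int = 0
    n_noise_signals: int = 0


# ---------------------------------------------------------------------------
# the hAGP-like preset
# ---------------------------------------------------------------------------

#: Five glycosites of a purified serum glycoprotein, tryptic-peptide scale.
HAGP_LIKE_PEPTIDES = [
    PlantedPeptide("P33", 2563.2719, 52.0, "AGP1", "33"),
    PlantedPeptide("P56", 1899.8921, 40.0, "AGP1", "56"),
    PlantedPeptide("P72", 1932.9663, 46.0, "AGP1", "72"),
    PlantedPeptide("P93", 1874.8377, 34.0, "AGP1", "93"),
    PlantedPeptide("P103", 759.3784, 22.0, "AGP1", "103"),
]

#: Two peptides absent from the sample: one unrelated mass and one offset
#: from P56 by Hex - dHex (+15.9949 Da), the classic near-miss that yields
#: shifted-composition pseudo-matches without glycan points.
HAGP_DECOY_PEPTIDES = [
    PlantedPeptide("DECOY1", 2103.4567, 44.0, "DECOY", "0"),
    PlantedPeptide("DECOY2", 1915.8870, 40.0, "DECOY", "0"),
]


def glycoform_lattice() -> list[Composition]:
    """The composition pool: Hex(3+a)HexNAc(2+a)dHex(f)NeuAc(s) for
    antennae a = 2..6, fucoses f = 0..2, sialic acids s = 0..min(a, 4)."""
    pool = []
    for a in range(2, 7):
        for f in range(0, 3):
            for s in range(0, min(a, 4) + 1):
                pool.append((3 + a, 2 + a, f, s))
    return pool


def _lattice_neighbors(node: Composition) -> list[Composition]:
    """Single-unit neighbours of a lattice node (LacNAc, dHex, NeuAc steps)."""
    i, j, k, l = node
    a = i - 3
    out = []
    for da in (-1, 1):
        if 2 <= a + da <= 6 and l <= min(a + da, 4):
            out.append((i + da, j + da, k, l))
    for dk in (-1, 1):
        if 0 <= k + dk <= 2:
            out.append((i, j, k + dk, l))
    for dl in (-1, 1):
        if 0 <= l + dl <= min(a, 4):
            out.append((i, j, k, l + dl))
    return out


#: Connected backbone planted at every site: bi- to tetraantennary growth,
#: a branch-fucosylated form, then the full sialo series on the
#: tetraantennary stem. Guarantees each site spans sialylation 0-4 and has
#: at least four neutral-connected members (single-unit steps throughout).
_FAMILY_BACKBONE: list[Composition] = [
    (5, 4, 0, 0), (6, 5, 0, 0), (7, 6, 0, 0), (7, 6, 1, 0),
    (7, 6, 0, 1), (7, 6, 0, 2), (7, 6, 0, 3), (7, 6, 0, 4),
]


def _grow_connected(rng: np.random.Generator, n: int) -> list[Composition]:
    """Grow a connected random subset of the lattice around the backbone,
    so single-unit edges always span the planted family.

    Returned in growth order: every prefix of the list is itself connected
    (adduct satellites copy a prefix and must cluster on their own).
    """
    order: list[Composition] = list(_FAMILY_BACKBONE)
    chosen = set(order)
    frontier: set[Composition] = set()
    for node in order:
        frontier |= set(_lattice_neighbors(node))
    frontier -= chosen
    while len(chosen) < n and frontier:
        pick = sorted(frontier)[rng.integers(len(frontier))]
        order.append(pick)
        chosen.add(pick)
        frontier |= set(_lattice_neighbors(pick))
        frontier -= chosen
    return order


def _neutral_connected_subset(comps: list[Composition], n: int) -> set[Composition]:
    """Up to ``n`` compositions forming the largest component connected by
    neutral (LacNAc/dHex) steps alone, breadth-first in list order."""
    comp_set = set(comps)

    def bfs(root: Composition) -> set[Composition]:
        seen = {root}
        queue = [root]
        while queue and len(seen) < n:
            i, j, k, l = queue.pop(0)
            for nb in [(i + 1, j + 1, k, l), (i - 1, j - 1, k, l),
                       (i, j, k + 1, l), (i, j, k - 1, l)]:
                if nb in comp_set and nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
                    if len(seen) >= n:
                        break
        return seen

    best: set[Composition] = set()
    for root in comps:
        if root in best:
            continue
        component = bfs(root)
        if len(component) > len(best):
            best = component
        if len(best) >= n:
            break
    return best


def hagp_like_spec(seed: int = 1, noise_fraction: float = 0.2,
                   with_adducts: bool = True) -> FixtureSpec:
    """A run emulating a purified multi-site sialylated glycoprotein:
    5 sites x 10-40 glycoforms, sialylation 0-4, adduct satellites, and
    ~``noise_fraction`` decoy signals on top of the planted ones."""
    rng = np.random.default_rng(seed)
    glycoforms = {
        pep.peptide_id: _grow_connected(rng, int(rng.integers(10, 41)))
        for pep in HAGP_LIKE_PEPTIDES
    }
    spec = FixtureSpec(
        seed=seed,
        peptides=list(HAGP_LIKE_PEPTIDES),
        glycoforms=glycoforms,
        decoy_peptides=list(HAGP_DECOY_PEPTIDES),
        adducts=[
            AdductSpec("P56", "NH4", n_members=6, intensity_fraction=0.3),
            AdductSpec("P72", "FeIII", n_members=5, intensity_fraction=0.25),
        ] if with_adducts else [],
    )
    # size the uniform noise to the requested fraction of total signals
    planted = _count_planted_signals(spec)
    spec.noise_signals = int(planted * noise_fraction / max(1e-9, 1 - noise_fraction))
    return spec


def _count_planted_signals(spec: FixtureSpec) -> int:
    """Closed-form estimate of planted signal count (envelope x elution)."""
    half = math.ceil(spec.elution_halfwidth_sigmas * spec.elution_sigma_scans)
    n_scans = 2 * half + 1
    total = 0
    for pep in spec.peptides:
        for comp in spec.glycoforms[pep.peptide_id]:
            env = averagine_envelope(pep.calc_mass + composition_mass(*comp),
                                     spec.envelope_min_rel)
            total += len(env.peaks) * n_scans
    return total


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _unit_coefficients(rng: np.random.Generator, spec: FixtureSpec) -> dict[str, float]:
    lo, hi = spec.neutral_shift_range
    alo, ahi = spec.neuac_shift_range
    return {
        "Hex": float(rng.uniform(lo, hi)),
        "HexNAc": float(rng.uniform(lo, hi)),
        "dHex": float(rng.uniform(lo, hi)),
        "NeuAc": float(rng.uniform(alo, ahi)),
    }


def _render_glycoform(
    spec: FixtureSpec,
    mono_mh: float,
    apex_rt: float,
    abundance: float,
) -> tuple[list[MS1Signal], int]:
    """Isotope envelope x Gaussian elution on the scan grid."""
    env = averagine_envelope(mono_mh - PROTON_MASS, spec.envelope_min_rel)
    apex_scan = int(round(apex_rt / spec.scan_interval_min))
    half = math.ceil(spec.elution_halfwidth_sigmas * spec.elution_sigma_scans)
    signals: list[MS1Signal] = []
    for ds in range(-half, half + 1):
        scan = apex_scan + ds
        if scan < 1 or scan * spec.scan_interval_min > spec.run_length_min:
            continue
        gauss = math.exp(-0.5 * (ds / spec.elution_sigma_scans) ** 2)
        rt = scan * spec.scan_interval_min
        for m, (_, rel) in enumerate(env.peaks):
            inten = abundance * rel * gauss
            if inten < spec.intensity_floor:
                continue
            signals.append(MS1Signal(scan, rt, mono_mh + m * ISOTOPE_SPACING, inten))
    return signals, len(signals)


def _make_spectrum(
    rng: np.random.Generator,
    spec: FixtureSpec,
    spectrum_id: str,
    mono_mh: float,
    apex_rt: float,
    pep_mh: float,
) -> MS2Spectrum:
    z = spec.ms2_charge
    precursor_mz = (mono_mh + (z - 1) * PROTON_MASS) / z
    frags: list[tuple[float, float]] = []
    for mz in DIAGNOSTIC_IONS.values():
        frags.append((mz, 500.0))
    if spec.ms2_y_series:
        for n in (0, 1, 2):
            frags.append((pep_mh + n * HEXNAC, 300.0))
    for _ in range(spec.ms2_decoy_fragments):
        frags.append((float(rng.uniform(250.0, 2000.0)), float(rng.uniform(10.0, 100.0))))
    frags.sort()
    return MS2Spectrum(spectrum_id, precursor_mz, z, apex_rt, frags)


def generate_fixture(spec: FixtureSpec) -> FixtureData:
    """Render the fixture: MS1 signals, lists, MGF spectra, truth table."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    signals: list[MS1Signal] = []
    spectra: list[MS2Spectrum] = []
    truth_rows: list[dict] = []
    spec_no = 0

    for pep in spec.peptides:
        coeffs = _unit_coefficients(rng, spec)
        for comp in spec.glycoforms[pep.peptide_id]:
            i, j, k, l = comp
            mono_mh = pep.calc_mass + composition_mass(*comp) + PROTON_MASS
            apex_rt = (
                pep.rt
                + i * coeffs["Hex"] + j * coeffs["HexNAc"]
                + k * coeffs["dHex"] + l * coeffs["NeuAc"]
            )
            abundance = spec.abundance_median * float(
                rng.lognormal(0.0, spec.abundance_sigma)
            )
            rendered, n = _render_glycoform(spec, mono_mh, apex_rt, abundance)
            signals.extend(rendered)
            has_ms2 = bool(rng.random() < spec.ms2_fraction)
            if has_ms2:
                spec_no += 1
                spectra.append(
                    _make_spectrum(rng, spec, f"spec_{spec_no}", mono_mh, apex_rt,
                                   pep.calc_mass + PROTON_MASS)
                )
            truth_rows.append(
                {
                    "peptide_id": pep.peptide_id,
                    "protein_id": pep.protein_id,
                    "site": pep.site,
                    "hex": i, "hexnac": j, "dhex": k, "neuac": l,
                    "mono_mh": mono_mh,
                    "apex_rt": apex_rt,
                    "abundance": abundance,
                    "n_signals": n,
                    "has_ms2": has_ms2,
                    "adduct": "",
                    "spectrum_id": f"spec_{spec_no}" if has_ms2 else "",
                }
            )

    # adduct satellite clusters: copy a neutral-connected subset so the
    # satellite forms a cluster of its own under the neutral-unit setting
    for adduct_spec in spec.adducts:
        shift = ADDUCT_SHIFTS[adduct_spec.adduct]
        chosen = _neutral_connected_subset(
            spec.glycoforms[adduct_spec.peptide_id], adduct_spec.n_members
        )
        base_rows = [r for r in truth_rows
                     if r["peptide_id"] == adduct_spec.peptide_id and not r["adduct"]
                     and (r["hex"], r["hexnac"], r["dhex"], r["neuac"]) in chosen]
        for row in base_rows:
            mono_mh = row["mono_mh"] + shift
            abundance = row["abundance"] * adduct_spec.intensity_fraction
            rendered, n = _render_glycoform(spec, mono_mh, row["apex_rt"], abundance)
            signals.extend(rendered)
            truth_rows.append(
                {
                    **{k: row[k] for k in
                       ("peptide_id", "protein_id", "site", "hex", "hexnac",
                        "dhex", "neuac", "apex_rt")},
                    "mono_mh": mono_mh,
                    "abundance": abundance,
                    "n_signals": n,
                    "has_ms2": False,
                    "adduct": adduct_spec.adduct,
                    "spectrum_id": "",
                }
            )

    n_planted = len(signals)

    # uniform decoy noise
    for _ in range(spec.noise_signals):
        rt = float(rng.uniform(*spec.noise_rt_range))
        scan = max(1, int(round(rt / spec.scan_interval_min)))
        signals.append(
            MS1Signal(
                scan,
                scan * spec.scan_interval_min,
                float(rng.uniform(*spec.noise_mass_range)),
                spec.noise_intensity_median * float(
                    rng.lognormal(0.0, spec.noise_intensity_sigma)
                ),
            )
        )

    signals.sort(key=lambda s: (s.scan_index, s.mass))

    peptides = [
        CorePeptide(p.peptide_id, p.calc_mass, p.rt, p.sequence, p.protein_id, p.site)
        for p in spec.peptides + spec.decoy_peptides
    ]
    planted_comps = sorted({c for comps in spec.glycoforms.values() for c in comps})
    glycans = [GlycanCompositionEntry(*c, points=1.0) for c in planted_comps]

    truth = pd.DataFrame(truth_rows)
    return FixtureData(
        spec=spec,
        signals=signals,
        peptides=peptides,
        glycans=glycans,
        spectra=spectra,
        truth=truth,
        n_signals=len(signals),
        n_noise_signals=len(signals) - n_planted,
    )


def spike_in(base_signals: list[MS1Signal], decoy_signals: list[MS1Signal]) -> list[MS1Signal]:
    """Merge a decoy signal list into a base run (contamination model)."""
    merged = list(base_signals) + list(decoy_signals)
    merged.sort(key=lambda s: (s.scan_index, s.mass))
    return merged


def contaminant_signals(seed: int, n_species: int = 100,
                        spec: FixtureSpec | None = None) -> list[MS1Signal]:
    """Signals of an unrelated peptide digest: independent ion species.

    Each species is one isotope envelope times a Gaussian elution profile at
    a random mass and RT — realistic MS1 content of a tryptic digest whose
    peptides are absent from the core peptide list and which carries no
    glycan-series ladder structure. Used for in-silico spike-in stability
    tests (contaminating a run with such a digest must not change cluster
    or selection output).
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(seed)
    signals: list[MS1Signal] = []
    for _ in range(n_species):
        mono_mh = float(rng.uniform(800.0, 4500.0))
        apex_rt = float(rng.uniform(12.0, 78.0))
        abundance = spec.abundance_median * float(rng.lognormal(0.0, spec.abundance_sigma))
        rendered, _ = _render_glycoform(spec, mono_mh, apex_rt, abundance)
        signals.extend(rendered)
    signals.sort(key=lambda s: (s.scan_index, s.mass))
    return signals


# ---------------------------------------------------------------------------
# file writers
# ---------------------------------------------------------------------------


def write_mgf(spectra: list[MS2Spectrum], path: str | Path) -> None:
    lines: list[str] = []
    for s in spectra:
        lines.append("BEGIN IONS")
        lines.append(f"TITLE={s.spectrum_id}")
        lines.append(f"PEPMASS={s.precursor_mz:.6f}")
        lines.append(f"CHARGE={s.precursor_charge}+")
        lines.append(f"RTINSECONDS={s.rt * 60.0:.3f}")
        for mz, inten in s.fragments:
            lines.append(f"{mz:.6f} {inten:.2f}")
        lines.append("END IONS")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def _b64_doubles(values: list[float]) -> str:
    return base64.b64encode(struct.pack(f"<{len(values)}d", *values)).decode()


def write_mzml(signals: list[MS1Signal], path: str | Path) -> None:
    """Write deconvoluted centroid MS1 spectra as minimal mzML.

    Emits one spectrum per scan over the contiguous scan range spanned by
    the signals (empty scans included, so scan adjacency survives a
    round-trip); 64-bit uncompressed arrays, masses as MH+.
    """
    by_scan: dict[int, list[MS1Signal]] = {}
    for s in signals:
        by_scan.setdefault(s.scan_index, []).append(s)
    if by_scan:
        scan_lo, scan_hi = min(by_scan), max(by_scan)
        rates = [lst[0].rt / scan for scan, lst in by_scan.items() if scan > 0]
        interval = float(np.median(rates)) if rates else 0.01
    else:
        scan_lo, scan_hi, interval = 1, 0, 0.01

    out: list[str] = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '<run id="synthetic">',
        f'<spectrumList count="{max(0, scan_hi - scan_lo + 1)}">',
    ]
    index = 0
    for scan in range(scan_lo, scan_hi + 1):
        members = sorted(by_scan.get(scan, []), key=lambda s: s.mass)
        rt = members[0].rt if members else (interval or 0.01) * scan
        mz = [s.mass for s in members]
        inten = [s.intensity for s in members]
        mz_b64, inten_b64 = _b64_doubles(mz), _b64_doubles(inten)
        out.append(
            f'<spectrum index="{index}" id="scan={scan}" defaultArrayLength="{len(mz)}">'
        )
        out.append('<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>')
        out.append('<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>')
        out.append('<scanList count="1"><scan>')
        out.append(
            f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
            f'value="{rt:.6f}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>'
        )
        out.append('</scan></scanList>')
        out.append('<binaryDataArrayList count="2">')
        out.append(f'<binaryDataArray encodedLength="{len(mz_b64)}">')
        out.append('<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>')
        out.append('<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>')
        out.append(
            '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" '
            'unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
        )
        out.append(f'<binary>{mz_b64}</binary></binaryDataArray>')
        out.append(f'<binaryDataArray encodedLength="{len(inten_b64)}">')
        out.append('<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>')
        out.append('<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>')
        out.append(
            '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" '
            'unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>'
        )
        out.append(f'<binary>{inten_b64}</binary></binaryDataArray>')
        out.append('</binaryDataArrayList></spectrum>')
        index += 1
    out.append('</spectrumList></run></mzML>')
    Path(path).write_text("\n".join(out))


def write_fixture(data: FixtureData, out_dir: str | Path, mzml: bool = False) -> dict[str, Path]:
    """Write all fixture artefacts; returns the path of each file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "signals": out_dir / "ms1_signals.tsv",
        "peptides": out_dir / "core_peptides.csv",
        "glycans": out_dir / "glycan_points.csv",
        "mgf": out_dir / "spectra.mgf",
        "truth": out_dir / "truth_glycoforms.tsv",
    }
    write_signal_table(data.signals, paths["signals"])
    pd.DataFrame(
        [
            {
                "peptide_id": p.peptide_id, "calc_mass": p.calc_mass, "rt": p.rt,
                "sequence": p.sequence, "protein_id": p.protein_id, "site": p.site,
            }
            for p in data.peptides
        ]
    ).to_csv(paths["peptides"], index=False)
    pd.DataFrame(
        [
            {"hex": g.hex, "hexnac": g.hexnac, "dhex": g.dhex, "neuac": g.neuac,
             "points": g.points, "unusual": g.unusual}
            for g in data.glycans
        ]
    ).to_csv(paths["glycans"], index=False)
    write_mgf(data.spectra, paths["mgf"])
    data.truth.to_csv(paths["truth"], sep="\t", index=False)
    if mzml:
        paths["mzml"] = out_dir / "ms1_signals.mzML"
        write_mzml(data.signals, paths["mzml"])
    return paths
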