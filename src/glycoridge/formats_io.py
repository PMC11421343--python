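"""Input/output for the four input artifacts and the result sheets.

Inputs
------
* deconvoluted LC/MS1 signals: either an mzML file of deconvoluted centroid
  MS1 spectra (masses already reduced to singly protonated MH+) or an
  equivalent tab-separated signal table with columns
  ``scan, rt_min, mass_mh, intensity``;
* a core peptide list (CSV/TSV/xlsx) with at least ``peptide_id``,
  ``calc_mass`` and ``rt`` columns;
* a glycan point list (CSV/TSV/xlsx) with per-composition plausibility
  points;
* LC/MS/MS fragment spectra in MGF.

Outputs are one TSV per result sheet plus an optional xlsx workbook.
"""

from __future__ import annotations

import base64
import logging
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable
from xml.etree import ElementTree

import pandas as pd
from pyteomics import mgf as _mgf

from .constants import PROTON_MASS

log = logging.getLogger(__name__)

SIGNAL_TABLE_COLUMNS = ["scan", "rt_min", "mass_mh", "intensity"]

#: Result sheet names; peak numbering is shared across all of them.
RESULT_SHEETS = [
    "Monoiso Peak List",
    "relation between clusters",
    "Selection results",
    "MS2 info for Clusters",
    "All MS2 info",
]


class FormatError(ValueError):
    """Raised when an input file cannot be parsed at all."""


class ValidationError(ValueError):
    """Raised when a parsed input violates a documented invariant."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MS1Signal:
    """One deconvoluted centroid: scan index, RT (min), MH+ mass (Da), intensity."""

    scan_index: int
    rt: float
    mass: float
    intensity: float

    @property
    def neutral_mass(self) -> float:
        return self.mass - PROTON_MASS


@dataclass(frozen=True)
class CorePeptide:
    """A candidate peptide backbone with its calculated neutral mass.

    ``rt == 0`` means the retention time is unknown; such peptides are kept
    and all RT gating is skipped for them.
    """

    peptide_id: str
    calc_mass: float
    rt: float
    sequence: str = ""
    protein_id: str = ""
    site: str = ""

    @property
    def rt_known(self) -> bool:
        return self.rt != 0

    @property
    def mh_mass(self) -> float:
        return self.calc_mass + PROTON_MASS


@dataclass(frozen=True)
class GlycanCompositionEntry:
    """One row of the glycan point list: a composition and its plausibility points."""

    hex: int
    hexnac: int
    dhex: int
    neuac: int
    points: float
    unusual: bool = False

    @property
    def key(self) -> tuple[int, int, int, int]:
        return (self.hex, self.hexnac, self.dhex, self.neuac)


@dataclass
class MS2Spectrum:
    """One fragment spectrum with its precursor description.

    ``fragments`` is a list of ``(mz, intensity)`` sorted by m/z.
    """

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int
    rt: float
    fragments: list[tuple[float, float]] = field(default_factory=list)

    @property
    def precursor_mh(self) -> float:
        """Precursor mass reduced to the singly protonated species."""
        z = self.precursor_charge
        return self.precursor_mz * z - (z - 1) * PROTON_MASS


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        if path.suffix.lower() in {".xlsx", ".xls"}:
            return pd.read_excel(path)
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else None
        return pd.read_csv(path, sep=sep, engine="python")
    except Exception as exc:  # noqa: BLE001 - normalised to FormatError
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def read_ms1_signals(path: str | Path, dialect: str = "signal-table") -> list[MS1Signal]:
    """Read deconvoluted MS1 centroids.

    Parameters
    ----------
    path:
        File to read.
    dialect:
        ``"signal-table"`` for the TSV/CSV dialect or ``"mzml-deconvoluted"``
        for an mzML file of deconvoluted centroid spectra. For mzML every
        peak of every MS1 spectrum is emitted, carrying the spectrum's scan
        index and RT; reported masses are treated as MH+.
    """
    if dialect == "signal-table":
        df = _read_table(path)
        missing = [c for c in SIGNAL_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"signal table missing columns {missing}")
        if (df["intensity"] < 0).any():
            raise ValidationError("negative intensity in signal table")
        if (df["mass_mh"] <= 0).any():
            raise ValidationError("non-positive mass in signal table")
        return [
            MS1Signal(int(r.scan), float(r.rt_min), float(r.mass_mh), float(r.intensity))
            for r in df.itertuples()
        ]
    if dialect == "mzml-deconvoluted":
        return _read_mzml_signals(path)
    raise ValueError(f"unknown dialect: {dialect}")


def _decode_binary_array(elem) -> list[float] | None:
    """Decode one mzML <binaryDataArray>: base64, 32/64-bit, zlib or none."""
    kind = None
    dtype = "d"
    compressed = False
    payload = ""
    for child in elem.iter():
        tag = child.tag.rsplit("}", 1)[-1]
        if tag == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000514":
                kind = "mz"
            elif acc == "MS:1000515":
                kind = "intensity"
            elif acc == "MS:1000521":
                dtype = "f"
            elif acc == "MS:1000523":
                dtype = "d"
            elif acc == "MS:1000574":
                compressed = True
        elif tag == "binary":
            payload = child.text or ""
    if kind is None:
        return None
    raw = base64.b64decode(payload)
    if compressed:
        raw = zlib.decompress(raw)
    n = len(raw) // struct.calcsize(dtype)
    values = list(struct.unpack(f"<{n}{dtype}", raw))
    return {"kind": kind, "values": values}  # type: ignore[return-value]


def _read_mzml_signals(path: str | Path) -> list[MS1Signal]:
    """Minimal reader for deconvoluted centroid MS1 mzML.

    Walks <spectrum> elements, keeping MS-level-1 spectra; RT comes from the
    scan-start-time cvParam (seconds converted to minutes), peak arrays from
    the base64 binary data arrays (64/32-bit, zlib or uncompressed).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    signals: list[MS1Signal] = []
    scan_index = 0
    try:
        context = ElementTree.iterparse(str(path), events=("end",))
    except ElementTree.ParseError as exc:
        raise FormatError(f"cannot parse mzML {path}: {exc}") from exc
    try:
        for _, elem in context:
            if elem.tag.rsplit("}", 1)[-1] != "spectrum":
                continue
            ms_level = 1
            rt = None
            arrays: dict[str, list[float]] = {}
            for child in elem.iter():
                tag = child.tag.rsplit("}", 1)[-1]
                if tag == "cvParam":
                    acc = child.get("accession", "")
                    if acc == "MS:1000511":
                        ms_level = int(child.get("value", "1"))
                    elif acc == "MS:1000016":
                        rt = float(child.get("value", "0"))
                        if child.get("unitName", "minute") == "second":
                            rt /= 60.0
                elif tag == "binaryDataArray":
                    decoded = _decode_binary_array(child)
                    if decoded:
                        arrays[decoded["kind"]] = decoded["values"]
            if ms_level == 1:
                scan_index += 1
                if rt is None:
                    raise ValidationError(
                        f"mzML spectrum {scan_index} lacks a scan start time"
                    )
                mz = arrays.get("mz", [])
                inten = arrays.get("intensity", [])
                for m, i in zip(mz, inten):
                    if i < 0:
                        raise ValidationError("negative intensity in mzML spectrum")
                    signals.append(MS1Signal(scan_index, rt, float(m), float(i)))
            elem.clear()
    except ElementTree.ParseError as exc:
        raise FormatError(f"cannot parse mzML {path}: {exc}") from exc
    return signals


def write_signal_table(signals: Iterable[MS1Signal], path: str | Path) -> None:
    """Write signals in the signal-table dialect (round-trips with read)."""
    df = pd.DataFrame(
        [(s.scan_index, s.rt, s.mass, s.intensity) for s in signals],
        columns=SIGNAL_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_core_peptides(path: str | Path) -> list[CorePeptide]:
    """Read the core peptide list; ``rt = 0`` rows are retained (RT unknown)."""
    df = _read_table(path)
    required = {"peptide_id", "calc_mass", "rt"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"core peptide list missing columns {sorted(missing)}")
    if df["calc_mass"].isna().any():
        raise ValidationError("core peptide list has rows without calc_mass")
    ids = df["peptide_id"].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValidationError(f"duplicate peptide ids: {dupes}")
    peptides = []
    for r in df.itertuples():
        rt = float(r.rt)
        pep = CorePeptide(
            peptide_id=str(r.peptide_id),
            calc_mass=float(r.calc_mass),
            rt=rt,
            sequence=str(getattr(r, "sequence", "") or ""),
            protein_id=str(getattr(r, "protein_id", "") or ""),
            site=str(getattr(r, "site", "") or ""),
        )
        if pep.calc_mass <= 0:
            raise ValidationError(f"non-positive calc_mass for {pep.peptide_id}")
        if not pep.rt_known:
            log.info("peptide %s has rt=0: flagged rt-unknown", pep.peptide_id)
        peptides.append(pep)
    return peptides


def read_glycan_points(path: str | Path) -> list[GlycanCompositionEntry]:
    """Read the glycan point list (Hex/HexNAc/dHex/NeuAc counts, points, unusual flag)."""
    df = _read_table(path)
    required = {"hex", "hexnac", "dhex", "neuac", "points"}
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"glycan point list missing columns {sorted(missing)}")
    entries: list[GlycanCompositionEntry] = []
    seen: set[tuple[int, int, int, int]] = set()
    for r in df.itertuples():
        counts = (int(r.hex), int(r.hexnac), int(r.dhex), int(r.neuac))
        if any(c < 0 for c in counts):
            raise ValidationError(f"negative monosaccharide count in {counts}")
        if counts in seen:
            raise ValidationError(f"duplicate glycan composition {counts}")
        seen.add(counts)
        unusual = bool(getattr(r, "unusual", False) or False)
        entries.append(GlycanCompositionEntry(*counts, points=float(r.points), unusual=unusual))
    return entries


def read_mgf(path: str | Path) -> list[MS2Spectrum]:
    """Read MS2 spectra from MGF.

    RTINSECONDS is converted to minutes. Spectra lacking PEPMASS are skipped
    with a warning; a missing CHARGE defaults to 1 with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    spectra: list[MS2Spectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for idx, entry in enumerate(reader):
            params = entry.get("params", {})
            title = str(params.get("title", f"spectrum_{idx + 1}"))
            pepmass = params.get("pepmass")
            if not pepmass or pepmass[0] is None:
                log.warning("MGF spectrum %s lacks PEPMASS; skipped", title)
                continue
            charge = params.get("charge")
            if charge:
                z = int(charge[0])
            else:
                log.warning("MGF spectrum %s lacks CHARGE; defaulting to 1+", title)
                z = 1
            rt = params.get("rtinseconds")
            if rt is not None:
                rt_min = float(rt) / 60.0
            else:
                rt_min = float(params.get("rtinminutes", 0.0))
            frags = sorted(zip(entry["m/z array"].tolist(), entry["intensity array"].tolist()))
            spectra.append(
                MS2Spectrum(
                    spectrum_id=title,
                    precursor_mz=float(pepmass[0]),
                    precursor_charge=z,
                    rt=rt_min,
                    fragments=[(float(m), float(i)) for m, i in frags],
                )
            )
    return spectra


# ---------------------------------------------------------------------------
# result writing
# ---------------------------------------------------------------------------

def _sheet_filename(sheet: str) -> str:
    return sheet.lower().replace(" ", "_") + ".tsv"


def write_results(sheets: dict[str, pd.DataFrame], out_dir: str | Path,
                  workbook: bool = False) -> list[Path]:
    """Write one TSV per result sheet, optionally plus a single xlsx workbook.

    ``sheets`` maps sheet names (see :data:`RESULT_SHEETS`) to data frames.
    Missing sheets are written as header-only files when a column layout is
    known, so downstream cross-sheet checks always find every file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for sheet in RESULT_SHEETS:
        df = sheets.get(sheet, pd.DataFrame())
        target = out_dir / _sheet_filename(sheet)
        df.to_csv(target, sep="\t", index=False)
        written.append(target)
    for sheet, df in sheets.items():
        if sheet not in RESULT_SHEETS:
            target = out_dir / _sheet_filename(sheet)
            df.to_csv(target, sep="\t", index=False)
            written.append(target)
    if workbook:
        book = out_dir / "results.xlsx"
        with pd.ExcelWriter(book, engine="openpyxl") as writer:
            for sheet, df in sheets.items():
                df.to_excel(writer, sheet_name=sheet[:31], index=False)
        written.append(book)
    return written
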