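"""MS2 evidence collection and confidence grading for assigned clusters.

MS1-based assignment leaves room for misassignment, so each assigned
cluster is graded with whatever fragment evidence exists:

* **High** — some member's spectrum shows Y0-related ions (observed Y0, a
  Y1/Y2 series implying a Y0, or a predicted Y0 from a HexNAc ladder)
  whose mass matches the assigned peptide's MH+, or the member appears in
  an optional external MS2-identification list with the same peptide;
* **Medium** — some member's spectrum shows glycan oxonium (diagnostic)
  ions, e.g. HexNAc at m/z 204.0866, confirming a glycopeptide spectrum
  without confirming the peptide;
* **Low** — no member has MS2 support.

Diagnostic ions never influence selection; they only annotate it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .constants import DIAGNOSTIC_IONS, HEXNAC, PROTON_MASS
from .formats_io import MS2Spectrum
from .peak_detection import MonoisotopicPeak
from .selection import ClusterAssignment

LEVEL_HIGH = "High"
LEVEL_MEDIUM = "Medium"
LEVEL_LOW = "Low"

BASIS_Y0 = "Y0-evidence"
BASIS_EXTERNAL = "external-ID"
BASIS_DIAGNOSTIC = "diagnostic-ions"
BASIS_NONE = "none"

Y_SERIES = {"Y0": 0, "Y1": 1, "Y2": 2}


@dataclass(frozen=True)
class DiagnosticIon:
    """A glycan fragment marker ion, singly charged."""

    name: str
    mz: float
    required: bool = False

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("mz must be positive")


def default_diagnostic_table() -> list[DiagnosticIon]:
    return [DiagnosticIon(name, mz) for name, mz in DIAGNOSTIC_IONS.items()]


@dataclass
class MS2Evidence:
    """Evidence gathered from one spectrum for one cluster member."""

    peak_no: int
    spectrum_id: str
    diag_found: list[str] = field(default_factory=list)
    y_ions_found: list[str] = field(default_factory=list)
    y0_observed: float | None = None
    y0_predicted: float | None = None
    peptide_confirmed: bool = False


@dataclass(frozen=True)
class ConfidenceLevel:
    level: str
    basis: str


# ---------------------------------------------------------------------------
# spectrum association
# ---------------------------------------------------------------------------

def associate_ms2(
    peak: MonoisotopicPeak,
    spectra: list[MS2Spectrum],
    precursor_tol_ppm: float = 5.0,
    rt_tol: float = 0.5,
) -> list[MS2Spectrum]:
    """Spectra whose precursor MH+ matches the peak within tolerance and
    whose RT falls inside the peak's elution span widened by ``rt_tol``."""
    tol = peak.mono_mass * precursor_tol_ppm * 1e-6
    lo = (peak.rt_start or peak.apex_rt) - rt_tol
    hi = (peak.rt_end or peak.apex_rt) + rt_tol
    return [
        s
        for s in spectra
        if abs(s.precursor_mh - peak.mono_mass) <= tol and lo <= s.rt <= hi
    ]


# ---------------------------------------------------------------------------
# fragment searches
# ---------------------------------------------------------------------------

def _has_fragment(spectrum: MS2Spectrum, mz: float, frag_tol: float) -> bool:
    return any(abs(f - mz) <= frag_tol for f, _ in spectrum.fragments)


def find_diagnostic_ions(
    spectrum: MS2Spectrum,
    diag_table: list[DiagnosticIon] | None = None,
    frag_tol: float = 0.02,
) -> list[str]:
    """Names of diagnostic-table ions present in the spectrum."""
    if diag_table is None:
        diag_table = default_diagnostic_table()
    return [d.name for d in diag_table if _has_fragment(spectrum, d.mz, frag_tol)]


def find_y_series(
    spectrum: MS2Spectrum,
    peptide_mh: float,
    frag_tol: float = 0.02,
    extra_offsets: dict[str, float] | None = None,
) -> tuple[list[str], float | None]:
    """Search Y0/Y1/Y2 at the assigned peptide's mass, singly and doubly charged.

    Yn is the peptide moiety retaining n HexNAc residues:
    ``Yn = peptide MH+ + n * 203.079373``. ``extra_offsets`` optionally adds
    further targets as name -> mass offset from the peptide MH+ (e.g.
    Y0+Hex, or a core-fucose Y1+dHex). Returns the names found and the
    observed Y0 mass (as MH+) when the Y0 ion itself is present.
    """
    found: list[str] = []
    y0_observed: float | None = None
    targets = {name: n * HEXNAC for name, n in Y_SERIES.items()}
    if extra_offsets:
        targets.update(extra_offsets)
    for name, offset in targets.items():
        target_mh = peptide_mh + offset
        singly = target_mh
        doubly = (target_mh + PROTON_MASS) / 2
        hit = None
        if _has_fragment(spectrum, singly, frag_tol):
            hit = singly
        elif _has_fragment(spectrum, doubly, frag_tol):
            hit = doubly * 2 - PROTON_MASS
        if hit is not None:
            found.append(name)
            if name == "Y0":
                matches = [f for f, _ in spectrum.fragments if abs(f - singly) <= frag_tol]
                if matches:
                    y0_observed = min(matches, key=lambda f: abs(f - singly))
                else:
                    y0_observed = hit
    return found, y0_observed


def predict_y0(spectrum: MS2Spectrum, frag_tol: float = 0.02,
               min_ladder: int = 2) -> float | None:
    """Predict the Y0 (peptide MH+) mass from a HexNAc ladder.

    Fragment pairs differing by one HexNAc residue are chained into
    descending ladders; the longest ladder with at least ``min_ladder``
    peaks (ties broken by total intensity) is extrapolated one HexNAc below
    its lowest rung. Absent when no ladder exists. The ladder is assumed to
    consist of Y ions above an unobserved Y0, which is why the weakest Y0
    signals can still be recovered.
    """
    mzs = [f for f, _ in spectrum.fragments]
    intens = {f: i for f, i in spectrum.fragments}
    if len(mzs) < min_ladder:
        return None
    # successor[i] = fragments one HexNAc above fragment i
    ladders: list[list[float]] = []
    for start in mzs:
        ladder = [start]
        current = start
        while True:
            nxt = [f for f in mzs if abs(f - current - HEXNAC) <= frag_tol]
            if not nxt:
                break
            current = min(nxt, key=lambda f: abs(f - ladder[-1] - HEXNAC))
            ladder.append(current)
        below = [f for f in mzs if abs(start - f - HEXNAC) <= frag_tol]
        if below:
            continue  # not the base of a maximal ladder
        if len(ladder) >= min_ladder:
            ladders.append(ladder)
    if not ladders:
        return None
    best = max(ladders, key=lambda L: (len(L), sum(intens[f] for f in L)))
    return best[0] - HEXNAC


# ---------------------------------------------------------------------------
# per-member evidence and cluster grading
# ---------------------------------------------------------------------------

def collect_evidence(
    peak: MonoisotopicPeak,
    spectra: list[MS2Spectrum],
    peptide_mh: float | None,
    diag_table: list[DiagnosticIon] | None = None,
    frag_tol: float = 0.02,
    precursor_tol_ppm: float = 5.0,
    rt_tol: float = 0.5,
) -> list[MS2Evidence]:
    """Associate spectra with one member and run all fragment searches."""
    out: list[MS2Evidence] = []
    for spectrum in associate_ms2(peak, spectra, precursor_tol_ppm, rt_tol):
        ev = MS2Evidence(peak_no=peak.peak_no, spectrum_id=spectrum.spectrum_id)
        ev.diag_found = find_diagnostic_ions(spectrum, diag_table, frag_tol)
        if peptide_mh is not None:
            ev.y_ions_found, ev.y0_observed = find_y_series(spectrum, peptide_mh, frag_tol)
            ev.y0_predicted = predict_y0(spectrum, frag_tol)
            confirmed = False
            if ev.y0_observed is not None and abs(ev.y0_observed - peptide_mh) <= frag_tol:
                confirmed = True
            if ev.y0_predicted is not None and abs(ev.y0_predicted - peptide_mh) <= frag_tol:
                confirmed = True
            ev.peptide_confirmed = confirmed
        out.append(ev)
    return out


def assign_confidence(
    assignment: ClusterAssignment,
    evidence_by_member: dict[int, list[MS2Evidence]],
    external_ids: dict[str, str] | None = None,
) -> ConfidenceLevel:
    """Grade an assigned cluster High/Medium/Low from member evidence.

    ``external_ids`` optionally maps spectrum ids to peptide ids from an
    MS2-based search engine; agreement with the assigned peptide also
    grants High.
    """
    if not assignment.assigned:
        raise ValueError("confidence applies only to assigned clusters")
    all_evidence = [ev for evs in evidence_by_member.values() for ev in evs]
    if any(ev.peptide_confirmed for ev in all_evidence):
        return ConfidenceLevel(LEVEL_HIGH, BASIS_Y0)
    if external_ids:
        for ev in all_evidence:
            if external_ids.get(ev.spectrum_id) == assignment.peptide_id:
                return ConfidenceLevel(LEVEL_HIGH, BASIS_EXTERNAL)
    if any(ev.diag_found for ev in all_evidence):
        return ConfidenceLevel(LEVEL_MEDIUM, BASIS_DIAGNOSTIC)
    return ConfidenceLevel(LEVEL_LOW, BASIS_NONE)
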