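"""Monoisotopic peak picking from deconvoluted MS1 centroids.

The stage proceeds in four steps:

1. range filtering (RT window, mass window, minimum intensity);
2. local-peak detection with a 5-scan x 5-Da dominance filter: a signal is
   recorded as a local peak iff it is the intensity maximum within +/-2
   scans and +/-2.5 Da of itself (ties broken toward the lower scan, then
   the lower mass); every other signal inside a recorded peak's window is
   excluded from candidacy;
3. ion-trace grouping: each local peak seeds a trace extended scan-by-scan
   in both directions, collecting signals within a ppm tolerance of the
   peak mass and tolerating short gaps, and the per-scan spectra around the
   trace apex are integrated into one isotope envelope;
4. monoisotopic assignment: the integrated envelope is fitted against
   theoretical averagine envelopes placed at isotope offsets -2..+2 from
   the initial (lowest observed) peak; if a nonzero offset fits best the
   monoisotopic mass is corrected and the peak carries ``update_flag = 1``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .constants import (
    AVERAGINE_COMPOSITION,
    AVERAGINE_MASS,
    ISOTOPE_ABUNDANCES,
    ISOTOPE_SPACING,
    PROTON_MASS,
)
from .formats_io import MS1Signal

# 5 scans x 5 Da dominance window, centered: +/-2 scans, +/-2.5 Da, closed.
LOCAL_PEAK_SCAN_HALFWIDTH = 2
LOCAL_PEAK_MASS_HALFWIDTH = 2.5

#: Isotope ladder offsets integrated around a trace apex (in isotope units).
ENVELOPE_LADDER = range(-3, 7)

#: Candidate monoisotopic offsets tried during correction.
CORRECTION_OFFSETS = (-2, -1, 0, 1, 2)


@dataclass(frozen=True)
class RangeSetting:
    """Analysis window: RT range (min), mass range (Da, MH+), intensity floor."""

    rt_min: float = 0.0
    rt_max: float = 90.0
    mass_min: float = 0.0
    mass_max: float = 10000.0
    min_intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.rt_min >= self.rt_max:
            raise ValueError("rt_min must be < rt_max")
        if self.mass_min >= self.mass_max:
            raise ValueError("mass_min must be < mass_max")
        if self.min_intensity < 0:
            raise ValueError("min_intensity must be >= 0")


@dataclass
class SignalGroup:
    """Signals of one ion species traced across scans, with its apex."""

    group_id: int
    members: list[MS1Signal]
    apex: MS1Signal

    @property
    def scan_span(self) -> tuple[int, int]:
        scans = [s.scan_index for s in self.members]
        return min(scans), max(scans)

    @property
    def rt_span(self) -> tuple[float, float]:
        rts = [s.rt for s in self.members]
        return min(rts), max(rts)


@dataclass
class IsotopeEnvelope:
    """An isotope pattern: (mass, intensity) peaks spaced ~1.0033548 Da."""

    peaks: list[tuple[float, float]]

    def masses(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    def intensities(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks])


@dataclass
class MonoisotopicPeak:
    """One ion species after grouping and monoisotopic correction."""

    peak_no: int
    mono_mass: float  # MH+, Da
    apex_rt: float
    intensity: float
    update_flag: int = 0
    rt_start: float = field(default=0.0)
    rt_end: float = field(default=0.0)

    @property
    def neutral_mass(self) -> float:
        return self.mono_mass - PROTON_MASS


# ---------------------------------------------------------------------------
# step 1: range filter
# ---------------------------------------------------------------------------

def filter_signals(signals: list[MS1Signal], setting: RangeSetting) -> list[MS1Signal]:
    """Keep signals inside the RT/mass windows with intensity >= threshold."""
    return [
        s
        for s in signals
        if setting.rt_min <= s.rt <= setting.rt_max
        and setting.mass_min <= s.mass <= setting.mass_max
        and s.intensity >= setting.min_intensity
    ]


# ---------------------------------------------------------------------------
# step 2: local peaks
# ---------------------------------------------------------------------------

def _dominates(a: MS1Signal, b: MS1Signal) -> bool:
    """True if *a* outranks *b* (higher intensity; ties to lower scan, lower mass)."""
    return (a.intensity, -a.scan_index, -a.mass) > (b.intensity, -b.scan_index, -b.mass)


def detect_local_peaks(signals: list[MS1Signal]) -> list[MS1Signal]:
    """Apply the 5-scan x 5-Da dominance filter.

    A signal survives iff no other signal within +/-2 scans and +/-2.5 Da
    outranks it. The window is symmetric, so any signal beaten inside some
    window is automatically excluded from candidacy.
    """
    by_scan: dict[int, list[MS1Signal]] = {}
    for s in signals:
        by_scan.setdefault(s.scan_index, []).append(s)
    for scan_signals in by_scan.values():
        scan_signals.sort(key=lambda s: s.mass)
    mass_index = {scan: [s.mass for s in lst] for scan, lst in by_scan.items()}

    peaks: list[MS1Signal] = []
    for s in signals:
        beaten = False
        for scan in range(s.scan_index - LOCAL_PEAK_SCAN_HALFWIDTH,
                          s.scan_index + LOCAL_PEAK_SCAN_HALFWIDTH + 1):
            lst = by_scan.get(scan)
            if not lst:
                continue
            masses = mass_index[scan]
            lo = bisect.bisect_left(masses, s.mass - LOCAL_PEAK_MASS_HALFWIDTH)
            hi = bisect.bisect_right(masses, s.mass + LOCAL_PEAK_MASS_HALFWIDTH)
            for other in lst[lo:hi]:
                if other is s:
                    continue
                if _dominates(other, s):
                    beaten = True
                    break
            if beaten:
                break
        if not beaten:
            peaks.append(s)
    peaks.sort(key=lambda s: (s.scan_index, s.mass))
    return peaks


# ---------------------------------------------------------------------------
# step 3: tracing and envelope integration
# ---------------------------------------------------------------------------

class SignalIndex:
    """Signals grouped by scan and sorted by mass, for windowed lookups."""

    def __init__(self, signals: list[MS1Signal]):
        by_scan: dict[int, list[MS1Signal]] = {}
        for s in signals:
            by_scan.setdefault(s.scan_index, []).append(s)
        for lst in by_scan.values():
            lst.sort(key=lambda s: s.mass)
        self.by_scan = by_scan
        self.masses = {scan: [s.mass for s in lst] for scan, lst in by_scan.items()}

    def window(self, scan: int, mass_lo: float, mass_hi: float) -> list[MS1Signal]:
        masses = self.masses.get(scan)
        if not masses:
            return []
        lo = bisect.bisect_left(masses, mass_lo)
        hi = bisect.bisect_right(masses, mass_hi)
        return self.by_scan[scan][lo:hi]


def index_by_scan(signals: list[MS1Signal] | SignalIndex) -> SignalIndex:
    """Build the scan/mass index (pass-through when already indexed)."""
    return signals if isinstance(signals, SignalIndex) else SignalIndex(signals)


def trace_ion_group(
    local_peak: MS1Signal,
    signals: list[MS1Signal] | SignalIndex,
    trace_tol_ppm: float = 10.0,
    max_gap_scans: int = 1,
    group_id: int = 0,
) -> SignalGroup:
    """Trace one ion across scans starting from a local peak.

    Extends forward and backward collecting, per scan, the signal closest in
    mass within ``trace_tol_ppm`` of the local peak's mass; the trace stops
    once ``max_gap_scans + 1`` consecutive scans lack a matching signal.
    """
    tol = local_peak.mass * trace_tol_ppm * 1e-6
    index = index_by_scan(signals)

    def best_in_scan(scan: int) -> MS1Signal | None:
        candidates = index.window(scan, local_peak.mass - tol, local_peak.mass + tol)
        if not candidates:
            return None
        return min(candidates, key=lambda s: abs(s.mass - local_peak.mass))

    members = [local_peak]
    for step in (1, -1):
        gap = 0
        scan = local_peak.scan_index
        while gap <= max_gap_scans:
            scan += step
            hit = best_in_scan(scan)
            if hit is None or hit is local_peak:
                gap += 1
            else:
                members.append(hit)
                gap = 0
    members.sort(key=lambda s: s.scan_index)
    apex = max(members, key=lambda s: (s.intensity, -s.scan_index))
    return SignalGroup(group_id=group_id, members=members, apex=apex)


def integrate_envelope(
    group: SignalGroup,
    signals: list[MS1Signal] | SignalIndex,
    n_flank_scans: int = 2,
    ladder_tol: float = 0.02,
) -> IsotopeEnvelope:
    """Sum isotope-ladder intensities over the scans around the group apex.

    The ladder comprises masses ``apex_mass + m * 1.0033548`` for
    ``m = -3..+6``; for every scan within ``apex +/- n_flank_scans`` the
    closest signal within ``ladder_tol`` Da of each rung is added.
    """
    apex = group.apex
    index = index_by_scan(signals)
    scans = range(apex.scan_index - n_flank_scans, apex.scan_index + n_flank_scans + 1)

    peaks: list[tuple[float, float]] = []
    for m in ENVELOPE_LADDER:
        target = apex.mass + m * ISOTOPE_SPACING
        total = 0.0
        seen = False
        for scan in scans:
            candidates = index.window(scan, target - ladder_tol, target + ladder_tol)
            if candidates:
                hit = min(candidates, key=lambda s: abs(s.mass - target))
                total += hit.intensity
                seen = True
        if seen:
            peaks.append((target, total))
    return IsotopeEnvelope(peaks=peaks)


# ---------------------------------------------------------------------------
# step 4: averagine envelope and monoisotopic correction
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4096)
def _averagine_distribution(counts: tuple[int, ...]) -> np.ndarray:
    """Aggregated isotope distribution for integer C/H/N/O/S atom counts,
    normalised to max = 1; per-element convolution with squaring."""
    dist = np.array([1.0])
    for element, count in zip(AVERAGINE_COMPOSITION, counts):
        if count == 0:
            continue
        iso = ISOTOPE_ABUNDANCES[element]
        base = np.zeros(max(d for d, _ in iso) + 1)
        for d, p in iso:
            base[d] = p
        power = base
        k = count
        acc = np.array([1.0])
        while k:
            if k & 1:
                acc = np.convolve(acc, power)
            k >>= 1
            if k:
                power = np.convolve(power, power)
        dist = np.convolve(dist, acc)
    return dist / dist.max()


def averagine_envelope(neutral_mass: float, min_rel_intensity: float = 1e-4) -> IsotopeEnvelope:
    """Theoretical isotope distribution of an averagine peptide of given mass.

    The averagine unit composition is scaled to ``neutral_mass`` and rounded
    to integer atom counts; the aggregated (nominal-mass) isotope
    distribution is obtained by per-element convolution over the C, H, N, O
    and S isotope abundances. Intensities are normalised to max = 1 and
    reported at ``neutral_mass + m * 1.0033548``.
    """
    if neutral_mass <= 0:
        raise ValueError("neutral_mass must be positive")
    n_units = neutral_mass / AVERAGINE_MASS
    counts = tuple(
        max(0, round(n * n_units)) for n in AVERAGINE_COMPOSITION.values()
    )
    dist = _averagine_distribution(counts)
    peaks = [
        (neutral_mass + m * ISOTOPE_SPACING, float(p))
        for m, p in enumerate(dist)
        if p >= min_rel_intensity
    ]
    return IsotopeEnvelope(peaks=peaks)


def _envelope_vector(env: IsotopeEnvelope, anchor: float) -> dict[int, float]:
    """Index envelope intensities by isotope offset relative to ``anchor``."""
    out: dict[int, float] = {}
    for mass, inten in env.peaks:
        idx = round((mass - anchor) / ISOTOPE_SPACING)
        out[idx] = out.get(idx, 0.0) + inten
    return out


def envelope_fit_score(observed: IsotopeEnvelope, theoretical: IsotopeEnvelope,
                       anchor: float) -> float:
    """Cosine similarity of the two envelopes aligned on the isotope ladder."""
    obs = _envelope_vector(observed, anchor)
    theo = _envelope_vector(theoretical, anchor)
    keys = sorted(set(obs) | set(theo))
    a = np.array([obs.get(k, 0.0) for k in keys])
    b = np.array([theo.get(k, 0.0) for k in keys])
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def assign_monoisotopic(
    observed: IsotopeEnvelope,
    initial_mono: float,
    score_margin: float = 1e-9,
) -> tuple[float, int]:
    """Choose the monoisotopic MH+ mass by averagine fitting.

    Candidate monoisotopic masses ``initial_mono + o * 1.0033548`` for
    ``o in {-2,-1,0,+1,+2}`` are each scored by the cosine similarity
    between the observed envelope and the theoretical averagine envelope of
    the candidate (both aligned on the common isotope ladder). Returns the
    best candidate mass and ``update_flag`` (1 iff the offset is nonzero).
    Ties within ``score_margin`` are resolved toward offset 0, then toward
    the more negative offset.
    """
    if len(observed.peaks) < 2:
        # a single rung carries no pattern to fit against
        return initial_mono, 0
    scored: list[tuple[float, int]] = []
    for offset in CORRECTION_OFFSETS:
        candidate = initial_mono + offset * ISOTOPE_SPACING
        if candidate <= PROTON_MASS:
            continue
        theo = averagine_envelope(candidate - PROTON_MASS)
        # place theoretical mono at the candidate MH+ position
        shift = candidate - theo.peaks[0][0]
        theo = IsotopeEnvelope([(m + shift, i) for m, i in theo.peaks])
        scored.append((envelope_fit_score(observed, theo, anchor=initial_mono), offset))
    if not scored:
        return initial_mono, 0
    best_score = max(s for s, _ in scored)
    contenders = [o for s, o in scored if s >= best_score - score_margin]
    if 0 in contenders:
        offset = 0
    else:
        offset = min(contenders)
    return initial_mono + offset * ISOTOPE_SPACING, int(offset != 0)


# ---------------------------------------------------------------------------
# full stage
# ---------------------------------------------------------------------------

def pick_monoisotopic_peaks(
    signals: list[MS1Signal],
    setting: RangeSetting,
    trace_tol_ppm: float = 10.0,
    max_gap_scans: int = 1,
    n_flank_scans: int = 2,
) -> list[MonoisotopicPeak]:
    """Run range filtering through monoisotopic correction; number the peaks.

    The initial monoisotopic guess for each ion group is the lowest-mass
    rung of its integrated envelope with intensity >= 5% of the envelope
    maximum (guards against stray low-mass noise rungs). Reported intensity
    is the trace apex intensity; the peak is deduplicated on (mono mass,
    apex scan) so one isotope cluster yields one peak.
    """
    kept = filter_signals(signals, setting)
    local_peaks = detect_local_peaks(kept)
    indexed = index_by_scan(kept)
    peaks: list[MonoisotopicPeak] = []
    seen: set[tuple[int, int]] = set()
    for lp in local_peaks:
        group = trace_ion_group(lp, indexed, trace_tol_ppm, max_gap_scans)
        envelope = integrate_envelope(group, indexed, n_flank_scans)
        if not envelope.peaks:
            continue
        max_inten = max(i for _, i in envelope.peaks)
        significant = [(m, i) for m, i in envelope.peaks if i >= 0.05 * max_inten]
        initial_mono = min(m for m, _ in significant)
        mono, flag = assign_monoisotopic(IsotopeEnvelope(significant), initial_mono)
        if not (setting.mass_min <= mono <= setting.mass_max):
            continue
        key = (round(mono / ISOTOPE_SPACING), group.apex.scan_index)
        if key in seen:
            continue
        seen.add(key)
        rt_lo, rt_hi = group.rt_span
        peaks.append(
            MonoisotopicPeak(
                peak_no=0,
                mono_mass=mono,
                apex_rt=group.apex.rt,
                intensity=group.apex.intensity,
                update_flag=flag,
                rt_start=rt_lo,
                rt_end=rt_hi,
            )
        )
    peaks.sort(key=lambda p: (p.apex_rt, p.mono_mass))
    for i, p in enumerate(peaks, start=1):
        p.peak_no = i
    return peaks
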