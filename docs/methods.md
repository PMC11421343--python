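# Methods

This note documents the models, defaults and design choices behind
`glycoridge`, and what the synthetic test harness does and does not show.

## Signal model and units

All masses are monoisotopic Daltons. Input MS1 masses are deconvoluted,
singly protonated (MH+); neutral masses are obtained by subtracting the
proton mass 1.00727646688 Da. Retention times are minutes everywhere
(MGF `RTINSECONDS` is divided by 60 on read). Scan indices are 1-based and
all intervals — RT windows, mass windows, unit RT-shift windows — are
closed.

Residue masses are computed from elemental monoisotopic masses:
Hex (C6H10O5) 162.052824, HexNAc (C8H13NO5) 203.079373, dHex (C6H10O4)
146.057909, NeuAc (C11H17NO8) 291.095417, and the LacNAc motif
Hex+HexNAc 365.132196. Adduct satellite shifts on MH+ masses are
NH4 = +NH3 = 17.026549 Da and Fe(III) = +Fe − 3H = 52.911461 Da
(Fe-56 = 55.934936). Default diagnostic oxonium ions are residue + proton:
HexNAc 204.086649 and HexNAc+Hex 366.139472 m/z.

## Monoisotopic peak picking

* **Local peaks.** The "five scans × 5 Da" dominance filter is read as a
  closed window of ±2 scans and ±2.5 Da centred on each signal; a signal is
  a local peak iff no signal in its window outranks it (intensity, ties
  broken toward the lower scan, then the lower mass). Because the window is
  symmetric, every non-maximal signal inside a recorded peak's window is
  automatically excluded. An exhaustive O(n²) oracle reproduces this
  definition exactly in the tests.
* **Tracing and integration.** Traces extend scan-by-scan within 10 ppm of
  the seed mass (default `trace_tol_ppm`), tolerating one missing scan
  (`max_gap_scans = 1`). Envelopes integrate the isotope ladder
  (offsets −3…+6 at 1.0033548 Da, the 13C−12C spacing) over the apex ±2
  scans (`flank_scans = 2`). Reported peak intensity is the apex intensity,
  not the area; elution start/end are kept for MS2 association.
* **Averagine correction.** The theoretical isotope distribution uses the
  standard averagine unit C4.9384 H7.7583 N1.3577 O1.4773 S0.0417 per
  111.1254 Da, scaled to the neutral mass, rounded to integer atom counts,
  and convolved per element over the natural isotope abundances
  (exponentiation-by-squaring; cached by atom-count tuple). Candidate
  monoisotopic masses at offsets −2…+2 isotopes are scored by cosine
  similarity between the observed and theoretical envelopes aligned on the
  isotope-index grid; ties resolve toward offset 0, then toward the more
  negative offset. The initial monoisotopic guess is the lowest envelope
  rung with ≥5% of the envelope maximum, which guards against stray
  low-mass rungs. Envelopes with a single rung carry no pattern and are
  never "corrected"; the choice is scale-invariant and idempotent.

## Clustering

Edges require both a residue-mass gap (within 10 ppm of the heavier mass)
and a unit-specific RT shift: neutral units −1…0 min, NeuAc +1…+4 min
(defaults mirroring the behaviour of sialylated tryptic glycopeptides on
C18). Components are undirected; the lighter→heavier direction is retained
for display only. The default parallel bundle is

| setting | units | min members | purpose |
|---|---|---|---|
| 1 | Hex, HexNAc, dHex, LacNAc | 4 | general detection, low misdetection |
| 2 | neutral + NeuAc | 10 | unify sialo-series into one cluster per site |
| 3 | Hex only | 3 | oligo-mannose ladders (M5–M9) |

`min_members` counts nodes and applies per setting *before* merging;
merging unions clusters sharing any peak and is invariant to setting
order. At most five settings run per analysis. Treating the per-unit RT
windows separately also guards against isobaric misreadings (e.g. a
Hex+dHex gap of 308.11 Da with a positive RT shift matches no single unit).

## Matching and selection

Composition enumeration is lexicographic with partial-sum pruning and an
analytic solve for the NeuAc count; it is tested against the exhaustive
four-loop oracle. Default ranges Hex 0–12, HexNAc 1–12, dHex 0–4,
NeuAc 0–4; dHex is capped at 4 because dHex(5) differs from
Hex(2)HexNAc(2) by only 0.0252 Da (~5 ppm at 5000 Da), below routine mass
accuracy. Per member, multiple solutions resolve to the smallest |ppm
error|, then the fewest residues, then lexicographic order. A coarse RT
gate (|median member RT − peptide RT| ≤ 30 min) pre-filters peptides with
known RT; peptides with `rt = 0` bypass every RT criterion, so predicted
peptide lists still work for purified proteins. Negative points for
unusual compositions exist but default off.

Selection applies, in order: score threshold (default 4 = four one-point
members, the smallest default cluster), the ΔRT window (default ±10 min; a
candidate survives if *any* member is inside), top total score, tie
exclusion, and the strict >50% point-bearing member ratio (denominator:
all cluster members). Members of an accepted candidate that violate the
ΔRT or ±5 ppm windows are flagged for inspection, never dropped.

Adduct relations between clusters require ≥3 member pairs (default)
agreeing on the shift within 10 ppm and 1 min; the heavier cluster is
reported as the satellite, which keeps the relation antisymmetric in
practice.

## MS2 confidence

Spectra associate to a peak when the precursor MH+ matches within 5 ppm
and the spectrum RT falls inside the peak's elution span ±0.5 min.
Fragment tolerance defaults to 0.02 Da. Y ions are searched singly and
doubly charged at Y0 = peptide MH+, Y1 = +203.0794, Y2 = +406.1587. Y0
prediction chains fragment pairs one HexNAc apart into maximal ladders
(≥2 rungs) and extrapolates one HexNAc below the longest ladder's base —
one defensible reading of "predict Y0 from related signals"; a peptide is
confirmed only when an observed or predicted Y0 matches its MH+ within the
fragment tolerance. Confidence maps fixed: Y0 evidence or an external MS2
identification of the same peptide → High; diagnostic ions only → Medium;
nothing → Low. The mapping is monotone in evidence, and selection output
is identical with MS2 processing disabled.

## Synthetic data generator

The generator emulates a purified, heavily sialylated multi-site
glycoprotein run on a 90-min gradient (0.01 min/scan grid):

* **Glycoform families.** Each site receives a connected subset of the
  N-glycan lattice Hex(3+a)HexNAc(2+a)dHex(f)NeuAc(s), a = 2–6, f = 0–2,
  s ≤ min(a, 4), grown at random around a fixed backbone (biantennary →
  tetraantennary, one branch-fucosylated form, and the full sialo series
  to s = 4). The backbone guarantees every site spans sialylation 0–4 and
  has at least four neutral-connected members; prefixes of the growth
  order stay connected so adduct satellites cluster on their own.
* **Retention model.** Per peptide, one shift coefficient per unit type is
  drawn once: neutral units U(−0.45, −0.05) min (so the two-residue LacNAc
  step also stays inside its −1…0 window) and NeuAc U(+1.1, +3.9) min.
  Glycoform RT = peptide RT + Σ count·coefficient. Drawing per-glycoform
  shifts instead would contradict any additive elution model and break the
  planted series.
* **Signals.** Each glycoform renders as its averagine envelope (rungs
  ≥ 0.1% relative) times a Gaussian elution profile (σ = 2 scans, ±3σ),
  with log-normal abundances (median 10⁶, σ = 1). Decoy noise signals are
  uniform in mass and RT at contaminant-level intensities; the default
  preset sizes them to ~20% of all signals. Adduct satellites copy a
  neutral-connected subset of a site's glycoforms shifted by the NH4 or
  Fe(III) mass at a fraction of the intensity.
* **MS2.** Planted spectra carry both oxonium ions, the Y0/Y1/Y2 series
  (charge 2 precursors) and uniform decoy fragments.
* **Spike-in model.** `contaminant_signals` renders independent ion
  species (envelope × elution at random masses/RTs) — the signal content
  of an unrelated digest with no glycan-ladder structure. Note that a
  mass-*shuffled* copy of the run itself is not a usable contaminant
  model: permutation preserves the unit-spaced mass multiset and
  manufactures spurious clusters.

What passing fixture tests show: the pipeline recovers planted structure
under the stated RT/mass model with realistic envelope shapes, noise
density, adducts and decoy peptides. What they do not show: robustness to
chromatographic tailing, RT drift between units beyond the additive model,
charge-state deconvolution errors other than isotope offsets, dynamic
exclusion, or real biological abundance distributions.

## Numerical choices and degenerate inputs

Mass tolerances are relative (ppm of the heavier/observed mass) except
fragment and envelope-ladder matching (absolute Da). Envelope fitting falls
back to "no correction" for single-rung envelopes and to offset 0 on score
ties. Empty inputs propagate: an empty signal list yields empty sheets and
a successful exit. All orderings (peak numbering, cluster ids, sheet rows)
are canonicalised, so identical inputs and configuration give byte-identical
outputs; the only randomness in the package lives in the fixture generator
and is fully seed-driven.

## Problem sizes

The default test and acceptance runs use the five-site preset (10–40
glycoforms per site, ~20–33k signals, ~5–6.5k monoisotopic peaks), 1000
random composition-enumeration instances, 20 local-peak instances up to 200
signals, 10 clustering instances up to 100 peaks, and 200 noisy envelopes
for offset-correction recovery — sizes chosen so the whole suite exercises
every code path in a few minutes on one CPU.

## Known limitations

* Averagine is a peptide model; glycopeptides are sugar-rich and their
  true isotope distributions deviate slightly. The deviation does not
  change the argmax behaviour the correction relies on at these masses.
* The >50% point-ratio rule uses all cluster members as denominator (the
  stricter reading); lists with sparse glycan points will exclude more
  clusters.
* Y0 prediction assumes HexNAc-ladder Y ions; exotic fragmentation
  patterns (extensive Y0+Hex, core-fucose ladders) are only covered via
  the configurable extra Y targets, which default off.
* O-glycan composition search, raw-spectrum deconvolution and FDR
  estimation are out of scope; the method's confidence is qualitative
  (High/Medium/Low), not probabilistic.
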