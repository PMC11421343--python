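# glycoridge

MS1-based detection and site-specific assignment of intact glycopeptides
from deconvoluted LC/MS data.

## The problem

Intact glycopeptides — proteolytic peptides still carrying their N-glycan —
are the direct readout of site-specific protein glycosylation
(micro-heterogeneity). MS2-based identification undersamples them: glycans
suppress ionization, sialylated species fragment poorly, and each glycoform
at a site divides the available signal. Many glycopeptide ions are visible
in MS1 but never yield an interpretable MS2 spectrum.

`glycoridge` implements the MS1-centric alternative: glycopeptides sharing
one core peptide form a *cluster* in the (retention time, mass) plane,
because their masses differ by whole glycan residues and their retention
times shift in a unit-specific way — each neutral residue (Hex, HexNAc,
dHex, or the Hex+HexNAc motif) shifts elution slightly earlier (about
−1 to 0 min per unit on a C18 gradient), while each sialic acid (NeuAc)
shifts it later (+1 to +4 min per unit). Exploiting both regularities lets
asialo- through tetrasialo-series collapse into a single cluster per
glycosite, and each cluster is then explained by accurate mass alone.

## The method

1. **Monoisotopic peak picking.** Deconvoluted MS1 centroids (masses as
   MH+) are range-filtered; a 5-scan × 5-Da dominance filter finds local
   peaks; each local peak seeds an ion trace whose flanking scans are
   integrated into an isotope envelope. The envelope is fitted against
   theoretical averagine isotope distributions (multinomial over C, H, N,
   O, S) placed at isotope offsets −2…+2; a better fit at a nonzero offset
   corrects the monoisotopic mass (`update_flag = 1`).
2. **Clustering.** Peaks become nodes; an edge joins two peaks whose mass
   gap matches one glycan residue within a ppm tolerance *and* whose RT gap
   falls in that unit's window. Connected components above a minimum size
   are clusters. Up to five search settings run in parallel (e.g. a
   neutral-only setting with min 4 members, a NeuAc-aware setting with min
   10, and a Hex-only/min-3 setting for oligo-mannose series) and their
   clusters merge on shared peaks.
3. **Matching.** For every cluster member and candidate core peptide, the
   observed neutral mass is explained as
   `M(glycopeptide) = M(peptide) + i·M(Hex) + j·M(HexNAc) + k·M(dHex) + l·M(NeuAc)`
   with integer counts in configurable ranges (defaults Hex 0–12,
   HexNAc 1–12, dHex 0–4, NeuAc 0–4). Compositions listed in a
   user-supplied glycan point list earn points; a candidate's total score
   sums over members. An inter-cluster analysis also flags cluster pairs
   offset by a constant ammonium (+17.0265 Da) or Fe(III) (+52.9115 Da)
   adduct shift, explaining detected-but-unmatched satellite clusters.
4. **Selection.** Per cluster: drop candidates below the score threshold or
   with all members outside the ΔRT window, keep the top score, exclude
   ties, and require the fraction of members with glycan points to exceed
   50%. Exactly one core peptide can win a cluster.
5. **MS2 confidence.** Associated MS2 spectra are searched for glycan
   oxonium ions (HexNAc 204.0866, HexNAc+Hex 366.1395) and the Y-ion series
   (Y0 = peptide MH+, Y1 = +HexNAc, Y2 = +2·HexNAc), with Y0 predicted from
   HexNAc ladders when unobserved. Clusters grade **High** (Y0-level
   evidence or external MS2 ID for the assigned peptide), **Medium**
   (diagnostic ions only), or **Low** (no MS2 support). Diagnostic ions
   never influence selection.

## Inputs

* deconvoluted LC/MS1 signals — mzML of deconvoluted centroid spectra, or a
  TSV signal table with columns `scan, rt_min, mass_mh, intensity`;
* core peptide list (CSV/TSV/xlsx): `peptide_id, calc_mass, rt` plus
  optional `sequence, protein_id, site`; `rt = 0` marks an unknown RT and
  disables RT gating for that peptide;
* glycan point list (CSV/TSV/xlsx): `hex, hexnac, dhex, neuac, points`
  (+ optional `unusual` flag; negative points are honoured only when
  enabled in the config);
* optional MGF of LC/MS/MS spectra for confidence grading.

## Worked example

Generate a synthetic five-site glycoprotein run with ground truth, then
analyse it:

```bash
glycoridge simulate --seed 7 --out sim
# signals=25264 noise=4836 glycoforms=132 spectra=121
glycoridge run --ms1 sim/ms1_signals.tsv --peptides sim/core_peptides.csv \
    --glycans sim/glycan_points.csv --mgf sim/spectra.mgf --out results
# signals=25264 monoisotopic_peaks=4956 corrected_peaks=2 clusters=7
#   matched_clusters=7 assigned_clusters=5
```

The run detects 7 clusters: one per planted glycosite (5) plus two adduct
satellites, which stay unassigned but appear in
`relation_between_clusters.tsv` as NH4/Fe(III) relations to their parent
clusters. `selection_results.tsv` holds one row per assigned cluster:

```
cluster_id  status    peptide_id  protein_id  site  total_score  n_members  n_matched  point_ratio  n_flagged  confidence
1           assigned  P103        AGP1        103   14.0         14         14         1.0          4          High
2           assigned  P93         AGP1        93    29.0         29         29         1.0          0          High
3           assigned  P56         AGP1        56    25.0         25         25         1.0          0          High
```

Every member matched its peptide (`point_ratio = 1.0`) and every cluster
carries Y0-level MS2 evidence (`High`). `final_glycoforms.tsv` lists one
row per site-specific glycoform with intensity, ΔRT and ppm error;
`monoiso_peak_list.tsv` carries the corrected monoisotopic peaks with their
update flags, and the same peak numbering links all sheets.

Stage subcommands (`peaks`, `cluster`, `match`, `select`, `ms2`)
recompute deterministically up to their stage and write the corresponding
sheets, so stepwise and single-shot runs produce identical files. A YAML
config (see `glycoridge.config`) overrides any threshold; the effective
configuration is persisted as `config_used.yaml` next to the results.

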