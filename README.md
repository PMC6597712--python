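# synquant

Quantification toolkit for the cell-biology and spectroscopy assays used to
characterize how alpha-synuclein (a-syn) — the 140-residue, intrinsically
disordered presynaptic protein central to Parkinson's disease — regulates
stimulated vesicle exocytosis and endocytosis in a mast-cell model, where
recycling endosomes (REs) stand in for synaptic vesicles. It is written for
cell biologists and spectroscopists who have the raw measurements (time-lapse
fluorescence, two-channel micrographs, blot densitometry, per-residue NMR
tables, cytometry quench courses) and want the derived numbers, and it ships
seeded synthetic-data generators so every analysis chain can be exercised and
validated end-to-end with known ground truth and no external data.

## What it computes

**Stimulated exocytosis** (`exo_quant`). pHluorin reporters are quenched in
acidic vesicles and dequenched on exocytic exposure; NH4Cl added at the end
of a time course neutralizes all compartments and reveals total reporter
fluorescence. Traces are normalized to a 0–1 scale,
`(value(t) − min)/(max − min)`, and

```
% exocytosis = (stimulated − basal) / (NH4Cl − basal) × 100
```

using window means (basal epoch; the stimulated plateau, by default the
final 60 s before NH4Cl; a 30 s NH4Cl window starting 10 s after addition).
TIRF movies of single fusion events — spreading flashes of fluorescence —
are counted automatically: rolling-median background subtraction, Gaussian
smoothing, spatiotemporal local maxima above 5 robust SDs with a one-frame
persistence check, deduplicated in space-time.

**Vesicle spatial statistics** (`spatial_coloc`). The membrane-proximal
fraction of RE fluorescence is the intensity inside an ~800 nm outer shell
of the cell mask (Euclidean erosion) divided by total cell intensity; the
released fraction compares shell intensity after stimulation to the same
shell after NH4Cl. Mitochondrial and lipid-droplet association use the
Manders overlap coefficient

```
MOC = Σ(R_i·G_i) / sqrt(ΣR_i² · ΣG_i²)
```

plus line-scan profiles and colocalized-puncta counts.

**Residue-resolved membrane binding by NMR** (`nmr_membrane`). Amide
chemical-shift deviations `Δδ_avg = sqrt(½(Δδ_HN² + Δδ_N²/25))`, secondary
carbon shifts against a random-coil reference (positive CA ⇒ helix), carbon
re-referencing of mutant spectra against wild type over residues 111–130,
and lipid/free peak-intensity ratios — the unbound fraction per residue —
with a logistic fit that locates a binding boundary (e.g. the helix-2
proline mutant V70P releases everything C-terminal to residue 70).

**Absolute intracellular concentration** (`abs_quant`). Blot band densities
are loading-normalized by three nonspecific bands, calibrated against
standards (2, 3.5, 5, 6.5, 8 µg/ml), interpolated, converted to pg/cell via
lane cell equivalents, then to µg/ml and µM using the mean cell volume
(2627 µm³) and the sequence-derived molecular mass (14,460 Da for a-syn;
ε280 = 4 × 1490 = 5960 M⁻¹cm⁻¹).

**Stimulated endocytosis** (`endo_quant`). FITC-IgE fluorescence quenches as
crosslinked receptors internalize into acidic endosomes; curves are set to
1.0 before stimulation, the fractional quench is 1 minus the endpoint
fluorescence, and each sample is reported relative to its paired
empty-vector control (100%).

**Synthetic data** (`syngen`). Deterministic, seeded generators for all of
the above with the true values recorded alongside: step-plateau dequench
traces, flash movies, shell-structured cell images, colocalization pairs,
perturbed mutant shift tables, sigmoidal binding profiles, calibration
blots with lane-loading variation, and exponential quench curves.

## Worked example

Generate a noisy pHluorin trace whose true stimulated release is 25% of the
NH4Cl-revealed total, then quantify it:

```
$ synquant simulate exo-trace --seed 11 --noise-sd 6 --out demo/
$ synquant exo trace demo/trace.csv
{
  "pct_exocytosis": 24.898698988118085,
  "basal_mean": 100.41773400461818,
  "stim_mean": 174.50455315045596,
  "nh4cl_mean": 397.97070727921687
}
```

The estimate (24.9%) recovers the generator's ground truth (25%) to within
the injected noise. The same pattern runs the blot chain end to end:

```
$ synquant simulate blot --seed 2 --out demo-blot/
$ synquant quant --table demo-blot/blot.csv
{
  "r_squared": 1.0,
  "unknowns": [
    {"lane": "unk1", "lysate_ug_per_ml": 3.0, "pg_per_cell": 0.4,
     "cellular_ug_per_ml": 152.26, "cellular_uM": 10.53},
    {"lane": "unk2", "lysate_ug_per_ml": 6.0, "pg_per_cell": 0.8,
     "cellular_ug_per_ml": 304.53, "cellular_uM": 21.06}
  ]
}
```

Each unknown lane's lysate concentration is read off the five-point
calibration line, divided over the cell equivalents loaded in the lane
(0.4 pg/cell), and converted to the concentration inside an average cell
(here ~152 µg/ml, i.e. ~10.5 µM of the 14.46 kDa protein).

The same operations are available as library calls
(`synquant.exo_quant.percent_exocytosis`, `synquant.abs_quant.*`, ...); the
CLI is a thin layer over them.

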