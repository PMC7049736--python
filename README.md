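# ptcmap

Quantitative analysis pipeline for a saturation single-point mutational
scan of the *E. coli* ribosome's active site — the peptidyl transferase
center (PTC) of the 23S rRNA. The scan builds every possible point mutant
across three catalytic regions (the central PTC-ring, the A-loop and the
P-loop; 61 positions, 183 mutants), measures each mutant ribosome's
protein-synthesis output in an in vitro ribosome synthesis-and-translation
(iSAT) reaction, and asks how "mutable" each nucleotide really is despite
near-universal sequence conservation.

The package is organised as an analysis project: every computation lives in
the `ptcmap` library (`src/`), and the numbered scripts under `analysis/`
drive the study stages in order, writing tables under `results/`.

## What is computed

* **Conservation** (`ptcmap.conservation`) — per-column Shannon entropy of
  an aligned LSU rRNA set, H = −Σᵢ pᵢ ln pᵢ over i ∈ {A,U,G,C}, with
  gapped records excluded per column. H = 0 means total conservation;
  ln 4 ≈ 1.386 nats means all four bases equally likely.
* **Activity and flexibility** (`ptcmap.activity`) — sfGFP reporter traces
  are converted RFU → μM through a linear standard curve; the bulk
  translation rate is the OLS slope over 0–2 h, the endpoint yield a
  plateau estimate over the final 10% of the run. Relative activity
  normalizes wild type to 1; the per-position **mutational flexibility
  score** is the sum of the three mutants' relative activities (0–3), with
  flags for score ≥ 1 and for any single mutant ≥ 75% of wild type.
* **Readthrough** (`ptcmap.readthrough`) — premature-stop reporter signal
  relative to wild type per construct, normalized by the mutant's
  translation activity (undefined below a 2% activity floor).
* **Assembly** (`ptcmap.sedimentation`) — sucrose-gradient A254 traces,
  blank/background-corrected and integrated by rectangle rule over the
  30S/50S/70S/polysome windows (13–21, 22–28, 30–40, 42–59 mm); reported
  as species fractions and the ratios (30S+50S)/(70S+polysomes) and
  70S/polysomes.
* **Structure mapping** (`ptcmap.structure`) — per-nucleotide heavy-atom
  geometric centers, Euclidean distances to the A76 reference points of
  the A- and P-site tRNAs (with Kabsch superposition when tRNA coordinates
  come from another crystal form), quantile binning into four flexibility
  shells, and B-factor export for heat-map rendering.
* **Statistics** (`ptcmap.stats`) — simple linear regression with a
  two-sided slope t test, for flexibility-vs-entropy and
  flexibility-vs-distance relationships.
* **Synthetic data** (`ptcmap.synth`) — seeded generators for every input
  (alignment, kinetics, readthrough signals, gradient traces, toy 3D
  structure) with known ground truth, so the whole pipeline is testable
  for parameter recovery without downloads.

## Worked example

```sh
python analysis/01_simulate_panel.py --seed 1          # inputs + truth
python analysis/02_conservation_profile.py             # entropy profile
python analysis/03_activity_flexibility.py             # activity + scores
python analysis/04_readthrough.py
python analysis/05_sedimentation.py
python analysis/06_structure_map.py
python analysis/07_regressions.py
```

With seed 1 the drivers print, among other lines:

```
flexibility scores for 61 positions -> results/flexibility_scores.tsv
  score >= 1: 28/61 positions; any mutant >= 75% WT: 21/61
  WT: subunits/(70S+poly) = 1.40, 70S/poly = 0.62
  assembly_defect: subunits/(70S+poly) = 14.34, 70S/poly = 1.57
  P-site distance span: 4.0-36.0 A
  A/P-loops vs distance to P-site tRNA: R^2 = 1.000, P = 7.07e-34 (n = 18)
```

Reading: about half the simulated positions tolerate mutation (flexibility
score ≥ 1) even though most alignment columns are near-monomorphic; the
assembly-defective sample accumulates free subunits (ratio ≫ the wild-type
~1.4); and in the A/P-loops flexibility rises with distance from the
P-site tRNA, spanning 4–36 Å — the noiseless panel reproduces its
generating gradient exactly, so with 10% measurement noise the regression
is still essentially perfect.

`analysis/06_structure_map.py` also accepts real coordinates
(`--ribosome`, `--trna`, chain options) to compute the same distances on a
deposited ribosome structure with tRNAs superposed from another entry.

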