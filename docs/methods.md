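# Methods

This note records the models, parameter choices and numerical conventions
behind `ptcmap`, and what the synthetic-data tests do and do not establish
about real measurements.

## Regions and the mutant catalogue

The three study regions are fixed in 1-based *E. coli* 23S numbering with
inclusive intervals: PTC-ring G2057–C2063, G2447–C2456, C2496–C2507,
G2582–G2588, A2602, C2606–C2611 (43 nt); A-loop U2548–A2560 (13 nt);
P-loop G2250–C2254 (5 nt). Enumerating all three single-point substitutions
at each of the 61 positions yields 183 mutants, ordered by position then
base (A<C<G<U) for reproducible output. Published descriptions of this
design quote "180 total mutations"; the stated ranges nevertheless
enumerate 61 positions × 3 = 183, and which three mutants (or one
position) were excluded is not recorded, so the catalogue here is the full
183 and downstream counts refer to it.

Wild-type identities ship in `src/ptcmap/data/regions.yaml`. 48 of the 61
positions carry the identity implied by their standard nucleotide names
(A2451, U2585, G2553, ...); the remaining 13 positions use the standard
*E. coli* 23S (rrnB) identities as curated from the structural and
modification literature. The file is a plain YAML config and can be
replaced wholesale for other organisms or numbering conventions; no
downstream computation depends on these identities beyond mutant naming.

## Conservation

Entropy is Shannon's H = −Σ pᵢ ln pᵢ over i ∈ {A,U,G,C} in nats (the
natural-log base is fixed by the conventional maximum ln 4 ≈ 1.386).
At each column, sequences carrying a gap are removed before counting; the
default rule generalizes this to any non-ACGU symbol after uppercasing and
T→U mapping (ambiguity codes, '.'), with `gap_only=True` restoring the
literal '-'-only rule. Exclusion counts are reported per column so the
stricter rule is auditable. A column where every record is excluded raises
an error — undefined entropy is distinct from H = 0 (total conservation).
Each sequence counts once: this is a variance-like score that ignores
phylogenetic relatedness, so a clade of near-duplicates deflates H.

Study positions are located by walking the ungapped coordinates of a named
reference record, which guarantees the mapped column's reference character
equals the reference sequence's character at that position.

## Activity and flexibility

Replicate RFU traces are converted to μM through an OLS standard curve
(slope must be positive; negative concentrations are floored at 0 with a
logged count, as noise near blank), then averaged pointwise on their
common time grid.

* **Bulk rate**: OLS slope of μM vs h over a window, default 0–2 h. The
  window is configurable; an early window keeps the secant close to the
  initial slope of a saturating trace.
* **Endpoint yield**: mean signal over the final 10% of the time axis
  (plateau estimate, robust to point noise); `last` point available as an
  alternative. Which summary the original study used is not stated; both
  are computed and the choice is an argument.
* **Relative activity**: endpoint yield / wild-type endpoint yield.
  Values are deliberately *not* capped at 1, so a hyperactive mutant can
  push a position's score above 3; the 0–3 framing assumes mutants ≤ WT.
* **Flexibility score**: the sum of the three mutants' relative activities
  at a position, requiring exactly three distinct mutants. Flags: score
  ≥ 1, and max single-mutant activity ≥ 0.75.

## Readthrough

Per construct (stop codon × amino-acid position), replicate endpoint
signals are averaged, divided by the construct's wild-type mean, then by
the mutant's relative activity. Below an activity floor (default 0.02 —
2% of wild type) the quotient amplifies noise without bound, so the record
is flagged undefined (NaN, never infinity) with the raw ratio retained.
Division by relative activity is the literal reading of
activity-normalization; no codon-specific release-factor correction is
applied. The assay conflates miscoding with termination fidelity, and so
does this analysis.

## Sedimentation

Blank and background traces are linearly interpolated onto the sample
grid; the output is restricted to the span common to all three traces
(no extrapolation) and clipped at 0 with the clipped mass logged.
Integration is the left-endpoint rectangle rule on the measured grid —
the closest literal reading of summing between x-axis coordinates — with
a trapezoidal option. Windows are half-open [start, end) so adjacent
windows never double-count a grid point; the defaults are the approximate
published boundaries (30S 13–21, 50S 22–28, 70S 30–40, polysomes
42–59 mm) and are overridable. Signal in the gaps between windows
(21–22, 28–30, 40–42 mm) belongs to no species and is reported as
unassigned mass. Both assembly ratios are area quotients and therefore
invariant under global trace rescaling.

## Structure mapping

Nucleotide centers are unweighted means over heavy atoms only — crystal
structures at ribosome resolutions lack reliable hydrogens, and altloc
duplicates resolve to the highest-occupancy copy. The tRNA-site reference
is the analogous mean over A76 plus any covalently attached amino-acid
moiety (configurable to A76 alone). When tRNA coordinates come from a
different entry than the ribosome, a Kabsch least-squares superposition
over shared atoms (default: phosphorus atoms matched by chain/residue
number) places them in one frame; the original study's placement protocol
is unpublished, so reproduced real-structure distances may shift by ~1 Å
under alternative alignments. Shells are quantile (equal-count) bins of
the flexibility score, four by default, with ties broken toward the lower
shell; published color thresholds are unavailable, so explicit thresholds
are accepted as an alternative. B-factor export writes one score per
residue (sentinel −1.00 for unmapped residues) and round-trips at PDB
precision, two decimals.

## Regression

Simple OLS with a two-sided t test on the slope (n−2 df); R² is the
squared Pearson correlation. A constant response returns slope 0, R² 0,
p 1 by convention. No multiple-testing correction, matching
per-comparison reporting. Calibration is verified by a seeded null
simulation (1000 replicates, n = 20): the rejection rate at α = 0.05 must
fall in [0.03, 0.07].

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (parameters, seed), via
`numpy.random.default_rng`.

* **Kinetics**: single-exponential saturation
  c(t) = P(1 − e^{−(r/P)t}), the simplest curve with initial slope r
  rising to plateau P. Wild-type defaults r = 1.03 μM/h and P = 10 μM over
  a 16 h horizon sampled every 15 min; the plateau/rate ratio keeps the
  0–2 h OLS secant within 10% of the generating rate. Mutant traces scale
  both r and P by the true relative activity, so the saturation constant
  is shared and the noiseless endpoint-yield ratio equals the truth
  exactly. sfGFP maturation delay is omitted. Noise is multiplicative
  Gaussian (CV-parameterized) on fluorescence, floored at 0.
* **Alignment**: columns drawn independently from per-position nucleotide
  frequencies with a uniform gap rate; the reference record is emitted
  gap-free. Real alignments are phylogenetically correlated across rows
  and columns; recovery results here certify the estimator, not
  robustness to tree structure.
* **Gradients**: Gaussian mixtures over the species windows plus linear
  drift and a stray background peak, with peak σ chosen so each peak lies
  ≥ 3σ inside its window (integration then captures essentially the full
  mass). Real traces have asymmetric, partially overlapping peaks that the
  windowed rectangle rule cannot deconvolve.
* **Toy structure**: each nucleotide is a 4-atom zero-sum cluster whose
  heavy-atom mean sits at prescribed distances from two A76-like reference
  clusters 30 Å apart (distances must satisfy the triangle inequality);
  recovery is exact by construction.
* **Default panel truth**: 61 positions × 3 mutants with positions drawn
  into inflexible/intermediate/flexible tiers (activity means 0.05 / 0.35
  / 0.85, SD 0.12, clipped to [0, 1.1]); alignment diversity loosely
  anti-correlated with conservation; an A/P-loop P-site-distance gradient
  spanning 4–36 Å anti-correlated with flexibility; five gradient samples
  including one severe assembly defect (subunit ratio ≈ 16.8 vs ≈ 1.4
  wild-type-like); most readthrough propensities near 1 with ~15%
  elevated 3–8×. Ranking-recovery checks for readthrough set the
  propensities to an explicit spread, since ranking near-ties is
  noise-dominated by construction.

Problem sizes used by the tests and the acceptance script — 60–400
alignment records, 3 replicates, 1000 null regression replicates — were
chosen to make sampling error small relative to the tolerances tested
while keeping each stage's runtime in seconds.

## Known limitations

* Conservation ignores phylogeny (see above).
* The activity summary (plateau of fluorescence-derived concentration)
  cannot distinguish slow-but-complete from fast-but-partial synthesis;
  bulk rate is reported alongside for that reason.
* Windowed integration assigns no signal to species outside its window
  and cannot separate overlapping peaks.
* Real-structure distance reproduction depends on an unpublished
  superposition protocol; expect ~1 Å sensitivity.
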