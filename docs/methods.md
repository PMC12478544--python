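# Methods

## The PQ1 composite score

PQ1 condenses an entry's validation record into one number in [0, 1] by
percentile-ranking it, component by component, against a reference
population of X-ray entries and then ranking the mean of those components.
Three conventions are deliberate package choices, stated here because the
published definition leaves them open:

* **Percentile convention.** Mid-rank fraction,
  `(#strictly worse + 0.5 × #ties) / n`. It is symmetric (a full tie-free
  population self-ranks with mean exactly 0.5), bounded in [0, 1], and
  reproducible regardless of tie structure.
* **Geometry PCA on z-standardized metrics.** Clashscore (overlaps per
  1000 atoms, unbounded) and the two outlier percentages live on
  incommensurate scales; PCA on raw values would simply follow the largest
  variance. Standardization uses the sample mean and sample standard
  deviation (ddof = 1) of the fit set; a zero-variance column is rejected
  as degenerate, since its z-scores are undefined.
* **PC1 sign.** Eigenvectors are sign-ambiguous; the loading on clashscore
  is constrained non-negative, so a larger projection always means worse
  geometry and the projection is ranked lower-is-better.

Further fixed behaviours: DCC-recalculated R_free takes priority over the
depositor-reported value (the independent recalculation avoids
typographical and bookkeeping errors); an entry that belongs to the
reference is scored against the reference as-is, with no leave-one-out;
when one of R_free / %RSRZ is missing, the mean is taken over the present
components, and only when both are missing is the score flagged as
geometry-only estimated; the mean-percentile re-ranking array is frozen at
fit time. Whether geometry-only entries should be ranked against a
geometry-only mean array instead of the full one is genuinely open; this
implementation ranks them against the same mean-percentile array, which
keeps a single frozen ranking and makes the estimated flag the only
difference in treatment.

## Ligand quality

The score is the equal-weight mean of the RSR percentile (lower better)
and the RSCC percentile (higher better) against a reference ligand
population supplied by the caller (there is no canonical scope for the
reference; the cohort itself is the default). The exact combination rule
used by the PDB's ligand-quality sliders is not public; the symmetric
two-percentile mean is this package's documented approximation. Solvent
and ions are excluded via a configurable chemical-component list before
scoring.

## Cohort comparison

Deltas are stored as re-refined minus original everywhere; the
presentation-layer helper negates them for plots drawn as original minus
re-refined. Quartiles use linear interpolation between order statistics
(numpy's default), so fixture tests are exact; whiskers sit at the most
extreme observations within 1.5×IQR of the hinges and the
whisker/outlier partition is exhaustive and exclusive. The
improved/worsened categories use a symmetric ±0.02 threshold on ΔR_free —
the worsening threshold is the published rule, the symmetric improvement
rule is this package's operationalization, and it is flagged in the
report metadata. "Top entries not improved" is likewise operationalized
as: top decile of original PQ1 with ΔR_free ≥ 0. A metric missing on one
side of a pair drops that pair from that metric's summary only (per-metric
n is reported).

## Superposition

Atoms are matched by identity keys (chain, residue number, insertion
code, residue name, atom name), not by sequence alignment: the two models
of one entry share numbering, and identity mapping avoids the whole-model
misalignment failures that produce artifactual RMSD values of tens of
Angstroms. Altloc 'A' or blank is kept; occupancy ignored; waters are
HOH/WAT/DOD; hydrogens are elements H/D. The Kabsch superposition uses
SVD of the coordinate cross-covariance with reflection correction
(determinant forced to +1). Fewer than 3 pairs, or a collinear
configuration (second singular value of the centered coordinates below
1e-8 of the first), is rejected: the rotation is underdetermined there.
Numeric parity with RMSDs computed by alignment-based tools is not
claimed, since those may pair atoms differently.

## Synthetic data

The generators emulate the statistical structure of deposited validation
data, not its empirical distributions:

* **Resolution** ~ log-normal(log 2.0, 0.25): right-skewed, median 2 Å,
  bulk between roughly 1.2 and 3.3 Å.
* **R_free** = 0.10 + 0.06·resolution + N(0, 0.02), clipped to [0, 1].
  At 2 Å this puts the median near 0.22, and the implied
  resolution–R_free Pearson correlation is ≈ 0.84 ("very strong"); the
  closed form is exposed as
  `PopulationSpec.expected_resolution_rfree_correlation`.
* **Geometry and %RSRZ** are gamma marginals (right-skewed, mass near
  zero) whose scales are multiplied by a shared latent per-entry "care"
  factor ~ Gamma(4, 1/4) (mean 1), inducing the positive correlation
  between outlier types seen in real data. Defaults put clashscore's mean
  near 6 and rotamer outliers near 3% — the magnitude class of a
  decades-spanning cohort.
* **Missing structure factors** with probability 0.10 (the survey's
  legacy fraction, 33/325): those entries lose both R_free values and
  %RSRZ and get pre-2008 dates.
* **Re-refinement deltas** are Gaussian per metric. Defaults encode a
  modest typical improvement (ΔR_free median −0.009, matching the
  magnitude of published cohort medians; clashscore −2.5), with
  probability 0.03 of a pathological large worsening
  (ΔR_free ~ N(+0.08, 0.04)) emulating automated-pipeline failures.
* **Coordinate pairs** are schematic poly-alanine helices (CA spiral,
  rise 1.5 Å, radius 2.3 Å, 100°/residue, fixed local-frame offsets for
  N/C/O/CB) — plausible spacing, not real stereochemistry — plus a
  uniform random rigid motion and per-atom isotropic Gaussian noise.
  After an optimal 6-dof fit the expected heavy-atom RMSD is
  σ·sqrt(3 − 6/n), the closed form the tests check against.

What passing on synthetic data does **not** show: agreement with the real
PDB's metric distributions (explicitly a non-goal), behaviour under the
messy missingness patterns of real validation reports, or numeric parity
with any specific survey's per-entry values.

The zero-median delta recovery check constructs its effect with
ΔR_free ~ N(0, 0.01) at n = 500: with the median's sampling standard
error 1.2533·σ/√n ≈ 0.00056, the ±0.002 acceptance band is a ≈3.6σ
bound.

## Problem sizes

Test and script cohorts use 300–2000 synthetic entries, 500–1000 paired
records, and 40–200-atom coordinate sets — large enough that the
closed-form expectations above bind to within a few percent, small enough
that the full suite runs in seconds.

## Known limitations

* The reference population is whatever the caller fits; no snapshot of
  the real PDB ships with the package, so absolute PQ1 values are only
  comparable within one fitted reference.
* Geometry metrics (clashscore, Ramachandran, rotamers) and real-space
  metrics (RSR/RSCC, %RSRZ) are consumed, never computed from
  coordinates or maps.
* Identity-key matching requires shared numbering between the two
  models; renumbered or re-chained re-refinements need external
  remapping first.
* Curated fixture lists carry two mutually inconsistent published counts
  of entries lacking diffraction data (33 stated vs 36 implied); both
  are kept with provenance labels rather than reconciled.
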