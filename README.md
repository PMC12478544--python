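# pqkit

Structure-quality survey toolkit for crystal structure deposits: the PQ1
single-number quality score, real-space ligand fit scoring, paired
original-vs-re-refined cohort comparison, and rigid-body RMSD between two
models of the same entry.

## Who this is for

Surveys of a protein family's deposits in the PDB — for example the
cAMP-dependent protein kinase (PKA) catalytic domain, with over 300 crystal
structures spanning three decades — need a way to rank entries by overall
quality, to judge whether automated re-refinement (PDB-REDO style) actually
improved them, and to flag the handful of deposits with structural problems.
`pqkit` packages that workflow so it can be applied to any family.

## The quality model

For an entry with validation metrics relative to a reference population of
X-ray entries,

```
PQ1(entry) = rank( (P_Rfree + P_%RSRZ + P_geometry) / 3 )
```

where `P_Rfree`, `P_%RSRZ` and `P_geometry` are mid-rank percentiles (higher
is better) of the entry's R_free, its percentage of RSRZ outlier residues,
and its projection on the first principal component of the z-standardized
triple (Ramachandran outlier %, rotamer outlier %, clashscore). The mean of
the available percentiles is itself percentile-ranked against the reference
population's mean-percentile distribution, so PQ1 ranges from 0 (worst) to
1 (best). Entries deposited without diffraction data are scored from the
geometry component alone and flagged as estimated.

Ligand fit quality is the mean of two oriented percentiles — RSR (real-space
R factor, lower better) and RSCC (real-space correlation, higher better) —
against a reference ligand population, after excluding solvent and ions.

Re-refined cohorts are compared through per-entry deltas (re-refined minus
original; DCC-recalculated R_free preferred over depositor values), Tukey
boxplot summaries with 1.5×IQR whiskers, cohort mean/median tables, and a
categorization into: no structure factors, free set not designated, improved
(ΔR_free ≤ −0.02), worsened (ΔR_free ≥ +0.02), and top-decile entries that
re-refinement could not improve. Model pairs are superposed by identity-key
atom matching plus Kabsch SVD superposition (Cα-only and all heavy atoms,
waters excluded), with warnings for misalignment-scale RMSD values.

## Worked example

```python
import numpy as np
from pqkit import (PopulationSpec, fit_reference, compute_pq1,
                   generate_reference_population)

records = generate_reference_population(PopulationSpec(n=2000, seed=1))
population = fit_reference(records)
result = compute_pq1(records[0], population)
print(result.entry_id, round(result.pq1, 3), round(result.mean_percentile, 3))
# 9000 0.566 0.537
```

The printed line is the entry's final PQ1 (here 0.566: slightly better than
the reference median) and the mean of its three component percentiles. The curated
PKA fixture table ships with the package:

```sh
pqkit fixtures --out fixtures.json
pqkit simulate --n 500 --seed 7 --out-dir sim/
pqkit fit-reference sim/population.csv --out pop.json
pqkit score sim/population.csv --population pop.json --out scores.csv
```

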