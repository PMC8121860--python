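# mtbottleneck

Stochastic simulation and single-cell statistics for the oxygen-modulated
mitochondrial DNA (mtDNA) genetic bottleneck.

## The problem

Heteroplasmic cells carry a mixture of wild-type and mutant mtDNA; the
mutant fraction *h* of a cell drifts randomly across cell divisions and
through ongoing mtDNA turnover. A transient fall in the per-cell mtDNA
copy number — a genetic bottleneck — amplifies this drift, so sibling
cells end up with very different heteroplasmies even without selection.
During in vitro germ-cell specification under low (3%) oxygen, the copy
number per cell drops ~4–5-fold (≈1240 copies at day 4 to ≈250 at day 6
in a heteroplasmic line) and recovers after the return to high oxygen,
and the across-cell heteroplasmy variance rises accordingly; at 20%
oxygen the copy number and variance are both flat.

This package is aimed at people analysing single-cell heteroplasmy /
copy-number measurements or modelling organelle-genome segregation. It
provides:

- `bottleneck_sim` — a forward simulator: per-molecule linear
  birth–death dynamics (replication rate λ(t) modulated by an oxygen
  schedule, constant degradation μ, optional replication selection s
  against the mutant), with binomial partitioning of nucleoid units
  (mean 1.4 molecules/unit) at each division. It doubles as the
  synthetic-data generator (Beta heteroplasmies, lognormal copy numbers,
  3D spot clouds, zero-inflated count matrices). An exact
  transition-matrix moment oracle verifies the simulator at small copy
  numbers.
- `hetstats` — grouped summaries (mean/SD/median/variance per
  line × protocol × day × gate), the one-sided bootstrap
  variance-increase test (default B = 50,000; p = P(ΔVar* ≤ 0) with the
  add-one convention) with Benjamini–Hochberg control at FDR 0.1,
  copy-number fold changes, and a Mann–Whitney median-shift test for
  selection.
- `polarity` — mitochondrial polarization from 3D spot coordinates:
  octant counts around a cell-centre reference and the entropy index
  H = −Σ pᵢ ln pᵢ (lower = more polarized), with Welch t comparisons.
- `sc_scores` — single-cell expression QC (≥200 genes/cell, ≥3
  cells/gene), 10,000-count normalization + log1p, per-cell gene-list
  scores (OXPHOS, glycolysis, mtDNA replication, autophagy, lysosomal),
  and Wilcoxon rank-sum differential expression with BH correction.
- `io_utils` / `cli` — CSV/MTX readers and writers, YAML run
  configuration, per-stage seed derivation, JSON manifests with
  checksums, and the `mtb` command line
  (`mtb simulate|hetstats|polarity|scores|deg|run`).

## Worked example

Simulate the calibrated bottleneck (5,000 lineages, seed 7) and test for
a variance increase at the reported day-4/day-6 group conditions:

```python
import numpy as np
from mtbottleneck import (
    default_params, simulate_population,
    sample_heteroplasmy, bootstrap_variance_increase_test,
    fold_change, TestConfig,
)

params = default_params(seed=7)           # 1240 -> ~249 -> ~1462 copies
for snap in simulate_population(params, 5000):
    h = snap.heteroplasmy[np.isfinite(snap.heteroplasmy)]
    print(snap.day, round(float(snap.copies.mean()), 1),
          round(float(h.mean()), 3), round(float(np.var(h, ddof=1)), 5))
```

```
D4 1240.0 0.296 0.0
D5 786.0 0.296 0.00039
D6 248.9 0.296 0.00149
D7 1447.3 0.297 0.00289
```

The mean heteroplasmy stays at the initial 0.296 (neutral drift is
mean-preserving) while the across-lineage variance grows monotonically,
fastest through the day-6 copy-number trough.

```python
rng = np.random.default_rng(7)
ref = sample_heteroplasmy(0.296, 0.020, 46, rng=rng)   # day-4 group
alt = sample_heteroplasmy(0.296, 0.041, 58, rng=rng)   # day-6 group
res = bootstrap_variance_increase_test(ref, alt, TestConfig(iterations=50_000, seed=7))
print(res.p_value, round(res.observed_delta, 4))       # 2.0e-05 0.0325
print(fold_change(1119, 319))                          # FoldChange(ratio=3.508, fold=4)
```

The bootstrap rejects the no-segregation null (p ≈ 2 × 10⁻⁵ at the
50,000-iteration floor of 1/(B+1) ≈ 2 × 10⁻⁵), and the day-4/day-6
copy-number means correspond to a ~3.5× (nearest fold: 4×) decrease.

The same stages run from the shell:

```bash
mtb simulate --out out/ --seed 17 --n-cells 1000
mtb hetstats --input out/cells.csv --out out/ --iters 50000 --fdr 0.1 --seed 17
```

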