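# Methods

## The scientific setting

Mammalian cells carry hundreds to thousands of copies of mitochondrial DNA
(mtDNA). When a cell is heteroplasmic — a mixture of wild-type and mutant
molecules — the mutant fraction *h* drifts between daughter cells over
successive divisions. A transient fall in the per-cell copy number (a
*genetic bottleneck*) amplifies this drift: fewer segregating units means
larger random sampling fluctuations, read out experimentally as an increase
in the across-cell variance of *h*. During in vitro germ-cell specification
the copy number per cell falls roughly 4–5-fold under low (3%) oxygen —
from ~1240 copies at day 4 to ~250 at day 6 in the heteroplasmic line —
and recovers to ~1460 by day 7 after the shift back to high oxygen, while
at 20% oxygen the copy number is maintained and heteroplasmy does not
segregate. This package implements (i) a forward stochastic simulator of
that mechanism and (ii) the statistics used to detect its consequences in
single-cell data.

## The intracellular model

Each lineage is a population of discrete molecules evolving by a linear
birth–death process ("relaxed replication": replication and turnover are
uncoupled from the cell cycle):

- wild-type molecules replicate at rate λ(t) and degrade at rate μ
  (per molecule per hour);
- mutant molecules replicate at rate λ(t)·(1 − s); s = 0 is neutral
  drift, s > 0 a replication disadvantage. Selection enters through
  replication rather than degradation — one of several observationally
  equivalent parameterisations, chosen because the oxygen effect is
  localised to replication;
- oxygen tension acts **only** as a multiplier on λ; μ is constant by
  default (autophagy-driven degradation is deliberately not modelled —
  the biology argues against it, and it is out of scope);
- at fixed intervals (default 16 h) the cell divides: molecules are
  grouped into nucleoid units of size 1 or 2 — a Bernoulli mixture with
  mean 1.4 molecules per unit, since fractional unit sizes are not
  physical — and each unit goes to daughter 1 independently with
  probability ½ (or α ≠ ½ in the polarized mode). One daughter, chosen
  uniformly, is followed; allele counts are conserved exactly at every
  division.

Neutral drift makes *h* a martingale: the across-lineage mean is
conserved while the variance grows, fastest when the copy number is low.
Extinct lineages (N = 0) are retained in snapshots with *h* undefined
(NaN) and excluded from variance summaries.

### Calibration

`default_params()` solves the deterministic mean trajectory
E[N(t)] = N₀·e^{(λ−μ)t}·2^{−divisions} for the replication rates that
reproduce the reference day-course of the heteroplasmic line under the
modified protocol — 1240 copies (D4) → 249 (D6, low oxygen) → 1462
(D7, high oxygen) — with μ = 0.02 h⁻¹ (turnover half-life ≈ 35 h, a
plausible constitutive rate) and a 16 h division interval. This yields
λ_base ≈ 0.123 h⁻¹ at 20% O₂ with a ≈ 0.24 multiplier at 3% O₂.
The initial heteroplasmy is h₀ = 0.296, the measured mean of the
heteroplasmic clone. The day-6→7 copy-number recovery is modelled as
replication-driven only; whether reduced degradation also contributes is
left open, and both knobs (λ multiplier, μ) are exposed without
asserting either.

### Integration

The default integrator is vectorised tau-leaping with a 0.05 h step:
births are Poisson with the start-of-step intensity, deaths are binomial
thinning with probability 1 − e^{−μΔt} (which keeps counts non-negative
without clipping). The step introduces a small deterministic bias
(< ~1.5% on the day-7 mean at the default rates); `tau` is configurable
and an exact event-driven Gillespie path (`method="exact"`) is provided
and used for all comparisons against the exact oracle.

### Exact moment oracle

For small populations (n₀ ≤ 20, one molecule per unit) the full
continuous-time Markov chain on states {(n_wt, n_mut) : n_wt + n_mut ≤ 64}
is propagated with sparse `expm_multiply`; divisions apply the exact
two-allele binomial partition kernel. Birth transitions out of the capped
boundary are truncated, so comparisons use subcritical or short-horizon
settings where boundary mass is negligible. Moments are over surviving
lineages. The oracle is an independent route to E[h](t) and Var(h)(t)
against which the Monte-Carlo simulator is tested, never a replacement
for it.

## Synthetic data for the downstream statistics

The simulator module doubles as the data generator for the statistical
stages, calibrated to the study conditions they emulate:

- **Heteroplasmy fractions** — Beta distributions moment-matched to a
  (mean, variance) pair. Defaults follow the reported group statistics: mean
  0.296 with day variances such as 0.020 (D4, n = 46), 0.041 (D6,
  n = 58), 0.036 (D7, n = 45) for the low-oxygen protocol, and 0.017
  (D7, n = 76) for the conventional one. Where a study reports a group
  *median* (26% at D4, 12% at D7 for the somatic gate at 3% O₂), a
  companion sampler solves for the Beta mean whose distribution has that
  median; the variance for those groups is set to 0.02, in the range of
  the neighbouring day groups.
- **Copy numbers** — moment-matched lognormals rounded to integers
  (e.g. mean 1119, SD 495 at D4).
- **Spot clouds** — a mixture of spots uniform in a ball around the
  reference point and spots confined to its all-positive octant; the
  mixture weight ("concentration") interpolates from unpolarized to
  fully polarized.
- **Count matrices** — negative-binomial background genes (gamma–Poisson,
  mean 2, dispersion 1, 1000 genes by default) plus gene-list genes that
  are zero-inflated with a group-specific detection probability. Ground
  truth (group labels, list membership) is retained for recovery tests.

What the generator does **not** emulate: batch/replicate structure,
cell-cycle covariation of copy number, measurement error of the
heteroplasmy assay, dropout correlated with depth, or spatial structure
beyond the single polarized octant. Tests passing on this generator
therefore certify the statistical machinery and the model's internal
consistency, not the full complexity of the real measurements. In
particular, library-size normalization propagates a composition effect
from strongly differential gene sets into background genes when the
background is small; recovery tests use transcriptome-sized backgrounds
(≥ 2000 genes) where this effect is negligible.

## Statistics

- **Group summaries** pool cells across biological replicates within a
  day (published group variances are reported once per day) and use the sample
  (n − 1) variance on the *fraction* scale — reported values 0.015–0.041
  are only consistent with fractions, not percent.
- **Variance-increase test**: nonparametric bootstrap, B = 50,000 by
  default. Each group is resampled with replacement to its own size;
  the statistic is ΔVar* = Var*(later) − Var*(D4) and the one-sided
  p-value is the bootstrap probability that ΔVar* ≤ 0 (equivalently, the
  percentile-CI criterion that the interval for ΔVar excludes 0) with
  the add-one convention p = (1 + #{Δ* ≤ 0})/(B + 1), so p is never
  exactly 0. This is the simplest construction consistent with a
  one-sided bootstrap confidence-interval test; p-values across later
  days are Benjamini–Hochberg adjusted at FDR q = 0.1 within each
  line × protocol × gate stratum (BH itself delegates to statsmodels and
  is cross-checked against a hand-coded step-up in the tests).
- **Median-shift test** (selection signal): no single canonical test exists
  for a reported median shift; the default here is the two-sided Mann–Whitney
  U (exact for small tie-free samples, tie-corrected normal approximation
  otherwise), exposed as a configuration choice.
- **Polarity index**: spots are assigned to the 8 octants around the
  cell-centre reference by the signs of their coordinate offsets; an
  offset of exactly 0 goes to the positive side (deterministic,
  reproducible without jitter). The index is the Shannon entropy
  H = −Σ pᵢ ln pᵢ of the octant proportions, in nats (the log base being
  unstated upstream, natural log is used and the normalized H/ln 8 is
  reported alongside so the base is immaterial); **lower** H means more
  polarized. Group comparisons use Welch's t-test. Only the statistic's
  definition — not any published axis magnitude — is asserted.
- **Single-cell scores**: QC removes cells with < 200 detected genes,
  then genes detected in < 3 cells (cells first, matching the stated
  order; the alternative order is exposed as a flag because it can change
  the result); counts are scaled to 10,000 per cell and ln(1 + x)
  transformed. "Expressed" is count > 0 — consistent with how detection
  is used in QC. The per-cell list score divides the number of expressed
  list genes by the number of list genes present in the matrix, giving
  [0, 1]; raw counts are always retained since the upstream normalisation
  is not fully specified. Gene symbols match case-insensitively (mouse
  capitalisation varies across curated lists) with a warning on
  collisions. DEG testing is a per-gene two-sided Wilcoxon rank-sum on
  the log-normalized values with BH across genes at 0.05; 'up' direction
  refers to the alphabetically first group label.
- **Gene lists**: the packaged lists are curated stand-ins built from
  canonical mouse pathway members at the stated sizes (85 glycolytic,
  96 OXPHOS, 18 mtDNA-replication, plus autophagy and lysosomal); they
  are plain text, one symbol per line, and any curated list of the same
  format is a drop-in replacement. The GO anchors GO:0006096 (glycolytic
  process) and GO:0006119 (oxidative phosphorylation) are the provenance
  for the two metabolic lists.

## Reproducibility

One top-level seed is split per stage by SHA-256 hashing of the stage
name (seeds stay below 2³¹), so any stage can be re-run in isolation;
identical (config, seed) pairs reproduce bit-identical outputs, recorded
as SHA-256 checksums in the JSON run manifest.

## Problem sizes

Monte-Carlo checks use 10⁴ lineages for population-level properties,
10⁵ replicates for partition-law comparisons, and a few hundred trials
for test-calibration (type-I error, power) properties; bootstrap
iteration counts in simulations are reduced from the 50,000 production
default to 499–2000, which leaves the p-value resolution far finer than
the thresholds being checked. These sizes give Monte-Carlo standard
errors comfortably below the assertion tolerances (all stochastic
assertions are stated in units of the measured SE).

## Known limitations

- The birth–death + binomial-partition model is the minimal mechanism
  consistent with relaxed replication and sub-compartmentalised
  segregation; it does not model nucleoid spatial dynamics, replication
  bursts, or cell-to-cell rate heterogeneity.
- No fitting of λ, μ, s to data is provided (forward simulation only).
- The division count between day 4 and day 6 is not known; the division
  interval is a free configuration parameter (default 16 h → 3 divisions
  in the low-oxygen window).
- The tau-leap integrator trades a < ~1.5% mean bias for a ~100× speedup
  over the exact path at realistic copy numbers.
- The moment oracle truncates the state space at 64 molecules and is
  meaningful only where boundary mass is negligible.
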