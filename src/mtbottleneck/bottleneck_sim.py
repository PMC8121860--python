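"""Stochastic simulator of intracellular mtDNA population dynamics.

The model is a linear birth-death process per mtDNA molecule (relaxed
replication: molecules replicate and degrade independently of the cell
cycle) combined with binomial partitioning of segregating units at cell
division.  Oxygen tension enters as a multiplier on the replication rate
only; degradation is held constant by default.  A transient reduction in
the per-cell copy number — the genetic bottleneck — amplifies random
drift of the heteroplasmy fraction h between lineages without moving its
mean (neutral drift is a martingale in h).

The module doubles as the synthetic-data generator for the downstream
statistics: per-cell heteroplasmy fractions (Beta), copy numbers
(lognormal), 3D mitochondrial spot clouds and single-cell count matrices
with condition-dependent gene-list expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimParams",
    "CellState",
    "Snapshot",
    "default_params",
    "simulate_population",
    "partition_molecules",
    "moment_oracle",
    "sample_heteroplasmy",
    "sample_copy_numbers",
    "sample_spot_cloud",
    "sample_expression",
    "SpotCloud",
    "GeneList",
]

DAY_LABELS = ("D4", "D5", "D6", "D7")
HOURS_PER_DAY = 24.0

# Reference per-cell mean copy numbers for the heteroplasmic line under the
# low-oxygen (modified) differentiation protocol: ~1240 at D4, trough ~249
# at D6, recovery ~1462 at D7 after the shift back to high oxygen.
DEFAULT_DAY_MEANS = {"D4": 1240.0, "D6": 249.0, "D7": 1462.0}
DEFAULT_H0 = 0.296
DEFAULT_NUCLEOID_SIZE = 1.4


class ConfigurationError(ValueError):
    """Invalid simulator configuration (schedule, rates, partition mode)."""


def day_to_hours(day: str) -> float:
    """Hours since the D4 harvest (t = 0 at D4)."""
    try:
        idx = int(day[1:]) - 4
    except (ValueError, IndexError):
        raise ConfigurationError(f"unrecognised day label: {day!r}")
    if day[0] != "D" or idx < 0:
        raise ConfigurationError(f"unrecognised day label: {day!r}")
    return HOURS_PER_DAY * idx


@dataclass(frozen=True)
class SimParams:
    """Parameters of the birth-death-partition model.

    Rates are per molecule per hour.  ``oxygen_schedule`` maps a day label
    to the multiplier applied to ``lambda_base`` during the 24 h window
    starting at that day (D4 covers [0, 24) h, D5 [24, 48) h, ...).
    The mutant allele replicates at rate ``lambda * (1 - s)``; s = 0 is
    neutral drift.  Molecules segregate at division in nucleoid units of
    mean size ``nucleoid_size`` (sizes 1 or 2, Bernoulli mixture).
    """

    lambda_base: float
    mu: float
    oxygen_schedule: Mapping[str, float]
    s: float = 0.0
    division_interval_hours: float | None = 16.0
    nucleoid_size: float = DEFAULT_NUCLEOID_SIZE
    n0: int = 1240
    h0: float = DEFAULT_H0
    partition_mode: str = "symmetric-binomial"
    alpha: float = 0.5
    tau: float = 0.05
    method: str = "tau"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.lambda_base < 0 or self.mu < 0:
            raise ConfigurationError("rates must be non-negative")
        if not 0.0 <= self.h0 <= 1.0:
            raise ConfigurationError("h0 must lie in [0, 1]")
        if self.nucleoid_size < 1.0:
            raise ConfigurationError("nucleoid_size must be >= 1")
        if self.nucleoid_size > 2.0:
            raise ConfigurationError(
                "nucleoid_size > 2 not supported by the size-1/2 Bernoulli mixture"
            )
        if self.n0 < 1:
            raise ConfigurationError("n0 must be >= 1")
        if not -1.0 <= self.s < 1.0:
            raise ConfigurationError("selection coefficient s must lie in [-1, 1)")
        if self.partition_mode not in ("symmetric-binomial", "polarized"):
            raise ConfigurationError(f"unknown partition_mode {self.partition_mode!r}")
        if self.partition_mode == "polarized" and not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("polarized alpha must lie in (0, 1)")
        if self.method not in ("tau", "exact"):
            raise ConfigurationError(f"unknown integration method {self.method!r}")
        if self.tau <= 0:
            raise ConfigurationError("tau step must be positive")

    def lambda_multiplier(self, t: float) -> float:
        idx = min(int(t // HOURS_PER_DAY), len(DAY_LABELS) - 1)
        day = f"D{4 + idx}"
        try:
            return float(self.oxygen_schedule[day])
        except KeyError:
            raise ConfigurationError(
                f"oxygen_schedule missing day {day} needed at t = {t:.1f} h"
            )


@dataclass
class CellState:
    """Per-cell molecule counts; heteroplasmy h = n_mut / (n_wt + n_mut)."""

    n_wt: int
    n_mut: int
    generation: int = 0
    lineage_id: int = 0
    t: float = 0.0

    @property
    def total(self) -> int:
        return self.n_wt + self.n_mut

    @property
    def h(self) -> float:
        if self.total == 0:
            return float("nan")
        return self.n_mut / self.total


@dataclass
class Snapshot:
    """All lineages observed at one harvest day, with provenance."""

    day: str
    cells: list[CellState]
    params: SimParams | None = None
    seed: int | None = None

    @property
    def heteroplasmy(self) -> np.ndarray:
        return np.array([c.h for c in self.cells], dtype=float)

    @property
    def copies(self) -> np.ndarray:
        return np.array([c.total for c in self.cells], dtype=int)

    def to_frame(
        self,
        line: str = "ND1",
        protocol: str = "modified-3pct",
        gate: str = "BV+",
    ) -> pd.DataFrame:
        """Tidy per-cell table matching the CellRecord CSV schema."""
        return pd.DataFrame(
            {
                "cell_id": [
                    f"{self.day}_L{c.lineage_id:05d}" for c in self.cells
                ],
                "line": line,
                "protocol": protocol,
                "day": self.day,
                "gate": gate,
                "heteroplasmy": self.heteroplasmy,
                "copies": self.copies,
                "lineage_id": [c.lineage_id for c in self.cells],
                "seed": self.seed,
            }
        )


def default_params(
    seed: int | None = None,
    mu: float = 0.02,
    division_interval_hours: float = 16.0,
    day_means: Mapping[str, float] | None = None,
    **overrides,
) -> SimParams:
    """Simulator calibration reproducing the reference mean copy-number course.

    Solves the deterministic mean trajectory
    ``E[N(t)] = n0 * exp((lambda - mu) t) * 2^-divisions`` for the replication
    rates that carry the heteroplasmic line from 1240 copies at D4 through the
    ~250-copy trough at D6 (low oxygen) to ~1460 at D7 (high oxygen), with a
    fixed 16 h division interval.  ``lambda_base`` is the high-oxygen rate;
    low oxygen enters as a multiplier < 1.
    """
    if day_means is None:
        day_means = DEFAULT_DAY_MEANS
    n0 = day_means["D4"]
    trough = day_means["D6"]
    recovery = day_means["D7"]
    t_d6 = day_to_hours("D6")
    t_d7 = day_to_hours("D7")
    ndiv_low = int(t_d6 / division_interval_hours)  # divisions in (0, 48]
    ndiv_high = int(t_d7 / division_interval_hours) - ndiv_low
    # net growth rates on each oxygen phase
    g_low = (np.log(trough / n0) + ndiv_low * np.log(2.0)) / t_d6
    g_high = (np.log(recovery / trough) + ndiv_high * np.log(2.0)) / (t_d7 - t_d6)
    lambda_base = g_high + mu
    m_low = (g_low + mu) / lambda_base
    params = dict(
        lambda_base=lambda_base,
        mu=mu,
        oxygen_schedule={"D4": m_low, "D5": m_low, "D6": 1.0, "D7": 1.0},
        division_interval_hours=division_interval_hours,
        n0=int(round(n0)),
        h0=DEFAULT_H0,
        seed=seed,
    )
    params.update(overrides)
    return SimParams(**params)


# ---------------------------------------------------------------------------
# partitioning


def _unit_sizes(n: int, p2: float, rng: np.random.Generator) -> np.ndarray:
    """Nucleoid unit sizes covering n molecules: 1 or 2 with P(2) = p2."""
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    if p2 <= 0.0:
        return np.ones(n, dtype=np.int64)
    sizes = 1 + (rng.random(n) < p2).astype(np.int64)
    cum = np.cumsum(sizes)
    k = int(np.searchsorted(cum, n))
    sizes = sizes[: k + 1].copy()
    sizes[-1] -= int(cum[k]) - n
    return sizes


def partition_molecules(
    state: CellState,
    mode: str = "symmetric-binomial",
    nucleoid_size: float = DEFAULT_NUCLEOID_SIZE,
    alpha: float = 0.5,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CellState, CellState]:
    """Split a mother cell's molecules between two daughters at division.

    Molecules are grouped into nucleoid units of size 1 or 2 (mean
    ``nucleoid_size``); each unit goes to daughter 1 independently with
    probability 1/2 (symmetric-binomial) or ``alpha`` (polarized).  Allele
    counts are conserved exactly: the daughters' (n_wt, n_mut) sum to the
    mother's.
    """
    if state.total <= 0:
        raise ValueError("cannot partition an empty cell")
    if mode not in ("symmetric-binomial", "polarized"):
        raise ConfigurationError(f"unknown partition mode {mode!r}")
    p1 = 0.5 if mode == "symmetric-binomial" else float(alpha)
    if not 0.0 < p1 < 1.0:
        raise ConfigurationError("alpha must lie strictly in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)

    w, m = state.n_wt, state.n_mut
    if nucleoid_size == 1.0:
        w1 = int(rng.binomial(w, p1))
        m1 = int(rng.binomial(m, p1))
    else:
        p2 = nucleoid_size - 1.0
        alleles = np.zeros(w + m, dtype=np.int64)
        alleles[w:] = 1
        rng.shuffle(alleles)
        sizes = _unit_sizes(w + m, p2, rng)
        bounds = np.concatenate(([0], np.cumsum(sizes)[:-1]))
        unit_mut = np.add.reduceat(alleles, bounds)
        to_d1 = rng.random(len(sizes)) < p1
        m1 = int(unit_mut[to_d1].sum())
        n1 = int(sizes[to_d1].sum())
        w1 = n1 - m1
    d1 = CellState(w1, m1, state.generation + 1, state.lineage_id, state.t)
    d2 = CellState(w - w1, m - m1, state.generation + 1, state.lineage_id, state.t)
    return d1, d2


# ---------------------------------------------------------------------------
# population simulation


def _tau_leap_segment(
    w: np.ndarray,
    m: np.ndarray,
    lam: float,
    lam_mut: float,
    mu: float,
    duration: float,
    tau: float,
    rng: np.random.Generator,
) -> None:
    """Advance all lineages through `duration` hours in place (tau-leaping).

    Births are Poisson with the current per-step intensity; deaths are
    binomial thinning with probability 1 - exp(-mu * dt), which keeps counts
    non-negative without clipping.
    """
    t = 0.0
    while t < duration - 1e-12:
        dt = min(tau, duration - t)
        p_die = -np.expm1(-mu * dt)
        if lam > 0:
            w += rng.poisson(lam * dt * w)
        if lam_mut > 0:
            m += rng.poisson(lam_mut * dt * m)
        if mu > 0:
            w -= rng.binomial(w, p_die)
            m -= rng.binomial(m, p_die)
        t += dt


def _gillespie_segment(
    w: np.ndarray,
    m: np.ndarray,
    lam: float,
    lam_mut: float,
    mu: float,
    duration: float,
    rng: np.random.Generator,
) -> None:
    """Exact event-driven advance, per lineage (suitable for small counts)."""
    for i in range(len(w)):
        wi, mi = int(w[i]), int(m[i])
        t = 0.0
        while True:
            rates = (lam * wi, lam_mut * mi, mu * wi, mu * mi)
            total = sum(rates)
            if total <= 0.0:
                break
            t += rng.exponential(1.0 / total)
            if t >= duration:
                break
            u = rng.random() * total
            if u < rates[0]:
                wi += 1
            elif u < rates[0] + rates[1]:
                mi += 1
            elif u < rates[0] + rates[1] + rates[2]:
                wi -= 1
            else:
                mi -= 1
        w[i], m[i] = wi, mi


def simulate_population(
    params: SimParams,
    n_cells: int,
    days: Sequence[str] = DAY_LABELS,
) -> list[Snapshot]:
    """Simulate independent lineages and harvest (h, N) snapshots at days.

    Each lineage starts at (n0, h0) at D4 and evolves by the birth-death
    process with the day-dependent replication multiplier; at every division
    time the mother is partitioned and one daughter is followed (keeping the
    number of tracked lineages fixed).  Extinct lineages (N = 0) are retained
    in snapshots with h = NaN.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    days = sorted(days, key=day_to_hours)
    rng = np.random.default_rng(params.seed)

    m0 = int(round(params.n0 * params.h0))
    w = np.full(n_cells, params.n0 - m0, dtype=np.int64)
    m = np.full(n_cells, m0, dtype=np.int64)
    generation = 0

    # checkpoints: day boundaries (multiplier changes), divisions, harvests
    horizon = day_to_hours(days[-1])
    times: set[float] = {day_to_hours(d) for d in days}
    times.update(np.arange(0.0, horizon + 1e-9, HOURS_PER_DAY))
    if params.division_interval_hours:
        k = np.arange(1, int(horizon / params.division_interval_hours) + 1)
        times.update(k * params.division_interval_hours)
    schedule = sorted(t for t in times if 0.0 < t <= horizon + 1e-9)

    harvest_at = {day_to_hours(d): d for d in days}
    snapshots: list[Snapshot] = []

    def harvest(day: str, t_now: float) -> None:
        cells = [
            CellState(int(w[i]), int(m[i]), generation, i, t_now)
            for i in range(n_cells)
        ]
        snapshots.append(Snapshot(day, cells, params, params.seed))

    t_now = 0.0
    if 0.0 in harvest_at:
        harvest(harvest_at[0.0], 0.0)
    for t_next in schedule:
        lam = params.lambda_base * params.lambda_multiplier(t_now)
        lam_mut = lam * (1.0 - params.s)
        duration = t_next - t_now
        if duration > 1e-12:
            if params.method == "exact":
                _gillespie_segment(w, m, lam, lam_mut, params.mu, duration, rng)
            else:
                _tau_leap_segment(
                    w, m, lam, lam_mut, params.mu, duration, params.tau, rng
                )
        t_now = t_next
        if params.division_interval_hours and _is_multiple(
            t_now, params.division_interval_hours
        ):
            _divide_all(w, m, params, rng)
            generation += 1
        if t_now in harvest_at:
            harvest(harvest_at[t_now], t_now)
    n_extinct = int(np.sum(w + m == 0))
    if n_extinct:
        warnings.warn(f"{n_extinct} of {n_cells} lineages went extinct", stacklevel=2)
    return snapshots


def _is_multiple(t: float, interval: float) -> bool:
    ratio = t / interval
    return abs(ratio - round(ratio)) < 1e-9


def _divide_all(
    w: np.ndarray, m: np.ndarray, params: SimParams, rng: np.random.Generator
) -> None:
    """Partition every lineage and follow one daughter, in place."""
    p1 = 0.5 if params.partition_mode == "symmetric-binomial" else params.alpha
    if params.nucleoid_size == 1.0:
        w1 = rng.binomial(w, p1)
        m1 = rng.binomial(m, p1)
    else:
        w1 = np.empty_like(w)
        m1 = np.empty_like(m)
        p2 = params.nucleoid_size - 1.0
        for i in range(len(w)):
            n = int(w[i] + m[i])
            if n == 0:
                w1[i] = m1[i] = 0
                continue
            alleles = np.zeros(n, dtype=np.int64)
            alleles[w[i]:] = 1
            rng.shuffle(alleles)
            sizes = _unit_sizes(n, p2, rng)
            bounds = np.concatenate(([0], np.cumsum(sizes)[:-1]))
            unit_mut = np.add.reduceat(alleles, bounds)
            to_d1 = rng.random(len(sizes)) < p1
            m1[i] = unit_mut[to_d1].sum()
            w1[i] = sizes[to_d1].sum() - m1[i]
    # follow daughter 1 or daughter 2 with equal probability
    take_d1 = rng.random(len(w)) < 0.5
    w[:] = np.where(take_d1, w1, w - w1)
    m[:] = np.where(take_d1, m1, m - m1)


# ---------------------------------------------------------------------------
# exact moment oracle (small copy numbers)


def moment_oracle(
    params: SimParams,
    horizon_hours: float,
    eval_times: Sequence[float] | None = None,
    cap: int = 64,
) -> pd.DataFrame:
    """Exact E[h] and Var(h) trajectory of the birth-death(+division) chain.

    Enumerates all states (n_wt, n_mut) with n_wt + n_mut <= cap, builds the
    continuous-time generator and propagates the full state distribution with
    ``scipy.sparse.linalg.expm_multiply``; divisions apply the exact two-allele
    binomial partition kernel.  Moments are over surviving lineages
    (total > 0).  Requires nucleoid_size = 1 and a starting copy number small
    enough that truncation at the cap is negligible.
    """
    from scipy import sparse
    from scipy.sparse.linalg import expm_multiply
    from scipy.stats import binom as binom_dist

    if params.nucleoid_size != 1.0:
        raise ConfigurationError("moment_oracle requires nucleoid_size = 1")
    if params.n0 > 20:
        raise ConfigurationError(
            "moment_oracle supports n0 <= 20; use a smaller initial copy number"
        )
    if params.n0 > cap:
        raise ConfigurationError("n0 exceeds the state-space cap")

    states = [(i, j) for tot in range(cap + 1) for i in range(tot + 1) for j in [tot - i]]
    index = {st: k for k, st in enumerate(states)}
    n_states = len(states)

    def build_generator(lam: float) -> sparse.csr_matrix:
        lam_mut = lam * (1.0 - params.s)
        rows, cols, vals = [], [], []
        for (i, j), k in index.items():
            out = 0.0
            if i + j < cap:
                if i > 0 and lam > 0:
                    r = lam * i
                    rows.append(index[(i + 1, j)]); cols.append(k); vals.append(r)
                    out += r
                if j > 0 and lam_mut > 0:
                    r = lam_mut * j
                    rows.append(index[(i, j + 1)]); cols.append(k); vals.append(r)
                    out += r
            if i > 0 and params.mu > 0:
                r = params.mu * i
                rows.append(index[(i - 1, j)]); cols.append(k); vals.append(r)
                out += r
            if j > 0 and params.mu > 0:
                r = params.mu * j
                rows.append(index[(i, j - 1)]); cols.append(k); vals.append(r)
                out += r
            rows.append(k); cols.append(k); vals.append(-out)
        return sparse.csr_matrix((vals, (rows, cols)), shape=(n_states, n_states))

    def division_kernel() -> sparse.csr_matrix:
        rows, cols, vals = [], [], []
        for (i, j), k in index.items():
            pw = binom_dist.pmf(np.arange(i + 1), i, 0.5)
            pm = binom_dist.pmf(np.arange(j + 1), j, 0.5)
            for a, pa in enumerate(pw):
                for b, pb in enumerate(pm):
                    rows.append(index[(a, b)]); cols.append(k); vals.append(pa * pb)
        return sparse.csr_matrix((vals, (rows, cols)), shape=(n_states, n_states))

    m0 = int(round(params.n0 * params.h0))
    dist = np.zeros(n_states)
    dist[index[(params.n0 - m0, m0)]] = 1.0

    h = np.array([j / (i + j) if i + j > 0 else np.nan for i, j in states])
    alive = np.array([i + j > 0 for i, j in states])

    def moments(d: np.ndarray) -> tuple[float, float, float]:
        p_alive = float(d[alive].sum())
        if p_alive <= 0:
            return np.nan, np.nan, 0.0
        da = d[alive] / p_alive
        eh = float(np.dot(da, h[alive]))
        vh = float(np.dot(da, h[alive] ** 2) - eh**2)
        return eh, max(vh, 0.0), p_alive

    events: list[tuple[float, str]] = [(0.0, "eval")]
    if eval_times is None:
        eval_times = [horizon_hours]
    events.extend((float(t), "eval") for t in eval_times if 0.0 < t <= horizon_hours)
    if params.division_interval_hours:
        k = np.arange(1, int(horizon_hours / params.division_interval_hours) + 1)
        events.extend((float(t), "divide") for t in k * params.division_interval_hours)
    boundaries = np.arange(
        HOURS_PER_DAY, horizon_hours + 1e-9, HOURS_PER_DAY
    )
    events.extend((float(t), "boundary") for t in boundaries)
    # divisions before evals at equal times (snapshot taken after division)
    order = {"boundary": 0, "divide": 1, "eval": 2}
    events.sort(key=lambda e: (e[0], order[e[1]]))

    D = division_kernel() if params.division_interval_hours else None
    rows_out = []
    t_now = 0.0
    Q = build_generator(params.lambda_base * params.lambda_multiplier(0.0))
    for t_ev, kind in events:
        if t_ev - t_now > 1e-12:
            dist = expm_multiply(Q * (t_ev - t_now), dist)
            dist = np.clip(dist, 0.0, None)
            dist /= dist.sum()
            t_now = t_ev
        if kind == "boundary":
            Q = build_generator(params.lambda_base * params.lambda_multiplier(t_ev))
        elif kind == "divide":
            dist = D @ dist
        else:
            eh, vh, pa = moments(dist)
            rows_out.append(
                {"t": t_ev, "mean_h": eh, "var_h": vh, "p_survive": pa}
            )
    return pd.DataFrame(rows_out)


# ---------------------------------------------------------------------------
# synthetic-data fixtures for downstream stages


def sample_heteroplasmy(
    mean: float,
    variance: float,
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-cell heteroplasmy fractions from a moment-matched Beta distribution."""
    if not 0.0 < mean < 1.0:
        raise ValueError("mean must lie strictly in (0, 1)")
    limit = mean * (1.0 - mean)
    if not 0.0 < variance < limit:
        raise ValueError(
            f"variance must lie in (0, {limit:.4f}) for mean {mean}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    nu = limit / variance - 1.0
    return rng.beta(mean * nu, (1.0 - mean) * nu, size=n)


def sample_copy_numbers(
    mean: float,
    sd: float,
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-cell mtDNA copy numbers: moment-matched lognormal, integer-rounded."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu_log = np.log(mean) - sigma2 / 2.0
    draws = rng.lognormal(mu_log, np.sqrt(sigma2), size=n)
    return np.rint(draws).astype(np.int64)


def sample_heteroplasmy_by_median(
    median: float,
    variance: float,
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Beta heteroplasmy draws whose population median hits a target.

    Useful when a study reports group medians rather than means: solves for
    the Beta mean whose (mean, variance)-matched distribution has the given
    median, then samples from it.
    """
    from scipy.optimize import brentq
    from scipy.stats import beta as beta_dist

    if not 0.0 < median < 1.0:
        raise ValueError("median must lie strictly in (0, 1)")

    def median_gap(mean: float) -> float:
        nu = mean * (1.0 - mean) / variance - 1.0
        return beta_dist.ppf(0.5, mean * nu, (1.0 - mean) * nu) - median

    # the Beta mean bracketing the target median; variance feasibility bounds
    lo = 0.5 * (1.0 - np.sqrt(1.0 - 4.0 * variance)) + 1e-6
    hi = 1.0 - lo
    mean = brentq(median_gap, max(lo, median / 2), min(hi, (1 + median) / 2))
    return sample_heteroplasmy(mean, variance, n, seed=seed, rng=rng)


@dataclass
class SpotCloud:
    """3D mitochondrial spot coordinates (µm) with a cell-centre reference."""

    cell_id: str
    points: np.ndarray  # (n, 3)
    reference: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.reference = np.asarray(self.reference, dtype=float).reshape(3)
        if len(self.points) < 1:
            raise ValueError("a spot cloud needs at least one point")


def sample_spot_cloud(
    n_spots: int,
    concentration: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    radius: float = 5.0,
    cell_id: str = "cell",
) -> SpotCloud:
    """Synthetic spot cloud interpolating uniform -> fully polarized.

    With probability ``1 - concentration`` a spot is uniform in a ball of the
    given radius around the reference (origin); with probability
    ``concentration`` it is uniform over the all-positive octant of that ball.
    concentration = 0 reproduces an unpolarized cell, 1 puts every spot in a
    single octant.
    """
    if n_spots < 1:
        raise ValueError("n_spots must be >= 1")
    if not 0.0 <= concentration <= 1.0:
        raise ValueError("concentration must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    direction = rng.normal(size=(n_spots, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    r = radius * rng.random(n_spots) ** (1.0 / 3.0)
    pts = direction * r[:, None]
    polar = rng.random(n_spots) < concentration
    pts[polar] = np.abs(pts[polar])
    return SpotCloud(cell_id=cell_id, points=pts, reference=np.zeros(3))


@dataclass(frozen=True)
class GeneList:
    """Named list of gene symbols used for per-cell expression scores."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene list {self.name!r} is empty")
        if len(set(g.lower() for g in self.genes)) != len(self.genes):
            raise ValueError(f"gene list {self.name!r} has duplicate symbols")

    def __len__(self) -> int:
        return len(self.genes)


def sample_expression(
    design: Mapping[str, Mapping],
    gene_lists: Sequence[GeneList],
    seed: int | None = None,
    n_background: int = 1000,
    background_mean: float = 2.0,
    background_dispersion: float = 1.0,
    expressed_mean: float = 2.0,
):
    """Synthetic cells x genes count matrix with condition-dependent list genes.

    ``design`` maps a group name to ``{"n_cells": int, "effects": {list: p}}``
    where p is the probability that a list gene is detected (count > 0) in a
    cell of that group.  Background genes are negative-binomial; list genes
    are zero-inflated (Bernoulli(p) gate times 1 + Poisson).  Ground-truth
    group labels and per-gene list membership are kept in ``obs`` / ``var``.
    Returns an :class:`anndata.AnnData` of integer counts.
    """
    import anndata as ad

    rng = np.random.default_rng(seed)
    list_genes: list[str] = []
    gene_to_list: dict[str, str] = {}
    for gl in gene_lists:
        for g in gl.genes:
            if g not in gene_to_list:
                gene_to_list[g] = gl.name
                list_genes.append(g)
    bg_genes = [f"Bg{i:04d}" for i in range(n_background)]
    genes = list_genes + bg_genes

    groups, cells, blocks = [], [], []
    for group, spec_d in design.items():
        n_cells = int(spec_d["n_cells"])
        effects = dict(spec_d.get("effects", {}))
        # negative binomial via gamma-Poisson mixture
        lam = rng.gamma(
            background_dispersion,
            background_mean / background_dispersion,
            size=(n_cells, n_background),
        )
        bg = rng.poisson(lam)
        lst = np.zeros((n_cells, len(list_genes)), dtype=np.int64)
        for j, g in enumerate(list_genes):
            p = float(effects.get(gene_to_list[g], 0.5))
            gate = rng.random(n_cells) < p
            lst[gate, j] = 1 + rng.poisson(expressed_mean, size=int(gate.sum()))
        blocks.append(np.hstack([lst, bg]))
        groups.extend([group] * n_cells)
        cells.extend(f"{group}_c{i:04d}" for i in range(n_cells))

    X = np.vstack(blocks).astype(np.int64)
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame({"group": pd.Categorical(groups)}, index=cells),
        var=pd.DataFrame(
            {"gene_list": [gene_to_list.get(g, "") for g in genes]}, index=genes
        ),
    )
    adata.uns["design"] = {k: dict(v) for k, v in design.items()}
    return adata
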