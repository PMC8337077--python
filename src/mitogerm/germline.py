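"""Two-tier model of mitochondrial heteroplasmy dynamics in the mammalian female germline.

The female germline is modeled from zygote to the next generation of mature
oocytes.  A zygote carries an extreme ploidy of mtDNA (M0 = 2**19 copies in
human), of which a fraction ``m0`` are deleterious mutants.  Development is a
fixed schedule of division phases:

1. **Cleavage** -- 12 cell divisions without mtDNA replication; copies
   segregate binomially, so per-cell copy number halves on average each
   division (down to a mean of 128 per cell).
2. **PGC specification** -- 32 cells are chosen uniformly at random as
   primordial germ cells; an optional bottleneck adds ``b`` extra segregating
   divisions without replication (mean copies 128 * 0.5**b).
3. **Proliferation** -- 18 divisions with replication.  Each wildtype copy is
   replicated and the new copy mutates with genome-wide probability
   U = g * mu; mutants breed true (no back mutation).  Copy number is held
   constant in expectation.
4. **Cull** -- the ~8.4e6 oogonia are reduced 8:1 to primary oocytes, either
   uniformly at random, by cell-fitness-weighted survival (follicular
   atresia), or by organizing 8-cell germline cysts whose members each donate
   a fraction ``f`` of their mitochondria -- sampled with weights p_wt/p_mut
   -- to the Balbiani body of a single primary oocyte (cytoplasmic transfer).
5. **Maturation** -- mtDNA doubles (with mutation) each round until M0 is
   restored: 12 rounds in the base model, 12+b with a bottleneck, 10 after
   cyst pooling (the oocyte starts fourfold richer).
6. **Individual selection** (bottleneck model only) -- prospective zygotes
   are weighted by the concave fitness 1 - (m/M)**5.

Two tiers share this schedule.  The *stochastic* tier is an agent-style
simulator of integer copy counts per cell, used for single-generation
summaries (the change in load, delta_m).  The *deterministic* tier propagates
a probability vector over mutant-copy number through explicit transition
operators (hypergeometric segregation, binomial replication-mutation,
noncentral-hypergeometric cytoplasmic transfer, multiplicative selection),
iterates generations to mutation-selection equilibrium under a
Kullback-Leibler stopping rule, and scores parameter combinations against
the clinical prevalence of mitochondrial carriers (~1/200) and disease
(~1/5000) with a two-binomial log-likelihood.

Sections below follow the order in which the method runs: configuration and
parameters; shared primitives; the stochastic simulator; the deterministic
evolutionary model; clinical likelihood and grid scans; reporting.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import sparse
from scipy.special import gammaln

__all__ = [
    "HUMAN_GENOME_SIZE_BP",
    "DEFAULT_DETECTION_THRESHOLD",
    "DEFAULT_DISEASE_THRESHOLD",
    "GermlineParams",
    "SelectionSpec",
    "MutationRateEstimate",
    "ClinicalModel",
    "ScenarioConfig",
    "ConvergenceError",
    "genome_wide_rate",
    "per_division_rate",
    "individual_fitness",
    "cell_fitness",
    "replicate_and_mutate_counts",
    "segregation_variance",
    "weighted_sample_indices",
    "wallenius_pmf",
    "CellPopulation",
    "GenerationSummary",
    "zygote",
    "cleavage_divide",
    "specify_pgcs",
    "apply_bottleneck",
    "proliferate",
    "cull_random",
    "cull_by_cell_fitness",
    "cyst_transfer",
    "maturation_rounds",
    "mature_oocytes",
    "select_individuals",
    "run_generation",
    "simulate_delta_m",
    "LoadDistribution",
    "segregation_operator",
    "proliferation_operator",
    "maturation_operator",
    "selection_update",
    "transfer_contribution_kernel",
    "transfer_operator",
    "clinical_fractions",
    "log_likelihood",
    "GenerationOperator",
    "EquilibriumResult",
    "iterate_to_equilibrium",
    "total_variation",
    "LikelihoodSurface",
    "scan_grid",
    "make_fixture",
    "load_config",
    "save_config",
    "report_tables",
    "write_manifest",
]

logger = logging.getLogger("mitogerm")

# ---------------------------------------------------------------------------
# Configuration constants
# ---------------------------------------------------------------------------

#: Human mitochondrial genome size in base pairs.
HUMAN_GENOME_SIZE_BP = 16_569

#: Heteroplasmy fraction above which a mutation is clinically detectable.
DEFAULT_DETECTION_THRESHOLD = 0.02
#: Heteroplasmy fraction above which mitochondrial disease manifests.
DEFAULT_DISEASE_THRESHOLD = 0.60

# Deterministic-tier numerical controls.  Kernel entries smaller than
# _ROW_TRUNC of a source state's row mass are dropped and the row is
# renormalized; matrices with M <= _EXACT_MAX_M are built exactly (full
# rows), which the banded path is tested against.
_ROW_TRUNC = 1e-16
_EXACT_MAX_M = 512
# half-width of banded kernels, in standard deviations; exp(-9**2/2) ~ 2.6e-18
_BAND_SIGMAS = 9.0
_BAND_PAD = 12
# probability floor used when evaluating KL divergence against states that
# fell below the truncation threshold in the previous iterate
_KL_FLOOR = 1e-30


class ConvergenceError(RuntimeError):
    """Equilibrium iteration exceeded ``max_gen`` without meeting the KL rule."""


# ---------------------------------------------------------------------------
# Parameters and domain types
# ---------------------------------------------------------------------------


def _is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


@dataclass(frozen=True)
class GermlineParams:
    """Constants of the germline developmental schedule.

    Defaults are the human scenario: a zygote with ``M0 = 2**19 = 524,288``
    mtDNA copies, 12 cleavage divisions, 32 PGCs proliferating for 18
    divisions to ``Nmax = 8,388,608`` oogonia, culled 8:1 to 1,048,576
    primary oocytes.

    Parameters
    ----------
    M0 : mtDNA copies in the zygote / mature oocyte.
    g : mitochondrial genome size (bp).
    mu : mutation probability per bp per replication.
    m0_frac : initial mutation load, as a fraction of ``M0``.
    n_pgc : number of primordial germ cells specified after cleavage.
    n_cleavage : cleavage divisions before PGC specification.
    n_prolif : proliferation divisions of the PGCs.
    b : extra bottleneck divisions without replication (>= 0).
    """

    M0: int = 2**19
    g: int = HUMAN_GENOME_SIZE_BP
    mu: float = 1e-8
    m0_frac: float = 0.0
    n_pgc: int = 32
    n_cleavage: int = 12
    n_prolif: int = 18
    b: int = 0

    def __post_init__(self) -> None:
        if self.M0 < 1:
            raise ValueError("M0 must be a positive count")
        if self.g <= 0:
            raise ValueError("genome size g must be positive")
        if not 0.0 <= self.m0_frac <= 1.0:
            raise ValueError("m0_frac must lie in [0, 1]")
        if self.n_pgc < 1 or self.n_cleavage < 0 or self.b < 0:
            raise ValueError("counts must be non-negative (n_pgc >= 1)")
        if self.n_prolif < 3:
            raise ValueError("n_prolif must be >= 3 (8:1 cull and cyst lineage)")
        if self.M0 % 2 ** (self.n_cleavage + self.b) != 0:
            raise ValueError(
                "M0 must be divisible by 2**(n_cleavage + b) so cleavage "
                "halving yields integer copy numbers"
            )
        # genome-wide rate must be a probability (also rejects mu < 0)
        genome_wide_rate(self.mu, self.g)
        if self.B_mean < 1:
            raise ValueError("bottleneck would reduce mean copies below 1")

    @property
    def U(self) -> float:
        """Genome-wide mutation probability per replication, U = g * mu."""
        return genome_wide_rate(self.mu, self.g)

    @property
    def Nmax(self) -> int:
        """Oogonia at the end of proliferation, n_pgc * 2**n_prolif."""
        return self.n_pgc * 2**self.n_prolif

    @property
    def n_oocytes(self) -> int:
        """Primary oocytes after the 8:1 cull, Nmax / 8."""
        return self.Nmax // 8

    @property
    def B_mean(self) -> float:
        """Mean mtDNA copies per PGC after cleavage and bottleneck."""
        return self.M0 / 2 ** (self.n_cleavage + self.b)


_REGIMES = ("none", "individual", "cell", "transfer")


@dataclass(frozen=True)
class SelectionSpec:
    """Which selection regime applies, and its parameters.

    ``individual`` weights prospective zygotes by ``1 - (m/M)**exponent_ind``;
    ``cell`` culls oogonia without replacement with weights
    ``1 - (m/M)**xi``; ``transfer`` pools a fraction ``f`` of each cyst
    cell's mitochondria into the primary oocyte with per-copy weights
    ``p_wt``/``p_mut``.
    """

    regime: str = "none"
    xi: float = 5.0
    exponent_ind: float = 5.0
    p_wt: float = 0.5
    p_mut: float = 0.5
    f: float = 0.5
    cyst_size: int = 8

    def __post_init__(self) -> None:
        if self.regime not in _REGIMES:
            raise ValueError(f"regime must be one of {_REGIMES}")
        if self.xi < 1:
            raise ValueError("xi must be >= 1 (negative epistasis or linear)")
        if self.exponent_ind < 1:
            raise ValueError("exponent_ind must be >= 1")
        if not self.p_wt > 0:
            raise ValueError("p_wt must be positive")
        if self.p_mut < 0:
            raise ValueError("p_mut must be non-negative")
        if not 0.0 < self.f <= 1.0:
            raise ValueError("transfer fraction f must lie in (0, 1]")
        if self.cyst_size < 2 or not _is_power_of_two(self.cyst_size):
            raise ValueError("cyst_size must be a power of two >= 2 (clonal lineage blocks)")


@dataclass(frozen=True)
class MutationRateEstimate:
    """Conversion of a per-generation mutation rate to a per-division rate.

    Germline development involves ~20 cell divisions from zygote to mature
    oocyte, so rates reported per site per *generation* are divided by 20 to
    compare with the per-division rate used by the model.
    """

    per_generation_rate: float
    divisions_per_generation: int = 20

    @property
    def per_division_rate(self) -> float:
        return per_division_rate(self.per_generation_rate, self.divisions_per_generation)


@dataclass(frozen=True)
class ClinicalModel:
    """Thresholds and observed counts for the clinical prevalence data.

    Carriers have a detectable (>= 2%) but sub-disease (< 60%) load; disease
    manifests at >= 60%.  The observed prevalences are ~1/200 carriers and
    ~1/5000 affected; counts default to X1/N1 = 50/10,000 and
    X2/N2 = 2/10,000, preserving those ratios.
    """

    detect_threshold: float = DEFAULT_DETECTION_THRESHOLD
    disease_threshold: float = DEFAULT_DISEASE_THRESHOLD
    X1: int = 50
    N1: int = 10_000
    X2: int = 2
    N2: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 < self.detect_threshold < self.disease_threshold < 1.0:
            raise ValueError("need 0 < detect_threshold < disease_threshold < 1")
        if not (0 <= self.X1 <= self.N1 and 0 <= self.X2 <= self.N2):
            raise ValueError("need 0 <= X_i <= N_i")


# ---------------------------------------------------------------------------
# Shared primitives
# ---------------------------------------------------------------------------


def genome_wide_rate(mu: float, g: int) -> float:
    """Genome-wide mutation probability per replication, ``U = g * mu``.

    The product form is the first-order expansion of ``1 - (1 - mu)**g`` and
    differs from it by < 1e-6 at the rates considered (mu <= 1e-7).
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    if g <= 0:
        raise ValueError("g must be positive")
    U = mu * g
    if U > 1:
        raise ValueError("mu * g exceeds 1: not a probability")
    return U


def per_division_rate(rate_per_generation: float, divisions: int = 20) -> float:
    """Convert a per-generation rate to a per-cell-division rate."""
    if rate_per_generation < 0:
        raise ValueError("rate must be non-negative")
    if divisions < 1:
        raise ValueError("divisions must be >= 1")
    return rate_per_generation / divisions


def _fitness(m, M, exponent):
    m = np.asarray(m, dtype=float)
    M = np.asarray(M, dtype=float)
    if np.any(M <= 0):
        raise ValueError("M must be positive")
    if np.any(m < 0) or np.any(m > M):
        raise ValueError("need 0 <= m <= M")
    out = 1.0 - (m / M) ** exponent
    return out if out.ndim else float(out)


def individual_fitness(m, M, exponent: float = 5.0):
    """Concave individual fitness ``1 - (m/M)**exponent``.

    Mutations are near-neutral at low load and sharply deleterious at high
    load (negative epistasis), matching the clinical observation that
    phenotypes typically manifest above ~60% heteroplasmy.
    """
    return _fitness(m, M, exponent)


def cell_fitness(m, M, xi: float):
    """Cell fitness ``1 - (m/M)**xi``; ``xi = 1`` is linear selection."""
    if np.any(np.asarray(xi) < 1):
        raise ValueError("xi must be >= 1")
    return _fitness(m, M, xi)


def replicate_and_mutate_counts(n_wt, n_mut, U: float, rng: np.random.Generator):
    """One round of mtDNA replication with copying-error mutation.

    Every copy is duplicated; each new replica of a wildtype copy mutates
    with genome-wide probability ``U`` (``dm ~ Binomial(n_wt, U)``), and
    mutants breed true.  Returns ``(2*n_wt - dm, 2*n_mut + dm)``; the total
    exactly doubles.  Accepts scalars or integer arrays (vectorized over
    cells).
    """
    if not 0.0 <= U <= 1.0:
        raise ValueError("U must lie in [0, 1]")
    scalar = np.isscalar(n_wt) and np.isscalar(n_mut)
    n_wt = np.asarray(n_wt, dtype=np.int64)
    n_mut = np.asarray(n_mut, dtype=np.int64)
    if np.any(n_wt < 0) or np.any(n_mut < 0):
        raise ValueError("counts must be non-negative")
    dm = rng.binomial(n_wt, U)
    new_wt = 2 * n_wt - dm
    new_mut = 2 * n_mut + dm
    if scalar:
        return int(new_wt), int(new_mut)
    return new_wt, new_mut


def segregation_variance(t: int, m0: float) -> float:
    """Variance of the per-cell mutant count after ``t`` segregating divisions.

    Repeated binomial halving of ``m0`` mutant copies composes to a single
    ``Binomial(m0, 2**-t)`` thinning, giving the closed form
    ``Var_t = m0 * 2**-t * (1 - 2**-t)``, equivalently the recursion
    ``Var_t = Var_{t-1} / 4 + 2**-(t+1) * m0``.  (The coefficient on the
    second term is 2**-(t+1), as the law of total variance requires; tests
    check this against enumeration.)
    """
    if t < 0 or m0 < 0:
        raise ValueError("t and m0 must be non-negative")
    p = 2.0**-t
    return m0 * p * (1.0 - p)


def weighted_sample_indices(weights, k: int, rng: np.random.Generator) -> np.ndarray:
    """Sample ``k`` indices without replacement, sequentially weight-proportional.

    Implements the successive-draws scheme (draw one index with probability
    proportional to its weight, remove it, renormalize, repeat) via
    exponential sort keys: ``E_i / w_i`` with ``E_i ~ Exp(1)`` ranks items
    identically in distribution to the sequential process.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if k > w.size:
        raise ValueError("cannot sample more items than available")
    if np.count_nonzero(w > 0) < k:
        raise ValueError("fewer positive weights than requested sample size")
    keys = np.full(w.size, np.inf)
    pos = w > 0
    keys[pos] = rng.exponential(size=int(pos.sum())) / w[pos]
    idx = np.argpartition(keys, k - 1)[:k]
    return idx


def wallenius_pmf(n: np.ndarray | int, M: int, m: int, draws: int, p_wt: float, p_mut: float):
    """Wallenius noncentral hypergeometric pmf by direct dynamic programming.

    Probability that ``draws`` sequential weighted draws without replacement
    from a pool of ``m`` mutants (weight ``p_mut``) and ``M - m`` wildtypes
    (weight ``p_wt``) contain exactly ``n`` mutants.  After each single draw
    the remaining weights are renormalized -- the process the stochastic
    tier's per-copy transfer sampler performs.
    """
    if draws > M:
        raise ValueError("cannot draw more copies than the pool holds")
    if not (0 <= m <= M):
        raise ValueError("need 0 <= m <= M")
    # prob[j] = P(j mutants among the first t draws)
    prob = np.zeros(draws + 1)
    prob[0] = 1.0
    for t in range(draws):
        j = np.arange(min(t, m) + 1)
        w_mut = np.maximum(m - j, 0) * p_mut
        w_wt = np.maximum(M - m - (t - j), 0) * p_wt
        tot = w_mut + w_wt
        if np.any((tot == 0) & (prob[: j.size] > 0)):
            raise ValueError("weighted draw impossible: all remaining weights zero")
        p_take = np.divide(w_mut, tot, out=np.zeros_like(tot), where=tot > 0)
        new = np.zeros_like(prob)
        new[: j.size] = prob[: j.size] * (1.0 - p_take)
        new[1 : j.size + 1] += prob[: j.size] * p_take
        prob = new
    n_arr = np.atleast_1d(np.asarray(n, dtype=int))
    out = np.where((n_arr >= 0) & (n_arr <= draws), prob[np.clip(n_arr, 0, draws)], 0.0)
    return float(out[0]) if np.isscalar(n) else out


# ---------------------------------------------------------------------------
# Stochastic tier: agent-style simulator of one generation
# ---------------------------------------------------------------------------

_STAGES = ("cleavage", "pgc", "oogonia", "primary_oocyte", "mature_oocyte")


@dataclass
class CellPopulation:
    """Per-cell integer mtDNA counts for one germline.

    ``mut[i]`` and ``total[i]`` are the mutant and total copy numbers of cell
    ``i``.  Cells are kept in lineage order: after each division the two
    daughters of cell ``i`` sit at positions ``2i`` and ``2i + 1``, so a
    contiguous block of ``2**k`` cells descends from a single ancestor ``k``
    divisions earlier (this is what defines germline cysts).

    Under tight bottlenecks segregation can leave a cell with zero copies;
    such cells are inviable -- they carry no load, never survive a cull, and
    contribute nothing to a cyst pool.
    """

    mut: np.ndarray
    total: np.ndarray
    stage: str

    def __post_init__(self) -> None:
        self.mut = np.asarray(self.mut, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        if self.stage not in _STAGES:
            raise ValueError(f"stage must be one of {_STAGES}")
        if self.mut.shape != self.total.shape:
            raise ValueError("mut and total must have the same shape")
        if np.any(self.mut < 0) or np.any(self.mut > self.total):
            raise ValueError("need 0 <= mut <= total per cell")

    @property
    def n_cells(self) -> int:
        return self.mut.size

    @property
    def viable(self) -> np.ndarray:
        """Boolean mask of cells that still carry mtDNA."""
        return self.total > 0

    @property
    def load(self) -> np.ndarray:
        """Mutation load m/M of each viable cell."""
        v = self.viable
        return self.mut[v] / self.total[v]

    @property
    def mean_load(self) -> float:
        """Mean of per-cell loads over viable cells."""
        return float(np.mean(self.load))


@dataclass(frozen=True)
class GenerationSummary:
    """Outcome of one simulated generation."""

    mean_load: float
    load_quantiles: tuple[float, float, float]  # 5% / 50% / 95%
    delta_m: float


def zygote(params: GermlineParams) -> CellPopulation:
    """Single-cell starting state with ``round(m0_frac * M0)`` mutant copies."""
    m0 = int(np.rint(params.m0_frac * params.M0))
    return CellPopulation(mut=np.array([m0]), total=np.array([params.M0]), stage="cleavage")


def _interleave(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = np.empty(a.size + b.size, dtype=a.dtype)
    out[0::2] = a
    out[1::2] = b
    return out


def _require_stage(pop: CellPopulation, *stages: str) -> None:
    if pop.stage not in stages:
        raise ValueError(f"operation requires stage in {stages}, got {pop.stage!r}")


def cleavage_divide(pop: CellPopulation, rng: np.random.Generator) -> CellPopulation:
    """One cleavage division: binomial segregation, no replication, both daughters kept.

    Each copy independently goes to either daughter with probability 1/2;
    population copy totals are conserved exactly.
    """
    _require_stage(pop, "cleavage")
    wt = pop.total - pop.mut
    a_mut = rng.binomial(pop.mut, 0.5)
    a_wt = rng.binomial(wt, 0.5)
    mut = _interleave(a_mut, pop.mut - a_mut)
    wt_both = _interleave(a_wt, wt - a_wt)
    return CellPopulation(mut=mut, total=mut + wt_both, stage="cleavage")


def specify_pgcs(pop: CellPopulation, n_pgc: int, rng: np.random.Generator) -> CellPopulation:
    """Choose ``n_pgc`` cells uniformly at random (without replacement) as PGCs."""
    if pop.n_cells < n_pgc:
        raise ValueError("fewer cells than requested PGCs")
    idx = rng.choice(pop.n_cells, size=n_pgc, replace=False)
    return CellPopulation(mut=pop.mut[idx], total=pop.total[idx], stage="pgc")


def apply_bottleneck(pop: CellPopulation, b: int, rng: np.random.Generator) -> CellPopulation:
    """``b`` extra segregating cell divisions without replication (both daughters kept).

    Mean copies per cell fall by a factor ``0.5**b`` while the germline's
    total copy pool is conserved exactly; the cell count grows ``2**b``-fold
    and the subsequent proliferation phase is correspondingly shorter, so the
    final oogonia count is unchanged.  The lower copy number is then held (in
    expectation) through proliferation, the extreme-bottleneck assumption
    that maximizes segregational variance.
    """
    _require_stage(pop, "pgc", "cleavage")
    if b < 0:
        raise ValueError("b must be >= 0")
    if float(np.mean(pop.total)) * 0.5**b < 1.0:
        raise ValueError("bottleneck would reduce mean copies below 1")
    mut, wt = pop.mut, pop.total - pop.mut
    for _ in range(b):
        a_mut = rng.binomial(mut, 0.5)
        a_wt = rng.binomial(wt, 0.5)
        mut = _interleave(a_mut, mut - a_mut)
        wt = _interleave(a_wt, wt - a_wt)
    return CellPopulation(mut=mut, total=mut + wt, stage=pop.stage)


def proliferate(
    pop: CellPopulation,
    n_div: int,
    U: float,
    rng: np.random.Generator,
    max_cells: int | None = None,
    uncapped_tail: int = 3,
) -> CellPopulation:
    """PGC proliferation: ``n_div`` rounds of replicate-mutate-segregate, both daughters kept.

    Copy number per cell stays constant in expectation; the final cell count
    is ``n_pgc * 2**n_div``.  Daughters are interleaved so that clonal
    relatives remain contiguous (cyst lineage blocks).

    ``max_cells`` caps the simulated pool for scaled-down replicates: after
    each division (except the last ``uncapped_tail``, which are left intact
    so cyst lineage blocks stay complete) the population is thinned by a
    uniform random subsample to ``max_cells / 2**uncapped_tail`` cells.
    Cells evolve independently, so uniform thinning commutes with the rest
    of the pipeline and leaves every per-oocyte distribution unchanged --
    only the pool carried forward (and hence the final oocyte count) shrinks.
    """
    _require_stage(pop, "pgc")
    mut, wt = pop.mut, pop.total - pop.mut
    cap = None
    if max_cells is not None:
        if max_cells < 2**uncapped_tail:
            raise ValueError("max_cells must allow at least one full lineage block")
        cap = max_cells >> uncapped_tail
    for div in range(n_div):
        wt2, mut2 = replicate_and_mutate_counts(wt, mut, U, rng)
        a_mut = rng.binomial(mut2, 0.5)
        a_wt = rng.binomial(wt2, 0.5)
        mut = _interleave(a_mut, mut2 - a_mut)
        wt = _interleave(a_wt, wt2 - a_wt)
        if cap is not None and div < n_div - uncapped_tail and mut.size > cap:
            idx = np.sort(rng.choice(mut.size, size=cap, replace=False))
            mut, wt = mut[idx], wt[idx]
    return CellPopulation(mut=mut, total=mut + wt, stage="oogonia")


def cull_random(pop: CellPopulation, survivors: int, rng: np.random.Generator) -> CellPopulation:
    """Uniform random cell death down to ``survivors`` cells (load-neutral)."""
    _require_stage(pop, "oogonia")
    alive = np.flatnonzero(pop.viable)
    if survivors > alive.size:
        raise ValueError("survivors exceed viable population size")
    idx = alive[rng.choice(alive.size, size=survivors, replace=False)]
    return CellPopulation(mut=pop.mut[idx], total=pop.total[idx], stage="primary_oocyte")


def cull_by_cell_fitness(
    pop: CellPopulation, xi: float, survivors: int, rng: np.random.Generator
) -> CellPopulation:
    """Fitness-weighted cull (follicular atresia as cell-level selection).

    Survivors are drawn without replacement with weights
    ``1 - (m/M)**xi`` (sequential weighted sampling).
    """
    _require_stage(pop, "oogonia")
    if survivors > pop.n_cells:
        raise ValueError("survivors exceed population size")
    w = np.zeros(pop.n_cells)
    v = pop.viable
    w[v] = cell_fitness(pop.mut[v], pop.total[v], xi)
    if not np.any(w > 0):
        raise ValueError("all cell-fitness weights are zero")
    idx = weighted_sample_indices(w, survivors, rng)
    return CellPopulation(mut=pop.mut[idx], total=pop.total[idx], stage="primary_oocyte")


def _transfer_draw_counts(
    mut: np.ndarray,
    wt: np.ndarray,
    k: np.ndarray,
    p_wt: float,
    p_mut: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mutants among ``k[i]`` sequential weighted draws without replacement, per cell.

    Vectorized across cells: each of up to ``max(k)`` rounds draws one copy
    from every still-active cell with probability of picking a mutant equal
    to its remaining weight share (the Wallenius process).
    """
    mut_rem = mut.astype(np.int64).copy()
    wt_rem = wt.astype(np.int64).copy()
    taken = np.zeros_like(mut_rem)
    for t in range(int(k.max())):
        active = k > t
        w_mut = mut_rem * p_mut
        w_wt = wt_rem * p_wt
        tot = w_mut + w_wt
        if np.any(active & (tot <= 0)):
            raise ValueError("weighted transfer impossible: remaining weights all zero")
        p = np.divide(w_mut, tot, out=np.zeros_like(w_mut, dtype=float), where=tot > 0)
        pick_mut = active & (rng.random(mut_rem.size) < p)
        pick_wt = active & ~pick_mut
        mut_rem -= pick_mut
        wt_rem -= pick_wt
        taken += pick_mut
    return taken


def cyst_transfer(
    pop: CellPopulation, spec: SelectionSpec, rng: np.random.Generator
) -> CellPopulation:
    """Cytoplasmic transfer into the Balbiani body of one primary oocyte per cyst.

    Cells are grouped by lineage into cysts of ``cyst_size`` clonal relatives
    (contiguous blocks; descendants of one cell ``log2(cyst_size)`` divisions
    prior).  From *every* cyst cell -- including the one designated primary
    oocyte, whose contribution goes to its own pool -- ``round(f * M)``
    copies are drawn sequentially without replacement with weights ``p_wt``
    (wildtype) and ``p_mut`` (mutant) and pooled; nurse cells then undergo
    apoptosis.  With ``f = 0.5`` and 8-cell cysts the primary oocyte holds
    four cells' worth of copies.  (Which cyst member is designated primary
    oocyte does not affect the pooled counts, so no designation is drawn.)
    """
    _require_stage(pop, "oogonia")
    cs = spec.cyst_size
    if pop.n_cells % cs != 0:
        raise ValueError("cyst_size must divide the oogonial population")
    k = np.rint(spec.f * pop.total).astype(np.int64)  # round-half-to-even
    if np.any((k < 1) & pop.viable):
        raise ValueError("f * M < 1: no copies would be transferred")
    taken_mut = _transfer_draw_counts(pop.mut, pop.total - pop.mut, k, spec.p_wt, spec.p_mut, rng)
    pooled_mut = taken_mut.reshape(-1, cs).sum(axis=1)
    pooled_tot = k.reshape(-1, cs).sum(axis=1)
    return CellPopulation(mut=pooled_mut, total=pooled_tot, stage="primary_oocyte")


def maturation_rounds(M0: int, start_copies: float) -> int:
    """Doubling rounds needed to restore ``M0`` from ``start_copies``.

    The ratio must be a power of two (the schedule doubles copies exactly):
    12 rounds from the base bottleneck of 128 in the human scenario, 12+b
    with ``b`` extra bottleneck divisions, 10 after fourfold cyst pooling.
    """
    ratio = M0 / start_copies
    r = int(round(math.log2(ratio)))
    if r < 0 or 2**r != ratio:
        raise ValueError("M0 / start_copies must be a non-negative power of two")
    return r


def mature_oocytes(
    pop: CellPopulation, U: float, rng: np.random.Generator, n_rounds: int
) -> CellPopulation:
    """Oocyte maturation: ``n_rounds`` of replication (with mutation) without division."""
    _require_stage(pop, "primary_oocyte")
    mut, wt = pop.mut, pop.total - pop.mut
    for _ in range(n_rounds):
        wt, mut = replicate_and_mutate_counts(wt, mut, U, rng)
    return CellPopulation(mut=mut, total=mut + wt, stage="mature_oocyte")


def select_individuals(
    loads: np.ndarray, exponent: float = 5.0, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Soft selection on prospective zygotes: fitness-weighted resampling.

    Individuals (mature-oocyte loads) are resampled with replacement with
    weights ``1 - load**exponent``, returning a post-selection sample of the
    same size.
    """
    loads = np.asarray(loads, dtype=float)
    w = 1.0 - loads**exponent
    if not np.any(w > 0):
        raise ValueError("all individual-fitness weights are zero")
    if rng is None:
        rng = np.random.default_rng()
    return rng.choice(loads, size=loads.size, replace=True, p=w / w.sum())


def run_generation(
    params: GermlineParams,
    spec: SelectionSpec,
    rng: np.random.Generator,
    max_cells: int | None = None,
) -> GenerationSummary:
    """Simulate one full generation and summarize the change in load.

    Pipeline: cleavage -> PGC specification -> (bottleneck) -> proliferation
    -> cull (random / fitness-weighted / cyst transfer) -> maturation ->
    (individual selection).  ``delta_m`` is the post-selection mean
    mature-oocyte load minus ``m0_frac``.  ``max_cells`` thins the oogonial
    pool (see :func:`proliferate`); the 8:1 cull ratio is preserved.
    """
    pop = zygote(params)
    for _ in range(params.n_cleavage):
        pop = cleavage_divide(pop, rng)
    logger.info(
        "cleavage done: %d cells, mean copies %.1f, mean load %.4g",
        pop.n_cells, pop.total.mean(), pop.mean_load,
    )
    pop = specify_pgcs(pop, params.n_pgc, rng)
    if params.b:
        pop = apply_bottleneck(pop, params.b, rng)
    logger.info(
        "PGCs specified: %d cells, mean copies %.1f", pop.n_cells, pop.total.mean()
    )
    # replicating divisions run until the fixed oogonia count Nmax is reached;
    # bottleneck divisions already doubled the cell count b times
    n_div = params.n_prolif - params.b
    min_div = 3 if spec.regime == "transfer" else 0
    if n_div < min_div:
        raise ValueError("bottleneck too deep for the proliferation schedule")
    pop = proliferate(pop, n_div, params.U, rng, max_cells=max_cells)
    logger.info(
        "proliferation done: %d oogonia, mean load %.4g", pop.n_cells, pop.mean_load
    )
    survivors = min(params.n_oocytes, pop.n_cells // 8)
    if spec.regime == "cell":
        pop = cull_by_cell_fitness(pop, spec.xi, survivors, rng)
    elif spec.regime == "transfer":
        pop = cyst_transfer(pop, spec, rng)
    else:
        pop = cull_random(pop, survivors, rng)
    start = params.B_mean * (spec.cyst_size * spec.f if spec.regime == "transfer" else 1.0)
    rounds = maturation_rounds(params.M0, start)
    pop = mature_oocytes(pop, params.U, rng, rounds)
    logger.info(
        "maturation done (%d rounds): %d oocytes, mean copies %.0f, mean load %.4g",
        rounds, pop.n_cells, pop.total.mean(), pop.mean_load,
    )
    loads = pop.load
    if spec.regime == "individual":
        loads = select_individuals(loads, spec.exponent_ind, rng)
    mean_load = float(np.mean(loads))
    q = np.quantile(loads, [0.05, 0.5, 0.95])
    return GenerationSummary(
        mean_load=mean_load,
        load_quantiles=(float(q[0]), float(q[1]), float(q[2])),
        delta_m=mean_load - params.m0_frac,
    )


def simulate_delta_m(
    params: GermlineParams,
    spec: SelectionSpec,
    reps: int,
    seed: int,
    max_cells: int | None = None,
) -> pd.DataFrame:
    """Replicate ``run_generation`` and tabulate per-replicate summaries.

    Each replicate uses an independent child stream spawned from ``seed``, so
    tables are bit-reproducible at fixed seed.
    """
    rows = []
    for rep, child in enumerate(np.random.SeedSequence(seed).spawn(reps)):
        s = run_generation(params, spec, np.random.default_rng(child), max_cells=max_cells)
        rows.append(
            {
                "rep": rep,
                "delta_m": s.delta_m,
                "mean_load": s.mean_load,
                "q05": s.load_quantiles[0],
                "q50": s.load_quantiles[1],
                "q95": s.load_quantiles[2],
            }
        )
    return pd.DataFrame(rows, columns=["rep", "delta_m", "mean_load", "q05", "q50", "q95"])


# ---------------------------------------------------------------------------
# Deterministic tier: transition operators on load distributions
# ---------------------------------------------------------------------------


@dataclass
class LoadDistribution:
    """Probability vector over mutant-copy number ``0..M`` at copy number ``M``.

    The deterministic tier assumes copy-number fluctuations are negligible:
    every cell holds exactly ``M`` copies, which follows the developmental
    schedule (halving in cleavage, constant in proliferation, doubling in
    maturation).
    """

    probs: np.ndarray
    M: int

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (self.M + 1,):
            raise ValueError("probs must have length M + 1")
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be non-negative")
        s = self.probs.sum()
        if not math.isclose(s, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("probabilities must sum to 1 within 1e-9")
        self.probs = self.probs / s

    @classmethod
    def point(cls, m: int, M: int) -> "LoadDistribution":
        p = np.zeros(M + 1)
        p[m] = 1.0
        return cls(p, M)

    @property
    def mean_count(self) -> float:
        return float(self.probs @ np.arange(self.M + 1))

    @property
    def mean_load(self) -> float:
        return self.mean_count / self.M

    @property
    def loads(self) -> np.ndarray:
        return np.arange(self.M + 1) / self.M


def _log_comb(n, k):
    """log C(n, k), vectorized; -inf outside 0 <= k <= n."""
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    with np.errstate(invalid="ignore"):
        out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where((k >= 0) & (k <= n), out, -np.inf)


def _hypergeom_pmf(n, M, m, d):
    """pmf of mutants in a uniform subset of size d from M copies (m mutant)."""
    logp = _log_comb(m, n) + _log_comb(M - m, d - n) - _log_comb(M, d)
    return np.where(np.isfinite(logp), np.exp(logp), 0.0)


def _binom_pmf(k, n, p):
    if p == 0.0:
        return np.where(np.asarray(k) == 0, 1.0, 0.0)
    if p == 1.0:
        return np.where(np.asarray(k) == np.asarray(n), 1.0, 0.0)
    logp = _log_comb(n, k) + np.asarray(k) * math.log(p) + (np.asarray(n) - np.asarray(k)) * math.log1p(-p)
    return np.where(np.isfinite(logp), np.exp(logp), 0.0)


def _assemble_kernel(rows, cols, data, shape) -> sparse.csr_matrix:
    """Build a column-stochastic sparse kernel with per-source truncation.

    ``cols`` index source states, ``rows`` destination states.  Entries below
    ``_ROW_TRUNC`` of their source state's largest entry are dropped, then
    each source column is renormalized to sum to exactly 1.
    """
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.concatenate(data)
    n_src = shape[1]
    colmax = np.zeros(n_src)
    np.maximum.at(colmax, cols, data)
    keep = data >= _ROW_TRUNC * colmax[cols]
    rows, cols, data = rows[keep], cols[keep], data[keep]
    colsum = np.bincount(cols, weights=data, minlength=n_src)
    data = data / colsum[cols]
    T = sparse.csr_matrix((data, (rows, cols)), shape=shape)
    return T


def _hypergeom_transition(M: int, d: int, exact: bool | None = None) -> sparse.csr_matrix:
    """Kernel of uniform sub-sampling: source ``m`` of ``M`` -> ``Hypergeom(M, m, d)``.

    Shape ``(d + 1, M + 1)``; column ``m`` is the pmf of the number of
    mutants in a uniform random subset of size ``d``.  Applied with
    ``d = M/2`` this is one segregating division (Eq.-1-style kernel);
    applied with ``d = B`` it collapses a whole cleavage phase in one step
    (uniform sub-sampling is consistent under composition).
    """
    if not 0 < d <= M:
        raise ValueError("need 0 < d <= M")
    if exact is None:
        exact = M <= _EXACT_MAX_M
    rows_l, cols_l, data_l = [], [], []
    frac = d / M
    if exact:
        half = None
    else:
        var_max = d * 0.25 * (M - d) / max(M - 1, 1)
        half = int(math.ceil(_BAND_SIGMAS * math.sqrt(max(var_max, 1.0)) + _BAND_PAD))
    width = (d + 1) if exact else min(d + 1, 2 * half + 1)
    block = max(1, 8_000_000 // width)
    for lo in range(0, M + 1, block):
        ms = np.arange(lo, min(lo + block, M + 1))
        if exact:
            n_grid = np.broadcast_to(np.arange(d + 1), (ms.size, d + 1))
        else:
            center = np.rint(ms * frac).astype(int)
            start = np.clip(center - half, 0, max(d + 1 - width, 0))
            n_grid = start[:, None] + np.arange(width)[None, :]
        valid = (
            (n_grid <= d)
            & (n_grid <= ms[:, None])
            & (d - n_grid <= (M - ms)[:, None])
            & (n_grid >= 0)
        )
        pmf = np.where(valid, _hypergeom_pmf(np.where(valid, n_grid, 0), M, ms[:, None], d), 0.0)
        nz = pmf > 0
        rows_l.append(n_grid[nz])
        cols_l.append(np.broadcast_to(ms[:, None], n_grid.shape)[nz])
        data_l.append(pmf[nz])
    return _assemble_kernel(rows_l, cols_l, data_l, (d + 1, M + 1))


def _replication_transition(M: int, U: float, exact: bool | None = None) -> sparse.csr_matrix:
    """Kernel of one replication round with mutation: ``m -> 2m + Binomial(M - m, U)``.

    Shape ``(2M + 1, M + 1)``.  Every copy duplicates; each new wildtype
    replica mutates with probability ``U``; mutants breed true, so at ``U=0``
    the kernel is the exact doubling map.
    """
    if not 0.0 <= U <= 1.0:
        raise ValueError("U must lie in [0, 1]")
    if exact is None:
        exact = M <= _EXACT_MAX_M
    ms_all = np.arange(M + 1)
    if U == 0.0:
        data = np.ones(M + 1)
        return sparse.csr_matrix((data, (2 * ms_all, ms_all)), shape=(2 * M + 1, M + 1))
    rows_l, cols_l, data_l = [], [], []
    if exact:
        width = M + 1
        half = None
    else:
        sd_max = math.sqrt(M * U * (1 - U))
        half = int(math.ceil(_BAND_SIGMAS * sd_max + _BAND_PAD))
        width = min(M + 1, 2 * half + 1)
    block = max(1, 8_000_000 // width)
    for lo in range(0, M + 1, block):
        ms = np.arange(lo, min(lo + block, M + 1))
        nwt = M - ms
        if exact:
            d_grid = np.broadcast_to(np.arange(width), (ms.size, width))
        else:
            center = np.rint(nwt * U).astype(int)
            start = np.clip(center - half, 0, None)
            d_grid = start[:, None] + np.arange(width)[None, :]
        valid = d_grid <= nwt[:, None]
        pmf = np.where(valid, _binom_pmf(np.where(valid, d_grid, 0), nwt[:, None], U), 0.0)
        nz = pmf > 0
        rows_l.append((2 * ms[:, None] + d_grid)[nz])
        cols_l.append(np.broadcast_to(ms[:, None], d_grid.shape)[nz])
        data_l.append(pmf[nz])
    return _assemble_kernel(rows_l, cols_l, data_l, (2 * M + 1, M + 1))


def _apply(T: sparse.csr_matrix, dist: LoadDistribution, M_new: int) -> LoadDistribution:
    out = T @ dist.probs
    s = out.sum()
    if s <= 0:
        raise ValueError("operator annihilated all probability mass")
    return LoadDistribution(out / s, M_new)


def segregation_operator(dist: LoadDistribution) -> LoadDistribution:
    """One segregating division without replication: ``M -> M/2``.

    The daughter receives a uniform random half of the ``M`` copies, so the
    transition from ``m`` mutants is ``Hypergeom(M, m, M/2)``; the expected
    mutant count halves exactly while the expected load is unchanged.
    """
    if dist.M % 2 != 0:
        raise ValueError("segregation requires even M")
    return _apply(_hypergeom_transition(dist.M, dist.M // 2), dist, dist.M // 2)


def maturation_operator(dist: LoadDistribution, U: float) -> LoadDistribution:
    """One maturation round: replication with mutation, no segregation; ``M -> 2M``."""
    return _apply(_replication_transition(dist.M, U), dist, 2 * dist.M)


def proliferation_operator(dist: LoadDistribution, U: float) -> LoadDistribution:
    """One proliferative division: replicate-mutate to ``2M`` then segregate back to ``M``.

    Composition of the replication kernel with the hypergeometric
    segregation kernel -- the distribution-level counterpart of the
    stochastic tier's replicate/mutate/segregate step, with copy number held
    at ``M``.
    """
    return segregation_operator(maturation_operator(dist, U))


def selection_update(dist: LoadDistribution, weights) -> LoadDistribution:
    """Multiplicative selection: ``p_m -> p_m w_m / sum(p w)``."""
    w = np.asarray(weights, dtype=float)
    if w.shape != dist.probs.shape:
        raise ValueError("weights must have length M + 1")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = float(dist.probs @ w)
    if total <= 0:
        raise ValueError("total selective weight is zero")
    return LoadDistribution(dist.probs * w / total, dist.M)


def transfer_contribution_kernel(
    M: int, p_wt: float, p_mut: float, f: float = 0.5, mode: str = "fisher"
) -> np.ndarray:
    """Per-cell Balbiani-body contribution kernel, shape ``(f*M + 1, M + 1)``.

    Column ``m`` is the pmf of the number of mutants among the ``f*M`` copies
    a cell with ``m`` mutants donates.  ``mode='fisher'`` uses the
    conditional-weight (Fisher noncentral hypergeometric) form

        ``C_mn \\propto C(m, n) p_mut**n  C(M-m, fM-n) p_wt**(fM-n)``,

    normalized over the feasible ``n``; ``mode='wallenius'`` uses the
    sequential draw-by-draw renormalized process (what the stochastic tier
    samples).  Columns whose support carries zero weight (e.g. ``p_mut = 0``
    with more mutants than can be left behind) are left all-zero; applying
    the kernel to a distribution with mass there raises.
    """
    d = f * M
    if d < 1 or d != int(d):
        raise ValueError("f * M must be a positive integer")
    d = int(d)
    if mode not in ("fisher", "wallenius"):
        raise ValueError("mode must be 'fisher' or 'wallenius'")
    if p_wt <= 0 or p_mut < 0:
        raise ValueError("need p_wt > 0 and p_mut >= 0")
    C = np.zeros((d + 1, M + 1))
    log_pm = math.log(p_mut) if p_mut > 0 else -math.inf
    log_pw = math.log(p_wt)
    for m in range(M + 1):
        lo = max(0, m - (M - d))
        hi = min(m, d)
        n = np.arange(lo, hi + 1)
        if mode == "fisher":
            if p_mut > 0:
                mut_term = n * log_pm
            else:
                mut_term = np.where(n > 0, -np.inf, 0.0)
            logw = (
                gammaln(m + 1) - gammaln(n + 1) - gammaln(m - n + 1)
                + gammaln(M - m + 1) - gammaln(d - n + 1) - gammaln(M - m - (d - n) + 1)
                + mut_term
                + (d - n) * log_pw
            )
            finite = np.isfinite(logw)
            if not np.any(finite):
                continue
            w = np.zeros(n.size)
            w[finite] = np.exp(logw[finite] - logw[finite].max())
            C[n, m] = w / w.sum()
        else:
            try:
                C[:, m] = wallenius_pmf(np.arange(d + 1), M, m, d, p_wt, p_mut)
            except ValueError:
                continue  # empty support for this source state
    return C


def transfer_operator(
    dist: LoadDistribution,
    p_wt: float,
    p_mut: float,
    U: float,
    cyst_size: int = 8,
    f: float = 0.5,
    mode: str = "fisher",
) -> LoadDistribution:
    """Cytoplasmic transfer at the distribution level: ``M -> cyst_size * f * M``.

    ``dist`` is the cyst-ancestor distribution (the oogonia distribution
    ``log2(cyst_size)`` divisions before the cyst completes).  The cyst is a
    clone: its total mtDNA content is the ancestor's content replicated
    (with mutation) ``log2(cyst_size)`` times, so within-cyst loads stay
    fully correlated -- a high-load ancestor yields a uniformly high-load
    cyst, which is what lets rare disease-level lineages persist across
    generations.  The Balbiani body then receives a fraction ``f`` of every
    cell's copies, i.e. ``f`` of the pooled cyst content, drawn by weighted
    sampling without replacement from that pool.
    """
    if not _is_power_of_two(cyst_size):
        raise ValueError("cyst_size must be a power of two")
    cur = dist
    for _ in range(int(math.log2(cyst_size))):
        cur = maturation_operator(cur, U)
    C = transfer_contribution_kernel(cur.M, p_wt, p_mut, f=f, mode=mode)
    dead = (C.sum(axis=0) == 0) & (cur.probs > 1e-15)
    if np.any(dead):
        raise ValueError("transfer kernel has empty support where the distribution has mass")
    contrib = C @ cur.probs
    s = contrib.sum()
    if s <= 0:
        raise ValueError("transfer annihilated all probability mass")
    return LoadDistribution(contrib / s, C.shape[0] - 1)


def clinical_fractions(
    dist: LoadDistribution, clinical: ClinicalModel | None = None
) -> tuple[float, float]:
    """Carrier and disease fractions of a zygote-stage load distribution.

    ``alpha1 = P(detect <= load < disease)`` (healthy carriers) and
    ``alpha2 = P(load >= disease)`` (affected); the remainder,
    ``P(load < detect)``, is the mutation-free fraction.
    """
    if clinical is None:
        clinical = ClinicalModel()
    loads = dist.loads
    alpha1 = float(dist.probs[(loads >= clinical.detect_threshold) & (loads < clinical.disease_threshold)].sum())
    alpha2 = float(dist.probs[loads >= clinical.disease_threshold].sum())
    return alpha1, alpha2


def log_likelihood(alpha1: float, alpha2: float, clinical: ClinicalModel | None = None) -> float:
    """Two-binomial log-likelihood of the observed clinical counts.

    ``sum_i [ log C(N_i, X_i) + X_i log(alpha_i) + (N_i - X_i) log(1 - alpha_i) ]``,
    maximal over ``alpha`` at ``alpha_i = X_i / N_i``.  Degenerate
    ``alpha_i`` in {0, 1} with mismatching counts return ``-inf``.
    """
    if clinical is None:
        clinical = ClinicalModel()
    ll = 0.0
    for X, N, a in ((clinical.X1, clinical.N1, alpha1), (clinical.X2, clinical.N2, alpha2)):
        if not 0.0 <= a <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if a == 0.0:
            if X > 0:
                return -math.inf
            continue  # log C(N,0) + 0 + N*log(1) = 0
        if a == 1.0:
            if X < N:
                return -math.inf
            continue
        ll += (
            gammaln(N + 1) - gammaln(X + 1) - gammaln(N - X + 1)
            + X * math.log(a) + (N - X) * math.log1p(-a)
        )
    return float(ll)


class GenerationOperator:
    """Precomputed one-generation map of the deterministic tier.

    All transition kernels for a scenario are built once (they do not change
    between generations) as banded sparse matrices, and ``step`` then
    propagates a zygote-stage probability vector through one generation:

    - collapse of the ``n_cleavage + b`` segregating cleavage divisions into
      a single uniform sub-sampling kernel ``M0 -> B`` (exact, since uniform
      sub-sampling composes);
    - ``n_prolif`` proliferative divisions at constant ``B``;
    - the regime-specific cull step (nothing, cell selection, or cytoplasmic
      transfer);
    - doubling maturation rounds back to ``M0``;
    - individual selection on the mature distribution (individual regime).

    ``B`` is the bottleneck size: ``M0 = 2**(n_cleavage + b) * B``.
    """

    def __init__(
        self,
        params: GermlineParams,
        spec: SelectionSpec,
        transfer_mode: str = "fisher",
    ) -> None:
        B = params.B_mean
        if B != int(B):
            raise ValueError("M0 / 2**(n_cleavage + b) must be an integer bottleneck size")
        B = int(B)
        self.params = params
        self.spec = spec
        self.B = B
        M0 = params.M0
        U = params.U
        self.compress = _hypergeom_transition(M0, B)
        self.prolif = (
            _hypergeom_transition(2 * B, B) @ _replication_transition(B, U)
        ).tocsr()
        self.w_cull = None
        self.cyst_growth: list[sparse.csr_matrix] = []
        self.transfer_kernel = None
        self.n_prolif_ops = params.n_prolif
        if spec.regime == "cell":
            self.w_cull = cell_fitness(np.arange(B + 1), B, spec.xi)
        M_after = B
        if spec.regime == "transfer":
            # last log2(cyst_size) divisions grow the (clonal) cyst: the
            # pooled cyst content is the ancestor's content replicated, so
            # within-cyst correlation is preserved exactly
            k = int(math.log2(spec.cyst_size))
            if params.n_prolif < k:
                raise ValueError("n_prolif too small for the cyst lineage")
            self.n_prolif_ops = params.n_prolif - k
            M = B
            for _ in range(k):
                self.cyst_growth.append(_replication_transition(M, U))
                M *= 2
            self.transfer_kernel = transfer_contribution_kernel(
                M, spec.p_wt, spec.p_mut, f=spec.f, mode=transfer_mode
            )
            M_after = int(spec.f * M)
        if M_after > M0 or M0 % M_after != 0 or not _is_power_of_two(M0 // M_after):
            raise ValueError("post-cull copy number must reach M0 by exact doublings")
        self.maturation = []
        M = M_after
        while M < M0:
            self.maturation.append(_replication_transition(M, U))
            M *= 2
        self.w_ind = None
        if spec.regime == "individual":
            self.w_ind = individual_fitness(np.arange(M0 + 1), M0, spec.exponent_ind)

    def _normalized(self, p: np.ndarray) -> np.ndarray:
        s = p.sum()
        if s <= 0:
            raise ValueError("generation map annihilated all probability mass")
        return p / s

    def step(self, p: np.ndarray) -> np.ndarray:
        """Advance a zygote-stage probability vector by one generation."""
        q = self._normalized(self.compress @ p)
        for _ in range(self.n_prolif_ops):
            q = self._normalized(self.prolif @ q)
        if self.spec.regime == "cell":
            q = self._normalized(q * self.w_cull)
        elif self.spec.regime == "transfer":
            for T in self.cyst_growth:
                q = self._normalized(T @ q)
            q = self._normalized(self.transfer_kernel @ q)
        for T in self.maturation:
            q = self._normalized(T @ q)
        if self.spec.regime == "individual":
            q = self._normalized(q * self.w_ind)
        return q


@dataclass(frozen=True)
class EquilibriumResult:
    """Stationary zygote-stage distribution and convergence diagnostics."""

    dist: LoadDistribution
    generations: int
    kl: float


def _kl_divergence(p_new: np.ndarray, p_old: np.ndarray) -> float:
    mask = p_new > 0
    ratio = p_new[mask] / np.maximum(p_old[mask], _KL_FLOOR)
    return float(np.sum(p_new[mask] * np.log(ratio)))


def total_variation(d1: LoadDistribution, d2: LoadDistribution) -> float:
    """Total-variation distance between two load distributions (same M)."""
    if d1.M != d2.M:
        raise ValueError("distributions must share the same copy number")
    return 0.5 * float(np.abs(d1.probs - d2.probs).sum())


def iterate_to_equilibrium(
    params: GermlineParams,
    spec: SelectionSpec,
    eta: float = 1e-9,
    max_gen: int = 100_000,
    init: LoadDistribution | None = None,
    transfer_mode: str = "fisher",
) -> EquilibriumResult:
    """Iterate the generation map to mutation-selection equilibrium.

    Generations are applied to the zygote-stage distribution until the
    Kullback-Leibler divergence between successive distributions falls below
    ``eta`` (0 log 0 := 0; states that fell below the truncation floor in
    the previous iterate are clipped at a small constant).  The stationary
    state is unique -- independent of ``init``, which defaults to a point
    mass at ``round(m0_frac * M0)``.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    op = GenerationOperator(params, spec, transfer_mode=transfer_mode)
    if init is None:
        init = LoadDistribution.point(int(np.rint(params.m0_frac * params.M0)), params.M0)
    if init.M != params.M0:
        raise ValueError("initial distribution must be at zygote copy number M0")
    p = init.probs
    for gen in range(1, max_gen + 1):
        q = op.step(p)
        kl = _kl_divergence(q, p)
        p = q
        if kl < eta:
            logger.info("equilibrium after %d generations (KL=%.3g)", gen, kl)
            return EquilibriumResult(LoadDistribution(p, params.M0), gen, kl)
    raise ConvergenceError(f"no equilibrium within {max_gen} generations (KL={kl:.3g})")


@dataclass
class LikelihoodSurface:
    """Log-likelihood of the clinical data over a (mu, B) grid for one model."""

    mu_grid: np.ndarray
    B_grid: np.ndarray
    loglik: np.ndarray  # shape (len(B_grid), len(mu_grid))
    alpha1: np.ndarray
    alpha2: np.ndarray
    generations: np.ndarray
    model: str

    @property
    def max_loglik(self) -> float:
        return float(np.max(self.loglik))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, B in enumerate(self.B_grid):
            for j, mu in enumerate(self.mu_grid):
                rows.append(
                    {
                        "model": self.model,
                        "mu": float(mu),
                        "B": int(B),
                        "alpha1": float(self.alpha1[i, j]),
                        "alpha2": float(self.alpha2[i, j]),
                        "loglik": float(self.loglik[i, j]),
                        "generations": int(self.generations[i, j]),
                    }
                )
        return pd.DataFrame(
            rows, columns=["model", "mu", "B", "alpha1", "alpha2", "loglik", "generations"]
        )


def scan_grid(
    mu_grid: Sequence[float],
    B_grid: Sequence[int],
    spec: SelectionSpec,
    clinical: ClinicalModel | None = None,
    n_cleavage: int = 12,
    n_prolif: int = 18,
    g: int = HUMAN_GENOME_SIZE_BP,
    eta: float = 1e-9,
    max_gen: int = 100_000,
) -> LikelihoodSurface:
    """Equilibrium log-likelihood over a (mu, B) grid for one selection model.

    For each grid cell the zygote copy number is tied to the bottleneck,
    ``M0 = 2**n_cleavage * B``, the generation map is iterated to
    equilibrium, and the carrier/disease fractions are scored against the
    clinical counts.
    """
    mu_grid = np.asarray(list(mu_grid), dtype=float)
    B_grid = np.asarray(list(B_grid), dtype=int)
    if mu_grid.size == 0 or B_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if clinical is None:
        clinical = ClinicalModel()
    shape = (B_grid.size, mu_grid.size)
    ll = np.empty(shape)
    a1 = np.empty(shape)
    a2 = np.empty(shape)
    gens = np.empty(shape, dtype=int)
    for i, B in enumerate(B_grid):
        for j, mu in enumerate(mu_grid):
            params = GermlineParams(
                M0=int(B) << n_cleavage,
                g=g,
                mu=float(mu),
                m0_frac=0.0,
                n_cleavage=n_cleavage,
                n_prolif=n_prolif,
            )
            res = iterate_to_equilibrium(params, spec, eta=eta, max_gen=max_gen)
            a1[i, j], a2[i, j] = clinical_fractions(res.dist, clinical)
            ll[i, j] = log_likelihood(a1[i, j], a2[i, j], clinical)
            gens[i, j] = res.generations
            logger.info(
                "scan %s: mu=%.3g B=%d -> alpha1=%.3g alpha2=%.3g loglik=%.2f (%d gen)",
                spec.regime, mu, B, a1[i, j], a2[i, j], ll[i, j], gens[i, j],
            )
    return LikelihoodSurface(mu_grid, B_grid, ll, a1, a2, gens, model=spec.regime)


# ---------------------------------------------------------------------------
# Scenario configuration, fixtures, reporting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioConfig:
    """A complete, serializable description of a simulation run."""

    params: GermlineParams = field(default_factory=GermlineParams)
    selection: SelectionSpec = field(default_factory=SelectionSpec)
    scale: str = "human"
    seed: int = 0
    reps: int = 100
    output_dir: str = "."

    def to_dict(self) -> dict:
        p, s = self.params, self.selection
        return {
            "M0": p.M0, "g": p.g, "mu": p.mu, "m0": p.m0_frac,
            "n_pgc": p.n_pgc, "n_cleavage": p.n_cleavage,
            "n_prolif": p.n_prolif, "b": p.b,
            "regime": s.regime, "xi": s.xi, "exponent_ind": s.exponent_ind,
            "p_wt": s.p_wt, "p_mut": s.p_mut, "f": s.f, "cyst_size": s.cyst_size,
            "scale": self.scale, "seed": self.seed, "reps": self.reps,
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        defaults = cls().to_dict()
        unknown = set(d) - set(defaults)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = {**defaults, **dict(d)}
        params = GermlineParams(
            M0=int(merged["M0"]), g=int(merged["g"]), mu=float(merged["mu"]),
            m0_frac=float(merged["m0"]), n_pgc=int(merged["n_pgc"]),
            n_cleavage=int(merged["n_cleavage"]), n_prolif=int(merged["n_prolif"]),
            b=int(merged["b"]),
        )
        selection = SelectionSpec(
            regime=str(merged["regime"]), xi=float(merged["xi"]),
            exponent_ind=float(merged["exponent_ind"]), p_wt=float(merged["p_wt"]),
            p_mut=float(merged["p_mut"]), f=float(merged["f"]),
            cyst_size=int(merged["cyst_size"]),
        )
        if merged["scale"] not in ("test", "human"):
            raise ValueError("scale must be 'test' or 'human'")
        return cls(
            params=params, selection=selection, scale=str(merged["scale"]),
            seed=int(merged["seed"]), reps=int(merged["reps"]),
            output_dir=str(merged["output_dir"]),
        )


def make_fixture(scale: str, seed: int = 0) -> ScenarioConfig:
    """Scenario preset at the requested scale.

    ``human`` is the full scenario (M0 = 2**19, 32 PGCs, 18 proliferative
    divisions).  ``test`` preserves every structural ratio -- mean bottleneck
    128, 8-cell cysts, 8:1 cull, halving/doubling schedule -- at desk size:
    M0 = 2**13, 6 cleavage divisions, 8 PGCs, 8 proliferative divisions
    (2048 oogonia, 256 oocytes).
    """
    if scale == "human":
        params = GermlineParams()
    elif scale == "test":
        params = GermlineParams(M0=2**13, n_cleavage=6, n_pgc=8, n_prolif=8)
    else:
        raise ValueError("scale must be 'test' or 'human'")
    return ScenarioConfig(params=params, scale=scale, seed=seed)


def load_config(path: str | Path) -> ScenarioConfig:
    """Read a YAML or JSON scenario config; missing keys take scenario defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ValueError("config file must contain a mapping of keys to values")
    return ScenarioConfig.from_dict(data)


def save_config(cfg: ScenarioConfig, path: str | Path) -> None:
    """Write a scenario config as JSON (.json) or YAML (any other suffix)."""
    path = Path(path)
    d = cfg.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))


_DELTA_M_COLUMNS = ["rep", "delta_m", "mean_load", "q05", "q50", "q95"]
_SURFACE_COLUMNS = ["model", "mu", "B", "alpha1", "alpha2", "loglik", "generations"]


def report_tables(results: Mapping, output_dir: str | Path) -> list[Path]:
    """Write deterministic TSV/JSON outputs for a set of results.

    Recognized keys: ``delta_m`` (DataFrame -> ``delta_m.tsv``), ``surface``
    (LikelihoodSurface or DataFrame -> ``surface.tsv``), ``summary`` (dict ->
    ``summary.json``).  Column order is fixed; files use tab separators, LF
    line endings and '.' decimals, so outputs are byte-stable at fixed seed.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "delta_m" in results:
        df = results["delta_m"]
        df = df.reindex(columns=_DELTA_M_COLUMNS) if len(df) else pd.DataFrame(columns=_DELTA_M_COLUMNS)
        path = outdir / "delta_m.tsv"
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")
        written.append(path)
    if "surface" in results:
        surf = results["surface"]
        df = surf.to_frame() if isinstance(surf, LikelihoodSurface) else surf
        df = df.reindex(columns=_SURFACE_COLUMNS) if len(df) else pd.DataFrame(columns=_SURFACE_COLUMNS)
        path = outdir / "surface.tsv"
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")
        written.append(path)
    if "summary" in results:
        path = outdir / "summary.json"
        path.write_text(json.dumps(results["summary"], indent=2, sort_keys=True) + "\n")
        written.append(path)
    return written


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(
    output_dir: str | Path, cfg: ScenarioConfig, files: Iterable[Path]
) -> Path:
    """Write ``manifest.json``: config snapshot, seed, version, checksums.

    Re-running the scenario described by the manifest (same config, same
    seed) reproduces every referenced output byte-identically.
    """
    from mitogerm import __version__

    outdir = Path(output_dir)
    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "version": __version__,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "files": {p.name: _sha256(p) for p in files},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
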