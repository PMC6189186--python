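"""Closed-form machinery of the deterministic branching model of brain development.

The brain is modelled as arising from a single founder cell that divides
``generations`` times (default 37), producing ``2**generations`` final cells,
half of which are neurons.  Every base of a sequenced target has a constant
probability of mutating per daughter-genome replication.  A mutation arising
during the replication that produces a generation-``i`` daughter is said to be
*seeded at generation i*: its mutant descendants form a clone ("region")
occupying a fraction ``2**-i`` of the adult brain, i.e. ``2**(G-i)`` cells.

Cell death during development is supported through a doomed-subtree mechanism
(see :class:`DeathAdjustedLineage`): each daughter cell is independently doomed
with probability ``q``; a doomed lineage keeps dividing for up to
``doomed_depth`` further generations and then dies entirely (a pruned complete
subtree).  ``q`` and the total generation count are solved so that survivors
equal ``2**generations`` and the fraction of ever-produced cells that die
equals ``death_fraction``.  At ``death_fraction == 0`` the machinery reduces
exactly to the base model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "LineageParams",
    "SeedingExpectation",
    "DeathAdjustedLineage",
    "region_fraction",
    "divisions_at_generation",
    "cumulative_divisions",
    "expected_seed_count",
    "total_expected_seed_count",
    "prob_at_least_one_region",
    "max_detectable_depth",
    "generation_for_size",
    "simulate_pruned_tree",
]


@dataclass(frozen=True)
class LineageParams:
    """Parameters of the synchronous branching model.

    Attributes
    ----------
    generations:
        Number of synchronous division rounds ``G`` (default 37).
    neuron_fraction:
        Proportion of final cells that are neurons (default 0.5, i.e. neurons
        and non-neurons in approximately equal proportions).
    death_fraction:
        Fraction of ever-produced cells that die during development
        (default 0: zero probability of cell death).
    doomed_depth:
        Number of further generations a doomed lineage divides before dying.
        Only used when ``death_fraction > 0``.
    """

    generations: int = 37
    neuron_fraction: float = 0.5
    death_fraction: float = 0.0
    doomed_depth: int = 6

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not (0.0 <= self.death_fraction < 1.0):
            raise ValueError("death_fraction must be in [0, 1)")
        if not (0.0 < self.neuron_fraction <= 1.0):
            raise ValueError("neuron_fraction must be in (0, 1]")
        if self.doomed_depth < 0:
            raise ValueError("doomed_depth must be >= 0")

    @property
    def final_cells(self) -> int:
        """Number of surviving cells in the adult brain, ``2**G``."""
        return 2 ** self.generations

    @property
    def final_neurons(self) -> float:
        return self.neuron_fraction * self.final_cells


@dataclass(frozen=True)
class SeedingExpectation:
    """Expected number of mutations seeded at one generation.

    ``divisions`` is ``d(i)``, the number of daughter-genome replications that
    produce generation-``i`` cells; ``expected_count`` is
    ``rate * n_sites * d(i)``.
    """

    generation: int
    divisions: float
    expected_count: float


def _check_generation(i: int, params: LineageParams, minimum: int = 1) -> None:
    if not (minimum <= i <= params.generations):
        raise ValueError(
            f"generation {i} outside [{minimum}, {params.generations}]"
        )


def region_fraction(i: int, params: LineageParams | None = None) -> float:
    """Fraction of the adult brain occupied by a clone seeded at generation i.

    A mutation seeded at generation ``i`` has ``2**(G-i)`` final descendants,
    i.e. a fraction ``2**-i`` of the brain; ``i = 0`` denotes a founder
    mutation filling the whole brain.
    """
    params = params or LineageParams()
    _check_generation(i, params, minimum=0)
    if params.death_fraction > 0 and i > 0:
        return 1.0 / DeathAdjustedLineage(params).divisions_at(i)
    return 2.0 ** (-i)


def divisions_at_generation(i: int, params: LineageParams | None = None) -> float:
    """Number of daughter-genome replications producing generation-i cells.

    In the deathless model each of the ``2**(i-1)`` generation-``i-1`` parents
    replicates its genome into two daughters, so ``d(i) = 2**i``.
    """
    params = params or LineageParams()
    _check_generation(i, params)
    if params.death_fraction > 0:
        return DeathAdjustedLineage(params).divisions_at(i)
    return 2.0 ** i


def cumulative_divisions(params: LineageParams | None = None,
                         through: int | None = None) -> float:
    """Total replication events through generation ``through`` (default G)."""
    params = params or LineageParams()
    through = params.generations if through is None else through
    _check_generation(through, params)
    if params.death_fraction > 0:
        lineage = DeathAdjustedLineage(params)
        return float(sum(lineage.divisions_at(i) for i in range(1, through + 1)))
    # geometric sum 2 + 4 + ... + 2**through
    return 2.0 ** (through + 1) - 2.0


def expected_seed_count(rate: float, n_sites: float, i: int,
                        params: LineageParams | None = None) -> float:
    """Expected (Poisson mean) number of mutations seeded at generation i.

    Each base mutates with constant probability ``rate`` per daughter-genome
    replication, so the expectation is ``rate * n_sites * d(i)``.
    """
    if rate < 0 or n_sites < 0:
        raise ValueError("rate and n_sites must be nonnegative")
    return rate * n_sites * divisions_at_generation(i, params)


def total_expected_seed_count(rate: float, n_sites: float,
                              params: LineageParams | None = None) -> float:
    """Expected mutation count summed over all generations."""
    if rate < 0 or n_sites < 0:
        raise ValueError("rate and n_sites must be nonnegative")
    return rate * n_sites * cumulative_divisions(params)


def prob_at_least_one_region(rate: float, n_sites: float, i: int,
                             params: LineageParams | None = None) -> float:
    """Probability an individual carries >= 1 mutant region seeded at generation i.

    Seeding events are Poisson with mean ``rate * n_sites * d(i)``, so the
    probability of at least one is ``1 - exp(-mean)``.
    """
    mean = expected_seed_count(rate, n_sites, i, params)
    return -math.expm1(-mean)


def max_detectable_depth(vaf_threshold: float) -> int:
    """Deepest relative generation at which a heterozygous clone is detectable.

    A heterozygous mutation seeded ``d`` generations below the sampled root
    has cell fraction ``2**-d`` and VAF ``2**-(d+1)``.  Returns the largest
    integer ``d`` with ``2**-(d+1) >= vaf_threshold``.
    """
    if not (0.0 < vaf_threshold <= 0.5):
        raise ValueError("vaf_threshold must be in (0, 0.5]")
    return int(math.floor(-math.log2(2.0 * vaf_threshold) + 1e-12))


def generation_for_size(size_cells: float, params: LineageParams | None = None,
                        strict: bool = False) -> int:
    """Seeding generation whose clone size is (closest to) ``size_cells``.

    With the exact-size convention a region of ``s`` cells is seeded at the
    unique generation with ``2**(G-i) == s``.  Non-power-of-two sizes map to
    the nearest generation (or raise if ``strict``).
    """
    params = params or LineageParams()
    if size_cells <= 0:
        raise ValueError("size_cells must be positive")
    exact = params.generations - math.log2(size_cells)
    i = int(round(exact))
    if strict and abs(exact - i) > 1e-9:
        raise ValueError(f"size {size_cells} is not a power-of-two clone size")
    if not (0 <= i <= params.generations):
        raise ValueError("size outside the lineage's clone-size range")
    return i


class DeathAdjustedLineage:
    """Closed-form doomed-subtree death model.

    Each daughter cell is independently doomed with probability ``q``.  A
    doomed lineage divides for up to ``doomed_depth`` further generations and
    then dies entirely, contributing a pruned complete subtree of
    ever-produced, eventually-dead cells.  Surviving cells divide for
    ``total_generations`` rounds, with ``(2(1-q))**total_generations ==
    2**G`` so the adult brain again holds ``2**G`` cells.

    Under this model the expected number of surviving generation-``i``
    daughters — the replication events whose mutations persist — is
    ``d(i) = (2(1-q))**i``, and a surviving clone seeded at generation ``i``
    occupies an expected fraction ``1/d(i)`` of the adult brain, mirroring the
    deathless identity ``f(i) = 1/d(i)``.
    """

    def __init__(self, params: LineageParams):
        self.params = params
        delta = params.death_fraction
        if delta == 0.0:
            self.q = 0.0
            self.total_generations = params.generations
            return
        self.q = self._solve_q(delta, params)
        g_eff = math.log2(2.0 * (1.0 - self.q))
        self.total_generations = params.generations / g_eff

    @staticmethod
    def _death_fraction_for_q(q: float, params: LineageParams) -> float:
        """Fraction of ever-produced cells that die, given doom probability q."""
        G = params.generations
        k = params.doomed_depth
        g_eff = math.log2(2.0 * (1.0 - q))
        if g_eff <= 0:
            return 1.0
        n_gen = G / g_eff  # real-valued total generation count
        gens = np.arange(1.0, math.floor(n_gen) + 1.0)
        surv = (2.0 * (1.0 - q)) ** gens          # surviving cells per generation
        daughters = 2.0 * np.concatenate(([1.0], surv[:-1]))  # all daughters produced
        doomed_roots = daughters * q
        # a doomed root at generation g spawns a dying subtree of
        # 2**(m+1) - 1 cells, m = min(doomed_depth, n_gen - g)
        depth = np.minimum(k, np.maximum(0.0, n_gen - gens))
        doomed_cells = doomed_roots * (2.0 ** (np.floor(depth) + 1.0) - 1.0)
        # produced = all daughters ever created (surviving + doomed roots)
        # plus the interiors of the doomed subtrees
        produced = float(np.sum(surv) + np.sum(doomed_cells))
        died = float(np.sum(doomed_cells))
        return died / produced

    @classmethod
    def _solve_q(cls, delta: float, params: LineageParams) -> float:
        f = lambda q: cls._death_fraction_for_q(q, params) - delta
        hi = 0.499
        if f(hi) < 0:
            raise ValueError(
                f"death_fraction={delta} unreachable with doomed_depth="
                f"{params.doomed_depth}; increase doomed_depth"
            )
        return float(brentq(f, 1e-12, hi, xtol=1e-14))

    def divisions_at(self, i: int) -> float:
        """Expected surviving-daughter replications d(i) = (2(1-q))**i."""
        if i < 1:
            raise ValueError("generation must be >= 1")
        return (2.0 * (1.0 - self.q)) ** i


def simulate_pruned_tree(params: LineageParams, rng: np.random.Generator,
                         ) -> dict[str, np.ndarray | float]:
    """Explicit small-G stochastic realisation of the doomed-subtree model.

    Generates the lineage generation by generation: every cell produces two
    daughters; each daughter is doomed with probability ``q``; doomed lineages
    divide for ``doomed_depth`` more generations then die.  Returns per-
    generation surviving-daughter counts (empirical ``d(i)``), the final
    survivor count and the realised death fraction.  Intended for validating
    :class:`DeathAdjustedLineage` at small ``G``; not usable at G = 37.
    """
    lineage = DeathAdjustedLineage(params)
    q = lineage.q
    n_gen = int(round(lineage.total_generations))
    surviving = 1
    d = np.zeros(n_gen)
    produced = 0.0
    died = 0.0
    k = params.doomed_depth
    for g in range(1, n_gen + 1):
        daughters = 2 * surviving
        doomed = rng.binomial(daughters, q) if q > 0 else 0
        surviving = daughters - doomed
        d[g - 1] = surviving
        produced += daughters
        # each doomed root spawns a complete dying subtree
        depth = min(k, n_gen - g)
        extra = doomed * (2 ** (depth + 1) - 2)
        produced += extra
        died += doomed * (2 ** (depth + 1) - 1)
    return {
        "divisions": d,
        "survivors": float(surviving),
        "death_fraction": died / produced if produced else 0.0,
        "total_generations": n_gen,
    }
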