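"""Monte-Carlo simulation of mutagenesis on the developmental lineage tree.

An *individual* is a realisation of Poisson mutation seeding on the branching
lineage: for each generation ``i`` and each target panel, the number of new
mutations is Poisson with mean ``rate * panel_bases * d(i)``; each mutation is
assigned a uniform site within the panel and a uniform lineage path (which
generation-``i`` node it arose in).

Tissue sampling maps a dissected block of tissue onto a lineage subtree: a
block is a uniformly chosen generation-``g`` subtree (``g`` = block
generation; smaller ``g`` means larger blocks).  A clone seeded at generation
``i <= g`` either contains the whole block (probability ``2**-i``) or misses
it; a clone seeded at ``i > g`` lies inside the block with probability
``2**-g`` and then occupies a within-block fraction ``2**(g-i)``.  The number
of mutant cells among ``n_c`` assayed cells is binomial, and the VAF of a
heterozygous mutation is ``mutant_cells / (2 * n_c)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lineage_model import LineageParams, divisions_at_generation

__all__ = [
    "MutationEvent",
    "Individual",
    "SampledMutation",
    "simulate_individual",
    "total_pathological_cells",
    "sample_tissue",
    "sample_regions",
]

PANELS = ("case", "control", "pathogenic")


@dataclass(frozen=True)
class MutationEvent:
    """A single somatic mutation on the lineage tree.

    ``path`` identifies which of the ``2**generation`` generation-``i`` nodes
    carries the mutation; the clone's ancestor at any shallower generation
    ``g`` is ``path >> (generation - g)``.
    """

    panel: str
    site_index: int
    generation: int
    path: int

    def __post_init__(self) -> None:
        if self.panel not in PANELS:
            raise ValueError(f"unknown panel {self.panel!r}")
        if not (0 <= self.path < 2 ** self.generation):
            raise ValueError("path outside the generation's node range")

    @property
    def fraction(self) -> float:
        """Fraction of the adult brain occupied by the clone, 2**-i."""
        return 2.0 ** (-self.generation)

    def ancestor_at(self, g: int) -> int:
        """Index of the clone's ancestral node at generation g <= i."""
        if g > self.generation:
            raise ValueError("no unique ancestor below the seeding generation")
        return self.path >> (self.generation - g)


@dataclass
class Individual:
    """All somatic mutations of one simulated person."""

    events: list[MutationEvent]
    params: LineageParams
    rate: float

    def events_in_panel(self, panel: str) -> list[MutationEvent]:
        return [e for e in self.events if e.panel == panel]


@dataclass(frozen=True)
class SampledMutation:
    """A mutation's appearance in one sampled tissue block."""

    event: MutationEvent
    block: int
    within_block_fraction: float
    mutant_cells: int
    cells_sampled: int

    @property
    def vaf(self) -> float:
        """Heterozygous VAF among the assayed cells."""
        return self.mutant_cells / (2.0 * self.cells_sampled)


def simulate_individual(rate: float, panel_sizes: dict[str, int],
                        params: LineageParams | None = None,
                        rng: np.random.Generator | int | None = None,
                        ) -> Individual:
    """Simulate the somatic mutations of one individual.

    For each generation ``i`` (1..G) and panel of ``L`` bases, the event count
    is Poisson with mean ``rate * L * d(i)``; each event receives a uniform
    site index and a uniform lineage path.  Deterministic under a fixed seed.
    """
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    params = params or LineageParams()
    rng = np.random.default_rng(rng)
    events: list[MutationEvent] = []
    for panel, n_sites in panel_sizes.items():
        if panel not in PANELS:
            raise ValueError(f"unknown panel {panel!r}")
        if n_sites < 0:
            raise ValueError("panel sizes must be nonnegative")
        for i in range(1, params.generations + 1):
            mean = rate * n_sites * divisions_at_generation(i, params)
            n = rng.poisson(mean)
            if n == 0:
                continue
            sites = rng.integers(0, max(n_sites, 1), size=n)
            paths = rng.integers(0, 2 ** i, size=n)
            events.extend(
                MutationEvent(panel, int(s), i, int(p))
                for s, p in zip(sites, paths)
            )
    return Individual(events=events, params=params, rate=rate)


def total_pathological_cells(individual: Individual,
                             params: LineageParams | None = None) -> float:
    """Total mutated-cell count summed over pathogenic-panel events.

    Overlapping clones are summed independently (nesting probability is
    O(f^2) for the rare events simulated here).
    """
    params = params or individual.params
    G = params.generations
    return float(sum(2.0 ** (G - e.generation)
                     for e in individual.events_in_panel("pathogenic")))


def _within_block_fraction(event: MutationEvent, block: int, g: int) -> float:
    """Fraction of a generation-g block occupied by the event's clone (0 if absent)."""
    if event.generation <= g:
        # clone covers whole blocks; this block is inside iff its ancestor
        # at the seeding generation is the mutated node
        if (block >> (g - event.generation)) == event.path:
            return 1.0
        return 0.0
    # clone is a sub-block region: present iff its ancestor at g is this block
    if event.ancestor_at(g) == block:
        return 2.0 ** (g - event.generation)
    return 0.0


def sample_tissue(individual: Individual, block_generation: int,
                  cells_sampled: int,
                  rng: np.random.Generator | int | None = None,
                  block: int | None = None) -> list[SampledMutation]:
    """Assay one tissue block: which mutations appear, at what cell counts.

    A uniformly chosen generation-``g`` subtree is the block (or a caller-
    specified ``block`` index).  Mutant cells among ``cells_sampled`` are
    binomial in the within-block clone fraction.
    """
    g = block_generation
    params = individual.params
    if not (0 <= g <= params.generations):
        raise ValueError("block generation outside [0, G]")
    if cells_sampled < 1:
        raise ValueError("cells_sampled must be >= 1")
    rng = np.random.default_rng(rng)
    if block is None:
        block = int(rng.integers(0, 2 ** g))
    elif not (0 <= block < 2 ** g):
        raise ValueError("block index outside the generation's range")
    out: list[SampledMutation] = []
    for event in individual.events:
        frac = _within_block_fraction(event, block, g)
        if frac == 0.0:
            continue
        mutant = int(rng.binomial(cells_sampled, frac))
        out.append(SampledMutation(event, block, frac, mutant, cells_sampled))
    return out


def sample_regions(individual: Individual, n_regions: int,
                   block_generation: int, cells_sampled: int,
                   rng: np.random.Generator | int | None = None,
                   ) -> list[list[SampledMutation]]:
    """Assay several anatomically distinct regions of one individual.

    Regions are disjoint generation-``g`` subtrees sampled without
    replacement, one list of sampled mutations per region.
    """
    g = block_generation
    if n_regions > 2 ** g:
        raise ValueError("more regions requested than disjoint blocks exist")
    rng = np.random.default_rng(rng)
    blocks = rng.choice(2 ** g, size=n_regions, replace=False)
    return [
        sample_tissue(individual, g, cells_sampled, rng, block=int(b))
        for b in blocks
    ]
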