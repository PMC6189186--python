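"""Rejection-ABC inference of the per-base per-division mutation rate.

The observable is the number of single-region mutations (SRMs) detected in a
multi-region deep-sequencing cohort.  Under the branching model the SRM count
is Poisson with a mean that is linear in the mutation rate ``lambda_m``:

    E[SRM] = lambda_m * L * sum_ind sum_i w_i(R_ind)

where ``L`` is the panel size, ``R_ind`` the number of regions sampled from
an individual, and ``w_i`` combines the number of replications at generation
``i`` with the probability that the resulting clone surfaces in exactly one
sampled block at a detectable VAF.  ``expected_srm_count`` evaluates this
composition exactly; ``simulate_summary`` draws from the corresponding
Poisson marginal (the event-level branching simulation in
:mod:`brainmosaic.brain_simulator` realises the same law and is used as an
independent cross-check in the test-suite).

Inference draws ``lambda_m`` from a log-uniform prior spanning four orders of
magnitude and accepts draws whose simulated summary matches the observed one
(exact integer match by default; an absolute tolerance is available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .brain_simulator import sample_regions, simulate_individual
from .lineage_model import LineageParams

__all__ = [
    "StudyDesign",
    "ABCConfig",
    "SummaryStats",
    "PosteriorSample",
    "COHORT_SRM_COUNTS",
    "default_samples_per_individual",
    "detection_probability",
    "expected_srm_count",
    "observed_summary",
    "simulate_summary",
    "simulate_summary_explicit",
    "abc_rejection",
    "posterior_interval",
]

#: SRM counts printed for the study cohort: 18 brain SRMs, 7 of them in the
#: neurodegeneration (case) panel and 11 in the control panel.
COHORT_SRM_COUNTS = {"case": 7, "control": 11, "total": 18}


def default_samples_per_individual() -> list[int]:
    """Region counts per brain implied by the cohort design.

    54 brains; cerebellum sampled in all 54, entorhinal cortex in 53,
    frontal cortex in 32, medulla in 24, cingulate in 10 (173 samples).
    """
    counts = []
    for b in range(54):
        n = 1  # cerebellum
        n += b < 53
        n += b < 32
        n += b < 24
        n += b < 10
        counts.append(n)
    assert sum(counts) == 173
    return counts


@dataclass(frozen=True)
class StudyDesign:
    """Sequencing design constants entering the detection model."""

    samples_per_individual: tuple[int, ...] = field(
        default_factory=lambda: tuple(default_samples_per_individual()))
    cells_per_sample: int = 3533
    block_generation: int = 7
    panel_bp: int = 132_617
    depth: float = 5374.0
    vaf_threshold: float = 0.005
    min_alt_reads: int = 10
    lineage: LineageParams = field(default_factory=LineageParams)

    @property
    def n_samples(self) -> int:
        return int(sum(self.samples_per_individual))


@dataclass(frozen=True)
class ABCConfig:
    """Prior, acceptance rule and draw budget for rejection ABC."""

    prior_low: float = 1e-11
    prior_high: float = 1e-7
    n_draws: int = 100_000
    tolerance: int = 0            # 0 = exact integer match on the count
    design: StudyDesign = field(default_factory=StudyDesign)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.prior_low < self.prior_high):
            raise ValueError("prior bounds must be positive and ordered")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


@dataclass(frozen=True)
class SummaryStats:
    """Observed or simulated SRM counts per panel."""

    case: int = 0
    control: int = 0

    @property
    def total(self) -> int:
        return self.case + self.control


@dataclass
class PosteriorSample:
    """Accepted mutation-rate draws from rejection ABC."""

    draws: np.ndarray
    acceptance_rate: float
    prior_low: float
    prior_high: float

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        return posterior_interval(self.draws, level)

    @property
    def mean(self) -> float:
        return float(np.mean(self.draws))

    @property
    def median(self) -> float:
        return float(np.median(self.draws))


def detection_probability(i: int, design: StudyDesign) -> float:
    """Probability a clone seeded at generation i is detected in a block it occupies.

    The clone's within-block cell fraction is 1 for ``i <= g`` and
    ``2**(g-i)`` below the block root.  Mutant cells among the assayed cells
    are binomial; detection requires a heterozygous VAF at or above the
    threshold and an implied alt-read count of at least ``min_alt_reads`` at
    the design depth.
    """
    g = design.block_generation
    n_c = design.cells_per_sample
    frac = 1.0 if i <= g else 2.0 ** (g - i)
    m_min = max(
        int(np.ceil(2.0 * n_c * design.vaf_threshold)),
        int(np.ceil(2.0 * n_c * design.min_alt_reads / design.depth)),
    )
    return float(stats.binom.sf(m_min - 1, n_c, frac))


def _srm_weight_per_rate(design: StudyDesign) -> float:
    """E[SRM count] / (lambda_m * panel_bp): the design's detection weight."""
    G = design.lineage.generations
    g = design.block_generation
    n_blocks = 2 ** g
    weight = 0.0
    for r in design.samples_per_individual:
        for i in range(1, G + 1):
            q = detection_probability(i, design)
            if q < 1e-15:
                break  # deeper clones are undetectably small
            if i <= g:
                # clone covers 2**(g-i) of the 2**g blocks; SRM iff exactly
                # one of the r sampled blocks falls inside it
                covered = 2 ** (g - i)
                p_one = float(stats.hypergeom.pmf(1, n_blocks, covered, r))
                weight += 2.0 ** i * p_one * q
            else:
                # clone lies inside a single block; that block is sampled
                # with probability r / 2**g
                weight += 2.0 ** i * (r / n_blocks) * q
    return weight


def expected_srm_count(rate: float, design: StudyDesign | None = None) -> float:
    """Expected number of detected SRMs in the design's panel at ``rate``."""
    design = design or StudyDesign()
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    return rate * design.panel_bp * _srm_weight_per_rate(design)


def observed_summary(classified=None, use_cohort_constants: bool = False,
                     ) -> SummaryStats:
    """SRM counts per panel from a classified-variant list (or study constants)."""
    if use_cohort_constants or classified is None:
        return SummaryStats(case=COHORT_SRM_COUNTS["case"],
                            control=COHORT_SRM_COUNTS["control"])
    case = sum(1 for v in classified if v.label == "SRM" and v.panel == "case")
    control = sum(1 for v in classified
                  if v.label == "SRM" and v.panel == "control")
    return SummaryStats(case=case, control=control)


def simulate_summary(rate: float, design: StudyDesign | None = None,
                     rng: np.random.Generator | int | None = None,
                     ) -> SummaryStats:
    """Draw one simulated SRM count from the branching model's marginal."""
    design = design or StudyDesign()
    rng = np.random.default_rng(rng)
    mean = expected_srm_count(rate, design)
    return SummaryStats(case=int(rng.poisson(mean)), control=0)


def simulate_summary_explicit(rate: float, design: StudyDesign,
                              rng: np.random.Generator | int | None = None,
                              ) -> SummaryStats:
    """Event-level SRM count via the full branching + block-sampling simulator.

    Slower than :func:`simulate_summary` but makes no use of the analytic
    composition; serves as the independent route in equivalence tests.
    Detection mirrors :func:`detection_probability` (VAF threshold plus the
    implied alt-read minimum).
    """
    rng = np.random.default_rng(rng)
    g = design.block_generation
    n_c = design.cells_per_sample
    G = design.lineage.generations
    m_min = max(
        int(np.ceil(2.0 * n_c * design.vaf_threshold)),
        int(np.ceil(2.0 * n_c * design.min_alt_reads / design.depth)),
    )
    # clones deeper than this are never detectable at the assayed cell count
    i_max = min(G, g + int(np.ceil(np.log2(4 * n_c))) )
    params = LineageParams(generations=i_max)
    count = 0
    for r in design.samples_per_individual:
        ind = simulate_individual(rate, {"case": design.panel_bp}, params, rng)
        regions = sample_regions(ind, r, g, n_c, rng)
        detected_in: dict[int, int] = {}
        for sampled in regions:
            for sm in sampled:
                if sm.mutant_cells >= m_min:
                    detected_in[id(sm.event)] = detected_in.get(id(sm.event), 0) + 1
        count += sum(1 for n in detected_in.values() if n == 1)
    return SummaryStats(case=count, control=0)


def abc_rejection(observed: SummaryStats | int,
                  config: ABCConfig | None = None,
                  rng: np.random.Generator | int | None = None,
                  ) -> PosteriorSample:
    """Rejection ABC for the mutation rate from an observed SRM count.

    Draws ``lambda_m`` log-uniformly from the prior, simulates the Poisson
    SRM-count marginal for each draw, and accepts draws whose count matches
    the observed one within ``config.tolerance`` (default: exact match).
    Deterministic under a fixed seed.  Raises if nothing is accepted.
    """
    config = config or ABCConfig()
    target = observed.case if isinstance(observed, SummaryStats) else int(observed)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    else:
        rng = np.random.default_rng(rng)

    weight = config.design.panel_bp * _srm_weight_per_rate(config.design)
    # expected acceptance rate under exact matching, for the draw-budget check
    log_lo, log_hi = np.log(config.prior_low), np.log(config.prior_high)
    rates = np.exp(rng.uniform(log_lo, log_hi, size=config.n_draws))
    counts = rng.poisson(rates * weight)
    accept = np.abs(counts - target) <= config.tolerance
    draws = rates[accept]
    if len(draws) == 0:
        raise RuntimeError(
            "ABC accepted no draws; increase n_draws or the tolerance")
    if len(draws) < 200:
        warnings.warn(
            f"only {len(draws)} accepted draws; credible intervals will be "
            "noisy — consider more prior draws", stacklevel=2)
    return PosteriorSample(
        draws=np.sort(draws),
        acceptance_rate=len(draws) / config.n_draws,
        prior_low=config.prior_low,
        prior_high=config.prior_high,
    )


def posterior_interval(samples, level: float = 0.95) -> tuple[float, float]:
    """Equal-tail credible interval from posterior draws."""
    samples = np.asarray(samples, dtype=float)
    if len(samples) < 2:
        raise ValueError("need >= 2 posterior samples")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [tail, 1.0 - tail])
    return float(lo), float(hi)
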