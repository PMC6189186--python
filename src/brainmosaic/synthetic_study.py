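"""Synthetic multi-region deep-sequencing cohorts with known ground truth.

Emulates the study design the screening and inference machinery expects:
54 brains (20 Alzheimer, 20 Lewy-body, 14 control) sampled across 173 regions
(cerebellum 54, entorhinal cortex 53, frontal cortex 32, medulla 24,
cingulate 10), sequenced on a 132,617 bp neurodegeneration panel and a
152,519 bp low-brain-expression cancer panel at ~5374x mean depth.

Planted signal classes:

* developmental clones — seeded on the branching lineage via
  :mod:`brainmosaic.brain_simulator`; whether they surface in one region
  (SRM-like) or several is an outcome of block sampling, recorded in truth;
* haematopoietic multi-region mutations — clonal-haematopoiesis variants in
  myeloproliferative genes of the control panel, present in every region at
  brain VAF = blood VAF / ratio (default 7.92), higher in medulla;
* germline heterozygotes at VAF ~ 0.5 in all samples;
* background (error-only) sites shared across all samples, drawn from a
  per-site beta-distributed error rate with beta-binomial overdispersion.

Read counts are emitted as a tidy per-sample per-site table; every planted
variant appears in a matching truth table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .brain_simulator import sample_regions, simulate_individual
from .lineage_model import LineageParams, max_detectable_depth

__all__ = [
    "StudyConfig",
    "generate_study",
    "sequence_counts",
    "spike_in_mixture",
    "READ_TABLE_COLUMNS",
    "TRUTH_COLUMNS",
]

READ_TABLE_COLUMNS = [
    "individual_id", "sample_id", "region", "panel", "gene_label",
    "position", "ref", "alt", "depth_fwd", "depth_rev",
    "alt_fwd", "alt_rev", "population_maf", "repeat_flag",
]

TRUTH_COLUMNS = [
    "individual_id", "sample_id", "panel", "gene_label", "position",
    "ref", "alt", "truth_class", "generation", "true_vaf",
]

_BASES = np.array(list("ACGT"))


@dataclass
class StudyConfig:
    """Design constants and noise parameters of a synthetic cohort."""

    n_control: int = 14
    n_ad: int = 20
    n_lb: int = 20
    region_design: dict[str, int] = field(default_factory=lambda: {
        "CB": 54, "EC": 53, "FC": 32, "Med": 24, "Cin": 10})
    n_blood_paired: int = 6
    depth_mean: float = 5374.0
    depth_sd: float = 745.0
    depth_floor: float = 500.0
    cells_per_sample: int = 3533
    case_panel_bp: int = 132_617
    control_panel_bp: int = 152_519
    rate: float = 1.2e-9                 # lambda_m, per base per division
    block_generation: int = 7
    max_seeding_generation: int | None = None   # default: g + detectable depth + 2
    mrm_per_brain: float = 0.3           # haematopoietic MRM Poisson mean
    blood_brain_ratio: float = 7.92
    blood_vaf_mean: float = 0.232        # median blood VAF; with the 7.92
    # blood:brain ratio, lognormal spread, region jitter and the medulla
    # multiplier this puts the mean brain MRM VAF at ~3.67 %
    blood_vaf_sigma: float = 0.35        # lognormal spread of blood VAF
    medulla_ec_ratio: float = 2.1
    region_vaf_jitter: float = 0.2       # lognormal sd of region-level VAF noise
    n_germline_per_individual: int = 2
    n_background_sites: int = 40         # per panel, shared across all samples
    error_rate_mean: float = 2e-4
    error_rate_dispersion: float = 0.005   # rho of the across-site error Beta:
    # heavy-tailed, so occasional hotspot sites reach 1e-3..1e-2
    error_sample_cv: float = 0.3         # sample-to-sample cv of a site's error
    lineage: LineageParams = field(default_factory=LineageParams)
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.region_design.values()):
            raise ValueError("region counts must be nonnegative")
        if max(self.region_design.values(), default=0) > self.n_brains:
            raise ValueError("a region cannot be sampled in more brains than exist")
        if self.depth_mean <= 0:
            raise ValueError("depth must be positive")
        for name in ("rate", "mrm_per_brain", "error_rate_mean",
                     "error_sample_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def n_brains(self) -> int:
        return self.n_control + self.n_ad + self.n_lb

    @property
    def n_samples(self) -> int:
        return sum(self.region_design.values())

    @property
    def seeding_ceiling(self) -> int:
        """Deepest generation simulated; deeper clones are unobservably small."""
        if self.max_seeding_generation is not None:
            return self.max_seeding_generation
        ceiling = self.block_generation + max_detectable_depth(0.005) + 3
        return min(ceiling, self.lineage.generations)


def sequence_counts(true_vaf, depth_fwd, depth_rev, error_rate,
                    overdispersion,
                    rng: np.random.Generator | int | None = None,
                    ):
    """Draw stranded alt-read counts for sites with known true VAF.

    Per strand, ``alt ~ BetaBinomial(depth, p, rho)`` with
    ``p = true_vaf + (1 - true_vaf) * error_rate`` and overdispersion
    ``rho``; ``rho = 0`` degrades to the plain binomial.  Accepts scalars or
    broadcastable arrays (including per-site ``rho``); returns
    ``(alt_fwd, alt_rev)``.
    """
    rng = np.random.default_rng(rng)
    true_vaf = np.asarray(true_vaf, dtype=float)
    error_rate = np.asarray(error_rate, dtype=float)
    rho = np.asarray(overdispersion, dtype=float)
    if np.any((true_vaf < 0) | (true_vaf > 1)):
        raise ValueError("true_vaf must be in [0, 1]")
    if np.any((error_rate < 0) | (error_rate > 1)):
        raise ValueError("error_rate must be in [0, 1]")
    if np.any((rho < 0) | (rho >= 1)):
        raise ValueError("overdispersion must be in [0, 1)")
    p = true_vaf + (1.0 - true_vaf) * error_rate
    p, rho = np.broadcast_arrays(p, rho)
    out = []
    for depth in (np.asarray(depth_fwd), np.asarray(depth_rev)):
        disp = rho > 0
        pp = np.array(np.broadcast_to(p, np.broadcast_shapes(p.shape, depth.shape)),
                      dtype=float)
        if np.any(disp):
            r = np.broadcast_to(rho, pp.shape)
            a = pp * (1.0 - r) / np.where(disp, r, 1.0)
            b = (1.0 - pp) * (1.0 - r) / np.where(disp, r, 1.0)
            draws = rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12))
            pp = np.where(np.broadcast_to(disp, pp.shape), draws, pp)
        out.append(rng.binomial(np.asarray(depth).astype(int),
                                np.clip(pp, 0.0, 1.0)))
    return out[0], out[1]


def _sample_rho(true_vaf, error_rate, cv: float) -> np.ndarray:
    """Beta-binomial rho giving sample-to-sample error sd = cv * error_rate.

    The biological VAF is a fixed property of the sample, so only the error
    component varies between samples; the resulting dispersion is tiny for
    large VAFs and ~cv^2 * e for error-only sites.
    """
    p = true_vaf + (1.0 - true_vaf) * error_rate
    sd = (1.0 - true_vaf) * cv * error_rate
    var = sd ** 2
    denom = np.maximum(p * (1.0 - p), 1e-30)
    return np.clip(var / denom, 0.0, 0.99)


def _allocate_regions(config: StudyConfig, rng: np.random.Generator,
                      ) -> dict[str, list[str]]:
    """Assign each designed region slot to a brain (each brain >= 1 region)."""
    brains = [f"b{k + 1:02d}" for k in range(config.n_brains)]
    assignment: dict[str, list[str]] = {b: [] for b in brains}
    for region, count in config.region_design.items():
        order = list(rng.permutation(brains))
        for b in order[:count]:
            assignment[b].append(region)
    # every brain must carry at least one region for within-individual tests
    for b, regions in assignment.items():
        if not regions:
            regions.append(max(config.region_design,
                               key=config.region_design.get))
    return assignment


def _site_coords(panel: str, site_index: int, n_genes: int = 50,
                 ) -> tuple[str, int]:
    gene = f"{panel.upper()[:2]}G{site_index % n_genes + 1:02d}"
    position = site_index // n_genes + 1
    return gene, position


class _SiteRegistry:
    """Deterministic per-site error rates, alleles and coordinates."""

    def __init__(self, config: StudyConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self._sites: dict[tuple[str, int], dict] = {}

    def get(self, panel: str, site_index: int) -> dict:
        key = (panel, site_index)
        if key not in self._sites:
            cfg = self.config
            rho = cfg.error_rate_dispersion
            a = cfg.error_rate_mean * (1.0 - rho) / rho
            b = (1.0 - cfg.error_rate_mean) * (1.0 - rho) / rho
            gene, pos = _site_coords(panel, site_index)
            ref, alt = self.rng.choice(4, size=2, replace=False)
            self._sites[key] = {
                "gene_label": gene, "position": pos,
                "ref": _BASES[ref], "alt": _BASES[alt],
                "error_rate": float(self.rng.beta(a, b)),
                "population_maf": 0.0, "repeat_flag": 0,
            }
        return self._sites[key]


def generate_study(config: StudyConfig | None = None,
                   rng: np.random.Generator | int | None = None,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a full synthetic cohort: read-count table plus ground truth.

    Returns ``(reads, truth)``; ``reads`` follows :data:`READ_TABLE_COLUMNS`
    and ``truth`` :data:`TRUTH_COLUMNS`.  Deterministic under
    ``config.seed`` / an explicit ``rng``.
    """
    config = config or StudyConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    else:
        rng = np.random.default_rng(rng)

    groups = (["control"] * config.n_control + ["AD"] * config.n_ad
              + ["LB"] * config.n_lb)
    assignment = _allocate_regions(config, rng)
    brains = sorted(assignment)
    blood_paired = set(brains[:: max(1, len(brains) // max(config.n_blood_paired, 1))]
                       [: config.n_blood_paired])

    registry = _SiteRegistry(config, rng)
    g = config.block_generation
    i_max = config.seeding_ceiling
    truncated = LineageParams(
        generations=config.lineage.generations,
        neuron_fraction=config.lineage.neuron_fraction,
        death_fraction=config.lineage.death_fraction,
        doomed_depth=config.lineage.doomed_depth,
    )

    # per (site_key) -> {sample_id: true_vaf}, plus metadata
    planted: dict[tuple[str, int], dict] = {}
    truth_rows: list[dict] = []
    sample_meta: list[tuple[str, str, str]] = []   # (individual, sample, region)

    def plant(panel: str, site_index: int, individual: str, sample: str,
              vaf: float, truth_class: str, generation) -> None:
        key = (panel, site_index)
        rec = planted.setdefault(key, {"vaf": {}, "class": truth_class})
        rec["vaf"][sample] = rec["vaf"].get(sample, 0.0) + vaf
        site = registry.get(panel, site_index)
        truth_rows.append({
            "individual_id": individual, "sample_id": sample, "panel": panel,
            "gene_label": site["gene_label"], "position": site["position"],
            "ref": site["ref"], "alt": site["alt"],
            "truth_class": truth_class, "generation": generation,
            "true_vaf": vaf,
        })

    n_myelo_sites = int(config.control_panel_bp * 19 / 46)
    region_mult = {r: 1.0 for r in config.region_design}
    region_mult["Med"] = config.medulla_ec_ratio

    for b, group in zip(brains, groups):
        regions = assignment[b]
        samples = [f"{b}_{r}" for r in regions]
        for s, r in zip(samples, regions):
            sample_meta.append((b, s, r))

        # --- developmental clones on the lineage tree (generations <= i_max;
        # deeper clones are smaller than any detectable VAF at this design)
        ind = simulate_individual(
            config.rate,
            {"case": config.case_panel_bp, "control": config.control_panel_bp},
            LineageParams(generations=i_max,
                          neuron_fraction=truncated.neuron_fraction),
            rng,
        )
        per_region = sample_regions(ind, len(regions), g,
                                    config.cells_per_sample, rng)
        seen: dict[int, list[tuple[str, float]]] = {}
        for sample, sampled in zip(samples, per_region):
            for sm in sampled:
                if sm.mutant_cells == 0:
                    continue
                seen.setdefault(id(sm.event), []).append((sample, sm.vaf))
        for event in ind.events:
            hits = seen.get(id(event), [])
            if not hits:
                continue
            n_detectable = sum(v >= 0.005 for _, v in hits)
            if n_detectable >= 2:
                truth_class = "MRM-developmental"
            elif n_detectable == 1:
                truth_class = "SRM-developmental"
            else:
                truth_class = "subthreshold-developmental"
            for sample, vaf in hits:
                plant(event.panel, event.site_index, b, sample,
                      min(vaf, 1.0), truth_class, event.generation)

        # --- clonal-haematopoiesis MRMs: present in every region, from blood
        for _ in range(rng.poisson(config.mrm_per_brain)):
            site_index = int(rng.integers(0, n_myelo_sites))
            blood_vaf = float(min(0.5, rng.lognormal(
                math.log(config.blood_vaf_mean), config.blood_vaf_sigma)))
            base_brain = blood_vaf / config.blood_brain_ratio
            for sample, r in zip(samples, regions):
                vaf = base_brain * region_mult.get(r, 1.0) * float(
                    rng.lognormal(0.0, config.region_vaf_jitter))
                plant("control", site_index, b, sample, min(vaf, 0.5),
                      "MRM-haematopoietic", None)
            if b in blood_paired:
                plant("control", site_index, b, f"{b}_Blood", blood_vaf,
                      "MRM-haematopoietic", None)

        # --- germline heterozygotes (VAF 0.5 everywhere)
        for k in range(config.n_germline_per_individual):
            panel = "case" if k % 2 == 0 else "control"
            panel_bp = (config.case_panel_bp if panel == "case"
                        else config.control_panel_bp)
            site_index = int(rng.integers(0, panel_bp))
            site = registry.get(panel, site_index)
            site["population_maf"] = 0.2 if k % 2 == 0 else 0.001
            targets = list(samples)
            if b in blood_paired:
                targets.append(f"{b}_Blood")
            for sample in targets:
                plant(panel, site_index, b, sample, 0.5, "germline", None)

    for b in sorted(blood_paired):
        sample_meta.append((b, f"{b}_Blood", "Blood"))

    # --- background error-only sites shared by every sample
    background: list[tuple[str, int]] = []
    for panel, bp in (("case", config.case_panel_bp),
                      ("control", config.control_panel_bp)):
        while len([s for s in background if s[0] == panel]) < config.n_background_sites:
            idx = int(rng.integers(0, bp))
            if (panel, idx) not in planted and (panel, idx) not in background:
                background.append((panel, idx))
                registry.get(panel, idx)

    # --- assemble the read-count table
    all_sites = list(planted) + background
    depths = np.maximum(
        rng.normal(config.depth_mean, config.depth_sd, size=len(sample_meta)),
        config.depth_floor).astype(int)
    rows: list[dict] = []
    for (individual, sample, region), depth in zip(sample_meta, depths):
        site_depths = rng.poisson(depth, size=len(all_sites))
        depth_fwd = rng.binomial(site_depths, 0.5)
        depth_rev = site_depths - depth_fwd
        vafs = np.array([
            planted.get(key, {}).get("vaf", {}).get(sample, 0.0)
            if key in planted else 0.0
            for key in all_sites])
        errs = np.array([registry.get(*key)["error_rate"] for key in all_sites])
        rhos = _sample_rho(vafs, errs, config.error_sample_cv)
        alt_fwd, alt_rev = sequence_counts(
            vafs, depth_fwd, depth_rev, errs, rhos, rng)
        for key, dfw, drv, afw, arv in zip(all_sites, depth_fwd, depth_rev,
                                           alt_fwd, alt_rev):
            site = registry.get(*key)
            rows.append({
                "individual_id": individual, "sample_id": sample,
                "region": region, "panel": key[0],
                "gene_label": site["gene_label"], "position": site["position"],
                "ref": site["ref"], "alt": site["alt"],
                "depth_fwd": int(dfw), "depth_rev": int(drv),
                "alt_fwd": int(afw), "alt_rev": int(arv),
                "population_maf": site["population_maf"],
                "repeat_flag": site["repeat_flag"],
            })
    reads = pd.DataFrame(rows, columns=READ_TABLE_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return reads, truth


def spike_in_mixture(vaf_levels=(0.002, 0.005, 0.01, 0.02, 0.05),
                     n_het_sites: int = 50, depth: float = 5374.0,
                     error_rate_mean: float = 2e-4,
                     error_rate_dispersion: float = 0.005,
                     error_sample_cv: float = 0.3,
                     n_replicates: int = 2, n_reference: int = 20,
                     n_null_sites: int = 200,
                     rng: np.random.Generator | int | None = None,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-genome mixture series for sensitivity/specificity scoring.

    Emulates spiking one genome into another so that the minor genome's
    heterozygous sites appear at each stated VAF level (the 0.2/0.5/1/2/5 %
    dilution design).  Reference (pure, 0 %) samples allow per-site error
    models to be fitted; ``n_null_sites`` error-only sites score specificity.
    Returns ``(reads, truth)`` in the cohort table schema.
    """
    for level in vaf_levels:
        if not (0.0 < level < 1.0):
            raise ValueError("VAF levels must be in (0, 1)")
    rng = np.random.default_rng(rng)
    cfg = StudyConfig(error_rate_mean=error_rate_mean,
                      error_rate_dispersion=error_rate_dispersion,
                      error_sample_cv=error_sample_cv)
    registry = _SiteRegistry(cfg, rng)
    sites = [("case", idx) for idx in range(n_het_sites + n_null_sites)]
    for key in sites:
        registry.get(*key)

    samples: list[tuple[str, float]] = []
    for level in vaf_levels:
        for rep in range(n_replicates):
            samples.append((f"mix_{level:g}_r{rep + 1}", level))
    for ref in range(n_reference):
        samples.append((f"pure_r{ref + 1}", 0.0))

    rows, truth_rows = [], []
    for sample, level in samples:
        total = rng.poisson(depth, size=len(sites))
        depth_fwd = rng.binomial(total, 0.5)
        depth_rev = total - depth_fwd
        vafs = np.array([level if idx < n_het_sites else 0.0
                         for _, idx in sites])
        errs = np.array([registry.get(*key)["error_rate"] for key in sites])
        rhos = _sample_rho(vafs, errs, error_sample_cv)
        alt_fwd, alt_rev = sequence_counts(vafs, depth_fwd, depth_rev, errs,
                                           rhos, rng)
        for key, vaf, dfw, drv, afw, arv in zip(sites, vafs, depth_fwd,
                                                depth_rev, alt_fwd, alt_rev):
            site = registry.get(*key)
            rows.append({
                "individual_id": "mixture", "sample_id": sample,
                "region": "mixture", "panel": "case",
                "gene_label": site["gene_label"], "position": site["position"],
                "ref": site["ref"], "alt": site["alt"],
                "depth_fwd": int(dfw), "depth_rev": int(drv),
                "alt_fwd": int(afw), "alt_rev": int(arv),
                "population_maf": 0.0, "repeat_flag": 0,
            })
            if vaf > 0:
                truth_rows.append({
                    "individual_id": "mixture", "sample_id": sample,
                    "panel": "case", "gene_label": site["gene_label"],
                    "position": site["position"], "ref": site["ref"],
                    "alt": site["alt"], "truth_class": "spike-in",
                    "generation": None, "true_vaf": vaf,
                })
    reads = pd.DataFrame(rows, columns=READ_TABLE_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return reads, truth
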