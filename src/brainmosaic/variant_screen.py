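"""Decision logic of the variant-confirmation pipeline.

Operates on tidy per-sample per-site read-count tables:

1. **Hard filters** — minimum total depth 1000, minimum alt reads 10, at
   least 4 alt reads on each strand, population MAF <= 1 %, no repeat flag.
2. **Per-site error model** — a beta-binomial fitted by method of moments to
   reference samples, capturing the site's error rate and an overdispersion
   factor for sample-to-sample variability beyond binomial.
3. **Confirmation test** — upper-tail beta-binomial probability of the
   observed alt count, Benjamini-Hochberg corrected over the samples tested.
4. **Classification** — single-region mutations (SRM: significant in exactly
   one region of an individual, against both the rest of that individual and
   the rest of the cohort), multi-region mutations (MRM: VAF 0.5–20 % in two
   or more regions, each significant against other individuals), germline
   (VAF ~ 0.5 across regions), or rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScreenConfig",
    "SiteErrorModel",
    "ClassifiedVariant",
    "hard_filter",
    "fit_site_error_model",
    "site_pvalue",
    "bh_adjust",
    "classify_variants",
    "detect_spike_ins",
    "screen_performance",
]


@dataclass(frozen=True)
class ScreenConfig:
    min_depth: int = 1000
    min_alt: int = 10
    min_strand_alt: int = 4
    max_population_maf: float = 0.01
    vaf_floor: float = 0.005
    mrm_vaf_ceiling: float = 0.20
    bh_alpha: float = 0.05
    pseudo_error_floor: float = 1e-5
    germline_band: tuple[float, float] = (0.35, 0.65)

    def __post_init__(self) -> None:
        if self.vaf_floor >= self.mrm_vaf_ceiling:
            raise ValueError("vaf_floor must be below mrm_vaf_ceiling")
        for name in ("min_depth", "min_alt", "min_strand_alt", "bh_alpha",
                     "pseudo_error_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SiteErrorModel:
    """Beta-binomial error model for one site, fitted from reference samples."""

    error_rate: float
    overdispersion: float
    n_reference_samples: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        if not (0.0 <= self.overdispersion < 1.0):
            raise ValueError("overdispersion must be in [0, 1)")


@dataclass
class ClassifiedVariant:
    """Outcome of the screen for one site in one individual."""

    panel: str
    gene_label: str
    position: int
    ref: str
    alt: str
    individual_id: str
    sample_ids: list[str]
    vafs: list[float]
    label: str                       # SRM | MRM | germline | rejected
    failed_filters: list[str] = field(default_factory=list)
    p_within: dict[str, float] = field(default_factory=dict)
    p_between: dict[str, float] = field(default_factory=dict)
    p_adjusted: dict[str, float] = field(default_factory=dict)

    @property
    def site(self) -> tuple[str, str, int, str, str]:
        return (self.panel, self.gene_label, self.position, self.ref, self.alt)

    @property
    def mean_vaf(self) -> float:
        return float(np.mean(self.vafs)) if self.vafs else 0.0


_ROW_FIELDS = ("depth_fwd", "depth_rev", "alt_fwd", "alt_rev",
               "population_maf", "repeat_flag")


def hard_filter(row, config: ScreenConfig | None = None) -> list[str]:
    """Apply the exclusion filters to one table row.

    Returns the list of failure reasons (empty list = pass): total depth
    < 1000, alt reads < 10, < 4 alt reads on either strand, population
    MAF > 1 %, or a repeat-region flag.
    """
    config = config or ScreenConfig()
    try:
        depth = row["depth_fwd"] + row["depth_rev"]
        alt = row["alt_fwd"] + row["alt_rev"]
        strand_min = min(row["alt_fwd"], row["alt_rev"])
        maf = row["population_maf"]
        repeat = row["repeat_flag"]
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed read-count row: {exc}") from exc
    reasons = []
    if depth < config.min_depth:
        reasons.append("depth")
    if alt < config.min_alt:
        reasons.append("alt_reads")
    if strand_min < config.min_strand_alt:
        reasons.append("strand")
    if maf > config.max_population_maf:
        reasons.append("population_maf")
    if repeat:
        reasons.append("repeat")
    return reasons


def fit_site_error_model(alts, depths,
                         config: ScreenConfig | None = None,
                         ) -> SiteErrorModel:
    """Method-of-moments beta-binomial fit across reference samples.

    The error rate is the pooled alt fraction (floored at
    ``pseudo_error_floor`` so tails are defined at zero-error sites); the
    overdispersion comes from the excess of the between-sample variance of
    per-sample alt fractions over the binomial expectation, clamped to 0
    when the moment estimate is negative.
    """
    config = config or ScreenConfig()
    alts = np.asarray(alts, dtype=float)
    depths = np.asarray(depths, dtype=float)
    usable = depths > 0
    if usable.sum() < 2:
        raise ValueError("need >= 2 reference samples with positive depth")
    alts, depths = alts[usable], depths[usable]
    e = float(np.sum(alts) / np.sum(depths))
    e = max(e, config.pseudo_error_floor)
    p_i = alts / depths
    w_var = float(np.var(p_i, ddof=1))
    inv_n = float(np.mean(1.0 / depths))
    denom = e * (1.0 - e) * (1.0 - inv_n)
    rho = 0.0
    if denom > 0:
        rho = (w_var - e * (1.0 - e) * inv_n) / denom
    rho = float(min(max(rho, 0.0), 1.0 - 1e-9))
    return SiteErrorModel(error_rate=min(e, 1.0 - 1e-12),
                          overdispersion=rho,
                          n_reference_samples=int(usable.sum()))


def site_pvalue(alt: int, depth: int, model: SiteErrorModel) -> float:
    """Upper-tail P(X >= alt) under the site's beta-binomial error model.

    With zero overdispersion this is the exact binomial survival function.
    Returns 1.0 for alt = 0; values are in (0, 1].
    """
    if alt > depth:
        raise ValueError("alt cannot exceed depth")
    if alt <= 0:
        return 1.0
    e, rho = model.error_rate, model.overdispersion
    if rho <= 0:
        return float(stats.binom.sf(alt - 1, depth, e))
    a = e * (1.0 - rho) / rho
    b = (1.0 - e) * (1.0 - rho) / rho
    return float(stats.betabinom.sf(alt - 1, depth, a, b))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    if n == 0:
        return p
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _vaf(row) -> float:
    depth = row["depth_fwd"] + row["depth_rev"]
    if depth == 0:
        return 0.0
    return (row["alt_fwd"] + row["alt_rev"]) / depth


def _strictest_reference_model(alts, depths,
                               config: ScreenConfig) -> SiteErrorModel:
    """Error model for 'significantly different from ALL reference samples'.

    A candidate that must exceed every reference sample is equivalently
    tested against the reference with the highest alt fraction, so the
    model's error rate is the maximum observed reference fraction (at least
    the pooled rate); the overdispersion is the method-of-moments fit across
    all references.  This rejects platform hotspots, where the whole cohort
    sits above the VAF floor, without costing sensitivity at clean sites.
    """
    pooled = fit_site_error_model(alts, depths, config)
    alts = np.asarray(alts, dtype=float)
    depths = np.asarray(depths, dtype=float)
    ok = depths > 0
    max_frac = float(np.max(alts[ok] / depths[ok]))
    e = min(max(max_frac, pooled.error_rate), 1.0 - 1e-12)
    return SiteErrorModel(error_rate=e,
                          overdispersion=pooled.overdispersion,
                          n_reference_samples=pooled.n_reference_samples)


_SITE_KEY = ["panel", "gene_label", "position", "ref", "alt"]


def classify_variants(table: pd.DataFrame,
                      config: ScreenConfig | None = None,
                      ) -> list[ClassifiedVariant]:
    """Run the full screen over a cohort read-count table.

    For every site with at least one candidate sample (hard filters passed,
    VAF >= the 0.5 % floor), two beta-binomial tests are run per sample of
    the carrying individual: against the individual's other samples (within)
    and against all samples of all other individuals (between).  P-values
    are BH-corrected over the samples tested at that site.  Labels:

    * ``germline`` — median VAF across the individual's regions inside the
      germline band with every region significant against the cohort;
    * ``SRM`` — exactly one region significant on both tests, with no other
      region of that individual significant against the cohort;
    * ``MRM`` — two or more regions with VAF in [0.5 %, 20 %], each
      significant against other individuals;
    * ``rejected`` — anything else.

    The BH family is the full set of comparisons run across the study (the
    number of samples tested): this keeps the probability of any false SRM
    call on an error-only cohort at or below ``bh_alpha``, which a per-site
    family cannot (each candidate site would separately spend the full
    alpha).  The output is invariant to row order and individual
    relabelling.
    """
    config = config or ScreenConfig()
    table = table.sort_values(_SITE_KEY + ["individual_id", "sample_id"],
                              kind="mergesort")
    # pass 1: compute raw p-values for every candidate (site, individual)
    pending: list[dict] = []
    for site_key, site_rows in table.groupby(_SITE_KEY, sort=True):
        depth = site_rows["depth_fwd"] + site_rows["depth_rev"]
        alt = site_rows["alt_fwd"] + site_rows["alt_rev"]
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
        site_rows = site_rows.assign(_depth=depth, _alt=alt, _vaf=vaf)

        candidates = []
        for _, row in site_rows.iterrows():
            fails = hard_filter(row, config)
            if not fails and row["_vaf"] >= config.vaf_floor:
                candidates.append(row)
        if not candidates:
            continue
        carriers = sorted({row["individual_id"] for row in candidates})

        for individual in carriers:
            mine = site_rows[site_rows["individual_id"] == individual]
            others = site_rows[site_rows["individual_id"] != individual]
            if len(others) < 2:
                raise ValueError(
                    "site lacks reference samples from other individuals: "
                    f"{site_key}")
            between_model = _strictest_reference_model(
                others["_alt"], others["_depth"], config)

            p_within: dict[str, float] = {}
            p_between: dict[str, float] = {}
            for _, row in mine.iterrows():
                sid = row["sample_id"]
                rest = mine[mine["sample_id"] != sid]
                if len(rest) >= 2:
                    within_model = _strictest_reference_model(
                        rest["_alt"], rest["_depth"], config)
                elif len(rest) == 1:
                    # too few samples for a dispersion fit: reuse the
                    # cohort's dispersion around the single reference
                    frac = float(rest["_alt"].iloc[0]
                                 / max(rest["_depth"].iloc[0], 1))
                    within_model = SiteErrorModel(
                        error_rate=min(max(frac, config.pseudo_error_floor),
                                       1.0 - 1e-12),
                        overdispersion=between_model.overdispersion,
                        n_reference_samples=1)
                else:
                    # single-region individuals: only the cohort test applies
                    within_model = between_model
                p_within[sid] = site_pvalue(
                    int(row["_alt"]), int(row["_depth"]), within_model)
                p_between[sid] = site_pvalue(
                    int(row["_alt"]), int(row["_depth"]), between_model)

            pending.append({
                "site_key": site_key, "individual": individual,
                "sids": list(p_within),
                "p_within": p_within, "p_between": p_between,
                "vaf_by_sid": dict(zip(mine["sample_id"], mine["_vaf"])),
                "fails_by_sid": {row["sample_id"]: hard_filter(row, config)
                                 for _, row in mine.iterrows()},
                "median_vaf": float(np.median(mine["_vaf"])),
            })

    # pass 2: BH over every comparison in the study, then label
    raw: list[float] = []
    for rec in pending:
        raw.extend(rec["p_within"][s] for s in rec["sids"])
        raw.extend(rec["p_between"][s] for s in rec["sids"])
    adj_all = bh_adjust(raw)
    cursor = 0
    out: list[ClassifiedVariant] = []
    alpha = config.bh_alpha
    for rec in pending:
        sids = rec["sids"]
        n = len(sids)
        adj_within = dict(zip(sids, adj_all[cursor: cursor + n]))
        adj_between = dict(zip(sids, adj_all[cursor + n: cursor + 2 * n]))
        cursor += 2 * n
        p_adjusted = {s: float(min(adj_within[s], adj_between[s]))
                      for s in sids}
        vaf_by_sid = rec["vaf_by_sid"]
        fails_by_sid = rec["fails_by_sid"]

        sig_both = [s for s in sids
                    if adj_within[s] <= alpha and adj_between[s] <= alpha]
        sig_between = [s for s in sids if adj_between[s] <= alpha]
        passing = [s for s in sids
                   if not fails_by_sid[s] and vaf_by_sid[s] >= config.vaf_floor]
        maf_failed = any("population_maf" in fails_by_sid[s] for s in sids)
        lo, hi = config.germline_band

        label = "rejected"
        if lo <= rec["median_vaf"] <= hi and len(sig_between) == len(sids):
            label = "germline"
        elif not maf_failed:
            mrm_regions = [
                s for s in sig_between
                if config.vaf_floor <= vaf_by_sid[s] <= config.mrm_vaf_ceiling
                and not fails_by_sid[s]]
            srm_regions = [s for s in sig_both if s in passing]
            if len(mrm_regions) >= 2:
                label = "MRM"
            elif (len(srm_regions) == 1
                  and len([s for s in sig_between if s in passing]) <= 1):
                label = "SRM"

        site_key = rec["site_key"]
        out.append(ClassifiedVariant(
            panel=site_key[0], gene_label=site_key[1],
            position=int(site_key[2]), ref=site_key[3], alt=site_key[4],
            individual_id=rec["individual"],
            sample_ids=sids,
            vafs=[float(vaf_by_sid[s]) for s in sids],
            label=label,
            failed_filters=sorted({f for fl in fails_by_sid.values()
                                   for f in fl}),
            p_within=rec["p_within"], p_between=rec["p_between"],
            p_adjusted=p_adjusted,
        ))
    return out


def detect_spike_ins(table: pd.DataFrame,
                     config: ScreenConfig | None = None,
                     reference_prefix: str = "pure_",
                     ) -> pd.DataFrame:
    """Score mixture samples against error models fitted on pure samples.

    Detection = hard filters passed + beta-binomial significance at the
    BH-corrected threshold (the operating point of the confirmation caller;
    the 0.5–20 % VAF band belongs to the cohort SRM/MRM classification, not
    to this per-site detection step).  Returns one row per (site, mixture
    sample) with the detection flag.
    """
    config = config or ScreenConfig()
    is_ref = table["sample_id"].str.startswith(reference_prefix)
    refs = table[is_ref].set_index(_SITE_KEY).sort_index()
    tests = table[~is_ref]
    rows = []
    raw_p = []
    for site_key, site_rows in tests.groupby(_SITE_KEY, sort=True):
        ref_rows = refs.loc[site_key]
        model = _strictest_reference_model(
            ref_rows["alt_fwd"] + ref_rows["alt_rev"],
            ref_rows["depth_fwd"] + ref_rows["depth_rev"], config)
        for _, row in site_rows.iterrows():
            depth = int(row["depth_fwd"] + row["depth_rev"])
            alt = int(row["alt_fwd"] + row["alt_rev"])
            p = site_pvalue(alt, depth, model)
            rows.append({
                "panel": site_key[0], "gene_label": site_key[1],
                "position": site_key[2], "ref": site_key[3],
                "alt": site_key[4], "sample_id": row["sample_id"],
                "vaf": alt / depth if depth else 0.0,
                "hard_filter_pass": not hard_filter(row, config),
                "p_raw": p,
            })
            raw_p.append(p)
    result = pd.DataFrame(rows)
    if len(result):
        result["p_bh"] = bh_adjust(raw_p)
        result["detected"] = (result["hard_filter_pass"]
                              & (result["p_bh"] <= config.bh_alpha))
    return result


def screen_performance(detected: pd.DataFrame, truth: pd.DataFrame,
                       vaf_bins=None) -> pd.DataFrame:
    """Sensitivity and specificity per true-VAF bin.

    ``sensitivity = TP / (TP + FN)``; ``specificity = 1 - FP / (FP + TN)``.
    Truth rows define the planted (site, sample) pairs and their true VAFs;
    detected rows not matching any truth pair are false positives (binned as
    VAF 0).  Empty bins report NaN, not 0.
    """
    key_cols = ["panel", "gene_label", "position", "ref", "alt", "sample_id"]
    truth_keys = truth.set_index(key_cols)["true_vaf"]
    merged = detected.set_index(key_cols)
    true_vaf = truth_keys.reindex(merged.index).fillna(0.0)
    merged = merged.assign(true_vaf=true_vaf.values)

    if vaf_bins is None:
        levels = sorted(truth["true_vaf"].unique())
        vaf_bins = [0.0] + levels
    rows = []
    for level in vaf_bins:
        sub = merged[np.isclose(merged["true_vaf"], level)]
        if len(sub) == 0:
            rows.append({"true_vaf": level, "n": 0, "sensitivity": np.nan,
                         "specificity": np.nan})
            continue
        det = sub["detected"].sum()
        if level > 0:
            rows.append({"true_vaf": level, "n": len(sub),
                         "sensitivity": det / len(sub), "specificity": np.nan})
        else:
            rows.append({"true_vaf": level, "n": len(sub),
                         "sensitivity": np.nan,
                         "specificity": 1.0 - det / len(sub)})
    return pd.DataFrame(rows)
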