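"""Summary-statistics data model, rescaling, meta-analysis, and QC.

Per-variant association results from sex-stratified case-control GWAS are the
atomic currency of the pipeline. This module rescales linear-mixed-model
output to the logistic scale, computes effective sample sizes for imbalanced
and proxy designs, combines cohorts by inverse-variance fixed-effects or
DerSimonian-Laird random-effects meta-analysis, tests for sex heterogeneity of
effect sizes, and applies the variant-level QC filters (anchor-cohort
presence, genotyping rate, cross-cohort frequency deviation).

p-values are computed from z-scores through log-scale survival functions so
that extremely significant variants (p << 1e-300) do not underflow the
intermediate computation; ``log10p_from_z`` is exact far beyond float range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

__all__ = [
    "AssocRecord", "MetaRecord", "SexMergedRecord",
    "p_from_z", "log10p_from_z",
    "rescale_lmm_to_logistic", "effective_sample_size",
    "harmonize", "meta_fixed", "meta_random",
    "sex_heterogeneity_test", "effect_ratio", "merge_sexes",
    "qc_filter", "meta_z_samplesize",
]


# ---------------------------------------------------------------------------
# data model

@dataclass
class AssocRecord:
    """One variant's association in one stratum (cohort x sex)."""

    variant_id: str
    chrom: str
    pos: int
    ea: str
    oa: str
    eaf: float
    beta: float
    se: float
    p: float
    n: float
    info: float = 1.0
    direction: str = ""

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError(f"{self.variant_id}: se must be positive")
        if str(self.ea) == str(self.oa):
            raise ValueError(f"{self.variant_id}: effect and other allele identical")
        if not (0 < self.eaf < 1):
            raise ValueError(f"{self.variant_id}: eaf must lie in (0,1)")

    @property
    def z(self) -> float:
        return self.beta / self.se


@dataclass
class MetaRecord(AssocRecord):
    """Meta-analyzed association with heterogeneity bookkeeping."""

    k_cohorts: int = 1
    q_stat: float = 0.0
    tau2: float = 0.0
    genotyping_rate: float = 1.0

    def __post_init__(self):
        super().__post_init__()
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        if self.k_cohorts < 1:
            raise ValueError("k_cohorts must be >= 1")


@dataclass
class SexMergedRecord:
    """Female and male meta-analysis results for one variant, with the
    cross-sex heterogeneity test attached."""

    female: MetaRecord
    male: MetaRecord
    z_het: float = field(default=np.nan)
    p_het: float = field(default=np.nan)
    effect_ratio: float = field(default=np.nan)


# ---------------------------------------------------------------------------
# z/p plumbing

def p_from_z(z) -> np.ndarray | float:
    """Two-sided normal p-value; vectorized, computed on the log scale."""
    z = np.abs(np.asarray(z, dtype=float))
    logp = np.log(2.0) + stats.norm.logsf(z)
    out = np.exp(logp)
    return out if out.ndim else float(np.minimum(out, 1.0))


def log10p_from_z(z) -> np.ndarray | float:
    """log10 of the two-sided normal p-value (exact below float range)."""
    z = np.abs(np.asarray(z, dtype=float))
    out = (np.log(2.0) + stats.norm.logsf(z)) / math.log(10.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# rescaling and effective sample size

def rescale_lmm_to_logistic(beta_raw: float, se_raw: float,
                            case_fraction: float) -> tuple[float, float]:
    """Rescale linear-mixed-model effect/SE to the log-odds scale.

    Divides both by mu*(1-mu) with mu the case fraction, leaving the z-score
    (and hence the p-value) invariant.
    """
    mu = case_fraction
    if not (0 < mu < 1):
        raise ValueError("case_fraction must lie strictly in (0,1)")
    scale = mu * (1.0 - mu)
    return beta_raw / scale, se_raw / scale


def effective_sample_size(n_cases: float, n_controls: float,
                          is_proxy: bool = False) -> float:
    """Effective sample size 4*N*v*(1-v), v the case fraction; proxy-design
    contributions are divided by 4 to reflect their reduced power."""
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    n = n_cases + n_controls
    v = n_cases / n
    n_eff = 4.0 * n * v * (1.0 - v)
    return n_eff / 4.0 if is_proxy else n_eff


# ---------------------------------------------------------------------------
# allele harmonization

class HarmonizationError(ValueError):
    pass


def harmonize(record: AssocRecord, ref_ea: str, ref_oa: str,
              drop_ambiguous: bool = True) -> AssocRecord | None:
    """Align a record to reference effect/other alleles.

    Tries a straight match, an EA/OA swap (flipping beta and eaf), then a
    strand complement of both. Strand-ambiguous variants (A/T, C/G) with
    eaf in [0.4, 0.6] are unresolvable and return None when
    ``drop_ambiguous`` (the caller logs the drop). Anything else that cannot
    be aligned raises :class:`HarmonizationError`.
    """
    ea, oa = record.ea.upper(), record.oa.upper()
    ref_ea, ref_oa = ref_ea.upper(), ref_oa.upper()
    ambiguous = _COMPLEMENT.get(ea) == oa
    if ambiguous and drop_ambiguous and 0.4 <= record.eaf <= 0.6:
        return None

    def flipped() -> AssocRecord:
        rec = AssocRecord(
            record.variant_id, record.chrom, record.pos, ref_ea, ref_oa,
            1.0 - record.eaf, -record.beta, record.se, record.p, record.n,
            record.info, record.direction)
        return rec

    if (ea, oa) == (ref_ea, ref_oa):
        return record
    if (ea, oa) == (ref_oa, ref_ea):
        return flipped()
    cea = _COMPLEMENT.get(ea)
    coa = _COMPLEMENT.get(oa)
    if (cea, coa) == (ref_ea, ref_oa):
        rec = AssocRecord(record.variant_id, record.chrom, record.pos,
                          ref_ea, ref_oa, record.eaf, record.beta, record.se,
                          record.p, record.n, record.info, record.direction)
        return rec
    if (cea, coa) == (ref_oa, ref_ea):
        return flipped()
    raise HarmonizationError(
        f"{record.variant_id}: alleles {ea}/{oa} cannot be aligned to "
        f"{ref_ea}/{ref_oa}")


def _direction_char(beta: float) -> str:
    if beta > 0:
        return "+"
    if beta < 0:
        return "-"
    return "0"


# ---------------------------------------------------------------------------
# meta-analysis

def _harmonized(records: list[AssocRecord]) -> list[AssocRecord | None]:
    ref = records[0]
    out: list[AssocRecord | None] = [ref]
    for rec in records[1:]:
        out.append(harmonize(rec, ref.ea, ref.oa))
    return out


def _meta_core(records: list[AssocRecord]):
    recs = [r for r in _harmonized(records) if r is not None]
    if not recs:
        raise HarmonizationError("no records left after ambiguity drops")
    betas = np.array([r.beta for r in recs])
    ses = np.array([r.se for r in recs])
    w = 1.0 / ses ** 2
    beta_f = float(np.sum(w * betas) / np.sum(w))
    q = float(np.sum(w * (betas - beta_f) ** 2))
    direction = "".join(_direction_char(b) for b in betas)
    return recs, betas, ses, w, beta_f, q, direction


def _assemble_meta(ref: AssocRecord, recs, beta: float, se: float, q: float,
                   tau2: float, direction: str, k_total: int) -> MetaRecord:
    z = beta / se
    eaf = float(np.average([r.eaf for r in recs], weights=[r.n for r in recs]))
    n = float(np.sum([r.n for r in recs]))
    info = float(np.average([r.info for r in recs], weights=[r.n for r in recs]))
    return MetaRecord(
        variant_id=ref.variant_id, chrom=ref.chrom, pos=ref.pos,
        ea=ref.ea, oa=ref.oa, eaf=eaf, beta=beta, se=se,
        p=p_from_z(z), n=n, info=info, direction=direction,
        k_cohorts=len(recs), q_stat=q, tau2=tau2,
        genotyping_rate=len(recs) / k_total,
    )


def meta_fixed(records: list[AssocRecord], k_total: int | None = None) -> MetaRecord:
    """Inverse-variance fixed-effects meta-analysis with allele harmonization.

    Cochran's Q and the per-cohort sign direction string are attached.
    """
    if not records:
        raise ValueError("at least one record required")
    recs, betas, ses, w, beta_f, q, direction = _meta_core(records)
    se_f = float(1.0 / math.sqrt(np.sum(w)))
    return _assemble_meta(recs[0], recs, beta_f, se_f, q, 0.0, direction,
                          k_total or len(records))


def meta_random(records: list[AssocRecord], k_total: int | None = None) -> MetaRecord:
    """DerSimonian-Laird random-effects meta-analysis (k >= 2).

    tau2 = max(0, (Q - (k-1)) / (sum(w) - sum(w^2)/sum(w))); weights are then
    1/(se^2 + tau2). With homogeneous cohorts (Q <= k-1) this collapses to the
    fixed-effects result.
    """
    if len(records) < 2:
        raise ValueError("random-effects meta-analysis needs >= 2 cohorts")
    recs, betas, ses, w, beta_f, q, direction = _meta_core(records)
    k = len(recs)
    denom = np.sum(w) - np.sum(w ** 2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (ses ** 2 + tau2)
    beta_r = float(np.sum(w_star * betas) / np.sum(w_star))
    se_r = float(1.0 / math.sqrt(np.sum(w_star)))
    return _assemble_meta(recs[0], recs, beta_r, se_r, q, tau2, direction,
                          k_total or len(records))


# ---------------------------------------------------------------------------
# sex heterogeneity

def sex_heterogeneity_test(female, male, rho: float = 0.0):
    """z-test on the female-male effect difference.

    z = (bF - bM) / sqrt(seF^2 + seM^2 - 2*rho*seF*seM); rho (cross-stratum
    overlap correlation) defaults to 0 for disjoint strata. Returns
    (z_het, p_het, effect_ratio).
    """
    bf, sf = float(female.beta), float(female.se)
    bm, sm = float(male.beta), float(male.se)
    if sf <= 0 or sm <= 0:
        raise ValueError("standard errors must be positive")
    denom = math.sqrt(sf ** 2 + sm ** 2 - 2.0 * rho * sf * sm)
    z = (bf - bm) / denom
    return z, p_from_z(z), effect_ratio(bf, bm)


def effect_ratio(beta_f: float, beta_m: float,
                 opposite_sign_inf: bool = False) -> float:
    """Cross-sex effect-magnitude ratio max(|bF|,|bM|)/min(|bF|,|bM|).

    With ``opposite_sign_inf`` (the locus-filter convention), effects of
    opposite sign count as infinitely discordant.
    """
    if opposite_sign_inf and beta_f * beta_m < 0:
        return math.inf
    a, b = abs(beta_f), abs(beta_m)
    lo, hi = min(a, b), max(a, b)
    if lo == 0.0:
        return math.inf if hi > 0 else np.nan
    return hi / lo


def merge_sexes(female: pd.DataFrame, male: pd.DataFrame,
                rho: float = 0.0) -> pd.DataFrame:
    """Join per-sex meta tables on variant_id and attach the heterogeneity
    test (vectorized); columns get _f/_m suffixes."""
    merged = female.merge(male, on=["variant_id", "chrom", "pos", "ea", "oa"],
                          suffixes=("_f", "_m"))
    sf = merged["se_f"].to_numpy()
    sm = merged["se_m"].to_numpy()
    bf = merged["beta_f"].to_numpy()
    bm = merged["beta_m"].to_numpy()
    z = (bf - bm) / np.sqrt(sf ** 2 + sm ** 2 - 2.0 * rho * sf * sm)
    merged["z_het"] = z
    merged["p_het"] = p_from_z(z)
    a = np.abs(bf)
    b = np.abs(bm)
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(lo > 0, hi / lo, np.where(hi > 0, np.inf, np.nan))
    merged["effect_ratio"] = ratio
    return merged


# ---------------------------------------------------------------------------
# QC filters

def qc_filter(merged_table: pd.DataFrame, anchor_cohort: str,
              rate_min: float = 0.9, freq_dev_max: float = 0.2,
              freq_cohorts: list[str] | None = None):
    """Apply the post-meta variant filters.

    ``merged_table`` carries per-cohort effect-allele frequencies in columns
    ``eaf_<cohort>`` (NaN = variant absent from that cohort). A variant is
    kept iff it is present in the anchor cohort, present in at least
    ``rate_min`` of all cohorts, and its max pairwise EAF deviation among the
    designated frequency cohorts is <= ``freq_dev_max``. Returns
    (filtered_table, drop_log) where the drop log records one row per dropped
    variant with a machine-readable reason.
    """
    eaf_cols = [c for c in merged_table.columns if c.startswith("eaf_")
                and c not in ("eaf_f", "eaf_m")]
    cohorts = [c[len("eaf_"):] for c in eaf_cols]
    if anchor_cohort not in cohorts:
        raise KeyError(f"unknown anchor cohort {anchor_cohort!r}; "
                       f"available: {cohorts}")
    if freq_cohorts is None:
        freq_cohorts = cohorts
    unknown = set(freq_cohorts) - set(cohorts)
    if unknown:
        raise KeyError(f"unknown frequency cohorts: {sorted(unknown)}")

    eaf = merged_table[eaf_cols].to_numpy(dtype=float)
    present = ~np.isnan(eaf)
    anchor_ix = cohorts.index(anchor_cohort)
    freq_ix = [cohorts.index(c) for c in freq_cohorts]

    in_anchor = present[:, anchor_ix]
    rate_ok = present.mean(axis=1) >= rate_min
    sub = eaf[:, freq_ix]
    dev = np.nanmax(sub, axis=1) - np.nanmin(sub, axis=1)
    dev = np.where(np.isnan(dev), 0.0, dev)
    freq_ok = dev <= freq_dev_max

    keep = in_anchor & rate_ok & freq_ok
    reasons = np.select(
        [~in_anchor, ~rate_ok, ~freq_ok],
        ["anchor", "genotyping_rate", "freq_deviation"], default="")
    drop_log = pd.DataFrame({
        "variant_id": merged_table.loc[~keep, "variant_id"].to_numpy(),
        "reason": reasons[~keep],
    })
    return merged_table.loc[keep].reset_index(drop=True), drop_log


# ---------------------------------------------------------------------------
# sample-size weighted z combination

def meta_z_samplesize(z1: float, n1: float, z2: float, n2: float) -> float:
    """Sample-size weighted combination of z-scores:
    (sqrt(n1)*z1 + sqrt(n2)*z2) / sqrt(n1 + n2)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    return (math.sqrt(n1) * z1 + math.sqrt(n2) * z2) / math.sqrt(n1 + n2)
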