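"""Bayesian colocalization (Wakefield ABF), SMR, and a HEIDI-style check.

Colocalization compares two association datasets at a locus under five
hypotheses: no association (H0), association with one trait only (H1/H2),
with both traits through distinct causal variants (H3), or through a shared
variant (H4). Per-SNP evidence is the Wakefield approximate log Bayes factor

    lABF = 0.5 * (log(1 - r) + r * z^2),   r = sd_prior^2 / (sd_prior^2 + se^2),

and hypothesis posteriors are computed by summing single-causal-variant
configurations in log space. The adjusted-prior mode re-runs with an
elevated shared-variant prior and the best PP4 across modes is kept.

SMR estimates the causal effect of an exposure (e.g. cis-regulated protein
abundance) on an outcome as the Wald ratio b_gwas/b_qtl with test statistic
z_smr^2 = z_gwas^2 z_qtl^2 / (z_gwas^2 + z_qtl^2) ~ chi2(1). The HEIDI-style
test asks whether LD-linked instruments around the top QTL give heterogeneous
Wald ratios (a signature of linkage rather than causality/pleiotropy); its
statistic is referred to a Satterthwaite-matched scaled chi-square, a
documented simplification of the original saddlepoint approach, hence the
``heidi_like`` name.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "ColocDataset", "ColocResult", "SmrResult",
    "wakefield_labf", "coloc_abf", "classify_pp4",
    "smr_test", "heidi_like", "validate_protein",
]

#: effect-scale prior SDs: quantitative traits, case-control (log-odds)
SD_PRIOR_QUANT = 0.2
SD_PRIOR_CC = 0.15


@dataclass
class ColocDataset:
    """One trait's summary statistics at a locus, allele-aligned with its
    partner dataset."""

    variant_ids: list[str]
    beta: np.ndarray
    se: np.ndarray
    trait_type: str = "quant"  # "quant" | "cc"
    sd_prior: float | None = None

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if self.sd_prior is None:
            self.sd_prior = (SD_PRIOR_CC if self.trait_type == "cc"
                             else SD_PRIOR_QUANT)
        if np.any(self.se <= 0):
            raise ValueError("standard errors must be positive")

    @property
    def labf(self) -> np.ndarray:
        return wakefield_labf(self.beta, self.se, self.sd_prior)


@dataclass
class ColocResult:
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_snps: int
    priors: tuple[float, float, float]
    mode: str = "default"

    def __post_init__(self):
        total = self.pp0 + self.pp1 + self.pp2 + self.pp3 + self.pp4
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"posteriors sum to {total}, not 1")

    @property
    def pp(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])


@dataclass
class SmrResult:
    b_xy: float
    z2_smr: float
    p_smr: float
    p_heidi: float | None = field(default=None)
    n_heidi_snps: int = 0


# ---------------------------------------------------------------------------

def wakefield_labf(beta, se, sd_prior) -> np.ndarray | float:
    """Wakefield approximate log Bayes factor (association vs null)."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0) or sd_prior <= 0:
        raise ValueError("se and sd_prior must be positive")
    r = sd_prior ** 2 / (sd_prior ** 2 + se ** 2)
    z2 = (beta / se) ** 2
    out = 0.5 * (np.log1p(-r) + r * z2)
    return out if out.ndim else float(out)


def _coloc_single(l1: np.ndarray, l2: np.ndarray,
                  p1: float, p2: float, p12: float, mode: str) -> ColocResult:
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    # H3 sums BF1_i * BF2_j over i != j = (sum_i)(sum_j) - sum_i(both)
    s3 = _logdiff(s1 + s2, s12)
    lh = np.array([
        0.0,
        math.log(p1) + s1,
        math.log(p2) + s2,
        math.log(p1) + math.log(p2) + s3,
        math.log(p12) + s12,
    ])
    pp = np.exp(lh - logsumexp(lh))
    return ColocResult(*pp, n_snps=len(l1), priors=(p1, p2, p12), mode=mode)


def _logdiff(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) computed stably; -inf when a <= b."""
    if b >= a:
        return -np.inf
    return a + math.log1p(-math.exp(b - a))


def coloc_abf(d1: ColocDataset, d2: ColocDataset,
              p1: float = 1e-4, p2: float = 1e-4, p12: float = 1e-5,
              p12_adjusted: float | None = 5e-5,
              min_snps: int = 10) -> ColocResult:
    """Single-causal-variant colocalization of two aligned datasets.

    Runs with the default per-SNP priors (p1, p2, p12) and, when
    ``p12_adjusted`` is given, a second adjusted-prior pass with the elevated
    shared prior; the result with the best PP4 is returned (its ``mode``
    records which). Requires >= ``min_snps`` shared variants aligned in the
    same order (default 10; tiny toy loci may lower it).
    """
    if d1.variant_ids != d2.variant_ids:
        raise ValueError("datasets are not variant-aligned; harmonize first")
    if len(d1.variant_ids) < min_snps:
        raise ValueError(
            f"need >= {min_snps} shared variants for colocalization")
    res = _coloc_single(d1.labf, d2.labf, p1, p2, p12, "default")
    if p12_adjusted is not None and p12_adjusted != p12:
        adj = _coloc_single(d1.labf, d2.labf, p1, p2, p12_adjusted, "adjusted")
        if adj.pp4 > res.pp4:
            return adj
    return res


def classify_pp4(pp4: float) -> str:
    """>= 0.7 strong, >= 0.4 suggestive, else none."""
    if not (0.0 <= pp4 <= 1.0):
        raise ValueError("PP4 must lie in [0,1]")
    if pp4 >= 0.7:
        return "strong"
    if pp4 >= 0.4:
        return "suggestive"
    return "none"


# ---------------------------------------------------------------------------
# SMR

def smr_test(z_gwas: float, z_qtl: float,
             b_gwas: float, b_qtl: float) -> SmrResult:
    """Wald-ratio causal test from top-QTL summary statistics."""
    if z_qtl == 0:
        raise ValueError("z_qtl must be nonzero")
    b_xy = b_gwas / b_qtl
    z2 = (z_gwas ** 2 * z_qtl ** 2) / (z_gwas ** 2 + z_qtl ** 2) \
        if z_gwas != 0 else 0.0
    p = float(stats.chi2.sf(z2, df=1)) if z2 > 0 else 1.0
    return SmrResult(b_xy=b_xy, z2_smr=z2, p_smr=p)


def heidi_like(b_gwas: np.ndarray, se_gwas: np.ndarray,
               b_qtl: np.ndarray, se_qtl: np.ndarray,
               ld_corr: np.ndarray, top_idx: int,
               p_qtl_enter: float = 1.6e-3, max_snps: int = 20) -> tuple[float | None, int]:
    """Heterogeneity of Wald ratios across LD-linked instruments.

    Instruments beside the top QTL variant are eligible when their QTL
    p-value passes ``p_qtl_enter`` (capped at the ``max_snps`` strongest).
    For each, d_i = b_xy(i) - b_xy(top); variances and covariances of the
    ratios come from the delta method with LD-derived covariances between
    effect estimates. The statistic sum(z_d^2) is referred to a
    Satterthwaite-matched scaled chi-square. Small p flags LD-driven
    heterogeneity. Returns (p_heidi, n_snps); p is None with < 3 eligible
    instruments.
    """
    b_gwas = np.asarray(b_gwas, float)
    se_gwas = np.asarray(se_gwas, float)
    b_qtl = np.asarray(b_qtl, float)
    se_qtl = np.asarray(se_qtl, float)
    z_qtl = b_qtl / se_qtl
    p_qtl = 2.0 * stats.norm.sf(np.abs(z_qtl))
    eligible = np.flatnonzero((p_qtl < p_qtl_enter)
                              & (np.arange(len(b_qtl)) != top_idx)
                              & (b_qtl != 0))
    if len(eligible) > max_snps:
        eligible = eligible[np.argsort(p_qtl[eligible])[:max_snps]]
        eligible = np.sort(eligible)
    k = len(eligible)
    if k < 3:
        return None, k

    t = top_idx
    bxy_t = b_gwas[t] / b_qtl[t]
    bxy_i = b_gwas[eligible] / b_qtl[eligible]
    d = bxy_i - bxy_t

    # delta-method gradient of b_xy(i) - b_xy(t) wrt (b_gwas_i, b_qtl_i,
    # b_gwas_t, b_qtl_t); effect-estimate covariances are r_ij * se_i * se_j
    # within each trait (independent across traits).
    idx = list(eligible)
    r_it = ld_corr[idx, t]
    r_ij = ld_corr[np.ix_(idx, idx)]
    gi_g = 1.0 / b_qtl[eligible]              # d d_i / d b_gwas_i
    gi_q = -b_gwas[eligible] / b_qtl[eligible] ** 2
    gt_g = -1.0 / b_qtl[t]
    gt_q = b_gwas[t] / b_qtl[t] ** 2

    seg_i = se_gwas[eligible]
    seq_i = se_qtl[eligible]
    seg_t = se_gwas[t]
    seq_t = se_qtl[t]

    cov = np.empty((k, k))
    for a in range(k):
        for b in range(k):
            cg = (gi_g[a] * gi_g[b] * r_ij[a, b] * seg_i[a] * seg_i[b]
                  + gi_g[a] * gt_g * r_it[b] * seg_i[a] * seg_t
                  + gt_g * gi_g[b] * r_it[a] * seg_t * seg_i[b]
                  + gt_g * gt_g * seg_t ** 2)
            cq = (gi_q[a] * gi_q[b] * r_ij[a, b] * seq_i[a] * seq_i[b]
                  + gi_q[a] * gt_q * r_it[b] * seq_i[a] * seq_t
                  + gt_q * gi_q[b] * r_it[a] * seq_t * seq_i[b]
                  + gt_q * gt_q * seq_t ** 2)
            cov[a, b] = cg + cq

    var = np.diag(cov).copy()
    if np.any(var <= 0):
        return None, k
    z_d = d / np.sqrt(var)
    C = cov / np.sqrt(np.outer(var, var))
    # drop near-perfect collinearity to keep the correlation matrix usable
    keep = _drop_collinear(C)
    if keep.sum() < 3:
        return None, int(keep.sum())
    z_d = z_d[keep]
    C = C[np.ix_(keep, keep)]
    stat = float(np.sum(z_d ** 2))
    mean = float(np.trace(C))           # = number kept
    var_stat = 2.0 * float(np.sum(C * C))
    c = var_stat / (2.0 * mean)
    nu = mean / c
    p = float(stats.chi2.sf(stat / c, df=nu))
    return p, int(keep.sum())


def _drop_collinear(C: np.ndarray, r_max: float = 0.995) -> np.ndarray:
    k = len(C)
    keep = np.ones(k, dtype=bool)
    for i in range(k):
        if not keep[i]:
            continue
        for j in range(i + 1, k):
            if keep[j] and abs(C[i, j]) > r_max:
                keep[j] = False
    return keep


# ---------------------------------------------------------------------------

def validate_protein(smr: SmrResult | None, coloc: ColocResult | None,
                     q_smr: float | None = None,
                     alpha_fdr: float = 0.05,
                     alpha_heidi: float = 0.05,
                     pp4_support: float = 0.4) -> str:
    """Combine SMR and colocalization into a support label.

    SMR supports a protein when its FDR-adjusted p (``q_smr``; falls back to
    the raw p) is significant and the HEIDI-like test is non-significant
    (no evidence of LD bias). Colocalization supports at suggestive PP4
    (>= 0.4). Returns 'both' / 'smr_only' / 'coloc_only' / 'none'.
    """
    smr_ok = False
    if smr is not None:
        p_eff = q_smr if q_smr is not None else smr.p_smr
        heidi_ok = smr.p_heidi is None or smr.p_heidi > alpha_heidi
        smr_ok = p_eff < alpha_fdr and heidi_ok
    coloc_ok = coloc is not None and coloc.pp4 >= pp4_support
    if smr_ok and coloc_ok:
        return "both"
    if smr_ok:
        return "smr_only"
    if coloc_ok:
        return "coloc_only"
    return "none"
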