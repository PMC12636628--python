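"""Synthetic data generation for end-to-end pipeline testing.

Every input the pipeline consumes can be generated here with the statistical
structure the downstream analyses assume: LD-block-structured haplotype
panels, per-sex case-control and proxy-phenotype GWAS summary statistics with
planted sex-specific effects, cis-QTL summary statistics whose causal variants
do or do not coincide with GWAS effects (ground-truth colocalization labels),
and a structural-variant locus tagged by SNVs at configurable r-squared.

LD is produced by a block copula: a latent AR(1) Gaussian per block,
thresholded to binary haplotype alleles. The latent autocorrelation is
calibrated (by inverting the bivariate-normal orthant probability) so that
the *realized* correlation between adjacent same-block variants equals the
requested ``within_block_r``; all variants in a block share an allele
frequency so this calibration is exact. Blocks are independent, emulating
LD blocks separated by recombination hotspots. This is deliberately simpler
than coalescent simulation: it is fast and exercises clumping, colocalization
and tagging, which is all the pipeline needs.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .sumstats import p_from_z

__all__ = [
    "HaplotypePanel", "PlantedEffect", "CohortSpec", "GeneModel", "SvLocus",
    "simulate_panel", "simulate_case_control_gwas", "build_proxy_phenotype",
    "simulate_qtl_and_weights", "simulate_sv_locus",
    "MissingVariantError", "InfeasibleLDError",
]


class MissingVariantError(KeyError):
    """A planted effect references a variant absent from the panel."""


class InfeasibleLDError(ValueError):
    """The requested two-locus r-squared is not achievable at the given
    allele frequencies."""


class Mechanism(str, Enum):
    direct = "direct"
    via_protein = "via_protein"


# ---------------------------------------------------------------------------
# domain types

@dataclass
class HaplotypePanel:
    """Binary haplotype matrix with block structure.

    ``haplotypes`` is (2N x M); haplotype pairs (2i, 2i+1) belong to sample i.
    Positions are 1-based and strictly increasing within a chromosome; every
    variant belongs to exactly one LD block.
    """

    variant_ids: list[str]
    chrom: np.ndarray
    positions: np.ndarray
    ea: list[str]
    oa: list[str]
    haplotypes: np.ndarray
    block_map: np.ndarray
    eaf: np.ndarray
    apoe_region: tuple[str, int, int] | None = None

    def __post_init__(self):
        if not np.all(np.isin(self.haplotypes, [0, 1])):
            raise ValueError("haplotype entries must be 0/1")
        for c in np.unique(self.chrom):
            pos = self.positions[self.chrom == c]
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def n_samples(self) -> int:
        return self.haplotypes.shape[0] // 2

    def index_of(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise MissingVariantError(variant_id) from None

    def dosages(self, variant_ids: Sequence[str] | None = None) -> np.ndarray:
        """Per-sample dosage matrix (N x M) for the requested variants."""
        H = self.haplotypes
        d = H[0::2, :].astype(np.int16) + H[1::2, :]
        if variant_ids is None:
            return d
        cols = [self.index_of(v) for v in variant_ids]
        return d[:, cols]

    def r2(self, ids_a: Sequence[str], ids_b: Sequence[str] | None = None) -> np.ndarray:
        """Empirical haplotype r-squared between two variant lists."""
        if ids_b is None:
            ids_b = ids_a
        A = self.haplotypes[:, [self.index_of(v) for v in ids_a]].astype(float)
        B = self.haplotypes[:, [self.index_of(v) for v in ids_b]].astype(float)
        A = A - A.mean(axis=0)
        B = B - B.mean(axis=0)
        sa = np.sqrt((A ** 2).mean(axis=0))
        sb = np.sqrt((B ** 2).mean(axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (A.T @ B) / len(A) / np.outer(sa, sb)
        return np.nan_to_num(r) ** 2


@dataclass
class PlantedEffect:
    """Ground-truth per-sex effect of one variant (log-odds units)."""

    variant_id: str
    beta_female: float
    beta_male: float
    mechanism: Mechanism = Mechanism.direct
    target_gene: str | None = None

    def beta(self, sex: str) -> float:
        return self.beta_female if sex == "female" else self.beta_male

    @property
    def cross_sex_ratio(self) -> float:
        a, b = abs(self.beta_female), abs(self.beta_male)
        if min(a, b) == 0:
            return np.inf if max(a, b) > 0 else np.nan
        return max(a, b) / min(a, b)


@dataclass
class CohortSpec:
    """One GWAS cohort: direct case-control or parental proxy design."""

    name: str
    n_cases: int
    n_controls: int
    design: str = "case_control"
    ancestry_label: str = "EUR"
    proxy_attenuation: float = 2.0  # planted beta divided by this for proxy

    def __post_init__(self):
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("case/control counts must be positive")
        if self.design not in ("case_control", "proxy"):
            raise ValueError(f"unknown design {self.design!r}")

    @property
    def n(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n


@dataclass
class GeneModel:
    """Ground truth for one gene's cis genetic regulation."""

    gene_id: str
    chrom: str
    tss: int
    causal_variants: list[str]
    beta_female: list[float]
    beta_male: list[float] | None = None  # None = sex-identical regulation
    cis_window: int = 1_000_000

    def betas(self, stratum: str) -> list[float]:
        if stratum == "male" and self.beta_male is not None:
            return self.beta_male
        return list(self.beta_female)


# ---------------------------------------------------------------------------
# panel simulation

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

#: (within_block_r, freq) -> calibrated latent AR(1) correlation
_RHO_CACHE: dict[tuple[float, float], float] = {}


def _latent_rho_for_binary_r(r_target: float, freq: float) -> float:
    """Invert the thresholded-Gaussian copula: latent correlation giving a
    binary (phi) correlation of ``r_target`` at shared allele frequency."""
    if r_target <= 0:
        return 0.0
    t = stats.norm.ppf(freq)
    var = freq * (1 - freq)

    def binary_corr(rho):
        p11 = stats.multivariate_normal(mean=[0, 0],
                                        cov=[[1, rho], [rho, 1]]).cdf([t, t])
        return (p11 - freq ** 2) / var

    f = lambda rho: binary_corr(rho) - r_target
    hi = 1 - 1e-9
    if f(hi) < 0:
        return hi
    return optimize.brentq(f, 0.0, hi, xtol=1e-10)


def simulate_panel(n_blocks: int, variants_per_block: int, within_block_r: float,
                   n_haplotypes: int, seed: int, *,
                   freq_range: tuple[float, float] = (0.1, 0.9),
                   chrom: str = "1", block_spacing: int = 3_000_000,
                   variant_spacing: int = 5_000,
                   apoe_block: int | None = None) -> HaplotypePanel:
    """Simulate a haplotype panel with independent LD blocks.

    Adjacent same-block variants realize correlation ``within_block_r`` (so
    r-squared ``within_block_r**2``); variants k apart decay approximately
    geometrically; cross-block r-squared is 0 in expectation. All variants in
    a block share one allele frequency drawn from ``freq_range``.

    ``apoe_block`` marks one block as a stand-in for a major-effect region to
    be excluded downstream; its span (plus or minus 5 Mb around its midpoint)
    is recorded in ``panel.apoe_region``.
    """
    if n_blocks <= 0 or variants_per_block <= 0 or n_haplotypes <= 0:
        raise ValueError("panel dimensions must be positive")
    if not (0.0 <= within_block_r < 1.0):
        raise ValueError("within_block_r must lie in [0,1)")
    rng = np.random.default_rng(seed)
    m = n_blocks * variants_per_block
    haplotypes = np.empty((n_haplotypes, m), dtype=np.uint8)
    block_map = np.repeat(np.arange(n_blocks), variants_per_block)
    freqs = np.empty(m)
    for b in range(n_blocks):
        # block frequencies live on a 0.01 grid so the copula calibration
        # (one brentq per (r, freq) pair) is cached across blocks and calls
        key = round(float(rng.uniform(*freq_range)), 2)
        cache_key = (round(within_block_r, 6), key)
        if cache_key not in _RHO_CACHE:
            _RHO_CACHE[cache_key] = _latent_rho_for_binary_r(
                within_block_r, key)
        rho = _RHO_CACHE[cache_key]
        t = stats.norm.ppf(key)
        z = rng.standard_normal((n_haplotypes, variants_per_block))
        for j in range(1, variants_per_block):
            z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho ** 2) * z[:, j]
        cols = slice(b * variants_per_block, (b + 1) * variants_per_block)
        haplotypes[:, cols] = (z < t).astype(np.uint8)
        freqs[cols] = key

    positions = np.empty(m, dtype=np.int64)
    for b in range(n_blocks):
        start = 1 + b * block_spacing
        cols = slice(b * variants_per_block, (b + 1) * variants_per_block)
        positions[cols] = start + variant_spacing * np.arange(variants_per_block)
    pair_ix = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    ea = [_ALLELE_PAIRS[i][0] for i in pair_ix]
    oa = [_ALLELE_PAIRS[i][1] for i in pair_ix]
    ids = [f"rs{b}_{j}" for b in range(n_blocks) for j in range(variants_per_block)]

    apoe_region = None
    if apoe_block is not None:
        cols = block_map == apoe_block
        mid = int(positions[cols].mean())
        apoe_region = (chrom, max(1, mid - 5_000_000), mid + 5_000_000)

    return HaplotypePanel(
        variant_ids=ids,
        chrom=np.array([chrom] * m, dtype=object),
        positions=positions, ea=ea, oa=oa,
        haplotypes=haplotypes, block_map=block_map,
        eaf=haplotypes.mean(axis=0),
        apoe_region=apoe_region,
    )


# ---------------------------------------------------------------------------
# GWAS simulation

def _marginal_betas(panel: HaplotypePanel, effects: Sequence[PlantedEffect],
                    sex: str) -> np.ndarray:
    """True marginal per-variant log-odds effects induced through LD:
    beta_marg(v) = sum_c beta_c * cov(g_v, g_c) / var(g_v)."""
    beta = np.zeros(panel.n_variants)
    if not effects:
        return beta
    H = panel.haplotypes.astype(float)
    var_v = np.var(H, axis=0)
    for eff in effects:
        b = eff.beta(sex)
        if b == 0.0:
            continue
        c = panel.index_of(eff.variant_id)
        gc = H[:, c] - H[:, c].mean()
        cov = (H - H.mean(axis=0)).T @ gc / H.shape[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            beta += np.where(var_v > 0, b * cov / var_v, 0.0)
    return beta


def simulate_case_control_gwas(panel: HaplotypePanel,
                               effects: Sequence[PlantedEffect],
                               spec: CohortSpec, sex: str,
                               covariate_model: dict | None = None,
                               seed: int = 0, mode: str = "approx",
                               mac_min: int = 20) -> pd.DataFrame:
    """Per-variant GWAS association records for one cohort and sex.

    Two modes (flag-controlled):

    ``approx``
        Asymptotic normal summary statistics: the estimate is drawn around
        the LD-induced true marginal log-odds effect with
        se = 1/sqrt(N * v(1-v) * 2f(1-f)). Null variants give exactly
        standard-normal z, hence uniform p-values.
    ``fit``
        Individual-level simulation: genotypes resampled from the panel,
        binary phenotypes from an additive logistic model (including two
        APOE-like dosage covariates when a covariate model is given), then a
        per-variant logistic regression. Validates the approximation at
        moderate n.

    Proxy cohorts attenuate planted effects by ``spec.proxy_attenuation``
    (one-parent transmission heuristic). Variants with expected minor allele
    count <= ``mac_min`` are flagged (``mac_pass=False``) for the downstream
    MAC filter.
    """
    for eff in effects:
        panel.index_of(eff.variant_id)  # raises MissingVariantError
    rng = np.random.default_rng(seed)
    atten = spec.proxy_attenuation if spec.design == "proxy" else 1.0
    eff_sex = [PlantedEffect(e.variant_id, e.beta_female / atten,
                             e.beta_male / atten, e.mechanism, e.target_gene)
               for e in effects]
    if mode == "approx":
        table = _gwas_approx(panel, eff_sex, spec, sex, rng)
    elif mode == "fit":
        table = _gwas_fit(panel, eff_sex, spec, sex, covariate_model, rng)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    mac = 2.0 * spec.n * np.minimum(table["eaf"], 1 - table["eaf"])
    table["mac"] = mac
    table["mac_pass"] = mac > mac_min
    table["cohort"] = spec.name
    table["case_frac"] = spec.case_fraction
    return table


def _base_table(panel: HaplotypePanel, spec: CohortSpec) -> pd.DataFrame:
    return pd.DataFrame({
        "variant_id": panel.variant_ids,
        "chrom": panel.chrom,
        "pos": panel.positions,
        "ea": panel.ea,
        "oa": panel.oa,
        "n": float(spec.n),
        "info": 1.0,
    })


def _gwas_approx(panel, effects, spec, sex, rng) -> pd.DataFrame:
    f = panel.eaf.astype(float)
    v = spec.case_fraction
    se = 1.0 / np.sqrt(spec.n * v * (1 - v) * 2.0 * f * (1 - f))
    beta_true = _marginal_betas(panel, effects, sex)
    beta_hat = beta_true + se * rng.standard_normal(panel.n_variants)
    eaf_hat = np.clip(f + rng.standard_normal(panel.n_variants)
                      * np.sqrt(f * (1 - f) / (2.0 * spec.n)), 1e-6, 1 - 1e-6)
    table = _base_table(panel, spec)
    table["eaf"] = eaf_hat
    table["beta"] = beta_hat
    table["se"] = se
    table["p"] = p_from_z(beta_hat / se)
    return table


def _gwas_fit(panel, effects, spec, sex, covariate_model, rng) -> pd.DataFrame:
    import statsmodels.api as sm

    n = spec.n
    hap_ix = rng.integers(0, panel.haplotypes.shape[0], size=2 * n)
    G = (panel.haplotypes[hap_ix[0::2], :].astype(np.int16)
         + panel.haplotypes[hap_ix[1::2], :])
    eta = np.full(n, np.log(spec.case_fraction / (1 - spec.case_fraction)))
    for eff in effects:
        b = eff.beta(sex)
        if b:
            eta = eta + b * G[:, panel.index_of(eff.variant_id)]
    covs = np.empty((n, 0))
    if covariate_model is not None:
        cm = covariate_model
        apoe4 = rng.binomial(2, cm.get("apoe4_freq", 0.15), size=n)
        apoe2 = rng.binomial(2, cm.get("apoe2_freq", 0.07), size=n)
        eta = eta + cm.get("apoe4_beta", 1.0) * apoe4 \
                  + cm.get("apoe2_beta", -0.4) * apoe2
        covs = np.column_stack([apoe4, apoe2]).astype(float)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)

    betas = np.empty(panel.n_variants)
    ses = np.empty(panel.n_variants)
    base = np.column_stack([np.ones(n), covs])
    for j in range(panel.n_variants):
        X = np.column_stack([base, G[:, j].astype(float)])
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=50)
            betas[j], ses[j] = res.params[-1], res.bse[-1]
        except Exception:
            betas[j], ses[j] = 0.0, np.inf
    table = _base_table(panel, spec)
    table["eaf"] = G.mean(axis=0) / 2.0
    table["beta"] = betas
    table["se"] = ses
    with np.errstate(divide="ignore", invalid="ignore"):
        table["p"] = p_from_z(np.where(ses > 0, betas / ses, 0.0))
    table["n_cases_realized"] = int(y.sum())
    return table


# ---------------------------------------------------------------------------
# proxy phenotype construction

_PROXY_FIELDS = ["mother_affected", "father_affected", "mother_age", "father_age"]


def build_proxy_phenotype(subject_table: pd.DataFrame,
                          sex_of_analysis: str,
                          parental_age_min: float = 65.0):
    """Parental-history proxy phenotype for one analysis sex.

    Female analyses use maternal affection status: subjects reporting an
    affected father are excluded outright; a parent younger than
    ``parental_age_min`` has phenotype-unknown status. Male analyses are
    symmetric (paternal). Returns (phenotype, weights): phenotype 1.0 =
    proxy-case, 0.0 = proxy-control, NaN = excluded/unknown; proxy-cases get
    weight 0.5 (one transmitting parent), controls 1.0.
    """
    missing = [c for c in _PROXY_FIELDS if c not in subject_table.columns]
    if missing:
        raise KeyError(f"subject table missing parental fields: {missing}")
    if sex_of_analysis == "female":
        own, other = "mother", "father"
    elif sex_of_analysis == "male":
        own, other = "father", "mother"
    else:
        raise ValueError(f"unknown analysis sex {sex_of_analysis!r}")

    affected = subject_table[f"{own}_affected"].astype(bool).to_numpy()
    other_affected = subject_table[f"{other}_affected"].astype(bool).to_numpy()
    age = subject_table[f"{own}_age"].to_numpy(dtype=float)

    pheno = np.where(affected, 1.0, 0.0)
    pheno = np.where(age >= parental_age_min, pheno, np.nan)  # age rule
    pheno = np.where(other_affected, np.nan, pheno)           # exclusion rule
    weights = np.where(pheno == 1.0, 0.5, 1.0)
    weights = np.where(np.isnan(pheno), np.nan, weights)
    idx = subject_table.index
    return pd.Series(pheno, index=idx, name="proxy_phenotype"), \
        pd.Series(weights, index=idx, name="weight")


# ---------------------------------------------------------------------------
# QTL + weight simulation

def simulate_qtl_and_weights(panel: HaplotypePanel,
                             gene_models: Sequence[GeneModel],
                             share_map: dict[str, bool],
                             n: int, seed: int, stratum: str = "combined"):
    """cis-QTL summary statistics plus ground-truth weight models per gene.

    Effects are planted on a standardized quantitative (protein abundance)
    trait; per-variant marginal effects arise through LD and estimates are
    drawn with se = 1/sqrt(n * 2f(1-f)), so causal-variant z grows as
    sqrt(n). ``share_map`` carries the ground-truth colocalization label per
    gene (True = the QTL causal variant is shared with a GWAS effect) into
    the returned metadata untouched.

    Returns (qtl_tables, weight_models, truth) keyed by gene id.
    """
    from .pwas import WeightModel

    rng = np.random.default_rng(seed)
    qtl_tables: dict[str, pd.DataFrame] = {}
    weights: dict[str, WeightModel] = {}
    truth: dict[str, dict] = {}
    for gm in gene_models:
        lo, hi = gm.tss - gm.cis_window, gm.tss + gm.cis_window
        in_cis = ((panel.chrom == gm.chrom)
                  & (panel.positions >= lo) & (panel.positions <= hi))
        cis_ids = [v for v, m in zip(panel.variant_ids, in_cis) if m]
        betas = gm.betas(stratum)
        for v in gm.causal_variants:
            j = panel.index_of(v)
            if not in_cis[j]:
                raise ValueError(
                    f"{gm.gene_id}: causal variant {v} outside cis window "
                    f"[{lo},{hi}]")
        effects = [PlantedEffect(v, b, b) for v, b in
                   zip(gm.causal_variants, betas)]
        sub = _subpanel(panel, cis_ids)
        f = sub.eaf.astype(float)
        se = 1.0 / np.sqrt(n * 2.0 * f * (1 - f))
        beta_true = _marginal_betas(sub, effects, "female")
        beta_hat = beta_true + se * rng.standard_normal(len(cis_ids))
        table = pd.DataFrame({
            "variant_id": cis_ids,
            "chrom": sub.chrom, "pos": sub.positions,
            "ea": sub.ea, "oa": sub.oa, "eaf": f,
            "beta": beta_hat, "se": se,
            "p": p_from_z(beta_hat / se), "n": float(n), "info": 1.0,
            "gene_id": gm.gene_id,
        })
        qtl_tables[gm.gene_id] = table
        if any(b != 0 for b in betas):
            weights[gm.gene_id] = WeightModel(
                gene_id=gm.gene_id, tissue="csf", stratum=stratum,
                variants=list(gm.causal_variants),
                weights=[float(b) for b in betas],
                window=(lo, hi), model_name="truth",
                cv_r2=np.nan, herit_p=np.nan)
        else:
            weights[gm.gene_id] = None  # null gene: no valid weight model
        truth[gm.gene_id] = {
            "shared_causal": bool(share_map.get(gm.gene_id, False)),
            "causal_variants": list(gm.causal_variants),
            "null": all(b == 0 for b in betas),
        }
    return qtl_tables, weights, truth


def _subpanel(panel: HaplotypePanel, variant_ids: list[str]) -> HaplotypePanel:
    cols = [panel.index_of(v) for v in variant_ids]
    return HaplotypePanel(
        variant_ids=[panel.variant_ids[c] for c in cols],
        chrom=panel.chrom[cols], positions=panel.positions[cols],
        ea=[panel.ea[c] for c in cols], oa=[panel.oa[c] for c in cols],
        haplotypes=panel.haplotypes[:, cols],
        block_map=panel.block_map[cols], eaf=panel.eaf[cols],
        apoe_region=panel.apoe_region)


# ---------------------------------------------------------------------------
# structural-variant locus

@dataclass
class SvLocus:
    """A biallelic structural variant plus tagging SNVs.

    ``phased`` is (2n x 1+T) with the SV in column 0; ``genotypes`` the
    collapsed unphased (n x 1+T) dosage matrix; ``sv_dosage`` the per-sample
    truth. ``realized_r2`` holds the phased-truth r-squared between the SV
    and each tag.
    """

    variant_ids: list[str]
    phased: np.ndarray
    genotypes: np.ndarray
    sv_dosage: np.ndarray
    realized_r2: np.ndarray
    target_r2: np.ndarray
    positions: np.ndarray = field(default=None)


def simulate_sv_locus(n: int, tag_r2_targets: Sequence[float], sv_freq: float,
                      seed: int, tag_freqs: Sequence[float] | None = None) -> SvLocus:
    """Phased SV + tag-SNV haplotypes with configurable SV-tag r-squared.

    Each tag is drawn conditionally on the SV allele so that the haplotype
    frequency f(SV=1, tag=1) = p*q + r*sqrt(p(1-p)q(1-q)) hits the target
    r = sqrt(r2); tag-tag LD arises through the shared SV. Raises
    :class:`InfeasibleLDError` when the target exceeds the frequency-bound
    constraint (f_AB must lie within [max(0, p+q-1), min(p, q)]).
    """
    if not (0.0 < sv_freq < 1.0):
        raise InfeasibleLDError(
            f"sv_freq={sv_freq} is monomorphic/degenerate; need 0 < freq < 1")
    targets = np.asarray(tag_r2_targets, dtype=float)
    if np.any((targets <= 0) | (targets > 1)):
        raise ValueError("tag r2 targets must lie in (0, 1]")
    if tag_freqs is None:
        tag_freqs = [sv_freq] * len(targets)
    tag_freqs = np.asarray(tag_freqs, dtype=float)

    rng = np.random.default_rng(seed)
    q = sv_freq
    sv = (rng.random(2 * n) < q).astype(np.uint8)
    cols = [sv]
    for r2, p in zip(targets, tag_freqs):
        r = np.sqrt(r2)
        f_ab = p * q + r * np.sqrt(p * (1 - p) * q * (1 - q))
        lo, hi = max(0.0, p + q - 1.0), min(p, q)
        if not (lo - 1e-12 <= f_ab <= hi + 1e-12):
            raise InfeasibleLDError(
                f"target r2={r2} infeasible at tag freq {p}, SV freq {q}: "
                f"haplotype frequency {f_ab:.4f} outside "
                f"[max(0,p+q-1), min(p,q)] = [{lo:.4f}, {hi:.4f}]")
        p_tag_given_sv1 = f_ab / q
        p_tag_given_sv0 = (p - f_ab) / (1 - q)
        u = rng.random(2 * n)
        tag = np.where(sv == 1, u < p_tag_given_sv1, u < p_tag_given_sv0)
        cols.append(tag.astype(np.uint8))

    phased = np.column_stack(cols)
    genotypes = phased[0::2, :].astype(np.int16) + phased[1::2, :]
    realized = np.empty(len(targets))
    s = phased[:, 0].astype(float)
    for t in range(len(targets)):
        x = phased[:, t + 1].astype(float)
        c = np.corrcoef(s, x)[0, 1]
        realized[t] = c ** 2
    ids = ["SV"] + [f"tag{t + 1}" for t in range(len(targets))]
    return SvLocus(variant_ids=ids, phased=phased, genotypes=genotypes,
                   sv_dosage=genotypes[:, 0].copy(), realized_r2=realized,
                   target_r2=targets,
                   positions=np.arange(len(ids), dtype=np.int64) * 10_000 + 1)
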