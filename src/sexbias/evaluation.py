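"""End-to-end evaluation experiments on synthetic data.

Each function runs one self-contained study at the package's reference
conditions — planting known effects with the generators in
:mod:`sexbias.synthetic`, running the relevant pipeline stage, and measuring
recovery/calibration — and returns a small dict of summary quantities.
They are shared by the acceptance test suite and ``scripts/acceptance.py``.

Problem sizes are the package's reference conditions (documented in
docs/methods.md): e.g. 2000 variants at n=20k/stratum for heterogeneity
calibration, 10 + 10 planted loci over 20 seeds for locus recovery, 100-200
replicates for colocalization and SMR behavior.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import hplocus, loci, prioritize, synthetic
from .coloc import ColocDataset, coloc_abf, heidi_like, smr_test
from .pwas import WeightModel, pwas_assoc
from .sumstats import merge_sexes, meta_fixed, meta_random, AssocRecord

__all__ = [
    "meta_oracle_check", "sexhet_null_calibration", "locus_recovery",
    "pwas_oracle_equivalence", "coloc_behavior", "smr_heidi_calibration",
    "priority_rule_table", "cubex_agreement", "sv_conditional_dissection",
    "pipeline_determinism",
]


def _rec(vid, beta, se, eaf=0.3, n=10000.0):
    from .sumstats import p_from_z
    return AssocRecord(vid, "1", 100, "A", "G", eaf, beta, se,
                       p_from_z(beta / se), n)


def meta_oracle_check() -> dict:
    """Fixed/random-effects meta-analysis vs closed-form oracles on 2-3
    cohort toys; returns max absolute deviations."""
    # two identical cohorts: beta unchanged, se / sqrt(2)
    m = meta_fixed([_rec("v", 0.1, 0.02), _rec("v", 0.1, 0.02)])
    d1 = max(abs(m.beta - 0.1), abs(m.se - 0.02 / np.sqrt(2)))
    # unequal: closed-form inverse-variance
    a, b = _rec("v", 0.1, 0.02), _rec("v", 0.0, 0.02)
    m = meta_fixed([a, b])
    w = np.array([1 / 0.02 ** 2, 1 / 0.02 ** 2])
    d2 = max(abs(m.beta - 0.05), abs(m.se - 1 / np.sqrt(w.sum())))
    # three cohorts, mixed ses
    recs = [_rec("v", 0.12, 0.02), _rec("v", 0.08, 0.03),
            _rec("v", 0.10, 0.025)]
    m = meta_fixed(recs)
    w = np.array([1 / r.se ** 2 for r in recs])
    bet = np.array([r.beta for r in recs])
    d3 = max(abs(m.beta - (w * bet).sum() / w.sum()),
             abs(m.se - 1 / np.sqrt(w.sum())))
    # DerSimonian-Laird closed form on a discordant pair
    recs = [_rec("v", 0.3, 0.02), _rec("v", -0.3, 0.02)]
    r = meta_random(recs)
    wp = np.array([1 / 0.02 ** 2, 1 / 0.02 ** 2])
    q = sum(wi * (bi - 0.0) ** 2 for wi, bi in zip(wp, (0.3, -0.3)))
    tau2 = (q - 1) / (wp.sum() - (wp ** 2).sum() / wp.sum())
    se_exp = 1 / np.sqrt((1 / (0.02 ** 2 + tau2)) * 2)
    d4 = max(abs(r.tau2 - tau2), abs(r.se - se_exp), abs(r.beta - 0.0))
    fixed_pair = meta_fixed(recs)
    return {"max_abs_dev": max(d1, d2, d3, d4),
            "random_se_ge_fixed": bool(r.se >= fixed_pair.se)}


def sexhet_null_calibration(seed: int, n_variants: int = 2000,
                            n_per_stratum: int = 20000,
                            alpha: float = 0.05) -> dict:
    """Type-I error of the sex-heterogeneity test under the shared-effect
    null: both sexes share the same true effects (a mix of null and non-null
    variants), estimated independently per stratum."""
    panel = synthetic.simulate_panel(n_variants // 10, 10, 0.4, 2000,
                                     seed=seed)
    rng = np.random.default_rng(seed + 1)
    causal = rng.choice(panel.variant_ids, size=50, replace=False)
    effects = [synthetic.PlantedEffect(v, 0.08, 0.08) for v in causal]
    spec = synthetic.CohortSpec("c", n_per_stratum // 2, n_per_stratum // 2)
    fem = synthetic.simulate_case_control_gwas(panel, effects, spec, "female",
                                               seed=seed + 2)
    mal = synthetic.simulate_case_control_gwas(panel, effects, spec, "male",
                                               seed=seed + 3)
    merged = merge_sexes(fem, mal)
    rate = float((merged["p_het"] < alpha).mean())
    half = 1.96 * np.sqrt(alpha * (1 - alpha) / len(merged))
    return {"rejection_rate": rate, "alpha": alpha,
            "binomial_halfwidth": half, "n_variants": len(merged)}


# ---------------------------------------------------------------------------
# locus recovery

def _plant_locus(panel, block, z_f, z_m, n, variant_ix=5):
    """Planted effect at one block scaled so the lead reaches target z."""
    vid = f"rs{block}_{variant_ix}"
    j = panel.index_of(vid)
    f = float(panel.eaf[j])
    se = 1.0 / np.sqrt(n * 0.25 * 2 * f * (1 - f))
    return synthetic.PlantedEffect(vid, z_f * se, z_m * se)


def locus_recovery(seed: int, n_seeds: int = 20, n_gwas: int = 100_000,
                   lead_z: float = 11.0, ratio: float = 2.0) -> dict:
    """Recovery of planted sex-biased loci.

    Per replicate genome: 10 female-biased genome-wide loci (cross-sex
    effect-magnitude ratio ``ratio``), 10 unbiased genome-wide loci, 5 null
    blocks. Reports, per seed, how many of the 10 biased loci were retained
    and how many unbiased loci slipped through the sex-bias filters.
    """
    recovered, admitted = [], []
    for s in range(n_seeds):
        sd = seed + 1000 * s
        panel = synthetic.simulate_panel(25, 12, 0.6, 4000, seed=sd)
        effects = []
        for b in range(10):
            effects.append(_plant_locus(panel, b, lead_z, lead_z / ratio,
                                        n_gwas))
        for b in range(10, 20):
            effects.append(_plant_locus(panel, b, lead_z, lead_z, n_gwas))
        spec = synthetic.CohortSpec("c", n_gwas // 2, n_gwas // 2)
        fem = synthetic.simulate_case_control_gwas(panel, effects, spec,
                                                   "female", seed=sd + 1)
        mal = synthetic.simulate_case_control_gwas(panel, effects, spec,
                                                   "male", seed=sd + 2)
        merged = merge_sexes(fem, mal)
        table, _ = loci.discover_loci(merged, loci.PanelLD(panel))
        if len(table):
            lead_blocks = {int(v.split("_")[0][2:])
                           for v in table["variant_id"]}
        else:
            lead_blocks = set()
        recovered.append(len(lead_blocks & set(range(10))))
        admitted.append(len(lead_blocks & set(range(10, 20))))
    return {"recovered_biased": recovered, "admitted_unbiased": admitted,
            "mean_recovered": float(np.mean(recovered)),
            "mean_admitted": float(np.mean(admitted)),
            "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# PWAS oracle

def _simple_ols_z(y: np.ndarray, x: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    sxx = (x ** 2).sum()
    if sxx == 0:
        return 0.0
    beta = (x * y).sum() / sxx
    resid = y - beta * x
    se = np.sqrt((resid ** 2).sum() / (len(y) - 2) / sxx)
    return float(beta / se)


class _CorrLD:
    def __init__(self, G, ids):
        self.R = np.corrcoef(G, rowvar=False)
        self.ids = {v: i for i, v in enumerate(ids)}

    def corr(self, ids):
        ix = [self.ids[v] for v in ids]
        return self.R[np.ix_(ix, ix)]


def pwas_oracle_equivalence(seed: int, n_genes: int = 200,
                            n_samples: int = 1000,
                            n_variants: int = 8) -> dict:
    """Summary-statistic weighted-burden z versus the individual-level
    two-stage oracle (impute abundance from weights, regress the phenotype
    on imputed abundance). Half of the genes carry a protein-mediated
    phenotype effect; the null half feeds the calibration check."""
    rng = np.random.default_rng(seed)
    z_pkg, z_oracle, null_p = [], [], []
    for g in range(n_genes):
        panel = synthetic.simulate_panel(1, n_variants, 0.6, 2 * n_samples,
                                         seed=seed + 7 * g + 1)
        G = panel.dosages().astype(float)
        w_true = np.zeros(n_variants)
        k = 1 + (g % 2)
        w_true[rng.choice(n_variants, size=k, replace=False)] = \
            rng.normal(0.3, 0.1, size=k)
        protein_gen = G @ w_true
        gamma = 0.0 if g < n_genes // 2 else rng.choice([-0.4, 0.4])
        y = gamma * protein_gen + rng.standard_normal(n_samples)

        z_gwas = np.array([_simple_ols_z(y, G[:, j])
                           for j in range(n_variants)])
        se = np.full(n_variants, 1.0)  # z-scale records
        model = WeightModel("g", "brain", "combined",
                            list(panel.variant_ids), w_true.tolist(),
                            (1, 2), "truth", np.nan, np.nan)
        gwas = pd.DataFrame({"variant_id": panel.variant_ids,
                             "beta": z_gwas, "se": se})
        z, p, _ = pwas_assoc(model, gwas, _CorrLD(G, panel.variant_ids),
                             shrink=0.0)
        imputed = G @ w_true
        zo = _simple_ols_z(y, imputed)
        z_pkg.append(z)
        z_oracle.append(zo)
        if g < n_genes // 2:
            null_p.append(p)
    r = float(np.corrcoef(z_pkg, z_oracle)[0, 1])
    ks = stats.kstest(null_p, "uniform")
    return {"pearson_r": r, "null_ks_p": float(ks.pvalue),
            "n_genes": n_genes, "n_null": len(null_p)}


# ---------------------------------------------------------------------------
# colocalization behavior

def _ar_corr(m: int, rho: float) -> np.ndarray:
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _sim_locus_z(rng, R, chol, causal, z_causal):
    mu = R[:, causal] * z_causal
    return mu + chol @ rng.standard_normal(len(R))


def coloc_behavior(seed: int, n_reps: int = 100, n_snps: int = 50,
                   rho: float = 0.9, z_causal: float = 8.0,
                   n: int = 10_000, distinct_gap: int = 8) -> dict:
    """Shared- versus distinct-causal colocalization behavior.

    Shared replicates plant the same causal variant in both traits (PP4
    should dominate); distinct replicates plant two linked variants
    ``distinct_gap`` apart in an AR(rho) LD block (PP3 should dominate).
    """
    rng = np.random.default_rng(seed)
    R = _ar_corr(n_snps, rho)
    chol = np.linalg.cholesky(R + 1e-10 * np.eye(n_snps))
    se = np.full(n_snps, 1.0 / np.sqrt(n))
    ids = [f"v{i}" for i in range(n_snps)]
    pp4_shared, pp3_gt_pp4 = 0, 0
    c1 = n_snps // 2
    c2 = c1 + distinct_gap
    for _ in range(n_reps):
        z1 = _sim_locus_z(rng, R, chol, c1, z_causal)
        z2 = _sim_locus_z(rng, R, chol, c1, z_causal)
        res = coloc_abf(ColocDataset(ids, z1 * se, se),
                        ColocDataset(ids, z2 * se, se))
        if res.pp4 > 0.7:
            pp4_shared += 1
        z1 = _sim_locus_z(rng, R, chol, c1, z_causal)
        z2 = _sim_locus_z(rng, R, chol, c2, z_causal)
        res = coloc_abf(ColocDataset(ids, z1 * se, se),
                        ColocDataset(ids, z2 * se, se))
        if res.pp3 > res.pp4:
            pp3_gt_pp4 += 1
    return {"shared_pp4_gt_07": pp4_shared, "distinct_pp3_gt_pp4": pp3_gt_pp4,
            "n_reps": n_reps}


def smr_heidi_calibration(seed: int, n_null: int = 2000,
                          n_reps: int = 100, n_snps: int = 20,
                          rho: float = 0.9) -> dict:
    """SMR p-value calibration under a null GWAS with a strong QTL, and
    HEIDI-like retention/flagging under single- versus two-causal-variant
    architectures."""
    rng = np.random.default_rng(seed)
    z_qtl = rng.normal(10.0, 1.0, size=n_null)
    z_gwas = rng.standard_normal(n_null)
    p_smr = np.array([smr_test(zg, zq, zg * 0.01, zq * 0.01).p_smr
                      for zg, zq in zip(z_gwas, z_qtl)])
    ks = stats.kstest(p_smr, "uniform")

    R = _ar_corr(n_snps, rho)
    chol = np.linalg.cholesky(R + 1e-10 * np.eye(n_snps))
    se_q = np.full(n_snps, 1.0 / np.sqrt(5000))
    se_g = np.full(n_snps, 1.0 / np.sqrt(50000))
    c_q = n_snps // 2
    retained = flagged = hom_n = het_n = 0
    for _ in range(n_reps):
        # homogeneous: one shared causal variant drives both traits
        zq = _sim_locus_z(rng, R, chol, c_q, 12.0)
        zg = _sim_locus_z(rng, R, chol, c_q, 7.0)
        top = int(np.argmax(np.abs(zq)))
        p, k = heidi_like(zg * se_g, se_g, zq * se_q, se_q, R, top)
        if p is not None:
            hom_n += 1
            retained += p > 0.05
        # heterogeneous: GWAS driven by a different linked variant
        zq = _sim_locus_z(rng, R, chol, c_q, 12.0)
        zg = _sim_locus_z(rng, R, chol, c_q + 5, 7.0)
        top = int(np.argmax(np.abs(zq)))
        p, k = heidi_like(zg * se_g, se_g, zq * se_q, se_q, R, top)
        if p is not None:
            het_n += 1
            flagged += p < 0.05
    return {"smr_null_ks_p": float(ks.pvalue),
            "heidi_retained_frac": retained / max(hom_n, 1),
            "heidi_flagged_frac": flagged / max(het_n, 1),
            "n_homogeneous": hom_n, "n_heterogeneous": het_n}


# ---------------------------------------------------------------------------
# priority rules

def priority_rule_fixture() -> list[tuple[prioritize.EvidenceLedger, int, str]]:
    """All scoring branches with their expected scores and rule ids."""
    E = prioritize.EvidenceLedger
    H = prioritize.XqtlHit
    fix = [
        # GWAS-locus branches
        (E("g1", "L1", "gwas_locus",
           xqtl_hits=[H("eQTL", "brain", 0.9), H("pQTL", "csf", 0.8)]),
         1, "gwas_multi_strong_xqtl"),
        (E("g2", "L1", "gwas_locus", is_pwas_gene=True,
           matching_pqtl_pp4=0.81), 1, "gwas_pwas_matching_pqtl_strong"),
        (E("g3", "L1", "gwas_locus", xqtl_hits=[H("sQTL", "brain", 0.75)]),
         2, "gwas_single_strong_xqtl"),
        (E("g4", "L1", "gwas_locus", xqtl_hits=[H("eQTL", "brain", 0.65)]),
         3, "gwas_no_strong_xqtl"),
        (E("g5", "L1", "gwas_locus",
           xqtl_hits=[H("mQTL", "brain", 0.95), H("haQTL", "brain", 0.9)]),
         3, "gwas_no_strong_xqtl"),  # epigenetic types never score
        # PWAS-locus branches
        (E("p1", "L2", "pwas_locus", is_pwas_gene=True,
           matching_pqtl_pp4=0.81), 1, "pwas_matching_pqtl_strong"),
        (E("p2", "L2", "pwas_locus", matching_pqtl_pp4=None,
           nonmatching_pqtl_pp4=0.85), 1,
         "pwas_nonmatching_pqtl_strong_unavailable_matching"),
        (E("p3", "L2", "pwas_locus",
           xqtl_hits=[H("eQTL", "monocyte", 0.9), H("eQTL", "microglia", 0.8)]),
         1, "pwas_multi_strong_xqtl"),
        (E("p4", "L2", "pwas_locus", is_pwas_gene=True,
           matching_pqtl_pp4=0.57, xqtl_hits=[H("eQTL", "monocyte", 0.9)]),
         1, "pwas_matching_suggestive_plus_strong_xqtl"),
        (E("p5", "L2", "pwas_locus", is_pwas_gene=True,
           matching_pqtl_pp4=0.5), 2, "pwas_matching_pqtl_suggestive"),
        (E("p6", "L2", "pwas_locus", xqtl_hits=[H("sQTL", "brain", 0.72)]),
         2, "pwas_single_strong_xqtl"),
        (E("p7", "L2", "pwas_locus"), 3, "pwas_no_strong_xqtl"),
        # differential-abundance upgrade and its non-firing complement
        (E("p8", "L2", "pwas_locus", da_sex_p=0.01), 2, "da_upgrade"),
        (E("p9", "L2", "pwas_locus", da_sex_p=0.4, da_interaction_p=0.6),
         3, "pwas_no_strong_xqtl"),
    ]
    return fix


def _random_ledger(rng) -> prioritize.EvidenceLedger:
    H = prioritize.XqtlHit
    origin = rng.choice(["gwas_locus", "pwas_locus"])
    hits = [H(rng.choice(["eQTL", "sQTL", "pQTL", "mQTL"]),
              f"d{rng.integers(5)}", float(rng.random()))
            for _ in range(rng.integers(0, 5))]
    m = rng.choice([None, float(rng.random())])
    return prioritize.EvidenceLedger(
        "g", "L", origin,
        is_pwas_gene=bool(rng.integers(2)),
        matching_pqtl_pp4=m,
        nonmatching_pqtl_pp4=rng.choice([None, float(rng.random())]),
        xqtl_hits=hits,
        da_sex_p=rng.choice([None, float(rng.random())]))


def priority_rule_table(seed: int = 0, n_random: int = 1000) -> dict:
    """Exact check of every scoring branch plus monotonicity under added
    strong colocalization evidence on random ledgers."""
    exact_failures = []
    for led, want_score, want_rule in priority_rule_fixture():
        got = prioritize.score_gene(led)
        if got.score != want_score or got.rule_fired != want_rule:
            exact_failures.append((led.gene_id, got.score, got.rule_fired))
    rng = np.random.default_rng(seed)
    mono_violations = 0
    for _ in range(n_random):
        led = _random_ledger(rng)
        before = prioritize.score_gene(led).score
        led.xqtl_hits = led.xqtl_hits + [
            prioritize.XqtlHit("eQTL", f"extra{rng.integers(1000)}", 0.95)]
        after = prioritize.score_gene(led).score
        if after > before:
            mono_violations += 1
    return {"n_branches": len(priority_rule_fixture()),
            "exact_failures": exact_failures,
            "monotonicity_violations": mono_violations,
            "n_random": n_random}


# ---------------------------------------------------------------------------
# cubic-Hill agreement

def cubex_agreement(seed: int, n_tables: int = 1000,
                    n_phased: int = 5000) -> dict:
    """Cubic-root vs EM agreement on random genotype tables, and genotype-
    collapsed r2 accuracy against the phased truth."""
    rng = np.random.default_rng(seed)
    max_dev = 0.0
    compared = 0
    while compared < n_tables:
        p, q = rng.uniform(0.05, 0.95, size=2)
        lo, hi = max(0.0, p + q - 1.0), min(p, q)
        f_ab = rng.uniform(lo, hi)
        h = np.array([f_ab, p - f_ab, q - f_ab, 1 - p - q + f_ab])
        if h.min() < 0.01:
            continue
        n = int(rng.integers(100, 2000))
        hap = rng.choice(4, size=2 * n, p=h / h.sum())
        a1 = np.isin(hap, [0, 1]).astype(int)
        a2 = np.isin(hap, [0, 2]).astype(int)
        g1 = a1[0::2] + a1[1::2]
        g2 = a2[0::2] + a2[1::2]
        tab = hplocus.genotype_table(g1, g2)
        sp, sq = tab.freqs
        if sp in (0, 1) or sq in (0, 1):
            continue
        res = hplocus.cubex_ld(tab)
        em = hplocus.em_haplotype_freq(tab)
        if em is not None:
            max_dev = max(max_dev, abs(res.f_ab - em))
            compared += 1
    # phased-truth r2 recovery
    sv = synthetic.simulate_sv_locus(n_phased, [0.75], 0.4, seed=seed + 1)
    tab = hplocus.genotype_table(sv.genotypes[:, 0], sv.genotypes[:, 1])
    r2_unphased = hplocus.cubex_ld(tab).r2
    return {"max_abs_dev_vs_em": max_dev, "n_tables": compared,
            "phased_truth_r2": float(sv.realized_r2[0]),
            "unphased_r2": float(r2_unphased),
            "r2_error": float(abs(r2_unphased - sv.realized_r2[0]))}


# ---------------------------------------------------------------------------
# SV conditional dissection

#: consensus-style imputation panel: 20 tag SNVs spanning strong to weak LD
#: with the SV, including the 0.97 / 0.75 / 0.27 index-variant geometry.
SV_TAG_R2 = (0.97, 0.9, 0.85, 0.8, 0.75, 0.7, 0.65, 0.6, 0.55, 0.5,
             0.45, 0.4, 0.35, 0.3, 0.27, 0.25, 0.2, 0.18, 0.15, 0.12)


def sv_conditional_dissection(seed: int, n_reps: int = 50,
                              n_train: int = 431, n_cohort: int = 3000,
                              beta_protein: float = 0.5,
                              beta_disease: float = 0.4) -> dict:
    """Conditional dissection at a causal-SV locus.

    The SV causes protein abundance; the index tag SNV (r2 ~= 0.75 to the
    SV) is only a proxy. The imputer is trained on a 20-SNV consensus-style
    tag panel in a long-read-sized cohort and applied in the larger
    proteogenomic cohort; conditioning the tag's protein association on the
    imputed SV genotype should remove it, while an SV-independent disease
    variant's association must survive conditioning.
    """
    tag_ix = SV_TAG_R2.index(0.75) + 1  # +1: SV occupies column 0
    rng = np.random.default_rng(seed)
    removed = survived = acc_gt_baseline = 0
    accs = []
    for rep in range(n_reps):
        sd = seed + 97 * rep
        train = synthetic.simulate_sv_locus(n_train, SV_TAG_R2, 0.4, seed=sd)
        tags = pd.DataFrame(train.genotypes[:, 1:],
                            columns=train.variant_ids[1:])
        model = hplocus.train_sv_imputer(tags, train.sv_dosage, seed=sd)
        cohort = synthetic.simulate_sv_locus(n_cohort, SV_TAG_R2,
                                             0.4, seed=sd + 1)
        cohort_tags = pd.DataFrame(cohort.genotypes[:, 1:],
                                   columns=cohort.variant_ids[1:])
        imputed = hplocus.impute_sv(model, cohort_tags)
        calls = imputed["sv_call"].to_numpy()
        condition = hplocus.sv_condition_matrix(imputed)
        acc = float(np.mean(calls == cohort.sv_dosage))
        baseline = float(np.max(np.bincount(cohort.sv_dosage,
                                            minlength=3)) / n_cohort)
        accs.append(acc)
        acc_gt_baseline += acc > baseline

        noise = rng.standard_normal(n_cohort)
        protein = beta_protein * cohort.sv_dosage + noise
        tag1 = cohort.genotypes[:, tag_ix].astype(float)
        uncond = hplocus.conditional_assoc(protein, tag1)
        cond = hplocus.conditional_assoc(protein, tag1,
                                         g_condition=condition)
        if uncond["p"] < 5e-8 and cond["p"] > 0.05:
            removed += 1

        # SV-independent disease signal survives conditioning
        g_dis = rng.binomial(2, 0.3, size=n_cohort).astype(float)
        eta = -0.5 + beta_disease * g_dis
        y = (rng.random(n_cohort) < 1 / (1 + np.exp(-eta))).astype(float)
        dis = hplocus.conditional_assoc(y, g_dis, g_condition=condition)
        if dis["p"] < 0.05:
            survived += 1
    return {"tag_assoc_removed": removed, "disease_assoc_survived": survived,
            "imputation_acc_gt_baseline": acc_gt_baseline,
            "mean_accuracy": float(np.mean(accs)), "n_reps": n_reps}


# ---------------------------------------------------------------------------
# determinism

def _mini_pipeline(seed: int, outdir) -> dict:
    from .report import results_bundle

    panel = synthetic.simulate_panel(6, 10, 0.6, 2000, seed=seed)
    effects = [_plant_locus(panel, 0, 10.0, 5.0, 50_000)]
    spec = synthetic.CohortSpec("c", 25_000, 25_000)
    fem = synthetic.simulate_case_control_gwas(panel, effects, spec,
                                               "female", seed=seed + 1)
    mal = synthetic.simulate_case_control_gwas(panel, effects, spec,
                                               "male", seed=seed + 2)
    merged = merge_sexes(fem, mal)
    table, excl = loci.discover_loci(merged, loci.PanelLD(panel))
    config = {"p_enter": 1e-5, "window": 1_000_000, "r2_clump": 0.01}
    results_bundle(
        {"loci": table, "merged": merged.head(100),
         "exclusions": {"log": excl}},
        outdir, config=config, seeds={"pipeline": seed})
    import json
    from pathlib import Path
    return json.loads((Path(outdir) / "MANIFEST.json").read_text())


def pipeline_determinism(seed: int, workdir) -> dict:
    """Run the mini pipeline twice with identical seeds; byte-identical
    bundles have identical checksum manifests."""
    from pathlib import Path

    m1 = _mini_pipeline(seed, Path(workdir) / "run1")
    m2 = _mini_pipeline(seed, Path(workdir) / "run2")
    return {"identical": m1 == m2, "n_files": len(m1)}
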