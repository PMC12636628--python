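"""Cubic-Hill LD, tag selection, SV imputation, conditional analyses."""

import numpy as np
import pandas as pd
import pytest

from sexbias import hplocus as hp
from sexbias import synthetic as syn


# ---------------------------------------------------------------------------
# cubic-Hill LD

def test_unambiguous_phase_equals_direct_count():
    # no double heterozygotes: haplotypes countable exactly
    counts = np.array([[30, 10, 0], [12, 0, 6], [0, 8, 20]])
    tab = hp.TwoLocusGenotypeTable(counts)
    n_ab, n_aB, n_ba, n_bb, n_dh = hp._known_haplotype_counts(counts)
    assert n_dh == 0
    res = hp.cubex_ld(tab)
    assert res.f_ab == pytest.approx(n_ab / (2 * tab.n), abs=1e-9)


def test_independent_loci_r2_shrinks_with_n(rng):
    r2s = []
    for n in (200, 20_000):
        g1 = rng.binomial(2, 0.4, size=n)
        g2 = rng.binomial(2, 0.3, size=n)
        r2s.append(hp.cubex_ld(hp.genotype_table(g1, g2)).r2)
    assert r2s[1] < 0.001 and r2s[1] < r2s[0] + 0.01


def test_unphased_estimate_close_to_phased_truth():
    sv = syn.simulate_sv_locus(5000, [0.75], 0.4, seed=8)
    tab = hp.genotype_table(sv.genotypes[:, 0], sv.genotypes[:, 1])
    res = hp.cubex_ld(tab)
    assert abs(res.r2 - sv.realized_r2[0]) < 0.05
    em = hp.em_haplotype_freq(tab)
    assert abs(res.f_ab - em) < 1e-6


def test_r2_invariant_to_allele_label_swap(rng):
    g1 = rng.binomial(2, 0.3, size=800)
    g2 = np.clip(g1 + rng.integers(-1, 2, size=800), 0, 2)
    base = hp.cubex_ld(hp.genotype_table(g1, g2)).r2
    assert hp.cubex_ld(hp.genotype_table(2 - g1, g2)).r2 == \
        pytest.approx(base, abs=1e-9)
    assert hp.cubex_ld(hp.genotype_table(g1, 2 - g2)).r2 == \
        pytest.approx(base, abs=1e-9)


def test_monomorphic_locus_rejected():
    counts = np.zeros((3, 3))
    counts[0, 0] = 50
    counts[0, 2] = 50
    with pytest.raises(ValueError, match="polymorphic"):
        hp.cubex_ld(hp.TwoLocusGenotypeTable(counts))


def test_genotype_table_pairwise_complete():
    g1 = np.array([0, 1, 2, np.nan, 1])
    g2 = np.array([0, 1, 2, 1, np.nan])
    tab = hp.genotype_table(g1, g2)
    assert tab.n == 3


# ---------------------------------------------------------------------------
# tag panel selection

def test_tag_panel_ordering_and_threshold():
    sv = syn.simulate_sv_locus(3000, [0.75, 0.97, 0.05], 0.4, seed=9)
    snvs = pd.DataFrame(sv.genotypes[:, 1:], columns=["t75", "t97", "t05"])
    panel = hp.select_tag_panel(sv.genotypes[:, 0], snvs)
    assert panel["variant_id"].tolist() == ["t97", "t75"]  # r2 > 0.1 only
    assert panel["r2"].is_monotonic_decreasing


def test_tag_panel_empty_raises(rng):
    snvs = pd.DataFrame({"x": rng.binomial(2, 0.3, 500)})
    sv_geno = rng.binomial(2, 0.4, 500)
    with pytest.raises(ValueError, match="no tag"):
        hp.select_tag_panel(sv_geno, snvs)


# ---------------------------------------------------------------------------
# SV imputation

def test_perfect_ld_tag_gives_perfect_accuracy():
    sv = syn.simulate_sv_locus(300, [1.0], 0.4, seed=10)
    tags = pd.DataFrame(sv.genotypes[:, 1:], columns=["t"])
    model = hp.train_sv_imputer(tags, sv.sv_dosage, n_splits=10, seed=0)
    assert model.mean_accuracy == 1.0


def test_imputer_reproducible_and_between_chance_and_one():
    sv = syn.simulate_sv_locus(400, [0.75], 0.4, seed=11)
    tags = pd.DataFrame(sv.genotypes[:, 1:], columns=["t"])
    a = hp.train_sv_imputer(tags, sv.sv_dosage, n_splits=15, seed=3)
    b = hp.train_sv_imputer(tags, sv.sv_dosage, n_splits=15, seed=3)
    assert np.array_equal(a.accuracy_distribution, b.accuracy_distribution)
    prior = np.max(np.bincount(sv.sv_dosage)) / len(sv.sv_dosage)
    assert prior < a.mean_accuracy < 1.0


def test_shuffled_labels_accuracy_near_prior(rng):
    sv = syn.simulate_sv_locus(400, [0.75], 0.4, seed=12)
    tags = pd.DataFrame(sv.genotypes[:, 1:], columns=["t"])
    y = rng.permutation(sv.sv_dosage)
    model = hp.train_sv_imputer(tags, y, n_splits=15, seed=4)
    prior = np.max(np.bincount(y)) / len(y)
    assert abs(model.mean_accuracy - prior) < 0.1


def test_impute_requires_full_panel_and_handles_empty():
    sv = syn.simulate_sv_locus(200, [0.9], 0.4, seed=13)
    tags = pd.DataFrame(sv.genotypes[:, 1:], columns=["t"])
    model = hp.train_sv_imputer(tags, sv.sv_dosage, n_splits=5, seed=0)
    with pytest.raises(KeyError, match="absent"):
        hp.impute_sv(model, pd.DataFrame({"other": [0, 1]}))
    assert hp.impute_sv(model, pd.DataFrame(columns=["t"])).empty


def test_imputer_input_validation():
    sv = syn.simulate_sv_locus(40, [0.9], 0.4, seed=14)
    tags = pd.DataFrame(sv.genotypes[:, 1:], columns=["t"])
    with pytest.raises(ValueError, match="100"):
        hp.train_sv_imputer(tags, sv.sv_dosage)
    big = syn.simulate_sv_locus(150, [0.9], 0.4, seed=15)
    bad = big.sv_dosage.copy()
    bad[0] = 5
    with pytest.raises(ValueError, match="0/1/2"):
        hp.train_sv_imputer(pd.DataFrame(big.genotypes[:, 1:],
                                         columns=["t"]), bad)


# ---------------------------------------------------------------------------
# conditional / stratified association

def test_orthogonal_condition_leaves_estimate(rng):
    n = 2000
    g = rng.binomial(2, 0.3, n).astype(float)
    other = rng.binomial(2, 0.4, n).astype(float)
    y = 0.3 * g + rng.standard_normal(n)
    plain = hp.conditional_assoc(y, g)
    cond = hp.conditional_assoc(y, g, g_condition=other)
    assert cond["beta"] == pytest.approx(plain["beta"], abs=0.05)
    assert cond["p"] < 1e-8


def test_collinear_condition_reported_non_estimable(rng):
    g = rng.binomial(2, 0.3, 500).astype(float)
    out = hp.conditional_assoc(rng.standard_normal(500), g, g_condition=g)
    assert not out["estimable"]
    assert out["reason"] == "collinear_with_condition"


def test_logistic_branch_for_binary_outcome(rng):
    n = 3000
    g = rng.binomial(2, 0.3, n).astype(float)
    eta = -1.0 + 0.5 * g
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    out = hp.conditional_assoc(y, g)
    assert abs(out["beta"] - 0.5) < 3.5 * out["se"]


def test_stratified_assoc_effect_isolated_to_stratum(rng):
    n = 4000
    strata = np.repeat(["A", "B"], n // 2)
    g = rng.binomial(2, 0.4, n).astype(float)
    y = rng.standard_normal(n)
    y[strata == "A"] += 0.4 * g[strata == "A"]
    out = hp.stratified_assoc(y, g, None, strata).set_index("stratum")
    assert out.loc["A", "p"] < 1e-8 and out.loc["B", "p"] > 1e-4


def test_stratified_assoc_flags_underpowered(rng):
    y = np.concatenate([rng.random(100).round(), np.ones(5)])
    g = rng.binomial(2, 0.3, 105).astype(float)
    strata = np.array(["big"] * 100 + ["tiny"] * 5)
    out = hp.stratified_assoc(y, g, None, strata).set_index("stratum")
    assert bool(out.loc["tiny", "underpowered"])
    assert not bool(out.loc["big", "underpowered"])


# ---------------------------------------------------------------------------
# locus pheWAS

def test_phewas_recovers_planted_trans_effect(rng):
    n, n_prot = 800, 50
    g = pd.DataFrame({"v1": rng.binomial(2, 0.3, n).astype(float)})
    proteins = pd.DataFrame(rng.standard_normal((n, n_prot)),
                            columns=[f"apt{i}" for i in range(n_prot)])
    proteins["apt7"] += 0.5 * g["v1"]
    sig, allr, log = hp.locus_phewas(g, proteins)
    assert sig["protein"].tolist() == ["apt7"]
    assert (allr["p"] < 0.05 / n_prot).sum() == 1


def test_phewas_bonferroni_threshold_scales_with_aptamers(rng):
    n = 400
    g = pd.DataFrame({"v1": rng.binomial(2, 0.3, n).astype(float)})
    proteins = pd.DataFrame(rng.standard_normal((n, 4)),
                            columns=list("abcd"))
    proteins["a"] += 0.14 * g["v1"]   # moderate effect: p ~ 1e-3
    sig4, allr, _ = hp.locus_phewas(g, proteins)
    p = allr.set_index("protein").loc["a", "p"]
    if 0.05 / 4 < p < 0.05:
        assert "a" not in sig4["protein"].tolist()


def test_phewas_mac_and_missingness_filters(rng):
    n = 300
    rare = np.zeros(n)
    rare[:4] = 1.0                    # MAC 4 < 10
    holey = rng.binomial(2, 0.3, n).astype(float)
    holey[: n // 2] = np.nan          # 50% missing
    g = pd.DataFrame({"rare": rare, "holey": holey,
                      "ok": rng.binomial(2, 0.3, n).astype(float)})
    proteins = pd.DataFrame({"p1": rng.standard_normal(n)})
    _, _, log = hp.locus_phewas(g, proteins)
    log = log.set_index("variant_id")
    assert log.loc["rare", "reason"] == "mac_below_minimum"
    assert log.loc["holey", "reason"] == "missingness_above_maximum"
    assert not log.loc["ok", "excluded"]
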