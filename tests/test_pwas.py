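"""Weight training, weighted-burden association, FDR, classification."""

import numpy as np
import pandas as pd
import pytest

from sexbias import pwas
from sexbias.loci import MatrixLD


def toy_genotypes(rng, n=200, m=6):
    return pd.DataFrame(rng.binomial(2, 0.4, size=(n, m)),
                        columns=[f"v{j}" for j in range(m)])


# ---------------------------------------------------------------------------
# weight training

def test_noise_abundance_fails_heritability_screen(rng):
    # n_perm must exceed 99 for the permutation p to be able to reach < 0.01
    G = toy_genotypes(rng)
    fails = 0
    for i in range(10):
        y = rng.standard_normal(len(G))
        out = pwas.train_weights(G, y, None, (1, 100), "combined",
                                 seed=i, n_perm=120)
        fails += isinstance(out, pwas.HeritFailure)
    assert fails >= 9          # pure noise passes p<0.01 about 1% of the time


def test_single_causal_variant_recovered(rng):
    G = toy_genotypes(rng, n=400)
    g = G["v2"].to_numpy(dtype=float)
    h2 = 0.4
    beta = np.sqrt(h2 / (1 - h2)) / g.std()
    y = beta * g + rng.standard_normal(len(G))
    model = pwas.train_weights(G, y, None, (1, 100), "combined",
                               seed=1, n_perm=120)
    assert isinstance(model, pwas.WeightModel)
    w = dict(zip(model.variants, model.weights))
    assert abs(w.get("v2", 0.0)) == max(abs(x) for x in model.weights)
    assert abs(model.cv_r2 - h2) < 0.1


def test_training_deterministic_given_seed(rng):
    G = toy_genotypes(rng, n=300)
    y = 0.5 * G["v1"].to_numpy() + rng.standard_normal(len(G))
    a = pwas.train_weights(G, y, None, (1, 100), "female", seed=3, n_perm=0)
    b = pwas.train_weights(G, y, None, (1, 100), "female", seed=3, n_perm=0)
    assert a.weights == b.weights and a.model_name == b.model_name


def test_monomorphic_window_is_herit_fail():
    G = pd.DataFrame(np.ones((60, 3)), columns=list("abc"))
    out = pwas.train_weights(G, np.zeros(60), None, (1, 2), "combined")
    assert isinstance(out, pwas.HeritFailure)
    assert "polymorphic" in out.reason


def test_too_few_samples_rejected(rng):
    G = toy_genotypes(rng, n=20)
    with pytest.raises(ValueError, match="50"):
        pwas.train_weights(G, np.zeros(20), None, (1, 2), "combined")


def test_csf_weight_gating_adds_opposite_sex():
    assert pwas.csf_weight_gating(
        {"female": 1e-9, "male": 0.5, "combined": 1e-10}) \
        == ["combined", "female", "male"]
    assert pwas.csf_weight_gating({"female": 0.5, "male": 0.5}) == []


# ---------------------------------------------------------------------------
# association

def signed_ld(ids, R):
    return MatrixLD(pd.DataFrame(R, index=ids, columns=ids), signed=True)


def gwas_frame(ids, z):
    return pd.DataFrame({"variant_id": ids, "beta": z, "se": 1.0})


def test_single_variant_model_reduces_to_gwas_z():
    model = pwas.WeightModel("g", "brain", "female", ["v1"], [0.7],
                             (1, 2), "top1", 0.3, 0.001)
    ld = signed_ld(["v1"], np.eye(1))
    z, p, cov = pwas_assoc_noshrink(model, gwas_frame(["v1"], [3.0]), ld)
    assert z == pytest.approx(3.0)
    negative = pwas.WeightModel("g", "brain", "female", ["v1"], [-0.7],
                                (1, 2), "top1", 0.3, 0.001)
    z, _, _ = pwas_assoc_noshrink(negative, gwas_frame(["v1"], [3.0]), ld)
    assert z == pytest.approx(-3.0)


def pwas_assoc_noshrink(model, gwas, ld):
    return pwas.pwas_assoc(model, gwas, ld, shrink=0.0)


def test_perfectly_correlated_pair_equals_single_variant():
    R = np.array([[1.0, 1.0], [1.0, 1.0]])
    model = pwas.WeightModel("g", "brain", "female", ["a", "b"], [0.5, 0.5],
                             (1, 2), "enet", 0.3, 0.001)
    ld = signed_ld(["a", "b"], R)
    z, _, _ = pwas.pwas_assoc(model, gwas_frame(["a", "b"], [4.0, 4.0]), ld,
                              shrink=1e-9)
    assert z == pytest.approx(4.0, rel=1e-3)


def test_low_coverage_refused():
    model = pwas.WeightModel("g", "csf", "male", ["a", "b"], [1.0, 1.0],
                             (1, 2), "lasso", 0.2, 0.001)
    ld = signed_ld(["a"], np.eye(1))
    with pytest.raises(pwas.LowCoverageError):
        pwas.pwas_assoc(model, gwas_frame(["a"], [2.0]), ld,
                        coverage_floor=0.6)


# ---------------------------------------------------------------------------
# FDR

def test_bh_fdr_hand_computation():
    q = pwas.bh_fdr([0.01, 0.02, 0.03, 0.9])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.9])
    assert np.all(pwas.bh_fdr([1.0, 1.0]) == 1.0)


def test_bh_fdr_grouping_respected():
    p = [0.01, 0.02, 0.5, 0.6]
    joint = pwas.bh_fdr(p)
    grouped = pwas.bh_fdr(p, grouping=["a", "a", "b", "b"])
    assert not np.allclose(joint, grouped)
    assert np.allclose(grouped[:2], pwas.bh_fdr(p[:2]))
    assert np.allclose(grouped[2:], pwas.bh_fdr(p[2:]))


def test_bh_fdr_empty():
    assert pwas.bh_fdr([]).size == 0


# ---------------------------------------------------------------------------
# sex-specificity classification

def results_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "gwas_sex",
                                       "weight_stratum", "z", "p", "p_fdr"])


def combo(gene, gsex, wstr, z, p, q=None, tissue="brain"):
    return (gene, tissue, gsex, wstr, z, p, q if q is not None else p)


def test_primary_discovery_female_biased():
    res = results_frame([
        combo("A", "female", "female", 5.0, 1e-6, 0.01),
        combo("A", "male", "male", 0.9, 0.33, 0.9),
    ])
    out = pwas.classify_sex_specific(res)
    row = out.iloc[0]
    assert row["sex_bias"] == "female" and row["discovery"] == "primary"


def test_concordant_nominal_opposite_sex_blocks():
    res = results_frame([
        combo("A", "female", "female", 5.0, 1e-6, 0.01),
        combo("A", "male", "male", 2.1, 0.04, 0.4),   # same sign, p < .05
    ])
    assert pwas.classify_sex_specific(res).iloc[0]["sex_bias"] == "none"


def test_discordant_opposite_sex_does_not_block():
    res = results_frame([
        combo("A", "female", "combined", 5.0, 1e-6, 0.01),
        combo("A", "male", "combined", -2.5, 0.01, 0.2),  # opposite sign
    ])
    row = pwas.classify_sex_specific(res).iloc[0]
    assert row["sex_bias"] == "female" and row["discovery"] == "secondary"


def test_locus_rule_demotes_whole_locus():
    res = results_frame([
        # top protein at locus: significant both sexes -> not sex-biased
        combo("TOP", "female", "female", 6.0, 1e-9, 1e-4),
        combo("TOP", "male", "male", 5.0, 1e-6, 1e-3),
        # weaker protein alone would be female-biased
        combo("B", "female", "female", 4.0, 1e-4, 0.01),
        combo("B", "male", "male", 0.5, 0.6, 0.9),
    ])
    out = pwas.classify_sex_specific(res, locus_map={"TOP": "L", "B": "L"})
    assert (out["sex_bias"] == "none").all()


def test_classification_order_invariant():
    rows = [
        combo("A", "female", "female", 5.0, 1e-6, 0.01),
        combo("A", "male", "male", 0.9, 0.33, 0.9),
        combo("B", "male", "combined", -4.0, 1e-4, 0.02),
        combo("B", "female", "female", 0.2, 0.8, 0.9),
    ]
    a = pwas.classify_sex_specific(results_frame(rows))
    b = pwas.classify_sex_specific(results_frame(rows[::-1]))
    pd.testing.assert_frame_equal(a.sort_values("gene_id").reset_index(drop=True),
                                  b.sort_values("gene_id").reset_index(drop=True))


# ---------------------------------------------------------------------------
# ancestry consistency and sensitivity rules

def test_afr_consistency_pwas_rules():
    # concordant AFR z improves discovery-sex p, opposite stays null
    assert pwas.afr_consistency_pwas((5.0, 0.5), (2.0, 0.1), 1e5, 1e4)
    # AFR z = 0 dilutes the discovery z -> p worsens
    assert not pwas.afr_consistency_pwas((5.0, 0.5), (0.0, 0.0), 1e5, 1e5)
    # opposite-sex meta becomes nominally significant -> fails
    assert not pwas.afr_consistency_pwas((5.0, 2.0), (3.0, 2.5), 1e5, 1e5)


def test_sensitivity_consistency_rules():
    full = {"z_disc": 4.0, "p_disc": 1e-4, "p_opp": 0.5}
    assert pwas.sensitivity_consistency(
        full, {"z_disc": 3.0, "p_disc": 0.01, "p_opp": 0.4})
    assert not pwas.sensitivity_consistency(
        full, {"z_disc": -3.0, "p_disc": 0.01, "p_opp": 0.4})  # sign flip
    assert not pwas.sensitivity_consistency(
        full, {"z_disc": 1.9, "p_disc": 0.06, "p_opp": 0.4})
    assert not pwas.sensitivity_consistency(
        full, {"z_disc": 3.0, "p_disc": 0.01, "p_opp": 0.03})
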