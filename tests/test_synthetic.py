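"""Generators: LD structure, GWAS calibration, proxy rules, QTLs, SV locus."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sexbias import synthetic as syn


# ---------------------------------------------------------------------------
# haplotype panel

def adjacent_r2(panel, n_blocks, per_block):
    out = []
    for b in range(n_blocks):
        ids = [f"rs{b}_{j}" for j in range(per_block)]
        m = panel.r2(ids, ids)
        out.extend(m[j, j + 1] for j in range(per_block - 1))
    return np.array(out)


def test_panel_independence_case():
    panel = syn.simulate_panel(4, 6, 0.0, 8000, seed=1)
    r2 = adjacent_r2(panel, 4, 6)
    assert np.all(np.sqrt(r2) < 3 / np.sqrt(8000))


def test_panel_realizes_target_adjacent_r2():
    panel = syn.simulate_panel(5, 10, 0.9, 20000, seed=2)
    assert abs(adjacent_r2(panel, 5, 10).mean() - 0.81) < 0.05


def test_panel_cross_block_independence():
    panel = syn.simulate_panel(3, 5, 0.8, 10000, seed=3)
    assert panel.r2(["rs0_0"], ["rs2_0"])[0, 0] < 0.01


def test_panel_seed_determinism():
    a = syn.simulate_panel(3, 4, 0.5, 1000, seed=9)
    b = syn.simulate_panel(3, 4, 0.5, 1000, seed=9)
    assert np.array_equal(a.haplotypes, b.haplotypes)
    assert np.array_equal(a.positions, b.positions)


def test_panel_invariants(small_panel):
    assert np.all(np.isin(small_panel.haplotypes, [0, 1]))
    assert np.all(np.diff(small_panel.positions) > 0)
    counts = np.bincount(small_panel.block_map)
    assert np.all(counts == 8)


def test_panel_rejects_bad_arguments():
    with pytest.raises(ValueError):
        syn.simulate_panel(0, 5, 0.5, 100, seed=1)
    with pytest.raises(ValueError):
        syn.simulate_panel(2, 5, 1.0, 100, seed=1)


def test_panel_apoe_block_region():
    panel = syn.simulate_panel(3, 5, 0.5, 200, seed=1, apoe_block=1)
    chrom, start, end = panel.apoe_region
    mid = int(panel.positions[panel.block_map == 1].mean())
    assert start <= mid <= end
    assert end == mid + 5_000_000 and start == max(1, mid - 5_000_000)


# ---------------------------------------------------------------------------
# case-control GWAS

SPEC = syn.CohortSpec("c1", 5000, 5000)


def test_null_gwas_p_uniform():
    panel = syn.simulate_panel(500, 10, 0.4, 2000, seed=4)
    table = syn.simulate_case_control_gwas(panel, [], SPEC, "female", seed=5)
    frac = (table["p"] < 0.05).mean()
    assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / len(table))
    assert stats.kstest(table["p"], "uniform").pvalue > 0.01


def test_planted_effect_recovered_fit_vs_approx():
    panel = syn.simulate_panel(2, 5, 0.5, 4000, seed=6)
    beta = np.log(1.5)
    eff = [syn.PlantedEffect("rs0_2", beta, beta)]
    spec = syn.CohortSpec("c", 2500, 2500)
    fit = syn.simulate_case_control_gwas(panel, eff, spec, "female",
                                         seed=7, mode="fit")
    approx = syn.simulate_case_control_gwas(panel, eff, spec, "female",
                                            seed=8, mode="approx")
    for table in (fit, approx):
        row = table.set_index("variant_id").loc["rs0_2"]
        assert abs(row["beta"] - beta) < 3.5 * row["se"]
    # the asymptotic se approximation matches the logistic fit
    se_fit = fit.set_index("variant_id").loc["rs0_2", "se"]
    se_app = approx.set_index("variant_id").loc["rs0_2", "se"]
    assert se_app == pytest.approx(se_fit, rel=0.25)


def test_missing_effect_variant_raises(small_panel):
    eff = [syn.PlantedEffect("nonexistent", 0.1, 0.1)]
    with pytest.raises(syn.MissingVariantError):
        syn.simulate_case_control_gwas(small_panel, eff, SPEC, "female")


def test_low_mac_variants_flagged():
    panel = syn.simulate_panel(2, 5, 0.3, 2000, seed=10,
                               freq_range=(0.15, 0.5))
    tiny = syn.CohortSpec("t", 15, 15)
    table = syn.simulate_case_control_gwas(panel, [], tiny, "male", seed=11)
    assert (~table["mac_pass"]).any()          # MAC <= 20 flagged
    big = syn.simulate_case_control_gwas(panel, [], SPEC, "male", seed=11)
    assert big["mac_pass"].all()


def test_proxy_effect_attenuation():
    panel = syn.simulate_panel(1, 4, 0.3, 2000, seed=12)
    eff = [syn.PlantedEffect("rs0_1", 0.4, 0.4)]
    proxy = syn.CohortSpec("p", 50_000, 50_000, design="proxy")
    direct = syn.CohortSpec("d", 50_000, 50_000)
    tp = syn.simulate_case_control_gwas(panel, eff, proxy, "female", seed=13)
    td = syn.simulate_case_control_gwas(panel, eff, direct, "female", seed=13)
    bp = tp.set_index("variant_id").loc["rs0_1", "beta"]
    bd = td.set_index("variant_id").loc["rs0_1", "beta"]
    assert bp == pytest.approx(bd / 2, abs=0.05)


# ---------------------------------------------------------------------------
# proxy phenotype

def subjects():
    return pd.DataFrame({
        "mother_affected": [True, False, True, False, True],
        "father_affected": [False, True, False, False, False],
        "mother_age": [80.0, 70.0, 60.0, 75.0, 90.0],
        "father_age": [78.0, 68.0, 70.0, 50.0, 82.0],
    })


def test_proxy_female_rules():
    pheno, weights = syn.build_proxy_phenotype(subjects(), "female")
    # affected mother (age 80) -> proxy case with half weight
    assert pheno[0] == 1.0 and weights[0] == 0.5
    # affected father -> excluded from female analysis
    assert np.isnan(pheno[1])
    # mother affected at 60 -> phenotype unknown (age >= 65 rule)
    assert np.isnan(pheno[2])
    # unaffected mother aged 75 -> proxy control, full weight
    assert pheno[3] == 0.0 and weights[3] == 1.0


def test_proxy_male_symmetric():
    pheno, _ = syn.build_proxy_phenotype(subjects(), "male")
    assert np.isnan(pheno[0])        # affected mother excludes from male run
    assert pheno[1] == 1.0           # affected father aged 68


def test_proxy_missing_fields_raise():
    with pytest.raises(KeyError):
        syn.build_proxy_phenotype(pd.DataFrame({"mother_affected": [1]}),
                                  "female")


# ---------------------------------------------------------------------------
# QTL simulation

def gene_model(panel, causal="rs0_2", beta=0.5):
    return syn.GeneModel("GENE1", "1", int(panel.positions[2]),
                         [causal], [beta])


def test_qtl_z_grows_with_sample_size(small_panel):
    gm = gene_model(small_panel)
    zs = []
    for n in (500, 50_000):
        tables, _, _ = syn.simulate_qtl_and_weights(
            small_panel, [gm], {"GENE1": True}, n=n, seed=20)
        row = tables["GENE1"].set_index("variant_id").loc["rs0_2"]
        zs.append(abs(row["beta"] / row["se"]))
    assert zs[1] > 5 * zs[0]         # z scales ~ sqrt(n): factor 10


def test_qtl_truth_labels_passed_through(small_panel):
    gm = gene_model(small_panel)
    _, weights, truth = syn.simulate_qtl_and_weights(
        small_panel, [gm], {"GENE1": True}, n=1000, seed=21)
    assert truth["GENE1"]["shared_causal"] is True
    assert weights["GENE1"].variants == ["rs0_2"]


def test_qtl_zero_effect_gene_is_null(small_panel):
    gm = syn.GeneModel("G0", "1", int(small_panel.positions[2]),
                       ["rs0_2"], [0.0])
    tables, weights, truth = syn.simulate_qtl_and_weights(
        small_panel, [gm], {}, n=2000, seed=22)
    assert truth["G0"]["null"]
    assert weights["G0"] is None     # fails the heritability screen downstream
    assert (tables["G0"]["p"] > 5e-8).all()


def test_qtl_causal_outside_cis_window_raises(small_panel):
    far = syn.GeneModel("G1", "1", 1, ["rs5_7"], [0.5], cis_window=1000)
    with pytest.raises(ValueError, match="outside cis window"):
        syn.simulate_qtl_and_weights(small_panel, [far], {}, 100, seed=0)


# ---------------------------------------------------------------------------
# structural-variant locus

def test_sv_perfect_tagging():
    sv = syn.simulate_sv_locus(2000, [1.0], 0.3, seed=30)
    assert sv.realized_r2[0] == pytest.approx(1.0)
    assert np.array_equal(sv.genotypes[:, 0], sv.genotypes[:, 1])


def test_sv_target_r2_realized():
    sv = syn.simulate_sv_locus(5000, [0.75], 0.4, seed=31)
    assert abs(sv.realized_r2[0] - 0.75) < 0.05


def test_sv_monomorphic_rejected():
    with pytest.raises(syn.InfeasibleLDError):
        syn.simulate_sv_locus(100, [0.5], 0.0, seed=0)


def test_sv_infeasible_r2_names_bound():
    with pytest.raises(syn.InfeasibleLDError, match="min"):
        syn.simulate_sv_locus(100, [0.9], 0.5, seed=0, tag_freqs=[0.05])


def test_sv_seed_determinism():
    a = syn.simulate_sv_locus(500, [0.75], 0.4, seed=5)
    b = syn.simulate_sv_locus(500, [0.75], 0.4, seed=5)
    assert np.array_equal(a.phased, b.phased)
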