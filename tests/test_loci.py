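"""Windowing, clumping, sex-bias filtering, novelty, ancestry consistency."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from sexbias import loci
from sexbias.sumstats import p_from_z


def merged_row(vid, chrom="1", pos=100, z_f=0.0, z_m=0.0, se=0.01):
    bf, bm = z_f * se, z_m * se
    z_het = (bf - bm) / np.sqrt(2 * se ** 2)
    return {
        "variant_id": vid, "chrom": chrom, "pos": pos, "ea": "A", "oa": "G",
        "beta_f": bf, "se_f": se, "p_f": p_from_z(z_f),
        "beta_m": bm, "se_m": se, "p_m": p_from_z(z_m),
        "z_het": z_het, "p_het": p_from_z(z_het),
    }


def merged_frame(rows):
    df = pd.DataFrame(rows)
    df["p_min"] = np.minimum(df["p_f"], df["p_m"])
    return df


class FlatLD:
    """All pairs share one r2 value."""

    def __init__(self, r2=0.0, known=None):
        self.value = r2
        self.known = known

    def __contains__(self, v):
        return self.known is None or v in self.known

    def r2(self, a, b):
        if a not in self or b not in self:
            raise loci.MissingLDError([a, b])
        return self.value

    def r2_with(self, lead, ids):
        missing = [v for v in [lead, *ids] if v not in self]
        if missing:
            raise loci.MissingLDError(missing)
        return np.full(len(ids), self.value)


# ---------------------------------------------------------------------------
# window clustering

def test_window_cluster_splits_distant_variants():
    df = merged_frame([merged_row("a", pos=1_000_000, z_f=6),
                       merged_row("b", pos=2_500_000, z_f=6)])
    clusters = loci.window_cluster(df)
    assert len(clusters) == 2


def test_window_cluster_chains_transitively():
    df = merged_frame([merged_row("a", pos=1_000_000, z_f=6),
                       merged_row("b", pos=1_900_000, z_f=6),
                       merged_row("c", pos=2_800_000, z_f=6)])
    clusters = loci.window_cluster(df)
    assert len(clusters) == 1 and len(clusters[0]) == 3


def test_window_cluster_empty_when_nothing_qualifies():
    df = merged_frame([merged_row("a", z_f=2.0)])
    assert loci.window_cluster(df) == []


def test_window_cluster_rejects_unsorted():
    df = merged_frame([merged_row("a", pos=200, z_f=6),
                       merged_row("b", pos=100, z_f=6)])
    with pytest.raises(ValueError, match="sorted"):
        loci.window_cluster(df)


# ---------------------------------------------------------------------------
# clumping

def test_clump_independent_variants_each_lead():
    df = merged_frame([merged_row(v, pos=100 + i, z_f=6 + i)
                       for i, v in enumerate("abc")])
    signals = loci.ld_clump(df, FlatLD(0.0))
    assert len(signals) == 3


def test_clump_absorbs_linked_weaker_variant():
    df = merged_frame([merged_row("weak", pos=100, z_f=6),
                       merged_row("strong", pos=200, z_f=8)])
    signals = loci.ld_clump(df, FlatLD(0.5))
    assert len(signals) == 1
    assert signals[0].lead_id == "strong"
    assert set(signals[0].members["variant_id"]) == {"weak", "strong"}


def test_clump_tie_breaks_by_position():
    rows = [merged_row("late", pos=200, z_f=6),
            merged_row("early", pos=100, z_f=6)]
    signals = loci.ld_clump(merged_frame(rows), FlatLD(0.5))
    assert signals[0].lead_id == "early"


def test_clump_invariant_to_row_order():
    rows = [merged_row(v, pos=100 * (i + 1), z_f=5 + i)
            for i, v in enumerate("abcd")]
    a = loci.ld_clump(merged_frame(rows), FlatLD(0.3))
    b = loci.ld_clump(merged_frame(rows[::-1]), FlatLD(0.3))
    assert [s.lead_id for s in a] == [s.lead_id for s in b]


def test_clump_missing_ld_is_explicit():
    df = merged_frame([merged_row("a", pos=100, z_f=6),
                       merged_row("b", pos=200, z_f=7)])
    with pytest.raises(loci.MissingLDError):
        loci.ld_clump(df, FlatLD(0.0, known={"b"}))


# ---------------------------------------------------------------------------
# sex-bias filter

def one_cluster(*rows):
    df = merged_frame(list(rows))
    return [loci.ld_clump(df, FlatLD(0.0))]


def test_filter_retains_sex_biased_lead():
    clusters = one_cluster(merged_row("hit", z_f=5.9, z_m=2.0))
    kept, log = loci.sex_bias_filter(clusters, None)
    assert len(kept) == 1 and kept[0].signals[0].discovery_sex == "female"
    assert log == []


def test_filter_drops_non_heterogeneous_genomewide_hit():
    clusters = one_cluster(merged_row("hit", z_f=6.0, z_m=5.5))
    kept, log = loci.sex_bias_filter(clusters, None)
    assert kept == []
    assert log[0]["reason"] == "not_sex_heterogeneous"


def test_filter_admits_het_gwas_route():
    # sub-genome-wide in each sex but genome-wide heterogeneity
    clusters = one_cluster(merged_row("het", z_f=4.3, z_m=-4.2))
    kept, _ = loci.sex_bias_filter(clusters, None)
    assert len(kept) == 1
    assert kept[0].signals[0].discovery_sex == "het_gwas"


def test_filter_keeps_single_signal_per_locus():
    df = merged_frame([merged_row("s1", pos=100, z_f=6.0, z_m=2.0),
                       merged_row("s2", pos=200, z_f=7.0, z_m=2.5)])
    clusters = [loci.ld_clump(df, FlatLD(0.0))]
    kept, log = loci.sex_bias_filter(clusters, None)
    assert len(kept) == 1 and kept[0].signals[0].lead_id == "s2"
    assert [e["reason"] for e in log] == ["secondary_signal"]


def test_filter_known_variant_exclusion():
    rows = [merged_row("new", pos=100, z_f=6.0, z_m=2.0),
            merged_row("known", pos=200, z_f=7.0, z_m=6.8)]
    merged = merged_frame(rows)
    clusters = [loci.ld_clump(merged_frame(rows[:1]), FlatLD(0.5))]
    catalog = pd.DataFrame({"variant_id": ["known"], "chrom": ["1"],
                            "pos": [200], "p_sexhet": [0.4], "maf": [0.3]})
    kept, log = loci.sex_bias_filter(clusters, catalog, FlatLD(0.5), merged)
    assert kept == []
    assert log[0]["reason"] == "known_variant_ld"
    assert log[0]["catalog_variant"] == "known"


def test_filter_catalog_without_sexhet_warns_not_fires():
    rows = [merged_row("new", pos=100, z_f=6.0, z_m=2.0)]
    catalog = pd.DataFrame({"variant_id": ["known"], "chrom": ["1"],
                            "pos": [200], "p_sexhet": [np.nan], "maf": [0.3]})
    clusters = [loci.ld_clump(merged_frame(rows), FlatLD(0.5))]
    with pytest.warns(UserWarning, match="cannot fire"):
        kept, _ = loci.sex_bias_filter(clusters, catalog, FlatLD(0.5),
                                       merged_frame(rows))
    assert len(kept) == 1


def test_filter_ratio_warn_vs_drop():
    row = merged_row("r", z_f=12.0, z_m=8.5)  # ratio 1.41, het p ~ .013
    with pytest.warns(UserWarning, match="effect ratio"):
        kept, _ = loci.sex_bias_filter(one_cluster(row), None)
    assert len(kept) == 1
    kept, log = loci.sex_bias_filter(one_cluster(row), None,
                                     ratio_rule="drop")
    assert kept == [] and log[0]["reason"] == "effect_ratio_below_min"


def test_exclusion_log_one_entry_per_excluded_signal():
    df = merged_frame([merged_row("a", pos=100, z_f=6.0, z_m=2.0),
                       merged_row("b", pos=200, z_f=5.7, z_m=2.0),
                       merged_row("c", pos=300, z_f=4.0, z_m=4.0)])
    clusters = [loci.ld_clump(df, FlatLD(0.0))]
    kept, log = loci.sex_bias_filter(clusters, None)
    ids = [e["variant_id"] for e in log]
    assert sorted(ids) == ["b", "c"] and len(set(ids)) == len(ids)


# ---------------------------------------------------------------------------
# novelty

CATALOG = pd.DataFrame({"variant_id": ["k1"], "chrom": ["1"],
                        "pos": [5_000_000]})


def lead_at(pos):
    return pd.Series({"variant_id": "lead", "chrom": "1", "pos": pos})


def test_novelty_three_way():
    assert loci.classify_novelty(lead_at(7_500_000), CATALOG,
                                 FlatLD(0.0)) == "novel_locus_novel_variant"
    assert loci.classify_novelty(lead_at(5_400_000), CATALOG,
                                 FlatLD(0.002)) == "known_locus_novel_variant"
    assert loci.classify_novelty(lead_at(5_100_000), CATALOG,
                                 FlatLD(0.3)) == "known_locus_known_variant"


def test_novelty_manual_override():
    got = loci.classify_novelty(lead_at(5_100_000), CATALOG, FlatLD(0.3),
                                overrides=["lead"])
    assert got == "known_locus_novel_variant"


# ---------------------------------------------------------------------------
# AFR consistency

def stat(beta, se):
    return SimpleNamespace(beta=beta, se=se)


def test_afr_consistency_concordant_improves():
    eur = (stat(0.2, 0.02), stat(0.05, 0.02))
    afr = (stat(0.2, 0.08), stat(0.05, 0.08))
    assert loci.afr_consistency(eur, afr) == "yes"


def test_afr_consistency_discordant_worsens():
    eur = (stat(0.2, 0.02), stat(0.05, 0.02))
    afr = (stat(0.1, 0.01), stat(0.1, 0.01))   # precise, equal across sexes
    assert loci.afr_consistency(eur, afr) == "no"


def test_afr_consistency_absent_variant():
    assert loci.afr_consistency((stat(0.2, 0.02), stat(0.0, 0.02)),
                                None) == "eur_only"


# ---------------------------------------------------------------------------
# region masking and end-to-end table

def test_mask_region_drops_inside_only():
    df = merged_frame([merged_row("in", pos=500), merged_row("out", pos=5000)])
    out = loci.mask_region(df, ("1", 1, 1000))
    assert out["variant_id"].tolist() == ["out"]


def test_discover_loci_reports_novelty_and_span(small_panel):
    from sexbias import synthetic as syn
    from sexbias.sumstats import merge_sexes

    eff = [syn.PlantedEffect("rs0_4", 0.12, 0.06)]
    spec = syn.CohortSpec("c", 50_000, 50_000)
    fem = syn.simulate_case_control_gwas(small_panel, eff, spec, "female",
                                         seed=1)
    mal = syn.simulate_case_control_gwas(small_panel, eff, spec, "male",
                                         seed=2)
    merged = merge_sexes(fem, mal)
    catalog = pd.DataFrame({"variant_id": ["far"], "chrom": ["1"],
                            "pos": [int(1e9)]})
    table, _ = loci.discover_loci(merged, loci.PanelLD(small_panel),
                                  catalog=catalog)
    assert len(table) == 1
    row = table.iloc[0]
    assert row["novelty"] == "novel_locus_novel_variant"
    assert row["span_end"] - row["pos"] == 1_000_000
    assert row["discovery_sex"] == "female"
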