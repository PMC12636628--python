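"""Gene-set enrichment, sex-specificity, cell-type and drug analyses.

Enrichment is upper-tail hypergeometric over a fixed gene universe with
Benjamini-Hochberg correction across sets; the gene ratio k/n uses the
number of query genes mapped to the universe as denominator (the fold filter
depends on this convention). Sex-specificity keeps a set for one sex only
when its gene ratio is at least 1.5-fold the other sex's. Cell-type
specificity assigns a gene to its predominant cell type when that type
carries at least 1.5x the expression share of the runner-up. Drug analyses
expand priority genes through file-based PPI / disease-literature /
druggable-tier tables before enrichment over drug gene sets and an
FDA-approval filter.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "hypergeom_enrich", "sex_specificity_filter", "cell_type_specificity",
    "cell_type_enrichment", "expand_drug_gene_network", "drug_enrichment",
]

_ROW_COLUMNS = ["set_name", "k_overlap", "n_query", "K_set", "N_universe",
                "gene_ratio", "fold", "p", "p_fdr", "genes"]


def hypergeom_enrich(query_genes, collection: dict[str, list[str]],
                     universe: list[str]) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a query against gene sets.

    Query genes outside the universe are logged and dropped; set members are
    restricted to the universe. p = P(X >= k) with X ~ Hypergeom(N, K, n);
    BH correction across all sets. fold = (k/n)/(K/N).
    """
    uni = set(universe)
    query = [g for g in dict.fromkeys(query_genes)]
    outside = [g for g in query if g not in uni]
    if outside:
        warnings.warn(f"{len(outside)} query gene(s) outside the universe "
                      "dropped", stacklevel=2)
    query = [g for g in query if g in uni]
    n = len(query)
    N = len(uni)
    if n == 0:
        warnings.warn("empty query after universe restriction", stacklevel=2)
        return pd.DataFrame(columns=_ROW_COLUMNS)
    qset = set(query)
    rows = []
    for name, members in collection.items():
        mem = set(members) & uni
        K = len(mem)
        overlap = sorted(qset & mem)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        ratio = k / n
        fold = (ratio / (K / N)) if K else np.nan
        rows.append({"set_name": name, "k_overlap": k, "n_query": n,
                     "K_set": K, "N_universe": N, "gene_ratio": ratio,
                     "fold": fold, "p": min(p, 1.0),
                     "genes": ";".join(overlap)})
    table = pd.DataFrame(rows)
    table["p_fdr"] = multipletests(table["p"], method="fdr_bh")[1]
    return table[_ROW_COLUMNS]


def sex_specificity_filter(rows_f: pd.DataFrame, rows_m: pd.DataFrame,
                           fold: float = 1.5, alpha_fdr: float = 0.05,
                           require_both_sexes: bool = False):
    """Keep FDR-significant sets whose gene ratio is >= ``fold`` times the
    other sex's ratio. A set absent from the other sex's results counts as
    ratio 0 there (always passes the fold rule) unless
    ``require_both_sexes``. Returns (kept_female, kept_male); no set can be
    retained for both sexes."""

    def _keep(own: pd.DataFrame, other: pd.DataFrame) -> pd.DataFrame:
        if not len(own):
            return own.copy()
        other_ratio = other.set_index("set_name")["gene_ratio"] \
            if len(other) else pd.Series(dtype=float)
        o = own["set_name"].map(other_ratio)
        missing = o.isna()
        o = o.fillna(0.0)
        ok = (own["p_fdr"] < alpha_fdr) & (own["gene_ratio"] >= fold * o)
        if require_both_sexes:
            ok &= ~missing
        return own.loc[ok].reset_index(drop=True)

    return _keep(rows_f, rows_m), _keep(rows_m, rows_f)


def cell_type_specificity(expression: pd.DataFrame,
                          fold: float = 1.5) -> pd.Series:
    """Assign each gene to its predominant cell type, or none.

    ``expression`` is genes x cell types (mean nonnegative expression). The
    per-type share of a gene's summed expression is computed; the top type is
    assigned iff its share is >= ``fold`` times the second highest. All-zero
    genes map to none.
    """
    X = expression.to_numpy(dtype=float)
    if np.any(X < 0):
        raise ValueError("expression must be nonnegative")
    total = X.sum(axis=1, keepdims=True)
    assigned = pd.Series("none", index=expression.index, dtype=object)
    nonzero = total[:, 0] > 0
    shares = np.divide(X, total, out=np.zeros_like(X), where=total > 0)
    order = np.argsort(shares, axis=1)
    top = order[:, -1]
    second = order[:, -2]
    top_share = shares[np.arange(len(X)), top]
    second_share = shares[np.arange(len(X)), second]
    specific = nonzero & ((second_share == 0)
                          | (top_share >= fold * second_share))
    assigned[specific] = expression.columns.to_numpy()[top[specific]]
    return assigned


def cell_type_enrichment(sex_genes: dict[str, list[str]],
                         ct_map: pd.Series, background: list[str],
                         min_annotated: int = 10) -> pd.DataFrame:
    """Hypergeometric cell-type enrichment per sex gene list.

    ``ct_map`` maps background genes to a cell type (or 'none'). Cell types
    with fewer than ``min_annotated`` annotated genes pooled across both sex
    lists are flagged unreliable (kept in the table, excluded from headline
    interpretation).
    """
    types = sorted(set(ct_map.unique()) - {"none"})
    collections = {t: ct_map.index[ct_map == t].tolist() for t in types}
    all_rows = []
    annotated_counts = {t: 0 for t in types}
    for sex, genes in sex_genes.items():
        in_bg = [g for g in genes if g in set(background)]
        for t in types:
            annotated_counts[t] += len(set(in_bg) & set(collections[t]))
    for sex, genes in sex_genes.items():
        if not genes:
            continue
        table = hypergeom_enrich(genes, collections, background)
        table.insert(0, "sex", sex)
        table["unreliable"] = table["set_name"].map(
            lambda t: annotated_counts[t] < min_annotated)
        all_rows.append(table)
    if not all_rows:
        return pd.DataFrame(columns=["sex", *_ROW_COLUMNS, "unreliable"])
    return pd.concat(all_rows, ignore_index=True)


def expand_drug_gene_network(seed_genes: list[str], ppi_edges: pd.DataFrame,
                             ad_literature_genes: list[str],
                             druggable_tiers: pd.DataFrame,
                             tier: str = "Tier 1"):
    """Expand priority genes into a disease-relevant druggable network.

    Added genes are PPI neighbors of a seed that are both flagged in the
    disease-literature table and in the requested druggable tier. Returns
    (expanded_genes, provenance): provenance records, per added gene, its
    seed(s) and qualifying edges; seeds absent from the PPI table are kept
    as isolated seeds and logged in provenance with no edges.
    """
    lit = set(ad_literature_genes)
    tier_genes = set(
        druggable_tiers.loc[druggable_tiers["tier"] == tier, "gene"])
    adjacency: dict[str, set[str]] = {}
    for _, row in ppi_edges.iterrows():
        a, b = str(row["gene_a"]), str(row["gene_b"])
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)
    expanded = list(dict.fromkeys(seed_genes))
    provenance: list[dict] = []
    for seed in dict.fromkeys(seed_genes):
        neighbors = adjacency.get(seed)
        if neighbors is None:
            provenance.append({"gene": seed, "seed": seed,
                               "role": "isolated_seed", "edge": None})
            continue
        for nb in sorted(neighbors):
            if nb in lit and nb in tier_genes:
                if nb not in expanded:
                    expanded.append(nb)
                provenance.append({"gene": nb, "seed": seed,
                                   "role": "expanded",
                                   "edge": f"{seed}-{nb}"})
    return expanded, pd.DataFrame(provenance)


def drug_enrichment(expanded_f: list[str], expanded_m: list[str],
                    drug_sets: dict[str, list[str]], fda_list: list[str],
                    universe: list[str], fold: float = 1.5,
                    alpha_fdr: float = 0.05):
    """Per-sex drug-set enrichment with FDA and sex-specificity filters.

    Hypergeometric enrichment of each sex's expanded gene network over the
    drug gene sets, restricted to FDA-approved drugs, then the fold-based
    sex-specificity filter. Returns (drugs_female, drugs_male).
    """
    fda = set(fda_list)
    rows_f = hypergeom_enrich(expanded_f, drug_sets, universe)
    rows_m = hypergeom_enrich(expanded_m, drug_sets, universe)
    rows_f = rows_f.loc[rows_f["set_name"].isin(fda)].reset_index(drop=True)
    rows_m = rows_m.loc[rows_m["set_name"].isin(fda)].reset_index(drop=True)
    return sex_specificity_filter(rows_f, rows_m, fold=fold,
                                  alpha_fdr=alpha_fdr)
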