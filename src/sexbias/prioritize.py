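"""Gene priority scoring: colocalization evidence + differential abundance.

Candidate genes at sex-biased GWAS and PWAS loci are ranked 1 (high), 2
(medium), or 3 (none) from an evidence ledger holding their QTL
colocalization results across tissues and datasets, PWAS status, and
protein differential-abundance p-values. Scoring is a pure, table-driven
function of the ledger; every score records the single rule that fired, and
literature/missense overrides and locus exclusions are applied explicitly at
list assembly.

Gene-specific QTL types are eQTL, sQTL, and pQTL; methylation, histone
acetylation and chromatin accessibility QTLs never count toward a gene's
score but are surfaced as locus-level "epigenetic feature" annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "XqtlHit", "EvidenceLedger", "GeneScore",
    "score_gwas_locus_gene", "score_pwas_locus_gene", "score_gene",
    "differential_abundance", "apply_da_upgrade", "assemble_final_lists",
    "epigenetic_feature_prioritized",
]

GENE_SPECIFIC_QTL = {"eQTL", "sQTL", "pQTL"}
STRONG_PP4 = 0.7
SUGGESTIVE_PP4 = 0.4


@dataclass
class XqtlHit:
    qtl_type: str
    dataset: str
    pp4: float

    def __post_init__(self):
        if not (0.0 <= self.pp4 <= 1.0):
            raise ValueError("PP4 must lie in [0,1]")


@dataclass
class EvidenceLedger:
    """One gene's evidence at one locus.

    ``matching_pqtl_pp4`` is the colocalization PP4 for this gene in the
    pQTL data matching the locus's discovery tissue (None = the gene is
    unavailable there); ``xqtl_hits`` lists all other QTL colocalizations
    and must not duplicate the matching-tissue pQTL comparison.
    """

    gene_id: str
    locus_id: str
    origin: str  # "gwas_locus" | "pwas_locus"
    is_pwas_gene: bool = False
    pwas_tissue: str | None = None
    matching_pqtl_pp4: float | None = None
    nonmatching_pqtl_pp4: float | None = None
    xqtl_hits: list[XqtlHit] = field(default_factory=list)
    da_sex_p: float | None = None
    da_interaction_p: float | None = None

    @property
    def gene_specific_hits(self) -> list[XqtlHit]:
        return [h for h in self.xqtl_hits if h.qtl_type in GENE_SPECIFIC_QTL]

    def n_strong_gene_specific(self) -> int:
        """Distinct (qtl_type, dataset) pairs with strong colocalization;
        two datasets of the same tissue count separately."""
        pairs = {(h.qtl_type, h.dataset) for h in self.gene_specific_hits
                 if h.pp4 >= STRONG_PP4}
        return len(pairs)


@dataclass
class GeneScore:
    gene_id: str
    score: int
    rule_fired: str
    overrides: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.score not in (1, 2, 3):
            raise ValueError("score must be 1, 2, or 3")


# ---------------------------------------------------------------------------
# scoring rules

def score_gwas_locus_gene(ledger: EvidenceLedger) -> GeneScore:
    """Priority score for a gene at a GWAS-discovered locus.

    1: >1 strong gene-specific colocalization across tissues/datasets, or a
    PWAS-identified gene with strong matching-tissue pQTL colocalization;
    2: exactly one strong gene-specific colocalization; 3 otherwise.
    """
    if ledger.origin != "gwas_locus":
        raise ValueError("ledger origin must be gwas_locus")
    n_strong = ledger.n_strong_gene_specific()
    if n_strong > 1:
        return GeneScore(ledger.gene_id, 1, "gwas_multi_strong_xqtl")
    if (ledger.is_pwas_gene and ledger.matching_pqtl_pp4 is not None
            and ledger.matching_pqtl_pp4 >= STRONG_PP4):
        return GeneScore(ledger.gene_id, 1, "gwas_pwas_matching_pqtl_strong")
    if n_strong == 1:
        return GeneScore(ledger.gene_id, 2, "gwas_single_strong_xqtl")
    return GeneScore(ledger.gene_id, 3, "gwas_no_strong_xqtl")


def score_pwas_locus_gene(ledger: EvidenceLedger) -> GeneScore:
    """Priority score for a gene at a PWAS-discovered locus.

    1: the PWAS gene with strong matching-tissue pQTL colocalization; or a
    same-locus gene strong in the non-matching pQTL tissue while unavailable
    in the matching one; or a gene with >1 strong gene-specific
    colocalizations. 2: the PWAS gene with suggestive matching-tissue
    colocalization (upgraded to 1 given any other strong gene-specific hit);
    or exactly one strong gene-specific colocalization. 3 otherwise.
    """
    if ledger.origin != "pwas_locus":
        raise ValueError("ledger origin must be pwas_locus")
    m = ledger.matching_pqtl_pp4
    n_strong = ledger.n_strong_gene_specific()
    if ledger.is_pwas_gene and m is not None and m >= STRONG_PP4:
        return GeneScore(ledger.gene_id, 1, "pwas_matching_pqtl_strong")
    if (m is None and ledger.nonmatching_pqtl_pp4 is not None
            and ledger.nonmatching_pqtl_pp4 >= STRONG_PP4):
        return GeneScore(ledger.gene_id, 1,
                         "pwas_nonmatching_pqtl_strong_unavailable_matching")
    if n_strong > 1:
        return GeneScore(ledger.gene_id, 1, "pwas_multi_strong_xqtl")
    if (ledger.is_pwas_gene and m is not None
            and SUGGESTIVE_PP4 <= m < STRONG_PP4):
        if n_strong >= 1:
            return GeneScore(ledger.gene_id, 1,
                             "pwas_matching_suggestive_plus_strong_xqtl")
        return GeneScore(ledger.gene_id, 2, "pwas_matching_pqtl_suggestive")
    if n_strong == 1:
        return GeneScore(ledger.gene_id, 2, "pwas_single_strong_xqtl")
    return GeneScore(ledger.gene_id, 3, "pwas_no_strong_xqtl")


def score_gene(ledger: EvidenceLedger,
               da_upgrade: bool = True) -> GeneScore:
    """Score a ledger by origin, then apply the differential-abundance
    upgrade for score-3 genes."""
    if ledger.origin == "gwas_locus":
        score = score_gwas_locus_gene(ledger)
    elif ledger.origin == "pwas_locus":
        score = score_pwas_locus_gene(ledger)
    else:
        raise ValueError(f"unknown ledger origin {ledger.origin!r}")
    return apply_da_upgrade(score, ledger) if da_upgrade else score


def apply_da_upgrade(score: GeneScore, ledger: EvidenceLedger,
                     alpha: float = 0.05) -> GeneScore:
    """Score-3 genes with nominally significant sex or sex-by-status
    differential abundance are upgraded to score 2."""
    if score.score != 3:
        return score
    ps = [p for p in (ledger.da_sex_p, ledger.da_interaction_p)
          if p is not None]
    if any(p < alpha for p in ps):
        return GeneScore(score.gene_id, 2, "da_upgrade", score.overrides)
    return score


def epigenetic_feature_prioritized(ledgers: list[EvidenceLedger],
                                   pp4_min: float = STRONG_PP4) -> bool:
    """Locus-level flag: any strong mQTL/haQTL/caQTL colocalization."""
    return any(h.pp4 >= pp4_min
               for led in ledgers for h in led.xqtl_hits
               if h.qtl_type not in GENE_SPECIFIC_QTL)


# ---------------------------------------------------------------------------
# differential abundance

def differential_abundance(abundance: pd.DataFrame, meta: pd.DataFrame,
                           covariates: pd.DataFrame | None = None,
                           mode: str = "interaction",
                           min_cell: int = 10):
    """Per-protein sex differential-abundance tests.

    ``abundance`` is samples x proteins; ``meta`` carries ``sex`` (female/
    male), ``diagnosis`` (any categorical), and ``at_status`` with 'A-T-' /
    'A+T+' labels marking biomarker-defined controls/cases (other labels are
    ignored for the case-control analysis).

    Two analyses per protein: (1) ``da_sex_p`` — sex main effect adjusting
    for diagnosis and covariates, all subjects; (2) the case-control
    analysis restricted to A-T-/A+T+ subjects — ``da_interaction_p`` from a
    sex x status interaction (default), or per-sex status contrasts
    (``mode='per_sex'``, columns ``p_status_female``/``p_status_male``).
    Proteins with any sex-by-status cell below ``min_cell`` non-missing
    observations are skipped and logged.

    Returns (results, skip_log).
    """
    sex = (meta["sex"].astype(str).str.lower()
           .map({"female": 1.0, "f": 1.0, "male": 0.0, "m": 0.0}))
    if sex.isna().any():
        raise ValueError("unrecognized sex labels")
    diag = pd.get_dummies(meta["diagnosis"].astype(str),
                          drop_first=True, dtype=float)
    cov = covariates.to_numpy(dtype=float) if covariates is not None \
        else np.empty((len(meta), 0))
    X_sex = np.column_stack([np.ones(len(meta)), sex.to_numpy(),
                             diag.to_numpy(), cov])

    cc = meta["at_status"].isin(["A-T-", "A+T+"]).to_numpy()
    status = (meta["at_status"] == "A+T+").astype(float).to_numpy()
    rows, skip_log = [], []
    for protein in abundance.columns:
        y = abundance[protein].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        res = {"protein": protein, "da_sex_p": np.nan,
               "da_interaction_p": np.nan}
        fit = sm.OLS(y[ok], X_sex[ok]).fit()
        res["da_sex_p"] = float(fit.pvalues[1])

        sub = ok & cc
        cells = pd.crosstab(sex.to_numpy()[sub], status[sub])
        if cells.size < 4 or (cells < min_cell).any().any():
            skip_log.append({"protein": protein,
                             "reason": "cell_below_minimum"})
            rows.append(res)
            continue
        s = sex.to_numpy()[sub]
        st = status[sub]
        if mode == "interaction":
            X = np.column_stack([np.ones(sub.sum()), s, st, s * st, cov[sub]])
            fit = sm.OLS(y[sub], X).fit()
            res["da_interaction_p"] = float(fit.pvalues[3])
        elif mode == "per_sex":
            for label, val in (("female", 1.0), ("male", 0.0)):
                m_ = s == val
                X = np.column_stack([np.ones(m_.sum()), st[m_], cov[sub][m_]])
                fit = sm.OLS(y[sub][m_], X).fit()
                res[f"p_status_{label}"] = float(fit.pvalues[1])
        else:
            raise ValueError(f"unknown mode {mode!r}")
        rows.append(res)
    return pd.DataFrame(rows).set_index("protein"), skip_log


# ---------------------------------------------------------------------------
# final list assembly

def assemble_final_lists(scores: pd.DataFrame,
                         literature_overrides: dict[str, str] | None = None,
                         exclusions: set[str] | None = None) -> dict[str, pd.DataFrame]:
    """Apply overrides/exclusions and emit per-sex prioritized gene tables.

    ``scores`` needs columns gene_id, locus_id, sex, score, rule_fired.
    ``literature_overrides`` maps gene -> provenance ('literature' or
    'missense_cadd') and forces score 1; ``exclusions`` lists locus ids
    dropped entirely. Output tables are sorted by (score, locus_id).
    """
    literature_overrides = literature_overrides or {}
    exclusions = set(exclusions or ())
    unknown = set(literature_overrides) - set(scores["gene_id"])
    if unknown:
        raise KeyError(f"override for unknown gene(s): {sorted(unknown)}")
    out = scores.copy()
    out["provenance"] = ""
    for gene, prov in literature_overrides.items():
        if prov not in ("literature", "missense_cadd"):
            raise ValueError(f"unknown override provenance {prov!r}")
        mask = out["gene_id"] == gene
        out.loc[mask, "score"] = 1
        out.loc[mask, "rule_fired"] = "override"
        out.loc[mask, "provenance"] = prov
    out = out.loc[~out["locus_id"].isin(exclusions)]
    lists = {}
    for sex, grp in out.groupby("sex"):
        lists[sex] = grp.sort_values(["score", "locus_id", "gene_id"]) \
                        .reset_index(drop=True)
    return lists
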