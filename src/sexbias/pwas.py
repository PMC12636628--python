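"""Proteome-wide association: weight training, weighted-burden tests,
FDR, and sex-specificity classification.

Variant-weight models predict protein abundance from cis genotypes. The
association statistic is the standard weighted burden over GWAS z-scores,

    z = w' z_gwas / sqrt(w' R w),

with R the variant correlation (LD) matrix regularized toward the identity.
Discoveries come in two designs: *primary* matches the GWAS sex with
sex-stratified weights, *secondary* uses combined-sex weights; both are
FDR-controlled per GWAS x weights x tissue combination and then filtered so
that a protein counts as sex-biased only when every opposite-sex combination
is direction-discordant or non-significant, with a locus-level demotion rule.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNetCV, LassoCV, Ridge, RidgeCV
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from .sumstats import meta_z_samplesize, p_from_z

__all__ = [
    "WeightModel", "HeritFailure", "LowCoverageError",
    "train_weights", "pwas_assoc", "bh_fdr", "classify_sex_specific",
    "afr_consistency_pwas", "sensitivity_consistency", "csf_weight_gating",
]


class LowCoverageError(ValueError):
    """Too little weight mass is covered by the GWAS variant set."""


@dataclass
class WeightModel:
    """Per-gene variant weights with training metadata."""

    gene_id: str
    tissue: str
    stratum: str
    variants: list[str]
    weights: list[float]
    window: tuple[int, int]
    model_name: str
    cv_r2: float
    herit_p: float

    def __post_init__(self):
        if not any(w != 0 for w in self.weights):
            raise ValueError(f"{self.gene_id}: all weights are zero")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "WeightModel":
        with open(path) as fh:
            d = json.load(fh)
        d["window"] = tuple(d["window"])
        return cls(**d)


@dataclass
class HeritFailure:
    """A gene that failed the heritability screen (or had no variants)."""

    gene_id: str
    reason: str
    herit_p: float = field(default=np.nan)


# ---------------------------------------------------------------------------
# weight training

def _residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    if covariates is None or covariates.size == 0:
        return y - y.mean()
    X = np.column_stack([np.ones(len(y)), covariates])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _cv_r2(fit_predict, G: np.ndarray, y: np.ndarray, folds) -> float:
    pred = np.empty_like(y)
    for tr, te in folds:
        pred[te] = fit_predict(G[tr], y[tr], G[te])
    ss_res = np.sum((y - pred) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0


def _fit_top1(G, y):
    sd = G.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = ((G - G.mean(0)) * (y - y.mean())[:, None]).mean(0) \
            / np.where(sd > 0, sd * y.std(), np.inf)
    j = int(np.nanargmax(np.abs(corr)))
    gj = G[:, j]
    denom = np.sum((gj - gj.mean()) ** 2)
    slope = np.sum((gj - gj.mean()) * (y - y.mean())) / denom if denom else 0.0
    w = np.zeros(G.shape[1])
    w[j] = slope
    return w


_RIDGE_ALPHAS = np.logspace(-2, 4, 13)


def _model_weights(name: str, G, y, seed: int) -> np.ndarray:
    if name == "top1":
        return _fit_top1(G, y)
    if name == "lasso":
        m = LassoCV(cv=3, alphas=20, random_state=seed, max_iter=5000)
    elif name == "enet":
        m = ElasticNetCV(cv=3, l1_ratio=0.5, alphas=20,
                         random_state=seed, max_iter=5000)
    elif name == "ridge_blup":
        m = RidgeCV(alphas=_RIDGE_ALPHAS)
    else:
        raise ValueError(f"unknown model {name!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m.fit(G, y)
    return np.asarray(m.coef_, dtype=float)


def train_weights(genotypes: pd.DataFrame, abundance: np.ndarray,
                  covariates: np.ndarray | None, window: tuple[int, int],
                  stratum: str, tissue: str = "brain", gene_id: str = "gene",
                  seed: int = 0, n_perm: int = 200, herit_alpha: float = 0.01,
                  model_names: Sequence[str] = ("top1", "lasso", "enet",
                                                "ridge_blup")):
    """Train a cis variant-weight model for one protein.

    ``genotypes`` is an (n x m) DataFrame whose columns are variant ids.
    Abundance is residualized on covariates; a heritability screen computes a
    permutation p-value for the cross-validated predictive r-squared of a
    ridge (BLUP-like) model (``n_perm`` label permutations; keep if
    p < ``herit_alpha``; ``n_perm=0`` skips the screen). Candidate models —
    top1, lasso, elastic net, and ridge standing in for dense BLUP — are
    compared by 5-fold CV r-squared and the best is refit on all data.

    Returns a :class:`WeightModel`, or :class:`HeritFailure` with a reason.
    """
    if len(genotypes) < 50:
        raise ValueError("need >= 50 samples to train weights")
    G_all = genotypes.to_numpy(dtype=float)
    poly = G_all.std(axis=0) > 0
    if not poly.any():
        return HeritFailure(gene_id, "no polymorphic variants in window")
    G = G_all[:, poly]
    variant_ids = [v for v, keep in zip(genotypes.columns, poly) if keep]
    y = _residualize(np.asarray(abundance, dtype=float), covariates)

    rng = np.random.default_rng(seed)
    kf = KFold(n_splits=5, shuffle=True, random_state=seed)
    folds = list(kf.split(G))

    def ridge_fit_predict(Gtr, ytr, Gte):
        m = Ridge(alpha=np.sqrt(_RIDGE_ALPHAS[0] * _RIDGE_ALPHAS[-1]))
        m.fit(Gtr, ytr)
        return m.predict(Gte)

    herit_p = np.nan
    if n_perm > 0:
        obs = _cv_r2(ridge_fit_predict, G, y, folds)
        null = np.empty(n_perm)
        for i in range(n_perm):
            null[i] = _cv_r2(ridge_fit_predict, G, rng.permutation(y), folds)
        herit_p = (1.0 + np.sum(null >= obs)) / (n_perm + 1.0)
        if herit_p >= herit_alpha:
            return HeritFailure(gene_id, "failed heritability screen", herit_p)

    best = (None, -np.inf)
    for name in model_names:
        def fit_predict(Gtr, ytr, Gte, _name=name):
            w = _model_weights(_name, Gtr, ytr, seed)
            return (Gte - Gtr.mean(0)) @ w + ytr.mean()
        r2 = _cv_r2(fit_predict, G, y, folds)
        if r2 > best[1]:
            best = (name, r2)
    name, cv_r2 = best
    w = _model_weights(name, G, y, seed)
    if not np.any(w != 0):  # e.g. lasso shrank everything away
        name, w = "top1", _fit_top1(G, y)
    return WeightModel(gene_id=gene_id, tissue=tissue, stratum=stratum,
                       variants=variant_ids, weights=w.tolist(),
                       window=tuple(window), model_name=name,
                       cv_r2=float(cv_r2), herit_p=float(herit_p))


def csf_weight_gating(lead_cis_p: dict[str, float],
                      gw_p: float = 5e-8) -> list[str]:
    """Which strata to train weights for, CSF convention: a stratum qualifies
    when its lead cis variant reaches genome-wide significance; if exactly
    one of female/male qualifies, the opposite sex is trained as well."""
    qualified = [s for s, p in lead_cis_p.items() if p < gw_p]
    sexes = {"female", "male"}
    hit = sexes & set(qualified)
    if len(hit) == 1:
        qualified.append((sexes - hit).pop())
    return sorted(set(qualified))


# ---------------------------------------------------------------------------
# association

def _regularized_corr(R: np.ndarray, shrink: float, floor: float = 1e-6):
    R = (1.0 - shrink) * R + shrink * np.eye(len(R))
    vals, vecs = np.linalg.eigh(R)
    if vals.min() < floor:
        vals = np.maximum(vals, floor)
        R = vecs @ np.diag(vals) @ vecs.T
    return R


def pwas_assoc(model: WeightModel, gwas_records: pd.DataFrame, ld_lookup,
               coverage_floor: float = 0.5, shrink: float = 0.1):
    """Weighted-burden association of one gene with a GWAS.

    z = w' z_gwas / sqrt(w' R w) over the variants shared between the weight
    model and the GWAS table (inputs must be allele-harmonized); R comes from
    ``ld_lookup.corr`` and is shrunk toward the identity then floored to
    positive definite. Returns (z, p, coverage); coverage is the fraction of
    absolute weight mass retained, and below ``coverage_floor`` the gene is
    refused with :class:`LowCoverageError`.
    """
    gwas = gwas_records.set_index("variant_id")
    kept = [(v, w) for v, w in zip(model.variants, model.weights)
            if v in gwas.index and w != 0]
    total_mass = sum(abs(w) for w in model.weights)
    coverage = sum(abs(w) for _, w in kept) / total_mass if total_mass else 0.0
    if not kept or coverage < coverage_floor:
        raise LowCoverageError(
            f"{model.gene_id}: coverage {coverage:.2f} below floor "
            f"{coverage_floor}")
    ids = [v for v, _ in kept]
    w = np.array([wt for _, wt in kept])
    sub = gwas.loc[ids]
    z_gwas = (sub["beta"] / sub["se"]).to_numpy() if "beta" in sub.columns \
        else sub["z"].to_numpy()
    R = _regularized_corr(ld_lookup.corr(ids), shrink)
    denom = float(w @ R @ w)
    if denom <= 0 or not np.isfinite(denom):
        raise np.linalg.LinAlgError(
            f"{model.gene_id}: LD matrix singular after regularization")
    z = float(w @ z_gwas / np.sqrt(denom))
    return z, p_from_z(z), coverage


def bh_fdr(pvalues: Sequence[float],
           grouping: Sequence | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, within each group when a
    grouping is supplied (the per GWAS x weights x tissue convention)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    q = np.empty_like(p)
    if grouping is None:
        q[:] = multipletests(p, method="fdr_bh")[1]
        return q
    groups = pd.Series(grouping)
    for _, idx in groups.groupby(groups).groups.items():
        q[np.asarray(idx)] = multipletests(p[np.asarray(idx)],
                                           method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# sex-specificity classification

_OPPOSITE = {"female": "male", "male": "female"}


def classify_sex_specific(results: pd.DataFrame,
                          locus_map: dict[str, str] | None = None,
                          alpha_fdr: float = 0.05,
                          alpha_nominal: float = 0.05) -> pd.DataFrame:
    """Classify proteins as female-/male-biased from all-combination results.

    ``results`` has one row per (gene_id, tissue, gwas_sex, weight_stratum)
    with columns z, p, p_fdr. A protein is sex-biased for sex S iff it is
    FDR-significant in the (S-GWAS x S-weights) primary or
    (S-GWAS x combined-weights) secondary design AND every available
    opposite-sex combination is effect-direction-discordant or has
    p > ``alpha_nominal``. The locus rule then demotes every protein at a
    locus whose most significant protein is not sex-biased. Output is one
    row per (gene_id, tissue) with sex_bias, discovery, and best p.
    """
    out_rows = []
    for (gene, tissue), grp in results.groupby(["gene_id", "tissue"],
                                               sort=True):
        row = {"gene_id": gene, "tissue": tissue, "sex_bias": "none",
               "discovery": "none", "best_p": float(grp["p"].min())}
        for sex in ("female", "male"):
            prim = grp.loc[(grp["gwas_sex"] == sex)
                           & (grp["weight_stratum"] == sex)]
            seco = grp.loc[(grp["gwas_sex"] == sex)
                           & (grp["weight_stratum"] == "combined")]
            prim_hit = len(prim) and (prim["p_fdr"] < alpha_fdr).any()
            seco_hit = len(seco) and (seco["p_fdr"] < alpha_fdr).any()
            if not (prim_hit or seco_hit):
                continue
            disc = prim if prim_hit else seco
            sign = np.sign(disc.sort_values("p").iloc[0]["z"])
            opp = grp.loc[grp["gwas_sex"] == _OPPOSITE[sex]]
            if len(opp) == 0:
                warnings.warn(f"{gene}/{tissue}: no opposite-sex results; "
                              "classifying from available combinations",
                              stacklevel=2)
            supported_opp = ((np.sign(opp["z"]) == sign)
                             & (opp["p"] <= alpha_nominal))
            if supported_opp.any():
                continue
            row["sex_bias"] = sex
            row["discovery"] = ("both" if prim_hit and seco_hit
                                else "primary" if prim_hit else "secondary")
            break
        out_rows.append(row)
    table = pd.DataFrame(out_rows)
    if locus_map and len(table):
        table["locus"] = table["gene_id"].map(locus_map)
        for locus, grp in table.groupby("locus"):
            top = grp.sort_values(["best_p", "gene_id"]).iloc[0]
            if top["sex_bias"] == "none":
                table.loc[table["locus"] == locus, "sex_bias"] = "none"
                table.loc[table["locus"] == locus, "discovery"] = "none"
    return table


def afr_consistency_pwas(z_eur: tuple[float, float],
                         z_afr: tuple[float, float],
                         n_eur: float, n_afr: float,
                         alpha: float = 0.05) -> bool:
    """Cross-ancestry consistency for a sex-biased protein.

    ``z_eur``/``z_afr`` are (discovery-sex z, opposite-sex z). Consistent iff
    the sample-size-weighted meta p in the discovery sex improves on the
    EUR-only p while the opposite-sex meta p stays above ``alpha``.
    """
    zd = meta_z_samplesize(z_eur[0], n_eur, z_afr[0], n_afr)
    zo = meta_z_samplesize(z_eur[1], n_eur, z_afr[1], n_afr)
    return bool(p_from_z(zd) < p_from_z(z_eur[0])
                and p_from_z(zo) > alpha)


def sensitivity_consistency(full: dict, noproxy: dict,
                            alpha: float = 0.05) -> bool:
    """Proxy-exclusion sensitivity rule: the discovery sex retains a
    concordant effect direction and p < alpha in the no-proxy run, while the
    opposite sex maintains p > alpha. Inputs are dicts with keys
    ``z_disc``/``p_disc``/``p_opp``."""
    concordant = np.sign(full["z_disc"]) == np.sign(noproxy["z_disc"])
    return bool(concordant and noproxy["p_disc"] < alpha
                and noproxy["p_opp"] > alpha)
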