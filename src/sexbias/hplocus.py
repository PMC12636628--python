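"""Structural-variant locus dissection.

A common intragenic structural variant (SV) is invisible to short reads but
taggable by nearby SNVs. This module estimates two-locus LD between the SV
and candidate SNVs from *unphased* genotypes by solving the cubic
EM-stationarity equation for the haplotype frequency (the cubic Hill
equation), selects a tag panel, trains a polynomial-kernel support-vector
classifier to impute SV genotype from the tags with repeated train/test
splits, and provides conditional, stratified, and locus-wide
protein-phenome (pheWAS) association analyses around the imputed SV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.svm import SVC

__all__ = [
    "TwoLocusGenotypeTable", "LDResult", "SvImputationModel",
    "cubex_ld", "em_haplotype_freq", "genotype_table",
    "select_tag_panel", "train_sv_imputer", "impute_sv",
    "sv_condition_matrix", "conditional_assoc", "stratified_assoc",
    "locus_phewas",
]


@dataclass
class TwoLocusGenotypeTable:
    """3x3 genotype count table; counts[i, j] = individuals with dosage i at
    locus 1 and j at locus 2."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (3, 3) or np.any(self.counts < 0):
            raise ValueError("counts must be a nonnegative 3x3 table")

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    @property
    def freqs(self) -> tuple[float, float]:
        """Sample allele frequencies (p at locus 1, q at locus 2)."""
        n2 = 2.0 * self.n
        row = self.counts.sum(axis=1)
        col = self.counts.sum(axis=0)
        p = (2 * row[2] + row[1]) / n2
        q = (2 * col[2] + col[1]) / n2
        return float(p), float(q)


@dataclass
class LDResult:
    f_ab: float
    d: float
    d_prime: float
    r2: float
    n_valid_roots: int


def genotype_table(g1: np.ndarray, g2: np.ndarray) -> TwoLocusGenotypeTable:
    """Cross-tabulate two dosage vectors (pairwise-complete on missing,
    encoded as negative or NaN)."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = ~(np.isnan(g1) | np.isnan(g2)) & (g1 >= 0) & (g2 >= 0)
    counts = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            counts[i, j] = np.sum((g1[ok] == i) & (g2[ok] == j))
    return TwoLocusGenotypeTable(counts)


# ---------------------------------------------------------------------------
# cubic-Hill LD

def _known_haplotype_counts(c: np.ndarray):
    """Phase-determined haplotype counts; the (1,1) cell is ambiguous."""
    n_ab = 2 * c[2, 2] + c[2, 1] + c[1, 2]           # A-B
    n_aB = 2 * c[2, 0] + c[2, 1] + c[1, 0]           # A-b
    n_ab_ = 2 * c[0, 2] + c[0, 1] + c[1, 2]          # a-B
    n_ab0 = 2 * c[0, 0] + c[0, 1] + c[1, 0]          # a-b
    return n_ab, n_aB, n_ab_, n_ab0, c[1, 1]


def _loglik(f: float, p: float, q: float, c: np.ndarray) -> float:
    """Multinomial log-likelihood of the genotype table given haplotype
    frequency f = f(AB) (HWE)."""
    f_ab = f
    f_aB = p - f
    f_bA = q - f
    f_00 = 1.0 - p - q + f
    h = np.array([f_ab, f_aB, f_bA, f_00])
    if np.any(h < -1e-12):
        return -np.inf
    h = np.clip(h, 1e-300, None)
    n_AB, n_Ab, n_aB, n_ab, n_dh = _known_haplotype_counts(c)
    ll = (n_AB * math.log(h[0]) + n_Ab * math.log(h[1])
          + n_aB * math.log(h[2]) + n_ab * math.log(h[3]))
    dh = 2.0 * (h[0] * h[3] + h[1] * h[2])
    if n_dh > 0:
        ll += n_dh * math.log(max(dh, 1e-300))
    return ll


def cubex_ld(table: TwoLocusGenotypeTable, tol: float = 1e-10) -> LDResult:
    """Two-locus LD from unphased genotypes via the cubic Hill equation.

    Allele frequencies come from the genotype margins; the haplotype
    frequency f(AB) is a real root of the EM-stationarity cubic inside the
    feasible interval [max(0, p+q-1), min(p, q)]. With several valid roots
    the one maximizing the multinomial likelihood is returned and the root
    count recorded. D = f(AB) - pq, D' = D/Dmax, r2 = D^2/(p(1-p)q(1-q)).
    Falls back to EM iteration if no numerical root lands in the interval.
    """
    c = table.counts
    n = table.n
    if n == 0:
        raise ValueError("empty genotype table")
    p, q = table.freqs
    if p in (0.0, 1.0) or q in (0.0, 1.0):
        raise ValueError("both loci must be polymorphic")

    n_AB, n_Ab, n_aB, n_ab, n_dh = _known_haplotype_counts(c)
    # stationarity of the EM update 2N f = n_AB + n_dh * f*f_ab/(f*f_ab + f_Ab*f_aB)
    # expands to the cubic below (f_ab = 1-p-q+f, f_Ab = p-f, f_aB = q-f)
    a3 = 4.0 * n
    a2 = 2.0 * n * (1.0 - 2.0 * p - 2.0 * q) - 2.0 * n_AB - n_dh
    a1 = (2.0 * n * p * q - n_AB * (1.0 - 2.0 * p - 2.0 * q)
          - n_dh * (1.0 - p - q))
    a0 = -n_AB * p * q

    roots = np.roots([a3, a2, a1, a0])
    lo, hi = max(0.0, p + q - 1.0), min(p, q)
    valid = []
    for r in roots:
        if abs(r.imag) < 1e-8 and lo - 1e-9 <= r.real <= hi + 1e-9:
            valid.append(float(np.clip(r.real, lo, hi)))
    valid = sorted(set(round(v, 12) for v in valid))
    if not valid:
        f = em_haplotype_freq(table)
        if f is None:
            raise ValueError("no valid cubic root and EM failed to converge")
        valid = [f]
    if len(valid) > 1:
        f = max(valid, key=lambda v: _loglik(v, p, q, c))
    else:
        f = valid[0]

    d = f - p * q
    if d >= 0:
        dmax = min(p * (1 - q), (1 - p) * q)
    else:
        dmax = min(p * q, (1 - p) * (1 - q))
    d_prime = d / dmax if dmax > 0 else 0.0
    r2 = d * d / (p * (1 - p) * q * (1 - q))
    return LDResult(f_ab=f, d=d, d_prime=d_prime, r2=r2,
                    n_valid_roots=len(valid))


def em_haplotype_freq(table: TwoLocusGenotypeTable, max_iter: int = 2000,
                      tol: float = 1e-12) -> float | None:
    """EM fixed-point estimate of f(AB); the independent cross-check for the
    cubic solution."""
    c = table.counts
    n = table.n
    p, q = table.freqs
    n_AB, n_Ab, n_aB, n_ab, n_dh = _known_haplotype_counts(c)
    f = p * q  # start at linkage equilibrium
    for _ in range(max_iter):
        f_ab = 1.0 - p - q + f
        f_Ab = p - f
        f_aB = q - f
        denom = f * f_ab + f_Ab * f_aB
        alpha = f * f_ab / denom if denom > 0 else 0.5
        f_new = (n_AB + alpha * n_dh) / (2.0 * n)
        f_new = min(max(f_new, max(0.0, p + q - 1.0)), min(p, q))
        if abs(f_new - f) < tol:
            return f_new
        f = f_new
    return None


# ---------------------------------------------------------------------------
# tag selection and SV imputation

def select_tag_panel(sv_genotypes: np.ndarray, snv_genotypes: pd.DataFrame,
                     r2_min: float = 0.1) -> pd.DataFrame:
    """SNVs whose cubic-Hill r2 with the SV exceeds ``r2_min``, ordered by
    descending r2 (position-order tie-break). Raises if no SNV qualifies."""
    rows = []
    for pos, col in enumerate(snv_genotypes.columns):
        tab = genotype_table(sv_genotypes, snv_genotypes[col].to_numpy())
        try:
            res = cubex_ld(tab)
        except ValueError:
            continue
        if res.r2 > r2_min:
            rows.append({"variant_id": col, "r2": res.r2, "order": pos})
    if not rows:
        raise ValueError(f"no tag SNVs with r2 > {r2_min}")
    panel = pd.DataFrame(rows).sort_values(
        ["r2", "order"], ascending=[False, True], kind="mergesort")
    return panel.drop(columns="order").reset_index(drop=True)


@dataclass
class SvImputationModel:
    snv_panel: list[str]
    classifier: SVC
    accuracy_distribution: np.ndarray = field(default=None)
    consensus: bool = True
    feature_means: np.ndarray = field(default=None)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracy_distribution))


def _impute_missing(X: np.ndarray, means: np.ndarray) -> np.ndarray:
    X = X.astype(float)
    nan = np.isnan(X) | (X < 0)
    if nan.any():
        X = np.where(nan, means, X)
    return X


def train_sv_imputer(panel_genotypes: pd.DataFrame, sv_genotypes: np.ndarray,
                     n_splits: int = 100, train_frac: float = 0.7,
                     seed: int = 0, C: float = 1.0) -> SvImputationModel:
    """Train the SV-genotype imputer on tag-SNV dosages.

    A degree-3 polynomial-kernel SVC is evaluated over ``n_splits`` repeated
    stratified 70/30 train/test splits (the accuracy distribution is
    recorded) and the final model is refit on all samples. Requires >= 100
    samples and SV genotypes in {0,1,2}; splits are stratified so every SV
    class appears in training.
    """
    y = np.asarray(sv_genotypes)
    if len(panel_genotypes) < 100:
        raise ValueError("need >= 100 samples to train the SV imputer")
    if not np.all(np.isin(y, [0, 1, 2])):
        raise ValueError("SV genotypes must be 0/1/2")
    means = np.nanmean(panel_genotypes.to_numpy(dtype=float), axis=0)
    X = _impute_missing(panel_genotypes.to_numpy(dtype=float), means)
    splitter = StratifiedShuffleSplit(n_splits=n_splits,
                                      train_size=train_frac,
                                      random_state=seed)
    acc = np.empty(n_splits)
    for i, (tr, te) in enumerate(splitter.split(X, y)):
        clf = SVC(kernel="poly", degree=3, C=C, random_state=seed)
        clf.fit(X[tr], y[tr])
        acc[i] = float(np.mean(clf.predict(X[te]) == y[te]))
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", FutureWarning)
        final = SVC(kernel="poly", degree=3, C=C, probability=True,
                    random_state=seed)
        final.fit(X, y)
    return SvImputationModel(snv_panel=list(panel_genotypes.columns),
                             classifier=final, accuracy_distribution=acc,
                             feature_means=means)


def impute_sv(model: SvImputationModel,
              genotype_matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-sample SV genotype calls + class probabilities. All panel SNVs
    must be present (missing columns raise with the absentee list)."""
    absent = [v for v in model.snv_panel if v not in genotype_matrix.columns]
    if absent:
        raise KeyError(f"panel SNVs absent from genotype matrix: {absent}")
    if not len(genotype_matrix):
        return pd.DataFrame(columns=["sv_call"])
    X = _impute_missing(
        genotype_matrix[model.snv_panel].to_numpy(dtype=float),
        model.feature_means)
    calls = model.classifier.predict(X)
    proba = model.classifier.predict_proba(X)
    out = pd.DataFrame({"sv_call": calls}, index=genotype_matrix.index)
    for k, cls in enumerate(model.classifier.classes_):
        out[f"p_{int(cls)}"] = proba[:, k]
    return out


def sv_condition_matrix(imputed: pd.DataFrame) -> np.ndarray:
    """Conditioning design for the imputed SV genotype.

    Conditioning on a single best-guess genotype under-corrects when
    imputation is imperfect: residual SV information leaks through the tag
    SNVs. This builds the full imputed-genotype representation — posterior
    class probabilities plus called-class indicators — so that a regression
    conditioned on it removes everything the imputer knows about the SV.
    """
    prob_cols = [c for c in imputed.columns if c.startswith("p_")]
    cols = [imputed[c].to_numpy(dtype=float) for c in prob_cols[1:]]
    calls = imputed["sv_call"].to_numpy()
    for cls in np.unique(calls)[1:]:
        cols.append((calls == cls).astype(float))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# conditional / stratified association

def _assoc(y, X, binary: bool):
    if binary:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
    else:
        fit = sm.OLS(y, X).fit()
    return float(fit.params[-1]), float(fit.bse[-1]), float(fit.pvalues[-1])


def conditional_assoc(y: np.ndarray, g_variant: np.ndarray,
                      covariates: np.ndarray | None = None,
                      g_condition: np.ndarray | None = None) -> dict:
    """Association of a variant with an outcome, optionally conditioning on
    another dosage (e.g. imputed SV genotype).

    Binary outcomes get logistic regression, continuous ones OLS. Near-
    collinearity between the variant and the conditioning dosage
    (r2 > 0.99) is reported as non-estimable rather than silently dropped.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g_variant, dtype=float)
    binary = set(np.unique(y)) <= {0.0, 1.0}
    cols = [np.ones(len(y))]
    if covariates is not None and np.size(covariates):
        cov = np.asarray(covariates, dtype=float)
        cols.append(cov if cov.ndim == 2 else cov[:, None])
    if g_condition is not None:
        gc = np.asarray(g_condition, dtype=float)
        gc = gc[:, None] if gc.ndim == 1 else gc
        for col in gc.T:
            if np.std(g) > 0 and np.std(col) > 0 \
                    and np.corrcoef(g, col)[0, 1] ** 2 > 0.99:
                return {"beta": np.nan, "se": np.nan, "p": np.nan,
                        "estimable": False,
                        "reason": "collinear_with_condition"}
        cols.append(gc)
    X = np.column_stack([*cols, g])
    beta, se, p = _assoc(y, X, binary)
    return {"beta": beta, "se": se, "p": p, "estimable": True}


def stratified_assoc(y: np.ndarray, g: np.ndarray,
                     covariates: np.ndarray | None,
                     strata_labels: np.ndarray,
                     min_cases: int = 10) -> pd.DataFrame:
    """Independent association per stratum with a shared covariate
    specification; strata with too few cases (binary y) or samples are
    flagged underpowered, empty strata skipped."""
    y = np.asarray(y, dtype=float)
    labels = np.asarray(strata_labels)
    binary = set(np.unique(y[~np.isnan(y)])) <= {0.0, 1.0}
    rows = []
    for stratum in pd.unique(labels):
        mask = labels == stratum
        if mask.sum() == 0:
            continue
        n_cases = int(np.nansum(y[mask])) if binary else int(mask.sum())
        flagged = n_cases < min_cases
        row = {"stratum": stratum, "n": int(mask.sum()),
               "n_cases": n_cases if binary else np.nan,
               "underpowered": flagged,
               "beta": np.nan, "se": np.nan, "p": np.nan}
        if not flagged or mask.sum() >= min_cases:
            cov = None if covariates is None else \
                np.asarray(covariates, dtype=float)[mask]
            try:
                res = conditional_assoc(y[mask], np.asarray(g)[mask], cov)
                row.update({k: res[k] for k in ("beta", "se", "p")})
            except Exception:
                pass
        rows.append(row)
    return pd.DataFrame(rows)


def locus_phewas(genotypes_of_interest: pd.DataFrame,
                 protein_matrix: pd.DataFrame,
                 covariates: np.ndarray | None = None,
                 mac_min: int = 10, miss_max: float = 0.1,
                 alpha: float = 0.05,
                 g_condition: np.ndarray | None = None):
    """Locus-wide protein pheWAS.

    Each variant column (dosages; NaN = missing) is regressed against every
    protein (aptamer) column, optionally conditioning on an SV dosage. The
    Bonferroni threshold is ``alpha`` divided by the number of aptamers in
    the tissue (the protein matrix width). Variants failing MAC >=
    ``mac_min`` or missingness <= ``miss_max`` are excluded with a reason.
    Returns (significant_pairs, all_results, variant_log).
    """
    n_aptamers = protein_matrix.shape[1]
    threshold = alpha / n_aptamers
    variant_log, results = [], []
    for variant in genotypes_of_interest.columns:
        g = genotypes_of_interest[variant].to_numpy(dtype=float)
        miss = np.mean(np.isnan(g))
        g_obs = g[~np.isnan(g)]
        mac = min(np.nansum(g_obs), 2 * len(g_obs) - np.nansum(g_obs))
        if mac < mac_min:
            variant_log.append({"variant_id": variant, "excluded": True,
                                "reason": "mac_below_minimum"})
            continue
        if miss > miss_max:
            variant_log.append({"variant_id": variant, "excluded": True,
                                "reason": "missingness_above_maximum"})
            continue
        variant_log.append({"variant_id": variant, "excluded": False,
                            "reason": ""})
        for protein in protein_matrix.columns:
            y = protein_matrix[protein].to_numpy(dtype=float)
            ok = ~(np.isnan(y) | np.isnan(g))
            cov = None if covariates is None else \
                np.asarray(covariates, dtype=float)[ok]
            cond = None if g_condition is None else \
                np.asarray(g_condition, dtype=float)[ok]
            res = conditional_assoc(y[ok], g[ok], cov, cond)
            results.append({"variant_id": variant, "protein": protein,
                            **{k: res[k] for k in ("beta", "se", "p")}})
    all_results = pd.DataFrame(results)
    if len(all_results):
        significant = all_results.loc[all_results["p"] < threshold] \
            .reset_index(drop=True)
    else:
        significant = all_results
    return significant, all_results, pd.DataFrame(variant_log)
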