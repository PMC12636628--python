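"""Locus discovery: windowing, LD clumping, sex-bias filtering, novelty.

Turns a sex-merged genome-wide table (from :mod:`sexbias.sumstats`) into
independent sex-biased loci:

1. mask the major-effect exclusion region (APOE-like, +/- 5 Mb);
2. cluster qualifying variants (p < 1e-5) by transitive 1 Mb chaining;
3. split each cluster into independent signals by greedy LD clumping at
   r-squared < 0.01;
4. retain signals that are genome-wide significant in one sex (p < 5e-8)
   with nominal sex heterogeneity (p_het < 0.05), or genome-wide significant
   in the heterogeneity GWAS itself (p_het < 5e-8);
5. drop signals tagging a known catalog variant that is more significant in
   the same sex but not sex-heterogeneous; keep one signal per locus;
6. classify novelty against the catalog by distance then LD.

Filters log every exclusion with a machine-readable reason code; they never
throw. Missing LD raises an explicit error rather than silently assuming
independence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .sumstats import p_from_z

__all__ = [
    "MissingLDError", "PanelLD", "MatrixLD", "Signal", "Locus",
    "window_cluster", "ld_clump", "sex_bias_filter", "classify_novelty",
    "afr_consistency", "mask_region", "discover_loci",
]

GENOME_WIDE_P = 5e-8


class MissingLDError(KeyError):
    """LD was required for a variant pair but is unavailable."""


class PanelLD:
    """LD lookup backed by a haplotype panel (empirical r-squared)."""

    def __init__(self, panel):
        self.panel = panel

    def __contains__(self, variant_id) -> bool:
        return variant_id in self.panel._index

    def r2(self, a: str, b: str) -> float:
        if a not in self or b not in self:
            missing = [v for v in (a, b) if v not in self]
            raise MissingLDError(f"no LD available for {missing}")
        return float(self.panel.r2([a], [b])[0, 0])

    def r2_with(self, lead: str, ids: Sequence[str]) -> np.ndarray:
        if lead not in self:
            raise MissingLDError(f"no LD available for [{lead!r}]")
        missing = [v for v in ids if v not in self]
        if missing:
            raise MissingLDError(f"no LD available for {missing}")
        return self.panel.r2([lead], list(ids))[0]

    def corr(self, ids: Sequence[str]) -> np.ndarray:
        """Signed haplotype correlation matrix for a variant list."""
        missing = [v for v in ids if v not in self]
        if missing:
            raise MissingLDError(f"no LD available for {missing}")
        H = self.panel.haplotypes[:, [self.panel.index_of(v)
                                      for v in ids]].astype(float)
        sd = H.std(axis=0)
        if np.any(sd == 0):
            mono = [v for v, s in zip(ids, sd) if s == 0]
            raise MissingLDError(f"monomorphic in panel: {mono}")
        return np.corrcoef(H, rowvar=False).reshape(len(ids), len(ids))


class MatrixLD:
    """LD lookup backed by a square matrix (DataFrame): r-squared by
    default, or signed correlation with ``signed=True`` (which also enables
    :meth:`corr`)."""

    def __init__(self, frame: pd.DataFrame, signed: bool = False):
        self.frame = frame
        self.signed = signed

    def __contains__(self, variant_id) -> bool:
        return variant_id in self.frame.index

    def _lookup(self, lead: str, ids: Sequence[str]) -> np.ndarray:
        missing = [v for v in [lead, *ids] if v not in self]
        if missing:
            raise MissingLDError(f"no LD available for {missing}")
        vals = self.frame.loc[lead, list(ids)].to_numpy(dtype=float)
        return vals ** 2 if self.signed else vals

    def r2(self, a: str, b: str) -> float:
        return float(self._lookup(a, [b])[0])

    def r2_with(self, lead: str, ids: Sequence[str]) -> np.ndarray:
        return self._lookup(lead, ids)

    def corr(self, ids: Sequence[str]) -> np.ndarray:
        if not self.signed:
            raise MissingLDError(
                "signed correlations requested from an r-squared matrix")
        missing = [v for v in ids if v not in self]
        if missing:
            raise MissingLDError(f"no LD available for {missing}")
        return self.frame.loc[list(ids), list(ids)].to_numpy(dtype=float)


@dataclass
class Signal:
    """One clump: a lead variant and its LD-absorbed members."""

    lead: pd.Series
    members: pd.DataFrame
    discovery_sex: str = ""

    @property
    def lead_id(self) -> str:
        return str(self.lead["variant_id"])


@dataclass
class Locus:
    chrom: str
    span: tuple[int, int]
    signals: list[Signal] = field(default_factory=list)
    label: str = ""
    novelty: str | None = None
    afr_consistency: str | None = None


# ---------------------------------------------------------------------------

def mask_region(records: pd.DataFrame,
                region: tuple[str, int, int] | None) -> pd.DataFrame:
    """Drop variants inside (chrom, start, end); None is a no-op."""
    if region is None:
        return records
    chrom, start, end = region
    drop = ((records["chrom"].astype(str) == str(chrom))
            & (records["pos"] >= start) & (records["pos"] <= end))
    return records.loc[~drop]


def window_cluster(records: pd.DataFrame, p_enter: float = 1e-5,
                   window: int = 1_000_000,
                   p_col: str = "p_min") -> list[pd.DataFrame]:
    """Merge qualifying variants into candidate loci by transitive chaining:
    consecutive qualifying variants closer than ``window`` bp join the same
    cluster. Input must be sorted by (chrom, pos)."""
    for chrom, grp in records.groupby("chrom", sort=False):
        if not np.all(np.diff(grp["pos"].to_numpy()) > 0):
            raise ValueError(f"records not sorted by position on {chrom}")
    qual = records.loc[records[p_col] < p_enter]
    clusters: list[pd.DataFrame] = []
    for chrom, grp in qual.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > window) + 1
        for chunk in np.split(np.arange(len(grp)), breaks):
            clusters.append(grp.iloc[chunk].copy())
    return clusters


def ld_clump(locus: pd.DataFrame, ld_lookup, r2_independent: float = 0.01,
             p_col: str = "p_min") -> list[Signal]:
    """Greedy clumping by ascending p: the best remaining variant seeds a
    signal and absorbs everything with r-squared >= ``r2_independent``.
    Ties in p break to the lower (chrom, pos)."""
    order = locus.sort_values([p_col, "chrom", "pos"],
                              kind="mergesort").reset_index(drop=True)
    remaining = order.copy()
    signals: list[Signal] = []
    while len(remaining):
        lead = remaining.iloc[0]
        others = remaining.iloc[1:]
        if len(others):
            r2 = ld_lookup.r2_with(lead["variant_id"],
                                   others["variant_id"].tolist())
        else:
            r2 = np.empty(0)
        absorbed = others.loc[r2 >= r2_independent].copy()
        absorbed["r2_to_lead"] = r2[r2 >= r2_independent]
        members = pd.concat(
            [lead.to_frame().T.assign(r2_to_lead=1.0), absorbed],
            ignore_index=True)
        signals.append(Signal(lead=lead, members=members))
        remaining = others.loc[r2 < r2_independent]
    return signals


# ---------------------------------------------------------------------------

def _discovery_route(lead: pd.Series, gw_p: float, het_p: float,
                     het_gw_p: float) -> str | None:
    p_f, p_m, p_het = lead["p_f"], lead["p_m"], lead["p_het"]
    if p_het < het_gw_p:
        return "het_gwas"
    if min(p_f, p_m) < gw_p and p_het < het_p:
        return "female" if p_f <= p_m else "male"
    return None


def sex_bias_filter(clusters: list[list[Signal]], catalog: pd.DataFrame | None,
                    ld_lookup=None, merged: pd.DataFrame | None = None,
                    gw_p: float = GENOME_WIDE_P, het_p: float = 0.05,
                    het_gw_p: float = GENOME_WIDE_P,
                    r2_known: float = 0.01, maf_known: float = 0.01,
                    ratio_min: float = 1.5, ratio_rule: str = "warn"):
    """Apply the sex-bias retention rules; returns (loci, exclusion_log).

    Per signal: keep iff genome-wide significant in a sex with nominal sex
    heterogeneity, or genome-wide in the heterogeneity GWAS. Signals whose
    lead tags (r-squared > ``r2_known``) a common catalog variant that is
    more significant in the same sex but not sex-heterogeneous are dropped.
    One signal (the most significant) is retained per locus. Retained leads
    are expected to show cross-sex effect-magnitude ratios >= ``ratio_min``;
    violations warn by default (``ratio_rule='drop'`` makes it a hard filter).
    Every exclusion is logged exactly once with a reason code.
    """
    exclusion_log: list[dict] = []
    retained: list[Locus] = []
    merged_by_id = None
    if merged is not None:
        merged_by_id = merged.set_index("variant_id")

    for ci, signals in enumerate(clusters):
        surviving: list[tuple[Signal, str]] = []
        for sig in signals:
            route = _discovery_route(sig.lead, gw_p, het_p, het_gw_p)
            if route is None:
                reason = ("not_genomewide"
                          if min(sig.lead["p_f"], sig.lead["p_m"]) >= gw_p
                          else "not_sex_heterogeneous")
                exclusion_log.append({"variant_id": sig.lead_id,
                                      "cluster": ci, "reason": reason})
                continue
            sig.discovery_sex = route
            if route != "het_gwas" and catalog is not None and len(catalog):
                known = _known_variant_conflict(
                    sig, route, catalog, ld_lookup, merged_by_id,
                    r2_known, maf_known, het_p)
                if known is not None:
                    exclusion_log.append({
                        "variant_id": sig.lead_id, "cluster": ci,
                        "reason": "known_variant_ld",
                        "catalog_variant": known})
                    continue
            surviving.append((sig, route))

        if not surviving:
            continue
        surviving.sort(key=lambda t: (
            min(t[0].lead["p_f"], t[0].lead["p_m"]), t[0].lead["pos"]))
        best, route = surviving[0]
        for sig, _ in surviving[1:]:
            exclusion_log.append({"variant_id": sig.lead_id, "cluster": ci,
                                  "reason": "secondary_signal"})
        ratio = _lead_ratio(best.lead)
        if ratio < ratio_min:
            if ratio_rule == "drop":
                exclusion_log.append({"variant_id": best.lead_id,
                                      "cluster": ci,
                                      "reason": "effect_ratio_below_min"})
                continue
            warnings.warn(
                f"retained lead {best.lead_id} has cross-sex effect ratio "
                f"{ratio:.2f} < {ratio_min}", stacklevel=2)
        pos = best.members["pos"].astype(int)
        retained.append(Locus(chrom=str(best.lead["chrom"]),
                              span=(int(pos.min()), int(pos.max())),
                              signals=[best]))
    return retained, exclusion_log


def _lead_ratio(lead: pd.Series) -> float:
    bf, bm = float(lead["beta_f"]), float(lead["beta_m"])
    if bf * bm < 0:
        return np.inf
    a, b = abs(bf), abs(bm)
    lo = min(a, b)
    return np.inf if lo == 0 else max(a, b) / lo


def _known_variant_conflict(sig: Signal, route: str, catalog: pd.DataFrame,
                            ld_lookup, merged_by_id, r2_known: float,
                            maf_known: float, het_p: float) -> str | None:
    if "p_sexhet" not in catalog.columns or catalog["p_sexhet"].isna().all():
        warnings.warn("catalog has no sex-heterogeneity p-values; the "
                      "known-variant exclusion rule cannot fire", stacklevel=3)
        return None
    p_col = "p_f" if route == "female" else "p_m"
    own_p = float(sig.lead[p_col])
    for _, kv in catalog.iterrows():
        maf = kv.get("maf", np.nan)
        if not (maf is not None and not np.isnan(maf) and maf > maf_known):
            continue
        if np.isnan(kv.get("p_sexhet", np.nan)) or kv["p_sexhet"] <= het_p:
            continue
        if merged_by_id is None or kv["variant_id"] not in merged_by_id.index:
            continue
        kv_p = float(merged_by_id.loc[kv["variant_id"], p_col])
        if kv_p >= own_p:
            continue
        if ld_lookup is None:
            raise MissingLDError(
                f"LD needed between {sig.lead_id} and catalog variant "
                f"{kv['variant_id']}")
        if ld_lookup.r2(sig.lead_id, kv["variant_id"]) > r2_known:
            return str(kv["variant_id"])
    return None


# ---------------------------------------------------------------------------

def classify_novelty(lead: pd.Series, catalog: pd.DataFrame, ld_lookup,
                     distance: int = 1_000_000, r2_known: float = 0.01,
                     overrides: Sequence[str] = ()) -> str:
    """Three-way novelty classification against prior lead variants:
    > ``distance`` bp from every catalog lead = novel locus & novel variant;
    closer but r-squared < ``r2_known`` = known locus & novel variant;
    otherwise known locus & known variant. ``overrides`` lists variant ids
    manually ruled to be novel independent signals despite LD."""
    if catalog is None or not len(catalog):
        raise ValueError("novelty classification requires a catalog")
    same_chrom = catalog.loc[catalog["chrom"].astype(str)
                             == str(lead["chrom"])]
    if len(same_chrom):
        dist = (same_chrom["pos"].astype(int) - int(lead["pos"])).abs()
        near = same_chrom.loc[dist <= distance]
    else:
        near = same_chrom
    if not len(near):
        return "novel_locus_novel_variant"
    r2 = ld_lookup.r2_with(str(lead["variant_id"]),
                           near["variant_id"].tolist())
    if np.max(r2) < r2_known or str(lead["variant_id"]) in set(overrides):
        return "known_locus_novel_variant"
    return "known_locus_known_variant"


def afr_consistency(eur_pair, afr_pair) -> str:
    """Cross-ancestry sex-heterogeneity consistency.

    ``eur_pair``/``afr_pair`` are (female, male) objects with ``beta``/``se``
    attributes; ``afr_pair`` may be None (variant absent) -> 'eur_only'.
    Sexes are combined across ancestries by inverse-variance fixed effects
    and the heterogeneity test recomputed; 'yes' iff the combined p_het
    improves on the EUR-only p_het.
    """
    if afr_pair is None:
        return "eur_only"

    def _ivw(a, b):
        w = np.array([1.0 / a.se ** 2, 1.0 / b.se ** 2])
        beta = (w[0] * a.beta + w[1] * b.beta) / w.sum()
        return beta, 1.0 / np.sqrt(w.sum())

    ef, em = eur_pair
    af, am = afr_pair
    z_eur = (ef.beta - em.beta) / np.sqrt(ef.se ** 2 + em.se ** 2)
    bf, sf = _ivw(ef, af)
    bm, sm = _ivw(em, am)
    z_comb = (bf - bm) / np.sqrt(sf ** 2 + sm ** 2)
    return "yes" if p_from_z(z_comb) < p_from_z(z_eur) else "no"


# ---------------------------------------------------------------------------

def discover_loci(merged: pd.DataFrame, ld_lookup,
                  catalog: pd.DataFrame | None = None,
                  p_enter: float = 1e-5, window: int = 1_000_000,
                  r2_clump: float = 0.01,
                  apoe_region: tuple[str, int, int] | None = None,
                  novelty_overrides: Sequence[str] = (),
                  **filter_kw):
    """End-to-end locus discovery on a sex-merged table.

    Returns (loci_table, exclusion_log). The loci table has one row per
    retained locus: lead variant, per-sex effects/p, heterogeneity test,
    discovery route, span (lead +/- 1 Mb for downstream colocalization
    windows), and novelty when a catalog is supplied.
    """
    merged = merged.sort_values(["chrom", "pos"], kind="mergesort")
    merged = mask_region(merged, apoe_region)
    merged = merged.assign(p_min=np.minimum(merged["p_f"], merged["p_m"]))
    clusters = window_cluster(merged, p_enter=p_enter, window=window)
    clumped = [ld_clump(c, ld_lookup, r2_independent=r2_clump)
               for c in clusters]
    loci, excl = sex_bias_filter(clumped, catalog, ld_lookup, merged,
                                 **filter_kw)
    rows = []
    for locus in loci:
        sig = locus.signals[0]
        lead = sig.lead
        novelty = None
        if catalog is not None and len(catalog):
            novelty = classify_novelty(lead, catalog, ld_lookup,
                                       overrides=novelty_overrides)
        rows.append({
            "variant_id": lead["variant_id"], "chrom": lead["chrom"],
            "pos": int(lead["pos"]), "ea": lead.get("ea"),
            "oa": lead.get("oa"),
            "beta_f": lead["beta_f"], "se_f": lead["se_f"],
            "p_f": lead["p_f"],
            "beta_m": lead["beta_m"], "se_m": lead["se_m"],
            "p_m": lead["p_m"],
            "p_het": lead["p_het"], "effect_ratio": _lead_ratio(lead),
            "discovery_sex": sig.discovery_sex,
            "span_start": max(1, int(lead["pos"]) - 1_000_000),
            "span_end": int(lead["pos"]) + 1_000_000,
            "n_members": len(sig.members),
            "novelty": novelty,
        })
    loci_table = pd.DataFrame(rows)
    return loci_table, excl
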