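"""Per-site Weir-Cockerham F_ST and F_ST-based selection comparisons.

The estimator contrasts two pooled sample sets (all African-ancestry
individuals vs all European-ancestry individuals) on a per-site basis using
the Weir & Cockerham (1984) variance components a (among populations),
b (among individuals within populations) and c (within individuals), with
theta-hat = a / (a + b + c).  Sites where a + b + c = 0 (monomorphic overall)
are undefined and reported as NaN; negative estimates are clamped to zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "weir_cockerham_fst",
    "pooled_fst",
    "assign_variants_to_cres",
    "max_fst_per_cre",
    "wilcoxon_compare",
    "decile_binned_tests",
    "fst_quantile_threshold",
]


def weir_cockerham_fst(n1, ac1, het1, n2, ac2, het2, clamp=True):
    """Per-site two-population Weir-Cockerham (1984) F_ST.

    Parameters
    ----------
    n1, n2 : int or array
        Number of diploid individuals genotyped in each group.
    ac1, ac2 : int or array
        Alternate-allele counts (out of ``2 * n`` alleles).
    het1, het2 : int or array
        Observed heterozygote individual counts.
    clamp : bool
        Clamp negative estimates to zero (the reported convention).

    Returns
    -------
    float or ndarray
        theta-hat per site; NaN where a + b + c = 0.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    scalar = n1.ndim == 0
    n1, n2 = np.atleast_1d(n1), np.atleast_1d(n2)
    ac1 = np.atleast_1d(np.asarray(ac1, dtype=float))
    ac2 = np.atleast_1d(np.asarray(ac2, dtype=float))
    het1 = np.atleast_1d(np.asarray(het1, dtype=float))
    het2 = np.atleast_1d(np.asarray(het2, dtype=float))
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise ValueError("each group needs at least one genotyped individual")

    r = 2.0
    p1, p2 = ac1 / (2 * n1), ac2 / (2 * n2)
    h1, h2 = het1 / n1, het2 / n2

    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        denom = a + b + c
        theta = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)
    if clamp:
        theta = np.where(np.isnan(theta), np.nan, np.clip(theta, 0.0, 1.0))
    return float(theta[0]) if scalar else theta


def pooled_fst(variants: pd.DataFrame, design: pd.DataFrame, clamp=True) -> pd.DataFrame:
    """Pool per-population genotype tallies by ancestry and estimate F_ST.

    ``variants`` carries per-population columns ``n_<pop>``, ``ac_<pop>``,
    ``het_<pop>``; ``design`` maps ``population`` to ``ancestry``
    (AFR/EUR).  Adds ``fst``, ``af_AFR``, ``af_EUR`` columns; rows with an
    undefined estimate are dropped, as in the reported convention.
    """
    out = variants.copy()
    pools = {}
    for anc in ("AFR", "EUR"):
        pops = design.loc[design["ancestry"] == anc, "population"].unique()
        if len(pops) == 0:
            raise ValueError(f"no populations with ancestry {anc}")
        n = sum(out[f"n_{p}"] for p in pops)
        ac = sum(out[f"ac_{p}"] for p in pops)
        het = sum(out[f"het_{p}"] for p in pops)
        pools[anc] = (np.asarray(n), np.asarray(ac), np.asarray(het))
        out[f"af_{anc}"] = np.asarray(ac) / (2 * np.asarray(n))
    (nA, acA, hetA), (nE, acE, hetE) = pools["AFR"], pools["EUR"]
    out["fst"] = weir_cockerham_fst(nA, acA, hetA, nE, acE, hetE, clamp=clamp)
    return out[out["fst"].notna()].reset_index(drop=True)


def assign_variants_to_cres(variants: pd.DataFrame, cres: pd.DataFrame) -> pd.DataFrame:
    """Attach ``cre_id`` of the containing element (NaN if intergenic).

    Assumes the CRE set is non-overlapping (guaranteed by construction),
    so a binary search over sorted starts suffices.
    """
    out = variants.copy()
    out["cre_id"] = pd.NA
    for chrom, sub in cres.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts, ends = sub["start"].to_numpy(), sub["end"].to_numpy()
        mask = out["chrom"] == chrom
        pos = out.loc[mask, "pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        ids = np.full(len(pos), None, dtype=object)
        ids[inside] = sub["cre_id"].to_numpy()[idx[inside]]
        out.loc[mask, "cre_id"] = ids
    return out


def max_fst_per_cre(variants: pd.DataFrame, cres: pd.DataFrame) -> pd.Series:
    """Maximum per-site F_ST over the variants contained in each CRE.

    CREs without variants get NaN.
    """
    if "cre_id" not in variants.columns:
        variants = assign_variants_to_cres(variants, cres)
    per = variants.dropna(subset=["cre_id"]).groupby("cre_id")["fst"].max()
    return per.reindex(cres["cre_id"])


def wilcoxon_compare(a, b, alternative: str = "greater") -> float:
    """One-sided Wilcoxon rank-sum P for a location shift of ``a`` vs ``b``.

    Exact enumeration when both groups are small (<= 50) and tie-free;
    otherwise the mid-rank normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        return float("nan")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (max(a.size, b.size) <= 50 and not ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative=alternative, method=method).pvalue)


def decile_binned_tests(qtl: pd.DataFrame, value_col: str = "fst",
                        flag_col: str = "is_diff", af_col: str = "mean_af",
                        n_bins: int = 10) -> pd.DataFrame:
    """Allele-frequency-matched F_ST comparisons.

    The combined diff + non-diff QTL set is split into ``n_bins`` equal-count
    bins of mean allele frequency (boundary ties broken by rank); within each
    bin a one-sided Wilcoxon (diff > non-diff) is run.  Bins with fewer than
    two observations on either side yield NaN.
    """
    df = qtl.copy()
    if df[af_col].nunique() <= 1:
        df["af_bin"] = 0
    else:
        df["af_bin"] = pd.qcut(df[af_col].rank(method="first"), n_bins, labels=False)
    rows = []
    for b in range(n_bins):
        sub = df[df["af_bin"] == b]
        x = sub.loc[sub[flag_col], value_col].to_numpy()
        y = sub.loc[~sub[flag_col], value_col].to_numpy()
        if x.size < 2 or y.size < 2:
            p = float("nan")
        else:
            p = wilcoxon_compare(x, y, alternative="greater")
        rows.append({"af_bin": b, "n_diff": x.size, "n_nondiff": y.size,
                     "mean_diff": x.mean() if x.size else np.nan,
                     "mean_nondiff": y.mean() if y.size else np.nan,
                     "p": p})
    return pd.DataFrame(rows)


def fst_quantile_threshold(fst_values, q: float = 0.95) -> float:
    """Empirical q-quantile (linear interpolation) of per-site F_ST in CREs."""
    v = np.asarray(fst_values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no F_ST values supplied")
    return float(np.quantile(v, q))
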