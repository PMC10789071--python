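"""One-sided Fisher enrichment framework for diff-CREs.

All tests are hypergeometric (one-sided Fisher's exact) on 2x2 tables in
which each CRE contributes at most one count.  Diff-CREs are defined at
nominal t-test P < 0.05 and non-diff-CREs at P >= 0.5; intermediate CREs
are excluded from every table.  The reported odds ratio is the sample OR
(ad/bc, infinity when bc = 0) and the interval bound is the exact one-sided
95% lower confidence bound from inversion of Fisher's noncentral
hypergeometric distribution.  Significance stars follow Bonferroni-corrected
P thresholds 0.05, 0.005, 5e-4 and 5e-5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .differential import dedup_by_bin, select_top_diff

__all__ = [
    "EnrichmentResult",
    "fisher_one_sided",
    "cre_level_diff",
    "de_overlap_test",
    "direction_match_test",
    "best_qtl_per_cre",
    "qtl_overlap_test",
    "qtl_direction_match_test",
    "sign_test",
    "bonferroni_stars",
]


@dataclass
class EnrichmentResult:
    """Outcome of a one-sided 2x2 enrichment test."""

    label: str
    table: tuple  # (a, b, c, d)
    odds_ratio: float
    p: float
    ci_lower: float
    n_cres: int = 0
    note: str = ""

    def as_dict(self) -> dict:
        a, b, c, d = self.table
        return {
            "test": self.label, "a": a, "b": b, "c": c, "d": d,
            "odds_ratio": self.odds_ratio, "p": self.p,
            "ci_lower": self.ci_lower, "n_cres": self.n_cres, "note": self.note,
        }


def _or_ci_lower(a: int, b: int, c: int, d: int, alpha: float = 0.05) -> float:
    """Exact one-sided lower 95% bound on the odds ratio.

    Solves P_psi(X >= a) = alpha in Fisher's noncentral hypergeometric
    model; 0 when a sits at the bottom of its support.
    """
    M, n, N = a + b + c + d, a + b, a + c
    lo_support = max(0, n + N - M)
    if a <= lo_support:
        return 0.0

    def tail(logpsi: float) -> float:
        return stats.nchypergeom_fisher.sf(a - 1, M, n, N, np.exp(logpsi)) - alpha

    lo, hi = -50.0, 50.0
    if tail(hi) < 0:  # even a huge odds ratio cannot reach alpha: bound is open
        return float("inf")
    if tail(lo) > 0:
        return 0.0
    return float(np.exp(brentq(tail, lo, hi, xtol=1e-10)))


def fisher_one_sided(a: int, b: int, c: int, d: int, label: str = "") -> EnrichmentResult:
    """One-sided (enrichment) Fisher's exact test on [[a, b], [c, d]].

    P is the upper hypergeometric tail P(X >= a); the odds ratio is the
    sample estimate ad/bc.  A zero margin makes the OR undefined (NaN) and
    P = 1, flagged in ``note``.
    """
    counts = (a, b, c, d)
    if any((x < 0 or int(x) != x) for x in counts):
        raise ValueError("2x2 counts must be nonnegative integers")
    a, b, c, d = (int(x) for x in counts)
    if a + b + c + d == 0:
        warnings.warn(f"empty 2x2 table for {label!r}: NA result")
        return EnrichmentResult(label, (0, 0, 0, 0), float("nan"), float("nan"),
                                float("nan"), n_cres=0, note="empty universe")
    if min(a + b, c + d, a + c, b + d) == 0:
        return EnrichmentResult(label, (a, b, c, d), float("nan"), 1.0, 0.0,
                                n_cres=a + b + c + d, note="zero margin")
    if b * c == 0:
        oddsr = float("inf") if a * d > 0 else float("nan")
    else:
        oddsr = (a * d) / (b * c)
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])
    return EnrichmentResult(label, (a, b, c, d), oddsr, p,
                            _or_ci_lower(a, b, c, d), n_cres=a + b + c + d)


def cre_level_diff(results: pd.DataFrame, bin_dedup: bool = False) -> pd.DataFrame:
    """Collapse pair-level differential results to one row per CRE.

    The representative pair is the most significant (lowest P, ties to
    larger |log2fc|); ChIP/HiC results are additionally deduplicated so
    diff-CREs sharing one 5-kb bin count once.
    """
    df = results.copy()
    df["_abs_lfc"] = df["log2fc"].abs().replace(np.inf, np.finfo(float).max)
    per_cre = (
        df.sort_values(["p", "_abs_lfc", "pair_id"], ascending=[True, False, True],
                       kind="stable")
        .groupby("cre_id", sort=False)
        .head(1)
        .drop(columns="_abs_lfc")
    )
    if bin_dedup:
        per_cre = dedup_by_bin(per_cre)
    return per_cre.reset_index(drop=True)


def _diff_status(df: pd.DataFrame) -> pd.Series:
    """'diff' / 'nondiff' / excluded (NaN) from the stored flags."""
    return pd.Series(
        np.where(df["diff_flag"], "diff", np.where(df["nondiff_flag"], "nondiff", None)),
        index=df.index,
    )


def _cre_de_frame(top: pd.DataFrame, de: pd.DataFrame, lfsr_max: float = 0.05) -> pd.DataFrame:
    """Per-CRE summary of DE targets among the genes it is top diff-CRE for."""
    de_sig = de[de["lfsr"] < lfsr_max].set_index("gene_id")["sign"]
    t = top.copy()
    t["is_de"] = t["gene_id"].isin(de_sig.index)
    t["de_sign"] = t["gene_id"].map(de_sig)
    grp = t.groupby("cre_id", sort=False)
    out = grp.agg(
        p=("p", "first"),
        direction=("direction", "first"),
        diff_flag=("diff_flag", "first"),
        nondiff_flag=("nondiff_flag", "first"),
        element_class=("element_class", "first"),
        n_de=("is_de", "sum"),
    )
    out["prom_for_de"] = grp.apply(
        lambda g: bool((g["is_de"] & g["is_promoter_pair"]).any()), include_groups=False
    )
    de_signs = grp.apply(
        lambda g: tuple(sorted(set(g.loc[g["is_de"], "de_sign"].dropna()))),
        include_groups=False,
    )
    out["de_signs"] = de_signs
    return out.reset_index()


def de_overlap_test(top: pd.DataFrame, de: pd.DataFrame, class_filter: str = "all",
                    lfsr_max: float = 0.05, label: str = "") -> EnrichmentResult:
    """Diff-CRE x DE-target enrichment on top diff-CREs.

    The universe is the per-gene top diff-CREs collapsed to unique CREs;
    a CRE is a "hit" if at least one of its target genes is ancestry-DE
    (LFSR < ``lfsr_max``).  ``class_filter`` = 'promoter' restricts to
    promoter-class CREs and requires the CRE to be a promoter for a DE
    target; 'enhancer' requires it to be a promoter for none of its DE
    targets (a distal promoter of another gene counts as an enhancer).
    """
    cre = _cre_de_frame(top, de, lfsr_max)
    cre["status"] = _diff_status(cre)
    cre = cre[cre["status"].notna()]
    if class_filter == "promoter":
        cre = cre[cre["element_class"] == "promoter"]
        hit = (cre["n_de"] > 0) & cre["prom_for_de"]
    elif class_filter == "enhancer":
        hit = (cre["n_de"] > 0) & ~cre["prom_for_de"]
    elif class_filter == "all":
        hit = cre["n_de"] > 0
    else:
        raise ValueError(f"unknown class_filter {class_filter!r}")
    diff = cre["status"] == "diff"
    a = int((diff & hit).sum())
    b = int((diff & ~hit).sum())
    c = int((~diff & hit).sum())
    d = int((~diff & ~hit).sum())
    return fisher_one_sided(a, b, c, d, label=label or f"de_overlap[{class_filter}]")


def direction_match_test(top: pd.DataFrame, de: pd.DataFrame, class_filter: str = "all",
                         lfsr_max: float = 0.05, label: str = "") -> EnrichmentResult:
    """Ancestry-direction matching between diff-CREs and their DE targets.

    Universe: diff-CREs whose DE targets all share one direction (CREs with
    targets DE in both directions are excluded).  Table: CRE direction
    (AFR/EUR) x DE direction (AFR/EUR); OR > 1 means matching enrichment.
    """
    cre = _cre_de_frame(top, de, lfsr_max)
    cre = cre[cre["diff_flag"] & (cre["n_de"] > 0) & (cre["de_signs"].str.len() == 1)]
    if class_filter == "promoter":
        cre = cre[cre["prom_for_de"]]
    elif class_filter == "enhancer":
        cre = cre[~cre["prom_for_de"]]
    elif class_filter != "all":
        raise ValueError(f"unknown class_filter {class_filter!r}")
    de_dir = cre["de_signs"].str[0]
    a = int(((cre["direction"] == "AFR") & (de_dir == "AFR")).sum())
    b = int(((cre["direction"] == "AFR") & (de_dir == "EUR")).sum())
    c = int(((cre["direction"] == "EUR") & (de_dir == "AFR")).sum())
    d = int(((cre["direction"] == "EUR") & (de_dir == "EUR")).sum())
    return fisher_one_sided(a, b, c, d, label=label or f"direction_match[{class_filter}]")


def best_qtl_per_cre(qtl: pd.DataFrame, qtl_type: str) -> pd.DataFrame:
    """Lowest-P QTL of one type per CRE, plus a direction-agreement flag.

    QTL direction is AFR when the high-affinity allele is at greater
    frequency in AFR than EUR.  ``all_agree`` records whether every QTL of
    the type in the CRE shares that direction (required for inclusion in
    direction tests).
    """
    sub = qtl[(qtl["qtl_type"] == qtl_type) & qtl["cre_id"].notna()].copy()
    if sub.empty:
        return sub.assign(qtl_direction=pd.Series(dtype=object), all_agree=pd.Series(dtype=bool))
    sub["qtl_direction"] = np.where(sub["af_AFR"] > sub["af_EUR"], "AFR",
                                    np.where(sub["af_AFR"] < sub["af_EUR"], "EUR", "tie"))
    agree = sub.groupby("cre_id")["qtl_direction"].nunique() == 1
    best = (
        sub.sort_values(["qtl_p", "variant_id"], kind="stable")
        .groupby("cre_id", sort=False)
        .head(1)
        .copy()
    )
    best["all_agree"] = best["cre_id"].map(agree)
    return best


def qtl_overlap_test(cre_diff: pd.DataFrame, qtl: pd.DataFrame, qtl_type: str,
                     class_filter: str = "all", label: str = "") -> EnrichmentResult:
    """Diff-CRE x contains-QTL enrichment for one QTL type."""
    df = cre_diff.copy()
    df["status"] = _diff_status(df)
    df = df[df["status"].notna()]
    if class_filter in ("promoter", "enhancer"):
        df = df[df["element_class"] == class_filter]
    elif class_filter != "all":
        raise ValueError(f"unknown class_filter {class_filter!r}")
    with_qtl = set(qtl.loc[qtl["qtl_type"] == qtl_type, "cre_id"].dropna())
    has = df["cre_id"].isin(with_qtl)
    diff = df["status"] == "diff"
    return fisher_one_sided(
        int((diff & has).sum()), int((diff & ~has).sum()),
        int((~diff & has).sum()), int((~diff & ~has).sum()),
        label=label or f"qtl_overlap[{qtl_type},{class_filter}]",
    )


def qtl_direction_match_test(cre_diff: pd.DataFrame, qtl: pd.DataFrame, qtl_type: str,
                             fst_threshold: float | None = None,
                             class_filter: str = "all", label: str = "") -> EnrichmentResult:
    """QTL-direction x diff-CRE-direction matching test.

    Universe: diff-CREs containing a QTL of the type whose QTL all agree in
    direction (representative = lowest QTL P).  With ``fst_threshold`` set,
    only QTL with per-site F_ST >= the threshold are considered (top-F_ST
    restriction).  OR > 1 means the high-affinity allele tends to be more
    frequent in the same ancestry that has the higher CRE activity.
    """
    sub = qtl[qtl["qtl_type"] == qtl_type]
    if fst_threshold is not None:
        sub = sub[sub["fst"] >= fst_threshold]
    best = best_qtl_per_cre(sub.assign(qtl_type=qtl_type), qtl_type)
    best = best[best["all_agree"] & (best["qtl_direction"] != "tie")]
    df = cre_diff[cre_diff["diff_flag"]].copy()
    if class_filter in ("promoter", "enhancer"):
        df = df[df["element_class"] == class_filter]
    merged = df.merge(best[["cre_id", "qtl_direction"]], on="cre_id", how="inner")
    a = int(((merged["direction"] == "AFR") & (merged["qtl_direction"] == "AFR")).sum())
    b = int(((merged["direction"] == "AFR") & (merged["qtl_direction"] == "EUR")).sum())
    c = int(((merged["direction"] == "EUR") & (merged["qtl_direction"] == "AFR")).sum())
    d = int(((merged["direction"] == "EUR") & (merged["qtl_direction"] == "EUR")).sum())
    # matching layout: rows CRE direction, cols QTL direction; a,d are matches
    return fisher_one_sided(a, b, c, d,
                            label=label or f"qtl_direction[{qtl_type},{class_filter}]")


def sign_test(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial P for AFR-direction asymmetry.

    k = matching QTL in diff-CREs whose direction is AFR, n = all matching
    QTL in diff-CREs, p0 = AFR proportion among matching QTL in all CREs.
    """
    if n == 0:
        return float("nan")
    return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)


def bonferroni_stars(p: float, n_tests: int) -> str:
    """Significance stars on the Bonferroni-corrected P value."""
    padj = min(1.0, p * n_tests)
    for stars, cut in (("****", 5e-5), ("***", 5e-4), ("**", 0.005), ("*", 0.05)):
        if padj < cut:
            return stars
    return ""
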