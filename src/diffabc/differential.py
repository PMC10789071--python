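"""Between-ancestry differential tests on E-G pair scores.

Each element-gene pair's per-sample scores (one score type at a time) are
compared between African- and European-ancestry samples with an unpaired
Welch t-test.  Effect sizes are log2(mean EUR / mean AFR), so positive
log2fc means EUR-high and the pair's ``direction`` is the ancestry with the
higher mean.  The score-type false-discovery rate at P < 0.05 is estimated
from a replicate-shuffle null that preserves the 8-vs-6 group structure:
per pair, one AFR population is held out (both replicates go to the group
of eight) and every remaining population contributes one replicate to each
group.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "welch_t",
    "diff_test",
    "diff_test_table",
    "estimate_fdr",
    "dedup_by_bin",
    "select_top_diff",
    "gsea_rank_genes",
]

_TINY_P = np.nextafter(0.0, 1.0)


def welch_t(mu1, var1, n1, mu2, var2, n2):
    """Welch statistic, Satterthwaite df and two-sided P, vectorized.

    Group 1 is EUR and group 2 AFR by convention, so t > 0 means EUR-high.
    Degenerate pairs (both variances zero) get t=0, p=1 when the means agree
    and p = smallest positive float when they differ.
    """
    mu1, var1 = np.asarray(mu1, float), np.asarray(var1, float)
    mu2, var2 = np.asarray(mu2, float), np.asarray(var2, float)
    se2 = var1 / n1 + var2 / n2
    degen = se2 == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (mu1 - mu2) / np.sqrt(np.where(degen, 1.0, se2))
        df = se2**2 / (
            (var1 / n1) ** 2 / (n1 - 1) + (var2 / n2) ** 2 / (n2 - 1)
        )
        p = 2 * stats.t.sf(np.abs(t), np.where(degen, 1.0, df))
    t = np.where(degen, 0.0, t)
    same = degen & (mu1 == mu2)
    p = np.where(degen, np.where(same, 1.0, _TINY_P), p)
    df = np.where(degen, np.nan, df)
    return t, df, p


def _group_arrays(scores: pd.DataFrame, design: pd.DataFrame):
    """Split a pairs x samples matrix into (EUR, AFR) sample blocks."""
    anc = design.set_index("sample")["ancestry"]
    eur = [s for s in scores.columns if anc[s] == "EUR"]
    afr = [s for s in scores.columns if anc[s] == "AFR"]
    if len(eur) < 2 or len(afr) < 2:
        raise ValueError("need at least two samples per ancestry")
    return scores[eur].to_numpy(float), scores[afr].to_numpy(float)


def diff_test_table(scores: pd.DataFrame, design: pd.DataFrame,
                    alpha: float = 0.05, nondiff: float = 0.5) -> pd.DataFrame:
    """Run the per-pair Welch test on every row of a pairs x samples matrix.

    Returns a frame indexed like ``scores`` with group statistics, t, p,
    log2fc (EUR over AFR; +/-inf flagged when a group mean is exactly zero),
    direction (AFR iff log2fc < 0), and the diff / non-diff flags at the
    ``alpha`` and ``nondiff`` P-value cutoffs.
    """
    E, A = _group_arrays(scores, design)
    nE, nA = E.shape[1], A.shape[1]
    muE, muA = E.mean(axis=1), A.mean(axis=1)
    varE, varA = E.var(axis=1, ddof=1), A.var(axis=1, ddof=1)
    t, df, p = welch_t(muE, varE, nE, muA, varA, nA)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(muE) - np.log2(muA)
    zero_mean = (muE == 0) | (muA == 0)
    out = pd.DataFrame(
        {
            "mu_EUR": muE, "mu_AFR": muA,
            "var_EUR": varE, "var_AFR": varA,
            "n_EUR": nE, "n_AFR": nA,
            "t": t, "df": df, "p": p,
            "log2fc": log2fc,
            "zero_mean_flag": zero_mean,
            "degenerate_flag": (varE == 0) & (varA == 0) & (muE != muA),
        },
        index=scores.index,
    )
    out["direction"] = np.where(out["log2fc"] < 0, "AFR", "EUR")
    out["diff_flag"] = out["p"] < alpha
    out["nondiff_flag"] = out["p"] >= nondiff
    return out


def diff_test(values, ancestries, alpha: float = 0.05, nondiff: float = 0.5) -> pd.Series:
    """Single-pair convenience wrapper around :func:`diff_test_table`."""
    values = np.asarray(values, float)
    design = pd.DataFrame(
        {"sample": [f"s{i}" for i in range(len(values))],
         "ancestry": list(ancestries)}
    )
    scores = pd.DataFrame([values], columns=design["sample"])
    return diff_test_table(scores, design, alpha=alpha, nondiff=nondiff).iloc[0]


def _null_masks(design: pd.DataFrame, n_pairs: int, rng: np.random.Generator) -> np.ndarray:
    """Per-pair boolean masks (n_pairs x n_samples) for the group of eight.

    One AFR population is held out at random (both replicates in the group
    of eight); each remaining population sends one random replicate to the
    group of eight and the other to the group of six.
    """
    samples = design["sample"].tolist()
    pops = design.groupby("population", sort=False)
    pop_names = list(pops.groups)
    afr_pops = design.loc[design["ancestry"] == "AFR", "population"].unique().tolist()
    pop_cols = {p: [samples.index(s) for s in g["sample"]] for p, g in pops}
    if any(len(c) != 2 for c in pop_cols.values()):
        raise ValueError("replicate-shuffle null needs exactly two replicates per population")

    mask = np.zeros((n_pairs, len(samples)), dtype=bool)
    held = rng.integers(0, len(afr_pops), size=n_pairs)
    flips = rng.integers(0, 2, size=(n_pairs, len(pop_names)))
    for k, pop in enumerate(pop_names):
        c0, c1 = pop_cols[pop]
        pick0 = flips[:, k] == 0
        mask[pick0, c0] = True
        mask[~pick0, c1] = True
    for k, pop in enumerate(afr_pops):
        c0, c1 = pop_cols[pop]
        rows = held == k
        mask[rows, c0] = True
        mask[rows, c1] = True
    return mask


def _masked_welch_p(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Welch two-sided P for each row of X split by a per-row boolean mask."""
    n1 = mask.sum(axis=1)
    n2 = (~mask).sum(axis=1)
    s1 = np.where(mask, X, 0.0).sum(axis=1)
    s2 = np.where(~mask, X, 0.0).sum(axis=1)
    q1 = np.where(mask, X**2, 0.0).sum(axis=1)
    q2 = np.where(~mask, X**2, 0.0).sum(axis=1)
    mu1, mu2 = s1 / n1, s2 / n2
    var1 = (q1 - n1 * mu1**2) / (n1 - 1)
    var2 = (q2 - n2 * mu2**2) / (n2 - 1)
    var1, var2 = np.maximum(var1, 0.0), np.maximum(var2, 0.0)
    _, _, p = welch_t(mu1, var1, n1, mu2, var2, n2)
    return p


def estimate_fdr(scores: pd.DataFrame, design: pd.DataFrame, seed: int,
                 n_shuffles: int = 1, alpha: float = 0.05,
                 real_p: np.ndarray | None = None) -> dict:
    """Replicate-shuffle FDR for diff calls at ``alpha`` on one score type.

    FDR = (mean null positives per shuffle) / (observed positives); capped
    at 1 for reporting and NaN when there are no observed positives.
    """
    rng = np.random.default_rng(seed)
    if real_p is None:
        real_p = diff_test_table(scores, design)["p"].to_numpy()
    X = scores.to_numpy(float)
    null_pos = 0
    for _ in range(n_shuffles):
        mask = _null_masks(design, X.shape[0], rng)
        null_pos += int((_masked_welch_p(X, mask) < alpha).sum())
    expected = null_pos / n_shuffles
    observed = int((np.asarray(real_p) < alpha).sum())
    fdr = np.nan if observed == 0 else expected / observed
    return {
        "expected": expected,
        "observed": observed,
        "fdr": fdr,
        "fdr_capped": np.nan if observed == 0 else min(fdr, 1.0),
        "seed": seed,
        "n_shuffles": n_shuffles,
    }


def dedup_by_bin(results: pd.DataFrame) -> pd.DataFrame:
    """Collapse diff-flagged rows sharing a 5-kb ``bin_key`` to one.

    ChIP and HiC signal is bin-resolution, so several CREs in one bin are a
    single piece of evidence.  The representative is the lowest-p row (ties
    broken by pair/cre id); rows that are not diff-flagged pass through.
    """
    flagged = results[results["diff_flag"]]
    keep = results[~results["diff_flag"]]
    id_col = "pair_id" if "pair_id" in results.columns else "cre_id"
    rep = (
        flagged.sort_values(["p", id_col], kind="stable")
        .groupby("bin_key", sort=False)
        .head(1)
    )
    return pd.concat([rep, keep]).sort_index()


def select_top_diff(results: pd.DataFrame) -> pd.DataFrame:
    """Most differential CRE per gene for one score type.

    Lowest P wins; ties go to the larger absolute log2 fold change, then to
    genomic coordinate for determinism.
    """
    df = results.copy()
    df["_abs_lfc"] = df["log2fc"].abs().replace(np.inf, np.finfo(float).max)
    sort_cols = ["p", "_abs_lfc"]
    ascending = [True, False]
    if "cre_start" in df.columns:
        sort_cols += ["chrom", "cre_start"] if "chrom" in df.columns else ["cre_start"]
        ascending += [True] * (len(sort_cols) - 2)
    top = (
        df.sort_values(sort_cols, ascending=ascending, kind="stable")
        .groupby("gene_id", sort=False)
        .head(1)
        .drop(columns="_abs_lfc")
    )
    return top.sort_values("gene_id").reset_index(drop=True)


def gsea_rank_genes(results: pd.DataFrame) -> pd.DataFrame:
    """Rank genes by their top diff-CRE's Welch-form statistic.

    statistic = (mu_EUR - mu_AFR) / sqrt(var_EUR/n_EUR + var_AFR/n_AFR),
    descending (EUR-high first).  Genes whose top CRE has a zero standard
    error are dropped with a warning.
    """
    top = select_top_diff(results)
    se2 = top["var_EUR"] / top["n_EUR"] + top["var_AFR"] / top["n_AFR"]
    bad = se2 == 0
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} gene(s) with zero-variance top CRE")
        top = top[~bad]
        se2 = se2[~bad]
    top = top.assign(stat=(top["mu_EUR"] - top["mu_AFR"]) / np.sqrt(se2))
    return (
        top[["gene_id", "cre_id", "stat"]]
        .sort_values("stat", ascending=False)
        .reset_index(drop=True)
    )
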