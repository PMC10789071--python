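"""Candidate cis-regulatory element (CRE) construction.

The candidate set is built from ATAC peaks called separately per ancestry:
each ancestry's peaks are ranked by summed read count, the top k resized to
500 bp around the summit, the two rankings interleaved evenly (AFR first)
with overlap merging so both ancestries contribute equally, 500-bp
TSS-centered windows added, blacklist-overlapping elements removed, and the
result classified into promoters (within 500 bp of a TSS) and enhancers.
All coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pyranges as pr

__all__ = [
    "rank_resize_peaks",
    "interleave_and_merge",
    "add_tss_and_blacklist",
    "classify_elements",
    "build_cre_set",
    "promoter_for_mask",
]

ELEMENT_WIDTH = 500
PROMOTER_DIST = 500


def _clip(df: pd.DataFrame, chrom_sizes: dict | None) -> pd.DataFrame:
    df["start"] = df["start"].clip(lower=0)
    if chrom_sizes is not None:
        sizes = df["chrom"].map(chrom_sizes)
        df["end"] = np.minimum(df["end"], sizes)
    return df


def rank_resize_peaks(peaks: pd.DataFrame, counts: pd.DataFrame, samples: list,
                      k: int = 150_000, chrom_sizes: dict | None = None) -> pd.DataFrame:
    """Rank one ancestry's peaks by summed read count; resize to 500 bp.

    ``peaks`` needs chrom/start/end/summit/peak_id; ``counts`` is a
    peak_id x sample matrix.  Output intervals are ELEMENT_WIDTH bp centered
    on the summit, clipped (not shifted) at chromosome edges, with a 1-based
    ``rank``.  Fewer than k peaks keeps all with a warning.
    """
    if peaks["summit"].isna().any():
        raise ValueError("every peak needs a summit")
    missing = [s for s in samples if s not in counts.columns]
    if missing:
        raise ValueError(f"counts missing samples: {missing}")
    total = counts.loc[peaks["peak_id"], samples].sum(axis=1)
    df = peaks.copy()
    df["summed_count"] = total.to_numpy()
    df = df.sort_values(["summed_count", "chrom", "start"],
                        ascending=[False, True, True], kind="stable")
    if len(df) < k:
        warnings.warn(f"only {len(df)} peaks available for top-{k} selection")
    df = df.head(k).copy()
    half = ELEMENT_WIDTH // 2
    df["start"] = df["summit"] - half
    df["end"] = df["summit"] + half
    df = _clip(df, chrom_sizes)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def _merge_keep_min(df: pd.DataFrame, order_col: str) -> pd.DataFrame:
    """Merge overlapping intervals (union); keep the best (min) order value.

    A merged element counts as peak-derived if any constituent is.
    """
    g = pr.PyRanges(df.rename(columns={"chrom": "Chromosome", "start": "Start", "end": "End"}))
    clustered = g.cluster().df
    agg = {order_col: "min", "Start": "min", "End": "max"}
    if "from_peak" in clustered.columns:
        agg["from_peak"] = "max"
    merged = clustered.groupby(["Chromosome", "Cluster"], observed=True).agg(agg).reset_index()
    merged = merged.rename(columns={"Chromosome": "chrom", "Start": "start", "End": "end"})
    merged["chrom"] = merged["chrom"].astype(str)
    return merged.drop(columns="Cluster")


def interleave_and_merge(afr_ranked: pd.DataFrame, eur_ranked: pd.DataFrame,
                         k: int = 150_000) -> pd.DataFrame:
    """Interleave two rank-sorted element lists evenly and merge overlaps.

    Order is AFR1, EUR1, AFR2, EUR2, ...; overlapping intervals are merged
    (union) and a merged element keeps the smallest interleaved position of
    its constituents; the first k elements by that order are returned,
    coordinate-sorted.
    """
    if len(afr_ranked) == 0 or len(eur_ranked) == 0:
        raise ValueError("both ancestry rankings must be non-empty")
    a = afr_ranked.copy()
    e = eur_ranked.copy()
    a["ipos"] = 2 * (a["rank"] - 1)
    e["ipos"] = 2 * (e["rank"] - 1) + 1
    both = pd.concat([a, e], ignore_index=True)[["chrom", "start", "end", "ipos"]]
    merged = _merge_keep_min(both, "ipos")
    merged = merged.sort_values("ipos", kind="stable").head(k)
    return merged.sort_values(["chrom", "start"]).reset_index(drop=True)


def add_tss_and_blacklist(candidates: pd.DataFrame, tss: pd.DataFrame,
                          blacklist: pd.DataFrame | None = None,
                          chrom_sizes: dict | None = None) -> pd.DataFrame:
    """Add 500-bp TSS-centered windows, merge, then drop blacklisted elements.

    Any element overlapping a blacklist interval by >= 1 bp is removed.
    Output is coordinate-sorted with stable ids cre_000001, ...
    """
    half = ELEMENT_WIDTH // 2
    tss_elems = pd.DataFrame(
        {
            "chrom": tss["chrom"],
            "start": tss["tss"] - half,
            "end": tss["tss"] + half,
            "ipos": np.inf,  # TSS additions rank after all peak-derived elements
            "from_peak": 0,
        }
    )
    tss_elems = _clip(tss_elems, chrom_sizes)
    cand = candidates.copy()
    cand["from_peak"] = 1
    if "ipos" not in cand.columns:
        cand["ipos"] = np.arange(len(cand))
    merged = _merge_keep_min(
        pd.concat([cand[["chrom", "start", "end", "ipos", "from_peak"]], tss_elems],
                  ignore_index=True),
        "ipos",
    )
    if blacklist is not None and len(blacklist):
        if (blacklist["start"] >= blacklist["end"]).any() or (blacklist["start"] < 0).any():
            raise ValueError("malformed blacklist intervals")
        bl = pr.PyRanges(blacklist.rename(
            columns={"chrom": "Chromosome", "start": "Start", "end": "End"}))
        g = pr.PyRanges(merged.rename(
            columns={"chrom": "Chromosome", "start": "Start", "end": "End"}))
        kept = g.overlap(bl, invert=True).df
        merged = kept.rename(columns={"Chromosome": "chrom", "Start": "start", "End": "end"})
        merged["chrom"] = merged["chrom"].astype(str)
    merged = merged.sort_values(["chrom", "start"]).reset_index(drop=True)
    merged["source"] = np.where(merged["from_peak"] > 0, "atac_peak", "tss_added")
    merged["cre_id"] = [f"cre_{i + 1:06d}" for i in range(len(merged))]
    return merged[["cre_id", "chrom", "start", "end", "source", "ipos"]]


def classify_elements(cres: pd.DataFrame, tss: pd.DataFrame) -> pd.DataFrame:
    """Label each CRE promoter or enhancer.

    Promoter iff the element overlaps any window [TSS - 500, TSS + 500]
    (closed on the TSS side), i.e. some TSS lies in [start - 500, end + 500).
    """
    out = cres.copy()
    out["element_class"] = "enhancer"
    for chrom, sub in tss.groupby("chrom", sort=False):
        t = np.sort(sub["tss"].to_numpy())
        mask = out["chrom"] == chrom
        lo = np.searchsorted(t, out.loc[mask, "start"].to_numpy() - PROMOTER_DIST, side="left")
        hi = np.searchsorted(t, out.loc[mask, "end"].to_numpy() + PROMOTER_DIST, side="left")
        out.loc[mask, "element_class"] = np.where(hi > lo, "promoter", "enhancer")
    return out


def promoter_for_mask(cres: pd.DataFrame, gene_tss: pd.Series, gene_chrom: pd.Series) -> np.ndarray:
    """Row-wise flag: is this CRE a promoter *for this particular gene*?

    Same overlap rule as :func:`classify_elements` but against a single
    gene's TSS per row (used for E-G pairs; a promoter CRE can act as an
    enhancer for a different gene).
    """
    t = gene_tss.to_numpy()
    same_chrom = (cres["chrom"].to_numpy() == gene_chrom.to_numpy())
    return same_chrom & (t >= cres["start"].to_numpy() - PROMOTER_DIST) \
        & (t < cres["end"].to_numpy() + PROMOTER_DIST)


def build_cre_set(peaks: pd.DataFrame, counts: pd.DataFrame,
                  afr_samples: list, eur_samples: list, tss: pd.DataFrame,
                  blacklist: pd.DataFrame | None = None, k: int = 150_000,
                  chrom_sizes: dict | None = None) -> pd.DataFrame:
    """Full candidate-element construction from peaks to classified CREs."""
    afr = rank_resize_peaks(peaks, counts, afr_samples, k=k, chrom_sizes=chrom_sizes)
    eur = rank_resize_peaks(peaks, counts, eur_samples, k=k, chrom_sizes=chrom_sizes)
    cand = interleave_and_merge(afr, eur, k=k)
    cres = add_tss_and_blacklist(cand, tss, blacklist, chrom_sizes=chrom_sizes)
    return classify_elements(cres, tss)
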