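"""ABC score decomposition for element-gene pairs.

Per sample, each candidate element E within 5 Mb of a gene G's TSS gets four
normalized scores, each the fraction of the gene's total regulatory input
carried by E under a different signal model:

    abc_E  = A_E * Q_EG / sum_e A_e * Q_eG      (accessibility x contact)
    atac_E = A_E / sum_e A_e                    (accessibility only)
    chip_E = sqrt(H_E H_G) / sum_e sqrt(H_e H_G)        (VC-sqrt activity)
    hic_E  = (C_EG / sqrt(H_E H_G)) / sum_e (C_eG / sqrt(H_e H_G))

A is quantile-normalized ATAC reads-per-million at the element, H the
quantile-normalized total valid cis-pair count of the 5-kb HiChIP bin
holding the element (or the gene promoter), C the quantile-normalized
valid cis-pair count connecting the two bins, and Q the per-gene
quantitative HiChIP signal (contacts sum-normalized then scaled so the
per-gene maximum is 1).  Quantile normalization is to the across-sample
mean distribution, separately for enhancer- and promoter-class features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cre import PROMOTER_DIST

__all__ = [
    "quantile_normalize",
    "assign_bins",
    "build_pair_universe",
    "bin_totals",
    "quantitative_hichip",
    "compute_scores",
    "score_samples",
    "define_eg_pairs",
]

BIN_SIZE = 5000
WINDOW = 5_000_000
SCORE_TYPES = ("abc", "atac", "chip", "hic")


def quantile_normalize(values: pd.DataFrame, classes: pd.Series) -> pd.DataFrame:
    """Quantile-normalize sample columns to their mean distribution, per class.

    Within each class (enhancer/promoter partition of the feature rows),
    every sample's values are replaced by the across-sample mean of the
    order statistics at the value's rank; tied values receive the average
    of the tied reference values, so the marginal distribution is identical
    across samples within a class.
    """
    out = values.astype(float).copy()
    for cls in classes.unique():
        idx = classes.index[classes == cls]
        X = values.loc[idx].to_numpy(dtype=float)
        if X.shape[0] == 0:
            continue
        zero = X.sum(axis=0) == 0
        if zero.any():
            bad = list(values.columns[zero])
            raise ValueError(f"all-zero {cls} vector for sample(s) {bad}: ranks uninformative")
        ref = np.sort(X, axis=0).mean(axis=1)
        res = np.empty_like(X)
        for c in range(X.shape[1]):
            order = np.argsort(X[:, c], kind="stable")
            tied_mean = (
                pd.Series(ref).groupby(X[order, c], sort=False).transform("mean").to_numpy()
            )
            res[order, c] = tied_mean
        out.loc[idx] = res
    return out


def assign_bins(positions, bin_size: int = BIN_SIZE) -> np.ndarray:
    """5-kb bin index of each position (element midpoints use floor division)."""
    return np.asarray(positions, dtype=np.int64) // bin_size


def build_pair_universe(cres: pd.DataFrame, tss: pd.DataFrame,
                        window: int = WINDOW, bin_size: int = BIN_SIZE) -> pd.DataFrame:
    """All candidate (element, gene) pairs with the element midpoint within
    ``window`` of the gene TSS, plus bin assignments and per-gene promoter
    flags (a promoter CRE is only a promoter *pair* for genes whose TSS it
    covers; for other genes it is a distal element)."""
    rows = []
    for chrom, csub in cres.groupby("chrom", sort=False):
        gsub = tss[tss["chrom"] == chrom]
        if gsub.empty:
            continue
        csub = csub.copy()
        csub["mid"] = (csub["start"] + csub["end"]) // 2
        csub = csub.sort_values("mid")
        mids = csub["mid"].to_numpy()
        lo = np.searchsorted(mids, gsub["tss"].to_numpy() - window, side="left")
        hi = np.searchsorted(mids, gsub["tss"].to_numpy() + window, side="right")
        for (gi, gene), l, h in zip(gsub.iterrows(), lo, hi):
            if h <= l:
                continue
            block = csub.iloc[l:h]
            t = int(gene["tss"])
            rows.append(pd.DataFrame({
                "gene_id": gene["gene_id"],
                "cre_id": block["cre_id"].to_numpy(),
                "chrom": chrom,
                "cre_start": block["start"].to_numpy(),
                "cre_end": block["end"].to_numpy(),
                "element_class": block["element_class"].to_numpy(),
                "distance": np.abs(block["mid"].to_numpy() - t),
                "bin_e": assign_bins(block["mid"].to_numpy(), bin_size),
                "bin_g": assign_bins(t, bin_size),
                "is_promoter_pair": (t >= block["start"].to_numpy() - PROMOTER_DIST)
                                    & (t < block["end"].to_numpy() + PROMOTER_DIST),
            }))
    if not rows:
        raise ValueError("no element-gene pairs within the window")
    uni = pd.concat(rows, ignore_index=True)
    uni["pair_id"] = uni["cre_id"] + "|" + uni["gene_id"]
    uni["bin_key"] = uni["chrom"] + ":" + uni["bin_e"].astype(str)
    # categorical ids keep the (pairs x samples) long tables compact
    for col in ("pair_id", "gene_id", "cre_id", "chrom", "element_class", "bin_key"):
        uni[col] = uni[col].astype("category")
    return uni


def bin_totals(contacts: pd.DataFrame) -> pd.Series:
    """Total valid cis-pair count per 5-kb bin (diagonal counted once).

    ``contacts`` holds upper-triangle sparse counts (chrom, i, j, count)
    with i <= j in bin units.
    """
    def _keyed(df: pd.DataFrame, col: str) -> pd.Series:
        s = df.groupby([df["chrom"], df[col]], sort=False, observed=True)["count"].sum()
        s.index = [f"{c}:{b}" for c, b in s.index]
        return s

    diag = contacts[contacts["i"] == contacts["j"]]
    return (_keyed(contacts, "i")
            .add(_keyed(contacts, "j"), fill_value=0)
            .sub(_keyed(diag, "i"), fill_value=0))


def quantitative_hichip(contacts_qnorm: np.ndarray) -> np.ndarray:
    """Per-gene quantitative HiChIP signal from quantile-normalized contacts.

    q_e = c_e / sum(c); Q_e = q_e / max(q).  All zeros when sum(c) = 0.
    """
    c = np.asarray(contacts_qnorm, dtype=float)
    s = c.sum()
    if s == 0:
        return np.zeros_like(c)
    q = c / s
    return q / q.max()


def compute_scores(df: pd.DataFrame, group_cols=("gene_id",)) -> pd.DataFrame:
    """Apply the four score formulas to a component table.

    ``df`` needs columns A, Q, H_E, H_G, C; each group (gene, or gene x
    sample) is normalized independently.  A zero denominator yields all-zero
    scores of that type for the gene; a contact over a zero-total bin is a
    data inconsistency and raises.
    """
    bad = (df["H_E"] * df["H_G"] == 0) & (df["C"] > 0)
    if bad.any():
        raise ValueError("bin with contacts but zero total valid cis-pair count")
    out = df.copy()
    chip_num = np.sqrt(out["H_E"] * out["H_G"])
    with np.errstate(divide="ignore", invalid="ignore"):
        hic_num = np.where(chip_num > 0, out["C"] / chip_num, 0.0)
    nums = pd.DataFrame({
        "abc": out["A"] * out["Q"],
        "atac": out["A"],
        "chip": chip_num,
        "hic": hic_num,
    }, index=out.index)
    out["chip_num"], out["hic_num"] = nums["chip"], nums["hic"]
    denom = nums.groupby([out[c] for c in group_cols], sort=False,
                         observed=True).transform("sum")
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = nums / denom
    out[list(SCORE_TYPES)] = scores.where(denom > 0, 0.0)
    return out


def _rpm(counts: pd.DataFrame, total_reads: pd.Series | None) -> pd.DataFrame:
    if total_reads is None:
        total_reads = counts.sum(axis=0)
    return counts * 1e6 / total_reads


def score_samples(cres: pd.DataFrame, cre_counts: pd.DataFrame, tss: pd.DataFrame,
                  contacts: dict, total_reads: pd.Series | None = None,
                  window: int = WINDOW, bin_size: int = BIN_SIZE) -> pd.DataFrame:
    """Compute per-sample score tables for the whole pair universe.

    Parameters
    ----------
    cres : classified CRE set (cre_id, chrom, start, end, element_class).
    cre_counts : cre_id x sample raw ATAC count matrix.
    tss : gene annotation (gene_id, chrom, tss).
    contacts : sample -> sparse upper-triangle contact frame (chrom, i, j, count).
    total_reads : per-sample library sizes for RPM; defaults to the column
        sums of ``cre_counts`` (documented fallback).

    Returns a long frame with one row per (pair, sample) carrying the
    components A, Q, H_E, H_G, C and the four scores.
    """
    samples = list(contacts)
    uni = build_pair_universe(cres, tss, window=window, bin_size=bin_size)

    # --- activity: quantile-normalized RPM per element class
    counts = cre_counts.reindex(cres["cre_id"]).fillna(0.0)[samples]
    A = quantile_normalize(_rpm(counts, total_reads),
                           classes=cres.set_index("cre_id")["element_class"])

    # --- bin features and classes (promoter wins when a bin holds both)
    cre_bins = pd.DataFrame({
        "bin_key": (cres["chrom"] + ":" +
                    assign_bins((cres["start"] + cres["end"]) // 2, bin_size).astype(str)),
        "is_prom": (cres["element_class"] == "promoter").to_numpy(),
    })
    gene_bins = pd.DataFrame({
        "bin_key": tss["chrom"] + ":" + assign_bins(tss["tss"], bin_size).astype(str),
        "is_prom": True,
    })
    feat = pd.concat([cre_bins, gene_bins]).groupby("bin_key")["is_prom"].max()
    bin_class = pd.Series(np.where(feat, "promoter", "enhancer"), index=feat.index)

    H_raw = pd.DataFrame(
        {s: bin_totals(contacts[s]).reindex(feat.index).fillna(0.0) for s in samples}
    )
    H = quantile_normalize(H_raw, classes=bin_class)

    # --- connecting contacts: unique bin-pair features across the universe
    lo = np.minimum(uni["bin_e"], uni["bin_g"])
    hi = np.maximum(uni["bin_e"], uni["bin_g"])
    chrom_str = uni["chrom"].astype(str)
    uni["_feat"] = (chrom_str + ":" + lo.astype(str) + "-" + hi.astype(str)).astype("category")
    uni["_gkey"] = (chrom_str + ":" + uni["bin_g"].astype(str)).astype("category")
    feats = pd.DataFrame(
        {"chrom": chrom_str.to_numpy(), "lo": lo.to_numpy(), "hi": hi.to_numpy()},
        index=pd.Index(uni["_feat"].astype(str).to_numpy(), name="_feat"),
    )
    feats = feats[~feats.index.duplicated()]
    lo_cls = bin_class.reindex(feats["chrom"] + ":" + feats["lo"].astype(str)).to_numpy()
    hi_cls = bin_class.reindex(feats["chrom"] + ":" + feats["hi"].astype(str)).to_numpy()
    pair_class = pd.Series(
        np.where((lo_cls == "promoter") | (hi_cls == "promoter"), "promoter", "enhancer"),
        index=feats.index,
    )
    fkey = feats.reset_index(names="_feat")
    C_raw = {}
    for s in samples:
        cm = contacts[s].copy()
        cm["chrom"] = cm["chrom"].astype(str)
        hit = fkey.merge(
            cm.rename(columns={"i": "lo", "j": "hi"}), how="left",
            on=["chrom", "lo", "hi"],
        )
        C_raw[s] = hit.set_index("_feat")["count"].fillna(0.0)
    C = quantile_normalize(pd.DataFrame(C_raw), classes=pair_class)

    # --- assemble long table and per-gene Q
    keep = ["pair_id", "gene_id", "cre_id", "chrom", "cre_start", "element_class",
            "is_promoter_pair", "bin_key"]
    blocks = []
    for s in samples:
        b = uni[keep].copy()
        b["sample"] = s
        b["A"] = A.loc[uni["cre_id"], s].to_numpy()
        b["H_E"] = H.loc[uni["bin_key"], s].to_numpy()
        b["H_G"] = H.loc[uni["_gkey"], s].to_numpy()
        b["C"] = C.loc[uni["_feat"], s].to_numpy()
        csum = b.groupby("gene_id", sort=False, observed=True)["C"].transform("sum")
        cmax = b.groupby("gene_id", sort=False, observed=True)["C"].transform("max")
        with np.errstate(divide="ignore", invalid="ignore"):
            b["Q"] = np.where(csum > 0, (b["C"] / csum) / (cmax / csum), 0.0)
        blocks.append(compute_scores(b, group_cols=("gene_id",)))
    out = pd.concat(blocks, ignore_index=True)
    out["sample"] = out["sample"].astype("category")
    return out


def define_eg_pairs(score_long: pd.DataFrame, abc_min: float = 0.015,
                    promoter_abc_min: float = 0.1) -> pd.DataFrame:
    """Apply the E-G pair candidacy filters across samples.

    Retain a pair iff (i) ABC >= ``abc_min`` in at least one sample,
    (ii) promoter-gene pairs (E is G's own promoter) additionally reach
    ``promoter_abc_min`` in at least one sample, and (iii) the connecting
    contact C and element activity A are nonzero in every sample.
    """
    samples = score_long["sample"].unique()
    g = score_long.groupby("pair_id", sort=False, observed=True)
    n = g.size()
    if n.nunique() != 1 or n.iloc[0] != len(samples):
        raise ValueError("samples have mismatched pair universes")
    agg = g.agg(
        max_abc=("abc", "max"),
        min_C=("C", "min"),
        min_A=("A", "min"),
        is_promoter_pair=("is_promoter_pair", "first"),
    )
    keep = (agg["max_abc"] >= abc_min) & (agg["min_C"] > 0) & (agg["min_A"] > 0)
    keep &= ~agg["is_promoter_pair"] | (agg["max_abc"] >= promoter_abc_min)
    kept = set(agg.index[keep])
    out = score_long[score_long["pair_id"].isin(kept)].reset_index(drop=True)
    # plain dtypes downstream: the filtered table is small
    for col in ("pair_id", "gene_id", "cre_id", "chrom", "element_class",
                "bin_key", "sample"):
        out[col] = out[col].astype(str)
    return out
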