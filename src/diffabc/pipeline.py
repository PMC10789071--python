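"""End-to-end differential activity-by-contact analysis on one input bundle.

Chains the stages: candidate-element construction, ABC score decomposition,
E-G pair filtering, per-score-type differential testing with the
replicate-shuffle FDR, and the bookkeeping (peak-to-CRE count transfer,
truth-to-pair mapping) that connects the synthetic generator to the
analysis modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cre as cre_mod
from . import differential as diff_mod
from . import scoring
from .simulate import SimData

__all__ = ["PipelineResult", "cre_counts_from_peaks", "run_pipeline", "truth_pair_map"]


@dataclass
class PipelineResult:
    cres: pd.DataFrame
    cre_counts: pd.DataFrame
    scores: pd.DataFrame           # long, all pairs x samples (unfiltered)
    filtered: pd.DataFrame         # long, pairs passing candidacy filters
    diff: dict = field(default_factory=dict)   # score type -> results frame
    fdr: dict = field(default_factory=dict)    # score type -> FDR summary
    design: pd.DataFrame = None

    def pair_table(self, score_type: str) -> pd.DataFrame:
        """Pairs x samples wide matrix of one score type (filtered pairs)."""
        return self.filtered.pivot_table(index="pair_id", columns="sample",
                                         values=score_type, sort=False)


def cre_counts_from_peaks(cres: pd.DataFrame, peaks: pd.DataFrame,
                          counts: pd.DataFrame) -> pd.DataFrame:
    """Sum peak counts into containing CREs (assignment by peak summit).

    TSS-added elements without an underlying peak get zero counts.
    """
    out = pd.DataFrame(0.0, index=cres["cre_id"], columns=counts.columns)
    assigned = {}
    for chrom, sub in cres.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        st, en = sub["start"].to_numpy(), sub["end"].to_numpy()
        m = peaks["chrom"] == chrom
        s = peaks.loc[m, "summit"].to_numpy()
        k = np.searchsorted(st, s, side="right") - 1
        ok = (k >= 0) & (s < en[np.clip(k, 0, len(en) - 1)])
        for pid, ki in zip(peaks.loc[m, "peak_id"].to_numpy()[ok],
                           sub["cre_id"].to_numpy()[k[ok]]):
            assigned.setdefault(ki, []).append(pid)
    for cid, pids in assigned.items():
        out.loc[cid] = counts.loc[pids].sum(axis=0).to_numpy()
    return out


def _pair_metadata(filtered: pd.DataFrame) -> pd.DataFrame:
    cols = ["pair_id", "gene_id", "cre_id", "chrom", "cre_start",
            "element_class", "is_promoter_pair", "bin_key"]
    return filtered[cols].drop_duplicates("pair_id").set_index("pair_id")


def run_pipeline(sim: SimData, alpha: float = 0.05, nondiff: float = 0.5,
                 fdr_seed: int = 0, n_shuffles: int = 1,
                 score_types=scoring.SCORE_TYPES, with_fdr: bool = True,
                 abc_min: float = 0.015, promoter_abc_min: float = 0.1) -> PipelineResult:
    """Run the full analysis on a (synthetic or loaded) input bundle."""
    design = sim.design
    afr = design.loc[design["ancestry"] == "AFR", "sample"].tolist()
    eur = design.loc[design["ancestry"] == "EUR", "sample"].tolist()
    cres = cre_mod.build_cre_set(
        sim.peaks, sim.counts, afr, eur, sim.annotation.tss,
        blacklist=sim.blacklist, chrom_sizes=sim.annotation.chrom_sizes,
    )
    ccounts = cre_counts_from_peaks(cres, sim.peaks, sim.counts)
    scores = scoring.score_samples(cres, ccounts, sim.annotation.tss, sim.contacts)
    filtered = scoring.define_eg_pairs(scores, abc_min=abc_min,
                                       promoter_abc_min=promoter_abc_min)
    meta = _pair_metadata(filtered)
    res = PipelineResult(cres=cres, cre_counts=ccounts, scores=scores,
                         filtered=filtered, design=design)
    for st in score_types:
        wide = res.pair_table(st)
        d = diff_mod.diff_test_table(wide, design, alpha=alpha, nondiff=nondiff)
        d = d.join(meta).reset_index().rename(columns={"index": "pair_id"})
        d["score_type"] = st
        res.diff[st] = d
        if with_fdr:
            res.fdr[st] = diff_mod.estimate_fdr(
                wide, design, seed=fdr_seed, n_shuffles=n_shuffles,
                alpha=alpha, real_p=d["p"].to_numpy())
    return res


def truth_pair_map(sim: SimData, result: PipelineResult) -> pd.DataFrame:
    """Join injected truth effects onto filtered pair ids.

    A truth peak maps to the CRE containing its summit; the truth pair is
    (that CRE, the truth target gene).  Rows whose pair did not survive
    filtering carry NaN pair metadata.
    """
    cres = result.cres
    rows = []
    for _, t in sim.truth.iterrows():
        sub = cres[(cres["chrom"] == t["chrom"])
                   & (cres["start"] <= t["summit"]) & (t["summit"] < cres["end"])]
        cid = sub["cre_id"].iloc[0] if len(sub) else None
        rows.append({"peak_id": t["peak_id"], "cre_id": cid,
                     "gene_id": t["gene_id"], "channel": t["channel"],
                     "sign": t["sign"],
                     "pair_id": (f"{cid}|{t['gene_id']}" if cid else None)})
    out = pd.DataFrame(rows)
    surviving = set(result.filtered["pair_id"].unique())
    out["pair_in_filtered"] = out["pair_id"].isin(surviving)
    return out
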