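"""Synthetic generator for every pipeline input, with known ground truth.

Emulates a two-ancestry pooled LCL assay design end to end at desk scale:
a 14-sample layout (4 AFR + 3 EUR populations x 2 replicates), ATAC peak
counts with
negative-binomial noise, 5-kb-binned HiChIP contact maps with exponential
distance decay and H3K27ac-style anchor enrichment, Balding-Nichols
between-ancestry allele-frequency divergence, bQTL tables with a
high-affinity allele, and per-context ancestry-DE tables.  A configurable
fraction of elements carries an injected ancestry effect on one score
channel (atac / chip / hic); the truth table records every injected effect
so downstream recovery is testable.

Determinism: every generator derives its RNG from ``(config.seed, stage)``,
so identical configs reproduce identical outputs byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig
from .scoring import BIN_SIZE

__all__ = [
    "Annotation",
    "SimData",
    "generate_annotation",
    "place_peaks",
    "generate_truth",
    "generate_atac",
    "generate_hichip",
    "generate_variants_and_qtl",
    "generate_de_tables",
    "simulate_all",
]

MIN_TSS_SPACING = 10_000
_TF_NAMES = ("JunD", "NFKB", "PU1", "Stat1", "Oct1", "H3K4me3")

# stage offsets for seed derivation, one per stochastic generator
_STAGES = {"annotation": 1, "peaks": 2, "truth": 3, "atac": 4,
           "hichip": 5, "variants": 6, "de": 7, "blacklist": 8}


def _rng(config: SimConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), _STAGES[stage]])


@dataclass
class Annotation:
    chrom_sizes: dict
    tss: pd.DataFrame  # gene_id, chrom, tss, strand


@dataclass
class SimData:
    """Bundle of all generated inputs plus the ground-truth table."""

    config: SimConfig
    annotation: Annotation
    peaks: pd.DataFrame
    counts: pd.DataFrame
    blacklist: pd.DataFrame
    contacts: dict
    truth: pd.DataFrame
    variants: pd.DataFrame = None
    qtl: pd.DataFrame = None
    de: dict = field(default_factory=dict)

    @property
    def design(self) -> pd.DataFrame:
        return self.config.design()


def generate_annotation(config: SimConfig) -> Annotation:
    """Place gene TSS uniformly with >= 10 kb spacing on each chromosome."""
    rng = _rng(config, "annotation")
    chrom_sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    per = np.full(config.n_chroms, config.n_genes // config.n_chroms)
    per[: config.n_genes % config.n_chroms] += 1
    rows = []
    g = 0
    for (chrom, size), n in zip(chrom_sizes.items(), per):
        slack = size - (n - 1) * MIN_TSS_SPACING - MIN_TSS_SPACING
        if n > 0 and slack <= 0:
            raise ValueError(
                f"{chrom} too short for {n} genes at {MIN_TSS_SPACING} bp spacing")
        raw = np.sort(rng.integers(0, slack, size=n))
        pos = raw + np.arange(n) * MIN_TSS_SPACING + MIN_TSS_SPACING // 2
        strand = rng.choice(["+", "-"], size=n)
        for p, s in zip(pos, strand):
            g += 1
            rows.append({"gene_id": f"G{g:05d}", "chrom": chrom, "tss": int(p), "strand": s})
    return Annotation(chrom_sizes, pd.DataFrame(rows))


def place_peaks(config: SimConfig, annotation: Annotation) -> pd.DataFrame:
    """Accessible-site universe: one promoter peak per TSS plus distal peaks."""
    rng = _rng(config, "peaks")
    tss = annotation.tss
    rows = []
    # promoter peaks, summit jittered around the TSS
    for _, gene in tss.iterrows():
        s = int(gene["tss"] + rng.integers(-50, 51))
        rows.append({"chrom": gene["chrom"], "summit": s, "is_promoter_peak": True,
                     "target_hint": gene["gene_id"]})
    n_distal = max(config.n_peaks_per_ancestry - len(tss), 0)
    chroms = list(annotation.chrom_sizes)
    for _ in range(n_distal):
        chrom = chroms[rng.integers(0, len(chroms))]
        s = int(rng.integers(1000, annotation.chrom_sizes[chrom] - 1000))
        rows.append({"chrom": chrom, "summit": s, "is_promoter_peak": False,
                     "target_hint": None})
    df = pd.DataFrame(rows)
    half = rng.integers(150, 401, size=len(df))
    df["start"] = np.maximum(df["summit"] - half, 0)
    df["end"] = df["summit"] + rng.integers(150, 401, size=len(df))
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    df["peak_id"] = [f"P{i + 1:06d}" for i in range(len(df))]
    return df[["peak_id", "chrom", "start", "end", "summit",
               "is_promoter_peak", "target_hint"]]


def _nearest_gene(peaks: pd.DataFrame, tss: pd.DataFrame, max_dist: int = 400_000):
    """Nearest gene per peak (id and distance; NaN beyond ``max_dist``)."""
    gid = np.full(len(peaks), None, dtype=object)
    dist = np.full(len(peaks), np.inf)
    for chrom, sub in tss.groupby("chrom", sort=False):
        t = np.sort(sub["tss"].to_numpy())
        names = sub.sort_values("tss")["gene_id"].to_numpy()
        m = (peaks["chrom"] == chrom).to_numpy()
        s = peaks.loc[m, "summit"].to_numpy()
        k = np.clip(np.searchsorted(t, s), 1, len(t) - 1) if len(t) > 1 else np.zeros(m.sum(), int)
        left, right = np.abs(s - t[k - 1]) if len(t) > 1 else np.abs(s - t[0]), np.abs(s - t[k])
        best = np.where(left <= right, k - 1, k) if len(t) > 1 else np.zeros(m.sum(), int)
        gid[m] = names[best]
        dist[m] = np.abs(s - t[best])
    gid[dist > max_dist] = None
    return gid, dist


def generate_truth(config: SimConfig, annotation: Annotation,
                   peaks: pd.DataFrame) -> pd.DataFrame:
    """Flag a fraction of distal peaks with an ancestry effect.

    Each flagged peak gets a score channel (atac / chip / hic), an ancestry
    sign (which ancestry the effect raises) and a target gene (nearest TSS
    within 400 kb) used for the hic bin-pair effect and for DE coupling.
    """
    rng = _rng(config, "truth")
    gid, dist = _nearest_gene(peaks, annotation.tss)
    eligible = peaks.index[(~peaks["is_promoter_peak"]) & pd.notna(gid)
                           & (dist <= 150_000)].to_numpy()
    n_flag = int(round(config.effect_fraction * len(peaks)))
    n_flag = min(n_flag, len(eligible))
    chosen = rng.choice(eligible, size=n_flag, replace=False) if n_flag else np.array([], int)
    chosen = np.sort(chosen)
    channels = np.array(["atac", "chip", "hic"])[np.arange(n_flag) % 3]
    signs = rng.choice(["AFR", "EUR"], size=n_flag)
    truth = pd.DataFrame({
        "peak_id": peaks.loc[chosen, "peak_id"].to_numpy(),
        "chrom": peaks.loc[chosen, "chrom"].to_numpy(),
        "summit": peaks.loc[chosen, "summit"].to_numpy(),
        "channel": channels,
        "sign": signs,
        "gene_id": gid[chosen],
    })
    truth["gene_tss"] = truth["gene_id"].map(annotation.tss.set_index("gene_id")["tss"])
    truth["bin_e"] = truth["summit"] // BIN_SIZE
    truth["bin_g"] = truth["gene_tss"] // BIN_SIZE
    return truth


def generate_atac(config: SimConfig, annotation: Annotation, peaks: pd.DataFrame,
                  truth: pd.DataFrame) -> pd.DataFrame:
    """Per-sample negative-binomial peak counts with injected atac effects.

    Counts ~ NB(mean, dispersion) around a lognormal per-peak baseline;
    peaks flagged on the atac channel have their mean multiplied by
    2**effect_log2fc in the flagged ancestry.
    """
    rng = _rng(config, "atac")
    design = config.design()
    base = config.read_depth_mean * rng.lognormal(-0.125, 0.5, size=len(peaks))
    base = base * np.where(peaks["is_promoter_peak"], config.promoter_boost, 1.0)
    mult = {"AFR": np.ones(len(peaks)), "EUR": np.ones(len(peaks))}
    atac_truth = truth[truth["channel"] == "atac"]
    pos = peaks.set_index("peak_id").index.get_indexer(atac_truth["peak_id"])
    for p, sign in zip(pos, atac_truth["sign"]):
        mult[sign][p] *= 2.0 ** config.effect_log2fc
    depth = rng.lognormal(0.0, config.sample_depth_sd, size=len(design))
    k = config.nb_dispersion
    cols = {}
    for (_, row), d in zip(design.iterrows(), depth):
        mu = base * mult[row["ancestry"]] * d
        cols[row["sample"]] = rng.negative_binomial(k, k / (k + mu))
    return pd.DataFrame(cols, index=peaks["peak_id"])


def _anchor_enrichment(config: SimConfig, annotation: Annotation,
                       peaks: pd.DataFrame) -> dict:
    """Per-chrom baseline bin enrichment from peak and promoter anchors."""
    enr = {c: np.ones(-(-size // BIN_SIZE))
           for c, size in annotation.chrom_sizes.items()}
    for _, p in peaks.iterrows():
        b = p["summit"] // BIN_SIZE
        boost = config.promoter_contact_boost if p["is_promoter_peak"] \
            else config.element_contact_boost
        enr[p["chrom"]][b] = max(enr[p["chrom"]][b], boost)
    return enr


def generate_hichip(config: SimConfig, annotation: Annotation, peaks: pd.DataFrame,
                    truth: pd.DataFrame) -> dict:
    """Per-sample sparse symmetric 5-kb contact maps (upper triangle).

    Expected counts decay exponentially with distance and are boosted at
    bins holding active elements.  Counts are gamma-Poisson: each library
    draws a per-bin visibility factor (mean 1, CV
    ``contact_overdispersion_cv``) multiplying both anchors, the standard
    overdispersion model for proximity-ligation counts.  chip-channel
    effects multiply the anchor bin's enrichment (hence its whole marginal)
    in the flagged ancestry; hic-channel effects multiply the single
    element-promoter bin pair.  Truth-flagged element-gene bin pairs get a
    floor on the expected count and a minimum of one observed contact so
    every injected pair remains observable in every sample.
    """
    rng = _rng(config, "hichip")
    design = config.design()
    enr = _anchor_enrichment(config, annotation, peaks)
    eff = 2.0 ** config.effect_log2fc

    # chip-channel effects scale a bin's whole marginal: multiply every pair
    # touching the bin by the factor, the diagonal once (not squared)
    chip_mult = {anc: {c: np.ones_like(v) for c, v in enr.items()}
                 for anc in ("AFR", "EUR")}
    for _, t in truth[truth["channel"] == "chip"].iterrows():
        chip_mult[t["sign"]][t["chrom"]][t["bin_e"]] *= eff

    max_off = config.max_contact_distance // BIN_SIZE
    flagged = truth.assign(lo=np.minimum(truth["bin_e"], truth["bin_g"]),
                           hi=np.maximum(truth["bin_e"], truth["bin_g"]))

    # per-ancestry expected-count arrays, chromosome by chromosome
    lam, index, fpos = {}, {}, {}
    for chrom, size in annotation.chrom_sizes.items():
        n_bins = -(-size // BIN_SIZE)
        offs = np.arange(0, min(max_off, n_bins - 1) + 1)
        starts = np.concatenate([[0], np.cumsum(n_bins - offs)[:-1]])
        i = np.concatenate([np.arange(n_bins - o) for o in offs])
        j = np.concatenate([np.arange(n_bins - o) + o for o in offs])
        decay = np.concatenate([
            np.full(n_bins - o, config.contact_depth
                    * np.exp(-config.contact_decay_rate * o * BIN_SIZE))
            for o in offs
        ])
        index[chrom] = (n_bins, i, j)
        fsub = flagged[flagged["chrom"] == chrom]
        fpos[chrom] = (starts[(fsub["hi"] - fsub["lo"]).to_numpy()]
                       + fsub["lo"].to_numpy())
        for anc in ("AFR", "EUR"):
            e = enr[chrom]
            m = chip_mult[anc][chrom]
            l = decay * e[i] * e[j] * m[i] * m[j]
            l[:n_bins] /= m  # diagonal touched the bin once, not twice
            hic_rows = fsub[fsub["channel"] == "hic"]
            hpos = (starts[(hic_rows["hi"] - hic_rows["lo"]).to_numpy()]
                    + hic_rows["lo"].to_numpy())
            l[hpos[(hic_rows["sign"] == anc).to_numpy()]] *= eff
            lam[(anc, chrom)] = l

    depth = rng.lognormal(0.0, config.sample_depth_sd, size=len(design))
    cv = config.contact_overdispersion_cv
    out = {}
    for (_, row), d in zip(design.iterrows(), depth):
        frames = []
        for chrom in annotation.chrom_sizes:
            n_bins, i, j = index[chrom]
            l = lam[(row["ancestry"], chrom)] * d
            if cv > 0:
                vis = rng.gamma(shape=1.0 / cv**2, scale=cv**2, size=n_bins)
                l = l * vis[i] * vis[j]
            l[fpos[chrom]] = np.maximum(l[fpos[chrom]], 3.0)  # injected pairs stay observable
            counts = rng.poisson(l)
            counts[fpos[chrom]] = np.maximum(counts[fpos[chrom]], 1)
            nz = counts > 0
            frames.append(pd.DataFrame({"chrom": chrom,
                                        "i": i[nz].astype(np.int32),
                                        "j": j[nz].astype(np.int32),
                                        "count": counts[nz].astype(np.int32)}))
        sdf = pd.concat(frames, ignore_index=True)
        sdf["chrom"] = sdf["chrom"].astype("category")
        out[row["sample"]] = sdf
    return out


def generate_blacklist(config: SimConfig, annotation: Annotation,
                       n_per_chrom: int = 3, width: int = 2000) -> pd.DataFrame:
    """A few artifact intervals per chromosome, away from nothing special."""
    rng = _rng(config, "blacklist")
    rows = []
    for chrom, size in annotation.chrom_sizes.items():
        for s in rng.integers(0, size - width, size=n_per_chrom):
            rows.append({"chrom": chrom, "start": int(s), "end": int(s) + width})
    return pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)


def generate_variants_and_qtl(config: SimConfig, cre_hint: pd.DataFrame,
                              truth: pd.DataFrame):
    """Biallelic variants with per-population genotype tallies, plus QTL.

    Allele frequencies follow a Balding-Nichols model: a shared ancestral
    frequency and per-ancestry draws with divergence F = divergence_param
    (F = 0 collapses to identical frequencies).  Population genotype counts
    are Hardy-Weinberg multinomials of ``diploids_per_population``.  A
    fraction of in-element variants are labelled bQTL for a named TF (or
    H3K4me3) with a QTL P-value and a high-affinity allele; in truth-flagged
    elements the high-affinity allele is forced to the truth ancestry's
    higher-frequency allele with probability ``coupling`` (otherwise chosen
    at random).
    """
    rng = _rng(config, "variants")
    chroms = cre_hint["chrom"].unique().tolist()
    sizes = {c: int(cre_hint.loc[cre_hint["chrom"] == c, "end"].max() + 10_000)
             for c in chroms}

    # guaranteed variant inside each truth-flagged element, rest uniform
    rows = [{"chrom": t["chrom"], "pos": int(t["summit"] + rng.integers(-100, 101)),
             "in_flagged": True, "peak_id": t["peak_id"], "sign": t["sign"]}
            for _, t in truth.iterrows()]
    for _ in range(max(config.n_variants - len(rows), 0)):
        chrom = chroms[rng.integers(0, len(chroms))]
        rows.append({"chrom": chrom, "pos": int(rng.integers(0, sizes[chrom])),
                     "in_flagged": False, "peak_id": None, "sign": None})
    var = pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    var["variant_id"] = [f"V{i + 1:06d}" for i in range(len(var))]

    F = config.divergence_param
    p_anc = rng.uniform(0.05, 0.95, size=len(var))
    freqs = {}
    for anc in ("AFR", "EUR"):
        if F == 0:
            freqs[anc] = p_anc.copy()
        else:
            a, b = p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F
            freqs[anc] = rng.beta(a, b)
    design = config.design()
    n_dip = config.diploids_per_population
    for pop, anc in config.populations:
        q = freqs[anc]
        geno = np.array([rng.multinomial(n_dip, [(1 - x) ** 2, 2 * x * (1 - x), x**2])
                         for x in q])
        var[f"n_{pop}"] = n_dip
        var[f"ac_{pop}"] = 2 * geno[:, 2] + geno[:, 1]
        var[f"het_{pop}"] = geno[:, 1]
    # pooled ancestry sample frequencies of the alternate allele
    for anc in ("AFR", "EUR"):
        pops = [p for p, a in config.populations if a == anc]
        var[f"alt_af_{anc}"] = (
            sum(var[f"ac_{p}"] for p in pops) / (2 * n_dip * len(pops)))

    # QTL labelling: variants inside candidate elements
    inside = np.zeros(len(var), dtype=bool)
    for chrom, sub in cre_hint.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        st, en = sub["start"].to_numpy(), sub["end"].to_numpy()
        m = (var["chrom"] == chrom).to_numpy()
        pos = var.loc[m, "pos"].to_numpy()
        k = np.searchsorted(st, pos, side="right") - 1
        inside[m] = (k >= 0) & (pos < en[np.clip(k, 0, len(en) - 1)])
    is_qtl = inside & ((rng.uniform(size=len(var)) < config.bqtl_fraction)
                       | var["in_flagged"].to_numpy())
    q = var[is_qtl].copy()
    q["qtl_type"] = rng.choice(_TF_NAMES, size=len(q))
    q["qtl_p"] = 10.0 ** (-rng.uniform(2, 10, size=len(q)))
    high = rng.choice(["ref", "alt"], size=len(q))
    force = q["in_flagged"].to_numpy() & (rng.uniform(size=len(q)) < config.coupling)
    sign = q["sign"].to_numpy()
    altA, altE = q["alt_af_AFR"].to_numpy(), q["alt_af_EUR"].to_numpy()
    for r in np.flatnonzero(force):
        hi_anc, lo_anc = (altA[r], altE[r]) if sign[r] == "AFR" else (altE[r], altA[r])
        if hi_anc == lo_anc:
            continue  # indistinguishable frequencies: leave the random draw
        high[r] = "alt" if hi_anc > lo_anc else "ref"
    q["high_affinity_allele"] = high
    q["af_AFR"] = np.where(high == "alt", altA, 1 - altA)
    q["af_EUR"] = np.where(high == "alt", altE, 1 - altE)
    qtl = q[["variant_id", "chrom", "pos", "qtl_type", "qtl_p",
             "high_affinity_allele", "af_AFR", "af_EUR", "peak_id", "in_flagged"]]
    return var.drop(columns=["in_flagged", "peak_id", "sign"]), qtl.reset_index(drop=True)


def generate_de_tables(config: SimConfig, annotation: Annotation, truth: pd.DataFrame,
                       n_contexts: int | None = None) -> dict:
    """Per-context ancestry-DE tables (gene, sign, LFSR).

    Genes targeted by truth-flagged elements are DE (LFSR < 0.05) with sign
    equal to the injected ancestry with probability ``de_match_prob``
    (flipped otherwise); all other genes draw a null LFSR >= 0.05.
    """
    rng = _rng(config, "de")
    n_contexts = n_contexts if n_contexts is not None else config.n_contexts
    m = config.de_match_prob if config.de_match_prob is not None else config.coupling
    flagged = truth.dropna(subset=["gene_id"]).drop_duplicates("gene_id")
    sign_of = dict(zip(flagged["gene_id"], flagged["sign"]))
    out = {}
    for ctx in range(n_contexts):
        genes = annotation.tss["gene_id"]
        lfsr = rng.uniform(0.05, 1.0, size=len(genes))
        sign = rng.choice(["AFR", "EUR"], size=len(genes))
        df = pd.DataFrame({"gene_id": genes, "sign": sign, "lfsr": lfsr})
        hit = df["gene_id"].isin(sign_of)
        df.loc[hit, "lfsr"] = rng.uniform(0.0, 0.05, size=int(hit.sum()))
        truth_sign = df.loc[hit, "gene_id"].map(sign_of)
        flip = rng.uniform(size=int(hit.sum())) >= m
        other = np.where(truth_sign == "AFR", "EUR", "AFR")
        df.loc[hit, "sign"] = np.where(flip, other, truth_sign)
        out[f"context_{ctx + 1:02d}"] = df
    return out


def simulate_all(config: SimConfig, cre_hint: pd.DataFrame | None = None) -> SimData:
    """Generate the full input bundle for one configuration."""
    ann = generate_annotation(config)
    peaks = place_peaks(config, ann)
    truth = generate_truth(config, ann, peaks)
    counts = generate_atac(config, ann, peaks, truth)
    contacts = generate_hichip(config, ann, peaks, truth)
    blacklist = generate_blacklist(config, ann)
    if cre_hint is None:
        cre_hint = pd.DataFrame({
            "chrom": peaks["chrom"],
            "start": np.maximum(peaks["summit"] - 250, 0),
            "end": peaks["summit"] + 250,
        })
    variants, qtl = generate_variants_and_qtl(config, cre_hint, truth)
    de = generate_de_tables(config, ann, truth)
    return SimData(config=config, annotation=ann, peaks=peaks, counts=counts,
                   blacklist=blacklist, contacts=contacts, truth=truth,
                   variants=variants, qtl=qtl, de=de)
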