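"""Per-site Weir-Cockerham F_ST and the selection-style comparisons.

Shows the two analytic anchor values (fixed difference -> 1, identical
frequencies -> 0), then computes per-site F_ST on synthetic
Balding-Nichols variants and compares diff- vs non-diff-element variants
with one-sided Wilcoxon tests inside allele-frequency decile bins.
"""

import numpy as np

from diffabc import SimConfig, simulate_all, run_pipeline
from diffabc import enrichment as en
from diffabc import popgen as pg

print("analytic anchors:")
print("  fixed difference (50+50 diploids) ->",
      pg.weir_cockerham_fst(50, 0, 0, 50, 100, 0))
print("  identical genotype counts         ->",
      pg.weir_cockerham_fst(50, 20, 16, 50, 20, 16))

cfg = SimConfig(n_chroms=4, chrom_length=12_000_000, n_genes=140,
                n_peaks_per_ancestry=900, effect_fraction=0.2,
                divergence_param=0.1, n_variants=2500, seed=9)
sim = simulate_all(cfg)
res = run_pipeline(sim, with_fdr=False)

var = pg.pooled_fst(sim.variants, sim.design)
var = pg.assign_variants_to_cres(var, res.cres)
in_cre = var.dropna(subset=["cre_id"])
thr = pg.fst_quantile_threshold(in_cre["fst"], 0.95)
print(f"\n{len(var)} variants, {len(in_cre)} inside elements; "
      f"mean F_ST {var['fst'].mean():.3f}; top-5% threshold {thr:.3f}")

cre_diff = en.cre_level_diff(res.diff["atac"]).set_index("cre_id")
in_cre = in_cre.assign(
    status=in_cre["cre_id"].map(
        lambda c: "diff" if c in cre_diff.index and cre_diff.loc[c, "diff_flag"]
        else ("nondiff" if c in cre_diff.index and cre_diff.loc[c, "nondiff_flag"]
              else None)))
scored = in_cre.dropna(subset=["status"])
d_f = scored.loc[scored["status"] == "diff", "fst"]
n_f = scored.loc[scored["status"] == "nondiff", "fst"]
p = pg.wilcoxon_compare(d_f, n_f)
print(f"diff-element variants: n={len(d_f)}, mean F_ST {d_f.mean():.3f}")
print(f"non-diff variants    : n={len(n_f)}, mean F_ST {n_f.mean():.3f}")
print(f"one-sided Wilcoxon (diff > non-diff) P = {p:.3f}")

qdf = scored.assign(mean_af=(scored["af_AFR"] + scored["af_EUR"]) / 2,
                    is_diff=scored["status"] == "diff")
bins = pg.decile_binned_tests(qdf)
print("\nallele-frequency decile bins (controls frequency confounding):")
print(bins.round(3).to_string(index=False))
print("\nUnder the default generator both groups share one divergence level, so")
print("bin-level P-values should be unremarkable; injected ancestry-coupled")
print("variants in flagged elements can tilt individual bins.")
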