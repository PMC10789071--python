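"""Generator contracts: determinism, injected effects, coupling, conservation."""

import numpy as np
import pandas as pd
import pytest

from conftest import tiny_config
from diffabc import SimConfig
from diffabc import simulate as sm
from diffabc import hicio


class TestConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(effect_fraction=1.5)
        with pytest.raises(ValueError):
            SimConfig(n_genes=0)
        with pytest.raises(ValueError):
            SimConfig(divergence_param=-0.1)

    def test_default_design_is_14_samples(self):
        d = SimConfig().design()
        assert len(d) == 14
        assert (d["ancestry"] == "AFR").sum() == 8
        assert (d["ancestry"] == "EUR").sum() == 6


class TestAnnotation:
    def test_count_range_and_spacing(self):
        cfg = tiny_config(n_genes=50, n_chroms=1, chrom_length=10_000_000)
        ann = sm.generate_annotation(cfg)
        assert len(ann.tss) == 50
        assert ann.tss["tss"].between(0, 10_000_000).all()
        gaps = np.diff(np.sort(ann.tss["tss"].to_numpy()))
        assert (gaps >= sm.MIN_TSS_SPACING).all()

    def test_determinism(self):
        cfg = tiny_config()
        a = sm.generate_annotation(cfg)
        b = sm.generate_annotation(cfg)
        pd.testing.assert_frame_equal(a.tss, b.tss)

    def test_infeasible_spacing_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            sm.generate_annotation(tiny_config(n_genes=200, n_chroms=1,
                                               chrom_length=1_000_000))


class TestAtac:
    def test_null_log_ratio_centered_at_zero(self):
        # depth factors cancel only after normalization, so hold them fixed
        cfg = tiny_config(effect_fraction=0.0, n_peaks_per_ancestry=400,
                          sample_depth_sd=0.0)
        sim = sm.simulate_all(cfg)
        d = cfg.design()
        afr = d[d["ancestry"] == "AFR"]["sample"]
        eur = d[d["ancestry"] == "EUR"]["sample"]
        lr = np.log2(sim.counts[afr].mean(1) + 1) - np.log2(sim.counts[eur].mean(1) + 1)
        assert abs(lr.mean()) < 0.05

    def test_injected_fold_change_recovered(self):
        """Monte-Carlo mean of the generative model: flagged peaks show an
        AFR/EUR expected-count ratio of 2^effect_log2fc."""
        cfg = tiny_config(n_peaks_per_ancestry=1500, effect_fraction=0.6,
                          effect_log2fc=1.0, n_genes=60,
                          n_chroms=4, chrom_length=8_000_000, seed=21)
        sim = sm.simulate_all(cfg)
        tr = sim.truth[sim.truth["channel"] == "atac"]
        assert len(tr) >= 100
        d = cfg.design()
        afr = d[d["ancestry"] == "AFR"]["sample"]
        eur = d[d["ancestry"] == "EUR"]["sample"]
        counts = sim.counts.loc[tr["peak_id"]]
        ratio = counts[afr].mean(1) / counts[eur].mean(1)
        sign = tr.set_index("peak_id")["sign"]
        oriented = np.where(sign == "AFR", ratio, 1 / ratio)
        assert np.mean(oriented) == pytest.approx(2.0, rel=0.1)

    def test_counts_deterministic(self):
        cfg = tiny_config()
        sim1 = sm.simulate_all(cfg)
        sim2 = sm.simulate_all(cfg)
        pd.testing.assert_frame_equal(sim1.counts, sim2.counts)
        s = cfg.samples[0]
        pd.testing.assert_frame_equal(sim1.contacts[s], sim2.contacts[s])
        pd.testing.assert_frame_equal(sim1.variants, sim2.variants)


class TestHichip:
    def test_written_totals_conserved(self, tmp_path, tiny_bundle):
        """HiC-Pro round trip preserves every triplet and the total count."""
        sim = tiny_bundle.sim
        s = tiny_bundle.cfg.samples[0]
        cm = sim.contacts[s]
        prefix = tmp_path / "rep"
        hicio.write_hicpro(cm, sim.annotation.chrom_sizes, prefix)
        back = hicio.read_hicpro(f"{prefix}.matrix", f"{prefix}_abs.bed")
        assert back["count"].sum() == cm["count"].sum()
        key = lambda df: df.assign(chrom=df["chrom"].astype(str)).sort_values(
            ["chrom", "i", "j"]).reset_index(drop=True)[["chrom", "i", "j", "count"]]
        a, b = key(cm), key(back)
        pd.testing.assert_frame_equal(a, b.astype(a.dtypes))

    def test_flat_profile_when_decay_vanishes(self):
        cfg = tiny_config(contact_decay_rate=1e-12, contact_depth=5.0,
                          max_contact_distance=300_000, n_peaks_per_ancestry=30,
                          effect_fraction=0.0)
        sim = sm.simulate_all(cfg)
        cm = sim.contacts[cfg.samples[0]]
        d = (cm["j"] - cm["i"]).to_numpy()
        # mean count at short vs long range indistinguishable
        near = cm.loc[d <= 20, "count"].mean()
        far = cm.loc[d >= 40, "count"].mean()
        assert near == pytest.approx(far, rel=0.05)

    def test_chip_effect_multiplies_bin_marginal(self):
        cfg = tiny_config(n_peaks_per_ancestry=1200, effect_fraction=0.3,
                          effect_log2fc=1.0, n_genes=60, n_chroms=4,
                          chrom_length=8_000_000, seed=23,
                          contact_overdispersion_cv=0.0, sample_depth_sd=0.0)
        sim = sm.simulate_all(cfg)
        tr = sim.truth[sim.truth["channel"] == "chip"]
        assert len(tr) >= 100
        from diffabc.scoring import bin_totals
        d = cfg.design()
        totals = {}
        for anc in ("AFR", "EUR"):
            cols = d[d["ancestry"] == anc]["sample"]
            per = [bin_totals(sim.contacts[s]) for s in cols]
            totals[anc] = pd.concat(per, axis=1).fillna(0).mean(1)
        ratios = []
        for _, t in tr.iterrows():
            k = f"{t['chrom']}:{t['bin_e']}"
            if k in totals["AFR"].index and k in totals["EUR"].index:
                r = totals["AFR"][k] / totals["EUR"][k]
                ratios.append(r if t["sign"] == "AFR" else 1 / r)
        assert len(ratios) >= 100
        # multiplicative effect -> estimate on the log scale (the arithmetic
        # mean is upward-biased by the diagonal term and neighbouring flags)
        assert np.mean(np.log2(ratios)) == pytest.approx(1.0, abs=0.15)

    def test_flagged_pairs_have_contacts_everywhere(self, tiny_bundle):
        sim = tiny_bundle.sim
        for s in tiny_bundle.cfg.samples:
            cm = sim.contacts[s].set_index(["chrom", "i", "j"])
            for _, t in sim.truth.iterrows():
                lo, hi = sorted((t["bin_e"], t["bin_g"]))
                assert cm.loc[(t["chrom"], lo, hi), "count"] >= 1


class TestVariantsAndQtl:
    def test_zero_divergence_equal_frequencies(self):
        cfg = tiny_config(divergence_param=0.0, n_variants=2000)
        sim = sm.simulate_all(cfg)
        gap = (sim.variants["alt_af_AFR"] - sim.variants["alt_af_EUR"]).abs()
        assert gap.mean() < 0.05  # sampling noise only

    def test_full_coupling_forces_direction_match(self, tiny_bundle):
        sim = tiny_bundle.sim
        q = sim.qtl[sim.qtl["in_flagged"]]
        sign = sim.truth.set_index("peak_id")["sign"]
        informative = q[q["af_AFR"] != q["af_EUR"]]
        hi_anc = np.where(informative["af_AFR"] > informative["af_EUR"], "AFR", "EUR")
        assert (hi_anc == sign[informative["peak_id"]].to_numpy()).all()

    def test_genotype_tallies_consistent(self, tiny_bundle):
        v = tiny_bundle.sim.variants
        for pop, _ in tiny_bundle.cfg.populations:
            assert (v[f"ac_{pop}"] <= 2 * v[f"n_{pop}"]).all()
            assert (v[f"het_{pop}"] <= v[f"ac_{pop}"]).all()


class TestDeTables:
    def test_full_match_probability(self, tiny_bundle):
        sim = tiny_bundle.sim
        flagged = sim.truth.dropna(subset=["gene_id"]).drop_duplicates("gene_id")
        sign = dict(zip(flagged["gene_id"], flagged["sign"]))
        de = sim.de["context_01"]
        hit = de[de["gene_id"].isin(sign)]
        assert (hit["lfsr"] < 0.05).all()
        assert (hit["sign"] == hit["gene_id"].map(sign)).all()

    def test_half_match_probability(self):
        cfg = tiny_config(de_match_prob=0.5, effect_fraction=0.8,
                          n_peaks_per_ancestry=1000, n_genes=300,
                          n_chroms=4, chrom_length=12_000_000, seed=31)
        ann = sm.generate_annotation(cfg)
        peaks = sm.place_peaks(cfg, ann)
        truth = sm.generate_truth(cfg, ann, peaks)
        de = sm.generate_de_tables(cfg, ann, truth, n_contexts=1)["context_01"]
        flagged = truth.dropna(subset=["gene_id"]).drop_duplicates("gene_id")
        assert len(flagged) >= 200
        sign = dict(zip(flagged["gene_id"], flagged["sign"]))
        hit = de[de["gene_id"].isin(sign)]
        match = (hit["sign"] == hit["gene_id"].map(sign)).mean()
        assert match == pytest.approx(0.5, abs=0.08)

    def test_no_flagged_genes_no_de(self):
        cfg = tiny_config(effect_fraction=0.0)
        ann = sm.generate_annotation(cfg)
        peaks = sm.place_peaks(cfg, ann)
        truth = sm.generate_truth(cfg, ann, peaks)
        de = sm.generate_de_tables(cfg, ann, truth, n_contexts=1)["context_01"]
        assert (de["lfsr"] >= 0.05).all()
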