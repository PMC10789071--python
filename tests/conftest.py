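"""Shared fixtures: one small structural bundle and two full-scale runs.

The two full-scale runs (an effect run with injected ancestry effects and a
null run with none) are expensive (~40 s each), so they are session-scoped
and slimmed after the pipeline finishes: contact maps and unused score
columns are dropped to keep the peak footprint modest.
"""

from __future__ import annotations

import warnings
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from diffabc import SimConfig, simulate_all, run_pipeline, truth_pair_map
from diffabc import popgen as pg

warnings.filterwarnings("ignore", message="only .* peaks available")


def tiny_config(**kw) -> SimConfig:
    base = dict(
        n_chroms=2, chrom_length=6_000_000, n_genes=24,
        n_peaks_per_ancestry=220, n_variants=500, n_contexts=2, seed=11,
    )
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def tiny_bundle():
    cfg = tiny_config()
    sim = simulate_all(cfg)
    res = run_pipeline(sim, fdr_seed=11)
    return SimpleNamespace(cfg=cfg, sim=sim, res=res)


def _slim_scores(scores: pd.DataFrame) -> pd.DataFrame:
    keep = ["pair_id", "gene_id", "sample", "A", "Q", "C",
            "chip_num", "hic_num", "abc", "atac", "chip", "hic"]
    return scores[keep]


@pytest.fixture(scope="session")
def effect_bundle():
    """Full-scale run under the default study conditions (injected effects,
    coupling = 1), plus the truth-to-pair map and QTL table with F_ST."""
    cfg = SimConfig(seed=1)
    sim = simulate_all(cfg)
    res = run_pipeline(sim, fdr_seed=1)
    tm = truth_pair_map(sim, res)
    var = pg.pooled_fst(sim.variants, sim.design)
    var = pg.assign_variants_to_cres(var, res.cres)
    qtl = sim.qtl.merge(var[["variant_id", "cre_id", "fst"]],
                        on="variant_id", how="left")
    res.scores = _slim_scores(res.scores)
    sim.contacts = None
    return SimpleNamespace(cfg=cfg, sim=sim, res=res, tm=tm, var=var, qtl=qtl)


@pytest.fixture(scope="session")
def null_bundle():
    """Full-scale run with no injected effects and no allele divergence."""
    cfg = SimConfig(seed=2, effect_fraction=0.0, divergence_param=0.0)
    sim = simulate_all(cfg)
    res = run_pipeline(sim, fdr_seed=2)
    var = pg.pooled_fst(sim.variants, sim.design)
    res.scores = None
    sim.contacts = None
    return SimpleNamespace(cfg=cfg, sim=sim, res=res, var=var)
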