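"""Simulation configuration for the synthetic pipeline inputs."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["SimConfig", "DEFAULT_POPULATIONS"]

# 14-sample design: four African and three European pooled populations,
# two replicates each (the post-CEU-removal design).
DEFAULT_POPULATIONS = (
    ("ESN", "AFR"), ("GWD", "AFR"), ("LWK", "AFR"), ("YRI", "AFR"),
    ("FIN", "EUR"), ("IBS", "EUR"), ("TSI", "EUR"),
)


@dataclass
class SimConfig:
    """Knobs of the synthetic data generator.

    Sizes are desk-scale defaults chosen to give a few thousand candidate
    element-gene pairs in well under a minute; the sample design mirrors
    the assayed 4 AFR + 3 EUR populations x 2 replicates.
    """

    n_chroms: int = 6
    chrom_length: int = 52_000_000          # bp per synthetic chromosome
    n_genes: int = 2184                     # TSS per genome, >=10 kb apart
    n_peaks_per_ancestry: int = 7000        # shared accessible-site universe
    populations: tuple = DEFAULT_POPULATIONS
    replicates_per_population: int = 2
    read_depth_mean: float = 100.0          # mean ATAC reads per distal peak
    nb_dispersion: float = 40.0             # negative-binomial size parameter
    promoter_boost: float = 3.0             # promoter peaks read-depth multiplier
    contact_depth: float = 20.0             # expected adjacent-bin contact count
    contact_decay_rate: float = 5e-5        # exponential decay, per bp
    max_contact_distance: int = 800_000     # sparsity horizon for contact draws
    element_contact_boost: float = 3.0      # H3K27ac enrichment at peak bins
    promoter_contact_boost: float = 5.0     # ... at TSS bins
    contact_overdispersion_cv: float = 0.15  # per-bin, per-library visibility CV
    sample_depth_sd: float = 0.2            # lognormal library-size sd (log scale)
    effect_fraction: float = 0.1            # fraction of peaks with ancestry effect
    effect_log2fc: float = 1.0
    divergence_param: float = 0.1           # Balding-Nichols F between ancestries
    n_variants: int = 3000
    bqtl_fraction: float = 0.4              # of in-CRE variants labelled as bQTL
    diploids_per_population: int = 50
    coupling: float = 1.0                   # P(bQTL / DE agree with injected effect)
    de_match_prob: float | None = None      # defaults to ``coupling``
    n_contexts: int = 22                    # cellular contexts with a DE table
    seed: int = 0

    def __post_init__(self):
        for name in ("n_chroms", "chrom_length", "n_genes", "n_peaks_per_ancestry",
                     "replicates_per_population", "n_variants", "diploids_per_population",
                     "n_contexts"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.effect_fraction <= 1:
            raise ValueError("effect_fraction must be in [0, 1]")
        if not 0 <= self.divergence_param <= 1:
            raise ValueError("divergence_param must be in [0, 1]")
        if not 0 <= self.coupling <= 1:
            raise ValueError("coupling must be in [0, 1]")

    @property
    def samples(self) -> list:
        return [f"{pop}_r{r + 1}"
                for pop, _ in self.populations
                for r in range(self.replicates_per_population)]

    def design(self):
        import pandas as pd
        rows = [
            {"sample": f"{pop}_r{r + 1}", "population": pop, "ancestry": anc,
             "replicate": r + 1}
            for pop, anc in self.populations
            for r in range(self.replicates_per_population)
        ]
        return pd.DataFrame(rows)
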