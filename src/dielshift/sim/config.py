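"""Simulation configuration and ground-truth bookkeeping."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dielshift.models import GeneModel, Interval

CONDITIONS = ("control", "HL", "HLUV")
TIMES = ("T0", "T1", "T2.5")
EXPERIMENTS = ("HL_experiment", "HLUV_experiment")


@dataclass
class SimConfig:
    """Knobs of the synthetic experiment.

    Defaults emulate the study conditions at desk scale: a 20 kb
    chloroplast (stand-in for the real 73 kb genome) holding ~30 gene
    features, half of all reads mapping to it, 90% of nuclear reads
    within 8 read lengths of the transcript 3' end, and negative-
    binomial replicate noise with stable housekeeping genes.
    """

    seed: int = 0
    chloroplast_length: int = 20_000
    nuclear_length: int = 96_000
    n_chloro_genes: int = 28          # protein genes, incl. the truncated one
    n_nuclear_genes: int = 30
    chloroplast_read_fraction: float = 0.5
    three_prime_bias: float = 0.9
    read_length: int = 50
    total_reads_per_sample: int = 100_000
    dispersion: float = 0.05          # NB: var = mu + phi * mu^2
    hk_dispersion: float = 0.002      # housekeeping genes are stable
    replicates: int = 3
    diel_amplitude: float = 0.3       # max relative diel drift by T2.5
    # flow cytometry
    fcm_events_per_sample: int = 2000
    fcm_bead_fraction: float = 0.1
    fcm_bead_mean: float = 4000.0     # arbitrary units, constant across samples
    fcm_log_scale: float = 0.15       # lognormal sigma for event scatter
    # qPCR
    qpcr_ct_noise: float = 0.1        # SD of Gaussian Ct noise (cycles)
    qpcr_replicates: int = 4

    def __post_init__(self) -> None:
        for name in ("chloroplast_read_fraction", "three_prime_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "chloroplast_length", "nuclear_length", "read_length",
            "replicates", "fcm_events_per_sample", "qpcr_replicates",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_chloro_genes", "n_nuclear_genes",
                     "total_reads_per_sample"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.dispersion < 0 or self.hk_dispersion < 0:
            raise ValueError("dispersion must be nonnegative")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-stream substream of the global seed."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        return np.random.default_rng(ss)


_STREAMS = {
    "genome": 0,
    "alignments": 1,
    "fcm": 2,
    "growth": 3,
    "qpcr": 4,
    "effects": 5,
}


def default_design(replicates: int = 3) -> pd.DataFrame:
    """Sample design table: two experiments, each with controls at
    T0/T1/T2.5 and the treatment at T1/T2.5, n biological replicates."""
    rows = []
    for exp, treat in zip(EXPERIMENTS, ("HL", "HLUV")):
        for cond, times in (("control", TIMES), (treat, ("T1", "T2.5"))):
            for t in times:
                for r in range(1, replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"{exp}.{cond}.{t}.r{r}",
                            "experiment": exp,
                            "condition": cond,
                            "time": t,
                            "replicate": r,
                        }
                    )
    return pd.DataFrame(rows)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    design: pd.DataFrame
    genes: list[GeneModel]
    # per-gene relative fold factor per (condition, time); housekeeping = 1
    fold_map: dict[str, dict[tuple[str, str], float]]
    # expected read count per gene (and planted ORF) per sample
    expected_counts: pd.DataFrame
    # spans used for read placement (true gene extents, incl. extensions)
    true_spans: dict[str, tuple[str, Interval]]
    novel_orfs: list[dict] = field(default_factory=list)
    truncated_genes: dict[str, dict] = field(default_factory=dict)
    identical_pairs: list[tuple[str, str]] = field(default_factory=list)
    convergent_pairs: list[tuple[str, str]] = field(default_factory=list)
    mu_by_irradiance: dict[float, float] = field(default_factory=dict)
    qpcr_true_folds: dict[str, dict[tuple[str, str], float]] = field(
        default_factory=dict
    )

    def fold_factor(self, gene_id: str, condition: str, time: str) -> float:
        return self.fold_map.get(gene_id, {}).get((condition, time), 1.0)

    def true_contrast_fold(
        self,
        gene_id: str,
        group_a: tuple[str, str],
        group_b: tuple[str, str],
    ) -> float:
        """True signed fold of group A over group B (normalized scale)."""
        ra = self.fold_factor(gene_id, *group_a)
        rb = self.fold_factor(gene_id, *group_b)
        r = ra / rb
        return r if r >= 1 else -1.0 / r
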