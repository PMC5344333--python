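"""Simulated read alignments with negative-binomial replicate noise.

Libraries are non-directional: a strand is recorded for every read but
drawn at random, so the pipeline can be tested for correctly ignoring
it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from dielshift.io import ALIGNMENT_COLUMNS
from dielshift.models import GeneModel
from dielshift.sim.config import GroundTruth, SimConfig


def _nb_draw(rng: np.random.Generator, mean, dispersion: float) -> np.ndarray:
    """NB with var = mu + phi mu^2 (Poisson when phi = 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(n, p[pos])
    return out


def simulate_alignments(
    annotation: list[GeneModel],
    truth: GroundTruth,
    config: SimConfig,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Draw per-gene read totals and place reads on the references.

    Chloroplast reads fall uniformly over (true) gene spans; nuclear
    reads start within the last ``8 * read_length`` of the transcript
    3' end with probability ``three_prime_bias`` and uniformly over the
    gene span otherwise.  Returns a table with columns sample_id,
    read_id, reference, start, end, strand (0-based half-open).
    """
    rng = config.rng("alignments")
    rl = config.read_length
    by_id = {g.gene_id: g for g in annotation}
    hk_ids = {g.gene_id for g in annotation
              if g.housekeeping_role.value != "none"}
    expected = truth.expected_counts
    if samples is None:
        samples = list(expected.columns)

    frames = []
    for sample in samples:
        mu = expected[sample]
        phi = np.where([g in hk_ids for g in mu.index],
                       config.hk_dispersion, config.dispersion)
        counts = {
            g: int(_nb_draw(rng, np.array([m]), float(p))[0])
            for (g, m), p in zip(mu.items(), phi)
        }
        recs = []
        for gid, n in counts.items():
            if n == 0:
                continue
            contig, span = truth.true_spans[gid]
            gene = by_id.get(gid)
            lo, hi = span.start, max(span.start + 1, span.end - rl + 1)
            if gene is not None and gene.compartment.value == "nuclear":
                starts = _nuclear_starts(rng, gene, span, n, rl,
                                         config.three_prime_bias)
            else:
                starts = rng.integers(lo, hi, size=n)
            strands = rng.choice(np.array(["+", "-"]), size=n)
            recs.append((contig, starts, strands))
        if not recs:
            frames.append(pd.DataFrame(columns=["sample_id", *ALIGNMENT_COLUMNS]))
            continue
        contigs = np.concatenate([
            np.repeat(c, len(s)) for c, s, _ in recs
        ])
        starts = np.concatenate([s for _, s, _ in recs])
        strands = np.concatenate([st for _, _, st in recs])
        df = pd.DataFrame(
            {
                "sample_id": sample,
                "read_id": [f"{sample}.r{i}" for i in range(len(starts))],
                "reference": contigs,
                "start": starts.astype(np.int64),
                "end": starts.astype(np.int64) + rl,
                "strand": strands,
            }
        )
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out


def _nuclear_starts(rng, gene, span, n, rl, bias) -> np.ndarray:
    """3'-biased start positions: within 8 read lengths of the 3' end."""
    window = 8 * rl
    biased = rng.random(n) < bias
    starts = np.empty(n, dtype=np.int64)
    lo, hi = span.start, max(span.start + 1, span.end - rl + 1)
    starts[~biased] = rng.integers(lo, hi, size=int((~biased).sum()))
    k = int(biased.sum())
    if gene.strand == "+":
        blo = max(lo, span.end - window)
        bhi = max(blo + 1, span.end - rl + 1)
    else:  # 3' terminus is the reference start
        blo = span.start
        bhi = max(blo + 1, min(hi, span.start + window - rl + 1))
    starts[biased] = rng.integers(blo, bhi, size=k)
    return starts


def simulate_count_table(
    n_genes: int,
    true_fold: float | np.ndarray,
    n_per_group: int = 3,
    mean_count: float = 500.0,
    dispersion: float = 0.05,
    hk_mean: float = 100_000.0,
    hk_dispersion: float = 0.002,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Direct NB count table for two replicate groups plus a stable
    housekeeping row ('hk'); group B is the baseline, group A carries
    ``true_fold``.  Used for calibration and power studies."""
    rng = np.random.default_rng(seed)
    fold = np.broadcast_to(np.asarray(true_fold, dtype=float), (n_genes,))
    base = rng.lognormal(np.log(mean_count), 0.4, size=n_genes)
    cols_a = [f"A{r}" for r in range(1, n_per_group + 1)]
    cols_b = [f"B{r}" for r in range(1, n_per_group + 1)]
    data = {}
    for c in cols_a:
        data[c] = np.append(_nb_draw(rng, base * fold, dispersion),
                            _nb_draw(rng, np.array([hk_mean]), hk_dispersion))
    for c in cols_b:
        data[c] = np.append(_nb_draw(rng, base, dispersion),
                            _nb_draw(rng, np.array([hk_mean]), hk_dispersion))
    idx = [f"g{i}" for i in range(1, n_genes + 1)] + ["hk"]
    return pd.DataFrame(data, index=idx), cols_a, cols_b
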