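"""End-to-end pipeline runner: simulate -> quantify -> refine ->
differential expression -> cytometry -> qPCR -> report.

Every stage writes its outputs under the configured directory; a run
manifest records the package version, seed and a hash of the
configuration so identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

import dielshift
from dielshift import cytometry as cyt
from dielshift import diffexpr, io, qpcr, quantify, refine
from dielshift.models import Compartment
from dielshift.sim import (
    SimConfig,
    generate_genome_annotation,
    lightshift_fcm_params,
    simulate_alignments,
    simulate_fcm,
    simulate_growth,
    simulate_qpcr,
)

log = logging.getLogger("dielshift")


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full synthetic run."""

    outdir: str | Path = "dielshift_run"
    seed: int = 0
    min_reads: int = diffexpr.DEFAULT_MIN_READS
    min_fold: float = diffexpr.DEFAULT_MIN_FOLD
    alpha: float = diffexpr.DEFAULT_ALPHA
    min_depth: float = 5.0
    min_codons: int = 100
    log_scale: bool = True
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if self.min_reads < 0 or self.min_fold < 0 or self.min_depth < 0:
            raise ValueError("thresholds must be nonnegative")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        self.sim = dataclasses.replace(self.sim, seed=self.seed)

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                **{k: v for k, v in dataclasses.asdict(self).items()
                   if k != "outdir"},
            },
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the report bundle as a dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    # ----------------------------------------------------- simulate
    stage = "simulate"
    try:
        contigs, annotation, truth = generate_genome_annotation(config.sim)
        io.write_fasta(contigs, out / "genome.fasta")
        io.write_gff3(annotation, out / "annotation.gff3")
        aln = simulate_alignments(annotation, truth, config.sim)
        aln_to_tsv(aln, out / "alignments.tsv")
        truth.design.to_csv(out / "design.csv", index=False)
        fcm_events = simulate_fcm(lightshift_fcm_params(config.sim), config.sim)
        fcm_events.to_csv(out / "fcm_events.csv", index=False)
        growth = simulate_growth(truth.mu_by_irradiance, seed=config.seed)
        growth.to_csv(out / "growth.csv", index=False)
        plate = simulate_qpcr(truth.qpcr_true_folds, seed=config.seed,
                              ct_noise=config.sim.qpcr_ct_noise,
                              replicates=config.sim.qpcr_replicates)
        plate.records.to_csv(out / "qpcr_plate.csv", index=False)
        plate.dilution_series.to_csv(out / "qpcr_dilution.csv", index=False)
        io.write_json(_truth_summary(truth), out / "ground_truth.json")

        # --------------------------------------------------- quantify
        stage = "quantify"
        windows = {g.gene_id: quantify.derive_count_window(g)
                   for g in annotation}
        status, merge_groups = quantify.flag_exclusions(
            annotation, genome=contigs, windows=windows
        )
        counts = quantify.count_reads(aln, windows, status, merge_groups)
        counts.counts.to_csv(out / "counts.csv")
        norm = quantify.normalize(counts, annotation)
        norm.ratios.to_csv(out / "normalized.csv")

        # ----------------------------------------------------- refine
        stage = "refine"
        chloro_len = len(contigs["chloro"])
        coverage = refine.compute_coverage(
            aln[aln["reference"] == "chloro"], "chloro", chloro_len
        )
        ext_rows = []
        for g in annotation:
            if g.compartment is not Compartment.CHLOROPLAST or g.cds is None:
                continue
            res = refine.extend_cds(g, coverage, contigs, config.min_depth)
            ext_rows.append(
                {
                    "gene_id": g.gene_id,
                    "original_cds": f"{g.cds.start1}-{g.cds.end1}",
                    "extended": res.extended,
                    "extension_nt": res.extension_nt,
                    "flag": res.flag,
                }
            )
        extensions = pd.DataFrame(ext_rows)
        extensions.to_csv(out / "cds_extensions.csv", index=False)
        novel = refine.detect_novel_orfs(
            coverage, annotation, contigs,
            min_codons=config.min_codons, min_depth=config.min_depth,
        )
        novel_df = pd.DataFrame([dataclasses.asdict(o) for o in novel])
        novel_df.to_csv(out / "novel_orfs.csv", index=False)

        # ---------------------------------------------------- diffexp
        stage = "diffexp"
        de = diffexpr.run_framework(
            norm, truth.design, counts=counts,
            min_reads=config.min_reads, alpha=config.alpha,
            min_fold=config.min_fold, log_scale=config.log_scale,
        )
        de.to_csv(out / "differential_expression.csv", index=False)

        # -------------------------------------------------- cytometry
        stage = "cytometry"
        fcm_rows = []
        for sid, sub in fcm_events.groupby("sample_id"):
            s = cyt.bead_normalize(sub, channels=("fals", "red"))
            fcm_rows.append(
                {"sample_id": sid, **s.meta,
                 "fals_rel": s.bead_relative["fals"],
                 "red_rel": s.bead_relative["red"]}
            )
        fcm_summary = pd.DataFrame(fcm_rows).sort_values(
            ["condition", "time_h", "replicate"]
        )
        for col in ("fals_rel", "red_rel"):
            pct = []
            for cond, sub in fcm_summary.groupby("condition"):
                ref = sub.loc[sub["time_h"] == 0.0, col].mean()
                pct.append(pd.Series(
                    cyt.percent_change(sub[col], ref), index=sub.index))
            fcm_summary[f"{col}_pct_change"] = pd.concat(pct)
        fcm_summary.to_csv(out / "fcm_summary.csv", index=False)

        rate_rows = []
        for (irr, rep), sub in growth.groupby(["irradiance", "replicate"]):
            res = cyt.growth_rate(sub)
            rate_rows.append({"irradiance": irr, "replicate": rep,
                              "mu": res.mu_mean})
        rates = pd.DataFrame(rate_rows)
        curve = cyt.growth_vs_irradiance(rates)
        curve.table.assign(
            divisions_per_day=cyt.divisions_per_day(curve.table["mu_mean"])
        ).to_csv(out / "growth_rates.csv", index=False)

        # ------------------------------------------------------- qpcr
        stage = "qpcr"
        qpcr_rows, qpcr_sig = [], []
        eff_rows = []
        for target, sub in plate.dilution_series.groupby("target"):
            e = qpcr.efficiency(sub)
            eff_rows.append({"target": target, "slope": e.slope,
                             "efficiency": e.efficiency,
                             "r_squared": e.r_squared, "linear": e.linear})
        pd.DataFrame(eff_rows).to_csv(out / "qpcr_efficiency.csv", index=False)
        for target in sorted(truth.qpcr_true_folds):
            per_sample = qpcr.ddct_fold(plate, target)
            summary = qpcr.fold_summary(per_sample).assign(target=target)
            qpcr_rows.append(summary)
            multi = per_sample.groupby("time")["condition"].transform("nunique") > 1
            sig = qpcr.qpcr_significance(per_sample[multi], alpha=config.alpha)
            qpcr_sig.append(sig.assign(target=target))
        qpcr_table = pd.concat(qpcr_rows, ignore_index=True)
        qpcr_table.to_csv(out / "qpcr_folds.csv", index=False)
        pd.concat(qpcr_sig, ignore_index=True).to_csv(
            out / "qpcr_significance.csv", index=False
        )

        # ----------------------------------------------------- report
        stage = "report"
        manifest = {
            "package": "dielshift",
            "version": dielshift.__version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
        }
        io.write_json(manifest, out / "manifest.json")
        report = _render_report(de, curve, qpcr_table, extensions, novel_df)
        (out / "report.txt").write_text(report)
        bundle = {
            "annotation": annotation,
            "truth": truth,
            "counts": counts,
            "normalized": norm,
            "de": de,
            "extensions": extensions,
            "novel_orfs": novel,
            "fcm_summary": fcm_summary,
            "growth_curve": curve,
            "qpcr": qpcr_table,
            "manifest": manifest,
        }
    except Exception as exc:  # noqa: BLE001 - abort names the stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return bundle


def aln_to_tsv(aln: pd.DataFrame, path: Path) -> None:
    out = aln.copy()
    out["start"] = out["start"] + 1
    out.to_csv(path, sep="\t", index=False)


def _truth_summary(truth) -> dict:
    return {
        "novel_orfs": truth.novel_orfs,
        "truncated_genes": truth.truncated_genes,
        "identical_pairs": [list(p) for p in truth.identical_pairs],
        "convergent_pairs": [list(p) for p in truth.convergent_pairs],
        "mu_by_irradiance": {str(k): v
                             for k, v in truth.mu_by_irradiance.items()},
    }


def _render_report(de, curve, qpcr_table, extensions, novel_df) -> str:
    lines = ["dielshift run report", "=" * 40, ""]
    lines.append("Fold changes are ratios of group means of normalized "
                 "abundances (signed convention: -1/r for r < 1).")
    sig = de[de["significant"]]
    lines.append(f"significant DE records: {len(sig)} of {len(de)}")
    if len(sig):
        cats = sig["category"].value_counts().sort_index()
        lines.append("fold-change categories among significant records:")
        for cat, n in cats.items():
            lines.append(f"  {cat:>16}: {n}")
    lines.append("")
    lines.append("growth vs irradiance (mu d^-1):")
    for _, r in curve.table.iterrows():
        lines.append(
            f"  {r['irradiance']:>6g} umol photons m^-2 s^-1: "
            f"{r['mu_mean']:.2f} +/- {r['mu_se']:.2f}"
        )
    lines.append(f"  mu_max {curve.mu_max:.2f} d^-1 at "
                 f"{curve.argmax_irradiance:g} umol photons m^-2 s^-1")
    lines.append("")
    lines.append("qPCR fold changes (2^-ddCt, T0-control calibrator):")
    for _, r in qpcr_table.iterrows():
        lines.append(
            f"  {r['target']:>8} {r['condition']:>8} {r['time']:>5}: "
            f"{r['fold_mean']:.2f} +/- {0.0 if pd.isna(r['fold_sd']) else r['fold_sd']:.2f}"
        )
    lines.append("")
    n_ext = int(extensions["extended"].sum()) if len(extensions) else 0
    lines.append(f"CDS extensions applied: {n_ext}")
    lines.append(f"novel ORFs detected: {len(novel_df)}")
    return "\n".join(lines) + "\n"
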