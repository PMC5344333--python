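"""Dual-baseline differential-expression framework.

Treatments are compared both to the pre-shift T0 control and to the
time-matched control; control time points are additionally compared to
T0 and to the immediately preceding time point, and the two
experiments' T0 controls are compared to each other as a cross-check.
Fold changes are ratios of arithmetic group means of housekeeping-
normalized abundances, reported with the signed convention (+r for
r >= 1, -1/r otherwise).  Significance is a per-contrast one-way ANOVA
(two groups) on log2 abundances at raw p < 0.01 combined with a
1.5-fold magnitude cutoff; no multiple-testing correction is applied,
by design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from dielshift.models import CountMatrix, GeneStatus, NormalizedMatrix

DEFAULT_MIN_READS = 100
DEFAULT_ALPHA = 0.01
DEFAULT_MIN_FOLD = 1.5

# |fold| category bins: edges inferred from the fold ranges the study
# design narrates (1.5, 2-4, 4-10, 10-30, 30-50, >=50); configurable
DEFAULT_BIN_EDGES = (1.5, 2.0, 4.0, 10.0, 30.0, 50.0)


def signed_fold(ratio: float) -> float:
    """Ratio r reported as +r when r >= 1 and as -1/r when r < 1.

    A zero ratio (no signal against a positive baseline) is an
    unbounded decrease and maps to -inf; negative or undefined ratios
    map to NaN.
    """
    if np.isnan(ratio) or ratio < 0:
        return np.nan
    if ratio == 0:
        return -np.inf
    return ratio if ratio >= 1 else -1.0 / ratio


def categorize_fold(
    fold: float, edges: tuple[float, ...] = DEFAULT_BIN_EDGES
) -> str:
    """Bin label for a signed fold, sign preserved for |fold| >= 1.5.

    With default edges: <1.5, 1.5 to <2, 2 to <4, 4 to <10, 10 to <30,
    30 to <50, >=50; e.g. +12 -> "10 to <30", -45 -> "-(30 to <50)".
    """
    if np.isnan(fold):
        return "undefined"
    mag = abs(fold)
    if mag < edges[0]:
        return f"<{edges[0]:g}"
    for lo, hi in zip(edges, edges[1:]):
        if lo <= mag < hi:
            label = f"{lo:g} to <{hi:g}"
            break
    else:
        label = f">={edges[-1]:g}"
    return label if fold > 0 else f"-({label})"


def filter_min_reads(
    counts: CountMatrix, threshold: int = DEFAULT_MIN_READS
) -> pd.DataFrame:
    """Inclusion filter on raw (un-normalized) counts.

    A gene is included iff its maximum raw count over samples reaches
    ``threshold`` in at least one sample; convergent-overlap genes are
    never included regardless of counts.  Returns a per-gene frame
    with columns included (bool) and reason.
    """
    rows = []
    for gid in counts.counts.index:
        base = gid.split("+", 1)[0]
        st = counts.status.get(base, GeneStatus.COUNTED)
        if st is GeneStatus.EXCLUDED_OVERLAP:
            rows.append((gid, False, "overlap"))
        elif counts.counts.loc[gid].max() >= threshold:
            rows.append((gid, True, ""))
        else:
            rows.append((gid, False, "below_min_reads"))
    return pd.DataFrame(rows, columns=["gene_id", "included", "reason"]).set_index(
        "gene_id"
    )


def _log_offset(ratios: pd.DataFrame) -> float:
    """Half the smallest nonzero abundance: used only inside log2."""
    vals = ratios.to_numpy(float)
    pos = vals[vals > 0]
    return float(pos.min()) / 2.0 if len(pos) else 1.0


def compare_groups(
    norm: NormalizedMatrix,
    group_a: list[str],
    group_b: list[str],
    log_scale: bool = True,
    offset: float | None = None,
) -> pd.DataFrame:
    """Per-gene signed fold (A over B) and ANOVA p-value.

    The fold is the ratio of arithmetic means of normalized abundances
    (computed on un-offset values); the p-value comes from a one-way
    fixed-effects ANOVA of the two groups on log2(abundance + offset)
    — with two groups this is the pooled-variance F test.  Zero
    variance in both groups with equal means yields p = 1 by
    convention; a zero B-group mean leaves the fold undefined and
    flags the record.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 replicates")
    ratios = norm.ratios
    a = ratios[group_a].to_numpy(float)
    b = ratios[group_b].to_numpy(float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)

    if log_scale:
        off = _log_offset(ratios) if offset is None else offset
        ta, tb = np.log2(a + off), np.log2(b + off)
    else:
        ta, tb = a, b

    pvals = np.ones(len(ratios))
    for i in range(len(ratios)):
        xa, xb = ta[i], tb[i]
        if np.ptp(xa) == 0 and np.ptp(xb) == 0:
            pvals[i] = 1.0 if xa[0] == xb[0] else 0.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pvals[i] = stats.f_oneway(xa, xb).pvalue
    ratio = np.divide(mean_a, mean_b, out=np.full(len(ratios), np.nan),
                      where=mean_b > 0)
    out = pd.DataFrame(
        {
            "fold": [signed_fold(r) for r in ratio],
            "p_value": pvals,
            "flag": np.where(mean_b > 0, "", "undefined_baseline"),
        },
        index=ratios.index,
    )
    return out


@dataclass(frozen=True)
class Contrast:
    label: str
    group_a: tuple[str, str, str]  # (experiment, condition, time)
    group_b: tuple[str, str, str]


def framework_contrasts(design: pd.DataFrame) -> list[Contrast]:
    """The full comparison list for a two-experiment light-shift design."""
    contrasts: list[Contrast] = []
    t0 = "T0"
    times = [t for t in ("T1", "T2.5") if t in set(design["time"])]
    for exp, sub in design.groupby("experiment"):
        conds = set(sub["condition"])
        treatment = next((c for c in conds if c != "control"), None)
        for t in times:
            if treatment and ((sub["condition"] == treatment)
                              & (sub["time"] == t)).any():
                contrasts.append(Contrast(
                    f"{exp}:{treatment}_{t}_vs_control_T0",
                    (exp, treatment, t), (exp, "control", t0)))
                contrasts.append(Contrast(
                    f"{exp}:{treatment}_{t}_vs_control_{t}",
                    (exp, treatment, t), (exp, "control", t)))
        prev = t0
        for t in times:
            contrasts.append(Contrast(
                f"{exp}:control_{t}_vs_control_{prev}",
                (exp, "control", t), (exp, "control", prev)))
            if prev != t0:
                contrasts.append(Contrast(
                    f"{exp}:control_{t}_vs_control_T0",
                    (exp, "control", t), (exp, "control", t0)))
            prev = t
    exps = sorted(set(design["experiment"]))
    if len(exps) == 2:
        contrasts.append(Contrast(
            "control_T0_cross_experiment",
            (exps[0], "control", t0), (exps[1], "control", t0)))
    return contrasts


def run_framework(
    norm: NormalizedMatrix,
    design: pd.DataFrame,
    counts: CountMatrix | None = None,
    min_reads: int = DEFAULT_MIN_READS,
    alpha: float = DEFAULT_ALPHA,
    min_fold: float = DEFAULT_MIN_FOLD,
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Emit the full DE table: one record per gene per comparison.

    Significance requires inclusion (raw-count filter and no overlap
    exclusion), |signed fold| >= ``min_fold`` and raw p < ``alpha``.
    Comparisons whose groups are missing from the design are skipped
    with a warning.
    """
    inclusion = (
        filter_min_reads(counts, min_reads) if counts is not None else None
    )
    samples_of = {
        key: list(grp["sample_id"])
        for key, grp in design.groupby(["experiment", "condition", "time"])
    }
    records = []
    for contrast in framework_contrasts(design):
        ga = samples_of.get(contrast.group_a, [])
        gb = samples_of.get(contrast.group_b, [])
        ga = [s for s in ga if s in norm.ratios.columns]
        gb = [s for s in gb if s in norm.ratios.columns]
        if len(ga) < 2 or len(gb) < 2:
            warnings.warn(
                f"contrast {contrast.label}: missing group, skipped",
                stacklevel=2,
            )
            continue
        res = compare_groups(norm, ga, gb, log_scale=log_scale)
        for gid, row in res.iterrows():
            if inclusion is not None and gid in inclusion.index:
                included = bool(inclusion.loc[gid, "included"])
                reason = inclusion.loc[gid, "reason"]
            else:
                included, reason = True, ""
            fold, p = row["fold"], row["p_value"]
            significant = bool(
                included
                and not np.isnan(fold)
                and abs(fold) >= min_fold
                and p < alpha
                and row["flag"] == ""
            )
            records.append(
                {
                    "gene_id": gid,
                    "contrast": contrast.label,
                    "fold": fold,
                    "p_value": p,
                    "significant": significant,
                    "category": categorize_fold(fold, bin_edges),
                    "included": included,
                    "status": reason or row["flag"] or "ok",
                }
            )
    return pd.DataFrame.from_records(records)
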