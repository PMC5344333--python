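"""Bead-normalized flow-cytometry summaries and growth-rate analysis.

All cytometric quantities are expressed in bead relative units: the
arithmetic mean of a cell channel divided by the arithmetic mean of
the same channel over the spiked reference beads, which cancels
instrument gain exactly.  Growth rates come from log-linear least
squares of bulk fluorescence against time within each transfer of a
semi-continuous culture; divisions per day are mu / ln 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

LN2 = float(np.log(2.0))
CHANNELS = ("fals", "ssc", "red")


@dataclass
class FCMSummary:
    sample_id: str
    bead_relative: dict[str, float]
    n_cells: int
    n_beads: int
    meta: dict = field(default_factory=dict)


def bead_normalize(
    events: pd.DataFrame,
    channels: tuple[str, ...] = ("fals", "red"),
    min_events: int = 100,
) -> FCMSummary:
    """Bead-relative means for one sample's event table.

    ``events`` needs a ``population`` column labelling each event
    'cell' or 'bead' plus the channel columns.  The bead-relative
    value per channel is mean(cell) / mean(bead).
    """
    cells = events[events["population"] == "cell"]
    beads = events[events["population"] == "bead"]
    if beads.empty:
        raise ValueError("no bead population in event table")
    if cells.empty:
        raise ValueError("no cell population in event table")
    if len(cells) < min_events or len(beads) < min_events:
        raise ValueError(
            f"fewer than {min_events} events in a population "
            f"({len(cells)} cells, {len(beads)} beads)"
        )
    rel = {
        c: float(cells[c].mean() / beads[c].mean()) for c in channels
    }
    sid = str(events["sample_id"].iloc[0]) if "sample_id" in events else ""
    meta_cols = [c for c in events.columns
                 if c not in ("population", "sample_id", *CHANNELS)]
    meta = {c: events[c].iloc[0] for c in meta_cols}
    return FCMSummary(sample_id=sid, bead_relative=rel,
                      n_cells=len(cells), n_beads=len(beads), meta=meta)


def percent_change(values: pd.Series | np.ndarray, reference: float) -> np.ndarray:
    """100 * (x_t - x_0) / x_0 relative to the T0 reference."""
    if reference <= 0:
        raise ValueError("reference value must be positive")
    return 100.0 * (np.asarray(values, dtype=float) - reference) / reference


@dataclass
class GrowthRateResult:
    per_transfer: pd.DataFrame  # columns transfer, mu, n_points
    mu_mean: float
    mu_se: float
    n_transfers: int


def growth_rate(
    series: pd.DataFrame,
    time_col: str = "time_d",
    value_col: str = "fluorescence",
    transfer_col: str = "transfer",
) -> GrowthRateResult:
    """Specific growth rate per transfer and the mean over transfers.

    Per transfer, mu is the least-squares slope of ln(signal) against
    time over that transfer's daily points (same clock time each day,
    so fluorescence tracks cell abundance).  The mean mu +/- SE is
    taken across transfers.
    """
    if (series[value_col] <= 0).any():
        raise ValueError("nonpositive signal in growth series")
    rows = []
    for tr, sub in series.groupby(transfer_col):
        sub = sub.sort_values(time_col)
        if len(sub) < 2:
            warnings.warn(f"transfer {tr}: fewer than 2 points, skipped",
                          stacklevel=2)
            continue
        fit = stats.linregress(sub[time_col], np.log(sub[value_col]))
        rows.append({"transfer": tr, "mu": float(fit.slope),
                     "n_points": len(sub)})
    if not rows:
        raise ValueError("no transfer with >= 2 points")
    per = pd.DataFrame(rows)
    mu = per["mu"].to_numpy(float)
    se = float(mu.std(ddof=1) / np.sqrt(len(mu))) if len(mu) > 1 else 0.0
    return GrowthRateResult(per_transfer=per, mu_mean=float(mu.mean()),
                            mu_se=se, n_transfers=len(mu))


def divisions_per_day(mu: float | np.ndarray) -> float | np.ndarray:
    """Base-2 equivalent of the specific growth rate: k = mu / ln 2."""
    return mu / LN2


@dataclass
class IrradianceCurve:
    table: pd.DataFrame          # irradiance, mu_mean, mu_se, n
    argmax_irradiance: float
    mu_max: float


def growth_vs_irradiance(rates: pd.DataFrame) -> IrradianceCurve:
    """Mean +/- SE growth rate per light level and the curve maximum.

    ``rates`` holds one row per replicate (or transfer) with columns
    irradiance and mu.
    """
    if rates["irradiance"].nunique() < 2:
        raise ValueError("need >= 2 light levels")
    g = rates.groupby("irradiance")["mu"]
    table = g.agg(
        mu_mean="mean",
        mu_se=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0,
        n="count",
    ).reset_index()
    best = table.loc[table["mu_mean"].idxmax()]
    return IrradianceCurve(
        table=table,
        argmax_irradiance=float(best["irradiance"]),
        mu_max=float(best["mu_mean"]),
    )


def anova_by_group(
    values: pd.DataFrame,
    value_col: str,
    group_col: str,
) -> float:
    """One-way ANOVA p-value across the groups of ``group_col``."""
    groups = [g[value_col].to_numpy(float)
              for _, g in values.groupby(group_col)]
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    if any(len(g) < 2 for g in groups):
        warnings.warn("group with a single replicate: test skipped",
                      stacklevel=2)
        return float("nan")
    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        return 1.0
    return float(stats.f_oneway(*groups).pvalue)


def compare_growth_rates(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample t-test p-value between growth-rate sets."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        warnings.warn("growth-rate set with < 2 values: test skipped",
                      stacklevel=2)
        return float("nan")
    return float(stats.ttest_ind(a, b).pvalue)


def group_tests(
    summaries: pd.DataFrame,
    value_cols: tuple[str, ...],
    group_col: str = "irradiance",
    time_col: str | None = "time_h",
) -> pd.DataFrame:
    """Per-time-point one-way ANOVAs of bead-relative summaries across
    light levels (or conditions)."""
    rows = []
    frames = (
        summaries.groupby(time_col) if time_col and time_col in summaries
        else [(None, summaries)]
    )
    for t, sub in frames:
        for col in value_cols:
            try:
                p = anova_by_group(sub, col, group_col)
            except ValueError:
                continue
            rows.append({"time": t, "value": col, "p_value": p})
    return pd.DataFrame(rows, columns=["time", "value", "p_value"])
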