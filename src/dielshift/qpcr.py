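"""Relative quantification by the 2^-ddCt method.

Per sample, the target Ct is corrected by the endogenous control
(dCt = Ct_target - Ct_endogenous); the mean dCt of the calibrator
group (T0 control) is subtracted (ddCt); fold change = 2^-ddCt.
Primer efficiency is estimated from a dilution series as
10^(-1/slope) - 1 with slope from least squares of Ct on log10 input
quantity; the method itself assumes efficiency ~ 1 (a separate
Pfaffl-style correction mode is available but off by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PLATE_COLUMNS = ["sample_id", "condition", "time", "replicate", "target", "ct"]


@dataclass
class QPCRPlate:
    """Ct records plus a dilution-series block for efficiency checks."""

    records: pd.DataFrame
    dilution_series: pd.DataFrame | None = None

    def validate(self, endogenous: str = "Actin") -> None:
        r = self.records
        missing = set(PLATE_COLUMNS) - set(r.columns)
        if missing:
            raise ValueError(f"plate missing columns: {sorted(missing)}")
        ct = r["ct"].to_numpy(float)
        if np.any(~np.isfinite(ct)) or np.any(ct <= 0) or np.any(ct > 40):
            raise ValueError("Ct values must lie in (0, 40]")
        have = r.loc[r["target"] == endogenous, "sample_id"]
        lacking = set(r["sample_id"]) - set(have)
        if lacking:
            raise ValueError(
                f"endogenous control {endogenous!r} missing for samples "
                f"{sorted(lacking)}"
            )


@dataclass(frozen=True)
class EfficiencyResult:
    slope: float
    efficiency: float
    r_squared: float
    linear: bool


def efficiency(
    dilution: pd.DataFrame,
    r2_threshold: float = 0.99,
) -> EfficiencyResult:
    """Primer efficiency from a dilution series for one primer-probe set.

    ``dilution`` needs columns log10_quantity and ct (>= 3 points).
    Perfect 2-fold chemistry gives slope -3.3219 and efficiency 1.0.
    """
    if len(dilution) < 3:
        raise ValueError("efficiency needs >= 3 dilution points")
    fit = stats.linregress(dilution["log10_quantity"], dilution["ct"])
    if fit.slope >= 0 or np.isclose(fit.slope, 0.0):
        raise ValueError("efficiency undefined: non-negative dilution slope")
    eff = 10 ** (-1.0 / fit.slope) - 1.0
    r2 = float(fit.rvalue**2)
    return EfficiencyResult(
        slope=float(fit.slope),
        efficiency=float(eff),
        r_squared=r2,
        linear=r2 >= r2_threshold,
    )


def ddct_fold(
    plate: QPCRPlate,
    target: str,
    endogenous: str = "Actin",
    calibrator: tuple[str, str] = ("control", "T0"),
    target_efficiency: float | None = None,
    endogenous_efficiency: float | None = None,
) -> pd.DataFrame:
    """Per-sample fold change of ``target`` relative to the calibrator.

    Returns one row per biological replicate with columns sample_id,
    condition, time, replicate, delta_ct, ddct, fold.  Samples lacking
    an endogenous Ct are dropped with a warning.  When efficiencies are
    given, an efficiency-corrected ratio (Pfaffl-style) replaces the
    2^-ddCt fold; by default the classic method is used.
    """
    r = plate.records
    tgt = r[r["target"] == target].set_index("sample_id")
    endo = r[r["target"] == endogenous].set_index("sample_id")
    missing = tgt.index.difference(endo.index)
    if len(missing):
        warnings.warn(
            f"dropping samples without endogenous Ct: {sorted(missing)}",
            stacklevel=2,
        )
        tgt = tgt.drop(index=missing)
    joined = tgt.join(endo["ct"], rsuffix="_endo")
    joined["delta_ct"] = joined["ct"] - joined["ct_endo"]

    cal_mask = (joined["condition"] == calibrator[0]) & (
        joined["time"] == calibrator[1]
    )
    if not cal_mask.any():
        raise ValueError(f"calibrator group {calibrator} absent from plate")
    cal_dct = float(joined.loc[cal_mask, "delta_ct"].mean())
    joined["ddct"] = joined["delta_ct"] - cal_dct

    if target_efficiency is None and endogenous_efficiency is None:
        joined["fold"] = 2.0 ** (-joined["ddct"])
    else:
        et = 1.0 + (target_efficiency if target_efficiency is not None else 1.0)
        ee = 1.0 + (
            endogenous_efficiency if endogenous_efficiency is not None else 1.0
        )
        cal_ct_t = float(joined.loc[cal_mask, "ct"].mean())
        cal_ct_e = float(joined.loc[cal_mask, "ct_endo"].mean())
        joined["fold"] = (et ** (cal_ct_t - joined["ct"])) / (
            ee ** (cal_ct_e - joined["ct_endo"])
        )
    out = joined.reset_index()[
        ["sample_id", "condition", "time", "replicate", "delta_ct", "ddct", "fold"]
    ]
    return out


def fold_summary(per_sample: pd.DataFrame) -> pd.DataFrame:
    """Group mean and SD of fold changes over biological replicates."""
    g = per_sample.groupby(["condition", "time"])["fold"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    return out.rename(columns={"mean": "fold_mean", "std": "fold_sd",
                               "count": "n"})


def qpcr_significance(
    per_sample: pd.DataFrame,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """One-way ANOVA across condition groups at each time point.

    Operates on the endogenous-corrected dCt values (equivalent to
    log2 folds up to sign and a constant).  Returns one p-value per
    time point covering all conditions present at that time.
    """
    rows = []
    for time, sub in per_sample.groupby("time"):
        groups = [g["delta_ct"].to_numpy(float)
                  for _, g in sub.groupby("condition")]
        if len(groups) < 2 or any(len(g) < 2 for g in groups):
            warnings.warn(f"time {time}: not enough groups/replicates, "
                          "test skipped", stacklevel=2)
            continue
        if all(np.ptp(g) == 0 for g in groups) and len(
            {g[0] for g in groups}
        ) == 1:
            p = 1.0  # identical constant groups: no evidence by convention
        else:
            p = float(stats.f_oneway(*groups).pvalue)
        rows.append({"time": time, "p_value": p, "significant": p < alpha,
                     "n_conditions": len(groups)})
    return pd.DataFrame(rows, columns=["time", "p_value", "significant",
                                       "n_conditions"])
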