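"""Synthetic bulk-fluorescence growth series and qPCR Ct plates."""

from __future__ import annotations

import numpy as np
import pandas as pd

from dielshift.qpcr import QPCRPlate

GROWTH_COLUMNS = [
    "irradiance", "replicate", "transfer", "time_d", "fluorescence",
]


def simulate_growth(
    mu_by_irradiance: dict[float, float],
    times: list[float] | np.ndarray | None = None,
    noise: float = 0.02,
    seed: int = 0,
    n_transfers: int = 4,
    replicates: int = 3,
    f0: float = 10.0,
) -> pd.DataFrame:
    """Exponential bulk-fluorescence series with daily sampling and
    transfer dilutions.

    ``times`` are the within-transfer sampling days (default 0..3, one
    fixed time each day); each transfer starts afresh from ``f0``
    (dilution back to the starting density).  Fluorescence is
    ``f0 * exp(mu * t) * (1 + eps)`` with multiplicative Gaussian noise
    of relative magnitude ``noise``.
    """
    if times is None:
        times = np.arange(4.0)
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 2:
        raise ValueError("need at least two sampling times per transfer")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if noise < 0:
        raise ValueError("noise must be nonnegative")
    for irr, mu in mu_by_irradiance.items():
        if not np.isfinite(mu):
            raise ValueError(f"growth rate at irradiance {irr} is not finite")

    rng = np.random.default_rng(seed)
    span = times[-1] - times[0]
    rows = []
    for irr, mu in mu_by_irradiance.items():
        for rep in range(1, replicates + 1):
            for tr in range(1, n_transfers + 1):
                offset = (tr - 1) * (span + 1.0)
                eps = rng.normal(0.0, noise, size=len(times)) if noise else 0.0
                f = f0 * np.exp(mu * (times - times[0])) * (1.0 + eps)
                for t, v in zip(times, np.atleast_1d(f)):
                    rows.append(
                        {
                            "irradiance": irr,
                            "replicate": rep,
                            "transfer": tr,
                            "time_d": offset + t,
                            "fluorescence": float(v),
                        }
                    )
    return pd.DataFrame(rows, columns=GROWTH_COLUMNS)


def simulate_qpcr(
    true_folds: dict[str, dict[tuple[str, str], float]],
    efficiencies: dict[str, float] | None = None,
    seed: int = 0,
    ct_noise: float = 0.1,
    replicates: int = 4,
    endogenous: str = "Actin",
    endogenous_ct: float = 20.0,
    target_base_ct: float = 26.0,
    dilution_log10: tuple[float, ...] = (0.0, -1.0, -2.0, -3.0, -4.0),
) -> QPCRPlate:
    """Ct plate consistent with 2-fold-per-cycle chemistry.

    ``true_folds`` maps target -> {(condition, time): fold relative to
    the T0-control calibrator}.  At efficiency 1 a sample with fold f
    sits ``log2 f`` cycles below the calibrator; general efficiency E
    uses ``log(f) / log(1 + E)`` cycles.  A dilution-series block is
    emitted for efficiency / linear-range checking.
    """
    efficiencies = efficiencies or {}
    for t, e in efficiencies.items():
        if not 0.0 < e <= 1.0:
            raise ValueError(f"efficiency for {t} must lie in (0, 1]")
    if ct_noise < 0:
        raise ValueError("ct_noise must be nonnegative")
    rng = np.random.default_rng(seed)

    conditions = sorted({ck for folds in true_folds.values() for ck in folds})
    rows = []
    for cond, time in conditions:
        for rep in range(1, replicates + 1):
            sample_id = f"{cond}.{time}.r{rep}"
            noise_e = rng.normal(0.0, ct_noise) if ct_noise else 0.0
            rows.append(
                {
                    "sample_id": sample_id, "condition": cond, "time": time,
                    "replicate": rep, "target": endogenous,
                    "ct": endogenous_ct + noise_e,
                }
            )
            for target, folds in true_folds.items():
                f = folds.get((cond, time))
                if f is None:
                    continue
                if f <= 0:
                    raise ValueError(f"true fold for {target} must be positive")
                eff = efficiencies.get(target, 1.0)
                cycles = np.log(f) / np.log(1.0 + eff)
                noise_t = rng.normal(0.0, ct_noise) if ct_noise else 0.0
                rows.append(
                    {
                        "sample_id": sample_id, "condition": cond,
                        "time": time, "replicate": rep, "target": target,
                        "ct": target_base_ct - cycles + noise_t,
                    }
                )
    records = pd.DataFrame(rows)

    dil_rows = []
    for target in list(true_folds) + [endogenous]:
        eff = efficiencies.get(target, 1.0)
        slope = -1.0 / np.log10(1.0 + eff)
        for lq in dilution_log10:
            noise_d = rng.normal(0.0, ct_noise) if ct_noise else 0.0
            dil_rows.append(
                {
                    "target": target, "log10_quantity": lq,
                    "ct": target_base_ct + slope * lq + noise_d,
                }
            )
    dilution = pd.DataFrame(dil_rows)
    return QPCRPlate(records=records, dilution_series=dilution)
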