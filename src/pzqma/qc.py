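"""Bioanalytical quality-control procedures.

Three independent checks around the LC-MS/MS assay:

* incurred sample reanalysis (ISR) — re-assay of real study samples;
  acceptance per the European bioanalytical guideline: at least 2/3 of
  pairs must agree within 20% on the mean-denominator percentage scale;
* calibration-range censoring — concentrations below the analyte LLOQ
  are flagged BLQ and cleared, values above the ULOQ are flagged but
  retained (dilution/reassay not modelled);
* in vitro blood:plasma partition — internal-standard-normalised peak
  ratios of spiked whole blood versus its centrifuged plasma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class IsrReport:
    n_pairs: int
    n_within_threshold: int
    pct_within: float
    threshold_pct: float
    required_fraction: float
    passed: bool
    by_matrix: pd.DataFrame  # matrix, n_pairs, n_within, pct_within


def isr_percentage_difference(original: float, repeat: float) -> float:
    """Percentage difference on the mean denominator:

        100 * (repeat - original) / mean(repeat, original)

    Antisymmetric under swapping the arguments and bounded in
    [-200, 200] for nonnegative inputs.  Undefined (NaN) when both
    measurements are zero.
    """
    if original < 0 or repeat < 0:
        raise ValueError("concentrations must be nonnegative")
    denom = (original + repeat) / 2.0
    if denom == 0:
        return np.nan
    return 100.0 * (repeat - original) / denom


def isr_assess(
    pairs: pd.DataFrame,
    threshold_pct: float = 20.0,
    required_fraction: float = 2.0 / 3.0,
) -> IsrReport:
    """Assess an ISR pair table against the guideline acceptance rule.

    A pair is within threshold when |percentage difference| <= threshold
    (boundary inclusive).  The run passes when the fraction of pairs
    within threshold is at least ``required_fraction`` (default exactly
    2/3).  Pairs where both measurements are zero are excluded.
    """
    if pairs.empty:
        raise ValueError("empty ISR table")
    diffs = np.array([
        isr_percentage_difference(o, r)
        for o, r in zip(pairs["original"], pairs["repeat"])
    ])
    valid = ~np.isnan(diffs)
    if (~valid).any():
        logger.info("isr_assess: %d pairs with both measurements zero "
                    "excluded", int((~valid).sum()))
    if not valid.any():
        raise ValueError("no valid ISR pairs")
    within = np.abs(diffs[valid]) <= threshold_pct
    by_rows = []
    if "matrix" in pairs.columns:
        for matrix, grp in pairs[valid].assign(_w=within).groupby("matrix"):
            by_rows.append({
                "matrix": matrix,
                "n_pairs": len(grp),
                "n_within": int(grp["_w"].sum()),
                "pct_within": 100.0 * grp["_w"].mean(),
            })
    n = int(valid.sum())
    n_within = int(within.sum())
    pct = 100.0 * n_within / n
    return IsrReport(
        n_pairs=n,
        n_within_threshold=n_within,
        pct_within=pct,
        threshold_pct=threshold_pct,
        required_fraction=required_fraction,
        passed=n_within / n >= required_fraction,
        by_matrix=pd.DataFrame(by_rows),
    )


def censor_to_range(
    records: pd.DataFrame,
    lloq_ug_ml: dict[str, float],
    uloq_ug_ml: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Apply calibration-range censoring to a long concentration table.

    Below-LLOQ concentrations are flagged ``blq=1`` and the stored value
    cleared (NaN); above-ULOQ values keep their value under an
    ``above_uloq`` flag.  Idempotent.  Empty tables pass through.
    """
    for analyte, lloq in lloq_ug_ml.items():
        if uloq_ug_ml is not None and analyte in uloq_ug_ml and lloq >= uloq_ug_ml[analyte]:
            raise ValueError(f"LLOQ >= ULOQ for {analyte}")
    out = records.copy()
    if "blq" not in out.columns:
        out["blq"] = 0
    if "above_uloq" not in out.columns:
        out["above_uloq"] = 0
    if out.empty:
        return out
    lloq = out["analyte"].map(lloq_ug_ml)
    below = out["conc_ug_ml"].lt(lloq) | (out["blq"] == 1)
    out.loc[below, "blq"] = 1
    out.loc[below, "conc_ug_ml"] = np.nan
    if uloq_ug_ml is not None:
        uloq = out["analyte"].map(uloq_ug_ml)
        above = out["conc_ug_ml"].gt(uloq) | (out["above_uloq"] == 1)
        out.loc[above, "above_uloq"] = 1
        if above.any():
            logger.info("censor_to_range: %d above-ULOQ values retained "
                        "with flag", int(above.sum()))
    n_blq = int(out["blq"].sum())
    if n_blq:
        logger.info("censor_to_range: %d values censored below LLOQ", n_blq)
    return out


def partition_ratio(spiked: pd.DataFrame) -> pd.DataFrame:
    """Blood:plasma partition ratios from a spiked-sample experiment.

    Per replicate: 100 * (blood response / blood IS) / (plasma response /
    plasma IS); summarised as mean +/- SD per analyte x nominal level.
    Replicates with a nonpositive plasma response are excluded (logged).
    """
    df = spiked.copy()
    ok = df["plasma_response"] > 0
    if (~ok).any():
        logger.info("partition_ratio: %d replicates with nonpositive plasma "
                    "response excluded", int((~ok).sum()))
    df = df[ok]
    if df.empty:
        raise ValueError("no usable replicates")
    blood_norm = df["blood_response"] / df["is_response_blood"]
    plasma_norm = df["plasma_response"] / df["is_response_plasma"]
    df = df.assign(ratio_pct=100.0 * blood_norm / plasma_norm)
    rows = []
    for (analyte, level), grp in df.groupby(["analyte", "level"], sort=True):
        n = len(grp)
        rows.append({
            "analyte": analyte,
            "nominal_level": float(level),
            "mean_ratio_pct": float(grp["ratio_pct"].mean()),
            "sd_pct": float(grp["ratio_pct"].std(ddof=1)) if n > 1 else np.nan,
            "n_replicates": n,
        })
    return pd.DataFrame(rows)
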