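"""Cross-matrix agreement statistics (Bland-Altman on percentage ratios).

Whole blood and dried blood spots are compared against plasma, the
reference matrix, on the ratio scale: each pair contributes
100 * test/reference.  Two estimators of the 95% limits of agreement
(LoA) are provided.

Conventional (independent observations, e.g. one AUC per subject):

    LoA = mean ratio +/- 1.96 * SD

Repeated-measures (multiple concentration pairs per subject): the total
variance is decomposed by one-way ANOVA into between-subject and
within-subject components.  With d_ij the ratio for subject i
observation j, k subjects, n_i observations each and N = sum n_i:

    MS_between = sum n_i (dbar_i - dbar)^2 / (k - 1)
    MS_within  = sum sum (d_ij - dbar_i)^2 / (N - k)
    n0 = (N - sum n_i^2 / N) / (k - 1)
    sigma2_within  = MS_within
    sigma2_between = max(0, (MS_between - MS_within) / n0)
    LoA = dbar +/- 1.96 * sqrt(sigma2_between + sigma2_within)

where dbar is pooled over all observations.  Confidence intervals use
the subject count m as the number of independent units:

    CI(mean) = mean +/- t(0.975, m-1) * SD_total / sqrt(m)
    CI(LoA)  = limit +/- t(0.975, m-1) * SD_total * sqrt(1/m + 1.96^2 / (2(m-1)))
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

Z_LOA = 1.96  # kept literal: the LoA definition, not a tunable quantile


@dataclass
class AgreementResult:
    n_pairs: int
    n_subjects: int
    mean_ratio_pct: float
    sd_total_pct: float
    loa_lower_pct: float
    loa_upper_pct: float
    sigma_between_pct: float = np.nan
    sigma_within_pct: float = np.nan
    ci_mean: tuple[float, float] | None = None
    ci_loa_lower: tuple[float, float] | None = None
    ci_loa_upper: tuple[float, float] | None = None
    method: str = "conventional"
    flags: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# Pairing and elementary statistics
# ---------------------------------------------------------------------------

def pair_measurements(
    table: pd.DataFrame,
    test_matrix: str,
    reference_matrix: str = "plasma",
    value_col: str = "conc_ug_ml",
    keys: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Inner-join test and reference matrix rows into paired measurements.

    For concentration tables the join key is (subject, analyte, time);
    for parameter tables pass ``keys=("subject_id", "analyte")`` and the
    appropriate ``value_col``.  Pairs with a BLQ or missing value on
    either side are dropped (count logged).
    """
    if keys is None:
        keys = ("subject_id", "analyte", "time_h")
    keys = list(keys)

    def side(matrix: str, name: str) -> pd.DataFrame:
        sub = table[table["matrix"] == matrix]
        if "blq" in sub.columns:
            sub = sub[sub["blq"] == 0]
        sub = sub.dropna(subset=[value_col])
        return sub[keys + [value_col]].rename(columns={value_col: name})

    test = side(test_matrix, "test_value")
    ref = side(reference_matrix, "reference_value")
    merged = test.merge(ref, on=keys, how="inner")
    n_dropped = max(len(test), len(ref)) - len(merged)
    if n_dropped:
        logger.info("pair_measurements: %d unmatched/censored rows dropped "
                    "(%s vs %s)", n_dropped, test_matrix, reference_matrix)
    if merged.empty:
        raise ValueError(
            f"no surviving pairs for {test_matrix} vs {reference_matrix}"
        )
    return merged


def pearson_pooled(pairs: pd.DataFrame) -> float:
    """Product-moment correlation pooled across subjects and times."""
    if len(pairs) < 3:
        raise ValueError("need >= 3 pairs for a correlation")
    x = pairs["reference_value"].to_numpy(float)
    y = pairs["test_value"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    return float(stats.pearsonr(x, y).statistic)


def percentage_ratios(pairs: pd.DataFrame) -> pd.DataFrame:
    """Append ``ratio_pct`` = 100 * test/reference; nonpositive references
    are excluded (count logged)."""
    ok = pairs["reference_value"] > 0
    if (~ok).any():
        logger.info("percentage_ratios: %d pairs with nonpositive reference "
                    "excluded", int((~ok).sum()))
    out = pairs[ok].copy()
    out["ratio_pct"] = 100.0 * out["test_value"] / out["reference_value"]
    return out


# ---------------------------------------------------------------------------
# Limits of agreement
# ---------------------------------------------------------------------------

def loa_conventional(ratios: np.ndarray | pd.Series,
                     n_subjects: int | None = None) -> AgreementResult:
    """Conventional Bland-Altman LoA: mean +/- 1.96 * sample SD (n-1)."""
    r = np.asarray(ratios, dtype=float)
    if r.size < 2:
        raise ValueError("need >= 2 ratios")
    mean = float(r.mean())
    sd = float(r.std(ddof=1))
    return AgreementResult(
        n_pairs=int(r.size),
        n_subjects=int(n_subjects if n_subjects is not None else r.size),
        mean_ratio_pct=mean,
        sd_total_pct=sd,
        loa_lower_pct=mean - Z_LOA * sd,
        loa_upper_pct=mean + Z_LOA * sd,
        method="conventional",
    )


def loa_repeated(ratios: np.ndarray | pd.Series,
                 subjects: np.ndarray | pd.Series) -> AgreementResult:
    """Repeated-measures LoA via one-way ANOVA variance components.

    Falls back to the conventional estimator (flag ``singleton_fallback``)
    when every subject contributes a single observation.
    """
    r = np.asarray(ratios, dtype=float)
    s = np.asarray(subjects)
    if r.size != s.size:
        raise ValueError("ratios and subjects must align")
    uniq, inverse, counts = np.unique(s, return_inverse=True, return_counts=True)
    k, n_total = uniq.size, r.size
    if k < 2:
        raise ValueError("need >= 2 subjects for the repeated-measures method")
    if counts.max() < 2:
        res = loa_conventional(r, n_subjects=k)
        res.flags.add("singleton_fallback")
        return res
    grand = float(r.mean())  # pooled over all observations
    subj_means = np.bincount(inverse, weights=r) / counts
    ss_between = float(np.sum(counts * (subj_means - grand) ** 2))
    ms_between = ss_between / (k - 1)
    ss_within = float(np.sum((r - subj_means[inverse]) ** 2))
    ms_within = ss_within / (n_total - k)
    n0 = (n_total - float(np.sum(counts**2)) / n_total) / (k - 1)
    var_within = ms_within
    var_between = max(0.0, (ms_between - ms_within) / n0)
    sd_total = float(np.sqrt(var_between + var_within))
    return AgreementResult(
        n_pairs=int(n_total),
        n_subjects=int(k),
        mean_ratio_pct=grand,
        sd_total_pct=sd_total,
        loa_lower_pct=grand - Z_LOA * sd_total,
        loa_upper_pct=grand + Z_LOA * sd_total,
        sigma_between_pct=float(np.sqrt(var_between)),
        sigma_within_pct=float(np.sqrt(var_within)),
        method="repeated",
    )


def loa_confidence_intervals(result: AgreementResult) -> AgreementResult:
    """95% confidence intervals for the mean ratio and both LoA limits.

    The effective unit count m is the number of subjects, since repeated
    observations within a subject are dependent.  m < 3 -> CIs flagged
    unavailable.
    """
    m = result.n_subjects
    if m < 3:
        result.flags.add("ci_unavailable")
        return result
    sd = result.sd_total_pct
    t_crit = float(stats.t.ppf(0.975, m - 1))
    se_mean = sd / np.sqrt(m)
    se_loa = sd * np.sqrt(1.0 / m + Z_LOA**2 / (2.0 * (m - 1)))
    result.ci_mean = (result.mean_ratio_pct - t_crit * se_mean,
                      result.mean_ratio_pct + t_crit * se_mean)
    result.ci_loa_lower = (result.loa_lower_pct - t_crit * se_loa,
                           result.loa_lower_pct + t_crit * se_loa)
    result.ci_loa_upper = (result.loa_upper_pct - t_crit * se_loa,
                           result.loa_upper_pct + t_crit * se_loa)
    return result


# ---------------------------------------------------------------------------
# Publication-shaped tables
# ---------------------------------------------------------------------------

def concentration_agreement_table(
    conc: pd.DataFrame,
    test_matrices: tuple[str, ...] = ("blood", "DBS"),
    reference_matrix: str = "plasma",
) -> pd.DataFrame:
    """Per-sample agreement per analyte x test matrix.

    Pooled Pearson correlation plus repeated-measures LoA on percentage
    ratios, with subject-level confidence intervals.
    """
    rows = []
    for analyte in sorted(conc["analyte"].unique()):
        sub = conc[conc["analyte"] == analyte]
        for matrix in test_matrices:
            pairs = percentage_ratios(
                pair_measurements(sub, matrix, reference_matrix)
            )
            res = loa_confidence_intervals(
                loa_repeated(pairs["ratio_pct"], pairs["subject_id"])
            )
            rows.append({
                "analyte": analyte, "matrix": matrix,
                "n": res.n_pairs, "n_subjects": res.n_subjects,
                "pearson_r": pearson_pooled(pairs),
                "mean_ratio_pct": res.mean_ratio_pct,
                "sd_total_pct": res.sd_total_pct,
                "sigma_between_pct": res.sigma_between_pct,
                "sigma_within_pct": res.sigma_within_pct,
                "loa_lower_pct": res.loa_lower_pct,
                "loa_upper_pct": res.loa_upper_pct,
                "method": res.method,
            })
    return pd.DataFrame(rows)


def bland_altman_points(
    conc: pd.DataFrame,
    test_matrix: str,
    reference_matrix: str = "plasma",
) -> pd.DataFrame:
    """Point data for Bland-Altman plots: pair mean vs percentage ratio."""
    pairs = percentage_ratios(pair_measurements(conc, test_matrix, reference_matrix))
    pairs["pair_mean"] = (pairs["test_value"] + pairs["reference_value"]) / 2.0
    cols = ["subject_id", "analyte", "time_h", "pair_mean", "ratio_pct"]
    return pairs[[c for c in cols if c in pairs.columns]]


def parameter_ratio_table(
    pk_parameters: pd.DataFrame,
    test_matrices: tuple[str, ...] = ("blood", "DBS"),
    reference_matrix: str = "plasma",
    parameters: tuple[str, ...] = ("auc_0_24", "t_half", "cmax", "tmax"),
) -> pd.DataFrame:
    """Per-subject PK-parameter ratios and their agreement statistics.

    One row per analyte x matrix x parameter with the mean percentage
    ratio; for AUC the conventional LoA with confidence intervals is
    included (one AUC per subject, so observations are independent).
    """
    rows = []
    for analyte in sorted(pk_parameters["analyte"].unique()):
        sub = pk_parameters[pk_parameters["analyte"] == analyte]
        for matrix in test_matrices:
            for name in parameters:
                cell = sub[sub["parameter"] == name]
                if cell.empty:
                    continue
                try:
                    pairs = percentage_ratios(pair_measurements(
                        cell, matrix, reference_matrix,
                        value_col="value", keys=("subject_id", "analyte"),
                    ))
                except ValueError:
                    logger.info("parameter_ratio_table: no pairs for %s/%s/%s",
                                analyte, matrix, name)
                    continue
                row = {
                    "analyte": analyte, "matrix": matrix, "parameter": name,
                    "n_subjects": len(pairs),
                    "mean_ratio_pct": float(pairs["ratio_pct"].mean()),
                }
                if name == "auc_0_24" and len(pairs) >= 2:
                    res = loa_confidence_intervals(
                        loa_conventional(pairs["ratio_pct"])
                    )
                    row.update({
                        "sd_pct": res.sd_total_pct,
                        "loa_lower_pct": res.loa_lower_pct,
                        "loa_upper_pct": res.loa_upper_pct,
                        "ci_mean_low": res.ci_mean[0] if res.ci_mean else np.nan,
                        "ci_mean_high": res.ci_mean[1] if res.ci_mean else np.nan,
                        "ci_loa_lower_low": res.ci_loa_lower[0] if res.ci_loa_lower else np.nan,
                        "ci_loa_lower_high": res.ci_loa_lower[1] if res.ci_loa_lower else np.nan,
                        "ci_loa_upper_low": res.ci_loa_upper[0] if res.ci_loa_upper else np.nan,
                        "ci_loa_upper_high": res.ci_loa_upper[1] if res.ci_loa_upper else np.nan,
                    })
                rows.append(row)
    return pd.DataFrame(rows)
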