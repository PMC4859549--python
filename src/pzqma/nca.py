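"""Non-compartmental pharmacokinetic analysis.

Per subject x analyte x matrix: AUC(0-24) by the linear trapezoidal
rule, Cmax/Tmax, and the terminal elimination rate constant lambda_z
from an ordinary least-squares fit of log concentration on time, with
t1/2 = ln2/lambda_z.  Cohort summaries report median and range per
parameter.

Below-LLOQ (BLQ) handling follows the usual NCA conventions: BLQ values
at and before the first quantifiable point are treated as zero, BLQ
values embedded between quantifiable points are excluded (the trapezoid
bridges across them), and trailing BLQ values truncate the profile at
the last quantifiable point.  When the last quantifiable sample falls
before the requested AUC endpoint and lambda_z is estimable, the AUC is
completed with the exponential tail C_last/lambda_z * (1 - exp(-lambda_z * dt))
and the extrapolated fraction is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PK_PARAMETER_NAMES = (
    "auc_0_24", "auc_extrapolated_fraction", "cmax", "tmax",
    "lambda_z", "t_half", "n_terminal_points", "terminal_r2",
)


@dataclass
class ConcentrationProfile:
    """One subject/analyte/matrix concentration-time profile.

    ``conc_ug_ml`` is NaN where ``blq`` is set.  Times must be strictly
    increasing and nonnegative.
    """

    subject_id: str
    analyte: str
    matrix: str
    time_h: np.ndarray
    conc_ug_ml: np.ndarray
    blq: np.ndarray

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.conc_ug_ml = np.asarray(self.conc_ug_ml, dtype=float)
        self.blq = np.asarray(self.blq, dtype=bool)
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.time_h < 0):
            raise ValueError("times must be nonnegative")
        quant = self.conc_ug_ml[~self.blq]
        if np.any(quant < 0) or np.any(np.isnan(quant)):
            raise ValueError("quantifiable concentrations must be finite and >= 0")

    def quantifiable(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, concs) after applying the BLQ conventions.

        Leading BLQ points become explicit zeros; embedded BLQ points are
        dropped; trailing BLQ points are dropped (profile truncated).
        """
        t, c, blq = self.time_h, self.conc_ug_ml, self.blq
        quant_idx = np.flatnonzero(~blq)
        if quant_idx.size == 0:
            return np.empty(0), np.empty(0)
        first, last = quant_idx[0], quant_idx[-1]
        keep_t, keep_c = [], []
        for i in range(last + 1):
            if blq[i]:
                if i < first:
                    keep_t.append(t[i])
                    keep_c.append(0.0)
                # embedded BLQ: bridge across
            else:
                keep_t.append(t[i])
                keep_c.append(c[i])
        return np.asarray(keep_t), np.asarray(keep_c)


@dataclass
class PKParameters:
    """NCA results for one profile."""

    subject_id: str
    analyte: str
    matrix: str
    auc_0_24: float = np.nan
    auc_extrapolated_fraction: float = 0.0
    cmax: float = np.nan
    tmax: float = np.nan
    lambda_z: float = np.nan
    t_half: float = np.nan
    n_terminal_points: int = 0
    terminal_r2: float = np.nan
    terminal_times: tuple[float, ...] = ()
    flags: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# Core estimators
# ---------------------------------------------------------------------------

def auc_linear_trapezoid(
    profile: ConcentrationProfile,
    t_end: float = 24.0,
    lambda_z: float | None = None,
) -> tuple[float, float]:
    """Linear-trapezoid AUC from 0 to ``t_end`` (ug/ml*h).

    Returns ``(auc, extrapolated_fraction)``.  Integration runs over the
    quantifiable profile up to min(t_last, t_end); if t_last < t_end and
    a ``lambda_z`` is supplied, the exponential tail is added.
    """
    t, c = profile.quantifiable()
    if t.size < 2:
        raise ValueError("insufficient profile: need >= 2 quantifiable points")
    if t_end <= t[0]:
        raise ValueError("t_end must exceed the first profile time")
    mask = t <= t_end
    tt, cc = t[mask], c[mask]
    if tt[-1] < t_end and t.size > tt.size:
        # interpolate to t_end within the observed range
        c_end = float(np.interp(t_end, t, c))
        tt = np.append(tt, t_end)
        cc = np.append(cc, c_end)
    auc = float(np.trapezoid(cc, tt))
    extra = 0.0
    t_last, c_last = tt[-1], cc[-1]
    if t_last < t_end and lambda_z is not None and lambda_z > 0 and c_last > 0:
        extra = (c_last / lambda_z) * (1.0 - np.exp(-lambda_z * (t_end - t_last)))
    total = auc + extra
    frac = extra / total if total > 0 else 0.0
    return total, frac


def cmax_tmax(profile: ConcentrationProfile) -> tuple[float, float]:
    """Maximal quantifiable concentration and its time (ties -> earliest)."""
    t, c = profile.quantifiable()
    if t.size == 0:
        raise ValueError("no quantifiable points")
    i = int(np.argmax(c))  # argmax returns the first maximum
    return float(c[i]), float(t[i])


def terminal_lambda_z(
    profile: ConcentrationProfile,
    terminal_times: tuple[float, ...] | None = None,
) -> tuple[float, float, int, float, tuple[float, ...]]:
    """Terminal slope by log-linear OLS.

    Candidate point sets are the last m quantifiable points strictly
    after Tmax, for m from 3 up to all available; the set maximising the
    adjusted r-squared wins (ties -> more points).  On sparse profiles
    (short DBS schedules) where fewer than 3 points follow Tmax, the
    Tmax point itself is admitted into the fit — detectable downstream
    because the returned point times then include Tmax.
    ``terminal_times`` overrides the automatic choice for audit or
    sensitivity work.
    Returns ``(lambda_z, t_half, n_points, r2, times_used)``; NaNs and
    n_points=0 when no admissible fit exists (nonnegative slope or too
    few points) — a flag, not an error.
    """
    t, c = profile.quantifiable()
    pos = c > 0
    t, c = t[pos], c[pos]
    if t.size == 0:
        return np.nan, np.nan, 0, np.nan, ()
    i_max = int(np.argmax(c))
    t_after, c_after = t[i_max + 1:], c[i_max + 1:]

    def fit(ts: np.ndarray, cs: np.ndarray):
        slope, intercept = np.polyfit(ts, np.log(cs), 1)
        pred = slope * ts + intercept
        logc = np.log(cs)
        ss_res = float(np.sum((logc - pred) ** 2))
        ss_tot = float(np.sum((logc - logc.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        return slope, r2

    if terminal_times is not None:
        sel = np.isin(t, np.asarray(terminal_times, dtype=float))
        ts, cs = t[sel], c[sel]
        if ts.size < 3:
            return np.nan, np.nan, 0, np.nan, ()
        slope, r2 = fit(ts, cs)
        if not slope < 0:
            return np.nan, np.nan, 0, np.nan, ()
        lz = -slope
        return lz, float(np.log(2) / lz), int(ts.size), r2, tuple(ts)

    if t_after.size < 3:
        # sparse-profile fallback: admit the Tmax point
        t_after, c_after = t[i_max:], c[i_max:]
    if t_after.size < 3:
        return np.nan, np.nan, 0, np.nan, ()
    best = None
    for m in range(3, t_after.size + 1):
        ts, cs = t_after[-m:], c_after[-m:]
        slope, r2 = fit(ts, cs)
        if not slope < 0 or np.isnan(r2):
            continue
        adj = 1.0 - (1.0 - r2) * (m - 1) / (m - 2)
        # ties broken toward more points for stability
        if best is None or adj >= best[0] - 1e-12:
            best = (adj, slope, r2, m, tuple(ts))
    if best is None:
        return np.nan, np.nan, 0, np.nan, ()
    _, slope, r2, m, ts = best
    lz = -slope
    return lz, float(np.log(2) / lz), m, r2, ts


# ---------------------------------------------------------------------------
# Table-level drivers
# ---------------------------------------------------------------------------

def analyze_profile(profile: ConcentrationProfile, t_end: float = 24.0) -> PKParameters:
    """Full NCA for one profile; quality issues land in ``flags``."""
    out = PKParameters(profile.subject_id, profile.analyte, profile.matrix)
    t, c = profile.quantifiable()
    if t.size < 2:
        out.flags.add("insufficient")
        return out
    out.cmax, out.tmax = cmax_tmax(profile)
    lz, th, n_pts, r2, ts = terminal_lambda_z(profile)
    out.lambda_z, out.t_half = lz, th
    out.n_terminal_points, out.terminal_r2 = n_pts, r2
    out.terminal_times = ts
    if n_pts == 0:
        out.flags.add("lambda_z_missing")
    elif out.tmax in ts:
        out.flags.add("terminal_includes_tmax")
    auc, frac = auc_linear_trapezoid(
        profile, t_end, lambda_z=None if n_pts == 0 else lz
    )
    out.auc_0_24, out.auc_extrapolated_fraction = auc, frac
    if frac > 0:
        out.flags.add("extrapolated")
    elif t[-1] < t_end:
        out.flags.add("truncated")
    return out


def profiles_from_table(conc: pd.DataFrame) -> list[ConcentrationProfile]:
    """Split a long-format concentration table into per-cell profiles."""
    profiles = []
    for (sid, analyte, matrix), grp in conc.groupby(
        ["subject_id", "analyte", "matrix"], sort=True
    ):
        grp = grp.sort_values("time_h")
        profiles.append(ConcentrationProfile(
            subject_id=str(sid), analyte=str(analyte), matrix=str(matrix),
            time_h=grp["time_h"].to_numpy(float),
            conc_ug_ml=grp["conc_ug_ml"].to_numpy(float),
            blq=grp["blq"].to_numpy(int).astype(bool),
        ))
    return profiles


def nca_analyze(conc: pd.DataFrame, t_end: float = 24.0) -> pd.DataFrame:
    """NCA over every subject x analyte x matrix cell of a long table.

    Returns a long parameter table (subject_id, analyte, matrix,
    parameter, value, flag).  Cells with fewer than two quantifiable
    points are skipped (they appear only as an ``insufficient`` flag row).
    """
    rows = []
    for profile in profiles_from_table(conc):
        res = analyze_profile(profile, t_end=t_end)
        flag = ";".join(sorted(res.flags))
        if "insufficient" in res.flags:
            rows.append({"subject_id": res.subject_id, "analyte": res.analyte,
                         "matrix": res.matrix, "parameter": "skipped",
                         "value": np.nan, "flag": flag})
            continue
        for name in PK_PARAMETER_NAMES:
            rows.append({"subject_id": res.subject_id, "analyte": res.analyte,
                         "matrix": res.matrix, "parameter": name,
                         "value": float(getattr(res, name)), "flag": flag})
    return pd.DataFrame(rows)


def summarize(parameters: pd.DataFrame) -> pd.DataFrame:
    """Median and range per analyte x matrix x parameter.

    Median for even n is the mean of the two central order statistics.
    """
    rows = []
    usable = parameters[parameters["parameter"] != "skipped"].dropna(subset=["value"])
    for (analyte, matrix, name), grp in usable.groupby(
        ["analyte", "matrix", "parameter"], sort=True
    ):
        v = grp["value"].to_numpy(float)
        rows.append({"analyte": analyte, "matrix": matrix, "parameter": name,
                     "median": float(np.median(v)), "min": float(v.min()),
                     "max": float(v.max()), "n": int(v.size)})
    return pd.DataFrame(rows)
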