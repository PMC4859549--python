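"""Synthetic cohort generator for a triple-dose praziquantel PK study.

Emulates the design of a nine-patient opisthorchiasis trial: three oral
doses of 25 mg/kg racemic praziquantel (PZQ) at 0, 4 and 8 h, venous
plasma/blood sampling at eleven nominal times over 24 h, two interleaved
six-point dried-blood-spot (DBS) schedules, and three analytes with very
different exposure scales (R-PZQ, S-PZQ and the main metabolite
R-trans-4-OH-PZQ).  Latent kinetics follow a one-compartment model with
first-order absorption and dose superposition; whole-blood and DBS
concentrations are the plasma curve scaled by a blood:plasma partition
ratio; measurement error is proportional Gaussian; values below the
assay's lower limit of quantification are censored.

The generator exists so that every downstream stage (NCA, agreement,
QC, efficacy) can be exercised against a known truth table.  Default
kinetic constants are calibrated so that the simulated plasma NCA
medians land on the reference study medians (see ``REFERENCE_PLASMA_PK``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANALYTES = ("R-PZQ", "S-PZQ", "R-trans-4-OH")
MATRICES = ("plasma", "blood", "DBS")

#: Published plasma NCA medians and (min, max) ranges across the nine
#: patients of the study this generator's defaults emulate.  Used as
#: calibration anchors for the default kinetic constants and as the
#: reference in calibration checks.  AUC in ug/ml*h, t1/2 in h, Cmax in
#: ug/ml, Tmax in h.
REFERENCE_PLASMA_PK = {
    "R-PZQ": {
        "auc_0_24": (1.1, 0.8, 10.7),
        "t_half": (1.1, 1.0, 3.0),
        "cmax": (0.2, 0.1, 1.1),
        "tmax": (7.00, 4.0, 11.8),
    },
    "S-PZQ": {
        "auc_0_24": (9.0, 6.1, 26.3),
        "t_half": (3.3, 1.9, 3.7),
        "cmax": (0.9, 0.6, 2.3),
        "tmax": (7.00, 4.0, 11.8),
    },
    "R-trans-4-OH": {
        "auc_0_24": (188.7, 157.2, 257.4),
        "t_half": (6.4, 4.1, 7.1),
        "cmax": (13.9, 13.1, 17.9),
        "tmax": (8.7, 8.0, 12.0),
    },
}

# Assay calibration ranges (ug/ml): parents 0.01-2.5, metabolite 0.1-25.
DEFAULT_LLOQ = {"R-PZQ": 0.01, "S-PZQ": 0.01, "R-trans-4-OH": 0.1}
DEFAULT_ULOQ = {"R-PZQ": 2.5, "S-PZQ": 2.5, "R-trans-4-OH": 25.0}

# In vitro spiking levels (ug/ml) for the blood:plasma partition experiment.
DEFAULT_PARTITION_LEVELS = {
    "R-PZQ": (0.05, 0.5),
    "S-PZQ": (0.05, 0.5),
    "R-trans-4-OH": (0.5, 5.0),
}

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class DosingRegimen:
    """An oral multiple-dose regimen given as mg/kg at stated hours."""

    dose_mg_per_kg: float = 25.0
    dose_times_h: tuple[float, ...] = (0.0, 4.0, 8.0)
    label: str = "3 x 25 mg/kg q4h"

    def __post_init__(self) -> None:
        if self.dose_mg_per_kg <= 0:
            raise ValueError("dose must be positive")
        times = tuple(float(t) for t in self.dose_times_h)
        if not times or times[0] != 0.0:
            raise ValueError("first dose time must be 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("dose times must be strictly increasing")
        object.__setattr__(self, "dose_times_h", times)


@dataclass(frozen=True)
class AnalyteModel:
    """Lumped one-compartment kinetics for one analyte.

    ``exposure_scale`` multiplies the dose and absorbs bioavailability
    and, for the metabolite, the formation fraction; ``r_blood_plasma``
    is the whole-blood to plasma concentration ratio.  ``bsv_cv`` is the
    between-subject lognormal coefficient of variation applied to ke and
    V/F.
    """

    analyte: str
    ka_per_h: float
    ke_per_h: float
    v_over_f_l_per_kg: float
    exposure_scale: float
    r_blood_plasma: float
    bsv_cv: float = 0.20

    def __post_init__(self) -> None:
        if min(self.ka_per_h, self.ke_per_h, self.v_over_f_l_per_kg) <= 0:
            raise ValueError("rates and volume must be positive")
        if self.r_blood_plasma <= 0:
            raise ValueError("r_blood_plasma must be positive")
        if self.ka_per_h == self.ke_per_h:
            # flip-flop singularity: perturb rather than reject
            object.__setattr__(self, "ka_per_h", self.ka_per_h * (1 + 1e-9))


@dataclass
class SubjectProfile:
    """Realized latent truth for one simulated subject."""

    subject_id: str
    weight_kg: float
    hematocrit: float
    regimen: DosingRegimen
    # analyte -> realized AnalyteModel (ka, ke, v_over_f, r_blood_plasma)
    kinetics: dict[str, AnalyteModel]
    doses_taken: tuple[bool, ...]
    exposure_outlier: bool = False

    def __post_init__(self) -> None:
        if not any(self.doses_taken):
            raise ValueError("at least one dose must be taken")


def default_analyte_models() -> dict[str, AnalyteModel]:
    """Default kinetic constants, calibrated to ``REFERENCE_PLASMA_PK``.

    ke is ln2 over the reference median half-life; exposure_scale sets
    the noiseless schedule-sampled AUC(0-24) onto the reference median
    AUC; the absorption rates place the noiseless Tmax (9 h, one sample
    after the last dose) and the Cmax/AUC shape inside the observed
    parameter ranges.  Between-subject CVs mirror the reference spread:
    wider for the parent enantiomers than for the metabolite, whose
    observed Cmax range is narrow.  Partition ratios: ~0.80 for the
    protein-bound parent enantiomers, 1.15 for the metabolite which
    distributes into erythrocytes.
    """
    return {
        "R-PZQ": AnalyteModel(
            analyte="R-PZQ",
            ka_per_h=1.5,
            ke_per_h=LN2 / 1.1,
            v_over_f_l_per_kg=1.0,
            exposure_scale=0.011219,
            r_blood_plasma=0.80,
            bsv_cv=0.15,
        ),
        "S-PZQ": AnalyteModel(
            analyte="S-PZQ",
            ka_per_h=1.5,
            ke_per_h=LN2 / 3.3,
            v_over_f_l_per_kg=1.0,
            exposure_scale=0.024465,
            r_blood_plasma=0.80,
            bsv_cv=0.15,
        ),
        "R-trans-4-OH": AnalyteModel(
            analyte="R-trans-4-OH",
            ka_per_h=2.5,
            ke_per_h=LN2 / 6.4,
            v_over_f_l_per_kg=1.0,
            exposure_scale=0.312518,
            r_blood_plasma=1.15,
            bsv_cv=0.10,
        ),
    }


@dataclass
class SimulationConfig:
    """Full description of one simulated study."""

    n_subjects: int = 9
    regimen: DosingRegimen = field(default_factory=DosingRegimen)
    analyte_models: dict[str, AnalyteModel] = field(
        default_factory=default_analyte_models
    )
    schedules: dict[str, list[list[float]]] | None = None  # filled per run
    lloq_ug_ml: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LLOQ))
    uloq_ug_ml: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ULOQ))
    assay_cv: float = 0.08
    dbs_extra_cv: float = 0.06
    outlier_fraction: float = 1.0 / 9.0
    outlier_fold_range: tuple[float, float] = (2.0, 10.0)
    outlier_skips_last_dose: bool = False
    weight_range_kg: tuple[float, float] = (40.0, 77.0)
    hematocrit_mean: float = 0.355
    hematocrit_sd: float = 0.041
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if min(self.assay_cv, self.dbs_extra_cv) < 0:
            raise ValueError("CVs must be nonnegative")
        for analyte, lloq in self.lloq_ug_ml.items():
            if lloq >= self.uloq_ug_ml[analyte]:
                raise ValueError(f"LLOQ >= ULOQ for {analyte}")


# ---------------------------------------------------------------------------
# Kinetic model
# ---------------------------------------------------------------------------

def plasma_concentration(profile: SubjectProfile, analyte: str, t: float) -> float:
    """Noiseless plasma concentration (ug/ml) at ``t`` hours post first dose.

    Superposition of one-compartment first-order-absorption terms over
    the doses actually taken:

        C(t) = sum_d s * (D/V) * ka/(ka-ke) * (exp(-ke*(t-tau_d)) - exp(-ka*(t-tau_d)))

    The regimen is dosed per kg and V is apparent volume per kg, so body
    weight cancels.
    """
    if t < 0:
        raise ValueError("time must be nonnegative")
    model = profile.kinetics[analyte]
    ka, ke = model.ka_per_h, model.ke_per_h
    d_over_v = profile.regimen.dose_mg_per_kg / model.v_over_f_l_per_kg
    amp = model.exposure_scale * d_over_v * ka / (ka - ke)
    c = 0.0
    for taken, tau in zip(profile.doses_taken, profile.regimen.dose_times_h):
        if not taken or t <= tau:
            continue
        dt = t - tau
        c += amp * (np.exp(-ke * dt) - np.exp(-ka * dt))
    return max(c, 0.0)


def matrix_concentration(
    c_plasma: float,
    analyte: str,
    matrix: str,
    profile: SubjectProfile,
    rng: np.random.Generator,
    assay_cv: float = 0.08,
    dbs_extra_cv: float = 0.06,
) -> float:
    """One measured concentration in the requested matrix.

    Blood and DBS scale plasma by the analyte's blood:plasma partition
    ratio; proportional Gaussian assay noise applies to every matrix and
    DBS carries an extra independent error term (card spotting, punch and
    extraction variability).  Negative draws are truncated at zero.
    """
    if c_plasma < 0:
        raise ValueError("plasma concentration must be nonnegative")
    if matrix not in MATRICES:
        raise ValueError(f"unknown matrix {matrix!r}")
    r = profile.kinetics[analyte].r_blood_plasma
    value = c_plasma if matrix == "plasma" else r * c_plasma
    value *= 1.0 + rng.normal(0.0, assay_cv) if assay_cv > 0 else 1.0
    if matrix == "DBS" and dbs_extra_cv > 0:
        value *= 1.0 + rng.normal(0.0, dbs_extra_cv)
    return max(value, 0.0)


# ---------------------------------------------------------------------------
# Sampling schedules
# ---------------------------------------------------------------------------

VENOUS_SCHEDULE = [0.0, 2.0, 4.0, 6.0, 8.0, 8.5, 9.0, 10.0, 11.0, 12.0, 24.0]
DBS_SCHEDULE_A = [0.0, 4.0, 8.0, 9.0, 11.0, 24.0]
DBS_SCHEDULE_B = [0.0, 2.0, 6.0, 8.5, 10.0, 12.0]


def default_schedules(n_subjects: int) -> dict[str, list[list[float]]]:
    """Per-subject nominal sampling times for each matrix.

    Venous plasma and blood share one eleven-point schedule.  DBS uses
    two interleaved six-point schedules: subjects in positions 1-5 of
    each block of nine get schedule A, positions 6-9 schedule B (the
    cycle restarts for larger cohorts).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    dbs = [
        list(DBS_SCHEDULE_A) if (i % 9) < 5 else list(DBS_SCHEDULE_B)
        for i in range(n_subjects)
    ]
    return {
        "plasma": [list(VENOUS_SCHEDULE) for _ in range(n_subjects)],
        "blood": [list(VENOUS_SCHEDULE) for _ in range(n_subjects)],
        "DBS": dbs,
    }


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _subject_rng(seed: int, index: int) -> np.random.Generator:
    # independent per-subject substream: adding subjects never perturbs
    # the draws of earlier subjects
    return np.random.default_rng(np.random.SeedSequence((seed, index)))


def _draw_profile(
    config: SimulationConfig, index: int, rng: np.random.Generator
) -> SubjectProfile:
    subject_id = f"S{index + 1:02d}"
    weight = rng.uniform(*config.weight_range_kg)
    hct = float(np.clip(rng.normal(config.hematocrit_mean, config.hematocrit_sd), 0.15, 0.60))
    outlier = rng.uniform() < config.outlier_fraction
    fold = rng.uniform(*config.outlier_fold_range) if outlier else 1.0
    kinetics: dict[str, AnalyteModel] = {}
    for analyte, model in config.analyte_models.items():
        cv = model.bsv_cv
        sigma = np.sqrt(np.log1p(cv**2))
        ke = model.ke_per_h * rng.lognormal(-0.5 * sigma**2, sigma)
        v = model.v_over_f_l_per_kg * rng.lognormal(-0.5 * sigma**2, sigma)
        kinetics[analyte] = dataclasses.replace(
            model, ke_per_h=ke, v_over_f_l_per_kg=v,
            exposure_scale=model.exposure_scale * fold,
        )
    n_doses = len(config.regimen.dose_times_h)
    doses = [True] * n_doses
    if outlier and config.outlier_skips_last_dose and n_doses > 1:
        doses[-1] = False
    return SubjectProfile(
        subject_id=subject_id,
        weight_kg=weight,
        hematocrit=hct,
        regimen=config.regimen,
        kinetics=kinetics,
        doses_taken=tuple(doses),
        exposure_outlier=outlier,
    )


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort.

    Returns ``(concentrations, truth)``.  The concentration table is
    long-format with one row per subject x analyte x matrix x scheduled
    time; concentrations below the analyte's LLOQ are flagged ``blq`` and
    stored as missing.  The truth table carries every realized latent
    parameter.  Identical config and seed give identical output.
    """
    from . import qc  # local import: qc is independent of simulate

    schedules = config.schedules or default_schedules(config.n_subjects)
    conc_rows: list[dict] = []
    truth_rows: list[dict] = []
    for i in range(config.n_subjects):
        rng = _subject_rng(config.rng_seed, i)
        profile = _draw_profile(config, i, rng)
        sid = profile.subject_id
        truth_rows.append({"subject_id": sid, "analyte": "all",
                           "parameter": "weight_kg", "value": profile.weight_kg})
        truth_rows.append({"subject_id": sid, "analyte": "all",
                           "parameter": "hematocrit", "value": profile.hematocrit})
        truth_rows.append({"subject_id": sid, "analyte": "all",
                           "parameter": "exposure_outlier",
                           "value": float(profile.exposure_outlier)})
        for d, taken in enumerate(profile.doses_taken):
            truth_rows.append({"subject_id": sid, "analyte": "all",
                               "parameter": f"dose_taken_{d + 1}",
                               "value": float(taken)})
        for analyte, model in profile.kinetics.items():
            for name, value in (
                ("ka_per_h", model.ka_per_h),
                ("ke_per_h", model.ke_per_h),
                ("t_half_h", LN2 / model.ke_per_h),
                ("v_over_f_l_per_kg", model.v_over_f_l_per_kg),
                ("exposure_scale", model.exposure_scale),
                ("r_blood_plasma", model.r_blood_plasma),
            ):
                truth_rows.append({"subject_id": sid, "analyte": analyte,
                                   "parameter": name, "value": value})
        for matrix in MATRICES:
            times = schedules[matrix][i]
            for analyte in config.analyte_models:
                for t in times:
                    c_true = plasma_concentration(profile, analyte, t)
                    c_obs = matrix_concentration(
                        c_true, analyte, matrix, profile, rng,
                        assay_cv=config.assay_cv,
                        dbs_extra_cv=config.dbs_extra_cv,
                    )
                    conc_rows.append({
                        "subject_id": sid, "analyte": analyte,
                        "matrix": matrix, "time_h": t,
                        "conc_ug_ml": c_obs, "blq": 0,
                    })
    conc = pd.DataFrame(conc_rows)
    conc = qc.censor_to_range(conc, config.lloq_ug_ml, config.uloq_ug_ml)
    truth = pd.DataFrame(truth_rows)
    return conc, truth


# ---------------------------------------------------------------------------
# Auxiliary experiment generators
# ---------------------------------------------------------------------------

def generate_isr_pairs(
    conc: pd.DataFrame,
    fraction: float = 0.56,
    repeat_cv: float = 0.08,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Incurred-sample-reanalysis pairs drawn from the quantifiable rows.

    ``round(fraction * n)`` samples are selected without replacement and
    re-measured with independent proportional error ``repeat_cv``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    quant = conc[conc["blq"] == 0].reset_index(drop=True)
    if quant.empty:
        raise ValueError("no quantifiable samples to reanalyse")
    n_pick = max(1, round(fraction * len(quant)))
    idx = np.sort(rng.choice(len(quant), size=n_pick, replace=False))
    picked = quant.iloc[idx]
    original = picked["conc_ug_ml"].to_numpy(float)
    noise = rng.normal(0.0, repeat_cv, size=len(picked)) if repeat_cv > 0 else 0.0
    repeat = np.maximum(original * (1.0 + noise), 0.0)
    return pd.DataFrame({
        "sample_id": [
            f"{r.subject_id}|{r.analyte}|{r.matrix}|{r.time_h:g}"
            for r in picked.itertuples()
        ],
        "analyte": picked["analyte"].to_numpy(),
        "matrix": picked["matrix"].to_numpy(),
        "original": original,
        "repeat": repeat,
    })


def generate_partition_experiment(
    levels: dict[str, tuple[float, ...]] | None = None,
    r_true: dict[str, float] | None = None,
    n_replicates: int = 3,
    cv: float = 0.04,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Spiked blood/plasma pairs for the in vitro partition experiment.

    Whole blood (hematocrit 0.35) is spiked at the nominal levels, plasma
    obtained by centrifugation, both extracted and measured against an
    internal standard (IS).  Raw peak responses are the IS-normalised
    value times a replicate-specific IS peak area, so IS normalisation
    cancels instrument scale exactly.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    if levels is None:
        levels = {a: DEFAULT_PARTITION_LEVELS[a] for a in ANALYTES}
    if r_true is None:
        r_true = {a: default_analyte_models()[a].r_blood_plasma for a in levels}
    rows = []
    for analyte, analyte_levels in levels.items():
        r = r_true[analyte]
        for level in analyte_levels:
            for rep in range(1, n_replicates + 1):
                eps_p = rng.normal(0.0, cv) if cv > 0 else 0.0
                eps_b = rng.normal(0.0, cv) if cv > 0 else 0.0
                is_p = 1e5 * rng.lognormal(0.0, 0.05)
                is_b = 1e5 * rng.lognormal(0.0, 0.05)
                rows.append({
                    "analyte": analyte, "level": level, "replicate": rep,
                    "blood_response": r * level * max(1.0 + eps_b, 0.0) * is_b,
                    "plasma_response": level * max(1.0 + eps_p, 0.0) * is_p,
                    "is_response_blood": is_b,
                    "is_response_plasma": is_p,
                })
    return pd.DataFrame(rows)


def generate_egg_counts(
    n_subjects: int = 9,
    pre_mean_epg: float = 5000.0,
    dispersion: float = 2.0,
    cure_probability: float = 1.0,
    rng: np.random.Generator | None = None,
    uncured_reduction: float = 0.05,
) -> pd.DataFrame:
    """Quadruplicate Kato-Katz smear counts before and after treatment.

    Pre-treatment smear counts are negative-binomial with subject-level
    dispersion so that the expected eggs-per-gram (6 x sum of the four
    smears) is ``pre_mean_epg``; every simulated subject is egg-positive
    at baseline.  Each subject clears infection with probability
    ``cure_probability`` (all post counts zero); otherwise post counts
    are drawn at ``uncured_reduction`` times the pre-treatment mean.
    """
    if pre_mean_epg <= 0:
        raise ValueError("pre_mean_epg must be positive")
    if not 0 <= cure_probability <= 1:
        raise ValueError("cure_probability must be in [0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    mu_smear = pre_mean_epg / 24.0  # EPG = 6 * sum of 4 smears
    rows = []

    def smears(mu: float) -> np.ndarray:
        p = dispersion / (dispersion + mu)
        return rng.negative_binomial(dispersion, p, size=4)

    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        pre = smears(mu_smear)
        while pre.sum() == 0:  # baseline egg-positive by design
            pre = smears(mu_smear)
        cured = rng.uniform() < cure_probability
        post = np.zeros(4, dtype=int) if cured else smears(mu_smear * uncured_reduction)
        for visit, counts in (("pre", pre), ("post", post)):
            rows.append({"subject_id": sid, "visit": visit,
                         "c1": int(counts[0]), "c2": int(counts[1]),
                         "c3": int(counts[2]), "c4": int(counts[3])})
    return pd.DataFrame(rows)
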