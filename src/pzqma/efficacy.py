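"""Parasitological efficacy statistics from Kato-Katz egg counts.

Each subject contributes quadruplicate Kato-Katz thick smears (duplicate
smears from each of two stool samples) before and 3 weeks after
treatment.  Eggs per gram of stool (EPG) is six times the summed smear
counts.  Group outcomes are the geometric mean EPG before and after
treatment, the cure rate (percentage of egg-positive subjects that
become egg-negative) and the egg-reduction rate (ERR), the percentage
drop in geometric-mean EPG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EPG_FACTOR = 6  # 41.7 mg Kato-Katz template: counts-to-EPG multiplier

#: EPG breakpoints for infection-intensity reporting classes
INTENSITY_CLASSES = (("light", 0, 1_000), ("moderate", 1_000, 10_000),
                     ("heavy", 10_000, np.inf))


@dataclass
class EfficacySummary:
    n_subjects: int
    gm_pre_epg: float
    gm_post_epg: float
    cure_rate_pct: float
    err_pct: float
    gm_shifted: bool = False  # geometric means used the log(x+1) form


def epg(smear_counts) -> int:
    """Eggs per gram from one subject-visit's four smear counts."""
    counts = list(smear_counts)
    if len(counts) != 4:
        raise ValueError("expected exactly 4 smear counts")
    if any(c < 0 or int(c) != c for c in counts):
        raise ValueError("smear counts must be nonnegative integers")
    return EPG_FACTOR * int(sum(counts))


def intensity_class(epg_value: float) -> str:
    """Infection-intensity class: light <1000, moderate 1000-10000,
    heavy >10000 EPG."""
    for name, low, high in INTENSITY_CLASSES:
        if low <= epg_value < high or (name == "moderate" and epg_value == high):
            return name
    return "heavy"


def geometric_mean_epg(values) -> tuple[float, bool]:
    """Geometric mean of EPG values; returns ``(gm, shifted)``.

    Zeros make the plain geometric mean degenerate, so when any value is
    zero the shifted form exp(mean(log(x+1))) - 1 is used and flagged;
    an all-zero input gives 0.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    if np.any(v < 0):
        raise ValueError("EPG values must be nonnegative")
    if np.all(v == 0):
        return 0.0, False
    if np.any(v == 0):
        return float(np.expm1(np.mean(np.log1p(v)))), True
    return float(np.exp(np.mean(np.log(v)))), False


def cure_rate(eggs: pd.DataFrame) -> float:
    """Percentage of assessable egg-positive subjects that are
    egg-negative after treatment.

    Assessable = pre-treatment EPG > 0 and a post-treatment record
    present; subjects without a post record are excluded (logged).
    """
    per = _per_subject_epg(eggs)
    assessable = per.dropna(subset=["post"])
    missing = len(per) - len(assessable)
    if missing:
        logger.info("cure_rate: %d subjects without post-treatment record "
                    "excluded", missing)
    assessable = assessable[assessable["pre"] > 0]
    if assessable.empty:
        raise ValueError("no assessable egg-positive subjects")
    return 100.0 * float((assessable["post"] == 0).mean())


def egg_reduction_rate(gm_pre: float, gm_post: float) -> float:
    """ERR = 100 * (1 - GM_post / GM_pre); undefined when GM_pre is 0."""
    if gm_pre <= 0:
        raise ValueError("egg-reduction rate undefined for zero pre-treatment "
                         "geometric mean")
    return 100.0 * (1.0 - gm_post / gm_pre)


def efficacy_summary(eggs: pd.DataFrame) -> EfficacySummary:
    """Cohort summary: geometric means, cure rate and ERR."""
    per = _per_subject_epg(eggs).dropna(subset=["pre", "post"])
    gm_pre, shifted_pre = geometric_mean_epg(per["pre"])
    gm_post, shifted_post = geometric_mean_epg(per["post"])
    return EfficacySummary(
        n_subjects=len(per),
        gm_pre_epg=gm_pre,
        gm_post_epg=gm_post,
        cure_rate_pct=cure_rate(eggs),
        err_pct=egg_reduction_rate(gm_pre, gm_post),
        gm_shifted=shifted_pre or shifted_post,
    )


def _per_subject_epg(eggs: pd.DataFrame) -> pd.DataFrame:
    count_cols = ["c1", "c2", "c3", "c4"]
    rows = {}
    for r in eggs.itertuples():
        value = epg([getattr(r, c) for c in count_cols])
        rows.setdefault(r.subject_id, {})[r.visit] = value
    out = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=["pre", "post"]
    )
    out.index.name = "subject_id"
    return out
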