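"""Independent reference implementations used only by the test suite.

Each oracle recomputes a quantity from first principles with explicit
loops / fine grids, deliberately avoiding the code paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


def trapezoid_fine_grid(times, concs, n_subdiv: int = 100_000) -> float:
    """AUC of the piecewise-linear interpolant by dense summation.

    Each observed segment is subdivided separately so the interpolation
    knots always lie on the integration grid.
    """
    times = np.asarray(times, float)
    concs = np.asarray(concs, float)
    per_segment = max(2, n_subdiv // max(1, times.size - 1))
    total = 0.0
    for i in range(times.size - 1):
        grid = np.linspace(times[i], times[i + 1], per_segment)
        values = np.interp(grid, times, concs)
        h = (times[i + 1] - times[i]) / (per_segment - 1)
        total += h * (values.sum() - 0.5 * (values[0] + values[-1]))
    return float(total)


def anova_variance_components(ratios_by_subject: list[list[float]]):
    """One-way ANOVA variance components for repeated-measures limits of
    agreement, written directly from the defining sums.

    Returns (grand_mean, sigma2_between, sigma2_within, sd_total).
    """
    k = len(ratios_by_subject)
    all_values = [v for group in ratios_by_subject for v in group]
    n_total = len(all_values)
    counts = [len(g) for g in ratios_by_subject]
    grand = sum(all_values) / n_total
    subject_means = [sum(g) / len(g) for g in ratios_by_subject]
    ss_between = sum(
        n_i * (mi - grand) ** 2 for n_i, mi in zip(counts, subject_means)
    )
    ss_within = sum(
        (v - mi) ** 2
        for g, mi in zip(ratios_by_subject, subject_means)
        for v in g
    )
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n_total - k)
    n0 = (n_total - sum(n_i**2 for n_i in counts) / n_total) / (k - 1)
    var_within = ms_within
    var_between = max(0.0, (ms_between - ms_within) / n0)
    return grand, var_between, var_within, math.sqrt(var_between + var_within)


def superposition_terms(dose_over_v, scale, ka, ke, dose_times, t):
    """Multi-dose concentration as an explicit sum of shifted single-dose
    curves, each term evaluated independently."""
    total = 0.0
    for tau in dose_times:
        if t <= tau:
            continue
        dt = t - tau
        total += (scale * dose_over_v * ka / (ka - ke)
                  * (math.exp(-ke * dt) - math.exp(-ka * dt)))
    return total
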