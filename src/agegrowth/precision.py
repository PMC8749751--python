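"""Reader-agreement statistics for repeated band counts.

All statistics operate on integer band counts. Per-fish dispersion
statistics (APE, CV) use the mean reading of that fish as the reference;
fish whose readings are all zero carry no information about relative
error and are excluded with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PrecisionReport:
    pa_exact: float      # % agreement, |a-b| == 0
    pa_within_1: float   # % agreement within +/-1 band
    pa_within_2: float   # % agreement within +/-2 bands
    ape: float           # average percent error, %
    cv: float            # mean coefficient of variation, %
    n_compared: int


@dataclass(frozen=True)
class SymmetryTestResult:
    statistic: float
    df: int
    p_value: float


def percent_agreement(counts_a, counts_b, tolerance: int = 0) -> float:
    """Percent of paired counts differing by at most ``tolerance``."""
    a = np.asarray(counts_a)
    b = np.asarray(counts_b)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("counts_a and counts_b must be equal-length, non-empty")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    return 100.0 * float(np.mean(np.abs(a - b) <= tolerance))


def _valid_matrix(count_matrix) -> np.ndarray:
    mat = np.asarray(count_matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("count_matrix must be fish x readings with >= 2 readings")
    means = mat.mean(axis=1)
    bad = means <= 0
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} fish with zero mean count from precision stats",
            stacklevel=3,
        )
        mat = mat[~bad]
    if mat.shape[0] == 0:
        raise ValueError("no fish with positive mean count")
    return mat


def average_percent_error(count_matrix) -> float:
    """Beamish-Fournier APE: per-fish mean absolute deviation from the fish
    mean, relative to that mean, averaged over fish. Returned in percent."""
    mat = _valid_matrix(count_matrix)
    means = mat.mean(axis=1, keepdims=True)
    per_fish = 100.0 * np.mean(np.abs(mat - means) / means, axis=1)
    return float(per_fish.mean())


def cv_ageing(count_matrix) -> float:
    """Chang's CV: per-fish sample standard deviation (divisor R-1) over the
    fish mean, averaged over fish. Returned in percent."""
    mat = _valid_matrix(count_matrix)
    means = mat.mean(axis=1)
    sds = mat.std(axis=1, ddof=1)
    return float(np.mean(100.0 * sds / means))


def precision_report(counts_a, counts_b) -> PrecisionReport:
    """Full two-reader report: PA at tolerances 0/1/2 plus APE and CV."""
    a = np.asarray(counts_a)
    b = np.asarray(counts_b)
    mat = np.column_stack([a, b])
    return PrecisionReport(
        pa_exact=percent_agreement(a, b, 0),
        pa_within_1=percent_agreement(a, b, 1),
        pa_within_2=percent_agreement(a, b, 2),
        ape=average_percent_error(mat),
        cv=cv_ageing(mat),
        n_compared=int(a.size),
    )


def bowker_symmetry(cross_tab) -> SymmetryTestResult:
    """Bowker's test of symmetry on a square reader-1 x reader-2 table.

    Only informative off-diagonal pairs (n_ij + n_ji > 0) contribute; df is
    the number of such pairs. With no informative pair the test is
    undefined and (0, 0, 1) is returned.
    """
    tab = np.asarray(cross_tab, dtype=float)
    if tab.ndim != 2 or tab.shape[0] != tab.shape[1]:
        raise ValueError("cross_tab must be square")
    stat = 0.0
    df = 0
    k = tab.shape[0]
    for i in range(k):
        for j in range(i + 1, k):
            tot = tab[i, j] + tab[j, i]
            if tot > 0:
                stat += (tab[i, j] - tab[j, i]) ** 2 / tot
                df += 1
    if df == 0:
        warnings.warn("Bowker test undefined: no informative off-diagonal pairs")
        return SymmetryTestResult(0.0, 0, 1.0)
    return SymmetryTestResult(float(stat), df, float(stats.chi2.sf(stat, df)))


def counts_to_crosstab(counts_a, counts_b) -> pd.DataFrame:
    """Square contingency table of reader-1 vs reader-2 counts over the
    union of observed levels (for Bowker's test)."""
    a = pd.Series(counts_a)
    b = pd.Series(counts_b)
    levels = sorted(set(a) | set(b))
    tab = pd.crosstab(a, b).reindex(index=levels, columns=levels, fill_value=0)
    tab.index.name = "reader_1"
    tab.columns.name = "reader_2"
    return tab


def age_bias_table(counts_a, counts_b) -> pd.DataFrame:
    """Mean/sd of reader-2 counts at each reader-1 count (age-bias plot data)."""
    a = np.asarray(counts_a)
    b = np.asarray(counts_b)
    if a.shape != b.shape:
        raise ValueError("counts_a and counts_b must be equal length")
    frame = pd.DataFrame({"reader_1": a, "reader_2": b})
    out = (
        frame.groupby("reader_1")["reader_2"]
        .agg(n="size", mean="mean", sd="std")
        .reset_index()
    )
    out["sd"] = out["sd"].fillna(0.0)
    return out
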