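"""Band-formation periodicity: marginal increment ratio, centrum edge
analysis, and the associated nonparametric tests."""

from __future__ import annotations

import itertools
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import SpecimenRecord


class MirExclusion(ValueError):
    """Specimen cannot contribute a marginal increment ratio."""


def marginal_increment_ratio(vr: float, r_n: float, r_n_minus_1: float) -> float:
    """(VR - R_n) / (R_n - R_{n-1}): margin width beyond the last band,
    scaled by the previous band-pair width.

    ``r_n``/``r_n_minus_1`` are the radii of the last and penultimate
    translucent bands (the birth band counts in this indexing, so a
    two-band fish has exactly one MIR).
    """
    if r_n == r_n_minus_1:
        raise ZeroDivisionError("last and penultimate band radii coincide")
    if not (r_n_minus_1 < r_n <= vr):
        raise ValueError(f"need r_n_minus_1 < r_n <= vr, got {r_n_minus_1}, {r_n}, {vr}")
    return (vr - r_n) / (r_n - r_n_minus_1)


def mir_records(specimens: Sequence[SpecimenRecord]) -> pd.DataFrame:
    """Per-specimen MIR table. Fish with fewer than two bands (birth band
    only) are excluded, per the measurement protocol."""
    rows = []
    for s in specimens:
        if len(s.band_radii) < 2:
            continue
        rows.append(
            {
                "specimen_id": s.specimen_id,
                "capture_month": s.capture_month,
                "mir": marginal_increment_ratio(
                    s.vertebral_radius, s.band_radii[-1], s.band_radii[-2]
                ),
            }
        )
    return pd.DataFrame(rows, columns=["specimen_id", "capture_month", "mir"])


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square approximate p.

    All-tied data yield H = 0 (the tie-correction limit) rather than an
    error.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, df, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), df, float(p)


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Sequence | None = None,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Dunn's pairwise mean-rank comparisons after a Kruskal-Wallis test.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j)) with
    the usual tie term T = sum(t^3 - t) / (12(N-1)). Two-sided p-values,
    Bonferroni-adjusted by default ('none' disables adjustment).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    if len(arrays) < 3:
        warnings.warn("post-hoc comparisons with fewer than 3 groups are uninformative")
    if labels is None:
        labels = list(range(len(arrays)))
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    # mean rank per group
    mean_ranks = []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start : start + a.size].mean())
        start += a.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = len(arrays) * (len(arrays) - 1) // 2
    rows = []
    for (i, a), (j, b) in itertools.combinations(enumerate(arrays), 2):
        se = np.sqrt(var_base * (1.0 / a.size + 1.0 / b.size))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * n_pairs) if adjust == "bonferroni" else p_raw
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "z": float(z),
                "p_raw": float(p_raw),
                "p_adjusted": float(p_adj),
            }
        )
    return pd.DataFrame(rows)


def edge_analysis(specimens: Sequence[SpecimenRecord]) -> pd.DataFrame:
    """Monthly edge-type proportions plus MIR mean/SE.

    Months never observed get n = 0 rows with NaN proportions so the
    output always spans January-December.
    """
    mir = mir_records(specimens)
    rows = []
    for month in range(1, 13):
        in_month = [s for s in specimens if s.capture_month == month]
        classified = [s for s in in_month if s.edge_type in ("opaque", "translucent")]
        n_trans = sum(1 for s in classified if s.edge_type == "translucent")
        m = mir.loc[mir["capture_month"] == month, "mir"]
        rows.append(
            {
                "month": month,
                "n": len(in_month),
                "n_classified": len(classified),
                "prop_translucent": n_trans / len(classified) if classified else np.nan,
                "prop_opaque": 1 - n_trans / len(classified) if classified else np.nan,
                "n_mir": int(m.size),
                "mean_mir": float(m.mean()) if m.size else np.nan,
                "se_mir": float(m.std(ddof=1) / np.sqrt(m.size)) if m.size > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov D and asymptotic p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)
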