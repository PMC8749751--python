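"""Radius-length regression and proportion-based back-calculation.

Orientation note (load-bearing): the regression is of vertebral radius on
total length, ``VR = a + b * TL`` (mm on cm). The back-calculation formula
``L_i = -(a/b) + (L_c + a/b) * (VR_i / VR_c)`` is the scale-proportional
hypothesis under exactly this orientation, and is exact at capture
(VR_i = VR_c gives L_c) for any (a, b).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .ages import AgeScheme, age_for_band, assign_age
from .types import SpecimenRecord, specimens_to_frame


@dataclass(frozen=True)
class RadiusLengthRegression:
    group: str
    a: float            # intercept, mm
    b: float            # slope, mm per cm
    r_squared: float
    n: int
    p_value: float      # slope t-test
    orientation: str = "radius_on_length"


@dataclass(frozen=True)
class SlopeElevationTest:
    slope_f: float
    slope_p: float
    elevation_f: float | None
    elevation_p: float | None
    note: str = ""


def fit_radius_length(
    specimens: Sequence[SpecimenRecord], group_by_sex: bool = True
) -> dict[str, RadiusLengthRegression]:
    """OLS of vertebral radius on total length, per sex or pooled."""
    frame = specimens_to_frame(specimens)
    groups = frame.groupby("sex") if group_by_sex else [("all", frame)]
    out: dict[str, RadiusLengthRegression] = {}
    for label, sub in groups:
        if len(sub) < 3:
            raise ValueError(f"group {label!r}: need >= 3 specimens, got {len(sub)}")
        if sub["total_length"].nunique() == 1:
            raise ValueError(f"group {label!r}: total_length is constant")
        res = stats.linregress(sub["total_length"], sub["vertebral_radius"])
        out[str(label)] = RadiusLengthRegression(
            group=str(label),
            a=float(res.intercept),
            b=float(res.slope),
            r_squared=float(res.rvalue**2),
            n=len(sub),
            p_value=float(res.pvalue),
        )
    return out


def compare_regressions(
    specimens: Sequence[SpecimenRecord], alpha: float = 0.05
) -> SlopeElevationTest:
    """Two-stage ANCOVA comparison of the sex-specific radius-length lines.

    Stage 1 tests slope equality (length x sex interaction). Only if slopes
    are homogeneous does stage 2 test elevations with a pooled slope;
    otherwise the elevation test is refused (fields None).
    """
    frame = specimens_to_frame(specimens)
    if frame["sex"].nunique() < 2:
        raise ValueError("need both sexes to compare regressions")
    full = smf.ols("vertebral_radius ~ total_length * sex", data=frame).fit()
    slope_test = full.f_test("total_length:sex[T.male] = 0")
    slope_f, slope_p = float(slope_test.fvalue), float(slope_test.pvalue)
    if slope_p < alpha:
        return SlopeElevationTest(
            slope_f,
            slope_p,
            None,
            None,
            note="slopes differ; elevation test not applicable",
        )
    reduced = smf.ols("vertebral_radius ~ total_length + sex", data=frame).fit()
    elev_test = reduced.f_test("sex[T.male] = 0")
    return SlopeElevationTest(slope_f, slope_p, float(elev_test.fvalue), float(elev_test.pvalue))


def back_calculate(l_c: float, vr_c: float, vr_i: float, a: float, b: float) -> float:
    """Length at the age when the structure radius was ``vr_i``."""
    if b == 0:
        raise ValueError("regression slope b must be nonzero")
    if vr_c <= 0:
        raise ValueError("vr_c must be > 0")
    if not 0 < vr_i <= vr_c:
        raise ValueError(f"vr_i must be in (0, vr_c], got {vr_i} vs vr_c={vr_c}")
    ratio = a / b
    return -ratio + (l_c + ratio) * (vr_i / vr_c)


def expand_dataset(
    specimens: Sequence[SpecimenRecord],
    scheme: AgeScheme,
    regression: RadiusLengthRegression,
    include_observed: bool = True,
) -> pd.DataFrame:
    """Expand specimens into the age-length records used for growth fitting.

    Per specimen: one back-calculated record per band (birth band
    included, ages from :func:`age_for_band`) plus, optionally, the
    observed capture record. Columns: specimen_id, band_index, age,
    length, source.
    """
    rows = []
    skipped = 0
    for s in specimens:
        if not s.band_radii:
            skipped += 1
            continue
        for i, radius in enumerate(s.band_radii):
            rows.append(
                {
                    "specimen_id": s.specimen_id,
                    "band_index": i,
                    "age": age_for_band(i, scheme),
                    "length": back_calculate(
                        s.total_length, s.vertebral_radius, radius, regression.a, regression.b
                    ),
                    "source": "back_calculated",
                }
            )
        if include_observed:
            assignment = assign_age(s.band_count, s.capture_month, scheme, s.specimen_id)
            rows.append(
                {
                    "specimen_id": s.specimen_id,
                    "band_index": len(s.band_radii),
                    "age": assignment.decimal_age,
                    "length": s.total_length,
                    "source": "observed",
                }
            )
    if skipped:
        warnings.warn(f"skipped {skipped} specimens without band radii")
    out = pd.DataFrame(
        rows, columns=["specimen_id", "band_index", "age", "length", "source"]
    )
    # sanity: within a specimen, back-calculated lengths follow band order
    for sid, sub in out[out["source"] == "back_calculated"].groupby("specimen_id"):
        lengths = sub.sort_values("band_index")["length"].to_numpy()
        if np.any(np.diff(lengths) < 0):
            raise ValueError(f"{sid}: back-calculated lengths decrease across bands")
    return out
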