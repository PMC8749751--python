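"""Synthetic specimen populations with the statistical structure the
analysis assumes.

The generator and the likelihood are deliberately conjugate: length error
is multiplicative lognormal, band radii lie on the radius-length
regression line (noise-free by default), so back-calculation followed by
growth fitting recovers the generating parameters exactly in the
noise-free limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ages import AgeScheme, age_for_band, assign_age, months_since_formation
from .growth import GrowthParams, predict_length
from .io import load_fixture
from .types import ReaderCountRecord, SpecimenRecord

#: Generating growth truth: the selected 3-parameter von Bertalanffy fit
#: of the capture-date-adjusted dataset.
DEFAULT_TRUTH = GrowthParams("VBG3", l_inf=81.87, k=0.168, t0=-1.384)


def _table3_age_probs() -> tuple[np.ndarray, np.ndarray]:
    marg = load_fixture("table3").age_marginal()
    return marg.index.to_numpy(), marg.to_numpy() / marg.sum()


def _table1_month_probs() -> tuple[np.ndarray, np.ndarray]:
    t1 = load_fixture("table1")
    return t1.index.to_numpy(), t1.to_numpy() / t1.sum()


@dataclass
class SyntheticConfig:
    n_specimens: int = 245
    truth: GrowthParams = field(default_factory=lambda: DEFAULT_TRUTH)
    sigma_length: float = 0.06          # lognormal scale on lengths
    radius_a: float = -0.65             # VR = a + b * TL
    radius_b: float = 0.08
    vr_noise_sd: float = 0.05           # mm, on the capture radius
    band_radius_noise_sd: float = 0.0   # mm, on band radii (0 = on the line)
    band_formation_month: int = 4
    birth_month: int = 8
    # (p_exact, p +/-1 split evenly, p +/-2 split evenly) for reader 2
    reader_error: tuple[float, float, float] = (0.69, 0.26, 0.05)
    # seasonal MIR settings
    mir_amplitude: float = 0.8
    mir_noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.reader_error) - 1.0) > 1e-9:
            raise ValueError("reader_error probabilities must sum to 1")
        if any(p < 0 for p in self.reader_error):
            raise ValueError("reader_error probabilities must be non-negative")
        for scale in (self.sigma_length, self.vr_noise_sd, self.band_radius_noise_sd,
                      self.mir_noise_sd):
            if scale < 0:
                raise ValueError("noise scales must be >= 0")

    def scheme(self) -> AgeScheme:
        return AgeScheme(
            "adjusted_dc",
            birth_month=self.birth_month,
            band_formation_month=self.band_formation_month,
        )


@dataclass
class SyntheticTruth:
    """Per-specimen generating values, exact on the truth curve."""

    specimens: pd.DataFrame   # specimen_id, band_count, true_age, true_length
    bands: pd.DataFrame       # specimen_id, band_index, band_age, band_length


def generate_age_length(
    n: int,
    truth: GrowthParams = DEFAULT_TRUTH,
    sigma_length: float = 0.06,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Plain age-length sample: age groups from the combined-table marginal
    (uniform within group), lengths from the truth curve times lognormal
    noise. The minimal input growth fitting needs."""
    if rng is None:
        rng = np.random.default_rng(seed)
    groups, probs = _table3_age_probs()
    drawn = rng.choice(groups, size=n, p=probs)
    ages = drawn + rng.uniform(0.0, 1.0, size=n)
    lengths = np.asarray(predict_length(truth, ages)) * np.exp(
        rng.normal(0.0, sigma_length, size=n)
    )
    return ages, lengths


def generate_population(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[list[SpecimenRecord], SyntheticTruth]:
    """Full specimen population: band counts from the combined-table
    marginal (groups >= 1), capture months from the monthly sample-size
    table, ages under the capture-date-adjusted scheme, vertebral and
    band radii through the radius-length line."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    scheme = config.scheme()
    groups, probs = _table3_age_probs()
    keep = groups >= 1
    groups, probs = groups[keep], probs[keep] / probs[keep].sum()
    months, month_probs = _table1_month_probs()

    specimens: list[SpecimenRecord] = []
    spec_rows = []
    band_rows = []
    for idx in range(config.n_specimens):
        sid = f"S{idx:05d}"
        band_count = int(rng.choice(groups, p=probs))
        month = int(rng.choice(months, p=month_probs))
        true_age = assign_age(band_count, month, scheme).decimal_age
        true_length = float(predict_length(config.truth, true_age))
        obs_length = true_length * float(np.exp(rng.normal(0.0, config.sigma_length)))

        band_ages = np.array([age_for_band(i, scheme) for i in range(band_count + 1)])
        band_lengths = np.asarray(predict_length(config.truth, band_ages))
        radii = config.radius_a + config.radius_b * band_lengths
        if config.band_radius_noise_sd > 0:
            radii = np.sort(radii + rng.normal(0.0, config.band_radius_noise_sd, radii.size))
        if radii[0] <= 0:
            raise ValueError("radius regression yields non-positive birth-band radius")

        vr = config.radius_a + config.radius_b * obs_length
        if config.vr_noise_sd > 0:
            vr += float(rng.normal(0.0, config.vr_noise_sd))
        vr = max(vr, float(radii[-1]) * (1.0 + 1e-9))  # edge cannot be inside a band

        elapsed = months_since_formation(month, scheme)
        p_translucent = max(0.0, 1.0 - elapsed / 12.0)
        edge = "translucent" if rng.uniform() < p_translucent else "opaque"

        specimens.append(
            SpecimenRecord(
                specimen_id=sid,
                sex="female",
                total_length=obs_length,
                capture_year=2014,
                capture_month=month,
                vertebral_radius=float(vr),
                band_radii=tuple(radii),
                edge_type=edge,
            )
        )
        spec_rows.append(
            {"specimen_id": sid, "band_count": band_count, "true_age": true_age,
             "true_length": true_length}
        )
        for i, (ba, bl) in enumerate(zip(band_ages, band_lengths)):
            band_rows.append(
                {"specimen_id": sid, "band_index": i, "band_age": float(ba),
                 "band_length": float(bl)}
            )
    truth = SyntheticTruth(
        specimens=pd.DataFrame(spec_rows),
        bands=pd.DataFrame(band_rows),
    )
    return specimens, truth


def generate_reader_counts(
    true_counts: dict[str, int] | pd.DataFrame,
    reader_error: tuple[float, float, float] = (0.69, 0.26, 0.05),
    seed: int = 0,
) -> list[ReaderCountRecord]:
    """Two-reader counts: reader 1 reads the truth; reader 2 adds a
    symmetric deviation of 0/±1/±2 bands (clipped at zero, which makes the
    realized error minutely asymmetric for counts < 2)."""
    if isinstance(true_counts, pd.DataFrame):
        true_counts = dict(zip(true_counts["specimen_id"], true_counts["band_count"]))
    p0, p1, p2 = reader_error
    offsets = np.array([0, -1, 1, -2, 2])
    probs = np.array([p0, p1 / 2, p1 / 2, p2 / 2, p2 / 2])
    rng = np.random.default_rng(seed)
    records = []
    for sid, count in true_counts.items():
        dev = int(rng.choice(offsets, p=probs))
        records.append(ReaderCountRecord(sid, 1, 1, int(count)))
        records.append(ReaderCountRecord(sid, 2, 1, max(int(count) + dev, 0)))
    return records


def generate_seasonal_mir(
    config: SyntheticConfig,
    seed: int | None = None,
    n_per_month: int = 20,
) -> pd.DataFrame:
    """MIR observations with an annual saw-tooth cycle.

    Expected MIR grows linearly with months since the band completed and
    resets the month after the formation month, so the monthly mean peaks
    in the formation month itself and bottoms out right after it.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    reset = config.band_formation_month % 12 + 1  # month after formation
    rows = []
    i = 0
    for month in range(1, 13):
        phase = (month - reset) % 12 / 11.0  # 0 just after formation, 1 at formation
        expected = config.mir_amplitude * phase
        for _ in range(n_per_month):
            mir = max(0.0, expected + float(rng.normal(0.0, config.mir_noise_sd)))
            rows.append(
                {"specimen_id": f"M{i:05d}", "capture_month": month, "mir": mir}
            )
            i += 1
    return pd.DataFrame(rows)
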