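"""Synthetic inputs for the full pipeline.

Three generators and one packaged fixture:

* :func:`generate_power_cohort` — regional band-power tables for three groups
  (left-focus patients LtMTLE, right-focus patients RtMTLE, healthy controls
  CTR) under a log-normal power model with known ground-truth effects. The
  defaults mirror the study conditions: 102 controls, 16 left and 19 right
  patients, seven bands x four regions x two hemispheres, a small nonzero
  control lateralization bias, and an ipsilateral multiplicative power
  elevation in the patient groups that is strongest in temporal/parietal
  theta.
* :func:`generate_recording` — multi-channel sensor time series on the toy
  geometry: gain-projected sinusoidal sources plus white noise plus a
  power-line sinusoid, with optional injected high-amplitude artifact epochs.
* :func:`generate_source_image_cohort` — per-subject source-space power images
  with the same region-level effect structure, feeding the mass-univariate
  group analysis directly.
* :func:`load_table1_fixture` — the packaged per-patient clinical table
  (35 unilateral MTLE cases with EEG/MRI/PET findings and the dipole-fit (ECD)
  and linear-SVM lateralization calls).

Power model
-----------
For subject i of group g, band f, region r, hemisphere h:

    log P = mu_f + s_i + a(h) * artanh(b[f,r]) + delta[f,r] * [h = ipsi(g)] + eps

with a(L) = +1, a(R) = -1, subject scaling s_i ~ N(0, 0.3^2) shared across all
cells (it cancels in any laterality index), and eps ~ N(0, sigma^2) i.i.d. per
cell, sigma = sqrt(log(1 + cv^2)) so that cv is the coefficient of variation
of power. In the noise-free limit the laterality index equals b[f,r] for
controls exactly, and the ipsilateral elevation shifts the log-power ratio by
delta (left-focus patients up on the left, right-focus on the right).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .bands import (
    BAND_NAMES,
    GROUP_CTR,
    GROUP_LT,
    GROUP_RT,
    HEMISPHERES,
    REGIONS,
    BandDefinition,
    CANONICAL_BANDS,
)
from .preprocess import Recording
from .sourcepower import ForwardModel, fibonacci_hemisphere, gain_kernel

__all__ = [
    "SynthConfig",
    "SubjectRecord",
    "FixtureError",
    "default_effect_delta",
    "default_baseline_li",
    "generate_power_cohort",
    "generate_recording",
    "generate_source_image_cohort",
    "load_table1_fixture",
]

#: Typical band power levels (arbitrary units^2), a 1/f-like profile with an
#: alpha bump; only their logs' differences matter to any laterality quantity.
_BASE_POWER = {
    "delta": 100.0,
    "theta": 60.0,
    "alpha": 80.0,
    "beta": 40.0,
    "low_gamma": 15.0,
    "high_gamma": 8.0,
    "hfo": 4.0,
}

#: Between-subject SD of the shared log-power scaling.
_SUBJECT_SD = 0.3


def default_effect_delta() -> pd.DataFrame:
    """Ipsilateral log-power elevation per band x region.

    The profile concentrates the effect in temporal and parietal cortex with a
    theta maximum and smaller elevations elsewhere, matching the reported
    topography of oscillatory power changes in unilateral MTLE.
    """
    data = {
        #               frontal temporal parietal occipital
        "delta": [0.05, 0.10, 0.10, 0.05],
        "theta": [0.25, 0.60, 0.60, 0.25],
        "alpha": [0.20, 0.40, 0.45, 0.20],
        "beta": [0.15, 0.35, 0.40, 0.15],
        "low_gamma": [0.15, 0.30, 0.35, 0.15],
        "high_gamma": [0.10, 0.25, 0.35, 0.10],
        "hfo": [0.05, 0.15, 0.20, 0.05],
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=list(REGIONS))


def default_baseline_li() -> pd.DataFrame:
    """Small nonzero control lateralization bias per band x region."""
    row = {"frontal": 0.03, "temporal": 0.05, "parietal": -0.04, "occipital": 0.02}
    return pd.DataFrame({r: [v] * len(BAND_NAMES) for r, v in row.items()}, index=list(BAND_NAMES))


def _as_band_region_frame(value, bands, regions) -> pd.DataFrame:
    """Coerce a scalar / dict / DataFrame to a bands x regions float frame."""
    if np.isscalar(value):
        return pd.DataFrame(float(value), index=list(bands), columns=list(regions))
    frame = pd.DataFrame(value)
    frame = frame.reindex(index=list(bands), columns=list(regions))
    if frame.isna().any().any():
        raise ValueError("per-band x region table does not cover all bands/regions")
    return frame.astype(float)


@dataclass
class SynthConfig:
    """Ground-truth parameters of a synthetic cohort."""

    n_ctr: int = 102
    n_lt: int = 16
    n_rt: int = 19
    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS
    regions: tuple[str, ...] = REGIONS
    baseline_li_mean: object = None  # scalar | dict | DataFrame, bands x regions
    effect_delta: object = None
    noise_cv: float = 0.3
    age_range: tuple[float, float] = (8.0, 75.0)
    seed: int = 0
    _baseline: pd.DataFrame = field(init=False, repr=False)
    _delta: pd.DataFrame = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if min(self.n_ctr, self.n_lt, self.n_rt) < 2:
            raise ValueError("each group needs at least 2 subjects")
        if len(self.bands) == 0:
            raise ValueError("at least one band required")
        if self.noise_cv <= 0:
            raise ValueError("noise_cv must be positive")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must be (min, max) with min < max")
        band_names = tuple(b.name for b in self.bands)
        base = default_baseline_li() if self.baseline_li_mean is None else self.baseline_li_mean
        delta = default_effect_delta() if self.effect_delta is None else self.effect_delta
        self._baseline = _as_band_region_frame(base, band_names, self.regions)
        self._delta = _as_band_region_frame(delta, band_names, self.regions)
        if (np.abs(self._baseline.to_numpy()) >= 1).any():
            raise ValueError("baseline_li_mean entries must lie in (-1, 1)")
        if (self._delta.to_numpy() < 0).any():
            raise ValueError("effect_delta must be non-negative")

    @property
    def band_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bands)

    @property
    def baseline_table(self) -> pd.DataFrame:
        return self._baseline.copy()

    @property
    def delta_table(self) -> pd.DataFrame:
        return self._delta.copy()

    @property
    def log_sigma(self) -> float:
        return float(np.sqrt(np.log1p(self.noise_cv**2)))


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's metadata plus their long-format power rows."""

    subject_id: str
    group: str
    age: float
    powers: pd.DataFrame


_IPSI = {GROUP_LT: "L", GROUP_RT: "R"}


def generate_power_cohort(config: SynthConfig) -> pd.DataFrame:
    """Draw a synthetic cohort's regional power table (tidy long format).

    Returns columns (subject_id, group, age, band, region, hemisphere, power);
    all powers strictly positive, deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    bands = config.band_names
    regions = config.regions
    n_b, n_r = len(bands), len(regions)
    mu_band = np.array([np.log(_BASE_POWER.get(b, 10.0)) for b in bands])
    asym = np.arctanh(config._baseline.to_numpy())  # (n_b, n_r)
    delta = config._delta.to_numpy()
    sigma = config.log_sigma

    frames = []
    groups = ((GROUP_CTR, config.n_ctr), (GROUP_LT, config.n_lt), (GROUP_RT, config.n_rt))
    prefix = {GROUP_CTR: "CTR", GROUP_LT: "LT", GROUP_RT: "RT"}
    for group, n in groups:
        ipsi = _IPSI.get(group)
        subj_scale = rng.normal(0.0, _SUBJECT_SD, size=n)
        ages = rng.uniform(*config.age_range, size=n)
        # log-power array (n, n_b, n_r, 2); hemisphere axis ordered (L, R)
        logp = mu_band[None, :, None, None] + subj_scale[:, None, None, None]
        logp = logp + np.stack([asym, -asym], axis=-1)[None]
        if ipsi is not None:
            h_idx = HEMISPHERES.index(ipsi)
            shift = np.zeros((n_b, n_r, 2))
            shift[:, :, h_idx] = delta
            logp = logp + shift[None]
        logp = logp + rng.normal(0.0, sigma, size=(n, n_b, n_r, 2))
        idx = pd.MultiIndex.from_product(
            [[f"{prefix[group]}{i + 1:03d}" for i in range(n)], bands, regions, HEMISPHERES],
            names=["subject_id", "band", "region", "hemisphere"],
        )
        df = pd.DataFrame({"power": np.exp(logp).ravel()}, index=idx).reset_index()
        df.insert(1, "group", group)
        df.insert(2, "age", np.repeat(ages, n_b * n_r * 2))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def iter_subjects(cohort: pd.DataFrame):
    """Yield :class:`SubjectRecord` views of a long-format cohort table."""
    for sid, sub in cohort.groupby("subject_id", sort=False):
        yield SubjectRecord(
            subject_id=sid,
            group=sub["group"].iloc[0],
            age=float(sub["age"].iloc[0]),
            powers=sub[["band", "region", "hemisphere", "power"]].reset_index(drop=True),
        )


def generate_recording(
    n_channels: int = 32,
    duration_s: float = 60.0,
    components: list[tuple[float, float, np.ndarray]] = (),
    utility_hz: int = 60,
    artifact_epochs: tuple[int, ...] = (),
    seed: int = 0,
    sampling_rate: float = 1000.0,
    noise_ft: float = 50.0,
    utility_amplitude_ft: float = 200.0,
    epoch_length_s: float = 10.0,
    sensor_locations: np.ndarray | None = None,
) -> Recording:
    """Simulate a resting-state sensor recording on the toy geometry.

    ``components`` is a list of (frequency Hz, amplitude fT, 3-D source
    location); each is projected to the sensors through the inverse-square
    gain kernel with a random phase. White sensor noise (``noise_ft`` SD) and
    a common-mode utility-frequency sinusoid are added. Epochs listed in
    ``artifact_epochs`` receive a 50-ms, 8000-fT excursion on one channel so
    the downstream amplitude criterion rejects exactly those epochs.

    ``duration_s`` must be a positive multiple of ``epoch_length_s``.
    """
    if utility_hz not in (50, 60):
        raise ValueError("utility_hz must be 50 or 60")
    n_epochs = duration_s / epoch_length_s
    if duration_s <= 0 or abs(n_epochs - round(n_epochs)) > 1e-9:
        raise ValueError("duration_s must be a positive multiple of epoch_length_s")
    n_epochs = int(round(n_epochs))
    if any(a < 0 or a >= n_epochs for a in artifact_epochs):
        raise ValueError("artifact epoch index out of range")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * sampling_rate))
    t = np.arange(n_samples) / sampling_rate
    if sensor_locations is None:
        sensor_locations = fibonacci_hemisphere(n_channels, 1.3)
    else:
        sensor_locations = np.asarray(sensor_locations, dtype=float)
        n_channels = sensor_locations.shape[0]
    data = np.zeros((n_channels, n_samples))
    for freq, amp, loc in components:
        if amp < 0:
            raise ValueError("component amplitudes must be non-negative")
        g = gain_kernel(sensor_locations, np.atleast_2d(np.asarray(loc, dtype=float)))[:, 0]
        g = g / g.max()  # unit peak gain so `amp` is the strongest sensor amplitude
        phase = rng.uniform(0, 2 * np.pi)
        data += np.outer(g, amp * np.sin(2 * np.pi * freq * t + phase))
    if noise_ft > 0:
        data += rng.normal(0.0, noise_ft, size=data.shape)
    if utility_amplitude_ft > 0:
        data += utility_amplitude_ft * np.sin(2 * np.pi * utility_hz * t)[None, :]
    n_per = int(round(epoch_length_s * sampling_rate))
    pulse = int(round(0.05 * sampling_rate))
    for k in artifact_epochs:
        start = k * n_per + n_per // 2
        ch = int(rng.integers(0, n_channels))
        data[ch, start : start + pulse] = 8000.0
    return Recording(data=data, sampling_rate=sampling_rate, utility_hz=utility_hz)


def generate_source_image_cohort(
    fm: ForwardModel,
    band_name: str,
    config: SynthConfig,
    seed: int | None = None,
    age_slope: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-subject source power images for one band, (images, groups, ages).

    Each source draws a log-normal power around its region x hemisphere mean
    under the same effect structure as :func:`generate_power_cohort`.
    ``age_slope`` adds a common log-power trend in (age - 40) years, useful
    for exercising nuisance-covariate handling.
    """
    if band_name not in config.band_names:
        raise ValueError(f"band {band_name!r} not in config")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    f = config.band_names.index(band_name)
    mu = np.log(_BASE_POWER.get(band_name, 10.0))
    asym = config._baseline.to_numpy()[f]  # per region
    delta = config._delta.to_numpy()[f]
    sigma = config.log_sigma
    region_idx = np.array([list(config.regions).index(r) for r in fm.region_labels])
    is_left = fm.hemisphere_labels == "L"

    images, groups, ages = [], [], []
    for group, n in ((GROUP_CTR, config.n_ctr), (GROUP_LT, config.n_lt), (GROUP_RT, config.n_rt)):
        ipsi = _IPSI.get(group)
        base = mu + np.where(is_left, 1.0, -1.0) * np.arctanh(asym[region_idx])
        if ipsi is not None:
            base = base + delta[region_idx] * (is_left == (ipsi == "L"))
        age = rng.uniform(*config.age_range, size=n)
        logp = (
            base[None, :]
            + rng.normal(0.0, _SUBJECT_SD, size=(n, 1))
            + age_slope * (age[:, None] - 40.0)
            + rng.normal(0.0, sigma, size=(n, fm.n_sources))
        )
        images.append(np.exp(logp))
        groups += [group] * n
        ages.append(age)
    return np.vstack(images), np.array(groups), np.concatenate(ages)


class FixtureError(RuntimeError):
    """The packaged clinical table failed its integrity checks."""


_ECD_DOMAIN = {"R", "L", "Bilateral", "No spike"}
_SVM_DOMAIN = {"R", "L", "CTR"}


def load_table1_fixture() -> pd.DataFrame:
    """Load and validate the packaged 35-patient clinical table.

    Normalizes the dipole-call spelling ("no spike" -> "No spike") and checks
    the invariants: 35 rows, 16 left-sided and 19 right-sided cases, and the
    categorical domains of the side, dipole (ECD), and SVM columns.
    """
    with resources.files("meglat.data").joinpath("table1.csv").open("r") as fh:
        df = pd.read_csv(fh, dtype={"engel": "string"}, keep_default_na=False)
    if len(df) != 35:
        raise FixtureError(f"expected 35 patients, found {len(df)}")
    if list(df["case_no"]) != list(range(1, 36)):
        raise FixtureError("case numbers must be 1..35")
    canonical = {"r": "R", "l": "L", "bilateral": "Bilateral", "no spike": "No spike"}
    df["ecd"] = df["ecd"].str.strip().map(lambda v: canonical.get(v.lower(), v))
    side_counts = df["side"].value_counts()
    if side_counts.get("L", 0) != 16 or side_counts.get("R", 0) != 19:
        raise FixtureError(f"side counts must be 16 L / 19 R, got {side_counts.to_dict()}")
    if not set(df["ecd"]).issubset(_ECD_DOMAIN):
        raise FixtureError(f"unknown ECD values: {set(df['ecd']) - _ECD_DOMAIN}")
    if not set(df["linear_svm"]).issubset(_SVM_DOMAIN):
        raise FixtureError(f"unknown SVM values: {set(df['linear_svm']) - _SVM_DOMAIN}")
    return df
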