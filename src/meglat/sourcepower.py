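"""Source-level oscillatory power on a toy geometry.

This is a desk-scale analog of a clinical MEG source pipeline: a linear
minimum-norm inverse with a spatially coherent (Gaussian-kernel) source
covariance — the smoothness prior underlying sLORETA-like estimators — applied
to band-filtered epochs, followed by Morlet-wavelet band power per source,
averaging over trials (retained epochs), and lobar region summarization.

The geometry is deliberately simple: sources sit in eight region x hemisphere
clusters on a unit hemisphere, sensors on a concentric shell above them, and
the gain is an isotropic inverse-square distance kernel. Hemisphere membership
is determined by the sign of the lateral (x) coordinate: x < 0 is left.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from mne.time_frequency import tfr_array_morlet

from .bands import HEMISPHERES, REGIONS, BandDefinition
from .preprocess import EpochSet

__all__ = [
    "ForwardModel",
    "SourceImage",
    "make_toy_forward",
    "compute_inverse_operator",
    "invert_coherent",
    "morlet_band_power",
    "average_trials",
    "summarize_regions",
    "regional_power_from_recording",
]

#: Softening constant of the inverse-square gain kernel (squared distance units).
GAIN_EPS = 0.05

#: Region cluster centroids (unit vectors, right hemisphere; left mirrors x).
_REGION_CENTROIDS = {
    "frontal": (0.50, 0.72, 0.48),
    "temporal": (0.92, 0.05, 0.25),
    "parietal": (0.48, -0.40, 0.78),
    "occipital": (0.35, -0.85, 0.40),
}


@dataclass
class ForwardModel:
    """Gain matrix plus source geometry and region/hemisphere labels."""

    gain: np.ndarray  # (n_sensors, n_sources)
    source_locations: np.ndarray  # (n_sources, 3)
    region_labels: np.ndarray  # (n_sources,) str
    hemisphere_labels: np.ndarray  # (n_sources,) {"L","R"}
    sensor_locations: np.ndarray  # (n_sensors, 3)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("gain matrix must be finite")
        n_sens, n_src = self.gain.shape
        if self.source_locations.shape != (n_src, 3):
            raise ValueError("source_locations shape mismatch with gain")
        if len(self.region_labels) != n_src or len(self.hemisphere_labels) != n_src:
            raise ValueError("label arrays must match source count")
        expect_l = self.source_locations[:, 0] < 0
        if not np.array_equal(expect_l, self.hemisphere_labels == "L"):
            raise ValueError("hemisphere labels inconsistent with sign of x coordinate")

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]

    @property
    def radius(self) -> float:
        return float(np.linalg.norm(self.source_locations, axis=1).max())


@dataclass
class SourceImage:
    """Per-source band power averaged over trials."""

    power: np.ndarray
    band: BandDefinition
    n_trials_averaged: int

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if np.any(self.power < 0) or not np.all(np.isfinite(self.power)):
            raise ValueError("source power must be finite and non-negative")


def gain_kernel(sensor_locations: np.ndarray, source_locations: np.ndarray) -> np.ndarray:
    """Inverse-square distance gain: g_ij = 1 / (eps + |c_i - s_j|^2)."""
    d2 = np.sum(
        (sensor_locations[:, None, :] - source_locations[None, :, :]) ** 2, axis=-1
    )
    return 1.0 / (GAIN_EPS + d2)


def fibonacci_hemisphere(n: int, radius: float) -> np.ndarray:
    """Quasi-uniform points on the upper half of a sphere of given radius."""
    k = np.arange(n)
    z = (k + 0.5) / n  # upper hemisphere only
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(1.0 - z**2)
    return radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def make_toy_forward(
    n_sensors: int = 32,
    sources_per_cell: int = 5,
    radius: float = 1.0,
    sensor_radius: float = 1.3,
    jitter: float = 0.12,
    seed: int = 0,
) -> ForwardModel:
    """Build the toy geometry: 4 regions x 2 hemispheres x ``sources_per_cell``.

    Sources are jittered around fixed lobar centroids on a hemisphere of
    ``radius``; the lateral coordinate is kept away from the midline so every
    source has an unambiguous hemisphere. Sensors form a quasi-uniform shell
    at ``sensor_radius``. Deterministic given ``seed``.
    """
    if sources_per_cell < 1 or n_sensors < 4:
        raise ValueError("need at least 1 source per cell and 4 sensors")
    rng = np.random.default_rng(seed)
    locs, regions, hemis = [], [], []
    for region in REGIONS:
        cx, cy, cz = _REGION_CENTROIDS[region]
        for hemi, sign in (("L", -1.0), ("R", 1.0)):
            centroid = np.array([sign * cx, cy, cz])
            centroid *= radius / np.linalg.norm(centroid)
            pts = centroid + rng.normal(0.0, jitter * radius, size=(sources_per_cell, 3))
            # keep sources strictly off the midsagittal plane, on their hemisphere
            pts[:, 0] = sign * np.maximum(np.abs(pts[:, 0]), 0.05 * radius)
            locs.append(pts)
            regions += [region] * sources_per_cell
            hemis += [hemi] * sources_per_cell
    source_locations = np.vstack(locs)
    sensor_locations = fibonacci_hemisphere(n_sensors, sensor_radius)
    return ForwardModel(
        gain=gain_kernel(sensor_locations, source_locations),
        source_locations=source_locations,
        region_labels=np.array(regions),
        hemisphere_labels=np.array(hemis),
        sensor_locations=sensor_locations,
    )


def coherence_kernel(source_locations: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian spatial-coherence source covariance R_ij = exp(-|si-sj|^2 / 2 sigma^2)."""
    d2 = np.sum(
        (source_locations[:, None, :] - source_locations[None, :, :]) ** 2, axis=-1
    )
    return np.exp(-d2 / (2.0 * sigma**2))


def compute_inverse_operator(
    fm: ForwardModel,
    lambda_reg: float | None = None,
    smoothness_sigma: float | None = None,
) -> np.ndarray:
    """Precompute the linear inverse K = R G' (G R G' + lambda I)^-1.

    ``smoothness_sigma`` defaults to 0.2 x geometry radius; ``lambda_reg``
    defaults to 0.1 x mean diagonal of G R G'. Both must be positive.
    """
    sigma = 0.2 * fm.radius if smoothness_sigma is None else smoothness_sigma
    if sigma <= 0:
        raise ValueError("smoothness_sigma must be positive")
    R = coherence_kernel(fm.source_locations, sigma)
    grg = fm.gain @ R @ fm.gain.T
    lam = 0.1 * float(np.mean(np.diag(grg))) if lambda_reg is None else lambda_reg
    if lam <= 0:
        raise ValueError("lambda_reg must be positive")
    rhs = np.linalg.solve(grg + lam * np.eye(fm.n_sensors), np.eye(fm.n_sensors))
    return R @ fm.gain.T @ rhs


def invert_coherent(
    epoch: np.ndarray,
    fm: ForwardModel,
    lambda_reg: float | None = None,
    smoothness_sigma: float | None = None,
) -> np.ndarray:
    """Minimum-norm inverse with coherence prior: J = K B for one epoch.

    ``epoch`` is (n_channels, n_samples) with channels matching the gain rows.
    Returns per-source time series (n_sources, n_samples). Linear and
    deterministic.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if epoch.shape[0] != fm.n_sensors:
        raise ValueError(
            f"epoch has {epoch.shape[0]} channels, forward model expects {fm.n_sensors}"
        )
    K = compute_inverse_operator(fm, lambda_reg, smoothness_sigma)
    return K @ epoch


def morlet_band_power(
    source_series: np.ndarray,
    sampling_rate: float,
    band: BandDefinition,
    cycles: float = 7.0,
) -> np.ndarray:
    """Time-averaged Morlet power per source over a 1-Hz in-band frequency grid.

    For each integer frequency in [max(1, ceil(lo)), floor(hi)], squared Morlet
    coefficient magnitudes are averaged over time with the edge samples (half
    the wavelet support at that frequency) excluded, then averaged across the
    grid. The series must be longer than the widest wavelet (``cycles`` cycles
    of the lowest grid frequency).
    """
    series = np.atleast_2d(np.asarray(source_series, dtype=float))
    n_times = series.shape[1]
    if band.hi >= sampling_rate / 2.0:
        raise ValueError("band above Nyquist")
    f_lo = max(1.0, np.ceil(band.lo))
    f_hi = np.floor(band.hi)
    freqs = np.arange(f_lo, f_hi + 0.5, 1.0)
    if len(freqs) == 0:
        raise ValueError(f"no integer frequencies inside band {band.name!r}")
    widest = cycles / freqs[0] * sampling_rate
    if n_times <= widest:
        raise ValueError(
            f"series of {n_times} samples shorter than the widest wavelet "
            f"({widest:.0f} samples at {freqs[0]:g} Hz)"
        )
    power = tfr_array_morlet(
        series[np.newaxis],
        sfreq=sampling_rate,
        freqs=freqs,
        n_cycles=cycles,
        output="power",
        verbose="error",
    )[0]  # (n_sources, n_freqs, n_times)
    per_freq = np.empty(power.shape[:2])
    for k, f in enumerate(freqs):
        edge = int(np.ceil(cycles / (2.0 * f) * sampling_rate))
        edge = min(edge, (n_times - 1) // 2)
        per_freq[:, k] = power[:, k, edge : n_times - edge].mean(axis=1)
    return per_freq.mean(axis=1)


def average_trials(per_trial_powers: list[np.ndarray], band: BandDefinition) -> SourceImage:
    """Element-wise mean of per-trial source powers."""
    if len(per_trial_powers) == 0:
        raise ValueError("no trials to average")
    stacked = np.vstack([np.asarray(p, dtype=float) for p in per_trial_powers])
    return SourceImage(
        power=stacked.mean(axis=0), band=band, n_trials_averaged=stacked.shape[0]
    )


def summarize_regions(img: SourceImage, fm: ForwardModel) -> pd.DataFrame:
    """Mean source power per region x hemisphere for one band (8 rows).

    Raises on degenerate geometry (an empty region x hemisphere cell).
    """
    if img.power.shape[0] != fm.n_sources:
        raise ValueError("source image not aligned to forward model")
    rows = []
    for region in REGIONS:
        for hemi in HEMISPHERES:
            mask = (fm.region_labels == region) & (fm.hemisphere_labels == hemi)
            if not mask.any():
                raise ValueError(f"no sources in cell ({region}, {hemi})")
            rows.append(
                {
                    "band": img.band.name,
                    "region": region,
                    "hemisphere": hemi,
                    "power": float(img.power[mask].mean()),
                }
            )
    return pd.DataFrame(rows)


def regional_power_from_recording(
    epochs: EpochSet,
    fm: ForwardModel,
    bands: tuple[BandDefinition, ...],
    lambda_reg: float | None = None,
    smoothness_sigma: float | None = None,
    cycles: float = 7.0,
) -> pd.DataFrame:
    """Cleaned epochs -> band x region x hemisphere power table.

    Per band: bandpass-filter each retained epoch, project to source space,
    take Morlet band power, average over trials, summarize by region. The
    inverse operator is band-independent (the estimator is linear), so it is
    computed once and applied to every band-filtered epoch.
    """
    from .preprocess import bandpass  # local import avoids cycle at module load

    K = compute_inverse_operator(fm, lambda_reg, smoothness_sigma)
    tables = []
    for band in bands:
        filtered = bandpass(epochs, band)
        trial_powers = [
            morlet_band_power(K @ ep, epochs.sampling_rate, band, cycles=cycles)
            for ep in filtered.epochs
        ]
        img = average_trials(trial_powers, band)
        tables.append(summarize_regions(img, fm))
    return pd.concat(tables, ignore_index=True)
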