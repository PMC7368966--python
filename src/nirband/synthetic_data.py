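"""Synthetic NIR-like mixture spectra with known ground truth.

Emulates a diffuse-reflectance feed-analysis dataset at realistic scale:
~200 samples on a 700-channel axis (1100 nm start, 2 nm step), analyte
content distributed with mean 60.7 wt.% and SD 4.36 on the observed
53–67 wt.% range.  Absorbance follows an additive Beer-Lambert
mixture model: each component contributes Gaussian absorption bands scaled
by its concentration, plus a per-sample baseline (offset + slope, the
scatter effects SNV is meant to remove) and i.i.d. Gaussian channel noise:

    A_i(lam) = g_i * sum_comp c_i,comp * sum_bands a * exp(-(lam - mu)^2 / (2 sigma^2))
               + offset_i + slope_i * (lam - lam_mid) + eps_i,lam

where g_i is a per-sample multiplicative scatter gain (lognormal, median 1)
— the particle-size/path-length effect SNV is designed to remove; without
it SNV's row statistics would themselves become a spurious, physically
meaningless carrier of concentration information.

Interferent concentrations can co-vary with the analyte (default correlation
0.3, mimicking co-varying moisture/ash in real feed), realized by mixing the
analyte's standardized deviate into each interferent's deviate.  The signal-
to-noise ratio is defined as (analyte peak band amplitude x concentration
SD) / noise SD and recorded in the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .spectra import SpectralDataset, WavelengthAxis

__all__ = ["GaussianBand", "Component", "SyntheticConfig", "GroundTruth",
           "generate", "standard_fixtures"]


@dataclass(frozen=True)
class GaussianBand:
    center_nm: float
    sigma_nm: float
    amplitude: float    # absorbance units per unit concentration

    def __post_init__(self) -> None:
        if self.sigma_nm <= 0 or self.amplitude < 0:
            raise ValueError(f"invalid band {self}")

    def profile(self, wavelengths: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(
            -((wavelengths - self.center_nm) ** 2) / (2 * self.sigma_nm ** 2))


@dataclass(frozen=True)
class Component:
    """One chemical component: absorption bands + concentration distribution.

    ``family`` selects the concentration law: ``"normal"``,
    ``"truncated_normal"`` (normal clipped to ``conc_bounds``), or
    ``"scaled_beta"`` (beta on ``conc_bounds`` with shape parameters
    moment-matched to ``conc_mean``/``conc_sd`` — the only bounded family
    here that can reproduce a target SD close to the range's uniform limit,
    as real feed data with mixed provenances does).
    """

    name: str
    bands: tuple[GaussianBand, ...]
    conc_mean: float
    conc_sd: float
    conc_bounds: tuple[float, float] | None = None
    family: str = "normal"
    corr_with_analyte: float = 0.0

    def __post_init__(self) -> None:
        if self.conc_sd < 0 or not -1 <= self.corr_with_analyte <= 1:
            raise ValueError(f"invalid component {self.name}")
        if self.family not in ("normal", "truncated_normal", "scaled_beta"):
            raise ValueError(f"unknown concentration family {self.family!r}")
        if self.family != "normal" and self.conc_bounds is None:
            raise ValueError(f"{self.family} requires conc_bounds ({self.name})")

    def profile(self, wavelengths: np.ndarray) -> np.ndarray:
        return sum((b.profile(wavelengths) for b in self.bands),
                   start=np.zeros_like(wavelengths, dtype=float))

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Concentration draws with the configured mean/SD/support."""
        if self.family == "normal":
            return self.conc_mean + self.conc_sd * rng.standard_normal(n)
        lo, hi = self.conc_bounds
        if self.family == "truncated_normal":
            a = (lo - self.conc_mean) / self.conc_sd
            b = (hi - self.conc_mean) / self.conc_sd
            z = stats.truncnorm.rvs(a, b, size=n, random_state=rng)
            return self.conc_mean + self.conc_sd * z
        # scaled beta: match first two moments on [lo, hi]
        m = (self.conc_mean - lo) / (hi - lo)
        v = (self.conc_sd / (hi - lo)) ** 2
        if not 0 < v < m * (1 - m):
            raise ValueError(
                f"no beta on [{lo}, {hi}] has mean {self.conc_mean}, SD {self.conc_sd}")
        ab = m * (1 - m) / v - 1
        u = stats.beta.rvs(m * ab, (1 - m) * ab, size=n, random_state=rng)
        return lo + (hi - lo) * u


def _default_analyte() -> Component:
    # protein-like analyte: main band spanning roughly 1980-2050 nm.
    # Concentration law: beta on the observed 53-67 wt.% range, moment-matched
    # to mean 60.7 / SD 4.36 (a normal truncated to that range cannot reach an
    # SD of 4.36; its limit is the uniform SD 14/sqrt(12) ~ 4.04).
    return Component(
        name="analyte",
        bands=(GaussianBand(center_nm=2015.0, sigma_nm=18.0, amplitude=0.010),),
        conc_mean=60.7, conc_sd=4.36, conc_bounds=(53.0, 67.0),
        family="scaled_beta")


def _default_interferents() -> tuple[Component, ...]:
    # "matrix" is the stable bulk absorbance of the sample (broad bands, no
    # concentration variation).  It keeps each spectrum's overall level and
    # row SD roughly constant, as in real diffuse-reflectance data — without
    # it SNV's per-row scaling would divide the analyte's own variation out
    # of its band (closure artifact) instead of removing scatter.
    return (
        Component(name="matrix", conc_mean=1.0, conc_sd=0.0,
                  bands=(GaussianBand(1250.0, 70.0, 0.30),
                         GaussianBand(1500.0, 90.0, 0.45),
                         GaussianBand(1740.0, 60.0, 0.35),
                         GaussianBand(2100.0, 100.0, 0.45),
                         GaussianBand(2380.0, 70.0, 0.30))),
        Component(name="moisture", conc_mean=8.0, conc_sd=1.5,
                  corr_with_analyte=0.3,
                  bands=(GaussianBand(1440.0, 30.0, 0.012),
                         GaussianBand(1930.0, 25.0, 0.010))),
        Component(name="ash", conc_mean=15.0, conc_sd=2.5,
                  corr_with_analyte=0.3,
                  bands=(GaussianBand(1690.0, 40.0, 0.008),
                         GaussianBand(2280.0, 35.0, 0.006))),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    axis: WavelengthAxis = field(
        default_factory=lambda: WavelengthAxis(1100.0, 2.0, 700))
    n_samples: int = 194
    analyte: Component = field(default_factory=_default_analyte)
    interferents: tuple[Component, ...] = field(default_factory=_default_interferents)
    baseline_offset_sd: float = 0.05
    baseline_slope_sd: float = 5e-5   # absorbance per nm
    scatter_gain_sd: float = 0.1      # lognormal sigma of the multiplicative gain
    noise_sd: float = 0.00436         # -> SNR ~= 10 with the default analyte band
    seed: int = 0

    def __post_init__(self) -> None:
        wl_lo, wl_hi = self.axis.start_nm, self.axis.end_nm
        for comp in (self.analyte, *self.interferents):
            for b in comp.bands:
                if not wl_lo <= b.center_nm <= wl_hi:
                    raise ValueError(
                        f"band center {b.center_nm} nm outside axis of {comp.name}")
        if min(self.noise_sd, self.baseline_offset_sd, self.baseline_slope_sd,
               self.scatter_gain_sd) < 0:
            raise ValueError("noise/baseline/scatter magnitudes must be >= 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    @property
    def snr(self) -> float:
        peak = max((b.amplitude for b in self.analyte.bands), default=0.0)
        if self.noise_sd == 0:
            return float("inf")
        return peak * self.analyte.conc_sd / self.noise_sd


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to regenerate a dataset bit-exactly given the seed."""

    config: SyntheticConfig
    concentrations: dict[str, np.ndarray]   # per component, incl. analyte
    gains: np.ndarray                       # multiplicative scatter per sample
    offsets: np.ndarray
    slopes: np.ndarray
    snr: float


def generate(config: SyntheticConfig) -> tuple[SpectralDataset, GroundTruth]:
    """Simulate a dataset; deterministic for a fixed config (incl. seed)."""
    rng = np.random.default_rng(config.seed)
    wl = config.axis.wavelengths()
    n = config.n_samples

    an = config.analyte
    c_an = an.draw(rng, n)
    # standardized analyte deviate drives interferent co-variation
    z_an = (c_an - an.conc_mean) / an.conc_sd if an.conc_sd > 0 else np.zeros(n)
    conc = {an.name: c_an}

    for comp in config.interferents:
        rho = comp.corr_with_analyte
        z = rho * z_an + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
        conc[comp.name] = np.maximum(comp.conc_mean + comp.conc_sd * z, 0.0)

    X = np.zeros((n, wl.size))
    for comp in (an, *config.interferents):
        X += np.outer(conc[comp.name], comp.profile(wl))

    if config.scatter_gain_sd > 0:
        gains = np.exp(rng.standard_normal(n) * config.scatter_gain_sd)
    else:
        gains = np.ones(n)
    X *= gains[:, None]

    offsets = rng.standard_normal(n) * config.baseline_offset_sd
    slopes = rng.standard_normal(n) * config.baseline_slope_sd
    lam_mid = 0.5 * (wl[0] + wl[-1])
    X += offsets[:, None] + np.outer(slopes, wl - lam_mid)
    if config.noise_sd > 0:
        X += rng.standard_normal(X.shape) * config.noise_sd

    ds = SpectralDataset(axis=config.axis, absorbance=X, y=conc[an.name])
    truth = GroundTruth(config=config, concentrations=conc, gains=gains,
                        offsets=offsets, slopes=slopes, snr=config.snr)
    return ds, truth


def standard_fixtures(seed: int = 0) -> dict[str, tuple[SpectralDataset, GroundTruth]]:
    """Named datasets used throughout the test suite.

    - ``planted_band``: full-scale default config — one analyte band at
      1980-2050 nm, two interferents, baseline and noise at SNR ~ 10;
    - ``tiny``: 20 channels x 30 samples, for brute-force oracles;
    - ``rank1``: noise-free, interferent-free, baseline-free — absorbance is
      exactly proportional to the analyte concentration (one latent factor).
    """
    planted = SyntheticConfig(seed=seed)

    tiny_axis = WavelengthAxis(1500.0, 2.0, 20)
    tiny = SyntheticConfig(
        axis=tiny_axis, n_samples=30,
        analyte=Component(
            name="analyte",
            bands=(GaussianBand(1520.0, 6.0, 0.010),),
            conc_mean=60.7, conc_sd=4.36, conc_bounds=(53.0, 67.0),
            family="scaled_beta"),
        interferents=(
            Component(
                name="matrix", conc_mean=1.0, conc_sd=0.0,
                bands=(GaussianBand(1510.0, 10.0, 0.35),
                       GaussianBand(1530.0, 12.0, 0.40))),
            Component(
                name="interferent",
                bands=(GaussianBand(1532.0, 5.0, 0.008),),
                conc_mean=10.0, conc_sd=2.0, corr_with_analyte=0.3),
        ),
        baseline_offset_sd=0.02, baseline_slope_sd=5e-5,
        noise_sd=0.002, seed=seed + 1)

    rank1 = SyntheticConfig(
        axis=WavelengthAxis(1900.0, 2.0, 80), n_samples=40,
        analyte=Component(
            name="analyte",
            bands=(GaussianBand(1980.0, 15.0, 0.010),),
            conc_mean=60.7, conc_sd=4.36, conc_bounds=(53.0, 67.0),
            family="scaled_beta"),
        interferents=(),
        baseline_offset_sd=0.0, baseline_slope_sd=0.0,
        scatter_gain_sd=0.0, noise_sd=0.0, seed=seed + 2)

    return {name: generate(cfg)
            for name, cfg in (("planted_band", planted), ("tiny", tiny),
                              ("rank1", rank1))}
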