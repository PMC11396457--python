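"""Synthetic saffron NIR datasets with known ground truth.

The generator is the statistical stand-in for the customs sample bank: no
spectra are publicly deposited, so every pipeline stage is exercised on
simulated data whose reference-value distributions match the published
calibration-set statistics and whose spectra carry the absorption bands,
multiplicative scatter, baseline drift and noise that the preprocessing
pipelines exist to handle.

Model
-----
Per-sample clean spectrum (Beer-Lambert additivity by construction)::

    clean(lambda) = background(lambda)
                  + sum_c conc_c * sum_{bands of c} amp * N(lambda; center, sigma)

with concentrations in % drawn from truncated normals matching the
published max/min/mean/SD per index. The emitted spectrum adds the
instrument artefacts the preprocessing is meant to remove::

    emitted = gain * clean + offset + slope * (lambda - lambda_0) + noise

gain ~ U[0.85, 1.15], offset ~ U[-0.05, 0.05], slope ~ U[-2e-5, 2e-5] per nm,
noise iid N(0, 0.002) absorbance units. Everything is reproducible from a
single integer seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .spectra import INDEX_NAMES, ReferenceTable, SpectraSet, WavelengthGrid

__all__ = [
    "BandSpec",
    "TruncNormSpec",
    "SyntheticConfig",
    "GroundTruth",
    "default_config",
    "generate",
    "sample_reference",
    "summarize",
]


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band contributed by a constituent."""

    center_nm: float
    width_nm: float  # Gaussian sigma
    amplitude: float  # absorbance per % constituent at the band centre

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError("band width must be > 0")
        if not np.isfinite(self.amplitude):
            raise ValueError("band amplitude must be finite")


@dataclass(frozen=True)
class TruncNormSpec:
    """Truncated-normal concentration distribution (% units)."""

    mean: float
    sd: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("require low < high")
        if self.sd <= 0:
            raise ValueError("require sd > 0")


@dataclass
class SyntheticConfig:
    n_samples: int
    grid_start: float
    grid_stop: float
    grid_step: float
    concentrations: dict[str, TruncNormSpec]
    bands: dict[str, list[BandSpec]]
    gain_range: tuple[float, float]
    offset_range: tuple[float, float]
    baseline_slope_range: tuple[float, float]  # absorbance per nm
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for name in self.concentrations:
            if name not in INDEX_NAMES:
                raise ValueError(f"unknown index {name!r}")
        if set(self.bands) != set(self.concentrations):
            raise ValueError("bands and concentrations must cover the same indices")
        for lo, hi in (self.gain_range, self.offset_range, self.baseline_slope_range):
            if lo > hi:
                raise ValueError("range bounds reversed")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def grid(self) -> WavelengthGrid:
        return WavelengthGrid(
            np.arange(self.grid_start, self.grid_stop + self.grid_step / 2, self.grid_step)
        )

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class GroundTruth:
    """The latent variables behind an emitted synthetic dataset."""

    sample_ids: list[str]
    concentrations: dict[str, np.ndarray]
    gain: np.ndarray
    offset: np.ndarray
    baseline_slope: np.ndarray
    seed: int

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "sample_ids": self.sample_ids,
                    "concentrations": {k: v.tolist() for k, v in self.concentrations.items()},
                    "gain": self.gain.tolist(),
                    "offset": self.offset.tolist(),
                    "baseline_slope": self.baseline_slope.tolist(),
                    "seed": self.seed,
                }
            )
        )
        return path


#: Published calibration-set statistics per index: (mean, SD, min, max), %.
PUBLISHED_REFERENCE_STATS = {
    "LD": (8.65, 0.91, 6.4, 11.2),
    "TCCC": (14.86, 2.00, 10.0, 19.5),
    "CP": (10.54, 1.46, 7.0, 14.8),
}

#: Constituent -> absorption-band mapping. The eight band centres are the
#: absorptions visible in saffron NIR spectra; assigning them to the three
#: indices is a modelling convenience (fixed so tests are stable), not a
#: chemical claim. Water/volatiles (LD) load the classic O-H bands at 1450
#: and 1950 nm and dominate; crocins load 1200/1700/2300 nm (C-H), and
#: picrocrocin 1380/1580/2100 nm.
DEFAULT_BANDS: dict[str, list[BandSpec]] = {
    "LD": [
        BandSpec(1450.0, 45.0, 0.010),
        BandSpec(1950.0, 55.0, 0.015),
    ],
    "TCCC": [
        BandSpec(1200.0, 40.0, 0.004),
        BandSpec(1700.0, 45.0, 0.0055),
        BandSpec(2300.0, 50.0, 0.0045),
    ],
    "CP": [
        BandSpec(1380.0, 25.0, 0.0035),
        BandSpec(1580.0, 30.0, 0.004),
        BandSpec(2100.0, 60.0, 0.0055),
    ],
}


def default_config(n_samples: int = 928, seed: int = 0) -> SyntheticConfig:
    """The canonical simulation: 928 samples on a 1 nm grid, 1000-2499 nm."""
    return SyntheticConfig(
        n_samples=n_samples,
        grid_start=1000.0,
        grid_stop=2499.0,
        grid_step=1.0,
        concentrations={
            name: TruncNormSpec(m, s, lo, hi)
            for name, (m, s, lo, hi) in PUBLISHED_REFERENCE_STATS.items()
        },
        bands={k: list(v) for k, v in DEFAULT_BANDS.items()},
        gain_range=(0.85, 1.15),
        offset_range=(-0.05, 0.05),
        baseline_slope_range=(-2e-5, 2e-5),
        noise_sd=0.002,
        seed=seed,
    )


def _sample_truncnorm(
    spec: TruncNormSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Plain normal draws with rejection outside [low, high]."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(spec.mean, spec.sd, size=2 * (n - filled))
        keep = draw[(draw >= spec.low) & (draw <= spec.high)][: n - filled]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def sample_reference(config: SyntheticConfig, seed: int | None = None) -> ReferenceTable:
    """Draw only the concentration table (cheap path used by generate)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ids = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    cols = {
        name: _sample_truncnorm(config.concentrations[name], config.n_samples, rng)
        for name in INDEX_NAMES
        if name in config.concentrations
    }
    return ReferenceTable(ids, cols)


def _matrix_background(lam: np.ndarray) -> np.ndarray:
    """Fixed absorbing matrix common to every sample: the steep upward ramp
    and broad water/carbohydrate envelope that plant powders share.

    The background deliberately dominates the wavelength-variance of the
    mean spectrum: per-sample constituent signal is a modest perturbation on
    it, so the MSC slope regression estimates the scatter gain rather than
    the chemistry — the regime multiplicative scatter correction assumes.
    """
    ramp = 0.50 + 6.0e-4 * (lam - lam[0])
    bowl = 0.65 * ((lam - 1750.0) / 750.0) ** 2
    hump1 = 0.28 * np.exp(-0.5 * ((lam - 1930.0) / 160.0) ** 2)
    hump2 = 0.14 * np.exp(-0.5 * ((lam - 1430.0) / 120.0) ** 2)
    return ramp + bowl + hump1 + hump2


def clean_spectra(config: SyntheticConfig, ref: ReferenceTable) -> np.ndarray:
    """Noise- and scatter-free spectra: background + concentration-weighted bands."""
    lam = config.grid.values
    X = np.tile(_matrix_background(lam), (len(ref), 1))
    for name in ref.indices:
        sig = np.zeros_like(lam)
        for band in config.bands[name]:
            sig += band.amplitude * np.exp(
                -0.5 * ((lam - band.center_nm) / band.width_nm) ** 2
            )
        X += np.outer(ref.values[name], sig)
    return X


def generate(
    config: SyntheticConfig,
    *,
    with_scatter: bool = True,
    with_noise: bool = True,
) -> tuple[SpectraSet, ReferenceTable, GroundTruth]:
    """Emit a full synthetic dataset, reproducible from ``config.seed``.

    ``with_scatter``/``with_noise`` switch off the instrument artefacts to
    obtain the clean Beer-Lambert limit (used by linearity checks).
    """
    rng = np.random.default_rng(config.seed)
    ref = sample_reference(config, seed=int(rng.integers(2**31)))
    n = config.n_samples
    lam = config.grid.values

    if with_scatter:
        gain = rng.uniform(*config.gain_range, size=n)
        offset = rng.uniform(*config.offset_range, size=n)
        slope = rng.uniform(*config.baseline_slope_range, size=n)
    else:
        gain = np.ones(n)
        offset = np.zeros(n)
        slope = np.zeros(n)

    X = clean_spectra(config, ref)
    X = gain[:, None] * X + offset[:, None] + np.outer(slope, lam - lam[0])
    if with_noise and config.noise_sd > 0:
        X = X + rng.normal(0.0, config.noise_sd, size=X.shape)

    spectra = SpectraSet(list(ref.sample_ids), config.grid, X)
    truth = GroundTruth(
        sample_ids=list(ref.sample_ids),
        concentrations={k: v.copy() for k, v in ref.values.items()},
        gain=gain,
        offset=offset,
        baseline_slope=slope,
        seed=config.seed,
    )
    return spectra, ref, truth


def summarize(r: ReferenceTable) -> pd.DataFrame:
    """Descriptive statistics per index in the published table's layout.

    Rows: Max, Min, Average, Standard deviation, Variance (SD squared, with
    the sample n-1 convention).
    """
    if len(r) == 0:
        raise ValueError("empty reference table")
    rows = {}
    for name in r.indices:
        v = r.values[name]
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        rows[name] = {
            "Max (%)": float(np.max(v)),
            "Min (%)": float(np.min(v)),
            "Average (%)": float(np.mean(v)),
            "Standard deviation": sd,
            "Variance": sd**2,
        }
    return pd.DataFrame(rows)
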