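"""Synthetic plasma-like mid-IR cohort generator.

No spectra were deposited with the study this package reanalyses, so
every pipeline stage is exercised on generated cohorts engineered to
carry the reported statistical structure:

* absorbance-like curves built from Gaussian bands at standard plasma
  assignments (CH stretches near 2960/2925/2850, lipid ester 1750,
  Amide I 1650, Amide II 1550, plus fingerprint bands);
* a class effect confined to 1750-1600 cm^-1 with the *negative*
  (control) class at higher amplitude, the rest of the wave pattern
  shared;
* subcluster structure (default two modes per class) with band-offset
  signatures shared across classes; the class is encoded purely in how
  strongly each mode expresses the effect — main modes at the class
  extremes, minor modes straddling the midpoint ("overlapping mode");
* a small fraction of outliers with a large smooth perturbation;
* smooth correlated noise plus white noise.

The generator emits absorbance curves, not derivatives: tests and the
acceptance run push them through the real preprocessing pipeline.  All
randomness flows from one seed through named per-sample streams, so
enlarging a cohort never reshuffles earlier samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .exceptions import ConfigError
from .spectra import SpectraSet, WavenumberGrid


@dataclass(frozen=True)
class Band:
    center: float  # cm^-1
    width: float  # Gaussian sigma, cm^-1
    amplitude: float  # relative absorbance


@dataclass(frozen=True)
class BandTemplate:
    """Sum-of-Gaussians absorbance template."""

    name: str
    bands: tuple[Band, ...]

    def profiles(self, wavenumbers: np.ndarray) -> np.ndarray:
        """(n_bands, n_wavenumbers) matrix of unit-amplitude band shapes."""
        w = np.asarray(wavenumbers, dtype=float)
        return np.exp(
            -0.5 * ((w[None, :] - np.array([b.center for b in self.bands])[:, None])
                    / np.array([b.width for b in self.bands])[:, None]) ** 2
        )

    def evaluate(self, wavenumbers: np.ndarray) -> np.ndarray:
        amps = np.array([b.amplitude for b in self.bands])
        return amps @ self.profiles(wavenumbers)


# Literature-plausible plasma band set: relative amplitudes are generator
# inputs, not spectroscopic claims.  Amide I dominates by construction.
_PLASMA_BANDS = (
    Band(2960.0, 18.0, 0.35),  # CH3 asym stretch
    Band(2925.0, 18.0, 0.45),  # CH2 asym stretch
    Band(2850.0, 16.0, 0.30),  # CH2 sym stretch
    Band(1750.0, 14.0, 0.30),  # lipid ester C=O
    Band(1650.0, 22.0, 1.00),  # Amide I
    Band(1550.0, 20.0, 0.65),  # Amide II
    Band(1400.0, 18.0, 0.35),  # COO- / CH bend
    Band(1155.0, 16.0, 0.25),  # carbohydrate C-O
    Band(1030.0, 18.0, 0.30),  # glycogen / carbohydrate
)

_PRESETS = {"plasma_default": BandTemplate("plasma_default", _PLASMA_BANDS)}


def make_band_template(preset: str = "plasma_default") -> BandTemplate:
    """Return a named band template (currently ``plasma_default``, 9 bands)."""
    try:
        return _PRESETS[preset]
    except KeyError:
        raise ConfigError(
            f"unknown band preset {preset!r}; available: {sorted(_PRESETS)}"
        ) from None


@dataclass
class SyntheticCohortConfig:
    """Study-condition parameters of the generated cohort.

    Defaults emulate the reanalysed study: 192 positive vs 202 negative
    samples on a 4000-400 cm^-1 grid at 4 cm^-1 resolution, a 15%
    relative amplitude excess of the negative class inside
    1750-1600 cm^-1, two subclusters per class whose minor modes
    overlap, and 2% outliers.  Noise scales are relative to the unit
    Amide I amplitude.
    """

    n_positive: int = 192
    n_negative: int = 202
    grid_high: float = 4000.0
    grid_low: float = 400.0
    grid_step: float = 4.0
    effect_size: float = 0.15
    effect_high: float = 1750.0
    effect_low: float = 1600.0
    effect_edge: float = 8.0  # logistic edge scale, cm^-1
    n_subclusters: int = 2
    subcluster_weights: tuple = (0.8, 0.2)
    subcluster_scale: float = 0.10  # sd of per-band amplitude offsets
    overlap_expression: float = 0.5  # midpoint of minor-mode effect expression
    overlap_gap: float = 0.4  # expression gap between the two minor modes
    amplitude_jitter: float = 0.03  # per-sample per-band sd
    global_scale_sd: float = 0.03  # per-sample multiplicative lognormal sd
    smooth_noise_sd: float = 0.006
    smooth_noise_width: float = 16.0  # correlation length, cm^-1
    white_noise_sd: float = 0.003
    outlier_fraction: float = 0.02
    outlier_scale: float = 0.30
    outlier_width: float = 60.0  # cm^-1
    band_preset: str = "plasma_default"
    seed: int = 0

    def __post_init__(self):
        if self.n_positive < 0 or self.n_negative < 0:
            raise ConfigError("cohort sizes must be non-negative")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if not 0 <= self.outlier_fraction <= 0.2:
            raise ConfigError("outlier_fraction must lie in [0, 0.2]")
        if self.grid_high <= self.grid_low or self.grid_step <= 0:
            raise ConfigError("invalid grid specification")
        if len(self.subcluster_weights) != self.n_subclusters:
            raise ConfigError("subcluster_weights length must equal n_subclusters")
        if abs(sum(self.subcluster_weights) - 1.0) > 1e-9:
            raise ConfigError("subcluster_weights must sum to 1")

    def grid(self) -> WavenumberGrid:
        n = int(round((self.grid_high - self.grid_low) / self.grid_step)) + 1
        return WavenumberGrid(self.grid_high - self.grid_step * np.arange(n))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["subcluster_weights"] = list(self.subcluster_weights)
        return d


def _effect_mask(w: np.ndarray, config: SyntheticCohortConfig) -> np.ndarray:
    """Smooth indicator of the effect window (1 inside, ~0 outside)."""
    e = config.effect_edge
    lo = 1.0 / (1.0 + np.exp(-(w - config.effect_low) / e))
    hi = 1.0 / (1.0 + np.exp(-(config.effect_high - w) / e))
    return lo * hi


def _smooth_noise(rng, n: int, sigma_points: float) -> np.ndarray:
    raw = gaussian_filter1d(rng.standard_normal(n), sigma_points, mode="reflect")
    sd = raw.std()
    return raw / sd if sd > 0 else raw


def generate_cohort(config: SyntheticCohortConfig | None = None) -> SpectraSet:
    """Generate a labelled synthetic cohort; fully determined by the seed.

    Per sample: class, subcluster (per-class mixture) and outlier status
    are drawn from a stream keyed by ``(seed, class, sample index)``;
    the absorbance is the band template scaled by the subcluster's
    band-offset signature (shared across classes), the class effect
    inside the effect window (negative main mode higher by
    ``effect_size``; minor modes of both classes straddle the
    ``overlap_expression`` midpoint by ``overlap_gap``), per-sample
    band jitter and a global intensity factor, plus smooth correlated
    noise, white noise and — for outliers — one large smooth
    perturbation.
    """
    config = config or SyntheticCohortConfig()
    grid = config.grid()
    w = grid.values
    template = make_band_template(config.band_preset)
    P = template.profiles(w)  # bands x wavenumbers
    base_amps = np.array([b.amplitude for b in template.bands])
    mask = _effect_mask(w, config)

    # cohort-level structure stream: fixed per-subcluster band offsets.
    # Signatures are shared by both classes, so outside the effect window
    # the classes follow the same wave pattern and effect_size=0 yields a
    # genuinely exchangeable (null) cohort.
    struct = np.random.default_rng(
        np.random.SeedSequence([int(config.seed) % (2**31), 7])
    )
    K, B = config.n_subclusters, len(template.bands)
    deltas = np.vstack(
        [struct.normal(0.0, config.subcluster_scale, B) for _ in range(K)]
    )  # subcluster x band

    # effect expression per (class, subcluster): the main modes sit at the
    # class extremes (negative 1.0, positive 0.0 of the effect); the minor
    # modes straddle the midpoint, overlapping but not coincident
    expr = np.zeros((2, K))
    expr[0, :] = config.effect_size
    if K > 1:
        mid, gap = config.overlap_expression, config.overlap_gap
        expr[0, K - 1] = config.effect_size * (mid + gap / 2.0)
        expr[1, K - 1] = config.effect_size * (mid - gap / 2.0)

    weights = np.asarray(config.subcluster_weights, dtype=float)
    sigma_smooth = config.smooth_noise_width / config.grid_step
    sigma_outlier = config.outlier_width / config.grid_step

    ids, labels, rows, meta = [], [], [], []
    for c, (label, count, prefix) in enumerate(
        [("negative", config.n_negative, "N"), ("positive", config.n_positive, "P")]
    ):
        for i in range(count):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(config.seed) % (2**31), c, i])
            )
            k = int(rng.choice(K, p=weights))
            is_outlier = bool(rng.random() < config.outlier_fraction)
            gscale = float(np.exp(rng.normal(0.0, config.global_scale_sd)))
            jitter = rng.normal(0.0, config.amplitude_jitter, B)
            amps = base_amps * (1.0 + deltas[k]) * (1.0 + jitter)
            profile = amps @ P
            profile = profile * (1.0 + expr[c, k] * mask)
            y = gscale * profile
            y = y + config.smooth_noise_sd * _smooth_noise(rng, w.size, sigma_smooth)
            y = y + config.white_noise_sd * rng.standard_normal(w.size)
            if is_outlier:
                y = y + config.outlier_scale * _smooth_noise(rng, w.size, sigma_outlier)
            ids.append(f"{prefix}{i + 1:03d}")
            labels.append(label)
            rows.append(y)
            meta.append({"subcluster": k, "outlier": is_outlier})
    X = np.vstack(rows) if rows else np.empty((0, w.size))
    return SpectraSet(grid, ids, labels, X, meta)
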