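"""Spectral preprocessing: vector normalisation, Savitzky-Golay
derivatives, and region standardisation.

The canonical pipeline, in order, is::

    vector_normalize -> savgol_derivative -> extract_region (per region)
        -> standardize_region -> concatenate regions

implemented end-to-end by :func:`preprocess_set`, which returns the
feature matrix the classifier consumes plus a column -> (region,
wavenumber) map.

Derivatives are taken with respect to wavenumber in physical units
(intensity per (cm^-1)^order), honouring the descending storage order of
the grid.  Standardisation defaults to per-spectrum-per-region (each
sample's region segment to mean 0, population variance 1), which removes
sample-level intensity nuisance and introduces no cross-sample coupling;
a leakage-safe per-wavenumber cohort mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .exceptions import ConfigError, DegenerateInputError, GridError
from .spectra import SpectraSet, SpectralRegion, Spectrum, extract_region

STANDARDIZE_MODES = ("per_spectrum_region", "per_wavenumber_cohort")


@dataclass
class PreprocessConfig:
    """Knobs for the derivative/standardisation pipeline.

    sg_window
        Savitzky-Golay window length in points; must be odd and larger
        than ``sg_polyorder``.  Default 9 (nine smoothing points).
    sg_polyorder
        Degree of the local least-squares polynomial; default 3, the
        common chemometrics choice for second derivatives.
    derivative_order
        0, 1 or 2; default 2 (second-derivative spectra).
    standardize_mode
        ``per_spectrum_region`` (default) or ``per_wavenumber_cohort``.
    """

    sg_window: int = 9
    sg_polyorder: int = 3
    derivative_order: int = 2
    standardize_mode: str = "per_spectrum_region"

    def __post_init__(self):
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ConfigError(
                f"sg_window must be odd and > sg_polyorder "
                f"(got {self.sg_window}, {self.sg_polyorder})"
            )
        if self.derivative_order not in (0, 1, 2):
            raise ConfigError("derivative_order must be 0, 1 or 2")
        if self.derivative_order > self.sg_polyorder:
            raise ConfigError("derivative_order must not exceed sg_polyorder")
        if self.standardize_mode not in STANDARDIZE_MODES:
            raise ConfigError(
                f"standardize_mode must be one of {STANDARDIZE_MODES}"
            )


# ---------------------------------------------------------------------------
# vector normalisation


def _vn_matrix(X: np.ndarray, ids: Sequence[str]) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    zero = norms < 1e-300
    if zero.any():
        bad = ids[int(np.where(zero)[0][0])]
        raise DegenerateInputError(
            f"constant spectrum {bad!r}: vector normalisation undefined"
        )
    return Xc / norms[:, None]


def vector_normalize(spectrum: Spectrum) -> Spectrum:
    """Centre then scale to unit Euclidean norm.

    Output has mean 0 and L2 norm 1 (to 1e-12).  A constant spectrum has
    zero centred norm and raises :class:`DegenerateInputError`.
    """
    y = _vn_matrix(np.asarray(spectrum.intensities, float)[None, :], [spectrum.sample_id])[0]
    return Spectrum(spectrum.sample_id, spectrum.label, y, dict(spectrum.meta))


def vector_normalize_set(spectra: SpectraSet) -> SpectraSet:
    """Vectorised :func:`vector_normalize` over a whole cohort."""
    return spectra.with_intensities(_vn_matrix(spectra.X, spectra.sample_ids))


# ---------------------------------------------------------------------------
# Savitzky-Golay derivative


def _savgol_matrix(X: np.ndarray, grid, config: PreprocessConfig) -> np.ndarray:
    if X.shape[1] < config.sg_window:
        raise GridError(
            f"spectrum length {X.shape[1]} shorter than sg_window "
            f"{config.sg_window}"
        )
    d = np.diff(grid.values)
    step = np.abs(d)
    if step.max() - step.min() > 1e-6 * step.max():
        raise GridError("Savitzky-Golay derivative requires a uniform grid")
    out = savgol_filter(
        X,
        window_length=config.sg_window,
        polyorder=config.sg_polyorder,
        deriv=config.derivative_order,
        delta=grid.spacing,
        axis=1,
        mode="interp",  # terminal windows: polynomial extrapolation
    )
    # grid stored descending: d(index)/d(wavenumber) = -1/spacing, so each
    # derivative order flips sign once
    if grid.descending and config.derivative_order % 2 == 1:
        out = -out
    return out


def savgol_derivative(spectrum: Spectrum, grid, config: PreprocessConfig) -> Spectrum:
    """Derivative of the local least-squares polynomial fit.

    Degree ``sg_polyorder`` over a centred ``sg_window``, scaled by the
    physical grid spacing (units: intensity per (cm^-1)^order); edge
    points come from polynomial fits of the terminal windows.
    """
    y = _savgol_matrix(np.asarray(spectrum.intensities, float)[None, :], grid, config)[0]
    return Spectrum(spectrum.sample_id, spectrum.label, y, dict(spectrum.meta))


def savgol_derivative_set(spectra: SpectraSet, config: PreprocessConfig) -> SpectraSet:
    return spectra.with_intensities(_savgol_matrix(spectra.X, spectra.grid, config))


# ---------------------------------------------------------------------------
# standardisation


@dataclass
class StandardizerParams:
    """Fitted standardisation parameters; allow exact re-application."""

    mode: str
    mean: np.ndarray | None = None  # per-wavenumber, cohort mode only
    std: np.ndarray | None = None

    def apply(self, spectra: SpectraSet) -> SpectraSet:
        if self.mode == "per_spectrum_region":
            return _standardize_rows(spectra)
        return spectra.with_intensities((spectra.X - self.mean) / self.std)


def _standardize_rows(spectra: SpectraSet) -> SpectraSet:
    mu = spectra.X.mean(axis=1, keepdims=True)
    sd = spectra.X.std(axis=1, keepdims=True)  # population (n-denominator)
    zero = sd[:, 0] < 1e-300
    if zero.any():
        bad = spectra.sample_ids[int(np.where(zero)[0][0])]
        raise DegenerateInputError(
            f"zero-variance region segment in sample {bad!r}"
        )
    return spectra.with_intensities((spectra.X - mu) / sd)


def standardize_region(
    train: SpectraSet,
    apply_to: SpectraSet,
    config: PreprocessConfig,
) -> tuple[SpectraSet, StandardizerParams]:
    """Scale one extracted region to zero mean, unit variance.

    ``per_spectrum_region``: each spectrum's segment is shifted/scaled
    independently (population variance 1); no training statistics are
    involved.  ``per_wavenumber_cohort``: column means/stds are
    estimated on ``train`` only and applied to ``apply_to``
    (leakage-safe).
    """
    if len(train.grid) != len(apply_to.grid) or not np.allclose(
        train.grid.values, apply_to.grid.values
    ):
        raise GridError("train and apply_to sets must share one region grid")
    if config.standardize_mode == "per_spectrum_region":
        return _standardize_rows(apply_to), StandardizerParams("per_spectrum_region")
    mu = train.X.mean(axis=0)
    sd = train.X.std(axis=0)  # population
    zero = sd < 1e-300
    if zero.any():
        w = train.grid.values[int(np.where(zero)[0][0])]
        raise DegenerateInputError(
            f"zero-variance column at wavenumber {w:g} in cohort standardisation"
        )
    params = StandardizerParams("per_wavenumber_cohort", mean=mu, std=sd)
    return params.apply(apply_to), params


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class FeatureMatrix:
    """Preprocessed features plus provenance.

    ``X`` is samples x features; ``feature_map`` maps each column to its
    (region index, region bounds, wavenumber); ``region_blocks`` gives
    the column slice of each region, in the order regions were supplied.
    """

    X: np.ndarray
    feature_map: pd.DataFrame
    region_blocks: dict[SpectralRegion, slice]
    sample_ids: list[str]
    labels: list[str]

    def by_region(self) -> dict[SpectralRegion, np.ndarray]:
        return {r: self.X[:, sl] for r, sl in self.region_blocks.items()}


def preprocess_set(
    spectra: SpectraSet,
    regions: Sequence[SpectralRegion],
    config: PreprocessConfig | None = None,
) -> FeatureMatrix:
    """Run the full preprocessing pipeline over a cohort.

    Applies vector normalisation and the Savitzky-Golay derivative on
    the full grid, then per region: extraction and standardisation; the
    regions are concatenated into one feature matrix.  In cohort
    standardisation mode the statistics are fitted on this same set
    (callers needing leakage-safe evaluation should fit via
    :func:`standardize_region` per split).
    """
    config = config or PreprocessConfig()
    if not regions:
        raise ConfigError("at least one spectral region is required")
    work = vector_normalize_set(spectra)
    work = savgol_derivative_set(work, config)
    blocks: list[np.ndarray] = []
    rows: list[dict] = []
    region_blocks: dict[SpectralRegion, slice] = {}
    col = 0
    for ri, region in enumerate(regions):
        seg = extract_region(work, region)
        seg, _ = standardize_region(seg, seg, config)
        blocks.append(seg.X)
        for w in seg.grid.values:
            rows.append(
                {
                    "column": col,
                    "region_index": ri,
                    "region_high": region.high,
                    "region_low": region.low,
                    "wavenumber": float(w),
                }
            )
            col += 1
        region_blocks[region] = slice(col - len(seg.grid), col)
    X = np.hstack(blocks)
    fmap = pd.DataFrame(rows).set_index("column")
    return FeatureMatrix(X, fmap, region_blocks, list(spectra.sample_ids), list(spectra.labels))
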