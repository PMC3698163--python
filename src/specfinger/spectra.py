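"""Labelled absorbance spectra on a shared wavenumber grid.

The in-memory container is :class:`SpectraSet`: a wavenumber grid stored
in descending spectroscopic order (e.g. 4000 -> 400 cm^-1) plus a dense
``samples x wavenumbers`` intensity matrix with per-sample ids, labels
and free-form metadata.  Readers normalise grid orientation and label
spelling, so downstream stages can assume a canonical layout.

Interchange format is a wide CSV: one row per sample, first column
``sample_id``, an optional label column, remaining columns the
wavenumbers.  A transposed dialect (first column = wavenumbers, one
column per sample) is auto-detected.  A minimal JCAMP-DX (XYDATA, AFFN)
reader is provided for single instrument exports.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    FormatError,
    GridError,
    IdentityError,
    RegionError,
)

LABELS = ("positive", "negative", "unknown")

_LABEL_ALIASES = {
    "positive": "positive",
    "pos": "positive",
    "1": "positive",
    "disease": "positive",
    "patient": "positive",
    "negative": "negative",
    "neg": "negative",
    "0": "negative",
    "control": "negative",
    "healthy": "negative",
    "unknown": "unknown",
    "": "unknown",
    "na": "unknown",
    "nan": "unknown",
}

#: relative tolerance for grid-spacing uniformity
GRID_RTOL = 1e-6


def normalize_label(raw: object) -> str:
    """Map a raw label cell onto {positive, negative, unknown}."""
    key = str(raw).strip().lower()
    try:
        return _LABEL_ALIASES[key]
    except KeyError:
        raise FormatError(f"unrecognised class label {raw!r}") from None


def parse_number(text: str) -> float:
    """Parse a number, tolerating European separators.

    Strings in European thousands grouping — 1-3 leading digits followed
    by dot-separated triplets, optionally a decimal comma — are read as
    grouped integers: ``"1.850"`` -> 1850.0, ``"95,2"`` -> 95.2.  Plain
    machine floats (``"1850.5"``) pass through unchanged.
    """
    s = str(text).strip().replace("−", "-")
    if re.fullmatch(r"-?\d{1,3}(\.\d{3})+(,\d+)?", s):
        return float(s.replace(".", "").replace(",", "."))
    if re.fullmatch(r"-?\d+(,\d+)?", s):
        return float(s.replace(",", "."))
    try:
        return float(s)
    except ValueError:
        raise FormatError(f"cannot parse number {text!r}") from None


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly monotone, uniformly spaced wavenumbers in cm^-1."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise GridError("grid needs at least two wavenumbers")
        if not np.all(np.isfinite(v)):
            raise GridError("grid contains non-finite wavenumbers")
        d = np.diff(v)
        if np.any(d == 0) or not (np.all(d > 0) or np.all(d < 0)):
            raise GridError("grid is non-monotone")
        step = np.abs(d)
        if np.max(step) - np.min(step) > GRID_RTOL * np.max(step):
            raise GridError("grid spacing is non-uniform beyond tolerance")

    def __len__(self) -> int:
        return self.values.size

    @property
    def descending(self) -> bool:
        return self.values[0] > self.values[-1]

    @property
    def spacing(self) -> float:
        """Absolute step in cm^-1 (always positive)."""
        return float(abs(self.values[1] - self.values[0]))

    @property
    def span(self) -> tuple[float, float]:
        """(low, high) endpoints in cm^-1."""
        lo = float(self.values.min())
        hi = float(self.values.max())
        return lo, hi


@dataclass(frozen=True)
class SpectralRegion:
    """Closed wavenumber interval [low, high] in cm^-1."""

    high: float
    low: float

    def __post_init__(self):
        if not self.high > self.low:
            raise RegionError(
                f"region high ({self.high}) must exceed low ({self.low})"
            )

    def __str__(self) -> str:
        return f"{self.high:g}-{self.low:g} cm^-1"


@dataclass
class Spectrum:
    """One labelled measurement aligned to an external grid."""

    sample_id: str
    label: str
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.label not in LABELS:
            self.label = normalize_label(self.label)


class SpectraSet:
    """A cohort of spectra sharing one wavenumber grid.

    Stores intensities as a dense ``(n_samples, n_wavenumbers)`` array.
    The grid is normalised to descending order at construction; any
    ascending input is flipped together with the intensity columns.
    """

    def __init__(
        self,
        grid: WavenumberGrid,
        sample_ids: Sequence[str],
        labels: Sequence[str],
        intensities: np.ndarray,
        meta: Sequence[Mapping] | None = None,
    ):
        X = np.asarray(intensities, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(grid):
            raise GridError(
                f"intensity matrix has {X.shape[1]} columns but grid has "
                f"{len(grid)} wavenumbers"
            )
        if X.shape[0] != len(sample_ids):
            raise IdentityError("sample_ids length does not match matrix rows")
        ids = [str(s) for s in sample_ids]
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise IdentityError(f"duplicate sample_id(s): {dupes}")
        if not grid.descending:
            grid = WavenumberGrid(grid.values[::-1].copy())
            X = X[:, ::-1].copy()
        self.grid = grid
        self.sample_ids = list(ids)
        self.labels = [normalize_label(l) if l not in LABELS else l for l in labels]
        if len(self.labels) != len(ids):
            raise IdentityError("labels length does not match sample count")
        self.X = X
        self.meta = [dict(m) for m in meta] if meta is not None else [
            {} for _ in ids
        ]

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_spectra(cls, grid: WavenumberGrid, spectra: Iterable[Spectrum]) -> "SpectraSet":
        spectra = list(spectra)
        if spectra:
            X = np.vstack([s.intensities for s in spectra])
        else:
            X = np.empty((0, len(grid)))
        return cls(
            grid,
            [s.sample_id for s in spectra],
            [s.label for s in spectra],
            X,
            [s.meta for s in spectra],
        )

    # -- basic protocol ------------------------------------------------------

    def __len__(self) -> int:
        return self.X.shape[0]

    def __iter__(self) -> Iterator[Spectrum]:
        for i in range(len(self)):
            yield self[i]

    def __getitem__(self, i: int) -> Spectrum:
        return Spectrum(self.sample_ids[i], self.labels[i], self.X[i], self.meta[i])

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)

    def subset(self, indices: Sequence[int]) -> "SpectraSet":
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(
            self.grid,
            [self.sample_ids[i] for i in idx],
            [self.labels[i] for i in idx],
            self.X[idx].copy(),
            [self.meta[i] for i in idx],
        )

    def with_intensities(self, X: np.ndarray, grid: WavenumberGrid | None = None) -> "SpectraSet":
        """Same samples, new intensity matrix (and optionally new grid)."""
        return SpectraSet(grid or self.grid, self.sample_ids, self.labels, X, self.meta)


# ---------------------------------------------------------------------------
# validation report


@dataclass
class GridReport:
    """Outcome of :func:`check_grid`."""

    ok: bool
    monotone: bool
    uniform: bool
    span: tuple[float, float]
    within_instrument_range: bool
    finite: bool
    issues: list[str]

    def __str__(self) -> str:
        status = "OK" if self.ok else "FAILED"
        lines = [f"grid check: {status} (span {self.span[0]:g}-{self.span[1]:g} cm^-1)"]
        lines += [f"  - {msg}" for msg in self.issues]
        return "\n".join(lines)


def check_grid(spectra: SpectraSet) -> GridReport:
    """Validate grid monotonicity/uniformity and per-spectrum finiteness.

    Reporting only; never raises.  ``ok`` is true when the grid is
    strictly monotone, uniformly spaced, and every spectrum is finite.
    A span outside the mid-IR instrument range 400-4000 cm^-1 is noted
    but does not fail the check.
    """
    issues: list[str] = []
    v = spectra.grid.values
    d = np.diff(v)
    monotone = bool(np.all(d > 0) or np.all(d < 0))
    if not monotone:
        issues.append("non-monotone wavenumber grid")
    step = np.abs(d)
    uniform = bool(step.size and np.max(step) - np.min(step) <= GRID_RTOL * np.max(step))
    if not uniform:
        issues.append("non-uniform grid spacing")
    span = (float(v.min()), float(v.max()))
    in_range = 400.0 - 1e-9 <= span[0] and span[1] <= 4000.0 + 1e-9
    if not in_range:
        issues.append(f"span {span[0]:g}-{span[1]:g} outside 400-4000 cm^-1")
    bad = ~np.isfinite(spectra.X)
    finite = not bool(bad.any())
    if not finite:
        for i in np.unique(np.where(bad)[0]):
            issues.append(f"non-finite intensity in sample {spectra.sample_ids[i]!r}")
    ok = monotone and uniform and finite
    return GridReport(ok, monotone, uniform, span, in_range, finite, issues)


# ---------------------------------------------------------------------------
# CSV interchange


def _looks_numeric(cells: Sequence[str]) -> bool:
    if not cells:
        return False
    good = 0
    for c in cells:
        try:
            parse_number(c)
            good += 1
        except FormatError:
            pass
    return good / len(cells) > 0.5


def read_spectra_table(
    path: str | Path,
    label_column: str = "label",
    labels: str | Path | Mapping[str, str] | None = None,
) -> SpectraSet:
    """Read a wide CSV of spectra into a :class:`SpectraSet`.

    Two dialects are auto-detected by testing whether the header row is
    numeric:

    * row-per-sample — header ``sample_id,<label_column>,w1,w2,...``;
    * column-per-sample (transposed) — first column wavenumbers, one
      column per sample; labels then come from ``labels`` (a two-column
      ``sample_id,label`` manifest path or a mapping).

    The returned grid is descending regardless of file order; labels are
    normalised to {positive, negative, unknown}.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: fewer than two columns")

    header_tail = [c for c in df.columns[1:] if c != label_column]
    if _looks_numeric(header_tail):
        return _read_rows_dialect(df, path, label_column, labels)
    return _read_columns_dialect(df, path, labels)


def _label_lookup(labels, sample_ids) -> list[str]:
    if labels is None:
        return ["unknown"] * len(sample_ids)
    if isinstance(labels, (str, Path)):
        man = pd.read_csv(labels, dtype=str)
        if man.shape[1] < 2:
            raise FormatError("label manifest needs two columns (sample_id,label)")
        labels = dict(zip(man.iloc[:, 0], man.iloc[:, 1]))
    return [normalize_label(labels.get(s, "unknown")) for s in sample_ids]


def _parse_matrix(df_vals: pd.DataFrame, path: Path, ids, wn) -> np.ndarray:
    X = np.empty(df_vals.shape, dtype=float)
    for j, col in enumerate(df_vals.columns):
        for i, cell in enumerate(df_vals[col]):
            try:
                X[i, j] = float(cell)
            except (TypeError, ValueError):
                try:
                    X[i, j] = parse_number(cell)
                except FormatError:
                    raise FormatError(
                        f"{path}: unparseable or missing intensity for sample "
                        f"{ids[i]!r} at wavenumber {wn[j]:g}"
                    ) from None
    bad = np.where(~np.isfinite(X))
    if bad[0].size:
        i, j = bad[0][0], bad[1][0]
        raise FormatError(
            f"{path}: non-finite intensity for sample {ids[i]!r} "
            f"at wavenumber {wn[j]:g}"
        )
    return X


def _read_rows_dialect(df, path, label_column, labels) -> SpectraSet:
    ids = [s.strip() for s in df.iloc[:, 0]]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise IdentityError(f"{path}: duplicate sample_id(s) {dupes}")
    if label_column in df.columns:
        lab = [normalize_label(v) for v in df[label_column]]
        value_cols = [c for c in df.columns[1:] if c != label_column]
    else:
        lab = _label_lookup(labels, ids)
        value_cols = list(df.columns[1:])
    try:
        wn = np.array([parse_number(c) for c in value_cols])
    except FormatError as exc:
        raise GridError(f"{path}: non-numeric wavenumber header ({exc})") from exc
    try:
        grid = WavenumberGrid(wn)
    except GridError as exc:
        raise GridError(f"{path}: {exc}") from exc
    X = _parse_matrix(df[value_cols], path, ids, wn)
    return SpectraSet(grid, ids, lab, X)


def _read_columns_dialect(df, path, labels) -> SpectraSet:
    try:
        wn = np.array([parse_number(c) for c in df.iloc[:, 0]])
    except FormatError:
        raise FormatError(
            f"{path}: neither header row nor first column is numeric"
        ) from None
    try:
        grid = WavenumberGrid(wn)
    except GridError as exc:
        raise GridError(f"{path}: {exc}") from exc
    ids = [c.strip() for c in df.columns[1:]]
    lab = _label_lookup(labels, ids)
    X = _parse_matrix(df.iloc[:, 1:], path, ids, wn).T
    return SpectraSet(grid, ids, lab, X)


def write_spectra_table(spectra: SpectraSet, path: str | Path) -> None:
    """Write the row-per-sample wide CSV; inverse of :func:`read_spectra_table`."""
    path = Path(path)
    cols = {"sample_id": spectra.sample_ids, "label": spectra.labels}
    df = pd.DataFrame(cols)
    wn_cols = pd.DataFrame(
        spectra.X, columns=[f"{w:.10g}" for w in spectra.grid.values]
    )
    out = pd.concat([df.reset_index(drop=True), wn_cols], axis=1)
    # repr-precision floats so read(write(s)) == s to 1e-12
    out.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# region extraction


def extract_region(spectra: SpectraSet, region: SpectralRegion) -> SpectraSet:
    """Restrict to wavenumbers ``low <= w <= high`` (closed interval).

    The input set is not modified; sample order, labels and metadata are
    preserved.  Idempotent: extracting the same region twice equals once.
    """
    w = spectra.grid.values
    mask = (w >= region.low - 1e-9) & (w <= region.high + 1e-9)
    if not mask.any():
        raise RegionError(
            f"region {region} does not intersect grid span "
            f"{spectra.grid.span[0]:g}-{spectra.grid.span[1]:g}"
        )
    if mask.sum() < 2:
        raise RegionError(f"region {region} retains fewer than two gridpoints")
    grid = WavenumberGrid(w[mask].copy())
    return spectra.with_intensities(spectra.X[:, mask].copy(), grid)


# ---------------------------------------------------------------------------
# JCAMP-DX single-spectrum reader


def read_jcamp(path: str | Path, label: str = "unknown") -> SpectraSet:
    """Read a single spectrum from a JCAMP-DX file (XYDATA, AFFN form).

    Supports the common ``##XYDATA=(X++(Y..Y))`` layout with plain
    space-separated numbers; compressed (SQZ/DIF/DUP) encodings are not
    supported.  Returns a one-spectrum :class:`SpectraSet`.
    """
    path = Path(path)
    header: dict[str, str] = {}
    ydata: list[float] = []
    in_xy = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("##"):
                key, _, val = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                if key == "XYDATA":
                    in_xy = True
                    continue
                if key == "END":
                    break
                in_xy = False
                header[key] = val.strip()
            elif in_xy:
                nums = line.replace(",", " ").split()
                try:
                    vals = [float(tok) for tok in nums]
                except ValueError as exc:
                    raise FormatError(f"{path}: bad XYDATA line {line!r}") from exc
                ydata.extend(vals[1:])  # first token is the line's X checkpoint
    if not ydata:
        raise FormatError(f"{path}: no XYDATA block found")
    try:
        firstx = float(header["FIRSTX"])
        lastx = float(header["LASTX"])
        npoints = int(float(header["NPOINTS"]))
    except KeyError as exc:
        raise FormatError(f"{path}: missing JCAMP header {exc}") from exc
    yfactor = float(header.get("YFACTOR", 1.0))
    if len(ydata) != npoints:
        raise FormatError(
            f"{path}: NPOINTS={npoints} but {len(ydata)} Y values present"
        )
    wn = np.linspace(firstx, lastx, npoints)
    y = np.asarray(ydata) * yfactor
    title = header.get("TITLE", path.stem) or path.stem
    return SpectraSet(WavenumberGrid(wn), [title], [label], y[None, :])
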