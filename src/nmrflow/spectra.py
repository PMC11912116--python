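"""Peak-list and grid representations of NMR spectra, with CSV I/O.

A spectrum is treated as a finite weighted point set in chemical-shift
space: a list of peaks, each a ppm position (1-3 axes) with a nonnegative
intensity weight.  Gridded intensity data is the same thing before
conversion -- every grid point is a candidate node with its intensity as
weight -- so both representations feed the same downstream flow network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PeakSpectrum",
    "GridSpectrum",
    "CompoundLibrary",
    "total_weight",
    "scale_spectrum",
    "read_peaklist",
    "write_peaklist",
    "read_grid",
    "write_grid",
    "bin_grid",
    "grid_to_peaks",
    "read_library_manifest",
    "write_library_manifest",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected CSV dialect."""


@dataclass(frozen=True)
class PeakSpectrum:
    """A weighted point set in chemical-shift space.

    Parameters
    ----------
    id : str
        Text label (compound name, mixture name, ...).
    dim : int
        Number of chemical-shift axes (1-3).
    positions : ndarray, shape (n_peaks, dim)
        Peak coordinates in ppm, stored exactly as given.
    weights : ndarray, shape (n_peaks,)
        Nonnegative peak intensities (integrals).  Zero-weight peaks are
        permitted but contribute nothing.
    """

    id: str
    dim: int
    positions: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.size == 0:
            pos = pos.reshape(0, self.dim)
        w = np.asarray(self.weights, dtype=float).ravel()
        if not 1 <= self.dim <= 3:
            raise ValueError(f"dim must be in 1..3, got {self.dim}")
        if pos.shape[1] != self.dim:
            raise ValueError(
                f"positions have {pos.shape[1]} axes, expected dim={self.dim}"
            )
        if pos.shape[0] != w.shape[0]:
            raise ValueError("positions and weights length mismatch")
        if np.any(w < 0):
            raise ValueError("peak weights must be nonnegative")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "weights", w)

    @property
    def n_peaks(self) -> int:
        return self.weights.shape[0]

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSpectrum):
            return NotImplemented
        return (
            self.id == other.id
            and self.dim == other.dim
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.weights, other.weights)
        )


@dataclass(frozen=True)
class GridSpectrum:
    """Intensity values on a rectilinear ppm grid.

    ``axes`` holds one strictly monotone coordinate vector per dimension
    (ascending or descending -- the input direction is preserved); ``values``
    has shape ``(len(axes[0]), ..., len(axes[dim-1]))``.  Negative values are
    permitted on input (baseline artifacts); conversion to a peak spectrum
    never emits negative weights.
    """

    axes: tuple[np.ndarray, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        axes = tuple(np.asarray(a, dtype=float).ravel() for a in self.axes)
        values = np.asarray(self.values, dtype=float)
        if not 1 <= len(axes) <= 3:
            raise ValueError("grid must have 1-3 axes")
        for a in axes:
            if a.size == 0:
                raise ValueError("empty grid axis")
            if a.size > 1:
                d = np.diff(a)
                if not (np.all(d > 0) or np.all(d < 0)):
                    raise ValueError("grid axis must be strictly monotone")
        if values.shape != tuple(a.size for a in axes):
            raise ValueError(
                f"values shape {values.shape} does not match axes "
                f"{tuple(a.size for a in axes)}"
            )
        object.__setattr__(self, "axes", axes)
        object.__setattr__(self, "values", values)

    @property
    def dim(self) -> int:
        return len(self.axes)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GridSpectrum):
            return NotImplemented
        return (
            len(self.axes) == len(other.axes)
            and all(np.array_equal(a, b) for a, b in zip(self.axes, other.axes))
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class LibraryEntry:
    compound_id: str
    spectrum: PeakSpectrum
    ref_concentration: float  # mM; acquisition concentration of the library spectrum

    def __post_init__(self) -> None:
        if self.ref_concentration <= 0:
            raise ValueError("ref_concentration must be positive")


@dataclass(frozen=True)
class CompoundLibrary:
    """Ordered collection of single-compound peak spectra.

    Each entry carries the concentration at which the library spectrum was
    acquired, linking assigned flow back to concentration units.
    """

    entries: tuple[LibraryEntry, ...]

    def __post_init__(self) -> None:
        entries = tuple(self.entries)
        ids = [e.compound_id for e in entries]
        if len(set(ids)) != len(ids):
            raise ValueError("compound_id values must be unique")
        if not entries:
            raise ValueError("library must contain at least one compound")
        dims = {e.spectrum.dim for e in entries}
        if len(dims) != 1:
            raise ValueError("all library spectra must share one dim")
        for e in entries:
            if e.spectrum.n_peaks == 0 or e.spectrum.total_weight <= 0:
                raise ValueError(
                    f"library spectrum {e.compound_id!r} must be nonempty with "
                    "positive total weight"
                )
        object.__setattr__(self, "entries", entries)

    @property
    def dim(self) -> int:
        return self.entries[0].spectrum.dim

    @property
    def compound_ids(self) -> list[str]:
        return [e.compound_id for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, compound_id: str) -> LibraryEntry:
        for e in self.entries:
            if e.compound_id == compound_id:
                return e
        raise KeyError(compound_id)


def total_weight(spectrum: PeakSpectrum) -> float:
    """Sum of all peak weights (V_X); 0 for an empty spectrum."""
    return spectrum.total_weight


def scale_spectrum(spectrum: PeakSpectrum, factor: float) -> PeakSpectrum:
    """Multiply every weight by ``factor`` (>= 0); positions unchanged."""
    if factor < 0:
        raise ValueError("scale factor must be nonnegative")
    return PeakSpectrum(
        id=spectrum.id,
        dim=spectrum.dim,
        positions=spectrum.positions.copy(),
        weights=spectrum.weights * factor,
    )


# ---------------------------------------------------------------------------
# Peak-list CSV dialect: header `shift_1`..`shift_dim`, `weight`; optional
# `compound_id` for concatenated library files.  UTF-8, '.' decimal, comma
# delimiter.  Axis order for dim=2 is 1H then 13C.
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # shortest format that round-trips any double exactly


def _shift_cols(dim: int) -> list[str]:
    return [f"shift_{a + 1}" for a in range(dim)]


def read_peaklist(path: str | Path, dim: int, id: str | None = None) -> PeakSpectrum:
    """Read a peak-list CSV into a :class:`PeakSpectrum`.

    Rejects missing columns, negative weights and non-numeric fields with
    the offending row number (1-based, counting the header as row 1).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    cols = _shift_cols(dim) + ["weight"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    positions = np.empty((len(df), dim), dtype=float)
    weights = np.empty(len(df), dtype=float)
    for row_i, (_, row) in enumerate(df.iterrows(), start=2):
        try:
            for a, c in enumerate(_shift_cols(dim)):
                positions[row_i - 2, a] = float(row[c])
            weights[row_i - 2] = float(row["weight"])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-numeric field at row {row_i}") from exc
        if weights[row_i - 2] < 0:
            raise FormatError(f"{path}: negative weight at row {row_i}")
    return PeakSpectrum(
        id=id if id is not None else path.stem,
        dim=dim,
        positions=positions,
        weights=weights,
    )


def write_peaklist(spectrum: PeakSpectrum, path: str | Path) -> None:
    """Write a peak-list CSV (see module docstring for the dialect)."""
    cols = {}
    for a, c in enumerate(_shift_cols(spectrum.dim)):
        cols[c] = spectrum.positions[:, a]
    cols["weight"] = spectrum.weights
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Grid CSV dialect.  dim=2: first row = axis-2 ppm coordinates with a blank
# leading cell, first column = axis-1 ppm coordinates, body = intensities.
# dim=1: two columns (ppm, intensity).
# ---------------------------------------------------------------------------


def read_grid(path: str | Path) -> GridSpectrum:
    """Read a grid CSV; the dimensionality is inferred from the header."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().strip()
    lead = first.split(",", 1)[0].strip()
    if lead == "":  # blank corner cell -> 2D matrix layout
        raw = pd.read_csv(path, header=None, dtype=str, skipinitialspace=True)
        if raw.isna().any(axis=None) and not raw.iloc[1:, 1:].notna().all(axis=None):
            raise FormatError(f"{path}: ragged rows in grid body")
        try:
            axis2 = raw.iloc[0, 1:].astype(float).to_numpy()
            axis1 = raw.iloc[1:, 0].astype(float).to_numpy()
            body = raw.iloc[1:, 1:].astype(float).to_numpy()
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-numeric field in grid") from exc
        try:
            return GridSpectrum(axes=(axis1, axis2), values=body)
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    # 1D layout: two columns (ppm, intensity), with header
    df = pd.read_csv(path)
    if df.shape[1] != 2:
        raise FormatError(f"{path}: 1D grid file must have two columns")
    try:
        return GridSpectrum(
            axes=(df.iloc[:, 0].astype(float).to_numpy(),),
            values=df.iloc[:, 1].astype(float).to_numpy(),
        )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_grid(grid: GridSpectrum, path: str | Path) -> None:
    """Write a grid CSV in the dialect read by :func:`read_grid`."""
    path = Path(path)
    fmt = _FLOAT_FMT
    if grid.dim == 1:
        pd.DataFrame({"ppm": grid.axes[0], "intensity": grid.values}).to_csv(
            path, index=False, float_format=fmt
        )
        return
    if grid.dim != 2:
        raise ValueError("grid CSV dialect supports dim 1 and 2 only")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("," + ",".join(fmt % v for v in grid.axes[1]) + "\n")
        for i, ppm1 in enumerate(grid.axes[0]):
            fh.write(
                (fmt % ppm1)
                + ","
                + ",".join(fmt % v for v in grid.values[i])
                + "\n"
            )


def _bin_edges(n_in: int, n_out: int) -> list[slice]:
    # equal-size bins; the last bin absorbs the remainder cells
    size = n_in // n_out
    slices = [slice(b * size, (b + 1) * size) for b in range(n_out)]
    slices[-1] = slice((n_out - 1) * size, n_in)
    return slices


def bin_grid(grid: GridSpectrum, target_shape: Sequence[int]) -> GridSpectrum:
    """Down-bin a grid by summing cells; total intensity is conserved exactly.

    Each output cell is the sum of its constituent input cells and sits at
    the arithmetic mean of their coordinates.  When an input axis length is
    not divisible by the target length the last bin absorbs the remainder.
    """
    target_shape = tuple(int(s) for s in target_shape)
    if len(target_shape) != grid.dim:
        raise ValueError("target_shape must give one length per axis")
    for s, n in zip(target_shape, grid.shape):
        if s <= 0:
            raise ValueError("target axis length must be positive")
        if s > n:
            raise ValueError(f"target length {s} exceeds input length {n}")
    values = grid.values
    new_axes = []
    for ax_i, (axis, s) in enumerate(zip(grid.axes, target_shape)):
        slices = _bin_edges(axis.size, s)
        new_axes.append(np.array([axis[sl].mean() for sl in slices]))
        # sum-pool along this axis
        values = np.stack(
            [values[(slice(None),) * ax_i + (sl,)].sum(axis=ax_i) for sl in slices],
            axis=ax_i,
        )
    return GridSpectrum(axes=tuple(new_axes), values=values)


def grid_to_peaks(
    grid: GridSpectrum, floor: float = 0.0, id: str = "grid"
) -> PeakSpectrum:
    """Turn every grid point with value > ``floor`` into a peak.

    Grid points are nodes just like picked peaks: position = the point's
    ppm coordinates, weight = its intensity.  Points at or below the floor
    (all negatives, for floor >= 0) are dropped, so baseline artifacts never
    become sink capacity.
    """
    mesh = np.meshgrid(*grid.axes, indexing="ij")
    coords = np.stack([m.ravel() for m in mesh], axis=1)
    vals = grid.values.ravel()
    keep = vals > floor
    return PeakSpectrum(
        id=id, dim=grid.dim, positions=coords[keep], weights=vals[keep]
    )


# ---------------------------------------------------------------------------
# Library manifest: CSV with columns compound_id, path, ref_concentration_mM;
# per-compound peak lists live in files referenced relative to the manifest.
# ---------------------------------------------------------------------------


def read_library_manifest(path: str | Path, dim: int) -> CompoundLibrary:
    path = Path(path)
    df = pd.read_csv(path, skipinitialspace=True)
    required = ["compound_id", "path", "ref_concentration_mM"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing columns {missing}")
    entries = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = path.parent / p
        spec = read_peaklist(p, dim=dim, id=str(row["compound_id"]))
        entries.append(
            LibraryEntry(
                compound_id=str(row["compound_id"]),
                spectrum=spec,
                ref_concentration=float(row["ref_concentration_mM"]),
            )
        )
    return CompoundLibrary(entries=tuple(entries))


def write_library_manifest(
    library: CompoundLibrary, directory: str | Path, manifest_name: str = "library.csv"
) -> Path:
    """Write one peak list per compound plus a manifest; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for e in library:
        fname = f"{e.compound_id}.csv"
        write_peaklist(e.spectrum, directory / fname)
        rows.append(
            {
                "compound_id": e.compound_id,
                "path": fname,
                "ref_concentration_mM": e.ref_concentration,
            }
        )
    manifest = directory / manifest_name
    pd.DataFrame(rows).to_csv(manifest, index=False, float_format=_FLOAT_FMT)
    return manifest
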