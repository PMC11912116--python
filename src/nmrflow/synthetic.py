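"""Seeded generators for compound libraries, mixtures, and gridded spectra.

These emulate the structure of HSQC benchmark data: a library of
single-compound peak lists acquired at a known reference concentration,
mixtures formed as scaled superpositions of library spectra with peak
position jitter and multiplicative intensity noise, and grid renderings
in which each peak is deposited as a discretized Gaussian plus additive
baseline noise.  Every generator is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import erf

from .spectra import CompoundLibrary, GridSpectrum, LibraryEntry, PeakSpectrum

__all__ = [
    "MixtureSpec",
    "PeakShape",
    "make_library",
    "make_mixture_peaks",
    "render_grid",
    "make_axes",
    "axes_covering",
]

# default ppm windows: 1H 0-10, 13C 0-160 (HSQC), third axis 0-10
_DEFAULT_RANGES = {
    1: ((0.0, 10.0),),
    2: ((0.0, 10.0), (0.0, 160.0)),
    3: ((0.0, 10.0), (0.0, 160.0), (0.0, 10.0)),
}


@dataclass(frozen=True)
class MixtureSpec:
    """Recipe for one synthetic mixture.

    ``contained`` maps compound ids to true concentrations c_k* (mM, > 0).
    ``shift_noise_sd`` gives the per-axis Gaussian SD of peak position
    jitter in ppm; ``weight_noise_cv`` the coefficient of variation of the
    multiplicative (lognormal) intensity noise; ``baseline_noise_sd`` is
    only used when the mixture is rendered to a grid.
    """

    contained: Mapping[str, float]
    shift_noise_sd: tuple[float, ...] = (0.0,)
    weight_noise_cv: float = 0.0
    baseline_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.contained:
            raise ValueError("mixture must contain at least one compound")
        if any(c <= 0 for c in self.contained.values()):
            raise ValueError("true concentrations must be positive")
        if self.weight_noise_cv < 0 or self.baseline_noise_sd < 0:
            raise ValueError("noise levels must be nonnegative")
        object.__setattr__(
            self, "shift_noise_sd", tuple(float(s) for s in self.shift_noise_sd)
        )


@dataclass(frozen=True)
class PeakShape:
    """Per-axis Gaussian standard deviations (ppm) used for grid rendering."""

    widths: tuple[float, ...]

    def __post_init__(self) -> None:
        widths = tuple(float(w) for w in self.widths)
        if any(w <= 0 for w in widths):
            raise ValueError("peak widths must be positive")
        object.__setattr__(self, "widths", widths)


def make_library(
    n_compounds: int,
    peaks_per_compound: tuple[int, int] = (1, 20),
    dim: int = 2,
    shift_ranges: Sequence[tuple[float, float]] | None = None,
    ref_concentration: float = 30.0,
    seed: int = 0,
) -> CompoundLibrary:
    """Generate a random compound library.

    Peak positions are uniform over the per-axis ppm ranges; raw weights
    are lognormal and then normalized so each compound's total weight is
    ref_concentration x n_peaks (total signal proportional to concentration
    times the number of contributing CH groups).
    """
    if n_compounds < 1:
        raise ValueError("n_compounds must be >= 1")
    lo, hi = peaks_per_compound
    if lo < 1 or hi < lo:
        raise ValueError("invalid peaks_per_compound range")
    if shift_ranges is None:
        shift_ranges = _DEFAULT_RANGES[dim]
    if len(shift_ranges) != dim or any(b <= a for a, b in shift_ranges):
        raise ValueError("shift_ranges must give a nonempty (lo, hi) per axis")
    rng = np.random.default_rng(seed)
    width = len(str(n_compounds))
    entries = []
    for k in range(n_compounds):
        n_peaks = int(rng.integers(lo, hi + 1))
        pos = np.column_stack(
            [rng.uniform(a, b, size=n_peaks) for a, b in shift_ranges]
        )
        w = rng.lognormal(mean=0.0, sigma=0.5, size=n_peaks)
        w *= ref_concentration * n_peaks / w.sum()
        cid = f"cmpd{(k + 1):0{width}d}"
        entries.append(
            LibraryEntry(
                compound_id=cid,
                spectrum=PeakSpectrum(id=cid, dim=dim, positions=pos, weights=w),
                ref_concentration=ref_concentration,
            )
        )
    return CompoundLibrary(entries=tuple(entries))


def make_mixture_peaks(
    library: CompoundLibrary, spec: MixtureSpec
) -> tuple[PeakSpectrum, dict[str, dict[str, float]]]:
    """Superpose contained compounds into a mixture peak list.

    Each contained compound contributes its peaks scaled by
    alpha_k* = c_k* / c_k°, positions jittered by zero-mean Gaussian shift
    noise (per axis) and weights multiplied by lognormal noise with the
    requested CV.  With all noise at zero the target is an exact
    superposition.  Returns the mixture and a ground-truth record
    {compound_id: {"concentration_mM": c_k*, "alpha": alpha_k*}}.
    """
    unknown = set(spec.contained) - set(library.compound_ids)
    if unknown:
        raise ValueError(f"unknown compound ids in mixture: {sorted(unknown)}")
    dim = library.dim
    shift_sd = spec.shift_noise_sd
    if len(shift_sd) == 1:
        shift_sd = shift_sd * dim
    if len(shift_sd) != dim:
        raise ValueError("shift_noise_sd must give one SD per axis")
    rng = np.random.default_rng(spec.seed)
    positions, weights, truth = [], [], {}
    cv = spec.weight_noise_cv
    sigma = np.sqrt(np.log1p(cv**2))
    for entry in library:  # library order keeps generation deterministic
        cid = entry.compound_id
        if cid not in spec.contained:
            continue
        c_true = float(spec.contained[cid])
        alpha = c_true / entry.ref_concentration
        pos = entry.spectrum.positions.copy()
        w = entry.spectrum.weights * alpha
        if any(s > 0 for s in shift_sd):
            pos = pos + rng.normal(0.0, shift_sd, size=pos.shape)
        if cv > 0:
            # lognormal with unit mean: E[exp(N(-s^2/2, s^2))] = 1
            w = w * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=w.shape)
        positions.append(pos)
        weights.append(w)
        truth[cid] = {"concentration_mM": c_true, "alpha": alpha}
    target = PeakSpectrum(
        id="mixture",
        dim=dim,
        positions=np.concatenate(positions),
        weights=np.concatenate(weights),
    )
    return target, truth


def make_axes(
    shape: Sequence[int], shift_ranges: Sequence[tuple[float, float]] | None = None
) -> tuple[np.ndarray, ...]:
    """Cell-center coordinate vectors over the default (or given) ppm windows."""
    if shift_ranges is None:
        shift_ranges = _DEFAULT_RANGES[len(shape)]
    axes = []
    for n, (a, b) in zip(shape, shift_ranges):
        step = (b - a) / n
        axes.append(a + step * (np.arange(n) + 0.5))
    return tuple(axes)


def axes_covering(
    spectrum: PeakSpectrum,
    shape: Sequence[int],
    pad: Sequence[float],
) -> tuple[np.ndarray, ...]:
    """Grid axes spanning a spectrum's peaks with a per-axis ppm margin.

    The margin should cover the rendered peak tails (e.g. 4x the Gaussian
    width) so every deposited peak fits on the grid.
    """
    if len(pad) != spectrum.dim:
        raise ValueError("pad must give one margin per axis")
    ranges = [
        (spectrum.positions[:, a].min() - pad[a], spectrum.positions[:, a].max() + pad[a])
        for a in range(spectrum.dim)
    ]
    return make_axes(shape, ranges)


def _axis_cell_masses(axis: np.ndarray, center: float, sd: float) -> np.ndarray:
    """Gaussian mass per cell along one axis, truncated at 4 SD.

    Cells are the Voronoi intervals of the axis coordinates; mass is the
    Gaussian CDF difference over each cell, so the discrete sum approaches
    the truncated-Gaussian total regardless of grid resolution.
    """
    asc = axis if axis.size < 2 or axis[1] > axis[0] else axis[::-1]
    edges = np.empty(asc.size + 1)
    edges[1:-1] = 0.5 * (asc[1:] + asc[:-1])
    edges[0] = asc[0] - (edges[1] - asc[0]) if asc.size > 1 else asc[0] - 0.5
    edges[-1] = asc[-1] + (asc[-1] - edges[-2]) if asc.size > 1 else asc[-1] + 0.5
    lo, hi = center - 4 * sd, center + 4 * sd
    a = np.clip(edges[:-1], lo, hi)
    b = np.clip(edges[1:], lo, hi)
    z = lambda t: erf((t - center) / (np.sqrt(2) * sd))
    masses = 0.5 * (z(b) - z(a))
    if axis.size >= 2 and axis[1] < axis[0]:
        masses = masses[::-1]
    return masses


def render_grid(
    spectrum: PeakSpectrum,
    axes: Sequence[np.ndarray],
    shape: PeakShape,
    baseline_noise_sd: float = 0.0,
    seed: int = 0,
) -> GridSpectrum:
    """Deposit each peak as a discretized Gaussian on the grid.

    Per-peak cell masses are renormalized after 4-SD truncation so that the
    discrete sum equals the peak weight exactly; additive Gaussian baseline
    noise (SD in intensity units) is applied afterwards.  Peaks outside the
    axis ranges are rejected.
    """
    axes = tuple(np.asarray(a, dtype=float).ravel() for a in axes)
    if len(axes) != spectrum.dim or len(shape.widths) != spectrum.dim:
        raise ValueError("axes and peak widths must match the spectrum dim")
    for a_i, axis in enumerate(axes):
        asc = np.sort(axis)
        # coverage extends half a boundary cell beyond the outer centers
        lo = asc[0] - (0.5 * (asc[1] - asc[0]) if asc.size > 1 else 0.5)
        hi = asc[-1] + (0.5 * (asc[-1] - asc[-2]) if asc.size > 1 else 0.5)
        p = spectrum.positions[:, a_i]
        if spectrum.n_peaks and (p.min() < lo or p.max() > hi):
            raise ValueError(f"peak positions outside axis {a_i} range")
    values = np.zeros(tuple(a.size for a in axes))
    for p in range(spectrum.n_peaks):
        masses = [
            _axis_cell_masses(axes[a_i], spectrum.positions[p, a_i], shape.widths[a_i])
            for a_i in range(spectrum.dim)
        ]
        cell = masses[0]
        for m in masses[1:]:
            cell = np.multiply.outer(cell, m)
        total = cell.sum()
        if total > 0:
            values += cell * (spectrum.weights[p] / total)
    if baseline_noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, baseline_noise_sd, size=values.shape)
    return GridSpectrum(axes=axes, values=values)
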