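"""Chemical-shift metric, radius queries, and flow-network construction.

The network routes intensity from a single source through one hub per
library compound, then through that compound's peak nodes, into target
peak nodes whose sink capacity equals the target peak weight.  A compound
peak connects to exactly the target peaks within the assignment radius r
(closed ball), at a cost equal to their spectral distance; unassignable
production drains to an absorption sink at cost c_ø > r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .spectra import CompoundLibrary, PeakSpectrum

__all__ = ["Metric", "default_metric", "distance", "neighbors_within", "build_network", "FlowNetwork"]

# relative slack on the closed neighborhood boundary: keeps a target peak at
# exactly radius distance inside the ball despite float rounding (1.05 - 1.0
# is one ulp above 0.05)
_R_TOL = 1e-9


@dataclass(frozen=True)
class Metric:
    """Scaled Euclidean metric on chemical-shift coordinates.

    Each axis is multiplied by a dimensionless scale before the Euclidean
    combination, so a single radius can act across axes with very different
    ppm ranges.  The HSQC default (1.0 for 1H, 0.1 for 13C) puts distances
    on the 1H ppm scale, where observed peak widths (0.03-0.09 ppm) guide
    the choice of radius.
    """

    axis_scales: tuple[float, ...]

    def __post_init__(self) -> None:
        scales = tuple(float(s) for s in self.axis_scales)
        if not scales or any(s <= 0 for s in scales):
            raise ValueError("axis_scales must be positive")
        object.__setattr__(self, "axis_scales", scales)

    @property
    def dim(self) -> int:
        return len(self.axis_scales)

    def scaled(self, coords: np.ndarray) -> np.ndarray:
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        if coords.shape[1] != self.dim:
            raise ValueError(
                f"coordinate dim {coords.shape[1]} != metric dim {self.dim}"
            )
        return coords * np.asarray(self.axis_scales)


def default_metric(dim: int) -> Metric:
    """Default per-dimension scales: 1H-scale for heteronuclear axes.

    dim=1 -> (1.0,); dim=2 -> (1.0, 0.1) for (1H, 13C) HSQC; dim=3 adds a
    second 0.1-scaled heteronuclear axis.
    """
    if dim == 1:
        return Metric((1.0,))
    if dim == 2:
        return Metric((1.0, 0.1))
    if dim == 3:
        return Metric((1.0, 0.1, 0.1))
    raise ValueError("dim must be in 1..3")


def distance(x, y, metric: Metric) -> float:
    """Scaled Euclidean distance between two ppm coordinate vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("coordinate length mismatch")
    if x.size != metric.dim:
        raise ValueError("coordinate length does not match metric dim")
    scales = np.asarray(metric.axis_scales)
    return float(np.sqrt(np.sum((scales * (x - y)) ** 2)))


def neighbors_within(
    target: PeakSpectrum, point, r: float, metric: Metric
) -> list[int]:
    """Indices of target peaks within distance r of ``point`` (closed ball).

    Returned ascending by index; equals an exhaustive scan of all pairwise
    distances (the KD-tree is an implementation detail).
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    if target.n_peaks == 0:
        return []
    tree = cKDTree(metric.scaled(target.positions))
    idx = tree.query_ball_point(metric.scaled(point)[0], r * (1 + _R_TOL))
    return sorted(int(i) for i in idx)


@dataclass(frozen=True)
class FlowNetwork:
    """The assignment network for one library/target pair.

    Arcs between compound-peak nodes and target nodes are stored flat:
    ``arc_compound[a]``, ``arc_peak[a]`` identify the compound peak (library
    order, then peak order), ``arc_target[a]`` the target peak, and
    ``arc_cost[a]`` the spectral distance between them.  Implicit structural
    arcs (source->hub, hub->peak at cost 0, source->absorption at cost c_ø)
    are recovered from the roster and are counted by :attr:`n_arcs`.
    """

    compound_ids: tuple[str, ...]
    peak_fractions: tuple[np.ndarray, ...]  # p_i = v_i / V_Xk per compound
    target_capacities: np.ndarray  # w_j
    production: float  # V_Y
    radius: float
    absorption_cost: float
    metric: Metric
    arc_compound: np.ndarray
    arc_peak: np.ndarray
    arc_target: np.ndarray
    arc_cost: np.ndarray

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def n_targets(self) -> int:
        return int(self.target_capacities.size)

    @property
    def n_compound_peaks(self) -> int:
        return int(sum(p.size for p in self.peak_fractions))

    @property
    def n_nodes(self) -> int:
        # source + absorption + hubs + compound peaks + target sinks
        return 2 + self.n_compounds + self.n_compound_peaks + self.n_targets

    @property
    def n_arcs(self) -> int:
        # s->ø, s->hubs, hub->peaks, peak->target assignments
        return 1 + self.n_compounds + self.n_compound_peaks + int(self.arc_cost.size)

    def arcs_of_compound(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.arc_compound == k)


def build_network(
    library: CompoundLibrary,
    target: PeakSpectrum,
    r: float,
    c_absorption: float = 1e6,
    metric: Metric | None = None,
) -> FlowNetwork:
    """Construct the flow network for ``library`` against ``target``.

    Every compound appears in the roster even if none of its peaks has a
    target neighbor within r (its hub then carries zero assignable flow), so
    downstream reports cover the whole library.  Production equals the total
    target weight, matching the total sink capacity.
    """
    if metric is None:
        metric = default_metric(library.dim)
    if r <= 0:
        raise ValueError("radius must be positive")
    if c_absorption <= r:
        raise ValueError(
            f"absorption cost ({c_absorption}) must exceed the assignment "
            f"radius ({r})"
        )
    if target.dim != library.dim:
        raise ValueError("target and library dimensionality differ")
    if target.n_peaks == 0 or target.total_weight <= 0:
        raise ValueError("target must be nonempty with positive total weight")

    tree = cKDTree(metric.scaled(target.positions))
    arc_compound: list[np.ndarray] = []
    arc_peak: list[np.ndarray] = []
    arc_target: list[np.ndarray] = []
    arc_cost: list[np.ndarray] = []
    fractions = []
    for k, entry in enumerate(library):
        spec = entry.spectrum
        fractions.append(spec.weights / spec.total_weight)
        scaled = metric.scaled(spec.positions)
        hits = tree.query_ball_point(scaled, r * (1 + _R_TOL))
        for i, js in enumerate(hits):
            if not js:
                continue
            js = np.sort(np.asarray(js, dtype=np.int64))
            d = np.sqrt(((scaled[i] - metric.scaled(target.positions[js])) ** 2).sum(axis=1))
            arc_compound.append(np.full(js.size, k, dtype=np.int64))
            arc_peak.append(np.full(js.size, i, dtype=np.int64))
            arc_target.append(js)
            arc_cost.append(d)

    def _cat(parts, dtype):
        return (
            np.concatenate(parts)
            if parts
            else np.empty(0, dtype=dtype)
        )

    return FlowNetwork(
        compound_ids=tuple(library.compound_ids),
        peak_fractions=tuple(fractions),
        target_capacities=target.weights.copy(),
        production=target.total_weight,
        radius=float(r),
        absorption_cost=float(c_absorption),
        metric=metric,
        arc_compound=_cat(arc_compound, np.int64),
        arc_peak=_cat(arc_peak, np.int64),
        arc_target=_cat(arc_target, np.int64),
        arc_cost=_cat(arc_cost, float),
    )
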