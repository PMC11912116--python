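"""Minimum-cost-flow solves: simultaneous, independent, and incremental.

The flow problem is a linear program.  Because every hub distributes its
flow over the compound's peaks in fixed proportions p_i, the hub->peak
flows are determined by the hub volume, and the LP needs only one volume
variable F_k per compound, one flow per peak->target arc, and the absorbed
volume:

    minimize    sum_a c_a f_a + c_abs f_abs
    subject to  sum_{a in arcs(k,i)} f_a = p_i F_k      (peak proportionality)
                sum_{a into j} f_a <= w_j               (sink capacity)
                sum_k F_k + f_abs = V_Y                 (source conservation)
                F_k, f_a, f_abs >= 0

A compound peak with positive fraction but no target within the radius
forces F_k = 0: the method has no tolerance for missing peaks.  The LP is
solved with HiGHS via :func:`scipy.optimize.linprog`; infeasibility cannot
occur because absorption has unlimited capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .network import FlowNetwork, Metric, build_network, default_metric
from .spectra import CompoundLibrary, LibraryEntry, PeakSpectrum

__all__ = [
    "FlowResult",
    "IncrementalSchedule",
    "SolverError",
    "solve_mcf",
    "solve_independent",
    "solve_incremental",
    "concentration_factors",
    "result_to_dict",
    "write_arc_flows",
]


class SolverError(RuntimeError):
    """LP backend failed to certify an optimal solution."""


@dataclass
class FlowResult:
    """Solved flow with per-compound volumes and assignment arcs.

    ``arc_flows`` maps ``(compound_id, compound_peak_index, target_index)``
    to the assigned volume (zero-flow arcs are omitted); ``arc_costs`` holds
    the matching unit costs for bookkeeping.  ``alpha`` is filled by
    :func:`concentration_factors`.
    """

    source_flows: dict[str, float]
    arc_flows: dict[tuple[str, int, int], float]
    arc_costs: dict[tuple[str, int, int], float]
    absorbed: float
    total_cost: float
    production: float
    params: dict
    status: str = "optimal"
    alpha: dict[str, float] = field(default_factory=dict)

    @property
    def assigned(self) -> float:
        return float(sum(self.source_flows.values()))

    def flow_fractions(self) -> dict[str, float]:
        """Share of total target intensity explained by each compound."""
        return {k: v / self.production for k, v in self.source_flows.items()}


@dataclass(frozen=True)
class IncrementalSchedule:
    """Strictly increasing assignment radii ending at r_max."""

    radii: tuple[float, ...]

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.radii)
        if not radii:
            raise ValueError("schedule must contain at least one radius")
        if radii[0] <= 0 or any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError("radii must be positive and strictly increasing")
        object.__setattr__(self, "radii", radii)

    @property
    def r_max(self) -> float:
        return self.radii[-1]

    @classmethod
    def default(cls, r_max: float, step: float = 0.01) -> "IncrementalSchedule":
        """Radii step, 2*step, ... up to r_max (r_max always included)."""
        if r_max <= 0 or step <= 0:
            raise ValueError("r_max and step must be positive")
        radii = list(np.arange(step, r_max + 1e-12, step))
        if not radii or abs(radii[-1] - r_max) > 1e-12:
            radii.append(r_max)
        return cls(tuple(float(r) for r in radii))


def _solve_network_lp(network: FlowNetwork) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Solve the reduced LP; returns (F_k, arc flows, absorbed, objective)."""
    K = network.n_compounds
    A = int(network.arc_cost.size)
    n_var = K + A + 1  # F_k | f_a | f_abs

    peak_offsets = np.concatenate(
        [[0], np.cumsum([p.size for p in network.peak_fractions])]
    )
    fractions_flat = (
        np.concatenate(network.peak_fractions)
        if K
        else np.empty(0)
    )
    n_peaks_total = int(peak_offsets[-1])

    # which compound peaks have at least one arc
    arc_gpeak = peak_offsets[network.arc_compound] + network.arc_peak
    has_arc = np.zeros(n_peaks_total, dtype=bool)
    has_arc[arc_gpeak] = True

    # a compound is assignable only if every positive-fraction peak has arcs
    blocked = np.zeros(K, dtype=bool)
    for k in range(K):
        sl = slice(peak_offsets[k], peak_offsets[k + 1])
        pk = network.peak_fractions[k]
        blocked[k] = np.any((pk > 0) & ~has_arc[sl])

    # equality rows: one per compound peak with arcs, plus conservation
    active_peaks = np.flatnonzero(has_arc)
    row_of_gpeak = np.full(n_peaks_total, -1, dtype=np.int64)
    row_of_gpeak[active_peaks] = np.arange(active_peaks.size)
    n_eq = active_peaks.size + 1

    # arc coefficients (+1) in their peak row
    eq_rows = [row_of_gpeak[arc_gpeak]]
    eq_cols = [K + np.arange(A)]
    eq_vals = [np.ones(A)]
    # -p_i F_k coefficient per active peak row
    gpk = active_peaks
    comp_of_gpeak = (
        np.searchsorted(peak_offsets, gpk, side="right") - 1
        if gpk.size
        else np.empty(0, dtype=np.int64)
    )
    pvals = fractions_flat[gpk]
    nz = pvals > 0
    eq_rows.append(row_of_gpeak[gpk[nz]])
    eq_cols.append(comp_of_gpeak[nz])
    eq_vals.append(-pvals[nz])
    # conservation row: sum F_k + f_abs = V_Y
    eq_rows.append(np.full(K + 1, n_eq - 1, dtype=np.int64))
    eq_cols.append(np.concatenate([np.arange(K), [K + A]]))
    eq_vals.append(np.ones(K + 1))

    A_eq = sparse.coo_matrix(
        (np.concatenate(eq_vals), (np.concatenate(eq_rows), np.concatenate(eq_cols))),
        shape=(n_eq, n_var),
    ).tocsr()
    b_eq = np.zeros(n_eq)
    b_eq[-1] = network.production

    # capacity rows: one per target with inbound arcs
    tgt_with_arcs = np.unique(network.arc_target)
    row_of_tgt = np.full(network.n_targets, -1, dtype=np.int64)
    row_of_tgt[tgt_with_arcs] = np.arange(tgt_with_arcs.size)
    A_ub = sparse.coo_matrix(
        (np.ones(A), (row_of_tgt[network.arc_target], K + np.arange(A))),
        shape=(tgt_with_arcs.size, n_var),
    ).tocsr()
    b_ub = network.target_capacities[tgt_with_arcs]

    c = np.concatenate([np.zeros(K), network.arc_cost, [network.absorption_cost]])
    bounds = [(0.0, 0.0) if blocked[k] else (0.0, None) for k in range(K)]
    bounds += [(0.0, None)] * (A + 1)

    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs"
    )
    if res.status != 0:
        raise SolverError(
            f"LP solver did not certify optimality (status {res.status}: {res.message})"
        )
    x = np.maximum(res.x, 0.0)  # clip solver-tolerance negatives
    return x[:K], x[K : K + A], float(x[K + A]), float(res.fun)


def solve_mcf(network: FlowNetwork) -> FlowResult:
    """Single-pass simultaneous minimum-cost flow over the whole library."""
    F, f_arc, absorbed, objective = _solve_network_lp(network)
    arc_flows: dict[tuple[str, int, int], float] = {}
    arc_costs: dict[tuple[str, int, int], float] = {}
    nz = np.flatnonzero(f_arc > 0)
    for a in nz:
        key = (
            network.compound_ids[int(network.arc_compound[a])],
            int(network.arc_peak[a]),
            int(network.arc_target[a]),
        )
        arc_flows[key] = float(f_arc[a])
        arc_costs[key] = float(network.arc_cost[a])
    return FlowResult(
        source_flows={cid: float(F[k]) for k, cid in enumerate(network.compound_ids)},
        arc_flows=arc_flows,
        arc_costs=arc_costs,
        absorbed=absorbed,
        total_cost=objective,
        production=network.production,
        params={
            "setup": "A",
            "r": network.radius,
            "absorption_cost": network.absorption_cost,
            "axis_scales": list(network.metric.axis_scales),
        },
    )


def solve_independent(
    library: CompoundLibrary,
    target: PeakSpectrum,
    r: float,
    c_absorption: float = 1e6,
    metric: Metric | None = None,
) -> FlowResult:
    """Fit each compound alone against the full target (independent fits).

    Every compound sees the full target capacities and full production, so
    compounds do not compete for intensity; summed source flows may exceed
    the target volume.  Source conservation holds per run, not globally:
    ``absorbed`` is the per-run sum, kept for bookkeeping only.
    """
    if metric is None:
        metric = default_metric(library.dim)
    source_flows: dict[str, float] = {}
    arc_flows: dict[tuple[str, int, int], float] = {}
    arc_costs: dict[tuple[str, int, int], float] = {}
    absorbed_per: dict[str, float] = {}
    total_cost = 0.0
    for entry in library:
        sub = CompoundLibrary(entries=(entry,))
        net = build_network(sub, target, r, c_absorption, metric)
        res = solve_mcf(net)
        source_flows[entry.compound_id] = res.source_flows[entry.compound_id]
        arc_flows.update(res.arc_flows)
        arc_costs.update(res.arc_costs)
        absorbed_per[entry.compound_id] = res.absorbed
        total_cost += res.total_cost
    return FlowResult(
        source_flows=source_flows,
        arc_flows=arc_flows,
        arc_costs=arc_costs,
        absorbed=float(sum(absorbed_per.values())),
        total_cost=total_cost,
        production=target.total_weight,
        params={
            "setup": "B",
            "r": float(r),
            "absorption_cost": float(c_absorption),
            "axis_scales": list(metric.axis_scales),
            "absorbed_per_compound": absorbed_per,
        },
    )


def solve_incremental(
    library: CompoundLibrary,
    target: PeakSpectrum,
    schedule: IncrementalSchedule,
    c_absorption: float = 1e6,
    metric: Metric | None = None,
) -> FlowResult:
    """Incremental assignment: solve at increasing radii, reserving flow.

    At each radius the network is rebuilt over the residual target
    capacities (production = residual capacity, so absorption cost never
    distorts a step's optimum); the step's arc flows are then reserved and
    can never be displaced by later, larger radii.  Within each step peak
    proportionality holds exactly; cumulatively only the relaxed
    conservation (arc flows consistent with cumulative hub flow) holds.
    """
    if metric is None:
        metric = default_metric(library.dim)
    V_Y = target.total_weight
    residual = target.weights.astype(float).copy()
    source_flows = {cid: 0.0 for cid in library.compound_ids}
    arc_flows: dict[tuple[str, int, int], float] = {}
    arc_costs: dict[tuple[str, int, int], float] = {}
    assign_cost = 0.0
    cap_eps = 1e-12 * max(V_Y, 1.0)
    for r_t in schedule.radii:
        keep = np.flatnonzero(residual > cap_eps)
        if keep.size == 0:
            break
        step_target = PeakSpectrum(
            id=target.id,
            dim=target.dim,
            positions=target.positions[keep],
            weights=residual[keep],
        )
        net = build_network(library, step_target, r_t, c_absorption, metric)
        step = solve_mcf(net)
        for cid, f in step.source_flows.items():
            source_flows[cid] += f
        for (cid, i, j_local), f in step.arc_flows.items():
            j = int(keep[j_local])
            key = (cid, i, j)
            arc_flows[key] = arc_flows.get(key, 0.0) + f
            arc_costs[key] = step.arc_costs[(cid, i, j_local)]
            residual[j] -= f
            assign_cost += f * step.arc_costs[(cid, i, j_local)]
    residual = np.maximum(residual, 0.0)
    absorbed = float(max(V_Y - sum(source_flows.values()), 0.0))
    return FlowResult(
        source_flows=source_flows,
        arc_flows=arc_flows,
        arc_costs=arc_costs,
        absorbed=absorbed,
        total_cost=assign_cost + absorbed * c_absorption,
        production=V_Y,
        params={
            "setup": "C",
            "r": schedule.r_max,
            "schedule": list(schedule.radii),
            "absorption_cost": float(c_absorption),
            "axis_scales": list(metric.axis_scales),
        },
    )


def concentration_factors(
    result: FlowResult, library: CompoundLibrary
) -> dict[str, float]:
    """Scale factors alpha_k = f_(s->k) / V_Xk linking library spectra to the fit.

    alpha_k is the multiple of compound k's library spectrum that accounts
    for its assigned flow; stored into ``result.alpha`` and returned.
    """
    alpha = {
        e.compound_id: result.source_flows.get(e.compound_id, 0.0)
        / e.spectrum.total_weight
        for e in library
    }
    result.alpha = alpha
    return alpha


def result_to_dict(result: FlowResult, library: CompoundLibrary | None = None) -> dict:
    """JSON-ready summary: params, per-compound flows/alpha, absorption, cost."""
    compounds = {}
    for cid, f in result.source_flows.items():
        row = {
            "source_flow": f,
            "flow_fraction": f / result.production,
        }
        if result.alpha:
            row["alpha"] = result.alpha.get(cid, 0.0)
        if library is not None and result.alpha:
            row["predicted_concentration_mM"] = (
                result.alpha.get(cid, 0.0) * library[cid].ref_concentration
            )
        compounds[cid] = row
    return {
        "params": result.params,
        "status": result.status,
        "production": result.production,
        "absorbed": result.absorbed,
        "total_cost": result.total_cost,
        "compounds": compounds,
    }


def write_arc_flows(result: FlowResult, path) -> None:
    """Dump assignment arcs as CSV (compound_id, peak_index, target_index, flow, cost)."""
    import pandas as pd

    rows = [
        {
            "compound_id": cid,
            "peak_index": i,
            "target_index": j,
            "flow": f,
            "cost": result.arc_costs[(cid, i, j)],
        }
        for (cid, i, j), f in sorted(result.arc_flows.items())
    ]
    pd.DataFrame(
        rows, columns=["compound_id", "peak_index", "target_index", "flow", "cost"]
    ).to_csv(path, index=False)
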