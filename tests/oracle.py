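"""Independent dense-LP oracle and feasibility residual checks.

The oracle formulates the FULL node-based flow program -- explicit source->hub,
source->absorption, hub->peak, and peak->target variables with conservation,
capacity, and proportionality constraints written per node -- as a dense LP.
It shares no code with the package's reduced formulation and is used only to
cross-check optimal objective values on small instances.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

from nmrflow.network import FlowNetwork
from nmrflow.solver import FlowResult


def dense_mcf_objective(network: FlowNetwork) -> float:
    """Optimal cost of the full flow program, solved densely.

    Variables, in order: f_(s->k) for each compound k, f_(s->abs),
    f_(k->i) for every compound peak i, f_(i->j) for every assignment arc.
    """
    K = network.n_compounds
    n_peaks = [p.size for p in network.peak_fractions]
    peak_off = np.concatenate([[0], np.cumsum(n_peaks)])
    P = int(peak_off[-1])
    A = int(network.arc_cost.size)
    n_var = K + 1 + P + A
    i_hub = 0                # f_(s->k) block
    i_abs = K                # f_(s->abs)
    i_peak = K + 1           # f_(k->i) block
    i_arc = K + 1 + P        # f_(i->j) block

    eq_rows = []
    eq_rhs = []
    # source conservation: sum_k f_(s->k) + f_(s->abs) = V_Y
    row = np.zeros(n_var)
    row[i_hub : i_hub + K] = 1.0
    row[i_abs] = 1.0
    eq_rows.append(row)
    eq_rhs.append(network.production)
    # proportionality per compound peak: f_(k->i) = p_i f_(s->k)
    for k in range(K):
        for i, p_i in enumerate(network.peak_fractions[k]):
            row = np.zeros(n_var)
            row[i_peak + peak_off[k] + i] = 1.0
            row[i_hub + k] = -p_i
            eq_rows.append(row)
            eq_rhs.append(0.0)
    # conservation at peak nodes: sum_j f_(i->j) = f_(k->i)
    for k in range(K):
        for i in range(n_peaks[k]):
            row = np.zeros(n_var)
            row[i_peak + peak_off[k] + i] = -1.0
            mask = (network.arc_compound == k) & (network.arc_peak == i)
            row[i_arc + np.flatnonzero(mask)] = 1.0
            eq_rows.append(row)
            eq_rhs.append(0.0)
    # capacity at target nodes: sum_in f_(i->j) <= w_j
    ub_rows = []
    ub_rhs = []
    for j in range(network.n_targets):
        mask = network.arc_target == j
        if not mask.any():
            continue
        row = np.zeros(n_var)
        row[i_arc + np.flatnonzero(mask)] = 1.0
        ub_rows.append(row)
        ub_rhs.append(network.target_capacities[j])

    c = np.zeros(n_var)
    c[i_abs] = network.absorption_cost
    c[i_arc:] = network.arc_cost
    res = linprog(
        c,
        A_ub=np.array(ub_rows) if ub_rows else None,
        b_ub=np.array(ub_rhs) if ub_rhs else None,
        A_eq=np.array(eq_rows),
        b_eq=np.array(eq_rhs),
        bounds=(0, None),
        method="highs",
    )
    assert res.status == 0, f"oracle LP failed: {res.message}"
    return float(res.fun)


def feasibility_residuals(result: FlowResult, network: FlowNetwork) -> dict[str, float]:
    """Worst-case violations of conservation, capacity, and proportionality.

    Returns absolute residuals (same units as flow volume):
    ``conservation``  |sum_k f_(s->k) + absorbed - V_Y|
    ``capacity``      max_j max(0, inflow_j - w_j)
    ``proportionality`` max over compound peaks of |sum_j f_(i->j) - p_i f_(s->k)|
    """
    cons = abs(sum(result.source_flows.values()) + result.absorbed - network.production)
    inflow = np.zeros(network.n_targets)
    per_peak: dict[tuple[str, int], float] = {}
    for (cid, i, j), f in result.arc_flows.items():
        inflow[j] += f
        per_peak[(cid, i)] = per_peak.get((cid, i), 0.0) + f
    cap = float(np.max(np.maximum(inflow - network.target_capacities, 0.0), initial=0.0))
    prop = 0.0
    for k, cid in enumerate(network.compound_ids):
        f_k = result.source_flows[cid]
        for i, p_i in enumerate(network.peak_fractions[k]):
            prop = max(prop, abs(per_peak.get((cid, i), 0.0) - p_i * f_k))
    return {"conservation": cons, "capacity": cap, "proportionality": prop}
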