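"""Containment calls, concentration estimates, and evaluation metrics.

A compound is called "contained" when the fraction of total target
intensity assigned to it, f_(s->k) / V_Y, reaches the dimensionless
detection threshold.  Predicted concentrations follow from the
concentration factors: c_k = alpha_k * c_k°, where c_k° is the library
acquisition concentration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import Metric, build_network, default_metric
from .solver import (
    FlowResult,
    IncrementalSchedule,
    concentration_factors,
    solve_incremental,
    solve_independent,
    solve_mcf,
)
from .spectra import CompoundLibrary, PeakSpectrum

__all__ = [
    "DetectionReport",
    "QuantReport",
    "detect",
    "quantify",
    "quant_errors",
    "classification_metrics",
    "parameter_scan",
]


@dataclass(frozen=True)
class DetectionReport:
    threshold: float
    flow_fractions: dict[str, float]
    detected: dict[str, bool]

    @property
    def detected_ids(self) -> set[str]:
        return {k for k, d in self.detected.items() if d}


@dataclass(frozen=True)
class QuantReport:
    """Predicted concentrations, with errors when the truth is known.

    ``errors`` holds e_k = (c_k - c_k*) / c_k* for compounds with positive
    true concentration; ``mean_abs_error`` is the mean |e_k| over those
    compounds and ``in_band`` the fraction with e_k in [-0.5, 1.0].
    """

    predicted: dict[str, float]
    errors: dict[str, float] | None = None
    mean_abs_error: float | None = None
    in_band: float | None = None
    excluded: tuple[str, ...] = ()


def detect(
    result: FlowResult, target_total: float | None = None, threshold: float = 0.005
) -> DetectionReport:
    """Call containment: detected iff f_(s->k) / V_Y >= threshold."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    V_Y = result.production if target_total is None else float(target_total)
    if V_Y <= 0:
        raise ValueError("target total weight must be positive")
    fractions = {k: f / V_Y for k, f in result.source_flows.items()}
    return DetectionReport(
        threshold=float(threshold),
        flow_fractions=fractions,
        detected={k: frac >= threshold for k, frac in fractions.items()},
    )


def quantify(
    result: FlowResult,
    library: CompoundLibrary,
    truth: Mapping[str, float] | None = None,
) -> QuantReport:
    """Predicted concentrations c_k = alpha_k * c_k°, plus errors vs truth."""
    if not result.alpha:
        concentration_factors(result, library)
    predicted = {
        e.compound_id: result.alpha[e.compound_id] * e.ref_concentration
        for e in library
    }
    if truth is None:
        return QuantReport(predicted=predicted)
    errors, e_bar, in_band, excluded = quant_errors(predicted, truth)
    return QuantReport(
        predicted=predicted,
        errors=errors,
        mean_abs_error=e_bar,
        in_band=in_band,
        excluded=tuple(excluded),
    )


def quant_errors(
    predicted: Mapping[str, float], truth: Mapping[str, float]
) -> tuple[dict[str, float], float, float, list[str]]:
    """Relative prediction errors against known true concentrations.

    Returns (errors, mean |e_k|, fraction of e_k in the closed band
    [-0.5, 1.0], excluded ids).  Compounds with true concentration <= 0 are
    excluded and flagged rather than silently dropped.
    """
    errors: dict[str, float] = {}
    excluded: list[str] = []
    for cid, c_true in truth.items():
        if c_true <= 0:
            excluded.append(cid)
            continue
        c_pred = predicted.get(cid, 0.0)
        errors[cid] = (c_pred - c_true) / c_true
    if not errors:
        return errors, float("nan"), float("nan"), excluded
    e = np.array(list(errors.values()))
    return (
        errors,
        float(np.mean(np.abs(e))),
        float(np.mean((e >= -0.5) & (e <= 1.0))),
        excluded,
    )


def classification_metrics(
    detected: Iterable[str], truth: Iterable[str], library_ids: Iterable[str]
) -> tuple[float, float, float]:
    """Precision, recall, and F1 of a detection call against ground truth.

    Every library compound not in the truth set is a negative; P (and F1)
    are reported as 0 when nothing is detected.
    """
    detected = set(detected)
    truth = set(truth)
    library_ids = set(library_ids)
    if not truth <= library_ids:
        raise ValueError("truth ids must be a subset of the library")
    tp = len(detected & truth)
    fp = len(detected - truth)
    fn = len(truth - detected)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return precision, recall, f1


def _solve_setup(
    library: CompoundLibrary,
    target: PeakSpectrum,
    setup: str,
    r: float,
    c_absorption: float,
    metric: Metric | None,
    schedule_step: float = 0.01,
) -> FlowResult:
    if setup in ("A", "D"):  # same solve; D differs only in target provenance
        return solve_mcf(build_network(library, target, r, c_absorption, metric))
    if setup == "B":
        return solve_independent(library, target, r, c_absorption, metric)
    if setup == "C":
        return solve_incremental(
            library,
            target,
            IncrementalSchedule.default(r, step=schedule_step),
            c_absorption,
            metric,
        )
    raise ValueError(f"unknown setup {setup!r} (expected A, B, C, or D)")


def parameter_scan(
    library: CompoundLibrary,
    target: PeakSpectrum,
    truth_ids: Iterable[str],
    r_values: Sequence[float],
    theta_values: Sequence[float],
    setup: str = "A",
    c_absorption: float = 1e6,
    metric: Metric | None = None,
    schedule_step: float = 0.01,
) -> tuple[pd.DataFrame, pd.Series]:
    """Scan assignment radii and detection thresholds; score each cell.

    One solve per radius; thresholds are pure post-processing of the same
    flow.  Returns the scan table (columns r, theta, tp, fp, fn, precision,
    recall, f1) and the arg-max row (ties: first in scan order).
    """
    truth_ids = set(truth_ids)
    lib_ids = set(library.compound_ids)
    rows = []
    for r in r_values:
        result = _solve_setup(
            library, target, setup, r, c_absorption, metric, schedule_step
        )
        for theta in theta_values:
            rep = detect(result, threshold=theta)
            det = rep.detected_ids
            tp = len(det & truth_ids)
            fp = len(det - truth_ids)
            fn = len(truth_ids - det)
            precision, recall, f1 = classification_metrics(det, truth_ids, lib_ids)
            rows.append(
                {
                    "r": float(r),
                    "theta": float(theta),
                    "tp": tp,
                    "fp": fp,
                    "fn": fn,
                    "precision": precision,
                    "recall": recall,
                    "f1": f1,
                }
            )
    table = pd.DataFrame(rows)
    best = table.loc[table["f1"].idxmax()]
    return table, best
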