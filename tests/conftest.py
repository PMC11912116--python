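"""Shared fixtures: tiny hand-built instances and seeded random generators."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

from nmrflow import (
    CompoundLibrary,
    LibraryEntry,
    Metric,
    PeakSpectrum,
)


def make_spectrum(positions, weights, dim=2, id="spec"):
    return PeakSpectrum(id=id, dim=dim, positions=np.asarray(positions, float),
                        weights=np.asarray(weights, float))


def make_entry(cid, positions, weights, dim=2, ref_conc=30.0):
    return LibraryEntry(
        compound_id=cid,
        spectrum=make_spectrum(positions, weights, dim=dim, id=cid),
        ref_concentration=ref_conc,
    )


@pytest.fixture
def metric_1h13c():
    return Metric((1.0, 0.1))


@pytest.fixture
def two_peak_compound_instance(metric_1h13c):
    """One compound, two equal peaks, each reaching one distinct unit target.

    Distances are 0.01 and 0.02 on the 1H axis; V_Y = 2, so the whole
    production routes through the compound at cost 0.01 + 0.02 = 0.03.
    """
    lib = CompoundLibrary(entries=(
        make_entry("only", [[1.0, 20.0], [3.0, 50.0]], [1.0, 1.0]),
    ))
    target = make_spectrum([[1.01, 20.0], [3.02, 50.0]], [1.0, 1.0], id="Y")
    return lib, target, metric_1h13c


@pytest.fixture
def competition_instance(metric_1h13c):
    """Two single-peak compounds both reaching one unit target peak.

    Compound "near" sits at distance 0.01, "far" at 0.02.  Simultaneous
    optimization must give everything to "near"; independent fits give full
    flow to both.
    """
    lib = CompoundLibrary(entries=(
        make_entry("near", [[1.01, 20.0]], [1.0]),
        make_entry("far", [[1.02, 20.0]], [1.0]),
    ))
    target = make_spectrum([[1.0, 20.0]], [1.0], id="Y")
    return lib, target, metric_1h13c


def separated_library(n_compounds, peaks_each, rng, dim=2, ref_conc=30.0,
                      spacing_1h=1.0, spacing_13c=20.0):
    """Library whose peaks sit on a lattice, pairwise far apart in the metric.

    With the (1.0, 0.1) scales, lattice spacing (1.0, 20.0) ppm keeps every
    pair of peaks at scaled distance >= 1.0, far above any radius used in
    tests, so exact superpositions decompose uniquely.
    """
    slots = [(i * spacing_1h, j * spacing_13c) for i in range(40) for j in range(8)]
    rng.shuffle(slots)
    entries = []
    used = 0
    for k in range(n_compounds):
        pos = np.array(slots[used:used + peaks_each], dtype=float)
        used += peaks_each
        w = rng.uniform(0.5, 2.0, size=peaks_each)
        w *= ref_conc * peaks_each / w.sum()
        entries.append(make_entry(f"c{k}", pos, w, ref_conc=ref_conc))
    return CompoundLibrary(entries=tuple(entries))


def random_instance(rng, max_compounds=5, max_peaks=4, max_targets=20):
    """Small random library/target pair with plenty of radius-reachable pairs.

    Positions are drawn from a compact window so that a radius of ~0.1
    yields a nontrivial arc set; weights are positive uniforms.
    """
    K = int(rng.integers(1, max_compounds + 1))
    entries = []
    for k in range(K):
        n = int(rng.integers(1, max_peaks + 1))
        pos = np.column_stack([rng.uniform(0, 1.0, n), rng.uniform(0, 10.0, n)])
        w = rng.uniform(0.2, 2.0, n)
        entries.append(make_entry(f"c{k}", pos, w))
    nt = int(rng.integers(1, max_targets + 1))
    tpos = np.column_stack([rng.uniform(0, 1.0, nt), rng.uniform(0, 10.0, nt)])
    tw = rng.uniform(0.2, 2.0, nt)
    target = make_spectrum(tpos, tw, id="Y")
    r = float(rng.uniform(0.05, 0.3))
    return CompoundLibrary(entries=tuple(entries)), target, r
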