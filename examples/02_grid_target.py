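"""Fit directly to gridded intensity data, without peak picking.

Renders a noisy mixture onto a 256 x 256 grid (Gaussian peaks + baseline
noise), converts every grid point above the noise floor into a flow-network
node, and compares quantification by single-pass and incremental assignment.
"""

import nmrflow as nf

library = nf.make_library(10, peaks_per_compound=(3, 8), seed=11)
truth = {cid: 3.0 for cid in library.compound_ids}
mixture, _ = nf.make_mixture_peaks(
    library,
    nf.MixtureSpec(contained=truth, shift_noise_sd=(0.01, 0.1),
                   weight_noise_cv=0.1, seed=12),
)
axes = nf.axes_covering(mixture, (256, 256), pad=(0.2, 2.0))
grid = nf.render_grid(mixture, axes, nf.PeakShape((0.03, 0.3)),
                      baseline_noise_sd=0.001, seed=13)
target = nf.grid_to_peaks(grid, floor=0.005)  # floor clips baseline noise
print(f"grid {grid.shape} -> {target.n_peaks} nodes above the floor")

for label, solve in [
    ("single pass, r=0.10",
     lambda: nf.solve_mcf(nf.build_network(library, target, r=0.10))),
    ("single pass, r=0.25",
     lambda: nf.solve_mcf(nf.build_network(library, target, r=0.25))),
    ("incremental, r=0.25",
     lambda: nf.solve_incremental(library, target, nf.IncrementalSchedule.default(0.25))),
]:
    result = solve()
    quant = nf.quantify(result, library, truth=truth)
    print(f"{label:<22} mean |rel error| = {quant.mean_abs_error:.3f}, "
          f"errors in [-0.5, 1.0]: {quant.in_band:.0%}")
print("\nIncremental assignment reserves flow at small radii first, which")
print("protects against displacement errors when the radius is large.")
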