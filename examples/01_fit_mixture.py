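"""Reconstruct a synthetic HSQC mixture and report containment + concentrations.

Builds a 12-compound library, mixes 5 of them at known concentrations with
peak jitter and intensity noise, fits the library with the simultaneous
minimum-cost flow, and prints per-compound flow fractions, containment
calls, and predicted concentrations next to the truth.
"""

import nmrflow as nf

library = nf.make_library(12, peaks_per_compound=(3, 8), seed=1)
truth = {cid: c for cid, c in zip(library.compound_ids[:5], [2.0, 3.0, 5.0, 10.0, 20.0])}
mixture, _ = nf.make_mixture_peaks(
    library,
    nf.MixtureSpec(contained=truth, shift_noise_sd=(0.01, 0.1),
                   weight_noise_cv=0.1, seed=2),
)

network = nf.build_network(library, mixture, r=0.05)
result = nf.solve_mcf(network)
nf.concentration_factors(result, library)
report = nf.detect(result, threshold=0.005)
quant = nf.quantify(result, library, truth=truth)

print(f"target volume V_Y = {mixture.total_weight:.2f}, "
      f"absorbed {result.absorbed:.2f} ({result.absorbed / mixture.total_weight:.1%})")
print(f"{'compound':<10} {'flow frac':>9} {'detected':>8} {'c_pred mM':>10} {'c_true mM':>10}")
for cid in library.compound_ids:
    frac = report.flow_fractions[cid]
    print(f"{cid:<10} {frac:>9.4f} {str(report.detected[cid]):>8} "
          f"{quant.predicted[cid]:>10.2f} {truth.get(cid, 0.0):>10.2f}")
print(f"\nmean |relative error| over contained compounds: {quant.mean_abs_error:.3f}")
print("A flow fraction is the share of total mixture intensity routed to a")
print("compound; detection compares it to the threshold. Concentrations are")
print("the library reference (30 mM) scaled by the fitted factor alpha.")
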