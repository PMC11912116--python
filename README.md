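# nmrflow

Minimum-cost-flow identification and quantification of compounds in NMR
mixture spectra.

## The problem

A liquid-state NMR spectrum of a mixture is, to first approximation, the
sum of the spectra of its constituents. Given a library of single-compound
peak lists (typically 2D ¹H,¹³C HSQC: each peak a (¹H ppm, ¹³C ppm)
position with an intensity weight) and a target mixture spectrum, the task
is to decide which library compounds the mixture contains and at what
concentrations — despite overlapping peaks, matrix-dependent peak shifts,
and, for raw grid data, the absence of picked peaks.

`nmrflow` solves this as one linear network-flow program. A source
produces the mixture's total intensity V_Y and routes it through one hub
per library compound k; each hub splits its volume F_k over the compound's
peaks in fixed proportions p_i = v_i / V_{X_k}; each compound peak may pass
flow only to target nodes within an assignment radius r of it in
chemical-shift space, at a cost equal to their spectral distance; whatever
cannot be assigned drains to an absorption sink at a large cost c_ø ≫ r.
Minimizing total cost

  min Σ_{i→j} d(x_i, y_j)·f_{i→j} + c_ø·f_ø

subject to source conservation, sink capacities w_j, and per-peak
proportionality yields per-compound assigned flows f_{s→k}. Target nodes
can be picked peaks *or raw grid points* — the method needs no peak
picking. Distances use a scaled Euclidean metric (default ¹H scale 1.0,
¹³C scale 0.1, so r is in ¹H ppm units).

Downstream:

- **Detection** — compound k is called contained when its flow fraction
  f_{s→k} / V_Y reaches a threshold ϑ (typical 0.003–0.01).
- **Quantification** — the concentration factor α_k = f_{s→k} / V_{X_k}
  scales the library acquisition concentration: c_k = α_k · c_k°.
- **Variants** — simultaneous single-pass optimization (setup A; D is the
  same solve on a peak-list target), independent per-compound fits
  (setup B, prone to over-detection since compounds do not compete), and
  incremental assignment (setup C: re-solve at increasing radii, reserving
  flow once assigned, which suppresses displacement errors at large r).

## Worked example

```python
import nmrflow as nf

library = nf.make_library(12, peaks_per_compound=(3, 8), seed=1)
truth = {cid: c for cid, c in zip(library.compound_ids[:5], [2.0, 3.0, 5.0, 10.0, 20.0])}
mixture, _ = nf.make_mixture_peaks(
    library, nf.MixtureSpec(contained=truth, shift_noise_sd=(0.01, 0.1),
                            weight_noise_cv=0.1, seed=2))

result = nf.solve_mcf(nf.build_network(library, mixture, r=0.05))
nf.concentration_factors(result, library)
report = nf.detect(result, threshold=0.005)
quant = nf.quantify(result, library, truth=truth)
```

Running `python examples/01_fit_mixture.py` (this exact computation)
prints:

```
target volume V_Y = 223.31, absorbed 27.18 (12.2%)
compound   flow frac detected  c_pred mM  c_true mM
cmpd01        0.0412     True       1.84       2.00
cmpd02        0.0675     True       2.51       3.00
cmpd03        0.1294     True       4.13       5.00
cmpd04        0.3145     True       8.78      10.00
cmpd05        0.3257     True      18.18      20.00
cmpd06        0.0000    False       0.00       0.00
...
mean |relative error| over contained compounds: 0.126
```

All five mixed compounds are detected, none of the seven absent ones is,
and the predicted concentrations land within ~13% of the truth on average;
the 12% absorbed volume is intensity that peak jitter pushed outside the
assignment radius. The other scripts in `examples/` show grid-data fits
without peak picking, radius/threshold parameter scans, and the shell
pipeline built on the `nmrflow` CLI (`simulate`, `fit`, `scan`,
`convert`).

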