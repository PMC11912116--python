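#!/usr/bin/env bash
# End-to-end shell pipeline: simulate fixtures, fit, scan, convert.
set -euo pipefail
out=$(mktemp -d)

nmrflow simulate --n-compounds 12 --n-contained 5 --concentration 3 \
    --shift-noise 0.01,0.1 --weight-cv 0.1 --grid 128x128 \
    --seed 7 --out "$out/sim"

nmrflow fit --library "$out/sim/library/library.csv" \
    --target "$out/sim/mixture_peaks.csv" \
    --setup C --radius 0.08 --threshold 0.005 --out "$out/fit"

nmrflow scan --library "$out/sim/library/library.csv" \
    --target "$out/sim/mixture_peaks.csv" --truth "$out/sim/truth.json" \
    --radii 0.02:0.1:0.02 --thresholds 0.003,0.005,0.01 --out "$out/scan"

nmrflow convert --grid "$out/sim/mixture_grid.csv" --bin 64x64 \
    --grid-floor 0 --out "$out/binned_peaks.csv"

echo "results in $out"
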