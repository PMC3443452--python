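#!/usr/bin/env bash
# End-to-end run from the shell: simulate a dataset, select markers on it,
# then score the markers on an independently simulated hold-out dataset.
set -euo pipefail

workdir=$(mktemp -d)

pathpin simulate --outdir "$workdir/train" --seed 7
pathpin simulate --outdir "$workdir/holdout" --seed 8

pathpin run \
  --expression "$workdir/train/expression.tsv" \
  --labels "$workdir/train/labels.tsv" \
  --gmt "$workdir/train/sets.gmt" \
  --ppi "$workdir/train/ppi.tsv" \
  --outdir "$workdir/run" --seed 7

echo "selected markers:"
cat "$workdir/run/markers.tsv"

# no re-selection: the training markers are scored on the hold-out data,
# whose own standardization and PCA define the activities
pathpin evaluate-holdout \
  --markers "$workdir/run/markers.tsv" \
  --expression "$workdir/holdout/expression.tsv" \
  --labels "$workdir/holdout/labels.tsv" \
  --gmt "$workdir/holdout/sets.gmt" --seed 7

rm -rf "$workdir"
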