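#!/bin/sh
# Shell workflow: simulate -> call -> evaluate, all through the svmix CLI.
# Intermediate files are plain text (SAM / BED-like TSV / JSON).
set -e
mkdir -p /tmp/svmix_demo
cd /tmp/svmix_demo

svmix simulate --out-pairs sim.sam --out-truth truth.bed --seed 42 \
    --genome-length 1000000 --n-deletions 12 --n-hom-del 6 --n-het-del 6 \
    --n-inversions 0 --n-decoy-deletions 5 --n-decoy-inversions 0

svmix call-deletions sim.sam --out calls.tsv

svmix evaluate --calls calls.tsv --truth truth.bed --sv-type DEL \
    --threshold 0.5 --report report.json

head -4 calls.tsv
cat report.json
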