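# corticonet

A compiler from quantitative mouse-brain anatomy to fully specified sparse
convolutional networks, plus the functional-comparison statistics used to
relate such networks to recorded neural populations.

The pipeline:

1. **anatomy** — laminar excitatory densities and 10-µm voxel counts become a
   per-region neuron census; cross-species connection statistics become
   interlaminar Gaussian widths (scaled by the mouse/cat L4→L4 anchor
   114/180 µm) and peak probabilities recovered from connection rates at
   75 µm offset.
2. **flatmap** — a voxel-level connectome is sphere-fit and flat-mapped;
   region surface areas come from convex hulls, interareal Gaussian widths
   from weighted standard deviations about the center of mass (with a
   unimodality filter), and peak probabilities from an extrinsic in-degree
   relation (e = 1000).
3. **archgen** — censuses and profiles compile into a 22-region feedforward
   DAG (dLGN plus 7 visual areas × 3 layers, 49 conv edges): channel counts
   `⌊n / (lx·ly)⌋`, kernels `2⌊σᵢ·d_w⌋+1`, strides 2 out of VISp and 1
   elsewhere, and a radially-Gaussian mask probability grid per cortical
   edge. Parameter accounting covers dense, masked-expected, masked-sampled
   and classifier counts.
4. **netruntime** — a NumPy execution engine: masked convolutions, one batch
   norm + ReLU per region over summed inputs, an average-pool/concat/linear
   classifier head, and a momentum-SGD harness that re-applies masks after
   every step (masked weights stay exactly zero).
5. **metrics** — Pearson similarity matrices, SSM (Spearman rank correlation
   of upper triangles), split-half reliability, thresholded noise ceilings,
   lifetime sparseness, circular selectivity, Jensen-Shannon distances, and
   metric-MDS layouts with a singular-value-product diversity index.
6. **synthdata** — ground-truth generators: spherical-shell voxel
   connectomes with known Gaussian profile widths, response tensors with
   closed-form split-half reliability, gratings and 1/f natural-like images.

The network runtime is implemented directly in NumPy (no deep-learning
framework dependency); it is meant for desk-scale verification, activation
extraction and toy training, not large-scale training runs.

## CLI

```sh
corticonet build --out arch.json                  # shipped anatomy tables
corticonet build --config my_anatomy.yaml --out arch.json
corticonet summarize arch.json                    # channel/kernel table
corticonet count-params arch.json --mode dense
corticonet count-params arch.json --mode masked-sampled --seed 3
corticonet train --arch arch.json --steps 50 --out weights.npz
corticonet activations --arch arch.json --weights weights.npz \
    --images imgs.npy --region VISp4 --out acts.npy
corticonet synth connectome --out conn.h5
corticonet synth responses --spec resp.yaml --out resp.h5
corticonet metrics reliability --in resp.h5 --out rel.csv
```

Every command writes a `<out>.manifest.json` with the config hash, seeds and
input/output digests; identical configs and seeds reproduce outputs
bit-identically.

Anatomy tables live in a human-editable YAML
(`src/corticonet/data/anatomy.yaml`); swap in a new census by pointing
`build --config` at an edited copy. As-published kernel sizes are frozen in
`src/corticonet/data/published_kernels.yaml`; the two cells where the
printed table disagrees with the width-to-pixels formula (VISli4→VISli2/3,
VISpl4→VISpl2/3) are flagged by the generator, never silently reconciled.

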