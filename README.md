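# plastoquant

Quantitative 3D morphometry of filamentous protein networks in confocal
z-stacks, built for the FtsZ "plastoskeleton" of plant chloroplasts: the
cage-like filament networks that FtsZ isoforms form inside the organelle and
that are thought to scaffold its shape.  Given a deconvolved single-channel
stack of one chloroplast's network, the package computes 25 structural
descriptors and compares two groups of networks (e.g. two protein isoforms)
statistically — the kind of analysis that distinguishes, say, an isoform
with many filaments leaving the organelle from one that builds very thick
"meganodes".

## What it computes

**Gross morphology** (from the *wrapped hull*, the union over z-slices of
each slice's 2D convex hull of the segmented network): enclosed volume
V_EN, network volume V_PN, volume density rho_PN = V_PN / V_EN, and, from
the eigenvalues lambda_1 >= lambda_2 >= lambda_3 of the hull-surface
covariance (shape matrix): greatest/smallest diameters d_max, d_min,
stretch St = 1 - sqrt(lambda_3 / lambda_1) and oblateness
Ob = 2 (sqrt(lambda_2) - sqrt(lambda_3)) / (sqrt(lambda_1) - sqrt(lambda_3)) - 1.

**Element descriptors** (from the spatial graph of points, nodes, segments
and connections extracted via distance-map-guided skeletonization): node
count N_n, node thickness th_n, node density rho_n, node-to-node /
-surface / -centre distances d_nn, d_ns, d_nc, their ratio, compactness
C_PN = (d_nc - d_ns) / d_nc, segment count N_s, segment length L_s, Menger
curvature kappa_s (reciprocal circumradius, averaged along each filament),
segment thickness th_s, segment inhomogeneity I_s, point spacing d_pp,
connections per node n_c, open-node percentage n_oe, and mean inter-segment
angles at 3- and 4-way junctions theta_c3, theta_c4.

**Statistics**: equal-variance unpaired Student's t-tests on all 25
descriptors at a chosen alpha, plus mean +/- SD distribution curves of the
element descriptors on fixed histogram bins (40 nm thickness bins, so the
480-520 nm meganode range is one bin).

A synthetic phantom generator (`plastoquant.synthetic_networks`) builds
ground-truth filament networks on a chloroplast-like ellipsoid shell,
renders them through an anisotropic confocal PSF with detector noise, and
reports every descriptor analytically — the basis of the package's
validation suite.  See `docs/methods.md` for the full model description and
known resolution limits.

## Worked example

Generate a phantom network (37 true nodes, 57 segments) and quantify it:

```
$ plastoquant generate --seed 11 --out phantom.tif --truth truth.json
phantom: 37 nodes, 57 segments, n_oe=5.4% -> phantom.tif

$ plastoquant quantify phantom.tif --group demo --out summary.json
N_n=42 N_s=60 V_EN=28.49 um^3 -> summary.json
```

The summary JSON holds all 25 descriptors plus the raw per-element arrays.
For this phantom the pipeline reports N_n = 42 nodes against 37 ground-truth
nodes (junction-zone artefacts under the simulated 300 nm axial PSF at
SNR 10), mean segment length L_s = 0.87 um, mean connections per node
n_c = 3.11, volume density rho_PN = 0.20 and mean 3-way junction angle
theta_c3 = 114 deg.  Measured thickness (th_s = 222 nm here for ~120 nm
filaments) is PSF-fattened and comparable only between identically processed
groups — see `docs/methods.md`.

Two groups of such summaries are compared with

```
$ plastoquant compare groupA/ groupB/ --alpha 0.05 --out report/
```

which writes `comparison.csv` (group means +/- SD, t, p and a significance
flag per descriptor) and distribution curves, and prints which descriptors
differ significantly (no multiple-testing correction is applied; the report
says so).

Library use mirrors the CLI: `read_stack` -> `segment_stack` ->
`quantify_mask` -> `compare_groups`.

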