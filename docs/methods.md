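# Methods

## Model

The detector assumes an unlabeled table whose rows come from two latent
distributions: a dominant normal-object distribution and a rare anomaly
distribution. A minimax GAN is trained on all rows; since the minority
contributes little to the empirical adversarial loss, the generator's
stationary target is dominated by the normal mass. Samples from the trained
generator ("fake normals", the synthetic set FD) therefore approximate the
normal distribution and serve as a reference population for density
comparison.

Scoring is purely geometric once FD is drawn. For each object the synthetic
neighborhood is every FD member within the k-distance (the defining
inequality is non-strict, so ties at the radius are all included and the
neighborhood can exceed k members). The local synthetic density (LSD) is the
reciprocal of the summed neighborhood distances; the anomaly factor (AF) is
the mean neighbor-to-own LSD ratio. If the density field were constant, AF
would be exactly 1; objects in regions sparser than the fake normals get
AF > 1 and are ranked more anomalous. Binary flags, when requested, mark the
top `ceil(contamination * n)` factors, ties broken toward the lower row index.

Synthetic-side densities, needed for the AF numerator, are computed
leave-one-out within FD with the same k: each FD row's self-distance of zero
would otherwise enter every sum. This symmetric reading is a design choice;
the alternative (scoring FD rows against the full FD including themselves)
systematically deflates the numerator for every object.

## Networks and training

Both networks are fully connected numpy MLPs: 3 hidden ReLU layers of width
`max(16, min(128, 4d))` and a sigmoid output, the smallest conventional
architecture at the stated depth for tabular data in [0, 1]^d. The latent
dimension defaults to the data dimension d. Hidden layers use He
initialization; the output layers of both networks use small
normal(0, 0.02) weights (the DCGAN convention), so the untrained generator
starts near the center of the normalized cube and the untrained
discriminator starts uninformative (output ≈ 0.5). Without the small output
init the generator starts spread toward the cube corners and, under the
saturating generator loss, travels slowly and unreliably toward the data.

Per iteration the discriminator takes one ascent step on
`Σ log D(x) + Σ log(1 − D(G(z)))` over a real minibatch of size m plus m
generated samples, then the generator takes one descent step on
`Σ log(1 − D(G(z)))` over m fresh latent draws — the literal saturating
form. Updates use Adam (β1 = 0.5, β2 = 0.999) at learning rate 1e-4 for
both networks; plain SGD is available via `GANConfig(optimizer="sgd")`.
Probabilities are clamped to [1e-7, 1 − 1e-7] before logarithms when the
objectives are evaluated for the loss history.

Defaults: learning rate 1e-4, 3 hidden layers, batch size min(n, 64),
1500 training iterations, synthetic-set size s = n. The iteration count was
chosen by pilot runs as the smallest round number at which generator samples
reliably recover the location and spread of compact normal clusters at
desk scale (a few hundred rows, 2–10 dimensions) under this learning rate;
substantially longer schedules eventually let the generator devote mass to
the minority mode as well, which is faithful to the asymptotic GAN objective
but weakens the fake-normal premise. Matching s to n keeps the density
scales of original and synthetic populations comparable.

## Preprocessing

Exact duplicate rows (identical in all features and, if present, the label)
are collapsed to their first occurrence before anything else; Min-Max
normalization to [0, 1] follows, computed per feature over the full
(unlabeled) dataset — at fit time labels are unknown, so statistics cannot
exclude anomalies. Constant features map to 0: they carry no distance
information and the alternative (0/0) is undefined. Missing values are a
hard error, not imputed. The fit-time min/max are stored and re-applied to
any rows scored later; scored rows outside the training range legitimately
map outside [0, 1].

## Numerical choices

- ε = 1e-12 is added to every LSD distance sum, so an object coincident
  with its whole neighborhood gets a large finite density instead of a
  division by zero.
- Neighbor search is exact (full pairwise distances via `scipy.spatial`),
  appropriate for the few-thousand-row scale this package targets;
  approximate indexes are out of scope.
- AUC uses the Mann–Whitney tie convention (ties count half).
- A single seed fans out through `numpy.random.SeedSequence` to independent
  sub-seeds for network init/minibatches and for the synthetic draw, making
  every stage independently reproducible; all derived seeds are < 2^31.

## Synthetic benchmarks

`make_blobs_with_outliers` emulates the structure of the public tabular
outlier benchmarks this method is aimed at: heavy imbalance (defaults mirror
a bearing-fault regime of ~7% anomalies), unit-variance Gaussian normal
clusters, and two anomaly regimes — "far" anomalies rejection-sampled at
≥ separation·σ from every cluster center, and "embedded" anomalies placed in
a cluster's 1–2σ shell, just outside the core where density rules are
hardest. `make_imbalanced_two_mode` builds the 95/5 two-mode table used to
check that the generator prefers the majority distribution. Both outputs are
Min-Max normalized with exact label counts and are fully seed-deterministic.

What these fixtures do not emulate: correlated or heteroscedastic feature
covariance, multimodal anomaly structure, discrete/ordinal features, and
dimensions beyond a few tens. Passing tests on them demonstrates the
pipeline's correctness and the claimed qualitative behaviors, not
benchmark-grade performance on real data.

Test and acceptance problem sizes (n ≈ 200–315, d = 2, 10 seeds) were
chosen so the full suite runs in well under a minute per property while
keeping the per-seed sampling error of AUC-type quantities near the percent
level.

## Known limitations

- GAN training quality varies across seeds; on the far-anomaly benchmark the
  per-seed AUC typically falls between 0.92 and 1.0. Averages over ten seeds
  are reported for this reason.
- The AF ranking along an outward ray from the synthetic mass is monotone in
  the large but can show small local dips where the neighbor set changes
  membership: the neighbor-mean numerator is piecewise constant in the ray
  parameter while the own-density denominator is continuous, and a swap to a
  lower-density neighbor can momentarily outweigh the denominator's growth.
  Along axis-aligned rays from the centroid the effect does not appear at
  the scales tested; oblique rays show dips of a few percent in roughly one
  in seven directions at k = 10.
- The mean in the AF numerator is not robust: a single synthetic near-
  duplicate pair inside a neighborhood can inflate its members' leave-one-out
  densities and hence their neighbors' factors.
- Scoring is transductive by design (score the rows you fitted on); unseen
  rows are supported but extrapolate the fit-time normalization.
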