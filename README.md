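# facecode

Information-theoretic comparison of two linear codes for face images:
**eigenface coding** (`RE`) — principal components of raw images — and
**decoupled coding** (`RD`) — separate principal components of shape-free
*uniformed* textures and of landmark *shape* coordinates, as in active
appearance models and as reported for face-selective neurons in primate
inferotemporal cortex.  The package asks the efficient-coding question: does
splitting a face into shape and shape-free texture *save bits*?

It is written for computational neuroscientists and vision researchers who
want a reproducible, testable implementation of the full analysis pipeline:

- **Description length.**  For a dataset `D` of `N` vectors in `R^d` and a
  `p`-component probabilistic PCA model `M`, the description length at
  per-coordinate precision `ε` is `L_M(D) = -log2 P_M(D) - N d log2 ε`,
  where `P_M(D)` is the Bayesian evidence.  It decomposes as `L = S + O`
  into the empirical entropy `S(D|θ*)` and the Occam length `O(θ*)` that
  pays for the parameters.  The evidence is computed analytically (exact
  mean and variance integrals, quadrature/Laplace over the principal-axis
  frame), stable for `N ≪ d`.
- **The information gap.**  `G1 = L(raw images) - L(uniformed images)` is
  the texture information gap; `G2 = L(landmarks)` is the shape cost;
  `G = G1 - G2 > 0` means the decoupled code is the more efficient one.
- **Image uniformation.**  Piecewise-affine backward warping over a shared
  Delaunay triangulation of the mean landmark configuration plus border
  anchors; de-uniformation is the inverse warp.
- **Face-processing tasks.**  Generative sampling from a trained code,
  nearest-neighbour identity recognition and novel-face reconstruction under
  a rank-`p` Mahalanobis (covariance-whitened) metric, plus a gender
  classifier.
- **A synthetic face generator** with a known decoupled ground truth
  (smooth texture components, landmark shape modes, a mouth-confined smiling
  direction, per-subject idiosyncratic texture, pose and annotation jitter),
  so every stage is testable end to end without any external face database.

## Worked example

```python
import numpy as np
from facecode import (default_truth, generate_dataset, downscale_dataset,
                      compute_gap)

truth = default_truth()                      # 100x120 px, 46 landmarks
faces = generate_dataset(truth, n_subjects=50, expressions_per_subject=2, seed=1)

for width in (25, 50, 100):
    rep = compute_gap(downscale_dataset(faces, width), native_height=120)
    print(f"w={width:3d}  G1={rep.G1:9.0f}  G2={rep.G2:7.0f}  "
          f"G={rep.G:9.0f}  G/(N*d_t)={rep.G_per_sample_per_coordinate:+.3f}")
```

prints

```
w= 25  G1=    52936  G2=  44529  G=     8407  G/(N*d_t)=+0.112
w= 50  G1=   230316  G2=  44529  G=   185787  G/(N*d_t)=+0.619
w=100  G1=   809213  G2=  44529  G=   764684  G/(N*d_t)=+0.637
```

Reading the numbers: uniformation saves `G1` bits of texture description,
at a shape cost `G2` that is *independent of resolution* (the landmark
precision scales with the image height, so the two effects cancel exactly).
The gap per sample and pixel grows with resolution, and the decoupled code
wins (`G > 0`) whenever the saving exceeds the shape cost — here at every
resolution, most clearly at the native one.  On a low-correlation variant of
the generator (`low_correlation_truth()`), uniformation has little structure
to exploit and `G` turns negative at low resolution.

The same benchmark supports the task evaluations:

```python
from facecode import recognition_error, chance_level
ds = generate_dataset(default_truth(width=50, height=60), 50, 2, seed=1)
for kind in ("uniformed", "raw", "shape"):
    print(kind, recognition_error(ds, kind, p=20, K=5, seed=0))
print("chance", chance_level(50))
```

```
uniformed 0.0
raw 0.16
shape 0.84
chance 0.98
```

A command-line interface mirrors the library:
`facecode synth | uniformize | dl | gap | sample | recognize | reconstruct |
gender` (see `facecode --help`).

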