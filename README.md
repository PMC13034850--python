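# embdist

Distortion diagnostics for nonlinear embeddings.

Nonlinear dimensionality-reduction methods (UMAP, t-SNE, DensMAP, ...) are
everywhere in high-throughput biology, and they all distort: the same
on-screen distance means different things in different parts of the plot,
directions are stretched unequally, and occasionally a contiguous
neighborhood is torn into pieces. `embdist` quantifies these effects for
any paired dataset — original coordinates `X` (n × D) plus an embedding
`Y` (n × d) produced by whatever method you like — without re-running or
modifying the embedder.

It is written for computational biologists inspecting single-cell atlases
and for anyone who needs to decide whether a feature of an embedding is
signal or artifact.

## What it computes

**Local metric distortion.** For each point the package estimates a
symmetric positive-semidefinite d × d matrix `H_i`, the dual of the
embedding's pushforward Riemannian metric. Its eigenvectors are the
principal directions of distortion and its eigenvalues λ_j carry the
*squared* linear stretch along them: an isometric embedding has `H_i = I`,
λ_j > 1 marks dilation, λ_j < 1 compression. The estimate comes from a
geometric (density-renormalized) graph Laplacian `L` built on the original
data,

    L = (4 / ε²) (P − I),      P = row-normalized D⁻¹ K D⁻¹,
    H_i[k,l] = ½ Σ_j L[i,j] (y_j − y_i)_k (y_j − y_i)_l,

with `K` a Gaussian kernel `exp(−‖x_i − x_j‖²/ε²)` truncated on a
radius-neighbor graph. Drawn as ellipses (a Tissot indicatrix for
embeddings) or as "hair" segments encoding the condition number λ₁/λ₂.

**Fragmented neighborhoods.** Over the set of neighbor pairs
(original distance, embedding distance), pairs whose embedding distance
leaves `median ± σ·IQR` within a stratum of comparable original distance
(fixed-width bins, or running windows) are outliers; a point is a
fragmented-neighborhood center when at least a fraction κ of its neighbor
pairs are outlying.

**Isometrization.** A locally averaged metric `H*` around a query point m
yields the correcting transform `y → (H*)^(−1/2) (y − m) + m`, applied
globally or blended smoothly into the original coordinates so that the
region around m becomes locally distortion-free.

**Sensitivity.** `expand_geoms` / `metric_sensitivity` re-estimate the
spectra over a grid of graph radii and rescaling bandwidths and summarize
per-point stability.

## Worked example

Two planar Gaussian clusters with a 10:1 spread ratio (500 points each,
centers (0,0) and (30,0), sd 10 and 1) are pushed through a synthetic
"embedding" that shrinks the wide cluster A tenfold about its centroid —
the classic failure where an embedder equalizes cluster sizes:

```python
import numpy as np
from embdist import (DistortionModel, MixtureConfig, analytic_embedding,
                     simulate_gaussian_mixture)

points = simulate_gaussian_mixture(MixtureConfig(seed=1))
embedding = analytic_embedding(points, "cluster_scale", scales={"A": 0.1})
res = DistortionModel(points, embedding).fit(k=50)
print(res.summary())

sizes = res.sizes()                      # lambda_1 * lambda_2 per point
for lab in ("A", "B"):
    m = points.labels == lab
    print(f"median ellipse size, cluster {lab}: {np.median(sizes[m]):.4g}")
print("fragmented centers:", res.fragmentation(L=10, sigma=2.0,
                                               kappa=0.2).n_flagged)
```

prints

```
Embedding distortion diagnostics
================================================
samples                    1000
data dim / embedding dim   2 / 2
graph                      radius (r=9.419)
edges                      151750
kernel epsilon             3.14
rescale epsilon            3.14
------------------------------------------------
median lambda_1            0.4807
median lambda_2            0.1901
median condition number    1.768
mean ||H - I||_F           1.3
================================================
median ellipse size, cluster A: 8.261e-05
median ellipse size, cluster B: 0.2138
fragmented centers: 83
```

The three-orders-of-magnitude gap in median ellipse size says that
embedding distances inside cluster A correspond to much larger original
distances than the same distances inside cluster B — exactly the variance
difference the fake embedding erased. The flagged centers are points whose
neighborhoods the shrinkage tore across the two density regimes.

A command-line interface mirrors the stages (`embdist simulate`, `graph`,
`rmetric`, `fragments`, `isometrize`, `sensitivity`, `render`, and `run`
for the full pipeline with a JSON manifest); see `embdist --help`.

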