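# fcekl — KL-divergence fuzzy cluster ensembles for image segmentation

`fcekl` segments noisy grayscale images — synthetic phantoms, MR/PET-style
data — by fusing several *soft* clusterings of the same image into one
consensus partition. It is aimed at people benchmarking fuzzy segmentation
methods under controlled noise: it ships the base clusterers, the consensus
algorithms, synthetic phantom/noise generators with ground truth, accuracy
metrics, and a seeded experiment runner.

## The method

A soft clusterer assigns every pixel *k* a membership vector
u<sub>·k</sub> ∈ Δ<sup>c</sup> (entries in [0,1], summing to 1). Running
*r* different fuzzy clusterers gives partitions U<sub>1</sub>…U<sub>r</sub>;
concatenating them column-wise and dividing by *r* turns each pixel into a
probability profile y<sub>k·</sub> of length s = Σ<sub>f</sub> c<sub>f</sub>.
The consensus (FCE_KL) clusters these profiles by minimizing

    J = Σₖ Σᵢ u_ik^m · D_KL(y_k· ‖ o_i·),     Σᵢ u_ik = 1,  Σⱼ o_ij = 1,

where D_KL(p‖q) = Σⱼ pⱼ log(pⱼ/qⱼ) and the centers o<sub>i·</sub> live on the
probability simplex. The alternating updates are closed-form:

    o_ij = Σₖ u_ik^m y_kj / Σₕ Σₖ u_ik^m y_kh
    u_ik = 1 / Σₗ ( D_KL(y_k·‖o_i·) / D_KL(y_k·‖o_ℓ·) )^{1/(m−1)}

The spatial variant (FCE_sKL) additionally averages each pixel's membership
with the mean over a square neighborhood after every membership update,

    û_ik = ( (1/|NB|) Σ_{ω∈NB(k)} u_iω + u_ik ) / 2,

which suppresses isolated noise-driven misclassifications. The base
clusterers provided are fuzzy c-means (FCM) on intensity and its spatial
variant (SFCM) using the same neighborhood operator; the default ensemble is
two independently seeded FCM runs plus SFCM at 3×3 and 5×5 windows (r = 4).

## Worked example

```python
import numpy as np
from fcekl import (make_two_value_phantom, NoiseSpec, add_noise,
                   generate_basic_partitions, KLConsensus, evaluate)

ph = make_two_value_phantom()                       # 50x50, intensities {0, 1}
noisy = add_noise(ph, NoiseSpec("gaussian", 20.0, seed=42))  # sigma = 0.2*range
parts = generate_basic_partitions(noisy, 2, seed=42)         # r = 4 soft partitions
model = KLConsensus.from_partitions(parts, 2, spatial=True,
                                    grid_shape=noisy.shape, window=5)
res = model.fit(seed=42)
print(res.summary())
print(evaluate(res.labels(noisy.shape), ph.labels).summary())
```

prints

```
fce_skl consensus: n=2500, c=2, s=8
  iterations: 6 (converged=True)
  objective J: 89.8965
  hard cluster sizes: 1249, 1251
segmentation accuracy: 0.9996
  class 0 Jaccard: 0.9992
  class 1 Jaccard: 0.9992
  label mapping: {0: 1, 1: 0}
```

At a noise standard deviation of 0.2 (20% of the 0–1 intensity range) the
spatial consensus mislabels 1 of 2500 pixels: the per-class Jaccard values
are the overlap-over-union of each region with the ground truth, and the
mapping records how arbitrary cluster indices were matched to reference
labels before scoring.

The same pipeline is available from a shell:

```bash
fcekl simulate --phantom two_value --noise gaussian --level 20 --seed 42 \
      --out-image noisy.npy --out-truth truth.txt
fcekl ensemble --image noisy.npy --clusters 2 --method fce_skl --out-labels pred.txt
fcekl evaluate --pred pred.txt --truth truth.txt --per-class
fcekl experiment --phantom two_value --levels 5,20,50 --replicates 5 --seed 0 \
      --out table.csv
```

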