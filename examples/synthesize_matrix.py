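"""Generate a synthetic expression matrix with a planted bicluster.

Builds a 100×20 matrix of standard-normal background, plants a 20×6
additive bicluster (shared condition profile + per-gene offset + noise),
then shows that the planted submatrix is far more coherent (lower mean
squared residue) than a random submatrix of the same shape.
"""

import numpy as np

from frogbic import Bicluster, PlantedBicluster, generate_synthetic, msr, row_variance

plant = PlantedBicluster(
    gene_indices=tuple(range(20)),
    condition_indices=tuple(range(6)),
    pattern="additive",
    noise_sd=0.3,
)
matrix, plants = generate_synthetic(100, 20, ("normal", 0.0, 1.0), [plant], seed=42)

planted = Bicluster(plant.gene_indices, plant.condition_indices)
rng = np.random.default_rng(0)
random_block = Bicluster(tuple(rng.choice(100, 20, replace=False)),
                         tuple(rng.choice(20, 6, replace=False)))

print(f"matrix: {matrix.n} genes x {matrix.m} conditions")
print(f"planted bicluster   MSR = {msr(matrix, planted):.3f}   "
      f"row variance = {row_variance(matrix, planted):.3f}")
print(f"random submatrix    MSR = {msr(matrix, random_block):.3f}   "
      f"row variance = {row_variance(matrix, random_block):.3f}")
print()
print("The planted block's MSR is close to its noise variance (0.3^2 = 0.09):")
print("its cells follow one additive pattern, while the random block's MSR")
print("sits near the background variance (1.0) - there is nothing to explain.")
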