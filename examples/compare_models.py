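"""Comparing and clustering shape reconstructions.

Ab initio shape determination from a 1-D curve is ambiguous, so several
independent models are compared: the normalised spatial discrepancy (NSD)
after superposition measures how similar two bead models are (0 identical,
≲1 similar), and Kelley-criterion clustering groups a set of models and
picks representatives.
"""

import numpy as np

from saskit import shapes, synthio
from saskit.sasio import BeadModel
from scipy.spatial.transform import Rotation

a = synthio.random_bead_model(40, envelope_radius=15.0, seed=6)
rng = np.random.default_rng(7)
moved = a.transformed(Rotation.random(rng=rng).as_matrix(), np.array([8.0, -5.0, 3.0]))
res = shapes.superpose(a, moved)
print(f"NSD between a model and a rigidly moved copy after superposition: "
      f"{res.nsd_min:.2e} (≈0: same shape)")

srcs = [synthio.random_bead_model(30, seed=k, envelope_radius=r)
        for k, r in ((20, 15), (21, 30), (22, 60))]
jrng = np.random.default_rng(23)
models = [BeadModel(coords=src.coords + jrng.normal(0, 0.15, src.coords.shape))
          for src, reps in zip(srcs, (3, 2, 2)) for _ in range(reps)]
cl = shapes.cluster_models(models, align_first=False)
print(f"7 models drawn from 3 shapes cluster into k = {cl.k_chosen} groups "
      f"of sizes {sorted(np.bincount(cl.labels))}")
print(f"representatives (indices): {cl.representatives}")
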