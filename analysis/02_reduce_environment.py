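"""Reduce the 30 collinear covariates to orthogonal components.

Correlation-matrix PCA on the current scenario; components reaching 95%
cumulative variance are kept and the transform is frozen for every future
scenario.  With 8 latent fields behind the covariates, 8 components should
carry the signal.
"""

import numpy as np
import pandas as pd

from common import ensure_out, load_world
from parasdm import pca

out = ensure_out()
world = load_world()
env = world.stacks["current"][0]

transform = pca.fit_pca(env, variance_target=0.95)
transform.to_json(out / "pca.json")

cum = np.cumsum(transform.explained_fraction)
scree = pd.DataFrame({
    "component": [f"PC{i+1}" for i in range(len(cum))],
    "explained_fraction": transform.explained_fraction,
    "cumulative": cum,
})
scree.to_csv(out / "pca_scree.csv", index=False)

print(f"kept {transform.n_kept} of {len(transform.layer_names)} components "
      f"({100 * cum[transform.n_kept - 1]:.2f}% cumulative variance)")
print(scree.head(10).to_string(index=False))
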