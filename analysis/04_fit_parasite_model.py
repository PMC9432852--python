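"""Fit the parasite model on predicted host suitability layers.

The second stage of the cascade: host suitabilities (cloglog scale) are the
covariates.  Also stores the parasite's training rows (presences +
background in host-suitability space), which later serve as the ExDet
reference, and the permutation importance of each host.
"""

import json

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from common import CASCADE, ensure_out, load_pca, load_world
from parasdm import cascade as cc
from parasdm import maxent as mx
from parasdm import pca
from parasdm.geodata import Stack, thin_to_cells

out = ensure_out()
world = load_world()
transform = load_pca()
pc_stack = pca.project(world.stacks["current"][0], transform)

host_suit = Stack(pc_stack.spec)
for host in world.config.hosts:
    model = mx.MaxentModel.from_json(out / "models" / f"{host}.json")
    host_suit.add(host, mx.predict(model, pc_stack))

occ = world.occurrences["parasite"]
fit = cc.fit_parasite(occ, host_suit, CASCADE, seed=world.config.seed + 1)
fit.model.to_json(out / "models" / "parasite.json")
pd.DataFrame(fit.metrics.to_rows("parasite", f"{fit.settings[0]}_rm{fit.settings[1]:g}")
             ).to_csv(out / "metrics_parasite.csv", index=False)

# the ExDet reference (training presences + background in host-suitability
# space) is regenerated deterministically by later scripts from fit.seed;
# persist only its summary statistics
thinned = thin_to_cells(occ, host_suit.spec)
rng = np.random.default_rng(fit.seed)
X_bg, _ = mx.sample_background(host_suit, CASCADE.background_n, rng)
X_pres = mx.covariates_at(thinned, host_suit)
reference = np.vstack([X_pres, X_bg])
ref_summary = pd.DataFrame({
    "covariate": host_suit.names,
    "min": reference.min(axis=0), "max": reference.max(axis=0),
    "mean": reference.mean(axis=0), "sd": reference.std(axis=0, ddof=1),
})
ref_summary.to_csv(out / "parasite_reference_summary.csv", index=False,
                   float_format="%.6f")
(out / "parasite_fit_seed.json").write_text(json.dumps(
    {"seed": fit.seed, "n_presence_rows": len(X_pres), "n_background_rows": len(X_bg)}))

imp = mx.permutation_importance(fit.model, host_suit, occ, n_perm=5,
                                seed=world.config.seed)
(out / "parasite_importance.json").write_text(json.dumps(imp, indent=2))
rho = spearmanr(fit.suitability.values.ravel(),
                world.parasite_truth["current"].values.ravel()).statistic

print(f"parasite model: classes={fit.settings[0]} rm={fit.settings[1]:g}  "
      f"CBI={fit.metrics.cbi_mean:.3f} AUC={fit.metrics.auc_mean:.3f} "
      f"OR={fit.metrics.or_mean:.3f}")
print(f"Spearman vs true parasite suitability: {rho:.3f}")
print("host permutation importance (%):",
      {h: round(v, 1) for h, v in sorted(imp.items(), key=lambda kv: -kv[1])})
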