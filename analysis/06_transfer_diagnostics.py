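"""Extrapolation risk and niche similarity of the transferred models.

ExDet (NT1/NT2 with MIC attribution) and the percentage of data nearby are
computed in host-suitability space against the parasite's training rows; the
niche similarity (Schoener's D, Warren's I) compares each host's suitability
surface with the parasite's, per scenario.
"""

import json

import numpy as np
import pandas as pd

from common import CASCADE, ensure_out, load_pca, load_world
from parasdm import cascade as cc
from parasdm import diagnostics as dg
from parasdm import maxent as mx
from parasdm import pca
from parasdm.geodata import ScenarioKey, Stack, thin_to_cells

out = ensure_out()
world = load_world()
transform = load_pca()
pc_stack = pca.project(world.stacks["current"][0], transform)

host_suit = Stack(pc_stack.spec)
host_fits = {}
for host in world.config.hosts:
    model = mx.MaxentModel.from_json(out / "models" / f"{host}.json")
    host_fits[host] = cc.SpeciesFit(host, ("", 0.0), model, None,
                                    mx.predict(model, pc_stack), [], 0, 0)
    host_suit.add(host, host_fits[host].suitability)
parasite_model = mx.MaxentModel.from_json(out / "models" / "parasite.json")
parasite_layer = mx.predict(parasite_model, host_suit)
run = cc.CascadeRun(ScenarioKey("current"), host_fits, host_suit,
                    cc.SpeciesFit("parasite", ("", 0.0), parasite_model, None,
                                  parasite_layer, [], 0, 0),
                    parasite_layer)

# regenerate the ExDet reference exactly as script 04 built it
fit_seed = json.loads((out / "parasite_fit_seed.json").read_text())["seed"]
thinned = thin_to_cells(world.occurrences["parasite"], host_suit.spec)
rng = np.random.default_rng(fit_seed)
X_bg, _ = mx.sample_background(host_suit, CASCADE.background_n, rng)
reference = np.vstack([mx.covariates_at(thinned, host_suit), X_bg])

exdet_rows, overlap_rows = [], []
runs = {"current": run}
for key_s, stacks in sorted(world.stacks.items()):
    if key_s != "current":
        runs[key_s] = cc.project_scenario(run, stacks, transform, ScenarioKey.parse(key_s))
# the %N pairwise neighbourhood test is the expensive part; run it for the
# current and end-of-century keys where transfer risk peaks
pctn_keys = {"current"} | {k for k in runs if k.endswith("2080-2100")}
for key_s, r in runs.items():
    result = dg.exdet(reference, r.host_suitability, host_suit.names)
    summary = dg.summarize_exdet(result)
    row = {
        "scenario": key_s,
        **{f"{name}_pct": v["percentage"] for name, v in summary["classes"].items()},
        "novel_subtotal_pct": summary["subtotal_novel"]["percentage"],
        "pct_nearby_mean": float("nan"),
    }
    if key_s in pctn_keys:
        pctn = dg.percent_nearby(reference, r.host_suitability, 1.0, host_suit.names)
        row["pct_nearby_mean"] = float(pctn.valid_values().mean())
    exdet_rows.append(row)
    for host in host_suit.names:
        score = dg.niche_overlap(r.host_suitability[host], r.parasite_suitability)
        overlap_rows.append({"scenario": key_s, "species": host,
                             "d": score.d, "i": score.i})

pd.DataFrame(exdet_rows).to_csv(out / "exdet_by_scenario.csv", index=False,
                                float_format="%.4f")
overlap = pd.DataFrame(overlap_rows)
overlap.to_csv(out / "niche_overlap.csv", index=False, float_format="%.5f")

# MIC table for the most distant future
far = dg.exdet(reference, runs["SSP585_2080-2100"].host_suitability, host_suit.names)
mic_summary = dg.summarize_exdet(far)["mic"]
mic_rows = [{"type": kind, "covariate": cov, **vals}
            for kind, covs in mic_summary.items() for cov, vals in covs.items()]
pd.DataFrame(mic_rows).to_csv(out / "mic_far_future.csv", index=False)

print("novel-environment share and mean %N per scenario:")
print(pd.DataFrame(exdet_rows)[["scenario", "novel_subtotal_pct", "pct_nearby_mean"]]
      .to_string(index=False))
print("\nmean niche similarity (I) per host:")
print(overlap.groupby("species")["i"].mean().round(3).to_string())
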