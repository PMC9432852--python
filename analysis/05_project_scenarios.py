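"""Transfer the frozen models to the 16 future scenario keys.

Per future key: ensemble the GCM variants by cellwise mean, project into the
frozen PC space, predict each host with its frozen model, then predict the
parasite from the host layers.  Nothing is refit.  Writes per-scenario
summary statistics of the parasite surface.
"""

import pandas as pd

from common import ensure_out, load_pca, load_world
from parasdm import cascade as cc
from parasdm import maxent as mx
from parasdm import pca
from parasdm.geodata import ScenarioKey, Stack

out = ensure_out()
world = load_world()
transform = load_pca()
pc_stack = pca.project(world.stacks["current"][0], transform)

host_suit = Stack(pc_stack.spec)
host_fits = {}
for host in world.config.hosts:
    model = mx.MaxentModel.from_json(out / "models" / f"{host}.json")
    host_fits[host] = cc.SpeciesFit(
        species=host, settings=("", 0.0), model=model, metrics=None,
        suitability=mx.predict(model, pc_stack), all_metrics=[], n_presences=0, seed=0)
    host_suit.add(host, host_fits[host].suitability)
parasite_model = mx.MaxentModel.from_json(out / "models" / "parasite.json")
parasite_layer = mx.predict(parasite_model, host_suit)
run = cc.CascadeRun(
    scenario=ScenarioKey("current"), host_fits=host_fits,
    host_suitability=host_suit,
    parasite_fit=cc.SpeciesFit("parasite", ("", 0.0), parasite_model, None,
                               parasite_layer, [], 0, 0),
    parasite_suitability=parasite_layer)

rows = [{"scenario": "current",
         "parasite_mean": float(parasite_layer.valid_values().mean()),
         "parasite_max": float(parasite_layer.valid_values().max())}]
for key_s, stacks in sorted(world.stacks.items()):
    if key_s == "current":
        continue
    fut = cc.project_scenario(run, stacks, transform, ScenarioKey.parse(key_s))
    v = fut.parasite_suitability.valid_values()
    rows.append({"scenario": key_s, "parasite_mean": float(v.mean()),
                 "parasite_max": float(v.max())})
table = pd.DataFrame(rows)
table.to_csv(out / "scenario_parasite_summary.csv", index=False, float_format="%.5f")
print(f"projected {len(rows) - 1} future keys; parasite mean suitability by scenario:")
print(table.to_string(index=False))
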