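"""Habitat levels and their change across climate scenarios.

Jenks natural breaks fitted on each species' current surface cut suitability
into ISH/LSH/MSH/HSH; the same breaks classify every future surface, and the
per-class area change ratios r = (A_future - A_current)/A_current are
tabulated with their extremes (MGR / MRR).
"""

import json

from common import ensure_out, load_pca, load_world
from parasdm import cascade as cc
from parasdm import habitat as hb
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
    host_fits[host] = cc.SpeciesFit(host, ("", 0.0), model, None,
                                    mx.predict(model, pc_stack), [], 0, 0)
    host_suit.add(host, host_fits[host].suitability)
parasite_model = mx.MaxentModel.from_json(out / "models" / "parasite.json")
parasite_layer = mx.predict(parasite_model, host_suit)
run = cc.CascadeRun(ScenarioKey("current"), host_fits, host_suit,
                    cc.SpeciesFit("parasite", ("", 0.0), parasite_model, None,
                                  parasite_layer, [], 0, 0),
                    parasite_layer)
futures = {key_s: cc.project_scenario(run, stacks, transform, ScenarioKey.parse(key_s))
           for key_s, stacks in sorted(world.stacks.items()) if key_s != "current"}

entries, breaks_doc = [], {}
for sp in world.config.hosts + ["parasite"]:
    cur_layer = parasite_layer if sp == "parasite" else host_suit[sp]
    breaks = hb.jenks_breaks(cur_layer.valid_values(), k=4, seed=world.config.seed)
    breaks_doc[sp] = [float(b) for b in breaks]
    cur_cls = hb.classify(cur_layer, breaks)
    for key_s, r in futures.items():
        fut_layer = r.parasite_suitability if sp == "parasite" else r.host_suitability[sp]
        entries.append((sp, key_s, hb.change_ratio(cur_cls, hb.classify(fut_layer, breaks))))

(out / "jenks_breaks.json").write_text(json.dumps(breaks_doc, indent=2))
trend = hb.trend_table(entries)
trend.to_csv(out / "trends.csv", index=False, float_format="%.4f")
ext = hb.trend_extremes(trend)
ext.to_csv(out / "trend_extremes.csv", index=False, float_format="%.4f")

print("habitat-class change extremes (MGR = max growth, MRR = max reduction):")
print(ext.to_string(index=False))
shrink = hb.shrinking_classes(trend[trend["species"] != "parasite"])
print("\nshrinking (species, class) pairs:", sorted(shrink))
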