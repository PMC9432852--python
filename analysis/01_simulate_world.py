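"""Generate the synthetic study system and record what it contains.

Five host plants respond to a shared latent environment (8 smooth fields
mixed into 30 collinear covariates); the parasite's true suitability depends
only on the host suitabilities, with weights (3, 3, 1, 0, 0).  Presences are
sampled proportionally to truth.  Everything downstream reruns from this
seed.
"""

import json

from common import WORLD_SEED, ensure_out, load_world
from parasdm.geodata import write_occurrences

out = ensure_out()
world = load_world()

occ_dir = out / "occurrences"
occ_dir.mkdir(exist_ok=True)
for species, occ in world.occurrences.items():
    write_occurrences(occ, occ_dir / f"{species}.csv")

summary = {
    "seed": WORLD_SEED,
    "grid": {"rows": world.spec.n_rows, "cols": world.spec.n_cols,
             "cell_size_deg": world.spec.cell_size},
    "covariates": len(world.covariate_names),
    "latent_fields": world.config.n_latent,
    "hosts": world.config.hosts,
    "parasite_weights": list(map(float, world.config.parasite_weights)),
    "presences_per_species": world.config.n_presence,
    "scenario_keys": sorted(world.stacks),
    "gcm_variants_per_future": world.config.n_gcm,
}
(out / "world_summary.json").write_text(json.dumps(summary, indent=2))
print(f"world: {world.spec.n_rows}x{world.spec.n_cols} cells, "
      f"{len(world.covariate_names)} covariates from {world.config.n_latent} latents, "
      f"{len(world.stacks)} scenario keys")
print(f"occurrences written for {len(world.occurrences)} species under {occ_dir}")
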