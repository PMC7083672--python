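"""Generate the synthetic study system and persist it.

Writes the environmental raster stack (ESRI ASCII), the true-suitability
surface of the virtual species, its sampled occurrences, and the zone
raster under results/world/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, study_config

import numpy as np
from chs_sdm.grids import write_raster
from chs_sdm.synthetic_world import generate_world


def main():
    cfg = study_config()
    stack, truth, occ, zones = generate_world(cfg.world, cfg.species,
                                              cfg.n_zones)
    out = RESULTS / "world"
    out.mkdir(parents=True, exist_ok=True)
    for name in stack.names:
        write_raster(stack[name], out / f"{name}.asc")
    write_raster(truth, out / "true_suitability.asc")
    write_raster(zones, out / "zones.asc")
    occ.to_frame().to_csv(out / "occurrences.csv", index=False)
    cfg.world.to_yaml(out / "world.yaml")

    tv = truth.masked()
    print(f"world: {stack.shape[0]}x{stack.shape[1]} cells, "
          f"{len(stack)} layers -> {out}")
    print(f"virtual species: {len(occ)} occurrences, "
          f"{100 * np.nanmean(tv > 0.5):.1f}% of cells above 0.5 true "
          f"suitability, mean truth at presences "
          f"{occ.true_suitability.mean():.2f}")


if __name__ == "__main__":
    main()
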