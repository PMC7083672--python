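"""Comprehensive habitat suitability maps, areas, transitions and curves.

Gates the ensemble with the soil-suitability model and the vegetation mask,
classifies the three habitat classes for the three periods, and writes the
zonal area tables, class-transition matrices, response curves and variable
importances.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CACHE, RESULTS, study_config

from chs_sdm.grids import write_raster
from chs_sdm.pipeline import run_pipeline, suitable_area_km2
from chs_sdm.reporting import response_curve


def main():
    res = run_pipeline(study_config(), cache_dir=CACHE)
    out = RESULTS / "habitat"
    out.mkdir(parents=True, exist_ok=True)

    res.soil_model.to_json(out / "soil_model.json")
    write_raster(res.soil_suitability, out / "soil_suitability.asc")
    write_raster(res.veg_mask, out / "vegetation_mask.asc")
    for period, m in res.chs.items():
        write_raster(m, out / f"CHS_{period}.asc")
        res.area_tables[period].round(2).to_csv(
            out / f"areas_{period}.csv", index=False)
    for name, t in res.transitions.items():
        t.round(2).to_csv(out / f"transition_{name}.csv")
    res.importance.rename("importance").round(4).to_csv(
        out / "variable_importance.csv")
    for var in ("bio1", "bio4", "bio10", "bio11", "bio12", "bio15"):
        rc = response_curve(res.predictor, res.stack, var)
        rc.to_frame().to_csv(out / f"response_{var}.csv", index=False)

    print(f"soil model mean AUC {res.soil_model.mean_auc:.3f}; "
          f"vegetation gate keeps "
          f"{int(res.veg_mask.values[res.veg_mask.valid_mask()].sum())} cells")
    for period in ("current", "2050s", "2070s"):
        s = suitable_area_km2(res, period) / 1e3
        m = suitable_area_km2(res, period, "marginally suitable") / 1e3
        print(f"  {period:8s} suitable {s:7.2f} x10^3 km^2, "
              f"marginal {m:7.2f} x10^3 km^2")
    imp = res.importance
    print(f"importance: temperature "
          f"{imp[['bio1', 'bio4', 'bio10', 'bio11']].sum():.3f} vs "
          f"precipitation {imp[['bio12', 'bio15', 'bio19']].sum():.3f}")


if __name__ == "__main__":
    main()
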