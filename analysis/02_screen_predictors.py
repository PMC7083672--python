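"""Collinearity screen of the candidate predictors.

Runs the PCA-guided Pearson screen (|r| >= 0.8) on a landscape sample of
the continuous layers and writes the keep/drop report; the downstream
analysis nevertheless uses the nine-variable reference preset, so this
step documents what a purely data-driven screen would do on this world.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, study_config

import numpy as np
from chs_sdm.evaluation import derive_seed
from chs_sdm.selection import REFERENCE_VARIABLES, pearson_matrix, \
    select_variables
from chs_sdm.synthetic_world import generate_world


def main():
    cfg = study_config()
    stack, *_ = generate_world(cfg.world, cfg.species, cfg.n_zones)
    candidates = [n for n in stack.names if n not in ("soil", "vegetation")]
    table = stack.table(candidates)
    rng = np.random.default_rng(derive_seed(cfg.seed, "screen"))
    table = table.iloc[rng.choice(len(table), 2000, replace=False)]

    keep, report = select_variables(table, r_threshold=cfg.r_threshold)
    out = RESULTS / "selection"
    out.mkdir(parents=True, exist_ok=True)
    report.to_csv(out / "screen_report.csv", index=False)
    pearson_matrix(table.drop(columns=["aspect"])).round(3).to_csv(
        out / "pearson_matrix.csv")

    print(f"data-driven screen keeps {len(keep)}/{len(candidates)}: {keep}")
    dropped = report[~report.kept]
    for _, row in dropped.iterrows():
        print(f"  dropped {row.variable}: {row.reason}")
    print(f"analysis uses the reference preset: {list(REFERENCE_VARIABLES)}")


if __name__ == "__main__":
    main()
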