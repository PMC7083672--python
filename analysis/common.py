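"""Shared configuration for the numbered analysis drivers.

All drivers use one frozen study configuration (100x100 synthetic world,
200-presence virtual species, full 3 x 10 x 10 protocol, 2 x 4 x 3 scenario
grid, seed 1) and share a stage cache under results/cache so the expensive
model-fitting stage is computed once.
"""

from pathlib import Path

from chs_sdm.pipeline import PipelineConfig
from chs_sdm.synthetic_world import VirtualSpeciesSpec, WorldSpec

RESULTS = Path(__file__).resolve().parent.parent / "results"
CACHE = RESULTS / "cache"
SEED = 1


def study_config() -> PipelineConfig:
    return PipelineConfig(
        world=WorldSpec(seed=SEED),
        species=VirtualSpeciesSpec(n_presences=200),
        seed=SEED,
    )
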