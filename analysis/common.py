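"""Shared configuration for the numbered analysis scripts.

All scripts derive their inputs from one deterministic demonstration
config (seed 1), so each can be re-run independently and reproduce the
same files under results/.
"""

from pathlib import Path

from kinomevo import pipeline

RESULTS = Path(__file__).resolve().parent.parent / "results"
SIM_DIR = RESULTS / "sim"
SIM_B_DIR = RESULTS / "sim_b"

SEED = 1


def demo_config() -> pipeline.PipelineConfig:
    cfg = pipeline.default_config(seed=SEED, outdir=str(RESULTS))
    return cfg
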