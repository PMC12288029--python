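"""Shared paths and run configuration for the analysis drivers."""

from pathlib import Path

from preyflow.pipeline import RunConfig

RESULTS = Path(__file__).resolve().parents[1] / "results"
RUN_DIR = RESULTS / "run"
MASTER_SEED = 1


def run_config() -> RunConfig:
    return RunConfig(out_dir=str(RUN_DIR), tier="series", master_seed=MASTER_SEED)
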