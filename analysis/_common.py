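"""Shared run configuration for the numbered analysis drivers.

All drivers operate on the same simulated five-condition study under
``results/run``; each script executes its stage (re-using upstream outputs
via the manifest) and reports what it found.
"""

from pathlib import Path

from herbscreen.pipeline import RunConfig

RESULTS = Path(__file__).resolve().parents[1] / "results"
RUN_DIR = RESULTS / "run"
SEED = 1


def run_config() -> RunConfig:
    return RunConfig.model_validate({
        "outdir": str(RUN_DIR),
        "seed": SEED,
        "simulate": {},          # default synthetic study design
        "params": {"n_random": 500},
    })
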