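"""Shared driver state: run pipeline stages once per invocation chain.

Each numbered analysis script calls :func:`stages_up_to` with the last stage
it needs; the default seed and configuration match the study conditions.
"""

from __future__ import annotations

from pathlib import Path

from hepatoseq.pipeline import STAGES, PipelineConfig, PipelineResult

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def stages_up_to(last: str, seed: int = SEED) -> tuple[PipelineConfig, PipelineResult]:
    cfg = PipelineConfig(seed=seed)
    res = PipelineResult()
    for name, fn in STAGES.items():
        res = fn(cfg, res)
        if name == last:
            break
    RESULTS.mkdir(parents=True, exist_ok=True)
    return cfg, res
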