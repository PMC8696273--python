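"""Shared plumbing for the numbered analysis drivers."""

import argparse
from pathlib import Path

from genefc.pipeline import PipelineConfig


def parse(description: str) -> PipelineConfig:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--outdir", type=Path, default=Path("results/benchmark"))
    args = parser.parse_args()
    return PipelineConfig(outdir=str(args.outdir), seed=args.seed)
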